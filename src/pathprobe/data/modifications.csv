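name,formula,category,subcategory
methylation,CH2,generic,none
methoxylation,CH2O,generic,none
hydroxylation,H2O,generic,none
methyl ammonia,CH3NH2,generic,none
acetylation,CH2CO,generic,none
carboxylation,COO,generic,none
sulfation,SO3,generic,none
malonyl,C3H2O3,generic,none
pentosylation,C5H8O4,generic,none
deoxyhexosylation,C6H10O4,generic,none
hexosylation,C6H10O5,generic,none
putrescine,C4H12N2,specific,amine-conjugation
cadaverine,C5H14N2,specific,amine-conjugation
agmatine,C5H14N4,specific,amine-conjugation
tyramine,C8H11NO,specific,amine-conjugation
spermidine,C7H19N3,specific,amine-conjugation
octopamine/dopamine,C8H11NO2,specific,amine-conjugation
tryptamine,C10H12N2,specific,amine-conjugation
3-methoxytyramine,C9H13NO2,specific,amine-conjugation
noradrenaline,C8H11NO3,specific,amine-conjugation
serotonin,C10H12N2O,specific,amine-conjugation
3'-methoxyoctopamine,C9H13NO3,specific,amine-conjugation
5-methoxytryptamine,C11H14N2O,specific,amine-conjugation
spermine,C10H26N4,specific,amine-conjugation
coumaroyl,C9H6O2,specific,hydroxycinnamoyl-conjugation
caffeoyl,C9H6O3,specific,hydroxycinnamoyl-conjugation
feruloyl,C10H8O3,specific,hydroxycinnamoyl-conjugation
5-OH-feruloyl,C10H8O4,specific,hydroxycinnamoyl-conjugation
sinapyl,C11H10O4,specific,hydroxycinnamoyl-conjugation
malate,C4H4O4,specific,acid-conjugation
glyceric acid coupling,C3H4O3,specific,acid-conjugation
phenylacetyl coupling,C8H6O,specific,acid-conjugation
hydroxybenzoate,C7H4O2,specific,acid-conjugation
p-hydroxybenzoylation,C7H6O2,specific,acid-conjugation
tartarate,C4H4O5,specific,acid-conjugation
dihydroxybenzoic acid coupling,C7H4O3,specific,acid-conjugation
hydroxyadipic acid coupling,C6H8O4,specific,acid-conjugation
vanillate,C8H6O3,specific,acid-conjugation
3-dehydroshikimic acid coupling,C7H6O4,specific,acid-conjugation
shikimic acid coupling,C7H8O4,specific,acid-conjugation
quinic acid coupling,C7H10O5,specific,acid-conjugation
syringate,C9H8O4,specific,acid-conjugation
glycerol,C3H6O2,specific,alcohol-conjugation
quinol,C6H4O,specific,alcohol-conjugation
hydroxybenzyl alcohol,C7H6O,specific,alcohol-conjugation
hydroxyquinol,C6H4O2,specific,alcohol-conjugation
vanillyl alcohol,C8H8O2,specific,alcohol-conjugation
coumaryl alcohol,C9H8O,specific,alcohol-conjugation
caffeyl alcohol,C9H8O2,specific,alcohol-conjugation
coniferyl alcohol,C10H10O2,specific,alcohol-conjugation
5-OH-feruloyl alcohol,C10H10O3,specific,alcohol-conjugation
sinapyl alcohol,C11H12O3,specific,alcohol-conjugation
non-condensed vanillyl alcohol,C8H10O3,specific,alcohol-conjugation
non-condensed coumaryl alcohol,C9H10O2,specific,alcohol-conjugation
non-condensed caffeyl alcohol,C9H10O3,specific,alcohol-conjugation
non-condensed coniferyl alcohol,C10H12O3,specific,alcohol-conjugation
non-condensed 5-OH-feruloyl alcohol,C10H12O4,specific,alcohol-conjugation
non-condensed sinapyl alcohol,C11H14O4,specific,alcohol-conjugation
dimethoxyquinol,C8H8O3,specific,alcohol-conjugation
syringyl alcohol,C9H10O3,specific,alcohol-conjugation
isoprenylation,C5H8,specific,isoprenylation
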