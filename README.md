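# pathprobe

Screening and annotation of target-pathway metabolites from untargeted
LC-HRMS/MS data, built around three ideas:

1. **Modified-metabolome screening** — a registry of 61 phenylpropanoid
   modification reactions (11 generic, 50 pathway-specific) is matched as
   neutral losses against MS/MS fragment ions, pulling out features that
   carry known modification moieties.
2. **Probe-based molecular networking** — reference spectra of pathway
   compounds ("probes") are co-networked with the modified metabolome using
   the modified cosine score under GNPS-style topology constraints
   (similarity ≥ 0.7, ≥ 6 matched fragments, top-50 neighbours, components
   capped at 500 nodes). Clusters containing a probe plus a modified
   metabolite — or a pathway-specific modification — are flagged as pathway
   clusters.
3. **Propagation / de-novo annotation** — probe identities propagate along
   edges by interpreting precursor mass differences as modification
   gains/losses; seedless clusters are annotated de novo from fragment-level
   substructure evidence (neutral losses, ±2H-adjusted losses, characteristic
   ions) and a small composition search.

A spectral-entropy similarity is included for re-scoring, and a synthetic
data generator (`pathprobe.synth`) produces probe libraries, modified
derivatives and noise with exact ground truth so the whole pipeline is
testable offline.

## Command line

```sh
# make a synthetic dataset with ground truth
pathprobe simulate --n-probes 20 --n-derived 50 --noise 0.1 --seed 7 --out-dir sim/

# stage by stage
pathprobe screen   --features sim/features.csv --msms sim/msms.mgf --out modified.tsv
pathprobe network  --msms sim/msms.mgf --probes sim/probes.mgf --out net.graphml
pathprobe annotate --msms sim/msms.mgf --probes sim/probes.mgf --out annotations.tsv

# or end to end from a YAML config
pathprobe run --config run.yaml
```

`run.yaml` mirrors the CLI flags (`features`, `msms`, `probes`, `out_dir`,
plus tolerances; defaults are the published operating points: 15 ppm mass
accuracy, 12 s RT window, minimum fragment intensity 100, similarity 0.7,
≥ 6 matched fragments, 0.01 Da precursor / 0.02 Da fragment tolerance).
The run directory contains `modified.tsv`, `net.graphml`, `edges.tsv`,
`clusters.tsv`, `annotations.tsv` and a deterministic `summary.json`.

## Layout

- `src/pathprobe/chem.py` — formula parsing, monoisotopic masses, the
  modification registry (`data/modifications.csv`), mass-delta matching with
  optional ±2H adjustment
- `src/pathprobe/msio.py` — MGF read/write, MSP read, feature tables, probe
  library construction by chemical-class filtering
- `src/pathprobe/screen.py` — feature↔MS/MS matching, neutral-loss
  detection, ion fusion, screening summary
- `src/pathprobe/network.py` — modified cosine (optimal assignment),
  spectral entropy similarity, network construction, pathway-cluster filter
- `src/pathprobe/annotate.py` — library match, propagation, fragment-level
  substructure annotation, de-novo composition search, exports
- `src/pathprobe/synth.py` — synthetic probes/derivatives/noise with ground
  truth
- `src/pathprobe/pipeline.py`, `cli.py` — orchestration and the `pathprobe`
  entry point
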