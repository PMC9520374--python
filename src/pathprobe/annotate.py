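"""Seed assignment, network-propagation annotation and de-novo annotation.

Annotation transfers probe identities across network edges by interpreting
the edge precursor mass difference as a modification gain/loss, annotates
fragment ions with substructure evidence (neutral losses and characteristic
ions), and falls back to de-novo composition search for seedless clusters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chem import ModificationRegistry, ModificationType, match_mass_delta
from .msio import MsmsSpectrum
from .network import MolecularNetwork, PathwayCluster, SimilarityFn, modified_cosine
from .msio import ProbeLibrary, ProbeRecord
from .screen import detect_modifications

__all__ = [
    "CharacteristicIon",
    "load_characteristic_ions",
    "FragmentAssignment",
    "AnnotationEvidence",
    "library_match",
    "propagate",
    "annotate_fragments",
    "de_novo_annotate",
    "export_annotations",
]


@dataclass(frozen=True)
class CharacteristicIon:
    """A diagnostic fragment m/z indicating a specific substructure."""

    name: str
    mz: float
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.name}: non-positive m/z")


def load_characteristic_ions(path: str | Path | None = None) -> list[CharacteristicIon]:
    """Load a characteristic-ion CSV (``name,mz,polarity``); default packaged table."""
    if path is None:
        ref = resources.files("pathprobe").joinpath("data/characteristic_ions.csv")
        with resources.as_file(ref) as p:
            return load_characteristic_ions(p)
    ions: list[CharacteristicIon] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ions.append(
                CharacteristicIon(
                    name=row["name"].strip(),
                    mz=float(row["mz"]),
                    polarity=row.get("polarity", "negative").strip(),
                )
            )
    return ions


@dataclass(frozen=True)
class FragmentAssignment:
    """Substructure evidence for one fragment ion or ion pair."""

    kind: str  # "neutral-loss" | "characteristic-ion"
    ion_pair: tuple[float, ...]  # (larger, smaller) for losses, (mz,) for ions
    assigned_name: str
    reference_mass: float  # registry mass or characteristic-ion m/z (unadjusted)
    observed_delta: float
    ppm_error: float
    adjustment: str = ""
    modification: ModificationType | None = None
    ion: CharacteristicIon | None = None

    @property
    def component_mass(self) -> float:
        """Mass this piece contributes in a composition sum (with adjustment)."""
        if self.modification is not None:
            base = self.modification.mass
            if self.adjustment == "-2H":
                base -= 2 * 1.00782503207
            elif self.adjustment == "+2H":
                base += 2 * 1.00782503207
            return base
        return self.reference_mass


@dataclass
class AnnotationEvidence:
    node_id: str
    status: str  # "library-hit" | "propagated" | "de-novo" | "unannotated"
    seed_id: str | None = None
    seed_name: str | None = None
    modification_chain: tuple[tuple[ModificationType, str], ...] = ()
    fragment_assignments: tuple[FragmentAssignment, ...] = ()
    propagation_depth: int = 0
    composition: tuple[str, ...] | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.status == "propagated" and (self.seed_id is None or self.propagation_depth < 1):
            raise ValueError(f"{self.node_id}: propagated evidence needs seed and depth >= 1")

    @property
    def chain_mass(self) -> float:
        """Signed sum of the modification chain (gain positive)."""
        total = 0.0
        for mod, direction in self.modification_chain:
            total += mod.mass if direction == "gain" else -mod.mass
        return total

    def chain_str(self) -> str:
        return ";".join(
            ("+" if d == "gain" else "-") + m.name for m, d in self.modification_chain
        )


def library_match(
    spectrum: MsmsSpectrum,
    probes: ProbeLibrary,
    sim_fn: SimilarityFn | None = None,
    threshold: float = 0.7,
    precursor_tol_ppm: float = 15.0,
) -> list[tuple[ProbeRecord, float]]:
    """Dereplicate a spectrum against the probe library.

    Only records with matching polarity and a precursor within
    ``precursor_tol_ppm`` are scored; hits at or above ``threshold`` are
    returned sorted by descending similarity.
    """
    if sim_fn is None:
        sim_fn = modified_cosine
    out: list[tuple[ProbeRecord, float]] = []
    for record in probes:
        ref = record.spectrum
        if ref.polarity != spectrum.polarity:
            continue
        if abs(ref.precursor_mz - spectrum.precursor_mz) > precursor_tol_ppm * 1e-6 * spectrum.precursor_mz:
            continue
        sim, _ = sim_fn(spectrum, ref)
        if sim >= threshold:
            out.append((record, sim))
    out.sort(key=lambda rs: (-rs[1], rs[0].spectrum.id))
    return out


def propagate(
    network: MolecularNetwork,
    seeds: Mapping[str, str],
    registry: ModificationRegistry,
    tol_ppm: float = 15.0,
    max_depth: int = 3,
    corroborate: bool = True,
) -> list[AnnotationEvidence]:
    """Breadth-first annotation transfer from seed nodes.

    For each edge from an annotated node the precursor mass difference is
    matched against the registry; a match extends the chain by one gain/loss
    step. Nodes reachable from several annotated nodes keep the candidate
    with (shallower depth, higher edge similarity, lexicographic parent).
    When ``corroborate``, a matching neutral loss found in the node's own
    MS/MS is recorded in the notes (never required). Returns evidence for
    every node in a seed-containing component.
    """
    unknown = set(seeds) - set(network.nodes)
    if unknown:
        raise ValueError(f"seeds not in network: {sorted(unknown)}")
    adjacency: dict[str, list] = {nid: [] for nid in network.nodes}
    for e in network.edges:
        adjacency[e.node_a].append((e.node_b, e))
        adjacency[e.node_b].append((e.node_a, e))

    evidence: dict[str, AnnotationEvidence] = {}
    for nid in sorted(seeds):
        evidence[nid] = AnnotationEvidence(
            node_id=nid, status="library-hit", seed_id=nid, seed_name=seeds[nid]
        )
    frontier = sorted(seeds)
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        candidates: dict[str, list[tuple[float, str, AnnotationEvidence]]] = {}
        for uid in frontier:
            parent = evidence[uid]
            for vid, edge in sorted(adjacency[uid], key=lambda ve: ve[0]):
                if vid in evidence:
                    continue
                u_spec = network.nodes[uid].spectrum
                v_spec = network.nodes[vid].spectrum
                delta = v_spec.precursor_mz - u_spec.precursor_mz
                if abs(delta) <= 0:
                    continue
                matches = match_mass_delta(abs(delta), registry, tol_ppm)
                if not matches:
                    continue
                best = matches[0]
                direction = "gain" if delta > 0 else "loss"
                notes = []
                if len(matches) > 1:
                    alts = ",".join(m.modification.name for m in matches[1:])
                    notes.append(f"alternatives:{alts}")
                if corroborate:
                    own = detect_modifications(v_spec, registry, tol_ppm)
                    if any(h.modification.name == best.modification.name for h in own):
                        notes.append(f"corroborated:{best.modification.name}")
                cand = AnnotationEvidence(
                    node_id=vid,
                    status="propagated",
                    seed_id=parent.seed_id,
                    seed_name=parent.seed_name,
                    modification_chain=parent.modification_chain
                    + ((best.modification, direction),),
                    propagation_depth=depth,
                    notes=";".join(notes),
                )
                candidates.setdefault(vid, []).append((edge.similarity, uid, cand))
        newly: list[str] = []
        for vid in sorted(candidates):
            ranked = sorted(candidates[vid], key=lambda c: (-c[0], c[1]))
            evidence[vid] = ranked[0][2]
            newly.append(vid)
        frontier = newly

    # mark remaining nodes of seed-containing components as unannotated
    seeded_components = [c for c in network.components if c & set(seeds)]
    for comp in seeded_components:
        for nid in sorted(comp):
            if nid not in evidence:
                evidence[nid] = AnnotationEvidence(node_id=nid, status="unannotated")
    return [evidence[nid] for nid in sorted(evidence)]


def annotate_fragments(
    spectrum: MsmsSpectrum,
    registry: ModificationRegistry,
    characteristic_ions: Sequence[CharacteristicIon] = (),
    tol_ppm: float = 15.0,
    allow_h2_adjustment: bool = True,
) -> list[FragmentAssignment]:
    """Substructure-annotate fragment ions of one spectrum.

    Tests precursor-fragment and fragment-fragment mass differences against
    the registry (with optional +-2H adjustment) and fragments directly
    against the characteristic-ion table. All explanations are reported.
    """
    if len(spectrum) == 0:
        raise ValueError("annotate_fragments requires a non-empty spectrum")
    assignments: list[FragmentAssignment] = []
    mzs = [p.mz for p in spectrum.peaks]

    def add_loss(hi: float, lo: float) -> None:
        delta = hi - lo
        if delta <= 0:
            return
        for m in match_mass_delta(delta, registry, tol_ppm, allow_h2_adjustment):
            assignments.append(
                FragmentAssignment(
                    kind="neutral-loss",
                    ion_pair=(hi, lo),
                    assigned_name=m.modification.name,
                    reference_mass=m.modification.mass,
                    observed_delta=delta,
                    ppm_error=m.ppm_error,
                    adjustment=m.adjustment,
                    modification=m.modification,
                )
            )

    for mz in mzs:
        add_loss(spectrum.precursor_mz, mz)
    for i, hi in enumerate(mzs):
        for lo in mzs[:i]:
            add_loss(hi, lo)
    for ion in characteristic_ions:
        if ion.polarity != spectrum.polarity:
            continue
        for mz in mzs:
            ppm = 1e6 * (mz - ion.mz) / ion.mz
            if abs(ppm) <= tol_ppm:
                assignments.append(
                    FragmentAssignment(
                        kind="characteristic-ion",
                        ion_pair=(mz,),
                        assigned_name=ion.name,
                        reference_mass=ion.mz,
                        observed_delta=mz,
                        ppm_error=ppm,
                        ion=ion,
                    )
                )
    assignments.sort(key=lambda a: (a.ion_pair, abs(a.ppm_error), a.assigned_name))
    return assignments


def _composition_search(
    precursor_mz: float,
    assignments: Sequence[FragmentAssignment],
    tol_ppm: float,
    max_parts: int = 3,
) -> tuple[str, ...] | None:
    """Find <= max_parts assigned substructures whose masses sum to the precursor."""
    unique: dict[tuple[str, str], float] = {}
    for a in assignments:
        label = a.assigned_name + (f" {a.adjustment}" if a.adjustment else "")
        unique[(label, a.adjustment)] = a.component_mass
    items = sorted(unique.items())
    best: tuple[float, int, tuple[str, ...]] | None = None
    tol = tol_ppm * 1e-6 * precursor_mz
    for k in range(1, max_parts + 1):
        for combo in combinations_with_replacement(items, k):
            total = sum(mass for (_, mass) in combo)
            err = abs(total - precursor_mz)
            if err > tol:
                continue
            # ties (equal-mass explanations) prefer unadjusted assignments
            n_adjusted = sum(1 for ((_, adj), _) in combo if adj)
            labels = tuple(label for ((label, _), _) in combo)
            key = (err, n_adjusted, labels)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def de_novo_annotate(
    cluster: PathwayCluster,
    spectra: Mapping[str, MsmsSpectrum],
    registry: ModificationRegistry,
    characteristic_ions: Sequence[CharacteristicIon] = (),
    tol_ppm: float = 15.0,
) -> list[AnnotationEvidence]:
    """Annotate a seedless specific-modification cluster from fragments alone.

    Every member with a spectrum gets de-novo evidence carrying its fragment
    assignments and, when a combination of at most three assigned
    substructure masses accounts for the precursor within tolerance, a
    composition summary.
    """
    out: list[AnnotationEvidence] = []
    for nid in sorted(cluster.members):
        spectrum = spectra.get(nid)
        if spectrum is None:
            continue
        assignments = tuple(
            annotate_fragments(spectrum, registry, characteristic_ions, tol_ppm)
        )
        composition = (
            _composition_search(spectrum.precursor_mz, assignments, tol_ppm)
            if assignments
            else None
        )
        out.append(
            AnnotationEvidence(
                node_id=nid,
                status="de-novo",
                fragment_assignments=assignments,
                composition=composition,
            )
        )
    return out


def export_annotations(
    evidence: Iterable[AnnotationEvidence],
    network: MolecularNetwork | None,
    tsv_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Write annotation evidence to TSV and optionally an annotated GraphML."""
    rows = sorted(evidence, key=lambda e: e.node_id)
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write(
            "node_id\tstatus\tseed_id\tseed_name\tdepth\tchain\t"
            "n_assignments\tassignments\tcomposition\tnotes\n"
        )
        for ev in rows:
            assignments = ";".join(
                f"{a.kind}:{a.assigned_name}{('(' + a.adjustment + ')') if a.adjustment else ''}"
                f":{a.ppm_error:.2f}ppm"
                for a in ev.fragment_assignments
            )
            composition = "+".join(ev.composition) if ev.composition else ""
            fh.write(
                f"{ev.node_id}\t{ev.status}\t{ev.seed_id or ''}\t{ev.seed_name or ''}\t"
                f"{ev.propagation_depth}\t{ev.chain_str()}\t"
                f"{len(ev.fragment_assignments)}\t{assignments}\t{composition}\t{ev.notes}\n"
            )
    if graphml_path is not None and network is not None:
        g = network.graph()
        for ev in rows:
            if ev.node_id in g:
                g.nodes[ev.node_id]["annotation_status"] = ev.status
                g.nodes[ev.node_id]["annotation_seed"] = ev.seed_name or ""
                g.nodes[ev.node_id]["annotation_chain"] = ev.chain_str()
        import networkx as nx

        nx.write_graphml(g, str(graphml_path))
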