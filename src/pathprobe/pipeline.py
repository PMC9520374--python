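"""End-to-end orchestration: screen -> network -> cluster filter -> annotate.

A run directory collects one artifact per stage (modified.tsv, net.graphml,
edges.tsv, clusters.tsv, annotations.tsv, summary.json) and the summary is a
deterministic function of the inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import msio, network, screen
from .chem import load_modification_registry

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("pathprobe")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published operating points."""

    features: str = ""
    msms: str = ""
    probes: str = ""
    registry: str | None = None
    characteristic_ions: str | None = None
    out_dir: str = "pathprobe-run"
    polarity: str = "positive"
    rt_unit: str = "s"

    tol_ppm: float = 15.0
    rt_window_s: float = 12.0
    min_fragment_intensity: float = 100.0
    similarity_threshold: float = 0.7
    min_matched_peaks: int = 6
    precursor_merge_tol_da: float = 0.01
    fragment_tol_da: float = 0.02
    max_neighbors: int = 50
    max_component: int = 500
    max_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tol_ppm",
            "rt_window_s",
            "min_fragment_intensity",
            "similarity_threshold",
            "precursor_merge_tol_da",
            "fragment_tol_da",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        for name in ("min_matched_peaks", "max_neighbors", "max_component", "max_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written to summary.json)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = load_modification_registry(config.registry)
    ions = ann.load_characteristic_ions(config.characteristic_ions)

    t0 = time.perf_counter()
    features = msio.read_feature_table(config.features, rt_unit=config.rt_unit)
    spectra = [s for s in msio.read_mgf(config.msms) if s.polarity == config.polarity]
    probe_spectra = [
        s for s in msio.read_mgf(config.probes) if s.polarity == config.polarity
    ]
    log.info("inputs: %d features, %d MS/MS, %d probes", len(features), len(spectra), len(probe_spectra))

    # stage 1: modified-metabolome screening
    params = screen.ScreenParams(
        tol_ppm=config.tol_ppm,
        rt_window_s=config.rt_window_s,
        min_fragment_intensity=config.min_fragment_intensity,
        fuse_tol_ppm=config.tol_ppm,
        fuse_rt_window_s=config.rt_window_s,
    )
    modified, screen_summary = screen.screen_modified_metabolome(
        features, spectra, registry, params
    )
    _write_modified_tsv(modified, out_dir / "modified.tsv")
    log.info("screen: %d modified metabolites (%.1fs)", len(modified), time.perf_counter() - t0)

    # stage 2: molecular network over probes + modified metabolome
    nodes = [
        network.NetworkNode(id=m.spectrum.id, kind="experimental", spectrum=m.spectrum, hits=m.hits)
        for m in modified
    ]
    nodes += [
        network.NetworkNode(id=s.id, kind="probe", spectrum=s) for s in probe_spectra
    ]

    def sim_fn(a, b):
        return network.modified_cosine(a, b, fragment_tol_da=config.fragment_tol_da)

    net = network.build_network(
        nodes,
        sim_fn=sim_fn,
        threshold=config.similarity_threshold,
        min_matched=config.min_matched_peaks,
        precursor_merge_tol_da=config.precursor_merge_tol_da,
        max_neighbors=config.max_neighbors,
        max_component=config.max_component,
    )
    net.to_graphml(out_dir / "net.graphml")
    net.write_edge_table(out_dir / "edges.tsv")
    log.info("network: %d nodes, %d edges", len(net.nodes), len(net.edges))

    # stage 3: pathway-cluster filter
    modified_ids = {m.spectrum.id for m in modified}
    clusters = network.filter_pathway_clusters(net, modified_ids, registry)
    _write_clusters_tsv(clusters, out_dir / "clusters.tsv")
    candidate_ids = sorted(
        nid
        for c in clusters
        for nid in c.members
        if net.nodes[nid].kind == "experimental"
    )
    log.info("filter: %d clusters, %d candidate metabolites", len(clusters), len(candidate_ids))

    # stage 4: annotation (propagation from probe seeds, de-novo for seedless)
    seeds = {
        nid: nid for nid in net.nodes if net.nodes[nid].kind == "probe"
    }
    cluster_members = {nid for c in clusters for nid in c.members}
    evidence = {}
    if seeds:
        for ev in ann.propagate(
            net, seeds, registry, tol_ppm=config.tol_ppm, max_depth=config.max_depth
        ):
            if ev.node_id in cluster_members:
                evidence[ev.node_id] = ev
    spectra_by_id = {nid: net.nodes[nid].spectrum for nid in net.nodes}
    for cluster in clusters:
        if cluster.probe_members or any(
            evidence.get(nid) is not None and evidence[nid].status != "unannotated"
            for nid in cluster.members
        ):
            continue
        for ev in ann.de_novo_annotate(
            cluster, spectra_by_id, registry, ions, tol_ppm=config.tol_ppm
        ):
            evidence[ev.node_id] = ev
    for nid in candidate_ids:
        evidence.setdefault(nid, ann.AnnotationEvidence(node_id=nid, status="unannotated"))
    evidence_list = [evidence[nid] for nid in sorted(evidence)]
    ann.export_annotations(
        evidence_list, net, out_dir / "annotations.tsv", out_dir / "net_annotated.graphml"
    )

    candidate_set = set(candidate_ids)
    status_counts: dict[str, int] = {}
    for ev in evidence_list:
        if ev.node_id in candidate_set:
            status_counts[ev.status] = status_counts.get(ev.status, 0) + 1

    summary = {
        "n_features": screen_summary.n_features,
        "n_spectra": screen_summary.n_spectra,
        "n_matched": screen_summary.n_matched,
        "n_modified_metabolites": screen_summary.n_fused,
        "n_modification_types": screen_summary.n_modification_types,
        "multi_modification_fraction": round(
            screen_summary.multi_modification_fraction, 6
        ),
        "counts_per_modification": screen_summary.counts_per_modification,
        "n_network_nodes": len(net.nodes),
        "n_network_edges": len(net.edges),
        "n_components": len(net.components),
        "n_pathway_clusters": len(clusters),
        "n_candidates": len(candidate_ids),
        "annotations_by_status": dict(sorted(status_counts.items())),
        "config": dataclasses.asdict(PipelineConfig(**dataclasses.asdict(config))),
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _write_modified_tsv(modified, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "feature_id\tspectrum_id\tmz\trt\tintensity\tmodification\tcategory\t"
            "subcategory\tdelta_kind\tobserved_delta\tppm_error\tfragment_mz\tfragment_intensity\n"
        )
        for m in sorted(modified, key=lambda m: m.feature.id):
            for h in m.hits:
                fh.write(
                    f"{m.feature.id}\t{m.spectrum.id}\t{m.feature.mz:.6f}\t{m.feature.rt:.2f}\t"
                    f"{m.feature.intensity:.1f}\t{h.modification.name}\t{h.modification.category}\t"
                    f"{h.modification.subcategory}\t{h.delta_kind}\t{h.observed_delta:.6f}\t"
                    f"{h.ppm_error:.2f}\t{h.ion_pair[1]:.6f}\t{h.fragment_intensity:.1f}\n"
                )


def _write_clusters_tsv(clusters, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("component_id\tqualification\tn_members\tprobes\tspecific_modifications\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.component_id}\t{c.qualification}\t{len(c.members)}\t"
                f"{';'.join(sorted(c.probe_members))}\t"
                f"{';'.join(sorted(c.specific_modifications))}\t"
                f"{';'.join(sorted(c.members))}\n"
            )
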