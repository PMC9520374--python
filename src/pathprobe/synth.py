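"""Synthetic probe libraries and modified-metabolome datasets with ground truth.

Every pipeline stage is testable offline: probes are random reference
spectra; derivatives shift a parent's fragments by registry modification
masses and carry exact planted neutral-loss peaks; noise is applied as a
separate, reproducible perturbation so zero-noise datasets support exact
recall assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import ModificationRegistry
from .msio import Feature, MsmsSpectrum, Peak, ProbeLibrary, ProbeRecord

__all__ = [
    "PHENYLPROPANOID_CLASSES",
    "NodeTruth",
    "GroundTruth",
    "generate_probes",
    "derive_modified",
    "add_noise",
]

PHENYLPROPANOID_CLASSES = (
    "flavonoids",
    "isoflavonoids",
    "coumarins and derivatives",
    "cinnamic acids and derivatives",
    "lignans, neolignans and related compounds",
    "stilbenes",
)

_ANCHOR_EPS = 1e-9


@dataclass(frozen=True)
class NodeTruth:
    """Ground truth for one generated experimental node."""

    node_id: str
    parent_id: str
    probe_id: str
    chain: tuple[str, ...]
    planted_losses: tuple[str, ...]
    precursor_mz: float
    rt: float
    is_intermediate: bool = False
    is_decoy: bool = False
    noise_peak_mz: tuple[float, ...] = ()


@dataclass
class GroundTruth:
    nodes: dict[str, NodeTruth] = field(default_factory=dict)

    @property
    def counts_per_modification(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for node in self.nodes.values():
            if node.is_decoy:
                continue
            for name in node.planted_losses:
                counts[name] = counts.get(name, 0) + 1
        return dict(sorted(counts.items()))

    def planted_pairs(self, include_intermediates: bool = True) -> list[tuple[str, str]]:
        """(node_id, modification name) pairs expected to be recovered by screening."""
        pairs: list[tuple[str, str]] = []
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            if node.is_decoy or (node.is_intermediate and not include_intermediates):
                continue
            for name in node.planted_losses:
                pairs.append((nid, name))
        return pairs

    def to_json(self, path: str | Path) -> None:
        payload = {nid: asdict(self.nodes[nid]) for nid in sorted(self.nodes)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        truth = cls()
        for nid, raw in payload.items():
            raw = dict(raw)
            for key in ("chain", "planted_losses", "noise_peak_mz"):
                raw[key] = tuple(raw[key])
            truth.nodes[nid] = NodeTruth(**raw)
        return truth


def generate_probes(
    n: int,
    peaks_per_spectrum: int = 8,
    mz_range: tuple[float, float] = (250.0, 600.0),
    polarity: str = "positive",
    seed: int = 0,
) -> ProbeLibrary:
    """Generate ``n`` reproducible probe reference spectra.

    Each probe has ``peaks_per_spectrum`` random fragments plus a residual
    precursor peak; precursors are pairwise separated by >= 0.05 Da. Class
    labels cycle through a fixed phenylpropanoid-subclass list.
    """
    rng = np.random.default_rng(seed)
    library = ProbeLibrary()
    precursors: list[float] = []
    lo, hi = mz_range
    for i in range(n):
        while True:
            prec = float(rng.uniform(lo, hi))
            if all(abs(prec - p) > 0.05 for p in precursors):
                break
        precursors.append(prec)
        frag_mz = rng.uniform(60.0, prec - 30.0, size=peaks_per_spectrum)
        frag_int = rng.uniform(500.0, 10000.0, size=peaks_per_spectrum)
        peaks = [Peak(float(m), float(h)) for m, h in zip(frag_mz, frag_int)]
        peaks.append(Peak(prec, float(rng.uniform(500.0, 10000.0))))
        spectrum = MsmsSpectrum(
            id=f"probe-{i:03d}",
            precursor_mz=prec,
            peaks=tuple(peaks),
            rt=None,
            polarity=polarity,
        )
        library.records.append(
            ProbeRecord(
                spectrum=spectrum,
                compound_name=f"probe compound {i}",
                chemical_class=PHENYLPROPANOID_CLASSES[i % len(PHENYLPROPANOID_CLASSES)],
                instrument="synthetic-TOF",
                library_source="synthetic",
            )
        )
    return library


def _sample_steps(distribution: Mapping[int, float], rng: np.random.Generator) -> int:
    ks = sorted(distribution)
    weights = np.array([distribution[k] for k in ks], dtype=float)
    weights /= weights.sum()
    return int(rng.choice(ks, p=weights))


def _derive_one_step(
    peaks: Sequence[Peak],
    parent_precursor: float,
    mod_mass: float,
    fraction: float,
    anchors: set[float],
    rng: np.random.Generator,
) -> tuple[list[Peak], set[float]]:
    """Shift a parent spectrum by one modification.

    Anchor peaks (planted loss fragments from earlier steps, plus the
    parent's residual precursor peak) are never dropped; the retention
    ``fraction`` applies to ordinary fragments only. The peak at the parent
    precursor stays unshifted and becomes the neutral-loss evidence for this
    step; everything else moves up by the modification mass.
    """
    core = [p for p in peaks if abs(p.mz - parent_precursor) > _ANCHOR_EPS]
    at_parent = [p for p in peaks if abs(p.mz - parent_precursor) <= _ANCHOR_EPS]
    ordinary = [p for p in core if not any(abs(p.mz - a) <= _ANCHOR_EPS for a in anchors)]
    anchored = [p for p in core if any(abs(p.mz - a) <= _ANCHOR_EPS for a in anchors)]
    n_keep = int(np.ceil(fraction * len(ordinary)))
    if n_keep < len(ordinary):
        idx = rng.choice(len(ordinary), size=n_keep, replace=False)
        ordinary = [ordinary[i] for i in sorted(idx)]
    new_peaks = [Peak(p.mz + mod_mass, p.intensity) for p in ordinary + anchored]
    new_anchors = {a + mod_mass for a in anchors}
    if at_parent:
        new_peaks.append(at_parent[0])
    else:
        new_peaks.append(Peak(parent_precursor, float(rng.uniform(500.0, 10000.0))))
    new_anchors.add(parent_precursor)
    return new_peaks, new_anchors


def derive_modified(
    probes: ProbeLibrary,
    registry: ModificationRegistry,
    n_derived: int = 50,
    steps_distribution: Mapping[int, float] | None = None,
    shared_fragment_fraction: float = 1.0,
    seed: int = 0,
    rt_range: tuple[float, float] = (60.0, 1500.0),
    modification_pool: Sequence[str] | None = None,
) -> tuple[list[MsmsSpectrum], list[Feature], GroundTruth]:
    """Derive modified metabolites from probe spectra, with ground truth.

    Each derivative applies a chain of 0+ registry modifications to a random
    probe; multi-step chains emit their intermediates as extra nodes so that
    network propagation can walk the chain edge by edge. Planted neutral-loss
    fragments are exact to float precision; feature rows mirror the emitted
    spectra. RT/m-z placement guarantees distinct features never fall inside
    the default ion-fusion windows of each other.
    """
    if steps_distribution is None:
        steps_distribution = {1: 1.0}
    if not 0.0 <= shared_fragment_fraction <= 1.0:
        raise ValueError("shared_fragment_fraction must be in [0, 1]")
    if modification_pool is None:
        pool = list(registry.names)
    else:
        pool = [name for name in modification_pool]
        for name in pool:
            if name not in registry:
                raise ValueError(f"unknown modification {name!r} in pool")
    if len(probes) == 0 and n_derived > 0:
        raise ValueError("cannot derive from an empty probe library")

    rng = np.random.default_rng(seed)
    spectra: list[MsmsSpectrum] = []
    features: list[Feature] = []
    truth = GroundTruth()
    taken_precursors = [r.spectrum.precursor_mz for r in probes]
    taken_placements: list[tuple[float, float]] = []  # (mz, rt)

    def place_rt(mz: float) -> float:
        for _ in range(1000):
            rt = float(rng.uniform(*rt_range))
            ok = all(
                abs(mz - omz) / (0.5 * (mz + omz)) > 40e-6 or abs(rt - ort) > 30.0
                for omz, ort in taken_placements
            )
            if ok:
                return rt
        raise RuntimeError("could not place feature without fusion collision")

    for d in range(n_derived):
        record = probes.records[int(rng.integers(len(probes)))]
        k = _sample_steps(steps_distribution, rng)
        node_base = f"mod-{d:03d}"

        if k == 0:
            prec = record.spectrum.precursor_mz
            rt = place_rt(prec)
            spec = MsmsSpectrum(
                id=node_base,
                precursor_mz=prec,
                peaks=record.spectrum.peaks,
                rt=rt,
                polarity=record.spectrum.polarity,
            )
            spectra.append(spec)
            intensity = float(rng.uniform(1e4, 1e6))
            features.append(Feature(id=node_base, mz=prec, rt=rt, intensity=intensity))
            taken_placements.append((prec, rt))
            truth.nodes[node_base] = NodeTruth(
                node_id=node_base,
                parent_id=record.spectrum.id,
                probe_id=record.spectrum.id,
                chain=(),
                planted_losses=(),
                precursor_mz=prec,
                rt=rt,
            )
            continue

        # sample parent+chain, rejecting precursor collisions (< 0.015 Da,
        # comfortably above the 0.01 Da network deduplication tolerance)
        for _ in range(1000):
            chain = [pool[int(i)] for i in rng.choice(len(pool), size=k, replace=False)]
            precs = []
            cur = record.spectrum.precursor_mz
            for name in chain:
                cur = cur + registry[name].mass
                precs.append(cur)
            if all(
                all(abs(p - t) > 0.015 for t in taken_precursors) for p in precs
            ) and len({round(p, 6) for p in precs}) == k:
                break
            record = probes.records[int(rng.integers(len(probes)))]
        else:
            raise RuntimeError("could not sample a collision-free chain")
        taken_precursors.extend(precs)

        peaks: Sequence[Peak] = record.spectrum.peaks
        anchors: set[float] = set()
        parent_id = record.spectrum.id
        parent_prec = record.spectrum.precursor_mz
        for step, name in enumerate(chain, start=1):
            mod = registry[name]
            peaks, anchors = _derive_one_step(
                peaks, parent_prec, mod.mass, shared_fragment_fraction, anchors, rng
            )
            prec = parent_prec + mod.mass
            node_id = node_base if step == k else f"{node_base}-s{step}"
            rt = place_rt(prec)
            spec = MsmsSpectrum(
                id=node_id,
                precursor_mz=prec,
                peaks=tuple(peaks),
                rt=rt,
                polarity=record.spectrum.polarity,
            )
            spectra.append(spec)
            features.append(
                Feature(id=node_id, mz=prec, rt=rt, intensity=float(rng.uniform(1e4, 1e6)))
            )
            taken_placements.append((prec, rt))
            planted = tuple(
                m
                for m in chain[:step]
                if any(abs((prec - registry[m].mass) - p.mz) <= 1e-6 for p in spec.peaks)
            )
            truth.nodes[node_id] = NodeTruth(
                node_id=node_id,
                parent_id=parent_id,
                probe_id=record.spectrum.id,
                chain=tuple(chain[:step]),
                planted_losses=planted,
                precursor_mz=prec,
                rt=rt,
                is_intermediate=step < k,
            )
            parent_id, parent_prec = node_id, prec
            peaks = spec.peaks
    return spectra, features, truth


def add_noise(
    spectra: Sequence[MsmsSpectrum],
    features: Sequence[Feature],
    noise_peak_rate: float = 0.0,
    mz_jitter_ppm: float = 0.0,
    rt_jitter_s: float = 0.0,
    decoy_feature_count: int = 0,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[list[MsmsSpectrum], list[Feature], GroundTruth | None]:
    """Perturb a clean dataset reproducibly.

    Fragment m/z jitter is clipped-normal (sigma = ppm/3, |jitter| <= ppm);
    precursor and feature m/z stay exact (MS1 mass error is modelled by the
    decoys, not by shifting planted signals). ``noise_peak_rate`` adds that
    fraction of extra random peaks per spectrum; decoy features come with
    random spectra carrying no planted losses. With all parameters zero the
    dataset is returned unchanged.
    """
    if noise_peak_rate == 0 and mz_jitter_ppm == 0 and rt_jitter_s == 0 and decoy_feature_count == 0:
        return list(spectra), list(features), truth
    rng = np.random.default_rng(seed)
    out_spectra: list[MsmsSpectrum] = []
    out_features = list(features)
    truth = truth if truth is not None else GroundTruth()

    def jitter(mz: float) -> float:
        if mz_jitter_ppm <= 0:
            return mz
        ppm = float(np.clip(rng.normal(0.0, mz_jitter_ppm / 3.0), -mz_jitter_ppm, mz_jitter_ppm))
        return mz * (1.0 + ppm * 1e-6)

    for spec in spectra:
        peaks = [Peak(jitter(p.mz), p.intensity) for p in spec.peaks]
        noise_mz: list[float] = []
        n_noise = int(round(noise_peak_rate * len(spec.peaks)))
        for _ in range(n_noise):
            mz = float(rng.uniform(60.0, spec.precursor_mz))
            noise_mz.append(mz)
            peaks.append(Peak(mz, float(rng.uniform(120.0, 3000.0))))
        rt = spec.rt
        if rt is not None and rt_jitter_s > 0:
            rt = rt + float(
                np.clip(rng.normal(0.0, rt_jitter_s / 3.0), -rt_jitter_s, rt_jitter_s)
            )
        out_spectra.append(
            MsmsSpectrum(
                id=spec.id,
                precursor_mz=spec.precursor_mz,
                peaks=tuple(peaks),
                rt=rt,
                polarity=spec.polarity,
            )
        )
        if spec.id in truth.nodes:
            node = truth.nodes[spec.id]
            truth.nodes[spec.id] = NodeTruth(
                **{**asdict(node), "noise_peak_mz": tuple(noise_mz)}
            )

    for d in range(decoy_feature_count):
        did = f"decoy-{d:03d}"
        mz = float(rng.uniform(200.0, 800.0))
        rt = float(rng.uniform(60.0, 1500.0))
        frag = rng.uniform(60.0, mz - 10.0, size=6)
        peaks = tuple(Peak(float(m), float(rng.uniform(120.0, 5000.0))) for m in frag)
        out_spectra.append(
            MsmsSpectrum(id=did, precursor_mz=mz, peaks=peaks, rt=rt, polarity=spectra[0].polarity if spectra else "positive")
        )
        out_features.append(Feature(id=did, mz=mz, rt=rt, intensity=float(rng.uniform(1e3, 1e5))))
        truth.nodes[did] = NodeTruth(
            node_id=did,
            parent_id="",
            probe_id="",
            chain=(),
            planted_losses=(),
            precursor_mz=mz,
            rt=rt,
            is_decoy=True,
        )
    return out_spectra, out_features, truth
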