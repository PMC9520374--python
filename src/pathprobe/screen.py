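"""Modified-metabolome screening.

Pipeline stage 1: match MS1 features to MS/MS spectra, detect modification
neutral losses against the registry, keep features with at least one hit,
and fuse redundant ions (same metabolite seen as several close features).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import ModificationRegistry, ModificationType, match_mass_delta
from .msio import Feature, MsmsSpectrum

__all__ = [
    "ScreenParams",
    "ModificationHit",
    "ModifiedMetabolite",
    "ScreenSummary",
    "match_features_to_msms",
    "detect_modifications",
    "fuse_ions",
    "screen_modified_metabolome",
]

DELTA_KINDS = ("precursor-fragment", "fragment-fragment")


@dataclass(frozen=True)
class ScreenParams:
    """Tolerances of the screening stage (defaults as published)."""

    tol_ppm: float = 15.0
    rt_window_s: float = 12.0
    min_fragment_intensity: float = 100.0
    fuse_tol_ppm: float = 15.0
    fuse_rt_window_s: float = 12.0
    delta_kinds: tuple[str, ...] = ("precursor-fragment",)

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.fuse_tol_ppm <= 0:
            raise ValueError("ppm tolerances must be positive")
        if self.rt_window_s < 0 or self.fuse_rt_window_s < 0:
            raise ValueError("RT windows must be non-negative")
        for kind in self.delta_kinds:
            if kind not in DELTA_KINDS:
                raise ValueError(f"unknown delta kind {kind!r}")


@dataclass(frozen=True)
class ModificationHit:
    """Evidence that a spectrum contains a modification neutral loss."""

    modification: ModificationType
    delta_kind: str
    ion_pair: tuple[float, float]  # (larger m/z, fragment m/z)
    observed_delta: float
    ppm_error: float
    fragment_intensity: float
    adjustment: str = ""


@dataclass(frozen=True)
class ModifiedMetabolite:
    feature: Feature
    spectrum: MsmsSpectrum
    hits: tuple[ModificationHit, ...]

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError(f"{self.feature.id}: modified metabolite without hits")

    @property
    def modification_names(self) -> frozenset[str]:
        return frozenset(h.modification.name for h in self.hits)


@dataclass
class ScreenSummary:
    """Per-run statistics in the shape of the published modified-metabolome counts."""

    n_features: int = 0
    n_spectra: int = 0
    n_matched: int = 0
    n_with_hits: int = 0
    n_fused: int = 0
    counts_per_modification: dict[str, int] = field(default_factory=dict)
    n_modification_types: int = 0
    multi_modification_fraction: float = 0.0


def match_features_to_msms(
    features: Sequence[Feature],
    spectra: Sequence[MsmsSpectrum],
    tol_ppm: float = 15.0,
    rt_window_s: float = 12.0,
) -> tuple[list[tuple[Feature, MsmsSpectrum]], list[Feature]]:
    """Pair each feature with its MS/MS spectrum.

    A spectrum matches when its precursor m/z is within ``tol_ppm`` of the
    feature m/z and its RT within ``rt_window_s``. Among several candidates
    the spectrum closest in RT wins (tie: closest m/z). Returns the matched
    pairs and the features left unpaired.
    """
    pairs: list[tuple[Feature, MsmsSpectrum]] = []
    unmatched: list[Feature] = []
    for feat in features:
        best: tuple[float, float, int] | None = None
        best_spec: MsmsSpectrum | None = None
        for idx, spec in enumerate(spectra):
            if spec.rt is None:
                continue
            if abs(spec.precursor_mz - feat.mz) > tol_ppm * 1e-6 * feat.mz:
                continue
            drt = abs(spec.rt - feat.rt)
            if drt > rt_window_s:
                continue
            key = (drt, abs(spec.precursor_mz - feat.mz), idx)
            if best is None or key < best:
                best, best_spec = key, spec
        if best_spec is None:
            unmatched.append(feat)
        else:
            pairs.append((feat, best_spec))
    return pairs, unmatched


def detect_modifications(
    spectrum: MsmsSpectrum,
    registry: ModificationRegistry,
    tol_ppm: float = 15.0,
    min_fragment_intensity: float = 100.0,
    delta_kinds: Iterable[str] = ("precursor-fragment",),
) -> list[ModificationHit]:
    """Find modification neutral losses in one spectrum.

    For ``precursor-fragment`` every fragment at or above the intensity floor
    whose loss from the precursor matches a registry mass within ``tol_ppm``
    yields a hit; ``fragment-fragment`` (opt-in) tests every ordered fragment
    pair likewise. Hits are sorted by absolute ppm error.
    """
    kinds = tuple(delta_kinds)
    for kind in kinds:
        if kind not in DELTA_KINDS:
            raise ValueError(f"unknown delta kind {kind!r}")
    peaks = [p for p in spectrum.peaks if p.intensity >= min_fragment_intensity]
    hits: list[ModificationHit] = []
    if "precursor-fragment" in kinds:
        for p in peaks:
            delta = spectrum.precursor_mz - p.mz
            if delta <= 0:
                continue
            for m in match_mass_delta(delta, registry, tol_ppm):
                hits.append(
                    ModificationHit(
                        modification=m.modification,
                        delta_kind="precursor-fragment",
                        ion_pair=(spectrum.precursor_mz, p.mz),
                        observed_delta=delta,
                        ppm_error=m.ppm_error,
                        fragment_intensity=p.intensity,
                    )
                )
    if "fragment-fragment" in kinds:
        for i, hi in enumerate(peaks):
            for lo in peaks[:i]:
                delta = hi.mz - lo.mz
                if delta <= 0:
                    continue
                for m in match_mass_delta(delta, registry, tol_ppm):
                    hits.append(
                        ModificationHit(
                            modification=m.modification,
                            delta_kind="fragment-fragment",
                            ion_pair=(hi.mz, lo.mz),
                            observed_delta=delta,
                            ppm_error=m.ppm_error,
                            fragment_intensity=lo.intensity,
                        )
                    )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.modification.name, h.ion_pair))
    return hits


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def fuse_ions(
    modified: Sequence[ModifiedMetabolite],
    tol_ppm: float = 15.0,
    rt_window_s: float = 12.0,
) -> list[ModifiedMetabolite]:
    """Merge redundant modified metabolites (single-linkage in m/z x RT).

    Members within both windows of each other (transitively) collapse into the
    highest-intensity feature; hits are unioned by modification name keeping
    the smallest-|ppm| hit per name. Deterministic: tie-breaks use
    (intensity desc, m/z asc, id asc).
    """
    n = len(modified)
    uf = _UnionFind(n)
    for i in range(n):
        fi = modified[i].feature
        for j in range(i + 1, n):
            fj = modified[j].feature
            ref = 0.5 * (fi.mz + fj.mz)
            if abs(fi.mz - fj.mz) <= tol_ppm * 1e-6 * ref and abs(fi.rt - fj.rt) <= rt_window_s:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    fused: list[ModifiedMetabolite] = []
    for root in sorted(groups):
        members = [modified[i] for i in groups[root]]
        members.sort(key=lambda m: (-m.feature.intensity, m.feature.mz, m.feature.id))
        rep = members[0]
        best_by_name: dict[str, ModificationHit] = {}
        for member in members:
            for hit in member.hits:
                name = hit.modification.name
                prev = best_by_name.get(name)
                if prev is None or abs(hit.ppm_error) < abs(prev.ppm_error):
                    best_by_name[name] = hit
        hits = tuple(best_by_name[name] for name in sorted(best_by_name))
        fused.append(replace(rep, hits=hits))
    return fused


def screen_modified_metabolome(
    features: Sequence[Feature],
    spectra: Sequence[MsmsSpectrum],
    registry: ModificationRegistry,
    params: ScreenParams = ScreenParams(),
) -> tuple[list[ModifiedMetabolite], ScreenSummary]:
    """Full screening pipeline: match -> detect -> keep hits -> fuse."""
    summary = ScreenSummary(n_features=len(features), n_spectra=len(spectra))
    pairs, _ = match_features_to_msms(features, spectra, params.tol_ppm, params.rt_window_s)
    summary.n_matched = len(pairs)
    modified: list[ModifiedMetabolite] = []
    for feat, spec in pairs:
        hits = detect_modifications(
            spec,
            registry,
            tol_ppm=params.tol_ppm,
            min_fragment_intensity=params.min_fragment_intensity,
            delta_kinds=params.delta_kinds,
        )
        if hits:
            modified.append(ModifiedMetabolite(feature=feat, spectrum=spec, hits=tuple(hits)))
    summary.n_with_hits = len(modified)
    fused = fuse_ions(modified, params.fuse_tol_ppm, params.fuse_rt_window_s)
    summary.n_fused = len(fused)

    counts: dict[str, int] = {}
    n_multi = 0
    for met in fused:
        names = met.modification_names
        if len(names) >= 2:
            n_multi += 1
        for name in names:
            counts[name] = counts.get(name, 0) + 1
    summary.counts_per_modification = dict(sorted(counts.items()))
    summary.n_modification_types = len(counts)
    summary.multi_modification_fraction = n_multi / len(fused) if fused else 0.0
    return fused, summary
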