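"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from pathprobe.chem import load_modification_registry
from pathprobe.msio import MsmsSpectrum, Peak


@pytest.fixture(scope="session")
def registry():
    return load_modification_registry()


def make_spectrum(
    precursor_mz: float,
    peaks: list[tuple[float, float]],
    id: str = "S",
    rt: float | None = None,
    polarity: str = "positive",
) -> MsmsSpectrum:
    return MsmsSpectrum(
        id=id,
        precursor_mz=precursor_mz,
        peaks=tuple(Peak(mz, h) for mz, h in peaks),
        rt=rt,
        polarity=polarity,
    )


def random_spectrum(
    rng: np.random.Generator,
    n_peaks: int,
    id: str = "R",
    mz_grid: np.ndarray | None = None,
    precursor_range: tuple[float, float] = (300.0, 400.0),
) -> MsmsSpectrum:
    """Random spectrum; drawing m/z from a shared grid forces peak collisions."""
    if mz_grid is None:
        mz = rng.uniform(50.0, 250.0, size=n_peaks)
    else:
        mz = rng.choice(mz_grid, size=n_peaks, replace=False) + rng.uniform(
            -0.005, 0.005, size=n_peaks
        )
    intensity = rng.uniform(10.0, 1000.0, size=n_peaks)
    return make_spectrum(
        float(rng.uniform(*precursor_range)),
        list(zip(map(float, mz), map(float, intensity))),
        id=id,
    )


def brute_force_modified_cosine(a: MsmsSpectrum, b: MsmsSpectrum, tol: float = 0.02) -> float:
    """Exhaustive maximum over all one-to-one candidate-pair matchings.

    Independent oracle: recursion over the peaks of ``a``, each either left
    unmatched or paired with an unused candidate peak of ``b``.
    """
    wa = np.sqrt(a.intensity)
    wa = wa / np.linalg.norm(wa)
    wb = np.sqrt(b.intensity)
    wb = wb / np.linalg.norm(wb)
    shift = a.precursor_mz - b.precursor_mz
    mz_a, mz_b = a.mz, b.mz
    candidates: list[list[int]] = []
    for i in range(len(mz_a)):
        cand = [
            j
            for j in range(len(mz_b))
            if abs(mz_a[i] - mz_b[j]) <= tol or abs(mz_a[i] - mz_b[j] - shift) <= tol
        ]
        candidates.append(cand)

    best = 0.0

    def recurse(i: int, used: frozenset[int], score: float) -> None:
        nonlocal best
        if i == len(mz_a):
            best = max(best, score)
            return
        recurse(i + 1, used, score)
        for j in candidates[i]:
            if j not in used:
                recurse(i + 1, used | {j}, score + float(wa[i] * wb[j]))

    recurse(0, frozenset(), 0.0)
    return min(best, 1.0)
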