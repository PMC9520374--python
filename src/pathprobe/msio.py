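"""Readers/writers for spectra and feature tables, and probe-library construction.

Supported formats: MGF (read/write), MSP (read), delimited feature tables and
chemical-class tables (read). The MGF dialect is deliberately small: TITLE
carries the node id used throughout the pipeline, PEPMASS the precursor m/z,
RTINSECONDS the retention time (optional for library records) and the CHARGE
sign the polarity.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "MsmsSpectrum",
    "Feature",
    "ProbeRecord",
    "ProbeLibrary",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "read_feature_table",
    "build_probe_library",
]

POLARITIES = ("positive", "negative")


@dataclass(frozen=True, order=True)
class Peak:
    """One fragment ion: m/z and abundance (arbitrary units)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


def _canonical_peaks(peaks: Iterable[Peak | tuple[float, float]]) -> tuple[Peak, ...]:
    """Sort by m/z and merge duplicates closer than 1e-6 (intensities summed)."""
    norm = [p if isinstance(p, Peak) else Peak(*p) for p in peaks]
    norm.sort(key=lambda p: p.mz)
    merged: list[Peak] = []
    for p in norm:
        if merged and p.mz - merged[-1].mz < 1e-6:
            prev = merged[-1]
            merged[-1] = Peak(prev.mz, prev.intensity + p.intensity)
        else:
            merged.append(p)
    return tuple(merged)


@dataclass(frozen=True)
class MsmsSpectrum:
    """A product-ion spectrum with precursor metadata.

    Peaks are stored sorted by ascending m/z with sub-1e-6 duplicates merged.
    ``rt`` is optional: library records usually carry no chromatography.
    """

    id: str
    precursor_mz: float
    peaks: tuple[Peak, ...]
    rt: float | None = None
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.id}: non-positive precursor m/z")
        if self.polarity not in POLARITIES:
            raise ValueError(f"{self.id}: unknown polarity {self.polarity!r}")
        object.__setattr__(self, "peaks", _canonical_peaks(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.fromiter((p.mz for p in self.peaks), dtype=float, count=len(self.peaks))

    @property
    def intensity(self) -> np.ndarray:
        return np.fromiter(
            (p.intensity for p in self.peaks), dtype=float, count=len(self.peaks)
        )

    @property
    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.peaks))


@dataclass(frozen=True)
class Feature:
    """One MS1 feature: m/z, retention time (seconds) and peak intensity."""

    id: str
    mz: float
    rt: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.id}: non-positive m/z")
        if self.rt < 0:
            raise ValueError(f"{self.id}: negative retention time")


@dataclass(frozen=True)
class ProbeRecord:
    """A reference MS/MS record for one probe (library) compound."""

    spectrum: MsmsSpectrum
    compound_name: str
    chemical_class: str
    instrument: str = ""
    library_source: str = ""


@dataclass
class ProbeLibrary:
    """A filtered set of probe records plus acquisition statistics."""

    records: list[ProbeRecord] = field(default_factory=list)
    dropped_no_class: int = 0
    dropped_class: int = 0
    dropped_polarity: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> Counter:
        return Counter(r.chemical_class for r in self.records)

    @property
    def instrument_counts(self) -> Counter:
        return Counter(r.instrument for r in self.records)

    @property
    def n_compounds(self) -> int:
        return len({r.compound_name for r in self.records})


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read an MGF file into a list of spectra (one per BEGIN/END IONS block)."""
    spectra: list[MsmsSpectrum] = []
    block: dict[str, str] | None = None
    peaks: list[Peak] = []
    n_anonymous = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if block is not None:
                    raise ValueError(f"{path}:{lineno}: nested BEGIN IONS")
                block, peaks = {}, []
            elif line == "END IONS":
                if block is None:
                    raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                if "PEPMASS" not in block:
                    raise ValueError(f"{path}:{lineno}: block without PEPMASS")
                title = block.get("TITLE")
                if title is None:
                    title = f"spectrum-{n_anonymous}"
                    n_anonymous += 1
                charge = block.get("CHARGE", "1+")
                polarity = "negative" if charge.endswith("-") else "positive"
                rt = None
                if "RTINSECONDS" in block:
                    rt = float(block["RTINSECONDS"])
                spectra.append(
                    MsmsSpectrum(
                        id=title,
                        precursor_mz=float(block["PEPMASS"].split()[0]),
                        peaks=tuple(peaks),
                        rt=rt,
                        polarity=polarity,
                    )
                )
                block = None
            elif block is not None:
                if "=" in line and not line[0].isdigit():
                    key, _, value = line.partition("=")
                    block[key.upper()] = value.strip()
                else:
                    fields = line.split()
                    if len(fields) < 2:
                        raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}")
                    peaks.append(Peak(float(fields[0]), float(fields[1])))
            # lines outside blocks are ignored (global headers)
    if block is not None:
        raise ValueError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Write spectra in the canonical MGF dialect (round-trips with read_mgf)."""
    with open(path, "w", encoding="utf-8") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            if spec.rt is not None:
                fh.write(f"RTINSECONDS={spec.rt:.3f}\n")
            fh.write("CHARGE=1{}\n".format("-" if spec.polarity == "negative" else "+"))
            for peak in spec.peaks:
                fh.write(f"{peak.mz:.6f} {peak.intensity:.4f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# MSP (read-only adapter)
# ---------------------------------------------------------------------------


def read_msp(path: str | Path) -> list[MsmsSpectrum]:
    """Read an NIST-style MSP file (Name/PrecursorMZ/Num Peaks records)."""
    spectra: list[MsmsSpectrum] = []
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    n_peaks_expected: int | None = None

    def flush() -> None:
        nonlocal meta, peaks, n_peaks_expected
        if not meta:
            return
        prec_key = next(
            (k for k in ("PRECURSORMZ", "PRECURSOR_MZ", "PEPMASS") if k in meta), None
        )
        if prec_key is None:
            raise ValueError(f"{path}: MSP record {meta.get('NAME')!r} lacks precursor m/z")
        mode = meta.get("ION_MODE", meta.get("IONMODE", "P")).upper()
        polarity = "negative" if mode.startswith("N") else "positive"
        rt = float(meta["RETENTIONTIME"]) if "RETENTIONTIME" in meta else None
        spectra.append(
            MsmsSpectrum(
                id=meta.get("NAME", f"msp-{len(spectra)}"),
                precursor_mz=float(meta[prec_key]),
                peaks=tuple(peaks),
                rt=rt,
                polarity=polarity,
            )
        )
        meta, peaks, n_peaks_expected = {}, [], None

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            if n_peaks_expected is not None and len(peaks) < n_peaks_expected:
                fields = line.replace(";", " ").split()
                peaks.append(Peak(float(fields[0]), float(fields[1])))
                continue
            key, _, value = line.partition(":")
            key = key.strip().upper().replace(" ", "_")
            if key == "NUM_PEAKS":
                n_peaks_expected = int(value)
            else:
                meta[key] = value.strip()
    flush()
    return spectra


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def read_feature_table(
    path: str | Path,
    mz_col: str = "mz",
    rt_col: str = "rt",
    intensity_col: str = "intensity",
    id_col: str | None = "id",
    rt_unit: str = "s",
) -> list[Feature]:
    """Read a delimited MS1 feature table into Features (RT normalised to s).

    ``rt_unit`` is ``"s"`` or ``"min"``. The delimiter is inferred from the
    file extension (.tsv/.txt -> tab, otherwise comma). Missing ``id_col``
    falls back to ``F<row-index>``.
    """
    if rt_unit not in ("s", "min"):
        raise ValueError(f"rt_unit must be 's' or 'min', got {rt_unit!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (mz_col, rt_col, intensity_col):
        if col not in df.columns:
            raise ValueError(f"feature table missing required column {col!r}")
    if df.empty:
        warnings.warn(f"empty feature table: {path}", stacklevel=2)
        return []
    scale = 60.0 if rt_unit == "min" else 1.0
    features: list[Feature] = []
    for i, row in df.iterrows():
        fid = str(row[id_col]) if id_col in df.columns else f"F{i}"
        features.append(
            Feature(
                id=fid,
                mz=float(row[mz_col]),
                rt=float(row[rt_col]) * scale,
                intensity=float(row[intensity_col]),
            )
        )
    return features


def write_feature_table(features: Iterable[Feature], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"id": f.id, "mz": f.mz, "rt": f.rt, "intensity": f.intensity} for f in features],
        columns=["id", "mz", "rt", "intensity"],
    )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_class_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (id/compound -> chemical class) CSV into a mapping."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("class table needs at least two columns (key, class)")
    key_col, class_col = df.columns[0], df.columns[1]
    return {str(k): str(c) for k, c in zip(df[key_col], df[class_col])}


# ---------------------------------------------------------------------------
# Probe library
# ---------------------------------------------------------------------------


def build_probe_library(
    records: Iterable[tuple[MsmsSpectrum, Mapping[str, str]]],
    class_table: Mapping[str, str],
    target_classes: Sequence[str] | set[str],
    polarity: str = "positive",
) -> ProbeLibrary:
    """Assemble the probe spectral library by chemical-class filtering.

    ``records`` yields (spectrum, metadata) pairs; metadata may provide
    ``compound_name``, ``instrument`` and ``library_source``. The class of a
    record is looked up in ``class_table`` by spectrum id first, then by
    compound name. Records without a class are dropped (counted); records
    whose class is outside ``target_classes`` or whose polarity differs are
    dropped likewise. A compound may contribute several spectra.
    """
    targets = set(target_classes)
    library = ProbeLibrary()
    for spectrum, meta in records:
        name = str(meta.get("compound_name", spectrum.id))
        cls = class_table.get(spectrum.id, class_table.get(name))
        if cls is None:
            library.dropped_no_class += 1
            warnings.warn(f"probe record {spectrum.id!r} has no class mapping", stacklevel=2)
            continue
        if cls not in targets:
            library.dropped_class += 1
            continue
        if spectrum.polarity != polarity:
            library.dropped_polarity += 1
            continue
        library.records.append(
            ProbeRecord(
                spectrum=spectrum,
                compound_name=name,
                chemical_class=cls,
                instrument=str(meta.get("instrument", "")),
                library_source=str(meta.get("library_source", "")),
            )
        )
    return library
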