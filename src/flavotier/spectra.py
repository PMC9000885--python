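"""Spectrum data model, MSP/MGF peak-list I/O, normalization, peak matching.

The in-memory unit is :class:`Spectrum`: a precursor (m/z, adduct,
optional retention time) plus an m/z-sorted peak list.  Libraries are
lists of :class:`LibraryRecord` (spectrum + compound identity +
provenance).  MSP (NIST text dialect) is the library interchange format,
MGF (Mascot generic format, read/written through pyteomics) carries
query spectra; both are plain text and diff-able.

Peak matching between two spectra is greedy on descending intensity
product with an absolute mDa tolerance (the MS2 convention used
throughout), each peak used at most once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

from pyteomics import mgf as _mgf

from .formulae import Formula

__all__ = [
    "Peak",
    "Spectrum",
    "LibraryRecord",
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
    "normalize",
    "match_peaks",
    "MspFormatError",
]

#: Peaks may sit at most this far above the precursor (isotope spillover guard).
PRECURSOR_GUARD = 0.5


class Peak(NamedTuple):
    mz: float
    intensity: float


class MspFormatError(ValueError):
    """Malformed MSP record (named in the message where possible)."""


@dataclass(frozen=True)
class Spectrum:
    """A positive-mode MS/MS spectrum: precursor plus sorted peak list."""

    identifier: str
    precursor_mz: float
    adduct: str = "[M+H]+"
    retention_time: Optional[float] = None  # minutes
    peaks: tuple[Peak, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.identifier}: precursor m/z must be positive")
        pk = tuple(sorted((Peak(float(m), float(i)) for m, i in self.peaks)))
        for p in pk:
            if not (math.isfinite(p.mz) and math.isfinite(p.intensity)):
                raise ValueError(f"{self.identifier}: non-finite peak {p}")
            if p.mz <= 0 or p.intensity < 0:
                raise ValueError(f"{self.identifier}: invalid peak {p}")
            if p.mz > self.precursor_mz + PRECURSOR_GUARD:
                raise ValueError(
                    f"{self.identifier}: peak {p.mz:.4f} above precursor "
                    f"{self.precursor_mz:.4f} + {PRECURSOR_GUARD}"
                )
        object.__setattr__(self, "peaks", pk)

    @property
    def base_peak(self) -> Peak:
        if not self.peaks:
            raise ValueError(f"{self.identifier}: spectrum has no peaks")
        return max(self.peaks, key=lambda p: (p.intensity, -p.mz))

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


REFERENCE_PROVENANCES = ("reference", "quasi-reference-2a", "quasi-reference-mzCloud")
PROVENANCES = REFERENCE_PROVENANCES + ("synthetic",)


@dataclass(frozen=True)
class LibraryRecord:
    """A library entry: spectrum plus compound identity and provenance."""

    spectrum: Spectrum
    name: str
    formula: Optional[Formula] = None
    subclass: Optional[str] = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance in REFERENCE_PROVENANCES and self.formula is None:
            raise ValueError(
                f"{self.name}: (quasi) reference records must carry a formula"
            )


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the base peak is 100 (idempotent, order kept)."""
    if not spectrum.peaks:
        raise ValueError(f"{spectrum.identifier}: cannot normalize empty spectrum")
    top = max(p.intensity for p in spectrum.peaks)
    if top <= 0:
        raise ValueError(f"{spectrum.identifier}: all-zero intensities")
    return spectrum.with_peaks(
        Peak(p.mz, 100.0 * p.intensity / top) for p in spectrum.peaks
    )


def match_peak_indices(
    a: Spectrum, b: Spectrum, tol_mda: float = 10.0
) -> list[tuple[int, int]]:
    """Index pairs of :func:`match_peaks` (see there for the rule)."""
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    tol = tol_mda / 1000.0 + 1e-9  # inclusive boundary, robust to float noise
    candidates = []
    for ia, pa in enumerate(a.peaks):
        for ib, pb in enumerate(b.peaks):
            if abs(pa.mz - pb.mz) <= tol:
                candidates.append((-(pa.intensity * pb.intensity), pa.mz, pb.mz, ia, ib))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib))
    pairs.sort(key=lambda pr: a.peaks[pr[0]].mz)
    return pairs


def match_peaks(
    a: Spectrum, b: Spectrum, tol_mda: float = 10.0
) -> list[tuple[Peak, Peak]]:
    """Greedy one-to-one peak pairing within an absolute mDa window.

    Candidate pairs within tolerance are taken in order of descending
    intensity product (ties broken by m/z), each peak used at most once.
    Tolerance comparisons are inclusive.
    """
    return [(a.peaks[ia], b.peaks[ib]) for ia, ib in match_peak_indices(a, b, tol_mda)]


# -- MSP (NIST text dialect) -------------------------------------------------

_MSP_KEYS = ("PrecursorMZ", "Precursor_type", "RETENTIONTIME", "Formula",
             "Subclass", "Provenance")


def write_msp(records: Iterable[LibraryRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            sp = rec.spectrum
            fh.write(f"Name: {rec.name}\n")
            fh.write(f"PrecursorMZ: {sp.precursor_mz:.6f}\n")
            fh.write(f"Precursor_type: {sp.adduct}\n")
            if sp.retention_time is not None:
                fh.write(f"RETENTIONTIME: {sp.retention_time:.4f}\n")
            if rec.formula is not None:
                fh.write(f"Formula: {rec.formula}\n")
            if rec.subclass:
                fh.write(f"Subclass: {rec.subclass}\n")
            fh.write(f"Provenance: {rec.provenance}\n")
            for key, value in sp.metadata.items():
                if key not in _MSP_KEYS and key != "Name":
                    fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(sp.peaks)}\n")
            for p in sp.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("\n")


def read_msp(path) -> list[LibraryRecord]:
    records: list[LibraryRecord] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i, n = 0, len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        header: dict[str, str] = {}
        while i < n and lines[i].strip():
            if ":" not in lines[i]:
                raise MspFormatError(f"expected 'Key: value', got {lines[i]!r}")
            key, _, value = lines[i].partition(":")
            key, value = key.strip(), value.strip()
            i += 1
            if key.lower() == "num peaks":
                break
            header[key] = value
        else:
            raise MspFormatError(
                f"record {header.get('Name', '<unnamed>')!r} has no 'Num Peaks' line"
            )
        name = header.get("Name")
        if not name:
            raise MspFormatError("record without a Name field")
        try:
            n_peaks = int(value)
        except ValueError:
            raise MspFormatError(f"record {name!r}: bad Num Peaks value {value!r}")
        peaks = []
        while i < n and lines[i].strip():
            fields = lines[i].replace(";", " ").split()
            if len(fields) < 2:
                raise MspFormatError(f"record {name!r}: bad peak line {lines[i]!r}")
            peaks.append(Peak(float(fields[0]), float(fields[1])))
            i += 1
        if len(peaks) != n_peaks:
            raise MspFormatError(
                f"record {name!r}: Num Peaks is {n_peaks} but {len(peaks)} "
                "peak lines found"
            )
        rt = header.get("RETENTIONTIME")
        spectrum = Spectrum(
            identifier=name,
            precursor_mz=float(header["PrecursorMZ"]),
            adduct=header.get("Precursor_type", "[M+H]+"),
            retention_time=float(rt) if rt is not None else None,
            peaks=tuple(peaks),
            metadata={
                k: v
                for k, v in header.items()
                if k not in ("Name", "PrecursorMZ", "Precursor_type",
                             "RETENTIONTIME", "Formula", "Subclass", "Provenance")
            },
        )
        formula = header.get("Formula")
        records.append(
            LibraryRecord(
                spectrum=spectrum,
                name=name,
                formula=Formula.parse(formula) if formula else None,
                subclass=header.get("Subclass") or None,
                provenance=header.get("Provenance", "synthetic"),
            )
        )
    return records


# -- MGF (Mascot generic format, via pyteomics) ------------------------------

def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    entries = []
    for sp in spectra:
        params = {"title": sp.identifier, "pepmass": sp.precursor_mz,
                  "charge": "1+", "adduct": sp.adduct}
        if sp.retention_time is not None:
            params["rtinseconds"] = sp.retention_time * 60.0
        params.update({k.lower(): v for k, v in sp.metadata.items()})
        entries.append(
            {
                "params": params,
                "m/z array": [p.mz for p in sp.peaks],
                "intensity array": [p.intensity for p in sp.peaks],
            }
        )
    _mgf.write(entries, str(path), write_charges=False, use_numpy=False)


def read_mgf(path) -> list[Spectrum]:
    out = []
    with _mgf.read(str(path), use_index=False, convert_arrays=0) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"spectrum-{len(out)}"))
            pepmass = params.get("pepmass")
            mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
            rt_s = params.get("rtinseconds")
            peaks = tuple(
                Peak(m, i)
                for m, i in zip(entry["m/z array"], entry["intensity array"])
            )
            if not peaks:
                warnings.warn(f"MGF spectrum {title!r} has no peaks")
            out.append(
                Spectrum(
                    identifier=title,
                    precursor_mz=float(mz0),
                    adduct=str(params.get("adduct", "[M+H]+")),
                    retention_time=float(rt_s) / 60.0 if rt_s is not None else None,
                    peaks=peaks,
                    metadata={
                        k: v
                        for k, v in params.items()
                        if k not in ("title", "pepmass", "charge", "adduct",
                                     "rtinseconds")
                    },
                )
            )
    return out
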