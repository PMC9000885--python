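"""Spectral similarity for library search: normalized dot product and
spectral-entropy similarity, reported on the 0-100 scale used by search
engines ("identification score").

Both scores align peaks with the same greedy mDa matcher used everywhere
else, use raw intensities (no m/z^k weighting) and are symmetric in
their arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .spectra import Spectrum, match_peak_indices, match_peaks

__all__ = ["SimilarityScore", "cosine_score", "entropy_score", "is_hit"]


@dataclass(frozen=True)
class SimilarityScore:
    value: float  # in [0, 1]
    method: str  # "dot_product" | "entropy"

    def __post_init__(self) -> None:
        # clamp tiny float excursions, reject real violations
        if not -1e-9 <= self.value <= 1.0 + 1e-9:
            raise ValueError(f"similarity out of range: {self.value}")
        object.__setattr__(self, "value", min(1.0, max(0.0, self.value)))

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def _require_peaks(*spectra: Spectrum) -> None:
    for sp in spectra:
        if not sp.peaks:
            raise ValueError(f"{sp.identifier}: empty spectrum has no similarity")


def cosine_score(a: Spectrum, b: Spectrum, tol_mda: float = 10.0) -> SimilarityScore:
    """Normalized dot product over the full peak vectors.

    Unmatched peaks contribute zero to the numerator but keep their full
    weight in the norms, so extra peaks in either spectrum pull the score
    down.  Invariant to global intensity scaling of either spectrum.
    """
    _require_peaks(a, b)
    pairs = match_peaks(a, b, tol_mda)
    num = sum(pa.intensity * pb.intensity for pa, pb in pairs)
    na = sum(p.intensity**2 for p in a.peaks)
    nb = sum(p.intensity**2 for p in b.peaks)
    value = num / math.sqrt(na * nb) if na > 0 and nb > 0 else 0.0
    return SimilarityScore(value=value, method="dot_product")


def _shannon(probs: list[float]) -> float:
    return -sum(p * math.log(p) for p in probs if p > 0)


def entropy_score(a: Spectrum, b: Spectrum, tol_mda: float = 10.0) -> SimilarityScore:
    """Spectral-entropy similarity.

    Intensities of each spectrum are normalized to sum 1; with S the
    Shannon entropy (natural log) and the merged spectrum the
    peak-aligned average of the two, the score is
    ``1 - (2*S_merged - S_a - S_b) / ln 4``.
    """
    _require_peaks(a, b)
    ta = sum(p.intensity for p in a.peaks)
    tb = sum(p.intensity for p in b.peaks)
    if ta <= 0 or tb <= 0:
        raise ValueError("all-zero intensities")
    pa = [p.intensity / ta for p in a.peaks]
    pb = [p.intensity / tb for p in b.peaks]
    sa, sb = _shannon(pa), _shannon(pb)

    matched_a: set[int] = set()
    matched_b: set[int] = set()
    merged: list[float] = []
    for ia, ib in match_peak_indices(a, b, tol_mda):
        matched_a.add(ia)
        matched_b.add(ib)
        merged.append((pa[ia] + pb[ib]) / 2.0)
    merged.extend(pa[i] / 2.0 for i in range(len(pa)) if i not in matched_a)
    merged.extend(pb[i] / 2.0 for i in range(len(pb)) if i not in matched_b)
    sm = _shannon(merged)
    value = 1.0 - (2.0 * sm - sa - sb) / math.log(4.0)
    return SimilarityScore(value=value, method="entropy")


def is_hit(score: SimilarityScore, cutoff_percent: float = 80.0) -> bool:
    """Inclusive pass mark on the percent scale ("cutoff, 80" admits 80.0)."""
    if not 0.0 <= cutoff_percent <= 100.0:
        raise ValueError("cutoff must lie in [0, 100]")
    return score.percent >= cutoff_percent
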