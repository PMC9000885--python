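"""Subclass fragmentation rules: verify an annotation, classify a spectrum.

Each of the twelve flavonoid subclasses carries a machine-checkable rule
(mandatory diagnostic ions, supporting ions, a base-peak condition and —
for flavanones/chalcones — a minimum share of the total fragment
intensity).  ``verify`` checks one candidate template against one
spectrum; ``classify`` enumerates the substituent placements compatible
with a precursor formula across all subclasses and ranks the subclasses
that pass.

Flavanones and chalcones are genuinely indistinguishable by MS/MS under
these rules (identical cleavage arithmetic); classify reports them as a
tied pair and callers should treat them as one equivalence class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .flavochem import (
    CompoundTemplate,
    compound_formula,
    expected_ions,
    registry,
)
from .formulae import F, Formula, IonSpec, ion_mz
from .spectra import Peak, Spectrum, normalize

__all__ = ["DiagnosticMatch", "RuleVerdict", "ClassificationResult",
           "verify", "classify", "enumerate_templates"]

#: Peaks closer than this to the precursor m/z are not counted as fragments.
_PRECURSOR_WINDOW = 0.5

#: Enumeration bounds for substituent placement: at most this many
#: O-bearing substituents (hydroxyl/methoxyl) per ring, and methyls per ring.
MAX_O_SUBS_PER_RING = 3
MAX_METHYLS_PER_RING = 2


@dataclass(frozen=True)
class DiagnosticMatch:
    label: str
    expected_mz: float
    observed: Optional[Peak]
    error_mda: Optional[float]
    mandatory: bool


@dataclass(frozen=True)
class RuleVerdict:
    subclass: str
    template: CompoundTemplate
    matches: tuple[DiagnosticMatch, ...]
    base_ok: bool
    base_share: Optional[float]
    explained_fraction: float
    verdict: str  # "pass" | "fail"
    reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def _nearest_peak(peaks, mz: float, tol: float) -> Optional[Peak]:
    best, best_err = None, tol + 1.0
    for p in peaks:
        err = abs(p.mz - mz)
        if err <= tol and err < best_err:
            best, best_err = p, err
    return best


def verify(spectrum: Spectrum, t: CompoundTemplate,
           tol_mda: float = 10.0) -> RuleVerdict:
    """Check one compound template's subclass rule against a spectrum."""
    if not spectrum.peaks:
        raise ValueError(f"{spectrum.identifier}: cannot verify empty spectrum")
    skel = registry()[t.skeleton]
    rule = skel.rule
    sp = normalize(spectrum)
    tol = tol_mda / 1000.0
    ions = expected_ions(t)

    reasons: list[str] = []
    matches: list[DiagnosticMatch] = []
    all_ok = True
    for label in rule.mandatory + rule.supporting:
        if label not in ions:
            if label in rule.mandatory:
                all_ok = False
                reasons.append(f"mandatory ion {label} not emittable")
            continue
        ion = ions[label][0]
        peak = _nearest_peak(sp.peaks, ion.mz, tol)
        matches.append(
            DiagnosticMatch(
                label=label,
                expected_mz=ion.mz,
                observed=peak,
                error_mda=None if peak is None else 1000.0 * (peak.mz - ion.mz),
                mandatory=label in rule.mandatory,
            )
        )
        if peak is None and label in rule.mandatory:
            all_ok = False
            reasons.append(f"mandatory ion {label} ({ion.mz:.4f}) unmatched")

    base_ok = True
    base_share: Optional[float] = None
    if rule.base_label is not None:
        if rule.base_label not in ions:
            base_ok = False
            reasons.append(f"base ion {rule.base_label} not emittable")
        else:
            expected_base = ions[rule.base_label][0]
            observed_base = sp.base_peak
            base_ok = abs(observed_base.mz - expected_base.mz) <= tol
            if not base_ok:
                reasons.append(
                    f"base peak {observed_base.mz:.4f} is not "
                    f"{rule.base_label} ({expected_base.mz:.4f})"
                )
            if rule.min_share is not None:
                frag = [p for p in sp.peaks
                        if p.mz < sp.precursor_mz - _PRECURSOR_WINDOW]
                total = sum(p.intensity for p in frag)
                matched = _nearest_peak(frag, expected_base.mz, tol)
                base_share = (matched.intensity / total
                              if matched is not None and total > 0 else 0.0)
                if base_share < rule.min_share:
                    base_ok = False
                    reasons.append(
                        f"{rule.base_label} carries {base_share:.0%} of the "
                        f"fragment intensity (< {rule.min_share:.0%})"
                    )

    expected_mzs = [ion.mz for ion, _ in ions.values()]
    total_int = sum(p.intensity for p in sp.peaks)
    explained = sum(
        p.intensity
        for p in sp.peaks
        if any(abs(p.mz - mz) <= tol for mz in expected_mzs)
    ) / total_int if total_int > 0 else 0.0

    passed = all_ok and base_ok
    return RuleVerdict(
        subclass=t.skeleton,
        template=t,
        matches=tuple(matches),
        base_ok=base_ok,
        base_share=base_share,
        explained_fraction=explained,
        verdict="pass" if passed else "fail",
        reasons=tuple(reasons),
    )


def _split(total: int, cap_a: int, cap_b: int):
    for a in range(min(total, cap_a) + 1):
        b = total - a
        if b <= cap_b:
            yield a, b


def enumerate_templates(subclass: str, formula: Formula,
                        name: str = "candidate") -> list[CompoundTemplate]:
    """All substituent placements of ``subclass`` matching a neutral formula.

    The difference formula - scaffold must decompose into hydroxyl (+O),
    methoxyl (+CH2O) and methyl (+CH2) increments; each CH2 unit
    contributes exactly two hydrogens, so the hydrogen excess fixes the
    total CH2 count and only the methoxyl/methyl split and the ring
    placement remain free.
    """
    skel = registry()[subclass]
    try:
        delta = formula - skel.scaffold
    except ValueError:
        return []
    if any(sym not in ("C", "H", "O") for sym, _ in delta):
        return []
    d_c, d_h, d_o = delta["C"], delta["H"], delta["O"]
    if d_h != 2 * d_c:
        return []
    out = []
    for n_methoxyl in range(min(d_c, d_o) + 1):
        n_methyl = d_c - n_methoxyl
        n_hydroxyl = d_o - n_methoxyl
        if n_methyl > 2 * MAX_METHYLS_PER_RING:
            continue
        for ha, hb in _split(n_hydroxyl, MAX_O_SUBS_PER_RING, MAX_O_SUBS_PER_RING):
            for ma, mb in _split(n_methoxyl, MAX_O_SUBS_PER_RING - ha,
                                 MAX_O_SUBS_PER_RING - hb):
                for mea, meb in _split(n_methyl, MAX_METHYLS_PER_RING,
                                       MAX_METHYLS_PER_RING):
                    ring_a = {k: v for k, v in
                              (("hydroxyl", ha), ("methoxyl", ma), ("methyl", mea))
                              if v}
                    ring_b = {k: v for k, v in
                              (("hydroxyl", hb), ("methoxyl", mb), ("methyl", meb))
                              if v}
                    out.append(CompoundTemplate(
                        name=f"{name}-{subclass}",
                        skeleton=subclass,
                        ring_a=ring_a,
                        ring_b=ring_b,
                    ))
    return out


@dataclass(frozen=True)
class ClassificationResult:
    ranking: tuple[tuple[str, RuleVerdict], ...]  # passing subclasses, best first
    failures: Mapping[str, str]  # subclass -> why it failed

    @property
    def top(self) -> Optional[str]:
        return self.ranking[0][0] if self.ranking else None

    @property
    def top_set(self) -> frozenset:
        """Top subclass plus any subclass tied with it (score equality)."""
        if not self.ranking:
            return frozenset()
        best = self.ranking[0][1].explained_fraction
        return frozenset(
            sub for sub, v in self.ranking
            if abs(v.explained_fraction - best) < 1e-9
        )


def classify(spectrum: Spectrum, precursor_formula: Formula,
             tol_mda: float = 10.0) -> ClassificationResult:
    """Rank the subclasses whose rule a spectrum satisfies.

    The precursor formula (neutral) constrains the substituent
    enumeration; for each subclass the best-verifying placement is kept.
    Subclasses that pass are ranked by explained intensity; flavanone and
    chalcone, when both pass, are inherently tied.
    """
    theo = ion_mz(IonSpec(precursor_formula, spectrum.adduct))
    if abs(theo - spectrum.precursor_mz) > tol_mda / 1000.0:
        raise ValueError(
            f"precursor formula {precursor_formula} ({theo:.4f}) inconsistent "
            f"with precursor m/z {spectrum.precursor_mz:.4f}"
        )
    ranking = []
    failures: dict[str, str] = {}
    for subclass in registry():
        best: Optional[RuleVerdict] = None
        for t in enumerate_templates(subclass, precursor_formula):
            v = verify(spectrum, t, tol_mda)
            if best is None or (v.passed, v.explained_fraction) > (
                best.passed, best.explained_fraction
            ):
                best = v
        if best is None:
            failures[subclass] = "no substituent placement matches the formula"
        elif best.passed:
            ranking.append((subclass, best))
        else:
            failures[subclass] = "; ".join(best.reasons) or "rule not satisfied"
    ranking.sort(key=lambda kv: (-kv[1].explained_fraction, kv[0]))
    return ClassificationResult(ranking=tuple(ranking), failures=failures)
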