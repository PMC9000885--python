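"""The multi-tiered annotation pipeline.

Queries are pushed through the evidence tiers in order of decreasing
confidence and assigned a Schymanski level:

* level 1 — matches a reference standard on all three orthogonal axes:
  retention time (|dRT| <= 0.05 min), precursor exact mass (<= 5 mDa) and
  fragment content (>= 3 matching MS2 ions);
* level 2a — spectral-library hit with identification score >= 80 %;
* level 2b — structure-candidate ranked by in-silico fragments and
  diagnostic ions, accepted when the subclass rule verifies;
* level 3 — de-novo: CHO formula decomposition, fragmentation tree and a
  subclass ranking (a candidate set, not one structure);
* level 4 — unique molecular formula only; level 5 — exact mass only.

Level-2a hits scoring above 90 % are promoted to quasi-reference library
records, the mechanism that grows the rule-derivation library beyond the
purchased standards.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .flavochem import CompoundTemplate, compound_formula, expected_ions
from .formulae import Formula, IonSpec, decompose, ion_mz, mass_error
from .fragtree import FragmentationTree, build_tree, tree_losses
from .insilico import insilico_fragments
from .rules import ClassificationResult, RuleVerdict, classify, verify
from .similarity import SimilarityScore, cosine_score, entropy_score, is_hit
from .spectra import LibraryRecord, Spectrum, match_peaks

__all__ = [
    "PipelineConfig",
    "Level1Match",
    "Hit2a",
    "Candidate2b",
    "EvidenceBundle",
    "AnnotationResult",
    "match_level1",
    "search_level2a",
    "rank_level2b",
    "assign_level",
    "promote_quasi_reference",
    "run_pipeline",
]

log = logging.getLogger("flavotier")

LEVEL_ORDER = {"1": 0, "2a": 1, "2b": 2, "3": 3, "4": 4, "5": 5}


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the tiering pipeline (units in names)."""

    rt_tol_min: float = 0.05
    ms1_tol_mda: float = 5.0  # level-1 exact-mass gate
    ms2_tol_mda: float = 10.0  # fragment matching everywhere
    precursor_filter_mda: float = 10.0  # MS1 pre-filter for 2a/2b/3
    score_cutoff_pct: float = 80.0  # level-2a identification score
    quasi_cutoff_pct: float = 90.0  # strict > for quasi-reference promotion
    min_matched_fragments: int = 3  # level-1 "matching fragment ions"
    adducts: tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[2M+H]+")
    similarity: str = "dot_product"  # or "entropy"
    use_insilico: bool = True
    max_breaks: int = 2
    decompose_max_c: int = 30
    decompose_max_h: int = 40
    decompose_max_o: int = 15

    def __post_init__(self) -> None:
        for name in ("rt_tol_min", "ms1_tol_mda", "ms2_tol_mda",
                     "precursor_filter_mda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("score_cutoff_pct", "quasi_cutoff_pct"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.similarity not in ("dot_product", "entropy"):
            raise ValueError("similarity must be dot_product or entropy")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "adducts" in raw:
            raw["adducts"] = tuple(raw["adducts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["adducts"] = list(data["adducts"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def score(self, a: Spectrum, b: Spectrum) -> SimilarityScore:
        fn = cosine_score if self.similarity == "dot_product" else entropy_score
        return fn(a, b, self.ms2_tol_mda)


@dataclass(frozen=True)
class Level1Match:
    record: LibraryRecord
    n_matched_fragments: int
    precursor_error_mda: float
    rt_error_min: float


@dataclass(frozen=True)
class Hit2a:
    record: LibraryRecord
    score: SimilarityScore


@dataclass(frozen=True)
class Candidate2b:
    template: CompoundTemplate
    explained_fraction: float
    verdict: RuleVerdict
    tied: bool = False  # indistinguishable from another candidate


@dataclass(frozen=True)
class EvidenceBundle:
    query: Spectrum
    level1: Optional[Level1Match] = None
    hits_2a: tuple[Hit2a, ...] = ()
    candidates_2b: tuple[Candidate2b, ...] = ()
    formula_candidates: tuple[Formula, ...] = ()
    tree: Optional[FragmentationTree] = None
    classification: Optional[ClassificationResult] = None
    validation: Optional[str] = None  # rule check of the accepted answer
    error: Optional[str] = None


@dataclass(frozen=True)
class AnnotationResult:
    query_id: str
    level: str  # "1" | "2a" | "2b" | "3" | "4" | "5"
    best_candidate: str
    score_percent: Optional[float]
    evidence: EvidenceBundle


def match_level1(query: Spectrum, standards: Sequence[LibraryRecord],
                 cfg: PipelineConfig) -> Optional[Level1Match]:
    """Reference-standard match on RT, exact mass and fragment ions."""
    if query.retention_time is None:
        log.warning("%s: no retention time; level 1 skipped", query.identifier)
        return None
    best: Optional[Level1Match] = None
    for rec in standards:
        rt = rec.spectrum.retention_time
        if rt is None:
            continue
        d_rt = abs(query.retention_time - rt)
        if d_rt > cfg.rt_tol_min:
            continue
        err = mass_error(query.precursor_mz, rec.spectrum.precursor_mz)
        if abs(err.mda) > cfg.ms1_tol_mda:
            continue
        n = len(match_peaks(query, rec.spectrum, cfg.ms2_tol_mda))
        if n < cfg.min_matched_fragments:
            continue
        cand = Level1Match(rec, n, err.mda, d_rt)
        if best is None or (
            (-cand.n_matched_fragments, abs(cand.precursor_error_mda))
            < (-best.n_matched_fragments, abs(best.precursor_error_mda))
        ):
            best = cand
    return best


def search_level2a(query: Spectrum, library: Sequence[LibraryRecord],
                   cfg: PipelineConfig) -> tuple[Hit2a, ...]:
    """Library search: MS1 pre-filter, similarity score, cutoff (inclusive)."""
    hits = []
    for rec in library:
        if abs(query.precursor_mz - rec.spectrum.precursor_mz) * 1000.0 > \
                cfg.precursor_filter_mda:
            continue
        score = cfg.score(query, rec.spectrum)
        if is_hit(score, cfg.score_cutoff_pct):
            hits.append(Hit2a(rec, score))
    hits.sort(key=lambda h: (-h.score.value, h.record.name))
    return tuple(hits)


def _candidate_ion_mzs(t: CompoundTemplate, cfg: PipelineConfig) -> list[float]:
    mzs = [ion.mz for ion, _ in expected_ions(t).values()]
    if cfg.use_insilico:
        for f in insilico_fragments(t, cfg.max_breaks):
            mzs.append(ion_mz(IonSpec(f, "cation")))
    return mzs


def rank_level2b(query: Spectrum, candidates: Sequence[CompoundTemplate],
                 cfg: PipelineConfig) -> tuple[Candidate2b, ...]:
    """Rank structure candidates by explained intensity.

    The candidate's fragment pool is its diagnostic-ion set united with
    the bond-breaking enumeration; the score is the fraction of query
    intensity it explains.  Ties (positional isomers explain identical
    peak sets) are flagged indistinguishable; rule verification breaks
    ties ahead of parsimony.
    """
    tol = cfg.ms2_tol_mda / 1000.0
    scored = []
    for t in candidates:
        theo = ion_mz(IonSpec(compound_formula(t), query.adduct))
        if abs(theo - query.precursor_mz) * 1000.0 > cfg.precursor_filter_mda:
            continue
        mzs = _candidate_ion_mzs(t, cfg)
        total = sum(p.intensity for p in query.peaks)
        explained = sum(
            p.intensity for p in query.peaks
            if any(abs(p.mz - m) <= tol for m in mzs)
        ) / total if total > 0 else 0.0
        verdict = verify(query, t, cfg.ms2_tol_mda)
        scored.append((explained, verdict, len(mzs), t))
    scored.sort(key=lambda s: (-s[0], not s[1].passed, s[2], s[3].name))
    out = []
    for i, (explained, verdict, _, t) in enumerate(scored):
        tied = any(
            j != i and abs(scored[j][0] - explained) < 1e-9
            for j in range(len(scored))
        )
        out.append(Candidate2b(t, explained, verdict, tied))
    return tuple(out)


def _level3_evidence(query: Spectrum, cfg: PipelineConfig):
    if query.adduct not in ("[M+H]+", "[M+Na]+"):
        return (), None, None
    formulas = decompose(
        query.precursor_mz,
        query.adduct,
        cfg.precursor_filter_mda,
        max_c=cfg.decompose_max_c,
        max_h=cfg.decompose_max_h,
        max_o=cfg.decompose_max_o,
    )
    tree = None
    classification = None
    for f in formulas[:3]:  # best-error formulas first
        cation = IonSpec(f, query.adduct).cation_formula
        try:
            tree = build_tree(query, cation, cfg.ms2_tol_mda)
            classification = classify(query, f, cfg.ms2_tol_mda)
        except ValueError:
            continue
        if classification.ranking:
            break
    return tuple(formulas), tree, classification


def gather_evidence(query: Spectrum, standards: Sequence[LibraryRecord],
                    library: Sequence[LibraryRecord],
                    candidates: Sequence[CompoundTemplate],
                    cfg: PipelineConfig) -> EvidenceBundle:
    level1 = match_level1(query, standards, cfg)
    hits = search_level2a(query, library, cfg)
    ranked = () if level1 or hits else rank_level2b(query, candidates, cfg)
    formulas: tuple[Formula, ...] = ()
    tree = classification = None
    accepted_2b = any(c.verdict.passed for c in ranked)
    if not (level1 or hits or accepted_2b):
        formulas, tree, classification = _level3_evidence(query, cfg)

    # rule validation of the accepted answer (levels 2a-3)
    validation = None
    if hits:
        top = hits[0].record
        if top.formula is not None and top.subclass is not None:
            try:
                check = classify(query, top.formula, cfg.ms2_tol_mda)
                ok = top.subclass in {s for s, _ in check.ranking}
                validation = "pass" if ok else "fail"
            except ValueError:
                validation = "n/a"
    elif accepted_2b:
        validation = "pass"  # acceptance of 2b requires a passing verdict
    elif classification is not None and classification.ranking:
        validation = "pass"
    return EvidenceBundle(
        query=query,
        level1=level1,
        hits_2a=hits,
        candidates_2b=ranked,
        formula_candidates=formulas,
        tree=tree,
        classification=classification,
        validation=validation,
    )


def assign_level(ev: EvidenceBundle, cfg: PipelineConfig) -> AnnotationResult:
    """Total, stable level precedence: 1 > 2a > 2b > 3 > 4 > 5."""
    qid = ev.query.identifier
    if ev.level1 is not None:
        return AnnotationResult(qid, "1", ev.level1.record.name, None, ev)
    if ev.hits_2a:
        top = ev.hits_2a[0]
        return AnnotationResult(qid, "2a", top.record.name,
                                top.score.percent, ev)
    passing = [c for c in ev.candidates_2b if c.verdict.passed]
    if passing:
        names = sorted({c.template.name for c in passing
                        if abs(c.explained_fraction
                               - passing[0].explained_fraction) < 1e-9})
        return AnnotationResult(
            qid, "2b", " | ".join(names),
            100.0 * passing[0].explained_fraction, ev
        )
    if ev.classification is not None and ev.classification.ranking:
        subclasses = " | ".join(s for s, _ in ev.classification.ranking[:2])
        f = ev.formula_candidates[0]
        return AnnotationResult(qid, "3", f"{f} ({subclasses})", None, ev)
    if len(ev.formula_candidates) == 1:
        return AnnotationResult(qid, "4", str(ev.formula_candidates[0]),
                                None, ev)
    return AnnotationResult(qid, "5", f"m/z {ev.query.precursor_mz:.4f}",
                            None, ev)


def promote_quasi_reference(results: Iterable[AnnotationResult],
                            cfg: PipelineConfig) -> list[LibraryRecord]:
    """Level-2a annotations scoring strictly above the quasi cutoff become
    quasi-reference library records (the query spectrum under the matched
    identity)."""
    out = []
    for res in results:
        if res.level != "2a" or not res.evidence.hits_2a:
            continue
        top = res.evidence.hits_2a[0]
        if top.score.percent > cfg.quasi_cutoff_pct:
            out.append(
                LibraryRecord(
                    spectrum=replace(res.evidence.query,
                                     identifier=top.record.name),
                    name=top.record.name,
                    formula=top.record.formula,
                    subclass=top.record.subclass,
                    provenance="quasi-reference-2a",
                )
            )
    return out


def run_pipeline(queries: Sequence[Spectrum],
                 standards: Sequence[LibraryRecord],
                 library: Sequence[LibraryRecord],
                 candidates: Sequence[CompoundTemplate],
                 cfg: PipelineConfig = PipelineConfig(),
                 ) -> tuple[list[AnnotationResult], pd.DataFrame]:
    """Annotate a batch; returns results plus the tabular report.

    Per-query failures are caught and reported as level 5 with a note —
    one bad query never aborts the batch.  Output ordering (by query id)
    and number formatting are fixed, so identical inputs give
    byte-identical reports.
    """
    results: list[AnnotationResult] = []
    for query in sorted(queries, key=lambda q: q.identifier):
        log.info("annotating %s (precursor %.4f)", query.identifier,
                 query.precursor_mz)
        try:
            ev = gather_evidence(query, standards, library, candidates, cfg)
            results.append(assign_level(ev, cfg))
        except Exception as exc:  # noqa: BLE001 - per-query isolation
            log.error("%s failed: %s", query.identifier, exc)
            results.append(
                AnnotationResult(
                    query.identifier, "5",
                    f"m/z {query.precursor_mz:.4f}", None,
                    EvidenceBundle(query=query, error=str(exc)),
                )
            )
    rows = []
    for res in results:
        ev = res.evidence
        losses = ""
        if ev.tree is not None:
            losses = "+".join(sorted(str(l) for l in tree_losses(ev.tree)))
        rows.append(
            {
                "query_id": res.query_id,
                "level": res.level,
                "best_candidate": res.best_candidate,
                "score_percent": (
                    "" if res.score_percent is None
                    else f"{res.score_percent:.2f}"
                ),
                "rule_verdict": ev.validation or "",
                "tree_losses": losses,
                "note": ev.error or "",
            }
        )
    report = pd.DataFrame(
        rows, columns=["query_id", "level", "best_candidate", "score_percent",
                       "rule_verdict", "tree_losses", "note"]
    )
    return results, report
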