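"""Synthetic stand-in for instrument data.

Builds the 39-compound (quasi-)reference fixture library — 12 flavonoid
subclasses in the fixed composition 4 flavones / 6 flavonols /
9 isoflavones / 1 aurone / 6 flavanones / 2 chalcones / 2 flavanols /
4 neoflavonoids I / 1 II / 1 III / 2 IV / 1 VIII — and simulates noisy
positive-mode HCD-like query spectra with full ground truth, so every
pipeline stage can be exercised and scored without any instrument files.

What the simulator emulates: diagnostic fragment content and base-peak
conventions per subclass, Gaussian m/z jitter (fragments worse than the
precursor, as on an Orbitrap), multiplicative intensity noise, uniform
decoy peaks and retention-time jitter.  What it does not: collision-energy
dependence, isotope envelopes, chromatographic peak shapes, co-elution.

All randomness flows from a single integer seed; identical seeds give
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .flavochem import CompoundTemplate, compound_formula, theoretical_spectrum
from .spectra import LibraryRecord, Peak, Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "EXPECTED_COMPOSITION",
    "build_quasi_library",
    "simulate_spectrum",
    "simulate_dataset",
]

#: Subclass composition of the 39-compound fixture; the builder hard-fails
#: if an edit to the compound table breaks it.
EXPECTED_COMPOSITION: Mapping[str, int] = {
    "flavone": 4,
    "flavonol": 6,
    "isoflavone": 9,
    "aurone": 1,
    "flavanone": 6,
    "chalcone": 2,
    "flavanol": 2,
    "neoflavonoid_I": 4,
    "neoflavonoid_II": 1,
    "neoflavonoid_III": 1,
    "neoflavonoid_IV": 2,
    "neoflavonoid_VIII": 1,
}

#: Retention-time grid of the fixture (min): start and spacing.  Spacing is
#: chosen far wider than the 0.05-min level-1 window so RT is discriminating.
RT_START, RT_STEP = 3.0, 0.75


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model for simulated query spectra.

    Defaults are the benchmark conditions: 3 mDa fragment jitter (1 mDa on
    the precursor), 5 decoy peaks at 5 % relative intensity, 5 %
    multiplicative intensity noise and 0.01 min retention-time jitter.
    """

    mz_jitter_mda: float = 3.0
    precursor_jitter_mda: float = 1.0
    n_decoys: int = 5
    decoy_intensity_pct: float = 5.0
    intensity_noise_pct: float = 5.0
    rt_jitter_min: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_jitter_mda < 0 or self.precursor_jitter_mda < 0:
            raise ValueError("jitter must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic call")


@dataclass(frozen=True)
class GroundTruth:
    """query id -> generating template, subclass and designed level."""

    entries: Mapping[str, tuple[CompoundTemplate, str, str]]

    def template(self, qid: str) -> CompoundTemplate:
        return self.entries[qid][0]

    def subclass(self, qid: str) -> str:
        return self.entries[qid][1]

    def level(self, qid: str) -> str:
        return self.entries[qid][2]


@lru_cache(maxsize=1)
def _load_compound_table() -> tuple[dict, ...]:
    with resources.files("flavotier.data").joinpath("compounds.yaml").open() as fh:
        return tuple(yaml.safe_load(fh)["compounds"])


def build_quasi_library() -> list[tuple[LibraryRecord, CompoundTemplate]]:
    """The 39 (quasi) reference compounds with their noise-free spectra.

    Retention times are assigned on a deterministic spaced grid (the
    source material has no RT model).  The composition invariant is
    enforced here so that any edit to the compound table that changes the
    subclass census fails loudly.
    """
    rows = _load_compound_table()
    out: list[tuple[LibraryRecord, CompoundTemplate]] = []
    census: dict[str, int] = {}
    for i, row in enumerate(rows):
        t = CompoundTemplate(
            name=row["name"],
            skeleton=row["skeleton"],
            ring_a=dict(row.get("ring_a", {})),
            ring_b=dict(row.get("ring_b", {})),
        )
        census[t.skeleton] = census.get(t.skeleton, 0) + 1
        spectrum = replace(
            theoretical_spectrum(t), retention_time=RT_START + RT_STEP * i
        )
        record = LibraryRecord(
            spectrum=spectrum,
            name=t.name,
            formula=compound_formula(t),
            subclass=t.skeleton,
            provenance=row.get("provenance", "synthetic"),
        )
        out.append((record, t))
    if len(out) != 39:
        raise AssertionError(f"fixture must hold 39 compounds, found {len(out)}")
    if census != dict(EXPECTED_COMPOSITION):
        raise AssertionError(f"fixture composition drifted: {census}")
    return out


def simulate_spectrum(t: CompoundTemplate, cfg: SimulationConfig,
                      rt: Optional[float] = None,
                      identifier: Optional[str] = None) -> Spectrum:
    """One noisy HCD-like spectrum of a template (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    theo = theoretical_spectrum(t)
    precursor = theo.precursor_mz + rng.normal(0.0, cfg.precursor_jitter_mda / 1000.0)
    peaks = []
    for p in theo.peaks:
        mz = p.mz + rng.normal(0.0, cfg.mz_jitter_mda / 1000.0)
        inten = p.intensity * max(
            0.0, 1.0 + rng.normal(0.0, cfg.intensity_noise_pct / 100.0)
        )
        mz = min(mz, precursor + 0.45)
        peaks.append(Peak(mz, inten))
    base = max((p.intensity for p in peaks), default=100.0)
    for _ in range(cfg.n_decoys):
        mz = rng.uniform(50.0, max(51.0, precursor - 20.0))
        peaks.append(Peak(mz, base * cfg.decoy_intensity_pct / 100.0))
    rt_out = None
    if rt is not None:
        rt_out = rt + rng.normal(0.0, cfg.rt_jitter_min)
    return Spectrum(
        identifier=identifier or t.name,
        precursor_mz=precursor,
        adduct="[M+H]+",
        retention_time=rt_out,
        peaks=tuple(peaks),
        metadata={"Subclass": t.skeleton},
    )


@dataclass(frozen=True)
class SimulatedDataset:
    """Queries plus the evidence sources each designed level is allowed."""

    queries: tuple[Spectrum, ...]
    truth: GroundTruth
    standards: tuple[LibraryRecord, ...]  # level-1 evidence (RT + spectrum)
    library: tuple[LibraryRecord, ...]  # level-2a evidence (spectra only)
    candidates: tuple[CompoundTemplate, ...]  # level-2b evidence (structures)


LEVELS = ("1", "2a", "2b", "3")


def _mass_groups(entries, tol_da: float = 0.02) -> list[list[int]]:
    """Union compounds whose precursors collide within ``tol_da``.

    Same-formula isomers (and near-isobars inside the MS1 window) must be
    assigned to the same designed level, otherwise e.g. a withheld
    compound would be "found" through its isomer's library record and the
    design would be unscoreable.
    """
    mzs = [rec.spectrum.precursor_mz for rec, _ in entries]
    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if abs(mzs[i] - mzs[j]) <= tol_da:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(entries)):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


def simulate_dataset(
    n: int,
    level_mix: Sequence[float] = (0.1, 0.4, 0.3, 0.2),
    cfg: SimulationConfig = SimulationConfig(),
) -> SimulatedDataset:
    """A seeded benchmark: ``n`` queries with designed confidence levels.

    ``level_mix`` gives the fractions of designed levels (1, 2a, 2b, 3).
    Templates are partitioned into mass-collision groups and each group is
    assigned one designed level; a level-1 query's compound appears in the
    standards list (with its RT), a 2a compound only in the spectral
    library, a 2b compound only in the candidate-structure table, and a
    level-3 compound is withheld everywhere.
    """
    if abs(sum(level_mix) - 1.0) > 1e-9 or len(level_mix) != 4:
        raise ValueError("level_mix must be 4 fractions summing to 1")
    if n < sum(1 for f in level_mix if f > 0):
        raise ValueError("n smaller than the number of requested levels")
    entries = build_quasi_library()
    rng = np.random.default_rng(cfg.seed)

    groups = _mass_groups(entries)
    order = rng.permutation(len(groups))
    quota = np.array([f * len(entries) for f in level_mix])
    assigned: dict[int, str] = {}
    filled = np.zeros(4)
    for gi in order:
        group = groups[gi]
        # most-underfilled level first, so every requested level gets mass
        lvl = int(np.argmax((quota - filled) / np.maximum(quota, 1e-9)))
        if quota[lvl] <= 0:
            lvl = int(np.argmax(quota - filled))
        for idx in group:
            assigned[idx] = LEVELS[lvl]
        filled[lvl] += len(group)

    by_level: dict[str, list[int]] = {lvl: [] for lvl in LEVELS}
    for idx, lvl in assigned.items():
        by_level[lvl].append(idx)
    for lvl, frac in zip(LEVELS, level_mix):
        if frac > 0 and not by_level[lvl]:
            raise AssertionError(f"no templates assigned to level {lvl}")

    standards = tuple(entries[i][0] for i in sorted(by_level["1"]))
    library = tuple(entries[i][0] for i in sorted(by_level["2a"]))
    candidates = tuple(entries[i][1] for i in sorted(by_level["2b"]))

    # draw queries according to the mix
    lvl_choices = rng.choice(
        4, size=n, p=np.asarray(level_mix) / sum(level_mix)
    )
    queries = []
    truth: dict[str, tuple[CompoundTemplate, str, str]] = {}
    for k, lc in enumerate(lvl_choices):
        lvl = LEVELS[int(lc)]
        pool = by_level[lvl]
        if not pool:  # a zero-fraction level can still be drawn? no: p=0
            raise AssertionError(f"empty pool for level {lvl}")
        idx = int(rng.choice(pool))
        rec, t = entries[idx]
        qid = f"q{k:04d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        qcfg = replace(cfg, seed=sub_seed)
        sp = simulate_spectrum(
            t, qcfg, rt=rec.spectrum.retention_time, identifier=qid
        )
        queries.append(sp)
        truth[qid] = (t, t.skeleton, lvl)
    return SimulatedDataset(
        queries=tuple(queries),
        truth=GroundTruth(truth),
        standards=standards,
        library=library,
        candidates=candidates,
    )
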