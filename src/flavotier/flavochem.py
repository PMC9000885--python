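"""Flavonoid chemistry core.

Twelve subclass skeletons (flavone, flavonol, isoflavone, flavanone,
chalcone, flavanol, aurone and five neoflavonoid types) are loaded from a
human-editable registry.  Each skeleton carries ring-cleavage templates —
the retro-Diels-Alder style i,j bond-pair splits whose two neutral parts
must sum exactly to the scaffold formula — and an emission table of the
diagnostic ions observed for that subclass under positive-mode HCD,
including neutral-loss cascades (CO, H2O, CH3 radical) and base-peak
conventions.

A :class:`CompoundTemplate` is a skeleton plus hydroxyl/methoxyl/methyl
substituents per ring; ring-A substituents travel with the A-part of each
cleavage and ring-B substituents with the B-part, which is what makes the
fragment m/z shift diagnostically with the substitution pattern (moving
one hydroxyl between rings moves the A- and B-fragments by one oxygen in
opposite directions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .formulae import F, Formula, IonSpec, ion_mz, subformula
from .spectra import Peak, Spectrum

__all__ = [
    "SUBSTITUENT_DELTAS",
    "CleavageTemplate",
    "IonRule",
    "SkeletonDef",
    "SubclassRuleSpec",
    "CompoundTemplate",
    "FragmentIon",
    "registry",
    "compound_formula",
    "rda_fragment_ions",
    "loss_series",
    "theoretical_spectrum",
    "expected_ions",
    "complementary_pair_check",
]

#: Elemental increment of each supported ring substituent.
SUBSTITUENT_DELTAS: Mapping[str, Formula] = {
    "hydroxyl": F("O"),
    "methoxyl": F("CH2O"),
    "methyl": F("CH2"),
}

#: Relative-intensity convention of the theoretical diagnostic spectrum.
TIER_INTENSITY = {"base": 100.0, "strong": 60.0, "minor": 20.0}

_PROTON = F("H")


@dataclass(frozen=True)
class CleavageTemplate:
    label: str
    part_a: Formula  # retains the A-ring system (gets ring-A substituents)
    part_b: Formula  # retains the B-ring system (gets ring-B substituents)


@dataclass(frozen=True)
class IonRule:
    """One entry of a skeleton's diagnostic-ion emission table."""

    label: str
    source: str  # "precursor" or a cleavage label
    side: Optional[str] = None  # "a" | "b" for cleavage sources
    form: str = "protonated"  # protonated | cation | radical
    h_offset: int = 0
    loss: Optional[Formula] = None
    gain: Optional[Formula] = None
    tier: str = "minor"
    requires: Optional[str] = None  # e.g. "methoxyl"


@dataclass(frozen=True)
class SubclassRuleSpec:
    """Machine-checkable verification rule of one subclass."""

    subclass: str
    mandatory: tuple[str, ...]
    supporting: tuple[str, ...]
    base_label: Optional[str]
    min_share: Optional[float] = None  # base ion's min fraction of fragment signal
    radical_base: bool = False


@dataclass(frozen=True)
class SkeletonDef:
    subclass: str
    scaffold: Formula
    smiles: str
    cleavages: Mapping[str, CleavageTemplate]
    ions: tuple[IonRule, ...]
    base_label: str
    share: Optional[dict]
    rule: SubclassRuleSpec


@dataclass(frozen=True)
class CompoundTemplate:
    """A decorated skeleton: the generator of theoretical fragments."""

    name: str
    skeleton: str
    ring_a: Mapping[str, int] = field(default_factory=dict)
    ring_b: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ring in (self.ring_a, self.ring_b):
            for kind, n in ring.items():
                if kind not in SUBSTITUENT_DELTAS:
                    raise ValueError(f"unknown substituent {kind!r}")
                if n < 0:
                    raise ValueError("substituent counts must be non-negative")

    def delta(self, ring: str) -> Formula:
        subs = self.ring_a if ring == "a" else self.ring_b
        out = Formula({})
        for kind, n in subs.items():
            out = out + SUBSTITUENT_DELTAS[kind] * n
        return out

    @property
    def has_methoxyl(self) -> bool:
        return self.ring_a.get("methoxyl", 0) + self.ring_b.get("methoxyl", 0) > 0


@dataclass(frozen=True)
class FragmentIon:
    label: str
    formula: Formula  # composition of the charged species
    mz: float
    parity: str  # "even" | "radical"


class RegistryError(ValueError):
    """Inconsistent skeleton registry (guards hand edits)."""


def _parse_skeleton(subclass: str, raw: dict) -> SkeletonDef:
    scaffold = F(raw["scaffold"])
    cleavages: dict[str, CleavageTemplate] = {}
    for c in raw.get("cleavages", ()):
        tmpl = CleavageTemplate(c["label"], F(c["part_a"]), F(c["part_b"]))
        if tmpl.label in cleavages:
            raise RegistryError(f"{subclass}: duplicate cleavage {tmpl.label}")
        if tmpl.part_a + tmpl.part_b != scaffold:
            raise RegistryError(
                f"{subclass} cleavage {tmpl.label}: {tmpl.part_a} + {tmpl.part_b}"
                f" != scaffold {scaffold}"
            )
        cleavages[tmpl.label] = tmpl
    ions = []
    for entry in raw["ions"]:
        ion = IonRule(
            label=entry["label"],
            source=entry["source"],
            side=entry.get("side"),
            form=entry.get("form", "protonated"),
            h_offset=int(entry.get("h_offset", 0)),
            loss=F(entry["loss"]) if "loss" in entry else None,
            gain=F(entry["gain"]) if "gain" in entry else None,
            tier=entry.get("tier", "minor"),
            requires=entry.get("requires"),
        )
        if ion.source != "precursor" and ion.source not in cleavages:
            raise RegistryError(f"{subclass}: ion {ion.label} cites unknown "
                                f"cleavage {ion.source!r}")
        if ion.tier not in TIER_INTENSITY:
            raise RegistryError(f"{subclass}: unknown tier {ion.tier!r}")
        ions.append(ion)
    labels = [i.label for i in ions]
    if len(labels) != len(set(labels)):
        raise RegistryError(f"{subclass}: duplicate ion labels")
    rule_raw = raw["rule"]
    rule = SubclassRuleSpec(
        subclass=subclass,
        mandatory=tuple(rule_raw["mandatory"]),
        supporting=tuple(rule_raw.get("supporting", ())),
        base_label=rule_raw.get("base_label"),
        min_share=rule_raw.get("min_share"),
        radical_base=bool(rule_raw.get("radical_base", False)),
    )
    for lbl in rule.mandatory + rule.supporting + (
        (rule.base_label,) if rule.base_label else ()
    ):
        if lbl not in labels:
            raise RegistryError(f"{subclass}: rule cites unknown ion {lbl!r}")
    return SkeletonDef(
        subclass=subclass,
        scaffold=scaffold,
        smiles=raw["smiles"],
        cleavages=cleavages,
        ions=tuple(ions),
        base_label=raw["base_label"],
        share=raw.get("share"),
        rule=rule,
    )


@lru_cache(maxsize=1)
def registry() -> Mapping[str, SkeletonDef]:
    """The validated skeleton registry (loaded once per process)."""
    with resources.files("flavotier.data").joinpath("skeletons.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    skeletons = {
        name: _parse_skeleton(name, body) for name, body in raw["skeletons"].items()
    }
    if len(skeletons) != 12:
        raise RegistryError(f"expected 12 skeletons, found {len(skeletons)}")
    return skeletons


def compound_formula(t: CompoundTemplate) -> Formula:
    """Neutral molecular formula: scaffold plus all substituent increments."""
    skel = registry().get(t.skeleton)
    if skel is None:
        raise KeyError(f"unknown skeleton {t.skeleton!r}")
    return skel.scaffold + t.delta("a") + t.delta("b")


def _evaluate_ion(skel: SkeletonDef, rule: IonRule,
                  t: CompoundTemplate) -> Optional[FragmentIon]:
    """Instantiate one emission entry for a concrete compound.

    Returns None when the entry does not apply (condition unmet) or the
    required neutral subtraction is infeasible (pruned branch).
    """
    if rule.requires == "methoxyl" and not t.has_methoxyl:
        return None
    if rule.source == "precursor":
        base = compound_formula(t) + _PROTON
    else:
        cleav = skel.cleavages[rule.source]
        if rule.side == "a":
            base = cleav.part_a + t.delta("a")
        else:
            base = cleav.part_b + t.delta("b")
        if rule.h_offset > 0:
            base = base + F("H") * rule.h_offset
        elif rule.h_offset < 0:
            try:
                base = base - F("H") * (-rule.h_offset)
            except ValueError:
                return None
        if rule.form == "protonated":
            base = base + _PROTON
    if rule.gain is not None:
        base = base + rule.gain
    if rule.loss is not None:
        try:
            base = base - rule.loss
        except ValueError:
            return None
    if not base:
        return None
    parity = "radical" if rule.form == "radical" else "even"
    return FragmentIon(
        label=rule.label,
        formula=base,
        mz=ion_mz(IonSpec(base, "cation")),
        parity=parity,
    )


def expected_ions(t: CompoundTemplate) -> dict[str, tuple[FragmentIon, str]]:
    """All diagnostic ions this template emits: label -> (ion, tier)."""
    skel = registry()[t.skeleton]
    out: dict[str, tuple[FragmentIon, str]] = {}
    for rule in skel.ions:
        ion = _evaluate_ion(skel, rule, t)
        if ion is not None:
            out[rule.label] = (ion, rule.tier)
    return out


def rda_fragment_ions(t: CompoundTemplate, label: str) -> list[FragmentIon]:
    """Diagnostic ions arising from one named ring cleavage."""
    skel = registry()[t.skeleton]
    if label not in skel.cleavages:
        raise KeyError(
            f"{t.skeleton} has no cleavage {label!r}; valid: "
            f"{sorted(skel.cleavages)}"
        )
    ions = []
    for rule in skel.ions:
        if rule.source != label:
            continue
        ion = _evaluate_ion(skel, rule, t)
        if ion is not None:
            ions.append(ion)
    return ions


def loss_series(start: FragmentIon, losses: Sequence[Formula],
                depth: int = 1) -> list[FragmentIon]:
    """All ordered neutral-loss combinations from a start ion up to ``depth``.

    Infeasible subtractions are silently pruned; labels are composed the
    way the field writes them (``[M-2CO+H]+``-style counting of repeated
    losses).  Depth 0 returns the start ion alone.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    results = [start]
    seen = {str(start.formula)}
    frontier: list[tuple[FragmentIon, tuple[str, ...]]] = [(start, ())]
    for _ in range(depth):
        nxt = []
        for ion, applied in frontier:
            for loss in losses:
                try:
                    f = ion.formula - loss
                except ValueError:
                    continue
                if not f:
                    continue
                chain = applied + (str(loss),)
                counts: dict[str, int] = {}
                for name in chain:
                    counts[name] = counts.get(name, 0) + 1
                inner = start.label.strip("+.").strip("[]")
                # compose e.g. "[M-2CO+H]+" from the root label "[M+H]+"
                stem, _, charge_tail = inner.partition("+")
                loss_txt = "".join(
                    f"-{n if n > 1 else ''}{name}" for name, n in sorted(counts.items())
                )
                label = f"[{stem}{loss_txt}+{charge_tail or 'H'}]+"
                child = FragmentIon(
                    label=label,
                    formula=f,
                    mz=ion_mz(IonSpec(f, "cation")),
                    parity=ion.parity,
                )
                nxt.append((child, chain))
                if str(f) not in seen:
                    seen.add(str(f))
                    results.append(child)
        frontier = nxt
    return results


def theoretical_spectrum(t: CompoundTemplate) -> Spectrum:
    """Noise-free diagnostic spectrum of a template.

    Intensities follow the registry tiers (base 100 / strong 60 /
    minor 20); where the subclass states that its base ion must carry a
    minimum share of the total fragment signal (flavanones/chalcones),
    that ion is boosted above the sum of the other fragments before
    normalization.  Coinciding ions merge keeping the larger intensity.
    """
    skel = registry()[t.skeleton]
    ions = expected_ions(t)
    if skel.base_label not in ions:
        raise ValueError(f"{t.name}: base ion {skel.base_label} not emitted")
    precursor_mz = ions["[M+H]+"][0].mz
    intensities: dict[str, float] = {
        label: TIER_INTENSITY[tier] for label, (ion, tier) in ions.items()
    }
    if skel.share:
        target = skel.share["label"]
        if target in intensities:
            others = sum(
                v for lbl, v in intensities.items()
                if lbl not in (target, "[M+H]+")
            )
            intensities[target] = max(
                intensities[target], skel.share["boost"] * others
            )
    merged: dict[float, float] = {}
    for label, (ion, _) in ions.items():
        key = round(ion.mz, 4)
        merged[key] = max(merged.get(key, 0.0), intensities[label])
    top = max(merged.values())
    peaks = tuple(
        Peak(mz, 100.0 * inten / top) for mz, inten in sorted(merged.items())
    )
    return Spectrum(
        identifier=t.name,
        precursor_mz=precursor_mz,
        adduct="[M+H]+",
        peaks=peaks,
        metadata={"Subclass": t.skeleton},
    )


#: Allowed m/z-sum offsets of a complementary fragment pair relative to the
#: precursor: H-transfer pair, radical split, and a pair formed after a
#: methyl-radical loss from the precursor.
_PAIR_OFFSETS = (1.00783, 0.0, 1.00783 - 15.0235)


def complementary_pair_check(p1: Peak, p2: Peak, precursor_mz: float,
                             tol_mda: float = 10.0) -> bool:
    """Do two fragments partition the precursor (with allowed H bookkeeping)?"""
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    s = p1.mz + p2.mz - precursor_mz
    return any(abs(s - off) <= tol_mda / 1000.0 for off in _PAIR_OFFSETS)


def conservation_check(t: CompoundTemplate) -> None:
    """Assert every emitted ion embeds in the protonated molecule.

    Water-transfer ions (``[...+H2O+H]+``) may exceed the bare part by one
    water picked up during the rearrangement, so the bound is M+H+H2O.
    """
    cation = compound_formula(t) + _PROTON
    for label, (ion, _) in expected_ions(t).items():
        if not subformula(ion.formula, cation + F("H2O")):
            raise AssertionError(
                f"{t.name}: ion {label} ({ion.formula}) exceeds precursor {cation}"
            )
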