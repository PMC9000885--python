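"""Bond-breaking fragment enumeration for structure-database ranking.

A compound template is rendered as an RDKit molecule (skeleton SMILES
with mapped substitution sites, decorated with its hydroxyl/methoxyl/
methyl substituents) and fragmented by iterative bond deletion: every
acyclic heavy-atom bond (and pairs of them), plus every pair of bonds
within one ring, yields connected components whose elemental compositions
— with +-1 H-transfer variants — are the candidate fragment pool used to
explain experimental peaks.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

from rdkit import Chem
from rdkit.Chem import RWMol

from .flavochem import CompoundTemplate, compound_formula, registry
from .formulae import F, Formula

__all__ = ["template_mol", "insilico_fragments"]

_SUB_SMILES = {"hydroxyl": "O", "methoxyl": "OC", "methyl": "C"}


def _decorate(mol: RWMol, sites: list[int], subs: dict[str, int]) -> None:
    queue = [k for k, n in sorted(subs.items()) for _ in range(n)]
    if len(queue) > len(sites):
        raise ValueError(
            f"not enough free ring positions ({len(sites)}) for {queue}"
        )
    for kind, site in zip(queue, sites):
        site_atom = mol.GetAtomWithIdx(site)
        site_atom.SetNumExplicitHs(0)  # the new substituent replaces the ring H
        site_atom.SetNoImplicit(True)
        first = None
        for symbol in _SUB_SMILES[kind]:
            idx = mol.AddAtom(Chem.Atom(symbol))
            if first is None:
                mol.AddBond(site, idx, Chem.BondType.SINGLE)
                first = idx
            else:
                mol.AddBond(first, idx, Chem.BondType.SINGLE)


def template_mol(t: CompoundTemplate) -> Chem.Mol:
    """RDKit molecule of a decorated template (H-complete, sanitized)."""
    skel = registry()[t.skeleton]
    base = Chem.MolFromSmiles(skel.smiles)
    if base is None:
        raise ValueError(f"{t.skeleton}: skeleton SMILES failed to parse")
    sites_a = [a.GetIdx() for a in base.GetAtoms() if a.GetAtomMapNum() == 1]
    sites_b = [a.GetIdx() for a in base.GetAtoms() if a.GetAtomMapNum() == 2]
    mol = RWMol(base)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    _decorate(mol, sites_a, dict(t.ring_a))
    _decorate(mol, sites_b, dict(t.ring_b))
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def _component_formulas(mol: Chem.Mol, drop_bonds: tuple[int, ...]) -> list[Formula]:
    em = RWMol(mol)
    pairs = []
    for b_idx in drop_bonds:
        b = mol.GetBondWithIdx(b_idx)
        pairs.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
    for i, j in pairs:
        em.RemoveBond(i, j)
    frags = Chem.GetMolFrags(em.GetMol(), asMols=False)
    out = []
    for atom_ids in frags:
        counts: dict[str, int] = {}
        for idx in atom_ids:
            sym = em.GetAtomWithIdx(idx).GetSymbol()
            counts[sym] = counts.get(sym, 0) + 1
        out.append(Formula(counts))
    return out


@lru_cache(maxsize=256)
def _fragments_cached(skeleton: str, ring_a: tuple, ring_b: tuple,
                      max_breaks: int) -> frozenset:
    t = CompoundTemplate("tmp", skeleton, dict(ring_a), dict(ring_b))
    return frozenset(str(f) for f in _enumerate(template_mol(t), max_breaks))


def _enumerate(mol: Chem.Mol, max_breaks: int) -> set[Formula]:
    molh = Chem.AddHs(mol)
    heavy_bonds = [
        b.GetIdx()
        for b in molh.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]
    ring_info = molh.GetRingInfo()
    acyclic = [i for i in heavy_bonds if ring_info.NumBondRings(i) == 0]
    ring_bonds = [i for i in heavy_bonds if ring_info.NumBondRings(i) > 0]

    cut_sets: list[tuple[int, ...]] = [()]
    if max_breaks >= 1:
        cut_sets += [(i,) for i in acyclic]
    if max_breaks >= 2:
        cut_sets += [tuple(c) for c in combinations(acyclic, 2)]
        for ring in ring_info.BondRings():
            in_ring = [i for i in ring if i in ring_bonds]
            cut_sets += [tuple(sorted(c)) for c in combinations(in_ring, 2)]

    seen: set[Formula] = set()
    for cuts in set(cut_sets):
        for f in _component_formulas(molh, cuts):
            if f["C"] == 0:
                continue  # bare substituent oxygens etc. are not ions
            for dh in (-1, 0, 1):
                if dh < 0:
                    try:
                        seen.add(f - F("H"))
                    except ValueError:
                        pass
                elif dh > 0:
                    seen.add(f + F("H"))
                else:
                    seen.add(f)
    return {f for f in seen if f}


def insilico_fragments(t: CompoundTemplate, max_breaks: int = 2) -> set[Formula]:
    """All fragment formulas reachable by <= ``max_breaks`` bond cuts.

    Breaks are deletions of acyclic heavy-atom bonds; a pair of bonds
    within one ring (counting as two breaks) opens that ring.  Each
    fragment is emitted with -1/0/+1 hydrogen-transfer variants.
    ``max_breaks=0`` returns the intact molecule (with H variants).
    """
    if max_breaks not in (0, 1, 2):
        raise ValueError("max_breaks must be 0, 1 or 2")
    mol = template_mol(t)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"{t.name}: molecular graph is disconnected")
    key = (
        t.skeleton,
        tuple(sorted(t.ring_a.items())),
        tuple(sorted(t.ring_b.items())),
        max_breaks,
    )
    return {F(s) for s in _fragments_cached(*key)}
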