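"""Fragmentation trees: formula-annotate fragment peaks and connect them
by neutral-loss edges.

Every fragment of a singly charged precursor must be a subformula of the
precursor cation, so peak annotation is an exhaustive subformula search
minimizing absolute mass error within tolerance.  Tree construction is a
deterministic best-parent heuristic: each node attaches to the heavier
node that explains it most cheaply — a loss composable from at most two
common small losses (CO, H2O, CH2O, C2H2O, CH3, CH4, CO2, styrene C8H8)
beats an arbitrary loss, then smaller loss mass wins.  The result is
always a tree rooted at the precursor, read out as a neutral-loss
summary rather than an optimally scored graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import pandas as pd

from .formulae import F, Formula, IonSpec, ion_mz
from .spectra import Peak, Spectrum

__all__ = ["FragNode", "FragEdge", "FragmentationTree", "COMMON_LOSSES",
           "annotate_peaks", "build_tree", "tree_losses"]

#: Losses treated as "cheap" edges; the styryl loss C8H8 is characteristic
#: of dihydro-C-ring flavonoids.
COMMON_LOSSES: tuple[Formula, ...] = tuple(
    F(s) for s in ("CO", "H2O", "CH2O", "C2H2O", "CH3", "CH4", "CO2", "C8H8")
)


@dataclass(frozen=True)
class FragNode:
    peak: Peak
    formula: Formula  # cation composition
    error_mda: float

    @property
    def mz(self) -> float:
        return self.peak.mz


@dataclass(frozen=True)
class FragEdge:
    parent: FragNode
    child: FragNode
    loss: Formula


@dataclass(frozen=True)
class FragmentationTree:
    root: FragNode
    nodes: tuple[FragNode, ...]  # includes the root
    edges: tuple[FragEdge, ...]
    unannotated: tuple[Peak, ...]

    def to_outline(self) -> str:
        """Indented text rendering, children by descending m/z."""
        children: dict[int, list[FragEdge]] = {}
        for e in self.edges:
            children.setdefault(id(e.parent), []).append(e)
        lines: list[str] = []

        def walk(node: FragNode, depth: int, loss: Optional[Formula]) -> None:
            tag = f"  -{loss} -> " if loss is not None else ""
            lines.append(
                "  " * depth
                + f"{tag}{node.formula}+ m/z {node.mz:.4f} "
                f"({node.error_mda:+.1f} mDa)"
            )
            for e in sorted(children.get(id(node), []),
                            key=lambda e: -e.child.mz):
                walk(e.child, depth + 1, e.loss)

        walk(self.root, 0, None)
        return "\n".join(lines)

    def to_edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parent_mz": e.parent.mz,
                    "child_mz": e.child.mz,
                    "loss": str(e.loss),
                    "loss_mass": ion_mz(IonSpec(e.parent.formula, "cation"))
                    - ion_mz(IonSpec(e.child.formula, "cation")),
                }
                for e in self.edges
            ],
            columns=["parent_mz", "child_mz", "loss", "loss_mass"],
        )


def _subformulas(cation: Formula):
    # fragment ions of an organic precursor must contain carbon
    cs, hs, os_ = cation["C"], cation["H"], cation["O"]
    for c in range(1, cs + 1):
        for h in range(hs + 1):
            for o in range(os_ + 1):
                yield Formula({"C": c, "H": h, "O": o})


def annotate_peaks(
    spectrum: Spectrum,
    precursor_cation: Formula,
    tol_mda: float = 10.0,
) -> tuple[list[FragNode], list[Peak]]:
    """Assign each peak the precursor subformula of least |mass error|.

    ``precursor_cation`` is the composition of the charged precursor
    (e.g. C15H13O4 for a protonated C15H12O4 molecule); it must agree
    with the spectrum's precursor m/z within tolerance.  Peaks without
    any subformula inside the window are returned unannotated.
    """
    tol = tol_mda / 1000.0
    root_mz = ion_mz(IonSpec(precursor_cation, "cation"))
    if abs(root_mz - spectrum.precursor_mz) > tol:
        raise ValueError(
            f"precursor cation {precursor_cation} ({root_mz:.4f}) does not "
            f"match precursor m/z {spectrum.precursor_mz:.4f} at {tol_mda} mDa"
        )
    candidates = [
        (f, ion_mz(IonSpec(f, "cation"))) for f in _subformulas(precursor_cation)
    ]
    candidates.sort(key=lambda t: t[1])
    nodes: list[FragNode] = []
    unannotated: list[Peak] = []
    for p in spectrum.peaks:
        best: Optional[tuple[float, Formula]] = None
        for f, mz in candidates:
            err = abs(mz - p.mz)
            if err <= tol and (best is None or err < best[0]):
                best = (err, f)
        if best is None:
            unannotated.append(p)
        else:
            signed = 1000.0 * (p.mz - ion_mz(IonSpec(best[1], "cation")))
            nodes.append(FragNode(peak=p, formula=best[1], error_mda=signed))
    return nodes, unannotated


def _composable(loss: Formula, commons: Sequence[Formula]) -> bool:
    if any(loss == c for c in commons):
        return True
    return any(
        loss == a + b for a, b in combinations_with_replacement(commons, 2)
    )


def _is_radical_loss(loss: Formula) -> bool:
    # closed-shell CHO neutrals carry an even hydrogen count; an odd count
    # (CH3, OH) marks a radical loss
    return loss["H"] % 2 == 1


def build_tree(
    spectrum: Spectrum,
    precursor_cation: Formula,
    tol_mda: float = 10.0,
    common_losses: Sequence[Formula] = COMMON_LOSSES,
    max_radical_losses: int = 1,
) -> FragmentationTree:
    """Annotate a spectrum and wire the nodes into a fragmentation tree.

    Nodes are attached in descending m/z; each attaches to the already
    placed heavier node minimizing (non-common loss, loss mass), with the
    even-electron rule limiting radical losses per root path.  A node with
    no feasible parent attaches directly to the root with the composite
    loss.  Ties break on smaller |mass error|, then input order — the
    whole construction is deterministic.
    """
    nodes, unannotated = annotate_peaks(spectrum, precursor_cation, tol_mda)
    root_mz = ion_mz(IonSpec(precursor_cation, "cation"))
    root: Optional[FragNode] = None
    rest: list[FragNode] = []
    for n in nodes:
        if n.formula == precursor_cation and root is None:
            root = n
        else:
            rest.append(n)
    if root is None:
        root = FragNode(
            peak=Peak(root_mz, 0.0), formula=precursor_cation, error_mda=0.0
        )
    order = sorted(
        range(len(rest)), key=lambda i: (-rest[i].mz, abs(rest[i].error_mda), i)
    )
    placed: list[FragNode] = [root]
    radicals_used: dict[int, int] = {id(root): 0}
    edges: list[FragEdge] = []
    for i in order:
        child = rest[i]
        best = None  # (cost tuple, parent, loss)
        for parent in placed:
            try:
                loss = parent.formula - child.formula
            except ValueError:
                continue
            if not loss:
                continue
            if loss["C"] == 0 and loss["O"] == 0 and loss["H"] > 2:
                continue  # bare H3+ losses are not chemistry, only jitter
            radical = _is_radical_loss(loss)
            if radical and radicals_used[id(parent)] >= max_radical_losses:
                continue
            cost = (
                0 if _composable(loss, common_losses) else 1,
                sum(n * {"C": 12.0, "H": 1.008, "O": 15.995}.get(s, 20.0)
                    for s, n in loss),
            )
            if best is None or cost < best[0]:
                best = (cost, parent, loss, radical)
        if best is None:
            # no embeddable parent at all: attach to root via composite loss
            loss = root.formula - child.formula
            if not loss:  # duplicate precursor-formula peak: not a fragment
                unannotated.append(child.peak)
                rest[i] = None  # type: ignore[call-overload]
                continue
            parent, radical = root, False
        else:
            _, parent, loss, radical = best
        edges.append(FragEdge(parent=parent, child=child, loss=loss))
        radicals_used[id(child)] = radicals_used[id(parent)] + (1 if radical else 0)
        placed.append(child)
    kept = tuple(n for n in rest if n is not None)
    return FragmentationTree(
        root=root,
        nodes=(root, *kept),
        edges=tuple(edges),
        unannotated=tuple(unannotated),
    )


def tree_losses(tree: FragmentationTree) -> list[Formula]:
    """Multiset of neutral-loss formulas over all edges."""
    return [e.loss for e in tree.edges]
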