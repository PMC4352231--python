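"""Hybridization designs for two-colour interwoven-loop microarray experiments.

A two-colour experiment is a directed multigraph: nodes are RNA populations,
edges are arrays, and the edge direction records which sample was labelled
with cy3 (tail) and which with cy5 (head).  Interwoven loops connect every
population through dye-swapped paths, so all pairwise contrasts are estimable
from within-array log ratios without a common reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Hybridization",
    "HybridizationDesign",
    "DesignError",
    "loop_design",
    "vk_design_2011",
    "vk_design_2012",
]


class DesignError(ValueError):
    """Raised for disconnected, self-looped or rank-deficient designs."""


@dataclass(frozen=True)
class Hybridization:
    """One array: a cy3-labelled and a cy5-labelled sample co-hybridized."""

    array_id: str
    cy3_sample: str
    cy5_sample: str
    replicate: int = 1


class HybridizationDesign:
    """An interwoven-loop design: populations as nodes, arrays as edges.

    Parameters
    ----------
    hybridizations
        One :class:`Hybridization` per array.  The undirected graph they
        induce must be connected; an array hybridizing a sample against
        itself is rejected.
    """

    def __init__(self, hybridizations: Iterable[Hybridization]):
        self.hybridizations = list(hybridizations)
        if not self.hybridizations:
            raise DesignError("design has no hybridizations")
        for h in self.hybridizations:
            if h.cy3_sample == h.cy5_sample:
                raise DesignError(
                    f"array {h.array_id!r} hybridizes {h.cy3_sample!r} against itself"
                )
        ids = [h.array_id for h in self.hybridizations]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate array_id in design")
        comps = self._components()
        if len(comps) > 1:
            raise DesignError(
                "design graph is disconnected; components: "
                + "; ".join(",".join(sorted(c)) for c in comps)
            )

    # -- graph structure ---------------------------------------------------

    @property
    def populations(self) -> list[str]:
        pops: set[str] = set()
        for h in self.hybridizations:
            pops.update((h.cy3_sample, h.cy5_sample))
        return sorted(pops)

    @property
    def array_ids(self) -> list[str]:
        return [h.array_id for h in self.hybridizations]

    def _components(self) -> list[set[str]]:
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h in self.hybridizations:
            parent[find(h.cy3_sample)] = find(h.cy5_sample)
        comps: dict[str, set[str]] = {}
        for p in {x for h in self.hybridizations for x in (h.cy3_sample, h.cy5_sample)}:
            comps.setdefault(find(p), set()).add(p)
        return list(comps.values())

    # -- model matrix ------------------------------------------------------

    def design_matrix(
        self, reference: str | None = None, dye_effect: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Fixed-effects model matrix for per-array log ratios M.

        E[M_h] = beta[cy5 population] - beta[cy3 population] (+ delta for the
        cy5 dye if ``dye_effect``), with the reference population's effect
        fixed at zero.  Row order follows ``hybridizations``; returns the
        matrix and its column labels (population names, then ``"dye"``).
        """
        pops = self.populations
        if reference is None:
            reference = pops[0]
        if reference not in pops:
            raise DesignError(f"reference population {reference!r} not in design")
        cols = [p for p in pops if p != reference]
        ncol = len(cols) + (1 if dye_effect else 0)
        X = np.zeros((len(self.hybridizations), ncol))
        idx = {p: j for j, p in enumerate(cols)}
        for i, h in enumerate(self.hybridizations):
            if h.cy5_sample != reference:
                X[i, idx[h.cy5_sample]] += 1.0
            if h.cy3_sample != reference:
                X[i, idx[h.cy3_sample]] -= 1.0
            if dye_effect:
                X[i, -1] = 1.0
        labels = cols + (["dye"] if dye_effect else [])
        rank = np.linalg.matrix_rank(X)
        if rank < ncol:
            raise DesignError(
                f"design matrix is rank deficient (rank {rank} < {ncol}); "
                "some population effects are inestimable"
            )
        return X, labels

    def contrast_vector(
        self, a: str, b: str, labels: Sequence[str], reference: str
    ) -> np.ndarray:
        """Coefficient vector for the contrast log2(a/b) = beta_a - beta_b."""
        for p in (a, b):
            if p not in self.populations:
                raise DesignError(f"population {p!r} not in design")
        c = np.zeros(len(labels))
        lab = list(labels)
        if a != reference:
            c[lab.index(a)] += 1.0
        if b != reference:
            c[lab.index(b)] -= 1.0
        return c

    # -- (de)serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": [h.array_id for h in self.hybridizations],
                "cy3_sample": [h.cy3_sample for h in self.hybridizations],
                "cy5_sample": [h.cy5_sample for h in self.hybridizations],
                "replicate": [h.replicate for h in self.hybridizations],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HybridizationDesign":
        return cls(
            Hybridization(
                str(r.array_id), str(r.cy3_sample), str(r.cy5_sample), int(r.replicate)
            )
            for r in frame.itertuples(index=False)
        )

    def __len__(self) -> int:
        return len(self.hybridizations)

    def __repr__(self) -> str:
        return (
            f"HybridizationDesign({len(self)} arrays, "
            f"{len(self.populations)} populations)"
        )


def loop_design(
    edges: Sequence[tuple[str, str]],
    n_replicates: int = 3,
    dye_swap: bool = True,
    prefix: str = "A",
) -> HybridizationDesign:
    """Build an interwoven loop with ``n_replicates`` arrays per edge.

    Each edge (a, b) is hybridized ``n_replicates`` times; with ``dye_swap``
    the dye orientation alternates between replicates (a->b, b->a, a->b, ...),
    which is what makes a common dye coefficient estimable.
    """
    hybs = []
    k = 0
    for a, b in edges:
        for r in range(1, n_replicates + 1):
            k += 1
            if dye_swap and r % 2 == 0:
                cy3, cy5 = b, a
            else:
                cy3, cy5 = a, b
            hybs.append(Hybridization(f"{prefix}{k:03d}", cy3, cy5, r))
    return HybridizationDesign(hybs)


def vk_design_2011(n_replicates: int = 3) -> HybridizationDesign:
    """The 2011 triangle: deltamethrin-selected VK7 (VKR), unexposed VK7
    (VKC) and the Mali susceptible colony (MAL), three dye-swapped
    replicates per comparison."""
    edges = [
        ("VKC2011", "VKR2011"),
        ("VKR2011", "MAL2011"),
        ("MAL2011", "VKC2011"),
    ]
    return loop_design(edges, n_replicates=n_replicates, prefix="H11_")


def vk_design_2012(n_replicates: int = 3) -> HybridizationDesign:
    """The 2012 four-population interwoven loop: selected VK7 (VKR),
    unexposed Tengrela (TEN) and two susceptible colonies (MAL, NG)."""
    edges = [
        ("VKR2012", "TEN2012"),
        ("TEN2012", "MAL2012"),
        ("MAL2012", "NG2012"),
        ("NG2012", "VKR2012"),
        ("VKR2012", "MAL2012"),
        ("TEN2012", "NG2012"),
    ]
    return loop_design(edges, n_replicates=n_replicates, prefix="H12_")
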