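"""Hypothesis-driven candidate-gene filtering of merged contrast tables.

The filtering schema encodes three biological hypotheses about genes
driving the escalating resistance phenotype:

* steps A-C — consistently over-expressed, at FDR q below threshold, in
  every resistant-field-vs-susceptible-colony comparison (2011 VK7/MAL,
  2012 VK7/MAL, 2012 VK7/NG);
* step E — a larger VK7/MAL fold change in 2012 than in 2011 (resistance
  rose sharply between the two collections; point-estimate comparison,
  no test on the difference);
* step D — significantly over-expressed in VK7 relative to the moderately
  resistant Tengrela population.

Steps are intersective, so the final probe set is order-independent;
intermediate counts are reported in the order A-C, E, D.  Surviving probes
are collapsed to genes (arithmetic mean of per-probe fold change on the
natural scale), and a mirrored list of consistently *down*-regulated probes
(all sign rules reversed, no year condition) is produced alongside.

Probes whose q-value is undefined (exact fit on zero-noise data) pass the
significance gate and are flagged; the strict sign rules then decide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .de import contrast_label

__all__ = [
    "CascadeConfig",
    "CascadeResult",
    "step_up_consistent",
    "step_year_increase",
    "step_vk7_over_ten",
    "collapse_probes_to_genes",
    "down_regulated_mirror",
    "cluster_candidates",
    "run_cascade",
]


@dataclass
class CascadeConfig:
    """Thresholds and contrast labels the cascade filters on."""

    q_threshold: float = 0.05
    #: resistant-field vs susceptible-colony contrasts (steps A-C, in order)
    resistant_vs_susceptible_contrasts: tuple[str, ...] = (
        contrast_label("VKR2011", "MAL2011"),
        contrast_label("VKR2012", "MAL2012"),
        contrast_label("VKR2012", "NG2012"),
    )
    vk7_vs_ten_contrast: str = contrast_label("VKR2012", "TEN2012")
    #: (2012 VK7/MAL, 2011 VK7/MAL) — step E keeps probes whose first
    #: fold change exceeds the second
    year_pair_for_step_E: tuple[str, str] = (
        contrast_label("VKR2012", "MAL2012"),
        contrast_label("VKR2011", "MAL2011"),
    )
    #: 'all' requires q < threshold in every A-C contrast; 'any' in at least one
    significance_mode: str = "all"
    #: contrast whose fold change is reported in the gene table
    fc_contrast: str = contrast_label("VKR2012", "MAL2012")
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.significance_mode not in ("all", "any"):
            raise ValueError("significance_mode must be 'all' or 'any'")

    def validate_against(self, contrasts: pd.DataFrame) -> None:
        present = set(contrasts["contrast"].unique())
        needed = {
            *self.resistant_vs_susceptible_contrasts,
            self.vk7_vs_ten_contrast,
            *self.year_pair_for_step_E,
        }
        missing = sorted(needed - present)
        if missing:
            raise ValueError(f"contrast table is missing contrasts: {missing}")


@dataclass
class CascadeResult:
    """Nested probe sets per step plus the gene-collapsed outputs."""

    surviving_probes_per_step: dict[str, set[str]]
    candidate_probes: set[str]
    candidate_genes: pd.DataFrame
    down_regulated_probes: set[str]
    down_regulated_genes: pd.DataFrame
    excluded_probes: dict[str, set[str]] = field(default_factory=dict)

    @property
    def step_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.surviving_probes_per_step.items()}


def _wide(contrasts: pd.DataFrame, value: str) -> pd.DataFrame:
    # pivot (not pivot_table) so all-NaN columns, e.g. q on exact-fit data,
    # survive the reshape
    dedup = contrasts.drop_duplicates(subset=["probe_id", "contrast"])
    return dedup.pivot(index="probe_id", columns="contrast", values=value)


def _sig_ok(q: pd.DataFrame, labels: list[str], thr: float, mode: str) -> pd.Series:
    """Significance gate over several contrasts; NaN q passes (flagged
    upstream as an exact fit, carrying no evidence against the probe)."""
    per = q[labels].lt(thr) | q[labels].isna()
    return per.all(axis=1) if mode == "all" else (
        q[labels].lt(thr).any(axis=1) | q[labels].isna().all(axis=1)
    )


def step_up_consistent(contrasts: pd.DataFrame, config: CascadeConfig) -> set[str]:
    """Steps A-C: up in every resistant-vs-susceptible contrast, q below
    threshold (per ``significance_mode``).  Probes missing any configured
    contrast are excluded, not errors."""
    labels = list(config.resistant_vs_susceptible_contrasts)
    fc = _wide(contrasts, "log2FC")
    q = _wide(contrasts, "q")
    missing_lab = [c for c in labels if c not in fc.columns]
    if missing_lab:
        raise ValueError(f"contrast table is missing contrasts: {missing_lab}")
    have = fc[labels].notna().all(axis=1)
    up = fc[labels].gt(0.0).all(axis=1)
    sig = _sig_ok(q, labels, config.q_threshold, config.significance_mode)
    return set(fc.index[have & up & sig])


def step_year_increase(
    survivors: set[str], contrasts: pd.DataFrame, config: CascadeConfig
) -> set[str]:
    """Step E: strictly larger VK7/MAL log2FC in 2012 than in 2011."""
    new, old = config.year_pair_for_step_E
    fc = _wide(contrasts, "log2FC")
    for lab in (new, old):
        if lab not in fc.columns:
            raise ValueError(f"contrast table is missing contrast: {lab}")
    keep = fc.index[(fc[new] > fc[old]) & fc[new].notna() & fc[old].notna()]
    return survivors & set(keep)


def step_vk7_over_ten(
    survivors: set[str], contrasts: pd.DataFrame, config: CascadeConfig
) -> set[str]:
    """Step D: significantly over-expressed in VK7 relative to Tengrela."""
    lab = config.vk7_vs_ten_contrast
    fc = _wide(contrasts, "log2FC")
    q = _wide(contrasts, "q")
    if lab not in fc.columns:
        raise ValueError(f"contrast table is missing contrast: {lab}")
    ok = (fc[lab] > 0.0) & (q[lab].lt(config.q_threshold) | q[lab].isna())
    return survivors & set(fc.index[ok & fc[lab].notna()])


def collapse_probes_to_genes(
    probes: set[str],
    probe_gene_map: pd.DataFrame,
    contrasts: pd.DataFrame,
    fc_contrast: str,
) -> pd.DataFrame:
    """Collapse a probe set to unique genes.

    Fold change is aggregated as the arithmetic mean of per-probe fold
    changes on the natural (de-logged) scale.  Probes absent from the map
    are retained under their own probe_id as the gene identifier.

    Returns a gene table with columns ``gene_id, mean_FC, n_probes``.
    """
    if not probes:
        return pd.DataFrame(columns=["gene_id", "mean_FC", "n_probes"])
    mapping = probe_gene_map.set_index("probe_id")["gene_id"]
    fc = (
        contrasts.loc[contrasts["contrast"] == fc_contrast]
        .set_index("probe_id")["log2FC"]
    )
    rows = []
    for p in sorted(probes):
        gene = mapping.get(p, p)
        rows.append((p, gene, float(2.0 ** fc.get(p, np.nan))))
    df = pd.DataFrame(rows, columns=["probe_id", "gene_id", "FC"])
    out = (
        df.groupby("gene_id")
        .agg(mean_FC=("FC", "mean"), n_probes=("FC", "size"))
        .reset_index()
        .sort_values("mean_FC", ascending=False, ignore_index=True)
    )
    return out


def down_regulated_mirror(
    contrasts: pd.DataFrame, config: CascadeConfig
) -> set[str]:
    """Mirror list: down in every resistant-vs-susceptible contrast and
    down in VK7-vs-TEN, with the same significance gates; no year step."""
    labels = list(config.resistant_vs_susceptible_contrasts)
    ten = config.vk7_vs_ten_contrast
    fc = _wide(contrasts, "log2FC")
    q = _wide(contrasts, "q")
    missing_lab = [c for c in (*labels, ten) if c not in fc.columns]
    if missing_lab:
        raise ValueError(f"contrast table is missing contrasts: {missing_lab}")
    have = fc[[*labels, ten]].notna().all(axis=1)
    down = fc[labels].lt(0.0).all(axis=1)
    sig = _sig_ok(q, labels, config.q_threshold, config.significance_mode)
    ten_ok = (fc[ten] < 0.0) & (q[ten].lt(config.q_threshold) | q[ten].isna())
    return set(fc.index[have & down & sig & ten_ok])


def cluster_candidates(
    fc_profiles: pd.DataFrame, linkage: str = "average"
) -> dict:
    """Hierarchical clustering of candidate probes by expression profile.

    ``fc_profiles`` is a probes x contrasts matrix of log2 fold changes
    (typically the three VK7-vs-susceptible comparisons).  Agglomerative
    clustering with Euclidean distance; rows are sorted by probe_id before
    linkage so ties break lexicographically and the output is deterministic.

    Returns ``{"linkage": Z, "leaves": [probe_id...], "probe_ids": [...],
    "newick": str}``; a single probe yields a degenerate single-leaf tree.
    """
    prof = fc_profiles.sort_index()
    ids = list(prof.index)
    if prof.isna().any().any():
        raise ValueError("profile matrix must be complete for clustered probes")
    if len(ids) < 2:
        return {
            "linkage": np.empty((0, 4)),
            "leaves": ids,
            "probe_ids": ids,
            "newick": (ids[0] + ";") if ids else ";",
        }
    Z = hierarchy.linkage(pdist(prof.to_numpy()), method=linkage)
    leaves = [ids[i] for i in hierarchy.leaves_list(Z)]
    return {
        "linkage": Z,
        "leaves": leaves,
        "probe_ids": ids,
        "newick": _to_newick(Z, ids),
    }


def _to_newick(Z: np.ndarray, ids: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - (0.0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0.0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def run_cascade(
    contrasts: pd.DataFrame,
    config: CascadeConfig,
    probe_gene_map: pd.DataFrame | None = None,
) -> CascadeResult:
    """Run the full filtering cascade on a merged contrast table.

    Steps are applied in reporting order A-C, E, D (the final set is the
    same for any order of these intersective filters); the surviving probes
    are collapsed to genes and the down-regulated mirror is computed.
    """
    config.validate_against(contrasts)
    if probe_gene_map is None:
        probe_gene_map = pd.DataFrame(columns=["probe_id", "gene_id"])
    s_abc = step_up_consistent(contrasts, config)
    s_e = step_year_increase(s_abc, contrasts, config)
    s_d = step_vk7_over_ten(s_e, contrasts, config)
    genes = collapse_probes_to_genes(
        s_d, probe_gene_map, contrasts, config.fc_contrast
    )
    down = down_regulated_mirror(contrasts, config)
    down_genes = collapse_probes_to_genes(
        down, probe_gene_map, contrasts, config.fc_contrast
    )
    return CascadeResult(
        surviving_probes_per_step={"A-C": s_abc, "E": s_e, "D": s_d},
        candidate_probes=s_d,
        candidate_genes=genes,
        down_regulated_probes=down,
        down_regulated_genes=down_genes,
    )
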