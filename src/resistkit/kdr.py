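"""kdr target-site resistance: allele frequencies, exact association tests,
two-locus EM haplotype phasing and haplotype-survival odds ratios.

The two loci are the voltage-gated sodium channel mutations L1014F and
N1575Y.  Unphased genotypes are coded ``LL/LF/FF`` and ``NN/NY/YY``.  The
only phase-ambiguous genotype class is the double heterozygote LF/NY, which
may carry {L-N, F-Y} or {L-Y, F-N}; EM under Hardy-Weinberg random pairing
resolves it.  In the field, 1575Y occurs exclusively on a 1014F background,
so the L-Y haplotype frequency is structurally (near) zero — the EM does not
assume this, it estimates it.

Odds-ratio orientation everywhere: OR > 1 means the allele/haplotype
increases the odds of SURVIVING insecticide exposure (survivors are cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "HAPLOTYPES",
    "AlleleCountRow",
    "AlleleFrequencyResult",
    "HaplotypeFreqs",
    "allele_frequency",
    "fisher_survival_test",
    "chi_square_homogeneity",
    "genotype_counts",
    "em_haplotype_frequencies",
    "haplotype_association",
]

HAPLOTYPES = ("L-N", "L-Y", "F-N", "F-Y")

_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class AlleleCountRow:
    """Allele counts for one locus in one collection round / status group."""

    site: str
    round: str
    status: str  # control | dead | survivor
    locus: str  # L1014F | N1575Y
    count_wildtype: int
    count_mutant: int

    def __post_init__(self) -> None:
        if self.count_wildtype < 0 or self.count_mutant < 0:
            raise ValueError("allele counts must be >= 0")

    @property
    def n_alleles(self) -> int:
        return self.count_wildtype + self.count_mutant


@dataclass(frozen=True)
class AlleleFrequencyResult:
    f: float
    ci_low: float
    ci_high: float
    method: str
    conf: float


def allele_frequency(
    row: AlleleCountRow,
    ci_method: str = "clopper_pearson",
    conf: float = 0.95,
) -> AlleleFrequencyResult:
    """Mutant allele frequency with a binomial confidence interval.

    Clopper-Pearson (exact, beta quantiles) is the default; Wilson score
    available.  Frequencies are returned at full precision; rounding to the
    3 decimals used in reports is a presentation concern.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    n = row.n_alleles
    if n == 0:
        raise ValueError("cannot estimate a frequency from zero alleles")
    f = row.count_mutant / n
    lo, hi = proportion_confint(
        row.count_mutant, n, alpha=1.0 - conf, method=_CI_METHODS[ci_method]
    )
    # boundary counts have one-sided intervals reaching 0/1 exactly
    lo = 0.0 if row.count_mutant == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if row.count_mutant == n else float(np.clip(hi, 0.0, 1.0))
    return AlleleFrequencyResult(f, lo, hi, ci_method, conf)


def fisher_survival_test(
    dead: AlleleCountRow, survivor: AlleleCountRow
) -> tuple[float, float]:
    """Two-tailed Fisher exact test of allele frequency between outcome arms.

    Returns ``(p_two_tailed, odds_ratio)`` where the odds ratio is the
    sample cross-product ratio oriented so that OR > 1 means the mutant
    allele increases survival odds; Haldane's 0.5 continuity correction is
    applied only when the table contains a zero cell.
    """
    for attr in ("locus", "site", "round"):
        if getattr(dead, attr) != getattr(survivor, attr):
            raise ValueError(
                f"rows disagree on {attr}: "
                f"{getattr(dead, attr)!r} vs {getattr(survivor, attr)!r}"
            )
    table = np.array(
        [
            [survivor.count_mutant, survivor.count_wildtype],
            [dead.count_mutant, dead.count_wildtype],
        ],
        dtype=float,
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table + 0.5 if (table == 0).any() else table
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(p), float(odds_ratio)


def chi_square_homogeneity(
    rows: list[AlleleCountRow],
) -> tuple[float, int, float, bool]:
    """Pearson chi-square for homogeneity of allele frequency across groups.

    Returns ``(statistic, df, p, low_expected_warning)``; the warning flags
    any expected cell count below 1 (the statistic is still computed).
    """
    if len(rows) < 2:
        raise ValueError("need at least two groups")
    loci = {r.locus for r in rows}
    if len(loci) > 1:
        raise ValueError(f"rows mix loci: {sorted(loci)}")
    table = np.array([[r.count_wildtype, r.count_mutant] for r in rows], dtype=float)
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p), bool((expected < 1).any())


# ---------------------------------------------------------------------------
# two-locus EM


def genotype_counts(
    genotypes: pd.DataFrame, allow_triallelic: bool = False
) -> np.ndarray:
    """3x3 genotype count matrix (rows: F copies 0/1/2; cols: Y copies).

    Specimens with a missing genotype at either locus are dropped.  An
    observed 1014S allele (codes containing ``S``) raises unless
    ``allow_triallelic`` collapses S with the wildtype L.
    """
    g1 = genotypes["genotype_1014"].astype("string")
    g2 = genotypes["genotype_1575"].astype("string")
    if g1.str.contains("S", na=False).any():
        if not allow_triallelic:
            raise ValueError(
                "observed 1014S allele; pass allow_triallelic=True to collapse S with L"
            )
        g1 = g1.str.replace("S", "L")
        g1 = g1.map(lambda s: "".join(sorted(s, key="LF".index)) if pd.notna(s) else s)
    ok = g1.isin(["LL", "LF", "FF"]) & g2.isin(["NN", "NY", "YY"])
    counts = np.zeros((3, 3), dtype=float)
    f_of = {"LL": 0, "LF": 1, "FF": 2}
    y_of = {"NN": 0, "NY": 1, "YY": 2}
    for a, b in zip(g1[ok], g2[ok]):
        counts[f_of[a], y_of[b]] += 1
    return counts


# fixed haplotype contributions of each unambiguous genotype class
# (i F copies, j Y copies) -> counts over (L-N, L-Y, F-N, F-Y)
_FIXED = {
    (0, 0): (2, 0, 0, 0),
    (0, 1): (1, 1, 0, 0),
    (0, 2): (0, 2, 0, 0),
    (1, 0): (1, 0, 1, 0),
    (1, 2): (0, 1, 0, 1),
    (2, 0): (0, 0, 2, 0),
    (2, 1): (0, 0, 1, 1),
    (2, 2): (0, 0, 0, 2),
}


@dataclass
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies."""

    frequencies: dict[str, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.frequencies[h] for h in HAPLOTYPES])


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    ll = 0.0
    f = dict(zip(HAPLOTYPES, p))
    for (i, j), contrib in _FIXED.items():
        n = counts[i, j]
        if n == 0:
            continue
        h = [k for k, c in zip(HAPLOTYPES, contrib) for _ in range(c)]
        prob = f[h[0]] * f[h[1]] * (2.0 if h[0] != h[1] else 1.0)
        ll += n * (np.log(prob) if prob > 0 else -np.inf)
    n_dh = counts[1, 1]
    if n_dh > 0:
        prob = 2.0 * (f["L-N"] * f["F-Y"] + f["L-Y"] * f["F-N"])
        ll += n_dh * (np.log(prob) if prob > 0 else -np.inf)
    return float(ll)


def em_haplotype_frequencies(
    genotypes: pd.DataFrame | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    allow_triallelic: bool = False,
) -> HaplotypeFreqs:
    """Two-locus haplotype frequencies by EM gene counting.

    Accepts a genotype table (or a precomputed 3x3 count matrix).  All
    genotype classes except the double heterozygote contribute fixed
    haplotype counts; the double-heterozygote class is split between its
    two phase resolutions in the E step (initially 50/50) and frequencies
    are re-estimated in the M step.  Iterates until the largest absolute
    frequency change falls below ``tol`` or ``max_iter`` is reached (the
    result is then flagged unconverged, not discarded).  The log-likelihood
    trace is recorded and is non-decreasing.
    """
    counts = (
        genotypes
        if isinstance(genotypes, np.ndarray)
        else genotype_counts(genotypes, allow_triallelic=allow_triallelic)
    )
    n = counts.sum()
    if n == 0:
        raise ValueError("no specimens with complete genotypes at both loci")
    fixed = np.zeros(4)
    for (i, j), contrib in _FIXED.items():
        fixed += counts[i, j] * np.asarray(contrib, dtype=float)
    n_dh = counts[1, 1]

    w = 0.5  # share of double heterozygotes phased as {L-N, F-Y}
    p = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
    p = p / (2.0 * n)

    trace = [_loglik(counts, p)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        a = p[0] * p[3]  # L-N * F-Y
        b = p[1] * p[2]  # L-Y * F-N
        w = a / (a + b) if (a + b) > 0 else 0.5
        # M step
        new = (fixed + n_dh * np.array([w, 1 - w, 1 - w, w])) / (2.0 * n)
        delta = float(np.max(np.abs(new - p)))
        p = new
        trace.append(_loglik(counts, p))
        if delta < tol:
            converged = True
            break
    return HaplotypeFreqs(
        frequencies=dict(zip(HAPLOTYPES, map(float, p))),
        log_likelihood=trace[-1],
        n_iterations=it,
        converged=converged,
        loglik_trace=trace,
    )


def _expected_haplotype_counts(counts: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Expected haplotype counts in a group given phase-split frequencies p."""
    out = np.zeros(4)
    for (i, j), contrib in _FIXED.items():
        out += counts[i, j] * np.asarray(contrib, dtype=float)
    n_dh = counts[1, 1]
    if n_dh > 0:
        a, b = p[0] * p[3], p[1] * p[2]
        w = a / (a + b) if (a + b) > 0 else 0.5
        out += n_dh * np.array([w, 1 - w, 1 - w, w])
    return out


def haplotype_association(
    genotypes: pd.DataFrame,
    case_status: tuple[str, str] = ("survivor", "dead"),
    em_mode: str = "pooled",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Per-haplotype association with insecticide survival.

    For each haplotype h, a 2x2 table of expected haplotype counts
    (h vs not-h) x (case vs control status) is formed from EM phase
    resolution — a single EM over the pooled sample by default
    (``em_mode='pooled'``), or one EM per status group
    (``em_mode='per_group'``).  Reports the cross-product odds ratio
    (Haldane 0.5 correction on zero cells; OR > 1 = higher survival odds),
    a 1-df Pearson chi-square and its p-value.  Haplotypes with fewer than
    half an expected copy across both groups are omitted as absent.
    """
    if em_mode not in ("pooled", "per_group"):
        raise ValueError("em_mode must be 'pooled' or 'per_group'")
    cases, controls = case_status
    gcase = genotypes[genotypes["status"] == cases]
    gctrl = genotypes[genotypes["status"] == controls]
    if gcase.empty or gctrl.empty:
        raise ValueError(f"both status groups {case_status} must be non-empty")
    c_case = genotype_counts(gcase)
    c_ctrl = genotype_counts(gctrl)
    if em_mode == "pooled":
        fit = em_haplotype_frequencies(c_case + c_ctrl, tol=tol, max_iter=max_iter)
        p_case = p_ctrl = fit.as_array()
    else:
        p_case = em_haplotype_frequencies(c_case, tol=tol, max_iter=max_iter).as_array()
        p_ctrl = em_haplotype_frequencies(c_ctrl, tol=tol, max_iter=max_iter).as_array()
    e_case = _expected_haplotype_counts(c_case, p_case)
    e_ctrl = _expected_haplotype_counts(c_ctrl, p_ctrl)
    tot_case, tot_ctrl = e_case.sum(), e_ctrl.sum()

    rows = []
    for k, h in enumerate(HAPLOTYPES):
        a, b = e_case[k], tot_case - e_case[k]  # case: h, not-h
        c, d = e_ctrl[k], tot_ctrl - e_ctrl[k]
        if a + c < 0.5:
            continue  # fewer than half an expected copy overall: absent
        t = np.array([[a, b], [c, d]])
        tc = t + 0.5 if (t == 0).any() else t
        orat = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
        exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float(np.nansum((t - exp) ** 2 / exp))
        pval = float(stats.chi2.sf(chi2, df=1))
        rows.append(
            {
                "haplotype": h,
                "odds_ratio": float(orat),
                "chi_square": chi2,
                "p": pval,
                f"count_{cases}": float(a),
                f"count_{controls}": float(c),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["orientation"] = (
        f"OR > 1 means the haplotype increases odds of being {cases!r}"
    )
    out.attrs["em_mode"] = em_mode
    return out
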