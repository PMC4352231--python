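"""Efficiency-corrected relative quantification of qPCR data (ddCt).

Expression of each target gene is expressed relative to a calibrator
population and normalized to a set of reference (housekeeping) genes.  Per
biological replicate of population s:

    target quantity  Q_t = E_t ^ (Ct_cal,t - Ct_s,t)
    normalizer       N   = geometric mean over references r of
                           E_r ^ (Ct_cal,r - Ct_s,r)
    ratio            R   = Q_t / N

where E is the per-primer amplification efficiency (fold amplification per
cycle, 2 = perfect doubling) and Ct_cal is the calibrator population's mean
Ct for that gene.  With all E = 2 this reduces to the familiar 2^-ddCt.
Ratios are summarized as mean +/- SEM per population; between-year changes
are tested on log-transformed ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["relative_expression", "year_comparison"]

_REQUIRED = ("replicate_id", "population_year", "gene", "role", "Ct", "efficiency")


def _validate_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table is missing columns: {missing}")
    if (plate["Ct"] <= 0).any() or not np.isfinite(plate["Ct"]).all():
        raise ValueError("Ct values must be finite and > 0")
    bad = plate.loc[(plate["efficiency"] <= 1.0) | (plate["efficiency"] > 2.0)]
    if not bad.empty:
        genes = sorted(bad["gene"].unique())
        raise ValueError(f"efficiencies must lie in (1, 2]; offending genes: {genes}")


def relative_expression(
    plate: pd.DataFrame,
    calibrator: str,
    ref_aggregation: str = "geometric",
) -> dict:
    """Efficiency-corrected expression ratios relative to a calibrator.

    ``ref_aggregation='geometric'`` (default) takes the geometric mean of
    per-reference-gene relative quantities; ``'mean_ct'`` instead averages
    the reference Ct values per replicate before applying a single
    efficiency correction (arithmetic-mean-of-Ct variant; uses the mean of
    the reference efficiencies).

    Replicates missing any reference gene (or the target) are dropped with
    a log entry in the result; a population losing all replicates is an
    error.  Returns a dict with per-target ``summary`` (mean ratio, SEM, n
    per population), per-replicate ``ratios`` (for downstream tests) and
    ``dropped`` replicate ids.
    """
    if ref_aggregation not in ("geometric", "mean_ct"):
        raise ValueError("ref_aggregation must be 'geometric' or 'mean_ct'")
    _validate_plate(plate)
    pops = plate["population_year"].unique()
    if calibrator not in pops:
        raise ValueError(f"calibrator {calibrator!r} not among populations {list(pops)}")
    targets = sorted(plate.loc[plate["role"] == "target", "gene"].unique())
    refs = sorted(plate.loc[plate["role"] == "reference", "gene"].unique())
    if not targets or not refs:
        raise ValueError("plate needs at least one target and one reference gene")

    # mean Ct per (population, gene, replicate): technical wells collapse here
    ct = (
        plate.groupby(["population_year", "replicate_id", "gene"])["Ct"]
        .mean()
        .unstack("gene")
    )
    eff = plate.groupby("gene")["efficiency"].first()

    cal_mean = ct.loc[calibrator].mean(axis=0)  # per-gene calibrator mean Ct

    dropped: list[str] = []
    ratio_rows = []
    for (pop, rep), row in ct.iterrows():
        if row[refs].isna().any() or row[targets].isna().all():
            dropped.append(rep)
            continue
        if ref_aggregation == "geometric":
            log_norm = np.mean(
                [
                    (cal_mean[r] - row[r]) * np.log(eff[r])
                    for r in refs
                ]
            )
        else:
            e_ref = float(np.mean([eff[r] for r in refs]))
            log_norm = (
                float(cal_mean[refs].mean() - row[refs].mean()) * np.log(e_ref)
            )
        for tgt in targets:
            if pd.isna(row[tgt]):
                continue
            log_q = (cal_mean[tgt] - row[tgt]) * np.log(eff[tgt])
            ratio_rows.append(
                {
                    "gene": tgt,
                    "population_year": pop,
                    "replicate_id": rep,
                    "ratio": float(np.exp(log_q - log_norm)),
                }
            )
    ratios = pd.DataFrame(ratio_rows)
    if ratios.empty:
        raise ValueError("all replicates were dropped; no usable data")
    for pop in pops:
        if pop not in set(ratios["population_year"]):
            raise ValueError(f"population {pop!r} lost all replicates")

    summary = (
        ratios.groupby(["gene", "population_year"])["ratio"]
        .agg(
            mean_ratio="mean",
            sem=lambda x: float(stats.sem(x)) if len(x) > 1 else 0.0,
            n="size",
        )
        .reset_index()
    )
    return {"summary": summary, "ratios": ratios, "dropped": dropped,
            "calibrator": calibrator}


def year_comparison(
    result: dict,
    gene: str,
    year_a: str,
    year_b: str,
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-tailed t-test of log relative expression between two time points.

    Operates on the per-replicate ratios of :func:`relative_expression`
    (log-transformed, as Ct-derived quantities are log-normal).  ``welch``
    (default) does not assume equal variances; ``pooled`` does.  Returns
    ``(t, p)``; p is reported unadjusted.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    ratios = result["ratios"]
    a = ratios.query("gene == @gene and population_year == @year_a")["ratio"]
    b = ratios.query("gene == @gene and population_year == @year_b")["ratio"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates in each group")
    res = stats.ttest_ind(np.log(a), np.log(b), equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)
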