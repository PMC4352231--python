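"""Differential expression from two-colour loop designs.

Workflow: within-array normalization of log ratios, then a per-probe
fixed-effects least-squares model over the loop design with an optional
common dye coefficient, then Benjamini-Hochberg FDR adjustment per contrast.

The central table formats are plain pandas DataFrames:

* intensity table — columns ``probe_id, array_id, cy3, cy5``;
* normalized table — columns ``probe_id, array_id, M, A, flag``;
* contrast table — columns ``probe_id, contrast, log2FC, p, q, flag``.

Contrast labels are ``"<a>_vs_<b>"`` with log2FC = log2(a/b).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .design import DesignError, HybridizationDesign

__all__ = [
    "normalize",
    "fit_contrasts",
    "bh_adjust",
    "contrast_label",
]

#: Residual sums of squares below this (relative to the mean squared signal)
#: are treated as an exact fit: the t statistic is undefined, not infinite.
_ZERO_RSS_TOL = 1e-20


def contrast_label(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def normalize(
    intensities: pd.DataFrame,
    method: str = "median",
    epsilon: float = 1.0,
    loess_frac: float = 0.4,
) -> pd.DataFrame:
    """Within-array normalization of two-colour intensities.

    Computes M = log2(cy5) - log2(cy3) and A = (log2(cy5) + log2(cy3)) / 2
    after flooring intensities at ``epsilon``, then centres M per array:
    ``median`` subtracts the per-array median of M; ``loess`` subtracts an
    intensity-dependent lowess smooth of M on A (removing dye/intensity
    trends).  A is returned uncentred.

    Intensities that were non-positive before flooring are flagged
    ``"floored"`` (kept if epsilon > 0); with epsilon <= 0 such spots get
    undefined M and are excluded from model fitting downstream.  An array
    whose spots are all non-positive is a hard error.
    """
    if method not in ("median", "loess"):
        raise ValueError(f"unknown normalization method {method!r}")
    df = intensities.copy()
    bad = (df["cy3"] <= 0) | (df["cy5"] <= 0)
    for arr, grp in df.groupby("array_id"):
        if ((grp["cy3"] <= 0) & (grp["cy5"] <= 0)).all():
            raise ValueError(f"array {arr!r} has no positive intensities")
    if epsilon > 0:
        cy3 = df["cy3"].clip(lower=epsilon)
        cy5 = df["cy5"].clip(lower=epsilon)
    else:
        cy3 = df["cy3"].where(df["cy3"] > 0)
        cy5 = df["cy5"].where(df["cy5"] > 0)
    M = np.log2(cy5) - np.log2(cy3)
    A = (np.log2(cy5) + np.log2(cy3)) / 2.0
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "array_id": df["array_id"],
            "M": M,
            "A": A,
            "flag": np.where(bad, "floored", ""),
        }
    )
    for arr, grp in out.groupby("array_id", sort=False):
        ok = grp["M"].notna()
        if method == "median":
            out.loc[grp.index[ok], "M"] = grp.loc[ok, "M"] - grp.loc[ok, "M"].median()
        else:
            sub = grp.loc[ok]
            smooth = lowess(
                sub["M"].to_numpy(),
                sub["A"].to_numpy(),
                frac=loess_frac,
                return_sorted=False,
            )
            out.loc[sub.index, "M"] = sub["M"].to_numpy() - smooth
    return out


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    NaN entries (undefined p) are left NaN and excluded from the adjustment;
    out-of-range p-values raise.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def _fit_block(
    Mmat: np.ndarray, X: np.ndarray, cvecs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS for many probes sharing the same model matrix.

    Mmat is (n_probes, n_arrays); returns per-probe contrast estimates
    (n_probes, n_contrasts), their two-sided p-values, and the residual df.
    Probes with an exact fit (RSS ~ 0) get NaN p.
    """
    n_arrays, rank = X.shape[0], np.linalg.matrix_rank(X)
    df = n_arrays - rank
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = Mmat @ (XtX_inv @ X.T).T  # (n_probes, n_params)
    resid = Mmat - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    est = beta @ cvecs.T  # (n_probes, n_contrasts)
    pvals = np.full_like(est, np.nan)
    if df > 0:
        sigma2 = rss / df
        scale = np.sqrt(np.abs(np.einsum("ij,jk,ik->i", cvecs, XtX_inv, cvecs)))
        zero = rss <= _ZERO_RSS_TOL * max(1.0, float(np.mean(Mmat**2)))
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2)[:, None] * scale[None, :]
            t = est / se
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        pv[zero, :] = np.nan
        pvals = pv
    return est, pvals, df


def fit_contrasts(
    normalized: pd.DataFrame,
    design: HybridizationDesign,
    contrasts: list[tuple[str, str]],
    dye_effect: bool = True,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-probe fixed-effects least squares on normalized log ratios.

    Each probe's M values over the arrays are regressed on the design
    matrix; each requested contrast (a, b) is reported as
    log2FC = beta_a - beta_b with a two-sided t-test p-value on
    ``arrays - rank`` residual degrees of freedom and a per-contrast BH
    q-value.  Probes with undefined p (no residual df, or an exact fit)
    are flagged, not dropped.

    Raises :class:`DesignError` before fitting if a requested contrast
    involves a population absent from the design.
    """
    pops = design.populations
    if reference is None:
        reference = pops[0]
    X, labels = design.design_matrix(reference=reference, dye_effect=dye_effect)
    cvecs = np.vstack(
        [design.contrast_vector(a, b, labels, reference) for a, b in contrasts]
    )

    order = design.array_ids
    wide = normalized.pivot_table(
        index="probe_id", columns="array_id", values="M", aggfunc="first"
    )
    missing_cols = [a for a in order if a not in wide.columns]
    if missing_cols:
        raise DesignError(f"no intensity data for arrays: {missing_cols}")
    wide = wide[order]

    complete = wide.notna().all(axis=1)
    frames: list[pd.DataFrame] = []
    df_resid = X.shape[0] - np.linalg.matrix_rank(X)

    def emit(probes: pd.Index, est: np.ndarray, pv: np.ndarray, df: int) -> None:
        for j, (a, b) in enumerate(contrasts):
            flag = np.where(
                np.isnan(pv[:, j]),
                "zero_residual" if df > 0 else "no_residual_df",
                "",
            )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probes,
                        "contrast": contrast_label(a, b),
                        "log2FC": est[:, j],
                        "p": pv[:, j],
                        "flag": flag,
                    }
                )
            )

    if complete.any():
        block = wide.loc[complete]
        est, pv, df = _fit_block(block.to_numpy(), X, cvecs)
        emit(block.index, est, pv, df)
    # probes with missing arrays (floored spots): fit on available rows
    for probe, row in wide.loc[~complete].iterrows():
        ok = row.notna().to_numpy()
        if ok.sum() == 0:
            continue
        Xs = X[ok]
        if np.linalg.matrix_rank(Xs) < X.shape[1]:
            continue  # inestimable for this probe; logged by caller
        est, pv, df = _fit_block(row.to_numpy()[ok][None, :], Xs, cvecs)
        emit(pd.Index([probe], name="probe_id"), est, pv, df)

    result = pd.concat(frames, ignore_index=True)
    result["q"] = np.nan
    for _, idx in result.groupby("contrast").groups.items():
        result.loc[idx, "q"] = bh_adjust(result.loc[idx, "p"])
    result.attrs["df_resid"] = int(df_resid)
    return result.sort_values(["contrast", "probe_id"], ignore_index=True)
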