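"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle sums
hypergeometric probabilities from its own log-factorial arithmetic; the CI
oracle inverts the beta quantiles directly; the EM oracle maximizes the
two-locus multinomial likelihood by grid scan.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import beta as beta_dist


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Sums the probabilities of every table (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's, using
    the standard relative slack for floating-point ties.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logpmf(k: int) -> float:
        return (
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = np.exp([logpmf(k) for k in range(lo, hi + 1)])
    p_obs = probs[a - lo]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-7)].sum()))


def clopper_pearson_oracle(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval straight from beta quantiles."""
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


# two-locus genotype classes: (F copies, Y copies) -> log-prob contribution
def _class_logprobs(freqs: np.ndarray) -> np.ndarray:
    """3x3 matrix of genotype class probabilities under HWE random pairing.

    freqs ordered (L-N, L-Y, F-N, F-Y).
    """
    ln, ly, fn, fy = freqs
    p = np.zeros((3, 3))
    p[0, 0] = ln * ln
    p[0, 1] = 2 * ln * ly
    p[0, 2] = ly * ly
    p[1, 0] = 2 * ln * fn
    p[1, 1] = 2 * (ln * fy + ly * fn)
    p[1, 2] = 2 * ly * fy
    p[2, 0] = fn * fn
    p[2, 1] = 2 * fn * fy
    p[2, 2] = fy * fy
    return p


def grid_haplotype_mle(
    counts: np.ndarray, step: float = 0.0005
) -> tuple[np.ndarray, float]:
    """Maximize the two-locus multinomial likelihood by grid scan.

    Every genotype class — including the phase-ambiguous double
    heterozygote — contributes a fixed number of F and Y *alleles*, so the
    maximum-likelihood allele frequencies equal the observed ones and the
    likelihood has a single free parameter, the F-Y haplotype frequency.
    The scan covers its full feasible range at ``step`` resolution.

    Returns (freqs over (L-N, L-Y, F-N, F-Y), max log-likelihood).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    two_n = 2.0 * n
    p_f = (counts[1, :].sum() + 2 * counts[2, :].sum()) / two_n
    p_y = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / two_n
    lo, hi = max(0.0, p_f + p_y - 1.0), min(p_f, p_y)
    grid = np.arange(lo, hi + step / 2, step)
    grid = np.clip(grid, lo, hi)
    best_ll, best = -np.inf, None
    for fy in grid:
        freqs = np.array([1 - p_f - p_y + fy, p_y - fy, p_f - fy, fy])
        if (freqs < -1e-12).any():
            continue
        freqs = np.clip(freqs, 0.0, 1.0)
        probs = _class_logprobs(freqs)
        with np.errstate(divide="ignore"):
            lp = np.where(counts > 0, np.log(np.where(probs > 0, probs, 1e-300)), 0.0)
        ll = float((counts * lp).sum())
        if ll > best_ll:
            best_ll, best = ll, freqs
    return best, best_ll
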