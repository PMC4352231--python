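"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's three data streams:

* :func:`simulate_two_color_experiment` — probe-level cy3/cy5 intensities
  over an interwoven loop design, from per-population true log2 abundances
  with additive Gaussian noise on the log2 scale, a per-array effect and a
  constant cy5 dye offset;
* :func:`simulate_genotypes` — unphased two-locus kdr genotypes (L1014F,
  N1575Y) with a survival outcome drawn from a per-haplotype multiplicative
  odds model;
* :func:`simulate_qpcr` — Ct tables for target and reference genes such
  that the efficiency-corrected ddCt estimator recovers the planted
  relative levels in expectation.

All generators are pure functions of their parameters and seed.  Planted
truth is returned (or carried in the tables) so tests can assert exact
recovery at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import HybridizationDesign

__all__ = [
    "PLANTED_CLASSES",
    "STUDY_POPULATIONS",
    "GenotypeSimParams",
    "make_expression_truth",
    "planted_log2fc",
    "simulate_two_color_experiment",
    "simulate_genotypes",
    "simulate_qpcr",
]

#: The seven RNA populations of the two experiments (year-suffixed).
STUDY_POPULATIONS = (
    "VKR2011",
    "VKC2011",
    "MAL2011",
    "VKR2012",
    "TEN2012",
    "MAL2012",
    "NG2012",
)

#: Ground-truth classes a probe can be planted as.  ``cascade_candidate``
#: satisfies every filtering rule; each ``fails_step_X`` violates rule X
#: (see the note on step B below); ``down_regulated`` satisfies the mirrored
#: down-regulation rules; ``null`` has no expression difference anywhere.
PLANTED_CLASSES = (
    "cascade_candidate",
    "fails_step_A",
    "fails_step_B",
    "fails_step_C",
    "fails_step_D",
    "fails_step_E",
    "down_regulated",
    "null",
)

_DEFAULT_FRACTIONS = {
    "cascade_candidate": 0.05,
    "fails_step_A": 0.02,
    "fails_step_B": 0.02,
    "fails_step_C": 0.02,
    "fails_step_D": 0.02,
    "fails_step_E": 0.02,
    "down_regulated": 0.05,
    "null": 0.80,
}

#: Planted log2 effect sizes are drawn uniformly from this range, matching
#: the fold-change magnitudes (about 2x to 9x and above) reported for field
#: resistant populations against susceptible colonies.
_EFFECT_RANGE = (1.2, 3.0)
#: Extra log2 increment separating the 2012 from the 2011 contrast, and the
#: VK7-over-Tengrela margin (the reported year-on-year fold-change
#: differences span about 1.4x to 3.6x).
_GAP_RANGE = (0.7, 1.6)


def _gene_sizes(n: int, rng: np.random.Generator) -> list[int]:
    """Partition n probes into genes of size 1-4 (most genes single-probe)."""
    sizes = []
    left = n
    while left > 0:
        s = int(rng.choice([1, 2, 3, 4], p=[0.7, 0.15, 0.1, 0.05]))
        sizes.append(min(s, left))
        left -= sizes[-1]
    return sizes


def make_expression_truth(
    n_probes: int = 1000,
    class_fractions: dict[str, float] | None = None,
    base_level: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a planted-truth table of per-population true log2 levels.

    Returns one row per probe with columns ``probe_id``, ``gene_id``,
    ``planted_class`` and ``level_<population>`` for each of the seven
    study populations.  Probes of the same gene share identical levels
    (duplicate probes / alternative transcripts of one gene).

    Effect construction per class (deltas are log2 offsets from the
    susceptible baseline; all draws are per gene):

    * ``cascade_candidate`` — up by d11 in 2011, up by d12 > d11 in 2012
      against both susceptible colonies, and above Tengrela;
    * ``fails_step_A`` — down in 2011, otherwise candidate-like;
    * ``fails_step_B`` — down against MAL in 2012 only (this necessarily
      also breaks the 2012-greater-than-2011 rule: the two cannot be
      decoupled for a sign violation);
    * ``fails_step_C`` — down against NG in 2012 only;
    * ``fails_step_D`` — below Tengrela, otherwise candidate-like;
    * ``fails_step_E`` — up both years but with a *smaller* 2012 effect;
    * ``down_regulated`` — down in every resistant-vs-susceptible
      comparison and below Tengrela;
    * ``null`` — flat across all populations.
    """
    fractions = dict(_DEFAULT_FRACTIONS if class_fractions is None else class_fractions)
    unknown = set(fractions) - set(PLANTED_CLASSES)
    if unknown:
        raise ValueError(f"unknown planted classes: {sorted(unknown)}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)

    counts = {c: int(round(n_probes * fractions.get(c, 0.0))) for c in PLANTED_CLASSES}
    counts["null"] += n_probes - sum(counts.values())  # absorb rounding

    rows: list[dict] = []
    probe_i = 0
    gene_i = 0
    for cls in PLANTED_CLASSES:
        n = counts[cls]
        if n <= 0:
            continue
        for size in _gene_sizes(n, rng):
            gene_i += 1
            gene = f"AGAP{gene_i:06d}"
            lv = dict.fromkeys(STUDY_POPULATIONS, base_level)
            d11 = rng.uniform(*_EFFECT_RANGE)
            gap = rng.uniform(*_GAP_RANGE)
            d12 = d11 + gap
            ten_gap = rng.uniform(*_GAP_RANGE)
            if cls == "cascade_candidate":
                lv["VKR2011"] += d11
                lv["VKC2011"] += d11 * 0.5
                lv["VKR2012"] += d12
                lv["TEN2012"] += max(d12 - ten_gap, 0.0)
            elif cls == "fails_step_A":
                lv["VKR2011"] -= d11
                lv["VKR2012"] += d12
                lv["TEN2012"] += max(d12 - ten_gap, 0.0)
            elif cls == "fails_step_B":
                lv["VKR2011"] += d11
                lv["MAL2012"] += d11 + gap  # VKR below MAL in 2012 only
                lv["VKR2012"] += 0.0
                lv["NG2012"] -= gap  # still up against NG
                lv["TEN2012"] -= ten_gap  # still up against TEN
            elif cls == "fails_step_C":
                lv["VKR2011"] += d11
                lv["VKR2012"] += d12
                lv["NG2012"] += d12 + gap  # VKR below NG
                lv["TEN2012"] += max(d12 - ten_gap, 0.0)
            elif cls == "fails_step_D":
                lv["VKR2011"] += d11
                lv["VKR2012"] += d12
                lv["TEN2012"] += d12 + ten_gap  # TEN above VKR
            elif cls == "fails_step_E":
                lv["VKR2011"] += d12  # larger effect in 2011
                lv["VKR2012"] += d11
                lv["TEN2012"] += max(d11 - ten_gap, 0.0)
            elif cls == "down_regulated":
                lv["VKR2011"] -= d11
                lv["VKC2011"] -= d11 * 0.5
                lv["VKR2012"] -= d12
                lv["TEN2012"] -= max(d12 - ten_gap, 0.0)  # VKR below TEN too
            for _ in range(size):
                probe_i += 1
                rows.append(
                    {
                        "probe_id": f"P{probe_i:05d}",
                        "gene_id": gene,
                        "planted_class": cls,
                        **{f"level_{p}": lv[p] for p in STUDY_POPULATIONS},
                    }
                )
    return pd.DataFrame(rows)


def planted_log2fc(truth: pd.DataFrame, a: str, b: str) -> pd.Series:
    """True log2 fold change of population a over b, indexed by probe_id."""
    s = truth.set_index("probe_id")
    return s[f"level_{a}"] - s[f"level_{b}"]


def simulate_two_color_experiment(
    design: HybridizationDesign,
    truth: pd.DataFrame,
    noise_sd: float = 0.25,
    dye_bias: float = 0.1,
    array_effect_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate probe-level cy3/cy5 intensities for every array of a design.

    Intensity model (log2 scale):
    ``log2(cy) = true level + array effect + dye bias (cy5 only) + noise``,
    with the array effect ~ N(0, array_effect_sd) shared by both channels
    of an array (it cancels in M) and independent N(0, noise_sd) noise per
    probe per channel.

    Returns a tidy intensity table with columns
    ``probe_id, array_id, cy3, cy5``.
    """
    if noise_sd < 0 or array_effect_sd < 0:
        raise ValueError("noise_sd and array_effect_sd must be >= 0")
    missing = [
        p for p in design.populations if f"level_{p}" not in truth.columns
    ]
    if missing:
        raise ValueError(f"design populations absent from truth: {missing}")
    rng = np.random.default_rng(seed)
    n = len(truth)
    probe_ids = truth["probe_id"].to_numpy()
    frames = []
    for h in design.hybridizations:
        ae = rng.normal(0.0, array_effect_sd) if array_effect_sd > 0 else 0.0
        l3 = truth[f"level_{h.cy3_sample}"].to_numpy() + ae
        l5 = truth[f"level_{h.cy5_sample}"].to_numpy() + ae + dye_bias
        if noise_sd > 0:
            l3 = l3 + rng.normal(0.0, noise_sd, n)
            l5 = l5 + rng.normal(0.0, noise_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "array_id": h.array_id,
                    "cy3": np.exp2(l3),
                    "cy5": np.exp2(l5),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# kdr genotypes


_HAPLOTYPES = ("L-N", "L-Y", "F-N", "F-Y")


@dataclass
class GenotypeSimParams:
    """Parameters of the two-locus genotype/survival simulator.

    ``haplotype_freqs`` are population frequencies of the 1014-1575
    haplotypes; the L-Y haplotype is structurally absent in the field (the
    1575Y mutation occurs only on a 1014F background), so its default
    frequency is zero.  ``survival_odds_ratio_per_haplotype`` gives the
    multiplicative effect of each haplotype copy on the odds of surviving
    insecticide exposure; ``baseline_odds`` is the survival odds of an
    individual carrying two reference (unlisted or OR = 1) haplotypes.
    """

    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: {"L-N": 0.15, "F-N": 0.55, "F-Y": 0.30}
    )
    survival_odds_ratio_per_haplotype: dict[str, float] = field(default_factory=dict)
    n_per_arm: int = 100
    n_controls: int = 0
    baseline_odds: float = 1.0
    site: str = "VK7"
    round: str = "Oct-11"
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict.fromkeys(_HAPLOTYPES, 0.0) | dict(self.haplotype_freqs)
        unknown = set(freqs) - set(_HAPLOTYPES)
        if unknown:
            raise ValueError(f"unknown haplotypes: {sorted(unknown)}")
        if any(f < 0 for f in freqs.values()):
            raise ValueError("haplotype frequencies must be >= 0")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if any(o <= 0 for o in self.survival_odds_ratio_per_haplotype.values()):
            raise ValueError("survival odds ratios must be > 0")
        self.haplotype_freqs = freqs


def _haplotypes_to_genotypes(h1: np.ndarray, h2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse phased haplotype indices to unphased genotype codes."""
    # allele at 1014: L for haplotypes 0,1 (L-N, L-Y); F for 2,3
    f_count = (h1 >= 2).astype(int) + (h2 >= 2).astype(int)
    # allele at 1575: Y for haplotypes 1,3
    y_count = ((h1 == 1) | (h1 == 3)).astype(int) + ((h2 == 1) | (h2 == 3)).astype(int)
    g1014 = np.array(["LL", "LF", "FF"])[f_count]
    g1575 = np.array(["NN", "NY", "YY"])[y_count]
    return g1014, g1575


def simulate_genotypes(params: GenotypeSimParams) -> pd.DataFrame:
    """Draw specimens with unphased kdr genotypes and a survival outcome.

    Each specimen receives two haplotypes i.i.d. from ``haplotype_freqs``;
    survival odds are ``baseline_odds`` times the product of the per-copy
    odds ratios of its two haplotypes.  Exposed specimens are accumulated
    until both the ``dead`` and ``survivor`` arms contain ``n_per_arm``
    specimens (outcome-based sampling leaves odds ratios unchanged);
    ``n_controls`` additional unexposed specimens are drawn without an
    outcome.  Phase is discarded in the output.
    """
    rng = np.random.default_rng(params.seed)
    freqs = np.array([params.haplotype_freqs[h] for h in _HAPLOTYPES])
    ors = np.array(
        [params.survival_odds_ratio_per_haplotype.get(h, 1.0) for h in _HAPLOTYPES]
    )

    def draw(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h1 = rng.choice(len(_HAPLOTYPES), size=n, p=freqs)
        h2 = rng.choice(len(_HAPLOTYPES), size=n, p=freqs)
        odds = params.baseline_odds * ors[h1] * ors[h2]
        p = odds / (1.0 + odds)
        survived = rng.random(n) < p
        return h1, h2, survived

    kept: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {"dead": [], "survivor": []}
    need = {"dead": params.n_per_arm, "survivor": params.n_per_arm}
    attempts = 0
    while any(need[a] > 0 for a in need):
        attempts += 1
        if attempts > 200:
            raise RuntimeError(
                "could not fill both outcome arms; check baseline_odds and ORs"
            )
        h1, h2, surv = draw(max(4 * params.n_per_arm, 200))
        for arm, mask in (("survivor", surv), ("dead", ~surv)):
            if need[arm] > 0 and mask.any():
                take = min(need[arm], int(mask.sum()))
                idx = np.nonzero(mask)[0][:take]
                kept[arm].append((h1[idx], h2[idx]))
                need[arm] -= take

    rows = []
    sid = 0
    for arm in ("dead", "survivor"):
        if kept[arm]:
            h1 = np.concatenate([a for a, _ in kept[arm]])
            h2 = np.concatenate([b for _, b in kept[arm]])
            g1, g2 = _haplotypes_to_genotypes(h1, h2)
            for a, b in zip(g1, g2):
                sid += 1
                rows.append((f"S{sid:05d}", params.site, params.round, arm, a, b))
    if params.n_controls > 0:
        h1 = rng.choice(len(_HAPLOTYPES), size=params.n_controls, p=freqs)
        h2 = rng.choice(len(_HAPLOTYPES), size=params.n_controls, p=freqs)
        g1, g2 = _haplotypes_to_genotypes(h1, h2)
        for a, b in zip(g1, g2):
            sid += 1
            rows.append((f"S{sid:05d}", params.site, params.round, "control", a, b))
    return pd.DataFrame(
        rows,
        columns=["specimen_id", "site", "round", "status", "genotype_1014", "genotype_1575"],
    )


# ---------------------------------------------------------------------------
# qPCR


DEFAULT_REFERENCE_GENES = ("UBIQ", "EF1A", "RPS7")


def simulate_qpcr(
    relative_levels: dict[str, float],
    efficiencies: dict[str, float] | None = None,
    n_replicates: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "GSTE2",
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 20.0,
) -> pd.DataFrame:
    """Simulate a qPCR plate whose ddCt analysis recovers planted levels.

    ``relative_levels`` maps each population_year label to the target
    gene's true expression relative to an arbitrary common baseline (the
    ddCt estimator recovers ratios between populations, so only ratios
    matter).  The target Ct is shifted by ``-log(level)/log(E)`` cycles;
    reference-gene Ct values are constant across populations up to noise.

    Returns a plate table with columns
    ``replicate_id, population_year, gene, role, Ct, efficiency``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(lv <= 0 for lv in relative_levels.values()):
        raise ValueError("relative levels must be > 0")
    eff = {g: 2.0 for g in (target_gene, *reference_genes)}
    if efficiencies:
        eff.update(efficiencies)
    for g, e in eff.items():
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency of {g!r} must lie in (1, 2], got {e}")
    rng = np.random.default_rng(seed)
    rows = []
    for pop, level in relative_levels.items():
        for r in range(1, n_replicates + 1):
            rep = f"{pop}_r{r}"
            ct_t = base_ct_target - np.log(level) / np.log(eff[target_gene])
            if noise_sd > 0:
                ct_t += rng.normal(0.0, noise_sd)
            rows.append((rep, pop, target_gene, "target", ct_t, eff[target_gene]))
            for g in reference_genes:
                ct_r = base_ct_reference
                if noise_sd > 0:
                    ct_r += rng.normal(0.0, noise_sd)
                rows.append((rep, pop, g, "reference", ct_r, eff[g]))
    return pd.DataFrame(
        rows,
        columns=["replicate_id", "population_year", "gene", "role", "Ct", "efficiency"],
    )
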