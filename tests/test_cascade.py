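import numpy as np
import pandas as pd
import pytest

import resistkit as rk
from resistkit.cascade import (
    CascadeConfig,
    cluster_candidates,
    collapse_probes_to_genes,
    down_regulated_mirror,
    run_cascade,
    step_up_consistent,
    step_vk7_over_ten,
    step_year_increase,
)
from resistkit.de import contrast_label

A = contrast_label("VKR2011", "MAL2011")
B = contrast_label("VKR2012", "MAL2012")
C = contrast_label("VKR2012", "NG2012")
D = contrast_label("VKR2012", "TEN2012")


def table(rows):
    """rows: (probe, contrast, log2FC, q)"""
    return pd.DataFrame(
        [(p, c, fc, q / 2 if q is not None else np.nan, q) for p, c, fc, q in rows],
        columns=["probe_id", "contrast", "log2FC", "p", "q"],
    )


def full_probe(probe, fcs, qs=0.01):
    """One probe with values in all four cascade contrasts."""
    if not isinstance(qs, dict):
        qs = {k: qs for k in (A, B, C, D)}
    return [(probe, k, fcs[k], qs[k]) for k in (A, B, C, D)]


class TestStepUpConsistent:
    def test_up_everywhere_retained(self):
        t = table(full_probe("p1", {A: 1, B: 2, C: 1.5, D: 1}))
        assert step_up_consistent(t, CascadeConfig()) == {"p1"}

    def test_single_sign_violation_excluded(self):
        t = table(full_probe("p1", {A: 1, B: 2, C: -0.1, D: 1}))
        assert step_up_consistent(t, CascadeConfig()) == set()

    def test_significance_mode_all_vs_any(self):
        t = table(full_probe("p1", {A: 1, B: 2, C: 1, D: 1},
                             {A: 0.01, B: 0.2, C: 0.01, D: 0.01}))
        assert step_up_consistent(t, CascadeConfig()) == set()
        assert step_up_consistent(
            t, CascadeConfig(significance_mode="any")
        ) == {"p1"}

    def test_missing_contrast_excludes_probe(self):
        t = table([("p1", A, 1.0, 0.01), ("p1", B, 1.0, 0.01), ("p1", D, 1.0, 0.01),
                   *full_probe("p2", {A: 1, B: 1, C: 1, D: 1})])
        assert step_up_consistent(t, CascadeConfig()) == {"p2"}


class TestStepYearIncrease:
    def test_strictly_greater_retained_tie_excluded(self):
        t = table(
            full_probe("p1", {A: 1.0, B: 3.245, C: 1, D: 1})  # e.g. FC 9.48 in 2012
            + full_probe("p2", {A: 1.0, B: 1.0, C: 1, D: 1})
        )
        survivors = {"p1", "p2"}
        assert step_year_increase(survivors, t, CascadeConfig()) == {"p1"}


class TestStepVk7OverTen:
    def test_threshold_boundary(self):
        t = table(
            full_probe("p1", {A: 1, B: 1, C: 1, D: 0.5}, {A: 0.01, B: 0.01, C: 0.01, D: 0.049})
            + full_probe("p2", {A: 1, B: 1, C: 1, D: 0.5}, {A: 0.01, B: 0.01, C: 0.01, D: 0.051})
            + full_probe("p3", {A: 1, B: 1, C: 1, D: -1.3})  # CYP6Z3-like, higher in TEN
        )
        out = step_vk7_over_ten({"p1", "p2", "p3"}, t, CascadeConfig())
        assert out == {"p1"}


class TestCollapse:
    def test_mean_fc_on_natural_scale(self):
        probes = {"p1", "p2", "p3", "p4"}
        fcs = dict(zip(sorted(probes), np.log2([8, 9, 10, 11])))
        t = pd.DataFrame(
            [(p, B, fcs[p], 0.1, 0.01) for p in sorted(probes)],
            columns=["probe_id", "contrast", "log2FC", "p", "q"],
        )
        pg = pd.DataFrame({"probe_id": sorted(probes), "gene_id": "g1"})
        out = collapse_probes_to_genes(probes, pg, t, B)
        assert len(out) == 1
        assert out["mean_FC"].iloc[0] == pytest.approx(9.5)
        assert out["n_probes"].iloc[0] == 4

    def test_duplicate_probe_map_mirrors_reported_reduction(self):
        # 157 probes -> 136 genes via 21 duplicate probes
        probes = [f"p{i:03d}" for i in range(157)]
        genes = [f"g{i:03d}" for i in range(136)]
        gene_of = {p: genes[i] if i < 136 else genes[i - 136] for i, p in enumerate(probes)}
        pg = pd.DataFrame({"probe_id": probes, "gene_id": [gene_of[p] for p in probes]})
        t = pd.DataFrame(
            [(p, B, 1.0, 0.1, 0.01) for p in probes],
            columns=["probe_id", "contrast", "log2FC", "p", "q"],
        )
        out = collapse_probes_to_genes(set(probes), pg, t, B)
        assert len(out) == 136

    def test_empty_probe_set(self):
        out = collapse_probes_to_genes(
            set(), pd.DataFrame(columns=["probe_id", "gene_id"]),
            table([]), B,
        )
        assert out.empty

    def test_unmapped_probe_kept_under_own_id(self):
        t = pd.DataFrame([("pX", B, 1.0, 0.1, 0.01)],
                         columns=["probe_id", "contrast", "log2FC", "p", "q"])
        out = collapse_probes_to_genes(
            {"pX"}, pd.DataFrame(columns=["probe_id", "gene_id"]), t, B
        )
        assert out["gene_id"].tolist() == ["pX"]


class TestDownRegulatedMirror:
    def test_all_down_retained_up_in_ten_excluded(self):
        t = table(
            full_probe("p1", {A: -1, B: -2, C: -1, D: -1})
            + full_probe("p2", {A: -1, B: -2, C: -1, D: 0.5})
        )
        assert down_regulated_mirror(t, CascadeConfig()) == {"p1"}

    def test_disjoint_from_up_candidates(self, merged_contrasts_zero_noise):
        res = run_cascade(merged_contrasts_zero_noise, CascadeConfig())
        assert not (res.candidate_probes & res.down_regulated_probes)


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["p1", "p2"])
        out = cluster_candidates(prof)
        assert out["linkage"][0, 2] == pytest.approx(0.0)

    def test_hand_euclidean_merge_order(self):
        prof = pd.DataFrame(
            [[0, 0, 0], [3, 3, 3], [3.1, 3.1, 3.1]],
            index=["p1", "p2", "p3"], dtype=float,
        )
        out = cluster_candidates(prof)
        # p2-p3 distance 0.1*sqrt(3)=0.173 merges before 3*sqrt(3)=5.196
        first = out["linkage"][0]
        assert sorted(first[:2]) == [1, 2]
        assert first[2] == pytest.approx(0.1 * np.sqrt(3), abs=1e-9)

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(size=(12, 3)),
                            index=[f"p{i:02d}" for i in range(12)])
        h1 = cluster_candidates(prof)["linkage"][:, 2]
        h2 = cluster_candidates(prof.sample(frac=1, random_state=1))["linkage"][:, 2]
        assert np.allclose(h1, h2)

    def test_single_probe_degenerate_tree(self):
        out = cluster_candidates(pd.DataFrame([[1.0, 2.0]], index=["p1"]))
        assert out["leaves"] == ["p1"] and out["linkage"].shape == (0, 4)

    def test_newick_has_all_leaves(self):
        prof = pd.DataFrame(np.eye(4), index=list("abcd"))
        nwk = cluster_candidates(prof)["newick"]
        assert all(leaf in nwk for leaf in "abcd") and nwk.endswith(";")


class TestFullCascade:
    def test_zero_noise_exact_planted_recovery(
        self, truth_small, merged_contrasts_zero_noise
    ):
        res = run_cascade(
            merged_contrasts_zero_noise,
            CascadeConfig(),
            truth_small[["probe_id", "gene_id"]],
        )
        cls = truth_small.set_index("probe_id")["planted_class"]
        planted = set(cls.index[cls == "cascade_candidate"])
        assert res.candidate_probes == planted
        fails = set(cls.index[cls.str.startswith("fails")])
        assert not (res.candidate_probes & fails)
        down = set(cls.index[cls == "down_regulated"])
        assert res.down_regulated_probes == down

    def test_nesting_invariant_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 60)
            probes = [f"p{i}" for i in range(n)]
            rows = []
            for p in probes:
                for k in (A, B, C, D):
                    rows.append((p, k, rng.normal(), rng.uniform(), rng.uniform()))
            t = pd.DataFrame(rows, columns=["probe_id", "contrast", "log2FC", "p", "q"])
            res = run_cascade(t, CascadeConfig())
            abc, e, d = (len(res.surviving_probes_per_step[k]) for k in ("A-C", "E", "D"))
            assert abc >= e >= d >= len(res.candidate_genes["gene_id"].unique() if len(res.candidate_genes) else [])
            assert res.surviving_probes_per_step["E"] <= res.surviving_probes_per_step["A-C"]
            assert res.surviving_probes_per_step["D"] <= res.surviving_probes_per_step["E"]

    def test_cascade_is_pure(self, merged_contrasts_zero_noise):
        r1 = run_cascade(merged_contrasts_zero_noise, CascadeConfig())
        r2 = run_cascade(merged_contrasts_zero_noise, CascadeConfig())
        assert r1.candidate_probes == r2.candidate_probes
        assert r1.step_counts == r2.step_counts

    def test_missing_configured_contrast_is_error(self):
        t = table(full_probe("p1", {A: 1, B: 1, C: 1, D: 1}))
        t = t[t["contrast"] != D]
        with pytest.raises(ValueError, match="VKR2012_vs_TEN2012"):
            run_cascade(t, CascadeConfig())

    def test_planted_fails_probes_dropped_at_their_step(
        self, truth_small, merged_contrasts_zero_noise
    ):
        res = run_cascade(merged_contrasts_zero_noise, CascadeConfig())
        cls = truth_small.set_index("probe_id")["planted_class"]
        abc = res.surviving_probes_per_step["A-C"]
        for failing in ("fails_step_A", "fails_step_B", "fails_step_C"):
            assert not (abc & set(cls.index[cls == failing]))
        assert not (
            res.surviving_probes_per_step["E"] & set(cls.index[cls == "fails_step_E"])
        )
        assert not (
            res.surviving_probes_per_step["D"] & set(cls.index[cls == "fails_step_D"])
        )
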