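"""Expression normalization, the filter cascade, clustering and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbomics.synthetic import default_ground_truth, make_design
from pbomics.transcripts import (
    ExpressionSet,
    anova2_bh,
    benjamini_hochberg,
    enrich,
    filter_detected,
    filter_foldchange,
    floor_and_median_normalize,
    global_normalize,
    hcluster_pearson,
    pathway_overlay,
    ratios_to_control,
    run_cascade,
)


def small_design():
    return make_design(2, doses=(0, 1000), days=(1, 3), seed=0)


class TestNormalization:
    def test_column_mean_500(self, rng):
        v = pd.DataFrame(rng.uniform(10, 2000, size=(30, 6)))
        out = global_normalize(v)
        assert np.allclose(out.mean(axis=0), 500.0, rtol=1e-9)

    def test_mean_1000_halved(self):
        v = pd.DataFrame({"a": [500.0, 1500.0]})  # mean 1000
        out = global_normalize(v)
        assert np.allclose(out["a"], [250.0, 750.0])

    def test_already_normalized_unchanged(self):
        v = pd.DataFrame({"a": [400.0, 600.0]})
        pd.testing.assert_frame_equal(global_normalize(v), v)

    def test_floor_and_median(self):
        v = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        out = floor_and_median_normalize(v)
        assert np.allclose(out.iloc[0], [0.5, 1.0, 1.5])
        assert np.allclose(out.iloc[1], 1.0)

    def test_floor_applied_before_division(self):
        v = pd.DataFrame([[0.001, 0.01, 0.1]])
        out = floor_and_median_normalize(v)
        # 0.001 floored to 0.01; row median of (0.01, 0.01, 0.1) is 0.01
        assert np.allclose(out.iloc[0], [1.0, 1.0, 10.0])


class TestDetectionFilter:
    def _es(self, values, flags):
        design = small_design()
        cols = design.sample_ids
        v = pd.DataFrame([values], index=["g"], columns=cols, dtype=float)
        f = pd.DataFrame([flags], index=["g"], columns=cols)
        return ExpressionSet(values=v, flags=f, design=design)

    def test_two_present_flags_excluded(self):
        es = self._es([1000.0] * 8, ["P", "P", "A", "A", "A", "A", "A", "A"])
        assert filter_detected(es) == []

    def test_three_above_threshold_and_flags_kept(self):
        es = self._es(
            [95.0, 92.0, 90.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            ["P", "P", "P", "P", "P", "A", "A", "A"],
        )
        assert filter_detected(es) == ["g"]

    def test_all_absent_flags_exclude_despite_intensity(self):
        es = self._es([1000.0] * 8, ["A"] * 8)
        assert filter_detected(es) == []


class TestFoldChangeFilter:
    def _values(self, treated_day1):
        design = small_design()
        # columns: d01 dose0 r1,r2; d01 dose1000 r1,r2; d03 dose0; d03 dose1000
        vals = [100.0, 100.0, treated_day1, treated_day1, 100.0, 100.0, 100.0, 100.0]
        return pd.DataFrame([vals], index=["g"], columns=design.sample_ids), design

    def test_identical_groups_excluded(self):
        v, d = self._values(100.0)
        assert filter_foldchange(v, d) == []

    def test_twofold_kept(self):
        v, d = self._values(200.0)
        assert filter_foldchange(v, d) == ["g"]

    def test_symmetric_downregulation_kept(self):
        v, d = self._values(60.0)  # r = 0.6, 1/r ~ 1.67
        assert filter_foldchange(v, d) == ["g"]

    def test_missing_control_cell_rejected(self):
        design = make_design(2, doses=(50, 1000), days=(1,), seed=0)
        v = pd.DataFrame(
            [[100.0, 100.0, 200.0, 200.0]], index=["g"], columns=design.sample_ids
        )
        with pytest.raises(ValueError, match="no control group"):
            filter_foldchange(v, design)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert (adj < 0.05).all()  # all four pass at alpha 0.05
        assert adj[3] == pytest.approx(0.04)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=400))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        mine = benjamini_hochberg(np.array(pvals))
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(mine, ref, atol=1e-12)


class TestAnova2BH:
    def test_balanced_matches_statsmodels(self, design80, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        frame = design80.to_frame()
        values = pd.DataFrame(
            rng.uniform(50, 5000, size=(5, 80)),
            index=[f"g{i}" for i in range(5)],
            columns=frame.index,
        )
        res = anova2_bh(values, design80).table
        for g in values.index:
            df = pd.DataFrame(
                {
                    "y": np.log2(values.loc[g].to_numpy()),
                    "dose": frame["dose_ppm"].to_numpy(),
                    "day": frame["day"].to_numpy(),
                }
            )
            ref = sm.stats.anova_lm(
                ols("y ~ C(day) + C(dose) + C(day):C(dose)", df).fit(), typ=2
            )
            assert res.at[g, "F_dose"] == pytest.approx(ref.loc["C(dose)", "F"])
            assert res.at[g, "p_day"] == pytest.approx(ref.loc["C(day)", "PR(>F)"])
            assert res.at[g, "F_dose:day"] == pytest.approx(
                ref.loc["C(day):C(dose)", "F"]
            )

    def test_unbalanced_design_falls_back_to_ols(self, rng):
        design = make_design(3, doses=(0, 1000), days=(1, 3), seed=0)
        frame = design.to_frame().iloc[:-1]  # drop one sample -> unbalanced
        sub = [s for s in design.samples if s.sample_id in frame.index]
        from pbomics.synthetic import StudyDesign

        design_u = StudyDesign(samples=tuple(sub))
        values = pd.DataFrame(
            rng.uniform(100, 1000, size=(3, len(sub))),
            index=["a", "b", "c"],
            columns=frame.index,
        )
        res = anova2_bh(values, design_u).table
        assert {"p_dose", "p_day", "p_dose_adj"} <= set(res.columns)
        assert ((res["p_dose"] >= 0) & (res["p_dose"] <= 1)).all()

    def test_massive_effect_tiny_p(self, design80, rng):
        frame = design80.to_frame()
        base = rng.uniform(400, 600, size=80)
        effect = np.where(frame["dose_ppm"] > 0, 50.0, 1.0)
        values = pd.DataFrame(
            [base * effect], index=["boom"], columns=frame.index
        )
        res = anova2_bh(values, design80).table
        assert res.at["boom", "p_dose_adj"] < 1e-6

    def test_adjusted_never_below_raw(self, design80, rng):
        values = pd.DataFrame(
            rng.uniform(50, 500, size=(40, 80)),
            index=[f"g{i}" for i in range(40)],
            columns=design80.sample_ids,
        )
        res = anova2_bh(values, design80).table
        assert (res["p_dose_adj"] >= res["p_dose"] - 1e-15).all()

    def test_null_false_positive_fraction_controlled(self):
        fractions = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            design = make_design(3, seed=seed)
            values = pd.DataFrame(
                r.lognormal(6, 0.3, size=(400, 48)),
                index=[f"g{i}" for i in range(400)],
                columns=design.sample_ids,
            )
            res = anova2_bh(values, design)
            fractions.append(len(res.significant_treatment) / 400)
        assert np.mean(fractions) <= 0.05


class TestRatiosAndClustering:
    def test_ratio_semantics(self):
        design = small_design()
        # day-1 controls (100, 200): median 150; treated 300 -> ratio 2
        vals = [100.0, 200.0, 300.0, 150.0, 50.0, 50.0, 50.0, 50.0]
        v = pd.DataFrame([vals], index=["g"], columns=design.sample_ids)
        out = ratios_to_control(v, design)
        assert out.iloc[0, 2] == pytest.approx(2.0)
        assert out.iloc[0, 3] == pytest.approx(1.0)
        # day-3 controls are their own denominator
        assert out.iloc[0, 4] == pytest.approx(1.0)

    def test_identical_profiles_merge_first(self):
        profiles = pd.DataFrame(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],  # r = 1 with row 0
                [4.0, 3.0, 2.0, 0.5],
            ],
            index=["a", "b", "c"],
        )
        z, _ = hcluster_pearson(profiles)
        assert set(z[0, :2].astype(int)) == {0, 1}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profile_merges_last(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        profiles = pd.DataFrame(
            [base, base + np.array([0.1, -0.1, 0.1, -0.1]), -base + 5.1],
            index=["a", "b", "c"],
        )
        z, _ = hcluster_pearson(profiles)
        assert z[-1, 2] > z[0, 2]

    def test_merge_order_matches_bruteforce_average_linkage(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(6, 10)))
        z, _ = hcluster_pearson(profiles)
        # brute-force nearest-pair agglomeration with average linkage
        dist = 1 - np.corrcoef(profiles.to_numpy())
        clusters = {i: [i] for i in range(6)}
        next_id = 6
        merges = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                d = np.mean(
                    [dist[a, b] for a in clusters[i] for b in clusters[j]]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
            d, i, j = best
            merges.append((min(i, j), max(i, j), d))
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        for row, (i, j, d) in zip(z, merges):
            assert {int(row[0]), int(row[1])} == {i, j}
            assert row[2] == pytest.approx(d, abs=1e-10)

    def test_constant_profile_rejected_by_name(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flatliner", "ok"]
        )
        with pytest.raises(ValueError, match="flatliner"):
            hcluster_pearson(profiles)


def exact_hypergeom_p(M, K, n, k):
    """Upper-tail hypergeometric by direct combinatorial sum."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestEnrichment:
    def test_toy_case_exact(self):
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        gene_list = {"g0", "g1", "g2"}
        res = enrich(gene_list, {"t": term}, universe)[0]
        assert res.p_value == pytest.approx(10 / 120)
        assert res.overlap == 3

    def test_list_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        res = enrich(universe, {"t": {"g0", "g1"}}, universe)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_kegg_min_overlap_gate(self):
        universe = {f"g{i}" for i in range(20)}
        term = {"g0", "g1", "g2", "g3"}
        gene_list = {"g0", "g1"}  # overlap 2, p tiny but below min_overlap 3
        res = enrich(gene_list, {"t": term}, universe, min_overlap=3)[0]
        assert res.overlap == 2
        assert not res.qualifies

    def test_matches_enumeration_small_universes(self):
        for M in (5, 8, 11, 15):
            universe = {f"g{i}" for i in range(M)}
            for K in (1, M // 2, M - 1):
                term = {f"g{i}" for i in range(K)}
                for n in (1, M // 3 + 1, M):
                    gene_list = {f"g{i}" for i in range(M - n, M)}
                    res = enrich(gene_list, {"t": term}, universe)[0]
                    expected = exact_hypergeom_p(M, K, n, res.overlap)
                    assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_gene_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="missing from universe"):
            enrich({"alien"}, {"t": {"g0"}}, {"g0", "g1"})


class TestPathwayOverlay:
    DEFS = {
        "glycogen_synthesis": ({"hexokinase_d"}, {"glycogen"}),
        "genes_only": ({"geneA"}, {"metB"}),
    }

    def test_co_perturbed_pathway_flagged(self):
        out = pathway_overlay(
            {"hexokinase_d": "down"}, {"glycogen": "down"}, self.DEFS
        )
        assert bool(out.at["glycogen_synthesis", "co_perturbed"])
        assert "hexokinase_d:down" in out.at["glycogen_synthesis", "gene_members"]

    def test_gene_only_changes_not_flagged(self):
        out = pathway_overlay({"geneA": "up"}, {}, self.DEFS)
        assert not out["co_perturbed"].any()

    def test_empty_de_list_flags_nothing(self):
        out = pathway_overlay({}, {"glycogen": "down"}, self.DEFS)
        assert not out["co_perturbed"].any()


class TestCascade:
    def test_stage_counts_non_increasing(self, design80, truth, expression):
        values, flags = expression
        es = ExpressionSet(values=values, flags=flags, design=design80)
        out = run_cascade(es)
        assert len(out["detected"]) <= values.shape[0]
        assert len(out["fold_change"]) <= len(out["detected"])
        assert len(out["significant"]) <= len(out["fold_change"])
        assert set(out["significant"]) <= set(out["fold_change"]) <= set(
            out["detected"]
        )

    def test_planted_genes_recovered(self, design80, truth, expression):
        values, flags = expression
        es = ExpressionSet(values=values, flags=flags, design=design80)
        out = run_cascade(es)
        assert "Cyp2b2" in out["significant"]
        assert "Gck_hexokinaseD" in out["significant"]
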