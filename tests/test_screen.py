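"""Expression filter, size factors, fold changes, clustering, and the screen."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from mycoflux import (
    CorrelationScreen,
    CountMatrix,
    MedianOfRatiosNormalizer,
    category_tally,
    cluster_order,
    filter_expressed,
    flag_extreme_condition,
    foldchange_matrix,
    pearson_critical_value,
    select_percentiles,
    size_factors,
)


def _meta(samples, conditions):
    return pd.DataFrame(
        {
            "sample": samples,
            "condition": conditions,
            "replicate": [f"R{i}" for i in range(len(samples))],
        }
    )


class TestCountMatrix:
    def test_validation(self):
        counts = pd.DataFrame([[1, 2]], index=["g1"], columns=["s1", "s2"])
        org = pd.Series({"g1": "plant"})
        CountMatrix(counts, org)
        with pytest.raises(ValueError, match="non-negative"):
            CountMatrix(counts - 5, org)
        with pytest.raises(ValueError, match="organism tag"):
            CountMatrix(counts, pd.Series({"other": "plant"}))
        dup = pd.DataFrame([[1, 2], [3, 4]], index=["g1", "g1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(dup, org)


class TestFilterExpressed:
    def test_threshold_is_per_condition_mean_in_at_least_one(self):
        # condition A: samples s1,s2; condition B: s3,s4
        counts = pd.DataFrame(
            {
                "s1": [10, 9, 5, 4],
                "s2": [10, 9, 5, 4],
                "s3": [0, 9, 0, 4],
                "s4": [0, 9, 0, 4],
            },
            index=["p_boundary", "p_below", "f_boundary", "f_below"],
        )
        org = pd.Series(
            ["plant", "plant", "fungus", "fungus"], index=counts.index
        )
        meta = _meta(list(counts.columns), ["A", "A", "B", "B"])
        kept, removed = filter_expressed(CountMatrix(counts, org), meta)
        assert list(kept.counts.index) == ["p_boundary", "f_boundary"]
        assert set(removed.index) == {"p_below", "f_below"}

    def test_unknown_organism_errors(self):
        counts = pd.DataFrame({"s1": [5], "s2": [5]}, index=["g"])
        cm = CountMatrix(counts, pd.Series({"g": "alga"}))
        with pytest.raises(ValueError, match="organism"):
            filter_expressed(cm, _meta(["s1", "s2"], ["A", "A"]))


class TestSizeFactors:
    def test_hand_example_doubled_library(self):
        counts = pd.DataFrame({"s1": [2, 4, 6], "s2": [4, 8, 12]})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert sf["s2"] == pytest.approx(math.sqrt(2), abs=1e-12)
        normed = counts / sf
        assert np.allclose(normed["s1"], normed["s2"])

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [3, 7, 11], "s2": [3, 7, 11], "s3": [3, 7, 11]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one library by c scales its factor *relative to the
        others* by c (the estimator is defined up to a common constant)."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(200, 4)) + 1, columns=list("abcd")
        )
        base = size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        got = size_factors(scaled)
        assert got["b"] / got["a"] == pytest.approx(3 * base["b"] / base["a"], rel=1e-9)
        assert got["c"] / got["a"] == pytest.approx(base["c"] / base["a"], rel=1e-9)

    def test_empty_reference_set_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="reference set"):
            size_factors(counts)

    def test_agrees_with_deseq2_reference_implementation(self):
        """Cross-check against the independent pydeseq2 estimator."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(3, 1, size=(300, 1)) * rng.uniform(0.5, 2, 6)),
            columns=[f"s{i}" for i in range(6)],
        ) + 1
        ours = size_factors(counts)
        _, theirs = deseq2_norm(counts.T)  # pydeseq2: samples x genes
        assert np.allclose(ours.to_numpy(), np.asarray(theirs).ravel(), rtol=1e-8)


class TestFoldChange:
    def test_uniform_gene_gives_zero_row(self):
        counts = pd.DataFrame(
            {"a1": [5.0], "a2": [5.0], "b1": [5.0], "b2": [5.0]}, index=["g"]
        )
        meta = _meta(list(counts.columns), ["A", "A", "B", "B"])
        fc = foldchange_matrix(counts, meta, ["g"])
        assert np.allclose(fc.loc["g"], 0.0)

    def test_doubled_condition_gives_log2_of_ratio_to_baseline(self):
        # condition means 4 and 2 -> baseline 3 -> log2(4/3), log2(2/3)
        counts = pd.DataFrame({"a1": [4.0], "b1": [2.0], "a2": [4.0], "b2": [2.0]},
                              index=["g"])
        meta = _meta(list(counts.columns), ["A", "B", "A", "B"])
        fc = foldchange_matrix(counts, meta, ["g"])
        assert fc.loc["g", "A"] == pytest.approx(math.log2(4 / 3))
        assert fc.loc["g", "B"] == pytest.approx(math.log2(2 / 3))

    def test_pseudocount_only_touches_genes_with_zero_mean(self):
        counts = pd.DataFrame(
            {"a1": [8.0, 8.0], "b1": [2.0, 0.0]}, index=["clean", "zeroed"]
        )
        meta = _meta(["a1", "b1"], ["A", "B"])
        fc = foldchange_matrix(counts, meta, ["clean", "zeroed"], pseudocount=1.0)
        assert fc.loc["clean", "A"] == pytest.approx(math.log2(8 / 5))
        assert fc.loc["zeroed", "A"] == pytest.approx(math.log2(9 / 5))
        with pytest.raises(ValueError, match="zero condition mean"):
            foldchange_matrix(counts, meta, ["zeroed"], pseudocount=0.0)

    def test_control_excluded_from_baseline_but_reported(self):
        counts = pd.DataFrame(
            {"a1": [4.0], "b1": [2.0], "c1": [30.0]}, index=["g"]
        )
        meta = _meta(["a1", "b1", "c1"], ["A", "B", "control"])
        fc = foldchange_matrix(counts, meta, ["g"], control_condition="control")
        assert fc.loc["g", "A"] == pytest.approx(math.log2(4 / 3))  # baseline is 3
        assert fc.loc["g", "control"] == pytest.approx(math.log2(30 / 3))


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        m = pd.DataFrame([[0, 0], [5, 5], [0, 0]], index=["x", "far", "y"])
        order = cluster_order(m)
        pos = {m.index[i]: rank for rank, i in enumerate(order)}
        assert abs(pos["x"] - pos["y"]) == 1

    def test_distant_row_outside_tight_pair(self):
        m = pd.DataFrame([[0.0, 0], [0.1, 0], [9, 9]])
        order = list(cluster_order(m))
        assert order.index(2) in (0, 2)  # leaf at one end, not between the pair

    def test_is_a_permutation_and_rejects_nan(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        order = cluster_order(m)
        assert sorted(order) == list(range(10))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cluster_order(m)

    def test_column_axis(self):
        m = pd.DataFrame([[0, 5, 0], [0, 5, 0]], columns=["a", "far", "b"])
        order = cluster_order(m, axis=1)
        assert sorted(order) == [0, 1, 2]


class TestFlagExtreme:
    def test_row_max_or_min_in_focal_condition(self):
        fc = pd.DataFrame(
            {"A": [3.0, 1.0, 2.0], "B": [2.0, 2.0, 1.0], "C": [1.0, 3.0, 3.0]},
            index=["maxA", "minA", "midA"],
        )
        flags = flag_extreme_condition(fc, "A")
        assert flags.tolist() == [True, True, False]
        with pytest.raises(KeyError):
            flag_extreme_condition(fc, "missing")


class TestSelectPercentiles:
    @pytest.mark.parametrize(
        "n, m", [(24615, 247), (12959, 130), (100, 1), (101, 2), (1000, 10)]
    )
    def test_tail_sizes(self, n, m):
        rng = np.random.default_rng(n)
        r = pd.Series(rng.uniform(-1, 1, n))
        sel = select_percentiles(r)
        assert sel.m == m == len(sel.top_ids) == len(sel.bottom_ids)

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(17)
        for n in (100, 137, 250, 999, 2500):
            r = pd.Series(rng.normal(0, 0.3, n), index=[f"t{i:05d}" for i in range(n)])
            sel = select_percentiles(r)
            m = math.ceil(0.01 * n)
            srt = r.sort_values(kind="stable")
            assert set(sel.bottom_ids) == set(srt.index[:m])
            assert set(sel.top_ids) == set(srt.index[-m:])
            assert sel.q99 == pytest.approx(srt.iloc[-m])
            assert sel.q01 == pytest.approx(srt.iloc[m - 1])

    def test_ties_broken_by_transcript_order(self):
        r = pd.Series(np.ones(150), index=[f"g{i:03d}" for i in range(150)])
        sel = select_percentiles(r)
        assert sel.top_ids == ["g000", "g001"]
        assert sel.bottom_ids == ["g000", "g001"]

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="at least 100"):
            select_percentiles(pd.Series(np.arange(99.0)))


class TestCriticalValue:
    def test_published_table_value_n9(self):
        assert pearson_critical_value(9, 0.05) == pytest.approx(0.666, abs=5e-4)

    def test_limits_and_monotonicity(self):
        assert pearson_critical_value(9, 0.9999) < 1e-3
        vals = [pearson_critical_value(n) for n in range(3, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            pearson_critical_value(2)


class TestCorrelationScreen:
    def _toy(self, n_genes=200, seed=0):
        rng = np.random.default_rng(seed)
        isolates = [f"I{i}" for i in range(9)]
        samples = [f"{iso}_R{r}" for iso in isolates for r in range(3)]
        cond = [s.split("_")[0] for s in samples]
        meta = _meta(samples, cond)
        c = pd.Series(rng.uniform(0.01, 0.15, 9), index=isolates)
        counts = pd.DataFrame(
            rng.poisson(50, size=(n_genes, len(samples))).astype(float),
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=samples,
        )
        return counts, meta, c

    def test_affine_transcript_is_top_with_r_one(self):
        counts, meta, c = self._toy()
        y = c.loc[[s.split("_")[0] for s in counts.columns]].to_numpy()
        counts.loc["g0000"] = 1000 * y + 5
        scr = CorrelationScreen().fit(counts, meta, c)
        row = scr.results_.loc["g0000"]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["selected"] == "top"
        assert row["significant"]

    def test_zero_variance_transcript_flagged_never_selected(self):
        counts, meta, c = self._toy()
        counts.loc["g0000"] = 7.0
        scr = CorrelationScreen().fit(counts, meta, c)
        row = scr.results_.loc["g0000"]
        assert row["r_undefined"] and row["pearson_r"] == 0.0
        assert row["selected"] == "none" and not row["significant"]

    def test_effective_n_by_pairing_mode(self):
        counts, meta, c = self._toy()
        rep = CorrelationScreen(pairing="replicate").fit(counts, meta, c)
        avg = CorrelationScreen(pairing="averaged").fit(counts, meta, c)
        assert rep.effective_n_ == 27
        assert avg.effective_n_ == 9
        assert avg.r_critical_ > rep.r_critical_

    def test_control_condition_excluded(self):
        counts, meta, c = self._toy()
        ctrl = pd.DataFrame(
            {f"Ctrl_R{r}": np.zeros(len(counts)) for r in range(3)},
            index=counts.index,
        )
        counts2 = pd.concat([counts, ctrl], axis=1)
        meta2 = _meta(
            list(counts2.columns),
            [s.split("_")[0] if not s.startswith("Ctrl") else "control"
             for s in counts2.columns],
        )
        a = CorrelationScreen().fit(counts, meta, c).results_["pearson_r"]
        b = CorrelationScreen().fit(counts2, meta2, c).results_["pearson_r"]
        assert np.allclose(a, b)

    def test_tail_counts_follow_percentile_rule(self):
        counts, meta, c = self._toy(n_genes=500)
        scr = CorrelationScreen().fit(counts, meta, c)
        assert (scr.results_["selected"] == "top").sum() == scr.m_per_tail_ == 5
        assert (scr.results_["selected"] == "bottom").sum() == 5


class TestCategoryTally:
    def _results(self, ids, selected):
        return pd.DataFrame({"selected": selected}, index=ids)

    def test_all_transcription_factors(self):
        res = self._results(["a", "b"], ["top", "bottom"])
        ann = pd.Series({"a": "zinc finger Transcription Factor", "b": "MYB protein"})
        tally = category_tally(res, ann).set_index(["tail", "category"])
        assert tally.loc[("top", "transcription regulation"), "percent"] == 100.0
        assert tally.loc[("bottom", "transcription regulation"), "percent"] == 100.0

    def test_manual_count_on_toy_set(self):
        ids = [f"g{i}" for i in range(4)]
        res = self._results(ids, ["top", "top", "bottom", "none"])
        ann = pd.Series(
            {
                "g0": "sugar transporter",  # C metabolism AND transport
                "g1": "hypothetical protein",
                "g2": "serine/threonine kinase",
                "g3": "cyclin",
            }
        )
        tally = category_tally(res, ann).set_index(["tail", "category"])
        assert tally.loc[("top", "transport"), "n_matching"] == 1
        assert tally.loc[("top", "C metabolism"), "n_matching"] == 1
        assert tally.loc[("top", "transport"), "percent"] == 50.0
        assert tally.loc[("bottom", "signal transduction"), "percent"] == 100.0

    def test_empty_selection_and_missing_annotations_warn(self):
        res = self._results(["a"], ["top"])
        with pytest.warns(UserWarning):
            tally = category_tally(res, pd.Series(dtype=object))
        assert (tally["percent"] == 0).all() or (tally["n_selected"] == 0).any()
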