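"""Wilcoxon/BH differential expression, survival, tissue/fraction summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sisrna.cohort import (
    bh_adjust,
    differential_expression,
    fraction_summary,
    km_logrank,
    read_metadata,
    tissue_summary,
    wilcoxon_rank_sum,
)


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled
    values (no ties assumed)."""
    pooled = list(x) + list(y)
    nx = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)
    stats = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        s = sum(sorted(pooled).index(pooled[i]) + 1 for i in combo)
        stats.append(s)
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats)


class TestWilcoxon:
    def test_identical_groups(self):
        assert wilcoxon_rank_sum([1, 1, 1], [1, 1, 1]) == 1.0

    def test_fully_separated_small_groups_exact(self):
        p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(wilcoxon_enumeration_oracle([1, 2, 3], [4, 5, 6]))

    def test_random_small_groups_match_enumeration(self, rng):
        for _ in range(15):
            vals = rng.choice(1000, size=9, replace=False).astype(float)
            x, y = vals[:4], vals[4:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_enumeration_oracle(x, y), abs=1e-9
            )

    def test_normal_approximation_close_to_exact_at_6_plus_6(self, rng):
        for _ in range(10):
            vals = rng.choice(10_000, size=12, replace=False).astype(float)
            x, y = vals[:6], vals[6:]
            exact = wilcoxon_enumeration_oracle(x, y)
            approx = wilcoxon_rank_sum(x, y, method="asymptotic")
            assert abs(approx - exact) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_step_up_definition_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_definition_oracle(self, rng):
        def oracle(ps):
            m = len(ps)
            order = np.argsort(ps)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                q[i] = running
            return q

        for _ in range(20):
            ps = rng.random(size=int(rng.integers(1, 30)))
            np.testing.assert_allclose(bh_adjust(ps), oracle(ps), atol=1e-12)

    def test_q_nondecreasing_along_sorted_p(self, rng):
        ps = np.sort(rng.random(25))
        qs = bh_adjust(ps)
        assert (np.diff(qs) >= -1e-12).all()
        assert (qs >= ps - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialExpression:
    def _inputs(self, counts_total=20, n_samples_detected=12):
        samples = [f"a{i}" for i in range(12)] + [f"b{i}" for i in range(12)]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "library_size": 1e6,
                "risk_class": ["1"] * 12 + ["2"] * 12,
            }
        ).set_index("sample_id", drop=False)
        per = counts_total // n_samples_detected
        row = [per] * n_samples_detected + [0] * (24 - n_samples_detected)
        raw = pd.DataFrame([row], index=["f1"], columns=samples)
        rpm = raw * 1.0
        return rpm, raw, meta

    def test_feature_with_exactly_min_reads_excluded(self):
        rpm, raw, meta = self._inputs(counts_total=10, n_samples_detected=10)
        de = differential_expression(rpm, raw, meta, min_reads=10, min_samples=10)
        assert len(de) == 0  # strictly more than ten reads required

    def test_feature_above_threshold_tested(self):
        rpm, raw, meta = self._inputs(counts_total=12, n_samples_detected=12)
        de = differential_expression(rpm, raw, meta, min_reads=10, min_samples=10)
        assert set(de["cluster_id"]) == {"f1"}

    def test_detection_breadth_filter(self):
        rpm, raw, meta = self._inputs(counts_total=40, n_samples_detected=8)
        de = differential_expression(rpm, raw, meta, min_reads=10, min_samples=10)
        assert len(de) == 0

    def test_bh_family_is_per_class_pair(self, rng):
        samples = [f"s{i}" for i in range(30)]
        classes = ["1"] * 10 + ["2"] * 10 + ["3"] * 10
        meta = pd.DataFrame(
            {"sample_id": samples, "library_size": 1e6, "risk_class": classes}
        ).set_index("sample_id", drop=False)
        raw = pd.DataFrame(
            rng.poisson(5, size=(6, 30)), columns=samples,
            index=[f"f{i}" for i in range(6)],
        )
        rpm = raw * 1.0
        de = differential_expression(rpm, raw, meta, min_reads=10, min_samples=10)
        for (_, _), fam in de.groupby(["group_a", "group_b"]):
            np.testing.assert_allclose(
                fam["q"].to_numpy(), bh_adjust(fam["p"].to_numpy()), atol=1e-12
            )

    def test_planted_shift_recovered(self, rng):
        from sisrna.simulate import simulate_de_matrix

        rpm, raw, meta, affected = simulate_de_matrix(
            rng, n_features=60, class_sizes={"1": 40, "2": 60},
            effect_logfc=2.0, fraction_affected=0.2,
        )
        de = differential_expression(rpm, raw, meta, min_reads=10, min_samples=10)
        called = set(de.loc[de["significant"], "cluster_id"])
        tested = set(de["cluster_id"])
        assert affected & tested, "planted features must pass the filters"
        sens = len(called & affected) / len(affected & tested)
        assert sens >= 0.8


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from the O-E/V formula."""
    all_times = sorted({t for t, e in zip(list(times_a) + list(times_b),
                                          list(events_a) + list(events_b)) if e})
    O_E = 0.0
    V = 0.0
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        exp_a = d * n_a / n
        O_E += d_a - exp_a
        V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestSurvival:
    def _meta(self, times, events):
        n = len(times)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "library_size": 1e6,
                "surv_time": times,
                "surv_event": events,
            }
        ).set_index("sample_id", drop=False)

    def test_eight_subject_fixture_matches_formula_oracle(self):
        # high group: values > median
        values = pd.Series(
            [5, 6, 7, 8, 1, 1, 2, 2], index=[f"s{i}" for i in range(8)], dtype=float
        )
        times = [10, 14, 18, 22, 3, 5, 7, 9]
        events = [1, 0, 1, 1, 1, 1, 0, 1]
        meta = self._meta(times, events)
        res = km_logrank(values, meta)
        expected = logrank_oracle(times[:4], events[:4], times[4:], events[4:])
        assert res.chi2 == pytest.approx(expected, rel=1e-6)

    def test_label_swap_invariance(self, rng):
        values = pd.Series(rng.random(30), index=[f"s{i}" for i in range(30)])
        meta = self._meta(rng.exponential(10, 30), rng.integers(0, 2, 30))
        p1 = km_logrank(values, meta).p
        p2 = km_logrank(-values, meta).p  # groups swap
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_median_splits_zero_vs_positive(self):
        values = pd.Series(
            [0, 0, 0, 0, 0, 1.0, 2.0, 3.0], index=[f"s{i}" for i in range(8)]
        )
        meta = self._meta([5] * 8, [1] * 8)
        res = km_logrank(values, meta, cutoff="median")
        assert res.cutoff == 0.0
        assert res.n_high == 3 and res.n_low == 5

    def test_degenerate_cutoff_rejected_with_suggestion(self):
        values = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        meta = self._meta([5] * 6, [1] * 6)
        with pytest.raises(ValueError, match="cutoff"):
            km_logrank(values, meta)

    def test_planted_hazard_ratio_detected(self):
        from sisrna.simulate import simulate_survival_cohort

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values, meta = simulate_survival_cohort(rng, n=200, hazard_ratio=2.0)
            if km_logrank(values, meta).p < 0.05:
                hits += 1
        assert hits >= 18


class TestTissueSummary:
    def _fixture(self):
        samples = ["t1a", "t1b", "t2a"]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "library_size": 1e6,
                "tissue": ["bladder", "bladder", "brain"],
            }
        ).set_index("sample_id", drop=False)
        rpm = pd.DataFrame(
            {"t1a": [90.0, 5.0, 5.0], "t1b": [90.0, 5.0, 5.0], "t2a": [0.0, 7.0, 0.0]},
            index=["f1", "f2", "f3"],
        )
        raw = (rpm > 0).astype(int) * 3
        return rpm, raw, meta

    def test_top_decile_contribution(self):
        rpm, raw, meta = self._fixture()
        res = tissue_summary(rpm, raw, meta)
        bl = res.per_tissue.set_index("tissue").loc["bladder"]
        # 3 detected features -> top decile = 1 feature = 90 of 100
        assert bl["n_detected"] == 3
        assert bl["top_decile_contribution"] == pytest.approx(0.9)

    def test_tissue_counts_per_feature(self):
        rpm, raw, meta = self._fixture()
        res = tissue_summary(rpm, raw, meta)
        assert res.tissues_per_feature["f1"] == 1
        assert res.tissues_per_feature["f2"] == 2
        assert res.tissues_per_feature["f3"] == 1

    def test_circle_fraction(self):
        rpm, raw, meta = self._fixture()
        classes = pd.Series(
            {"f1": "intronic_circle", "f2": "stable_lariat", "f3": "stable_lariat"}
        )
        res = tissue_summary(rpm, raw, meta, classes)
        bl = res.per_tissue.set_index("tissue").loc["bladder"]
        assert bl["circle_fraction"] == pytest.approx(1 / 3)

    def test_detection_threshold(self):
        rpm, raw, meta = self._fixture()
        raw.loc["f2", ["t1a", "t1b"]] = 0  # below the 2-read rule in bladder
        res = tissue_summary(rpm, raw, meta)
        bl = res.per_tissue.set_index("tissue").loc["bladder"]
        assert bl["n_detected"] == 2


class TestFractionSummary:
    def test_quartiles_and_overlap(self):
        samples = ["nuc", "cyt"]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "library_size": 1e6,
                "tissue": ["K562", "K562"],
                "fraction": ["nuclear", "cytoplasmic"],
            }
        ).set_index("sample_id", drop=False)
        feats = [f"f{i}" for i in range(5)]
        rpm = pd.DataFrame(
            {"nuc": [0, 0, 1, 1, 1], "cyt": [1, 1, 1, 1, 1]}, index=feats, dtype=float
        )
        lengths = pd.Series([1, 2, 3, 4, 5], index=feats, dtype=float)
        res = fraction_summary(rpm, meta, lengths)
        cyt = res.per_fraction.set_index("fraction").loc["cytoplasmic"]
        assert cyt["median_length"] == 3.0 and cyt["iqr_length"] == 2.0
        row = res.overlap.set_index("cell_line").loc["K562"]
        assert (row["n_nuclear"], row["n_cytoplasmic"], row["n_overlap"]) == (3, 5, 3)

    def test_disjoint_sets_zero_overlap(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["n", "c"],
                "library_size": 1e6,
                "tissue": ["L", "L"],
                "fraction": ["nuclear", "cytoplasmic"],
            }
        ).set_index("sample_id", drop=False)
        rpm = pd.DataFrame({"n": [1.0, 0.0], "c": [0.0, 1.0]}, index=["a", "b"])
        res = fraction_summary(rpm, meta, pd.Series({"a": 10.0, "b": 20.0}))
        assert res.overlap["n_overlap"].tolist() == [0]


def test_read_metadata_survival_jointness(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(
        "sample_id\tlibrary_size\tsurv_time\tsurv_event\n"
        "s1\t1000000\t10.0\t1\n"
        "s2\t1000000\t\t\n"
    )
    meta = read_metadata(path)
    assert meta.loc["s1", "surv_event"] == 1
    assert math.isnan(meta.loc["s2", "surv_time"])
    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "sample_id\tlibrary_size\tsurv_time\tsurv_event\ns1\t1000000\t10.0\t\n"
    )
    with pytest.raises(ValueError, match="jointly"):
        read_metadata(bad)
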