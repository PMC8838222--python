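"""Karyotype morphometrics: Levan classes, indices, formulae, Stebbins."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoploid import (
    ArmPair,
    EmptyKaryotypeError,
    InvalidMeasurementError,
    MetaphaseKaryotype,
    arm_ratio_mean,
    ask_percent,
    centromeric_index_mean,
    classify_levan,
    classify_levan_ratio,
    karyotype_formula,
    parse_karyotype_formula,
    s_percent,
    stebbins_class,
    summarize_karyotype,
    syi_percent,
    tf_percent,
)
from karyoploid.karyotype import mean_karyotype, read_measurements_csv


def uniform_karyotype(q, p, n=8, two_n=16):
    return MetaphaseKaryotype("test", tuple(ArmPair(q, p) for _ in range(n)), two_n)


arm_lists = st.lists(
    st.tuples(
        st.floats(0.1, 5.0, allow_nan=False, allow_infinity=False),
        st.floats(0.1, 5.0, allow_nan=False, allow_infinity=False),
    ),
    min_size=1,
    max_size=24,
)


def karyotype_from(arms, two_n=None):
    pairs = tuple(ArmPair(q, p) for q, p in arms)
    return MetaphaseKaryotype("hyp", pairs, two_n or 2 * len(pairs))


# ---------------------------------------------------------------------------
# ArmPair / MetaphaseKaryotype construction
# ---------------------------------------------------------------------------

class TestConstruction:
    def test_arm_pair_swaps_misordered_input(self):
        pair = ArmPair(2.0, 1.0)
        assert (pair.q, pair.p) == (1.0, 2.0)
        assert pair.ratio == 2.0

    @pytest.mark.parametrize("q,p", [(0.0, 1.0), (-1.0, 1.0), (float("nan"), 1.0), (1.0, float("inf"))])
    def test_invalid_arms_rejected(self, q, p):
        with pytest.raises(InvalidMeasurementError):
            ArmPair(q, p)

    def test_empty_karyotype_rejected(self):
        with pytest.raises(EmptyKaryotypeError):
            MetaphaseKaryotype("x", (), 16)

    def test_odd_somatic_number_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            MetaphaseKaryotype("x", (ArmPair(1, 1),), 15)

    def test_chromosomes_sorted_longest_first(self):
        k = karyotype_from([(0.5, 0.6), (1.0, 2.0), (0.9, 1.0)])
        totals = [c.total for c in k.chromosomes]
        assert totals == sorted(totals, reverse=True)

    def test_ploidy_from_base_number(self):
        assert karyotype_from([(1, 1)] * 8, two_n=16).ploidy == 2
        assert karyotype_from([(1, 1)] * 24, two_n=48).ploidy == 6
        assert karyotype_from([(1, 1)] * 7, two_n=14).ploidy is None  # 14 not divisible by 8


# ---------------------------------------------------------------------------
# Levan classification
# ---------------------------------------------------------------------------

def levan_oracle(r, tol=0.05):
    """Independent threshold-table lookup used to cross-check the classifier."""
    table = [(1.0 + tol, "M"), (1.7, "m"), (3.0, "sm"), (7.0, "st"), (float("inf"), "t")]
    for upper, label in table:
        if r <= upper:
            return label
    raise AssertionError


class TestLevan:
    @pytest.mark.parametrize(
        "q,p,expected",
        [
            (1.0, 1.0, "M"),     # exactly median
            (1.0, 1.5, "m"),
            (1.0, 2.5, "sm"),
            (1.0, 10.0, "t"),
            (1.0, 1.05, "M"),    # boundary grid: lower class wins
            (1.0, 1.7, "m"),
            (1.0, 3.0, "sm"),
            (1.0, 7.0, "st"),
        ],
    )
    def test_examples_and_boundaries(self, q, p, expected):
        assert classify_levan(ArmPair(q, p)) == expected

    def test_matches_oracle_on_dense_grid(self):
        grid = np.concatenate([np.linspace(1.0, 9.0, 801), [1.05, 1.7, 3.0, 7.0]])
        for r in grid:
            assert classify_levan_ratio(float(r)) == levan_oracle(float(r))

    def test_median_tolerance_configurable(self):
        assert classify_levan_ratio(1.09, median_tolerance=0.1) == "M"
        assert classify_levan_ratio(1.09, median_tolerance=0.05) == "m"

    def test_ratio_below_one_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            classify_levan_ratio(0.9)


# ---------------------------------------------------------------------------
# karyotype formula
# ---------------------------------------------------------------------------

class TestFormula:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["m"] * 8, "8m"),
            (["M"] + ["m"] * 6 + ["sm"], "1M + 6m + 1sm"),
            (["t", "M", "st"], "1M + 1st + 1t"),  # canonical ordering
        ],
    )
    def test_render(self, labels, expected):
        assert karyotype_formula(labels) == expected

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(EmptyKaryotypeError):
            karyotype_formula([])
        with pytest.raises(ValueError):
            karyotype_formula(["m", "xx"])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.sampled_from(["M", "m", "sm", "st", "t"]), min_size=1, max_size=30)
    )
    def test_roundtrip_preserves_multiset(self, labels):
        rendered = karyotype_formula(labels)
        recovered = parse_karyotype_formula(rendered)
        assert sorted(recovered) == sorted(labels)
        assert len(recovered) == len(labels)


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

class TestIndices:
    @pytest.mark.parametrize(
        "q,p,field,expected",
        [
            (1.44, 1.95, "tf_pct", 42),   # most symmetric arms, largest species
            (1.44, 1.95, "ask_pct", 57),
            (0.66, 0.81, "tf_pct", 45),   # highest TF% in the section
            (0.99, 1.76, "tf_pct", 36),   # lowest TF%
            (0.96, 1.15, "syi_pct", 83),  # highest Syi%
            (0.96, 1.15, "ask_pct", 54),  # lowest AsK%
            (0.66, 0.81, "syi_pct", 81),
        ],
    )
    def test_headline_values(self, q, p, field, expected):
        row = summarize_karyotype(uniform_karyotype(q, p)).report_row()
        assert row[field] == expected

    def test_symmetric_karyotype_extremes(self):
        k = uniform_karyotype(1.0, 1.0)
        assert tf_percent(k) == 50.0
        assert ask_percent(k) == 50.0
        assert syi_percent(k) == 100.0
        assert s_percent(k) == 100.0
        assert arm_ratio_mean(k) == 1.0
        assert centromeric_index_mean(k) == 0.5

    def test_centromeric_index_headline(self):
        assert round(centromeric_index_mean(uniform_karyotype(0.96, 1.15)), 2) == 0.45

    def test_per_chromosome_averaging_matches_loop(self):
        arms = [(0.9, 1.2), (0.5, 2.1), (1.0, 1.0), (0.7, 3.5)]
        k = karyotype_from(arms)
        assert arm_ratio_mean(k) == pytest.approx(np.mean([p / q for q, p in arms]))
        assert centromeric_index_mean(k) == pytest.approx(
            np.mean([q / (q + p) for q, p in arms])
        )

    def test_s_percent_matches_min_max_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            arms = rng.uniform(0.3, 3.0, size=(rng.integers(2, 12), 2))
            k = karyotype_from([tuple(a) for a in arms])
            totals = [c.total for c in k.chromosomes]
            assert s_percent(k) == pytest.approx(100 * min(totals) / max(totals))

    def test_forced_two_chromosome_ratio(self):
        k = karyotype_from([(1.0, 1.0), (2.0, 2.0)], two_n=4)
        assert s_percent(k) == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=150)
    @given(arm_lists)
    def test_tf_ask_complement_identity(self, arms):
        k = karyotype_from(arms)
        assert tf_percent(k) + ask_percent(k) == pytest.approx(100.0, abs=1e-9)
        assert 0 < tf_percent(k) <= 50.0 + 1e-9

    @settings(derandomize=True, max_examples=150)
    @given(arm_lists, st.floats(0.1, 10.0))
    def test_scaling_and_order_invariance(self, arms, factor):
        k = karyotype_from(arms)
        scaled = karyotype_from([(q * factor, p * factor) for q, p in arms])
        shuffled = karyotype_from(arms[::-1])
        for fn in (tf_percent, ask_percent, syi_percent, s_percent, arm_ratio_mean,
                   centromeric_index_mean):
            assert fn(scaled) == pytest.approx(fn(k), rel=1e-9)
            assert fn(shuffled) == pytest.approx(fn(k), rel=1e-9)

    @settings(derandomize=True, max_examples=80)
    @given(arm_lists)
    def test_identical_chromosomes_link_ci_and_tf(self, arms):
        # for a complement of identical chromosomes Ci == TF/100 exactly
        q, p = arms[0]
        k = uniform_karyotype(q, p, n=6, two_n=12)
        assert centromeric_index_mean(k) == pytest.approx(tf_percent(k) / 100.0)


# ---------------------------------------------------------------------------
# Stebbins classification
# ---------------------------------------------------------------------------

def stebbins_oracle(totals, ratios):
    ls = max(totals) / min(totals)
    letter = "A" if ls < 2 else ("B" if ls <= 4 else "C")
    pi = sum(r >= 2 for r in ratios) / len(ratios)
    digit = "1" if pi == 0 else "2" if pi <= 0.5 else "3" if pi < 1 else "4"
    return digit + letter


class TestStebbins:
    def test_trivial_corners(self):
        assert stebbins_class(uniform_karyotype(1.0, 1.0)) == "1A"
        assert stebbins_class(uniform_karyotype(0.5, 1.5)) == "4A"  # all r = 3

    def test_random_sets_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            arms = [tuple(a) for a in rng.uniform(0.2, 4.0, size=(rng.integers(2, 16), 2))]
            k = karyotype_from(arms)
            totals = [c.total for c in k.chromosomes]
            ratios = [c.ratio for c in k.chromosomes]
            assert stebbins_class(k) == stebbins_oracle(totals, ratios)


# ---------------------------------------------------------------------------
# summaries and measurement I/O
# ---------------------------------------------------------------------------

class TestSummary:
    def test_uniform_complement_summary(self):
        s = summarize_karyotype(uniform_karyotype(1.44, 1.95))
        assert s.cl == pytest.approx(3.39)
        assert s.kf == "8m"  # identical arms with r = 1.35 are all metacentric
        row = s.report_row()
        assert row["tf_pct"] == 42
        assert row["ask_pct"] == 57  # truncated, so TF + AsK prints as 99
        assert row["syi_pct"] == 74
        assert row["cl_um"] == 3.39

    def test_all_median_complement(self):
        s = summarize_karyotype(uniform_karyotype(1.0, 1.0, n=4, two_n=8))
        assert s.cl == pytest.approx(2.0)
        assert s.tf == pytest.approx(50.0)
        assert s.syi == pytest.approx(100.0)
        assert s.kf == "4M"
        assert s.stebbins == "1A"

    def test_generator_roundtrip_recovers_formula(self):
        from karyoploid import SimKaryotypeSpec, gen_karyotype

        spec = SimKaryotypeSpec(formula="2M + 12m + 2sm", noise_sd=0.0, seed=42)
        k, _ = gen_karyotype(spec)
        assert summarize_karyotype(k).kf == "2M + 12m + 2sm"

    def test_read_measurements_reports_bad_lines_and_continues(self, tmp_path):
        csv = tmp_path / "m.csv"
        csv.write_text(
            "individual_id,plate_id,chromosome_index,short_arm_um,long_arm_um\n"
            "ind1,p1,1,1.0,1.2\n"
            "ind1,p1,2,-1.0,1.2\n"   # invalid arm
            "ind1,p1,3,0.9,1.1\n"
        )
        karyotypes, errors = read_measurements_csv(csv)
        assert len(errors) == 1 and "line 3" in errors[0]
        assert karyotypes[("ind1", "p1")].n == 2

    def test_mean_across_plates(self):
        a = uniform_karyotype(1.0, 2.0, n=4, two_n=8)
        b = uniform_karyotype(2.0, 4.0, n=4, two_n=8)
        merged = mean_karyotype([a, b])
        assert merged.chromosomes[0].q == pytest.approx(1.5)
        assert merged.chromosomes[0].p == pytest.approx(3.0)
        with pytest.raises(InvalidMeasurementError):
            mean_karyotype([a, uniform_karyotype(1, 2, n=5, two_n=10)])
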