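"""Window classification: normalization, Poisson class scores, contig cleanup, N50."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msynet.synthetic_data import example_cohort, example_template, simulate_depths, window_truth
from msynet.window_classification import (
    WindowDepthTable,
    WindowClassification,
    assembly_stats,
    classify_windows,
    clean_contigs,
    normalize_depths,
    tile_windows,
)


def make_table(depths_by_sample, sexes, window=50):
    n = len(next(iter(depths_by_sample.values())))
    frame = pd.DataFrame(
        {
            "contig": ["c1"] * n,
            "start": np.arange(n) * window,
            "end": (np.arange(n) + 1) * window,
            **depths_by_sample,
        }
    )
    return WindowDepthTable(frame=frame, sexes=sexes)


# ---------------------------------------------------------------------------
# Normalization


def test_constant_depth_sample_normalizes_to_one():
    t = make_table({"M": [7.0] * 10, "F": [3.0] * 10}, {"M": "male", "F": "female"})
    norm = normalize_depths(t)
    assert (norm.frame["M"] == 1.0).all()
    assert norm.norm_factors["M"] == 7.0


def test_normalization_is_scale_invariant_between_samples():
    t = make_table({"A": [10.0, 30.0], "F": [1.0, 3.0]}, {"A": "male", "F": "female"})
    norm = normalize_depths(t)
    assert norm.frame["A"].tolist() == norm.frame["F"].tolist() == [0.5, 1.5]


def test_excluded_sample_absent_from_output():
    t = make_table(
        {"DC269": [5.0, 5.0], "M": [4.0, 6.0], "F": [4.0, 4.0]},
        {"DC269": "male", "M": "male", "F": "female"},
    )
    norm = normalize_depths(t, exclude=("DC269",))
    assert "DC269" not in norm.samples


def test_zero_total_sample_errors_with_name():
    t = make_table({"M": [0.0, 0.0], "F": [1.0, 1.0]}, {"M": "male", "F": "female"})
    with pytest.raises(ValueError, match="M"):
        normalize_depths(t)


# ---------------------------------------------------------------------------
# Classification


def normalized_table(m_mean, f_mean, n=5):
    return make_table(
        {"M": [m_mean] * n, "F": [f_mean] * n}, {"M": "male", "F": "female"}
    )


def poisson_ll(x, lam):
    return x * math.log(lam) - lam


def direct_class_scores(m, f, D=20.0, eps=0.02, k_max=20):
    """Independent evaluation of the three class likelihoods (and best k)."""
    scores = {
        "nonMSY": poisson_ll(m * D, D) + poisson_ll(f * D, D),
        "scY": poisson_ll(m * D, 0.5 * D) + poisson_ll(f * D, eps * D),
    }
    best = max(range(2, k_max + 1), key=lambda k: poisson_ll(m * D, 0.5 * k * D))
    scores["mcY"] = poisson_ll(m * D, 0.5 * best * D) + poisson_ll(f * D, eps * D)
    return scores, best


@pytest.mark.parametrize(
    "m,f,expected,k",
    [
        (1.0, 1.0, "nonMSY", 0),
        (0.5, 0.02, "scY", 1),
        (1.5, 0.02, "mcY", 3),
        (2.0, 0.02, "mcY", 4),
    ],
)
def test_classification_matches_direct_likelihood_argmax(m, f, expected, k):
    cls = classify_windows(normalized_table(m, f), ref_depth=20.0)
    assert (cls.frame["assigned"] == expected).all()
    if k:
        assert (cls.frame["copy_number"] == k).all()
    scores, best_k = direct_class_scores(m, f)
    assert max(scores, key=scores.get) == expected
    if expected == "mcY":
        assert best_k == k


def test_all_zero_window_gets_nocall_sentinel():
    cls = classify_windows(normalized_table(0.0, 0.0), ref_depth=20.0)
    assert (cls.frame["assigned"] == "nocall").all()


@given(st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=20, deadline=None)
def test_assignments_invariant_to_per_sample_rescaling(c):
    """Multiplying one sample's raw depths by any constant changes nothing."""
    rng = np.random.default_rng(42)
    raw = {
        "M1": rng.poisson(10.0, 200).astype(float),
        "M2": rng.poisson(5.0, 200).astype(float),
        "F1": rng.poisson(12.0, 200).astype(float),
        "F2": rng.poisson(8.0, 200).astype(float),
    }
    sexes = {"M1": "male", "M2": "male", "F1": "female", "F2": "female"}
    base = classify_windows(normalize_depths(make_table(raw, sexes)))
    scaled = dict(raw, M1=raw["M1"] * c)
    rescaled = classify_windows(normalize_depths(make_table(scaled, sexes)))
    assert base.frame["assigned"].tolist() == rescaled.frame["assigned"].tolist()


def test_true_classes_recovered_on_synthetic_cohort():
    """>= 95% of windows recover their simulated class at 10x+ depth."""
    template = example_template(seed=2)
    cohort = example_cohort(seed=2)
    depths = simulate_depths(template, cohort)
    truth = window_truth(template, cohort.window_size)
    cls = classify_windows(normalize_depths(depths, exclude=("DC269",)))
    agree = (cls.frame["assigned"].to_numpy() == truth["copy_class"].to_numpy()).mean()
    assert agree >= 0.95


# ---------------------------------------------------------------------------
# Contig cleanup


def toy_classification(rows):
    frame = pd.DataFrame(rows, columns=["contig", "start", "end", "assigned"])
    frame["copy_number"] = 0
    frame["ll_nonMSY"] = frame["ll_scY"] = frame["ll_mcY"] = 0.0
    return WindowClassification(frame=frame, epsilon=0.02)


def test_short_contig_discarded_even_if_pure_scY():
    cls = toy_classification([("c", 0, 50, "scY"), ("c", 50, 100, "scY"), ("c", 100, 150, "scY")])
    report, beds = clean_contigs(cls, {"c": 150})
    assert not report.frame["kept"].any()
    assert beds["scY"] == []


def test_low_y_fraction_contig_discarded():
    rows = [("c", i * 50, (i + 1) * 50, "scY" if i < 2 else "nonMSY") for i in range(5)]
    report, _ = clean_contigs(toy_classification(rows), {"c": 300})
    assert not report.frame["kept"].any()  # 40% Y content


def test_adjacent_windows_merge_into_intervals():
    rows = [
        ("c", 0, 50, "scY"),
        ("c", 50, 100, "scY"),
        ("c", 100, 150, "nonMSY"),
        ("c", 150, 200, "scY"),
    ]
    # pad to reach >= 50% Y fraction and length >= 200
    report, beds = clean_contigs(toy_classification(rows), {"c": 200})
    assert report.frame["kept"].all()
    assert beds["scY"] == [("c", 0, 100), ("c", 150, 200)]


def test_intervals_disjoint_sorted_and_bp_consistent():
    template = example_template(seed=9)
    cohort = example_cohort(seed=9)
    cls = classify_windows(normalize_depths(simulate_depths(template, cohort)))
    report, beds = clean_contigs(cls, template.contig_lengths)
    for intervals in beds.values():
        assert intervals == sorted(intervals)
        for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
            if c1 == c2:
                assert e1 <= s2
        for c, s, e in intervals:
            assert 0 <= s < e <= template.contig_lengths[c]
    kept = set(report.frame.loc[report.frame["kept"], "contig"])
    n_scy_windows = (
        (cls.frame["assigned"] == "scY") & cls.frame["contig"].isin(kept)
    ).sum()
    bp = sum(e - s for _, s, e in beds["scY"])
    assert bp == sum(
        e - s
        for _, s, e in cls.frame[
            (cls.frame["assigned"] == "scY") & cls.frame["contig"].isin(kept)
        ][["contig", "start", "end"]].itertuples(index=False)
    )
    assert bp <= 50 * n_scy_windows  # equality up to truncation at contig ends


def test_window_with_unknown_contig_errors():
    cls = toy_classification([("c", 0, 50, "scY")])
    with pytest.raises(ValueError, match="no length"):
        clean_contigs(cls, {"other": 500})


# ---------------------------------------------------------------------------
# Assembly statistics


@pytest.mark.parametrize(
    "lengths,total,n50",
    [
        ([1000], 1000, 1000),
        ([500, 300, 200], 1000, 500),
        ([400, 300, 300], 1000, 300),
        ([100, 100, 100, 100], 400, 100),
    ],
)
def test_n50_on_hand_computed_sets(lengths, total, n50):
    stats = assembly_stats(lengths)
    assert stats["total_bp"] == total
    assert stats["n_contigs"] == len(lengths)
    assert stats["n50"] == n50


def test_empty_length_set_errors():
    with pytest.raises(ValueError):
        assembly_stats([])


def test_tile_windows_final_window_truncated():
    w = tile_windows({"c": 120}, 50)
    assert w[["start", "end"]].values.tolist() == [[0, 50], [50, 100], [100, 120]]
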