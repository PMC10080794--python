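"""Detection rules, resampling null, DEG calling and the statistics toolbox."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mzt_m6a import GeneSet, SimConfig, de_test, simulate_counts, simulate_truth
from mzt_m6a.integration import (
    bh_adjust,
    deg_status,
    detected_gene_set,
    enrichment_test,
    overlap_venn,
    resample_ratio_null,
    sample_correlation,
    translation_active_ratio,
    upper_quartile_normalize,
)


def _detection_sheet(stages=("MII", "L1C", "L2C"), reps=3):
    rows = [
        {"sample_id": f"{s}_{r}", "stage": s, "assay": "ribo", "replicate": r}
        for s in stages
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def test_detection_requires_two_replicates_within_one_stage():
    sheet = _detection_sheet()
    values = pd.DataFrame(0.0, index=["two_in_mii", "once_per_stage", "nan_gene"],
                          columns=sheet.index)
    values.loc["two_in_mii", ["MII_1", "MII_2"]] = [5.0, 3.0]
    values.loc["once_per_stage", ["MII_1", "L1C_1", "L2C_1"]] = 4.0
    values.loc["nan_gene"] = np.nan
    detected = detected_gene_set(values, sheet, min_value=0.0)
    assert "two_in_mii" in detected
    assert "once_per_stage" not in detected  # rule is within-stage
    assert "nan_gene" not in detected


def test_upper_quartile_normalization_properties():
    rng = np.random.default_rng(2)
    a = rng.lognormal(10, 1, size=200)
    values = pd.DataFrame({"A": a, "B": 2 * a})
    normed = upper_quartile_normalize(values)
    np.testing.assert_allclose(normed["A"], normed["B"], rtol=1e-12)
    q75 = [np.percentile(normed[c][normed[c] > 0], 75) for c in normed]
    np.testing.assert_allclose(q75[0], q75[1], rtol=1e-9)

    hand = upper_quartile_normalize(
        pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0], "B": [2.0, 4.0, 6.0, 8.0]})
    )
    np.testing.assert_allclose(hand["A"], hand["B"], rtol=1e-12)

    with pytest.raises(ValueError, match="C"):
        upper_quartile_normalize(pd.DataFrame({"C": [0.0, 0.0]}))


def test_translation_active_ratio_counts():
    gs = GeneSet("g", frozenset({"a", "b", "c", "d"}))
    detected = GeneSet("d", frozenset({"a", "b", "x"}))
    ratio, n_hit, n_tot = translation_active_ratio(gs, detected)
    assert (ratio, n_hit, n_tot) == (0.5, 2, 4)
    assert translation_active_ratio(gs, GeneSet("all", gs.members))[0] == 1.0
    assert translation_active_ratio(gs, GeneSet("none", frozenset({"zzz"})))[0] == 0.0
    with pytest.raises(ValueError):
        translation_active_ratio(GeneSet("empty", frozenset()), detected)


def test_resampling_null_mean_matches_hypergeometric_expectation():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(4000)]
    detected = GeneSet("d", frozenset(g for g in genes if rng.random() < 0.5))
    true_frac = len(detected) / len(genes)
    null = resample_ratio_null(609, GeneSet("u", frozenset(genes)), detected,
                               n_iter=2000, seed=3)
    assert null.null_ratios.mean() == pytest.approx(true_frac, abs=0.01)
    # determinism and the p floor
    again = resample_ratio_null(609, GeneSet("u", frozenset(genes)), detected,
                                n_iter=2000, seed=3)
    np.testing.assert_array_equal(null.null_ratios, again.null_ratios)
    assert null.empirical_p(1.1) == pytest.approx(1 / 2001)
    with pytest.raises(ValueError):
        resample_ratio_null(5000, GeneSet("u", frozenset(genes)), detected, 10, 0)


def test_deg_status_thresholds():
    p = np.array([0.01, 0.01, 0.01, 0.2, np.nan])
    lfc = np.array([-1.5, 0.9, 1.2, 3.0, 2.0])
    assert list(deg_status(p, lfc)) == ["down", "ns", "up", "ns", "ns"]


def test_knockdown_recovery_and_type_one_error():
    # 200 genes knocked down at log2FC -2 -> mostly recovered as 'down'
    cfg = SimConfig(n_genes=2000, seed=5, library_size=5e5)
    truth = simulate_truth(cfg)
    deg = de_test(simulate_counts(truth, cfg))
    kd = truth.genes.index[truth.genes["kd_effect"] != 0]
    assert (deg.loc[kd, "status"] == "down").mean() >= 0.80
    # and with the knockdown disabled the test is calibrated
    cfg0 = SimConfig(n_genes=2000, seed=5, library_size=5e5, n_kd_genes=0)
    deg0 = de_test(simulate_counts(simulate_truth(cfg0), cfg0))
    assert np.nanmean(deg0["wald_p"] < 0.05) <= 0.08


def test_venn_regions_sum_to_union():
    a = GeneSet("a", frozenset("ab"))
    b = GeneSet("b", frozenset("bc"))
    assert overlap_venn([a, b]) == {(1, 0): 1, (0, 1): 1, (1, 1): 1}
    c = GeneSet("c", frozenset("cd"))
    regions = overlap_venn([a, b, c])
    assert sum(regions.values()) == len(a.members | b.members | c.members)
    disjoint = overlap_venn([a, GeneSet("z", frozenset("z"))])
    assert disjoint[(1, 1)] == 0
    with pytest.raises(ValueError):
        overlap_venn([a])


def test_fisher_exact_examples():
    odds, p = enrichment_test([[10, 10], [10, 10]])
    assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)
    _, p2 = enrichment_test([[8, 2], [1, 9]])
    assert p2 == pytest.approx(0.005477, abs=1e-5)
    odds3, p3 = enrichment_test([[5, 0], [0, 5]])
    assert p3 == pytest.approx(2 / 252, rel=1e-9)
    assert np.isfinite(odds3)  # Haldane correction keeps zero cells finite
    with pytest.raises(ValueError):
        enrichment_test([[-1, 2], [3, 4]])


def test_bh_examples_and_nan_passthrough():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.42]), [0.42])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    out = bh_adjust([0.01, np.nan, 0.03])
    assert np.isnan(out[1]) and np.isfinite(out[0])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


@given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
@settings(max_examples=50, deadline=None)
def test_bh_is_permutation_equivariant(pvals, rnd):
    p = np.array(pvals)
    perm = np.arange(len(p))
    rnd.shuffle(perm)
    adjusted = bh_adjust(p)
    np.testing.assert_allclose(bh_adjust(p[perm]), adjusted[perm], rtol=1e-12)


def test_sample_correlation_values_and_flags():
    values = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 4.0]})
    corr, degenerate = sample_correlation(values, log_transform=False)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(0.981980506, abs=1e-6)
    assert degenerate == []

    with pytest.warns(UserWarning, match="zero-variance"):
        _, bad = sample_correlation(
            pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]}), log_transform=False
        )
    assert bad == ["flat"]
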