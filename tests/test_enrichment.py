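"""Normalization, NB testing and the m6A calling rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mzt_m6a import SimConfig, compute_size_factors, counts_to_tpm, simulate_counts, simulate_truth
from mzt_m6a.enrichment import (
    build_stage_call_table,
    call_m6a_stage,
    estimate_dispersions,
    m6a_gene_sets,
    nb_wald_two_group,
    per_replicate_lfc,
    shrink_lfc,
)


# ---------------------------------------------------------------- size factors

def test_size_factors_symmetry_and_hand_values():
    np.testing.assert_allclose(compute_size_factors(np.array([[10, 10], [7, 7]])), [1, 1])
    # second column is twice the first -> factors 1/sqrt(2), sqrt(2)
    np.testing.assert_allclose(
        compute_size_factors(np.array([[10, 20], [30, 60]])),
        [1 / np.sqrt(2), np.sqrt(2)],
        rtol=1e-12,
    )
    # gene containing a zero is excluded from the reference set
    np.testing.assert_allclose(compute_size_factors(np.array([[0, 5], [10, 10]])), [1, 1])


def test_size_factor_fallback_when_no_common_gene():
    counts = np.array([[0, 5], [10, 0]])
    with pytest.warns(UserWarning, match="total-count"):
        sf = compute_size_factors(counts)
    assert (sf > 0).all()
    np.testing.assert_allclose(np.exp(np.mean(np.log(sf))), 1.0)


# ------------------------------------------------------------------------ TPM

def test_tpm_normalization_and_degenerate_columns():
    counts = pd.DataFrame({"s1": [100, 100], "s2": [0, 0]}, index=["a", "b"])
    lengths = pd.Series({"a": 1000.0, "b": 2000.0})
    tpm = counts_to_tpm(counts, lengths)
    np.testing.assert_allclose(tpm["s1"], [2e6 / 3, 1e6 / 3])
    assert (tpm["s2"] == 0).all()
    single = counts_to_tpm(pd.DataFrame({"s": [7]}, index=["a"]), lengths)
    assert single.iloc[0, 0] == 1e6


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_tpm_columns_sum_to_a_million(seed):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(rng.poisson(30, size=(20, 4)), index=[f"g{i}" for i in range(20)])
    lengths = pd.Series(rng.integers(500, 5000, 20).astype(float), index=counts.index)
    tpm = counts_to_tpm(counts, lengths)
    sums = tpm.sum(axis=0).to_numpy()
    nonzero = counts.sum(axis=0).to_numpy() > 0
    np.testing.assert_allclose(sums[nonzero], 1e6, rtol=1e-9)


def test_tpm_zero_length_rejected():
    with pytest.raises(ValueError):
        counts_to_tpm(pd.DataFrame({"s": [1]}, index=["a"]), pd.Series({"a": 0.0}))


# ----------------------------------------------------------------- dispersions

def test_dispersion_recovery_poisson_and_nb():
    rng = np.random.default_rng(1)
    design = np.array(["in"] * 3 + ["ip"] * 3)
    pois = rng.poisson(500.0, size=(2000, 6)).astype(float)
    assert np.median(estimate_dispersions(pois, np.ones(6), design)) <= 0.01
    npar = 1 / 0.5
    nb = rng.negative_binomial(npar, npar / (npar + 200.0), size=(2000, 6)).astype(float)
    assert 0.3 <= np.median(estimate_dispersions(nb, np.ones(6), design)) <= 0.7


def test_constant_gene_hits_dispersion_floor():
    counts = np.vstack([np.full(6, 40.0), np.arange(1, 7) * 10.0] * 10)
    alphas = estimate_dispersions(counts, np.ones(6), np.array(["a"] * 3 + ["b"] * 3))
    assert alphas[0] == pytest.approx(1e-8)


# ------------------------------------------------------------------- NB Wald

def test_wald_type_one_error_on_exchangeable_groups():
    """IP and input drawn from the same NB law -> ~nominal significance rate."""
    rng = np.random.default_rng(7)
    npar = 1 / 0.05
    mu = np.exp(rng.normal(np.log(60), 1.2, size=2000)).clip(0.5)
    y = rng.negative_binomial(npar, npar / (npar + mu[:, None]), size=(2000, 6)).astype(float)
    res = nb_wald_two_group(pd.DataFrame(y), np.ones(6), np.array([False] * 3 + [True] * 3))
    frac = np.nanmean(res["wald_p"] < 0.05)
    assert 0.03 <= frac <= 0.08


def test_wald_recovers_fourfold_enrichment():
    rng = np.random.default_rng(7)
    npar = 1 / 0.01
    inp = rng.negative_binomial(npar, npar / (npar + 200.0), size=(2000, 3))
    ip = rng.negative_binomial(npar, npar / (npar + 800.0), size=(2000, 3))
    counts = pd.DataFrame(np.hstack([inp, ip]))
    res = nb_wald_two_group(
        counts, np.ones(6), np.array([False] * 3 + [True] * 3),
        dispersions=np.full(2000, 0.01),
    )
    assert res["log2fc"].mean() == pytest.approx(2.0, abs=0.2)
    assert (res["wald_p"] < 0.05).mean() > 0.95


def test_all_zero_gene_is_untestable():
    counts = pd.DataFrame([[0] * 6, [50, 60, 55, 200, 210, 190]], index=["dead", "live"])
    res = nb_wald_two_group(counts, np.ones(6), np.array([False] * 3 + [True] * 3))
    assert np.isnan(res.loc["dead", "wald_p"]) and res.loc["dead", "log2fc"] == 0
    assert np.isfinite(res.loc["live", "wald_p"])


def test_fold_changes_match_independent_nb_glm_fit():
    """Cross-check the two-group NB MLE against pydeseq2 on shared data."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(42)
    n = 300
    mu = np.exp(rng.normal(np.log(200), 0.8, size=n))
    lfc_true = np.where(rng.random(n) < 0.3, rng.normal(2, 0.5, n), 0.0)
    npar = 1 / 0.05
    ref = rng.negative_binomial(npar, npar / (npar + mu[:, None]), size=(n, 3))
    trt = rng.negative_binomial(
        npar, npar / (npar + (mu * 2.0 ** lfc_true)[:, None]), size=(n, 3)
    )
    counts = pd.DataFrame(
        np.hstack([ref, trt]),
        index=[f"g{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(6)],
    )
    sf = compute_size_factors(counts)
    ours = nb_wald_two_group(counts, sf, np.array([False] * 3 + [True] * 3))

    meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
    dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    ds_stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
    ds_stats.summary()
    theirs = ds_stats.results_df["log2FoldChange"]
    assert np.corrcoef(ours["log2fc"], theirs)[0, 1] > 0.999
    assert (ours["log2fc"] - theirs).abs().median() < 0.01


# ----------------------------------------------------------------- shrinkage

def test_shrinkage_limits_and_closed_form():
    res = pd.DataFrame(
        {"log2fc": [2.0, 2.0, 2.0], "se": [1e-9, 1e6, 1.0], "wald_p": [0.01] * 3},
        index=["no_noise", "pure_noise", "balanced"],
    )
    rel = shrink_lfc(res, prior_sd=1.0)
    assert rel["no_noise"] == pytest.approx(2.0)
    assert rel["pure_noise"] == pytest.approx(0.0, abs=1e-9)
    assert rel["balanced"] == pytest.approx(1.0)


@given(
    st.floats(-8, 8), st.floats(1e-3, 10), st.floats(1e-3, 10)
)
@settings(max_examples=100, deadline=None)
def test_shrinkage_is_a_contraction(lfc, se, prior_sd):
    res = pd.DataFrame({"log2fc": [lfc], "se": [se], "wald_p": [0.5]})
    rel = float(shrink_lfc(res, prior_sd=prior_sd).iloc[0])
    assert abs(rel) <= abs(lfc) + 1e-12
    assert rel * lfc >= 0  # shrinkage never flips the sign


# ------------------------------------------------------- per-replicate log2FC

def test_per_replicate_lfc_identity_and_arithmetic(toy_dataset):
    ds = toy_dataset
    # identical IP and input counts, unit size factors -> exactly zero
    ds.counts[[c for c in ds.counts.columns if "IP" in c]] = ds.counts[
        [c for c in ds.counts.columns if "input" in c]
    ].to_numpy()
    sf = pd.Series(1.0, index=ds.counts.columns)
    lfc = per_replicate_lfc(ds, "MII", size_factors=sf)
    np.testing.assert_allclose(lfc.to_numpy(), 0.0)

    # normalized ip=31.5, input=7.5 with pseudocount 0.5 -> log2(32/8) = 2
    ds.counts.loc["gA", "MII_IP_1"] = 63
    ds.counts.loc["gA", "MII_input_1"] = 15
    sf2 = sf.copy()
    sf2["MII_IP_1"] = 2.0
    sf2["MII_input_1"] = 2.0
    lfc2 = per_replicate_lfc(ds, "MII", size_factors=sf2)
    assert lfc2.loc["gA", 1] == pytest.approx(2.0)

    # zero/zero with pseudocount -> 0 by symmetry
    ds.counts.loc["gB", ["MII_IP_2", "MII_input_2"]] = 0
    lfc3 = per_replicate_lfc(ds, "MII", size_factors=sf)
    assert lfc3.loc["gB", 2] == 0.0


def test_unpaired_replicate_is_an_error(toy_dataset):
    ds = toy_dataset.subset([c for c in toy_dataset.counts.columns if c != "MII_IP_3"])
    with pytest.raises(ValueError, match="3"):
        per_replicate_lfc(ds, "MII")


# ------------------------------------------------------------- calling rule

def _one_gene_call(input_count, rep_lfc, p):
    rep = pd.DataFrame({1: [rep_lfc], 2: [-5.0], 3: [-5.0]}, index=["g"])
    inputs = pd.DataFrame(
        {"i1": [input_count], "i2": [input_count], "i3": [input_count]}, index=["g"]
    )
    stage = pd.DataFrame({"wald_p": [p], "log2fc": [rep_lfc], "se": [1.0]}, index=["g"])
    calls = call_m6a_stage(rep, inputs, stage)
    return bool(calls.loc["g", "rep1_called"])


@pytest.mark.parametrize(
    "input_count, rep_lfc, p, expected",
    [
        (5, 1.2, 0.01, True),     # significant and positive
        (1, 3.0, 0.001, False),   # input count must strictly exceed 1
        (5, -0.1, 0.001, False),  # fold-change must be positive
        (5, 1.2, 0.20, False),    # P above threshold
        (5, 2.5, np.nan, True),   # undefined P falls back to lfc > 2
        (5, 1.9, np.nan, False),
        (5, 2.0, np.nan, False),  # strict inequality at the NA threshold
    ],
)
def test_replicate_call_branches(input_count, rep_lfc, p, expected):
    assert _one_gene_call(input_count, rep_lfc, p) is expected


@pytest.mark.parametrize(
    "flags, expected", [((True, True, False), True), ((True, False, False), False),
                        ((True, True, True), True), ((False, False, False), False)]
)
def test_two_of_three_consensus(flags, expected):
    rep = pd.DataFrame({r: [4.0 if f else -4.0] for r, f in zip((1, 2, 3), flags)}, index=["g"])
    inputs = pd.DataFrame({f"i{r}": [10] for r in (1, 2, 3)}, index=["g"])
    stage = pd.DataFrame({"wald_p": [0.001], "log2fc": [2.0], "se": [0.5]}, index=["g"])
    assert bool(call_m6a_stage(rep, inputs, stage)["stage_called"].iloc[0]) is expected


def test_consensus_warns_when_unreachable():
    rep = pd.DataFrame({1: [4.0]}, index=["g"])
    inputs = pd.DataFrame({"i1": [10]}, index=["g"])
    stage = pd.DataFrame({"wald_p": [0.001], "log2fc": [2.0], "se": [0.5]}, index=["g"])
    with pytest.warns(UserWarning, match="consensus"):
        calls = call_m6a_stage(rep, inputs, stage)
    assert not calls["stage_called"].iloc[0]


# ----------------------------------------------------------- stage gene sets

def test_gene_sets_union_and_complement(small_sim):
    _, truth, dataset = small_sim
    table = build_stage_call_table(dataset)
    sets = m6a_gene_sets(table)
    union = sets["MII"].members | sets["L1C"].members | sets["L2C"].members
    assert sets["m6A_any"].members == union
    assert sets["m6A_neg"].members == frozenset(dataset.gene_ids) - union
    assert not sets["m6A_any"].members & sets["m6A_neg"].members


def test_increasing_enrichment_never_unsets_a_call(small_sim):
    """Monotonicity: scaling a called gene's IP counts up keeps it called."""
    _, truth, dataset = small_sim
    table = build_stage_call_table(dataset)
    patt = table.pattern_frame()
    gene = patt.index[patt["MII"]][0]
    ip_cols = dataset.samples_for(stage="MII", assay="IP")
    was_called = True
    for factor in (2, 4, 8):
        boosted = dataset.counts.copy()
        boosted.loc[gene, ip_cols] = (boosted.loc[gene, ip_cols] * factor).round()
        ds2 = type(dataset)(
            counts=boosted, samples=dataset.samples.reset_index(),
            gene_lengths=dataset.gene_lengths,
        )
        patt2 = build_stage_call_table(ds2).pattern_frame()
        assert patt2.loc[gene, "MII"] or not was_called
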