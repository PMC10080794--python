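"""IP-vs-input enrichment calling for gene-level m6A profiling.

The modification status of a gene is inferred from paired antibody-IP and
input sequencing libraries.  Counts are modelled as negative binomial
(variance ``mu + alpha * mu**2``); per stage, a two-group NB log-linear
model with log size-factor offsets yields the IP/input log2 fold-change
and a Wald P value.  A gene is m6A-tagged in a stage when, in at least two
of the three replicate pairs, its input library shows real signal
(raw count > 1) and its replicate-level log2 fold-change is positive with
a significant stage-level P value (or exceeds 2 when the P value is
undefined).  A gene tagged in at least one stage enters the m6A-positive
universe.

The "relative m6A level" reported per gene and stage is the shrunken
(normal-prior posterior mean) log2 fold-change, a moderated estimate that
pulls noisy fold-changes toward zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, OmicsDataset

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: Dispersion floor; genes with zero empirical variance land here.
ALPHA_MIN = 1e-8

#: Default thresholds of the stage-level calling rule.
P_CALL = 0.05
LFC_NA = 2.0
MIN_INPUT_COUNT = 1.0
CONSENSUS = 2
PSEUDOCOUNT = 0.5
PRIOR_SD = 1.0


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------

def compute_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per sample (column).

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median ratio of its counts to the per-gene
    geometric means.  When no gene is nonzero everywhere, falls back to
    total-count ratios with a warning.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D matrix (genes x samples)")
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have at least one nonzero count")
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        warnings.warn(
            "no gene has nonzero counts in all samples; "
            "falling back to total-count normalization",
            stacklevel=2,
        )
        sf = totals / np.exp(np.mean(np.log(totals)))
        return sf
    logs = np.log(mat[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return sf


def counts_to_tpm(
    counts: pd.DataFrame, gene_lengths: pd.Series
) -> pd.DataFrame:
    """Transcripts-per-million from counts and gene lengths.

    ``tpm[g, j] = 1e6 * (count[g, j] / length[g]) / sum_g'(count/length)``;
    every column sums to 1e6 except all-zero columns, which stay zero.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"genes without a length: {list(missing[:5])}")
    lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(denom > 0, 1e6 * rate / denom, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------

def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    size_factors: np.ndarray,
    design: np.ndarray,
    alpha_min: float = ALPHA_MIN,
    shrink: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersions with trend shrinkage.

    Within each design group a method-of-moments estimate
    ``max(0, (s2 - mean) / mean**2)`` is computed on size-factor
    normalized counts; group estimates are averaged.  ``log(alpha)`` is
    then regressed on ``log(mean)`` with a robust (Theil–Sen) line and
    each gene is shrunk ``shrink`` of the way toward the fitted trend.
    All values are floored at ``alpha_min``.

    ``design`` is a vector of group labels (one per sample); a group with
    fewer than two replicates contributes nothing and, if no group has
    replication, the trend cannot be fit and a flat prior dispersion is
    returned with a warning.
    """
    mat = np.asarray(counts, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    norm = mat / sf[None, :]
    design = np.asarray(design)
    groups = [design == g for g in pd.unique(design)]
    ests, n_groups = np.zeros(mat.shape[0]), 0
    for g in groups:
        if g.sum() < 2:
            continue
        sub = norm[:, g]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        ests += np.maximum(a, 0.0)
        n_groups += 1
    if n_groups == 0:
        warnings.warn(
            "no design group has >=2 replicates; using flat prior dispersion 0.1",
            stacklevel=2,
        )
        return np.full(mat.shape[0], 0.1)
    raw = ests / n_groups
    mean_all = norm.mean(axis=1)

    ok = (raw > alpha_min) & (mean_all > 0)
    if ok.sum() >= 10:
        x, y = np.log(mean_all[ok]), np.log(raw[ok])
        slope, intercept, _, _ = stats.theilslopes(y, x)
        with np.errstate(divide="ignore"):
            log_trend = intercept + slope * np.log(np.maximum(mean_all, 1e-300))
        trend = np.exp(np.clip(log_trend, np.log(alpha_min), 50.0))
    else:
        trend = np.full(mat.shape[0], max(np.median(raw[raw > 0]) if (raw > 0).any() else 0.1, alpha_min))

    raw_f = np.maximum(raw, alpha_min)
    shrunk = np.exp((1.0 - shrink) * np.log(raw_f) + shrink * np.log(np.maximum(trend, alpha_min)))
    # genes with zero empirical overdispersion stay at the floor
    shrunk[raw <= 0] = alpha_min
    return np.maximum(shrunk, alpha_min)


# ---------------------------------------------------------------------
# NB two-group Wald test
# ---------------------------------------------------------------------

def _fit_group_means(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the per-gene group mean q (mu_j = sf_j * q) at fixed dispersion.

    Solves ``sum_j (y_j - sf_j q) / (1 + alpha sf_j q) = 0`` by Newton
    iteration in log q, vectorized across genes.  Returns (q, fisher_info)
    where ``info = sum_j mu_j / (1 + alpha mu_j)`` is the information for
    log q.  Genes with an all-zero group get q floored at half a read per
    (summed) size factor so downstream fold-changes stay finite.
    """
    total_sf = sf.sum()
    q_floor = 0.5 / total_sf
    q = np.maximum(y.sum(axis=1) / total_sf, q_floor)
    t = np.log(q)
    for _ in range(n_iter):
        mu = np.exp(t)[:, None] * sf[None, :]
        denom = 1.0 + alpha[:, None] * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = np.where(fp != 0, f / fp, 0.0)
        step = np.clip(step, -5.0, 5.0)
        t_new = t - step
        t_new = np.maximum(t_new, np.log(q_floor))
        if np.max(np.abs(t_new - t)) < 1e-10:
            t = t_new
            break
        t = t_new
    q = np.exp(t)
    mu = q[:, None] * sf[None, :]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return q, info


def nb_wald_two_group(
    counts: pd.DataFrame,
    size_factors: np.ndarray,
    is_treatment: np.ndarray,
    dispersions: np.ndarray | None = None,
    t_df: float | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test; log2 fold-change is treatment over reference.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc``, ``se``, ``wald_p`` and ``dispersion``.  Genes with zero
    counts in every sample are untestable: ``wald_p`` is NaN and
    ``log2fc`` is 0 — the "NA" state of the calling rule.

    The Wald statistic is referred to a t distribution whose degrees of
    freedom account for dispersion-estimation noise: the 50% shrinkage of
    each gene's dispersion toward the mean-dispersion trend (fit across
    thousands of genes, hence effectively noise-free) doubles the
    residual information, giving ``df = (N - 2) / (1 - w) = 2 (N - 2)``
    at the default shrinkage weight w = 0.5.  With known dispersions the
    plain normal reference applies (``t_df=inf``).  At small replicate
    numbers the normal reference is markedly anticonservative.
    """
    y = counts.to_numpy(dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    trt = np.asarray(is_treatment, dtype=bool)
    if trt.sum() < 1 or (~trt).sum() < 1:
        raise ValueError("both design groups need at least one sample")
    if dispersions is None:
        design = np.where(trt, "trt", "ref")
        dispersions = estimate_dispersions(y, sf, design)
        if t_df is None:
            t_df = 2.0 * max(len(trt) - 2, 1)
    alpha = np.asarray(dispersions, dtype=float)

    q_ref, info_ref = _fit_group_means(y[:, ~trt], sf[~trt], alpha)
    q_trt, info_trt = _fit_group_means(y[:, trt], sf[trt], alpha)

    log2fc = (np.log(q_trt) - np.log(q_ref)) / LN2
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / info_ref + 1.0 / info_trt) / LN2
    z = np.where(se > 0, log2fc / se, 0.0)
    if t_df is None or not np.isfinite(t_df):
        wald_p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        wald_p = 2.0 * stats.t.sf(np.abs(z), df=t_df)

    all_zero = (y.sum(axis=1) == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    wald_p = np.where(all_zero, np.nan, wald_p)
    se = np.where(all_zero, np.nan, se)

    base_mean = (y / sf[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_p": wald_p,
            "dispersion": alpha,
        },
        index=counts.index,
    )


def nb_wald_stage_test(
    dataset: OmicsDataset,
    stage: str,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Stage-level IP-vs-input NB Wald test (all replicates jointly).

    ``log2fc`` is IP over input.  Size factors default to median-of-ratios
    computed on the stage's own IP+input samples.
    """
    ip = dataset.samples_for(stage=stage, assay="IP")
    inp = dataset.samples_for(stage=stage, assay="input")
    if not ip or not inp:
        raise ValueError(f"stage {stage!r} needs at least one IP and one input sample")
    cols = inp + ip
    sub = dataset.counts[cols]
    if size_factors is None:
        sf = compute_size_factors(sub)
    else:
        sf = size_factors.loc[cols].to_numpy(dtype=float)
    is_ip = np.array([False] * len(inp) + [True] * len(ip))
    return nb_wald_two_group(sub, sf, is_ip)


def shrink_lfc(
    result: pd.DataFrame,
    prior_sd: float = PRIOR_SD,
    fallback_lfc: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Normal-prior posterior-mean shrinkage of the log2 fold-change.

    ``rel = log2fc * prior_sd**2 / (prior_sd**2 + se**2)`` — a contraction
    toward zero that vanishes as the standard error grows.  Genes with an
    undefined test (NaN ``wald_p``) take ``fallback_lfc`` (typically the
    mean per-replicate log2FC) unshrunk, or 0 when no fallback is given.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    lfc = result["log2fc"].to_numpy(dtype=float)
    se = result["se"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        rel = lfc * prior_sd**2 / (prior_sd**2 + se**2)
    undefined = np.isnan(result["wald_p"].to_numpy(dtype=float))
    if fallback_lfc is not None:
        fb = np.asarray(fallback_lfc, dtype=float)
        rel = np.where(undefined, fb, rel)
    else:
        rel = np.where(undefined, 0.0, rel)
    rel = np.where(np.isnan(rel), 0.0, rel)
    return pd.Series(rel, index=result.index, name="rel_m6a")


# ---------------------------------------------------------------------
# replicate-level fold-changes and the calling rule
# ---------------------------------------------------------------------

def per_replicate_lfc(
    dataset: OmicsDataset,
    stage: str,
    pseudocount: float = PSEUDOCOUNT,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-replicate-pair IP/input log2 fold-changes for one stage.

    IP and input samples are paired by replicate number;
    ``lfc = log2((ip/sf_ip + c) / (in/sf_in + c))`` with pseudocount c.
    Returns genes x replicates (columns are replicate numbers).
    """
    ip = dataset.samples_for(stage=stage, assay="IP")
    inp = dataset.samples_for(stage=stage, assay="input")
    sheet = dataset.samples
    ip_by_rep = {int(sheet.loc[s, "replicate"]): s for s in ip}
    in_by_rep = {int(sheet.loc[s, "replicate"]): s for s in inp}
    orphans = set(ip_by_rep) ^ set(in_by_rep)
    if orphans:
        raise ValueError(
            f"unpaired replicates at stage {stage!r}: {sorted(orphans)}"
        )
    reps = sorted(ip_by_rep)
    cols = [in_by_rep[r] for r in reps] + [ip_by_rep[r] for r in reps]
    if size_factors is None:
        sf = pd.Series(compute_size_factors(dataset.counts[cols]), index=cols)
    else:
        sf = size_factors
    out = {}
    for r in reps:
        ip_n = dataset.counts[ip_by_rep[r]].to_numpy(dtype=float) / sf[ip_by_rep[r]]
        in_n = dataset.counts[in_by_rep[r]].to_numpy(dtype=float) / sf[in_by_rep[r]]
        out[r] = np.log2((ip_n + pseudocount) / (in_n + pseudocount))
    return pd.DataFrame(out, index=dataset.counts.index)


def call_m6a_stage(
    rep_log2fc: pd.DataFrame,
    input_counts: pd.DataFrame,
    stage_result: pd.DataFrame,
    p_call: float = P_CALL,
    lfc_na: float = LFC_NA,
    min_input_count: float = MIN_INPUT_COUNT,
    consensus: int = CONSENSUS,
) -> pd.DataFrame:
    """Apply the replicate-consensus m6A calling rule for one stage.

    A replicate pair calls a gene when its raw input count exceeds
    ``min_input_count`` and either the stage P value is below ``p_call``
    with a positive replicate log2FC, or the P value is undefined and the
    replicate log2FC exceeds ``lfc_na``.  The stage call requires at least
    ``consensus`` replicate-level calls.

    ``input_counts`` columns must align with ``rep_log2fc`` columns
    (same replicate order).  Returns a DataFrame with per-replicate call
    flags and the ``stage_called`` consensus.
    """
    reps = list(rep_log2fc.columns)
    if input_counts.shape[1] != len(reps):
        raise ValueError("input_counts must have one column per replicate pair")
    if len(reps) < consensus:
        warnings.warn(
            f"only {len(reps)} replicate pair(s); consensus of {consensus} unreachable",
            stacklevel=2,
        )
    p = stage_result["wald_p"].reindex(rep_log2fc.index).to_numpy(dtype=float)
    p_na = np.isnan(p)
    called = {}
    for i, r in enumerate(reps):
        lfc = rep_log2fc[r].to_numpy(dtype=float)
        raw_in = input_counts.iloc[:, i].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            ok_sig = (~p_na) & (p < p_call) & (lfc > 0)
        ok_na = p_na & (lfc > lfc_na)
        called[r] = (raw_in > min_input_count) & (ok_sig | ok_na)
    out = pd.DataFrame(called, index=rep_log2fc.index)
    out.columns = [f"rep{r}_called" for r in reps]
    out["n_reps_called"] = out.sum(axis=1).astype(int)
    out["stage_called"] = out["n_reps_called"] >= consensus
    return out


# ---------------------------------------------------------------------
# the stage-call table and gene sets
# ---------------------------------------------------------------------

@dataclass
class StageCallTable:
    """Per gene x stage calling results in tidy form.

    ``df`` columns: ``gene_id``, ``stage``, ``rep<r>_log2fc``,
    ``rep<r>_called``, ``stage_p``, ``rel_m6a``, ``n_reps_called``,
    ``stage_called``.
    """

    df: pd.DataFrame
    stage_order: tuple[str, ...] = field(default=("MII", "L1C", "L2C"))

    def pattern_frame(self) -> pd.DataFrame:
        """genes x stages boolean matrix of stage calls."""
        wide = self.df.pivot(index="gene_id", columns="stage", values="stage_called")
        missing = [s for s in self.stage_order if s not in wide.columns]
        if missing:
            raise ValueError(f"calls missing for stage(s): {missing}")
        return wide[list(self.stage_order)].fillna(False).astype(bool)

    def rel_m6a_frame(self) -> pd.DataFrame:
        wide = self.df.pivot(index="gene_id", columns="stage", values="rel_m6a")
        return wide[[s for s in self.stage_order if s in wide.columns]]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, stage_order=("MII", "L1C", "L2C")) -> "StageCallTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        for c in df.columns:
            if c.endswith("_called") or c == "stage_called":
                df[c] = df[c].astype(bool)
        return cls(df, tuple(stage_order))


def build_stage_call_table(
    dataset: OmicsDataset,
    pseudocount: float = PSEUDOCOUNT,
    prior_sd: float = PRIOR_SD,
    p_call: float = P_CALL,
    lfc_na: float = LFC_NA,
    min_input_count: float = MIN_INPUT_COUNT,
    consensus: int = CONSENSUS,
    stages: tuple[str, ...] | None = None,
) -> StageCallTable:
    """Run the full per-stage calling workflow on an IP/input dataset."""
    stages = stages or tuple(
        s for s in dataset.stage_order if dataset.samples_for(stage=s, assay="IP")
    )
    rows = []
    for stage in stages:
        res = nb_wald_stage_test(dataset, stage)
        rep_lfc = per_replicate_lfc(dataset, stage, pseudocount=pseudocount)
        rel = shrink_lfc(res, prior_sd=prior_sd, fallback_lfc=rep_lfc.mean(axis=1))
        inp_samples = dataset.samples_for(stage=stage, assay="input")
        sheet = dataset.samples
        rep_order = sorted(int(sheet.loc[s, "replicate"]) for s in inp_samples)
        in_by_rep = {int(sheet.loc[s, "replicate"]): s for s in inp_samples}
        input_counts = dataset.counts[[in_by_rep[r] for r in rep_order]]
        calls = call_m6a_stage(
            rep_lfc,
            input_counts,
            res,
            p_call=p_call,
            lfc_na=lfc_na,
            min_input_count=min_input_count,
            consensus=consensus,
        )
        block = pd.DataFrame({"gene_id": dataset.counts.index, "stage": stage})
        for r in rep_lfc.columns:
            block[f"rep{r}_log2fc"] = rep_lfc[r].to_numpy()
        for c in calls.columns:
            block[c] = calls[c].to_numpy()
        block["stage_p"] = res["wald_p"].to_numpy()
        block["rel_m6a"] = rel.to_numpy()
        rows.append(block)
    return StageCallTable(pd.concat(rows, ignore_index=True), tuple(stages))


def m6a_gene_sets(
    table: StageCallTable,
    expressed_universe: set[str] | None = None,
) -> dict[str, GeneSet]:
    """Per-stage m6A gene sets plus the union ('m6A_any') and complement.

    ``m6A_neg`` is the complement of the union within the expressed
    universe (all genes in the table when not given explicitly).
    """
    patt = table.pattern_frame()
    sets: dict[str, GeneSet] = {}
    union: set[str] = set()
    for stage in patt.columns:
        members = frozenset(patt.index[patt[stage]])
        sets[stage] = GeneSet(stage, members)
        union |= members
    sets["m6A_any"] = GeneSet("m6A_any", frozenset(union))
    universe = expressed_universe if expressed_universe is not None else set(patt.index)
    sets["m6A_neg"] = GeneSet("m6A_neg", frozenset(universe - union))
    return sets
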