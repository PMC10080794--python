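"""Integration of m6A gene sets with translation and proteome detection.

Ribosome-profiling (TPM) and proteomics (intensity) matrices are reduced
to "detected" gene sets with the same within-stage replication rule
(value above threshold in >= 2 replicates of at least one stage).  The
translation-active ratio of a gene set — the fraction of its members that
are detected — is compared against a resampling null built from random
gene sets of the same size, giving an empirical P value.

Also provided: knockdown differential-expression calling on the shared NB
Wald machinery, Venn region counts, Fisher's exact over-representation
test, Benjamini–Hochberg correction and pairwise sample correlation QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import compute_size_factors, nb_wald_two_group
from .io import GeneSet, OmicsDataset

DEG_P = 0.05
DEG_LFC = 1.0
DETECTION_REPS = 2


# ---------------------------------------------------------------------
# detection rules
# ---------------------------------------------------------------------

def detected_gene_set(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    min_value: float = 0.0,
    min_reps: int = DETECTION_REPS,
    name: str = "detected",
) -> GeneSet:
    """Genes detected in >= ``min_reps`` replicates of at least one stage.

    A measurement counts as detection when it is non-NaN and strictly
    above ``min_value``.  NaN encodes a missing proteomic measurement.
    """
    if min_value < 0:
        raise ValueError("min_value must be >= 0")
    sheet = samples.loc[[c for c in values.columns if c in samples.index]]
    detected = np.zeros(values.shape[0], dtype=bool)
    for _, grp in sheet.groupby("stage", observed=True):
        sub = values[list(grp.index)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            hits = (~np.isnan(sub)) & (sub > min_value)
        detected |= hits.sum(axis=1) >= min_reps
    return GeneSet(name, frozenset(values.index[detected]))


def upper_quartile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization of an intensity matrix.

    Each sample is scaled so that the 75th percentile of its positive
    values equals the geometric mean of the raw 75th percentiles across
    samples.  Zeros and NaNs are preserved.
    """
    q75 = {}
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        pos = v[np.isfinite(v) & (v > 0)]
        if pos.size == 0:
            raise ValueError(f"sample {col!r} has no positive values")
        q75[col] = float(np.percentile(pos, 75))
    anchor = float(np.exp(np.mean(np.log(list(q75.values())))))
    out = values.astype(float).copy()
    for col in values.columns:
        out[col] = out[col] * (anchor / q75[col])
    return out


# ---------------------------------------------------------------------
# translation-active ratio and its resampling null
# ---------------------------------------------------------------------

def translation_active_ratio(gs: GeneSet, detected: GeneSet) -> tuple[float, int, int]:
    """Fraction of a gene set detected as translated: |gs & detected| / |gs|."""
    if len(gs) == 0:
        raise ValueError("gene set is empty")
    n_hit = len(gs.members & detected.members)
    return n_hit / len(gs), n_hit, len(gs)


@dataclass
class ResampleNull:
    """Null distribution of detected fractions for random size-n sets."""

    null_ratios: np.ndarray
    n: int
    n_iter: int

    def empirical_p(self, observed_ratio: float) -> float:
        """(1 + #{null >= observed}) / (1 + n_iter) — never exactly zero."""
        return float(
            (1 + int((self.null_ratios >= observed_ratio).sum())) / (1 + self.n_iter)
        )


def resample_ratio_null(
    n: int,
    universe: GeneSet,
    detected: GeneSet,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ResampleNull:
    """Detected-fraction null from random gene sets of size ``n``.

    Draws ``n_iter`` uniform subsets of size ``n`` from the universe
    (without replacement within a draw) and records the detected fraction
    of each.  Reproducible for a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    genes = sorted(universe.members)
    if n > len(genes):
        raise ValueError(f"n={n} exceeds universe size {len(genes)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.fromiter((g in detected.members for g in genes), dtype=bool, count=len(genes))
    ratios = np.empty(n_iter, dtype=float)
    # random-key trick: the n smallest of U(0,1) keys form a uniform subset
    chunk = max(1, min(n_iter, int(2e7 / max(len(genes), 1))))
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        keys = rng.random((b, len(genes)))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        ratios[done : done + b] = mask[idx].mean(axis=1)
        done += b
    return ResampleNull(null_ratios=ratios, n=n, n_iter=n_iter)


# ---------------------------------------------------------------------
# knockdown differential expression
# ---------------------------------------------------------------------

def de_test(
    dataset: OmicsDataset,
    group_ref: str = "Ctrl",
    group_trt: str = "KD",
    assay: str = "rna",
    p_thresh: float = DEG_P,
    lfc_thresh: float = DEG_LFC,
) -> pd.DataFrame:
    """NB Wald differential-expression test between two groups.

    ``log2fc`` is treatment (knockdown) over reference.  Status is ``up``
    for ``wald_p < p_thresh`` and ``log2fc > lfc_thresh``, ``down`` for
    ``log2fc < -lfc_thresh``, else ``ns``.  ``padj`` is BH-adjusted.
    """
    ref = dataset.samples_for(assay=assay, group=group_ref)
    trt = dataset.samples_for(assay=assay, group=group_trt)
    if len(ref) < 2 or len(trt) < 2:
        raise ValueError(
            f"need >=2 replicates per group; got {len(ref)} {group_ref!r} "
            f"and {len(trt)} {group_trt!r}"
        )
    cols = ref + trt
    sub = dataset.counts[cols]
    sf = compute_size_factors(sub)
    is_trt = np.array([False] * len(ref) + [True] * len(trt))
    res = nb_wald_two_group(sub, sf, is_trt)
    res["padj"] = bh_adjust(res["wald_p"].to_numpy())
    res["status"] = deg_status(
        res["wald_p"].to_numpy(), res["log2fc"].to_numpy(), p_thresh, lfc_thresh
    )
    return res


def deg_status(
    wald_p: np.ndarray,
    log2fc: np.ndarray,
    p_thresh: float = DEG_P,
    lfc_thresh: float = DEG_LFC,
) -> np.ndarray:
    """DEG status labels: significant P and |log2FC| above threshold."""
    p = np.asarray(wald_p, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    with np.errstate(invalid="ignore"):
        sig = p < p_thresh
    return np.where(
        sig & (lfc > lfc_thresh), "up", np.where(sig & (lfc < -lfc_thresh), "down", "ns")
    )


def deg_sets(deg_table: pd.DataFrame) -> dict[str, GeneSet]:
    return {
        "deg_up": GeneSet("deg_up", frozenset(deg_table.index[deg_table["status"] == "up"])),
        "deg_down": GeneSet("deg_down", frozenset(deg_table.index[deg_table["status"] == "down"])),
    }


# ---------------------------------------------------------------------
# set arithmetic and tests
# ---------------------------------------------------------------------

def overlap_venn(sets: list[GeneSet]) -> dict[tuple[int, ...], int]:
    """Venn region counts for 2 or 3 gene sets.

    Keys are membership tuples aligned with the input order, e.g. for two
    sets ``(1, 0)`` counts members of the first set only.  Region counts
    sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_venn supports 2 or 3 sets")
    members = [s.members for s in sets]
    regions: dict[tuple[int, ...], int] = {}
    for signature in product((0, 1), repeat=len(sets)):
        if not any(signature):
            continue
        region = None
        for bit, m in zip(signature, members):
            if bit:
                region = m if region is None else region & m
        for bit, m in zip(signature, members):
            if not bit:
                region = region - m
        regions[signature] = len(region)
    return regions


def enrichment_test(table: np.ndarray | list) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 contingency table.

    Returns ``(odds_ratio, p)``.  P is the exact two-sided probability
    (sum over tables with point probability <= the observed one, margins
    fixed).  The odds ratio uses the Haldane half-integer correction when
    any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("cells must be integers")
    t = np.round(t).astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def sample_correlation(
    values: pd.DataFrame, log_transform: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation between samples (columns).

    TPM-scale inputs are log2(x+1)-transformed by default.  Returns the
    correlation matrix and the list of zero-variance samples, whose rows
    and columns are NaN by construction (flagged, not silently dropped).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = values.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    sd = x.std(axis=0)
    degenerate = [str(c) for c, s in zip(values.columns, sd) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance samples: {degenerate}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = pd.DataFrame(corr, index=values.columns, columns=values.columns)
    np.fill_diagonal(corr.values, 1.0)
    return corr, degenerate
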