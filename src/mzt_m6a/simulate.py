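"""Synthetic MZT multi-omics data with known ground truth.

The generator emulates the structure of a low-input m6A profiling study
of the mouse maternal-to-zygotic transition: three stages (MII oocyte,
late 1-cell, late 2-cell) x three replicates x paired IP/input
sequencing libraries, plus knockdown RNA-seq, ribosome-profiling and
proteomics detection matrices and qPCR Ct tables.

Per gene, a dynamics category is drawn (maternal loss / inherited /
de-novo gain / transient / untagged) at proportions matching the class
frequencies observed in real MZT m6A profiling (roughly 5.6% / 3.5% /
7.2% / 3.2% of a ~17k-gene universe, the rest untagged).  m6A-tagged
stages carry a log2 IP enrichment drawn around 3; expression couples to
the modification the way the biology suggests: about half of the
maternal-loss genes decay after fertilization, about half of the
de-novo-gain genes ride a zygotic-genome-activation burst, and inherited
genes have a strongly elevated probability of being translation-active.
Counts are negative binomial; detection is Bernoulli on a latent
translated state; Ct values follow a log-abundance model with Gaussian
cycle noise.

One global seed expands into independent substreams for the truth,
count, detection and Ct stages, so regenerating one block never
reshuffles another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneSet, OmicsDataset, STAGE_ORDER

CATEGORY_ORDER = ("maternal_loss", "inherited", "de_novo_gain", "transient", "untagged")


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study-scale conditions.

    Sizes are scaled for desk runs (5000 genes, 1e6 reads/sample); class
    proportions, detection rates and effect couplings mirror the observed
    MZT m6A landscape.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    library_size: float = 1e6
    dispersion: float = 0.05
    #: category proportions (maternal_loss, inherited, de_novo_gain,
    #: transient, untagged); must sum to 1.
    proportions: tuple[float, ...] = (0.056, 0.035, 0.072, 0.032, 0.805)
    #: log2 IP/input enrichment of m6A-tagged stages: Normal(mean, sd),
    #: floored at enrichment_min.
    enrichment_mean: float = 3.0
    enrichment_sd: float = 0.5
    enrichment_min: float = 0.5
    #: natural-log sd of the lognormal base-expression distribution.
    expr_sigma: float = 1.2
    #: fold drop of maternal-loss mRNAs from MII to L2C (applied to the
    #: decay-coupled half).
    maternal_decay_fold: float = 4.0
    decay_coupling: float = 0.5
    #: ZGA burst fold for burst-coupled de-novo-gain genes and for the
    #: non-m6A ZGA background drawn from the untagged pool.
    zga_burst_fold: float = 10.0
    burst_coupling: float = 0.5
    zga_frac_untagged: float = 0.22
    #: fraction of untagged-pool ZGA genes bursting at L1C (minor wave)
    #: rather than L2C (major wave).
    zga_minor_frac: float = 0.2
    #: within the de-novo class, fraction gaining m6A only at L2C
    #: (pattern 001) versus from L1C on (011).
    denovo_l2c_frac: float = 0.8
    #: translation detection: baseline propensity and the additive lift
    #: for inherited genes (0.52 + 0.40 ~ 0.92, the observed gap).
    base_detect: float = 0.52
    detection_link: float = 0.40
    detect_hit_rate: float = 0.95
    detect_noise_rate: float = 0.02
    #: knockdown: number of affected genes (drawn from m6A-tagged genes,
    #: reader-dependent destabilization) and their log2 effect.
    n_kd_genes: int = 200
    kd_log2fc: float = -2.0
    #: qPCR model: Ct at unit abundance, cycle noise sd, RIP input aliquot,
    #: baseline IP recovery and the spike-in true enrichment fold.
    ct_intercept: float = 35.0
    ct_sd: float = 0.2
    input_fraction: float = 0.1
    rip_base_recovery: float = 0.005
    spike_enrichment_fold: float = 20.0
    n_qpcr_targets: int = 5
    qpcr_replicates: int = 3
    #: per-sample depth wobble (lognormal sd, natural log).
    depth_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if len(self.proportions) != 5:
            raise ValueError("five category proportions required")
        for name in (
            "library_size", "enrichment_mean", "expr_sigma", "maternal_decay_fold",
            "zga_burst_fold", "ct_intercept",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.ct_sd < 0:
            raise ValueError("dispersion and ct_sd must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream generator (0=truth 1=counts 2=detection 3=ct)."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), stream)))


@dataclass
class SimTruth:
    """Ground truth per gene: category, per-stage m6A status and
    enrichment, expected expression trajectory, translation state and
    knockdown effect."""

    genes: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def category_set(self, category: str) -> GeneSet:
        return GeneSet(category, frozenset(self.genes.index[self.genes["category"] == category]))

    def m6a_any_set(self) -> GeneSet:
        cols = [f"m6a_{s}" for s in STAGE_ORDER]
        return GeneSet("true_m6a_any", frozenset(self.genes.index[self.genes[cols].any(axis=1)]))

    def zga_set(self, which: str = "zga_major") -> GeneSet:
        return GeneSet(which, frozenset(self.genes.index[self.genes[which]]))

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", float_format="%.6g")


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw per-gene categories, enrichments and expression trajectories."""
    config.validate()
    rng = config.rng(0)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    cats = rng.choice(len(CATEGORY_ORDER), size=n, p=list(config.proportions))
    category = np.array(CATEGORY_ORDER, dtype=object)[cats]

    # stage pattern per gene
    patt = np.zeros((n, 3), dtype=bool)
    patt[category == "maternal_loss"] = (True, False, False)
    patt[category == "inherited"] = (True, True, True)
    is_denovo = category == "de_novo_gain"
    late = rng.random(n) < config.denovo_l2c_frac
    patt[is_denovo & late] = (False, False, True)
    patt[is_denovo & ~late] = (False, True, True)
    is_trans = category == "transient"
    tri = rng.integers(0, 3, size=n)
    transient_patterns = np.array(
        [(False, True, False), (True, False, True), (True, True, False)]
    )
    patt[is_trans] = transient_patterns[tri[is_trans]]

    enrich = np.maximum(
        rng.normal(config.enrichment_mean, config.enrichment_sd, size=n),
        config.enrichment_min,
    )
    enrich[category == "untagged"] = 0.0

    # base expression (arbitrary molar units) and stage trajectories
    base = np.exp(rng.normal(0.0, config.expr_sigma, size=n))
    expr = np.tile(base[:, None], (1, 3))

    decay_coupled = (category == "maternal_loss") & (rng.random(n) < config.decay_coupling)
    f = config.maternal_decay_fold
    expr[decay_coupled, 1] /= np.sqrt(f)
    expr[decay_coupled, 2] /= f

    burst_coupled = is_denovo & (rng.random(n) < config.burst_coupling)
    zga_minor = np.zeros(n, dtype=bool)
    zga_major = np.zeros(n, dtype=bool)
    # burst-coupled de novo genes start low and burst at the stage of gain
    start_low = burst_coupled
    expr[start_low] = (base[start_low] / config.zga_burst_fold)[:, None]
    major_burst = burst_coupled & late
    minor_burst = burst_coupled & ~late
    expr[major_burst, 2] *= config.zga_burst_fold
    expr[minor_burst, 1] *= config.zga_burst_fold
    expr[minor_burst, 2] *= config.zga_burst_fold
    zga_major |= major_burst
    zga_minor |= minor_burst

    # non-m6A ZGA background from the untagged pool
    untagged = category == "untagged"
    zga_bg = untagged & (rng.random(n) < config.zga_frac_untagged)
    bg_minor = zga_bg & (rng.random(n) < config.zga_minor_frac)
    bg_major = zga_bg & ~bg_minor
    expr[zga_bg] = (base[zga_bg] / config.zga_burst_fold)[:, None]
    expr[bg_major, 2] *= config.zga_burst_fold
    expr[bg_minor, 1] *= config.zga_burst_fold
    expr[bg_minor, 2] *= config.zga_burst_fold
    zga_major |= bg_major
    zga_minor |= bg_minor

    # translation: inherited genes get the propensity lift
    propensity = np.full(n, config.base_detect)
    propensity[category == "inherited"] = min(
        1.0, config.base_detect + config.detection_link
    )
    translated = rng.random(n) < propensity

    # knockdown targets: m6A-tagged genes destabilized by reader loss
    kd_effect = np.zeros(n)
    m6a_any = patt.any(axis=1)
    pool = np.flatnonzero(m6a_any)
    if len(pool) < config.n_kd_genes:
        pool = np.arange(n)
    kd_idx = rng.choice(pool, size=min(config.n_kd_genes, len(pool)), replace=False)
    kd_effect[kd_idx] = config.kd_log2fc

    lengths = np.round(np.exp(rng.normal(np.log(2000.0), 0.5, size=n))).clip(200, None)

    genes = pd.DataFrame(
        {
            "category": pd.Categorical(category, categories=list(CATEGORY_ORDER)),
            "m6a_MII": patt[:, 0],
            "m6a_L1C": patt[:, 1],
            "m6a_L2C": patt[:, 2],
            "enrichment": np.where(patt.any(axis=1), enrich, 0.0),
            "expr_MII": expr[:, 0],
            "expr_L1C": expr[:, 1],
            "expr_L2C": expr[:, 2],
            "translation_propensity": propensity,
            "translated": translated,
            "kd_effect": kd_effect,
            "zga_minor": zga_minor,
            "zga_major": zga_major,
            "length": lengths,
        },
        index=gene_ids,
    )
    return SimTruth(genes=genes, config=config)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if alpha <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mean)
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def simulate_counts(truth: SimTruth, config: SimConfig | None = None) -> OmicsDataset:
    """NB-distributed IP/input counts per stage plus Ctrl/KD RNA-seq.

    Input read mass per gene is proportional to expression x length
    (longer transcripts yield more fragments, so TPM recovers relative
    expression); IP mass multiplies in ``2**enrichment`` for m6A-tagged
    stages and is renormalized to the library size, as in a real IP where
    enriched species crowd out the rest.  Knockdown RNA-seq samples are
    generated at L2C with ``2**kd_effect`` applied in the KD group.
    """
    config = config or truth.config
    rng = config.rng(1)
    g = truth.genes
    n = len(g)
    lengths = g["length"].to_numpy()
    alpha = config.dispersion

    counts: dict[str, np.ndarray] = {}
    meta_rows = []

    def add_sample(name: str, mean: np.ndarray, stage: str, assay: str, rep: int, group=None):
        counts[name] = _nb_draw(rng, mean, alpha)
        meta_rows.append(
            {"sample_id": name, "stage": stage, "assay": assay, "replicate": rep,
             "group": group if group is not None else ""}
        )

    for si, stage in enumerate(STAGE_ORDER):
        expr = g[f"expr_{stage}"].to_numpy()
        mass_in = expr * lengths
        w_in = mass_in / mass_in.sum()
        m6a = g[f"m6a_{stage}"].to_numpy()
        mass_ip = mass_in * np.where(m6a, 2.0 ** g["enrichment"].to_numpy(), 1.0)
        w_ip = mass_ip / mass_ip.sum()
        for rep in range(1, config.n_replicates + 1):
            depth_in = config.library_size * np.exp(rng.normal(0, config.depth_sigma))
            depth_ip = config.library_size * np.exp(rng.normal(0, config.depth_sigma))
            add_sample(f"{stage}_input_{rep}", depth_in * w_in, stage, "input", rep)
            add_sample(f"{stage}_IP_{rep}", depth_ip * w_ip, stage, "IP", rep)

    # knockdown RNA-seq at L2C
    expr_l2c = g["expr_L2C"].to_numpy() * lengths
    w_ctrl = expr_l2c / expr_l2c.sum()
    kd_mass = expr_l2c * 2.0 ** g["kd_effect"].to_numpy()
    w_kd = kd_mass / kd_mass.sum()
    for rep in range(1, config.n_replicates + 1):
        depth_c = config.library_size * np.exp(rng.normal(0, config.depth_sigma))
        depth_k = config.library_size * np.exp(rng.normal(0, config.depth_sigma))
        add_sample(f"rna_Ctrl_{rep}", depth_c * w_ctrl, "L2C", "rna", rep, group="Ctrl")
        add_sample(f"rna_KD_{rep}", depth_k * w_kd, "L2C", "rna", rep, group="KD")

    counts_df = pd.DataFrame(counts, index=g.index)
    samples = pd.DataFrame(meta_rows)
    return OmicsDataset(
        counts=counts_df,
        samples=samples,
        gene_lengths=g["length"].astype(float),
    )


def simulate_detection_and_ct(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ribosome-profiling TPM, proteomics intensities, their sample sheet,
    and a qPCR Ct table.

    Detection per replicate is Bernoulli: translated genes are seen at
    ``detect_hit_rate``, others at ``detect_noise_rate``.  Ribo values are
    TPM-scale lognormal where detected (0 otherwise); protein intensities
    are lognormal with NaN dropout.  The Ct table contains knockdown
    validation runs (targets + an ``Actb`` reference amplicon, Ctrl vs KD),
    RIP percent-input runs for the same targets, and GFP/mCherry spike-in
    MeRIP records with the configured true enrichment fold.
    """
    config = config or truth.config
    rng = config.rng(2)
    g = truth.genes
    n = len(g)
    hit_p = np.where(g["translated"], config.detect_hit_rate, config.detect_noise_rate)

    ribo_cols, prot_cols, meta_rows = {}, {}, []
    for stage in STAGE_ORDER:
        for rep in range(1, config.n_replicates + 1):
            seen = rng.random(n) < hit_p
            ribo = np.where(seen, np.exp(rng.normal(np.log(50.0), 1.0, size=n)), 0.0)
            prot = np.where(seen, np.exp(rng.normal(np.log(1e6), 1.0, size=n)), np.nan)
            ribo_cols[f"ribo_{stage}_{rep}"] = ribo
            prot_cols[f"prot_{stage}_{rep}"] = prot
            meta_rows.append({"sample_id": f"ribo_{stage}_{rep}", "stage": stage,
                              "assay": "ribo", "replicate": rep})
            meta_rows.append({"sample_id": f"prot_{stage}_{rep}", "stage": stage,
                              "assay": "protein", "replicate": rep})
    ribo_df = pd.DataFrame(ribo_cols, index=g.index)
    prot_df = pd.DataFrame(prot_cols, index=g.index)
    det_samples = pd.DataFrame(meta_rows).set_index("sample_id")

    ct_df = _simulate_ct(truth, config)
    return ribo_df, prot_df, det_samples, ct_df


def _simulate_ct(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    rng = config.rng(3)
    g = truth.genes
    kd_genes = g.index[g["kd_effect"] != 0]
    targets = list(kd_genes[: config.n_qpcr_targets])

    def ct_of(abundance: float) -> float:
        noise = rng.normal(0.0, config.ct_sd) if config.ct_sd > 0 else 0.0
        return config.ct_intercept - np.log2(max(abundance, 1e-12)) + noise

    rows = []
    # knockdown validation, total RNA fraction, Ctrl vs KD
    for target in targets + ["Actb"]:
        if target == "Actb":
            abund, kd = 100.0, 0.0
        else:
            abund = float(g.loc[target, "expr_L2C"])
            kd = float(g.loc[target, "kd_effect"])
        for cond, shift in (("Ctrl", 0.0), ("KD", kd)):
            for rep in range(1, config.qpcr_replicates + 1):
                rows.append({"target": target, "condition": cond, "fraction_kind": "total",
                             "ct": ct_of(abund * 2.0 ** shift), "replicate": rep})

    # RIP percent-input for the targets (reader pulls down m6A-tagged RNA)
    for target in targets:
        abund = float(g.loc[target, "expr_L2C"])
        enriched = bool(g.loc[target, "m6a_L2C"])
        recovery = config.rip_base_recovery * (
            2.0 ** float(g.loc[target, "enrichment"]) if enriched else 1.0
        )
        for rep in range(1, config.qpcr_replicates + 1):
            rows.append({"target": target, "condition": "RIP", "fraction_kind": "input",
                         "ct": ct_of(abund * config.input_fraction), "replicate": rep})
            rows.append({"target": target, "condition": "RIP", "fraction_kind": "IP",
                         "ct": ct_of(abund * recovery), "replicate": rep})

    # spike-in MeRIP: methylated GFP vs unmodified mCherry
    spike_abund = 10.0
    for name, fold in (("GFP", config.spike_enrichment_fold), ("mCherry", 1.0)):
        recovery = config.rip_base_recovery * fold
        for rep in range(1, config.qpcr_replicates + 1):
            rows.append({"target": name, "condition": "spikein", "fraction_kind": "input",
                         "ct": ct_of(spike_abund * config.input_fraction), "replicate": rep})
            rows.append({"target": name, "condition": "spikein", "fraction_kind": "IP",
                         "ct": ct_of(spike_abund * recovery), "replicate": rep})
    return pd.DataFrame(rows)


def write_simulation(
    truth: SimTruth, out_dir: str | Path, config: SimConfig | None = None
) -> dict[str, Path]:
    """Materialize a full synthetic dataset as TSV files."""
    from .io import write_dataset

    config = config or truth.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_counts(truth, config)
    paths = write_dataset(ds, out)
    ribo, prot, det_samples, ct = simulate_detection_and_ct(truth, config)
    for name, df in (("ribo_tpm", ribo), ("protein", prot)):
        p = out / f"{name}.tsv"
        df.index.name = "gene_id"
        df.to_csv(p, sep="\t", float_format="%.6g")
        paths[name] = p
    p = out / "detection_samples.tsv"
    det_samples.reset_index().to_csv(p, sep="\t", index=False)
    paths["detection_samples"] = p
    p = out / "ct.tsv"
    ct.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["ct"] = p
    p = out / "truth.tsv"
    truth.to_tsv(p)
    paths["truth"] = p
    return paths
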