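"""End-to-end orchestration: calling -> dynamics/ZGA -> integration.

:func:`run_pipeline` wires the stages together on either user-supplied
TSVs or a synthetic dataset, applies every documented threshold from a
single :class:`PipelineConfig`, and emits one JSON-serializable report
with all set sizes, ratios and null P values.  All randomness flows from
the config seeds; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import integration as integ
from .enrichment import (
    StageCallTable,
    build_stage_call_table,
    counts_to_tpm,
    m6a_gene_sets,
)
from .io import GeneSet, OmicsDataset, write_gene_set

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, with the published defaults.

    ``p_call`` / ``lfc_na`` / ``min_input_count`` / ``consensus`` govern
    the m6A calling rule; ``zga_fc`` the strict ZGA fold-change bound;
    ``deg_p`` / ``deg_lfc`` the knockdown DEG rule; ``detection_reps`` the
    within-stage detection rule for ribo/protein matrices.
    """

    p_call: float = 0.05
    lfc_na: float = 2.0
    min_input_count: float = 1.0
    consensus: int = 2
    pseudocount: float = 0.5
    prior_sd: float = 1.0
    zga_fc: float = 5.0
    zga_pseudocount: float = 0.1
    deg_p: float = 0.05
    deg_lfc: float = 1.0
    detection_reps: int = 2
    detection_min_value: float = 0.0
    n_replicates: int = 3
    resample_iters: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("p_call", "lfc_na", "zga_fc", "deg_p", "deg_lfc", "prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.consensus > self.n_replicates:
            raise ValueError(
                f"consensus of {self.consensus} unreachable with "
                f"{self.n_replicates} replicates"
            )


def run_pipeline(
    dataset: OmicsDataset,
    config: PipelineConfig | None = None,
    ribo: pd.DataFrame | None = None,
    protein: pd.DataFrame | None = None,
    detection_samples: pd.DataFrame | None = None,
) -> dict:
    """Run calling, dynamics, ZGA and (when matrices are given) integration.

    Returns the report dict; when ``config.out_dir`` is set, also writes
    stage tables, gene sets and ``report.json`` there.
    """
    config = config or PipelineConfig()
    config.validate()
    report: dict = {"thresholds": asdict(config)}
    t0 = time.perf_counter()

    logger.info("stage 1/4: m6A calling")
    calls = build_stage_call_table(
        dataset,
        pseudocount=config.pseudocount,
        prior_sd=config.prior_sd,
        p_call=config.p_call,
        lfc_na=config.lfc_na,
        min_input_count=config.min_input_count,
        consensus=config.consensus,
    )
    sets = m6a_gene_sets(calls)
    report["m6a_set_sizes"] = {name: len(s) for name, s in sets.items()}

    logger.info("stage 2/4: dynamics classification")
    records, sankey = dyn.classify_dynamics(calls)
    report["category_counts"] = (
        records["category"].value_counts().sort_index().astype(int).to_dict()
    )
    report["pattern_counts"] = records["pattern"].value_counts().astype(int).to_dict()
    report["sankey"] = sankey

    logger.info("stage 3/4: ZGA calling")
    if dataset.gene_lengths is None:
        raise ValueError("gene lengths are required for TPM-based ZGA calling")
    input_cols = dataset.samples_for(assay="input")
    tpm = counts_to_tpm(dataset.counts[input_cols], dataset.gene_lengths)
    means = dyn.stage_means(tpm, dataset.samples, assay="input")
    zga = dyn.detect_zga(means, fc_threshold=config.zga_fc, pseudocount=config.zga_pseudocount)
    report["zga_counts"] = {
        "minor": int(zga["minor_zga"].sum()),
        "major": int(zga["major_zga"].sum()),
    }
    overlap = dyn.zga_m6a_overlap(zga, sets["L2C"], which="major_zga")
    report["zga_m6a_overlap"] = {
        "n_overlap": overlap.n_overlap,
        "n_zga": overlap.n_zga,
        "n_zga_without_m6a": overlap.n_zga_without_m6a,
    }
    records, coupled = dyn.couple_mrna_change(records, means)
    report["coupled_sets"] = {name: len(s) for name, s in coupled.items()}

    logger.info("stage 4/4: integration")
    patt = calls.pattern_frame()
    inherited = GeneSet("inherited", frozenset(patt.index[patt.all(axis=1)]))
    report["integration"] = {}
    if ribo is not None and detection_samples is not None:
        detected = integ.detected_gene_set(
            ribo,
            detection_samples,
            min_value=config.detection_min_value,
            min_reps=config.detection_reps,
            name="translation_active",
        )
        universe = GeneSet("universe", frozenset(dataset.gene_ids))
        block: dict = {"n_detected": len(detected)}
        if len(inherited):
            ratio, n_hit, n_tot = integ.translation_active_ratio(inherited, detected)
            null = integ.resample_ratio_null(
                n=len(inherited),
                universe=universe,
                detected=detected,
                n_iter=config.resample_iters,
                seed=config.seed,
            )
            block["inherited_ratio"] = ratio
            block["inherited_counts"] = [n_hit, n_tot]
            block["null_mean_ratio"] = float(null.null_ratios.mean())
            block["inherited_empirical_p"] = null.empirical_p(ratio)
        report["integration"]["ribo"] = block
    if protein is not None and detection_samples is not None:
        prot_norm = integ.upper_quartile_normalize(protein)
        prot_detected = integ.detected_gene_set(
            prot_norm,
            detection_samples,
            min_value=config.detection_min_value,
            min_reps=config.detection_reps,
            name="protein_detected",
        )
        report["integration"]["protein"] = {"n_detected": len(prot_detected)}

    deg_report: dict = {}
    has_groups = "group" in dataset.samples.columns and set(
        dataset.samples.get("group", pd.Series(dtype=str))
    ) >= {"Ctrl", "KD"}
    if has_groups:
        deg = integ.de_test(
            dataset, p_thresh=config.deg_p, lfc_thresh=config.deg_lfc
        )
        dsets = integ.deg_sets(deg)
        deg_report = {
            "n_up": len(dsets["deg_up"]),
            "n_down": len(dsets["deg_down"]),
        }
        venn = integ.overlap_venn([dsets["deg_down"], sets["m6A_any"]])
        deg_report["down_and_m6a"] = venn[(1, 1)]
        if len(dsets["deg_down"]):
            deg_report["down_m6a_fraction"] = venn[(1, 1)] / len(dsets["deg_down"])
    report["deg"] = deg_report

    report["runtime_s"] = round(time.perf_counter() - t0, 3)
    _check_set_algebra(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls.to_tsv(out / "calls.tsv")
        records.to_csv(out / "dynamics.tsv", sep="\t", float_format="%.6g")
        zga.to_csv(out / "zga.tsv", sep="\t", float_format="%.6g")
        sets_dir = out / "sets"
        for s in sets.values():
            write_gene_set(s, sets_dir / f"{s.name}.txt")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _check_set_algebra(report: dict) -> None:
    """Internal consistency: category counts partition the gene universe."""
    sizes = report["m6a_set_sizes"]
    cats = report["category_counts"]
    n_genes = sum(cats.values())
    n_tagged = n_genes - cats.get("untagged", 0)
    if sizes["m6A_any"] != n_tagged:
        raise AssertionError(
            f"set algebra violated: |m6A_any|={sizes['m6A_any']} but "
            f"{n_tagged} genes have a tagged category"
        )
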