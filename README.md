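# mzt-m6a

Gene-level m6A enrichment calling and multi-omics integration for the
mouse **maternal-to-zygotic transition** (MZT).

During the MZT, maternally deposited mRNAs are cleared while the zygotic
genome switches on (zygotic genome activation, ZGA — a minor wave at the
1-cell and a major wave at the 2-cell stage). The N6-methyladenosine
(m6A) mark on mRNA steers both processes: it can route maternal
transcripts into decay or protect an inherited subset for translation.
Low-input, gene-level m6A immunoprecipitation (paired IP and input
libraries per stage) makes this measurable in oocytes and early embryos,
where material is scarce.

This package provides the complete downstream analysis for such a study,
for computational biologists working from count matrices:

* **Enrichment calling** — median-of-ratios size factors, TPM, a
  negative-binomial Wald test of IP vs input per stage
  (`Var = μ + αμ²`, log-linear model with log size-factor offsets), and
  the replicate-consensus decision rule: a gene is m6A-tagged in a stage
  when, in ≥ 2 of 3 replicate pairs, the raw input count exceeds 1 and
  the replicate log2(IP/input) is positive with stage P < 0.05 (or
  exceeds 2 when the P value is NA). The reported "relative m6A level"
  is the shrunken fold-change `lfc · τ²/(τ² + se²)` with prior scale
  τ = 1 log2 unit.
* **Dynamics & ZGA** — the (MII, L1C, L2C) call pattern maps onto
  maternal-loss / inherited / de-novo-gain / transient / untagged
  categories with Sankey transition counts; minor/major ZGA genes are
  called at a strict stage-mean TPM fold-change > 5.
* **Multi-omics integration** — translation (ribosome profiling) and
  proteome detection sets (detected in ≥ 2 replicates of ≥ 1 stage),
  translation-active ratios with a resampling null
  (`p = (1 + #{null ≥ obs})/(1 + B)`), knockdown DEG calling
  (P < 0.05, |log2FC| > 1), Venn regions, Fisher's exact test and BH
  correction, and sample-correlation QC.
* **qPCR quantification** — ΔΔCt relative expression
  (`RQ = 2^−ΔΔCt`), RIP percent-input with dilution adjustment, and
  spike-in signal-to-noise ratios (methylated GFP vs unmodified mCherry).
* **Synthetic data** — a fully seeded generator producing
  stage-structured NB counts, detection matrices and Ct tables with
  known per-gene truth, so every stage is testable end-to-end without
  any download.

See `docs/methods.md` for the model details, calibration choices and
generator assumptions.

## Worked example

```python
from mzt_m6a import (SimConfig, simulate_truth, simulate_counts,
                     simulate_detection_and_ct, build_stage_call_table,
                     m6a_gene_sets, classify_dynamics, GeneSet)
from mzt_m6a.integration import (detected_gene_set, translation_active_ratio,
                                 resample_ratio_null)

cfg = SimConfig(seed=7)                      # 5000 genes, 3 stages x 3 reps
truth = simulate_truth(cfg)
dataset = simulate_counts(truth, cfg)

calls = build_stage_call_table(dataset)      # NB test + consensus rule
sets = m6a_gene_sets(calls)
print({s: len(g) for s, g in sets.items()})
# {'MII': 592, 'L1C': 418, 'L2C': 613, 'm6A_any': 1082, 'm6A_neg': 3918}

records, sankey = classify_dynamics(calls)
print(records["category"].value_counts().to_dict())
# {'untagged': 3918, 'de_novo_gain': 368, 'maternal_loss': 296,
#  'transient': 224, 'inherited': 194}

ribo, protein, sheet, ct = simulate_detection_and_ct(truth, cfg)
detected = detected_gene_set(ribo, sheet, name="translation_active")
inherited = GeneSet("inherited",
                    frozenset(records.index[records["category"] == "inherited"]))
ratio, n_hit, n_tot = translation_active_ratio(inherited, detected)
null = resample_ratio_null(n_tot, GeneSet("universe", frozenset(dataset.gene_ids)),
                           detected, n_iter=999, seed=7)
print(f"inherited translation-active ratio: {n_hit}/{n_tot} = {100*ratio:.1f}%")
print(f"random-set null mean: {100*null.null_ratios.mean():.1f}%"
      f"  empirical p = {null.empirical_p(ratio):.3f}")
# inherited translation-active ratio: 180/194 = 92.8%
# random-set null mean: 54.1%  empirical p = 0.001
```

Reading the output: the caller recovers ~1100 m6A-tagged genes of 5000
(the generator plants ~19.5%), splits them into the dynamics categories,
and shows that the *inherited* genes — m6A-tagged at every stage — are
detected as translated far more often (92.8%) than random gene sets of
the same size (54.1%), with the smallest P the 999-draw null can
produce. This is the package's core biological readout: maternally
inherited m6A marks a translated, stabilized subset of transcripts.

The same workflow is scriptable from the shell:

```bash
mzt-m6a simulate --seed 7 --out-dir sim/
mzt-m6a call-m6a --counts sim/counts.tsv --samples sim/samples.tsv \
    --lengths sim/lengths.tsv --out calls.tsv --sets-dir sets/
mzt-m6a run --counts sim/counts.tsv --samples sim/samples.tsv \
    --lengths sim/lengths.tsv --ribo sim/ribo_tpm.tsv \
    --detection-samples sim/detection_samples.tsv --seed 7 --out-dir out/
```

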