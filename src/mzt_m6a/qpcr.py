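"""qPCR quantification: ddCt relative expression, RIP percent-input, and
spike-in signal-to-noise ratios.

All calculations assume a perfect amplification efficiency of 2 (one
template doubling per cycle) unless an efficiency is supplied; replicate
Ct values are averaged on the cycle scale before exponentiation, the
conventional ddCt procedure.

Input is a tidy Ct table with columns ``target``, ``condition``,
``fraction_kind`` (``total`` / ``IP`` / ``input``), ``ct`` and
``replicate`` — e.g. knockdown-validation runs normalized to a reference
amplicon such as Actb, or RNA-immunoprecipitation runs where a fixed
fraction (typically 10%) of the lysate was set aside as input.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("target", "condition", "fraction_kind", "ct", "replicate")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(records["ct"].to_numpy(dtype=float)).all():
        raise ValueError("all Ct values must be finite")
    return records


def _mean_ct(
    records: pd.DataFrame, target: str, condition: str, fraction_kind: str
) -> float:
    sel = records[
        (records["target"] == target)
        & (records["condition"] == condition)
        & (records["fraction_kind"] == fraction_kind)
    ]
    if sel.empty:
        raise ValueError(
            f"no Ct for target={target!r}, condition={condition!r}, "
            f"fraction={fraction_kind!r}"
        )
    return float(sel["ct"].mean())


def ddct_relative_expression(
    records: pd.DataFrame,
    target: str,
    reference_gene: str,
    baseline_condition: str,
    fraction_kind: str = "total",
    efficiency: float = 2.0,
) -> pd.Series:
    """Relative quantity per condition by the ddCt method.

    ``RQ(cond) = E ** -[(Ct_target - Ct_ref)(cond) - (Ct_target - Ct_ref)(base)]``
    with replicate Cts averaged first; the baseline condition is 1 by
    construction.  Adding a constant to every Ct (an instrument offset)
    leaves all RQs unchanged.
    """
    records = _check_records(records)
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    measured = records[records["fraction_kind"] == fraction_kind]
    conditions = sorted(measured.loc[measured["target"] == target, "condition"].unique())
    if baseline_condition not in conditions:
        raise ValueError(f"baseline condition {baseline_condition!r} not measured")
    dct_base = _mean_ct(records, target, baseline_condition, fraction_kind) - _mean_ct(
        records, reference_gene, baseline_condition, fraction_kind
    )
    out = {}
    for cond in conditions:
        dct = _mean_ct(records, target, cond, fraction_kind) - _mean_ct(
            records, reference_gene, cond, fraction_kind
        )
        out[cond] = float(efficiency ** -(dct - dct_base))
    return pd.Series(out, name=f"RQ_{target}")


def percent_input(
    records: pd.DataFrame,
    target: str,
    condition: str,
    input_fraction: float = 0.1,
    efficiency: float = 2.0,
) -> float:
    """RIP recovery as percent of (dilution-adjusted) input.

    ``%input = 100 * E ** [(Ct_input - log_E(1/f)) - Ct_IP]`` where ``f``
    is the fraction of lysate kept as input (0.1 for a 10% aliquot, an
    adjustment of ~3.32 cycles at perfect efficiency).
    """
    records = _check_records(records)
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ct_in = _mean_ct(records, target, condition, "input")
    ct_ip = _mean_ct(records, target, condition, "IP")
    dilution_cycles = np.log(1.0 / input_fraction) / np.log(efficiency)
    return float(100.0 * efficiency ** ((ct_in - dilution_cycles) - ct_ip))


def spikein_sn_ratio(
    records: pd.DataFrame,
    condition: str = "spikein",
    positive: str = "GFP",
    negative: str = "mCherry",
    input_fraction: float = 0.1,
    efficiency: float = 2.0,
) -> float:
    """MeRIP selectivity: percent-input of the methylated spike-in divided
    by percent-input of the unmethylated one.

    By convention the positive control is an in-vitro-transcribed GFP RNA
    carrying m6A and the negative an unmodified mCherry RNA.  A zero
    negative recovery yields +inf with a warning.
    """
    pos = percent_input(records, positive, condition, input_fraction, efficiency)
    neg = percent_input(records, negative, condition, input_fraction, efficiency)
    if neg == 0:
        warnings.warn("negative spike-in recovery is zero; SN ratio is infinite", stacklevel=2)
        return float("inf")
    return pos / neg
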