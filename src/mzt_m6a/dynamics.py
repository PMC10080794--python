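"""Cross-stage m6A dynamics and zygotic genome activation calls.

Across the three profiled stages (MII oocyte -> late 1-cell -> late 2-cell)
each gene's ordered triple of m6A calls defines a dynamics category:

====================  ==========================================
pattern (MII,L1C,L2C)  category
====================  ==========================================
(1, 0, 0)              maternal_loss — tagged in the oocyte only
(1, 1, 1)              inherited — tagged throughout
(0, 0, 1) / (0, 1, 1)  de_novo_gain — tagged after fertilization
(0,1,0)/(1,0,1)/(1,1,0) transient
(0, 0, 0)              untagged
====================  ==========================================

The raw 8-pattern tabulation is always reported alongside so users can
regroup (e.g. count L1C gains separately from L2C gains).

ZGA genes are called from TPM fold-changes between stage means: minor ZGA
when L1C/MII > 5, major ZGA when L2C/L1C > 5 (strict inequalities, small
pseudocount on the means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import StageCallTable
from .io import GeneSet

CATEGORIES = ("maternal_loss", "inherited", "de_novo_gain", "transient", "untagged")

_PATTERN_TO_CATEGORY = {
    (True, False, False): "maternal_loss",
    (True, True, True): "inherited",
    (False, False, True): "de_novo_gain",
    (False, True, True): "de_novo_gain",
    (False, True, False): "transient",
    (True, False, True): "transient",
    (True, True, False): "transient",
    (False, False, False): "untagged",
}

ZGA_FC = 5.0
ZGA_PSEUDOCOUNT = 0.1


def classify_dynamics(
    calls: StageCallTable | pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Categorize every gene by its stage-call pattern.

    Parameters
    ----------
    calls
        A :class:`~mzt_m6a.enrichment.StageCallTable` covering all three
        stages, or an equivalent genes x stages boolean frame.

    Returns
    -------
    records, sankey
        ``records`` has one row per gene with the boolean pattern columns,
        a ``pattern`` string (e.g. ``"101"``) and ``category``.  ``sankey``
        maps each stage boundary to ``kept`` / ``lost`` / ``gained`` counts.
    """
    patt = calls.pattern_frame() if isinstance(calls, StageCallTable) else calls.astype(bool)
    if patt.shape[1] != 3:
        raise ValueError("dynamics classification requires exactly three stages")
    stages = list(patt.columns)
    arr = patt.to_numpy(dtype=bool)
    cats = [_PATTERN_TO_CATEGORY[tuple(row)] for row in arr]
    records = patt.copy()
    records["pattern"] = ["".join("1" if v else "0" for v in row) for row in arr]
    records["category"] = pd.Categorical(cats, categories=list(CATEGORIES))

    sankey: dict[str, dict[str, int]] = {}
    for a, b in zip(stages[:-1], stages[1:]):
        sa, sb = patt[a].to_numpy(), patt[b].to_numpy()
        sankey[f"{a}->{b}"] = {
            "kept": int((sa & sb).sum()),
            "lost": int((sa & ~sb).sum()),
            "gained": int((~sa & sb).sum()),
        }
    return records, sankey


def stage_means(
    tpm: pd.DataFrame, samples: pd.DataFrame, assay: str = "input"
) -> pd.DataFrame:
    """Mean TPM per stage over replicates of the given assay."""
    sheet = samples.loc[[c for c in tpm.columns if c in samples.index]]
    sel = sheet[sheet["assay"] == assay]
    out = {}
    for stage, grp in sel.groupby("stage", observed=True):
        out[str(stage)] = tpm[list(grp.index)].mean(axis=1)
    return pd.DataFrame(out)


def detect_zga(
    tpm_stage_means: pd.DataFrame,
    fc_threshold: float = ZGA_FC,
    pseudocount: float = ZGA_PSEUDOCOUNT,
    stage_order: tuple[str, str, str] = ("MII", "L1C", "L2C"),
) -> pd.DataFrame:
    """Call minor and major ZGA genes from stage-mean TPM.

    Minor ZGA: TPM fold-change L1C vs MII strictly above ``fc_threshold``;
    major ZGA: L2C vs L1C.  Fold-changes are ``(mean+c)/(mean+c)`` with
    pseudocount ``c`` so silent-oocyte genes (the dominant ZGA case) stay
    finite.  ``c`` is expressed in TPM units (columns summing to 1e6) and
    is internally rescaled with the matrix, so calls are invariant to a
    uniform rescaling of all columns.
    """
    mii, l1c, l2c = stage_order
    for s in stage_order:
        if s not in tpm_stage_means.columns:
            raise ValueError(f"stage mean TPM missing stage {s!r}")
    m = tpm_stage_means
    col_sums = m[[mii, l1c, l2c]].sum(axis=0)
    scale = float(col_sums.mean()) / 1e6 if (col_sums > 0).all() else 1.0
    pseudocount = pseudocount * scale
    fc_minor = (m[l1c] + pseudocount) / (m[mii] + pseudocount)
    fc_major = (m[l2c] + pseudocount) / (m[l1c] + pseudocount)
    return pd.DataFrame(
        {
            "fc_l1c_mii": fc_minor,
            "fc_l2c_l1c": fc_major,
            "minor_zga": fc_minor > fc_threshold,
            "major_zga": fc_major > fc_threshold,
        },
        index=m.index,
    )


def couple_mrna_change(
    records: pd.DataFrame,
    tpm_stage_means: pd.DataFrame,
    from_stage: str = "MII",
    to_stage: str = "L2C",
    fc_threshold: float = 1.0,
    pseudocount: float = ZGA_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, dict[str, GeneSet]]:
    """Annotate dynamics records with the mRNA direction over a transition.

    ``mrna_direction`` is ``up`` when (to+c)/(from+c) exceeds
    ``fc_threshold``, ``down`` when it is below ``1/fc_threshold``, else
    ``flat``.  The default threshold of 1 reduces to the sign of the
    change.  Also returns the coupled sets ``loss_down``
    (maternal-loss genes whose mRNA decreases) and ``gain_up``
    (de-novo-gain genes whose mRNA increases).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    for s in (from_stage, to_stage):
        if s not in tpm_stage_means.columns:
            raise ValueError(f"unknown stage {s!r}")
    fc = (
        (tpm_stage_means[to_stage] + pseudocount)
        / (tpm_stage_means[from_stage] + pseudocount)
    ).reindex(records.index)
    direction = np.where(fc > fc_threshold, "up", np.where(fc < 1.0 / fc_threshold, "down", "flat"))
    annotated = records.copy()
    annotated["mrna_fc"] = fc
    annotated["mrna_direction"] = direction
    loss_down = frozenset(
        annotated.index[
            (annotated["category"] == "maternal_loss") & (annotated["mrna_direction"] == "down")
        ]
    )
    gain_up = frozenset(
        annotated.index[
            (annotated["category"] == "de_novo_gain") & (annotated["mrna_direction"] == "up")
        ]
    )
    sets = {
        "loss_down": GeneSet("loss_down", loss_down),
        "gain_up": GeneSet("gain_up", gain_up),
    }
    return annotated, sets


@dataclass
class ZGAOverlap:
    overlap: GeneSet
    n_zga: int
    n_m6a: int
    n_overlap: int
    n_zga_without_m6a: int


def zga_m6a_overlap(
    zga_calls: pd.DataFrame,
    stage_set: GeneSet,
    which: str = "major_zga",
) -> ZGAOverlap:
    """Intersect a ZGA gene set with a stage's m6A-tagged set.

    Returns the overlap set plus counts, including the complement count
    (ZGA genes carrying no m6A mark at that stage).
    """
    zga_genes = frozenset(zga_calls.index[zga_calls[which]])
    inter = zga_genes & stage_set.members
    return ZGAOverlap(
        overlap=GeneSet(f"{which}&{stage_set.name}", inter),
        n_zga=len(zga_genes),
        n_m6a=len(stage_set),
        n_overlap=len(inter),
        n_zga_without_m6a=len(zga_genes - stage_set.members),
    )
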