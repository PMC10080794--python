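"""Shared data model and tabular I/O.

Everything downstream consumes one of two containers:

* :class:`OmicsDataset` — an integer count matrix (genes x samples) plus a
  sample sheet and an optional gene-length table.  IP/input SLIM-seq
  libraries, knockdown RNA-seq and plain RNA-seq all arrive in this shape.
* :class:`GeneSet` — a named collection of gene identifiers used for all
  overlap / Venn / enrichment arithmetic.

All tables are plain TSV: counts with a ``gene_id`` first column and one
column per sample; the sample sheet with columns ``sample_id``, ``stage``,
``assay``, ``replicate`` and optional ``group``; lengths with ``gene_id``
and ``length``.  Gene identifiers are opaque strings — no annotation or
species assumptions are made anywhere in the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Developmental stages in biological order: metaphase-II oocyte, late
#: 1-cell embryo, late 2-cell embryo.  Every stage comparison in the
#: package uses this order unless an explicit override is given.
STAGE_ORDER: tuple[str, ...] = ("MII", "L1C", "L2C")

#: Recognised assay labels.  ``IP`` / ``input`` are the antibody-enriched
#: and matched non-enriched sequencing libraries; ``rna`` is ordinary
#: RNA-seq; ``ribo`` and ``protein`` mark detection-style matrices.
ASSAYS: tuple[str, ...] = ("IP", "input", "rna", "ribo", "protein")

#: Count-based assays for which counts must be non-negative integers.
_INTEGER_ASSAYS = frozenset({"IP", "input", "rna"})


class SchemaError(ValueError):
    """A table violates the documented schema (columns, keys, enums)."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}", self.members & other.members)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.members | other.members)

    def difference(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}-{other.name}", self.members - other.members)


@dataclass
class OmicsDataset:
    """Count matrix + sample metadata + gene lengths.

    Parameters
    ----------
    counts
        genes x samples DataFrame; index holds gene ids, columns sample ids.
    samples
        Sample sheet indexed by ``sample_id`` with columns ``stage``,
        ``assay``, ``replicate`` and optional ``group``.
    gene_lengths
        Series mapping gene id -> length in nucleotides; required only when
        TPM is requested.
    stage_order
        Ordered stage vocabulary; defaults to MII -> L1C -> L2C.  A sheet
        containing stages outside this vocabulary is rejected.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None
    stage_order: tuple[str, ...] = STAGE_ORDER
    validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        counts, samples = self.counts, self.samples
        if samples.index.name != "sample_id":
            if "sample_id" in samples.columns:
                samples = samples.set_index("sample_id")
            else:
                raise SchemaError("sample sheet must have a 'sample_id' column")
        if samples.index.duplicated().any():
            dups = samples.index[samples.index.duplicated()].tolist()
            raise SchemaError(f"duplicate sample_id in sheet: {dups}")
        missing = [c for c in counts.columns if c not in samples.index]
        if missing:
            raise SchemaError(f"samples in counts absent from sheet: {missing}")
        for col in ("stage", "assay", "replicate"):
            if col not in samples.columns:
                raise SchemaError(f"sample sheet missing column '{col}'")
        bad_stage = set(samples["stage"]) - set(self.stage_order)
        if bad_stage:
            raise SchemaError(
                f"unknown stages {sorted(bad_stage)}; allowed: {list(self.stage_order)}"
            )
        bad_assay = set(samples["assay"]) - set(ASSAYS)
        if bad_assay:
            raise SchemaError(f"unknown assays {sorted(bad_assay)}; allowed: {list(ASSAYS)}")
        rep = pd.to_numeric(samples["replicate"], errors="raise")
        if (rep < 1).any() or (rep != rep.astype(int)).any():
            raise SchemaError("replicate numbers must be positive integers")
        samples = samples.assign(replicate=rep.astype(int))
        key_cols = ["stage", "assay", "replicate"]
        if "group" in samples.columns:
            key_cols.append("group")
        if samples.loc[list(counts.columns)].duplicated(subset=key_cols).any():
            dup = samples.loc[list(counts.columns)]
            dup = dup[dup.duplicated(subset=key_cols, keep=False)]
            raise SchemaError(
                f"duplicate (stage, assay, replicate[, group]) triples: {dup.index.tolist()}"
            )
        if counts.index.duplicated().any():
            raise SchemaError("duplicate gene ids in counts")

        vals = counts.to_numpy()
        try:
            numeric = vals.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric count value: {exc}") from exc
        if pd.isna(numeric).any():
            gene, sample = _locate_offender(counts, pd.isna(numeric))
            raise ValueError(f"missing count for gene {gene!r}, sample {sample!r}")
        if (numeric < 0).any():
            gene, sample = _locate_offender(counts, numeric < 0)
            raise ValueError(f"negative count for gene {gene!r}, sample {sample!r}")
        int_samples = [
            s for s in counts.columns if samples.loc[s, "assay"] in _INTEGER_ASSAYS
        ]
        if int_samples:
            sub = counts[int_samples].to_numpy().astype(float)
            if (sub % 1 != 0).any():
                mask = pd.DataFrame(False, index=counts.index, columns=counts.columns)
                mask[int_samples] = counts[int_samples].astype(float) % 1 != 0
                gene, sample = _locate_offender(counts, mask.to_numpy())
                raise ValueError(
                    f"non-integral count for gene {gene!r}, sample {sample!r} "
                    "(counts for IP/input/rna assays must be integers)"
                )
        if self.gene_lengths is not None:
            gl = pd.to_numeric(self.gene_lengths, errors="raise")
            if (gl <= 0).any():
                bad = gl.index[gl <= 0].tolist()
                raise ValueError(f"non-positive gene lengths: {bad[:5]}")
            self.gene_lengths = gl.astype(float)
        self.samples = samples
        self.validated = True

    # -- convenience ----------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def samples_for(
        self,
        stage: str | None = None,
        assay: str | None = None,
        group: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given stage/assay/group, replicate-sorted."""
        sheet = self.samples.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=sheet.index)
        if stage is not None:
            mask &= sheet["stage"] == stage
        if assay is not None:
            mask &= sheet["assay"] == assay
        if group is not None:
            if "group" not in sheet.columns:
                return []
            mask &= sheet["group"] == group
        sel = sheet[mask].sort_values("replicate")
        return list(sel.index)

    def subset(self, sample_ids: Sequence[str]) -> "OmicsDataset":
        return OmicsDataset(
            counts=self.counts[list(sample_ids)],
            samples=self.samples.loc[list(sample_ids)].copy(),
            gene_lengths=self.gene_lengths,
            stage_order=self.stage_order,
        )


def _locate_offender(counts: pd.DataFrame, mask) -> tuple[str, str]:
    import numpy as np

    gi, si = map(int, next(zip(*np.nonzero(mask))))
    return str(counts.index[gi]), str(counts.columns[si])


# -- file I/O -----------------------------------------------------------


def load_dataset(
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path | None = None,
    stage_order: Iterable[str] = STAGE_ORDER,
) -> OmicsDataset:
    """Read counts/sample-sheet/length TSVs into a validated dataset.

    Raises ``FileNotFoundError`` for missing files, :class:`SchemaError`
    for metadata problems and ``ValueError`` for malformed counts — never
    a silent coercion.
    """
    counts_path, samples_path = Path(counts_path), Path(samples_path)
    counts = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if counts.columns[0] != "gene_id":
        raise SchemaError(
            f"first column of {counts_path} must be 'gene_id', got {counts.columns[0]!r}"
        )
    counts = counts.set_index("gene_id")
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    if "replicate" in samples.columns:
        samples["replicate"] = pd.to_numeric(samples["replicate"])
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", dtype={"gene_id": str})
        if not {"gene_id", "length"} <= set(lt.columns):
            raise SchemaError(f"{lengths_path} must have columns gene_id, length")
        lengths = lt.set_index("gene_id")["length"].astype(float)
    return OmicsDataset(
        counts=counts, samples=samples, gene_lengths=lengths, stage_order=tuple(stage_order)
    )


def write_dataset(ds: OmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts.tsv / samples.tsv / lengths.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
    }
    counts = ds.counts.copy()
    counts.index.name = "gene_id"
    # float_format guards against scientific notation in large counts
    counts.to_csv(paths["counts"], sep="\t", float_format="%.10g")
    ds.samples.reset_index().to_csv(paths["samples"], sep="\t", index=False)
    if ds.gene_lengths is not None:
        paths["lengths"] = out / "lengths.tsv"
        gl = ds.gene_lengths.rename("length")
        gl.index.name = "gene_id"
        gl.to_csv(paths["lengths"], sep="\t")
    return paths


def write_gene_set(gs: GeneSet, path: str | Path) -> Path:
    """Write a gene set as one id per line with a ``#name=`` header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#name={gs.name}\n")
        for gene in sorted(gs.members):
            fh.write(f"{gene}\n")
    return path


def read_gene_set(path: str | Path) -> GeneSet:
    """Read a gene set file; the name defaults to the file stem.

    Duplicate lines are deduplicated with a warning; an empty file yields
    an empty set (also with a warning), not an error.
    """
    path = Path(path)
    name = path.stem
    members: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#name="):
                name = line[len("#name="):].strip() or name
            elif not line.startswith("#"):
                members.append(line)
    if len(set(members)) < len(members):
        warnings.warn(f"duplicate gene ids in {path}; deduplicated", stacklevel=2)
    if not members:
        warnings.warn(f"gene set file {path} is empty", stacklevel=2)
    return GeneSet(name, frozenset(members))
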