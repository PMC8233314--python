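"""Shared data model plus readers/writers for every on-disk format the pipeline touches.

Tabular files are TSV (tab-separated, header row, UTF-8, ``.`` decimal point).
Gene identifiers are opaque, case-sensitive strings: human ``HLA-A`` and mouse
``H2-K1`` style symbols must never collide through case folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPECIES = ("human", "mouse")

__all__ = [
    "FormatError",
    "ExpressionTable",
    "OrthologTable",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gene_set",
    "write_gene_set",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]


class FormatError(ValueError):
    """A file or in-memory table violates the documented format contract."""


@dataclass
class ExpressionTable:
    """Gene x sample matrix of nonnegative expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one numeric column per sample.
    meta
        DataFrame indexed by sample id. Required columns: ``species``
        (``human`` or ``mouse``) and ``condition``. Optional columns:
        ``replicate_pair`` and ``strain``.
    unit
        ``"counts"`` for raw counts or ``"rpkm"`` for length/depth-normalized
        values.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if v.isna().any().any():
            raise FormatError("missing values in expression matrix")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if (arr < 0).any():
            raise FormatError("negative values in expression matrix")
        if self.meta.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = set(v.columns) - set(self.meta.index)
        if missing:
            raise FormatError(f"samples absent from metadata: {sorted(missing)}")
        extra = set(self.meta.index) - set(v.columns)
        if extra:
            raise FormatError(f"metadata samples absent from matrix: {sorted(extra)}")
        for col in ("species", "condition"):
            if col not in self.meta.columns:
                raise FormatError(f"metadata lacks required column {col!r}")
            if self.meta[col].isna().any():
                raise FormatError(f"metadata column {col!r} has missing entries")
        bad = set(self.meta["species"]) - set(SPECIES)
        if bad:
            raise FormatError(f"unknown species labels: {sorted(bad)}")
        # keep metadata row order aligned with matrix columns
        self.meta = self.meta.loc[list(v.columns)]

    # -- convenience --------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every ``column=value`` condition."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            mask &= self.meta[col] == val
        return list(self.meta.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(
            self.values[list(sample_ids)].copy(),
            self.meta.loc[list(sample_ids)].copy(),
            unit=self.unit,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(
            self.values.loc[list(gene_ids)].copy(), self.meta.copy(), unit=self.unit
        )


@dataclass
class OrthologTable:
    """Strictly one-to-one (human gene, mouse gene) identifier pairs."""

    pairs: pd.DataFrame  # columns: human, mouse
    n_dropped: int = 0

    def __post_init__(self) -> None:
        p = self.pairs
        if list(p.columns) != ["human", "mouse"]:
            p = p.copy()
            p.columns = ["human", "mouse"]
            self.pairs = p
        if p["human"].duplicated().any() or p["mouse"].duplicated().any():
            raise FormatError("ortholog table is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def human_to_mouse(self) -> dict[str, str]:
        return dict(zip(self.pairs["human"], self.pairs["mouse"]))

    def mouse_to_human(self) -> dict[str, str]:
        return dict(zip(self.pairs["mouse"], self.pairs["human"]))

    def subset(self, human_ids: Iterable[str]) -> "OrthologTable":
        keep = self.pairs["human"].isin(set(human_ids))
        return OrthologTable(self.pairs.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_expression(path, meta_path, unit: str = "counts") -> ExpressionTable:
    """Load a TSV count/RPKM matrix (first column gene id) and its sample sheet."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression values in {path}: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return ExpressionTable(values, meta, unit=unit)


def write_expression(table: ExpressionTable, path, meta_path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")
    table.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_ortholog_table(path, strict: bool = True) -> OrthologTable:
    """Load a two-column (human id, mouse id) TSV.

    Under ``strict=True`` any identifier seen twice on either side is an error.
    Under ``strict=False`` every pair touching a duplicated identifier is
    dropped (both members of a conflict set), and the count of dropped pairs
    is recorded on the returned table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise FormatError("ortholog table must have exactly two columns")
    df.columns = ["human", "mouse"]
    return make_ortholog_table(df, strict=strict)


def make_ortholog_table(df: pd.DataFrame, strict: bool = True) -> OrthologTable:
    dup = df["human"].duplicated(keep=False) | df["mouse"].duplicated(keep=False)
    if dup.any():
        if strict:
            raise FormatError(
                f"{int(dup.sum())} pairs violate the one-to-one ortholog rule"
            )
        df = df.loc[~dup]
    return OrthologTable(df.reset_index(drop=True), n_dropped=int(dup.sum()))


def write_ortholog_table(table: OrthologTable, path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    """Load a (gene_id, length_bp) TSV into a Series of exonic lengths."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.iloc[:, 0].astype(int)
    validate_gene_lengths(lengths)
    return lengths


def validate_gene_lengths(lengths: pd.Series) -> None:
    if lengths.index.has_duplicates:
        raise FormatError("duplicate gene ids in gene annotation")
    if (lengths < 1).any():
        raise FormatError("gene lengths must be >= 1 bp")


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


def read_gene_set(path) -> set[str]:
    """One gene id per line."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_gene_set(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


# ---------------------------------------------------------------------------
# sequence IO (Sanger FASTQ, Phred+33)
# ---------------------------------------------------------------------------

_VALID_BASES = set("ACGTN")


def _check_alphabet(records: list[SeqRecord]) -> list[SeqRecord]:
    for rec in records:
        if set(str(rec.seq).upper()) - _VALID_BASES:
            raise FormatError(f"record {rec.id}: sequence outside A/C/G/T/N")
    return records


def read_fasta(path) -> list[SeqRecord]:
    try:
        return _check_alphabet(list(SeqIO.parse(str(path), "fasta")))
    except ValueError as exc:
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def read_fastq(path) -> list[SeqRecord]:
    try:
        return _check_alphabet(list(SeqIO.parse(str(path), "fastq")))
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ {path}: {exc}") from exc


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    records = list(records)
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            raise FormatError(f"record {rec.id}: missing or mismatched qualities")
    SeqIO.write(records, str(path), "fastq")


def make_record(rec_id: str, sequence: str, qualities: Sequence[int] | None = None,
                description: str = "") -> SeqRecord:
    rec = SeqRecord(Seq(sequence), id=rec_id, description=description)
    if qualities is not None:
        rec.letter_annotations["phred_quality"] = list(qualities)
    return rec
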