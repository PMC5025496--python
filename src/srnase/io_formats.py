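"""Readers and writers for the external formats the pipeline touches.

Sequences travel as :class:`SequenceRecord` (FASTA), matrices as
:class:`TabularMatrix` (TSV, optionally symmetric with an upper-triangle
input convention), trees as :class:`dendropy.Tree` (Newick, bootstrap
supports as internal node labels) and distance matrices as square PHYLIP.

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "TabularMatrix",
    "read_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_newick",
    "write_newick",
    "write_phylip_distances",
    "read_table_tsv",
]

#: IUPAC nucleotide one-letter codes (incl. ambiguity codes and gap).
NUCLEOTIDE_ALPHABET = set("ACGTURYSWKMBDHVN-")
#: The twenty amino acids plus X (unknown) and the gap symbol.
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")

MISSING_MARKERS = {"", "-", "–", "—", "NA", "na", "nan"}


@dataclass
class SequenceRecord:
    """A labelled nucleotide or protein sequence, possibly gapped."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        self.residues = self.residues.upper()
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = (
            NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        )
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: symbols {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def degap(self) -> "SequenceRecord":
        return SequenceRecord(
            self.id, self.ungapped, self.description, self.alphabet
        )


def _guess_alphabet(residues: str) -> str:
    letters = set(residues.upper()) - {"-"}
    if letters <= NUCLEOTIDE_ALPHABET and letters <= set("ACGTUN-"):
        return "nucleotide"
    return "protein"


def read_fasta(path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased and input order is preserved. Duplicate ids and
    empty files are hard errors. When *alphabet* is None it is guessed per
    record (sequences of only ACGTUN- are called nucleotide).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        alph = alphabet or _guess_alphabet(residues)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, residues, desc, alph))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records as FASTA, wrapping at *width* columns."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


@dataclass
class TabularMatrix:
    """A labelled numeric matrix with explicit missing cells (NaN)."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label counts")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def get(self, row: str, col: str) -> float:
        return float(
            self.values[self.row_labels.index(row), self.col_labels.index(col)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.col_labels
        )

    def mirrored(self, diagonal_fill: float | None = None) -> "TabularMatrix":
        """Return a symmetric copy: missing (i,j) filled from (j,i).

        Mirroring an already-full symmetric matrix is the identity. When
        *diagonal_fill* is given, missing diagonal cells are set to it
        (similarity matrices use 100).
        """
        if not self.is_square:
            raise ValueError("mirroring requires identical row and column labels")
        vals = self.values.copy()
        n = len(self.row_labels)
        for i in range(n):
            for j in range(n):
                if math.isnan(vals[i, j]) and not math.isnan(vals[j, i]):
                    vals[i, j] = vals[j, i]
        if diagonal_fill is not None:
            for i in range(n):
                if math.isnan(vals[i, i]):
                    vals[i, i] = diagonal_fill
        mism = [
            (self.row_labels[i], self.row_labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not math.isnan(vals[i, j])
            and not math.isnan(vals[j, i])
            and not math.isclose(vals[i, j], vals[j, i])
        ]
        if mism:
            raise ValueError(f"asymmetric cells in symmetric matrix: {mism}")
        return TabularMatrix(list(self.row_labels), list(self.col_labels), vals)


def read_matrix_tsv(path, symmetric: bool = False,
                    diagonal_fill: float | None = None) -> TabularMatrix:
    """Read a labelled TSV matrix.

    Layout: header row of column labels; first column holds row labels;
    cells are numeric or a missing marker ("", "-", en-dash). With
    *symmetric*, an upper-triangle-only input is mirrored into a full
    symmetric matrix, and missing diagonal cells take *diagonal_fill*.
    """
    with open(path, newline="") as handle:
        rows = list(csv.reader(handle, delimiter="\t"))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty matrix file {path}")
    header = [c.strip() for c in rows[0]]
    col_labels = header[1:]
    width = len(col_labels)
    row_labels: list[str] = []
    values = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) - 1 != width:
            raise ValueError(
                f"{path}: row {lineno} has {len(row) - 1} cells, expected {width}"
            )
        row_labels.append(row[0].strip())
        parsed = []
        for cell in row[1:]:
            cell = cell.strip()
            if cell in MISSING_MARKERS:
                parsed.append(math.nan)
            else:
                try:
                    parsed.append(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {lineno}: non-numeric cell {cell!r}"
                    ) from exc
        values.append(parsed)
    matrix = TabularMatrix(row_labels, col_labels, np.array(values, dtype=float))
    if symmetric:
        matrix = matrix.mirrored(diagonal_fill=diagonal_fill)
    return matrix


def write_matrix_tsv(matrix: TabularMatrix, path, fmt: str = "%.6g") -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([""] + matrix.col_labels)
        for label, row in zip(matrix.row_labels, matrix.values):
            writer.writerow(
                [label] + ["" if math.isnan(v) else fmt % v for v in row]
            )


# ---------------------------------------------------------------------------
# Trees


def write_newick(tree: dendropy.Tree, path, with_supports: bool = True) -> None:
    """Write a tree as Newick with ≥6-significant-digit branch lengths.

    Bootstrap supports (``node.label``) are emitted as internal node labels
    when *with_supports* is set. Unnamed leaves are an error.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unnamed leaf")
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=not with_supports,
        real_value_format_specifier=".8g",
    )
    with open(path, "w") as handle:
        handle.write(text)


def read_newick(path_or_string,
                taxon_namespace: dendropy.TaxonNamespace | None = None
                ) -> dendropy.Tree:
    """Read a Newick tree; internal node labels are kept as supports."""
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    text = str(path_or_string)
    if text.lstrip().startswith("("):
        return dendropy.Tree.get(data=text, **kwargs)
    with open(path_or_string) as handle:
        return dendropy.Tree.get(file=handle, **kwargs)


def write_phylip_distances(labels, matrix, path) -> None:
    """Write a square PHYLIP distance matrix (relaxed label width)."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as handle:
        handle.write(f"{len(labels)}\n")
        for label, row in zip(labels, matrix):
            cells = " ".join(f"{v:.8f}" for v in row)
            handle.write(f"{label:<12s} {cells}\n")


def read_table_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a plain TSV table (diallel, progeny, primer lists) as a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)
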