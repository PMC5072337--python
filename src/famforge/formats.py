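"""Sequence, alignment and tree I/O.

All coordinates in this package are 0-based, half-open; conversion to
1-based happens only in human-readable reports.  'X' is a legal residue
everywhere and is scored as background by the profile machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import AlignIO, SeqIO

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet accepted in a ProteinRecord ('X' = unknown residue).
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One database sequence with proteome/taxon provenance."""

    id: str
    residues: str
    description: str = ""
    proteome_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple alignment: ordered mapping id -> aligned row.

    Rows are strings over the residue alphabet plus ``-``; all rows have
    equal length ``n_cols``.
    """

    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            bad = [i for i, r in self.rows.items() if len(r) != len(next(iter(self.rows.values())))]
            raise ValueError(f"ragged alignment rows: {bad}")
        for rid, row in self.rows.items():
            ungapped = row.replace(GAP, "")
            if not ungapped:
                raise ValueError(f"row {rid!r} is all gaps")
            for ch in ungapped:
                if ch not in ALLOWED_RESIDUES:
                    raise ValueError(f"row {rid!r}: illegal character {ch!r}")

    @property
    def n_cols(self) -> int:
        if not self.rows:
            return 0
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows.values())

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Alignment restricted to the given row ids, in the given order."""
        return Alignment({i: self.rows[i] for i in ids})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return list(self.rows.items()) == list(other.rows.items())


def read_fasta(path: str | Path, proteome_id: str | None = None) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The proteome identifier defaults to the file stem.  Sequences are
    uppercased and a trailing ``*`` (stop) is stripped.  Duplicate ids and
    illegal characters raise ``ValueError``.
    """
    path = Path(path)
    pid = proteome_id if proteome_id is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        desc = rec.description[len(rec.id):].strip()
        records.append(
            ProteinRecord(id=rec.id, residues=seq, description=desc, proteome_id=pid)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n" + rec.residues + "\n")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an alignment from aligned FASTA or Stockholm.

    The format is inferred from the suffix (``.sto``/``.stk`` -> Stockholm,
    anything else -> aligned FASTA) unless given explicitly.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix in {".sto", ".stk", ".stockholm"} else "fasta"
    if fmt == "fasta":
        # Use a raw parse so ragged rows give a helpful error rather than
        # Biopython's generic one.
        rows: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in rows:
                raise ValueError(f"duplicate row id {rec.id!r} in {path}")
            rows[rec.id] = str(rec.seq).upper()
        if not rows:
            raise ValueError(f"no alignment rows in {path}")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) > 1:
            ref = len(next(iter(rows.values())))
            bad = [i for i, r in rows.items() if len(r) != ref]
            raise ValueError(f"ragged rows in {path}: {bad}")
        return Alignment(rows)
    msa = AlignIO.read(str(path), fmt)
    return Alignment({rec.id: str(rec.seq).upper() for rec in msa})


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (one line per sequence).

    ``read_alignment(write_alignment(aln)) == aln``.
    """
    with open(path, "w") as fh:
        for rid, row in aln.rows.items():
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# Newick


def _needs_quoting(label: str) -> bool:
    # underscores must be quoted: standard Newick reads them as spaces
    return any(ch in label for ch in " \t()[]':;,_")


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree) -> str:
    """Serialize a dendropy tree deterministically, with branch lengths."""

    def fmt(node) -> str:
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("unlabeled leaf in tree")
            s = _format_label(node.taxon.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.child_nodes()) + ")"
            if node.taxon is not None and node.taxon.label:
                s += _format_label(node.taxon.label)
        bl = node.edge.length
        if bl is not None:
            s += f":{float(bl)}"
        return s

    root = tree.seed_node
    body = "(" + ",".join(fmt(c) for c in root.child_nodes()) + ")"
    bl = root.edge.length
    if bl:
        body += f":{float(bl)}"
    return body + ";"


def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree as Newick with branch lengths.

    Leaf labels containing whitespace or Newick metacharacters are quoted.
    An unlabeled leaf raises ``ValueError``.
    """
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
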