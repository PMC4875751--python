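"""Sequence / species-table data model and standard-format I/O.

Coordinate convention used throughout the package: alignment columns are
1-based and ranges are inclusive ("mass alignment positions"), so the first
column of a master alignment is position 1.  'X' is accepted on input as
missing data and excluded from all downstream counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, LookupMissingError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}
GAP = "-"

#: Fixed order -> regulatory-role mapping (tested species per order).
ORDER_ROLE = {
    "Enterobacteriales": "global",
    "Vibrionales": "global",
    "Pasteurellales": "local",
    "Alteromonadales": "unknown",
}

GENES = ("lrp", "asnC", "recA", "rpoB", "rRNA16S")


@dataclass(frozen=True)
class ProteinSequence:
    """One protein sequence with an accession-like id.

    ``residues`` is a plain string over the 20 standard amino-acid letters
    plus 'X' (missing data); gaps never appear here — gapped rows live in
    :class:`MasterAlignment`.
    """

    id: str
    residues: str
    species_abbr: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residues")
        for i, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValidationError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesRecord:
    species_name: str
    abbr: str
    order: str
    role_label: str
    accessions: Mapping[str, str]

    @staticmethod
    def from_fields(species_name: str, abbr: str, order: str,
                    accessions: Mapping[str, str]) -> "SpeciesRecord":
        if order not in ORDER_ROLE:
            raise ValidationError(f"unknown bacterial order: {order!r}")
        return SpeciesRecord(species_name=species_name, abbr=abbr, order=order,
                             role_label=ORDER_ROLE[order], accessions=dict(accessions))


@dataclass
class OrthologSet:
    """A labeled family of orthologous proteins for one gene."""

    gene_name: str
    members: list[tuple[ProteinSequence, SpeciesRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_sp: set[str] = set()
        for seq, rec in self.members:
            if seq.id in seen_ids:
                raise ValidationError(f"duplicate sequence id {seq.id!r} in {self.gene_name}")
            if rec.abbr in seen_sp:
                raise ValidationError(f"two {self.gene_name} sequences for species {rec.abbr!r}")
            seen_ids.add(seq.id)
            seen_sp.add(rec.abbr)

    def __len__(self) -> int:
        return len(self.members)

    def role_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, rec in self.members:
            out[rec.role_label] = out.get(rec.role_label, 0) + 1
        return out


@dataclass
class MasterAlignment:
    """Gap-containing multiple alignment; columns are 1-based and inclusive."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate row ids in alignment")
        if self.rows:
            L = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != L:
                    raise ValidationError(f"row {rid!r} length {len(row)} != {L}")
                for i, ch in enumerate(row):
                    if ch != GAP and ch not in ALPHABET:
                        raise ValidationError(
                            f"row {rid!r}: illegal character {ch!r} at column {i + 1}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise LookupMissingError(f"row {rid!r} not in alignment") from None

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def subset(self, ids: Sequence[str]) -> "MasterAlignment":
        return MasterAlignment(ids=list(ids), rows=[self.row(r) for r in ids])

    def column(self, position: int) -> str:
        """Residues of a 1-based column, one character per row."""
        if not 1 <= position <= self.length:
            raise ValidationError(f"column {position} outside 1..{self.length}")
        return "".join(row[position - 1] for row in self.rows)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, *, gapped: bool = False) -> list[ProteinSequence] | MasterAlignment:
    """Read a (possibly gapped) protein FASTA file.

    With ``gapped=False`` returns a list of :class:`ProteinSequence`
    (gaps and '*' stop symbols stripped, letters uppercased).  With
    ``gapped=True`` returns a :class:`MasterAlignment` preserving gaps.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids, rows = [], []
    for rec in records:
        seq = str(rec.seq).upper().replace("*", "")
        ids.append(rec.id)
        rows.append(seq)
    if gapped:
        return MasterAlignment(ids=ids, rows=rows)
    return [ProteinSequence(id=i, residues=s.replace(GAP, "")) for i, s in zip(ids, rows)]


def write_fasta(seqs: Iterable[ProteinSequence] | MasterAlignment, path: str | Path) -> None:
    path = Path(path)
    if isinstance(seqs, MasterAlignment):
        records = [SeqRecord(Seq(r), id=i, description="") for i, r in zip(seqs.ids, seqs.rows)]
    else:
        records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Species table (Table-1-style fixture)

def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the tab-separated species table.

    Expected header: species, abbr, order, lrp, asnC, recA, rpoB, rRNA16S.
    The regulatory-role label is filled deterministically from the order.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty species table")
    header = lines[0].split("\t")
    expected = ["species", "abbr", "order", *GENES]
    if header != expected:
        raise FormatError(f"{path}: header {header} != {expected}")
    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(expected):
            raise FormatError(f"{path}: row has {len(fields)} fields, expected {len(expected)}")
        species, abbr, order, *accs = fields
        if abbr in seen:
            raise ValidationError(f"duplicate species abbreviation {abbr!r}")
        seen.add(abbr)
        records.append(SpeciesRecord.from_fields(
            species, abbr, order, dict(zip(GENES, accs))))
    return records


def load_table1() -> list[SpeciesRecord]:
    """The shipped 40-species study table (10 species per order)."""
    ref = importlib.resources.files("ortho_signature.data") / "table1_species.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_species_table(p)


# ---------------------------------------------------------------------------
# Newick

_NEWICK_META = set("():;, '\t\n[]")


def write_newick(tree: dendropy.Tree, path: str | Path, *, strict: bool = False) -> None:
    """Write a tree as Newick with bootstrap support as internal node labels.

    Leaf names containing Newick metacharacters are quoted automatically;
    with ``strict=True`` they raise instead.
    """
    if strict:
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else ""
            if any(c in _NEWICK_META for c in name):
                raise ValidationError(f"leaf name {name!r} contains Newick metacharacters")
    txt = tree.as_string(schema="newick", suppress_rooting=True,
                         unquoted_underscores=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(txt)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
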