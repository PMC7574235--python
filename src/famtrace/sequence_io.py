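"""FASTA, GFF3 and newick input/output plus core nucleotide/protein helpers.

Coordinate conventions: everything in memory is 0-based half-open on the
forward strand; conversion to the 1-based inclusive GFF3 convention happens
only inside :func:`read_gff3` / :func:`write_gff3`.  Minus-strand features are
stored with forward-strand coordinates plus a strand flag.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Phylo, SeqIO
from Bio.Seq import Seq

from ._scoring import PROTEIN_ALPHABET, standard_codon_tables

DNA_CHARS = set("ACGTN")
PROTEIN_CHARS = set(PROTEIN_ALPHABET)

FEATURE_KINDS = ("gene", "mRNA", "CDS", "exon", "marker", "repeat")


@dataclass
class GenomeRecord:
    """A contig or chromosome: identifier plus DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A protein sequence; '*' is permitted only for conceptual translations
    of pseudogenes and 'X' marks unknown residues."""

    id: str
    seq: str


@dataclass
class Feature:
    """One GFF3 row (gene, mRNA, CDS, exon, marker or repeat).

    ``start``/``end`` are 0-based half-open forward-strand coordinates.
    """

    seqid: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    phase: int | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, kind: str = "auto"):
    """Read a FASTA file into :class:`GenomeRecord` or :class:`ProteinRecord`.

    ``kind`` is one of ``dna``, ``protein`` or ``auto`` (decide per file from
    the residue alphabet).  Sequences are uppercased; duplicate identifiers
    and empty files raise ``ValueError``.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper().replace(" ", "")))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if kind == "auto":
        kind = "dna" if all(set(s) <= DNA_CHARS for _, s in records) else "protein"
    cls = {"dna": GenomeRecord, "protein": ProteinRecord}[kind]
    out = []
    for rid, seq in records:
        if kind == "dna" and not set(seq) <= DNA_CHARS:
            raise ValueError(f"record {rid!r} contains non-DNA characters")
        if kind == "protein" and not set(seq) <= PROTEIN_CHARS:
            raise ValueError(f"record {rid!r} contains non-protein characters")
        out.append(cls(rid, seq))
    return out


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Nucleotide / protein manipulation
# ---------------------------------------------------------------------------

def _check_dna(dna: str) -> str:
    bad = set(dna) - DNA_CHARS
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return dna


def translate(dna: str, offset: int = 0) -> str:
    """Conceptual translation with the standard genetic code.

    Trailing partial codons are dropped, stops render as '*', and any codon
    containing 'N' renders as 'X'.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    _check_dna(dna)
    codon_to_aa, _ = standard_codon_tables()
    sub = dna[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    return "".join(
        codon_to_aa.get(sub[i:i + 3], "X") for i in range(0, len(sub), 3)
    )


def reverse_complement(dna: str) -> str:
    _check_dna(dna)
    return str(Seq(dna).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in (".", ""):
        return attrs
    for chunk in text.rstrip(";").split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(path) -> list[Feature]:
    """Parse a GFF3 file (nine tab-separated columns) into Features.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, kind, start, end, _score, strand, phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            features.append(Feature(
                seqid=seqid, kind=kind, start=start_i - 1, end=end_i,
                strand=strand if strand in "+-" else "+",
                phase=None if phase == "." else int(phase),
                attributes=_parse_attributes(attrs),
            ))
    return features


def write_gff3(features, path, source: str = "famtrace") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in features:
            phase = "." if feat.phase is None else str(feat.phase)
            handle.write("\t".join([
                feat.seqid, source, feat.kind,
                str(feat.start + 1), str(feat.end), ".",
                feat.strand, phase, _format_attributes(feat.attributes),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Newick trees (Bio.Phylo containers)
# ---------------------------------------------------------------------------

def read_newick(text: str):
    """Parse a newick string into a rooted ``Bio.Phylo`` tree.

    Duplicate leaf labels raise ``ValueError``; malformed strings raise the
    parser's error.  Use :func:`find_polytomies` to flag non-binary nodes.
    """
    tree = Phylo.read(io.StringIO(text), "newick")
    leaves = [leaf.name for leaf in tree.get_terminals()]
    if len(leaves) != len(set(leaves)):
        dupes = sorted({name for name in leaves if leaves.count(name) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree) -> str:
    handle = io.StringIO()
    Phylo.write(tree, handle, "newick", format_branch_length="%r")
    return handle.getvalue().strip()


def read_newick_file(path: str | Path):
    return read_newick(Path(path).read_text())


def find_polytomies(tree) -> list:
    """Return the internal nodes with more than two children."""
    return [clade for clade in tree.find_clades() if len(clade.clades) > 2]
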