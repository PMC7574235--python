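"""Shared scoring machinery: protein alphabet, BLOSUM matrices, codon tables
and thin wrappers around the pairwise alignment engine.

Conventions used throughout the package:

* Protein alphabet is the 24-letter BLOSUM order ``ARNDCQEGHILKMFPSTWYVBZX*``.
* An affine gap of length ``L`` costs ``gap_open + L * gap_extend`` (both
  negative), i.e. the first gapped column already pays the extension.
* In-frame stop codons ('*') act as alignment barriers: no local alignment
  column may pair a translated stop with a query residue.  Spliced gene-model
  alignment relaxes this with an explicit stop penalty instead.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
STOP_INDEX = AA_INDEX["*"]
X_INDEX = AA_INDEX["X"]

# Score used to forbid pairing a residue with a translated stop codon.
STOP_BARRIER = -10_000

DNA_ALPHABET = "ACGTN"
DNA_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # the 20 canonical residues


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a 24x24 int32 substitution matrix in ``PROTEIN_ALPHABET`` order.

    Stop-vs-anything entries are set to :data:`STOP_BARRIER` so that local
    alignments never cross an in-frame stop codon.
    """
    mat = substitution_matrices.load(name)
    out = np.zeros((24, 24), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = int(mat[a][b])
    out[STOP_INDEX, :] = STOP_BARRIER
    out[:, STOP_INDEX] = STOP_BARRIER
    return out


@lru_cache(maxsize=1)
def standard_codon_tables():
    """Forward table (codon -> aa) and synonymous-codon map (aa -> codons)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = "*"
    aa_to_codons: dict[str, tuple[str, ...]] = {}
    for codon, aa in sorted(codon_to_aa.items()):
        aa_to_codons.setdefault(aa, [])
        aa_to_codons[aa].append(codon)
    return codon_to_aa, {aa: tuple(cs) for aa, cs in aa_to_codons.items()}


@lru_cache(maxsize=1)
def codon_aa_table() -> np.ndarray:
    """125-entry lookup: encoded codon (base5 over ACGTN) -> protein index.

    Codons containing N translate to 'X'.
    """
    codon_to_aa, _ = standard_codon_tables()
    out = np.full(125, X_INDEX, dtype=np.int8)
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                idx = DNA_INDEX[b1] * 25 + DNA_INDEX[b2] * 5 + DNA_INDEX[b3]
                out[idx] = AA_INDEX[codon_to_aa[codon]]
    return out


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[aa] for aa in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown amino-acid symbol {exc} in sequence") from exc


def encode_dna(seq: str) -> np.ndarray:
    try:
        return np.array([DNA_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid DNA symbol {exc}") from exc


def score_columns(aligned_a: str, aligned_b: str, matrix: np.ndarray,
                  gap_open: int, gap_extend: int) -> int:
    """Re-score a gapped alignment column by column.

    Used to verify the 'score recomputability' contract of emitted alignments.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    score = 0
    in_gap = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            raise ValueError("double-gap column")
        if ca == "-" or cb == "-":
            if not in_gap:
                score += gap_open
            score += gap_extend
            in_gap = True
        else:
            score += int(matrix[AA_INDEX[ca], AA_INDEX[cb]])
            in_gap = False
    return score


# ---------------------------------------------------------------------------
# Pairwise alignment engine (biotite-backed)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _biotite_objects(name: str):
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alphabet = bseq.Alphabet(list(PROTEIN_ALPHABET))
    matrix = balign.SubstitutionMatrix(alphabet, alphabet, load_matrix(name))
    return alphabet, matrix


def _to_biotite_seq(seq: str):
    import biotite.sequence as bseq

    alphabet, _ = _biotite_objects("BLOSUM62")
    return bseq.GeneralSequence(alphabet, list(seq))


def _gapped_strings(alignment, a: str, b: str) -> tuple[str, str]:
    rows = ["", ""]
    for i0, i1 in alignment.trace:
        rows[0] += a[i0] if i0 >= 0 else "-"
        rows[1] += b[i1] if i1 >= 0 else "-"
    return rows[0], rows[1]


def local_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                gap_open: int = -11, gap_extend: int = -1):
    """Best local (Smith-Waterman) affine-gap alignment of two proteins.

    Returns ``(a_start, a_end, b_start, b_end, score, aligned_a, aligned_b)``
    with half-open intervals, or ``None`` if no column scores positive.
    Ties resolve deterministically (diagonal before gap-in-b before
    gap-in-a; first maximum in row-major order).
    """
    from ._local_sw import sw_align

    if not a or not b:
        return None
    matrix = load_matrix(matrix_name)
    sub = matrix[np.ix_([AA_INDEX[c] for c in a],
                        [AA_INDEX[c] for c in b])].astype(np.int32)
    score, i1, j1, ptr_m, ptr_x, ptr_y = sw_align(sub, gap_open, gap_extend)
    if score <= 0:
        return None
    # traceback
    ga, gb = [], []
    i, j = int(i1), int(j1)
    state = 0  # 0 = M, 1 = Ix (gap in a), 2 = Iy (gap in b)
    while True:
        if state == 0:
            came = ptr_m[i, j]
            if came == 0:
                break
            if came == 1:
                ga.append(a[i - 1])
                gb.append(b[j - 1])
                i, j = i - 1, j - 1
            elif came == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ga.append("-")
            gb.append(b[j - 1])
            came = ptr_x[i, j]
            j -= 1
            if came == 1:
                state = 0
        else:
            ga.append(a[i - 1])
            gb.append("-")
            came = ptr_y[i, j]
            i -= 1
            if came == 1:
                state = 0
    ga.reverse()
    gb.reverse()
    return (i, int(i1), j, int(j1), int(score), "".join(ga), "".join(gb))


def global_align_pair(a: str, b: str, matrix_name: str = "BLOSUM62",
                      gap_open: int = -11, gap_extend: int = -1):
    """Optimal global (Needleman-Wunsch/Gotoh) alignment; returns
    ``(aligned_a, aligned_b, score)``."""
    import biotite.sequence.align as balign

    _, matrix = _biotite_objects(matrix_name)
    alns = balign.align_optimal(
        _to_biotite_seq(a), _to_biotite_seq(b), matrix,
        gap_penalty=(gap_open + gap_extend, gap_extend),
        local=False, max_number=1,
    )
    aln = alns[0]
    ga, gb = _gapped_strings(aln, a, b)
    return ga, gb, int(aln.score)
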