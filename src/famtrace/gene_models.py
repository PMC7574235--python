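"""From translated hits to refined gene models.

``cluster_hits`` groups colinear hits into candidate loci; ``splice_align``
refines one locus window into an exon/intron model by splice-aware dynamic
programming (canonical GT-AG introns, phase 0/1/2, frameshift jumps,
penalised in-frame stops); ``classify_status`` separates functional genes
from pseudogenes; ``scan_motifs`` locates family signature motifs in the
predicted proteins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


from . import _splice_dp as dp
from ._scoring import (AA_INDEX, PROTEIN_ALPHABET, codon_aa_table, encode_dna,
                       encode_protein, load_matrix)
from .sequence_io import GenomeRecord, ProteinRecord, reverse_complement
from .translated_search import TranslatedHit


@dataclass
class GeneModelParams:
    """Splice-alignment and locus parameters (all config-exposed)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    intron_penalty: int = -12
    min_intron: int = 40
    frameshift_penalty: int = -30
    stop_penalty: int = -30
    min_model_score: int = 50
    max_intron: int = 20_000
    min_locus_score: int = 50
    splice_window_pad: int = 1_500   # genomic padding around hits for the DP
    max_end_extension: int = 6       # residues of forced query-end extension
    min_functional_coverage: float = 0.9
    max_dp_cells: int = 80_000_000

    def __post_init__(self):
        if self.min_intron <= 4:
            raise ValueError("min_intron too small for GT..AG geometry")
        if self.max_intron <= self.min_intron:
            raise ValueError("max_intron must exceed min_intron")


@dataclass
class CandidateLocus:
    contig: str
    strand: str
    window: tuple[int, int]        # padded forward-strand interval
    hit_span: tuple[int, int]      # unpadded extent of member hits
    member_hits: list[TranslatedHit]
    best_query_id: str
    aggregate_score: int


@dataclass
class GeneModel:
    """An annotated coding gene (functional or pseudogene)."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]   # transcription order, forward coords
    cds: str                       # spliced exon sequence, coding strand
    protein: str                   # conceptual translation from the parse
    status: str = "functional"
    defects: list[str] = field(default_factory=list)
    score: int = 0
    query_id: str = ""
    q_start: int = 0
    q_end: int = 0
    query_length: int = 0
    locus_label: str | None = None
    aligned_query: str = ""
    aligned_target: str = ""
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def coverage(self) -> float:
        return (self.q_end - self.q_start) / self.query_length if self.query_length else 0.0


# ---------------------------------------------------------------------------
# Hit clustering
# ---------------------------------------------------------------------------

def cluster_hits(hits: list[TranslatedHit], max_intron: int = 20_000,
                 min_locus_score: int = 50,
                 contig_lengths: dict[str, int] | None = None
                 ) -> list[CandidateLocus]:
    """Chain colinear same-contig, same-strand hits into candidate loci.

    Hits are sorted by genomic start; consecutive hits join one chain when
    their genomic gap is at most ``max_intron`` and their query intervals
    advance with genomic order (descending for minus-strand loci).  Tandem
    copies, whose query order resets, therefore split into separate loci.
    Windows are padded by ``max_intron`` on both sides, clipped to the
    contig.
    """
    groups: dict[tuple[str, str], list[TranslatedHit]] = {}
    for hit in hits:
        groups.setdefault((hit.contig, hit.strand), []).append(hit)

    loci: list[CandidateLocus] = []
    for (contig, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: h.g_start)

        def chainable(prev: TranslatedHit, hit: TranslatedHit) -> bool:
            gap = hit.g_start - prev.g_end
            if gap > max_intron:
                return False
            if strand == "+":
                colinear = (hit.q_start >= prev.q_start
                            and hit.q_end > prev.q_end)
            else:
                colinear = (hit.q_start < prev.q_start
                            and hit.q_end <= prev.q_end)
            # chained hits must cover mostly different query segments: a
            # second full-length copy (same query span) starts a new chain
            # even though it is technically "colinear"
            q_ov = min(hit.q_end, prev.q_end) - max(hit.q_start, prev.q_start)
            shortest = min(hit.q_end - hit.q_start, prev.q_end - prev.q_start)
            return colinear and q_ov < 0.5 * shortest

        chains: list[list[TranslatedHit]] = []
        for hit in members:
            # join the open chain with the nearest compatible end, so an
            # interleaved spurious hit cannot break a gene's exon chain
            best_chain = None
            for chain in chains:
                if chainable(chain[-1], hit):
                    if (best_chain is None
                            or chain[-1].g_end > best_chain[-1].g_end):
                        best_chain = chain
            if best_chain is not None:
                best_chain.append(hit)
            else:
                chains.append([hit])
        for comp_hits in chains:
            total = sum(h.score for h in comp_hits)
            if total < min_locus_score:
                continue
            lo = min(h.g_start for h in comp_hits)
            hi = max(h.g_end for h in comp_hits)
            clen = (contig_lengths or {}).get(contig)
            win_lo = max(0, lo - max_intron)
            win_hi = hi + max_intron if clen is None else min(clen, hi + max_intron)
            best = max(comp_hits, key=lambda h: h.score)
            loci.append(CandidateLocus(
                contig=contig, strand=strand, window=(win_lo, win_hi),
                hit_span=(lo, hi), member_hits=comp_hits,
                best_query_id=best.query_id, aggregate_score=total))
    loci.sort(key=lambda l: (-l.aggregate_score, l.contig, l.window[0]))
    return loci


# ---------------------------------------------------------------------------
# Splice-aware alignment
# ---------------------------------------------------------------------------

def _traceback(dna_str: str, query: str, best_i, best_j, ptrC, auxC,
               ptrGX, ptrGY, codon_aa):
    """Recover parse operations from the DP pointers.

    Returns columns (reversed in-place to forward order), introns, frameshift
    positions and the consumed-genome interval.
    """
    cols = []       # (kind, g_lo, g_hi, q_index) kind: M, GX, GY
    introns = []    # (start, end) window coords
    frameshifts = []
    i, j = int(best_i), int(best_j)
    state = "C"
    while True:
        if state == "C":
            kind = ptrC[i, j]
            if kind == dp.P_START:
                break
            if kind == dp.P_DIAG:
                cols.append(("M", i - 3, i, j - 1))
                i, j = i - 3, j - 1
            elif kind == dp.P_FROM_GX:
                state = "GX"
            elif kind == dp.P_FROM_GY:
                state = "GY"
            elif kind == dp.P_FS1:
                frameshifts.append(i - 1)
                cols.append(("FS", i - 1, i, -1))
                i -= 1
            elif kind == dp.P_FS2:
                frameshifts.append(i - 2)
                cols.append(("FS", i - 2, i, -1))
                i -= 2
            elif kind == dp.P_CLOSE0:
                t = int(auxC[i, j])
                introns.append((t, i))
                i = t
            elif kind == dp.P_CLOSE1:
                t = int(auxC[i, j])
                introns.append((t, i - 2))
                cols.append(("M1", t - 1, i, j - 1))  # split codon
                i, j = t - 1, j - 1
            elif kind == dp.P_CLOSE2:
                t = int(auxC[i, j])
                introns.append((t, i - 1))
                cols.append(("M2", t - 2, i, j - 1))
                i, j = t - 2, j - 1
        elif state == "GX":
            cols.append(("GX", i, i, j - 1))
            came = ptrGX[i, j]
            j -= 1
            if came == 1:
                state = "C"
        else:  # GY
            cols.append(("GY", i - 3, i, -1))
            came = ptrGY[i, j]
            i -= 3
            if came == 1:
                state = "C"
    cols.reverse()
    introns.reverse()
    frameshifts.reverse()
    return cols, introns, frameshifts, (i, j)


def _column_strings(cols, introns, dna_str, query, codon_aa_map):
    aligned_q, aligned_t = [], []
    intron_set = set(introns)
    for kind, g_lo, g_hi, q_idx in cols:
        if kind == "M":
            codon = dna_str[g_lo:g_hi]
            aligned_q.append(query[q_idx])
            aligned_t.append(codon_aa_map(codon))
        elif kind in ("M1", "M2"):
            # codon split by an intron: pending bases before, rest after
            span = dna_str[g_lo:g_hi]
            # remove the intron bases from the span
            intron = next((s, e) for s, e in intron_set if g_lo <= s and e <= g_hi)
            codon = dna_str[g_lo:intron[0]] + dna_str[intron[1]:g_hi]
            aligned_q.append(query[q_idx])
            aligned_t.append(codon_aa_map(codon))
        elif kind == "GX":
            aligned_q.append(query[q_idx])
            aligned_t.append("-")
        elif kind == "GY":
            aligned_q.append("-")
            aligned_t.append(codon_aa_map(dna_str[g_lo:g_hi]))
        # FS columns contribute no alignment column
    return "".join(aligned_q), "".join(aligned_t)


def _codon_aa(codon: str) -> str:
    table = codon_aa_table()
    if len(codon) != 3 or any(b not in "ACGTN" for b in codon):
        return "X"
    idx = ("ACGTN".index(codon[0]) * 25 + "ACGTN".index(codon[1]) * 5
           + "ACGTN".index(codon[2]))
    return PROTEIN_ALPHABET[table[idx]]


def splice_align(query: ProteinRecord, locus: CandidateLocus,
                 genome: GenomeRecord, params: GeneModelParams | None = None,
                 gene_id: str | None = None) -> GeneModel | None:
    """Refine one candidate locus into a gene model by splice-aware DP.

    Returns ``None`` when no parse reaches ``params.min_model_score``.
    Ties between equal-scoring parses resolve deterministically (the DP
    prefers matches, then gap states, then introns, at equal score).
    """
    params = params or GeneModelParams()
    pad = params.splice_window_pad
    win_lo = max(locus.window[0], locus.hit_span[0] - pad)
    win_hi = min(locus.window[1], locus.hit_span[1] + pad)
    window = genome.seq[win_lo:win_hi]
    if locus.strand == "-":
        window = reverse_complement(window)
    n, m = len(window), len(query.seq)
    if (n + 1) * (m + 1) > params.max_dp_cells:
        raise ValueError(
            f"splice DP of {n} x {m} exceeds max_dp_cells; narrow the window")

    best, best_i, best_j, ptrC, auxC, ptrGX, ptrGY = dp.fill(
        encode_dna(window), encode_protein(query.seq),
        load_matrix(params.matrix_name), codon_aa_table(),
        params.gap_open, params.gap_extend, params.frameshift_penalty,
        params.stop_penalty, params.intron_penalty, params.min_intron)
    if best < params.min_model_score:
        return None

    cols, introns, frameshifts, (start_i, start_j) = _traceback(
        window, query.seq, best_i, best_j, ptrC, auxC, ptrGX, ptrGY,
        codon_aa_table())

    q_start, q_end = start_j, best_j
    g_start, g_end = start_i, best_i
    score = int(best)

    # forced extension to the query termini: a handful of terminal residues
    # whose codons diverged should not shorten the model
    if params.max_end_extension > 0:
        cols, q_start, q_end, g_start, g_end, delta = _extend_ends(
            window, query.seq, cols, q_start, q_end, g_start, g_end, params)
        score += delta

    aligned_q, aligned_t = _column_strings(cols, introns, window, query.seq,
                                           _codon_aa)

    # exons: maximal consumed-genome runs between introns (window coords)
    consumed = sorted({(lo, hi) for kind, lo, hi, _ in cols if kind != "GX"})
    intron_iv = sorted(introns)
    exons_w = []
    for lo, hi in consumed:
        pieces = _subtract_introns(lo, hi, intron_iv)
        for p_lo, p_hi in pieces:
            if exons_w and p_lo <= exons_w[-1][1]:
                exons_w[-1] = (exons_w[-1][0], max(exons_w[-1][1], p_hi))
            else:
                exons_w.append((p_lo, p_hi))
    # merge runs separated only by introns into distinct exons already done;
    # adjacent runs with no gap merge above

    if locus.strand == "+":
        exons = [(int(win_lo + a), int(win_lo + b)) for a, b in exons_w]
        introns_c = [(win_lo + a, win_lo + b) for a, b in intron_iv]
    else:
        exons = [(int(win_lo + n - b), int(win_lo + n - a)) for a, b in exons_w]
        exons = sorted(exons, reverse=True)
        introns_c = sorted(
            [(win_lo + n - b, win_lo + n - a) for a, b in intron_iv],
            reverse=True)

    cds = "".join(
        genome.seq[s:e] if locus.strand == "+" else reverse_complement(genome.seq[s:e])
        for s, e in exons)
    protein = aligned_t.replace("-", "")

    model = GeneModel(
        gene_id=gene_id or f"{locus.contig}:{win_lo + g_start}",
        contig=locus.contig, strand=locus.strand, exons=exons, cds=cds,
        protein=protein, score=score, query_id=query.id,
        q_start=q_start, q_end=q_end, query_length=m,
        aligned_query=aligned_q, aligned_target=aligned_t,
        introns=introns_c)
    if frameshifts:
        model.defects.append("frameshift")
    model.status, model.defects = classify_status(model, params)
    return model


def _subtract_introns(lo, hi, introns):
    pieces = [(lo, hi)]
    for s, e in introns:
        nxt = []
        for a, b in pieces:
            if e <= a or s >= b:
                nxt.append((a, b))
            else:
                if a < s:
                    nxt.append((a, s))
                if e < b:
                    nxt.append((e, b))
        pieces = nxt
    return pieces


def _extend_ends(window, query, cols, q_start, q_end, g_start, g_end, params):
    """Append/prepend up to ``max_end_extension`` unaligned terminal query
    residues as plain codons when the window has room and no stop intrudes."""
    matrix = load_matrix(params.matrix_name)
    score_delta = 0

    missing_tail = len(query) - q_end
    if 0 < missing_tail <= params.max_end_extension:
        if g_end + 3 * missing_tail <= len(window):
            new_cols = []
            ok = True
            for t in range(missing_tail):
                lo = g_end + 3 * t
                aa = _codon_aa(window[lo:lo + 3])
                if aa == "*":
                    ok = False
                    break
                new_cols.append(("M", lo, lo + 3, q_end + t))
                score_delta += int(matrix[AA_INDEX[aa], AA_INDEX[query[q_end + t]]])
            if ok:
                cols = cols + new_cols
                g_end += 3 * missing_tail
                q_end = len(query)

    if 0 < q_start <= params.max_end_extension:
        if g_start - 3 * q_start >= 0:
            new_cols = []
            ok = True
            for t in range(q_start):
                lo = g_start - 3 * (q_start - t)
                aa = _codon_aa(window[lo:lo + 3])
                if aa == "*":
                    ok = False
                    break
                new_cols.append(("M", lo, lo + 3, t))
                score_delta += int(matrix[AA_INDEX[aa], AA_INDEX[query[t]]])
            if ok:
                cols = new_cols + cols
                g_start -= 3 * q_start
                q_start = 0

    return cols, q_start, q_end, g_start, g_end, score_delta


# ---------------------------------------------------------------------------
# Status classification
# ---------------------------------------------------------------------------

def classify_status(model: GeneModel, params: GeneModelParams | None = None
                    ) -> tuple[str, list[str]]:
    """Functional iff the parse is clean: no internal stop, no frameshift,
    starts with M and covers (nearly) the whole query."""
    params = params or GeneModelParams()
    defects = [d for d in model.defects if d == "frameshift"]
    internal = model.protein[:-1] if model.protein else ""
    if "*" in internal:
        defects.append("premature_stop")
    if not model.protein.startswith("M") or model.coverage < params.min_functional_coverage:
        defects.append("truncated")
    defects = sorted(set(defects))
    return ("pseudogene", defects) if defects else ("functional", [])


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    name: str
    start: int   # 0-based
    end: int     # half-open
    match: str


#: Schematic family signatures (overridable): the MACPF-like GG-X(n)-W motif
#: and a C2-like acidic patch.  Patterns are plain regular expressions.
DEFAULT_MOTIFS = {
    "ggxnw": r"GG.{3,60}W",
    "c2_acidic": r"D.{5}D.{5}D",
}


def scan_motifs(protein: str, patterns: dict[str, str] | None = None
                ) -> list[MotifHit]:
    """All non-overlapping matches of each motif pattern, leftmost-first."""
    patterns = patterns or DEFAULT_MOTIFS
    out = []
    for name, pattern in patterns.items():
        try:
            rx = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"malformed motif pattern {pattern!r}: {exc}") from exc
        for match in rx.finditer(protein):
            out.append(MotifHit(name, match.start(), match.end(), match.group()))
    out.sort(key=lambda h: (h.start, h.name))
    return out
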