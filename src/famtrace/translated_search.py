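"""Translated homology search: protein queries against six genome frames.

Seed-and-extend architecture: exact and neighborhood k-mer word hits between
the query and each frame translation, ungapped X-drop extension along the
diagonal, then a gapped local alignment restricted to a window around each
surviving seed region.  In-frame stop codons act as barriers, so hits never
cross a stop — a premature stop splits what would be one hit in two, which
is exactly the signal the pseudogene classifier consumes downstream.

Raw alignment scores only; no E-value statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._scoring import AA_INDEX, PROTEIN_ALPHABET, load_matrix, local_align
from .sequence_io import GenomeRecord, ProteinRecord, reverse_complement, translate


@dataclass
class SearchParams:
    """Knobs of the translated search; defaults mirror common tblastn usage."""

    matrix_name: str = "BLOSUM62"
    word_size: int = 4
    seed_threshold: int = 21   # neighborhood words must score at least this
    x_drop: int = 20           # ungapped extension drop-off, matrix units
    gap_open: int = -11
    gap_extend: int = -1
    min_score: int = 50        # minimum reported hit score
    ungapped_trigger: int = 25  # ungapped segment score required to go gapped
    window_pad: int = 40       # extra frame residues around a gapped window
    max_hsps_per_region: int = 4

    def __post_init__(self):
        if self.word_size < 2:
            raise ValueError("word size must be >= 2")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.x_drop <= 0:
            raise ValueError("X-drop must be positive")


@dataclass
class TranslatedHit:
    """One gapped local protein-vs-translated-genome alignment segment."""

    query_id: str
    contig: str
    strand: str
    frame: int
    g_start: int   # 0-based half-open, forward-strand nucleotides
    g_end: int
    q_start: int   # 0-based half-open, query residues
    q_end: int
    score: int
    aligned_query: str = ""
    aligned_target: str = ""

    @property
    def frame_label(self) -> str:
        return f"{self.strand}{self.frame}"


@dataclass
class FrameTranslation:
    strand: str
    frame: int
    protein: str
    genome_length: int

    def codon_interval(self, prot_index: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval of one translated residue."""
        if self.strand == "+":
            start = self.frame + 3 * prot_index
            return start, start + 3
        end = self.genome_length - self.frame - 3 * prot_index
        return end - 3, end

    def prot_index(self, forward_pos: int) -> int:
        if self.strand == "+":
            return (forward_pos - self.frame) // 3
        return (self.genome_length - self.frame - forward_pos - 3) // 3


def six_frame(genome: GenomeRecord) -> list[FrameTranslation]:
    """All six conceptual translations with coordinate maps."""
    if genome.length < 3:
        raise ValueError("genome shorter than one codon")
    frames = []
    rc = reverse_complement(genome.seq)
    for frame in range(3):
        frames.append(FrameTranslation("+", frame, translate(genome.seq, frame),
                                       genome.length))
        frames.append(FrameTranslation("-", frame, translate(rc, frame),
                                       genome.length))
    return frames


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _neighborhood(word: str, matrix: np.ndarray, threshold: int) -> list[str]:
    """All words scoring >= threshold against ``word`` (branch and bound)."""
    k = len(word)
    letters = PROTEIN_ALPHABET[:20]
    scores = np.array([[matrix[AA_INDEX[w], AA_INDEX[c]] for c in letters]
                       for w in word])
    best_rest = [int(scores[i:].max(axis=1).sum()) for i in range(k)] + [0]
    out: list[str] = []

    def grow(prefix: str, acc: int):
        i = len(prefix)
        if i == k:
            out.append(prefix)
            return
        for j, c in enumerate(letters):
            s = acc + int(scores[i, j])
            if s + best_rest[i + 1] >= threshold:
                grow(prefix + c, s)

    grow("", 0)
    return out


def _seed_words(query: str, matrix: np.ndarray, k: int, threshold: int
                ) -> dict[str, list[int]]:
    """Map each seeding word to the query positions it represents."""
    words: dict[str, list[int]] = {}
    cache: dict[str, list[str]] = {}
    for qpos in range(len(query) - k + 1):
        word = query[qpos:qpos + k]
        if "*" in word:
            continue
        if word not in cache:
            cache[word] = _neighborhood(word, matrix, threshold)
            if word not in cache[word]:
                cache[word].append(word)
        for neighbor in cache[word]:
            words.setdefault(neighbor, []).append(qpos)
    return words


def _ungapped_extend(q_codes, f_codes, matrix, qpos, fpos, k, x_drop):
    """Extend a word hit along its diagonal with X-drop; returns
    (q_start, f_start, length, score)."""
    score = int(matrix[q_codes[qpos:qpos + k], f_codes[fpos:fpos + k]].sum())
    best = score
    # right
    qi, fi = qpos + k, fpos + k
    right_end = qpos + k
    cur = score
    while qi < len(q_codes) and fi < len(f_codes):
        cur += int(matrix[q_codes[qi], f_codes[fi]])
        if cur > best:
            best, right_end = cur, qi + 1
        if best - cur > x_drop or cur < -5000:
            break
        qi += 1
        fi += 1
    # left
    cur = best
    left_start = qpos
    qi, fi = qpos - 1, fpos - 1
    while qi >= 0 and fi >= 0:
        cur += int(matrix[q_codes[qi], f_codes[fi]])
        if cur > best:
            best, left_start = cur, qi
        if best - cur > x_drop or cur < -5000:
            break
        qi -= 1
        fi -= 1
    length = right_end - left_start
    return left_start, fpos - (qpos - left_start), length, best


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX[c] for c in seq], dtype=np.int16)


# ---------------------------------------------------------------------------
# Search proper
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Six-frame translations plus per-frame k-mer word indexes.

    Building the index dominates search time on large genomes; reuse one
    index across queries (the iterative annotator does).
    """

    def __init__(self, genome: GenomeRecord, word_size: int = 4):
        self.genome = genome
        self.word_size = word_size
        self.frames = six_frame(genome)
        self.word_index: list[dict[str, list[int]]] = []
        self.frame_codes: list[np.ndarray] = []
        for ft in self.frames:
            index: dict[str, list[int]] = {}
            prot = ft.protein
            for fpos in range(len(prot) - word_size + 1):
                index.setdefault(prot[fpos:fpos + word_size], []).append(fpos)
            self.word_index.append(index)
            self.frame_codes.append(_encode(prot))


def search(query: ProteinRecord, genome: GenomeRecord | GenomeIndex,
           params: SearchParams | None = None) -> list[TranslatedHit]:
    """Find gapped local hits of ``query`` in all six frames of ``genome``.

    ``genome`` may be a prebuilt :class:`GenomeIndex`.  Hits are sorted by
    score (descending); overlapping hits in the same frame are merged to the
    higher-scoring one.
    """
    params = params or SearchParams()
    k = params.word_size
    if len(query.seq) < k:
        raise ValueError(f"query shorter than word size {k}")
    if isinstance(genome, GenomeIndex):
        gindex = genome
        if gindex.word_size != k:
            raise ValueError("index word size does not match params")
    else:
        gindex = GenomeIndex(genome, k)
    genome = gindex.genome
    matrix = load_matrix(params.matrix_name)
    words = _seed_words(query.seq, matrix, k, params.seed_threshold)
    q_codes = _encode(query.seq)

    hits: list[TranslatedHit] = []
    for ft, index, f_codes in zip(gindex.frames, gindex.word_index,
                                  gindex.frame_codes):
        if len(ft.protein) < k:
            continue

        # ungapped extensions, deduplicated per diagonal
        segments: list[tuple[int, int]] = []  # frame-protein intervals
        covered: dict[int, int] = {}  # diagonal -> rightmost frame pos seen
        for word, fpositions in index.items():
            qpositions = words.get(word)
            if not qpositions:
                continue
            for fpos in fpositions:
                for qpos in qpositions:
                    diag = fpos - qpos
                    if covered.get(diag, -1) >= fpos:
                        continue
                    qs, fs, length, score = _ungapped_extend(
                        q_codes, f_codes, matrix, qpos, fpos, k, params.x_drop)
                    covered[diag] = fs + length
                    if score >= params.ungapped_trigger:
                        segments.append((fs, fs + length))
        if not segments:
            continue

        # merge overlapping/padded segments into gapped-alignment windows
        pad = len(query.seq) + params.window_pad
        segments.sort()
        windows: list[list[int]] = []
        for s, e in segments:
            lo, hi = max(0, s - pad), min(len(ft.protein), e + pad)
            if windows and lo <= windows[-1][1]:
                windows[-1][1] = max(windows[-1][1], hi)
            else:
                windows.append([lo, hi])

        for lo, hi in windows:
            segs = [(s, e) for s, e in segments if s < hi and e > lo]
            hits.extend(_gapped_hits(query, ft, lo, hi, segs, params, genome))

    hits.sort(key=lambda h: (-h.score, h.contig, h.g_start))
    return _merge_overlapping(hits)


def _gapped_hits(query, ft, lo, hi, segments, params, genome):
    """Best local alignments inside one frame window.

    The window is split at in-frame stop codons first — a stop can be
    crossed neither by a residue pairing nor by a gap — then each stop-free
    stretch containing a triggering ungapped segment is aligned,
    iteratively masking found HSPs.
    """
    out = []
    text = ft.protein[lo:hi]
    pos = 0
    for chunk in text.split("*"):
        c_lo, c_hi = lo + pos, lo + pos + len(chunk)
        seeded = any(s < c_hi and e > c_lo for s, e in segments)
        if seeded and len(chunk) >= params.word_size:
            out.extend(_chunk_hits(query, ft, c_lo, chunk, params, genome))
        pos += len(chunk) + 1
    return out


def _chunk_hits(query, ft, lo, window, params, genome):
    out = []
    for _ in range(params.max_hsps_per_region):
        res = local_align(query.seq, window, params.matrix_name,
                          params.gap_open, params.gap_extend)
        if res is None:
            break
        q0, q1, w0, w1, score, ga, gb = res
        if score < params.min_score:
            break
        f0, f1 = lo + w0, lo + w1
        iv0 = ft.codon_interval(f0)
        iv1 = ft.codon_interval(f1 - 1)
        g_start, g_end = min(iv0[0], iv1[0]), max(iv0[1], iv1[1])
        out.append(TranslatedHit(
            query_id=query.id, contig=genome.id, strand=ft.strand,
            frame=ft.frame, g_start=g_start, g_end=g_end,
            q_start=q0, q_end=q1, score=score,
            aligned_query=ga, aligned_target=gb))
        # mask the matched stretch and look for further HSPs in the window
        window = window[:w0] + "*" * (w1 - w0) + window[w1:]
    return out


def _merge_overlapping(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Drop hits overlapping a higher-scoring hit in the same frame."""
    kept: list[TranslatedHit] = []
    for hit in hits:  # already sorted by descending score
        clash = any(
            k.contig == hit.contig and k.strand == hit.strand
            and k.frame == hit.frame
            and not (hit.g_end <= k.g_start or k.g_end <= hit.g_start)
            for k in kept)
        if not clash:
            kept.append(hit)
    return kept


def rescore_hit(hit: TranslatedHit, params: SearchParams | None = None) -> int:
    """Recompute a hit's score from its gapped strings (contract check)."""
    from ._scoring import score_columns

    params = params or SearchParams()
    return score_columns(hit.aligned_query, hit.aligned_target,
                         load_matrix(params.matrix_name),
                         params.gap_open, params.gap_extend)


def write_hits_tsv(hits: list[TranslatedHit], path) -> None:
    """Tabular-BLAST-like output; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("query\tcontig\tstrand\tframe\tg_start\tg_end\t"
                 "q_start\tq_end\tscore\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.contig}\t{h.strand}\t{h.frame}\t"
                     f"{h.g_start + 1}\t{h.g_end}\t{h.q_start + 1}\t{h.q_end}\t"
                     f"{h.score}\n")
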