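"""Protein alignments and trees for annotated gene families.

Self-contained desk-scale replacements for the heavyweight inference stack:
center-star multiple alignment over an optimal pairwise (Gotoh) engine,
alignment trimming with missing-character conversion, p/Poisson distances,
Saitou-Nei neighbor joining, Fitch/Hartigan parsimony scoring (gaps as a
21st state) and nonparametric bootstrap with support-based collapsing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from ._scoring import AA_INDEX, global_align_pair
from .sequence_io import ProteinRecord


@dataclass
class MSA:
    """Equal-length gapped rows over amino acids plus '-' (gap) and '?'
    (missing)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in MSA")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def to_fasta(self, path) -> None:
        from .sequence_io import write_fasta
        write_fasta([ProteinRecord(i, r) for i, r in zip(self.ids, self.rows)],
                    path)


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: int = -11, gap_extend: int = -1):
    """Optimal global affine-gap alignment; returns (aligned_a, aligned_b,
    score)."""
    if not a or not b:
        raise ValueError("global_align requires nonempty sequences")
    return global_align_pair(a, b, matrix_name, gap_open, gap_extend)


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def center_star_msa(records: list[ProteinRecord], matrix_name: str = "BLOSUM62",
                    gap_open: int = -11, gap_extend: int = -1,
                    center: int | None = None) -> MSA:
    """Align all sequences to the center (the sequence maximizing summed
    pairwise alignment scores), merging by 'once a gap, always a gap'.

    ``center`` forces a star center by index (used for testing the center
    choice); by default the best center is selected automatically.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    n = len(records)
    totals = np.zeros(n)
    pair_cache: dict[tuple[int, int], tuple[str, str, int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, score = global_align(records[i].seq, records[j].seq,
                                         matrix_name, gap_open, gap_extend)
            pair_cache[(i, j)] = (ga, gb, score)
            totals[i] += score
            totals[j] += score
    center = int(np.argmax(totals)) if center is None else center

    center_seq = records[center].seq
    # merged center row as a list of per-position gap counts:
    # inserts[k] = number of gap columns before center residue k
    inserts = [0] * (len(center_seq) + 1)
    pairs = []  # (index, center_aligned, other_aligned)
    for i in range(n):
        if i == center:
            continue
        key = (min(i, center), max(i, center))
        ga, gb, _ = pair_cache[key]
        c_aln, o_aln = (gb, ga) if i < center else (ga, gb)
        pairs.append((i, c_aln, o_aln))
        # count runs of center gaps before each center residue
        pos = 0
        run = 0
        for cc in c_aln:
            if cc == "-":
                run += 1
            else:
                inserts[pos] = max(inserts[pos], run)
                run = 0
                pos += 1
        inserts[len(center_seq)] = max(inserts[len(center_seq)], run)

    def render(c_aln: str | None, o_aln: str | None) -> str:
        """Project one pairwise alignment onto the merged column space."""
        out = []
        pos = 0
        run_chars: list[str] = []
        if c_aln is None:  # the center itself
            for k in range(len(center_seq)):
                out.append("-" * inserts[k])
                out.append(center_seq[k])
            out.append("-" * inserts[len(center_seq)])
            return "".join(out)
        for cc, oc in zip(c_aln, o_aln):
            if cc == "-":
                run_chars.append(oc)
            else:
                out.append("".join(run_chars) + "-" * (inserts[pos] - len(run_chars)))
                run_chars = []
                out.append(oc)
                pos += 1
        out.append("".join(run_chars) + "-" * (inserts[len(center_seq)] - len(run_chars)))
        return "".join(out)

    rows: list[str | None] = [None] * n
    rows[center] = render(None, None)
    for i, c_aln, o_aln in pairs:
        rows[i] = render(c_aln, o_aln)
    return MSA([r.id for r in records], [str(r) for r in rows])


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_alignment(msa: MSA, max_gap_fraction: float = 0.5,
                   end_agreement: float = 0.3,
                   internal_gap_run: int = 20) -> MSA:
    """Clean an alignment before tree building.

    Rows with gap fraction above ``max_gap_fraction`` are deleted; leading
    and trailing columns whose majority-residue agreement is below
    ``end_agreement`` are masked to '?'; internal gap runs longer than
    ``internal_gap_run`` columns are rewritten to '?' (missing), reflecting
    uncertainty of the underlying annotation rather than true deletion.
    """
    keep = [i for i, row in enumerate(msa.rows)
            if row.count("-") / len(row) <= max_gap_fraction]
    if len(keep) < 2:
        raise ValueError("fewer than two rows survive gap-fraction trimming")
    ids = [msa.ids[i] for i in keep]
    rows = [list(msa.rows[i]) for i in keep]
    n_col = len(rows[0])

    def agreement(col: int) -> float:
        residues = [r[col] for r in rows if r[col] not in "-?"]
        if not residues:
            return 0.0
        best = max(residues.count(x) for x in set(residues))
        return best / len(rows)

    lo = 0
    while lo < n_col and agreement(lo) < end_agreement:
        for r in rows:
            r[lo] = "?"
        lo += 1
    hi = n_col - 1
    while hi > lo and agreement(hi) < end_agreement:
        for r in rows:
            r[hi] = "?"
        hi -= 1

    for r in rows:
        run_start = None
        for c in range(n_col + 1):
            ch = r[c] if c < n_col else "X"
            if ch == "-":
                if run_start is None:
                    run_start = c
            else:
                if run_start is not None and c - run_start > internal_gap_run:
                    for k in range(run_start, c):
                        r[k] = "?"
                run_start = None
    return MSA(ids, ["".join(r) for r in rows])


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def distance_matrix(msa: MSA, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over columns where neither row has '-' or '?'.

    ``p`` is the mismatch fraction; ``poisson`` applies -ln(1-p).  p == 1 is
    capped just below 1 with a warning.
    """
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    n = len(msa.ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = [(a, b) for a, b in zip(msa.rows[i], msa.rows[j])
                      if a not in "-?" and b not in "-?"]
            if not shared:
                raise ValueError(
                    f"no shared columns between {msa.ids[i]} and {msa.ids[j]}")
            p = sum(a != b for a, b in shared) / len(shared)
            if correction == "poisson":
                if p >= 1.0:
                    warnings.warn("p-distance of 1 capped for Poisson correction")
                    p = 1.0 - 1e-6
                d = -np.log(1.0 - p)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=msa.ids)


def neighbor_joining(dm: DistanceMatrix):
    """Saitou-Nei neighbor joining; returns a rooted ``Bio.Phylo`` tree.

    The root is placed at the final join with the remaining distance split
    equally (the rooted position is arbitrary; path lengths between leaves
    are preserved exactly on additive inputs).  Negative branch lengths are
    clamped to zero with a warning.
    """
    from Bio.Phylo.BaseTree import Clade, Tree

    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    d = {(a, b): float(dm[a, b]) for a in ids for b in ids}
    nodes = {name: Clade(name=name) for name in ids}
    active = list(ids)
    counter = 0

    def clamp(x: float) -> float:
        if x < -1e-9:
            warnings.warn("negative NJ branch length clamped to 0")
        return max(0.0, x)

    while len(active) > 2:
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        n_act = len(active)
        best = None
        for ai in range(n_act):
            for bi in range(ai + 1, n_act):
                a, b = active[ai], active[bi]
                q = (n_act - 2) * d[(a, b)] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (n_act - 2))
        lb = d[(a, b)] - la
        nodes[a].branch_length = clamp(la)
        nodes[b].branch_length = clamp(lb)
        counter += 1
        new = f"__nj{counter}"
        nodes[new] = Clade(clades=[nodes[a], nodes[b]])
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        active = [c for c in active if c not in (a, b)] + [new]

    a, b = active
    dv = d[(a, b)] if len(ids) > 2 or (a, b) in d else float(dm[a, b])
    nodes[a].branch_length = clamp(dv / 2)
    nodes[b].branch_length = clamp(dv / 2)
    root = Clade(clades=[nodes[a], nodes[b]])
    return Tree(root=root, rooted=True)


def tree_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (for checking additivity)."""
    leaves = tree.get_terminals()
    out = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            dist = tree.distance(a, b)
            key = tuple(sorted([a.name, b.name]))
            out[key] = dist
    return out


def reroot_on_outgroup(tree, outgroup_name: str):
    """Reroot on the pendant edge of the named leaf; returns the tree."""
    tree.root_with_outgroup({"name": outgroup_name})
    return tree


# ---------------------------------------------------------------------------
# Parsimony scoring
# ---------------------------------------------------------------------------

_GAP_STATE = 20  # gaps are a character of their own


def _state_set(ch: str) -> frozenset:
    if ch in ("?", "X"):
        return frozenset(range(21))   # compatible with any state
    if ch == "-":
        return frozenset([_GAP_STATE])
    return frozenset([AA_INDEX[ch] if AA_INDEX[ch] < 20 else 19])


def fitch_parsimony_score(tree, msa: MSA) -> int:
    """Minimum substitution count summed over columns (Fitch, generalised to
    polytomies via Hartigan's frequency rule); '-' is a 21st state and '?'
    is compatible with every state."""
    row_by_id = dict(zip(msa.ids, msa.rows))
    for leaf in tree.get_terminals():
        if leaf.name not in row_by_id:
            raise ValueError(f"leaf {leaf.name!r} has no MSA row")
    total = 0
    for col in range(msa.n_columns):
        def score(clade) -> tuple[frozenset, int]:
            if clade.is_terminal():
                return _state_set(row_by_id[clade.name][col]), 0
            sets, cost = [], 0
            for kid in clade.clades:
                s, c = score(kid)
                sets.append(s)
                cost += c
            counts: dict[int, int] = {}
            for s in sets:
                for state in s:
                    counts[state] = counts.get(state, 0) + 1
            kmax = max(counts.values())
            chosen = frozenset(s for s, c in counts.items() if c == kmax)
            return chosen, cost + (len(sets) - kmax)
        _, cost = score(tree.root)
        total += cost
    return total


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------

def _bipartitions(tree) -> set[frozenset]:
    """Nontrivial unrooted bipartitions, each canonicalised to the side not
    containing the alphabetically first leaf."""
    all_leaves = frozenset(l.name for l in tree.get_terminals())
    anchor = min(all_leaves)
    splits = set()
    for clade in tree.get_nonterminals():
        side = frozenset(l.name for l in clade.get_terminals())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def default_tree_builder(msa: MSA):
    return neighbor_joining(distance_matrix(msa, "poisson"))


def bootstrap_support(msa: MSA, tree_builder=None, n_reps: int = 100,
                      seed: int = 0, collapse_cutoff: float = 50.0):
    """Column-resampling bootstrap; returns the full-data tree with percent
    supports on internal nodes, splits below ``collapse_cutoff`` collapsed
    to polytomies."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree_builder = tree_builder or default_tree_builder
    rng = np.random.default_rng(seed)
    full = tree_builder(msa)
    counts: dict[frozenset, int] = {s: 0 for s in _bipartitions(full)}
    n_col = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, n_col, size=n_col)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        try:
            rep_tree = tree_builder(MSA(list(msa.ids), rows))
        except ValueError:
            continue  # e.g. no shared columns in a pathological resample
        rep_splits = _bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    all_leaves = frozenset(l.name for l in full.get_terminals())
    anchor = min(all_leaves)
    to_collapse = []
    for clade in full.get_nonterminals():
        side = frozenset(l.name for l in clade.get_terminals())
        canon = side if anchor not in side else all_leaves - side
        if canon in counts:
            support = 100.0 * counts[canon] / n_reps
            clade.confidence = round(support, 1)
            if support < collapse_cutoff and collapse_cutoff > 0:
                to_collapse.append(clade)
    for clade in to_collapse:
        if clade is not full.root:
            full.collapse(clade)
    return full
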