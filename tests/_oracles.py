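"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: plain dynamic programs, exhaustive
enumerations and substring scans written without reference to the package's
own algorithms, so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from famtrace._scoring import AA_INDEX, load_matrix
from famtrace.sequence_io import reverse_complement, translate


from numba import njit


@njit(cache=True)
def _sw_kernel(sub, gap_open, gap_extend):
    """Textbook three-matrix affine local alignment, score only."""
    n, m = sub.shape
    NEGINF = -(10 ** 9)
    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEGINF, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), NEGINF, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i, j] = max(M[i, j - 1] + gap_open + gap_extend,
                           Ix[i, j - 1] + gap_extend)
            Iy[i, j] = max(M[i - 1, j] + gap_open + gap_extend,
                           Iy[i - 1, j] + gap_extend)
            cand = M[i - 1, j - 1] + sub[i - 1, j - 1]
            if Ix[i, j] > cand:
                cand = Ix[i, j]
            if Iy[i, j] > cand:
                cand = Iy[i, j]
            if cand < 0:
                cand = 0
            M[i, j] = cand
            if cand > best:
                best = cand
    return best


def smith_waterman_score(a: str, b: str, matrix=None, gap_open=-11,
                         gap_extend=-1) -> int:
    """Plain affine-gap local alignment score (full DP, no heuristics)."""
    if not a or not b:
        return 0
    matrix = load_matrix() if matrix is None else matrix
    a_idx = np.array([AA_INDEX[c] for c in a])
    b_idx = np.array([AA_INDEX[c] for c in b])
    sub = matrix[np.ix_(a_idx, b_idx)].astype(np.int64)
    return int(_sw_kernel(sub, gap_open, gap_extend))


def best_six_frame_score(query: str, genome: str, **kw) -> int:
    """Brute-force optimum: full Smith-Waterman against every frame.

    In-frame stops are barriers (no alignment column, paired or gapped, may
    consume a '*'), so each frame is scored per stop-free stretch.
    """
    frames = []
    rc = reverse_complement(genome)
    for off in range(3):
        frames.append(translate(genome, off))
        frames.append(translate(rc, off))
    return max(
        (smith_waterman_score(query, chunk, **kw)
         for f in frames for chunk in f.split("*") if chunk),
        default=0)


# ---------------------------------------------------------------------------
# Exhaustive GT..AG splice-parse enumeration
# ---------------------------------------------------------------------------

def enumerate_splice_optimum(query: str, window: str, min_intron: int,
                             intron_penalty: int, max_introns: int = 2,
                             gap_open=-11, gap_extend=-1) -> int:
    """Optimum over all parses with up to ``max_introns`` canonical introns.

    Each candidate intron is a GT..AG interval of length >= min_intron; for
    every non-overlapping subset the introns are spliced out and the best
    local alignment of the query against the three translation offsets of
    the spliced sequence is taken, plus the intron penalties.  Frameshift
    parses are not enumerated, so this equals the splice DP optimum only
    when that optimum uses no frameshift (e.g. identity-level queries).
    """
    matrix = load_matrix()
    gt = [i for i in range(len(window) - 1) if window[i:i + 2] == "GT"]
    ag = [i for i in range(len(window) - 1) if window[i:i + 2] == "AG"]
    introns = [(s, e + 2) for s in gt for e in ag
               if e + 2 - s >= min_intron]

    def alignment_score(seq: str) -> int:
        best = 0
        for off in range(3):
            prot = translate(seq, off)
            if prot:
                best = max(best, smith_waterman_score(query, prot, matrix,
                                                      gap_open, gap_extend))
        return best

    best = alignment_score(window)
    for k in range(1, max_introns + 1):
        for combo in itertools.combinations(introns, k):
            combo = sorted(combo)
            if any(combo[i][1] > combo[i + 1][0] for i in range(k - 1)):
                continue
            spliced = []
            pos = 0
            for s, e in combo:
                spliced.append(window[pos:s])
                pos = e
            spliced.append(window[pos:])
            score = alignment_score("".join(spliced)) + k * intron_penalty
            if score > best:
                best = score
    return best


# ---------------------------------------------------------------------------
# Naive global alignment (exponential recursion, tiny inputs only)
# ---------------------------------------------------------------------------

def naive_global_score(a: str, b: str, gap_open=-11, gap_extend=-1) -> int:
    matrix = load_matrix()

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0
        best = -(10 ** 9)
        if i < len(a) and j < len(b):
            best = max(best, int(matrix[AA_INDEX[a[i]], AA_INDEX[b[j]]])
                       + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open + gap_extend
            best = max(best, cost + rec(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open + gap_extend
            best = max(best, cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "start")


# ---------------------------------------------------------------------------
# Naive motif scan
# ---------------------------------------------------------------------------

def naive_ggxnw_hits(protein: str, min_gap=3, max_gap=60):
    """Leftmost non-overlapping GG-X(min,max)-W matches by substring scan.

    Mirrors the greedy leftmost-then-shortest semantics of a regular
    expression without backtracking into accepted matches.
    """
    hits = []
    i = 0
    while i < len(protein) - 1:
        if protein[i:i + 2] == "GG":
            found = None
            for gap in range(min_gap, max_gap + 1):
                w = i + 2 + gap
                if w >= len(protein):
                    break
                if protein[w] == "W":
                    found = (i, w + 1)
                    break
            if found:
                hits.append(found)
                i = found[1]
                continue
        i += 1
    return hits


# ---------------------------------------------------------------------------
# Brute-force duplication/loss reconciliation
# ---------------------------------------------------------------------------

def brute_force_reconcile(gene_tree_nodes, species_nodes, species_parent,
                          species_depth, leaf_assignment):
    """Minimum duplications+losses over all valid gene->species mappings.

    ``gene_tree_nodes``: postorder list of (node_id, child_ids or None).
    ``leaf_assignment``: node_id -> species node for gene leaves.
    A mapping is valid when every internal node maps to an ancestor-or-equal
    of each child's image.  Cost: a node whose two children map into two
    different child subtrees of its image is a speciation (each child path
    pays depth-difference-minus-one losses); otherwise it is a duplication
    (one event, each child path pays the full depth difference in losses).
    """
    def is_ancestor_or_equal(a, b):
        while True:
            if a == b:
                return True
            if b not in species_parent:
                return False
            b = species_parent[b]

    def child_subtree_of(ancestor, node):
        """Which child of ancestor contains node (None if node==ancestor)."""
        if node == ancestor:
            return None
        prev = node
        while species_parent.get(prev) != ancestor:
            prev = species_parent[prev]
        return prev

    internal = [(nid, kids) for nid, kids in gene_tree_nodes if kids]
    best = [None]

    def cost_of(mapping):
        dups = losses = 0
        for nid, kids in internal:
            mv = mapping[nid]
            subtrees = [child_subtree_of(mv, mapping[k]) for k in kids]
            speciation = (None not in subtrees
                          and len(set(subtrees)) == len(subtrees))
            if speciation:
                for k in kids:
                    losses += species_depth[mapping[k]] - species_depth[mv] - 1
            else:
                dups += 1
                for k in kids:
                    losses += species_depth[mapping[k]] - species_depth[mv]
        return dups + losses, dups, losses

    choices = [nid for nid, kids in internal]
    for assignment in itertools.product(species_nodes, repeat=len(choices)):
        mapping = dict(leaf_assignment)
        mapping.update(dict(zip(choices, assignment)))
        valid = all(
            is_ancestor_or_equal(mapping[nid], mapping[k])
            for nid, kids in internal for k in kids)
        if not valid:
            continue
        total, dups, losses = cost_of(mapping)
        if best[0] is None or total < best[0][0]:
            best[0] = (total, dups, losses)
    return best[0]
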