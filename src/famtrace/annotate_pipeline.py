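"""Iterative annotation driver, model deduplication and synteny loci.

The driver searches a genome with seed protein queries, refines hits into
gene models, then recycles the conceptual translations of newly found
functional models as additional queries, iterating until an iteration adds
no model — divergent paralogs invisible to the original seed are picked up
through intermediate relatives.  Models are deduplicated by reciprocal CDS
overlap, and each surviving model is assigned a synteny locus label from its
nearest flanking non-family genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gene_models import (CandidateLocus, GeneModel, GeneModelParams,
                          cluster_hits, splice_align)
from .sequence_io import Feature, GenomeRecord, ProteinRecord
from .translated_search import GenomeIndex, SearchParams, search


@dataclass
class AnnotationRun:
    iteration: int
    query_ids: list[str]
    new_model_ids: list[str]
    cumulative: int


@dataclass
class SyntenyLocus:
    label: str
    upstream: str | None
    downstream: str | None
    member_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _exon_overlap(a: GeneModel, b: GeneModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _is_duplicate(a: GeneModel, b: GeneModel) -> bool:
    if a.contig != b.contig or a.strand != b.strand:
        return False
    ov = _exon_overlap(a, b)
    len_a = sum(e - s for s, e in a.exons)
    len_b = sum(e - s for s, e in b.exons)
    return ov > 0.5 * len_a and ov > 0.5 * len_b


def merge_models(existing: list[GeneModel], new: list[GeneModel]
                 ) -> list[GeneModel]:
    """Greedy highest-score-first deduplication.

    Two models are duplicates iff they share strand and reciprocally overlap
    more than 50% of each other's CDS; the result contains no duplicate pair.
    """
    pool = sorted(existing + new, key=lambda m: (-m.score, m.contig,
                                                 m.span[0], m.gene_id))
    kept: list[GeneModel] = []
    for model in pool:
        if not any(_is_duplicate(model, k) for k in kept):
            kept.append(model)
    kept.sort(key=lambda m: (m.contig, m.span[0]))
    return kept


def filter_shadowed(models: list[GeneModel], frac: float = 0.5
                    ) -> list[GeneModel]:
    """Drop fragments shadowed by a better model of the same gene.

    A model is shadowed when more than ``frac`` of its own exonic length
    lies under a strictly higher-scoring same-strand model.  This is
    one-sided, unlike duplicate merging: a partial rediscovery of a gene by
    a recycled query never outlives the full-length model.
    """
    kept = []
    for model in models:
        own = sum(e - s for s, e in model.exons)
        shadowed = any(
            other is not model and other.score > model.score
            and other.contig == model.contig and other.strand == model.strand
            and _exon_overlap(model, other) > frac * own
            for other in models)
        if not shadowed:
            kept.append(model)
    return kept


# ---------------------------------------------------------------------------
# Iterative annotation
# ---------------------------------------------------------------------------

def annotate_genome(genomes: list[GenomeRecord], queries: list[ProteinRecord],
                    search_params: SearchParams,
                    model_params: GeneModelParams,
                    name_prefix: str = "gene",
                    indexes: dict[str, GenomeIndex] | None = None
                    ) -> list[GeneModel]:
    """One annotation pass: search every query, refine every locus."""
    contig_lengths = {g.id: g.length for g in genomes}
    models: list[GeneModel] = []
    counter = 0
    for genome in genomes:
        gindex = (indexes or {}).get(genome.id) or GenomeIndex(
            genome, search_params.word_size)
        hits = []
        for query in queries:
            hits.extend(search(query, gindex, search_params))
        loci = cluster_hits(hits, model_params.max_intron,
                            model_params.min_locus_score, contig_lengths)
        loci = _dedupe_loci(loci)
        by_query = {q.id: q for q in queries}
        for locus in loci:
            query = by_query[locus.best_query_id]
            counter += 1
            model = splice_align(query, locus, genome, model_params,
                                 gene_id=f"{name_prefix}{counter:03d}")
            if model is not None:
                models.append(model)
    return merge_models([], models)


def _dedupe_loci(loci: list[CandidateLocus]) -> list[CandidateLocus]:
    """Keep the best-scoring locus among those with overlapping hit spans
    (multiple queries rediscover the same gene)."""
    kept: list[CandidateLocus] = []
    for locus in loci:  # already sorted by aggregate score desc
        lo, hi = locus.hit_span
        clash = any(
            k.contig == locus.contig and k.strand == locus.strand
            and not (hi <= k.hit_span[0] or k.hit_span[1] <= lo)
            for k in kept)
        if not clash:
            kept.append(locus)
    return kept


def iterate(genomes, seed_queries: list[ProteinRecord],
            search_params: SearchParams | None = None,
            model_params: GeneModelParams | None = None,
            max_iter: int = 6) -> tuple[list[GeneModel], list[AnnotationRun]]:
    """Iterate annotation until no new paralog is found (or ``max_iter``).

    Translations are recycled as queries only when they cannot poison
    seeding: no internal stop, no frameshift scar, and at least half the
    query covered (functional models always qualify; a merely truncated
    model does too, since its product is clean).  Convergence is judged
    after merging, so rediscovering a known gene never loops.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    search_params = search_params or SearchParams()
    model_params = model_params or GeneModelParams()
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    indexes = {g.id: GenomeIndex(g, search_params.word_size) for g in genomes}

    queries = list(seed_queries)
    seen_query_seqs = {q.seq for q in queries}
    cumulative: list[GeneModel] = []
    log: list[AnnotationRun] = []

    for iteration in range(1, max_iter + 1):
        found = annotate_genome(genomes, queries, search_params, model_params,
                                name_prefix=f"it{iteration}_g",
                                indexes=indexes)
        before = list(cumulative)
        before_ids = {m.gene_id for m in before}
        merged = filter_shadowed(merge_models(cumulative, found))
        # a model is new only if it is not a rescored duplicate of a model
        # from an earlier iteration
        new_ids = [m.gene_id for m in merged
                   if m.gene_id not in before_ids
                   and not any(_is_duplicate(m, p) for p in before)]
        log.append(AnnotationRun(iteration, [q.id for q in queries],
                                 sorted(new_ids), len(merged)))
        converged = not new_ids
        cumulative = merged
        if converged:
            break
        for model in cumulative:
            recyclable = ("*" not in model.protein
                          and "frameshift" not in model.defects
                          and model.coverage >= 0.5)
            if recyclable and model.protein not in seen_query_seqs:
                seen_query_seqs.add(model.protein)
                queries.append(ProteinRecord(model.gene_id, model.protein))
    return cumulative, log


# ---------------------------------------------------------------------------
# Synteny locus assignment
# ---------------------------------------------------------------------------

def assign_locus(models: list[GeneModel], neighbors: list[Feature],
                 max_distance: int = 1_000_000
                 ) -> tuple[list[GeneModel], list[SyntenyLocus]]:
    """Label each model by its nearest flanking non-family genes.

    The nearest neighbor gene ending before the model (upstream on the
    forward strand) and the nearest starting after it (downstream) within
    ``max_distance`` define the label ``"UP–DOWN"``; a missing side becomes
    '·'.  Models sharing a label are grouped into one :class:`SyntenyLocus`.

    Neighbor features carrying a ``status`` attribute are family genes
    (truth rows or previously emitted models) and are excluded — only
    non-family genes define a synteny locus.
    """
    spans = [(m.contig, *m.span) for m in models]

    def is_family(feat: Feature) -> bool:
        if feat.kind == "marker":
            return False  # markers are non-family annotations by definition
        if "status" in feat.attributes:
            return True
        return any(c == feat.seqid and feat.start < hi and lo < feat.end
                   for c, lo, hi in spans)

    flank = [f for f in neighbors if f.kind in ("gene", "marker")
             and not is_family(f)]
    loci: dict[str, SyntenyLocus] = {}
    for model in models:
        lo, hi = model.span
        up = down = None
        up_d = down_d = None
        for feat in flank:
            if feat.seqid != model.contig:
                continue
            name = feat.attributes.get("Name") or feat.attributes.get("ID") or "?"
            if feat.end <= lo:
                dist = lo - feat.end
                if dist <= max_distance and (up_d is None or dist < up_d):
                    up, up_d = name, dist
            elif feat.start >= hi:
                dist = feat.start - hi
                if dist <= max_distance and (down_d is None or dist < down_d):
                    down, down_d = name, dist
        label = f"{up or '·'}–{down or '·'}"
        model.locus_label = label
        if label not in loci:
            loci[label] = SyntenyLocus(label, up, down)
        loci[label].member_ids.append(model.gene_id)
    return models, list(loci.values())


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def models_to_features(models: list[GeneModel]) -> list[Feature]:
    feats: list[Feature] = []
    for m in models:
        lo, hi = m.span
        attrs = {"ID": m.gene_id, "status": m.status,
                 "defects": ",".join(m.defects) or ".",
                 "score": str(m.score), "query": m.query_id}
        if m.locus_label:
            attrs["locus"] = m.locus_label
        feats.append(Feature(m.contig, "gene", lo, hi, m.strand, attributes=attrs))
        feats.append(Feature(m.contig, "mRNA", lo, hi, m.strand,
                             attributes={"ID": m.gene_id + ".t1", "Parent": m.gene_id}))
        phase = 0
        exons = m.exons if m.strand == "+" else list(m.exons)
        for i, (s, e) in enumerate(exons, start=1):
            feats.append(Feature(m.contig, "CDS", s, e, m.strand, phase=phase,
                                 attributes={"ID": f"{m.gene_id}.cds{i}",
                                             "Parent": m.gene_id + ".t1"}))
            phase = (3 - ((e - s) - phase) % 3) % 3
    feats.sort(key=lambda f: (f.seqid, f.start, f.kind))
    return feats


def iteration_table(log: list[AnnotationRun]) -> pd.DataFrame:
    return pd.DataFrame([
        {"iteration": r.iteration, "n_queries": len(r.query_ids),
         "new_models": ",".join(r.new_model_ids) or ".",
         "cumulative_models": r.cumulative}
        for r in log
    ])


def locus_table(loci: list[SyntenyLocus]) -> pd.DataFrame:
    return pd.DataFrame([
        {"locus": l.label, "upstream": l.upstream or ".",
         "downstream": l.downstream or ".", "n_members": len(l.member_ids),
         "members": ",".join(l.member_ids)}
        for l in loci
    ])
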