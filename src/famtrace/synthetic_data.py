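"""Synthetic genomes and gene-family scenarios with known ground truth.

Every downstream stage of the pipeline (translated search, gene-model
refinement, iterative annotation, synteny labelling, tree building and
duplication/loss reconciliation) is exercised against data produced here, so
the generator plants genes whose exact coordinates, splice structure, status
and lineage are recorded as :class:`TruthRecord` objects.

What is emulated: multi-exon gene copies derived from a seed protein at
controlled divergence, tandem amplifications within one locus, pseudogenized
copies (premature stops, frameshifts, truncations), flanking marker genes
that define synteny loci, transposon-like repeat insertions, and
assembly-artifact genes split across two short contigs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._scoring import AMINO_ACIDS, standard_codon_tables
from .sequence_io import (Feature, GenomeRecord, ProteinRecord,
                          reverse_complement, translate)

MIN_INTRON_LENGTH = 60  # keeps GT/AG junction detection unambiguous


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """A planted gene: where it is, what it encodes and what is wrong with it.

    ``exons`` are 0-based half-open forward-strand intervals in transcription
    order (descending start for minus-strand genes).  For pseudogenes the
    ``protein`` field holds the conceptual translation including '*'.
    """

    gene_id: str
    contig: str
    exons: list[tuple[int, int]]
    strand: str
    protein: ProteinRecord
    status: str = "functional"
    defects: list[str] = field(default_factory=list)
    lineage: str = "root"

    def __post_init__(self):
        if self.status == "functional" and self.defects:
            raise ValueError("functional gene cannot carry defects")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError("exons not ordered along strand")

    def spliced_cds(self, contig_seq: str) -> str:
        parts = []
        for s, e in self.exons:
            chunk = contig_seq[s:e]
            parts.append(chunk if self.strand == "+" else reverse_complement(chunk))
        return "".join(parts)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class GenePlan:
    """One gene to plant: identity to the seed protein, exon count, status."""

    gene_id: str
    identity: float = 0.8
    n_exons: int = 3
    strand: str = "+"
    status: str = "functional"
    defect: str | None = None  # premature_stop | frameshift | truncated
    cluster: str | None = None  # genes sharing a cluster become tandem copies
    lineage: str = "root"
    protein: ProteinRecord | None = None  # explicit product overrides identity


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic genome (a stand-in for a real assembly)."""

    seed_protein: ProteinRecord
    genes: list[GenePlan] = field(default_factory=list)
    contig_length: int = 100_000
    contig_name: str = "contig1"
    gc: float = 0.42
    intron_length_range: tuple[int, int] = (MIN_INTRON_LENGTH, 1_500)
    marker_length: int = 1_200
    place_markers: bool = True
    n_repeats: int = 0
    repeat_length: int = 400
    split_contig_gene: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if self.intron_length_range[0] < MIN_INTRON_LENGTH:
            raise ValueError(f"introns must be >= {MIN_INTRON_LENGTH} bases")
        for plan in self.genes:
            if plan.protein is None and not 0 < plan.identity <= 1:
                raise ValueError("identity must be in (0,1]")


@dataclass
class SimulatedGenome:
    genomes: list[GenomeRecord]
    truth: list[TruthRecord]
    features: list[Feature]
    spec: GenomeSpec

    def truth_table(self):
        import pandas as pd

        return pd.DataFrame([
            {"gene_id": t.gene_id, "contig": t.contig, "status": t.status,
             "strand": t.strand, "start": t.span[0], "end": t.span[1],
             "n_exons": len(t.exons), "defects": ",".join(t.defects) or ".",
             "lineage": t.lineage}
            for t in self.truth
        ])


# ---------------------------------------------------------------------------
# Protein-level operations
# ---------------------------------------------------------------------------

def mutate_protein(protein: ProteinRecord, target_identity: float,
                   rng: np.random.Generator | int) -> ProteinRecord:
    """Substitute residues uniformly to reach ``target_identity``.

    An initial methionine is never touched (a planted functional gene must
    keep its start codon); substitutions never introduce '*' or 'X'.
    """
    if target_identity < 0.05:
        raise ValueError("target identity below 0.05 is alignment-meaningless")
    if target_identity > 1:
        raise ValueError("identity cannot exceed 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    seq = list(protein.seq)
    n_sub = round((1.0 - target_identity) * len(seq))
    first = 1 if seq and seq[0] == "M" else 0
    candidates = np.arange(first, len(seq))
    n_sub = min(n_sub, len(candidates))
    positions = rng.choice(candidates, size=n_sub, replace=False)
    for pos in sorted(positions):
        choices = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return ProteinRecord(protein.id, "".join(seq))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform choice among synonymous codons (no codon-usage bias)."""
    _, aa_to_codons = standard_codon_tables()
    codons = []
    for aa in protein:
        if aa == "X":
            aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        options = aa_to_codons[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


# ---------------------------------------------------------------------------
# Gene planting
# ---------------------------------------------------------------------------

def _random_intron(length: int, gc: float, rng: np.random.Generator) -> str:
    if length < MIN_INTRON_LENGTH:
        raise ValueError(f"intron shorter than {MIN_INTRON_LENGTH}")
    body = random_dna(length - 4, gc, rng)
    return "GT" + body + "AG"


def plant_gene(contig: str, protein: ProteinRecord, n_exons: int,
               intron_lengths, position: int, strand: str,
               rng: np.random.Generator | int, gene_id: str | None = None,
               gc: float = 0.42, lineage: str = "root"):
    """Write a multi-exon gene encoding ``protein`` into ``contig``.

    Introns are phase-aware (they may fall between codons or split one) and
    always match ``GT...AG``.  A stop codon is appended in the genome right
    after the final coding exon but is not part of the exon intervals, so the
    spliced exons translate to ``protein`` exactly.

    Returns ``(modified contig, TruthRecord)``.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    gene_id = gene_id or protein.id
    cds = reverse_translate(protein.seq, rng)

    if isinstance(intron_lengths, tuple) and len(intron_lengths) == 2 and n_exons > 1:
        lengths = [int(rng.integers(intron_lengths[0], intron_lengths[1] + 1))
                   for _ in range(n_exons - 1)]
    else:
        lengths = list(intron_lengths)[: n_exons - 1]
    if n_exons > 1 and len(lengths) != n_exons - 1:
        raise ValueError("need one intron length per junction")

    # intron insertion points in CDS coordinates (any phase), kept apart so
    # every exon has at least 9 coding bases
    if n_exons > 1:
        if len(cds) < 9 * n_exons:
            raise ValueError("protein too short for requested exon count")
        while True:
            cuts = sorted(rng.choice(np.arange(9, len(cds) - 9), size=n_exons - 1,
                                     replace=False).tolist())
            if all(b - a >= 9 for a, b in zip(cuts, cuts[1:])):
                break
    else:
        cuts = []

    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    pieces, exon_lens = [], []
    prev = 0
    for idx, cut in enumerate(cuts + [len(cds)]):
        pieces.append(cds[prev:cut])
        exon_lens.append(cut - prev)
        if idx < len(cuts):
            pieces.append(_random_intron(lengths[idx], gc, rng))
        prev = cut
    assembled = "".join(pieces) + stop

    if position < 0 or position + len(assembled) > len(contig):
        raise ValueError("contig too short for gene plus introns at position")

    insert = assembled if strand == "+" else reverse_complement(assembled)
    new_contig = contig[:position] + insert + contig[position + len(insert):]

    # exon intervals in assembled coordinates
    exons_local = []
    offset = 0
    for idx, exon_len in enumerate(exon_lens):
        exons_local.append((offset, offset + exon_len))
        offset += exon_len
        if idx < len(lengths):
            offset += lengths[idx]
    if strand == "+":
        exons = [(position + a, position + b) for a, b in exons_local]
    else:
        total = len(assembled)
        exons = [(position + total - b, position + total - a) for a, b in exons_local]

    truth = TruthRecord(gene_id=gene_id, contig="", exons=exons, strand=strand,
                        protein=ProteinRecord(gene_id, protein.seq),
                        lineage=lineage)
    assert translate(truth.spliced_cds(new_contig)) == protein.seq
    return new_contig, truth


# ---------------------------------------------------------------------------
# Pseudogenization
# ---------------------------------------------------------------------------

def pseudogenize(contig: str, truth: TruthRecord, mode: str,
                 rng: np.random.Generator | int):
    """Introduce a defect into a planted gene, editing genome and truth.

    Modes: ``premature_stop`` (an internal codon becomes TAA/TAG/TGA),
    ``frameshift`` (1-2 bases inserted in an exon, compensated by deleting
    the same number of bases immediately downstream of the gene so all other
    coordinates stay put), ``truncated`` (the terminal exon is overwritten
    with background sequence and dropped from the record).

    Returns ``(modified contig, new TruthRecord)``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if mode not in ("premature_stop", "frameshift", "truncated"):
        raise ValueError(f"unknown pseudogene mode {mode!r}")
    if len(truth.protein.seq) < 2:
        raise ValueError("cannot pseudogenize a 1-codon gene")
    truth = copy.deepcopy(truth)

    if mode == "premature_stop":
        return _plant_premature_stop(contig, truth, rng)
    if mode == "frameshift":
        return _plant_frameshift(contig, truth, rng)
    return _truncate(contig, truth, rng)


def _codon_genome_positions(truth: TruthRecord):
    """Forward-strand position of every spliced-CDS base, in CDS order."""
    positions = []
    for s, e in truth.exons:
        coords = range(s, e) if truth.strand == "+" else range(e - 1, s - 1, -1)
        positions.extend(coords)
    return positions


def _write_base(contig: str, pos: int, base: str) -> str:
    return contig[:pos] + base + contig[pos + 1:]


def _plant_premature_stop(contig, truth, rng):
    n_res = len(truth.protein.seq)
    positions = _codon_genome_positions(truth)
    # internal codon, fully inside one exon, and away from splice junctions
    candidates = []
    for c in range(1, n_res - 1):
        idx = [positions[3 * c + k] for k in range(3)]
        step = -1 if truth.strand == "-" else 1
        if idx[1] == idx[0] + step and idx[2] == idx[1] + step:
            candidates.append(c)
    codon_i = candidates[rng.integers(len(candidates))]
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    stop_bases = stop if truth.strand == "+" else reverse_complement(stop)
    idx = sorted(positions[3 * codon_i + k] for k in range(3))
    for pos, base in zip(idx, stop_bases):
        contig = _write_base(contig, pos, base)
    prot = truth.protein.seq
    truth.protein = ProteinRecord(truth.gene_id, prot[:codon_i] + "*" + prot[codon_i + 1:])
    truth.status = "pseudogene"
    truth.defects = ["premature_stop"]
    return contig, truth


def _plant_frameshift(contig, truth, rng):
    k = int(rng.integers(1, 3))  # 1 or 2 bases, never a multiple of 3
    order = list(range(len(truth.exons)))
    exon_i = order[rng.integers(max(1, len(order) - 1))] if len(order) > 1 else 0
    s, e = truth.exons[exon_i]
    pos = int(rng.integers(s + 3, e - 3))
    ins = random_dna(k, 0.5, rng)
    gene_lo, gene_hi = truth.span
    # insert k bases inside the exon, delete k right after the gene span
    # (plus the trailing stop codon region) so downstream coordinates hold
    contig = contig[:pos] + ins + contig[pos:gene_hi + 3] + contig[gene_hi + 3 + k:]
    new_exons = []
    for a, b in truth.exons:
        a2 = a + k if a > pos else a
        b2 = b + k if b > pos else b
        new_exons.append((a2, b2))
    truth.exons = new_exons
    spliced = truth.spliced_cds(contig)
    truth.protein = ProteinRecord(truth.gene_id, translate(spliced))
    truth.status = "pseudogene"
    truth.defects = ["frameshift"]
    return contig, truth


def _truncate(contig, truth, rng):
    if len(truth.exons) < 2:
        raise ValueError("cannot truncate a single-exon gene")
    lost = truth.exons[-1]
    truth.exons = truth.exons[:-1]
    # overwrite the removed exon with background so it cannot be rediscovered
    contig = contig[:lost[0]] + random_dna(lost[1] - lost[0], 0.42, rng) + contig[lost[1]:]
    truth.protein = ProteinRecord(truth.gene_id, translate(truth.spliced_cds(contig)))
    truth.status = "pseudogene"
    truth.defects = ["truncated"]
    return contig, truth


# ---------------------------------------------------------------------------
# Whole-genome simulation
# ---------------------------------------------------------------------------

_REPEAT_SEED_RNG = 987654321


def repeat_seed_sequence(length: int = 400) -> str:
    """The literal transposon-like repeat unit (fixed, generated once)."""
    return random_dna(length, 0.45, np.random.default_rng(_REPEAT_SEED_RNG))


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Emit a genome FASTA, truth features and truth records from a spec.

    Deterministic for a fixed ``spec.seed``.  Genes sharing a ``cluster``
    label are planted adjacently (tandem copies) and, when markers are
    enabled, each cluster is flanked by an upstream and a downstream marker
    gene feature, emulating conserved neighbours such as flanking
    housekeeping genes at a synteny locus.
    """
    rng = np.random.default_rng(spec.seed)
    contig = random_dna(spec.contig_length, spec.gc, rng)

    # group genes into clusters, preserving plan order
    clusters: dict[str, list[GenePlan]] = {}
    for i, plan in enumerate(spec.genes):
        key = plan.cluster if plan.cluster is not None else f"__single{i}"
        clusters.setdefault(key, []).append(plan)

    # estimate footprint of each gene generously
    def footprint(plan: GenePlan) -> int:
        prot = plan.protein or spec.seed_protein
        return 3 * len(prot.seq) + 3 + (plan.n_exons - 1) * spec.intron_length_range[1] + 40

    gap_between = 800
    cluster_gap = 3_000
    needed = sum(
        2 * (spec.marker_length if spec.place_markers else 0)
        + sum(footprint(p) + gap_between for p in plans) + cluster_gap
        for plans in clusters.values()
    ) + spec.n_repeats * spec.repeat_length + 2_000
    if needed > spec.contig_length:
        raise ValueError(
            f"contig of {spec.contig_length} bases cannot hold the requested "
            f"placements (~{needed} bases needed)")

    truth: list[TruthRecord] = []
    features: list[Feature] = []
    cursor = int(rng.integers(500, 1_500))
    marker_n = 0

    for key, plans in clusters.items():
        if spec.place_markers:
            up_name = f"MARK{_letters(marker_n)}"
            marker_n += 1
            features.append(Feature(spec.contig_name, "marker", cursor,
                                    cursor + spec.marker_length, "+",
                                    attributes={"ID": up_name, "Name": up_name}))
            cursor += spec.marker_length + int(rng.integers(300, 900))
        for plan in plans:
            prot = plan.protein
            if prot is None:
                prot = mutate_protein(
                    ProteinRecord(plan.gene_id, spec.seed_protein.seq),
                    plan.identity, rng)
            contig, rec = plant_gene(
                contig, ProteinRecord(plan.gene_id, prot.seq), plan.n_exons,
                spec.intron_length_range, cursor, plan.strand, rng,
                gene_id=plan.gene_id, gc=spec.gc, lineage=plan.lineage)
            rec.contig = spec.contig_name
            if plan.status == "pseudogene":
                mode = plan.defect or "premature_stop"
                contig, rec = pseudogenize(contig, rec, mode, rng)
            truth.append(rec)
            cursor = rec.span[1] + 3 + int(rng.integers(gap_between // 2, gap_between))
        if spec.place_markers:
            down_name = f"MARK{_letters(marker_n)}"
            marker_n += 1
            features.append(Feature(spec.contig_name, "marker", cursor,
                                    cursor + spec.marker_length, "+",
                                    attributes={"ID": down_name, "Name": down_name}))
            cursor += spec.marker_length
        cursor += cluster_gap

    # transposon-like repeats: mutated copies of the fixed repeat unit,
    # dropped into intergenic space after the last cluster
    repeat_unit = repeat_seed_sequence(spec.repeat_length)
    for r in range(spec.n_repeats):
        if cursor + spec.repeat_length + 200 > spec.contig_length:
            break
        unit = _mutate_dna(repeat_unit, 0.05, rng)
        contig = contig[:cursor] + unit + contig[cursor + len(unit):]
        features.append(Feature(spec.contig_name, "repeat", cursor,
                                cursor + len(unit), "+",
                                attributes={"ID": f"repeat{r + 1}"}))
        cursor += len(unit) + int(rng.integers(200, 600))

    genomes = [GenomeRecord(spec.contig_name, contig)]

    # assembly artifact: cut one gene at an intron midpoint onto two contigs
    if spec.split_contig_gene is not None:
        genomes, truth, features = _split_contig(genomes[0], truth, features, spec, rng)

    for rec in truth:
        attrs = {"ID": rec.gene_id, "status": rec.status,
                 "defects": ",".join(rec.defects) or ".", "lineage": rec.lineage}
        lo, hi = rec.span
        features.append(Feature(rec.contig, "gene", lo, hi, rec.strand, attributes=attrs))
        for i, (s, e) in enumerate(sorted(rec.exons), start=1):
            features.append(Feature(rec.contig, "exon", s, e, rec.strand,
                                    attributes={"Parent": rec.gene_id,
                                                "ID": f"{rec.gene_id}.exon{i}"}))
    features.sort(key=lambda f: (f.seqid, f.start, f.kind))
    return SimulatedGenome(genomes=genomes, truth=truth, features=features, spec=spec)


def _letters(n: int) -> str:
    out = ""
    while True:
        out = chr(ord("A") + n % 26) + out
        n //= 26
        if n == 0:
            return out
        n -= 1


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[rng.integers(4)]
    return "".join(out)


def _split_contig(genome: GenomeRecord, truth, features, spec, rng):
    target = next((t for t in truth if t.gene_id == spec.split_contig_gene), None)
    if target is None or len(target.exons) < 2:
        raise ValueError("split_contig_gene must name a planted multi-exon gene")
    exons_sorted = sorted(target.exons)
    # cut between the first and second exon (forward order)
    cut = (exons_sorted[0][1] + exons_sorted[1][0]) // 2
    left = GenomeRecord(genome.id + "a", genome.seq[:cut])
    right = GenomeRecord(genome.id + "b", genome.seq[cut:])
    new_features = []
    for feat in features:
        feat = copy.deepcopy(feat)
        if feat.end <= cut:
            feat.seqid = left.id
        else:
            feat.seqid = right.id
            feat.start -= cut
            feat.end -= cut
        new_features.append(feat)
    new_truth = []
    for rec in truth:
        rec = copy.deepcopy(rec)
        if rec.gene_id != target.gene_id:
            if rec.span[1] <= cut:
                rec.contig = left.id
            else:
                rec.contig = right.id
                rec.exons = [(s - cut, e - cut) for s, e in rec.exons]
            new_truth.append(rec)
            continue
        # the split gene becomes two truncated records, one per contig
        left_exons = [(s, e) for s, e in rec.exons if e <= cut]
        right_exons = [(s - cut, e - cut) for s, e in rec.exons if s >= cut]
        for part, (cid, exons) in enumerate(
                [(left.id, left_exons), (right.id, right_exons)]):
            if not exons:
                continue
            prot_len = sum(e - s for s, e in exons) // 3
            piece = TruthRecord(
                gene_id=f"{rec.gene_id}.part{part + 1}", contig=cid,
                exons=exons if rec.strand == "+" else sorted(exons, reverse=True),
                strand=rec.strand,
                protein=ProteinRecord(f"{rec.gene_id}.part{part + 1}",
                                      rec.protein.seq[:prot_len] if part == 0
                                      else rec.protein.seq[-prot_len:]),
                status="pseudogene", defects=["truncated"], lineage=rec.lineage)
            new_truth.append(piece)
    return [left, right], new_truth, new_features


# ---------------------------------------------------------------------------
# Birth-and-death family simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilyScenario:
    """Gene-family evolution along a binary species tree.

    ``birth_rate``/``death_rate`` are per gene lineage per unit branch
    length; ``subst_rate`` is the expected per-site substitutions per unit
    branch length used to evolve the root protein.
    """

    species_tree_newick: str
    birth_rate: float = 0.5
    death_rate: float = 0.0
    subst_rate: float = 0.05
    root_protein: ProteinRecord | None = None
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class FamilySimulation:
    gene_tree: object | None  # Bio.Phylo tree, None if family went extinct
    events: list[dict]
    leaf_proteins: dict[str, ProteinRecord]
    leaf_species: dict[str, str]
    extinct: bool

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e["type"] == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e["type"] == "loss")


class _GNode:
    __slots__ = ("children", "length", "name", "event")

    def __init__(self, length=0.0, name=None, event=None):
        self.children = []
        self.length = length
        self.name = name
        self.event = event


def simulate_family(scenario: FamilyScenario) -> FamilySimulation:
    """Simulate duplications and losses of a gene family along a species tree.

    Each extant gene lineage duplicates at rate ``birth_rate`` and dies at
    rate ``death_rate`` along species-tree branches (a linear birth-death
    process); at speciation nodes every surviving lineage is inherited by
    both daughter species.  Leaf names are ``<species>_g<k>``.
    """
    from .sequence_io import read_newick
    from .reconciliation import check_binary

    sp_tree = read_newick(scenario.species_tree_newick)
    check_binary(sp_tree)
    rng = np.random.default_rng(scenario.seed)
    lam, mu = scenario.birth_rate, scenario.death_rate
    events: list[dict] = []
    leaf_species: dict[str, str] = {}
    counter = {"n": 0}

    def branch_name(clade):
        if clade.name:
            return clade.name
        leaves = sorted(l.name for l in clade.get_terminals())
        return f"mrca({leaves[0]},{leaves[-1]})"

    def evolve_branch(gnode: _GNode, length: float, clade) -> list[_GNode]:
        """Run birth-death for one gene lineage along one species branch.

        Returns the list of lineage tips alive at the branch end; dead
        lineages are recorded as loss events and dropped later.
        """
        t = 0.0
        tips = [(gnode, t)]
        alive_out = []
        while tips:
            node, t0 = tips.pop()
            total = lam + mu
            while True:
                if total == 0:
                    node.length += length - t0
                    alive_out.append(node)
                    break
                wait = rng.exponential(1.0 / total)
                if t0 + wait >= length:
                    node.length += length - t0
                    alive_out.append(node)
                    break
                t0 += wait
                node.length += wait
                if rng.random() < lam / total:
                    events.append({"type": "duplication",
                                   "species_branch": branch_name(clade),
                                   "time": t0})
                    left, right = _GNode(), _GNode()
                    node.children = [left, right]
                    node.event = "duplication"
                    tips.append((right, t0))
                    node = left
                else:
                    events.append({"type": "loss",
                                   "species_branch": branch_name(clade),
                                   "time": t0})
                    node.event = "dead"
                    break
        return alive_out

    def recurse(clade, lineages: list[_GNode]):
        for lineage in list(lineages):
            survivors = evolve_branch(lineage, clade.branch_length or 1.0, clade)
            if clade.is_terminal():
                for tip in survivors:
                    counter["n"] += 1
                    tip.name = f"{clade.name}_g{counter['n']}"
                    leaf_species[tip.name] = clade.name
            else:
                for tip in survivors:
                    kids = [_GNode(), _GNode()]
                    tip.children = kids
                    tip.event = "speciation"
                    for kid, sub in zip(kids, clade.clades):
                        recurse_single(sub, kid)

    def recurse_single(clade, lineage):
        recurse(clade, [lineage])

    root = _GNode()
    sp_root = sp_tree.root
    if sp_root.branch_length:
        survivors = evolve_branch(root, sp_root.branch_length, sp_root)
    else:
        survivors = [root]
    for tip in survivors:
        kids = [_GNode(), _GNode()]
        tip.children = kids
        tip.event = "speciation"
        for kid, sub in zip(kids, sp_root.clades):
            recurse_single(sub, kid)

    pruned = _prune_dead(root)
    if pruned is None:
        return FamilySimulation(None, events, {}, {}, extinct=True)

    gene_tree = _to_phylo(pruned)
    leaf_proteins = _evolve_proteins(pruned, scenario, rng)
    return FamilySimulation(gene_tree, events, leaf_proteins, leaf_species,
                            extinct=False)


def _prune_dead(node: _GNode):
    """Remove extinct lineages; collapse unary nodes, summing lengths."""
    if not node.children:
        return None if node.event == "dead" else node
    kept = [c for c in (_prune_dead(ch) for ch in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    node.children = kept
    return node


def _to_phylo(node: _GNode):
    from Bio.Phylo.BaseTree import Clade, Tree

    def build(n: _GNode) -> Clade:
        clade = Clade(branch_length=n.length, name=n.name)
        clade.clades = [build(c) for c in n.children]
        return clade

    return Tree(root=build(node), rooted=True)


def _evolve_proteins(root: _GNode, scenario: FamilyScenario,
                     rng: np.random.Generator) -> dict[str, ProteinRecord]:
    base = scenario.root_protein or default_seed_protein()
    out: dict[str, ProteinRecord] = {}

    def mutate_along(seq: str, t: float) -> str:
        p = 1.0 - float(np.exp(-scenario.subst_rate * t))
        chars = list(seq)
        start = 1 if chars and chars[0] == "M" else 0
        for i in range(start, len(chars)):
            if rng.random() < p:
                choices = [aa for aa in AMINO_ACIDS if aa != chars[i]]
                chars[i] = choices[rng.integers(len(choices))]
        return "".join(chars)

    def walk(node: _GNode, seq: str):
        seq = mutate_along(seq, node.length)
        if not node.children:
            out[node.name] = ProteinRecord(node.name, seq)
        for child in node.children:
            walk(child, seq)

    walk(root, base.seq)
    return out


# ---------------------------------------------------------------------------
# Default seed protein (synthetic)
# ---------------------------------------------------------------------------

_DEFAULT_SEED = 424242


def default_seed_protein(length: int = 420) -> ProteinRecord:
    """A synthetic perforin-like seed protein (not a database sequence).

    Deterministically generated; begins with 'M' and carries a planted
    GG-X(n)-W motif and a schematic C2-like acidic patch so that motif
    scanning has something real to find.
    """
    rng = np.random.default_rng(_DEFAULT_SEED)
    residues = [AMINO_ACIDS[rng.integers(20)] for _ in range(length)]
    residues[0] = "M"
    # MACPF-like GGXnW motif around one third of the way in
    motif_at = length // 3
    residues[motif_at] = "G"
    residues[motif_at + 1] = "G"
    residues[motif_at + 10] = "W"
    # schematic C2 Ca2+-binding aspartates near the C-terminus
    c2_at = length - 60
    for off in (0, 6, 12):
        residues[c2_at + off] = "D"
    return ProteinRecord("seedPRF1", "".join(residues))
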