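# Methods

## Scope and design

famtrace re-implements, as a tested and fully synthetic-data-driven
pipeline, the workflow used to chart birth-and-death evolution of a
multi-copy gene family: iterative homology-based annotation of gene copies
in genome assemblies, pseudogene diagnosis, synteny-locus assignment,
protein tree construction, and duplication/loss reconciliation against a
species tree. The package never downloads or bundles real assemblies; the
synthetic-data module generates genomes whose every planted feature is
recorded, so each stage is validated against exact ground truth.

## Translated search (`translated_search`)

Queries are aligned to all six conceptual translations of a genome by
seed-and-extend: exact and neighborhood k-mer word seeds (word size 4,
neighborhood words must score ≥ 21 against the query word under BLOSUM62),
ungapped X-drop diagonal extension (X = 20), and a gapped local alignment
restricted to a window around each surviving seed region. Scoring is
BLOSUM62 with affine gaps costing `open + L·extend` (open −11, extend −1).
These parameters mirror common translated-search defaults and are all
config-exposed; none is derived from data.

Two deliberate choices:

* **Stops are barriers.** No alignment column — paired or gapped — may
  consume an in-frame stop. A hit that would cross a stop is therefore
  emitted as two hits. This makes premature stops visible to the
  downstream classifier instead of smoothing over them.
* **No E-values.** Selection is by raw score threshold (default 50); the
  original workflow is expert-supervised rather than E-value-driven, and
  Karlin–Altschul calibration is out of scope.

The best-hit score is validated against an independent full
Smith–Waterman over all six frames (same matrix, same gap model, same
stop-barrier rule) on planted instances; agreement is exact.

## Candidate loci and splice-aware parsing (`gene_models`)

Hits on one contig and strand are sorted by genomic start and chained:
a hit joins the chain whose last member ends nearest upstream, provided
the genomic gap is ≤ `max_intron` (default 20 kb) and the query interval
advances with genomic order while overlapping the previous hit's query
interval by less than half. Query-interval resets — the signature of a
tandem copy — start a new locus; interleaved spurious hits form their own
singleton chains without breaking a gene's exon chain.

Each locus window (hits padded by `splice_window_pad`, default 1.5 kb,
within the `max_intron`-padded cluster window) is parsed by a dynamic
program over (genome position, query position) with codon-boundary,
gap-in-query and gap-in-genome states. Introns open at any `GT` and close
at any `AG` at least `min_intron` = 40 bases later, in any codon phase;
a codon split by an intron is reassembled from the recorded open position.
Intron penalty −12, frameshift (1–2-base genomic jump) −30, in-frame stop
−30, canonical `GT–AG` only. These values are package choices, set so that
identity-level parses dominate; non-canonical junctions surface as
frameshift or low-score defects rather than being modelled. Ties between
equal-scoring parses resolve deterministically through the fixed
evaluation order of the DP (match before gaps before introns).

The DP is local; optionally (default on) up to 6 unaligned terminal query
residues are appended as plain codons when the window has room and no stop
intrudes, so a single diverged terminal residue does not shorten an exon.
The emitted score includes this extension and is exactly recomputable from
the gapped alignment strings.

Correctness is checked against exhaustive enumeration of all ≤2-intron
GT…AG parses on small planted genes (identity 1, where the optimum uses
neither frameshifts nor stops, which the enumeration does not model).

**Status rules.** Pseudogene iff internal `*` in the parse translation, a
frameshift jump in the optimal parse, or truncation (no initial M, or
query coverage < 0.9). Everything else is functional. Fragments above the
score floor are reported with defect `truncated` rather than suppressed;
filtering is left to the user.

## Iteration and loci (`annotate_pipeline`)

Iteration n searches with the seed queries plus conceptual translations of
models found so far whose products cannot poison seeding: no internal
stop, no frameshift scar, and at least half the query covered. Functional
models always qualify; merely truncated models do too (their products are
clean, and real partial paralogs are exactly what the next round should
search with); stop- or frameshift-carrying pseudogene products never do. After each pass, models
are deduplicated (duplicates = same strand, reciprocal exonic overlap >
50%, higher score kept) and shadowed fragments (> 50% of their own exonic
length under a strictly better same-strand model) are dropped. Convergence
is declared when an iteration adds no model that is not a rescored
duplicate of an existing one; model count is bounded, so termination is
guaranteed. The per-iteration discovery log is written as a TSV — the
audit surface replacing step-by-step expert supervision.

Synteny labels: for each model, the nearest non-family gene ending before
it and starting after it (gene-body distance on the forward strand, within
`max_distance` = 1 Mb — conserved loci in this family are sub-megabase)
define the label `UP–DOWN`; `·` marks a missing side. Features carrying a
`status` attribute are family annotations and never serve as flanks;
`marker` features always may.

## Trees (`phylogenetics`)

Bayesian MCMC and heuristic parsimony tree search are deliberately not
re-implemented; the reconciliation stage consumes any rooted tree, so the
package provides a self-contained desk-scale stack: optimal pairwise
global alignment (Gotoh) under the same scoring model, center-star MSA
(center = maximal summed pairwise score; "once a gap, always a gap"
merging), trimming, p or Poisson (−ln(1−p)) distances over shared columns,
Saitou–Nei neighbor joining (exact on additive matrices; negative branch
lengths clamped to 0 with a warning; rooted at the final join with the
remaining edge split equally — leaf-to-leaf path lengths are preserved),
Fitch parsimony scoring generalised to polytomies by Hartigan's frequency
rule (gap is a 21st state, `?`/`X` compatible with everything), and a
column-resampling bootstrap whose percent supports collapse splits below
the cutoff (default 100 replicates, cutoff 50).

Trimming defaults: rows with > 50% gaps deleted; leading/trailing columns
with < 30% residue agreement masked to `?`; internal gap runs longer than
20 columns rewritten to `?`. The original procedure applies expert
judgment for the last rule ("some" internal gaps); the run-length rule
here is an explicit, documented stand-in.

Rooting uses a named outgroup leaf (rerooted on its pendant edge), which
the pipeline simulates as a deeply diverged relative of the root protein.

## Reconciliation (`reconciliation`)

Classic LCA reconciliation of a rooted gene tree against a rooted binary
species tree: a node is a duplication iff its mapping equals at least one
child's mapping; losses are the species edges skipped between a node's
mapping and each child's (one-edge discount per speciation child, none at
duplications). The totals are the minimum duplication+loss reconciliation,
verified exhaustively against a brute-force minimum over all valid
mappings for every labelled gene tree of up to five leaves on a
three-species tree. Leaf mapping follows the `Species_gene` naming
convention with an explicit TSV override. Polytomous species trees are
rejected with the offending node named; transfers and support-aware edge
rearrangement are out of scope.

## Synthetic data (`synthetic_data`)

What the generator emulates, and how:

* **Planted genes**: the seed protein is mutated to a target identity
  (uniform substitutions, never creating `*`/`X`; an initial M is held
  fixed because a functional gene keeps its start codon), reverse
  translated with uniform synonymous codon choice (codon-usage bias is
  irrelevant to protein-level search), and planted with phase-aware
  `GT…AG` introns of ≥ 60 bases (short enough for desk scale, long enough
  for unambiguous junction detection). A stop codon follows the final
  exon but is not part of it, so spliced exons translate exactly to the
  planted protein.
* **Divergence defaults**: paralog identities 0.6–0.9 to the seed —
  a free choice (no quantitative divergences are prescribed by the study
  design this emulates) and config-exposed.
* **Pseudogenes**: premature stop (one internal codon → TAA/TAG/TGA),
  frameshift (1–2 bases inserted in an exon, compensated just downstream
  so all other coordinates are stable), truncation (terminal exon
  overwritten with background).
* **Loci**: tandem cluster members are planted adjacently and flanked by
  marker features, so synteny labelling has real structure to recover.
* **Repeats**: literal copies of a fixed repeat unit at 5% per-site
  mutation, emulating transposon-like insertions without a transposon
  database (planted but not detected — detection is out of scope).
* **Assembly artifacts**: a designated gene is cut at an intron midpoint
  onto two contigs, reproducing partial genes on short contigs.
* **Families**: a linear birth-death process (rates λ, μ per lineage per
  unit branch length) along a binary species tree; surviving lineages are
  inherited by both daughters at speciations; leaf proteins evolve by
  per-site substitution with probability 1−e^(−rt) per branch. The event
  log records every duplication and loss, surviving or not.

What it does **not** emulate: indel evolution in background DNA,
codon-level substitution models, sequencing error, heterogeneous intron
length distributions, and realistic intergenic composition. Passing tests
therefore demonstrate algorithmic correctness under controlled conditions,
not performance on real assemblies.

## Pipeline, determinism and problem sizes

All randomness derives from one root seed through named `SeedSequence`
substreams per stage, so a fixed seed reproduces every output byte for
byte (no timestamps are written). Default end-to-end scale — four species,
λ = 0.5 per unit branch, a 420-residue seed protein, one contig of 25 kb +
12 kb per planted copy per species, 100 bootstrap replicates — was chosen
so the whole pipeline and its acceptance checks run in minutes on one CPU
while still containing tandem clusters, pseudogenes and multi-copy
reconciliation. The acceptance script scales two checks down relative to
the test suite (the reconciliation oracle enumerates trees to four leaves
there, five in the suite).

## Known limitations

* The splice DP opens introns only from codon-boundary or mid-codon
  coding states, not from within gap states; a deletion spanning an
  intron junction is parsed as separate events.
* Heuristic seeding can in principle miss an optimum whose alignment
  contains no seed word; at the tested divergences (identity ≥ 0.6) this
  was never observed.
* NJ rooting at the final join is arbitrary; downstream reconciliation
  relies on outgroup rerooting, and a misplaced root inflates inferred
  duplications.
* The greedy duplicate merge maximises score locally, not the total score
  of the kept set; the difference can matter only in overlap chains of
  near-equal scores.
* `c2`-style short derived genes (secretion peptide + single domain) are
  not modelled by the generator; the pipeline would report them as
  truncated fragments.
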