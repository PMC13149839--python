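# Methods

## Scope and coordinates

`codtr` annotates T-cell receptor (TR) gene segments in genomic
sequence, simulates V(D)J recombination over a known germline, and
computes descriptive statistics over CDR3-collapsed clonotype tables.
All coordinates are 0-based half-open on the forward strand internally;
GFF3 output is 1-based inclusive.

## Germline annotation

**Homology scan.** V and C genes are located by a seed-and-extend
protein-level search: exact 6-mer amino-acid seeds between the genome's
six-frame translation and a reference V/C protein set define candidate
diagonals, and each candidate window is rescored with a Biopython
local alignment (BLOSUM62, gap open 11 / extend 1).  Candidates below
`min_score` (default 100, raw score units — no E-value statistics) are
dropped; overlapping same-strand candidates keep the best score.  A
segment's chain (A/B/G/D) is the chain label of its best reference hit.

**RSS scan.** Every position on both strands is tested for heptamer +
spacer + nonamer with spacer in {12, 22, 23} and mismatch budgets of
≤1 (heptamer) and ≤2 (nonamer); the cleavage-critical first three
heptamer bases (CAC) must match exactly.  This budget admits the known
ACATAAACC nonamer variant while keeping the expected chance-hit rate
below about one per 100 kb of random sequence.  All knobs sit in
`RssConfig`.

**Pairing rules.** A V gene takes the nearest correctly oriented
22/23-spacer motif whose heptamer starts within `max_gap` (default
10 nt, configurable — adjacency tolerance is a judgment call) of its
coding 3' end, and its coding interval is extended to the heptamer so
the partial-codon CDR3 opening after the 2nd-CYS is included.  J genes
are delineated from 12-spacer motifs: the coding region runs from the
heptamer edge to the earliest F/W-G-X-G anchor in any reading frame
plus a fixed 6-nt tail, and the anchor's frame becomes the J frame.
D genes are reported wherever two opposite-orientation motifs face
each other across a 1..40-nt core with one 12- and one 22/23-bp
spacer (the 12/23 rule); the D strand is '+' when the 12-spacer flank
is on the genomic left.  Motifs already consumed by V attachment or D
detection are excluded from J delineation, which prevents a D's
12-spacer flank from spawning a phantom J.

**Functionality.** A V gene is functional iff its frame-0 translation
is internally stop-free up to the 2nd-CYS, an RSS is attached, and a
Cys codon lies within the last 4 codons in frame 0.  A terminal Cys
present only in a shifted frame is read as a register shift and flagged
`frameshift`; no Cys at all flags `missing_cys104` + `incomplete_cdr3`.
J functionality requires the RSS, the F/W-G-X-G anchor in the J frame
(the check can be disabled — J criteria are a package convention, not a
community standard), and a stop-free reading up to the anchor.  D genes
need their two opposite RSSs; C genes only an open reading frame.  All
failures accumulate as defect reasons; any defect makes a pseudogene.

**Grouping and names.** V subgroups are single-linkage clusters at
>80% pairwise amino-acid identity (global alignment; matches over
aligned columns with gaps/ambiguities deleted pairwise); single linkage
makes subgroup membership transitive, as in IMGT practice, and
guarantees that lowering the threshold only coarsens the partition.
Translocons are maximal runs from a V-run start to the last segment
before the next V run (the final translocon absorbs trailing J/D/C,
which places the delta-specific genes of a shared alpha/delta
translocon correctly).  Mini-clusters are seeded by V genes; J/C
members join the V on their transcription-upstream side, so a
reverse-orientation partial cluster groups correctly.  Names follow the
IMGT-style grammar (`TRB{translocon}V{subgroup}-{n}`, locus-wide
`TRBJ{n}`, shared cluster numbers with skip-on-missing and letter
suffixes for in-cluster duplicates, `/D` marker for the
delta-preferential alpha subgroup).  J and D genes inherit the chain of
their nearest downstream (transcription direction) C gene.

**Phylogeny.** Classic iterative Q-matrix neighbour joining, written
in-package so tie-breaking (lexicographically smallest taxon pair) and
the negative-branch policy (clamp to zero, transfer the deficit to the
sister branch) are deterministic; NJ is exact on additive matrices and
the test suite cross-checks the topology against scikit-bio's NJ.
Distances: p-distance, or Kimura 2-parameter with the optional
Jin–Nei gamma-rate correction (shape 5 by default); ambiguous sites
and gaps are deleted pairwise; saturated K2P pairs raise an error
naming the pair.  Both models are exposed because either may be wanted
for V-gene subgroup confirmation.  Bootstrap resamples alignment
columns with replacement; supports are the percentage of replicates
containing each internal bipartition.

## Synthetic loci

Three presets emulate the cod TR architectures with exact ground
truth: `cod_AD` (52 forward V genes in five subgroups — 14/11/8/10/9;
subgroup 5 is delta-preferential with a 23-bp spacer and the ACATAAACC
nonamer; the ninth subgroup-1 gene is planted as a missing-Cys104
pseudogene; one reverse alpha C + 21 reverse J; reverse delta C/J/D),
`cod_B` (three forward translocons with 10/10/14 V, one D, 8/7/8 J — 
the terminal J of each translocon distinctly longer — and one C each),
and `cod_G` (six complete forward V-J-C mini-clusters plus one partial
reverse V-J cluster).

Genes are realised from random founder proteins per subgroup
(terminal Cys anchor; members diverge by ~7% amino-acid substitutions
with protected termini, guaranteeing >86% within-subgroup identity and
<~20% between subgroups), back-translated with random codon choice.
V genes carry a 2-nt germline CDR3 opening after the Cys codon, and
alpha/delta J genes place their anchor at an offset ≡ 0 (mod 3), so
the zero-trim, zero-insertion V–J (and V–D–J) junction is out of frame
by 2 nt: the germline configuration is non-productive and any single
non-templated insertion restores the frame — a property the test suite
verifies by enumerating all four 1-nt insertions against a translation
oracle.  Intergenic spacer is random sequence, re-drawn wherever a
chance RSS-budget hit appears, so the planted motif set is exactly the
recoverable one.  Generation is deterministic per seed.

What the fixtures deliberately do **not** model: introns/leader exons
(splice boundaries are out of scope), allelic variation, non-canonical
RSSs beyond the scanner budget, and realistic intergenic composition
(uniform random nucleotides).  Truth recovery on these fixtures
therefore demonstrates the pipeline's internal consistency and rule
implementation, not its performance on a real assembly with repeats,
degenerate motifs and fragmented genes.

## Recombination and repertoires

A rearrangement draws V (D) J uniformly, trims each coding end by
geometric(p=0.35) draws (mean ≈1.9 nt; trims never cross the Cys or
F/W anchors — draws that would are redrawn), inserts Poisson(λ=4)
uniform nucleotides at each junction, and defines the CDR3 as the
2nd-CYS codon through the J F/W codon inclusive (the AIRR "junction"
convention; length statistics depend on this boundary choice).
Productivity is a pure CDR3-level predicate — in frame, stop-free,
Cys first, F/W last — which coincides with a whole-chain reading
because the germline portions outside the CDR3 are stop-free by
construction.  `selection_mode="productive_only"` rejects
non-productive draws (alpha/beta-like repertoires); `"none"` keeps
them (delta-like repertoires, which then show a large non-productive
fraction).

Clone sizes follow a Zipf law: clone at rank i receives weight
i^(−α), α = 1.1, allocated by largest remainder over 100,000 total
reads across 1,500 distinct clones (every clone ≥1 read; read totals
are conserved exactly).  Read-level substitution noise (default
10⁻³/nt) mutates individual reads before CDR3 collapse, creating the
low-count artefact clonotypes that the ≥5-read filter exists to
remove.  With these defaults the analytic expectation for the D50
proportion-of-unique is ≈1% (≈15 of ~1,500 clonotypes cover half the
reads), i.e. a rank-abundance in the "few percent of clones dominate"
regime; the acceptance script reports the realised value.  The
junctional parameters are package choices — no cod-specific trimming
or insertion rates have been published.

## Repertoire statistics

Filtering keeps clonotypes with ≥5 reads (strict less-than is
discarded) and, by default, productive ones only; the filter is
idempotent.  Rarefaction subsamples reads without replacement via
multivariate hypergeometric draws over aa-CDR3 read counts, so the
full-depth value equals the unique count exactly and small cases match
closed-form hypergeometric expectations.  D50 sorts by read count with
deterministic lexicographic aa tie-breaks and is reported both as a
count and as a proportion of unique clonotypes.  Shannon entropy uses
log base 2 (configurable; no base is canonical).  V usage removes
ambiguous (multi-gene) calls by default and reports the dropped
fraction; usage correlation is Pearson (Spearman available), with
zero-variance vectors excluded as undefined.  Replicate overlap works
at the aa-CDR3 level; Kendall τ-b on shared clonotype counts uses
exact-enumeration p-values for n ≤ 8 without ties and the normal
approximation otherwise.  Sharedness (public/private) counts distinct
fish per aa CDR3, one sample per fish (the deeper technical replicate
is selected upstream).  Whole-organ bounds are [U, ⌊U/f⌋] for U
observed unique and sampling fraction f (default 0.15); flooring is
the documented convention.  Inter-translocon events count clonotypes
with unambiguous V and J calls whose genes lie in different
translocons, with both the all-clonotype and unambiguous-only
denominators reported.

## Numerical and testing notes

All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give byte-identical outputs (FASTA, GFF3, tables,
trees), and every CLI run writes a manifest (version + seed +
parameters).  Problem sizes in the test and acceptance runs — fixture
loci of 13–45 kb, repertoires of 100–1,500 clones, 25–100 bootstrap
replicates in tests — were chosen so the full suite completes in a few
seconds while still exercising every rule on realistic structure
counts.  Known limitations: no splice inference, no allele calling, no
E-value statistics in the homology scan, no PCR-bias or paired-chain
simulation, and no hypothesis tests comparing diversity between
groups.
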