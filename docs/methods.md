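# Methods

## Scope and model

`cypcensus` implements a comparative P450/BGC census pipeline as a chain of
small, individually testable stages:

    triage → pairwise identity → classification → census →
    {diversity statistics, presence/absence profiles, NJ tree} + BGC cross-reference

The central modelling assumption is the operational definition of P450
families: membership is decided purely by pairwise amino-acid identity of a
query to its single best hit among *named* reference P450s, with fixed
thresholds (family > 40%, subfamily > 55%). No profile HMMs, no
phylogeny-aware reassignment; the NJ tree is used only afterwards, as a
sanity check that same-family sequences group together.

## Triage

Upstream candidate selection (domain-detection services) is out of scope;
this package starts from a candidate FASTA and applies its own reproducible
stand-in rules:

| parameter | default | meaning |
|---|---|---|
| `heme_motif` | `F..G...C.G` | P450 heme-binding signature around the axial cysteine |
| `min_full_length` | 300 aa | below this (motif present) → fragment; bacterial P450s run ~400 aa |
| `require_exxr` | off | optional second check for the K-helix E-x-x-R motif |

Motif absent → false positive; motif present but short → fragment; else
full length. These rules are a declared convention of this package, not a
community standard: they make the fragment/false-positive split reproducible
and tunable, but they will not reproduce any particular published count that
was produced with an external domain search.

## Pairwise identity

Global Needleman–Wunsch alignment (via `Bio.Align.PairwiseAligner`), BLOSUM62,
gap open 10, gap extend 1; a gap of length L costs `open + (L−1)·extend`.
Identity = identical columns / aligned columns after trimming terminal-gap
columns (internal gaps count in the denominator). Rationale: for
near-full-length homologs this approximates the identity a local aligner
would report while staying deterministic and parameter-light. The
denominator is switchable to `shorter_sequence`.

The original committee rule was applied with heuristic local search tools
whose parameters and identity definition are rarely stated; near the 40/55
boundaries the assignment is therefore *definition-sensitive*. This is
documented rather than resolved: thresholds compare strictly (`>`), so
exactly 40.0/55.0 falls to the lower category, and an inclusive mode exists.

Co-optimal alignments: the aligner's first traceback is taken, which is a
pure function of the inputs — determinism is what matters downstream, since
identity values, not alignments, drive classification.

## Classification and provisional labels

Only the rank-1 hit is used (ties broken by ascending reference label).
Genuinely novel families/subfamilies cannot be named by software (numbers
are committee-assigned), so they receive provisional labels with a reserved
infix that can never collide with a real CYP label: `CYP_NF<k>` for new
families (global ordinals), `<family>_NS<k>` for new subfamilies (ordinals
per family). Records are processed in sorted (species, protein) order and
identical sequences share one label, so provisional labels are reproducible
run-to-run. Two-letter subfamily runs are ordered like spreadsheet columns
(A..Z, AA..) where ordering is needed; the committee's own ordering beyond Z
is not published.

## Census statistics and rounding

With S species, P P450s in F families, C clusters in T types, N_in P450s
inside clusters:

    P450 diversity    = 100·F/(P·S)     cluster diversity = 100·T/(C·S)
    avg P450s = P/S   avg BGCs = C/S    share in BGCs = 100·N_in/P

Rounding is half-up: two decimals for the diversity percentages, nearest
integer for averages and shares — the convention of the published
comparative tables this package ships as its worked example. Two
consequences worth knowing:

- `S` is the **total species analyzed**, including species whose genomes
  yielded no clusters. For the packaged cyanobacterial column (S = 114, of
  which only 103 produced cluster-detector output) this is the only choice
  consistent with the printed 0.08; using the 103 with results gives 0.09.
  Callers choosing the other convention simply pass a different S.
- Doubling S exactly halves both diversity percentages (formula-forced);
  the statistics are for comparing groups, not absolute measures.

"Blooming" (one family with many members) is reported descriptively as a
top-k ranking; no significance test is attached because none is defined for
these census counts.

## Presence/absence profiles

The census collapses to 3 (present) / −3 (absent) — the encoding heat-map
viewers render red/green. Both axes are clustered agglomeratively under
Euclidean distance with average linkage (single/complete available).
The clustering is implemented in-package because reproducibility requires a
stated tie-break: among equidistant pairs, the pair whose merged sorted
label set is lexicographically smallest merges first (distance ties are
compared at 1e-12). Dendrograms serialize to Newick with child edge length
= parent merge height − child merge height, so root-to-tip distance equals
the final merge height. The linkage choice is a free parameter of the
original GUI workflows; only determinism, not a particular linkage, is
asserted.

## Neighbor joining and family grouping

Distances are d = 1 − identity/100. Standard NJ agglomeration with
Q-matrix ties broken by smallest sorted label pair; the terminal three-taxon
star uses the closed-form three-point branch lengths. On additive inputs NJ
is exact (recovered path lengths agree to 1e-9 in the tests). Identity
distances from real proteins are not additive and negative branch lengths
are kept as computed: the tree is a grouping sanity check, not a published
phylogeny — a deliberate substitute for multi-algorithm ML/MP/NJ ensembles,
whose role here is only the monophyly score.

`family_grouping_score` = fraction of multi-member families whose leaf set
(or its complement) coincides with a bipartition of the unrooted tree;
singleton families are trivially monophyletic and excluded from the
denominator.

## BGC cross-referencing

Coordinates are 1-based inclusive throughout (GFF3/GenBank convention), with
a converter from 0-based half-open. Membership = ≥ 1 base of overlap between
gene locus and cluster interval on the same species and contig, strand
ignored; published surveys "manually mined" cluster sequences without
stating a rule, so the permissive rule is the default and a strict
containment rule is available. Hybrid cluster types keep the detector's
component order (`"NRPS, T1PKS"`, never sorted) and each distinct canonical
string counts as its own type — the convention is declared, since published
type counts do not state how hybrids were counted.

## Synthetic data

The generator fabricates the full input set with known truth, emulating the
real study shape at desk scale: 3 species, 4 families × 2 subfamilies,
30 planted P450s (10 per species at 65–90% identity to their source
reference), 2 decoys + 1 fragment per species, 6 clusters with 1–2 planted
members each. Design choices:

- Reference families are numbered from 9001 to stay clear of real CYP
  families. Founders are 350-aa uniform-random proteins rejection-sampled to
  < 30% pairwise identity; subfamily exemplars are mutated to 60–90%
  identity to their founder.
- Mutation is substitution-only by default (uniform over the 19 other
  residues), which keeps measured identity controllable; the contract of
  `mutate_to_identity` is *checked* — identity is re-measured with the
  package's own aligner until within ±2 points of target.
- A canonical heme-motif window is stamped near the C terminus and protected
  from mutation, so planted categories survive triage by construction.
- Genes are spaced 2 kb apart on one synthetic contig per species; cluster
  intervals span their members plus a 100-bp margin (smaller than the
  spacing), so planted membership equals interval intersection exactly.

What this does **not** emulate: real domain architecture and composition
bias, indel-rich divergence, operon structure, overlapping genes, multiple
contigs, or the detection behaviour of cluster-finding software. Passing
tests therefore demonstrate the pipeline's internal correctness
(classification thresholds, counting, intersection, statistics), not
recovery of any real organism's census; absolute published census numbers
depend on external databases and detection tools and are out of scope.

## Problem sizes and tolerances

The test suite runs entirely on synthetic data at the sizes above (~160
tests, well under a minute of alignment work). Oracle checks use exhaustive
enumeration where feasible: all global alignments for sequence pairs up to
length 8 over a reduced alphabet, quadratic all-pairs interval intersection
on 50 random toy genomes, direct-mean agglomerative clustering on 4×3
matrices. Classifier-recovery tests plant identities ≥ 5 points away from
both thresholds (the ±2-point mutation tolerance plus alignment-definition
slack make closer targets ambiguous by design, not by defect) and require
100% family and ≥ 95% subfamily recovery over 100 queries. Numeric
comparisons use exact equality for counts and rounded statistics, 1e-9 for
NJ branch-length recovery, and byte equality for the determinism contract.
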