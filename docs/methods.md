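# Methods

This note records the models, conventions and numerical choices behind
`mirclust`, and what the synthetic-data generator does and does not
emulate.

## Hairpin folding and the miR\* window

The validation stage needs a base-pairing of the precursor only to count
duplex pairs and place the miR\* window, not free energies. We therefore
fold by Nussinov-style base-pair maximization: dynamic programming over
Watson–Crick plus G·U pairs with a minimum hairpin loop of 3 unpaired
nucleotides (no pair (i, j) with j − i < 4). Ties in the traceback are
broken deterministically (leave the 5′ base unpaired before pairing it;
pair with the smallest admissible partner), so the same sequence always
yields the same structure. An externally computed dot-bracket string
(e.g. from a thermodynamic folder) can be supplied instead and is parsed
into the same pairing structure; energy-model folding is deliberately out
of scope. Sequences with more than 20% ambiguous bases are refused.

Given a miR interval, the miR\* is the contiguous span of its duplex
partners shifted by +2 nt, producing the canonical 2-nt 3′ overhang on
each strand of a Drosha/Dicer product. On a perfect stem this map is an
involution up to the overhangs (applying it twice recovers an interval
overlapping the original miR by ≥ 18 nt of a 22-mer). When fewer than half
the miR positions are paired there is no duplex: criterion 3 fails and the
remaining criteria are still evaluated with an empty miR\* window. A
consequence of the overhang shift worth knowing when constructing
fixtures: on a straight stem of k pairs, k − 2 of the miR's partners fall
inside the shifted window.

## The five validation criteria

A hairpin passes when all five hold: (1) ≥ 1 read on the miR\* window;
(2) ≥ 20 reads on miR and miR\* combined; (3) ≥ 13 miR positions paired
into the miR\* window; (4) the top 3 isomiRs carry ≥ 85% of miR-arm
reads; (5) duplex : background reads > 1. Conventions the criteria
definitions leave open, fixed here: a read "maps to" a window when it
overlaps it by at least 50% of the read length (strict containment is
brittle for isomiRs); an isomiR is a unique (start, length) pair on the
miR arm, ranked by count with ties broken by (start, length) ascending;
the 85% threshold is non-strict (≥); zero background reads give an
infinite ratio and criterion 5 passes; when no miR annotation is given,
the dominant read defines the miR window.

## Dollo dating, age classes and sub-clusters

De novo miRNAs are not expected to arise twice, so gain/loss history is
modelled by Dollo parsimony: a member originates once, at the MRCA of the
species with expression-validated homologs, and may be lost any number of
times. Losses are placed minimally — one loss on the stem of every maximal
subtree (under the origin) whose scored leaves are all absent; this is the
unique minimal placement. Presence means *validated expression*: sequence
homologs without read support count as absent, which is what makes the
dating conservative (a silent homolog is treated as a loss of the
expressed miRNA, not as presence).

A member is *new* when its origin lies inside the subtree rooted at the
reference split's ingroup-side child (inclusive of that child: an origin
exactly at the ingroup child post-dates the split), *old* otherwise. The
ingroup side is named by a species, not a node, so the call is invariant
to re-rooting within the ingroup subtree.

Sub-clusters are maximal single-linkage chains of loci with inter-locus
gaps ≤ `max_gap` (default 1000 nt); overlapping loci are treated as gap 0
with a warning; singletons are orphans.

## Seed innovation and event placement

The seed is mature nucleotides 2–8 (a 7-mer). Differences between two
species' dominant products are classified as: *arm switch* when the arm
differs; *seed shift* when, on the same arm, one seed equals the other
mature sequence read out at a register shifted by up to 5 nt (larger
shifts are not Drosha/Dicer register changes and fall through to
substitution-type divergence, with a warning); *substitution* otherwise.
The dominant product is the highest-count isomiR — a count tie across arms
is refused as ambiguous rather than silently resolved.

Events are placed by small parsimony on the composite (arm, seed) state
over the tree restricted to species bearing the member. All
maximum-parsimony ancestral labelings are enumerated exhaustively (the
restricted trees have a handful of internal nodes and at most a few
states, so enumeration is exact and cheap). When every labeling puts the
changes on the same branches, each change is one resolved event; when
placements differ, the union of candidate branches is clustered by
adjacency and each cluster becomes one event with `resolved = False` and
the full candidate set — e.g. a derived state shared by a cherry against
one outgroup species yields one event on either the cherry stem or the
outgroup branch, which is exactly the ambiguity parsimony cannot break.
The number of events always equals the parsimony score. A change observed
between only two species is never resolvable; three or more species with
an outgroup state are needed.

## Target prediction

Site classes follow the canonical hierarchy, with M the reverse complement
of the seed on the UTR: **8mer** = M followed by A (the A opposite mature
position 1); **7mer-m8** = M alone; **7mer-1A** = M minus its 5′-most base,
followed by A. Each UTR position is reported once under its most specific
class; a flag disables collapsing for class-consistency checks. The
default class set is {8mer, 7mer-m8} — the two strongest canonical
classes — with 7mer-1A available by option; scanning is on the UTR sense
strand only. Expression filtering removes genes with mean TPM across
replicates below 1 (strictly below: a gene at exactly 1 is kept) before
scanning. TPM is computed per sample as the length-normalized count rate
scaled to one million.

The UTR base pairing mature nucleotide 9 — used in the site-composition
analysis — is the base immediately 5′ of the seed match on the UTR
(position p − 1 for an 8mer/7mer-m8 at p, p − 2 for a 7mer-1A), because
the seed pairs the UTR antiparallel with mature nt 8 opposite the match's
5′ end. Sites at the UTR boundary without that context are excluded and
counted.

## Overlap statistics

Cross-species comparison requires an explicit one-to-one ortholog map;
genes without a tuple stay in per-species set sizes but cannot be shared
(this avoids double counting under paralogy). The headline percentage is
shared/union × 100 — the convention under which 6 shared genes out of
sets of 36 and 35 give 9.2% — and shared/|set_s| per species is emitted
alongside, since published Venn percentages do not always state their
denominator. Pooled overlap takes the union over members per species
before intersecting, and attributes every shared gene to the member(s)
targeting it in each species; the pooled shared set is always a superset
of the union of per-member shared sets, strictly larger whenever a gene is
targeted by different members in different species.

## Repression analysis

Replicate columns are averaged before the per-gene log₂ fold change
(treatment over control); genes with a zero mean in either condition are
excluded as non-expressed. The KS comparison of target vs non-target LFC
distributions is two-sided (the repression direction is checked separately
via the median target LFC); p-values use the exact null distribution of D
when min(n) < 10 and the asymptotic Kolmogorov distribution with effective
n = n_x·n_y/(n_x + n_y) otherwise, with a permutation option. The
non-target background is all expressed genes that are not predicted
targets of the focal miRNA (a full-transcriptome background can be
substituted by passing the unfiltered set). Down-regulated targets are
genes with LFC ≤ −log₂(cutoff), cutoff 1.2-fold by default, boundary
included. Fisher's exact test is the standard two-sided hypergeometric
sum; zero margins are rejected rather than reported as p = 1.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs, not
their sequences' biology:

* **Histories** — members originate at configured nodes and are lost on
  configured branches; presence is exact, with no detection noise.
* **Precursors** — perfect-stem hairpins (33-nt arm, 15-nt loop, reverse
  complement arm), so duplex geometry is analytic: the miR\* window of a
  product at offset s is (L − s − m + 2, L − s + 2) for precursor length L
  and mature length m. Scheduled events act root-to-tip: arm switches move
  the product to the partner window, seed shifts advance the register by
  2 nt, substitutions mutate one seed base with a compensatory change on
  the partner strand (preserving the stem).
* **Read profiles** — total depth is negative binomial (mean `depth`,
  size `dispersion`, defaults 1000 and 10); duplex reads split miR : miR\*
  at the configured ratio (default 10); miR-arm reads spread over isomiRs
  within ±3 nt of the canonical product by a Dirichlet-multinomial whose
  mass concentrates on the canonical product (concentration 100 against
  0.1 per off-register variant, giving top-3 isomiR fractions around
  0.95 — comfortably above, but of the same order as, the 85% validation
  threshold); background reads (default fraction 0.02) are 15-mers placed
  uniformly outside both windows.
* **UTRs** — random sequences at 60% AU (fly-like 3′UTRs), default 400 nt;
  non-target genes are rejection-sampled until they contain *no*
  qualifying site of any class for *any* member's seed (preventing
  accidental cross-member targets from corrupting pooled-overlap truth);
  target genes get one exact planted site (8mer by default) and are
  re-drawn if the planting creates a site for another member. Orthologs
  share gene ids across species; a configured fraction of each member's
  planted targets (default 0.5) is planted in every species to create
  known shared targets.
* **Expression** — per-gene lognormal baselines (log-mean 3, log-sd 1);
  treatment means of true targets are divided by the repression factor f
  (default 1.3, the weak-repression regime typical of miRNA targets);
  every measurement carries multiplicative lognormal noise (sd 0.25 on the
  log scale, two replicates per condition). The expected target LFC is
  −log₂ f exactly.

Everything is deterministic given the config seed. What the generator does
*not* emulate — and what passing tests therefore do not demonstrate about
real data: sequence evolution of precursors (events are imposed, not
evolved), mapping artifacts and multi-mapping reads, 3′UTR length/isoform
variation and non-canonical or conserved-context target sites, ortholog
ambiguity, and count-based expression noise (the noise model is
lognormal, not NB sampling of reads).

## Problem sizes and defaults

The shipped experiments use desk-scale sizes chosen to make the
statistical claims sharp while keeping the full suite fast: recovery runs
use 100 seeded configurations on a six-leaf tree; target-recovery runs use
30-gene universes with 3 planted targets per member; the KS calibration
uses 100 targets against 2000 non-targets for 200 replicates, where the
power at f = 1.3 and the type-I rate at f = 1 are measured at α = 0.05.
Genome-scale figures (tens of thousands of genes, full transcriptomes)
are outside what the examples compute, but every operation is linear or
near-linear in the input and runs unchanged at that scale.

## Known limitations

* Base-pair maximization can overpair relative to a thermodynamic fold;
  duplex pair counts near the 13-pair threshold on marginal hairpins are
  the place where a supplied dot-bracket override matters.
* Event placement reports candidate branch sets, not probabilities; it
  cannot weigh branch lengths.
* The 7mer-1A/7mer-m8 nomenclature split for the "second" canonical class
  is resolved in favour of 7mer-m8 as the default companion to 8mer; the
  choice is configurable per run.
* `classify_change` is pairwise; the composite arm-switch-plus-seed-shift
  label only emerges from `summarize_changes` over three or more species.
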