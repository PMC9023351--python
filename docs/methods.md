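# Methods

## The inference problem

Given gene trees with bootstrap supports, a species tree, coding
sequences, gene orders and homologous gene pairs, decide whether one
branch of the species phylogeny carries a whole-genome duplication, and
date it.  paleowgd implements the three classical evidence channels
(duplication mapping, collinearity, Ks distributions) plus the LTR
molecular clock, and a simulator that plants a WGD with known ground
truth so that each channel's recovery can be measured.

## Duplication scoring and mapping (`paleowgd.dupmap`)

A rooted binary gene-tree node is a **duplication** when its two child
subtrees contain genes of at least one common species.  This
species-overlap criterion needs no duplication–loss cost model and is
robust to missing taxa, at the price of missing duplications whose
descendant copies survive in disjoint species sets.

A duplication is **reliable** when (1) the overlap criterion holds and
(2) the node's own support and the support of at least one of its two
children are both ≥ `min_support` (default 50, on a 0–100 bootstrap
scale).  Numerical policies, all configurable:

* leaf children count as support 100 — a single gene is not a
  bootstrap-estimated clade, treating it as certain is the permissive
  reading; an "ignore leaves" mode is available via `leaf_support`;
* absent support values count as 0 (they fail the filter);
* multifurcations are resolved arbitrarily into zero-length branches
  with support 0, so a resolved node can never be called reliable.

Each reliable event is mapped to the species-tree branch subtending the
MRCA of the **union** of the two child species sets: the event cannot
postdate that ancestor.  Branches are identified by the sorted leaf set
of their child node, so identifiers survive any tree rotation.  The
per-branch summary reports both event counts and distinct-family counts
(a family with nested duplications contributes several events but one
family), and, when block evidence is supplied, how many of those
families also have anchors in intra-genome collinear blocks.

Rooting of unrooted input trees is outgroup-first: if the genes of the
configured outgroup species form one side of a bipartition, the root
goes mid-way on that edge; otherwise midpoint rooting is the fallback.
Supports are held on edges through rerooting so they stay attached to
their bipartitions.

## Ka/Ks estimation (`paleowgd.ks`)

NG86 counting, matching the yn00 conventions:

* **Sites.** For each codon position, the three possible single-nucleotide
  changes are examined; changes creating a stop codon are excluded and
  the rest rescaled so each position contributes exactly one site.
  Hence S + N = 3 per codon exactly — asserted to 1e-9 per pair.
* **Differences.** For a differing codon pair, all k! orderings of the k
  differing positions are enumerated; orderings passing through a stop
  are discarded and syn/nonsyn step counts averaged over the survivors.
  If every ordering is blocked (unreachable for sense codons under the
  standard code, but guarded) the average is over all orderings, scoring
  steps into or out of a stop as nonsynonymous.
* **Correction.** pS = Sd/S and pN = Nd/N are corrected with
  Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3).  pS ≥ 3/4 is reported as
  saturated (dS undefined) rather than clipped.  Pathway weighting is
  uniform — the unweighted NG86, not a transition/transversion-weighted
  variant.

Codon alignments are protein-guided: translated proteins are aligned
globally (Needleman–Wunsch, BLOSUM62, gap open −10, extend −0.5) and
codons are threaded back; gapped or ambiguous columns are excluded from
counting.  This replaces an external MAFFT + PAL2NAL step so the package
is self-contained; the aligner is validated against an exhaustive
affine-gap DP oracle.  Identical proteins skip the DP entirely.

The **Ks distribution** keeps defined dS values inside
[`ks_min`, `ks_max`] (defaults 0.01 and 5.0).  The lower bound strips
the zero-inflation produced by alleles and alternative transcripts, the
upper bound strips near-saturated estimates; counts of everything
excluded are reported, never silently dropped.

**Peak detection** runs on ln Ks, where WGD cohorts are closer to
symmetric.  Default: Gaussian KDE with Silverman bandwidth on a
512-point grid padded by 3 bandwidths; modes are interior local maxima
(falling back to the global maximum of a monotone density), and each
pair is assigned to its nearest mode to report per-peak mass.
Alternative: a Gaussian mixture with BIC-selected component count
(1–4); component means give the modes and weights the masses.  Samples
below 50 values yield an "insufficient data" report instead of a peak
call, and a degenerate all-equal sample short-circuits to a single
exact mode.

## Collinear blocks and duplicate classes (`paleowgd.synteny`)

Anchors are homologous gene pairs located on a pair of chromosomes
(self-pairs of a gene with itself excluded).  Chaining maximizes anchor
count by O(n²) dynamic programming under strict monotonicity in both
genomes and a rank gap ≤ `max_gap` (default 25) per step, run separately
for parallel and inverted orientation; the best chain is extracted
greedily, its anchors removed, and chaining repeats until no chain
reaches `min_block_size` (default 5).  Ties go to the earliest-ranked
chain for determinism.  Anchor count replaces MCScanX's e-value block
score; the defaults mirror MCScanX's default gap and size settings.

In a chromosome's self-comparison, pairs closer than
`self_min_distance` ranks (default: `max_gap`) are not used as anchors.
Without this exclusion, runs of tandem duplicates from unrelated
families chain along the diagonal and masquerade as duplicated
segments — the same reason self-comparison synteny tools apply a
"tandem fuzz" near the diagonal.  Two regions closer than the permitted
intra-chain gap are one genomic neighbourhood, not two duplicated
regions.

Duplicate pairs within a genome are then classified with priority
WGD > tandem > proximal > transposed > dispersed:

* **WGD** — anchor of an intra-genome block;
* **tandem** — same chromosome, rank distance exactly 1 (co-family genes
  separated by one intervening gene fall to proximal; configurable);
* **proximal** — same chromosome, rank distance ≤ `proximal_window`
  (default 10, the DupGen_finder convention);
* **transposed** — exactly one member anchors a block against a
  designated reference genome, a deliberate simplification of the
  ancestral-locus test: the syntenic member marks the parental copy.
  Without a configured reference genome the category is unreachable;
* **dispersed** — everything else.

The five categories partition the intra-genome pair list exactly; the
partition is asserted in tests.  `syntenic_ks_pairs` restricts a Ks
table to intra-genome anchors — the cohort whose peak dates the WGD —
and reports per-block median Ks and any anchors lacking an estimate.

## LTR insertion times (`paleowgd.ltr`)

The two LTRs of a retroelement are identical at insertion, so their
corrected divergence K gives the age T = K/(2r); the factor 2 counts
both repeats accumulating substitutions independently.  The default
rate r = 2.2 × 10⁻⁹ substitutions per site per year is the conventional
plant synonymous rate; it is a configurable `ClockParams` field because
applying a synonymous rate to non-coding repeats is itself an
approximation.  K comes from a global nucleotide alignment (match 1,
mismatch −1, gap open −5, extend −1); p is the mismatch proportion over
ungapped columns (gapped columns excluded, the distmat convention) and
the correction is Jukes–Cantor by default with Kimura 2-parameter
behind a flag.  p ≥ 3/4 is a saturation flag, not an exception that
stops a batch: batch output always satisfies
processed + saturated + errored = input.

## The simulator (`paleowgd.simulate`)

What it emulates, and the parameters (defaults in brackets):

* **Species tree**: rooted, ultrametric, `n_species` [8] tips, height
  `species_tree_height` [1.0] (1.0 = root-to-tip); random recursive
  splits with internal node ages uniform within the ultrametric span.
* **Gene families**: one gene at the root; along each species-tree
  branch, background duplication at `birth_rate` [0.05] and loss at
  `loss_rate` [0.05] per lineage per time unit (rates comparable to the
  branch lengths, giving the sparse background duplication counts real
  family sets show).  On `wgd_branch` ("auto": the largest non-root
  clade) at `wgd_time` (branch midpoint by default), every live lineage
  duplicates with probability `retention` [0.3], independently.
  Extinct families are resimulated up to `retry_cap` [100] attempts —
  conditioning on survival, as implicit in any observed family set.
  Supports are 100, with a `support_noise` [0.0] fraction of nodes
  dropped below 50 so the bootstrap filter is exercisable without a
  tree inferrer.
* **Sequences**: `codons_per_gene` [300; ≥30 enforced — shorter genes
  make Ks too noisy for calibration] codons drawn from fourfold-
  degenerate amino acids with no synonymous first/second-position
  changes (Ala, Gly, Pro, Thr, Val, Ser-TCN).  Only third positions
  mutate, Jukes–Cantor at `syn_rate` [0.5] substitutions per synonymous
  site per time unit, amino acids frozen.  Two genes at divergence time
  t therefore have expected Ks = 2·t·`syn_rate` and expected Ka ≈ 0 —
  the Ks channel is isolated and analytically predictable, while the
  nonsynonymous machinery is validated separately against codon-level
  oracles.
* **Gene orders**: one ancestral chromosome, one shuffled slot per
  family.  WGD descendants carry a duplicated copy whose slots are
  deleted with probability `fractionation` [0.3] per species and
  family; deleted genes are pruned from the entire dataset (trees,
  sequences, pairs), which is what fractionation does.  Extra
  background-duplicate copies are placed adjacent to a family member
  with probability `tandem_prob` [0.5], else at a random position —
  populating the tandem/proximal and dispersed classes.
* **LTR elements**: `n_ltr_elements` [50] template pairs of
  `ltr_length` [500] nt, ages uniform on [0, `ltr_max_age_years`
  [5e6]], each repeat mutated independently under Jukes–Cantor at
  `ltr_rate` [2.2e-9] per site per year, so expected K = 2·r·T.

All randomness flows from a single `numpy` generator seeded by `seed`;
a fixed (config, seed) reproduces byte-identical output files, which is
asserted at the manifest-checksum level.

What the simulator does **not** emulate — and therefore what passing
recovery tests do not show about real data: selection on nonsynonymous
sites and codon-usage bias; among-lineage and among-site rate
heterogeneity (real Ks peaks are broader and skewed); allopolyploidy
and homoeologous exchange; tandem-array expansion dynamics;
rearrangements beyond fractionation (inversions, translocations), so
simulated blocks are always same-oriented; gene-tree estimation error
beyond the support-noise knob; incomplete lineage sorting.

## Pipeline and verdict (`paleowgd.pipeline`)

Stages run in dependency order (simulate → blocks/classification → Ks →
duplication mapping → LTR dating → verdict), every intermediate is
written with checksums, and per-stage counts (families, events scored
and reliable, blocks, anchors, Ks pairs retained/saturated/missing) are
carried into the report so nothing is dropped silently.  A failure
leaves a `failed` marker naming the stage.

The literature usually asserts a WGD from joint evidence without a
formal decision rule; the verdict here is an explicit heuristic, and is
reported as such: the branch with the most synteny-supported duplicated
families is named **only if** its duplicated-family count is ≥
`verdict_concentration` [3.0] × the median per-branch family count
(median floored at 1) **and** it has ≥ `verdict_min_synteny_families`
[3] block-supported families; otherwise the verdict is "no supported
WGD".  The reported Ks mode is the largest-mass mode of the syntenic
anchor cohort.

Problem sizes used by the test suite and the acceptance script — 8
species, 200 families with retention 0.3 for recovery; 500 pairs of
2,000 codons at true divergence 0.85 for the Ks peak; 10,000 random
codon pairs for site conservation; 200 instances of ≤12 anchors for
chaining optimality — are the package's own validation choices: large
enough that the planted signal dominates sampling noise, small enough
that the whole suite runs in well under a minute per module.

## Known limitations

* Species-overlap duplication scoring cannot see duplications whose
  surviving copies share no species, and maps events no finer than the
  MRCA of the surviving species — losses can pull an event below the
  true branch.
* The chaining DP maximizes anchor count, not a statistical block
  score; heavily fractionated or rearranged blocks below
  `min_block_size` anchors are invisible.
* The transposed class depends on the choice of reference genome and is
  a coarse proxy for a true ancestral-locus test.
* NG86 with Jukes–Cantor underestimates distances under strong
  transition bias or unequal base frequencies; the package deliberately
  excludes ML codon models.
* The LTR clock inherits whatever rate is supplied; inter-element rate
  variation and gene conversion between LTRs are not modelled.
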