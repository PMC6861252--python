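# Methods

## The system and the question

The E chromosome of *Drosophila subobscura* carries a series of overlapping
inversions.  Five arrangements matter here: the ancestral E_st and the
derived E_1+2, E_1+2+9, E_1+2+9+3 and E_1+2+9+12, formed by the sequential
inversions E1+E2, E9, E3 and E12.  Inversions E1, E2, E9 and E3 share their
most centromere-proximal breakpoint, so one sequence block — fragment A,
split into a proximal section A_p and a distal section A_d — flanks a
breakpoint of every arrangement.  A_d was duplicated when E9 arose, leaving
one copy in the proximal breakpoint region of the derived chromosome (region
AK, later AH2 after E3) and one in the distal GAL region.  The AK/AH2
regions additionally carry a ~500-nt fragment B_p that, in E_st, sits in the
B part adjacent to fragment A but is absent from the corresponding region of
E_1+2.

If every inversion arises by non-homologous end joining (NHEJ) in a single
chromosome, each origin is a unique event: the new arrangement starts from
one haplotype and its breakpoint flank accrues variation only by mutation
(recombination with other arrangements is suppressed near breakpoints;
only gene conversion leaks variation across).  The genealogy of fragment A
should then recapitulate the cytological order of origins.  The package
formalizes the alternative: if E9 arose in an E_st/E_1+2 *heterokaryotype*
and its proximal flank was taken from (or copied off) the E_st homolog, the
AK/AH2 copies of fragment A descend from E_st while the GAL copy descends
from E_1+2 — and the molecular genealogy must disagree with cytology in a
specific, testable way.

## Arrangement model

Chromosomes are ordered proximal→distal lists of atomic oriented fragments
(A_p, A_d, B_p, B_d, G, K, L, H2, F plus neutral fillers W1..Wn).  Breaks
occur only at fragment boundaries, because every break in the mechanisms
modeled is specified between named sections.  Default lengths are notional
(A_p + A_d ≈ the 2-kb sequenced window, B_p = 500 nt) and configurable; no
statistic depends on them.

The canonical fragment orders are one consistent choice among those
satisfying the known adjacency constraints (E_st begins A_p, A_d, B_p, B_d;
E_1+2 begins A_p, A_d, G, keeps K|L adjacent and carries a B_p|F junction;
E_1+2+9 exposes A_p, A_d, B_p|K and G, A_d|L; E_1+2+9+3 replaces B_p|K with
B_p|H2; E_1+2+9+12 keeps both E9 junctions).  One deliberate choice: the F
fragment sits proximal to the K|L junction in both E_st and E_1+2, making
the two homologs identical distal of the E9 distal break.  This is what
lets the three heterokaryotype mechanisms produce literally the same derived
fragment order while differing in provenance and side products — the
property the mechanism comparison rests on.  Region extraction scans for
named windows (AB, AG, AK, AH2, GAL, KL, BF) in either reading direction;
an adjacency involving fragment A that matches no window is reported as an
unknown junction (logged warning) rather than silently named.

Per-arrangement A-fragment copy numbers (1/1/2/2/2) are derived by counting
A-bearing regions structurally, and `expected_a_fragment_count` sums them
over a karyotype table.  The bundled 29-individual heterokaryotype survey is
synthetic: it matches the published constraints of the sampling design
(29 heterokaryotypic individuals across the five arrangements; 36 homologs
with one A copy and 22 with two, hence 80 expected fragments) without
reproducing any individual-level table.

## Origin mechanisms

Six mechanisms produce a candidate E_1+2+9:

* **cut_and_paste** — two breaks (A_p|A_d and K|L) on one E_1+2 chromosome,
  central segment rejoined inverted.  No duplication: the single A_d ends up
  at the distal junction, and no B_p is captured.
* **isochromatid** — two staggered proximal breaks in one chromatid plus the
  distal break; the inter-stagger stretch (A_d) is duplicated at both
  breakpoints, the distal copy inverted.  Three breaks.
* **chromatid** — two breaks in each of two sister chromatids; one sister
  inherits the duplication, the reciprocal sister carries the deletion and
  is flagged non-surviving.  Four breaks.
* **nhej4** — heterokaryotype; staggered proximal breaks on both homologs
  (past B_p on E_st, at A_p|A_d on E_1+2) and a distal break at the same K|L
  boundary on both.  The E_1+2 central segment is rejoined inverted between
  the external E_st pieces; the reciprocal rejoining is a non-surviving side
  product.  Four breaks, all NHEJ.
* **nhej3** — as above but the distal break hits only E_1+2; the derived
  chromosome keeps the E_1+2 distal tail and the leftover pieces form an
  E_st chromosome lacking A_d and B_p.  Three breaks.
* **bir_nhej** — two breaks on a single E_1+2 chromatid; the proximal break
  is repaired by break-induced replication, invading the E_st homolog and
  copying its A_d and B_p before the inverted central segment is joined on;
  the distal break is repaired by NHEJ.  The E_st homolog survives intact.
  Two breaks.

Fragment accounting is exact per mechanism: NHEJ-4/NHEJ-3 conserve the input
multiset across derived + side products; BIR-NHEJ adds one (A_d, B_p) copy
pair; isochromatid adds one A_d to its single input chromatid; the chromatid
model conserves across the two sisters.  The NHEJ-3 and NHEJ-4 derived
chromosomes also differ in the provenance of the distal tail (E_1+2 vs
E_st), a consequence of which homolog contributes the segment distal of K|L;
this does not affect the sequenced A window.

Each mechanism maps to a sister-clade prediction for the sequenced A window
(which lies in A_d): heterokaryotype mechanisms predict {AK, AH2} sister to
AB and GAL sister to AG — for the BIR route too, since the copied proximal
A_d is an E_st copy even though A_p remains E_1+2 — while single-chromosome
mechanisms keep every A-bearing region with AG.

## Synthetic sequence evolution

The generator encodes a mechanism's lineage routing as a structured
coalescent over per-arrangement pools:

* Within a pool, sampled lineages coalesce as a Kingman coalescent with
  effective size `pool_ne` (in time units; pairwise coalescence rate
  1/`pool_ne`).
* At the pool's origin time, all surviving lineages are forced into a single
  founder (the single-haplotype bottleneck) which joins the parent pool:
  AH2 (E_1+2+9+3) joins the E_[1+2+9] complex pool at the E3 origin; the
  complex pool joins E_st (heterokaryotype mechanisms) or E_1+2
  (single-chromosome mechanisms) at the E9 origin; GAL joins E_1+2 at the
  E9 origin; under single-chromosome mechanisms the complex and GAL founders
  first coalesce with each other at the E9 origin, because both A_d copies
  then descend from one founding chromosome.  E_1+2 joins E_st at the E1+E2
  origin.  AK pools E_1+2+9 with E_1+2+9+12 samples (E12 does not touch the
  E9 breakpoints); GAL pools all three carriers.
* An outgroup lineage splits from the ingroup ancestor at the deepest time;
  ingroup lineages still separate there are force-merged (negligibly rare
  at the defaults).

Mutations are Poisson(branch × μ × L) with Jukes–Cantor substitution on a
uniform random root sequence.  Defaults — L = 2000 nt; μ = 0.005 /site/time
unit; `pool_ne` = 1; origin times outgroup = 9, E_1+2 = 5, E_9 = 2, E_3 = 1,
E_12 = 1.5; sample sizes AB 18, AG 6, GAL 10, AK 11, AH2 5 — are artifact
choices fixed by closed-form calibration, since no real divergence times or
rates are available for this window: within-pool diversity is
π ≈ 2·`pool_ne`·μ = 0.01 before origin-time truncation (younger pools are
truncated lower, giving the observed 0.005–0.013 spread), and outgroup
divergence is K ≈ 2·t_outgroup·μ = 0.09 because the Jukes–Cantor correction
inverts the substitution process exactly in expectation.  These land in the
empirically reported ranges (per-region π ≈ 0.006–0.015, K ≈ 0.075–0.096)
by construction, not by fitting.

Gene conversion (default off) is a tip-level approximation: Poisson-many
events copy a random 50–500-nt tract between sampled sequences.  It captures
the homogenizing effect of conversion between arrangements, not the timing
or donor structure of real conversion events.

What the generator does *not* emulate: indel/alignment error (simulated
alignments are gap-free, so deletion filters are exercised by separate
gapped fixtures), double crossovers, demographic change, rate variation
across sites, and the SGM transposable-element insertions that complicated
the real sequencing.  Passing end-to-end tests therefore shows that the
inference chain recovers the lineage routing encoded by a mechanism under
clean neutral evolution at realistic diversity — not that it is robust to
alignment artifacts.

## Statistics

All statistics operate on a labeled alignment over {A, C, G, T, -, N}.

* *Complete deletion* keeps columns with no gap/ambiguity in any retained
  sequence (the default for the polymorphism table); *pairwise deletion*
  compares each pair over its own both-valid columns (available behind the
  `deletion` flag).  Divergence K re-filters columns including the outgroup,
  which is why its site count can be smaller than the polymorphism one.
* π is the mean pairwise difference proportion; S counts polymorphic
  retained columns; a singleton site has some state carried by exactly one
  sequence; a multiple-hit site shows more than two states; h counts
  distinct retained-site haplotypes.  K Jukes–Cantor-corrects the mean
  ingroup–outgroup difference proportion; the correction is undefined at
  p ≥ 0.75 and the code raises rather than extrapolating.
* F_ST is the Hudson-style 1 − π_within/π_between with π_within the
  unweighted mean of the two within-group diversities.  When π_between = 0
  the statistic is undefined and an error state is raised.
* The permutation test shuffles labels without replacement and reports
  p = #{F_ST(perm) > F_ST(obs)}/n_perm (default 10 000), with no +1 term.
  Permutations reproducing the observed statistic exactly are not counted
  against it, so a maximally differentiated configuration reports p = 0.
  **A degeneracy worth knowing:** with *equal* group sizes, 1 − π_w/π_b is a
  monotone function of the integer sum of within-group pairwise differences
  alone (total pair sum is permutation-invariant), so the permutation
  distribution is massively tied and no tie-handling rule is well
  calibrated.  With unequal sizes — every comparison in the intended use —
  ties are negligible and the test holds its nominal level (~5–6% rejection
  at α = 0.05 by exact enumeration).  Calibration tests therefore use
  unequal groups.

## Genealogy inference

* Partial deletion keeps columns with ≥ 95% unambiguous bases (coverage
  configurable); the mask is computed once from the full data and reused by
  every bootstrap replicate (whether to re-mask per replicate is ambiguous
  in common practice; fixing it keeps replicates comparable).
* Distances are Jukes–Cantor on pairwise-complete columns within the mask; a
  saturated pair is an error naming the pair.
* Neighbor joining is the standard Saitou–Nei agglomeration on the Q
  criterion.  Q ties are broken by the lexicographically smallest pair of
  cluster keys (a cluster's key is the smallest leaf label it contains), and
  negative branch lengths are clamped to zero with a warning — both purely
  for determinism and display; topology-level conclusions never depend on
  them.
* Bootstrap supports resample masked columns with replacement (one
  multinomial draw per replicate), rebuild the tree, and report the
  percentage of replicates recovering each full-tree internal bipartition.
  Supports are computed for every internal edge; any ">70%" display cut is
  cosmetic.  A replicate in which some pair has no comparable site is
  dropped; resampled difference proportions are capped just below the
  Jukes–Cantor saturation limit so a borderline replicate perturbs one
  distance rather than aborting the run.
* Rooting splits the outgroup's pendant edge at its midpoint.
* The verdict: find the smallest clade containing all AK and AH2 leaves.  If
  it contains other AB/AG leaves, the genealogy is `unresolved`.  Otherwise
  walk rootward; the first split whose far side carries AB or AG leaves
  decides — only AB → `discordant`, only AG → `concordant`, both →
  `unresolved`.  GAL and outgroup leaves are ignored throughout: GAL's
  predicted affinity is to AG under every mechanism, so it cannot
  discriminate, but it is reported in the tree.

## Design choices and limitations

* The five canonical fragment orders are a model, not genome coordinates;
  no nucleotide-level breakpoint positions or cytological band mapping are
  implied.
* Chromatid vs chromosome scope is a flag on break specifications;
  sister-chromatid DNA is not replicated as a data structure, so the
  chromatid model's sister bookkeeping is implicit.
* Side products of an origin event are retained and flagged (surviving or
  not) so that conservation is testable; the package assigns no viability
  semantics beyond the flag.
* No likelihood or model selection over mechanisms is attempted: the
  mechanisms differ in break counts and repair pathways whose rates are
  unknown, so the package exposes each mechanism's predictions and lets the
  genealogy discriminate the classes (heterokaryotype vs single-chromosome)
  that *are* distinguishable from sequence data.
* Default problem sizes for the stochastic end-to-end checks are 100 seeded
  replicates per mechanism class for verdict rates and 200 trials × 400
  permutations for null calibration — sizes at which the binomial noise is
  well inside the decision margins.
* The neighbor-joining implementation is quadratic per join and intended
  for the study's scale (~50 sequences); it is exact on additive matrices
  (property-tested) but makes no claim of statistical consistency beyond
  what NJ itself provides.
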