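# Methods

`longevol` implements a four-stage evolutionary screen relating the
molecular evolution of a gene network to mammalian longevity: (1)
longevity-quotient classification of species, (2) per-lineage positive
selection tests under codon substitution models, (3) phylogenetic
regression of evolutionary rate on life-history traits, and (4) a scan for
convergent amino-acid substitutions shared by independent long-lived
lineages.  A synthetic-data generator reproduces the statistical structure
of each stage's inputs so the whole screen is testable without genome
downloads.

## Longevity quotients and the cohort partition

The longevity quotient is LQ = MLS / (6.32 · BM^0.139), with MLS the
maximum lifespan in years and BM the adult body mass in grams; the
constants come from the mammalian lifespan–mass allometry and are treated
as fixed, not refit.  Body mass must be supplied in grams — the published
reference values (LQ 3.91 for a 34-year, 10-gram bat; LQ 2.86 for a
54.8-year, 2.9-kg capuchin) only reproduce under that unit, and both are
pre-build oracle checks in the test suite.

A cohort is split at mean(LQ) + 1 SD.  Choices a user may care about:

- the SD is the sample standard deviation (n−1), toggleable via ``ddof``;
- the comparison is strict (LQ > threshold); ties go to the control group;
- the cohort mean is not renormalised to 1;
- species present in alignments or the tree but missing trait data are
  excluded from the partition with a warning, never silently imputed.

## Codon models

All models use the Goldman–Yang parameterisation: the rate from codon i to
j is zero unless they differ at one position, otherwise
π_j · κ^[transition] · ω^[nonsynonymous], reversible with respect to the
codon frequencies π.  π defaults to F3x4 (position-specific nucleotide
frequencies of the alignment, floored at 1e-10 and renormalised); a
uniform-π option exists for controlled experiments.  Generators are scaled
so branch lengths are expected substitutions per codon; mixture models
share one scaling constant, the background-mixture-averaged rate, so all
site classes run on a single clock.  exp(Qt) is computed through the
symmetrised eigendecomposition that reversibility guarantees, with
scaling-and-squaring as a fallback.

Model menu: M0 (single ω); M8/M8a (ten equal-probability beta(p,q)
categories on (0,1) plus one class with ω ≥ 1, pinned to 1 in M8a);
branch-site model A and its null (classes 0, 1, 2a, 2b; ω₂ applies on
foreground branches only and is pinned to 1 in the null); a three-class
episodic model in the spirit of BUSTED (ω₁ ≤ ω₂ ≤ 1 shared everywhere, a
third class neutral on the background and ω₃ ≥ 1 on the foreground;
synonymous rate variation is deliberately out of scope); and a free-ratio
model (one ω per branch, shared κ).

Likelihoods are computed by Felsenstein pruning over the 61 sense codons
with per-node rescaling, site-pattern compression, and gaps/ambiguities
treated as missing data.  Equality with exhaustive summation over internal
states is asserted on 3- and 4-taxon trees to 1e-6.

### Optimisation

Free parameters are optimised by bounded L-BFGS-B in transformed space
(log for κ ∈ [0.1, 20] and ω ∈ [1e-4, 50], softmax logits for class
proportions, log for beta shapes ∈ [0.005, 100]), with fixed restart seeds
(0, 1, 2) so fits are reproducible; a fit that never reports convergence
is flagged, never silently returned.  Branch lengths are estimated once
per gene under M0 — alternating a quasi-Newton step in (κ, ω) with a Brent
line search per branch — and held fixed for every other model of that
gene.  This keeps each mixture fit low-dimensional and leaves model
nesting intact.  The practical cost, documented rather than hidden: when
the foreground is a short terminal branch, foreground substitutions are
partly absorbed into the M0 length estimate, which lowers branch-site
power (it does not inflate false positives).  Alternative-model fits are
warm-started from their null's optimum with the extra ω at its boundary,
which enforces the nesting inequality numerically.

Nested-pair statistics are referred to: a 50:50 mixture of χ²₀ and χ²₁ for
the branch-site test (the asymptotic null when ω₂ sits on the boundary;
the plain-χ²₁ conservative convention is available via
``lrt(..., boundary_mixture=False)``), χ²₁ for M8 vs M8a, and χ²₂ for the
episodic test (a conservative bound for its composite null).  A 2ΔlnL
below −1e-4 raises an optimiser-failure error instead of producing a
p-value.

### Site identification

Positively selected sites are reported from an empirical-Bayes posterior
that a column belongs to an ω > 1 class, averaged over a uniform 5-point
grid per parameter spanning ±2 standard errors (from the numerical
Hessian, capped) around the MLE of the class-proportion logits and the
positive ω.  This grid integration is a coarse stand-in for full
hierarchical-prior BEB; the cutoff semantics (posterior > 0.80, strict by
default with a ``strict=False`` toggle) are preserved.

### Free-ratio dN/dS bookkeeping

Each branch's length is apportioned into dN and dS by the nonsynonymous
flux fraction of its fitted generator, so dN + dS equals the branch length
exactly and root-to-tip ω is the ratio of path-summed dN to path-summed
dS.  A tip whose whole path has dS = 0 gets a missing ω and is dropped
pairwise from regressions.  Branches of length ~0 carry an unidentifiable
ω recorded as 1.  Note the two branches meeting at the root of a two-tip
tree are jointly unidentifiable under a reversible model; per-branch ω is
only meaningful where other taxa anchor the ancestral states.

## Testing, FDR and the candidate rule

Branch-site and episodic tests run per long-lived lineage (terminal
branches by default; clade foregrounds via the groups file and
``foreground_mode: clades``).  Benjamini–Hochberg q-values are computed
across all gene × lineage tests within each method (``fdr_scope: method``;
``global`` pools everything), significance at q < α = 0.05.  The
control-group M8 vs M8a contrast runs on the alignment and tree restricted
to control species (the pruned tree keeps the M0 lengths, summing through
removed unifurcations) and is judged at raw p < α.  A gene is a candidate
iff both branch-site-style tests are significant for at least one
long-lived lineage and the control-group site model shows nothing; a
missing control result is an error, never assumed non-significant.

## PGLS with Pagel's lambda

Root-to-tip ω (and MLS, BM, LQ) are log10-transformed; the residual
covariance is σ²V(λ) with V(1) the Brownian matrix of shared root-to-MRCA
path lengths and λ scaling off-diagonals only.  λ is profiled by ML on a
0.01 grid refined by bounded scalar search, closed at [0, 1].  R² is
computed against a GLS intercept-only null at the fitted λ (GLS-weighted
mean), clipped at 0 with a flag if negative; the slope p-value is a t-test
with n − 2 df.  Near-singular V (effectively duplicated tips) gets an
escalating diagonal jitter (1e-8, then 1e-6 of the mean diagonal), logged.
Association calls use raw p < 0.05, matching how such screens report this
stage; a BH column is emitted alongside.

## Convergence scan

A column is convergent when some residue occurs in ≥ 2 distinct long-lived
groups (one carrier per group suffices by default; a strict all-members
mode exists) and every ungapped control species carries a different
residue.  Gapped controls are uninformative and do not veto; a column
where more than half the controls are gapped is flagged low-confidence.
No ancestral-state reconstruction is attempted, so parallel and convergent
origins are not distinguished — a documented limitation shared with the
screening tools this mirrors.  Expanded-panel verification recomputes each
extra carrier's LQ from the expanded trait table: all extra carriers must
exceed the cohort threshold, one control-like carrier rejects the site,
and a carrier without trait data leaves verification indeterminate.
Positions are reported 1-based, in the original (pre-cleaning) alignment
coordinates, and additionally in the reference species' ungapped protein
coordinates where a reference is configured; mapping onto a reference gap
is an explicit error carrying the nearest mappable position.  Domain
placement is interval membership on 1-based inclusive reference
coordinates, all overlapping domains reported.

## Alignment cleaning

The block filter drops codon columns whose gap fraction exceeds
``max_gap_fraction`` (default 0 — no gaps allowed) or where no amino acid
is shared by a strict majority (≥ 50% + 1) of species; ``min_block``
optionally removes retained runs shorter than a given length.  This is a
simplified, auditable stand-in for the conventional block-filtering step
of such pipelines, with the retained intervals written to the cleaning
report; externally cleaned alignments can be supplied directly.  Mixed
base/gap codon cells are gap-masked with a warning; ambiguity codes become
missing data for the likelihood and 'X' in translations; a terminal stop
column is trimmed and internal stops are a frame error.

## Synthetic data

The generator and the likelihood engine share the same GY94 generators, so
simulation truth is exactly the inference model's data-generating process.
Alignments are evolved by event-level (Gillespie) simulation per site and
branch, recording realised synonymous/nonsynonymous event counts and
site-class assignments.  Trees are pure-birth, rescaled to a mean
root-to-tip path of 0.3 substitutions/codon and floored at 1e-3 of that so
sister tips never coincide.  Traits: Brownian motion on log10 body mass
(root 3.5 ≈ 3 kg, tip sd 1.5 log10 units, i.e. tens of grams to tonnes);
log10 MLS = allometric intercept + 0.139·log10 BM + correlated noise with
λ = 0.5 phylogenetic signal.  The noise sd (0.29 log10 units, with the
lognormal mean correction folded into the intercept) is calibrated so a
related 48-species cohort realises a sample LQ sd near 0.57 and mean near
1 — the shape of a broad mammal panel; the realised mean+1SD threshold
then lands near 1.5.  What the generator does not emulate: indels and
alignment error, selection-strength heterogeneity across genes beyond the
planted classes, body-mass measurement error, and the heavy bat-driven
right tail of real LQ distributions — so passing tests demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to real-data violations of them.

One integer seed drives every stream through a ``SeedSequence`` splitting
scheme; the same seed yields byte-identical bundles, and the bundled
``truth.json`` records every planted signal.

## Problem sizes

Simulation-backed checks run at desk scale, chosen as the smallest designs
at which the measured quantities are statistically meaningful: codon-model
recovery at 16 taxa × 300 codons (10 replicates), the branch-site type-I
experiment at 6 taxa × 100 codons (40 null replicates against the
[0.01, 0.10] band at nominal 0.05), BEB site recovery at 12 taxa × 200
codons, PGLS recovery at 48 species × 20 replicates, and the end-to-end
study at 8 tips × 60 codons × 6 genes, run twice to assert
checksum-identical outputs.

## Known limitations

- Branch-site power against short terminal foreground branches is limited
  by the fixed-M0-branch-length design (see above).
- The episodic model omits synonymous rate variation and BUSTED's full
  random-effects structure; its χ²₂ reference is conservative.
- Grid-BEB approximates, and can smooth over, the full BEB posterior when
  the likelihood surface is strongly non-quadratic.
- The convergence scan is pattern-based; it cannot separate convergence
  from identity by descent through incomplete lineage sorting, and does
  not model alignment error.
- λ is restricted to [0, 1]; no OU or other correlation structures.
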