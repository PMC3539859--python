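# Methods

This note documents the models, estimators and numerical choices behind
`aflpop`, and what the synthetic-data generator does and does not
emulate.

## Clone calling from dominant fingerprints

Dominant markers score each fragment as band present (1) or absent (0);
heterozygotes are invisible, so clonemates can only be recognised by
near-identity of the whole fingerprint.  The operational definition used
throughout the package is:

* The **genotyping error rate** `e` is estimated from replicate
  re-extractions: the number of genotype mismatches divided by (number of
  replicate pairs × number of loci).  The denominator deliberately uses
  the *full* locus count even when some replicate cells are missing
  (mismatches at half-missing loci are not counted), so the printed
  arithmetic of the estimate is exactly `mismatches / (pairs × loci)`.
  This makes `e` a slightly conservative (downward-biased) estimate when
  missingness is appreciable; at the missingness levels of scored AFLP
  data (<1%) the effect is negligible.
* The **pairwise mismatch** `d(i,j)` is the fraction of differing bands
  over loci scored in both samples (pairwise deletion).  Pairs with no
  jointly scored locus are undefined, reported as missing with a warning
  and excluded from clone calling.
* Two samples are **clones** when `d(i,j) < e` (strict inequality —
  "below" the error rate).  Clonal lineages are the connected components
  of this relation (single-linkage closure).  Clonehood as measured is
  not guaranteed transitive; triples where a–b and b–c are clone pairs
  but a–c is not are flagged in the output rather than broken, because no
  principled tie-break exists at this measurement scale.

Raising the threshold can only merge components, never split them, so
the number of lineages is monotone non-increasing in the threshold — a
property the test suite asserts.

## Diversity statistics

Per group the package reports polymorphic fragments (present *and*
absent among scored members), fixed fragments (present in every scored
member), and private fragments (present in the group, absent outside
it).  Percentages are always relative to the full locus count.  Note the
three classes do not partition the locus set (a fragment can be, e.g.,
absent from the group entirely); the output reports the explicit
three-way split rather than forcing the classes to add up.

Nei's gene diversity is computed on band-phenotype frequencies:

    h_l = n/(n−1) · (1 − p_l² − q_l²),   Hj = mean over loci,

with `p_l` the presence fraction among the `n` scored members.  This is
assumption-free for clonal material, where Hardy–Weinberg
back-transformation of dominant phenotypes is not defensible; a
square-root (pure-recessive) allele-frequency variant is available via
`allele_freq=True` for comparison with sexual populations.  The n/(n−1)
small-sample correction can push `h_l` above 0.5 (up to 1.0 at n = 2 and
p = 0.5); no cap is applied.  SD and variance of `Hj` come from a seeded
bootstrap over loci (1000 replicates by default), with Var = SD² by
construction.

Rare fragments: the frequency of a fragment in an area is its presence
fraction among that area's scored samples; a fragment is *rare* at
threshold `t` (default 0.15) when its frequency is below `t` in every
area where it occurs.

## AMOVA

Distances are squared Euclidean on the 0/1 band vectors — i.e. the
mismatch count over jointly scored loci — the standard choice for AFLP
AMOVA (a flag substitutes Nei–Li distances).  Sums of squares use the
distance-based identity `SS(set) = Σ_{i<j} d²_ij / |set|`; variance
components come from the expected mean squares with unequal group sizes
(coefficients n, n′, n″ in the two-level design).  Negative variance
components are reported raw in the σ² column; for the percent-variance
display they are truncated at zero (disable with
`truncate_negative=False`).  φ_ST is among-group variance over total
(plus φ_CT/φ_SC in two-level designs).  Permutation p-values permute
sample labels at the tested level and use `(count ≥ observed + 1) /
(n_perm + 1)`; exact ties count toward the numerator.  When the data
carry no molecular variance at all, φ is undefined (NaN) and the
permutation p is reported as 1 (nothing to reject).

## Ordination

PCoA is classical metric scaling: double-centre `−½·d²`,
eigendecompose, scale eigenvectors by the square root of their positive
eigenvalues.  Percent variance per axis is taken over the
positive-eigenvalue sum; negative eigenvalues (expected for the
non-Euclidean Nei–Li coefficient) are counted and reported, not
corrected, by default — a Lingoes additive correction is available
behind a flag.  Group tests on coordinates run per axis (axes 1–3 by
default): Mann–Whitney U with average-rank ties and the normal
approximation for two groups, Kruskal–Wallis beyond.

## Crossing groups and mate availability

A population pair is **incompatible** when at least one flower was
tested (configurable minimum) and not a single seed was set, reciprocal
directions pooled — capsule formation without seeds does not confer
compatibility, and one seed suffices for compatibility (seed *counts*
feed the trait analyses, not the partition).  Crossing groups are the
connected components of the incompatibility graph; compatible pairs
falling inside one component are reported as conflicts; populations with
no flowering records remain "unknown" and are never forced into a
group.  Intra-population crossings that set no seed are recorded as
self-incompatibility confirmations.  Mate availability is the fraction
of unordered grouped-population pairs whose members lie in different
groups.

## Traits and correlations

Pollen per flower uses the dilution estimator: the mean of the ten 1-µl
aliquot counts times the dilution factor (1000).  The P/O ratio divides
that total by the flower's ovule count.  Seed size is analysed as the
per-capsule mean width (capsules, not individual seeds, are the unit).
Viability uses the three-class vocabulary viable/abnormal/dead; every
reported fraction carries its numerator and denominator.  Group
comparisons use rank tests (Mann–Whitney, Kruskal–Wallis); the package
deliberately stays non-parametric — mixed-model or GLM refinements are
left to downstream statistical software.

The correlation suite computes Spearman rank correlations for a fixed
pair list linking trait summaries to genetic indices, reporting raw
two-sided p-values alongside a Holm-adjusted column.  The
geographic–genetic distance association uses great-circle (haversine)
distances from decimal-degree coordinates and a Mantel-style test —
rows and columns of one matrix permuted together, preserving symmetry
and the zero diagonal — because distance pairs are not independent
observations.

## The synthetic colonization scenario

The generator emulates the data streams of a clonality study on an
introduced self-incompatible creeping plant.  Its default scenario is
fixed at the study scale: 20 introduced populations on a ~150 km
transect (93 samples) plus 3 native populations (15 samples), 294 loci
of which 4 are universally fixed and 45 occur only in the native area
(40 of them planted below the 0.15 rarity threshold), 9 replicate
pairs, five planted crossing groups of sizes 13/3/1/1/1 plus one
population that never flowers, and ten multi-member clonal lineages
covering 54 of the 93 introduced samples (58.06%), one of which spans
eight populations.

Key model choices:

* **Founder pools.**  Each introduction is a bottleneck: a single
  ancestor band genotype, from which every founder diverges by a fixed
  per-locus flip rate (8% by default).  Founders of one introduction
  therefore share most bands — the genetic signature of a handful of
  closely related imported plants — which is what gives per-population
  fixed-fragment counts their smooth dependence on the number of
  distinct resident genotypes.  Native samples are instead drawn
  independently from diverse regional frequency profiles.
* **Somatic mutation** is a symmetric 0↔1 band flip accumulated over a
  population's clonal age (generations), applied per sample.
* **Scoring error** has two components: a per-scoring flip rate applied
  to every scoring event (0.002 by default), and an *extra* flip rate
  applied only to replicate re-extractions (0.0425), putting the
  replicate-based error estimate in the ~4.6% regime.  The split is
  deliberate: if every scoring carried the full error rate, a
  within-clone pair would have expected mismatch at least equal to a
  replicate pair's — i.e. exactly at the clone-calling threshold — and
  threshold-based clone recognition could not work, for this or any
  dataset.  Replicate-based error estimates are dominated by
  re-extraction noise (DNA quality, PCR stochasticity), which ordinary
  sample-to-sample comparisons of good primary extractions do not incur;
  the generator encodes that asymmetry explicitly.
* **Incompatibility rule**: identical unordered S-genotype ⇒ zero seeds;
  any allele difference ⇒ seeds.  This is the inference rule the
  crossing analysis itself uses, so recovery is exact by construction
  when all pairs are tested; the simulator is not a model of the true
  (unknown) SI mechanism and does not attempt partial compatibility.
* **Mutation load** is a latent per-sample scalar, Poisson-distributed
  with mean proportional to the population's clonal age; clonal age in
  the default scenario increases with the planted clonal fraction, which
  couples load to clonality.  All trait decays are driven by this one
  scalar: pollen = baseline · (1 − decay)^load; mutant-flower
  probability = logistic in load; seed death probability and germination
  logistic in the mother population's mean load; seed width linear in
  load.  Setting the decays to zero (`ratchet_off`) severs every
  trait–genetics link while leaving the genetic structure intact — the
  negative control used in the tests.

What the generator does **not** emulate: linkage or homoplasy among AFLP
fragments (loci are independent), peak-intensity scoring ambiguity
(error is a symmetric flip), pollinator behaviour and seed dispersal,
real S-locus genetics (dominance hierarchies, partial compatibility),
and native-range demography (native samples are independent draws, not
a coalescent).  Passing the recovery tests therefore shows the pipeline
is correct and well-calibrated under its own assumptions — not that
those assumptions hold for any particular field dataset.

## Problem sizes and determinism

Simulated datasets are 117 × 294 (108 primary samples plus 9 replicate
re-scorings) and simulate in ~30 ms, so the test suite validates
end-to-end recovery over several master seeds, permutation-test
calibration over 500 null replicates at 99 permutations each, and the
documented worked examples, in well under a minute of compute.  All
randomness flows from a single `numpy` Generator seeded by the
user-supplied seed; identical configuration plus seed reproduces every
table bit for bit.

## Known limitations

* The error-rate denominator convention (full locus count) and pairwise
  deletion are documented choices; with heavy missingness other
  conventions give materially different thresholds.
* Single-linkage clone calling can chain distinct genets through
  intermediate samples in dense datasets; the flagged-triples output is
  the diagnostic for this.
* Hj at very small n (2–3 scored samples) exceeds the two-state
  theoretical maximum of 0.5 by construction of the unbiased correction;
  compare groups of similar size.
* The FAMD-style two-row dominant export uses a documented coding
  (present = one dominant allele + one unknown), not a reproduction of
  any particular external tool's convention.
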