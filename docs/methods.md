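# Methods

This note records the models implemented in cyclehic, the parameter
defaults and why they hold, what the synthetic generator emulates, and the
numerical choices made where the design was genuinely open.

## Contact maps and normalisation

A `ContactMap` is a genome-wide symmetric sparse matrix over fixed-width
bins; `total_contacts` is the upper-triangle sum. Balancing is iterative
correction (ICE) per chromosome to an equal-cis-margin fixed point
(tolerance 1e-6 on the relative margin spread, at most 500 iterations;
non-convergence is flagged on the result, never silent). We use ICE rather
than a literal Knight–Ruiz solver: both converge to the same doubly
balanced matrix, and ICE is simpler to reason about. Bins whose raw cis
marginal falls below 2 % of the chromosome median (of non-zero marginals)
are masked before balancing; this prevents weight blow-up on
near-empty rows and is standard practice. Weights are rescaled so the
balanced cis sum equals the raw cis sum, keeping "expected counts" on the
raw-depth scale.

The expected profile is the per-distance mean of the (by default,
balanced) signal, excluding masked bins. The working quantity everywhere
downstream is the pseudocounted distance-normalised signal

    z(i, j) = (observed(i, j) + 1) / (expected(|i - j|) + 1),

which is defined on zero-count pixels (z = 1/(expected+1)) and identically
1 when observed matches expected on every diagonal. Whether the
pseudocount formula sees balanced or raw signal is a flag
(`use_weights`, balanced by default); results at toy scale are
insensitive to the choice because balancing weights are near 1.

Equal-depth comparison uses exact multivariate-hypergeometric
downsampling at the contact level: the target total is hit exactly and
every cell keeps an expectation proportional to its original count.

Replicate distances are Euclidean distances on log2 z over the union of
informative cis pairs, embedded by classical MDS. "Informative" means
separations whose expected signal is at least 20 contacts
(`informative_max_dist`); beyond that the per-pair shot noise swamps any
replicate structure and the distances degenerate toward a common constant.

## Compartments

Per chromosome: balanced map → observed/expected → Pearson correlation
over unmasked bins → eigenvector of the largest-magnitude eigenvalue.
The sign is oriented so the track correlates positively with an activity
proxy (ATAC-peak count per bin by default, TSS density as fallback);
without a proxy the track is returned unoriented and flagged.
Eigenvectors are scaled to unit standard deviation before any comparison:
an absolute difference threshold presupposes comparable scales, and
unit-SD makes the quartile interpretation reproducible across samples.

Differential rule: a bin is flagged when |e_A − e_B| > τ, default
τ = 0.42 (a shift of about one quartile). `tau="auto"` derives τ as the
interquartile range of the pooled eigenvector distribution — the plain
reading of "moved from one quartile to another". Differential bins are
counted singly (no contiguity requirement), and the spanned Mb is the
bookkeeping identity `flagged bins × bin size`.

Group comparisons (X vs autosomes) use a two-sided Wilcoxon rank-sum on
per-bin |Δe| (scipy's exact small-sample path engages automatically).
Direction concordance between two condition contrasts restricts to bins
flagged in either contrast and reports the sign-agreement fraction plus a
Spearman correlation; with no flagged bins the quantity is reported as
undefined rather than NaN-propagated.

## Loop calling

The caller is a declared re-implementation of the *contract* of punctate
loop callers (Gaussian σ = 1 smoothing, regional maxima, local-background
significance, BH at FDR 0.01, span cap 2000 bins, minimum separation
5 bins), not a port of any specific tool. Internals:

- **Background.** The background at a pixel is the maximum over five
  local estimates of mean z: an inner 5×5−3×3 annulus, an outer
  (2·window_r+1)²−5×5 annulus, horizontal and vertical bands at offsets
  2..5 bins, and the immediate 3×3 ring. The max-of-filters construction
  (in the spirit of HiCCUPS' donut/band filters) matters on plaid maps:
  at compartment-block corners every wide filter mixes A and B parity and
  underestimates the local rate, which floods the caller with
  false foci; the immediate ring stays parity-correct there.
- **Candidates.** 3×3 local maxima of the smoothed z whose smoothed value
  exceeds 1.2× the local smoothed background. A tight footprint keeps
  punctate foci detectable next to compartment edges; the relative floor
  replaces an absolute one, which would suppress real loops sitting in
  B–A contact depletion.
- **Significance.** Observed raw count vs Poisson with mean =
  background·(expected+1)−1. Because each candidate is by construction
  the maximum of its 3×3 footprint, the p-value is Šidák-corrected for
  the footprint size. Benjamini–Hochberg then runs with the family size
  set to *all examined local maxima*, not only floor-passing candidates:
  the floor is a computational screen, and shrinking the BH family to the
  screened set anti-conservatively inflates discoveries.
- **Enrichment guard.** Pixels with pseudocounted observed/background
  below 2.0 are discarded regardless of p; at high depth, tiny model
  misfits become "significant" without being loops.

These internals were fixed by calibrating on null simulations (planted
checkerboard, no loops) and recovery runs before the acceptance tests
were frozen; on 20-seed nulls the caller is empty in ≥ 95 % of maps and
pooled empirical FDR on planted worlds stays within 2× nominal.

Master merging is single-linkage clustering of loops whose anchors both
lie within 25 kb, represented by the highest-z member; it is idempotent.
Differential z is read per condition as the maximum over the 3×3
neighbourhood of the master pixel (absorbing 1-bin peak drift between
samples, mirroring the 25-kb merge tolerance), and the rule is
max z > 2 and fold ≥ 2.5, with fold computed on the pseudocounted z
values directly (no further pseudocount). A consequence of the 3×3-max
read worth knowing: in the weaker condition the max over nine background
pixels biases the denominator upward, so fold changes of loops sitting in
depleted (cross-compartment) neighbourhoods are conservative.

APA is the element-wise mean of (2h+1)² z-windows centred on the supplied
pixel pairs (default h = 10; sites nearer than h to the diagonal or edges
are excluded); the score is the centre pixel, with a centre/corner ratio
as a secondary column since "APA score" has both conventions in the
field. Insulation is log2 of the sliding window×window square bridging
each bin over the chromosome-wide mean of such squares (default window
20 bins); domain aggregates rescale each region (with half-length flanks)
onto a common grid and average.

## Interactions

Significance is a deliberately simplified one-pass Fit-Hi-C: cis pairs at
separations 2..2000 bins are grouped into up to 100 equal-contact-
occupancy distance strata (empty strata collapse into neighbours); the
per-stratum contact probability is stratum sum / (N·pairs); each pair is
tested upper-tail Binomial(N, p̂) and BH runs over the *full* family
(zero-count pairs enter with p = 1); q < 0.05 is kept. No spline
refinement and no bias regression — the analysis chain this package
exists for is the q-threshold → loop-exclusion → classification →
differential sequence, and the simplification is calibrated: on
uniform-decay nulls the significant fraction stays within 2× the nominal
q cutoff. Note that on compartmentalised maps the distance model is
genuinely mis-specified (same-compartment pairs are enriched relative to
the distance mean), so large significant sets on such maps are expected
and real; they land in the "other" category unless they touch annotated
bins.

Loop exclusion drops any interaction whose anchors both lie within 20 kb
of some called loop's anchors (anchor-pair distance, sorted orientation —
the pixel-vs-anchor ambiguity is resolved toward anchors and recorded
here). Classification: a promoter bin contains ≥ 1 TSS; an enhancer bin
overlaps ≥ 1 ATAC peak whose closest edge is strictly > 10 kb from every
TSS and itself contains no TSS; E–P / E–E / P–P by the bin pair, all else
"other" (kept for FDR accounting, excluded from E–P summaries). Gene
connectivity counts distinct enhancer bins linked to each gene's promoter
bin(s), binned {0,1,2,3,4,5,>5}; set-overlap tests are upper-tail
hypergeometric.

## Expression integration

X escapees: female TPM ≥ 1 and female/male ratio ≥ 1.5 (both inclusive),
ranked by ratio. The rule is read one-sided — escape means expression
from the inactive X, i.e. females above males; a two-sided reading would
conflate escape with male-biased expression. A male TPM of 0 takes a 0.01
pseudocount, declared in the output. "Female" is a single named group,
not an average across female groups, so dioestrus and proestrus can be
tested separately. Expression-matched controls are the k nearest pool
genes in log10 TPM, assigned greedily in target order without
replacement; the pool must be disjoint from the targets, so a target can
never be its own control.

## The synthetic world

The generator realises cell probabilities
p(i,j) ∝ max(d,1)^−α · (1 + γ·e_i·e_j) · m(i,j) and draws each
replicate as one multinomial of fixed total depth — not independent
Poisson cells — so equal-depth comparisons are exact by construction,
mirroring the equal-depth downsampling applied to real libraries.
Defaults: two chromosomes (one autosome, one X) of 500 bins at 10 kb,
depth 2e6 per replicate, α = 1, γ = 0.4, square-wave compartments of
40-bin period (jitter off by default, so truth is crisp), cis-only
(trans is exercised explicitly at a planted rate when the trans fraction
itself is under test), three replicates per condition.

Loops multiply single cells (punctate); interactions multiply a 3×3 patch
(diffuse) — deliberately, because that is the signal-shape distinction
that lets a punctate caller and a distance-model caller coexist on the
same map, exactly as CTCF loops and E–P contacts do in real data.
Condition effects are sign flips of e over windows and per-element fold
overrides; replicate variation is sampling only. Matching annotations are
emitted: one TSS per promoter bin, ATAC peaks at enhancer bins (placed
> 10 kb from every TSS), ATAC + convergent CTCF motifs (+ left, − right)
at loop anchors, and a TPM table in which expression scales with planted
enhancer connectivity and five X genes are planted escapees.

In the standard demo world the anchors sit at compartment-block centres
and outside the condition flip windows, and the differential elements sit
on same-parity anchor pairs. These are deliberate benchmark choices, not
cosmetics: an anchor on a block edge confounds focal and compartmental
signal, an anchor inside a flip window makes a loop genuinely change
through the compartment effect (the caller then flags it, correctly, but
the truth table would call it a false positive), and cross-parity
differential elements meet the conservative bias of the 3×3-max read
described above.

What a green test does **not** establish: the generator has no
restriction-fragment or ligation artefacts, no copy-number or mappability
structure, no haplotype-resolved Xa/Xi (the X flip emulates the *mixed*
eigenvector shift a bulk female sample shows), no TAD hierarchy beyond
the planted checkerboard, and replicate variability is pure counting
noise — real biological replicates over-disperse. Calibration and
recovery results transfer to real data only to the extent those factors
are handled upstream.

## Pipeline

`run_all` chains: per-replicate QC distances → replicate combination →
equal-depth downsampling to the smallest condition → balancing →
compartments (native bin size; the synthetic world is single-resolution,
whereas the published analyses used 25 kb for compartments and 10 kb for
loops — with real multi-resolution inputs, load each resolution
separately) → loops → master merge → differential loops → interactions
(on the pooled equal-depth map) → exclusion → classification →
differential interactions → gene connectivity → escapees. Differential
stages compare the first two conditions; a third condition contributes
the direction-concordance contrast. All thresholds default to the
published values (τ 0.42, loop FDR 0.01, merge 25 kb, z > 2, fold ≥ 2.5,
q < 0.05, exclusion 20 kb, enhancer > 10 kb, TPM ≥ 1, fold ≥ 1.5); every
run is deterministic given the seed, every reported number is also
written to a machine-readable table, and a stage failure raises with the
stage name.

## Known limitations

- The loop caller's Poisson model ignores overdispersion beyond what the
  multi-filter background absorbs; on real (biologically noisy) data the
  nominal FDR will be optimistic.
- The interaction model has no per-bin bias regression; balancing weights
  enter only through the expected profile.
- Insulation and domain aggregates are summaries, not a TAD caller; no
  boundary significance is attached.
- `merge_master`'s clustering is O(n²) per chromosome — fine for
  thousands of loops, not for millions of candidate pixels.
- The quartile threshold τ = 0.42 is taken as a constant of the analysis;
  on unit-SD eigenvectors its quartile interpretation holds only
  approximately for strongly non-Gaussian compartment profiles (the
  "auto" mode re-derives it from the data at hand).
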