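# Methods

## The model

A cancer specimen is a mixture: a fraction *p* of tumor cells (purity)
and 1−*p* of diploid normal cells.  A genomic segment present at integer
copy number *C* in the tumor contributes *pC* + 2(1−*p*) chromosome
copies per cell on average; the tumor ploidy Ψ = Σ lᵢCᵢ / Σ lᵢ is the
length-weighted mean copy number and defines the coverage baseline.  Two
observables carry the copy-number signal:

* the per-bin **log-ratio** of tumor to process-matched-normal coverage,
  Gaussian around log2[(pC + 2(1−p)) / (pΨ + 2(1−p))] with per-bin
  scatter σ_r;
* the **minor allele fraction** of heterozygous genome-wide SNPs, Gaussian
  around (pM + 1−p) / (pC + 2(1−p)) with per-SNP scatter σ_f, where
  *M* ≤ C/2 is the minor-allele copy count.

Variant classification rests on the same mixture arithmetic.  For a
variant on *V* of the *C* tumor copies,

    AF_germline(V) = (pV + 1−p) / (pC + 2(1−p))     V ∈ {0, M, C−M}
    AF_somatic(V)  =  pV        / (pC + 2(1−p))     V ∈ {M, C−M}, V ≥ 1

differ by exactly (1−p)/(pC + 2(1−p)) — the normal's one alt copy — which
is why the method needs admixture (the gap vanishes as p → 1) and depth
(the gap must exceed binomial noise at the variant's coverage).

## Pipeline stages and their parameters

**Preprocessing.**  log2(tumor/normal) per bin, median-centered (median,
not mean: robust to focal amplifications).  GC bias is removed by Lowess
regression of log-ratio on GC fraction (frac = 0.3, 1 robustness
iteration) and re-centering; with fewer than 30 bins the smoother is
skipped with a warning.  Bins with zero tumor or normal depth are dropped,
not imputed — a failed process-matched normal marks an unreliable bin.
Heterozygous SNPs are selected tumor-only by an allele-fraction window
[0.10, 0.90] at depth ≥ 20.  The window is a sensitivity knob: it must be
wide enough to retain het SNPs displaced by LOH at moderate purity, and it
is deliberately generous; truly homozygous SNPs it admits are rare at
depth ≥ 20 (binomial tails) and inflate σ_f slightly rather than bias the
segment mean.  Non-het SNPs stay in the profile, flagged, because the
near-purity heuristic (below) needs them.

**Segmentation.**  Canonical recursive circular binary segmentation on the
log-ratio data only, per chromosome: the arc maximizing the mean-shift
statistic against its complement is accepted when its permutation p-value
(n_perm = 1000, seeded, early-stopped once significance is impossible)
falls below cbs_alpha = 0.01; splits leaving any piece below min_bins = 10
are not considered.  SNP minor fractions are attached to segments
afterwards.  Per-segment SDs are floored (0.05 log2 units for log-ratio,
0.02 for MAF) so degenerate segments cannot collapse a likelihood.

**Copy-number fit.**  Two routes, then selection:

* *Sampler.*  Metropolis-within-Gibbs over (p, b, {Cᵢ, Mᵢ}) where b is the
  free normalization offset standing in for log2(pΨ + 2(1−p)) (the profile
  is median-centered, so b ≈ 1 when the modal copy number is 2).  Each
  segment's summary enters the likelihood weighted by its observation
  count (n_bins for the log-ratio term, n_snps for the MAF term): each bin
  and each SNP is one observation, and the per-segment medians/means stand
  in for them.  Purity and offset move against the *marginal* likelihood
  with the discrete states summed out, so a chain is never trapped by its
  current copy-number assignment; exact categorical (Gumbel-max) draws
  then refresh all (Cᵢ, Mᵢ).  Settings: 9 chains with stratified dispersed
  purity starts, 500 burn-in, 500 retained sweeps, thinning 1; proposal
  scales adapt per chain toward ~30% acceptance during burn-in.
* *Degeneracy handling.*  The model family has exact symmetries: doubling
  every C and M while halving the purity odds (and shifting b) changes no
  expectation at all.  Three mechanisms address this: (i) a mildly
  decaying prior over copy number, P(C) ∝ exp(−0.4·C), which is the only
  thing that can rank exactly-equivalent solutions and is the standard
  parsimony resolution; (ii) a reversible doubling/halving jump move so
  chains can hop between family modes and settle in the preferred one;
  (iii) a burn-in relocation step that re-seeds chains stranded in basins
  ≥ 15 nats below the best chain — modes of comparable posterior are left
  alone, so genuine ambiguity still surfaces as disagreeing chains.  The
  point estimate is mode-seeking: posterior-median purity and modal states
  of the best chain (blending chains across distinct modes would average
  incompatible solutions).  Split-R̂ of purity above 1.1 flags
  non-convergence; with an essentially point-mass posterior (pooled spread
  < 0.005) the ratio diagnostic is meaningless and the fit counts as
  converged.
* *Grid.*  Purity 0.05–1.00 (step 0.01) × proposal ploidy 1.0–8.0 (step
  0.05); at each point every segment takes the error-minimizing integer
  (C, M), and all local minima of the length-weighted MSE surface are
  rebuilt as candidates with Ψ re-derived from the fitted C (one
  self-consistency pass), so every returned model satisfies the ploidy
  identity exactly.  Candidates are ordered by the same penalized
  log-posterior the sampler targets; raw MSE would rank fine-lattice
  noise-chasing solutions first at low purity.
* *Selection.*  The sampler's model is the default.  A grid candidate
  (among the first three) replaces it only if **all** hold: (0) it is not
  worse under the shared penalized posterior; (1) it reduces both the
  log-ratio MSE and the MAF MSE; (2) its ploidy exceeds 1.2; (3) it has
  no excessive copy-number loss (< 10% of the genome at C = 0); (4) it is
  not merely an alternative re-reading of the same data — |ΔΨ| ≥ 1.1
  together with |Δp| ≥ 0.1 rejects both the genome-doubled and the
  upshifted solution families; (5) its purity does not exceed 0.99 unless
  the independent near-purity heuristic agrees.  Guard (0) exists because
  at purity ≲ 0.25 the doubled family's purity delta is p(1−p)/(2−p) <
  0.1, so guard (4) structurally cannot fire there while raw MSE always
  favors the overfit candidate.
* *Near-purity heuristic.*  In an admixed specimen a large fraction of
  assayed SNPs sit inside the het window; near purity 1 with widespread
  LOH the het band empties (displaced alleles collapse onto 0/1).  The
  specimen is flagged plausibly-near-pure when het-window occupancy among
  depth-passing SNPs falls below 30% (requires ≥ 50 SNPs; returns false
  otherwise, conservatively).  This is the package's own construction —
  the selection literature it supports names no algorithm — and can be
  disabled.

**Classification.**  k = alt reads (or round(n·f) when only a frequency is
given).  Exact two-tailed binomial tests by the minimum-likelihood
convention: p = Σ pmf(j) over all j with pmf(j) ≤ pmf(k)·(1+1e−7); the
tolerance absorbs floating-point ties.  Per hypothesis the V maximizing
the p-value wins (ties → smaller V, for determinism).  Decision rules at
α = 0.01: somatic iff P(y|S) > α ≥ P(y|G); germline symmetric; subclonal
somatic iff both ≤ α, f < min AF_somatic / 1.5 and purity > 0.20;
otherwise ambiguous, with one reason — high_purity (model purity > 0.95),
model_misfit (variant's segment deviates > 3σ_r from its expectation, or
variant outside every modeled segment), compatible_with_both,
outside_both, or undefined_expectations (the p = 1, C = 0 point).
Classification depends on the model only through the expected-AF
candidate sets plus the purity gates, which makes expectation-equivalent
models (e.g. the doubling family) produce identical calls — a robustness
property the tests verify directly.  Variants spanning no segment are
assigned the nearest segment on their chromosome by midpoint.  The
optional germline-homozygous extension (normal carrying two alt copies,
AF → 1) is off by default: the germline expectation above encodes a het
normal, so f ≈ 1 variants fall to outside_both.

**Cohort posterior.**  P(S|n_G, n_S) with a flat prior and binomial
likelihoods at conservative per-call error rates e_G = 0.05, e_S = 0.10;
ambiguous tallies carry no likelihood weight.  Log-space evaluation keeps
posteriors finite at arbitrarily large counts (they can reach 1e−200 and
below with a few hundred concordant calls).

## The simulator

`sgz.simdata` draws specimens from exactly the generative model above:
deterministic normal depth, tumor depth = mean_depth · 2^(expected
log-ratio + N(0, σ)) with σ = 0.1 log2 units, SNP alt reads binomial at
the (randomly oriented) mixture fraction, hom-alt SNPs at 1 − 0.001,
variant alt reads binomial at the germline or subclonality-thinned
somatic expectation (thinning multiplies the somatic numerator term).
Coordinates are synthetic 0-based half-open uniform bins.

Default study conditions: a 22-chromosome, 44-segment aneuploid genome
(C ∈ 1..5, balanced and LOH states, ~60 bins of width 1 kb per segment,
≈ 2650 bins total), 15 SNPs per segment (≈ 660 genome-wide), mean depth
800×, het-SNP fraction 0.6.  Segment sizes matter: with many fewer bins
per segment the per-segment median is imprecise enough that a fine-lattice
high-ploidy solution can chase noise below the true model's residuals, a
regime real capture panels (hundreds of exons per segment) are not in.
Adjacent same-chromosome segments always differ in C so every true
breakpoint is visible to coverage-only segmentation.  The default variant
panel covers germline variants on major/minor/lost alleles, clonal
somatic variants, and subclonal somatics simulated as single-copy hits in
half the tumor cells — a fraction chosen so the thinned AF does not
systematically coincide with a germline expectation at the titration
purities (at specific purities such coincidences are unavoidable and the
caller correctly returns germline or ambiguous; the clash purity for a
half-fraction single-copy subclone in a diploid segment is 2/3).

What the simulator does **not** emulate: mapping artifacts, FFPE damage,
overdispersed coverage, position-correlated noise, germline CNVs in the
normal, or sequencing error beyond the binomial draw.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's own assumptions, not robustness to real-data pathologies.

## Numerical and degenerate-input choices

* p = 1 with C = 0 yields −∞ log-ratio / undefined AF; flagged, never
  thrown.
* q ∈ {0, 1} binomial tests short-circuit to the exact degenerate values.
* Purity grid starts at 0.05; the sampler's purity prior is uniform on
  [0.05, 1].
* C_max = 10; larger amplifications saturate at 10 (out-of-range amplicon
  calling is not this tool's focus).
* Empty candidate-V sets (somatic in a C = 0 segment) make the somatic
  hypothesis unsatisfiable; the variant can still be called germline.
* Single-segment genomes and score-flat (all-diploid-like) genomes are
  fitted but flagged `degenerate_single_segment` / `non_identifiable`.
* All randomness flows from explicit seeds (numpy Generator streams);
  byte-identical outputs for identical (inputs, config, seed).

## Known limitations

* At exactly 50% purity, AF_somatic(V) equals AF_germline(V−1) in every
  segment, so many clonal somatic variants are honestly ambiguous; call
  rate dips there by design.
* Below ~20% purity the copy-number solution may be reported in an
  expectation-equivalent re-scaling (e.g. halved-odds purity with doubled
  copy numbers); classifications are unaffected — only the *labels* p, C
  are rescaled — but the reported purity should not be over-interpreted
  at the low end.
* Zygosity is suppressed below 20% purity and all calling above 95%.
* The subclonal call is a flag, not a cancer-cell-fraction estimate.
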