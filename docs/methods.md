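# Methods

This note documents the models, conventions and numerical choices behind
`nacmap`, and what the synthetic validation does and does not establish.

## Connectivity model

Each subject contributes up to three runs of node × volume time series
(102 volumes at TR = 3 s by default). Per run, after temporal cleaning,
functional connectivity between two nodes is the Pearson correlation `r` of
their series, converted to

    Z = atanh(r) · sqrt(N_eff − 3),

with the Bartlett AR(1) effective sample size

    N_eff = n · (1 − a_x a_y) / (1 + a_x a_y),

where `a_x`, `a_y` are the *sample* lag-1 autocorrelations of the two
series. The correction matters: for independent AR(1) pairs with
coefficient 0.45 and n = 102, the uncorrected Z > 2.58 rate is ~0.017
instead of the nominal one-tail 0.005; with the correction it sits on
0.005 (this is verified by simulation in the test suite). The `−3` in the
variance term follows the standard Fisher-transform convention. A
truncated-lag-sum Bartlett variant is not implemented; the lag-1 plug-in is
the default and only form, chosen because the cleaned signals are well
approximated by AR(1) over the retained band.

Run-wise Z matrices are averaged element-wise over the *retained* runs
(runs excluded by motion QC drop out of the denominator), and the mean Z
matrix is binarized at a two-sided normal quantile. Three conventional
cutoffs are exposed (1.96, 2.58, 3.28 for p = .05, .01, .001); edges require
`Z > threshold` strictly, a measure-zero choice on real data. Note that the
exact two-sided quantile for p = .001 is 3.2905 (3.29 to two decimals); the
conventional printed cutoff 3.28 corresponds to p ≈ .00104 and is kept as
the named threshold constant because it is the customary value.

## Normalized alpha centrality

Alpha centrality `c(α) = (I − αA)⁻¹ A·1` is computed by a sparse linear
solve; at α = 0 it reduces to the degree vector, and its direction converges
to the principal eigenvector of `A` as α → 1/λ₁. Each vector is normalized
to sum to 100, making per-node values comparable across the family:

* nAC₀ = 100·degreeᵢ/Σdegree (local strength),
* nAC₁ = 100·vᵢ/Σv with `v` the Perron eigenvector (global standing),
* GC = nAC₁ − nAC₀, with Σ GC = 0 exactly.

With N nodes the mean of nAC₀ and nAC₁ is 100/N; at the emulated
whole-brain scale (N = 5,916) that is 0.0169, and the mean GC is 0.00 —
these are normalization identities, independent of the particular graph.

The eigenvector limit uses shifted power iteration (`A + I`) from a uniform
start, which converges on bipartite graphs where plain power iteration
oscillates; the successive-change tolerance is 1e-13 so that agreement with
a dense eigendecomposition holds to better than 1e-8 even when the spectral
gap is small. On disconnected graphs the limit concentrates on the
component with the largest spectral radius (first-found on ties, with a
warning); nodes outside it, and isolated nodes, score 0 before
normalization. Edgeless graphs are rejected — the normalization is
undefined.

## Temporal preprocessing and motion QC

Two cleaning variants mirror common practice: `full_denoise` regresses
CompCor components (top-5 principal components of the designated noise-node
signals, by SVD of the centered volumes × nodes matrix), the six rigid-body
motion parameters, and the global signal (across-node mean) jointly;
`compcor_only` omits motion and global-signal regression. All regressors
are computed from the raw series and removed in one least-squares step
(rank-deficient designs are rejected; constant regressor columns are
dropped with a warning since the intercept absorbs them), then a
zero-phase order-4 Butterworth band-pass (0.01–0.1 Hz, forward–backward)
removes offsets, slow trends and high-frequency noise without phase
distortion. The regression-then-filter order is fixed.

Framewise displacement is Power's: FD_t = Σ|Δtranslation| + 50 mm ·
Σ|Δrotation|, first frame 0. A run is excluded when any raw realignment
parameter reaches 2 mm translation or 0.02 rad rotation on any axis
(inclusive, per axis); subjects with no retained runs are dropped from
group analyses with a logged roster.

## Node typing and group inference

For a two-group comparison the per-subject centrality maps are averaged
into two group mean maps. Thresholds are mean + 1 sample SD (ddof = 1,
configurable) of the *pooled* node values of the two mean maps, separately
for nAC₀ and GC; because pooled GC has mean 0, its threshold is always
positive. A node is a hub iff nAC₀ strictly exceeds its threshold and
global iff GC strictly exceeds its threshold, giving four exclusive types.
The thresholds are re-derived per comparison (gender, digit-ratio split,
menstrual split) from the two maps being compared.

Regional distributions count the four types within each of the 14
AAL-derived region groups (FRv, FRm, FRl, SM, CIN, PAl, PAm, INS, LIM, TE,
OC, CER, BG, TH — the atlas is an input labeling, not reconstructed).

Two tests compare distributions between groups:

* **Chi-square homogeneity** per node type on the 2 × 14 count table
  (Pearson, no continuity correction; df = 13), Bonferroni-corrected ×4 for
  the four types. Regions with zero counts of a type in both groups are
  dropped with df reduced. *Caveat*: this test treats nodes as independent
  observations. Node classifications are spatially correlated in any
  realistically modular signal, and the statistic is anticonservative under
  the null — on null synthetic cohorts it frequently reports corrected
  p < .05 even with 50 subjects per group. This is a property of the
  procedure, not of the implementation (which matches the brute-force
  Σ(O−E)²/E oracle exactly); it is the reason the permutation test below is
  the inferential workhorse, with the chi-square retained as a descriptive
  screen.
* **Permutation test**: subjects are relabeled into two groups of the
  original sizes; per permutation the mean maps, pooled thresholds, node
  typing and regional percentages are fully re-derived (nothing is frozen
  from the observed split). The one-sided p per (region, type) cell is
  `#{permuted difference ≥ observed}/n_perm` with the group-1-minus-group-2
  orientation fixed in advance and ties counted as exceeding; the opposite
  tail is always reported alongside so dominance in either direction can be
  read off. An `(n+1)/(n_perm+1)` variant and a sign-of-observed direction
  mode exist behind flags; the latter is anticonservative under the null
  (it doubles the nominal exceedance rate) and is off by default. Because
  the regional percentage is discrete (steps of one node), the tie rule
  makes the p-values *valid but conservative*: on null cohorts the
  exceedance rate sits at roughly two-thirds of each nominal level rather
  than exactly on it, approaching nominal as nodes per region grow. The
  default iteration count is 10,000; the desk-scale tests use fewer.

Digit-ratio subgroups use a stable median split: subjects sorted ascending
(ties keep subject order), first ⌊n/2⌋ to the low group, the rest —
including the middle subject of an odd-sized group — to the high group, so
a tied median value can appear in both subgroups. Menstrual phase is
assigned from days since last menses: 1–14 follicular, 15–28 luteal, and
beyond 28 unknown (excluded from phase analyses).

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes, not
images: no hemodynamic forward model, no volumetric synthesis.

Node signals are latent-factor mixtures. Each of the 14 regions owns a
module signal `s_m = ρ·(W v)_m + √(1−ρ²)·u_m`, where `v` are four
cohort-wide *network* factors (each region loads one primary factor,
assigned cyclically, at weight √(1−β²) with β = 0.5 on a secondary factor)
and `u_m` is region-specific; all latents and node noises are
unit-variance stationary AR(1) with coefficient 0.3. A node in region m is
`x_i = a·g_i·s_m + w·p + ε_i` with module loading a = 0.9, a cohort-fixed
per-node gain jitter `g_i ~ U(0.6, 1.4)`, a subject- and region-level gain
`~ N(1, 0.2)`, a small physiological artifact `p` (loading 0.15) shared
with the CompCor noise nodes, and unit node noise. The factor structure is
deliberate: a single uniform global factor would be removed almost entirely
by global-signal regression, fragmenting the graph; distinct overlapping
networks with uneven regional weights survive it, as in real data. The
heterogeneity terms keep subjects from being statistical clones — without
them node classifications flip region-coherently and group count tables
become quasi-deterministic, which no real cohort shows.

Planted **global-hub regions** (per group) additionally load 2.0 on their
region's primary network factor, correlating them with every region on that
factor and tightly with each other — they become the eigenvector core of
their network, the graph signature the GC statistic is designed to detect.
Planted effect sizes are free parameters of the generator, not calibrated
to any particular dataset; the defaults produce an unambiguous hub
phenotype that the pipeline detects in ≥ 80% of replicate cohorts at 20
subjects per group.

Motion traces are mean-reverting AR(1) walks (stationary SD `motion_scale`
= 0.1 mm for translations and `motion_scale`/100 rad for rotations),
giving mean FD near 0.1 mm; optional single-volume spikes exercise the
exclusion rule. Metadata: digit ratios are normal per group (male
0.938 ± 0.026, female 0.951 ± 0.030); days since menses are uniform on
1–28 with a 7% fraction beyond 28 (the "unknown" stratum).

Default cohort size is 100 subjects per group with 300 nodes; the test
suite runs 6–20 subjects per group at 140–280 nodes (desk scale). What
passing tests show: the implementation recovers planted structure, its
p-values are valid, and its constants are exact. What they do not show:
performance on real BOLD data, with its non-AR(1) spectra, spatial
autocorrelation within regions, scanner drifts and registration errors.

## Determinism and caching

Every stochastic step takes an explicit seed (`numpy.random.default_rng`);
identical configuration and seed reproduce cohorts, permutation tables and
report bundles bit-for-bit. The pipeline caches per-subject centrality maps
on disk under the output directory, keyed by a SHA-256 content hash of the
run data, motion, noise series, preprocessing spec and Z threshold, so
re-runs with unchanged inputs reload instead of recomputing.

## Known limitations

* The chi-square node-independence caveat above.
* Tie-conservatism of the permutation p on small regions (discrete
  percentages); use more nodes per region or larger `n_perm` when fine
  p-resolution matters.
* The eigenvector limit on disconnected graphs ignores non-dominant
  components entirely; desk-scale synthetic graphs thresholded at Z = 2.58
  are frequently disconnected, which is handled but noisier than the
  connected whole-brain regime.
* NIfTI ingestion is not implemented; inputs are plain matrix files (the
  cohort I/O format documented in `nacmap.synthetic`). nibabel-based
  extraction can sit in front of the same entry points.
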