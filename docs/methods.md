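# Methods

`perilipid` analyses the fatty-acid composition of breast adipose tissue
around a tumour from chemical-shift-encoded (CSE) multi-echo MRI, and ships
a digital phantom so every stage can be validated against known ground
truth. This note records the models, the defaults and why they were chosen,
the numerical choices, and the limits of what the synthetic validation can
show.

## Signal model

A CSE acquisition samples the complex gradient-echo signal at echo times
TE₁, TE₁+ΔTE, … (here TE₁ = ΔTE = 1.14 ms, up to 174 echoes; the pipeline
fits the first 16). Per voxel,

    s(TE) = [ W + F · c(TE) ] · exp(i 2π ψ TE) · exp(−R2* TE)

where W and F are the water and fat proton amplitudes, ψ (Hz) the static
off-resonance field, R2* (1/s) the effective transverse relaxation rate,
and c(TE) = Σₘ αₘ exp(i 2π fₘ TE) the fat spectral modulation over nine
triglyceride peaks at {0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19,
5.29} ppm (water 4.70 ppm; 1 ppm = 127.74 Hz at 3 T).

The amplitudes αₘ follow from proton bookkeeping on a triglyceride with
mean chain length CL, `ndb` double bonds per molecule and `nmidb`
methylene-interrupted double bonds: e.g. the olefinic peak carries 2·ndb
protons, the diallylic peak 2·nmidb, the bulk methylene peak
6(CL−4) − 8·ndb + 2·nmidb, with the total 6·CL + 2 − 2·ndb. CL is fixed at
17.5 (it is weakly identifiable at 16 echoes). By default nmidb is tied to
ndb through the empirical triglyceride relation nmidb = 0.093·ndb², leaving
ndb as the single composition unknown; `FitOptions(constrain_nmidb=False)`
frees it.

Chain fractions come from the three-chain structure of a triglyceride,
counting a polyunsaturated chain's two methylene-interrupted bonds:

    PUFA = nmidb / 3,   MUFA = (ndb − 2·nmidb) / 3,   SFA = 1 − MUFA − PUFA.

Inputs with 2·nmidb > ndb are rejected (MUFA would be negative); in
constrained fitting the ndb upper bound defaults to 1/(2·0.093) ≈ 5.38 so
the conversion is always valid.

## Voxelwise fitting

The model is linear in (W, F), so the fit uses variable projection: a
bounded trust-region search over (ndb[, nmidb], ψ, R2*) in which (W, F) are
solved by real-stacked linear least squares at every step (non-negative
solve when the unconstrained solution goes negative). The field map is the
classic failure mode — ψ is only identified modulo 1/ΔTE and wrong basins
produce water–fat swaps — so ψ is initialised on a 13-point grid spanning
±1/(2ΔTE) ≈ ±438.6 Hz, each candidate scored cheaply at three ndb starts,
and the best three candidates polished to convergence; the lowest residual
wins. Magnitude-mode fitting (field map discarded) is available and uses
water-dominant and fat-dominant starts to resolve the |W + F·c| ambiguity.

Degenerate inputs return flagged results, not exceptions: an all-zero voxel
is non-converged; a water-only voxel fits F ≈ 0 with ndb unidentifiable.
The volume validity mask requires convergence and W+F above 5% of the
volume's 95th-percentile amplitude.

Noiseless round trips recover fat fraction, ndb, ψ and R2* to better than
1e-3 relative; at SNR 50 with 16 echoes the median |ndb| error over 500
simulated adipose voxels is ≈ 0.08 and the fat-fraction bias ≈ 3e-4 (the
test suite asserts < 0.15 and < 0.01).

## Digital phantom

Anatomy is procedural: a half-ellipsoid breast (default semi-axes 90 × 150
× 52 mm) on a posterior chest-wall slab, a 7.5 mm subcutaneous-fat shell on
the breast surface, an inner fibroglandular core, adipose elsewhere, and an
optional spherical tumour (default radius 10 mm). The grid defaults to
64 × 64 × 30 voxels at 3.75 × 3.75 × 4 mm. Per-voxel truth values are drawn
i.i.d. from per-tissue normal distributions and clipped to physical ranges;
slices share a single smooth field map (second-order polynomial, tens of
Hz) as in a 2-D multi-slice acquisition; noise is i.i.d. complex Gaussian
with SD = (mean adipose first-echo magnitude)/SNR, SNR defaulting to 50.

Breast adipose defaults to ndb = 2.0 ± 0.10, which under the constrained
nmidb relation gives MUFA/PUFA/SFA ≈ 0.42/0.12/0.46 — typical of
postmenopausal breast fat. The peri-tumoural deregulation is modelled as an
ndb decrement of amplitude 0.4 decaying exponentially (length scale 10 mm)
with physical distance from the tumour surface, nmidb following
quadratically; averaged over a 15 mm rim this depresses mean MUFA by about
0.01–0.02 against the far field, shifting composition toward SFA.

What the phantom does *not* emulate: between-subject biological variation
of adipose composition (subjects differ only by sampling noise), coil
sensitivities and correlated noise, k-space effects, T1 weighting (TR
200 ms, flip 15° are metadata only), motion, and irregular tumour or
fibroglandular morphology. Passing the cohort tests therefore demonstrates
that the pipeline's geometry, estimators and statistics behave correctly
under a known effect — not that effect sizes in real cohorts will match.

## Regions of interest

The peri-tumoural rim is the 3-D set of non-tumour voxels within 15 mm
Euclidean distance (anisotropic voxel spacing respected) of the tumour,
computed by a distance transform. At 3.75 mm in-plane pixels this reaches
exactly 4 voxels in plane; through 4 mm slices the physical-distance
definition reaches 3 slices, which we consider the defensible
generalisation of a "15 mm (4 voxels)" shell on anisotropic grids. The
whole breast keeps adipose + fibroglandular tissue only (chest wall,
subcutaneous fat, background removed; tumour excluded in participants,
peri-tumoural tissue retained). Histogram analysis uses voxels whose fat
fraction strictly exceeds 0.60, guaranteeing fat-dominated signal.
An empty tumour mask or an empty filtered region raises a typed
`EmptyRegionError` so downstream statistics skip it explicitly.

## Heterogeneity measures

Per lipid and region: mean; median; skewness m₃/m₂^1.5 and non-excess
kurtosis m₄/m₂² from population central moments (thousands of voxels per
region make small-sample corrections negligible; both conventions are the
common radiomics ones — Gaussian kurtosis = 3, long left tail → negative
skewness); and Shannon entropy in bits over a 256-bin histogram spanning
[0, 1] shared by all lipids.

Entropy needs one correction: the plugin estimate −Σ pᵢ log₂ pᵢ increases
with the number of voxels sampled, so comparing a ~250-voxel rim against a
~1700-voxel whole breast on raw values turns region size into a spurious
"heterogeneity difference" (measured ≈ 0.15 bits, large against the
between-subject spread). The reported entropy is therefore *rarefied*: the
exact expected plugin entropy of a 200-voxel subsample, computed from the
hypergeometric distribution of bin counts. Because a subsample of an
i.i.d. sample is itself an i.i.d. sample, this estimator's expectation
depends on the underlying distribution only through the depth, never the
region size. Regions at or below the depth are summarised in full (the raw
formula), and `HistogramSpec(rarefaction_depth=None)` restores the plugin
estimator everywhere. Bin count, range, depth and the minimum region size
(20 voxels; smaller regions are flagged and their higher-order measures
excluded from testing) are all configurable.

## Statistics

Three contrasts per measure per lipid: Wilcoxon signed-rank (paired within
participants) for rim vs whole breast, Mann-Whitney U for the two contrasts
against the control whole breast, all two-sided, Bonferroni-corrected at
α/3 (α = 0.05; displayed 0.017, compared unrounded). Exact null
distributions are used where feasible (Mann-Whitney: both n ≤ 12, no ties;
Wilcoxon: ≤ 25 nonzero untied differences), otherwise tie- and
continuity-corrected normal approximations; the tests are verified against
full enumeration oracles. Spearman correlations of rim measures against
tumour covariates carry Fisher-z confidence intervals (SE 1/√(n−3)).
Planning utilities compute Cohen's d with (n−1)-weighted pooled SD and the
smallest per-group n reaching target power under the noncentral-t
distribution (d = 1.2, 80% power, α = 0.05 two-sided → 12 per group); the
t-family is used for planning even though the analysis tests are
nonparametric, mirroring standard practice. The Nottingham Prognostic
Index utility is grade + nodal category + 0.2 × size (cm).

## Problem sizes in the test suite

Cohort-level simulations run on 32 × 32 × 12 phantom grids (rim ≈ 250
adipose voxels, whole breast ≈ 1700), which we chose as the smallest
geometry that keeps all regions comfortably above the rarefaction depth
and minimum-voxel thresholds; the null type-I simulation uses 200 replicate
12-participant cohorts, the Monte-Carlo fit-precision checks 500 voxels,
and the Mann-Whitney power check 4000 replicate samples. Full-resolution
64 × 64 × 30 phantoms run through the same code paths via the CLI.

## Known limitations

- Constrained fitting inherits any error in the nmidb–ndb relation; when
  the true composition departs from it, ndb absorbs a small bias (the
  free-nmidb mode removes it at the cost of noisier estimates).
- No spatial regularisation of the field map; isolated voxels in very low
  SNR can still swap. The candidate grid makes this rare but not
  impossible.
- The rarefied entropy equalises expectations across region sizes but not
  variances; smaller regions still yield noisier entropies.
- T1 bias, multi-coil combination and DICOM ingestion are out of scope.
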