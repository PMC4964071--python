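# Methods

## Model and procedure

varstab assumes that after a suitable asinh scaling, the cell populations
visible in a single fluorescence channel are approximately Gaussian with
a common within-population variance, and that what spoils this on the raw
scale is the monotone mean–variance dependence of fluorescence detection.
Compensation (spectral unmixing) is assumed done upstream; channels are
treated as independent and stabilized one at a time, and scatter channels
are never transformed (there is little benefit, and the tool skips any
channel matching FSC/SSC naming patterns with a warning).

For one channel and one candidate cofactor c the pipeline is:

1. transform the channel in every sample by `asinh(z / c)`;
2. estimate each transformed channel's density, detect density peaks
   (1-D clusters) and delimit them by the inter-peak density minima;
3. pool the peaks from all samples and summarize each by its event count
   n_i, mean, and unbiased variance s_i²;
4. score homogeneity of the pooled variances with Bartlett's statistic
   B(c), computed from the summaries alone.

The cofactor search minimizes B(c) over the log-domain [c_low, c_high] =
[−2, 10] split into unit-width log intervals (a non-integer span gets a
final partial interval). B(c) is not differentiable in c — it changes
discontinuously wherever the detected peak count or a peak boundary
moves — so each interval is searched as a black box and the best interval
optimum wins, with ties going to the smaller cofactor. The winning c* is
applied to the channel in **every** sample; population MFI differences
between samples are preserved, peak alignment is deliberately not a goal.

Bartlett's statistic is used purely as a score. No p-values are reported:
the null "all populations have exactly equal variance" is not the
question, and p-values would conflate cluster size with homogeneity. For
data with heavier-tailed populations the objective can be switched to
Levene or Brown–Forsythe (`ScanSettings(objective=...)`), which require
the raw per-peak events and are correspondingly slower; Bartlett is the
default because populations in typical FC data are near-Gaussian and the
likelihood-ratio statistic is the more sensitive objective there.

Metacluster homogeneity is quantified by the between/within-cluster
variation ratio `Σ(n_i−1)(μ_i−μ)² / Σ(n_i−1)s_i²`, an effect size that is
invariant to affine rescaling of the data, does not grow with cell count,
and shrinks as a metacluster becomes more homogeneous.

### Microarray mode

Each gene's expressions across the N samples form one variance group of
size N (no peak detection), and a single cofactor is selected for the
whole matrix with the identical interval scheme. Rows containing any
non-finite value are dropped before analysis — the simplest defensible
missing-data policy. The mean–sd profile table (per-gene mean, sd, rank
of mean, running median of sd over a sliding rank window) is the
diagnostic for residual mean–variance dependence: a flat running median
means none.

## Parameters that matter

| parameter | default | units / scale | why |
|---|---|---|---|
| c_low, c_high | −2, 10 | natural log of cofactor | spans cofactors 0.135–22026, covering both low-range (≈10⁴ max) and high-range (≈10⁶ max) instruments |
| inner search tol | 1e−4 | relative, on the cofactor | below any biologically meaningful cofactor resolution |
| KDE bandwidth | 0.9·min(sd, IQR/1.34)·n^(−1/5) | transformed scale | the nrd0 rule-of-thumb; overridable when populations are very unbalanced |
| grid size | 512 points, ±3 bandwidths margin | — | resolves peaks while keeping the objective cheap inside the optimizer |
| min_height_frac | 0.01 | fraction of max density | discards baseline ripple |
| min_prominence_frac | 0.05 | fraction of max density | the operational "significant curvature" filter: a shoulder must rise 5% of the max above its saddle to count as a population |
| min_events | 50 | events per peak | variance estimates on tiny peaks destabilize the log-variance terms of B |
| variance floor | 1e−12 | transformed scale² | peaks/genes below it are dropped to avoid ln(0) |

## Synthetic data: what it emulates and what it does not

Ground truth is constructive: populations (or genes) are drawn Gaussian
on the transformed scale, t ~ N(μ_t, σ_t), and pushed to the raw scale
through the exact inverse z = c₀·sinh(t). Transforming back at c₀
restores homogeneous variances identically, so the recovery target is
analytically correct rather than assumed; because sinh is convex and
increasing for t > 0, the raw scale shows the variance-grows-with-MFI
phenomenon of real fluorescence data. Per-sample jitter (sd 0.1 on the
transformed scale) shifts population MFIs only — between-subject
variation moves populations around but is not supposed to change the
spread the stabilization targets.

Default study conditions: 3 samples × 10,000 events, two populations of
equal weight at μ_t = 1.0 and 3.0 with common σ_t = 0.25; microarray
mode: 2,000 genes × 6 samples, gene means spread over [0.5, 4.0] on the
transformed scale, σ_t = 0.15, true cofactor exp(6).

The generator does not emulate: non-Gaussian (heavy-tailed or skewed)
populations, doublets and debris, acquisition-time drift, spillover
between channels, or population proportions varying with condition.
Passing the recovery suite therefore shows the estimator is correct when
its model holds; on real data the achievable minimum of B is larger and
the optimum can be less sharply defined (a channel where nearly all cells
are positive, for instance, gives a flat, low B curve).

## Numerical choices

- **KDE evaluation.** Gaussian-kernel density via linear binning onto the
  512-point grid followed by FFT convolution with the kernel (truncated
  at ±6 bandwidths) — the classical fast KDE, accurate to well below the
  peak-detection thresholds and ~50× faster than direct evaluation, which
  matters because the optimizer evaluates hundreds of densities per scan.
  The test suite cross-checks it against direct Gaussian KDE evaluation.
- **Peak boundaries** are placed at the lowest-density grid point between
  two adjacent retained maxima (leftmost on ties); the outermost
  boundaries are the grid ends, so peak regions partition the span and
  event assignment (half-open intervals) is a partition — no event is
  counted twice. A curve with no interior maximum passing the filters is
  treated as unimodal with its global maximum as the single peak.
- **Inner minimization.** Each log interval is searched on the raw
  cofactor scale by a uniform 21-point coarse scan followed by a
  Brent-style bounded refinement (golden section + successive parabolic
  interpolation) around the best coarse point. The coarse seeding is
  there because B(c) can be flat over stretches and can jump: a purely
  local method started blind can settle on a plateau and miss a narrow
  lower region. Evaluations returning +inf (fewer than 2 peaks at that
  cofactor) are legal and simply never win.
- **Objective granularity.** Because peak boundaries are quantized to the
  density grid, B(c) carries a small discrete jitter; a finely sampling
  search can legitimately land slightly below the minimum of any fixed
  coarse grid of cofactors. The oracle test in the suite therefore checks
  the one-sided property that matters — the interval search never does
  worse than a 400-point brute-force grid (within 2%) — rather than exact
  two-sided agreement with it.
- **Degenerate inputs.** Constant vectors are rejected for density
  estimation and [0,1] rescaling; Bartlett's statistic requires ≥ 2
  groups with n_i ≥ 2 and positive variances, and the floating-point
  statistic is clamped at 0 from below; a channel that never yields ≥ 2
  peaks anywhere in the domain raises an optimization failure naming the
  channel (other channels proceed).
- **Determinism.** Scans contain no randomness: identical inputs and
  settings give bit-identical traces. All simulation randomness flows
  through explicit integer seeds.

## Known limitations

- Covariance between correlated markers is not stabilized — the method is
  strictly per-channel.
- The method needs identifiable density peaks; very smeared channels or
  single-sample inputs with one population give an undefined objective.
- Bartlett's objective presumes approximate normality of the 1-D
  clusters; strong departures call for the Levene/Brown–Forsythe
  objective at extra cost.
- The exact numeric behavior of curvature-based peak filters used
  elsewhere in the FC ecosystem is not reproduced; on real data peak
  counts — and hence the selected cofactor within a log interval — can
  differ slightly from tools using those filters.
- FCS support covers list-mode 3.0/3.1 with float or masked-integer data;
  FCS 2.0 and analysis segments are out of scope.
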