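# varstab

Channel-specific variance stabilization for multi-sample flow cytometry,
with a microarray mode.

## The problem

Fluorescence measurements have variance that grows with signal intensity:
in a flow-cytometry (FC) channel, a cell population with high mean
fluorescence intensity (MFI) is also wider than a dim population. This
mean–variance dependence breaks the homoskedasticity assumption behind
the standard statistics used to compare populations across samples —
ANOVA-style comparisons of MFIs, metaclustering of phenotypically matched
populations, uniform feature extraction. varstab removes the dependence
explicitly, per channel, for a whole collection of samples at once.

## The method

Each fluorescence channel *z* is transformed by the inverse hyperbolic
sine with a single scale parameter, the **cofactor** *c*:

    asinh(z / c) = ln(z/c + sqrt((z/c)^2 + 1))

For a candidate cofactor, every sample's channel is transformed, the 1-D
kernel density of each transformed channel is estimated, and **density
peaks** (1-D cell populations, delimited by inter-peak density minima) are
collected from all N samples. With m pooled peaks, the i-th holding n_i
cells with unbiased variance s_i², variance homogeneity is scored by
**Bartlett's statistic**

    B(c) = [(n − m) ln s_p² − Σ (n_i − 1) ln s_i²]
           / [1 + (Σ 1/(n_i−1) − 1/(n−m)) / (3(m−1))]

where s_p² is the pooled variance and n = Σ n_i. The stabilizing cofactor
is c* = argmin B(c), found by splitting the log-cofactor domain
[−2, 10] (cofactors 0.135 … 22026) into unit-width log intervals and
running a derivative-free bounded search in each; the same c* then
transforms that channel in every sample, so between-sample MFI differences
— potential biology — are preserved rather than aligned away.

For microarrays the grouping changes: each gene's expressions across the
N samples form one variance group, and a single cofactor is chosen for
the whole matrix.

The package also provides Levene / Brown–Forsythe as drop-in robust
objectives, a two-step rectangle + ellipse gating utility, a [0,1]
rescaling for cross-method comparisons, the between/within-cluster
effect-size ratio for scoring metacluster homogeneity, and a synthetic
data generator with analytically known stabilizing cofactors.

## Worked example

Simulate three samples (10,000 events each, two populations that are
Gaussian on the transformed scale) whose true stabilizing cofactor is
exp(4) ≈ 54.6, then recover it:

```sh
$ varstab simulate --seed 3 --out sims
$ varstab stabilize 'sims/*.fcs' -c FL1 --out run
FL1     cofactor=57.0748        bartlett=5.66321
```

The recovered cofactor 57.07 (ln 4.044) sits within 0.05 log units of the
truth; Bartlett's statistic 5.66 at the optimum is at the null level for
the six pooled peaks (≈ χ² with 5 degrees of freedom), i.e. the peak
variances are as homogeneous as sampling noise allows. `run/` contains
the scan trace (`scan_FL1.tsv`, the data behind a B-vs-cofactor curve),
per-peak summaries, the transformed FCS files and a JSON summary.

The same from Python, for a microarray matrix built to stabilize at
exp(6) ≈ 403:

```python
>>> from varstab import simulate_expression_matrix, optimize_cofactor_microarray
>>> mat = simulate_expression_matrix(seed=5)   # 2000 genes x 6 samples
>>> scan = optimize_cofactor_microarray(mat)
>>> round(scan.c_star, 1), round(scan.b_star, 1)
(388.5, 1925.7)
```

ln(388.5) = 5.96, again within 0.05 log units of the construction truth;
B* ≈ 1926 is the null level for 2000 gene groups.

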