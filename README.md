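# codaprop

Error propagation for compositional data in pivot (ilr) log-ratio
coordinates.

## The problem

Compositional data — element concentrations of a soil sample, relative
abundances in a community, sand/silt/clay fractions — carry only *relative*
information: two proportional vectors describe the same composition.  The
standard way to analyse them is to map each D-part composition
`x = (x_1, …, x_D)` to D−1 real coordinates with the pivot isometric
log-ratio (ilr) transform

```
z_j = sqrt((D−j)/(D−j+1)) · ln( x_j / gm(x_{j+1}, …, x_D) ),   j = 1, …, D−1,
```

where `gm` is the geometric mean.  Because the transform runs every part
through geometric means, practitioners worry that measurement problems in a
few parts — values rounded at a detection limit, or multiplicative
imprecision — poison every coordinate.  This package provides the machinery
to study that question quantitatively:

* **Aitchison geometry** (`codaprop.core`): closure, perturbation `⊕`,
  powering `⊙`, inner product/norm/distance, clr coefficients and the pivot
  ilr map with its inverse.  The map is an isometry; `z_1` carries all
  relative information about the first part, so a part of interest is rotated
  to the front with `pivot_to_front`.
* **Simplicial calculus** (`codaprop.calculus`): first-order Taylor error
  propagation in Euclidean space and on the simplex; C-derivatives of
  scale-invariant functions; the variance decomposition
  `Var(z_j) = A − B`, with `A` the averaged log-ratio variances of the error
  involving the pivot part and `B` those among the remaining parts.  ilr
  coordinates are *additive* under multiplicative error:
  `ilr(μ ⊕ ε) = ilr(μ) + ilr(ε)`.
* **Contamination generators** (`codaprop.contamination`): detection-limit
  rounding — values at or below a per-part limit `DL_j` (a column quantile)
  become `(2/3)·DL_j` — and imprecision — each cell multiplied by
  `1 + γ`, `γ ~ U(−α, α)`.
* **Distortion metrics** (`codaprop.metrics`): Spearman rank correlation and
  mean absolute scaled deviation (MASD) between original and contaminated
  first coordinates, and between robust Mahalanobis distances of all
  coordinates jointly (location/scatter via a reweighted minimum covariance
  determinant fit of the *uncontaminated* coordinates only); classical and
  robust principal components.
* **Simulation harness** (`codaprop.simulate`) and a seeded logistic-normal
  generator (`codaprop.synthetic`) emulating a continental geochemical survey
  (n = 2107 observations, D = 20 parts) for fully reproducible Monte-Carlo
  designs: incremental contamination, amount sweeps, sample-size sweeps and
  the A/B variance-ratio study.

## Worked example

```python
import codaprop as cp

X = cp.gemas_like_fixture(seed=7, scale="small")        # 300 x 10 synthetic survey
dirty = tuple(X.columns[5:])                            # contaminate last 5 parts

Xdl, counts = cp.apply_detection_limit(X, cp.DLSpec(parts=dirty, quantile=0.25))
r = cp.distortion_report(X, Xdl, seed=0)
print(r)
```

prints

```
DistortionReport(spearman_first=0.9743281592017689, masd_first=0.13936317354908648,
                 spearman_md=0.9131105901176679, masd_md=0.0630236476945757)
```

Half the parts had 25% of their values collapsed onto a detection limit, yet
the ordering of the first pivot coordinate is almost untouched (Spearman
0.97) and its values move by only 0.14 original standard deviations; the
joint multivariate structure (robust Mahalanobis distances) degrades more
(Spearman 0.91) but is far from destroyed.  `examples/` contains four short
scripts covering the geometry, the analytic error propagation, the
contamination metrics and the simulation designs.

A thin CLI mirrors the library:

```
codaprop synth --n 2107 --d 20 --seed 1 -o data.csv
codaprop contaminate data.csv --scheme dl --parts 11-20 --quantile 0.25 --seed 1 -o cont.csv
codaprop metrics data.csv cont.csv --seed 1 -o report.json
codaprop simulate --design 2 --scheme ir --reps 100 --seed 1 -o result.csv
```

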