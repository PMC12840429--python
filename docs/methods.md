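# Methods

## Model and observables

The simulation starts from a fully occupied `L × L` square lattice
(`L` odd, so a unique central site exists; even `L` is rejected rather than
guessing a center convention). Each site carries a removal probability

    q(d, qp) = 1 − (1 − qp) · d / dmax,     dmax = (L − 1) / 2,

with `d` its distance from the center under the Chebyshev (default),
Euclidean or Manhattan metric. Under the L2/L1 metrics the corners lie
beyond `dmax`, where the raw linear form is negative; values are clamped to
`[0, 1]` while the normalization stays `dmax` for every metric, so the
printed formula is preserved and the field remains a valid probability.

Sites are inspected in uniformly random order and removed when a uniform
draw falls below their `q`; retained sites may be re-inspected without
bound. Conditional on an acceptance, the removed site is therefore
distributed proportionally to `q` among the occupied sites — successive
weighted sampling without replacement. The process runs until spanning
(a 4-connected cluster of occupied sites touching top and bottom, or left
and right; open boundaries) is lost. The last spanning configuration is the
red-bond point; all critical observables — occupied fraction `pc`,
largest-cluster size `Smax/L²`, non-spanning cluster count `n(pc)/L²` and
the size histogram `N(s)` (spanning clusters excluded) — are measured
there, with the red-bond site still present. The alternative convention
(first non-spanning configuration) differs by a single site.

## Samplers

Two implementations share the removal-law contract:

* the literal rejection loop (reference; used in equivalence tests), and
* an exponential-race sampler: site `i` draws key `E_i / q_i` with `E_i` a
  unit exponential, and ascending keys give the full removal order in one
  sort. This is an exact realization of successive weighted sampling
  without replacement, not an approximation; the suite verifies
  distributional equivalence by chi-square on small lattices (full-order
  law on a 4-site configuration, first-two-removal law on 3 × 3).

Sites with `q = 0` (the perimeter ring at `qp = 0`) receive an infinite key
and are reported as *excluded*; a trajectory that never breaks spanning
raises a dedicated error carrying the excluded-site count. Ensembles count
and drop such realizations instead of re-drawing seeds, which would bias
the average.

## Critical-point search

Spanning is monotone along a trajectory (removals only cut connectivity),
so the critical index `k*` — removals applied in the last spanning
configuration — is unique and bracketable. The production search removes
sites in batches of `max(1, ⌊L²/100⌋)` (configurable) with a full,
stateless cluster relabeling per checkpoint, then binary-searches inside
the last batch; this costs on the order of a hundred relabelings per
realization regardless of `L`. An independent reverse union-find
pass (sites added back in reverse order, cluster border contacts tracked as
bitmasks at the union-find roots) recomputes `k*` in a single sweep and is
cross-checked against both the binary search and a relabel-after-every-
removal linear scan on hundreds of trajectories, plus an exhaustive
enumeration of all 5! removal orders of a plus-shaped fixture.

Cluster labeling itself is delegated to `scipy.ndimage.label` with a
plus-shaped structuring element; the tested contract is the partition
(verified against a hand-written BFS flood fill), not the algorithm.

## Randomness and reproducibility

Realization `r` at qp-grid index `qi` uses
`numpy.random.default_rng([base_seed, qi, r])` (the `qi` entry is dropped
for standalone ensembles). Every reported number is a pure function of
`(L, metric, qp grid, N, base_seed)`; reruns are bit-identical, which the
suite asserts.

## Fits

* **Fisher exponent.** `N(s)` is binned with factor-2 edges; each non-empty
  bin fully inside the fit window contributes its count density
  (count / bin width) at the bin's mass-weighted mean size. τ is minus the
  least-squares log–log slope. The mass-weighted abscissa makes the
  estimator essentially exact on a pure power law (a geometric bin center
  overestimates the exponent at small `s`); an exact `s^−2` input is
  recovered to ±0.01. The default window is `s ∈ [5, s90]`, where `s90` is
  the size below which 90% of the non-spanning occupied mass lies after
  dropping the single largest cluster: the lower cut avoids small-`s`
  lattice curvature, the upper cut the finite-size hump near the cutoff.
  Fewer than 4 usable bins is an error.
* **Threshold curve.** `pc(1 − qp)` is fitted with a fourth-order
  polynomial, weighted by `1/se²` when standard errors are present
  (reduced χ² is reported only then); at least 6 distinct grid points are
  required.
* **Largest cluster.** `Smax/L²` versus `(1 − qp)` is an ordinary
  least-squares line (≥ 3 points).

## Problem sizes and defaults

The package defaults to a desk scale of `L = 201` with `N = 200`
realizations (100 per grid point in sweeps), which resolves every
qualitative feature of the transition in about a minute per sweep; the
publication scale `L = 1001`, `N = 1000` sits behind
`gradperc sweep --full-scale`. The default `1 − qp` grid is
`{0, 0.1, …, 0.9, 0.99}`.

## Known finite-size deviations at desk scale

The synthetic ensembles emulate exactly the stated stochastic process —
there is no real-data noise, boundary disorder or measurement error — so
test outcomes speak to the model itself, at the simulated sizes only.
Three desk-scale observations differ systematically from the
infinite-size/publication-scale picture:

* **Effective τ is depressed.** At `L = 201`, `qp = 1`, the log-binned
  slope lands well below the asymptotic `187/91 ≈ 2.055`, and the value is
  insensitive to the lower window edge: corrections to scaling, not
  sampling noise or the window choice, dominate the gap, and the same
  depression appears for uniform occupation at fixed density. The
  asymptotic exponent emerges only for much larger systems and fit
  windows.
* **The τ-minimum location shifts.** Because the depression above is
  strongest in the classical-like small-`(1 − qp)` regime, the minimum of
  τ over the grid tends to sit at a grid edge at desk scale rather than in
  mid-grid; the distribution at `1 − qp = 0.99` is additionally a poor
  power law.
* **`pc(1 − qp)` has a weak bump.** Mean `pc` rises slightly (beyond two
  standard errors) between `1 − qp = 0` and ≈ 0.2 at desk-scale lattices
  before the strong decrease sets in; the monotone-decrease tests
  therefore start at `1 − qp = 0.3`.

The `Smax` slope is likewise somewhat flattened relative to larger
lattices, consistent with the larger `Smax/L²` of smaller systems.

## Degenerate inputs and tie-breaks

`qp = 0` is refused by sweeps unless explicitly overridden, since the
untouched perimeter ring spans forever under the Chebyshev metric.
Histograms with no mass besides their largest cluster, rank-deficient
polynomial designs, empty lattices and out-of-range coordinates raise
typed errors rather than returning silent defaults. Sorting of exponential
keys is stable, so exact key ties (probability zero in theory, possible
only through float coincidence) resolve by site index.
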