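# gradperc

Inverse site percolation on a square lattice with a **distance-dependent
removal probability**. The model is motivated by the tumor microenvironment:
a damage source at the lattice center depletes its surroundings most
strongly nearby, so sites close to the center are removed almost surely
while the perimeter is (partially) protected. `gradperc` simulates the
removal process, locates the red-bond critical point of each realization,
and measures how the percolation transition deforms as the gradient
steepens.

## Model

Sites of a fully occupied `L × L` lattice are inspected in uniformly random
order. A site at distance `d` from the center is removed, when inspected,
with probability

```
q(d, qp) = 1 − (1 − qp) · d / dmax,        dmax = (L − 1) / 2
```

clamped to `[0, 1]`; `q = 1` at the center and `q = qp` at the perimeter.
The perimeter parameter `qp ∈ [0, 1]` controls the gradient: `qp = 1` is
uniform (classical) removal, `qp → 0` a maximally protected boundary.
Distances can be Chebyshev (L∞, square iso-probability contours, the
default), Euclidean (circles) or Manhattan (diamonds).

Removal continues until the **red-bond point**: the last configuration in
which a cluster of occupied nearest neighbors still spans the lattice
(top–bottom or left–right). There the library records

- `pc` — the occupied fraction (≈ 0.5927 for `qp = 1`, the classical 2D
  site-percolation threshold; it collapses to ≈ 0.20 as `qp → 0`),
- `Smax / L²` — the normalized largest-cluster size, which falls roughly
  linearly in `(1 − qp)` with slope ≈ −0.2,
- `n(pc) / L²` — the normalized count of non-spanning clusters, peaking
  near `1 − qp ≈ 0.9`,
- `N(s)` — the cluster-size histogram, whose power law `N(s) ~ s^−τ`
  defines the Fisher exponent (`τ = 187/91 ≈ 2.055` for classical 2D
  percolation in the infinite-size limit).

The critical index is found with the two-phase scheme of coarse batched
removals plus binary search, each spanning check being a full cluster
relabeling; an independent reverse union-find pass (Newman–Ziff style)
cross-validates it in the test suite. The removal order itself is drawn
with an exact-equivalent weighted sampler (one exponential key per site),
so a full trajectory costs one sort instead of millions of rejected
inspections.

## Worked example

```python
from gradperc import LatticeSpec, run_ensemble, estimate_tau

res = run_ensemble(LatticeSpec(L=201, qp=0.5), N=50, base_seed=0)
print(f"pc = {res.mean_pc:.4f} +/- {res.se_pc:.4f}")
print(f"Smax/L^2 = {res.mean_smax_norm:.4f}")
print(f"n(pc)/L^2 = {res.mean_n_norm:.4f}")
fit = estimate_tau(res.histogram)
print(f"tau = {fit.tau:.3f} over s in [{fit.fit_range[0]:.0f}, {fit.fit_range[1]:.0f}]")
```

prints

```
pc = 0.5778 +/- 0.0020
Smax/L^2 = 0.1599
n(pc)/L^2 = 0.0367
tau = 1.946 over s in [5, 4405]
```

i.e. with a mid-strength gradient (`qp = 0.5`) the lattice loses spanning
at 57.8% occupancy instead of the classical 59.3%, the spanning cluster at
criticality holds 16% of the lattice, and the non-spanning cluster sizes
follow a power law with an effective exponent of about 1.95 (finite-size
depressed relative to the asymptotic 2.055; see `docs/methods.md`).

The same run from the shell:

```
$ gradperc simulate --L 201 --qp 0.5 --n 5 --seed 7 --out sim_demo
wrote 5 realizations to sim_demo
$ head -3 sim_demo/realizations.csv
seed,qp,L,metric,k_star,pc,smax_norm,n_norm
0,0.5,201,chebyshev,16995,0.5793420954926858,0.1602930620529195,0.03650899730204698
1,0.5,201,chebyshev,17560,0.5653572931363086,0.11071508130986857,0.04254845177099577
```

Other commands: `gradperc sweep` (full `1 − qp` grid with summary CSV,
per-qp histograms and fit report), `gradperc fit` (re-fit an existing sweep
directory), `gradperc snapshot` (ASCII-PGM renderings of the probability
field, the red-bond occupancy and the largest cluster). Every output
directory contains a `provenance.json` that reproduces it exactly.

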