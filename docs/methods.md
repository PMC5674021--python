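# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `fragdd` pipeline.

## Landscapes and quality

A landscape is a set of forest patch size classes, each with a mean patch
size s (ha), a patch count and a total area A(s). County-level class tables
are pooled by summing counts and areas per class; the landscape class mean
is Σarea/Σcount, the patch-count-weighted mean implied by assuming patches
within a county/class are equal in area. Classes that end up with zero
patches are retained with zero area (so curve point counts are stable
across landscapes) and carry a nominal midpoint size: the value from the
input's `mean_size_ha` column if present, otherwise the midpoint of the
configured class edges. Default class edges are the geometric-ish ladder
1, 5, 10, 25, 50, 100, 250, 500, ≥500 ha; every downstream computation
depends only on per-class mean sizes and areas, so the edges matter only to
the synthetic generator's binning.

Landscape quality is Q = core forest area / total forest area, classified
good (Q > 0.7), moderate (0.6 ≤ Q ≤ 0.7) or poor (Q < 0.6); the boundary
Q = 0.7 deliberately belongs to "moderate".

## Vital-rate curves

Nest survival follows the saturating curve f(s) = f_max·s/(s_half+s) with
defaults f_max = 0.85, s_half = 42 ha. Saturation density follows a
reverse sigmoid with defaults l = 0.13 pairs ha⁻¹, α = 0.18 ha⁻¹,
t = 13.4 ha.

**Sigmoid orientation.** Two published forms of the density sigmoid exist
that share the same parameters but differ in sign convention. The literal
form d = 1 + (l−1)/(1+e^{α(s−t)}) *increases* with patch size toward 1,
which contradicts the repeatedly documented field pattern of higher
densities in smaller patches that the curve is meant to describe. The
package therefore defaults to the `decreasing` orientation
d = l + (1−l)/(1+e^{α(s−t)}), which keeps the printed parameter values and
the midpoint value (1+l)/2 at s = t but declines from ≈ 1 pair ha⁻¹ in the
smallest patches to the asymptote l in contiguous forest. The literal form
remains available (`orientation="literal"`) so the discrepancy can be
inspected rather than silently reconciled. Both forms saturate numerically:
beyond α(s−t) ≈ 40 the sigmoid term is below float64 resolution of the
asymptote.

Units: d and the BBS-derived breeding density are treated as the same unit
(pairs ha⁻¹), as overlaying estimated densities on the fecundity–density
curves requires; nothing distinguishes nests from pairs in the model.

Curve fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`) with data-driven starts (f_max ← max value,
s_half ← first size exceeding half of it; l ← min value, t ← steepest
observed drop, α ← 4/size-range) and up to 10 seeded log-normal-jittered
restarts before declaring non-convergence. Identifiability contracts: ≥ 3
survival points at ≥ 2 distinct sizes; ≥ 4 density points at ≥ 3 distinct
sizes.

## Site-dependence occupancy model

The occupancy sums run over class mean sizes with class areas as weights —
a discrete model, with no within-class integration. One (D, F) point is
produced per non-empty class, thresholds descending from the largest class
sU to the smallest sL; density is strictly increasing and fecundity
non-increasing along the series (each newly occupied class has the lowest
survival so far). An optional fractional-occupancy refinement
(`interpolate=m`) linearly interpolates both sums in the occupied fraction
of the marginal class to densify curves; it is off by default since eight
class points suffice to fit the three Beverton-Holt parameters.

## Beverton-Holt shape analysis

F(D) = F_max/(1+(D/K)^γ). Closed forms used throughout (x = D/K):

* slope: F′ = −F_max·γ·x^{γ−1}/(K(1+x^γ)²)
* curvature: F″ = −F_max·γ·x^{γ−2}((γ−1)−(γ+1)x^γ)/(K²(1+x^γ)³)
* inflection: D_infl = K·((γ−1)/(γ+1))^{1/γ} for γ > 1, none otherwise.

The *convex* region in this analysis is the shallow-then-steep decline
below D_infl, where F″ < 0; the tipping point is the argmax of |F″| on
(0, D_infl), found from a 10⁴-point grid refined by bounded scalar
minimization (grid argmax as fallback). The search is restricted below the
inflection because |F″| grows again on the concave side. **Degenerate
regime:** for 1 < γ ≤ 2, F″ ∝ x^{γ−2} diverges as D → 0, so the argmax
sits at the boundary and the returned tipping density is the search
resolution's floor, not an interior optimum; the tipping point is a
resolution-independent quantity only for γ > 2. b′ = |F′(D̂)| at the
estimated density D̂, and the realized nest survival is F(D̂).

The fit optimizes log-parameters (positivity by construction) with
Levenberg-Marquardt, starting from F_max ← max F, K ← density of the point
nearest F_max/2, γ ← 1, with ≤ 10 jittered seeded restarts. A fit is
flagged poor when residual_ss/var(F) > 0.05 — a package convention standing
in for visual goodness-of-fit checks.

## Trends, density, buffer effect

The annual trend is the geometric mean annual proportional change between
endpoint years, (index(y1)/index(y0))^{1/(y1−y0)} − 1 (window 1987–1997 by
default), which inverts compounding exactly; an arithmetic mean of annual
changes is available by configuration since the two readings of "average
annual proportional change" differ. Breeding density is population
size / 2 / total forest area (pairs ha⁻¹). The buffer-effect test is a
Pearson correlation of |trend| against Q, classified inverse_buffer
(r > 0), buffer (r < 0) at two-sided p < 0.05, else none; the signed
trend-vs-Q correlation is reported alongside.

## Two-season analysis

|Δn| = |ΔF|·b′/(b′+d′) + |ΔM|·d′/(b′+d′); the weights sum to one. The
one-term variants c·d′/(b′+d′) (non-breeding) and c·b′/(b′+d′) (breeding)
are fitted to (b′, |Δn|) pairs by least squares over (c, d′) in log space.
d′ is treated as a single constant shared across landscapes and estimated
jointly with c; a fixed d′ (fitting c alone, a linear problem) is available
since published applications sometimes assume a value. When the observed
b′ span is below d′/10, c and d′ are nearly confounded and the fit is
flagged weakly identified. Diagnosis combines the Spearman rank correlation
of |Δn| with b′ (indeterminate below |ρ| = 0.3, a package convention) with
which variant fits better.

## Synthetic data: what it emulates and what it does not

* **Landscapes.** Patch areas are log-normal(μ, σ = 1.2) — the standard
  heavy-tailed patch-mosaic model — with the fragmentation gradient moving
  only μ (11 values, 0–4 log-ha), so fragmentation is not confounded with
  forest amount: class counts/areas are rescaled to a fixed 5×10⁵ ha of
  forest per landscape. Core area uses a square-patch geometry: side
  L = 100·√A m, core = max(0, L−2·30 m)² (the 30 m edge depth follows the
  standard core-forest definition; geometry is configurable). This yields
  Q spanning ≈ 0.47–0.91, covering the poor/moderate/good classes like the
  study region. The default 20 000 patches per landscape is census scale:
  inventory class tables enumerate every patch in a state, so the area
  weights of the sparse upper size classes must not carry Monte-Carlo
  noise; small patch samples (≲ 5×10³) make the largest-class weights of
  fragmented landscapes unstable and with them the fitted K and b′.
* **Vital-rate observations.** Gaussian noise (sd 0.05 by default) around
  the curves, clipped to valid ranges — no exposure-day structure, no
  covariates, no overdispersion.
* **Trend scenarios.** Per landscape, |Δn| = predicted_change(b′, scenario)
  plus truncated Gaussian noise (sd 0.005 = 0.5 %/yr), compounded into an
  index series declining from 100. The non-breeding default
  (|ΔM| = 0.11, |ΔF| = 0, d′ = 2.0) is calibrated so the steepest decline —
  in the least-regulated, best-quality landscape (b′ ≈ 0.6) — is ≈ 8 %/yr
  and moderate landscapes decline a few %/yr, matching the range reported
  for the study region; the breeding and mixed scenarios mirror it.

Consequences for interpretation: passing tests show the *pipeline* and the
*model logic* are correct under these idealized conditions. They do not
validate the square-core geometry against real edge delineation, the
log-normal mosaic against real inventories, or the noise structure of
BBS-derived indices (whose hierarchical index model is out of scope —
indices and population sizes are inputs here).

## Numerical conventions

* Degenerate inputs fail loudly: zero forest area, constant correlation
  inputs, all-equal b′, thresholds that are not class sizes, and missing
  endpoint years all raise typed errors rather than returning NaN.
* All fits bound restarts (≤ 10) and report the best residual on failure.
* Finite-difference verification of the Beverton-Holt calculus uses
  4th-order central stencils (relative steps 10⁻⁴ for F′, 5×10⁻³ for F″):
  plain central differences cannot reach 10⁻⁶ relative agreement for F″ in
  float64, and where a derivative is orders of magnitude below the function
  scale the comparison is anchored to the grid maximum since a pure
  relative test would only measure cancellation.
* Pipeline outputs are written with a fixed float format (`%.10g`) so
  same-seed runs are byte-identical.
* Replicate problem sizes (100 trend replicates, 200 fit-recovery
  replicates, 10⁶-point tipping grids) were chosen to make the Monte-Carlo
  checks stable at interactive runtimes.

## Known limitations

* The discrete class-threshold sweep produces at most one curve point per
  non-empty class; landscapes dominated by a single class give degenerate
  1–2 point series that cannot constrain the three-parameter fit.
* γ ≤ 2 tipping points are boundary-degenerate (above).
* b′ is a point estimate: uncertainty from the curve fits is not
  propagated, matching the source analysis.
* The full two-season equilibrium model (intersecting seasonal curves) is
  not implemented — only the shift-decomposition prediction; |ΔF| and |ΔM|
  are scenario inputs, never estimated from data.
* No GIS processing: core-vs-edge delineation from land-cover rasters is
  upstream of this package except in the synthetic generator's idealized
  geometry.
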