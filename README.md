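# fragdd

**Does forest fragmentation change the *shape* of density dependence — and
can that explain why a declining songbird declines fastest in its best
breeding habitat?**

`fragdd` is an analysis pipeline for quantitative population ecologists
studying territorial migratory birds (the motivating system is the wood
thrush, *Hylocichla mustelina*, in the northeastern USA). It links three
pieces of theory into one reproducible chain:

1. **Site dependence.** Breeders occupy forest patches largest-first, each
   patch filling to a saturation density d(s). With nest survival
   f(s) = f_max·s/(s_half + s) rising with patch size s and
   d(s) = l + (1−l)/(1+e^{α(s−t)}) falling with it, the mean nest survival
   of the population when all classes of size ≥ a are full is

   F(a) = Σ_{s≥a} f(s)d(s)A(s) / Σ_{s≥a} d(s)A(s),  D(a) = Σ_{s≥a} d(s)A(s) / Σ A(s),

   where A(s) is the area in size class s. Sweeping a from the largest
   class to the smallest traces the landscape's fecundity–density curve.

2. **Generalized Beverton–Holt shape analysis.** Each curve is summarized
   by F = F_max/(1+(D/K)^γ). The abruptness γ controls the shape: γ ≤ 1 is
   concave, γ > 1 a reverse sigmoid with an inflection at
   K·((γ−1)/(γ+1))^{1/γ} and a *tipping point* (argmax of |F″| below the
   inflection) where strong density dependence sets in. The realized
   strength of density dependence is b′ = |dF/dD| at the landscape's
   breeding density.

3. **Two-season (Sutherland) limitation.** For a migrant regulated in both
   seasons, a seasonal habitat shift changes population size by
   |Δn| = |ΔF|·b′/(b′+d′) + |ΔM|·d′/(b′+d′). The sign of the |Δn|-vs-b′
   relation across landscapes diagnoses whether breeding or non-breeding
   events drive the trends, and together with landscape quality
   Q = core forest / total forest it explains *buffer* (bigger changes in
   poor habitat) versus *inverse buffer* (bigger changes in good habitat)
   patterns.

Because the original inventory and survey data are not distributed, the
package ships a first-class synthetic-data module that generates landscapes
along a fragmentation gradient (log-normal patch mosaics with square-patch
30 m core geometry), vital-rate field observations, and abundance-index
series under either limitation scenario.

## Worked example

Run the numbered analysis scripts in order (each prints what it found and
writes tables under `results/`):

```sh
python analysis/01_simulate_inputs.py        # 11-landscape gradient
python analysis/02_landscape_quality.py      # Q = core/total per landscape
python analysis/03_fecundity_density_curves.py
python analysis/04_density_dependence_summary.py
python analysis/05_trends_and_two_season.py
```

The gradient spans Q ≈ 0.47–0.91 (poor → good). Step 03 fits the
generalized Beverton–Holt per landscape and prints

```
abruptness gamma rank-correlates with quality Q: Spearman rho = +1.000
```

— fragmented landscapes have almost linear (γ ≈ 0.5) fecundity–density
curves while contiguous ones are abruptly convex (γ ≈ 3.2), with tipping
points at 0.05–0.09 pairs ha⁻¹. Step 04 places each landscape's breeding
density on the flat low-density part of its curve and finds

```
b' vs Q:                Spearman rho = -0.991
realized survival vs Q: Spearman rho = +0.973
```

— better landscapes are *more weakly* regulated. Step 05 simulates declines
driven by non-breeding habitat loss and closes the argument:

```
trends span -0.0826 .. -0.0116 per year
|trend| vs Q: r = +0.932 (df = 9, p = 2.938e-05)
buffer-effect classification: inverse_buffer
rank corr(|dn|, b') = -0.973
limitation diagnosis: nonbreeding-limited
```

The steepest declines (≈ −8 % yr⁻¹) fall in the highest-quality landscapes:
two negative relations (|Δn| with b′, and b′ with Q) compose into the
inverse buffer effect.

The same chain is available as one command (`fragdd run --seed 0 --out
results/run`) or programmatically via
`fragdd.pipeline.run_full_analysis(PipelineConfig(...))`; `fragdd simulate`,
`quality`, `curves` and `diagnose` expose the individual stages.

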