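# wallbrown

Local adaptation of diapause timing in the range-expanding wall brown
butterfly (*Lasiommata megera*).

Swedish wall brown populations have expanded northwards along both the
eastern and western coasts since about 2000. For a bivoltine butterfly the
decision that matters most at a new latitude is *when to stop breeding*:
larvae use daylength as the calendar cue, entering winter diapause when
days are long enough to signal late season. The **critical daylength**
(CDL) — the photoperiod at which half of a population enters diapause — is
therefore expected to evolve upwards as populations move north, where
summers end under longer days. This package implements the full analysis
chain used to test that prediction, for ecologists who want to rerun,
check or adapt it: common-garden rearing data → diapause scoring → logistic
reaction norms → critical daylengths → latitudinal cline; and, in parallel,
citizen-science occurrence records → effort-controlled grid → range-margin
shift tests.

## The models

**Photoperiodic reaction norm.** For individual *i* of family *f* in
population *p*, the probability of diapause follows a binomial GLMM with
logit link:

    logit P(diapause_i) = β0_p + β1 · D_i + β_T · 1[22 °C] + u_f,
    u_f ~ N(0, σ_f²)

with daylength *D* in hours, one intercept per population (no global
intercept), a shared negative slope β1, a warm-treatment offset β_T, and a
family random intercept integrated out by adaptive Gauss–Hermite
quadrature (15 nodes). Fixed terms are tested with Type-II likelihood-ratio
tests, populations compared pairwise with single-step (Tukey-type)
max-|z| adjustment, and σ_f² tested with a boundary-corrected (halved-p)
LRT. The critical daylength is the inverse prediction

    CDL_p = β0_p / (−β1),

estimated from per-temperature models and given percentile-bootstrap 95%
intervals (resampling individuals within population × daylength cells,
refitting fixed-effects logistic models).

**Latitudinal cline.** CDL estimates θ_i with bootstrap variances v_i are
regressed on latitude x_i by random-effects meta-regression,
θ_i = α + γ·x_i + δ_i + ε_i with ε_i ~ N(0, v_i), δ_i ~ N(0, τ²), τ²
by REML — so imprecise estimates are down-weighted and residual
heterogeneity is explicit.

**Range expansion.** Occurrence records are projected (spherical transverse
Mercator, 15 °E), binned into 20 × 20 km squares, and compared across the
periods 1901–2000, 2001–2010 and 2011–2020. Squares with ≥ 100 butterfly
records in *every* period count as well-recorded; margin shifts are tested
on the 10 most extreme target-occupied squares per period (northernmost by
latitude, east/west of 14.31 °E; furthest inland by ln coastline distance)
with one-way ANOVA and Tukey HSD.

A synthetic-data module generates rearing experiments and occurrence
scenarios with known ground truth, so every stage is testable without any
data download.

## Worked example

Run the numbered drivers in order (about a minute in total):

```sh
python analysis/01_simulate.py          # synthetic inputs -> scratch/data/
python analysis/02_reaction_norms.py    # GLMM fits, LRTs, contrasts
python analysis/03_critical_daylengths.py
python analysis/04_latitude_cline.py
python analysis/05_range_expansion.py   # grid, margins, shift tests
```

`02` prints, for the simulated eastern cline (610 survivors after 4.7%
mortality):

```
                  term  chi2  df         p
             daylength 365.3   1 1.944e-81
  daylength:population 1.875   3    0.5988
            population 36.85   3 4.953e-08
           temperature 22.96   1 1.652e-06
temperature:population 3.278   3    0.3507
family variance estimate 0, boundary-adjusted p = 0.50
```

Daylength dominates the diapause decision; populations differ in their
intercepts (hence CDLs) but not in slope (no daylength × population
interaction); fewer larvae diapause at 22 °C; families add nothing beyond
the fixed effects. `03` then recovers the critical daylengths, e.g. for
the eastern cline at 16 °C:

```
Hassleholm   lat 56.16  CDL 15.60 h [15.29, 15.87]  (generator truth 15.90)
Rindo        lat 59.40  CDL 16.57 h [16.26, 16.89]  (generator truth 16.50)
```

— the northern population needs almost an hour more daylight to develop
directly. `04` quantifies the cline (`absolute: slope 12.7 min/degree
latitude, Z = 2.84, p = 0.00455`), and `05` shows the simulated front in
the occurrence grid (`latitude (east): F(2,27) = 623.80, p = 2.52e-23`,
with the mean top-10 latitude moving 1.7° north between the first and last
period).

The same stages are available as a CLI (`wallbrown simulate-experiment`,
`score`, `fit`, `cdl`, `cline`, `range`, `all`; see `wallbrown --help`)
driven by a flat YAML config, and as library functions in
`wallbrown.pipelines`.

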