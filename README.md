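# gatedscanner

Stochastic simulation and analysis of recombination-hotspot (Chi) recognition
by the bacterial helicase-nuclease AddAB.

When a double-stranded DNA break occurs in *Bacillus subtilis*, AddAB loads at
the broken end and translocates along the DNA, degrading it, until it reads a
Chi hotspot sequence.  Chi recognition flips the enzyme into a
recombination-promoting state (AddAB*): it pauses at the hotspot, resumes at a
reduced speed, protects the 3′ strand, and remains stably bound to Chi.  This
package implements a two-state **gated-scanner model** of that decision and
the analysis pipelines used to measure it in three classes of experiment:

* **magnetic-tweezers translocation traces** — position-vs-time records of
  single molecules, with pause detection at the Chi locus under the
  instrument's temporal resolution limit;
* **exonuclease-chase assays** — Chi-fragment survival time courses whose
  single-exponential decay reports the enzyme:Chi off-rate;
* **stopped-flow triplex-displacement assays** — population transients whose
  biphasic shape separates fast (unconverted) from slow (Chi-modified)
  translocating enzymes.

It is aimed at single-molecule biophysicists and enzymologists who want to
test pause-detection and kinetic-fitting procedures against ground truth, or
to explore how mutations (the ionic-latch mutant E129A, the Chi-binding
mutants F68A/F210A, and their combinations) reshape these observables.

## The model

A molecule enters the substrate at position 0 and translocates at `v_pre`
(bp/s).  At each Chi position met in the scanning state it forms a *stalled
encounter complex* with probability `p_pause`; the stall dwell is gamma
distributed with integer shape `pause_shape` (sequential kinetic sub-steps)
and scale `pause_scale` (s).  A stall ends in *commitment* to the Chi-modified
state with probability `p_commit` (translocation resumes at `v_post < v_pre`
and further Chi are ignored) or in release back to scanning.  Two independent
exponential clocks run during translocation: spontaneous isomerization to the
Chi-modified state at rate `k_iso` (per s; the latch-mutant phenotype) and
detachment at rate `k_detach` (per s; processivity).  The mature enzyme:Chi
complex dissociates at rate `k_off_chi` (per min), giving the chase half-life
t½ = ln2 / `k_off_chi`.

Key derived quantities:

* per-Chi conversion probability `c = p_pause * p_commit`, so the fast
  fraction on an *n*-Chi substrate is `(1 - c)^n`;
* fast fraction at distance `L` on Chi-free DNA is `exp(-k_iso * L / v_pre)`;
* locus pause frequency over an *m*-Chi locus is `1 - (1 - p_pause)^m`.

Packaged parameter sets (`make_default_params`) reproduce the measured values
for each enzyme variant at 22 °C and 37 °C; `list-variants --notes` prints the
observable behind every default.

## Worked example

```python
import numpy as np
import gatedscanner as g

# Single-molecule assay: 48 wild-type and 44 latch-mutant traces on the
# 7.7 kb, 10-Chi substrate; 60 Hz acquisition filtered to 3 Hz; pauses
# detected with the 0.33 s resolution censor.
bundle = g.run_scenario(g.single_molecule_scenario(seed=0))
print(bundle.tables["wildtype_traces"][["frequency", "median_s"]])
print(bundle.tables["E129A_traces"][["frequency", "median_s"]])

# Exonuclease chase: 500 molecules per lane, 5% densitometry noise.
wt = g.make_default_params("wildtype")
series = g.simulate_chase(wt, np.linspace(0, 6, 8), 500, noise_cv=0.05,
                          rng_seed=1)
fit = g.fit_exponential_decay(series, rng_seed=1)
print(f"t_half = {fit.t_half:.2f} min (95% CI {fit.ci_t_half[0]:.2f}-"
      f"{fit.ci_t_half[1]:.2f})")

# Triplex displacement on the 3-Chi substrate, 5000 molecules.
curve = g.simulate_triplex_curve(g.make_default_params("wildtype_37C"),
                                 g.triplex_substrate(n_chi=3), 5000, 10.0,
                                 rng_seed=1)
bf = g.fit_biphasic(curve, rng_seed=1)
print(f"converted to the slow state: {100 * (1 - bf.a1):.1f}%")
```

Output:

```
   frequency  median_s
0      0.708     1.292
   frequency  median_s
0      0.523     0.995
t_half = 2.92 min (95% CI 2.71-3.25)
converted to the slow state: 49.7%
```

Reading: 70.8% of wild-type traces show a detectable pause at the Chi locus
with a censored median dwell of 1.29 s (the latch mutant pauses less often
and for shorter: 52.3%, 1.00 s); a single 48/44-trace ensemble carries ~15%
sampling noise on these medians.  The fitted chase half-life recovers the
wild-type enzyme:Chi off-rate (t½ ≈ 3 min), and the biphasic fit of the
triplex transient reports that about half the wild-type population was
converted to the slow Chi-modified state by three hotspots.

The same pipelines are exposed on the command line:

```sh
gatedscanner simulate --variant wildtype --n-traces 10 --seed 1 --out traces/
gatedscanner analyze-traces traces/trace_*.csv
gatedscanner run-scenario --seed 0
gatedscanner list-variants --notes
```

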