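# glympipe

Glymphatic-function MRI biomarkers in amyotrophic lateral sclerosis (ALS),
implemented as a tested, reusable analysis pipeline. The glymphatic system —
the perivascular pathway thought to clear interstitial solutes via CSF–ISF
exchange — cannot be observed directly in humans, so studies proxy it with
three MRI-derived markers. This package computes all three from tabular /
1-D signal inputs, runs the cohort statistics around them, and fits the
combined diagnostic model, for researchers who have the upstream imaging
derivatives (or want to study the methods on simulated cohorts).

## The markers and the model

**gBOLD–CSF coupling.** During low-frequency drops in global cortical
activity, reduced cerebral blood volume draws fresh CSF into the imaging
volume, so the CSF inflow signal tracks the *negated time derivative* of the
global BOLD signal (−d/dt gBOLD). The coupling statistic is the lagged
Pearson correlation r(L) between gBOLD (advanced by L) and CSF on a ±10 s
grid; the scalar **coupling index** is −r(+4 s), where the cross-correlogram
of derivative-coupled signals with a ~16 s dominant period has its negative
extremum. Group-level significance comes from a subject-pair permutation
test (CSF series reassigned across subjects, 10,000 draws, two-sided
add-one p per lag).

**DTI-ALPS.** "Analysis along the perivascular space": at the level of the
lateral-ventricle body, the perivascular direction (x) is perpendicular to
both projection fibers (z) and association fibers (y), so the ratio

```
ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)
```

of directional diffusivities isolates perivascular diffusion; values near 1
mean none, higher values more. Computed per hemisphere and averaged
(a pooled mode is also provided).

**CPV fraction.** Choroid-plexus volume as a percentage of total
intracranial volume, `100 · CPV / TIV`; the choroid plexus produces CSF and
enlarges in neuroinflammation.

**Statistics & diagnostics.** Normality-gated group comparisons
(Shapiro–Wilk, then Student's t or Mann–Whitney U), Pearson correlations
with Benjamini–Hochberg FDR over a declared family, duration-adjusted
partial correlation, two-way ICC for retest reliability, per-marker ROC
(AUC = Mann–Whitney probability, DeLong 95% CI, Youden cut-off), an
unregularized three-marker logistic model rendered as a 0–100-point
nomogram, bootstrap optimism-corrected calibration, and decision-curve
net benefit `TP/N − FP/N · pt/(1−pt)`.

Because the source study's subject-level data are not deposited, the
package ships a seeded **synthetic cohort generator** that reproduces the
published group distributions (ALPS 1.20±0.16 vs 1.36±0.14; coupling
0.01±0.13 vs 0.16±0.14; CPV fraction ~0.09% vs ~0.06%; 41 ALS / 43 HC),
imposes the within-ALS ALPS–CPV-fraction correlation of −0.537 through a
Gaussian copula, and synthesizes gBOLD/CSF signal pairs obeying the
derivative coupling — so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (seed 17), writing tables to `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_coupling.py
python analysis/03_markers_stats.py
python analysis/04_diagnostics.py
```

`02_coupling.py` prints:

```
84 subjects, 230 time points each after discarding 10 volumes
group-mean correlogram: negative extremum r = -0.937 at +4 s, positive extremum r = 0.936 at -4 s
permutation test (n_perm = 10000): p = 1.00e-04 at +4 s
```

i.e. the derivative coupling places the anticorrelation peak exactly at the
+4 s lag where the coupling index is read, and no permutation of
subject pairings reproduces it. `04_diagnostics.py` prints:

```
coupling_index: AUC = 0.799 (95% CI 0.703-0.895), cutoff = 0.151, sens = 0.854, spec = 0.674
alps_index: AUC = 0.748 (95% CI 0.640-0.856), cutoff = 1.26, sens = 0.707, spec = 0.791
cpv_fraction_pct: AUC = 0.736 (95% CI 0.623-0.848), cutoff = 0.0668, sens = 0.756, spec = 0.698
combined_model: AUC = 0.884 (95% CI 0.813-0.955), cutoff = 0.581, sens = 0.780, spec = 0.884
```

each marker discriminates moderately on its own; combining the three in the
logistic nomogram lifts the AUC to ~0.88 on this cohort.

The same stages are exposed as a CLI (`glympipe simulate|prep|coupling|
markers|stats|roc|model|dca|run|validate`), e.g.

```bash
glympipe run --simulate --seed 7 --out /tmp/run
glympipe validate /tmp/run/subject_table.csv
```

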