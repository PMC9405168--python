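# spinemorph

Dendritic spine morphometry for traced neuron reconstructions: rule-based
four-class spine classification, spine density per 10 µm of dendritic
trunk, and nonparametric cross-group comparison — built around the
granule-cell spine analysis of the European eel (*Anguilla anguilla*)
olfactory bulb across its four continental life stages (glass eel, elver,
yellow eel, silver eel).

It is written for neuroanatomists who have traced dendritic segments (SWC
dialect with per-node radii, or pre-measured per-spine geometry tables)
and want a deterministic, scriptable replacement for interactive spine
scoring, plus the statistics that go with it. A calibrated synthetic-study
generator makes the whole pipeline testable end to end without microscopy
data.

## What it computes

**Classification.** Each spine is measured as (total length, head
diameter, maximum neck diameter, neck length), all µm, and assigned by
fixed rules: a headed spine is **mushroom (M)** when its neck is thicker
than it is long and **long thin (LT)** otherwise; a headless protrusion is
**stubby (S)** below 1 µm total length and **filopodium (F)** above 10 µm.
Headless protrusions between those bounds are assigned to S with an
explicit audit flag.

**Density.** For a traced segment of arc length ℓ ≥ 10 µm bearing n_c
spines of class c,

    density_c = n_c / ℓ × 10   (spines/10 µm),

summarised as mean ± SE per stage × class over segments.

**Inference.** Tie-corrected Kruskal–Wallis H with χ² p (df = k − 1),
Dunn's pairwise post hoc Z on pooled mean ranks (optionally Bonferroni/
Holm adjusted), an advisory Shapiro–Wilk gate, significance codes
(`****` < 0.0001 … `*` < 0.05, else `ns`), and OLS regressions of
per-animal mean density on log10 body metrics with the R² ≥ 0.7 & p < 0.05
significance criterion.

**Synthesis.** A stage × class rate table calibrated so that its rows sum
to the published stage totals (6.67, 4.45, 3.73, 5.71 spines/10 µm) and
its balanced pooled class means match the published pooled values; Poisson
(or over/under-dispersed) per-segment counts; class-conditional geometries
the classifier recovers exactly; 19 animals' biometrics. See
`docs/methods.md` for the model details and design choices.

## Worked example

Run the full synthetic pipeline from the shell:

```sh
spinemorph run-all --seed 42 --out-dir demo
```

`demo/summary_table.tsv` then holds the stage × class density summary
(rounded here):

```
 stage  total_mean  total_se  M_mean  LT_mean  S_mean  F_mean
 glass        6.40      0.26    2.55     2.48    1.24    0.13
 elver        4.14      0.24    1.97     1.04    1.02    0.11
yellow        3.59      0.20    1.40     0.92    1.26    0.01
silver        5.87      0.26    2.72     1.61    1.54    0.00
pooled        5.00      0.14    2.16     1.52    1.27    0.06
```

Each row is the mean spine density (spines/10 µm) over that stage's 77
simulated segments with its standard error: total density is high in the
two migratory stages (glass, silver), dips through the resident stages,
and mushroom spines are everywhere the dominant class — the pattern the
calibration encodes. `demo/kw_dunn_total.tsv` carries the four-stage
comparison of total density:

```
group_a group_b    KW_H       Z        p_raw significance
  glass   elver 74.4545  5.7992 6.664107e-09         ****
  glass  yellow 74.4545  7.3320 2.267576e-13         ****
  glass  silver 74.4545  1.2541 2.097981e-01           ns
  elver  yellow 74.4545  1.5328 1.253216e-01           ns
  elver  silver 74.4545 -4.5451 5.492051e-06         ****
 yellow  silver 74.4545 -6.0779 1.217889e-09         ****
```

The Kruskal–Wallis H of 74.45 (df = 3) rejects equality of the stage
medians; Dunn's Z shows the two migratory stages indistinguishable from
each other (`ns`) but separated from the trophic stages. The remaining
outputs are the per-segment density records, the class-within-stage and
stage-within-class Dunn tables, the biometric regression table, and a
JSON manifest making the run reproducible byte for byte.

The same verbs work stepwise (`generate`, `classify`, `density`, `stats`,
`report`) and on your own data: `run-all --mode from_files --spines
spines.tsv --segments segments.tsv --biometrics biometrics.tsv`.

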