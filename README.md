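# itraqdiff

Differential protein inference for iTRAQ 4-plex reporter-ion proteomics,
built around a Gaussian null model of log-ratio technical variation.

In a 4-plex isobaric-label experiment, each channel (reporter ions at m/z
114–117) carries one pooled sample — for instance epithelial lining fluid
from groups of smokers before and after an acute smoking exposure. For
every identified peptide, the MS/MS reporter-ion peak areas give relative
abundances, and the ratio of two channels' areas measures the change of
that peptide's protein between the two conditions. The analytical problem
is deciding which ratios reflect real regulation rather than random
technical variation. `itraqdiff` answers it the way small pooled designs
without biological replicates require: by *estimating the technical null
directly from the bulk of the data*.

For each contrast `c = ln(area_num / area_den)`, the natural-log ratios of
all peptides are histogrammed on [−1, +1] in 200 bins, smoothed with a
Savitzky–Golay filter, and a Gaussian `A·exp(−(x−μ)²/(2σ²))` is fitted to
the smoothed counts. Since most proteins do not change, the fitted σ
estimates random ratio variation. A peptide is *discriminatory* when

```
|ln_ratio − μ| ≥ k·σ        (k = 2.5 → two-sided confidence 2Φ(2.5)−1 ≈ 98.8%)
```

and carries the two-sided p-value `2(1 − Φ(|ln_ratio − μ|/σ))`. Proteins
are reported as the median ratio of their discriminatory peptides, and a
protein becomes a candidate only if it is significantly changed *in the
same direction in both technical duplicates*, with ≥ 2 peptides at
p < 0.02 in each. A companion module provides the exact (fully enumerated)
Wilcoxon signed-rank and Mann–Whitney U tests used to validate candidates
on per-subject concentrations, plus a ground-truth synthetic-data
generator for end-to-end verification.

## Worked example

```python
from itraqdiff import (SimulationConfig, generate_replicate_pair,
                       run_quantification, run_report)

cfg = SimulationConfig(n_proteins=300, de_fraction=0.05, effect_ln_fc=1.0,
                       null_sigma=0.15, seed=1)
exp1, exp2, truth = generate_replicate_pair(cfg)
print("peptides per experiment:", len(exp1))
print("truly changed proteins:", sum(t.is_changed for t in truth))

bundle = run_quantification([exp1, exp2])
fit = bundle.null_fits[("exp1", "s_after_vs_before")]
print(f"fitted null (exp1, s_after_vs_before): mu={fit.mu:+.4f} sigma={fit.sigma:.4f}")
print("candidates:", len(bundle.candidates))
```

prints

```
peptides per experiment: 1239
truly changed proteins: 18
fitted null (exp1, s_after_vs_before): mu=+0.0006 sigma=0.1561
candidates: 18
```

The generator planted 18 truly changed proteins (5% of 300) at
|ln FC| = 1.0 on the susceptible after/before contrast (channels 116/117);
the fitted σ of 0.156 recovers the generating technical SD of 0.15 from
the contaminated mixture, and the duplicate-concordance selection returns
exactly the planted proteins — for example:

```
protein_accession          contrast call  median_ratio_exp1  median_ratio_exp2
         SIM00009 s_after_vs_before   up              2.68               2.79
         SIM00034 s_after_vs_before down              0.34               0.40
```

(`exp(±1.0) ≈ 2.72 / 0.37`, so the median discriminatory-peptide ratios sit
on the planted effects). `run_report(bundle)` renders the same content as
a text table in which proteins that did not reach significance show the
`σ <2.5` marker and single-peptide values carry a `*` footnote.

The same pipeline runs from the shell:

```bash
itraqdiff simulate --n-proteins 300 --seed 1 --out-dir sim/
itraqdiff quantify --table sim/exp1.tsv --table sim/exp2.tsv --k 2.5 --out-dir run/
itraqdiff report --table sim/exp1.tsv --table sim/exp2.tsv
itraqdiff compare --measurements elisa.tsv --out stats.tsv
```

For the validation arm, exact small-sample rank tests:

```python
from itraqdiff import wilcoxon_signed_rank
res = wilcoxon_signed_rank(before, after, method="exact")  # enumerates 2^n sign flips
res.statistic, res.p_two_sided
```

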