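# phyloinv

Phylogenetic relatedness, phylogenetic signal, spatial statistics and
trait models for analyses of plant invasiveness — built around the
question raised by Darwin's naturalization hypothesis: are invasive
alien species more, or less, closely related to the native flora than
alien species that never become invasive?

The package is aimed at ecologists and evolutionary biologists who have
(i) a dated, ultrametric phylogeny of a regional flora, (ii) a species
table classifying taxa as native, non-invasive alien or invasive alien
(with alien group, Ellenberg indicator values, height, life-form,
clonality and a range-change index), (iii) survey plot occurrences
(square → plot → species), and (iv) gridded richness of the two alien
groups.  A synthetic-data module generates all four inputs with the
statistical structure the analyses assume, so the whole pipeline runs
and is testable without any restricted survey data.

## What it computes

**Relatedness of aliens to natives**, at two spatial scales, using two
per-alien metrics on the dated tree (branch lengths in My):

- *PNND* — phylogenetic nearest-neighbour distance,
  `PNND(a) = min over natives j of d(a, j)`, where `d` is the patristic
  distance (total intervening branch length);
- *MPD* — mean phylogenetic distance,
  `MPD(a) = mean over natives j of d(a, j)`.

At the country scale the native pool is the whole native flora; at the
plot scale it is the natives co-occurring in each survey plot (plots
without at least one native and one alien are excluded and counted).
Group differences are tested with a two-group linear model at the
country scale, and at the plot scale with a REML linear mixed model,
`PNND or MPD ~ invasiveness + (1 | species/square)`.

**Phylogenetic signal of invasiveness** with the Fritz–Purvis D
statistic for binary traits:

```
D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian)
```

where `d` is the sum of sister-clade contrasts of the 0/1 trait under a
branch-length-weighted down-pass, and the two null means come from
permuting the labels across tips and from a Brownian threshold model
(both at the observed prevalence, simulated on the same tree).
E[D] = 1 for a random trait, E[D] = 0 for a Brownian-threshold trait;
D < 1 indicates phylogenetic clustering of invasiveness.

**Spatial congruence of invasive vs non-invasive richness** with
Spearman's rank correlation tested by Dutilleul's modified test, which
replaces the nominal n − 2 degrees of freedom with an effective sample
size estimated from the Moran correlograms of both surfaces; and
loess (local second-degree polynomial) regression of invasive on
non-invasive richness, whose residuals locate invasion "hot spots".

**Trait models of invasiveness**: a design matrix of treewide PNND,
alien group, absolute traits, and differences to the nearest native
relative (native − alien for continuous traits, 0/1 mismatch for
categorical ones) feeds all-subsets binomial GLMs with at most five
variables per model, combined by AICc model averaging (Akaike weights,
full zero-substituted averages, unconditional SEs, 95% CIs and relative
variable importance).  A Wilcoxon rank-sum test checks that invasive
aliens increased more in range (change index) than non-invasive aliens.

## Worked example

```python
from phyloinv import synthetic_data as sd, signal_d as sig
from phyloinv import relatedness as rel, trait_models as tm

cfg = sd.SimConfig(n_tips=400, n_squares=40, plots_per_square=25, seed=42)
data = sd.simulate_dataset(cfg)
tree, species = data["tree"], data["species"]

print(sig.d_by_group(tree, species, n=1000, seed=0).round(3))
country = rel.country_relatedness(tree, species)
print(tm.country_group_lm(country).round(3))
```

prints

```
             group  n_invasive  n_noninvasive      D  p_random  p_brownian
naturalized aliens          22             68 -0.278     0.000       0.808
         neophytes          14             43 -0.354     0.000       0.783
     archaeophytes           8             25  0.094     0.046       0.478

response  mean_invasive  mean_noninvasive      t  df     p
    pnnd         90.267            71.267  1.174  88 0.243
     mpd        660.207           711.737 -3.444  88 0.001
```

The default generator assigns invasiveness by thresholding a Brownian
liability, so D sits near its Brownian anchor of 0 (well below the
random anchor of 1, with small `p_random`: invasiveness is strongly
clustered on the tree).  The country-scale PNND of invasive aliens does
not differ significantly from that of non-invasive aliens (t = 1.174,
df = 88, p = 0.24).  Continuing with the survey plots:

```python
plot_recs, filt = rel.plot_relatedness(tree, species, data["plots"])
res = tm.fit_nested_lmm(plot_recs, "pnnd")
print(res.mean_invasive, res.mean_noninvasive)
```

retains 1000 of 1000 plots (the generator enforces the ≥1 native and
≥1 alien survey filter) with 1463 alien occurrences and estimates
plot-scale mean PNND 407.1 ± 19.0 My for invasive vs 414.4 ± 10.6 My for
non-invasive aliens — again no significant difference, the pattern the
relatedness analysis is designed to detect or reject.

The same analyses run from the command line on files:

```
phyloinv simulate --seed 1 --out-dir data/
phyloinv all --tree data/tree.nwk --species data/species.csv \
    --plots data/plots.csv --grid data/grid.csv --out-dir results/
```

writing one CSV per result table plus a machine-readable
`run_report.json` (versions, seeds, filter counts, warnings).  Runs are
byte-identical under a fixed seed.

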