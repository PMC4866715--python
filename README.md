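# otbiomon

Analysis toolkit for organotin biomonitoring with marine neogastropods.

Tributyltin (TBT) and triphenyltin (TPT), the active agents of legacy
antifouling paints, induce **imposex** — the superimposition of a penis and
vas deferens on female snails — at vanishingly small exposures. Long-term
monitoring programmes therefore survey rocky-shore populations of rock
shells (*Reishia clavigera*), score each female's vas deferens sequence
(VDS) stage 0–6, and measure six organotin residues in pooled tissue. This
package implements the full analysis chain for such surveys, for
ecotoxicologists and environmental managers running or re-analysing them:

* **Imposex indices** per site: mean/median VDSI, RPSI
  (100 × (mean female penis length)³ / (mean male penis length)³),
  % imposex, % sterile females (VDS ≥ 5), and the condition index
  (fresh tissue × 100 / (fresh tissue + dry shell)).
* **Tissue chemistry** for the six-analyte panel MBT/DBT/TBT/MPT/DPT/TPT:
  left-censoring substitution, totals and composition, degradation indices
  BDI = ([MBT]+[DBT])/[TBT] and PDI = ([MPT]+[DPT])/[TPT], and dry-weight →
  wet-weight tin-equivalent conversion.
* **Probabilistic risk assessment**: fit measured tissue concentrations
  (MTC) and literature no-effect tissue concentrations (PNETC) with
  log-logistic or Pareto models (selected by Kolmogorov–Smirnov distance),
  then estimate P(RQ ≥ 1) for the risk quotient RQ = MTC/PNETC by Monte
  Carlo (10,000 iterations × 10 repeats).
* **Trend statistics**: paired t tests on log10 indices and Wilcoxon
  signed-rank tests between survey epochs, Spearman rank correlations with
  Holm (sequential Bonferroni) correction, including distance-to-shipping
  gradients.
* **Synthetic data**: a seeded generator in which one latent per-site
  exposure, decaying with distance from shipping, drives both imposex
  stages and tissue concentrations — so every stage of the chain is
  testable end to end without field data.

A site-level index table for three survey epochs (2004–06, 2010, 2015;
29 sites along the Hong Kong coast) ships with the package as a worked
reference dataset.

## Worked example

```python
import otbiomon as ob

tidy = ob.load_table1_fixture()          # 29 sites x 3 epochs, tidy frame
trends = ob.epoch_trend_tests(tidy)
print(trends[["variable", "epoch_x", "epoch_y", "statistic", "n_pairs", "p_value"]])
```

```
      variable  epoch_x epoch_y  statistic  n_pairs   p_value
0    mean_vdsi  2004-06    2010   0.330207       28  0.741244
1    mean_vdsi     2010    2015   2.411655       10  0.039143
2         rpsi  2004-06    2010   4.350221       28  0.000174
3         rpsi     2010    2015   2.428809       10  0.038057
4  pct_sterile  2004-06    2010   3.457143       24  0.000546
5  pct_sterile     2010    2015   1.885695       10  0.059336
```

Mean VDSI did not change between 2004–06 and 2010 (Wilcoxon Z = 0.33,
p = 0.74) but rose significantly from 2010 to 2015 (paired t on log10
values, t = 2.41, p = 0.039); RPSI rose in both intervals. The degree of
imposex, not its incidence, carries the temporal signal — every surveyed
site already shows 100 % imposex.

The same API runs the risk assessment on any tissue/toxicity tables:

```python
config = ob.GeneratorConfig(seed=1, n_sites=25)
table = ob.site_chemistry_table(ob.generate_tissue(config))
endpoints = ob.generate_toxicity("log_logistic", {"alpha": 2000.0, "beta": 1.5},
                                 n=6, seed=1)
inputs = ob.RiskInputs(mtc_values=table["total_pts"],
                       pnetc_values=[e.endpoint_ug_kg_dw for e in endpoints])
result = ob.monte_carlo_rq(inputs, iterations=10_000, repeats=10, seed=1)
print(f"P(RQ >= 1) = {result.p_at_risk:.3f} +/- {result.sd_over_repeats:.4f}")
```

```
P(RQ >= 1) = 0.541 +/- 0.0042
```

i.e. in this synthetic phenyltin scenario the population has a 54 % chance
of being at risk (risk quotient at least 1), with the spread over the ten
Monte-Carlo repeats shown after the estimate.

A `click` CLI wraps the same functions:

```sh
otbiomon simulate --seed 1 --n-sites 25 --out data/
otbiomon indices data/survey.csv --out summaries.csv
otbiomon chem data/tissue.csv --out chem.csv
otbiomon risk data/tissue.csv data/toxicity.csv --group PT --seed 1 --out risk.json
otbiomon trends --out-dir trends/
```

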