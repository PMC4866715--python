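# Methods

This note records the statistical conventions, defaults and numerical
choices the package commits to, and what its synthetic data can and cannot
tell you about real surveys.

## Imposex indices

Each female carries a vas deferens sequence (VDS) stage 0–6. Site-level
indices:

* **VDSI** — arithmetic mean (and median) of stages over staged females.
* **% imposex** — fraction of females with stage > 0, × 100.
* **% sterile females** — fraction at or above the sterile threshold,
  default stage 5 (the proliferating vas deferens tissue blocks the
  vulva). The threshold is configurable (`ImposexConfig`); 5 is the
  conventional choice and is consistent with the packaged reference table
  (the site with mean VDSI 5.73 shows 93.3 % sterile females).
* **RPSI** — 100 × (mean female penis length / mean male penis length)³.
  The cube approximates a bulk comparison; the exponent is configurable.
  Females whose penis is unmeasurable contribute length 0 to the female
  mean rather than being dropped: this is conservative and keeps RPSI
  defined at low-imposex sites. RPSI is dimensionless — any common
  rescaling of lengths cancels.
* **Condition index** — fresh tissue weight × 100 / (fresh tissue weight +
  dry shell mass), averaged over every individual carrying both masses.

## Tissue chemistry

The panel is MBT, DBT, TBT (butyltins) and MPT, DPT, TPT (phenyltins), in
μg of compound (cation basis) per kg dry tissue.

* **Censoring**: values below the analytical detection limit (0.2–1.5
  μg kg⁻¹ dw, per analyte) are substituted at DL/2 by default — the common
  ecotoxicological convention; `zero` and `dl` policies are available and
  the censoring flag is retained on the substituted value so analyses can
  exclude censoring-dominated replicates.
* **Replicates**: tissue replicates (pools of 8–15 snails, 3–4 pools per
  site) are averaged per site-year; all site-level analyses consume those
  means, matching the one-point-per-site construction of the SSD figures.
* **Degradation indices**: BDI = ([MBT]+[DBT])/[TBT], PDI =
  ([MPT]+[DPT])/[TPT]. Values > 1 indicate aged inputs, < 1 recent inputs.
  A zero denominator leaves the index undefined (reported as missing, not
  an error).
* **Tin equivalents**: μg compound kg⁻¹ dw × (118.71 / cation molecular
  mass) × (1 − moisture) gives μg Sn kg⁻¹ ww. Cation masses: MBT 175.87,
  DBT 232.97, TBT 290.06, MPT 195.86, DPT 272.97, TPT 350.03 g mol⁻¹;
  default moisture 0.80. With these defaults the conversion reproduces
  published dw/ww-Sn concentration pairs for this matrix to ~0.3 %; the
  residual suggests slightly different speciation or per-sample moisture
  upstream, so both knobs are exposed.

## Species-sensitivity distributions and risk

MTC (measured tissue concentration, one replicate-mean total per site) and
PNETC (literature chronic tissue-residue endpoints, ≥ 3 values) samples are
each fitted with two positive-support families:

* log-logistic, F(x) = 1/(1 + (x/α)^(−β)) — fitted by maximum likelihood
  as a logistic model on log values (Nelder–Mead, parameter tolerance
  1e-9, non-convergence raises);
* Pareto, F(x) = 1 − (x_m/x)^a — closed-form MLE x_m = min x,
  a = n / Σ ln(x_i/x_m). A zero-log-spread sample is flagged degenerate
  (point mass, a → ∞) rather than fitted.

The family with the smaller Kolmogorov–Smirnov distance to the empirical
CDF is selected; both candidates (with KS and AIC) are retained in the
result so the other choice can be replayed. Endpoint sets smaller than 3
are rejected: a two-point sample cannot meaningfully identify a
two-parameter family.

**Risk quotient**: RQ = MTC/PNETC, with the population "at risk" when
RQ ≥ 1. MTC and PNETC are drawn independently (no dependence structure is
assumed); per repeat, 10,000 pairs are drawn by inverse-CDF sampling, the
RQ sample is truncated at RQ ≥ 0 (vacuous for these families; kept for
procedural fidelity and config extensibility), and P(RQ ≥ 1) is the
exceedance fraction. The reported probability is the mean over 10 repeats,
with the between-repeat SD and pooled RQ quantiles (5/50/95 %) alongside.
Substreams derive deterministically from the user seed via
`numpy.random.SeedSequence.spawn`, so results are reproducible per seed and
the two analyte groups in a report use independent streams (seeds `s` and
`s + 1`). P(RQ ≥ 1) is exactly invariant under a common rescaling of MTC
and PNETC units. The Monte-Carlo estimate is validated in the tests against
a quadrature oracle, P = ∫₀¹ S_MTC(F⁻¹_PNETC(u)) du.

A report additionally tallies "severely impacted" sites: those whose MTC
exceeds the smallest PNETC endpoint.

## Trend statistics

* **Paired t on log10**: classical paired t on d = log10(later) −
  log10(earlier); requires positive values; two-sided p; zero-variance
  differences raise a degenerate-input error.
* **Wilcoxon signed-rank**: zero differences dropped; midranks on tied
  |d|; W⁺ compared with n(n+1)/4; variance n(n+1)(2n+1)/24 − Σ(t³−t)/48
  over tie groups; **no continuity correction**; two-sided normal p. This
  dialect is pinned deliberately: it exactly reproduces the reference
  Z = 0.330 for the 2004–06 vs 2010 VDSI comparison, which identifies the
  convention the original analysis used. Note the Z statistic is only
  invariant under increasing *affine* transforms of the data — nonlinear
  monotone maps reorder the absolute differences and change Z (the signs,
  and hence the sign test, are what survive arbitrary monotone maps).
* **Pairing** across epochs is by site identifier; sites missing either
  epoch drop out of that comparison.
* **Spearman** uses midranks with the two-sided t approximation (n − 2 df).
* **Multiplicity**: Holm's step-down procedure (the standard "sequential
  Bonferroni"), applied per correlation family (one table at a time).
* The default epoch-comparison plan tests mean VDSI, RPSI and % sterile
  females; the Wilcoxon test is used for indices with many ties or
  boundary values (stage means, percentages), the log10 paired t where the
  change is near-multiplicative on a positive scale (RPSI; VDSI for the
  2010→2015 pair, where the 10-site subsample is tie-free).

## Synthetic data generator

One latent per-site exposure, E_s = exp(a − b·distance_s) × lognormal
noise, drives everything: female VDS stages (mean stage = 4.5 +
0.6 ln E_s plus unit-SD individual noise, rounded and clipped to 0–6) and
per-analyte tissue geometric means (GM ∝ E_s, TPT base 2000 μg kg⁻¹ dw
dominating the panel, replicate log-SD 0.3). Defaults — 25 sites at
distances uniform on 0.2–15 km, a = 1.5, b = 0.25 km⁻¹, 40 individuals per
site with shell lengths 17–36 mm and roughly even sex ratio — were chosen
once so that site summaries span a realistic contaminated-harbour
gradient: mean VDSI ≈ 2.5–5.7, RPSI from ~1 % to tens of percent, TPT
composition ≈ 90 %, and phenyltin totals spanning roughly 250–10,000
μg kg⁻¹ dw. Toxicity endpoint sets are drawn from a chosen log-logistic or
Pareto truth (default size 6) so parameter recovery can be verified.

What the generator does *not* emulate: temporal autocorrelation between
epochs, within-site spatial structure, sex-ratio bias, measurement error
in staging, inter-laboratory analytical bias, or any toxicokinetics — the
exposure→stage link is a phenomenological monotone map, not a dose–response
model. Passing the end-to-end tests therefore shows the analysis chain
recovers structure that is present by construction; it does not validate
the biological model against field data.

## Numerical and validation choices

* All validation runs are seeded; the test suite uses modest problem sizes
  (Monte-Carlo 10,000 × 10; parameter recovery at n = 50–5000; exact
  Wilcoxon enumeration at n ≤ 10; 1,000 random p-vectors for the Holm
  cross-check).
* Degenerate inputs fail loudly (zero-variance differences, constant
  correlation vectors, zero totals, censored entries without a detection
  limit) except where a missing value is the scientifically meaningful
  answer (degradation index with a zero denominator).
* CSV I/O is comma-separated UTF-8 with a header row, "." decimals and
  empty strings for missing values; floats are written at full precision
  (`repr`) so write→read round-trips exactly. The CLI's JSON reports round
  to 6 significant digits for regression-stable output.
* Reference statistics on the packaged index table treat 2004–06 as a
  single baseline epoch, join epochs on site id, and drop sites missing
  either member of a pair (one 2010 site lost to shoreline development;
  19 sites not revisited in 2015).

## Known limitations

* The % sterile-female 2004–06 vs 2010 comparison yields Z ≈ 3.46 under
  this package's Wilcoxon dialect; reference analyses of the same table
  have reported other values for this one statistic (percentage data may
  have been transformed before testing), so it is reported but not pinned
  to a reference value.
* Model selection by minimum KS distance is a pragmatic rule (commercial
  fit-ranking tools rank by GOF statistic); AIC is reported alongside and
  both candidate fits are kept, but no model averaging is attempted.
* PNETC endpoint values are inputs; the package does not re-derive them
  from the primary toxicological literature, and no HC5-style regulatory
  threshold is computed.
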