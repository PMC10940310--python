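# Methods

## The problem

Effective dose, as commonly produced for CT, comes in flavors that are not
interchangeable. The DLP-based estimate `E_DLP = k · DLP` converts a scanner
output (dose–length product, mGy·cm) to mSv with a body-region coefficient
for a reference adult, ignoring the patient entirely. The organ-dose based
estimate `E_OD = Σ_T w_T · OD_T` weights Monte-Carlo organ doses with the
ICRP 103 tissue weighting factors, capturing the irradiated anatomy but still
averaging radio-sensitivity over ages and sexes. Radiation detriment,
however, depends strongly on both: the BEIR VII lifetime attributable risk
(LAR) of cancer incidence falls steeply with age at exposure and differs by
sex.

The package implements a risk-aware chain of metrics for cohorts of patients
with recurrent CT imaging:

- **Risk index** `RI = Σ_T r_T(sex, age) · OD_T`, with `r_T` the BEIR VII
  incidence LAR of the cancer site fed by organ `T`, expressed as cancers per
  100 patients (raw table values, cases per 100,000 per 0.1 Gy, are divided
  by 100,000 and organ doses in mGy are treated as mSv, exact for photons).
- **Reference-patient risk index** `RI_rp`: the same sum with sex-averaged
  coefficients at age 35, on the identical organ-dose vector.
- **f-factor** `f = RI / RI_rp`, a dimensionless age/sex adjustment
  (elderly patients have `f < 1`).
- **Relative effective dose** `E_r = f · E_OD` (unit mSv'), an
  effective-dose-like quantity carrying age and sex dependence.

Cohort-level comparison regresses each of `E_DLP`, `E_OD`, `E_r` on `RI`
through the origin (`slope = Σxy / Σx²`) and reports the **Risk Sensitivity
Index** `RSI = slope / (mean(y)/mean(RI))` (1 is ideal) and the **Risk
Differentiability Index** `RDI = RMSE / slope` (0 is ideal).

## Coefficient data and conventions

- **Tissue weights** (ICRP 103): 14 individually weighted tissues plus a
  0.12 remainder block evaluated as the arithmetic mean of its member
  tissues. The monitored-organ vocabulary (25 names) covers every weighted
  tissue (testes/ovaries feed the `gonads` weight) and ten remainder members.
  Prostate and uterus are alternate remainder members, so the averaging
  divisor is the per-sex member count (9 here); with that convention the
  weights of one reference person's tissues sum to exactly 1, and a uniform
  dose D to every organ yields `E_OD = D`.
- **DLP coefficients** (ICRP 102, Table A.2 adults): closed vocabulary of
  eight region names; unknown regions are rejected, never defaulted.
- **LAR table** (BEIR VII, incidence, US population): per site, sex, and
  tabulated age at exposure 0–80. Ages are interpolated linearly and clamped
  above 80 (cohort ages reach ~100); linear interpolation preserves
  monotonicity and matches every knot exactly. Sex-averaged coefficients are
  the arithmetic mean over sexes, with sex-specific sites (breast, ovary,
  uterus, prostate) contributing 0 for the missing sex — i.e. half weight, as
  for a population-averaged reference person. Organs without a site-specific
  coefficient map to the catch-all "other solid" site; red bone marrow maps
  to leukemia. When several organs share a site each contributes with its own
  dose (organ masses are not available for a mass-weighted site dose; this
  inflates the absolute RI where many organs feed "other", but cancels in
  `f`, and RSI/RDI compare metrics against the same RI).
- All four tables ship as CSV resources and are checksum-verified on load;
  user-supplied replacement files are accepted unverified.

## Accumulation and the inclusion filter

Recurrent exams are evaluated at the age of each exam and summed:
cumulative `E_DLP`, `E_OD`, `RI`, `RI_rp`, `E_r` are sums, the cumulative
`f` is `ΣRI / ΣRI_rp` (the dose-weighted choice; a plain mean of per-exam
`f` would not preserve additivity). The cumulative `E_r` is the sum of the
per-exam `f·E_OD` terms — canonical because it is additive — and the
alternative `cum_f · cum_E_OD` is also reported
(`e_r_from_cumulative_f`); the two coincide exactly when all exams share one
dose-vector shape and diverge otherwise. `f` at zero dose is defined as 0 to
keep the metric set total. The cohort filter keeps patients with cumulative
`E_OD ≥ 100 mSv`, inclusive (the published cohort's minimum is exactly
100.0).

## Regression diagnostics

The through-origin slope is the closed-form least-squares solution
`Σxy/Σx²`; `RMSE = sqrt(SSE/n)`. Normalized RMSE is defined as
`RMSE / mean(y)` — the unique simple normalization under which the published
(nRMSE, slope, RDI) triples are mutually consistent, verified in the tests by
reconstructing the printed RDI values (0.48 and 0.41) from the printed nRMSE
and means. Because the through-origin R² convention is ambiguous, both the
uncentered (`1 − SSE/Σy²`) and centered (`1 − SSE/Σ(y−ȳ)²`) versions are
computed; neither enters RSI or RDI. Significance is a two-sided t test on
the slope with `n−1` degrees of freedom. Display output rounds summaries to
1 decimal and fit diagnostics to 2; machine output keeps full precision so
the rounding never contaminates downstream computation.

Note on reconstruction precision: recomputing RSI for `E_r` from the printed
one-decimal means gives 0.984, vs 0.99 in the published table — consistent
with rounding of the printed means, and left as is.

## Synthetic cohort generator

Hospital dose-monitoring extracts are not redistributable, so the generator
emulates their statistical structure:

- **Demographics**: multinomial over 10-year age band × sex cells with the
  published cohort counts as default weights (median ~71 y, 48.3% female),
  age uniform within a band, the open 90+ band capped at 100. Uniform-in-band
  is the simplest distribution consistent with banded reporting.
- **Exams per patient**: minimum 2 ("recurrent"), a shifted negative
  binomial (default mean 8, dispersion 2, truncated at 30) over a 5-year
  follow-up window with uniformly scattered, strictly increasing exam times.
  The real exam-count distribution is unpublished; these are plausibility
  choices.
- **Protocols**: four adult templates (chest, abdomen–pelvis, head, pelvis)
  with organ doses strictly proportional to DLP (mGy per mGy·cm, magnitudes
  chosen so that E_OD per unit DLP is close to the region's k-factor) and
  log-normal DLP per protocol (dose metrics are right-skewed in practice;
  the published cohort shows mean > median for every metric). Default mix
  0.35/0.45/0.12/0.08 — recurrent high-dose imaging is dominated by chest
  and abdominal work. Strict proportionality deliberately ignores
  tube-current modulation; `tcm_noise` adds a per-organ log-normal jitter
  when that assumption should be stressed (default off).
- **Calibration**: all doses are scaled by one global factor so that a
  configurable fraction of patients (default 0.75) passes the 100 mSv
  filter, anchoring the post-filter distribution at the threshold.
- **Single-protocol mode** uses the sex-neutral chest template only, which
  makes `E_r = RI · (E_OD0/RI_rp0)` exactly for every patient — an
  end-to-end oracle: the fitted E_r-on-RI slope must equal the template
  ratio to 1e-9, with RSI = 1, RDI = 0 and uncentered R² = 1.

Identical config and seed give byte-identical exam tables.

### What passing tests do and do not show

The generator reproduces the cohort's age/sex structure, recurrence, dose
skew, and the filter geometry, so downstream code is fully exercised; it does
not reproduce real anatomy-dependent organ-dose physics, scanner/protocol
heterogeneity, or TCM. Consequently the qualitative published ordering —
E_r closest to RI on both RSI and RDI, mean f < 1 on an elderly cohort — is
recovered (and asserted at n = 2000, fixed seed), while the published
absolute slopes and R² values, which depend on the unavailable hospital
data, are not targets. The synthetic cohort's absolute RI scale also sits
above the published one because of the own-dose convention for organs
sharing the "other" site (see above); all comparative diagnostics are
unaffected.

## Numerical and degenerate-input choices

- Ages are real-valued years throughout; no integer truncation.
- `f`: 0/0 → 0 (flagged semantics documented above); RI > 0 with RI_rp = 0
  raises.
- Regression requires n ≥ 2 and Σx² > 0; all-zero regressors raise.
- Empty post-filter cohorts raise an explicit error rather than emitting an
  empty report.
- Exam-table cells may be empty (organ absent = zero dose, never imputed);
  negative doses, unknown organs/regions, and sex-incompatible organ doses
  are rejected with the offending row and column named.

## Known limitations

- Adult coefficients only; no pediatric extension, no non-US risk tables,
  no mortality-based risk, no uncertainty bands on `r_T`.
- Organ doses are inputs; the package does not compute them from scanner
  parameters or images.
- The 25-organ vocabulary is an assumption (the source system's organ list
  is not published); replace `organ_site_map.csv` to adapt it.
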