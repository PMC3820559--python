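# Methods

## The screening model

The package models universal molecular screening of newly diagnosed
endometrial cancers (EC) for Lynch syndrome (LS). Every tumor receives
three assays; their calls feed a deterministic decision tree; the tree's
per-patient labels aggregate into a screening cascade from which the
cohort prevalence is estimated.

### Assay calling

**Microsatellite instability.** Five quasi-monomorphic mononucleotide
markers (BAT26, BAT25, NR21, NR24, NR27) are scored stable / unstable /
failed. The tumor is **MSI** when two or more markers are unstable,
regardless of failures. Failed markers are excluded from the informative
count; a panel with fewer than `min_informative` (default 3) informative
markers and fewer than two unstable ones is **indeterminate** rather than
MSS, so a mostly-failed panel can never produce a false stable call. The
indeterminate state is this package's construct for an input the source
procedure never had to handle; it propagates to an explicit
"unresolvable" triage state instead of a silent default.

**Immunohistochemistry.** The four MMR proteins (MLH1, MSH2, MSH6, PMS2)
are scored retained / lost / unreliable, where *unreliable* means the
internal positive control (normal tissue on the same section) failed to
stain. Only definite `lost` calls enter the loss pattern; a fully
unreliable panel yields an empty pattern with a flag, and MMR status then
rests on MSI alone. There is no rescue protocol for unreliable staining —
it is surfaced, not imputed.

**MLH1-promoter methylation.** MS-MLPA reports per-probe methylation
ratios for the two probes covering the C and D promoter regions. The
sample ratio is the arithmetic mean of the available probes (a
single-probe mean draws a warning); the call is **methylated iff
ratio ≥ 0.15**. The boundary is closed on the methylated side so the
stated 15% cutoff is itself actionable. Ratios are accepted up to 1.5 to
tolerate MS-MLPA normalisation overshoot (values above 1.0 warn, above
1.5 error).

### Decision tree

MMR-deficient iff MSI and/or any protein loss; MSS with intact staining
is proficient and exits. For deficient tumors the rules fire in a fixed
order, each appending a stable identifier (R1–R7) to the decision's
audit trail:

| rule | condition | outcome |
|------|-----------|---------|
| R1 | proficient | end of screening |
| R2 | MLH1 lost, tumor methylated | sporadic; blood methylated instead ⇒ constitutional-epimutation work-up |
| R3 | MLH1 lost, tumor unmethylated | suspected; test MLH1 |
| R4 | MSH2 lost | suspected; test MSH2 → MSH6 → EPCAM |
| R5 | MSH6 lost, MSH2 retained | suspected; test MSH6 |
| R6 | PMS2 lost, MLH1 retained | suspected; test PMS2 |
| R7 | MSI with intact IHC | suspected; test MLH1 → MSH2 → MSH6 → PMS2 |

Heterodimer biology shapes the guards: PMS2 co-loss is explained by MLH1
loss (R6 requires MLH1 retained) and MSH6 co-loss by MSH2 loss (R5
requires MSH2 retained). Design choices where the tree was genuinely
open:

- **MSI with intact IHC (R7)** tests all four genes in
  prevalence order. Any of the four can be mutated without loss of
  staining (e.g. missense alleles producing stable but inactive protein),
  so the plan must span the panel.
- **Combined MSH6 + PMS2 loss** merges R5 and R6 into the plan
  [MSH6, PMS2] in that order.
- **Blood methylation is optional**: a methylated tumor without a blood
  sample is still called sporadic, with a "blood unconfirmed" note, since
  constitutional MLH1 epimutations are rare.
- **MLH1 loss with no tumor methylation result** returns an explicit
  `pending_methylation` decision — the tree never defaults a missing
  prerequisite.
- **Methylated MLH1 loss co-occurring with MSH2/MSH6 loss** (not a
  pattern in the reference data): methylation explains only the
  MLH1/PMS2 axis, so rules R4–R6 still fire and escalate the label to
  suspected; if blood methylation makes the case
  epimutation-suspected, that label wins and the deferred plan is kept
  as a note (preserving the invariant that a gene plan exists exactly
  for suspected cases).
- **`next_gene` chain**: testing proceeds to the next plan gene while
  earlier results are non-pathogenic; a variant of unknown significance
  does not stop the chain (only a pathogenic finding is diagnostic), and
  a pathogenic result anywhere ends it.

The **two-antibody comparator** (`two_antibody_triage`) screens with
PMS2 + MSH6 only, flagging any loss of either; under heterodimer co-loss
it captures every four-antibody abnormality, which the tests verify on
the reference cohort.

### Cascade statistics

`cascade_summary` counts each funnel node from the decisions plus
per-patient germline outcomes. Observed prevalence is
`n_pathogenic / n_total`. The **predictive frequency**
`(n_suspected · n_pathogenic / n_tested) / n_total` extrapolates the
yield among tested cases to all suspected cases, assuming the tested
subset is representative — an assumption, not a theorem, since refusal
and loss to follow-up need not be independent of carrier status.

Association statistics follow standard epidemiological practice:

- **Woolf odds-ratio CI**: `exp(ln(ad/bc) ± z₁₋α/₂ √(1/a+1/b+1/c+1/d))`,
  z₀.₉₇₅ = 1.959964. Zero cells error unless the Haldane–Anscombe +0.5
  correction is explicitly enabled.
- **Exact conditional OR** for sparse tables: the distribution of the
  `a` cell given both margins is noncentral hypergeometric with the odds
  ratio as noncentrality; the point estimate solves `E[A|ψ] = a` and the
  limits invert the tail probabilities at α/2 (Cornfield/Fisher exact
  limits). Binomial coefficients are continued via the gamma function so
  the same routine handles Haldane-corrected (non-integer) tables, for
  which the limits become finite even on degenerate counts. The
  automatic selector uses the exact method when any cell is below 5.
- **Pearson chi-squared** without continuity correction by default
  (Yates available behind a flag); no correction is the reporting
  convention the package matches.
- **Pooled t test** from summary statistics (mean, SD, n), df = n₁+n₂−2.
- Report percentages use half-up rounding at a configurable number of
  decimals (default 1), matching clinical-table printing.

## Cohort generation

### Reference cohort (`paper_fixture`)

A deterministic 173-patient cohort encoding the joint structure of the
screening series the package models: 58 tumors with protein loss and 47
MSI (44 overlapping: 14 loss-with-MSS and 3 MSI-with-intact-IHC
discordances), 44 MLH1-loss tumors of which 34 methylated (9 with a
blood sample, all blood-negative), 27 suspected cases split
10 / 5 / 7 / 1 / 1 / 3 across the six IHC patterns, 19 tested, and 8
pathogenic carriers whose ages, MSI/IHC results, mutated genes and
variant labels are encoded verbatim (mean carrier age 49). Conventions
for detail the source tables do not pin down:

- **Co-loss**: MLH1-loss patients carry MLH1+PMS2 loss and MSH2-loss
  patients MSH2+MSH6 loss (heterodimer degradation), except the isolated
  patterns named explicitly.
- **MSS assignment among loss cases**: the two carriers known to be MSS
  are fixed; the remaining 12 MSS-with-loss slots go 8 to the methylated
  MLH1 group and 4 to the MSH6 group (including the two MSH6-VUS
  patients, described as MSS with isolated MSH6 loss); within groups,
  lowest patient index first.
- **Ages**: non-carrier ages are deterministic evenly spaced normal
  quantiles per group (suspected vs rest), truncated to 29–90 years; the
  suspected group's location is set so that, with the carriers included,
  its mean is ≈ 57.7 vs ≈ 64.3 elsewhere (cohort mean ≈ 63).
- **Pathology and family-history fields** (stage, histology, grade,
  myometrial invasion, TILs, LVI, lower-uterine-segment, synchronous
  ovarian cancer, revised-Bethesda/Amsterdam-II flags) reproduce the
  printed marginal counts exactly, including the reduced denominators
  (missing values are explicit). Each field is laid out over its own
  fixed md5-derived permutation of patient ids rather than id order:
  with a shared ordering every unstated field would be spuriously
  correlated with the screening category, whereas per-field permutations
  make the unstated joint structure near-null while remaining
  byte-identical across runs and platforms. Family history is known for
  87 patients (38 rBG, 4 AmII, 45 neither; the source's text and table
  disagree — 42 vs 38 rBG — and the fixture follows the table, noting
  the discrepancy in its provenance dict).

The fixture is pure construction — no RNG — and `triage_cohort` over it
reproduces the funnel (173, 61, 44, 34, 27, 19, 8) with zero tolerance.

### Simulator (`simulate_cohort`)

Per patient, a hierarchical draw: deficient (p = 61/173) → MLH1-loss
(44/61) → methylated (34/44, sporadic) or unmethylated (suspected);
non-MLH1 deficiency draws a pattern from the observed weights
(5, 7, 1, 1, 3)/17; loss patterns are MSS with the observed discordance
rate 14/58; suspected cases are tested with p = 19/27 and tested cases
pathogenic with p = 8/19 (the pathogenic gene is the head of the
pattern's plan). Ages come from group-specific truncated normals
(57.70 ± 12.45 suspected, 64.31 ± 12.12 otherwise, range 29–90, rejection
sampling). Assay values are drawn consistently with the assigned
category — methylated tumors get probe ratios in (0.18, 0.60), unmethylated
in (0, 0.12); MSI panels get 2–5 unstable markers — so triage over the
raw simulated table recovers the simulated truth. All draws come from a
single `numpy` generator seeded by `params.seed`.

Under this chain the expected observed prevalence is
`p_def · (1 − p_mlh1·p_meth) · p_tested · p_path = 8/173 ≈ 4.62%`, which
the recovery test confirms to within three Monte-Carlo standard errors
over 200 cohorts.

**What the simulator does not emulate**: somatic biallelic inactivation
as a distinct unexplained-deficiency stratum, BRAF status, epimutation
carriers (rate set to zero), family-structure/pedigree correlation,
assay-level noise such as electropherogram artifacts, and any
age-category dependence beyond the two-group means. Passing recovery
tests therefore demonstrate internal consistency of the pipeline, not
external validity on real laboratory data.

## Numerical and testing choices

- Exact-OR limits are found by Brent root-finding on log ψ in [−50, 50];
  bracket failure returns the appropriate infinite/zero limit. The
  independent test oracles are scipy's conditional odds ratio (integer
  tables) and a brute-force tail-probability grid.
- Chi-squared p-values come from the χ²(1) survival function; the t test
  delegates to `scipy.stats.ttest_ind_from_stats` with a manual
  pooled-variance formula as the in-test oracle.
- Property tests (hypothesis, derandomised): MSI monotonicity and
  permutation invariance, methylation monotonicity in both probes,
  OR inversion under row swap, CI-width shrinkage under table scaling,
  chi-squared transposition invariance. Enumeration tests cover the full
  3⁵ MSI rule table and the complete triage input space
  (3 MSI states × 16 loss sets × 3 × 3 methylation states).
- Problem sizes: the recovery test uses 200 cohorts of 173 patients and
  the sporadic-mislabelling check 20 cohorts; both are comfortably
  desk-scale (the whole suite runs in a few seconds).

## Known limitations

- The decision tree encodes one published screening algorithm; sites
  using age-restricted or IHC-only triage need different rule sets.
- The predictive frequency inherits the representativeness assumption
  noted above and has no uncertainty interval attached.
- Variant interpretation is out of scope: germline outcomes are consumed
  as given (pathogenic / VUS / negative), with no ACMG/InSiGHT logic.
- The reference cohort is a reconstruction from printed margins; its
  unstated joint structure (beyond the conventions listed) is a modelling
  choice, so cross-tabulations not pinned by those margins are synthetic.
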