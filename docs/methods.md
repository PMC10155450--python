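# Methods

## Extraction model

Narratives are treated as bags of token sequences.  Normalisation
lowercases, maps curly apostrophes to straight ones, strips punctuation,
and drops apostrophes inside contractions ("wouldn't" → "wouldnt"); the
operation is idempotent.  A canonical symptom is extracted when at least
one of its surface forms occurs as a contiguous token subsequence; at each
position the longest matching form wins and scanning resumes after the
matched span, so a multiword form can never additionally trigger one of
its own sub-forms.  There is no stemming or lemmatisation beyond the
explicit variant lists: merging lay variants is a vocabulary decision, not
an algorithmic one, and the lexicon file is the single place it happens.

Negation is deliberately ignored by default.  Lay narratives routinely
express symptoms through negated phrasings ("I wouldn't be able to sleep
at night" reports a sleep problem), and a screen built on co-mention
counts treats any mention as a report.  An optional negation window
(`negation_window=k` skips a match within k tokens after a negator) is
provided for sensitivity analyses and is documented as a divergence from
the default behaviour.

## Encoding and cleaning

The analysis dataset is a patient × symptom {0,1} matrix: 1 means the
symptom was mentioned at least once; mention multiplicity is discarded.
Cleaning applies, in order: (1) variant-named columns are merged into
their canonical by logical OR; (2) blacklisted (non-symptom) columns are
dropped; (3) rows with no symptoms are dropped; (4) exact duplicate
records are dropped, keeping the first.  The order matters only for the
bookkeeping: zero-row removal is counted before deduplication, and the
report enforces `rows_out = rows_in − zero_rows − duplicates` on every
run.

Duplicate detection uses raw narrative text when the texts are available.
Deduplicating on the binary pattern alone would delete every pair of
distinct patients who happen to report the same symptom combination —
thousands of rows in any large corpus — and is never done; without texts,
a row is a duplicate only if both its pattern and its patient id repeat.

Columns that appear in no lexicon entry are kept as their own canonicals
with a warning rather than dropped: unknown words can be scientifically
interesting (e.g. somatic terms like "head"), and silently deleting them
would hide vocabulary gaps.

## Screening statistics

All statistics are computed on n patients with the index symptom's
indicator as the fixed variable.

* **Phi coefficient.**  Computed from the 2×2 contingency table;
  algebraically identical to the Pearson product-moment correlation of
  the 0/1 vectors (property-tested to 1e−12 against the textbook
  formula).  Constant columns have no defined correlation; the screen
  skips them with a warning rather than failing the run.
* **Confidence interval.**  Fisher z: atanh(r) ± z·SE with SE = 1/√(n−3),
  back-transformed.  This is the most parsimonious method consistent with
  the published two-decimal intervals this package reproduces; five of the
  seven distinct published (r, CI) rows reproduce exactly from the rounded
  r, and the remaining two (r = 0.14, 0.11) evidently used unrounded r,
  so they are excluded from reproduction checks.
* **p-value.**  Exact t reference: t = r√((n−2)/(1−r²)) on n−2 df,
  two-sided.  At n ≈ 10⁴ the t and normal references agree to far beyond
  the printed "< 0.0001"; the t form is kept for small-n correctness.
* **Post-hoc power.**  Normal approximation on the Fisher-z scale with
  the observed r as the true effect:
  Φ(|atanh r|√(n−3) − z₁₋α/₂) + Φ(−|atanh r|√(n−3) − z₁₋α/₂).
  At r = 0 this equals α exactly (the implementation returns α directly
  to avoid a 1-ulp float discrepancy).  α defaults to 0.05.  Validated
  against a 10⁵-replicate Monte-Carlo at ρ = 0.2, n = 100 (±0.01).
* **Effect bands.**  Cohen's conventions with inclusive lower edges:
  |r| < 0.10 negligible, 0.10–0.30 small, 0.30–0.50 medium, ≥ 0.50 large.
  The screen's headline subset ("top correlates") is the small band in
  both signs; manual curation of which correlates are *meaningful* is
  editorial judgement and is not automated.
* **Independence scan.**  "Coefficient = 0" is operationalised as
  |r| < 0.005, i.e. exactly the values that round to 0.00 at the
  two-decimal reporting precision.
* **Multiple testing.**  Raw p-values by default (matching how such
  screens are conventionally reported); Benjamini–Hochberg adjustment is
  available by flag and adds an adjusted column without changing the
  ordering.

Degenerate inputs: a column identical (or complementary) to the index has
|r| = 1, where the Fisher interval and t statistic are undefined; the
screen reports CI = [r, r], p = 0, power = 1.  With n < 4 the Fisher SE
is undefined; the screen reports the uninformative interval [−1, 1] and
power α.  The elementary functions themselves reject these inputs so that
misuse fails loudly outside the screen.

## Synthetic corpus generator

**Binary layer.**  Symptom indicators come from a latent-threshold
(Gaussian copula) model: X_j = 1{Z_j > Φ⁻¹(1−p_j)} with Z multivariate
standard normal.  A pairwise phi target is converted to the latent
correlation by solving φ(ρ) = target with Brent's method; the orthant
probability P(Z₁ > t₁, Z₂ > t₂; ρ) is evaluated by adaptive quadrature of
φ(z)·Φ̄((t₂−ρz)/√(1−ρ²)) to ~1e−10, so the inversion is accurate to well
below 1e−6.  φ(ρ) is monotone in ρ, and at half margins the closed form
φ = (2/π)arcsin ρ provides an independent check.  Pairs without a target
are independent.  If the assembled latent matrix is not positive
semidefinite the generator fails loudly, naming the target pairs; an
explicit `nearest_psd=True` clips negative eigenvalues with a warning,
at the documented cost of ground-truth drift.

**Feasibility.**  Phi targets are validated against the Fréchet bounds
implied by the two prevalences (joint cell between max(0, p₁+p₂−1) and
min(p₁, p₂)) before any solving.

**Text layer.**  Each present symptom is rendered as 1 + Poisson(λ)
mentions (λ = `repeat_mention_rate`, default 0.5), each mention a
uniformly chosen surface form; filler words are interleaved with at least
one filler between consecutive mentions.  The filler vocabulary is
required to be disjoint from every *token* of every surface form — a
stronger condition than form-level disjointness — which guarantees that
no concatenation of fillers and mentions can spell out an absent
symptom's form.  Together these make the round trip render → extract →
encode exactly lossless, which the test suite verifies across seeds.

**Study profile.**  The default corpus has 10,933 raw records: 10,228
symptom-bearing rows drawn from the latent model conditioned on being
non-zero (all-zero draws are rejected), 704 injected zero-symptom records
(filler-only text), and 1 exact duplicate of a random record with a fresh
patient id — so the cleaning arithmetic 10,933 − 704 − 1 = 10,228 is
exercisable exactly rather than in expectation.  The index symptom's
prevalence is 6.1% of symptom-bearing rows, i.e. ≈ 5.7% of the raw
corpus.  Ten correlates carry planted phi between 0.10 and 0.26 with the
index; six symptoms (dissociation, obsession, compulsion, hypertension,
nausea, weight loss) are planted exactly independent of it; the most
frequent symptoms are depression, anxiety, fear, loneliness.  Remaining
prevalences are set to values typical of lay mental-health narratives,
giving ≈ 4.6 symptoms per record so roughly three quarters of
symptom-bearing records carry four or more — approximating the stratified
shape of such corpora; the strata are configurable where a different
shape is needed.

**Joint feasibility of the planted effects.**  At a 6% index prevalence,
phi values of 0.10–0.26 correspond to latent correlations of roughly
0.45–0.75; ten such pairs cannot all load on an otherwise-independent
index (the latent matrix would lose positive semidefiniteness).  The
default profile therefore fills the correlate–correlate pairs with a
one-factor structure — ρ_jk = ρ_ij·ρ_ik, the index's latent acting as a
shared severity factor — which is PSD by construction for any loadings
and is also substantively reasonable: symptoms that co-occur with
hallucinations also co-occur with each other.  The implied pairwise phi
values are materialised in the config, so the ground truth remains fully
pairwise-specified.

**What the generator does not emulate.**  Real narrative language
(syntax, negation, misspellings, paraphrase beyond the variant lists),
demographic structure, temporal ordering, and any dependence beyond
pairwise latent correlations.  Passing the round-trip and recovery tests
therefore shows the pipeline's bookkeeping and statistics are correct
under the stated model; it does not validate lexicon coverage or
extraction recall on real free text, which depend on the user's lexicon.

**Determinism and conditioning.**  One integer seed drives two documented
generator streams (binary sampling; rendering), so corpus files are
byte-identical across runs.  Rejection of all-zero rows conditions the
core matrix on being non-zero, which shifts empirical phi slightly
upward relative to the unconditioned targets (the (0,0) cell loses ~0.6%
of its mass); parameter-recovery checks are therefore run on the
unconditioned sampler, while pipeline-level checks on the study profile
treat the planted values as approximate (observed deviations are within
per-seed sampling noise, sd ≈ 0.017 at the rare margins, plus that small
conditioning shift).

## Reporting conventions

The stratified co-occurrence table buckets narratives by symptoms
reported (0, 1, 2, 3, 4 or more) and is computed on the pre-row-cleaning
matrix — the zero-symptom stratum must still be present — but after
column merging, the only ordering consistent with reporting both the raw
total and merged symptom counts.  Percentages and coefficients are
displayed at two decimals with round-half-away-from-zero; power of
1.00 prints as "1" and p below 10⁻⁴ prints as "< 0.0001", matching the
conventions of published screen tables.  Empty strata print percentage 0
and are flagged rather than hidden.

## Problem sizes used in the checks

The automated checks run the full 10,933-record study profile once;
parameter recovery uses 20 seeds at n = 10,000 on a 7-symptom config
(planted phi 0.26/0.15/0.20 plus five exact-zero pairs); the render →
extract → encode round trip uses 10 seeds at n = 200 with multiword
forms in play; the Monte-Carlo power oracle uses 10⁵ replicates of
n = 100.  These sizes give sampling error comfortably inside the asserted
tolerances (e.g. a 20-seed mean of phi-hat has sd ≈ 0.004 at the rare
margins, against a 0.01 bound).

## Known limitations

* Lexicon-driven extraction has no recall beyond its surface forms;
  coverage of real corpora is a vocabulary problem the package cannot
  solve by itself.
* Phi at very unequal margins is range-restricted (Fréchet bounds); two
  symptoms can be strongly dependent yet show small phi.  The screen
  reports phi because it is the convention for one-hot co-occurrence
  data; tetrachoric correlation is out of scope.
* Post-hoc power at the observed effect is reported because published
  screen tables carry it; it is a deterministic transform of (r, n) and
  adds no evidence beyond the p-value.
* The independence scan's |r| < 0.005 rule inherits the two-decimal
  reporting precision; at n ≈ 10⁴ a true-zero pair lands inside it only
  ~38% of the time, so the scan under-counts true independents — it is a
  reporting convention, not a test.
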