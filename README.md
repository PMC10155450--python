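# symptomics

Screening free-text patient narratives for symptom co-occurrence.

## The problem

Survey-based psychopathology research restricts respondents to a fixed item
list, so symptoms the instrument never asks about cannot be reported.
Unrestricted first-person narratives (forum posts, interview transcripts)
avoid that restriction, but they arrive as text, not as variables.  This
package turns a corpus of narratives into an analysable dataset and asks,
for a chosen *index symptom* (the motivating case is auditory
hallucination — hearing voices without an external source): *which other
reported symptoms co-occur with it, how strongly, and which are
independent of it?*

The pipeline:

1. **Lexicon** — a user-editable vocabulary mapping surface forms
   ("hearing voices", "hear voices") to canonical symptoms ("auditory
   hallucination"), plus a blacklist of non-symptom words.  A ~28-symptom
   demonstration lexicon ships with the package.
2. **Extraction** — each narrative is normalised and scanned for surface
   forms (longest match first); the output is the set of canonical
   symptoms it mentions.
3. **Encoding** — one-hot encoding into a patient × symptom binary matrix
   (a symptom mentioned ten times is still a 1), then cleaning: variant
   columns merged by logical OR, blacklisted columns dropped, zero-symptom
   rows dropped, exact duplicate records (by raw text) dropped.
4. **Screening** — for every symptom *j* with indicator x_j and index
   indicator y on n patients, the phi coefficient

   φ_j = (n₁₁n₀₀ − n₁₀n₀₁) / √(n₁·n₀·n·₁n·₀),

   which is exactly the Pearson correlation of the two 0/1 vectors;
   a 95% Fisher-z confidence interval tanh(atanh r ∓ z₀.₉₇₅/√(n−3));
   a two-sided p-value from t = r√((n−2)/(1−r²)) on n−2 df; post-hoc
   power of the ρ=0 test at the observed effect; Cohen's effect-size band
   (|r| < 0.10 negligible, 0.10–0.30 small, 0.30–0.50 medium, ≥ 0.50
   large); and an independence scan listing symptoms whose r rounds to
   0.00.
5. **Reporting** — symptom frequency table, and the co-occurrence table
   stratified by symptoms-per-narrative (0, 1, 2, 3, 4 or more).

Because real clinical narrative corpora are rarely shareable, the package
includes a **synthetic corpus generator**: correlated binary symptom
indicators from a latent-threshold Gaussian copula (pairwise phi targets
inverted to latent correlations by root-finding on the bivariate-normal
orthant probability), rendered into narrative text through the lexicon
with filler words and repeated mentions.  The generated ground truth is
recovered exactly by the extraction/encoding path, which makes every
downstream stage testable end to end.

## Worked example

```python
import symptomics as sy

config, profile, lex = sy.default_profile(seed=42, n_patients=2000)
records, truth, manifest = sy.simulate_corpus(config, lex, profile)

model = sy.SymptomScreen.from_corpus(records, lex,
                                     index_symptom="auditory hallucination")
print(model.cleaning_report.as_text())
res = model.fit()
print(res.summary())
```

prints (abridged):

```
n_input_rows: 2000
n_zero_symptom_rows_removed: 129
n_duplicate_rows_removed: 1
n_output_rows: 1870
n_output_columns: 28

Symptom correlation screen
==========================
index symptom : auditory hallucination
n patients    : 1870   (df = 1868)

             symptom     R        CI 95%  p-value power       band
visual hallucination  0.24  [0.19, 0.28] < 0.0001     1      small
       schizophrenia  0.22  [0.17, 0.26] < 0.0001     1      small
            delusion  0.17  [0.13, 0.22] < 0.0001     1      small
            paranoia  0.17  [0.12, 0.21] < 0.0001     1      small
...
```

Reading the first row: among the 1,870 cleaned narratives, patients who
report visual hallucinations are more likely to also report hearing
voices (φ = 0.24, a *small* effect by Cohen's conventions), the 95%
Fisher-z interval excludes zero by a wide margin, and at this sample size
the test had essentially full power to detect it.  The generator planted
φ = 0.26 for this pair, so the screen recovers the ground truth within
sampling error.  `res.independent_symptoms()` lists the symptoms whose
coefficient is 0.00 at two decimals, and `res.top_correlates()` the
small-band rows.

The same pipeline is scriptable from the shell:

```bash
symptomics simulate --n 2000 --seed 42 --out-dir sim/
symptomics analyze --corpus sim/corpus.tsv --out-dir results/
```

## Layout

- `src/symptomics/lexicon.py` — vocabulary, normalisation, lexicon file I/O
- `src/symptomics/extraction.py` — narrative → canonical symptom sets
- `src/symptomics/encoding.py` — one-hot matrix, cleaning rules, matrix I/O
- `src/symptomics/screen.py` — `SymptomScreen` / `ScreenResults` and the statistics
- `src/symptomics/synthetic.py` — latent-threshold generator and corpus profiles
- `src/symptomics/reporting.py` — stratified table, frequency table, plotting
- `src/symptomics/cli.py` — `symptomics` command-line interface
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
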