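# dialib

Spectral library searching for **spectrum-centric DIA proteomics**.

Data-independent acquisition (DIA) co-fragments all precursors in wide
isolation windows; tools such as DIA-Umpire de-convolve the signal into
DDA-like *pseudo-MS2 spectra*, graded into quality tiers Q1 > Q2 > Q3.
These spectra are noisier, more incomplete and more chimeric than true DDA
spectra, so a search engine tuned for DDA loses sensitivity on them.
`dialib` searches pseudo-MS2 spectra against a DDA-style spectral library
with preprocessing defaults optimized for pseudo-MS2 data, describes every
spectrum–spectrum match (SSM) with a rich feature vector, and validates
matches by target–decoy FDR, with Percolator-compatible export.

## Method

**Preprocessing.** Query pipeline: signal-to-noise filter (keep peaks
strictly above max/`SNfilter`) → intensity power *IP* (intensity ←
intensity^IP, default **0.33**) → 1-Th binning (round-half-up; bin value =
`Max` or `Sum` of member peaks, default **Max**) → optional Spillover
(half of each bin's intensity shared with ±1-Th neighbours) → L2
normalization (Σ intensity² = 1). Library pipeline: IP → unassigned-peak
scaling *UPS* (peaks without a b/y annotation × **0.4**) → binning →
Spillover → normalization.

**Search.** For each query, every library entry (target or decoy) with
precursor m/z within ±0.5 Th is a candidate; the candidate with the highest
dot product ⟨q, ℓ⟩ of the unit intensity vectors is the reported SSM.

**Features (19 per SSM).** Mass difference, precursor m/z difference, dot,
deltaD = (best − second)/best, dotBias, Fval = 0.6·dot + 0.4·deltaD −
penalty(dotBias), penalty, second-best dot, Xcorr (aligned dot minus the
mean over ±75-bin shifts), **library-centric cosine similarity** (cosine
with the query norm reduced to the bins matched by the library spectrum —
robust to chimeric extra signal), Kendall-τ, hypergeometric −log₁₀ tail
score of the matched-bin count, Pearson r, plus candidate statistics
(hits_num, hits_mean, hits_stdev, normal-tail Pval of the top hit) and two
one-hot categoricals: precursor charge (5 columns, 1–5) and quality tier
(3 columns, Q1–Q3) — 25 numeric columns in all.

**Validation.** Target–decoy competition q-values at SSM and peptide level
(FDR(t) = #decoys ≥ t / #targets ≥ t, q = running minimum), either on the
dot product or after semi-supervised iterative linear rescoring over all 25
feature columns in cross-validated folds (a lightweight stand-in for
Percolator; a standard `pin` file is also written so external Percolator
can be used instead).

A synthetic benchmark generator (`dialib.simulate`) builds b/y fragment
libraries in sptxt, shuffled-sequence decoys, and noise-perturbed MGF query
files across the three quality tiers, with known ground truth.

## Worked example

```sh
dialib simulate --n 100 --seed 7 --queries 300 --null-fraction 0.4 --out bench/
dialib search --query bench/queries_Q1.mgf --query bench/queries_Q2.mgf \
              --query bench/queries_Q3.mgf --lib bench/library.sptxt \
              --out bench/ssms.tsv
dialib validate --ssms bench/ssms.tsv --rescore --seed 7 --out bench/val/
```

which prints

```
library: bench/library.sptxt
queries Q1: bench/queries_Q1.mgf
queries Q2: bench/queries_Q2.mgf
queries Q3: bench/queries_Q3.mgf
INFO dialib: 95 queries had no library candidate within +-0.5 Th
205 SSMs written to bench/ssms.tsv
accepted at q<=0.01: 183 SSMs, 100 peptides
```

300 queries were simulated, of which 40% are junk spectra unrelated to the
library; 205 found at least one candidate within ±0.5 Th. Validation with
iterative rescoring accepts 183 SSMs (and 100 distinct peptides) at
q ≤ 0.01 — i.e. with an estimated ≤1% of them expected to be false —
while the junk queries are rejected. `bench/val/` also holds the pin
export, per-SSM and per-peptide q-value tables and a JSON run summary.

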