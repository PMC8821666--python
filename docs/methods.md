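# Methods

## Problem and model

`dialib` performs spectrum-centric identification of DIA data: pseudo-MS2
query spectra (as extracted by DIA-Umpire-style tools, with per-file
quality tiers Q1/Q2/Q3) are matched against a concatenated target+decoy
spectral library. A match is a spectrum–spectrum match (SSM); the engine's
ranking score is the cosine similarity (dot product of L2-normalized,
1-Th-binned intensity vectors), and statistical confidence comes from
target–decoy competition (TDC): decoy entries are shuffled-sequence
spectra assumed exchangeable with false target matches, so the number of
decoy matches above a score threshold estimates the number of false target
matches above it.

## Preprocessing

Stage order — query: SNfilter → intensity power → binning → spillover →
normalization; library: intensity power → unassigned-peak scaling →
binning → spillover → normalization. The stages are applied in the order
they are listed because each operates on the output domain of the
previous one (peak filtering before per-peak transforms, per-peak
transforms before binning, bin-level smoothing before normalization).

| parameter | default | unit | role |
|---|---|---|---|
| `ip_exponent` (IP) | 0.33 | — | intensity ← intensity^IP; < 1 damps dominant peaks. The default is the setting optimized for pseudo-MS2 data (DDA-tuned engines typically use 0.5). |
| `ups_factor` (UPS) | 0.4 | — | multiplies library peaks lacking an ion annotation, up-weighting the annotated backbone fragments. |
| `sn_factor` (SNfilter) | disabled | — | keeps query peaks strictly above max-intensity / factor ("dynamic range" filtering); off by default. |
| `bin_strategy` | Max | — | bin intensity = max (Max) or sum (Sum) of member peaks in each 1-Th bin. |
| `spillover_target` | none | — | which side(s) receive neighbour spillover. |
| precursor tolerance | 0.5 | Th | symmetric closed window for candidate retrieval; candidates of any charge are admitted (charge is a validation feature, not a filter). |

Numerical conventions:

* **Binning** uses round-half-up (`floor(mz + 0.5)`): a peak at 500.5 Th
  goes to bin 501.
* **Spillover** uses simultaneous semantics — all half-intensities are
  computed from the pre-spillover vector. Max strategy: a neighbour whose
  original intensity is below v/2 is replaced by v/2, collisions keeping
  the larger assignment; Sum strategy: both neighbours receive +v/2 (which
  exactly doubles total intensity when no occupied bins are adjacent).
* **SNfilter** keeps peaks *strictly* greater than the threshold, so a
  peak exactly at max/factor is removed.
* **Normalization** rejects empty/all-zero spectra; such queries are
  dropped from the search with a logged count.

## Similarity measures

Dot product, deltaD, dotBias, penalty and Fval follow the SpectraST
formulation; Xcorr follows Comet's mean-of-shifts form (aligned dot minus
the mean dot over ±75-bin shifts of the library spectrum); Kendall-τ (the
tau-b tie-corrected variant) and the hypergeometric score follow the
Pepitome family, computed here on binned spectra for uniformity. The
library-centric cosine similarity divides the matched-bin inner product by
the *reduced* query norm (over matched bins only) and the full library
norm, so it always dominates the dot product and is insensitive to extra
query signal from co-fragmented precursors. Each measure lives behind its
own function so any one formulation can be swapped independently.

Conventions for degenerate inputs: Pearson r and Kendall-τ are 0 for
constant vectors or fewer than two (matched) bins; dotBias is 0 when the
dot is 0; deltaD is 1 when there is no runner-up candidate and 0 when the
best dot is 0; the hypergeometric population N is the span (max − min + 1)
of the union of the two binned m/z supports unless overridden. The
penalty is piecewise constant in dotBias b: 0.12 for b < 0.09 (dot spread
suspiciously thin), 0 for 0.09 ≤ b ≤ 0.35, then 0.12 / 0.18 / 0.24 for
b in (0.35, 0.40] / (0.40, 0.45] / (0.45, ∞) (dot dominated by one or two
bins). Candidate-dot ties break by ascending library index, making search
output deterministic.

## Validation

Each SSM carries 19 named features: 17 scalars (mass difference, precursor
m/z difference, dot, deltaD, dotBias, Fval, penalty, second-best dot,
Xcorr, library-centric cosine, Kendall-τ, hypergeometric score, Pearson r,
hits_num, hits_mean, hits_stdev, Pval) plus charge state and quality tier
one-hot encoded (5 + 3 columns; charges outside 1–5 clamp to the boundary
column; a query with unreported charge takes its matched library entry's
charge so the one-hot block always has exactly one 1). The 25-column row
order is frozen and covered by a golden test.

TDC q-values use FDR(t) = #decoys ≥ t / max(1, #targets ≥ t) without the
+1 correction (documented choice, kept simple and switchable at one
site); tied scores share a q-value; peptide-level q-values take the best
SSM per modified peptide string (charge not part of the key) and rerun TDC
over the representatives.

The iterative rescorer is a deliberately small stand-in for Percolator:
3 cross-validated folds × 3 iterations; per iteration the positives are
targets at q ≤ 0.01 under the current score and the negatives are all
decoys; a shrinkage LDA on the standardized 25 columns rescores the
held-out fold, and fold scores are aligned by mapping the weakest
still-accepted target to 0 and the decoy median to −1 before the final
TDC pass. With fewer than 20 targets or 20 decoys it falls back to
dot-product TDC; within a fold, an iteration with fewer than 5 confident
positives keeps the current score (both guards matter on null data, where
no confident positives exist). It makes no claim of matching Percolator's
SVM numerically; the `pin` export exists for users who want the real
thing.

## Synthetic benchmarks

The generator emulates the statistical shape of pseudo-MS2 data: library
entries are singly-charged b/y fragment ladders at monoisotopic masses
(residue masses from the standard table; no modified peptides are
generated, though modified sequences are parsed), intensities drawn from
a seeded lognormal with a y > b prior, plus a configurable fraction of
unannotated contaminant peaks. Decoys shuffle the sequence keeping the
C-terminal residue and reposition the annotated fragments (the
SpectraST-style decoy construction). Queries degrade a source entry with
multiplicative lognormal intensity jitter (CV 0.3), independent peak
dropout (0.1), Poisson-distributed uniform noise peaks (mean 5), Gaussian
m/z jitter (0.02 Th) and, with probability 0.05, half-intensity chimeric
peaks from a second entry; quality tiers are assigned by largest-remainder
allocation of the 0.5/0.3/0.2 mix. These defaults describe mid-quality
pseudo-MS2 extractions; tests that need harsher conditions say so
explicitly. A `null_fraction` generates queries from a disjoint peptide
set (ground truth "noise") — the null condition for FDR calibration.

What the generator does **not** model: DIA isolation-window structure,
isotope envelopes, retention time, modified peptides, and
intensity-dependent m/z error. Quality tiers are labels with the stated
proportions, not distinct noise regimes. Passing tests therefore
demonstrate correctness of the algorithms and calibration machinery under
a controlled fragment-spectrum model, not performance on real DIA data.
One known artefact: a target and its decoy share the C-terminal y-ion
series start, so sparse null matches tie between the pair and the
deterministic tie-break favours the target; decoy counts at very low
scores are correspondingly slightly conservative.

Printed precisions are part of the fixture contract: sptxt stores m/z to
4 decimals and intensity to 1, and the MGF writer uses the same precision,
so a noise-free query and its source entry rebin identically and
self-search returns dot = 1.0 exactly.

## Problem sizes

The shipped tests and the acceptance script use 60–200-peptide libraries,
120–500 queries per run and 20 Monte-Carlo seeds for the null
calibration — sizes at which every algorithmic path (multi-candidate
windows, decoy competition, fold-wise rescoring) is exercised and results
are stable across seeds.

## Limitations

* sptxt is the only library format (no splib/blib); consensus-library
  building is out of scope — the library is consumed as given.
* Only rank-1 SSMs are reported and validated.
* The internal rescorer is linear; feature interactions that a kernel SVM
  could exploit are not.
* Protein-level inference and protein FDR are not implemented.
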