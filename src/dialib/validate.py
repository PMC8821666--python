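"""SSM validation: feature assembly, Percolator pin export, target-decoy
q-values, and a self-contained iterative linear rescorer.

Every SSM is described by 19 named features — 17 scalars plus two
categoricals expanded one-hot: precursor charge (5 columns, charges 1-5)
and spectrum quality tier (3 columns, Q1-Q3) — 25 numeric columns in all.
The feature rows can be exported as a standard Percolator ``pin`` file for
external semi-supervised rescoring, or validated internally: plain
target-decoy competition (TDC) q-values on the dot product, optionally
sharpened by a cross-validated iterative linear discriminant over all 25
columns. The internal rescorer is a lightweight stand-in, not a Percolator
reimplementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .search import SSMRecord

# Frozen column order: 17 scalars, then the two one-hot blocks.
SCALAR_FEATURES = [
    "massDiff", "precursorMzDiff", "dot", "deltaD", "dotBias", "fval",
    "penalty", "secondScore", "xcorr", "libc_cosSim", "kt", "hgt", "pcc",
    "hits_num", "hits_mean", "hits_stdev", "pval",
]
CHARGE_COLUMNS = [f"charge{c}" for c in range(1, 6)]
QUALITY_COLUMNS = ["qualityQ1", "qualityQ2", "qualityQ3"]
FEATURE_COLUMNS = SCALAR_FEATURES + CHARGE_COLUMNS + QUALITY_COLUMNS

N_NAMED_FEATURES = 19  # 17 scalars + charge + quality
N_FEATURE_COLUMNS = len(FEATURE_COLUMNS)  # 25


def assemble_features(r: SSMRecord) -> np.ndarray:
    """The 25-column numeric feature row for one SSM (frozen order).

    Charge states above 5 map onto the charge-5 one-hot column; below 1
    onto charge-1.
    """
    s = r.scores
    scalars = [
        r.mass_difference, r.precursor_mz_difference, s.dot, s.deltaD,
        s.dotBias, s.fval, s.penalty, r.second_best_dot, s.xcorr,
        s.libc_cosSim, s.kt, s.hgt, s.pcc,
        float(r.hits_num), r.hits_mean, r.hits_stdev, r.pval,
    ]
    if any(not np.isfinite(v) for v in scalars):
        raise ValueError(f"non-finite feature for SSM {r.query_id!r}")
    charge = min(max(int(r.charge_state), 1), 5)
    charge_block = [1.0 if c == charge else 0.0 for c in range(1, 6)]
    quality_block = [1.0 if r.quality_level == q else 0.0
                     for q in ("Q1", "Q2", "Q3")]
    return np.array(scalars + charge_block + quality_block, dtype=float)


def feature_matrix(records: list[SSMRecord]) -> np.ndarray:
    return np.vstack([assemble_features(r) for r in records]) if records \
        else np.empty((0, N_FEATURE_COLUMNS))


def write_pin(records: list[SSMRecord], path,
              features: np.ndarray | None = None) -> None:
    """Write Percolator input (pin): SpecId, Label, ScanNr, 25 features,
    Peptide (flanked ``-.SEQ.-``), Proteins."""
    if features is None:
        features = feature_matrix(records)
    header = ["SpecId", "Label", "ScanNr", *FEATURE_COLUMNS,
              "Peptide", "Proteins"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r, row in zip(records, features):
            label = "-1" if r.is_decoy else "1"
            feats = "\t".join(f"{v:.6g}" for v in row)
            prots = ";".join(r.proteins) if r.proteins else "UNKNOWN"
            fh.write(f"{r.query_id}\t{label}\t{r.scan_number}\t{feats}\t"
                     f"-.{r.peptide}.-\t{prots}\n")


@dataclass
class ValidationResult:
    """Per-record scores, labels and q-values at SSM and peptide level."""

    records: list[SSMRecord]
    scores: np.ndarray
    qvalues: np.ndarray                      # SSM-level
    peptide_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def n_accepted(self, q: float = 0.01, level: str = "ssm") -> int:
        if level == "ssm":
            mask = (self.qvalues <= q) & ~np.array(
                [r.is_decoy for r in self.records])
            return int(mask.sum())
        tab = self.peptide_table
        return int(((tab["qvalue"] <= q) & ~tab["is_decoy"]).sum())

    def ssm_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "query_id": [r.query_id for r in self.records],
            "peptide": [r.peptide for r in self.records],
            "is_decoy": [r.is_decoy for r in self.records],
            "score": self.scores,
            "qvalue": self.qvalues,
        })


def _tdc_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Target-decoy q-values: FDR(t) = #decoys>=t / max(1, #targets>=t),
    q = running minimum from the permissive end; tied scores share a q."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = is_decoy[order].astype(int)
    n_dec = np.cumsum(d)
    n_tgt = np.cumsum(1 - d)
    fdr = n_dec / np.maximum(1, n_tgt)
    # ties: every member of a tie group takes the group's last (full) counts
    for i in range(len(s) - 2, -1, -1):
        if s[i] == s[i + 1]:
            fdr[i] = fdr[i + 1]
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def tdc_qvalues(records: list[SSMRecord],
                scores: np.ndarray | None = None,
                score_field: str = "dot") -> ValidationResult:
    """SSM-level q-values by target-decoy competition on ``score_field``."""
    is_decoy = np.array([r.is_decoy for r in records], dtype=bool)
    if len(records) and (is_decoy.all() or not is_decoy.any()):
        raise ValueError(
            "target-decoy validation needs both targets and decoys; search "
            "against a concatenated target+decoy library")
    if scores is None:
        scores = np.array([getattr(r.scores, score_field) for r in records])
    q = _tdc_qvalues(scores, is_decoy) if len(records) else np.empty(0)
    result = ValidationResult(records=records, scores=np.asarray(scores),
                              qvalues=q)
    result.peptide_table = peptide_qvalues(result)
    return result


def peptide_qvalues(v: ValidationResult) -> pd.DataFrame:
    """Peptide-level q-values: best SSM per modified peptide, then TDC.

    Decoy peptides (their shuffled sequences) group separately from any
    target peptide; charge is not part of the grouping key.
    """
    if not len(v.records):
        return pd.DataFrame(columns=["peptide", "is_decoy", "score", "qvalue"])
    df = pd.DataFrame({
        "peptide": [r.peptide for r in v.records],
        "is_decoy": [r.is_decoy for r in v.records],
        "score": v.scores,
    })
    best = (df.sort_values(["score"], ascending=False, kind="stable")
              .groupby("peptide", sort=True).head(1)
              .sort_values(["score", "peptide"],
                           ascending=[False, True], kind="stable")
              .reset_index(drop=True))
    best["qvalue"] = _tdc_qvalues(best["score"].to_numpy(),
                                  best["is_decoy"].to_numpy())
    return best


def _fold_normalize(scores: np.ndarray, is_decoy: np.ndarray,
                    q_anchor: float) -> np.ndarray:
    """Put one fold's scores on the common scale: the weakest target still
    accepted at ``q_anchor`` maps to 0, the decoy median to -1."""
    if not is_decoy.any() or is_decoy.all():
        return scores
    q = _tdc_qvalues(scores, is_decoy)
    accepted = scores[(q <= q_anchor) & ~is_decoy]
    t = float(accepted.min()) if accepted.size \
        else float(scores[~is_decoy].max())
    m = float(np.median(scores[is_decoy]))
    denom = t - m if t > m else 1.0
    return (scores - t) / denom


def iterative_rescore(records: list[SSMRecord],
                      features: np.ndarray | None = None,
                      n_iter: int = 3, n_folds: int = 3,
                      q_train: float = 0.01, seed: int = 0,
                      min_class_size: int = 20,
                      min_positives: int = 5) -> ValidationResult:
    """Semi-supervised linear rescoring in cross-validated folds.

    The ranking is initialized by the dot product. Each iteration takes
    targets at q <= ``q_train`` as positives and all decoys as negatives,
    fits a linear discriminant on the 25 features over the training folds,
    and rescores the held-out fold. Final q-values come from TDC on the
    learned score. Deterministic for a fixed seed.

    Falls back to plain dot-product TDC when either class has fewer than
    ``min_class_size`` members; within a fold, an iteration with fewer than
    ``min_positives`` confident targets keeps the current score.
    """
    is_decoy = np.array([r.is_decoy for r in records], dtype=bool)
    n = len(records)
    dot = np.array([r.scores.dot for r in records])
    n_targets = int((~is_decoy).sum())
    n_decoys = int(is_decoy.sum())
    if n_targets < min_class_size or n_decoys < min_class_size:
        return tdc_qvalues(records, scores=dot)

    if features is None:
        features = feature_matrix(records)
    keep = np.ptp(features, axis=0) > 0
    if not keep.all():
        import logging
        logging.getLogger("dialib").warning(
            "dropping %d constant feature columns", int((~keep).sum()))
    X = features[:, keep]
    # standardize for a well-conditioned discriminant
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % n_folds
    scores = dot.copy()
    for _ in range(n_iter):
        new_scores = scores.copy()
        for f in range(n_folds):
            train = fold != f
            held = ~train
            q_train_scores = _tdc_qvalues(scores[train], is_decoy[train])
            pos = train.copy()
            pos[train] = (~is_decoy[train]) & (q_train_scores <= q_train)
            neg = train & is_decoy
            if pos.sum() < min_positives or neg.sum() < min_positives:
                continue
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            idx = pos | neg
            lda.fit(X[idx], pos[idx].astype(int))
            held_scores = lda.decision_function(X[held])
            new_scores[held] = _fold_normalize(held_scores, is_decoy[held],
                                               q_train)
        scores = new_scores
    result = ValidationResult(records=records, scores=scores,
                              qvalues=_tdc_qvalues(scores, is_decoy))
    result.peptide_table = peptide_qvalues(result)
    return result
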