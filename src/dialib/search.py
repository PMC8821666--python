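"""Candidate retrieval, dot-product ranking and SSM assembly.

For each query spectrum, all library entries (targets and decoys) whose
precursor m/z lies within the tolerance (default 0.5 Th, symmetric, any
charge) are candidates. The candidate with the highest dot product is the
reported spectrum-spectrum match (SSM); the distribution of candidate dot
products yields the hits_num / hits_mean / hits_stdev / Pval statistics used
as validation features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import LibraryEntry, QuerySpectrum, SpectralLibrary
from .preprocess import BinnedSpectrum, PreprocessConfig, preprocess_library, \
    preprocess_query
from .similarity import ScoreSet, dot_product, score_pair

logger = logging.getLogger("dialib")

DEFAULT_PRECURSOR_TOL = 0.5  # Th


@dataclass
class SSMRecord:
    """One reported spectrum-spectrum match with every score and statistic."""

    query_id: str
    scan_number: int
    peptide: str
    charge: int
    proteins: list[str]
    is_decoy: bool
    scores: ScoreSet
    second_best_dot: float
    mass_difference: float
    precursor_mz_difference: float
    charge_state: int
    quality_level: str
    hits_num: int
    hits_mean: float
    hits_stdev: float
    pval: float
    rank: int = 1
    lib_index: int = 0

    def as_row(self) -> dict:
        s = self.scores
        return {
            "query_id": self.query_id, "scan_number": self.scan_number,
            "peptide": self.peptide, "charge": self.charge,
            "proteins": ";".join(self.proteins), "is_decoy": self.is_decoy,
            "rank": self.rank, "dot": s.dot, "deltaD": s.deltaD,
            "dotBias": s.dotBias, "fval": s.fval, "penalty": s.penalty,
            "second_best_dot": self.second_best_dot, "xcorr": s.xcorr,
            "libc_cosSim": s.libc_cosSim, "kt": s.kt, "hgt": s.hgt,
            "pcc": s.pcc, "mass_difference": self.mass_difference,
            "precursor_mz_difference": self.precursor_mz_difference,
            "charge_state": self.charge_state,
            "quality_level": self.quality_level, "hits_num": self.hits_num,
            "hits_mean": self.hits_mean, "hits_stdev": self.hits_stdev,
            "pval": self.pval,
        }

    @classmethod
    def from_row(cls, row) -> "SSMRecord":
        scores = ScoreSet(
            dot=float(row["dot"]), libc_cosSim=float(row["libc_cosSim"]),
            xcorr=float(row["xcorr"]), pcc=float(row["pcc"]),
            kt=float(row["kt"]), hgt=float(row["hgt"]),
            dotBias=float(row["dotBias"]), deltaD=float(row["deltaD"]),
            penalty=float(row["penalty"]), fval=float(row["fval"]))
        prot = row["proteins"]
        proteins = [] if (isinstance(prot, float) and math.isnan(prot)) \
            else str(prot).split(";")
        return cls(
            query_id=str(row["query_id"]), scan_number=int(row["scan_number"]),
            peptide=str(row["peptide"]), charge=int(row["charge"]),
            proteins=proteins, is_decoy=bool(row["is_decoy"]), scores=scores,
            second_best_dot=float(row["second_best_dot"]),
            mass_difference=float(row["mass_difference"]),
            precursor_mz_difference=float(row["precursor_mz_difference"]),
            charge_state=int(row["charge_state"]),
            quality_level=str(row["quality_level"]),
            hits_num=int(row["hits_num"]), hits_mean=float(row["hits_mean"]),
            hits_stdev=float(row["hits_stdev"]), pval=float(row["pval"]),
            rank=int(row["rank"]))


def find_candidates(query: QuerySpectrum, lib: SpectralLibrary,
                    tol: float = DEFAULT_PRECURSOR_TOL) -> list[LibraryEntry]:
    """All entries with |precursor_mz - query precursor_mz| <= tol, any charge."""
    if tol <= 0:
        raise ValueError("precursor tolerance must be > 0")
    return lib.range_query(query.precursor_mz - tol, query.precursor_mz + tol)


def candidate_stats(dots: list[float]) -> tuple[int, float, float, float]:
    """(hits_num, hits_mean, hits_stdev, pval) of the candidate dot products.

    Pval is the upper-tail normal probability of the top dot under the
    candidate distribution: 1 - Phi((max - mean) / sd). With a single
    candidate or zero spread, Pval = 1.0.
    """
    if not dots:
        raise ValueError("candidate_stats requires at least one dot product")
    n = len(dots)
    mean = float(np.mean(dots))
    sd = float(np.std(dots, ddof=1)) if n > 1 else 0.0
    if n < 2 or sd == 0:
        pval = 1.0
    else:
        pval = float(norm.sf((max(dots) - mean) / sd))
    return n, mean, sd, pval


def score_query(query: QuerySpectrum, candidates: list[LibraryEntry],
                cfg: PreprocessConfig | None = None, *,
                binned_query: BinnedSpectrum | None = None,
                binned_candidates: list[BinnedSpectrum] | None = None,
                ) -> SSMRecord | None:
    """Rank candidates by dot product and assemble the rank-1 SSM.

    Ties in dot break by ascending lib_index for reproducibility. Returns
    ``None`` when there are no candidates. Pre-binned spectra may be passed
    to reuse a preprocessing cache; otherwise both sides are preprocessed
    with ``cfg``.
    """
    if not candidates:
        return None
    if binned_query is None:
        cfg = cfg or PreprocessConfig()
        binned_query = preprocess_query(query, cfg)
    if binned_candidates is None:
        cfg = cfg or PreprocessConfig()
        binned_candidates = [preprocess_library(e, cfg) for e in candidates]
    dots = [dot_product(binned_query, b) for b in binned_candidates]
    order = sorted(range(len(candidates)),
                   key=lambda i: (-dots[i], candidates[i].lib_index))
    best_i = order[0]
    best_dot = dots[best_i]
    second_dot = dots[order[1]] if len(order) > 1 else 0.0
    winner = candidates[best_i]

    scores = score_pair(binned_query, binned_candidates[best_i],
                        best_dot, second_dot)
    hits_num, hits_mean, hits_stdev, pval = candidate_stats(dots)
    charge_state = (query.precursor_charge
                    if query.precursor_charge is not None else winner.charge)
    mz_diff = query.precursor_mz - winner.precursor_mz
    return SSMRecord(
        query_id=query.spectrum_id, scan_number=query.scan_number,
        peptide=winner.peptide, charge=winner.charge,
        proteins=list(winner.proteins), is_decoy=winner.is_decoy,
        scores=scores, second_best_dot=second_dot,
        mass_difference=mz_diff * winner.charge,
        precursor_mz_difference=mz_diff, charge_state=charge_state,
        quality_level=query.quality_level, hits_num=hits_num,
        hits_mean=hits_mean, hits_stdev=hits_stdev, pval=pval,
        lib_index=winner.lib_index)


def search_file(queries: list[QuerySpectrum], lib: SpectralLibrary,
                cfg: PreprocessConfig | None = None,
                tol: float = DEFAULT_PRECURSOR_TOL) -> list[SSMRecord]:
    """Search every query against the library; one SSM per matched query.

    Library spectra are preprocessed once and cached by lib_index; output is
    deterministic for fixed inputs and configuration.
    """
    cfg = cfg or PreprocessConfig()
    binned_lib: dict[int, BinnedSpectrum] = {}
    records: list[SSMRecord] = []
    n_no_candidates = 0
    for query in queries:
        if not query.peaks:
            n_no_candidates += 1
            continue
        candidates = find_candidates(query, lib, tol)
        if not candidates:
            n_no_candidates += 1
            continue
        try:
            binned_q = preprocess_query(query, cfg)
        except ValueError:  # all-zero after filtering
            n_no_candidates += 1
            continue
        binned_c = []
        for entry in candidates:
            if entry.lib_index not in binned_lib:
                binned_lib[entry.lib_index] = preprocess_library(entry, cfg)
            binned_c.append(binned_lib[entry.lib_index])
        record = score_query(query, candidates, binned_query=binned_q,
                             binned_candidates=binned_c)
        if record is not None:
            records.append(record)
    if n_no_candidates:
        logger.info("%d queries had no library candidate within +-%g Th",
                    n_no_candidates, tol)
    return records
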