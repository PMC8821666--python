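"""Synthetic benchmark generation with known ground truth.

Builds self-contained test data for the search engine: a target+decoy
spectral library in sptxt (singly-charged b/y fragment spectra of random
tryptic-like peptides, with optional unannotated contaminant peaks and
shuffled-sequence decoys) and DIA-like pseudo-MS2 query files in MGF,
perturbed with intensity jitter, peak dropout, added noise peaks, m/z
jitter and chimeric mixing, split across the three quality tiers.

The emulation covers the statistical shape of pseudo-MS2 spectra (noisy,
incomplete, partly chimeric fragment spectra); it does not model DIA
isolation windows, isotope envelopes or retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mass as pmass
from pyteomics import mgf as pmgf

from .io import (DEFAULT_DECOY_PREFIX, LibraryEntry, Peak, PROTON_MASS,
                 QuerySpectrum, WATER_MASS, write_sptxt)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_MASS = {aa: pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}

# lognormal intensity priors (log-scale mean): y-ions run hotter than b-ions
_LOG_MEAN_Y = np.log(1000.0)
_LOG_MEAN_B = np.log(400.0)
_LOG_MEAN_CONTAMINANT = np.log(120.0)
_LOG_SD = 0.6


@dataclass
class SimConfig:
    """Benchmark generator parameters (defaults emulate mid-quality
    pseudo-MS2 data)."""

    n_peptides: int = 100
    length_range: tuple[int, int] = (8, 16)
    charge_set: tuple[int, ...] = (2, 3)
    noise_peaks: float = 5.0          # mean count of added noise peaks
    dropout_prob: float = 0.1
    intensity_cv: float = 0.3
    mz_jitter_sd: float = 0.02        # Th
    chimera_prob: float = 0.05
    quality_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    contaminant_frac: float = 0.1     # unannotated peaks per library entry
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.quality_mix) - 1.0) > 1e-9:
            raise ValueError("quality_mix proportions must sum to 1")
        for name in ("noise_peaks", "dropout_prob", "intensity_cv",
                     "mz_jitter_sd", "chimera_prob", "contaminant_frac"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not (0 <= self.dropout_prob < 1 and 0 <= self.chimera_prob < 1):
            raise ValueError("dropout_prob and chimera_prob must be in [0, 1)")


@dataclass
class GroundTruth:
    """Maps each generated query spectrum id to its source peptide
    (or ``"noise"`` for queries unrelated to the library)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tpeptide\n")
            for qid in sorted(self.mapping):
                fh.write(f"{qid}\t{self.mapping[qid]}\n")


def zero_noise_config(n_peptides: int = 200, seed: int = 0) -> SimConfig:
    """A noise-free SimConfig: queries reproduce their library entries
    exactly (no jitter, dropout, noise peaks, chimeras or contaminants)."""
    return SimConfig(n_peptides=n_peptides, seed=seed, noise_peaks=0.0,
                     dropout_prob=0.0, intensity_cv=0.0, mz_jitter_sd=0.0,
                     chimera_prob=0.0, contaminant_frac=0.0)


def peptide_mass(peptide: str) -> float:
    """Monoisotopic neutral mass of an unmodified peptide."""
    try:
        return sum(RESIDUE_MASS[aa] for aa in peptide) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue in {peptide!r}") from exc


def fragment_mz(peptide: str, ion: str) -> float:
    """m/z of a singly-charged b- or y-ion (e.g. ``"b5"``, ``"y3"``)."""
    kind, k = ion[0], int(ion[1:])
    if kind == "b":
        return sum(RESIDUE_MASS[aa] for aa in peptide[:k]) + PROTON_MASS
    if kind == "y":
        return sum(RESIDUE_MASS[aa] for aa in peptide[-k:]) \
            + WATER_MASS + PROTON_MASS
    raise ValueError(f"unsupported ion {ion!r}")


def theoretical_spectrum(peptide: str, charge: int, seed: int = 0,
                         contaminant_frac: float = 0.0) -> LibraryEntry:
    """Annotated b/y fragment spectrum of a peptide at a given charge.

    Fragment intensities are drawn from a seeded lognormal with a y > b
    prior; ``contaminant_frac`` adds that fraction of unannotated peaks at
    uniform random m/z.
    """
    for aa in peptide:
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} in {peptide!r}")
    rng = np.random.default_rng(seed)
    neutral = peptide_mass(peptide)
    precursor_mz = (neutral + charge * PROTON_MASS) / charge
    peaks: list[Peak] = []
    for k in range(1, len(peptide)):
        for kind, mu in (("b", _LOG_MEAN_B), ("y", _LOG_MEAN_Y)):
            ion = f"{kind}{k}"
            intensity = float(rng.lognormal(mu, _LOG_SD))
            peaks.append(Peak(mz=fragment_mz(peptide, ion),
                              intensity=intensity, annotation=ion))
    n_contam = int(round(contaminant_frac * len(peaks)))
    lo, hi = 150.0, max(300.0, precursor_mz * charge)
    for _ in range(n_contam):
        peaks.append(Peak(mz=float(rng.uniform(lo, hi)),
                          intensity=float(rng.lognormal(
                              _LOG_MEAN_CONTAMINANT, _LOG_SD)),
                          annotation=None))
    return LibraryEntry(peptide=peptide, charge=charge,
                        precursor_mz=precursor_mz, neutral_mass=neutral,
                        peaks=peaks)


def make_decoy(entry: LibraryEntry, seed: int = 0,
               decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> LibraryEntry:
    """Shuffled-sequence decoy: permute all residues but the C-terminal one,
    reposition annotated fragments onto the shuffled sequence's theoretical
    m/z (intensities preserved), copy unannotated peaks."""
    pep = entry.stripped_peptide
    if len(pep) < 3:
        raise ValueError(f"peptide {pep!r} too short to shuffle into a decoy")
    rng = np.random.default_rng(seed)
    prefix = list(pep[:-1])
    for _ in range(50):
        rng.shuffle(prefix)
        shuffled = "".join(prefix) + pep[-1]
        if shuffled != pep:
            break
    peaks = []
    for p in entry.peaks:
        if p.annotation is None:
            peaks.append(p)
        else:
            peaks.append(Peak(mz=fragment_mz(shuffled, p.annotation),
                              intensity=p.intensity, annotation=p.annotation))
    return LibraryEntry(peptide=decoy_prefix + shuffled, charge=entry.charge,
                        precursor_mz=entry.precursor_mz,
                        neutral_mass=entry.neutral_mass, peaks=peaks,
                        is_decoy=True, proteins=["DECOY_synthetic"],
                        stripped_peptide=shuffled)


def perturb_to_pseudo_ms2(entry: LibraryEntry, cfg: SimConfig, seed: int,
                          quality_level: str = "Q1",
                          spectrum_id: str | None = None,
                          scan_number: int = 1,
                          chimera_source: LibraryEntry | None = None,
                          ) -> QuerySpectrum:
    """Degrade a library spectrum into a DIA-like pseudo-MS2 query.

    Intensities get multiplicative lognormal jitter at the configured CV,
    peaks drop out independently, Poisson-many uniform noise peaks are
    added, m/z values are jittered, and (when a ``chimera_source`` is
    given) half-intensity peaks of a second entry are mixed in.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cfg.intensity_cv ** 2))
    peaks: list[Peak] = []
    for p in entry.peaks:
        if rng.random() < cfg.dropout_prob:
            continue
        intensity = p.intensity * float(rng.lognormal(-sigma ** 2 / 2, sigma)) \
            if sigma > 0 else p.intensity
        mz = p.mz + float(rng.normal(0.0, cfg.mz_jitter_sd)) \
            if cfg.mz_jitter_sd > 0 else p.mz
        peaks.append(Peak(mz=max(mz, 1e-3), intensity=intensity))
    if chimera_source is not None:
        for p in chimera_source.peaks:
            peaks.append(Peak(mz=p.mz, intensity=0.5 * p.intensity))
    n_noise = int(rng.poisson(cfg.noise_peaks)) if cfg.noise_peaks > 0 else 0
    if peaks or entry.peaks:
        lo = 150.0
        hi = max(300.0, entry.precursor_mz * entry.charge)
        ref = np.median([p.intensity for p in entry.peaks]) \
            if entry.peaks else 100.0
        for _ in range(n_noise):
            peaks.append(Peak(mz=float(rng.uniform(lo, hi)),
                              intensity=float(ref * rng.uniform(0.05, 0.5))))
    sid = spectrum_id or f"sim.{entry.stripped_peptide}.{scan_number}"
    return QuerySpectrum(spectrum_id=sid, scan_number=scan_number,
                         precursor_mz=entry.precursor_mz,
                         precursor_charge=entry.charge,
                         quality_level=quality_level, peaks=peaks)


def _random_peptides(rng: np.random.Generator, n: int,
                     length_range: tuple[int, int],
                     exclude: set[str] | None = None) -> list[str]:
    exclude = set(exclude or ())
    peptides: list[str] = []
    while len(peptides) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1)) \
            + str(rng.choice(["K", "R"]))  # tryptic-like C-terminus
        if pep not in exclude:
            exclude.add(pep)
            peptides.append(pep)
    return peptides


def _tier_assignment(rng: np.random.Generator, n: int,
                     mix: tuple[float, float, float]) -> list[str]:
    """Largest-remainder allocation of n queries over Q1/Q2/Q3, shuffled."""
    raw = [m * n for m in mix]
    counts = [int(c) for c in raw]
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[order[i % 3]] += 1
    tiers = [f"Q{i + 1}" for i in range(3) for _ in range(counts[i])]
    rng.shuffle(tiers)
    return tiers


def build_library(cfg: SimConfig,
                  peptides: list[str] | None = None) -> list[LibraryEntry]:
    """Target entries plus one shuffled decoy per target, decoys appended."""
    rng = np.random.default_rng(cfg.seed)
    if peptides is None:
        peptides = _random_peptides(rng, cfg.n_peptides, cfg.length_range)
    charges = rng.choice(list(cfg.charge_set), size=len(peptides))
    target_set = set(peptides)
    targets, decoys = [], []
    for i, (pep, z) in enumerate(zip(peptides, charges)):
        entry = theoretical_spectrum(pep, int(z), seed=cfg.seed + 1000 + i,
                                     contaminant_frac=cfg.contaminant_frac)
        targets.append(entry)
        for attempt in range(20):
            decoy = make_decoy(entry, seed=cfg.seed + 2000 + 97 * i + attempt)
            if decoy.stripped_peptide not in target_set:
                break
        decoys.append(decoy)
    entries = targets + decoys
    for i, e in enumerate(entries):
        e.lib_index = i
    return entries


def write_query_mgf(queries: list[QuerySpectrum], path: str | Path) -> None:
    """Write queries as MGF.

    Printed precision (m/z 4 decimals, intensity 1) matches the sptxt
    writer, so a noise-free query and its source library entry survive the
    round trip as identical peak lists.
    """
    spectra = []
    for q in queries:
        spectra.append({
            "m/z array": np.round([p.mz for p in q.peaks], 4),
            "intensity array": np.round([p.intensity for p in q.peaks], 1),
            "params": {
                "title": q.spectrum_id,
                "pepmass": round(q.precursor_mz, 5),
                "charge": q.precursor_charge,
                "scans": q.scan_number,
            },
        })
    pmgf.write(spectra, str(path), file_mode="w")


def generate_benchmark(cfg: SimConfig, out_dir: str | Path,
                       n_queries: int | None = None,
                       null_queries: bool = False,
                       null_fraction: float = 0.0,
                       ) -> tuple[Path, dict[str, Path], GroundTruth]:
    """Write a full benchmark: target+decoy sptxt, per-tier MGF query files
    and a ground-truth TSV. Returns (sptxt path, {tier: mgf path}, truth).

    ``null_fraction`` makes that share of the queries come from a disjoint
    foreign peptide set (ground truth ``"noise"``), emulating the junk
    pseudo-MS2 spectra of real DIA extractions. ``null_queries=True`` is
    shorthand for ``null_fraction=1.0`` — the pure null condition used for
    FDR calibration.
    """
    if null_queries:
        null_fraction = 1.0
    if not 0 <= null_fraction <= 1:
        raise ValueError("null_fraction must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    peptides = _random_peptides(rng, cfg.n_peptides, cfg.length_range)
    entries = build_library(cfg, peptides)
    targets = [e for e in entries if not e.is_decoy]
    sptxt_path = out_dir / "library.sptxt"
    write_sptxt(entries, sptxt_path)

    n_queries = n_queries if n_queries is not None else len(targets)
    n_null = int(round(null_fraction * n_queries))
    foreign = _random_peptides(rng, n_null, cfg.length_range,
                               exclude={e.stripped_peptide for e in entries})
    charges = rng.choice(list(cfg.charge_set), size=max(n_null, 1))
    null_sources = [theoretical_spectrum(p, int(z),
                                         seed=cfg.seed + 5000 + i,
                                         contaminant_frac=cfg.contaminant_frac)
                    for i, (p, z) in enumerate(zip(foreign, charges))]
    true_sources = [targets[i % len(targets)]
                    for i in range(n_queries - n_null)]
    sources: list[LibraryEntry | None] = true_sources + null_sources
    is_null = [False] * len(true_sources) + [True] * n_null

    tiers = _tier_assignment(rng, n_queries, cfg.quality_mix)
    truth = GroundTruth()
    by_tier: dict[str, list[QuerySpectrum]] = {"Q1": [], "Q2": [], "Q3": []}
    for i, (src, null, tier) in enumerate(zip(sources, is_null, tiers)):
        chimera = None
        if cfg.chimera_prob > 0 and rng.random() < cfg.chimera_prob \
                and len(targets) > 1:
            chimera = targets[int(rng.integers(len(targets)))]
        q = perturb_to_pseudo_ms2(
            src, cfg, seed=cfg.seed + 9000 + i, quality_level=tier,
            spectrum_id=f"sim.{i:05d}", scan_number=i + 1,
            chimera_source=chimera)
        truth.mapping[q.spectrum_id] = "noise" if null else src.peptide
        by_tier[tier].append(q)

    mgf_paths: dict[str, Path] = {}
    for tier, qs in by_tier.items():
        path = out_dir / f"queries_{tier}.mgf"
        write_query_mgf(qs, path)
        mgf_paths[tier] = path
    truth.write(out_dir / "ground_truth.tsv")
    return sptxt_path, mgf_paths, truth
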