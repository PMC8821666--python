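"""Spectrum preprocessing: SNfilter, intensity power, unassigned-peak
scaling, 1-Th binning, Spillover, and L2 normalization.

Query pipeline:   SNfilter -> IP -> bin -> spillover -> normalize
Library pipeline: IP -> UPS -> bin -> spillover -> normalize

IP (intensity power) raises every peak intensity to an exponent < 1 to damp
dominant peaks; UPS (unassigned-peak scaling) multiplies library peaks that
lack an ion-type annotation by a factor < 1; the SNfilter keeps query peaks
strictly above max-intensity / factor (SpectraST's "dynamic range").
Defaults (IP = 0.33, UPS = 0.4, Max binning) are the setting optimized for
pseudo-MS2 spectra, which differs from typical DDA-tuned values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

from .io import LibraryEntry, Peak, QuerySpectrum

Spectrum = Union[QuerySpectrum, LibraryEntry]

BIN_STRATEGIES = ("Max", "Sum")
SPILLOVER_TARGETS = ("none", "query", "library", "both")


@dataclass
class BinnedSpectrum:
    """Sparse 1-Th binned intensity vector keyed by integer bin index."""

    bins: dict[int, float] = field(default_factory=dict)
    normalized: bool = False

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.bins.values()))

    def total(self) -> float:
        return sum(self.bins.values())


@dataclass
class PreprocessConfig:
    """Preprocessing parameters; the defaults are the optimized setting."""

    ip_exponent: float = 0.33
    ups_factor: float = 0.4
    sn_factor: float | None = None  # None disables the SNfilter
    bin_strategy: str = "Max"
    spillover_target: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.ip_exponent <= 1:
            raise ValueError("ip_exponent must be in (0, 1]")
        if not 0 < self.ups_factor <= 1:
            raise ValueError("ups_factor must be in (0, 1]")
        if self.sn_factor is not None and self.sn_factor <= 1:
            raise ValueError("sn_factor must be > 1 (or None to disable)")
        if self.bin_strategy not in BIN_STRATEGIES:
            raise ValueError(f"bin_strategy must be one of {BIN_STRATEGIES}")
        if self.spillover_target not in SPILLOVER_TARGETS:
            raise ValueError(f"spillover_target must be one of {SPILLOVER_TARGETS}")


def _with_peaks(spectrum: Spectrum, peaks: list[Peak]) -> Spectrum:
    return replace(spectrum, peaks=peaks)


def apply_intensity_power(spectrum: Spectrum, exponent: float) -> Spectrum:
    """Raise every peak intensity to ``exponent`` (m/z and order unchanged)."""
    if exponent <= 0:
        raise ValueError("intensity-power exponent must be > 0")
    peaks = [Peak(p.mz, p.intensity ** exponent, p.annotation)
             for p in spectrum.peaks]
    return _with_peaks(spectrum, peaks)


def apply_ups(entry: LibraryEntry, factor: float) -> LibraryEntry:
    """Scale unannotated library peaks by ``factor``; annotated peaks as is."""
    if not 0 < factor <= 1:
        raise ValueError("UPS factor must be in (0, 1]")
    peaks = [p if p.annotation is not None
             else Peak(p.mz, p.intensity * factor, None)
             for p in entry.peaks]
    return _with_peaks(entry, peaks)


def apply_sn_filter(spectrum: QuerySpectrum, factor: float) -> QuerySpectrum:
    """Keep peaks strictly above max-intensity / ``factor``."""
    if factor <= 1:
        raise ValueError("SNfilter factor must be > 1")
    if not spectrum.peaks:
        return spectrum
    threshold = max(p.intensity for p in spectrum.peaks) / factor
    peaks = [p for p in spectrum.peaks if p.intensity > threshold]
    return _with_peaks(spectrum, peaks)


def bin_spectrum(spectrum: Spectrum, strategy: str = "Max") -> BinnedSpectrum:
    """Assign peaks to 1-Th bins by round-half-up of m/z.

    Bin intensity is the max (``Max``) or the sum (``Sum``) of member peaks.
    """
    if strategy not in BIN_STRATEGIES:
        raise ValueError(f"strategy must be one of {BIN_STRATEGIES}")
    bins: dict[int, float] = {}
    for p in spectrum.peaks:
        b = math.floor(p.mz + 0.5)  # round half up
        if strategy == "Max":
            bins[b] = max(bins.get(b, 0.0), p.intensity)
        else:
            bins[b] = bins.get(b, 0.0) + p.intensity
    return BinnedSpectrum(bins=bins, normalized=False)


def apply_spillover(b: BinnedSpectrum, strategy: str = "Max") -> BinnedSpectrum:
    """Share half of each bin's intensity with its +-1 Th neighbours.

    All contributions are computed from the pre-spillover vector
    (simultaneous semantics). ``Max``: a neighbour whose original intensity
    is below v/2 is replaced by v/2 (collisions keep the larger assignment).
    ``Sum``: both neighbours each receive +v/2.
    """
    if b.normalized:
        raise ValueError("spillover must run before normalization")
    if strategy not in BIN_STRATEGIES:
        raise ValueError(f"strategy must be one of {BIN_STRATEGIES}")
    original = b.bins
    out = dict(original)
    for idx, v in original.items():
        half = v / 2.0
        for nb in (idx - 1, idx + 1):
            if strategy == "Max":
                if original.get(nb, 0.0) < half:
                    out[nb] = max(out.get(nb, 0.0), half)
            else:
                out[nb] = out.get(nb, 0.0) + half
    return BinnedSpectrum(bins=out, normalized=False)


def normalize(b: BinnedSpectrum) -> BinnedSpectrum:
    """Scale so the squared intensities sum to 1 (unit Euclidean norm)."""
    n = b.norm()
    if n == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return BinnedSpectrum(bins={k: v / n for k, v in b.bins.items()},
                          normalized=True)


def preprocess_query(s: QuerySpectrum, cfg: PreprocessConfig) -> BinnedSpectrum:
    """SNfilter -> IP -> bin -> spillover (if enabled on queries) -> normalize."""
    if cfg.sn_factor is not None:
        s = apply_sn_filter(s, cfg.sn_factor)
    s = apply_intensity_power(s, cfg.ip_exponent)
    b = bin_spectrum(s, cfg.bin_strategy)
    if cfg.spillover_target in ("query", "both"):
        b = apply_spillover(b, cfg.bin_strategy)
    return normalize(b)


def preprocess_library(e: LibraryEntry, cfg: PreprocessConfig) -> BinnedSpectrum:
    """IP -> UPS -> bin -> spillover (if enabled on library) -> normalize."""
    e = apply_intensity_power(e, cfg.ip_exponent)
    e = apply_ups(e, cfg.ups_factor)
    b = bin_spectrum(e, cfg.bin_strategy)
    if cfg.spillover_target in ("library", "both"):
        b = apply_spillover(b, cfg.bin_strategy)
    return normalize(b)
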