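"""Spectrum and spectral-library I/O.

Readers for query pseudo-MS2 spectra (MGF, mzML, mzXML — the formats emitted
by DIA pseudo-spectrum extraction tools) and for spectral libraries in the
SpectraST ``sptxt`` text format, plus the tab-separated result table writer.

Query files carry a spectrum quality tier (Q1 best, Q3 worst) encoded as a
``_Q1``/``_Q2``/``_Q3`` token in the filename; files without the token are
treated as Q1.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mgf, mzxml

logger = logging.getLogger("dialib")

PROTON_MASS = 1.007276466879  # Da
WATER_MASS = 18.010564684  # Da

QUALITY_LEVELS = ("Q1", "Q2", "Q3")
DEFAULT_DECOY_PREFIX = "DECOY_"

_QUALITY_TOKEN = re.compile(r"_Q([123])(?=[_.\-]|$)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z (Th, > 0), intensity (>= 0), optional ion label.

    ``annotation`` is e.g. ``"b5"``, ``"y7"`` or ``"y3^2"``; ``None`` means
    the peak carries no ion-type annotation (serialized as ``?`` in sptxt).
    """

    mz: float
    intensity: float
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class QuerySpectrum:
    """One pseudo-MS2 query spectrum with precursor metadata."""

    spectrum_id: str
    scan_number: int
    precursor_mz: float
    precursor_charge: int | None
    quality_level: str = "Q1"
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.quality_level not in QUALITY_LEVELS:
            raise ValueError(f"quality_level must be one of {QUALITY_LEVELS}")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)


@dataclass
class LibraryEntry:
    """A reference library spectrum for one (modified peptide, charge)."""

    peptide: str
    charge: int
    precursor_mz: float
    neutral_mass: float
    peaks: list[Peak] = field(default_factory=list)
    is_decoy: bool = False
    proteins: list[str] = field(default_factory=list)
    lib_index: int = 0
    stripped_peptide: str = ""

    def __post_init__(self) -> None:
        if not self.stripped_peptide:
            self.stripped_peptide = strip_modifications(self.peptide)
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def check_mass_consistency(self, tol: float = 0.01) -> None:
        expected = (self.neutral_mass + self.charge * PROTON_MASS) / self.charge
        if abs(expected - self.precursor_mz) > tol:
            raise ValueError(
                f"{self.peptide}/{self.charge}: PrecursorMZ {self.precursor_mz:.4f} "
                f"inconsistent with neutral mass {self.neutral_mass:.4f} "
                f"(expected {expected:.4f})"
            )


def strip_modifications(peptide: str) -> str:
    """Remove bracketed/numeric modification tags: ``AAC[160]K`` -> ``AACK``."""
    return re.sub(r"[\[\(][^\]\)]*[\]\)]|[^A-Z]", "", peptide)


class SpectralLibrary:
    """A list of :class:`LibraryEntry` with a precursor-m/z range index."""

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries: list[LibraryEntry] = list(entries)
        order = sorted(range(len(self.entries)),
                       key=lambda i: self.entries[i].precursor_mz)
        self._sorted_mz = [self.entries[i].precursor_mz for i in order]
        self._order = order

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def range_query(self, lo: float, hi: float) -> list[LibraryEntry]:
        """All entries with precursor m/z in the closed interval [lo, hi]."""
        i = bisect_left(self._sorted_mz, lo)
        j = bisect_right(self._sorted_mz, hi)
        return [self.entries[self._order[k]] for k in range(i, j)]

    @property
    def n_targets(self) -> int:
        return sum(not e.is_decoy for e in self.entries)

    @property
    def n_decoys(self) -> int:
        return sum(e.is_decoy for e in self.entries)


# ---------------------------------------------------------------------------
# Query spectrum readers
# ---------------------------------------------------------------------------

def quality_from_filename(path: str | Path) -> str:
    """Infer the Q1/Q2/Q3 tier from a ``_Qn`` token in the file name."""
    m = _QUALITY_TOKEN.search(Path(path).stem + ".")
    return f"Q{m.group(1)}" if m else "Q1"


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("mgf", "mzml", "mzxml"):
        return suffix
    raise ValueError(f"cannot determine spectrum file format from {path.name!r}; "
                     "pass format explicitly (mgf, mzml or mzxml)")


def read_query_spectra(path: str | Path, format: str = "auto") -> list[QuerySpectrum]:
    """Read pseudo-MS2 query spectra from an MGF, mzML or mzXML file.

    Spectra with no peaks are dropped (count logged); spectra lacking a
    precursor m/z are skipped and counted. The quality tier is inferred from
    the filename.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format.lower()
    quality = quality_from_filename(path)

    if fmt == "mgf":
        raw = _iter_mgf(path)
    elif fmt == "mzml":
        raw = _iter_mzml(path)
    elif fmt == "mzxml":
        raw = _iter_mzxml(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    spectra: list[QuerySpectrum] = []
    n_empty = n_noprec = 0
    for sid, scan, prec_mz, charge, mzs, ints in raw:
        if prec_mz is None:
            n_noprec += 1
            continue
        peaks = [Peak(mz=float(m), intensity=float(i))
                 for m, i in zip(mzs, ints) if m > 0 and i >= 0]
        if not peaks:
            n_empty += 1
            continue
        spectra.append(QuerySpectrum(
            spectrum_id=sid, scan_number=scan, precursor_mz=float(prec_mz),
            precursor_charge=charge, quality_level=quality, peaks=peaks))
    if n_empty:
        logger.info("%s: dropped %d empty spectra", path.name, n_empty)
    if n_noprec:
        logger.info("%s: skipped %d spectra without precursor m/z", path.name, n_noprec)
    return spectra


def _iter_mgf(path: Path):
    try:
        reader = mgf.read(str(path), use_index=False)
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            title = str(params.get("title", f"{path.stem}.{i}"))
            pepmass = params.get("pepmass")
            prec_mz = pepmass[0] if pepmass else None
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            scan = _scan_from_title(title, default=i + 1)
            yield title, scan, prec_mz, charge, spec["m/z array"], spec["intensity array"]
    except Exception as exc:  # noqa: BLE001 - surface parser context
        if isinstance(exc, (ValueError, FileNotFoundError)):
            raise
        raise ValueError(f"failed to parse MGF file {path.name}: {exc}") from exc


def _scan_from_title(title: str, default: int) -> int:
    m = re.search(r"scan[=:\s]*(\d+)", title, flags=re.I)
    if m:
        return int(m.group(1))
    m = re.search(r"\.(\d+)\.\d+(?:\.\d+)?$", title)
    return int(m.group(1)) if m else default


def _decode_mzml_binary(elem) -> "np.ndarray":
    """Decode one mzML <binaryDataArray>: base64, optional zlib, 32/64-bit."""
    import base64
    import zlib

    import numpy as np

    dtype = "<f8"
    compressed = False
    for cv in elem.iter("{*}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    binary = elem.find("{*}binary")
    if binary is None or not (binary.text or "").strip():
        return np.empty(0)
    raw = base64.b64decode(binary.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype)


def _iter_mzml(path: Path):
    # minimal MS2 reader on lxml (mzML cvParam layout, HUPO-PSI 1.1)
    from lxml import etree

    for i, (_, spec) in enumerate(
            etree.iterparse(str(path), tag="{*}spectrum")):
        ms_level = None
        for cv in spec.findall("{*}cvParam"):
            if cv.get("accession") == "MS:1000511":
                ms_level = int(cv.get("value"))
        if ms_level != 2:
            spec.clear()
            continue
        sid = spec.get("id", f"{path.stem}.{i}")
        m = re.search(r"scan=(\d+)", str(sid))
        scan = int(m.group(1)) if m else i + 1
        prec_mz = charge = None
        for cv in spec.iter("{*}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000744":
                prec_mz = float(cv.get("value"))
            elif acc == "MS:1000041" and cv.get("value"):
                charge = int(cv.get("value"))
        mzs = ints = None
        for arr in spec.iter("{*}binaryDataArray"):
            accs = {cv.get("accession") for cv in arr.iter("{*}cvParam")}
            data = _decode_mzml_binary(arr)
            if "MS:1000514" in accs:
                mzs = data
            elif "MS:1000515" in accs:
                ints = data
        spec.clear()
        if mzs is None or ints is None:
            mzs, ints = [], []
        yield str(sid), scan, prec_mz, charge, mzs, ints


def _iter_mzxml(path: Path):
    with mzxml.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            if int(spec.get("msLevel", 0)) != 2:
                continue
            scan = int(spec.get("num", i + 1))
            prec = spec.get("precursorMz")
            prec_mz = charge = None
            if prec:
                prec_mz = prec[0].get("precursorMz")
                if prec[0].get("precursorCharge") is not None:
                    charge = int(prec[0]["precursorCharge"])
            yield f"{path.stem}.{scan}", scan, prec_mz, charge, \
                spec["m/z array"], spec["intensity array"]


# ---------------------------------------------------------------------------
# sptxt library reader / writer
# ---------------------------------------------------------------------------

def read_sptxt(path: str | Path,
               decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> SpectralLibrary:
    """Parse a SpectraST-style sptxt text library.

    Each record is a block of ``Key: value`` header lines (Name, MW,
    PrecursorMZ, Comment, NumPeaks, ...) followed by ``NumPeaks`` peak lines
    of ``mz<TAB>intensity<TAB>annotation[<TAB>info]``. An annotation of ``?``
    means unannotated. Entries whose Name starts with ``decoy_prefix`` are
    flagged as decoys.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    header: dict[str, str] = {}
    peaks: list[Peak] = []
    n_expected: int | None = None

    def finish() -> None:
        nonlocal header, peaks, n_expected
        if not header:
            return
        name = header.get("Name", "<unnamed>")
        if n_expected is None:
            raise ValueError(f"sptxt entry {name!r}: missing NumPeaks")
        if len(peaks) != n_expected:
            raise ValueError(
                f"sptxt entry {name!r}: NumPeaks is {n_expected} "
                f"but {len(peaks)} peak lines were found")
        entries.append(_entry_from_block(name, header, peaks, len(entries),
                                         decoy_prefix))
        header, peaks, n_expected = {}, [], None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                finish()
                continue
            if line.startswith("#"):
                continue
            in_peaks = n_expected is not None and len(peaks) < n_expected
            m = re.match(r"^([A-Za-z]\w*):\s?(.*)$", line)
            if m and not in_peaks:
                key, value = m.group(1), m.group(2)
                if key == "Name":
                    finish()
                header[key] = value
                if key == "NumPeaks":
                    n_expected = int(value)
                continue
            if not in_peaks:
                name = header.get("Name", "<unnamed>")
                raise ValueError(
                    f"sptxt entry {name!r}, line {lineno}: unexpected peak "
                    f"line {line!r} (more peaks than NumPeaks declares)")
            cols = line.split("\t")
            if len(cols) < 2:
                cols = line.split()
            try:
                mz_v, int_v = float(cols[0]), float(cols[1])
            except (ValueError, IndexError) as exc:
                name = header.get("Name", "<unnamed>")
                raise ValueError(
                    f"sptxt entry {name!r}, line {lineno}: "
                    f"non-numeric peak line {line!r}") from exc
            ann = cols[2].strip() if len(cols) > 2 else "?"
            ann_main = ann.split("/")[0].split(",")[0]
            annotation = None if ann_main in ("?", "") else ann_main
            peaks.append(Peak(mz=mz_v, intensity=int_v, annotation=annotation))
    finish()
    return SpectralLibrary(entries)


def _entry_from_block(name: str, header: dict[str, str], peaks: list[Peak],
                      lib_index: int, decoy_prefix: str) -> LibraryEntry:
    is_decoy = name.startswith(decoy_prefix)
    bare = name[len(decoy_prefix):] if is_decoy else name
    if "/" in bare:
        peptide, charge_s = bare.rsplit("/", 1)
        charge = int(charge_s)
    else:
        peptide, charge = bare, 1
    stripped = strip_modifications(peptide)
    if is_decoy:
        peptide = decoy_prefix + peptide
    try:
        precursor_mz = float(header["PrecursorMZ"])
    except KeyError as exc:
        raise ValueError(f"sptxt entry {name!r}: missing PrecursorMZ") from exc
    neutral_mass = float(header.get("MW", precursor_mz * charge - charge * PROTON_MASS))
    proteins = []
    comment = header.get("Comment", "")
    m = re.search(r"Protein=(?:\d+/)?(\S+)", comment)
    if m:
        proteins = m.group(1).split("/")
    entry = LibraryEntry(peptide=peptide, charge=charge, precursor_mz=precursor_mz,
                         neutral_mass=neutral_mass, peaks=peaks, is_decoy=is_decoy,
                         proteins=proteins, lib_index=lib_index,
                         stripped_peptide=stripped)
    entry.check_mass_consistency()
    return entry


def write_sptxt(entries: Sequence[LibraryEntry], path: str | Path,
                decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> None:
    """Serialize entries to sptxt (m/z to 4 decimals, intensity to 1)."""
    with open(path, "w") as fh:
        for i, e in enumerate(entries):
            bare = e.peptide
            if e.is_decoy and bare.startswith(decoy_prefix):
                bare = bare[len(decoy_prefix):]
            name = (decoy_prefix if e.is_decoy else "") + f"{bare}/{e.charge}"
            fh.write(f"Name: {name}\n")
            fh.write(f"LibID: {i}\n")
            fh.write(f"MW: {e.neutral_mass:.4f}\n")
            fh.write(f"PrecursorMZ: {e.precursor_mz:.4f}\n")
            fh.write("Status: Normal\n")
            prots = "/".join(e.proteins) if e.proteins else "UNKNOWN"
            fh.write(f"Comment: Protein={prots}\n")
            fh.write(f"NumPeaks: {len(e.peaks)}\n")
            for p in e.peaks:
                ann = p.annotation if p.annotation else "?"
                fh.write(f"{p.mz:.4f}\t{p.intensity:.1f}\t{ann}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# SSM result table
# ---------------------------------------------------------------------------

SSM_TABLE_COLUMNS = [
    "query_id", "scan_number", "peptide", "charge", "proteins", "is_decoy",
    "rank", "dot", "deltaD", "dotBias", "fval", "penalty", "second_best_dot",
    "xcorr", "libc_cosSim", "kt", "hgt", "pcc",
    "mass_difference", "precursor_mz_difference", "charge_state",
    "quality_level", "hits_num", "hits_mean", "hits_stdev", "pval",
]


def write_ssm_table(records: Sequence, path: str | Path) -> None:
    """Write SSM records as a TSV, one row per match, sorted by query id."""
    import pandas as pd

    rows = [r.as_row() for r in sorted(records, key=lambda r: r.query_id)]
    df = pd.DataFrame(rows, columns=SSM_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ssm_table(path: str | Path):
    """Read a TSV written by :func:`write_ssm_table` back into records."""
    import pandas as pd

    from .search import SSMRecord

    df = pd.read_csv(path, sep="\t")
    return [SSMRecord.from_row(row) for _, row in df.iterrows()]
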