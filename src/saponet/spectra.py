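"""Spectrum data model, MGF/TSV readers and writers, and the packaged
reference compound library of the ginseng-polygala drug pair.

The library ships 40 constituents characterized in negative-mode
UHPLC-QTOF-MS from the combined ginseng (Panax ginseng) and polygala
(Polygala tenuifolia) extract: protopanaxadiol (PPD), protopanaxatriol
(PPT) and oleanane (OLE) ginsenosides, polygala saponins, oligosaccharide
esters and xanthone glycosides.  Twelve of the records were confirmed
against reference standards.  No fragment intensities are recorded, so
library-derived spectra carry unit intensities throughout.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mgf as _mgf

from .chem import MolecularFormula, parse_formula

__all__ = [
    "SCAN_RANGE",
    "Peak",
    "Spectrum",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "CompoundRecord",
    "CLASS_LABELS",
    "load_reference_db",
    "db_to_spectra",
]

#: Acquisition scan range (m/z); peaks outside trigger a validation warning,
#: not an error.
SCAN_RANGE: tuple[float, float] = (100.0, 2000.0)

#: The closed six-class set used across the package.
CLASS_LABELS: tuple[str, ...] = (
    "PPD",
    "PPT",
    "OLE",
    "polygala-saponin",
    "oligosaccharide-ester",
    "xanthone",
)

_LIBRARY_SHA256 = "a5c7accb765c7096e09e12d57086a532bcf40fb1e4212bdcc425508d59c606f0"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative intensity at m/z {self.mz}")


@dataclass
class Spectrum:
    """One MS/MS scan: precursor m/z, retention time, ordered fragment peaks.

    Peaks are kept sorted ascending by m/z; peaks closer than 1e-6 Da are
    merged (intensities summed).  Polarity is fixed negative.
    """

    id: str
    precursor_mz: float
    rt: float | None = None
    peaks: list[Peak] = field(default_factory=list)
    polarity: str = "negative"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"spectrum {self.id!r}: precursor m/z must be > 0")
        merged: list[Peak] = []
        for pk in sorted(self.peaks, key=lambda p: p.mz):
            if merged and abs(pk.mz - merged[-1].mz) < 1e-6:
                prev = merged[-1]
                merged[-1] = Peak(prev.mz, prev.intensity + pk.intensity)
            else:
                merged.append(pk)
        self.peaks = merged
        lo, hi = SCAN_RANGE
        out = [p.mz for p in self.peaks if not (lo <= p.mz <= hi)]
        if out:
            warnings.warn(
                f"spectrum {self.id!r}: {len(out)} peak(s) outside the "
                f"{lo:g}-{hi:g} scan range (e.g. {out[0]:.4f})",
                stacklevel=2,
            )

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


class SpectraFormatError(ValueError):
    """Malformed spectrum file; the message carries file/line context."""


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _validate_mgf_blocks(path: Path) -> int:
    """Cheap structural pass; returns block count, raises with line numbers."""
    depth = 0
    blocks = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if depth:
                    raise SpectraFormatError(
                        f"{path}:{lineno}: nested BEGIN IONS"
                    )
                depth = 1
            elif token == "END IONS":
                if not depth:
                    raise SpectraFormatError(
                        f"{path}:{lineno}: END IONS without BEGIN IONS"
                    )
                depth = 0
                blocks += 1
    if depth:
        raise SpectraFormatError(f"{path}: unterminated BEGIN IONS block at EOF")
    return blocks


def _read_mgf(path: Path) -> list[Spectrum]:
    n_blocks = _validate_mgf_blocks(path)
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (None,))
            precursor = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
            if precursor is None:
                raise SpectraFormatError(
                    f"{path}: spectrum block {i + 1} lacks PEPMASS"
                )
            rt = params.get("rtinseconds")
            title = str(params.get("title", f"scan_{i + 1}"))
            peaks = [
                Peak(float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            ]
            meta = {
                k: v
                for k, v in params.items()
                if k not in {"pepmass", "rtinseconds", "title", "charge"}
            }
            spectra.append(
                Spectrum(
                    id=title,
                    precursor_mz=float(precursor),
                    rt=float(rt) / 60.0 if rt is not None else None,
                    peaks=peaks,
                    metadata=meta,
                )
            )
    if len(spectra) != n_blocks:
        raise SpectraFormatError(
            f"{path}: parsed {len(spectra)} spectra from {n_blocks} blocks"
        )
    return spectra


def _write_mgf(spectra: Sequence[Spectrum], path: Path) -> None:
    entries = []
    for s in spectra:
        params: dict = {"TITLE": s.id, "PEPMASS": s.precursor_mz, "CHARGE": "1-"}
        if s.rt is not None:
            params["RTINSECONDS"] = s.rt * 60.0
        for k, v in s.metadata.items():
            params[str(k).upper()] = v
        entries.append(
            {
                "m/z array": s.mzs,
                "intensity array": s.intensities,
                "params": params,
            }
        )
    with open(path, "w") as handle:
        _mgf.write(entries, handle)


# ---------------------------------------------------------------------------
# TSV fixture dialect: one row per spectrum,
#   id <tab> rt_min <tab> precursor_mz <tab> mz1;mz2;...
# "-" or empty fourth column means a spectrum without recorded fragments.
# ---------------------------------------------------------------------------

_TSV_HEADER = "#id\trt_min\tprecursor_mz\tfragments"


def _parse_fragment_field(text: str) -> list[float]:
    text = text.strip()
    if not text or text == "-":
        return []
    return [float(tok) for tok in text.split(";") if tok.strip()]


def _read_tsv(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SpectraFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            sid, rt_text, prec_text = fields[0], fields[1], fields[2]
            frag_text = fields[3] if len(fields) > 3 else ""
            try:
                rt = float(rt_text) if rt_text.strip() not in {"", "-"} else None
                precursor = float(prec_text)
                frags = _parse_fragment_field(frag_text)
            except ValueError as exc:
                raise SpectraFormatError(f"{path}:{lineno}: {exc}") from exc
            spectra.append(
                Spectrum(
                    id=sid,
                    precursor_mz=precursor,
                    rt=rt,
                    peaks=[Peak(mz) for mz in frags],
                )
            )
    return spectra


def _write_tsv(spectra: Sequence[Spectrum], path: Path) -> None:
    with open(path, "w") as handle:
        handle.write(_TSV_HEADER + "\n")
        for s in spectra:
            rt = f"{s.rt:.6g}" if s.rt is not None else "-"
            frags = ";".join(f"{p.mz:.6f}" for p in s.peaks) or "-"
            handle.write(f"{s.id}\t{rt}\t{s.precursor_mz:.6f}\t{frags}\n")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"mgf", "tsv", "txt"}:
        return "tsv" if suffix == "txt" else suffix
    raise SpectraFormatError(
        f"cannot infer format of {path}; pass format='mgf' or 'tsv'"
    )


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from an MGF file or the one-row-per-spectrum TSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mgf":
        spectra = _read_mgf(path)
    elif fmt == "tsv":
        spectra = _read_tsv(path)
    else:
        raise SpectraFormatError(f"unsupported format {fmt!r}")
    if not spectra:
        warnings.warn(f"{path}: no spectra found", stacklevel=2)
    return spectra


def write_spectra(
    spectra: Sequence[Spectrum], path: str | Path, format: str | None = None
) -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mgf":
        _write_mgf(spectra, path)
    elif fmt == "tsv":
        _write_tsv(spectra, path)
    else:
        raise SpectraFormatError(f"unsupported format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Reference compound library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: identity, formula, RT, reference m/z and fragments.

    ``cal_mz`` is the library's calculated quasi-molecular ion m/z
    ([M-H]- or [M+HCOOH-H]-), ``obs_mz`` the observed value, ``ppm`` the
    recorded mass error.  ``reference_confirmed`` marks compounds identified
    against an authentic standard.
    """

    index: int
    name: str
    formula: MolecularFormula
    rt: float
    cal_mz: float
    obs_mz: float
    ppm: float
    fragments: tuple[float, ...]
    class_label: str
    reference_confirmed: bool

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"record {self.index}: unknown class {self.class_label!r}"
            )


def _library_text() -> str:
    return (
        resources.files("saponet.data")
        .joinpath("compound_library.tsv")
        .read_text()
    )


def load_reference_db() -> list[CompoundRecord]:
    """Load the packaged 40-compound library (checksum-verified).

    Exactly 40 records, 12 of them reference-confirmed; deterministic and
    idempotent.
    """
    text = _library_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _LIBRARY_SHA256:
        raise RuntimeError(
            "packaged compound library failed its checksum; the data file "
            "was modified without updating _LIBRARY_SHA256"
        )
    records: list[CompoundRecord] = []
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        records.append(
            CompoundRecord(
                index=int(row["index"]),
                name=row["name"],
                formula=parse_formula(row["formula"]),
                rt=float(row["rt_min"]),
                cal_mz=float(row["cal_mz"]),
                obs_mz=float(row["obs_mz"]),
                ppm=float(row["ppm_printed"]),
                fragments=tuple(_parse_fragment_field(row["fragments"])),
                class_label=row["class_label"],
                reference_confirmed=row["reference_confirmed"] == "1",
            )
        )
    if len(records) != 40:
        raise RuntimeError(f"expected 40 library records, found {len(records)}")
    n_confirmed = sum(r.reference_confirmed for r in records)
    if n_confirmed != 12:
        raise RuntimeError(
            f"expected 12 reference-confirmed records, found {n_confirmed}"
        )
    return records


def db_to_spectra(db: Iterable[CompoundRecord]) -> list[Spectrum]:
    """Turn library records into unit-intensity query spectra.

    Precursor m/z is the observed value; peaks are the recorded fragment
    ions.  Records without fragments yield zero-peak spectra flagged in
    metadata.
    """
    spectra: list[Spectrum] = []
    for rec in db:
        meta = {
            "name": rec.name,
            "class_label": rec.class_label,
            "index": rec.index,
        }
        if not rec.fragments:
            meta["empty_fragments"] = True
            warnings.warn(
                f"library record {rec.index} ({rec.name}) has no recorded "
                "fragments; emitting a zero-peak spectrum",
                stacklevel=2,
            )
        spectra.append(
            Spectrum(
                id=str(rec.index),
                precursor_mz=rec.obs_mz,
                rt=rec.rt,
                peaks=[Peak(mz) for mz in rec.fragments],
                metadata=meta,
            )
        )
    return spectra
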