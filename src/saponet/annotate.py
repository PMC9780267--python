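"""Database annotation of MS/MS spectra against the compound library.

Candidates are gated by precursor mass error (ppm) against the library's
calculated quasi-molecular m/z, optionally by retention-time proximity, and
ranked by fragment corroboration.  Confidence tiers follow the usual
dereplication ladder: reference-confirmed (record verified against an
authentic standard), database-match (>=1 corroborating fragment), or
class-only (precursor/RT match alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .chem import adduct_mz, ppm_error
from .spectra import CompoundRecord, Spectrum

__all__ = [
    "AnnotationHit",
    "annotate_spectrum",
    "annotate_cohort",
    "summarize_annotations",
]

DEFAULT_PPM_WINDOW = 10.0
DEFAULT_RT_WINDOW = 0.5
DEFAULT_FRAG_TOL = 0.02


@dataclass(frozen=True)
class AnnotationHit:
    spectrum_id: str
    index: int
    name: str
    class_label: str
    delta_ppm: float
    rt_diff: float | None
    n_fragment_matches: int
    tier: str  # reference-confirmed | database-match | class-only


def _candidate_ppm(record: CompoundRecord, precursor_mz: float) -> float:
    """Signed ppm of the query precursor against the record's reference m/z.

    The stored calculated m/z is used when present (it encodes which adduct
    the record was assigned under); otherwise both supported adducts are
    tried and the smaller error kept ([M-H]- first).
    """
    if record.cal_mz and record.cal_mz > 0:
        return ppm_error(record.cal_mz, precursor_mz)
    errors = [
        ppm_error(adduct_mz(record.formula, name), precursor_mz)
        for name in ("[M-H]-", "[M+HCOOH-H]-")
    ]
    return min(errors, key=abs)


def _n_fragment_matches(
    record: CompoundRecord, spectrum: Spectrum, frag_tol: float
) -> int:
    """Number of library fragments corroborated by a query peak."""
    mzs = spectrum.mzs
    count = 0
    for frag in record.fragments:
        if any(abs(mz - frag) <= frag_tol for mz in mzs):
            count += 1
    return count


def _tier(record: CompoundRecord, n_fragment_matches: int) -> str:
    if record.reference_confirmed:
        return "reference-confirmed"
    return "database-match" if n_fragment_matches >= 1 else "class-only"


def annotate_spectrum(
    spectrum: Spectrum,
    db: Sequence[CompoundRecord],
    ppm_window: float = DEFAULT_PPM_WINDOW,
    rt_window: float = DEFAULT_RT_WINDOW,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> list[AnnotationHit]:
    """All library hits for *spectrum*, best first.

    Filtering: |ppm| <= ppm_window, then |rt difference| <= rt_window when
    both retention times are present.  Ranking: fragment corroboration
    (desc), |ppm| (asc), RT proximity, record index.  Deterministic; an
    empty list when nothing passes.
    """
    hits: list[AnnotationHit] = []
    for record in db:
        ppm = _candidate_ppm(record, spectrum.precursor_mz)
        if abs(ppm) > ppm_window:
            continue
        rt_diff: float | None = None
        if spectrum.rt is not None and record.rt is not None:
            rt_diff = abs(spectrum.rt - record.rt)
            if rt_diff > rt_window:
                continue
        n_frag = _n_fragment_matches(record, spectrum, frag_tol)
        hits.append(
            AnnotationHit(
                spectrum_id=spectrum.id,
                index=record.index,
                name=record.name,
                class_label=record.class_label,
                delta_ppm=ppm,
                rt_diff=rt_diff,
                n_fragment_matches=n_frag,
                tier=_tier(record, n_frag),
            )
        )
    hits.sort(
        key=lambda h: (
            -h.n_fragment_matches,
            abs(h.delta_ppm),
            h.rt_diff if h.rt_diff is not None else float("inf"),
            h.index,
        )
    )
    return hits


def annotate_cohort(
    spectra: Iterable[Spectrum],
    db: Sequence[CompoundRecord],
    ppm_window: float = DEFAULT_PPM_WINDOW,
    rt_window: float = DEFAULT_RT_WINDOW,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> pd.DataFrame:
    """One row per query spectrum with its best hit (or none)."""
    rows = []
    for s in spectra:
        hits = annotate_spectrum(s, db, ppm_window, rt_window, frag_tol)
        if hits:
            best = hits[0]
            rows.append(
                {
                    "spectrum_id": s.id,
                    "annotated": True,
                    "index": best.index,
                    "compound": best.name,
                    "class_label": best.class_label,
                    "delta_ppm": best.delta_ppm,
                    "rt_diff": best.rt_diff,
                    "n_fragment_matches": best.n_fragment_matches,
                    "tier": best.tier,
                    "n_candidates": len(hits),
                }
            )
        else:
            rows.append(
                {
                    "spectrum_id": s.id,
                    "annotated": False,
                    "index": pd.NA,
                    "compound": pd.NA,
                    "class_label": pd.NA,
                    "delta_ppm": pd.NA,
                    "rt_diff": pd.NA,
                    "n_fragment_matches": 0,
                    "tier": pd.NA,
                    "n_candidates": 0,
                }
            )
    return pd.DataFrame(rows)


def summarize_annotations(table: pd.DataFrame) -> dict[str, int]:
    """Headline counts: spectra, annotated, reference-confirmed among them."""
    if table.empty:
        return {"n_spectra": 0, "n_annotated": 0, "n_reference_confirmed": 0}
    annotated = table[table["annotated"] == True]  # noqa: E712
    return {
        "n_spectra": int(len(table)),
        "n_annotated": int(len(annotated)),
        "n_reference_confirmed": int(
            (annotated["tier"] == "reference-confirmed").sum()
        ),
    }
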