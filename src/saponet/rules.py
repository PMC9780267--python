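"""Diagnostic-ion and characteristic-neutral-loss classification.

Assigns MS/MS spectra to one of six compound classes of the
ginseng-polygala drug pair — PPD-, PPT- and OLE-type ginsenosides,
polygala saponins, oligosaccharide esters and xanthone glycosides — from
class-diagnostic fragment ions (e.g. m/z 455.3555 for the oleanane
aglycone core, m/z 137.0248 for the p-hydroxybenzoyl anion) and
characteristic neutral losses of glycosyl residues (glucose 162.0528,
rhamnose 146.0579, pentose 132.0423 Da).

Scoring: score(class) = ion_weight * matched diagnostic ions
                      + loss_weight * matched characteristic losses.
A spectrum is classified when at least one diagnostic ion or at least two
characteristic losses match (a single 162.0528 loss is shared by four
classes and cannot discriminate).  Score ties fall to the class with more
matched ions, then to a fixed specificity order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .spectra import CLASS_LABELS, CompoundRecord, Spectrum, db_to_spectra

__all__ = [
    "ClassRule",
    "IonMatch",
    "LossMatch",
    "ClassificationResult",
    "DEFAULT_ION_TOL",
    "DEFAULT_LOSS_TOL",
    "SPECIFICITY_ORDER",
    "load_rules",
    "default_rules",
    "match_diagnostic_ions",
    "match_characteristic_losses",
    "classify",
    "classify_cohort",
    "library_agreement",
]

#: Default match tolerances (Da).  Observed diagnostic ions in reference
#: data deviate from the rule masses by up to ~7 mDa.
DEFAULT_ION_TOL = 0.01
DEFAULT_LOSS_TOL = 0.02

#: Tie-break order after score and matched-ion count: more structure-specific
#: classes first.
SPECIFICITY_ORDER: tuple[str, ...] = (
    "PPT",
    "OLE",
    "PPD",
    "polygala-saponin",
    "oligosaccharide-ester",
    "xanthone",
)


@dataclass(frozen=True)
class ClassRule:
    """Diagnostic ions and characteristic losses defining one class."""

    class_label: str
    diagnostic_ions: tuple[float, ...]
    characteristic_losses: tuple[float, ...]
    required_diag_matches: int = 1
    ion_weight: float = 2.0
    loss_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.diagnostic_ions and not self.characteristic_losses:
            raise ValueError(
                f"rule {self.class_label}: needs at least one diagnostic ion "
                "or characteristic loss"
            )


@dataclass(frozen=True)
class IonMatch:
    ion: float
    peak_mz: float
    dm: float  # peak - ion


@dataclass(frozen=True)
class LossMatch:
    loss: float
    upper_mz: float  # precursor or upper fragment
    lower_mz: float
    dm: float  # observed loss - characteristic loss


@dataclass
class ClassificationResult:
    spectrum_id: str
    scores: dict[str, float]
    best_class: str  # a class label or "unclassified"
    ion_matches: dict[str, list[IonMatch]]
    loss_matches: dict[str, list[LossMatch]]
    tied_with: tuple[str, ...] = ()


def load_rules(path_or_text: str | None = None) -> list[ClassRule]:
    """Load a rule set from the packaged delimited file (or a custom one).

    Columns: class_label, diagnostic_ions (;-separated), characteristic_losses,
    required_diag_matches, ion_weight, loss_weight.
    """
    if path_or_text is None:
        text = (
            resources.files("saponet.data").joinpath("class_rules.tsv").read_text()
        )
    else:
        with open(path_or_text) as handle:
            text = handle.read()
    rules: list[ClassRule] = []
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        rules.append(
            ClassRule(
                class_label=row["class_label"],
                diagnostic_ions=tuple(
                    float(x) for x in row["diagnostic_ions"].split(";") if x
                ),
                characteristic_losses=tuple(
                    float(x) for x in row["characteristic_losses"].split(";") if x
                ),
                required_diag_matches=int(row.get("required_diag_matches", 1)),
                ion_weight=float(row.get("ion_weight", 2.0)),
                loss_weight=float(row.get("loss_weight", 1.0)),
            )
        )
    return rules


def default_rules() -> list[ClassRule]:
    """The packaged six-class rule set."""
    rules = load_rules(None)
    labels = {r.class_label for r in rules}
    if labels != set(CLASS_LABELS):
        raise RuntimeError(f"packaged rule set covers {labels}, expected {CLASS_LABELS}")
    return rules


def match_diagnostic_ions(
    spectrum: Spectrum, rule: ClassRule, tol: float = DEFAULT_ION_TOL
) -> list[IonMatch]:
    """Diagnostic ions of *rule* matched by peaks of *spectrum*.

    Each peak is assigned to its nearest diagnostic ion (at most one ion per
    peak); an ion is matched when some assigned peak lies within *tol*.
    Returns one match per matched ion (the closest peak).
    """
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    best: dict[float, IonMatch] = {}
    for peak in spectrum.peaks:
        if not rule.diagnostic_ions:
            break
        ion = min(rule.diagnostic_ions, key=lambda d: abs(peak.mz - d))
        dm = peak.mz - ion
        if abs(dm) <= tol:
            prev = best.get(ion)
            if prev is None or abs(dm) < abs(prev.dm):
                best[ion] = IonMatch(ion=ion, peak_mz=peak.mz, dm=dm)
    return [best[ion] for ion in rule.diagnostic_ions if ion in best]


def match_characteristic_losses(
    spectrum: Spectrum, rule: ClassRule, tol: float = DEFAULT_LOSS_TOL
) -> list[LossMatch]:
    """Characteristic losses of *rule* found in *spectrum*.

    Candidate losses are precursor-to-fragment differences plus all
    fragment-to-fragment ladder differences; each candidate matches its
    nearest characteristic loss when within *tol*.
    """
    if not rule.characteristic_losses:
        return []
    mzs = spectrum.mzs
    candidates: list[tuple[float, float, float]] = []  # (upper, lower, diff)
    for mz in mzs:
        diff = spectrum.precursor_mz - mz
        if diff > tol:  # skip the quasi-molecular peak itself
            candidates.append((spectrum.precursor_mz, mz, diff))
    for i in range(len(mzs)):
        for j in range(i + 1, len(mzs)):
            candidates.append((mzs[j], mzs[i], mzs[j] - mzs[i]))
    matches: list[LossMatch] = []
    for upper, lower, diff in candidates:
        loss = min(rule.characteristic_losses, key=lambda c: abs(diff - c))
        dm = diff - loss
        if abs(dm) <= tol:
            matches.append(LossMatch(loss=loss, upper_mz=upper, lower_mz=lower, dm=dm))
    return matches


def _rank_key(label: str) -> int:
    return SPECIFICITY_ORDER.index(label)


def classify(
    spectrum: Spectrum,
    rules: Sequence[ClassRule] | None = None,
    tol_ion: float = DEFAULT_ION_TOL,
    tol_loss: float = DEFAULT_LOSS_TOL,
) -> ClassificationResult:
    """Assign *spectrum* to a compound class (or ``"unclassified"``).

    Deterministic; a zero-peak spectrum is unclassified.  Residual score
    ties after the more-ions tie-break are reported in ``tied_with``.
    """
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("empty rule set")
    scores: dict[str, float] = {}
    ion_matches: dict[str, list[IonMatch]] = {}
    loss_matches: dict[str, list[LossMatch]] = {}
    eligible: list[str] = []
    for rule in rules:
        ions = match_diagnostic_ions(spectrum, rule, tol_ion)
        losses = match_characteristic_losses(spectrum, rule, tol_loss)
        ion_matches[rule.class_label] = ions
        loss_matches[rule.class_label] = losses
        scores[rule.class_label] = (
            rule.ion_weight * len(ions) + rule.loss_weight * len(losses)
        )
        if len(ions) >= rule.required_diag_matches or len(losses) >= 2:
            eligible.append(rule.class_label)
    if not eligible or not spectrum.peaks:
        return ClassificationResult(
            spectrum_id=spectrum.id,
            scores=scores,
            best_class="unclassified",
            ion_matches=ion_matches,
            loss_matches=loss_matches,
        )
    ordered = sorted(
        eligible,
        key=lambda c: (-scores[c], -len(ion_matches[c]), _rank_key(c)),
    )
    best = ordered[0]
    tied = tuple(
        c
        for c in ordered[1:]
        if scores[c] == scores[best]
        and len(ion_matches[c]) == len(ion_matches[best])
    )
    return ClassificationResult(
        spectrum_id=spectrum.id,
        scores=scores,
        best_class=best,
        ion_matches=ion_matches,
        loss_matches=loss_matches,
        tied_with=tied,
    )


def classify_cohort(
    spectra: Iterable[Spectrum],
    rules: Sequence[ClassRule] | None = None,
    tol_ion: float = DEFAULT_ION_TOL,
    tol_loss: float = DEFAULT_LOSS_TOL,
) -> pd.DataFrame:
    """Per-spectrum classification table."""
    if rules is None:
        rules = default_rules()
    rows = []
    for s in spectra:
        res = classify(s, rules, tol_ion, tol_loss)
        best = res.best_class
        rows.append(
            {
                "spectrum_id": s.id,
                "best_class": best,
                "score": res.scores.get(best, 0.0),
                "n_diagnostic_ions": len(res.ion_matches.get(best, [])),
                "n_characteristic_losses": len(res.loss_matches.get(best, [])),
                "tied_with": ";".join(res.tied_with),
            }
        )
    return pd.DataFrame(rows)


def library_agreement(
    db: Sequence[CompoundRecord],
    rules: Sequence[ClassRule] | None = None,
    tol_ion: float = DEFAULT_ION_TOL,
    tol_loss: float = DEFAULT_LOSS_TOL,
) -> pd.DataFrame:
    """Compare rule-based classification with the library class labels.

    One row per record with recorded fragments: the library label, the
    predicted class, whether the library class's own diagnostic ions are
    evident in the fragment list, and agreement.  Disagreements are a
    report, not an error — several library rows record fragment lists in
    which their class's diagnostic ions do not appear.
    """
    if rules is None:
        rules = default_rules()
    by_label = {r.class_label: r for r in rules}
    rows = []
    for rec, spec in zip(db, db_to_spectra(db)):
        if not spec.peaks:
            continue
        res = classify(spec, rules, tol_ion, tol_loss)
        own_rule = by_label[rec.class_label]
        ion_evident = bool(match_diagnostic_ions(spec, own_rule, tol_ion))
        rows.append(
            {
                "index": rec.index,
                "name": rec.name,
                "library_class": rec.class_label,
                "predicted_class": res.best_class,
                "agree": res.best_class == rec.class_label,
                "class_ions_evident": ion_evident,
            }
        )
    return pd.DataFrame(rows)
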