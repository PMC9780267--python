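"""In-silico negative-mode CID of glycoconjugates.

Generates the fragment ladders that collision-induced dissociation of
saponins, oligosaccharide esters and xanthone glycosides produces in
negative ESI: the quasi-molecular ion followed by sequential losses of
glycosyl/acyl residues down to the aglycone, optionally perturbed by m/z
jitter and uniform noise peaks.  Cohorts simulated here carry ground-truth
class labels and drive the end-to-end tests of the classifier and the
molecular network.

Model notes
-----------
* Losses are prefix-closed along the substituent order (sequential
  cascades: terminal residues cleave first); a ``powerset`` flag switches
  to all detachable subsets for users who prefer over-generation.
* "COOH" and "CH2OH" substituents are modelled as the net even-electron
  neutral losses CO2 (43.9898 Da) and CH2O (30.0106 Da); this reproduces
  observed saponin ladders such as 517.32 -> 455.32 -> 425.31.
* Aromatic acyl residues (p-hydroxybenzoyl, trimethoxycinnamoyl-type)
  additionally emit their deprotonated acyl anion (e.g. C7H5O3- at
  m/z 137.0244), the high-response signature of oligosaccharide esters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    ELECTRON_MASS,
    MolecularFormula,
    PROTON_MASS,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
)
from .spectra import CLASS_LABELS, Peak, Spectrum

__all__ = [
    "RESIDUES",
    "ACYL_RESIDUES",
    "StructureTemplate",
    "SimConfig",
    "enumerate_fragments",
    "simulate_spectrum",
    "CLASS_TEMPLATES",
    "make_class_template",
    "simulate_cohort",
]

#: Neutral residues available as template substituents (name -> formula).
RESIDUES: dict[str, MolecularFormula] = {
    "glucose-residue": parse_formula("C6H10O5"),
    "rhamnose-residue": parse_formula("C6H10O4"),
    "pentose-residue": parse_formula("C5H8O4"),
    "pentose": parse_formula("C5H10O5"),
    "p-hydroxybenzoyl": parse_formula("C7H6O3"),
    "trimethoxycinnamoyl": parse_formula("C12H16O5"),
    "H2O": parse_formula("H2O"),
    "COOH": parse_formula("CO2"),   # net decarboxylation
    "CH2OH": parse_formula("CH2O"),  # net formaldehyde loss
}

#: Residues whose deprotonated anion is emitted alongside the neutral loss.
ACYL_RESIDUES: frozenset[str] = frozenset(
    {"p-hydroxybenzoyl", "trimethoxycinnamoyl"}
)


@dataclass(frozen=True)
class StructureTemplate:
    """A class-level glycoconjugate: aglycone plus an ordered substituent
    stack.  Substituents are (residue name, detachable) pairs; detachable
    residues are cleaved sequentially in list order during CID."""

    aglycone_formula: MolecularFormula
    aglycone_class: str
    substituents: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.aglycone_class not in CLASS_LABELS:
            raise ValueError(f"unknown compound class {self.aglycone_class!r}")
        for name, _ in self.substituents:
            if name not in RESIDUES:
                raise KeyError(
                    f"unknown residue {name!r}; supported: {sorted(RESIDUES)}"
                )

    @property
    def total_formula(self) -> MolecularFormula:
        total = self.aglycone_formula
        for name, _ in self.substituents:
            total = total + RESIDUES[name]
        return total


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; ``seed`` fixes all randomness."""

    adduct: str = "[M-H]-"
    mz_jitter_sd: float = 0.0
    n_noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (100.0, 2000.0)
    seed: int = 0
    max_cascade_depth: int = 12
    powerset: bool = False

    def __post_init__(self) -> None:
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


def _anion_mz(formula: MolecularFormula) -> float:
    return monoisotopic_mass(formula) - PROTON_MASS


def enumerate_fragments(
    template: StructureTemplate,
    adduct: str = "[M-H]-",
    max_cascade_depth: int = 12,
    powerset: bool = False,
) -> list[tuple[MolecularFormula, float, str]]:
    """Predict the CID product ions of *template*.

    Returns (neutral formula, m/z, provenance) triples sorted by descending
    m/z, deduplicated at 1e-6 Da.  The quasi-molecular ion is always
    emitted; every further ion arises from a prefix-closed subset of the
    detachable substituents (sequential losses), or from every detachable
    subset when ``powerset`` is set.  Aromatic acyl residues also emit
    their deprotonated anion.
    """
    detachable = [name for name, d in template.substituents if d]
    total = template.total_formula
    quasi = adduct_mz(total, adduct)

    ions: dict[float, tuple[MolecularFormula, float, str]] = {}

    def emit(formula: MolecularFormula, mz: float, provenance: str) -> None:
        key = round(mz, 6)
        if key not in ions:
            ions[key] = (formula, mz, provenance)

    emit(total, quasi, "quasi-molecular ion")

    if powerset:
        subsets: list[tuple[str, ...]] = [()]
        for name in detachable:
            subsets += [s + (name,) for s in subsets]
        cascades: Iterable[tuple[str, ...]] = (s for s in subsets if s)
    else:
        cascades = (tuple(detachable[:k]) for k in range(1, len(detachable) + 1))

    truncated = False
    for losses in cascades:
        if len(losses) > max_cascade_depth:
            truncated = True
            continue
        remaining = total
        mz = quasi
        for name in losses:
            remaining = remaining - RESIDUES[name]
            mz -= monoisotopic_mass(RESIDUES[name])
        emit(remaining, mz, "loss of " + " + ".join(losses))
    if truncated:
        warnings.warn(
            f"cascade depth exceeds max_cascade_depth={max_cascade_depth}; "
            "deeper losses truncated",
            stacklevel=2,
        )

    for name, _ in template.substituents:
        if name in ACYL_RESIDUES:
            residue = RESIDUES[name]
            emit(
                residue - parse_formula("H"),
                _anion_mz(residue),
                f"deprotonated {name} anion",
            )

    return sorted(ions.values(), key=lambda t: -t[1])


def simulate_spectrum(
    template: StructureTemplate,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
) -> Spectrum:
    """One simulated MS/MS spectrum: theoretical ions +- Gaussian jitter
    plus uniform noise peaks; deterministic under a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fragments = enumerate_fragments(
        template,
        adduct=cfg.adduct,
        max_cascade_depth=cfg.max_cascade_depth,
        powerset=cfg.powerset,
    )
    precursor = fragments[0][1]
    peaks = []
    for _, mz, _ in fragments:
        jitter = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd else 0.0
        peaks.append(Peak(mz + jitter, 1.0))
    lo, hi = cfg.noise_mz_range
    for _ in range(cfg.n_noise_peaks):
        peaks.append(Peak(float(rng.uniform(lo, hi)), 1.0))
    return Spectrum(
        id=spectrum_id or f"{template.aglycone_class}-sim",
        precursor_mz=precursor,
        rt=None,
        peaks=peaks,
        metadata={
            "class": template.aglycone_class,
            "aglycone": str(template.aglycone_formula),
            "n_substituents": len(template.substituents),
            "n_true_peaks": len(fragments),
        },
    )


@dataclass(frozen=True)
class _ClassTemplateSpec:
    aglycone: str
    tail: tuple[tuple[str, bool], ...]
    k_range: tuple[int, int]  # inclusive range of variable glucose residues


#: Class-plausible aglycones and loss cascades.  One representative aglycone
#: per class; the variable glucosyl count k sweeps ``k_range`` to produce a
#: homologous series.  These are class abstractions, not structure
#: elucidations.
CLASS_TEMPLATES: dict[str, _ClassTemplateSpec] = {
    # dammarane diol aglycone; ladder ...945.54/783.49/621.44/459.38
    "PPD": _ClassTemplateSpec("C30H52O3", (), (2, 6)),
    # dammarane triol aglycone; ladder ...799.48/637.43/475.37
    "PPT": _ClassTemplateSpec("C30H52O4", (), (2, 6)),
    # oleanolic-acid aglycone; aglycone ion 455.35
    "OLE": _ClassTemplateSpec("C30H48O3", (), (2, 6)),
    # fully stripped presenegenin-like core: core + CH2O + CO2 + H2O + glc
    # re-assembles C36H56O12; the cascade reproduces the observed ladder
    # 679.37 -> 517.32 -> 499.31 -> 455.32 -> 425.31
    "polygala-saponin": _ClassTemplateSpec(
        "C28H42O3",
        (
            ("glucose-residue", True),
            ("H2O", True),
            ("COOH", True),
            ("CH2OH", True),
        ),
        (0, 4),
    ),
    # sucrose core bearing trimethoxycinnamoyl + p-hydroxybenzoyl groups
    "oligosaccharide-ester": _ClassTemplateSpec(
        "C12H22O11",
        (
            ("trimethoxycinnamoyl", True),
            ("p-hydroxybenzoyl", True),
        ),
        (0, 4),
    ),
    # dehydrated xanthone core; the cascade ends 315.05 -> 297.04
    "xanthone": _ClassTemplateSpec(
        "C16H10O6",
        (
            ("glucose-residue", True),
            ("pentose-residue", True),
            ("H2O", True),
        ),
        (0, 4),
    ),
}


def make_class_template(class_label: str, n_glucose: int) -> StructureTemplate:
    """Template for *class_label* carrying *n_glucose* variable glucosyl
    residues on top of the fixed class cascade."""
    try:
        spec = CLASS_TEMPLATES[class_label]
    except KeyError:
        raise KeyError(
            f"unknown compound class {class_label!r}; "
            f"supported: {sorted(CLASS_TEMPLATES)}"
        ) from None
    subs = tuple(("glucose-residue", True) for _ in range(n_glucose)) + spec.tail
    return StructureTemplate(
        aglycone_formula=parse_formula(spec.aglycone),
        aglycone_class=class_label,
        substituents=subs,
    )


def simulate_cohort(
    classes: Sequence[str],
    n_per_class: int,
    cfg: SimConfig,
) -> list[Spectrum]:
    """Simulate *n_per_class* labelled spectra per class.

    Variable glucosyl counts sweep the class range cyclically so each class
    forms a connected homologous series; jitter and noise are drawn from a
    single generator seeded by ``cfg.seed`` (byte-identical under a fixed
    configuration).
    """
    rng = np.random.default_rng(cfg.seed)
    cohort: list[Spectrum] = []
    for cls in classes:
        if cls not in CLASS_TEMPLATES:
            raise KeyError(
                f"unknown compound class {cls!r}; supported: "
                f"{sorted(CLASS_TEMPLATES)}"
            )
        k_min, k_max = CLASS_TEMPLATES[cls].k_range
        span = k_max - k_min + 1
        for i in range(n_per_class):
            template = make_class_template(cls, k_min + (i % span))
            cohort.append(
                simulate_spectrum(
                    template, cfg, rng=rng, spectrum_id=f"{cls}-{i}"
                )
            )
    return cohort
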