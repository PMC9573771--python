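"""Ionization-efficiency-corrected (MRI) semi-quantification and the
impurity mass-balance calculator.

Electrospray response differs by orders of magnitude across metabolite
classes, so raw peak areas are not comparable between, say, a sulfate and a
glucuronide. The molecular response-independent (MRI) intensity divides the
internal-standard-normalized intensity by a per-class relative ionization
efficiency (IE), and class profiles are expressed as MRI percentages of the
total. IE values are consumed from a user-supplied table; with no table,
all IE default to 1 and the output is a *normalized* profile, not an MRI
profile (a warning says so).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ImpurityBudget",
    "IntensityRecord",
    "MetaboliteProfile",
    "class_profile",
    "cosine_similarity",
    "impurity_amount",
    "mri_intensity",
    "normalized_intensity",
]

#: Scale factor applied to IS-normalized intensities.
IS_SCALE = 1000.0


def normalized_intensity(raw: float, is_raw: float) -> float:
    """Internal-standard normalization: raw / IS_raw * 1000."""
    if is_raw <= 0:
        raise ValueError("internal-standard intensity must be positive")
    if raw < 0:
        raise ValueError("raw intensity must be >= 0")
    return raw / is_raw * IS_SCALE


def mri_intensity(normalized: float, ie: float) -> float:
    """Ionization-efficiency correction: normalized / IE."""
    if ie <= 0:
        raise ValueError("ionization efficiency must be positive")
    return normalized / ie


@dataclass(frozen=True)
class IntensityRecord:
    """One quantified isomer: raw intensity, internal-standard intensity in
    the same run, and the class's relative ionization efficiency."""

    class_id: str
    raw_intensity: float
    is_raw_intensity: float
    ionization_efficiency: float = 1.0

    def __post_init__(self):
        if self.raw_intensity < 0:
            raise ValueError("raw intensity must be >= 0")
        if self.is_raw_intensity <= 0:
            raise ValueError("IS intensity must be positive")
        if self.ionization_efficiency <= 0:
            raise ValueError("ionization efficiency must be positive")


@dataclass(frozen=True)
class MetaboliteProfile:
    """Per-class MRI percentages under one exposure condition."""

    entries: dict[str, float] = field(default_factory=dict)
    condition: str = ""

    def total(self) -> float:
        return sum(self.entries.values())


def class_profile(
    records: list[IntensityRecord], condition: str = ""
) -> MetaboliteProfile:
    """Aggregate isomer records into a per-class MRI percentage profile.

    Per class: isomer normalized intensities are summed, the class IE is
    the mean of the isomer IEs, and the class MRI intensity is the summed
    normalized intensity divided by that mean IE. Percentages are of the
    grand MRI total.
    """
    if not records:
        raise ValueError("no intensity records")
    norm_by_class: dict[str, float] = {}
    ies_by_class: dict[str, list[float]] = {}
    for r in records:
        norm_by_class[r.class_id] = norm_by_class.get(r.class_id, 0.0) + (
            normalized_intensity(r.raw_intensity, r.is_raw_intensity)
        )
        ies_by_class.setdefault(r.class_id, []).append(r.ionization_efficiency)
    mri_by_class = {
        cid: mri_intensity(norm, sum(ies_by_class[cid]) / len(ies_by_class[cid]))
        for cid, norm in norm_by_class.items()
    }
    total = sum(mri_by_class.values())
    if total <= 0:
        warnings.warn("all intensities are zero: empty profile", stacklevel=2)
        return MetaboliteProfile({}, condition)
    return MetaboliteProfile(
        {cid: 100.0 * v / total for cid, v in mri_by_class.items()}, condition
    )


def cosine_similarity(p: MetaboliteProfile, q: MetaboliteProfile) -> float:
    """cos(theta) between two profiles over the union of their classes.

    Missing classes contribute 0; a zero-norm profile yields 0.0.
    """
    keys = sorted(set(p.entries) | set(q.entries))
    if not keys:
        raise ValueError("both profiles are empty")
    pv = [p.entries.get(k, 0.0) for k in keys]
    qv = [q.entries.get(k, 0.0) for k in keys]
    np_ = math.sqrt(sum(x * x for x in pv))
    nq = math.sqrt(sum(x * x for x in qv))
    if np_ == 0.0 or nq == 0.0:
        return 0.0
    return sum(x * y for x, y in zip(pv, qv)) / (np_ * nq)


@dataclass(frozen=True)
class ImpurityBudget:
    """Inputs of the impurity mass balance: how much of a trace impurity in
    the dosing material entered the experiment.

    ``impurity_mass_fraction`` is in ng impurity per mg parent compound
    (i.e. parts in 1e6 by mass); molecular weights are g/mol.
    """

    concentration: float  # mol/L of the parent in the exposure medium
    volume: float         # L of medium
    impurity_mass_fraction: float  # ng impurity / mg parent
    mw_parent: float
    mw_impurity: float

    def __post_init__(self):
        for name in ("concentration", "volume", "mw_parent", "mw_impurity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.impurity_mass_fraction < 0:
            raise ValueError("impurity_mass_fraction must be >= 0")


def impurity_amount(b: ImpurityBudget) -> float:
    """Moles of impurity dosed alongside the parent compound.

    moles_parent * MW_parent gives grams of parent; the ng/mg fraction
    (x 1e-6) gives grams of impurity; dividing by the impurity MW returns
    moles. Used to bound how much metabolite the impurity could possibly
    yield under complete biotransformation.
    """
    moles_parent = b.concentration * b.volume
    grams_parent = moles_parent * b.mw_parent
    grams_impurity = grams_parent * b.impurity_mass_fraction * 1e-6
    return grams_impurity / b.mw_impurity


def max_metabolite_mass(b: ImpurityBudget, mw_metabolite: float) -> float:
    """Grams of a single metabolite if the impurity converts completely."""
    if mw_metabolite <= 0:
        raise ValueError("mw_metabolite must be positive")
    return impurity_amount(b) * mw_metabolite
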