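"""Ground-truthed synthetic feature tables and MS/MS spectra.

Two generators live here. :func:`generate_dataset` plants user-specified
metabolites with ppm-scale Gaussian mass error, retention-time jitter,
multiplicative intensity noise, chlorine isotope clusters, diagnostic MS/MS
spectra, and decoy features, all reproducible from a seed.
:func:`study_table_fixture` reconstructs the observed screening table of the
HepG2 study — 20 metabolites in 13 classes across a high (10 uM) and a low
(3.6 nM) exposure group — by shifting each calculated anion m/z by the
reported ppm error, so the full pipeline is exercised without instrument
data.

What this emulates — and what it does not: features are ideal centroids
with independent Gaussian mass errors; real data add coelution,
in-source fragmentation, detector saturation, and correlated drift, none of
which are simulated. Decoys are kept at least 25 ppm away from any planted
(or excluded) mass so that recall and false-match rates are identifiable;
real matrices offer no such separation guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biotransform import CandidateMetabolite, generate_candidates
from .chem import ElementalFormula, chlorine_isotope_pattern, parse_formula
from .screening import Feature, Ms2Spectrum

__all__ = [
    "GroundTruthEntry",
    "NoiseModel",
    "SyntheticDataset",
    "catalog_candidates",
    "default_truth",
    "generate_dataset",
    "study_table_fixture",
    "study_table_rows",
]

PCB2 = "C12H9Cl"

#: Transcription of the observed HepG2 screening table: one row per
#: detected metabolite (class, rt/min, anion formula, mean intensity and
#: ppm error per exposure group — None = not detected — and the reported
#: MS/MS fragment m/z values, printed to 2 decimals).
_STUDY_TABLE = [
    ("1.1", 5.43, "C12H8ClO",  50.0,  2.0,   2.9, 3.5,  (174.99, 167.05), 2),
    ("1.2", 4.22, "C12H8ClSO4", 80.0, 16.2,  1.9, 2.0,  (203.03,), 2),
    ("1.3", 3.68, "C18H16ClO7", 3.2,  0.05,  1.6, 1.1,  (203.03,), 2),
    ("1.3", 3.78, "C18H16ClO7", 0.44, None,  1.9, None, (203.03,), 2),
    ("2.1", 3.56, "C12H8ClSO5", 1.8,  0.31,  2.0, 2.1,  (), 3),
    ("2.1", 4.24, "C12H8ClSO5", 0.66, 0.30,  2.0, 2.0,  (), 3),
    ("3.1", 5.72, "C13H10ClO2", 4.5,  0.30,  2.5, 2.1,  (218.01,), 2),
    ("3.2", 4.09, "C13H10ClSO5", 1.07, 0.16, 2.6, 2.6,  (233.04, 218.01), 2),
    ("3.2", 4.19, "C13H10ClSO5", 1.8,  0.38, 2.5, 2.6,  (233.04, 218.01, 196.09), 2),
    ("3.2", 4.30, "C13H10ClSO5", 6.6,  1.29, 2.4, 2.6,  (233.04, 218.01), 2),
    ("3.3", 3.65, "C19H18ClO8", 0.12, None,  1.7, None, (233.04, 218.01), 2),
    ("3.3", 3.76, "C19H18ClO8", 0.45, None,  1.7, None, (233.04, 218.01), 2),
    ("3.4", 3.76, "C13H10ClSO6", 0.18, 0.054, 2.2, 2.2, (249.03, 234.01), 2),
    ("3.4", 3.88, "C13H10ClSO6", 0.07, 0.015, 2.2, 2.2, (249.03, 234.01), 2),
    ("4.1", 3.97, "C12H9SO5",   6.1,  6.1,   2.2, 2.3,  (185.06,), 2),
    ("4.2", 3.95, "C13H11SO5",  41.0, 6.6,   1.9, 2.1,  (199.08, 184.05, 79.96), 2),
    ("4.2", 4.00, "C13H11SO5",  106.0, 19.0, 1.9, 2.0,  (199.08, 184.05, 79.96), 2),
    ("4.3", 3.51, "C19H19O8",   2.7,  None,  2.3, None, (199.08, 184.05), 2),
    ("4.4", 3.65, "C13H11SO6",  25.0, 2.0,   1.7, 1.9,  (215.07, 200.05, 79.96), 2),
    ("4.5", 3.75, "C15H14NSO3", 26.0, None,  3.7, None, (201.04, 127.09), 2),
]

M2_SPACING = 1.99704992  # Da, 37Cl - 35Cl


def study_table_rows() -> pd.DataFrame:
    """The transcribed screening table as a DataFrame (for tests/docs)."""
    return pd.DataFrame(
        _STUDY_TABLE,
        columns=["class_id", "rt", "anion_formula", "intensity_high",
                 "intensity_low", "ppm_high", "ppm_low", "ms2",
                 "confidence"],
    )


def catalog_candidates(
    parent: ElementalFormula | str = PCB2,
) -> list[CandidateMetabolite]:
    """Candidates of the named classes only (intermediates dropped)."""
    if isinstance(parent, str):
        parent = parse_formula(parent)
    return [
        c for c in generate_candidates(parent)
        if c.class_id not in ("parent", "intermediate")
    ]


def _cluster_for(anion: ElementalFormula, mz: float, intensity: float,
                 noise: float = 0.0, rng: np.random.Generator | None = None):
    """M / M+2 isotopologue cluster for a composition's chlorine count."""
    pattern = chlorine_isotope_pattern(anion)
    cluster = [(mz, intensity)]
    if anion["Cl"] >= 1:
        ratio = pattern.m2_over_m
        wobble = 1.0 + noise * rng.standard_normal() if rng is not None else 1.0
        cluster.append((mz + M2_SPACING, intensity * ratio * max(wobble, 0.05)))
    return tuple(cluster)


def _diagnostic_losses(c: CandidateMetabolite) -> list[str]:
    """Loss-library names expected for a candidate's conjugation state."""
    s = c.state
    losses: list[str] = []
    if s.n_sulfate:
        losses.append("-SO3")
        if s.n_methoxy:
            losses.append("-CH3-SO3")
        losses.append("SO3-")
    elif s.n_glucuronide:
        losses.append("-C6H8O6")
        if s.n_methoxy:
            losses.append("-CH3-C6H8O6")
    elif s.n_methoxy:
        losses.append("-CH3")
    if s.n_cysteine:
        losses.append("-C3H5NO2")
    if not losses and s.n_free_OH and s.n_Cl:
        losses.append("-HCl")
    return losses


def _loss_mass(name: str) -> float:
    from .screening import default_loss_library

    for entry in default_loss_library():
        if entry.name == name:
            return entry.mass
    raise KeyError(name)


@dataclass(frozen=True)
class GroundTruthEntry:
    """A planted metabolite: candidate, elution time, abundance, groups."""

    candidate: CandidateMetabolite
    rt: float
    abundance: float
    groups_present: tuple[str, ...] = ("high", "low")

    def __post_init__(self):
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Noise and nuisance settings; the seed fixes the full random stream.

    The 2 ppm mass-error sigma matches the observed accurate-mass errors
    of the study (1.1-3.7 ppm)."""

    mass_error_sigma_ppm: float = 2.0
    rt_jitter_sd: float = 0.02
    intensity_cv: float = 0.2
    isotope_noise: float = 0.05
    decoy_count: int = 0
    decoy_mass_range: tuple[float, float] = (150.0, 450.0)
    decoy_exclusion_ppm: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if min(self.mass_error_sigma_ppm, self.rt_jitter_sd,
               self.intensity_cv) < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class SyntheticDataset:
    features: list[Feature]
    spectra: list[Ms2Spectrum]
    truth: pd.DataFrame = field(repr=False)


def generate_dataset(
    truth: list[GroundTruthEntry],
    noise: NoiseModel,
    exclude_mz: list[float] | None = None,
) -> SyntheticDataset:
    """Simulate a feature table, MS/MS spectra, and a truth table.

    Each entry yields, per group it is present in, one feature at the anion
    m/z perturbed by Normal(0, sigma_ppm) ppm, with jittered retention
    time, log-normal-ish intensity scatter, and a chlorine isotope cluster.
    Conjugated candidates also yield one MS/MS spectrum carrying their
    diagnostic fragments (rounded to 2 decimals, as screening tables print
    them) plus random noise fragments. Decoy features are drawn uniformly
    from ``decoy_mass_range`` excluding +-25 ppm around every planted (or
    explicitly excluded) mass.
    """
    rng = np.random.default_rng(noise.seed)
    avoid = sorted(set([e.candidate.mz for e in truth] + list(exclude_mz or [])))
    features: list[Feature] = []
    spectra: list[Ms2Spectrum] = []
    truth_rows = []
    for e in truth:
        anion = e.candidate.anion
        for group in e.groups_present:
            eps = noise.mass_error_sigma_ppm * rng.standard_normal()
            mz = e.candidate.mz * (1.0 + eps * 1e-6)
            rt = e.rt + noise.rt_jitter_sd * rng.standard_normal()
            intensity = e.abundance * float(
                np.exp(noise.intensity_cv * rng.standard_normal())
            )
            features.append(
                Feature(
                    mz=mz, rt=rt, intensity=intensity,
                    sample_id=f"{group}_1", group=group,
                    isotope_cluster=_cluster_for(
                        anion, mz, intensity, noise.isotope_noise, rng
                    ),
                )
            )
            losses = _diagnostic_losses(e.candidate)
            if losses:
                frags = []
                for name in losses:
                    calc = (
                        _loss_mass(name) if name.endswith("-") and not
                        name.startswith("-") else e.candidate.mz - _loss_mass(name)
                    )
                    frags.append((round(calc, 2), 100.0))
                n_noise = int(rng.integers(2, 6))
                for _ in range(n_noise):
                    fmz = float(rng.uniform(50.0, max(60.0, mz - 5.0)))
                    frags.append((fmz, float(rng.uniform(10.0, 100.0))))
                frags.sort()
                spectra.append(
                    Ms2Spectrum(precursor_mz=mz, fragments=tuple(frags), rt=rt)
                )
            truth_rows.append(
                {
                    "class_id": e.candidate.class_id,
                    "anion_formula": e.candidate.anion.hill(),
                    "group": group,
                    "true_mz": e.candidate.mz,
                    "observed_mz": mz,
                    "rt": e.rt,
                }
            )
    # decoys
    lo, hi = noise.decoy_mass_range
    groups = sorted({g for e in truth for g in e.groups_present}) or ["high"]
    for i in range(noise.decoy_count):
        mz = _draw_decoy(rng, lo, hi, avoid, noise.decoy_exclusion_ppm)
        for group in groups:
            features.append(
                Feature(
                    mz=mz,
                    rt=float(rng.uniform(0.5, 8.0)),
                    intensity=float(rng.uniform(1.0, 100.0)),
                    sample_id=f"{group}_1",
                    group=group,
                    isotope_cluster=None,
                )
            )
            truth_rows.append(
                {
                    "class_id": "decoy",
                    "anion_formula": "",
                    "group": group,
                    "true_mz": mz,
                    "observed_mz": mz,
                    "rt": np.nan,
                }
            )
    return SyntheticDataset(
        features=features, spectra=spectra, truth=pd.DataFrame(truth_rows)
    )


def _draw_decoy(rng, lo, hi, avoid, exclusion_ppm, max_tries=10000):
    half = exclusion_ppm * 1e-6
    excluded = sum(2 * m * half for m in avoid if lo <= m <= hi)
    if excluded >= (hi - lo):
        raise ValueError("decoy mass range is fully excluded by truth masses")
    for _ in range(max_tries):
        mz = float(rng.uniform(lo, hi))
        if all(abs(mz - m) / m > half for m in avoid):
            return mz
    raise ValueError("could not place decoy outside exclusion zones")


def default_truth(
    parent: str = PCB2, groups: tuple[str, ...] = ("high", "low")
) -> list[GroundTruthEntry]:
    """One planted metabolite per named class, at study-like abundances.

    Retention times and abundances are taken from the observed screening
    table (first isomer per class, high-exposure intensities)."""
    by_class: dict[str, CandidateMetabolite] = {
        c.class_id: c for c in catalog_candidates(parent)
    }
    entries = []
    seen = set()
    for class_id, rt, _, high, _, _, _, _, _ in _STUDY_TABLE:
        if class_id in seen:
            continue
        seen.add(class_id)
        entries.append(
            GroundTruthEntry(
                candidate=by_class[class_id], rt=rt, abundance=high,
                groups_present=groups,
            )
        )
    return entries


def study_table_fixture() -> tuple[list[Feature], list[Ms2Spectrum]]:
    """Deterministic reconstruction of the observed screening table.

    Per detected (row, group): one feature whose m/z is the calculated
    anion m/z shifted up by the reported ppm error, with the 1-Cl (or
    Cl-free) isotope cluster, plus one MS/MS spectrum per row and group
    built from the printed fragment list. Not-detected cells are omitted.
    """
    features: list[Feature] = []
    spectra: list[Ms2Spectrum] = []
    by_class = {c.class_id: c for c in catalog_candidates(PCB2)}
    for class_id, rt, anion_s, i_high, i_low, ppm_high, ppm_low, ms2, _ in _STUDY_TABLE:
        cand = by_class[class_id]
        assert cand.anion.hill() == parse_formula(anion_s).hill()
        calc = cand.mz
        for group, intensity, ppm in (
            ("high", i_high, ppm_high), ("low", i_low, ppm_low)
        ):
            if intensity is None:
                continue
            mz = calc * (1.0 + ppm * 1e-6)
            features.append(
                Feature(
                    mz=mz, rt=rt, intensity=float(intensity),
                    sample_id=f"{group}_1", group=group,
                    isotope_cluster=_cluster_for(cand.anion, mz, float(intensity)),
                )
            )
            if ms2:
                spectra.append(
                    Ms2Spectrum(
                        precursor_mz=mz,
                        fragments=tuple((f, 100.0) for f in ms2),
                        rt=rt,
                    )
                )
    return features, spectra
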