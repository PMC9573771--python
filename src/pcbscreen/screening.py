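"""Suspect screening: accurate-mass matching, chlorine-isotope verification,
diagnostic neutral-loss MS/MS annotation, and confidence assignment.

Identification confidence follows the tiered scheme standard in
environmental screening: level 1 requires an authentic standard (declared
explicitly in the configuration, never inferred), level 2 requires accurate
mass, isotope pattern, and at least one annotated MS/MS fragment, level 3
rests on accurate mass and isotope pattern alone. A candidate whose observed
isotope cluster contradicts its chlorine count is rejected outright.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .biotransform import CandidateMetabolite, class_name
from .chem import (
    ElementalFormula,
    chlorine_isotope_pattern,
    delta_mass,
    ppm_difference,
)

__all__ = [
    "Annotation",
    "Feature",
    "FragmentMatch",
    "LossEntry",
    "Ms2Spectrum",
    "NeutralLossLibrary",
    "ScreenConfig",
    "ScreeningReport",
    "annotate_ms2",
    "assign_confidence",
    "default_loss_library",
    "match_features",
    "score_isotope_pattern",
    "screen",
]


@dataclass(frozen=True)
class Feature:
    """One centroided MS1 feature: m/z, retention time, intensity, and an
    optional isotopologue cluster [(mz, intensity) for M, M+2, M+4]."""

    mz: float
    rt: float
    intensity: float
    sample_id: str = ""
    group: str = ""
    isotope_cluster: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("feature intensity must be >= 0")
        if self.isotope_cluster is not None:
            mzs = [m for m, _ in self.isotope_cluster]
            if mzs != sorted(mzs):
                raise ValueError("isotope cluster m/z must be ascending")


@dataclass(frozen=True)
class Ms2Spectrum:
    """A product-ion spectrum: precursor m/z, fragment (mz, intensity) list."""

    precursor_mz: float
    fragments: tuple[tuple[float, float], ...]
    rt: float | None = None

    def __post_init__(self):
        for mz, inten in self.fragments:
            if mz >= self.precursor_mz + 0.5:
                raise ValueError(
                    f"fragment {mz} above precursor {self.precursor_mz}"
                )
            if inten < 0:
                raise ValueError("fragment intensity must be >= 0")


@dataclass(frozen=True)
class LossEntry:
    """A neutral loss (matched as precursor - mass) or a diagnostic anion
    (matched at its own m/z, e.g. the sulfate radical anion SO3-)."""

    name: str
    mass: float
    kind: str = "loss"  # "loss" | "ion"


@dataclass(frozen=True)
class NeutralLossLibrary:
    entries: tuple[LossEntry, ...]

    def __iter__(self):
        return iter(self.entries)


#: Single neutral losses of the default library, as formula deltas so the
#: masses are computed, never transcribed. C3H5NO2 (dehydroalanine) is the
#: standard diagnostic loss of cysteine S-conjugates.
_SINGLE_LOSSES: dict[str, dict[str, int]] = {
    "H2O": {"H": 2, "O": 1},
    "CO": {"C": 1, "O": 1},
    "CH3": {"C": 1, "H": 3},
    "Cl": {"Cl": 1},
    "HCl": {"H": 1, "Cl": 1},
    "SO3": {"S": 1, "O": 3},
    "C6H8O6": {"C": 6, "H": 8, "O": 6},
    "C3H5NO2": {"C": 3, "H": 5, "N": 1, "O": 2},
}


def default_loss_library(max_depth: int = 2) -> NeutralLossLibrary:
    """Diagnostic losses and ions for conjugated biphenyl metabolites.

    Combined losses (all unordered pairs of distinct single losses, e.g.
    SO3 then CH3) are included up to ``max_depth`` = 2; the sulfate radical
    anion SO3- is carried as a diagnostic ion.
    """
    entries = [
        LossEntry(f"-{name}", delta_mass(d)) for name, d in _SINGLE_LOSSES.items()
    ]
    if max_depth >= 2:
        for (n1, d1), (n2, d2) in itertools.combinations(
            _SINGLE_LOSSES.items(), 2
        ):
            entries.append(LossEntry(f"-{n1}-{n2}", delta_mass(d1) + delta_mass(d2)))
    entries.append(LossEntry("SO3-", delta_mass({"S": 1, "O": 3}), kind="ion"))
    return NeutralLossLibrary(tuple(entries))


def match_features(
    features: list[Feature],
    candidates: list[CandidateMetabolite],
    window_ppm: float = 10.0,
) -> list[tuple[Feature, CandidateMetabolite, float]]:
    """All (feature, candidate) pairs within the ppm mass window.

    A feature may match several candidates; matches are ordered by feature
    position, then |ppm|, then candidate parsimony (fewer rule steps).
    """
    if window_ppm <= 0:
        raise ValueError("window_ppm must be positive")
    out = []
    for i, f in enumerate(features):
        hits = []
        for c in candidates:
            ppm = ppm_difference(f.mz, c.mz)
            if ppm <= window_ppm:
                hits.append((ppm, c.n_steps, c.class_id, c))
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        out.extend((f, c, ppm) for ppm, _, _, c in hits)
    return out


@dataclass(frozen=True)
class IsotopeVerdict:
    status: str  # "pass" | "fail" | "untested"
    observed_ratio: float | None = None
    expected_ratio: float | None = None

    def __bool__(self) -> bool:
        return self.status == "pass"


def score_isotope_pattern(
    f: Feature,
    expected_cl: int,
    rel_tol: float = 0.30,
    noise_fraction: float = 0.05,
) -> IsotopeVerdict:
    """Check the observed (M+2)/M ratio against the binomial expectation.

    For ``expected_cl`` = 0 the check passes when no M+2 peak is present,
    or when it sits below ``noise_fraction`` of the monoisotopic peak. A
    feature without a recorded cluster is "untested" — distinct from a
    failure, and non-blocking downstream.
    """
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must be in (0, 1)")
    if f.isotope_cluster is None or len(f.isotope_cluster) == 0:
        return IsotopeVerdict("untested")
    base_int = f.isotope_cluster[0][1]
    if base_int <= 0:
        return IsotopeVerdict("untested")
    m2_int = f.isotope_cluster[1][1] if len(f.isotope_cluster) > 1 else 0.0
    observed = m2_int / base_int
    if expected_cl == 0:
        ok = observed <= noise_fraction
        return IsotopeVerdict("pass" if ok else "fail", observed, 0.0)
    expected = chlorine_isotope_pattern(
        ElementalFormula.from_counts({"Cl": expected_cl, "C": 1})
    ).m2_over_m
    ok = abs(observed - expected) <= rel_tol * expected
    return IsotopeVerdict("pass" if ok else "fail", observed, expected)


@dataclass(frozen=True)
class FragmentMatch:
    observed_mz: float
    name: str
    calculated_mz: float


def annotate_ms2(
    s: Ms2Spectrum,
    c: CandidateMetabolite,
    lib: NeutralLossLibrary | None = None,
    frag_tol: float = 0.01,
    precursor_window_ppm: float = 10.0,
) -> list[FragmentMatch]:
    """Assign observed fragments to library losses/ions within ``frag_tol``.

    The spectrum's precursor must agree with the candidate anion m/z within
    ``precursor_window_ppm``; otherwise the pairing is rejected with a
    ValueError. Each observed fragment takes at most one assignment (the
    closest); each library entry may explain several observed fragments
    only through distinct observed m/z values.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    lib = default_loss_library() if lib is None else lib
    precursor_calc = c.mz
    if ppm_difference(s.precursor_mz, precursor_calc) > precursor_window_ppm:
        raise ValueError(
            f"precursor {s.precursor_mz} does not match candidate "
            f"{c.class_id} ({precursor_calc:.5f}) within "
            f"{precursor_window_ppm} ppm"
        )
    matches: list[FragmentMatch] = []
    for obs_mz, _ in s.fragments:
        best: tuple[float, LossEntry, float] | None = None
        for entry in lib:
            calc = precursor_calc - entry.mass if entry.kind == "loss" else entry.mass
            if calc <= 0:
                continue
            err = abs(obs_mz - calc)
            if err <= frag_tol and (best is None or err < best[0]):
                best = (err, entry, calc)
        if best is not None:
            matches.append(FragmentMatch(obs_mz, best[1].name, best[2]))
    return matches


@dataclass
class Annotation:
    """A candidate-feature match with its full evidence trail."""

    candidate: CandidateMetabolite
    feature: Feature
    mass_error_ppm: float
    isotope: IsotopeVerdict
    matched_fragments: list[FragmentMatch] = field(default_factory=list)
    confidence: int | None = None
    background: bool = False


def assign_confidence(a: Annotation, has_standard: bool = False) -> int | None:
    """Tiered identification confidence; None = rejected (isotope fail)."""
    if a.isotope.status == "fail":
        return None
    if has_standard:
        return 1
    if len(a.matched_fragments) >= 1:
        return 2
    return 3


@dataclass
class ScreenConfig:
    """Tolerances and labels steering the end-to-end screen."""

    window_ppm: float = 10.0
    frag_tol: float = 0.01
    isotope_rel_tol: float = 0.30
    isotope_noise_fraction: float = 0.05
    rt_distinct: float = 0.05       # min; RT gap separating isomers
    ms2_rt_tol: float = 0.2         # min; MS2-to-feature RT pairing
    control_group: str = "DMSO"
    background_ratio: float = 0.10
    standards: frozenset[str] = frozenset()  # class_ids with authentic standards
    parent_label: str = "PCB 2"
    dechloro_label: str = "BP"

    def __post_init__(self):
        for name in ("window_ppm", "frag_tol", "isotope_rel_tol",
                     "rt_distinct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetaboliteHit:
    """One distinct metabolite: a (class, retention time) isomer with
    per-group intensity and mass-error summaries."""

    class_id: str
    name: str
    anion_formula: str
    calc_mz: float
    rt: float
    intensity_by_group: dict[str, float]
    ppm_by_group: dict[str, float]
    fragments: list[str]
    confidence: int | None


@dataclass
class Rejection:
    feature: Feature
    candidate_class: str
    reason: str


@dataclass
class ScreeningReport:
    annotations: list[Annotation]
    metabolites: list[MetaboliteHit]
    rejections: list[Rejection]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def classes(self) -> list[str]:
        return sorted({m.class_id for m in self.metabolites})

    @property
    def dechlorinated_classes(self) -> list[str]:
        return [c for c in self.classes if c.startswith("4.")]


def _pair_ms2(
    feature: Feature,
    spectra: list[Ms2Spectrum],
    window_ppm: float,
    rt_tol: float,
) -> Ms2Spectrum | None:
    best, best_ppm = None, None
    for s in spectra:
        ppm = ppm_difference(s.precursor_mz, feature.mz)
        if ppm > window_ppm:
            continue
        if s.rt is not None and abs(s.rt - feature.rt) > rt_tol:
            continue
        if best_ppm is None or ppm < best_ppm:
            best, best_ppm = s, ppm
    return best


def screen(
    features: list[Feature],
    ms2_spectra: list[Ms2Spectrum],
    candidates: list[CandidateMetabolite],
    config: ScreenConfig | None = None,
    lib: NeutralLossLibrary | None = None,
) -> ScreeningReport:
    """End-to-end suspect screen.

    Pipeline: ppm matching -> chlorine-isotope verification -> MS/MS
    annotation -> confidence -> background exclusion against the control
    group -> isomer grouping by retention time. Missing MS2 degrades a hit
    to level 3; an isotope contradiction rejects it. Metabolites whose
    control-group intensity reaches ``background_ratio`` of the lowest
    exposed-group intensity are flagged background and excluded.
    """
    config = config or ScreenConfig()
    lib = default_loss_library() if lib is None else lib
    control = config.control_group

    pairs = match_features(features, candidates, config.window_ppm)
    annotations: list[Annotation] = []
    rejections: list[Rejection] = []
    for f, c, ppm in pairs:
        verdict = score_isotope_pattern(
            f, c.anion["Cl"], config.isotope_rel_tol,
            config.isotope_noise_fraction,
        )
        ann = Annotation(candidate=c, feature=f, mass_error_ppm=ppm,
                         isotope=verdict)
        if verdict.status == "fail":
            rejections.append(Rejection(f, c.class_id, "isotope_fail"))
            continue
        spec = _pair_ms2(f, ms2_spectra, config.window_ppm, config.ms2_rt_tol)
        if spec is not None:
            ann.matched_fragments = annotate_ms2(
                spec, c, lib, config.frag_tol, config.window_ppm
            )
        ann.confidence = assign_confidence(
            ann, has_standard=c.class_id in config.standards
        )
        annotations.append(ann)

    # Background exclusion: compare control vs exposed intensity per
    # candidate class.
    by_class: dict[str, list[Annotation]] = {}
    for ann in annotations:
        by_class.setdefault(ann.candidate.class_id, []).append(ann)
    kept: list[Annotation] = []
    for class_id, anns in by_class.items():
        control_int = [a.feature.intensity for a in anns
                       if a.feature.group == control]
        exposed = [a for a in anns if a.feature.group != control]
        exposed_int = [a.feature.intensity for a in exposed]
        if control_int and exposed_int:
            if max(control_int) >= config.background_ratio * min(exposed_int):
                for a in anns:
                    a.background = True
                    rejections.append(
                        Rejection(a.feature, class_id, "background")
                    )
                continue
        elif control_int and not exposed_int:
            for a in anns:
                a.background = True
                rejections.append(Rejection(a.feature, class_id, "background"))
            continue
        kept.extend(exposed)

    # Isomer grouping: within one (class, anion formula), annotations whose
    # RTs fall within rt_distinct of a cluster seed are one metabolite.
    metabolites: list[MetaboliteHit] = []
    groups: dict[tuple[str, str], list[Annotation]] = {}
    for ann in kept:
        key = (ann.candidate.class_id, ann.candidate.anion.hill())
        groups.setdefault(key, []).append(ann)
    for (class_id, anion), anns in sorted(groups.items()):
        anns.sort(key=lambda a: a.feature.rt)
        clusters: list[list[Annotation]] = []
        for ann in anns:
            # strict <: features a full rt_distinct apart are distinct
            # isomers; the gap is rounded because retention times carry
            # ~0.01 min precision and the threshold must not be eaten by
            # float subtraction error
            if clusters and (
                round(ann.feature.rt - clusters[-1][0].feature.rt, 6)
                < config.rt_distinct
            ):
                clusters[-1].append(ann)
            else:
                clusters.append([ann])
        for cluster in clusters:
            frag_names = sorted(
                {fm.name for a in cluster for fm in a.matched_fragments}
            )
            conf = min(
                (a.confidence for a in cluster if a.confidence is not None),
                default=None,
            )
            metabolites.append(
                MetaboliteHit(
                    class_id=class_id,
                    name=class_name(class_id, config.parent_label,
                                    config.dechloro_label),
                    anion_formula=anion,
                    calc_mz=cluster[0].candidate.mz,
                    rt=cluster[0].feature.rt,
                    intensity_by_group={
                        a.feature.group: a.feature.intensity for a in cluster
                    },
                    ppm_by_group={
                        a.feature.group: a.mass_error_ppm for a in cluster
                    },
                    fragments=frag_names,
                    confidence=conf,
                )
            )
    metabolites.sort(key=lambda m: (m.class_id, m.rt))
    return ScreeningReport(
        annotations=annotations, metabolites=metabolites, rejections=rejections
    )
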