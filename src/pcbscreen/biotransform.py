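"""Rule-based generation of candidate (chloro)biphenyl metabolites.

Candidates are elemental formulas plus substitution bookkeeping, not
structures: ring positions are deliberately unmodeled, so several observed
positional isomers map onto one candidate and are later separated by
retention time. The built-in rule set covers P450 hydroxylation, phase-II
conjugation (sulfation, glucuronidation, catechol O-methylation, cysteine
S-conjugation via the mercapturic-acid route), and the two dechlorination
modes of hydroxylated chlorobiphenyls: reductive (Cl -> H) and oxidative
(Cl -> OH via a 3,4-arene-oxide-type intermediate).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Mapping

from .chem import (
    ElementalFormula,
    InfeasibleTransformation,
    anion_mz,
    combine,
    delta_mass,
    parse_formula,
)

__all__ = [
    "CandidateMetabolite",
    "MetaboliteState",
    "TransformationRule",
    "apply_rule",
    "builtin_rules",
    "class_catalog",
    "class_name",
    "generate_candidates",
]

#: Default per-rule application caps; hydroxylation must allow three
#: applications to reach trisoxygenated conjugates such as the
#: methoxy-hydroxy sulfates (class 3.4).
DEFAULT_CAPS = {
    "hydroxylation": 3,
    "sulfation": 1,
    "glucuronidation": 1,
    "methylation": 1,
    "cysteine_conjugation": 1,
    "reductive_dechlorination": 1,
    "oxidative_dechlorination": 1,
}

#: Closure depth that reaches every named metabolite class (the deepest,
#: methoxy-hydroxy sulfates, take five rule applications).
DEFAULT_MAX_STEPS = 5


@dataclass(frozen=True)
class MetaboliteState:
    """Substitution bookkeeping carried alongside the formula.

    ``catechol`` records that at some point two free hydroxyls coexisted on
    the skeleton (positions unmodeled): the prerequisite for catechol
    O-methyltransferase methylation. Conjugations consume one free hydroxyl
    but do not clear the flag.
    """

    n_free_OH: int = 0
    n_sulfate: int = 0
    n_glucuronide: int = 0
    n_methoxy: int = 0
    n_cysteine: int = 0
    n_Cl: int = 0
    catechol: bool = False

    def counts(self) -> dict[str, int]:
        return {
            "n_free_OH": self.n_free_OH,
            "n_sulfate": self.n_sulfate,
            "n_glucuronide": self.n_glucuronide,
            "n_methoxy": self.n_methoxy,
            "n_cysteine": self.n_cysteine,
            "n_Cl": self.n_Cl,
        }


@dataclass(frozen=True)
class TransformationRule:
    """One biotransformation step expressed as a formula delta plus
    declarative preconditions and state increments.

    ``requires`` maps state fields to minimum counts (plus the special key
    ``catechol`` demanding the flag); ``update`` maps state fields to signed
    increments applied after the formula delta.
    """

    name: str
    delta: Mapping[str, int]
    requires: Mapping[str, int | bool] = field(default_factory=dict)
    update: Mapping[str, int] = field(default_factory=dict)
    max_applications: int = 1

    def applicable(self, state: MetaboliteState) -> bool:
        for key, need in self.requires.items():
            if key == "catechol":
                if need and not state.catechol:
                    return False
            elif getattr(state, key) < need:
                return False
        return True

    def next_state(self, state: MetaboliteState) -> MetaboliteState:
        fields = state.counts()
        for key, inc in self.update.items():
            fields[key] += inc
        catechol = state.catechol or fields["n_free_OH"] >= 2
        return MetaboliteState(**fields, catechol=catechol)

    @property
    def mass_shift(self) -> float:
        return delta_mass(self.delta)


def builtin_rules(caps: Mapping[str, int] | None = None) -> list[TransformationRule]:
    """The default rule set for (chloro)biphenyl metabolism.

    Dechlorination requires at least one free hydroxyl — the ortho
    OH/Cl relationship seen in the proposed pathway, abstracted to counts
    because positions are unmodeled. Quinone/hydroquinone/glutathione
    chemistry is excluded by default (those intermediates were not observed
    as stable products); callers may append their own rules.
    """
    caps = {**DEFAULT_CAPS, **(caps or {})}
    return [
        TransformationRule(
            name="hydroxylation",
            delta={"O": 1},
            update={"n_free_OH": 1},
            max_applications=caps["hydroxylation"],
        ),
        TransformationRule(
            name="sulfation",
            delta={"S": 1, "O": 3},
            requires={"n_free_OH": 1},
            update={"n_free_OH": -1, "n_sulfate": 1},
            max_applications=caps["sulfation"],
        ),
        TransformationRule(
            name="glucuronidation",
            delta={"C": 6, "H": 8, "O": 6},
            requires={"n_free_OH": 1},
            update={"n_free_OH": -1, "n_glucuronide": 1},
            max_applications=caps["glucuronidation"],
        ),
        TransformationRule(
            name="methylation",
            delta={"C": 1, "H": 2},
            requires={"catechol": True, "n_free_OH": 1},
            update={"n_free_OH": -1, "n_methoxy": 1},
            max_applications=caps["methylation"],
        ),
        TransformationRule(
            name="cysteine_conjugation",
            delta={"C": 3, "H": 5, "N": 1, "O": 2, "S": 1},
            requires={"n_free_OH": 1},
            update={"n_cysteine": 1},
            max_applications=caps["cysteine_conjugation"],
        ),
        TransformationRule(
            name="reductive_dechlorination",
            delta={"Cl": -1, "H": 1},
            requires={"n_free_OH": 1, "n_Cl": 1},
            update={"n_Cl": -1},
            max_applications=caps["reductive_dechlorination"],
        ),
        TransformationRule(
            name="oxidative_dechlorination",
            delta={"Cl": -1, "O": 1, "H": 1},
            requires={"n_free_OH": 1, "n_Cl": 1},
            update={"n_Cl": -1, "n_free_OH": 1},
            max_applications=caps["oxidative_dechlorination"],
        ),
    ]


@dataclass(frozen=True)
class CandidateMetabolite:
    """A candidate: neutral formula, state, class label, rule history."""

    neutral: ElementalFormula
    state: MetaboliteState
    class_id: str
    history: tuple[str, ...] = ()
    parent: str = ""

    @property
    def anion(self) -> ElementalFormula:
        return combine(self.neutral, {"H": -1})

    @property
    def mz(self) -> float:
        return anion_mz(self.neutral)

    @property
    def n_steps(self) -> int:
        return len(self.history)

    @property
    def dechlorinated(self) -> bool:
        return self.class_id.startswith("4.")


def root_candidate(parent: ElementalFormula) -> CandidateMetabolite:
    state = MetaboliteState(n_Cl=parent["Cl"])
    return CandidateMetabolite(
        neutral=parent, state=state, class_id="parent", parent=parent.hill()
    )


def apply_rule(c: CandidateMetabolite, r: TransformationRule) -> CandidateMetabolite:
    """Apply one rule, or raise :class:`InfeasibleTransformation`."""
    if not r.applicable(c.state):
        raise InfeasibleTransformation(
            f"rule {r.name!r} not applicable to state {c.state}"
        )
    if c.history.count(r.name) >= r.max_applications:
        raise InfeasibleTransformation(
            f"rule {r.name!r} exceeds cap {r.max_applications}"
        )
    neutral = combine(c.neutral, r.delta)
    state = r.next_state(c.state)
    cand = CandidateMetabolite(
        neutral=neutral,
        state=state,
        class_id="",
        history=c.history + (r.name,),
        parent=c.parent,
    )
    return replace(cand, class_id=_classify(cand, parent_cl=_parent_cl(c)))


def _parent_cl(c: CandidateMetabolite) -> int:
    return parse_formula(c.parent)["Cl"] if c.parent else c.state.n_Cl


#: (dechlorinated, n_free_OH, n_sulfate, n_glucuronide, n_methoxy,
#:  n_cysteine) -> class id of the named screening scheme.
_CLASS_SIGNATURES: dict[tuple[bool, int, int, int, int, int], str] = {
    (False, 1, 0, 0, 0, 0): "1.1",
    (False, 0, 1, 0, 0, 0): "1.2",
    (False, 0, 0, 1, 0, 0): "1.3",
    (False, 1, 1, 0, 0, 0): "2.1",
    (False, 1, 0, 0, 1, 0): "3.1",
    (False, 0, 1, 0, 1, 0): "3.2",
    (False, 0, 0, 1, 1, 0): "3.3",
    (False, 1, 1, 0, 1, 0): "3.4",
    (True, 1, 1, 0, 0, 0): "4.1",
    (True, 0, 1, 0, 1, 0): "4.2",
    (True, 0, 0, 1, 1, 0): "4.3",
    (True, 1, 1, 0, 1, 0): "4.4",
    (True, 1, 0, 0, 0, 1): "4.5",
}

_CLASS_NAME_TEMPLATES = {
    "1.1": "OH-{P}",
    "1.2": "{P} sulfate",
    "1.3": "{P} glucuronide",
    "2.1": "OH-{P} sulfate",
    "3.1": "MeO-OH-{P}",
    "3.2": "MeO-{P} sulfate",
    "3.3": "MeO-{P} glucuronide",
    "3.4": "MeO-OH-{P} sulfate",
    "4.1": "OH-{D} sulfate",
    "4.2": "MeO-{D} sulfate",
    "4.3": "MeO-{D} glucuronide",
    "4.4": "MeO-OH-{D} sulfate",
    "4.5": "OH-{D} cysteine",
}


def class_name(class_id: str, parent_label: str = "PCB 2",
               dechloro_label: str = "BP") -> str:
    """Human-readable metabolite-class name, e.g. ``"MeO-BP sulfate"``."""
    tpl = _CLASS_NAME_TEMPLATES.get(class_id)
    if tpl is None:
        return class_id
    return tpl.format(P=parent_label, D=dechloro_label)


def _classify(c: CandidateMetabolite, parent_cl: int) -> str:
    s = c.state
    key = (
        s.n_Cl < parent_cl,
        s.n_free_OH,
        s.n_sulfate,
        s.n_glucuronide,
        s.n_methoxy,
        s.n_cysteine,
    )
    return _CLASS_SIGNATURES.get(key, "intermediate")


def generate_candidates(
    parent: ElementalFormula,
    rules: list[TransformationRule] | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> list[CandidateMetabolite]:
    """Breadth-first closure of rule applications from the parent.

    Candidates are deduplicated on (anion formula, class id) — the first
    (shortest-history) representative is kept — and returned sorted by anion
    mass then class id, so output order is deterministic regardless of rule
    order.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    rules = builtin_rules() if rules is None else rules
    root = root_candidate(parent)
    seen: dict[tuple[str, str], CandidateMetabolite] = {
        (root.anion.hill(), root.class_id): root
    }
    frontier = deque([root])
    depth = 0
    while frontier and depth < max_steps:
        next_frontier: deque[CandidateMetabolite] = deque()
        for cand in frontier:
            for rule in rules:
                if not rule.applicable(cand.state):
                    continue
                if cand.history.count(rule.name) >= rule.max_applications:
                    continue
                nxt = apply_rule(cand, rule)
                key = (nxt.anion.hill(), nxt.class_id)
                if key not in seen:
                    seen[key] = nxt
                next_frontier.append(nxt)
        frontier = next_frontier
        depth += 1
    return sorted(seen.values(), key=lambda c: (c.mz, c.class_id))


def class_catalog(parent: ElementalFormula) -> dict[str, ElementalFormula]:
    """Anion formula of each named class, computed by delta arithmetic.

    P-classes (1.x-3.x) retain the parent's chlorination; D-classes (4.x)
    carry one chlorine fewer. A chlorine-free parent has no 4.x entries.
    """
    if parent["H"] < 1:
        raise ValueError("parent must contain hydrogen")
    deltas = {
        "1.1": {"O": 1},                                # +OH
        "1.2": {"O": 4, "S": 1},                        # +OH +SO3
        "1.3": {"C": 6, "H": 8, "O": 7},                # +OH +glucuronyl
        "2.1": {"O": 5, "S": 1},                        # +2 OH +SO3
        "3.1": {"C": 1, "H": 2, "O": 2},                # +2 OH +CH2
        "3.2": {"C": 1, "H": 2, "O": 5, "S": 1},        # +2 OH +CH2 +SO3
        "3.3": {"C": 7, "H": 10, "O": 8},               # +2 OH +CH2 +gluc
        "3.4": {"C": 1, "H": 2, "O": 6, "S": 1},        # +3 OH +CH2 +SO3
    }
    # 4.x = 2.1/3.x/cysteine composition on the dechlorinated skeleton
    deltas_d = {
        "4.1": deltas["2.1"],
        "4.2": deltas["3.2"],
        "4.3": deltas["3.3"],
        "4.4": deltas["3.4"],
        "4.5": {"C": 3, "H": 5, "N": 1, "O": 3, "S": 1},  # +OH +cysteinyl
    }
    catalog = {
        cid: combine(combine(parent, d), {"H": -1}) for cid, d in deltas.items()
    }
    if parent["Cl"] >= 1:
        dparent = combine(parent, {"Cl": -1, "H": 1})
        for cid, d in deltas_d.items():
            catalog[cid] = combine(combine(dparent, d), {"H": -1})
    else:
        warnings.warn(
            "parent has no chlorine: dechlorinated classes 4.x omitted",
            stacklevel=2,
        )
    return catalog
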