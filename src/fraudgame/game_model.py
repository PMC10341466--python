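"""Parameter space, strategy profiles and the payoff matrix of the
healthcare-fraud supervision game.

Three boundedly rational players interact repeatedly: a hospital that
either operates in compliance with healthcare regulations or commits
fraud ("illegal operation"), a for-profit third-party investigator hired
by the local government that either investigates truthfully or colludes
with the fraudulent hospital and files a false report, and a local
government that either supervises strictly (at cost ``Cg``) or not at
all.  A reward-and-punishment mechanism couples the players: a compliant
hospital earns a reward ``Ah`` under strict supervision, fraud is fined
``Ph`` whenever it is detected (by a true investigation or by strict
supervision), a colluding investigator is fined ``Pt`` under strict
supervision, and the local government itself is rewarded ``Ag`` or fined
``Pg`` by the superior government.

The eight pure-strategy payoff cells are the single source of truth for
the whole package: mixed-strategy expected payoffs (and, downstream, the
replicator dynamics) are derived from them by probability weighting,
never re-keyed from closed-form expansions.
"""

from __future__ import annotations

import itertools
import math
import numbers
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "PARAMETER_NAMES",
    "ParameterSet",
    "Hospital",
    "ThirdParty",
    "Government",
    "StrategyProfile",
    "ALL_PROFILES",
    "MixedState",
    "PayoffTriple",
    "PayoffMatrix",
    "ExpectedPayoffs",
    "validate_parameters",
    "payoff_for_profile",
    "build_payoff_matrix",
    "expected_payoffs",
]

#: The sixteen monetary parameters, in canonical order: costs, incomes,
#: then the reward/fine instruments.
PARAMETER_NAMES: tuple[str, ...] = (
    "Ch1", "Ch2", "Ct1", "Ct2", "Cg",
    "Ih1", "Ih2", "It1", "It2", "Ig1", "Ig2",
    "Ah", "Ph", "Pt", "Ag", "Pg",
)


@dataclass(frozen=True)
class ParameterSet:
    """The sixteen non-negative monetary parameters of the game.

    Costs
        ``Ch1``/``Ch2`` hospital compliant/illegal operation,
        ``Ct1``/``Ct2`` third-party true/false investigation,
        ``Cg`` government strict supervision.
    Incomes
        ``Ih1``/``Ih2`` hospital compliant/illegal operation,
        ``It1`` third-party income from a true investigation,
        ``It2`` third-party income (bribe included) from a false
        investigation of a fraudulent hospital,
        ``Ig1``/``Ig2`` social benefit to the government under
        compliant/illegal hospital operation.
    Reward-and-punishment instruments
        ``Ah`` reward to a compliant hospital, ``Ph`` fine on a detected
        fraudulent hospital, ``Pt`` fine on a colluding third party,
        ``Ag`` superior-government reward for strict supervision,
        ``Pg`` superior-government fine for lost social benefit under
        non-supervision.

    All values are plain reals in one arbitrary currency unit.  The
    constructor only enforces well-formedness (finite numbers); the
    economic ordering constraints are checked by
    :func:`validate_parameters`.
    """

    Ch1: float
    Ch2: float
    Ct1: float
    Ct2: float
    Cg: float
    Ih1: float
    Ih2: float
    It1: float
    It2: float
    Ig1: float
    Ig2: float
    Ah: float
    Ph: float
    Pt: float
    Ag: float
    Pg: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool) or not isinstance(value, numbers.Real):
                raise TypeError(f"parameter {f.name} must be a real number, got {value!r}")
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"parameter {f.name} must be finite, got {value!r}")
            object.__setattr__(self, f.name, value)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        """Build a set from a flat mapping with exactly the 16 symbol keys.

        Unknown keys are rejected rather than ignored so that a typo in a
        config file cannot silently fall back to another value.
        """
        unknown = sorted(set(mapping) - set(PARAMETER_NAMES))
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        missing = sorted(set(PARAMETER_NAMES) - set(mapping))
        if missing:
            raise ValueError(f"missing parameter keys: {', '.join(missing)}")
        return cls(**{name: mapping[name] for name in PARAMETER_NAMES})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with some parameters overridden."""
        unknown = sorted(set(overrides) - set(PARAMETER_NAMES))
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        values = self.as_dict()
        values.update(overrides)
        return ParameterSet(**values)


class Hospital(str, Enum):
    """Hospital pure strategies."""

    COMPLIANT = "compliant"
    ILLEGAL = "illegal"


class ThirdParty(str, Enum):
    """Third-party investigator pure strategies."""

    TRUE_INVESTIGATION = "true_investigation"
    FALSE_INVESTIGATION = "false_investigation"


class Government(str, Enum):
    """Local-government pure strategies."""

    STRICT = "strict"
    NON_SUPERVISION = "non_supervision"


@dataclass(frozen=True)
class StrategyProfile:
    """One pure-strategy choice per player; eight profiles in total."""

    hospital: Hospital
    third_party: ThirdParty
    government: Government


#: The eight profiles in payoff-table order (hospital strategy outermost,
#: then the investigator, then the government).
ALL_PROFILES: tuple[StrategyProfile, ...] = tuple(
    StrategyProfile(h, t, g)
    for h, t, g in itertools.product(Hospital, ThirdParty, Government)
)


@dataclass(frozen=True)
class MixedState:
    """Mixed-strategy state (x, y, z).

    ``x`` is the probability of compliant hospital operation, ``y`` of a
    true investigation, ``z`` of strict supervision.  Instances are not
    clamped on construction: stationary-point *candidates* may lie outside
    the unit cube and are flagged, not rejected.  Operations that require
    a probability state (expected payoffs, the vector field) check
    :attr:`in_unit_cube` and raise.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, numbers.Real):
                raise TypeError(f"coordinate {name} must be a real number, got {value!r}")
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"coordinate {name} must be finite")
            object.__setattr__(self, name, value)

    @property
    def in_unit_cube(self) -> bool:
        return all(0.0 <= v <= 1.0 for v in (self.x, self.y, self.z))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())


@dataclass(frozen=True)
class PayoffTriple:
    """(hospital, third party, government) payoffs for one profile."""

    hospital: float
    third_party: float
    government: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.hospital, self.third_party, self.government)


def _profile_payoffs(p, profile: StrategyProfile):
    """Payoff cell for ``profile``; works for numeric and symbolic ``p``.

    ``p`` is any object with the sixteen parameter attributes, so the same
    cell definitions serve :func:`payoff_for_profile` and the sympy audit
    in :mod:`fraudgame.symbolic`.
    """
    compliant = profile.hospital is Hospital.COMPLIANT
    true_inv = profile.third_party is ThirdParty.TRUE_INVESTIGATION
    strict = profile.government is Government.STRICT

    # Hospital: a compliant hospital earns the reward only under strict
    # supervision; fraud is fined unless it goes entirely undetected
    # (false investigation AND non-supervision).
    if compliant:
        hosp = p.Ih1 + p.Ah - p.Ch1 if strict else p.Ih1 - p.Ch1
    else:
        undetected = (not true_inv) and (not strict)
        hosp = p.Ih2 - p.Ch2 if undetected else p.Ih2 - p.Ch2 - p.Ph

    # Third party: a true investigation always earns It1 at cost Ct1; a
    # false investigation earns the bribe-inflated It2 only when the
    # hospital is fraudulent, and is fined under strict supervision.
    if true_inv:
        third = p.It1 - p.Ct1
    else:
        income = p.It1 if compliant else p.It2
        third = income - p.Ct2 - p.Pt if strict else income - p.Ct2

    # Government: strict supervision costs Cg, pays the hospital reward
    # when earned, collects fines, and earns the superior-government
    # reward Ag; unsupervised undetected fraud draws the fine Pg.
    if strict:
        gov = (p.Ig1 if compliant else p.Ig2) - p.Cg + p.Ag
        if compliant:
            gov = gov - p.Ah
            if not true_inv:
                gov = gov + p.Pt
        else:
            gov = gov + p.Ph
            if not true_inv:
                gov = gov + p.Pt
    else:
        if compliant:
            gov = p.Ig1
        elif true_inv:
            gov = p.Ig2 + p.Ph
        else:
            gov = p.Ig2 - p.Pg

    return hosp, third, gov


@dataclass(frozen=True)
class PayoffMatrix:
    """Complete mapping of the eight pure profiles to payoff triples."""

    cells: Mapping[StrategyProfile, PayoffTriple]

    def __post_init__(self) -> None:
        if set(self.cells) != set(ALL_PROFILES):
            raise ValueError("payoff matrix must cover exactly the 8 strategy profiles")

    def __getitem__(self, profile: StrategyProfile) -> PayoffTriple:
        return self.cells[profile]

    def items(self):
        return ((profile, self.cells[profile]) for profile in ALL_PROFILES)


@dataclass(frozen=True)
class ExpectedPayoffs:
    """Per-player expected payoffs at a mixed state.

    ``E11``/``E12`` are the hospital's expected payoffs for compliant and
    illegal operation, ``E1bar`` their population average ``x*E11 +
    (1-x)*E12``; likewise ``E21``/``E22``/``E2bar`` for the investigator
    (true/false investigation) and ``E31``/``E32``/``E3bar`` for the
    government (strict/non-supervision).
    """

    E11: float
    E12: float
    E1bar: float
    E21: float
    E22: float
    E2bar: float
    E31: float
    E32: float
    E3bar: float


_CONSTRAINTS = (
    # name, predicate (core tier: the economic ordering assumptions)
    ("Ch1>Ch2", lambda p: p.Ch1 > p.Ch2),
    ("Ch2>=0", lambda p: p.Ch2 >= 0),
    ("Ct1>Ct2", lambda p: p.Ct1 > p.Ct2),
    ("Ct2>=0", lambda p: p.Ct2 >= 0),
    ("Cg>0", lambda p: p.Cg > 0),
    ("Ih2>Ih1", lambda p: p.Ih2 > p.Ih1),
    ("Ih1>=0", lambda p: p.Ih1 >= 0),
    ("It2>=It1", lambda p: p.It2 >= p.It1),
    ("It1>=0", lambda p: p.It1 >= 0),
    ("Ig1>Ig2", lambda p: p.Ig1 > p.Ig2),
    ("Ig2>=0", lambda p: p.Ig2 >= 0),
    ("Ah<Ch1", lambda p: p.Ah < p.Ch1),
    ("Ag<Cg", lambda p: p.Ag < p.Cg),
    ("Ah>=0", lambda p: p.Ah >= 0),
    ("Ph>=0", lambda p: p.Ph >= 0),
    ("Pt>=0", lambda p: p.Pt >= 0),
    ("Ag>=0", lambda p: p.Ag >= 0),
    ("Pg>=0", lambda p: p.Pg >= 0),
)

_STRICT_CONSTRAINTS = (
    # strict tier: positivity needed by the threshold formulas, which
    # divide by Ph, Pt, It2-It1 and Ah+Pg+Ph
    ("Ph>0", lambda p: p.Ph > 0),
    ("Pt>0", lambda p: p.Pt > 0),
    ("Pg>0", lambda p: p.Pg > 0),
    ("It2>It1", lambda p: p.It2 > p.It1),
)


def validate_parameters(params: ParameterSet, strict: bool = False) -> list[str]:
    """Return the names of all violated ordering constraints.

    The core tier checks the economic ordering assumptions (compliant
    operation costs more than fraud, fraud pays more than compliance,
    rewards are smaller than the corresponding costs, everything
    non-negative).  With ``strict=True`` the fines ``Ph``, ``Pt``, ``Pg``
    and the bribe margin ``It2-It1`` must additionally be strictly
    positive, which is what the threshold and stability formulas need.
    An empty list means the set is valid.
    """
    if not isinstance(params, ParameterSet):
        params = ParameterSet.from_mapping(dict(params))
    violated = [name for name, ok in _CONSTRAINTS if not ok(params)]
    if strict:
        violated += [name for name, ok in _STRICT_CONSTRAINTS if not ok(params)]
    return violated


def payoff_for_profile(params: ParameterSet, profile: StrategyProfile) -> PayoffTriple:
    """Payoff triple for one pure-strategy profile."""
    hosp, third, gov = _profile_payoffs(params, profile)
    return PayoffTriple(hosp, third, gov)


def build_payoff_matrix(params: ParameterSet) -> PayoffMatrix:
    """All eight payoff cells for ``params``."""
    return PayoffMatrix({profile: payoff_for_profile(params, profile) for profile in ALL_PROFILES})


def _opponent_weight(profile: StrategyProfile, state: MixedState, player: str) -> float:
    """Probability of the opponents' part of ``profile`` at ``state``."""
    w = 1.0
    if player != "hospital":
        w *= state.x if profile.hospital is Hospital.COMPLIANT else 1.0 - state.x
    if player != "third_party":
        w *= state.y if profile.third_party is ThirdParty.TRUE_INVESTIGATION else 1.0 - state.y
    if player != "government":
        w *= state.z if profile.government is Government.STRICT else 1.0 - state.z
    return w


def expected_payoffs(params: ParameterSet, state: MixedState) -> ExpectedPayoffs:
    """Expected payoffs at a mixed state, weighted from the payoff matrix.

    Raises :class:`ValueError` if ``state`` lies outside the unit cube.
    """
    if not isinstance(state, MixedState):
        state = MixedState(*state)
    if not state.in_unit_cube:
        raise ValueError(f"mixed state {state.as_tuple()} outside [0,1]^3")
    matrix = build_payoff_matrix(params)

    def conditional(player: str, attr: str, strategy) -> float:
        total = 0.0
        for profile, cell in matrix.items():
            if getattr(profile, player) is strategy:
                total += _opponent_weight(profile, state, player) * getattr(cell, attr)
        return total

    E11 = conditional("hospital", "hospital", Hospital.COMPLIANT)
    E12 = conditional("hospital", "hospital", Hospital.ILLEGAL)
    E21 = conditional("third_party", "third_party", ThirdParty.TRUE_INVESTIGATION)
    E22 = conditional("third_party", "third_party", ThirdParty.FALSE_INVESTIGATION)
    E31 = conditional("government", "government", Government.STRICT)
    E32 = conditional("government", "government", Government.NON_SUPERVISION)
    return ExpectedPayoffs(
        E11=E11, E12=E12, E1bar=state.x * E11 + (1.0 - state.x) * E12,
        E21=E21, E22=E22, E2bar=state.y * E21 + (1.0 - state.y) * E22,
        E31=E31, E32=E32, E3bar=state.z * E31 + (1.0 - state.z) * E32,
    )
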