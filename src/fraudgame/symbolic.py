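"""Symbolic audits of the replicator field against the payoff matrix.

Everything here is exact sympy algebra, used to certify three structural
facts about the model rather than to run it:

* the hospital and government components of the published replicator
  field coincide exactly with the payoff-matrix derivation;
* the third-party component differs by exactly
  ``y*(1-y)*x*z*(It1 - It2)``;
* the published three-term expansion of the government's expected payoff
  under strict supervision omits exactly the undetected-fraud cell
  ``(1-x)*(1-y)*(Ig2 - Cg + Ph + Pt + Ag)`` relative to the full matrix
  weighting (a typographical omission: the published government
  replicator equation itself is matrix-consistent).
"""

from __future__ import annotations

from types import SimpleNamespace

import sympy as sp

from .game_model import (
    ALL_PROFILES,
    Government,
    Hospital,
    PARAMETER_NAMES,
    ParameterSet,
    ThirdParty,
    _profile_payoffs,
)
from .replicator import _G, _H, _J_matrix, _J_published

__all__ = [
    "parameter_symbols",
    "state_symbols",
    "symbolic_parameters",
    "expected_payoff_exprs",
    "vector_field_exprs",
    "mode_residual",
    "published_strict_payoff_expr",
    "strict_payoff_residual",
]

#: sympy symbols for x, y, z
state_symbols: tuple[sp.Symbol, ...] = sp.symbols("x y z", real=True)

#: sympy symbols for the sixteen parameters, in canonical order
parameter_symbols: tuple[sp.Symbol, ...] = sp.symbols(
    " ".join(PARAMETER_NAMES), real=True, nonnegative=True
)

_SYMBOLS = dict(zip(PARAMETER_NAMES, parameter_symbols))


def symbolic_parameters() -> SimpleNamespace:
    """A parameter container whose fields are sympy symbols.

    Shares attribute names with :class:`~fraudgame.game_model.ParameterSet`
    so that the payoff-cell definitions evaluate symbolically.
    """
    return SimpleNamespace(**_SYMBOLS)


def _subs_map(params: ParameterSet | None) -> dict:
    if params is None:
        return {}
    return {sym: sp.Float(getattr(params, name)) for name, sym in _SYMBOLS.items()}


def expected_payoff_exprs(params: ParameterSet | None = None) -> dict[str, sp.Expr]:
    """Symbolic E11 ... E32 weighted from the payoff matrix."""
    p = symbolic_parameters()
    x, y, z = state_symbols
    weights = {
        Hospital.COMPLIANT: x, Hospital.ILLEGAL: 1 - x,
        ThirdParty.TRUE_INVESTIGATION: y, ThirdParty.FALSE_INVESTIGATION: 1 - y,
        Government.STRICT: z, Government.NON_SUPERVISION: 1 - z,
    }
    exprs = {name: sp.Integer(0) for name in ("E11", "E12", "E21", "E22", "E31", "E32")}
    for profile in ALL_PROFILES:
        hosp, third, gov = _profile_payoffs(p, profile)
        w_t, w_g = weights[profile.third_party], weights[profile.government]
        w_h = weights[profile.hospital]
        key = "E11" if profile.hospital is Hospital.COMPLIANT else "E12"
        exprs[key] += w_t * w_g * hosp
        key = "E21" if profile.third_party is ThirdParty.TRUE_INVESTIGATION else "E22"
        exprs[key] += w_h * w_g * third
        key = "E31" if profile.government is Government.STRICT else "E32"
        exprs[key] += w_h * w_t * gov
    subs = _subs_map(params)
    return {name: sp.expand(expr.subs(subs)) for name, expr in exprs.items()}


def vector_field_exprs(mode: str = "published",
                       params: ParameterSet | None = None) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Symbolic (dx/dt, dy/dt, dz/dt) in the requested dynamics mode.

    ``mode='matrix'`` builds the field from the symbolic expected
    payoffs; ``mode='published'`` uses the printed closed forms.
    """
    p = symbolic_parameters()
    x, y, z = state_symbols
    if mode == "published":
        fx = x * (1 - x) * _G(p, y, z)
        fy = y * (1 - y) * _J_published(p, x, z)
        fz = z * (z - 1) * _H(p, x, y)
    elif mode == "matrix":
        E = expected_payoff_exprs()
        fx = x * (1 - x) * (E["E11"] - E["E12"])
        fy = y * (1 - y) * (E["E21"] - E["E22"])
        fz = z * (1 - z) * (E["E31"] - E["E32"])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    subs = _subs_map(params)
    return tuple(sp.expand(f.subs(subs)) for f in (fx, fy, fz))


def mode_residual(params: ParameterSet | None = None):
    """Component-wise difference published-minus-matrix of the field."""
    from .replicator import ModeResidual

    pub = vector_field_exprs("published", params)
    mat = vector_field_exprs("matrix", params)
    diffs = [sp.simplify(a - b) for a, b in zip(pub, mat)]
    return ModeResidual(dx=diffs[0], dy=diffs[1], dz=diffs[2])


def published_strict_payoff_expr(params: ParameterSet | None = None) -> sp.Expr:
    """The government strict-supervision expected payoff as published.

    Three probability-weighted cells only; the undetected-fraud cell
    ``(1-x)(1-y)(...)`` is absent.  Kept verbatim so the omission can be
    audited, never used to drive dynamics.
    """
    p = symbolic_parameters()
    x, y, _ = state_symbols
    expr = (
        x * y * (p.Ig1 - p.Cg - p.Ah + p.Ag)
        + x * (1 - y) * (p.Ig1 - p.Cg - p.Ah + p.Pt + p.Ag)
        + (1 - x) * y * (p.Ig2 - p.Cg + p.Ph + p.Ag)
    )
    return sp.expand(expr.subs(_subs_map(params)))


def strict_payoff_residual(params: ParameterSet | None = None) -> sp.Expr:
    """Matrix-derived E31 minus the published three-term expansion.

    Equals ``(1-x)*(1-y)*(Ig2 - Cg + Ph + Pt + Ag)`` identically — the
    single payoff cell the published expansion dropped.
    """
    matrix_e31 = expected_payoff_exprs(params)["E31"]
    return sp.simplify(matrix_e31 - published_strict_payoff_expr(params))
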