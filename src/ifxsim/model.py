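"""Mass-action model of TNF-α, its cell-surface receptor, and an anti-TNF antibody.

The model tracks four quantities in a well-mixed compartment:

* ``L`` — free TNF-α concentration (M),
* ``r`` — fraction of TNF receptors occupied by TNF-α (dimensionless),
* ``A`` — free antibody (infliximab) concentration (M),
* ``C`` — antibody–TNF complex concentration (M).

TNF-α binds receptors reversibly (``k_on``/``k_off``) with bound receptors
internalised at rate ``k_int``, and binds the antibody reversibly
(``k_on_ab``/``k_off_ab``) with the complex eliminated at rate ``k_el_cx``.
Free antibody is cleared at rate ``k_el_ab`` — the patient-specific clearance
that drives treatment response — and enters via a timed infusion rate.

Two TNF-α production closures are provided.  The *constant-production* system
feeds ``L`` with a fixed zeroth-order rate ``omega1`` and clears it at
``k_el_tnf``.  The *dynamic-production* system replaces ``omega1`` by the loss
terms evaluated along the trajectory (internalised receptor, degraded complex,
direct clearance), which makes the weighted total ``L + r_tot*r + C`` an exact
invariant and keeps TNF-α suppressed for the full inter-dose interval.  A
*reduced* three-variable form eliminates ``L`` through that conservation law.

All quantities are strict SI-molar (mol/L) and seconds; clinical week/hour and
mg/L framings are handled at the dosing and CLI layers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ModelParams",
    "ModelState",
    "EquilibriumResult",
    "TheoreticalBounds",
    "rhs_full",
    "rhs_constant_production",
    "rhs_reduced",
    "jac_full",
    "jac_constant_production",
    "jac_reduced",
    "conserved_total",
    "drug_free_equilibria",
    "equilibrium_bound_fraction",
    "production_rate_at_equilibrium",
    "theoretical_bounds",
]

#: Literature plausibility window for the antibody clearance rate (1/s).
DEFAULT_CLEARANCE_WINDOW = (1.5e-6, 5.0e-6)

#: Absolute tolerance for solver-scale negative undershoot of concentrations.
NEGATIVE_UNDERSHOOT_TOL = 1e-18


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and clearance rate constants of the model.

    Defaults are literature estimates for IBD patients; only ``k_el_ab``
    (infliximab clearance) is expected to vary strongly between patients.
    """

    k_on: float = 1.7e7        # TNF–receptor association rate, 1/(M s)
    k_off: float = 5.5e-4      # TNF–receptor dissociation rate, 1/s
    r_tot: float = 1.5e-10     # total receptor concentration, M
    k_int: float = 6.0e-4      # internalisation rate of bound receptor, 1/s
    k_el_tnf: float = 1.0e-5   # elimination rate of free TNF-α, 1/s
    k_on_ab: float = 1.0e6     # TNF–antibody association rate, 1/(M s)
    k_off_ab: float = 1.0e-4   # TNF–antibody dissociation rate, 1/s
    k_el_cx: float = 8.5e-7    # elimination rate of antibody–TNF complex, 1/s
    k_el_ab: float = 3.5e-6    # clearance rate of free antibody, 1/s
    #: plausibility window for k_el_ab; values outside warn, not error
    clearance_window: tuple = field(
        default=DEFAULT_CLEARANCE_WINDOW, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "clearance_window":
                continue
            value = getattr(self, f.name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{f.name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value}")
        lo, hi = self.clearance_window
        if not lo <= self.k_el_ab <= hi:
            warnings.warn(
                f"antibody clearance k_el_ab={self.k_el_ab:g} 1/s lies outside the "
                f"literature range [{lo:g}, {hi:g}] 1/s",
                stacklevel=2,
            )

    def with_clearance(self, k_el_ab: float) -> "ModelParams":
        """Return a copy with the antibody clearance rate replaced."""
        kw = {f.name: getattr(self, f.name) for f in fields(self)}
        kw["k_el_ab"] = k_el_ab
        return ModelParams(**kw)


@dataclass(frozen=True)
class ModelState:
    """State of the system at one time point (molar except ``r``)."""

    tnf: float       # free TNF-α, M
    r: float         # bound receptor fraction, dimensionless
    ab: float = 0.0  # free antibody, M
    cx: float = 0.0  # antibody–TNF complex, M

    def __post_init__(self) -> None:
        self.validate(strict=True)

    def validate(self, strict: bool = True, clamp_tol: float = NEGATIVE_UNDERSHOOT_TOL) -> None:
        """Check positivity and ``0 <= r <= 1``.

        ``strict=False`` downgrades violations beyond the undershoot tolerance
        to warnings, which is what the integrator uses mid-run.
        """
        problems = []
        for name, value in (("tnf", self.tnf), ("ab", self.ab), ("cx", self.cx)):
            if not math.isfinite(value):
                raise ValueError(f"non-finite state component {name}={value!r}")
            if value < -clamp_tol:
                problems.append(f"{name}={value:g} < 0")
        if not math.isfinite(self.r):
            raise ValueError(f"non-finite state component r={self.r!r}")
        if self.r < -clamp_tol or self.r > 1.0 + 1e-9:
            problems.append(f"r={self.r:g} outside [0, 1]")
        if problems:
            msg = "invalid model state: " + "; ".join(problems)
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    def as_array(self) -> np.ndarray:
        return np.array([self.tnf, self.r, self.ab, self.cx], dtype=float)

    @classmethod
    def from_array(cls, y, strict: bool = False) -> "ModelState":
        L, r, A, C = (float(v) for v in y)
        obj = object.__new__(cls)
        object.__setattr__(obj, "tnf", L)
        object.__setattr__(obj, "r", r)
        object.__setattr__(obj, "ab", A)
        object.__setattr__(obj, "cx", C)
        obj.validate(strict=strict)
        return obj


def _state_array(state) -> np.ndarray:
    if isinstance(state, ModelState):
        return state.as_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"expected 4 state components, got shape {y.shape}")
    return y


def _input_rate(drug_input_rate, t: float) -> float:
    if drug_input_rate is None:
        return 0.0
    w = float(drug_input_rate(t)) if callable(drug_input_rate) else float(drug_input_rate)
    if not math.isfinite(w):
        raise ValueError(f"drug input rate at t={t} is not finite: {w!r}")
    if w < 0:
        raise ValueError(f"drug input rate at t={t} is negative: {w:g}")
    return w


def rhs_full(t, state, params: ModelParams, drug_input_rate=None) -> np.ndarray:
    """Derivatives of the dynamic-production system ``(dL, dr, dA, dC)``.

    TNF-α production exactly balances the three loss routes (receptor
    internalisation, complex degradation, direct clearance), so
    ``dL + r_tot*dr + dC == 0`` identically for any state and input.
    """
    L, r, A, C = _state_array(state)
    if not np.all(np.isfinite([L, r, A, C])):
        raise ValueError(f"non-finite state at t={t}: {(L, r, A, C)}")
    p = params
    w = _input_rate(drug_input_rate, t)
    bind_r = p.k_on * (1.0 - r) * L          # receptor association flux / r_tot
    bind_a = p.k_on_ab * L * A               # antibody association flux
    dL = (
        p.k_int * r * p.r_tot
        + p.k_el_cx * C
        - bind_r * p.r_tot
        + p.k_off * p.r_tot * r
        - bind_a
        + p.k_off_ab * C
    )
    dr = bind_r - p.k_off * r - p.k_int * r
    dA = w - bind_a + p.k_off_ab * C - p.k_el_ab * A
    dC = bind_a - p.k_off_ab * C - p.k_el_cx * C
    return np.array([dL, dr, dA, dC])


def rhs_constant_production(
    t, state, params: ModelParams, omega1: float, drug_input_rate=None
) -> np.ndarray:
    """Derivatives of the constant-production system.

    Identical to :func:`rhs_full` except in the ``L`` equation, where a fixed
    zeroth-order production ``omega1`` (M/s) and first-order clearance
    ``k_el_tnf * L`` replace the dynamic production terms.
    """
    if omega1 < 0:
        raise ValueError(f"omega1 must be non-negative, got {omega1:g}")
    L, r, A, C = _state_array(state)
    p = params
    d = rhs_full(t, (L, r, A, C), p, drug_input_rate)
    d[0] += (
        omega1
        - p.k_el_tnf * L
        - (p.k_int * r * p.r_tot + p.k_el_cx * C)
    )
    return d


def rhs_reduced(
    t, reduced_state, params: ModelParams, total_pool: float, drug_input_rate=None
) -> np.ndarray:
    """Derivatives ``(dr, dA, dC)`` of the conservation-reduced system.

    ``L`` is reconstructed from the conserved TNF pool as
    ``L = total_pool - r_tot*r - C``; a negative reconstruction signals a
    conservation violation and raises.
    """
    r, A, C = (float(v) for v in reduced_state)
    p = params
    L = total_pool - p.r_tot * r - C
    if L < -NEGATIVE_UNDERSHOOT_TOL:
        raise ValueError(
            f"conservation violation at t={t}: reconstructed L={L:g} < 0 "
            f"(total_pool={total_pool:g}, r={r:g}, C={C:g})"
        )
    L = max(L, 0.0)
    d = rhs_full(t, (L, r, A, C), p, drug_input_rate)
    return d[1:]


def jac_full(t, state, params: ModelParams, drug_input_rate=None) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_full` (used by the implicit solver)."""
    L, r, A, C = _state_array(state)
    p = params
    return np.array(
        [
            [
                -p.k_on * p.r_tot * (1.0 - r) - p.k_on_ab * A,
                p.k_int * p.r_tot + p.k_on * p.r_tot * L + p.k_off * p.r_tot,
                -p.k_on_ab * L,
                p.k_el_cx + p.k_off_ab,
            ],
            [p.k_on * (1.0 - r), -p.k_on * L - p.k_off - p.k_int, 0.0, 0.0],
            [-p.k_on_ab * A, 0.0, -p.k_on_ab * L - p.k_el_ab, p.k_off_ab],
            [p.k_on_ab * A, 0.0, p.k_on_ab * L, -p.k_off_ab - p.k_el_cx],
        ]
    )


def jac_constant_production(
    t, state, params: ModelParams, omega1: float, drug_input_rate=None
) -> np.ndarray:
    L, r, A, C = _state_array(state)
    p = params
    J = jac_full(t, state, p, drug_input_rate)
    # L-row: omega1 - k_on r_tot (1-r) L + k_off r_tot r - k_on_ab L A + k_off_ab C - k_el_tnf L
    J[0, 0] = -p.k_on * p.r_tot * (1.0 - r) - p.k_on_ab * A - p.k_el_tnf
    J[0, 1] = p.k_on * p.r_tot * L + p.k_off * p.r_tot
    J[0, 3] = p.k_off_ab
    return J


def jac_reduced(
    t, reduced_state, params: ModelParams, total_pool: float, drug_input_rate=None
) -> np.ndarray:
    r, A, C = (float(v) for v in reduced_state)
    p = params
    L = max(total_pool - p.r_tot * r - C, 0.0)
    return np.array(
        [
            [
                -p.k_on * L - p.k_on * (1.0 - r) * p.r_tot - p.k_off - p.k_int,
                0.0,
                -p.k_on * (1.0 - r),
            ],
            [
                p.k_on_ab * A * p.r_tot,
                -p.k_on_ab * L - p.k_el_ab,
                p.k_on_ab * A + p.k_off_ab,
            ],
            [
                -p.k_on_ab * A * p.r_tot,
                p.k_on_ab * L,
                -p.k_on_ab * A - p.k_off_ab - p.k_el_cx,
            ],
        ]
    )


def conserved_total(state, params: ModelParams) -> float:
    """Total TNF pool ``L + r_tot*r + C`` (M), invariant under dynamic production."""
    L, r, A, C = _state_array(state)
    return L + params.r_tot * r + C


@dataclass(frozen=True)
class EquilibriumResult:
    """Drug-free equilibria of the dynamic-production system.

    With no antibody (``A = C = 0``) the equilibrium receptor occupancies are
    the roots of ``a r² + b r + c = 0`` with ``a = k_on * r_tot``,
    ``b = -k_on (P0 + r_tot) - k_off - k_int`` and ``c = k_on * P0`` where
    ``P0`` is the conserved TNF pool; the TNF level follows from
    ``L* = P0 - r_tot * r*``.  Exactly one root is normally admissible
    (``0 <= r* <= 1`` and ``0 <= L* <= P0``).
    """

    a: float
    b: float
    c: float
    r1_star: float
    r2_star: float
    L1_star: float
    L2_star: float
    total_pool: float
    #: 1 or 2 when exactly one root is admissible, else None
    meaningful_root: int | None

    @property
    def r_star(self) -> float:
        if self.meaningful_root is None:
            raise ValueError("no unique biologically admissible equilibrium")
        return self.r1_star if self.meaningful_root == 1 else self.r2_star

    @property
    def L_star(self) -> float:
        if self.meaningful_root is None:
            raise ValueError("no unique biologically admissible equilibrium")
        return self.L1_star if self.meaningful_root == 1 else self.L2_star


def drug_free_equilibria(
    params: ModelParams, L0: float, r0: float, C0: float = 0.0
) -> EquilibriumResult:
    """Closed-form equilibria of the drug-free dynamic-production system.

    Selection of the meaningful pair is by the admissibility test
    (``r* in [0, 1]``, ``L* in [0, P0]``) rather than by a root-sign
    convention, so it is correct for arbitrary positive parameters.
    """
    p = params
    P0 = L0 + p.r_tot * r0 + C0
    a = p.k_on * p.r_tot
    b = -p.k_on * (P0 + p.r_tot) - p.k_off - p.k_int
    c = p.k_on * P0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError(f"negative discriminant {disc:g}: no real drug-free equilibrium")
    sq = math.sqrt(disc)
    r1 = (-b + sq) / (2.0 * a)
    r2 = (-b - sq) / (2.0 * a)
    L1 = P0 - p.r_tot * r1
    L2 = P0 - p.r_tot * r2
    tol = 1e-12 * max(1.0, abs(P0))
    admissible = [
        -1e-12 <= r <= 1.0 + 1e-12 and -tol <= L <= P0 + tol
        for r, L in ((r1, L1), (r2, L2))
    ]
    if admissible[0] and not admissible[1]:
        root = 1
    elif admissible[1] and not admissible[0]:
        root = 2
    elif all(admissible) and math.isclose(r1, r2, rel_tol=1e-9, abs_tol=1e-15):
        root = 2  # double root: the single pair, reported twice
    else:
        root = None
        warnings.warn(
            "drug-free equilibrium selection is ambiguous: "
            f"{sum(admissible)} admissible roots (r1={r1:g}, r2={r2:g})",
            stacklevel=2,
        )
    return EquilibriumResult(
        a=a, b=b, c=c,
        r1_star=r1, r2_star=r2, L1_star=L1, L2_star=L2,
        total_pool=P0, meaningful_root=root,
    )


def equilibrium_bound_fraction(L: float, params: ModelParams) -> float:
    """Quasi-steady receptor occupancy at TNF level ``L``.

    ``r = k_on L / (k_on L + k_off + k_int)`` — monotone in ``L``, in [0, 1).
    """
    if L < 0:
        raise ValueError(f"L must be non-negative, got {L:g}")
    if math.isinf(L):
        return 1.0
    p = params
    return p.k_on * L / (p.k_on * L + p.k_off + p.k_int)


def production_rate_at_equilibrium(
    params: ModelParams, L_eq: float, r_eq: float, C_eq: float = 0.0
) -> float:
    """Zeroth-order TNF-α production (M/s) that holds a given state stationary.

    Balances the three loss routes: receptor internalisation, complex
    degradation and direct clearance.  Used to calibrate the
    constant-production system to a disease equilibrium.
    """
    if min(L_eq, r_eq, C_eq) < 0:
        raise ValueError("equilibrium components must be non-negative")
    p = params
    return p.k_int * r_eq * p.r_tot + p.k_el_cx * C_eq + p.k_el_tnf * L_eq


@dataclass(frozen=True)
class TheoreticalBounds:
    """A-priori trajectory bounds implied by the model structure."""

    r_max: float      # receptor occupancy never exceeds 1
    ab_cx_max: float  # bound on A + C (and hence each separately), M
    tnf_max: float    # free TNF-α never exceeds the conserved pool, M


def theoretical_bounds(
    init: ModelState, params: ModelParams, omega_star: float
) -> TheoreticalBounds:
    """Uniform bounds on every trajectory of the dynamic-production system.

    ``omega_star`` is the maximal drug input rate (M/s).  ``A + C`` is bounded
    by ``max(A0 + C0, omega_star / min(k_el_ab, k_el_cx))`` and ``L`` by the
    conserved pool.
    """
    if omega_star < 0:
        raise ValueError(f"omega_star must be non-negative, got {omega_star:g}")
    p = params
    delta = min(p.k_el_ab, p.k_el_cx)
    ac0 = init.ab + init.cx
    return TheoreticalBounds(
        r_max=1.0,
        ab_cx_max=max(ac0, omega_star / delta),
        tnf_max=conserved_total(init, p),
    )
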