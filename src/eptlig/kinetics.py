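"""Forward kinetics of templated EPT ligation.

The model: ligation proceeds only within the ternary complex (template
bound by both the EPT donor and the amino acceptor), and only through the
unprotonated amine. Hybridization is fast relative to the chemistry, so
occupancy is treated as a quasi-equilibrium that is re-solved as the
composition evolves. The EPT electrophile hydrolyses in parallel with
first-order constant k_hyd (hours-scale half-life), which caps the
attainable yield.

Acceptor consumption therefore follows

    dB/dt = -k_chem * f_unprot(pKa, pH) * occ(t) * B(t)

where occ(t) is the ternary occupancy of the acceptor pool recomputed with
the surviving active-EPT total, and active EPT decays as exp(-k_hyd t)
(hydrolysis is applied equally to free and bound EPT by default; a
protection factor for the bound state is exposed). In the pseudo-first-
order regime (occupancy and protonation gates constant) the system has the
closed form

    B/B0 = exp(-(k0/k_hyd) (1 - exp(-k_hyd t))),   plateau = 1 - exp(-k0/k_hyd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import equilibria
from .equilibria import ReactionConditions, unprotonated_fraction
from .errors import ConfigurationError, DomainError
from .strands import Strand


@dataclass(frozen=True)
class KineticParams:
    """Rate parameters of one ligation system.

    k_chem : min^-1
        Intrinsic ligation rate inside the ternary complex for the
        unprotonated amine.
    k_hyd : min^-1
        EPT hydrolysis rate (ln2 / half-life).
    pKa : unitless
        pKa of the acceptor's terminal amine.
    k_app_override : min^-1 or None
        If set, bypasses the gating model and uses this apparent constant
        directly.
    ept_protection : unitless
        Multiplier on k_hyd for template-bound EPT (1 = no protection).
    inactive_fraction : fraction
        Acceptor subpopulation that never reacts; a phenomenological knob
        for sub-unity plateaus with no mechanistic claim attached.
    """

    k_chem: float
    k_hyd: float = 0.0
    pKa: float = 7.8
    k_app_override: float | None = None
    ept_protection: float = 1.0
    inactive_fraction: float = 0.0

    def __post_init__(self):
        for name in ("k_chem", "k_hyd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.k_app_override is not None and self.k_app_override < 0:
            raise DomainError("k_app_override must be non-negative")
        if not 0 <= self.inactive_fraction < 1:
            raise DomainError("inactive_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TimeCourse:
    """Sampled reaction progress.

    times in minutes (non-decreasing, starting at 0 for simulations);
    frac_amino_remaining is C/C0 of the acceptor strand; frac_product the
    ligated fraction; frac_ept_active the surviving electrophile fraction.
    """

    times: np.ndarray
    frac_amino_remaining: np.ndarray | None = None
    frac_product: np.ndarray | None = None
    frac_ept_active: np.ndarray | None = None
    provenance: str = "user"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if np.any(np.diff(t) < 0):
            raise DomainError("times must be non-decreasing")
        for name in ("frac_amino_remaining", "frac_product", "frac_ept_active"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != t.shape:
                    raise DomainError(f"{name} must match times in shape")
                if np.any(v < -1e-12) or np.any(v > 1 + 1e-9):
                    raise DomainError(f"{name} must lie in [0, 1]")
        if self.frac_amino_remaining is not None and self.frac_product is not None:
            if np.any(self.frac_amino_remaining + self.frac_product > 1 + 1e-9):
                raise DomainError("remaining + product fractions exceed 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LigationSystem:
    """A complete description of one templated ligation reaction."""

    cond: ReactionConditions
    params: KineticParams
    K_A: float | None = None  # donor(EPT)-template association constant, M^-1
    K_B: float | None = None  # acceptor(amino)-template association constant, M^-1
    template_present: bool = True
    cooperativity: float = 1.0
    strands: tuple[Strand, Strand, Strand] | None = None

    def _require_K(self):
        if self.K_A is None or self.K_B is None:
            raise ConfigurationError(
                "K_A and K_B are required (supply association constants or a "
                "k_app_override)"
            )


def _occupancy(system: LigationSystem, ept_total: float, amino_total: float) -> float:
    """Ternary occupancy of the acceptor pool at the given instantaneous
    totals (quasi-equilibrium)."""
    if amino_total <= 0:
        return 0.0
    cond = ReactionConditions(
        pH=system.cond.pH,
        temperature_c=system.cond.temperature_c,
        conc_ept=ept_total,
        conc_amino=amino_total,
        conc_template=system.cond.conc_template,
        mg_mM=system.cond.mg_mM,
    )
    res = equilibria.ternary_fractions(
        system.K_A, system.K_B, cond, cooperativity=system.cooperativity
    )
    return res.fraction_of("ternary_TAB", "amino")


def effective_k_app(system: LigationSystem) -> float:
    """Apparent first-order constant at t = 0 (min^-1).

    k_app = k_chem * unprotonated_fraction(pKa, pH) * (acceptor ternary
    occupancy at the initial composition). Zero without a template; the
    override short-circuits the gates.
    """
    if not system.template_present:
        return 0.0
    p = system.params
    if p.k_app_override is not None:
        return p.k_app_override
    system._require_K()
    gate_pH = unprotonated_fraction(p.pKa, system.cond.pH)
    occ = _occupancy(system, system.cond.conc_ept, system.cond.conc_amino)
    return p.k_chem * gate_pH * occ


def closed_form_competing(k0: float, k_hyd: float, t: float | np.ndarray):
    """Analytic competing-hydrolysis solution.

    Returns (frac_amino_remaining, plateau_yield) for acceptor decay at
    initial apparent rate k0 while the electrophile decays at k_hyd:
    B/B0 = exp(-(k0/k_hyd)(1 - exp(-k_hyd t))); as t -> inf the yield
    plateaus at 1 - exp(-k0/k_hyd). k_hyd = 0 reduces to exp(-k0 t).
    """
    if k0 < 0 or k_hyd < 0:
        raise DomainError("rate constants must be non-negative")
    t = np.asarray(t, dtype=float)
    if k_hyd == 0.0:
        remaining = np.exp(-k0 * t)
        plateau = 1.0 if k0 > 0 else 0.0
    else:
        remaining = np.exp((k0 / k_hyd) * np.expm1(-k_hyd * t))
        plateau = 1.0 - np.exp(-k0 / k_hyd)
    if remaining.ndim == 0:
        remaining = float(remaining)
    return remaining, float(plateau)


def simulate_ept_decay(k_hyd: float, times: np.ndarray) -> TimeCourse:
    """Exponential loss of active electrophile: frac = exp(-k_hyd t);
    half-life ln2/k_hyd."""
    if k_hyd < 0:
        raise DomainError("k_hyd must be non-negative")
    t = np.asarray(times, dtype=float)
    return TimeCourse(
        times=t,
        frac_ept_active=np.exp(-k_hyd * t),
        provenance="closed_form",
        meta={"k_hyd": k_hyd, "half_life_min": np.inf if k_hyd == 0 else np.log(2) / k_hyd},
    )


def simulate_ligation(system: LigationSystem, times: np.ndarray) -> TimeCourse:
    """Integrate the gated ligation model on the given time grid (min).

    The acceptor ODE dB/dt = -k_app(t) B is integrated with an adaptive
    explicit Runge-Kutta method (rtol 1e-9, atol 1e-12), where k_app(t)
    re-evaluates the ternary occupancy with the surviving active-EPT pool
    and the current acceptor total. Product is B0 - B (mass conserved); an
    inactive acceptor fraction, if set, is excluded from the reactive pool.
    """
    t = np.asarray(times, dtype=float)
    if len(t) == 0 or t[0] != 0:
        raise DomainError("time grid must start at 0")
    if np.any(np.diff(t) < 0):
        raise DomainError("times must be non-decreasing")
    p = system.params
    B0 = system.cond.conc_amino
    active0 = 1.0 - p.inactive_fraction

    ept_active = np.exp(-p.k_hyd * t)
    if not system.template_present or B0 == 0 or p.k_chem == 0 and p.k_app_override is None:
        remaining = np.ones_like(t)
        return TimeCourse(
            times=t,
            frac_amino_remaining=remaining,
            frac_product=1.0 - remaining,
            frac_ept_active=ept_active,
            provenance="simulated",
        )

    gate_pH = unprotonated_fraction(p.pKa, system.cond.pH) if p.k_app_override is None else 1.0
    if p.k_app_override is None:
        system._require_K()

    def k_app_at(time, b_frac):
        if p.k_app_override is not None:
            return p.k_app_override * np.exp(-p.k_hyd * time)
        ept_total = system.cond.conc_ept * np.exp(-p.k_hyd * p.ept_protection * time)
        occ = _occupancy(system, ept_total, max(b_frac, 1e-30) * B0 * active0)
        return p.k_chem * gate_pH * occ

    def rhs(time, y):
        return [-k_app_at(time, y[0]) * y[0]]

    if len(t) == 1:
        b = np.array([1.0])
    else:
        sol = solve_ivp(
            rhs,
            t_span=(0.0, float(t[-1])),
            y0=[1.0],
            t_eval=t,
            method="RK45",
            rtol=1e-9,
            atol=1e-12,
        )
        if not sol.success:
            raise DomainError(f"integration failed: {sol.message}")
        b = np.clip(sol.y[0], 0.0, 1.0)

    remaining = 1.0 - active0 * (1.0 - b)
    return TimeCourse(
        times=t,
        frac_amino_remaining=remaining,
        frac_product=1.0 - remaining,
        frac_ept_active=ept_active,
        provenance="simulated",
        meta={"k_app_t0": effective_k_app(system)},
    )
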