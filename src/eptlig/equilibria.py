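"""Equilibrium speciation of the three-strand system and amine protonation.

The reactive species in templated EPT ligation is the ternary complex TAB:
template T simultaneously bound by the EPT donor A and the amino acceptor B.
With association constants K_A (T+A) and K_B (T+B) and an optional
cooperativity factor omega, the equilibria are

    [TA]  = K_A [T][A]
    [TB]  = K_B [T][B]
    [TAB] = omega K_A K_B [T][A][B]

and the speciation follows from the three strand mass balances. Because the
binding polynomial is monotone in free template, the system reduces to a
one-dimensional bisection on [T] with closed-form elimination of [A] and
[B] at each step - bracketing is guaranteed and no starting guess is needed.

The fraction of acceptor amine that is nucleophilic (unprotonated) follows
the Henderson-Hasselbalch relation 1/(1 + 10^(pKa - pH)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConvergenceError, DomainError

#: Reported pKa values for the terminal amino groups by amine class.
DEFAULT_PKA = {
    "5p_amino": 7.8,
    "3p_amino_dna": 7.7,
    "3p_amino_rna": 7.0,
}


@dataclass(frozen=True)
class ProtonationModel:
    """pKa registry keyed by amine class; entries may be overridden."""

    pka: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self):
        for k, v in self.pka.items():
            if not 0 < v < 14:
                raise DomainError(f"pKa for {k!r} must be in (0, 14), got {v}")

    def unprotonated_fraction(self, amine_class: str, pH: float) -> float:
        return unprotonated_fraction(self.pka[amine_class], pH)


def unprotonated_fraction(pKa: float, pH: float) -> float:
    """Fraction of amine in the free-base (nucleophilic) form.

    Henderson-Hasselbalch: f = 1 / (1 + 10**(pKa - pH)); strictly
    increasing in pH, equal to 1/2 at pH = pKa.
    """
    for name, v in (("pKa", pKa), ("pH", pH)):
        if not (math.isfinite(v) and 0 < v < 14):
            raise DomainError(f"{name} must be a finite value in (0, 14), got {v}")
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


@dataclass(frozen=True)
class ReactionConditions:
    """Ligation reaction conditions.

    Concentrations are total strand concentrations in molar; mg_mM is an
    annotation only (no salt correction is applied).
    """

    pH: float = 8.0
    temperature_c: float = 25.0
    conc_ept: float = 4e-6
    conc_amino: float = 2e-6
    conc_template: float = 4e-6
    mg_mM: float = 10.0

    def __post_init__(self):
        if not 0 <= self.pH <= 14:
            raise DomainError(f"pH must be in [0, 14], got {self.pH}")
        for name in ("conc_ept", "conc_amino", "conc_template"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


_SPECIES = ("free_template", "free_ept", "free_amino", "duplex_TA", "duplex_TB", "ternary_TAB")
_TOTALS_OF = {
    "template": ("free_template", "duplex_TA", "duplex_TB", "ternary_TAB"),
    "ept": ("free_ept", "duplex_TA", "ternary_TAB"),
    "amino": ("free_amino", "duplex_TB", "ternary_TAB"),
}


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium concentrations (M) of all six species plus diagnostics.

    ``residual`` is the worst relative mass-balance violation across the
    three strands.
    """

    free_template: float
    free_ept: float
    free_amino: float
    duplex_TA: float
    duplex_TB: float
    ternary_TAB: float
    totals: dict[str, float]
    residual: float

    def concentration(self, species: str) -> float:
        if species not in _SPECIES:
            raise DomainError(f"unknown species {species!r}; choose from {_SPECIES}")
        return getattr(self, species)

    def fraction_of(self, species: str, reference: str) -> float:
        """Fraction of the ``reference`` strand pool found in ``species``.

        reference is one of ``template``, ``ept`` (donor), ``amino``
        (acceptor) or ``limiting`` (the strand with the smallest total).
        Returns 0 when the reference total is zero.
        """
        ref = self._resolve_reference(reference)
        total = self.totals[ref]
        if total == 0:
            return 0.0
        if species not in _TOTALS_OF[ref]:
            raise DomainError(f"species {species!r} contains no {ref} strand")
        return self.concentration(species) / total

    def _resolve_reference(self, reference: str) -> str:
        if reference == "limiting":
            positive = {k: v for k, v in self.totals.items() if v > 0}
            if not positive:
                return "template"
            return min(positive, key=positive.get)
        if reference not in _TOTALS_OF:
            raise DomainError(f"unknown reference {reference!r}")
        return reference

    @property
    def ternary_fraction_limiting(self) -> float:
        """Headline number: fraction of the limiting strand in the ternary
        complex."""
        return self.fraction_of("ternary_TAB", "limiting")


def _free_AB(T: float, K_A: float, K_B: float, c: float, A_tot: float, B_tot: float):
    """Free donor and acceptor at fixed free template.

    With a1 = 1 + K_A T, b1 = 1 + K_B T and c = omega K_A K_B T, the donor
    balance gives A = A_tot / (a1 + c B) and substituting into the acceptor
    balance yields a quadratic in B with exactly one non-negative root.
    """
    a1 = 1.0 + K_A * T
    b1 = 1.0 + K_B * T
    if c == 0.0:
        return A_tot / a1, B_tot / b1
    # c*b1*B^2 + (a1*b1 + c*(A_tot - B_tot))*B - B_tot*a1 = 0
    # qa > 0 and qc < 0, so exactly one root is positive; use the
    # cancellation-free form via q = -(qb + sign(qb) sqrt(disc))/2
    qa = c * b1
    qb = a1 * b1 + c * (A_tot - B_tot)
    qc = -B_tot * a1
    disc = math.sqrt(max(qb * qb - 4.0 * qa * qc, 0.0))
    q = -0.5 * (qb + math.copysign(disc, qb))
    B = max(q / qa, qc / q if q != 0 else 0.0)
    B = min(max(B, 0.0), B_tot)
    A = A_tot / (a1 + c * B)
    return A, B


def ternary_fractions(
    K_A: float,
    K_B: float,
    cond: ReactionConditions,
    cooperativity: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciationResult:
    """Solve the T/A/B mass-balance equilibrium.

    Parameters
    ----------
    K_A, K_B : float
        Association constants (M^-1) of the donor-template and
        acceptor-template duplexes.
    cond : ReactionConditions
        Total concentrations (the pH/temperature fields are carried as
        annotations; the constants are assumed valid at ``temperature_c``).
    cooperativity : float
        omega factor multiplying K_A*K_B in the ternary complex; 1 means
        independent binding sites.

    Returns a :class:`SpeciationResult` with mass balances satisfied to a
    relative residual <= 1e-9.
    """
    if K_A < 0 or K_B < 0:
        raise DomainError("association constants must be non-negative")
    if not cooperativity > 0:
        raise DomainError("cooperativity must be positive")
    T_tot, A_tot, B_tot = cond.conc_template, cond.conc_ept, cond.conc_amino
    totals = {"template": T_tot, "ept": A_tot, "amino": B_tot}

    if T_tot == 0.0:
        return _assemble(0.0, A_tot, B_tot, K_A, K_B, 0.0, totals)

    def template_balance(T: float) -> float:
        c = cooperativity * K_A * K_B * T
        A, B = _free_AB(T, K_A, K_B, c, A_tot, B_tot)
        bound = K_A * T * A + K_B * T * B + c * A * B
        return T + bound - T_tot

    lo, hi = 0.0, T_tot
    f_lo = template_balance(lo)  # = -T_tot < 0
    f_hi = template_balance(hi)  # >= 0
    if f_lo > 0 or f_hi < 0:  # pragma: no cover - cannot happen for valid input
        raise ConvergenceError("template balance does not bracket a root")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if template_balance(mid) > 0:
            hi = mid
        else:
            lo = mid
        # relative to the bracket location so tiny free-template solutions
        # (very strong binding) are still resolved
        if hi - lo <= tol * max(hi, 1e-300):
            break
    T = 0.5 * (lo + hi)
    c = cooperativity * K_A * K_B * T
    A, B = _free_AB(T, K_A, K_B, c, A_tot, B_tot)
    result = _assemble(T, A, B, K_A, K_B, c, totals)
    if result.residual > 1e-9:
        raise ConvergenceError(
            f"speciation solver residual {result.residual:.3e} exceeds 1e-9",
            residual=result.residual,
        )
    return result


def _assemble(T, A, B, K_A, K_B, c, totals) -> SpeciationResult:
    TA = K_A * T * A
    TB = K_B * T * B
    TAB = c * A * B
    recovered = {
        "template": T + TA + TB + TAB,
        "ept": A + TA + TAB,
        "amino": B + TB + TAB,
    }
    residual = 0.0
    for k, tot in totals.items():
        if tot > 0:
            residual = max(residual, abs(recovered[k] - tot) / tot)
        else:
            residual = max(residual, abs(recovered[k]))
    return SpeciationResult(
        free_template=T,
        free_ept=A,
        free_amino=B,
        duplex_TA=TA,
        duplex_TB=TB,
        ternary_TAB=TAB,
        totals=dict(totals),
        residual=residual,
    )


def ternary_occupancy_report(
    K_A: float,
    K_B: float,
    cond: ReactionConditions,
    cooperativity: float = 1.0,
) -> pd.DataFrame:
    """Ternary-complex occupancy framed against every reference species.

    A statement like "98.8% ternary complex" is ambiguous: the percentage
    depends on whether it is taken over the template, the donor, the
    acceptor, or the limiting strand. This report computes all four
    framings (percent of each reference pool residing in TAB).
    """
    res = ternary_fractions(K_A, K_B, cond, cooperativity=cooperativity)
    rows = []
    limiting = res._resolve_reference("limiting")
    for ref in ("template", "ept", "amino", "limiting"):
        resolved = res._resolve_reference(ref)
        rows.append(
            {
                "reference": ref,
                "strand": resolved,
                "total_M": res.totals[resolved],
                "ternary_percent": 100.0 * res.fraction_of("ternary_TAB", ref),
                "is_limiting": resolved == limiting,
            }
        )
    return pd.DataFrame(rows)
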