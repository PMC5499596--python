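"""Duplex hybridization thermodynamics.

Implements the two-state (all-or-none) description of probe/template duplex
formation: nearest-neighbor prediction of (dH, dS), van't Hoff evaluation of
the association constant K(T), melting-temperature calculation, and
least-squares fitting of (dH, dS) from a melting curve.

Conventions
-----------
* dH in kcal/mol, dS in cal/(mol K), both negative for a forming duplex.
* R = 1.9872e-3 kcal/(mol K); temperatures are kelvin internally and
  degrees Celsius at every public interface.
* Non-self-complementary duplex with equal strand totals C per strand;
  the duplex fraction theta is defined on the limiting strand, so
  K = theta / ((1 - theta)^2 * C).

The shipped nearest-neighbor table is the unified DNA/DNA dinucleotide
parameter set (SantaLucia-type), stored as editable delimited text; no salt
correction is applied by default, but an additive dS correction hook is
provided.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import (
    AlphabetError,
    ComplementarityError,
    DomainError,
    NonIdentifiabilityError,
    RangeError,
)
from .strands import DNA_ALPHABET, Strand, reverse_complement

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3

CELSIUS_OFFSET = 273.15

THERMO_SOURCES = ("nearest_neighbor", "melt_fit", "user_supplied")


def celsius_to_kelvin(t_c: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(t_c, dtype=float) + CELSIUS_OFFSET if np.ndim(t_c) else float(t_c) + CELSIUS_OFFSET


@dataclass(frozen=True)
class DuplexThermo:
    """Two-state thermodynamic parameters of one probe/template duplex.

    dH : kcal/mol, dS : cal/(mol K); both must be negative (the duplex
    forms exothermically with an entropic penalty). ``source`` records how
    the numbers were obtained.
    """

    dH: float
    dS: float
    source: str = "user_supplied"

    def __post_init__(self):
        if not (np.isfinite(self.dH) and np.isfinite(self.dS)):
            raise DomainError("dH and dS must be finite")
        if self.dH >= 0 or self.dS >= 0:
            raise DomainError(
                f"a forming duplex requires dH < 0 and dS < 0; got dH={self.dH}, dS={self.dS}"
            )
        if self.source not in THERMO_SOURCES:
            raise DomainError(f"unknown thermo source {self.source!r}")

    def dG(self, temperature_c: float) -> float:
        """Free energy of duplex formation (kcal/mol) at ``temperature_c`` (C)."""
        t = celsius_to_kelvin(temperature_c)
        return self.dH - t * self.dS / 1000.0

    def with_dS_correction(self, delta_dS_cal: float) -> "DuplexThermo":
        """Return a copy with an additive entropy correction (e.g. a user's
        salt adjustment, cal/(mol K))."""
        return DuplexThermo(self.dH, self.dS + delta_dS_cal, source=self.source)


class NNParameterTable:
    """Dinucleotide nearest-neighbor parameters for a DNA/DNA duplex.

    Maps each of the 16 dinucleotide steps (read 5'->3' on the probe) to a
    (dH step, dS step) pair, plus the two terminal-pair initiation terms
    (``init_AT``, ``init_GC``). All step enthalpies must be negative.
    """

    STEPS = tuple(a + b for a in "ACGT" for b in "ACGT")
    INITS = ("init_AT", "init_GC")

    def __init__(self, steps: dict[str, tuple[float, float]], alphabet: str = "DNA"):
        missing = [s for s in self.STEPS + self.INITS if s not in steps]
        if missing:
            raise DomainError(f"NN table missing entries: {missing}")
        extra = [s for s in steps if s not in self.STEPS + self.INITS]
        if extra:
            raise DomainError(f"NN table has unknown entries: {extra}")
        for s in self.STEPS:
            if steps[s][0] >= 0:
                raise DomainError(f"step {s}: enthalpy must be negative, got {steps[s][0]}")
        self._steps = dict(steps)
        self.alphabet = alphabet

    def __getitem__(self, key: str) -> tuple[float, float]:
        return self._steps[key]

    @classmethod
    def from_csv(cls, path: str | Path) -> "NNParameterTable":
        df = pd.read_csv(path, comment="#")
        required = {"step", "dH_kcal", "dS_cal"}
        if not required <= set(df.columns):
            raise DomainError(f"NN table needs columns {sorted(required)}, got {list(df.columns)}")
        if df["step"].duplicated().any():
            dups = df.loc[df["step"].duplicated(), "step"].tolist()
            raise DomainError(f"duplicate NN table entries: {dups}")
        steps = {r.step: (float(r.dH_kcal), float(r.dS_cal)) for r in df.itertuples()}
        return cls(steps)

    @classmethod
    def default_dna(cls) -> "NNParameterTable":
        """The packaged unified DNA/DNA parameter set."""
        ref = importlib.resources.files("eptlig.data") / "nn_dna.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)


def _initiation(base: str) -> str:
    return "init_AT" if base in "AT" else "init_GC"


def nn_duplex_thermo(
    probe: Strand | str,
    template: Strand | str,
    params: NNParameterTable | None = None,
) -> DuplexThermo:
    """Predict duplex (dH, dS) for a probe bound to its template window.

    The probe must be perfectly complementary to a contiguous window of the
    template (antiparallel). dH is the sum of the dinucleotide step
    enthalpies along the probe plus one initiation term per terminal base
    pair; dS likewise.

    Raises
    ------
    ComplementarityError
        If no template window is a perfect complement; the error names the
        first mismatching probe position of the best-matching window.
    AlphabetError
        For non-DNA sequences (the packaged table is DNA/DNA only).
    """
    params = params or NNParameterTable.default_dna()
    pseq = probe.sequence if isinstance(probe, Strand) else probe.upper()
    tseq = template.sequence if isinstance(template, Strand) else template.upper()
    for name, seq in (("probe", pseq), ("template", tseq)):
        if not set(seq) <= DNA_ALPHABET:
            raise AlphabetError(f"{name} sequence is not plain DNA: {seq}")
    n = len(pseq)
    if n < 2:
        raise DomainError("duplex must be at least 2 bp")
    if n > len(tseq):
        raise ComplementarityError(
            f"probe ({n} nt) longer than template ({len(tseq)} nt)"
        )

    target = reverse_complement(pseq)  # what a matching template window reads 5'->3'
    best_mismatches, best_pos = None, None
    for start in range(len(tseq) - n + 1):
        window = tseq[start : start + n]
        mism = [i for i in range(n) if window[i] != target[i]]
        if not mism:
            break
        if best_mismatches is None or len(mism) < len(best_mismatches):
            best_mismatches, best_pos = mism, start
    else:
        # report the mismatch in probe coordinates (probe index n-1-i pairs
        # with window index i)
        i = best_mismatches[0]
        probe_pos = n - 1 - i
        raise ComplementarityError(
            f"probe is not complementary to any template window; best window at "
            f"template offset {best_pos} mismatches at probe position {probe_pos} "
            f"(probe base {pseq[probe_pos]} vs template base {tseq[best_pos + i]})",
            position=probe_pos,
        )

    dH = dS = 0.0
    for i in range(n - 1):
        h, s = params[pseq[i : i + 2]]
        dH += h
        dS += s
    for terminal in (pseq[0], pseq[-1]):
        h, s = params[_initiation(terminal)]
        dH += h
        dS += s
    return DuplexThermo(dH, dS, source="nearest_neighbor")


def vant_hoff_K(thermo: DuplexThermo, temperature_c: float) -> float:
    """Association constant K (M^-1) at ``temperature_c`` (C).

    K = exp(-(dH - T dS)/(R T)) with dS converted to kcal/(mol K).
    Strictly positive; strictly decreasing in T for a forming duplex.
    """
    if not np.isfinite(temperature_c):
        raise DomainError("temperature must be finite")
    t = celsius_to_kelvin(temperature_c)
    if t <= 0:
        raise DomainError(f"absolute temperature must be positive, got {t} K")
    dG = thermo.dH - t * thermo.dS / 1000.0
    return float(np.exp(-dG / (R_KCAL * t)))


def theta_two_state(K: float | np.ndarray, conc: float) -> float | np.ndarray:
    """Duplex fraction of the limiting strand at association constant K and
    per-strand total concentration ``conc`` (M), non-self-complementary
    equal-totals convention: K = theta/((1-theta)^2 conc).
    """
    x = np.asarray(K, dtype=float) * conc
    with np.errstate(divide="ignore"):
        b = 2.0 + 1.0 / x
    theta = np.where(x > 0, 2.0 / (b + np.sqrt(b * b - 4.0)), 0.0)
    return float(theta) if np.ndim(K) == 0 else theta


@dataclass(frozen=True)
class MeltingCurve:
    """An observed (or simulated) two-state melting curve.

    temperatures: strictly increasing C grid; theta: duplex fraction in
    [0,1] at each temperature; total_conc: total concentration of each
    strand (M, equal totals).
    """

    temperatures: np.ndarray
    theta: np.ndarray
    total_conc: float

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "theta", th)
        if t.shape != th.shape or t.ndim != 1:
            raise DomainError("temperatures and theta must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise DomainError("temperatures must be strictly increasing")
        if np.any(th < 0) or np.any(th > 1):
            raise DomainError("theta values must lie in [0, 1]")
        if not self.total_conc > 0:
            raise DomainError("total_conc must be positive")

    def __len__(self) -> int:
        return len(self.temperatures)


def predicted_theta(thermo: DuplexThermo, temperatures_c: np.ndarray, conc: float) -> np.ndarray:
    """Model melting curve theta(T) for given parameters."""
    t_k = np.asarray(temperatures_c, dtype=float) + CELSIUS_OFFSET
    dG = thermo.dH - t_k * thermo.dS / 1000.0
    K = np.exp(-dG / (R_KCAL * t_k))
    return theta_two_state(K, conc)


@dataclass(frozen=True)
class MeltFitResult:
    thermo: DuplexThermo
    residual_norm: float
    n_points: int


def fit_two_state_melt(curve: MeltingCurve, full_output: bool = False):
    """Least-squares (dH, dS) estimate from a melting curve.

    Initial values come from a linearized van't Hoff plot restricted to
    points with theta in [0.15, 0.85]; the final estimate is a bounded
    least-squares fit of the two-state theta(T) model (xtol 1e-10).

    Returns the fitted :class:`DuplexThermo` (and a :class:`MeltFitResult`
    with diagnostics when ``full_output`` is true).

    Raises
    ------
    NonIdentifiabilityError
        If the curve is essentially entirely melted or entirely duplexed.
    """
    if len(curve) < 6:
        raise DomainError(f"need at least 6 points, got {len(curve)}")
    th = curve.theta
    if np.all(th > 0.8):
        raise NonIdentifiabilityError("curve never melts (all theta > 0.8); dH, dS not identifiable")
    if np.all(th < 0.2):
        raise NonIdentifiabilityError("curve never forms duplex (all theta < 0.2); dH, dS not identifiable")

    # linearized initialization: ln K affine in 1/T
    mid = (th >= 0.15) & (th <= 0.85)
    if mid.sum() >= 2:
        t_k = curve.temperatures[mid] + CELSIUS_OFFSET
        K = th[mid] / ((1.0 - th[mid]) ** 2 * curve.total_conc)
        slope, intercept = np.polyfit(1.0 / t_k, np.log(K), 1)
        dH0 = -slope * R_KCAL
        dS0 = intercept * R_KCAL * 1000.0
    else:
        dH0, dS0 = -70.0, -200.0
    dH0 = min(dH0, -1e-3)
    dS0 = min(dS0, -1e-3)

    def residuals(p):
        model = predicted_theta(
            DuplexThermo(min(p[0], -1e-12), min(p[1], -1e-12)), curve.temperatures, curve.total_conc
        )
        return model - th

    sol = least_squares(
        residuals,
        x0=[dH0, dS0],
        bounds=([-500.0, -2000.0], [-1e-6, -1e-6]),
        xtol=1e-10,
        ftol=1e-14,
        gtol=1e-14,
    )
    thermo = DuplexThermo(float(sol.x[0]), float(sol.x[1]), source="melt_fit")
    result = MeltFitResult(thermo, residual_norm=float(np.linalg.norm(sol.fun)), n_points=len(curve))
    return result if full_output else thermo


def melting_temperature(thermo: DuplexThermo, total_conc: float) -> float:
    """Tm in C: the temperature at which theta = 0.5 under the equal-totals
    two-state convention, i.e. K(Tm) * total_conc = 2.

    Raises :class:`RangeError` if no root lies in (0, 120) C.
    """
    if not total_conc > 0:
        raise DomainError("total_conc must be positive")

    def f(t_c):
        return theta_two_state(vant_hoff_K(thermo, t_c), total_conc) - 0.5

    lo, hi = 1e-6, 120.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RangeError(
            f"theta = 0.5 has no solution in (0, 120) C (theta(0)={flo + 0.5:.3g}, "
            f"theta(120)={fhi + 0.5:.3g})"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))
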