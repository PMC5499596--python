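"""Synthetic-data generators for every pipeline input.

The generators emulate the study conditions of the templated-ligation
system: a 10-mer EPT donor and a 13-mer FAM-labelled amino acceptor tiling
a 23-mer template with a central nick; first-order ligation time courses
that plateau below 100%; hours-scale exponential electrophile decay
(half-lives in the 6.4-8.9 h regime); two-state melting curves for duplexes
with K around 1e9-1e10 M^-1 at 25 C; and gel lane tables whose intensity
ratios encode the true yield. Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .kinetics import TimeCourse, closed_form_competing
from .strands import Strand, reverse_complement
from .thermo import DuplexThermo, MeltingCurve, predicted_theta

#: Default measurement noise on fractional quantities (gel-quantitation
#: scale scatter), additive Gaussian.
DEFAULT_NOISE_SD = 0.02


@dataclass
class NoiseSpec:
    """Measurement-noise description for generated fractions.

    kind is ``additive_gaussian`` or ``multiplicative_gaussian``; generated
    fractions are clipped to [0, 1] and the number of clipped values is
    recorded on ``clipped`` after each application.
    """

    kind: str = "additive_gaussian"
    sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    clipped: int = 0

    def __post_init__(self):
        if self.kind not in ("additive_gaussian", "multiplicative_gaussian"):
            raise DomainError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise DomainError("noise sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator | None = None,
              clip: tuple[float, float] | None = (0.0, 1.0)) -> np.ndarray:
        """Apply noise to ``values``; counts clipped entries on self."""
        values = np.asarray(values, dtype=float)
        if self.sd == 0:
            self.clipped = 0
            return values.copy()
        rng = rng or self.rng()
        eps = rng.normal(0.0, self.sd, size=values.shape)
        if self.kind == "additive_gaussian":
            noisy = values + eps
        else:
            noisy = values * (1.0 + eps)
        if clip is not None:
            out = np.clip(noisy, *clip)
            self.clipped = int(np.sum(out != noisy))
            return out
        self.clipped = 0
        return noisy


def gen_strand_trio(
    donor_len: int = 10,
    acceptor_len: int = 13,
    seed: int = 0,
    rna: bool = False,
) -> tuple[Strand, Strand, Strand]:
    """Generate a random nicked-duplex strand trio.

    The donor (3'-EPT, default 10-mer) and acceptor (5'-amino, FAM-labelled
    13-mer) sequences are drawn uniformly; the template is the reverse
    complement of the acceptor followed by the reverse complement of the
    donor, so the two probes tile it contiguously with the nick between the
    donor's 3' end and the acceptor's 5' end.
    """
    if donor_len < 2 or acceptor_len < 2:
        raise DomainError("strand lengths must be at least 2")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU" if rna else "ACGT"))
    donor_seq = "".join(rng.choice(alphabet, size=donor_len))
    acceptor_seq = "".join(rng.choice(alphabet, size=acceptor_len))
    template_seq = reverse_complement(acceptor_seq, rna=rna) + reverse_complement(
        donor_seq, rna=rna
    )
    donor = Strand("donor", donor_seq, role="donor", end_chem="EPT_3p")
    acceptor = Strand(
        "acceptor", acceptor_seq, role="acceptor", end_chem="NH2_5p", label="FAM_3p"
    )
    template = Strand("template", template_seq, role="template")
    return donor, acceptor, template


def gen_ligation_timecourse(
    k0: float,
    k_hyd: float,
    times: np.ndarray,
    plateau_cap: float = 1.0,
    noise: NoiseSpec | None = None,
) -> TimeCourse:
    """Generate a ligation time course with plateau and noise.

    The mean product curve is plateau_cap * (1 - closed-form remaining
    fraction) under competing hydrolysis; t = 0 product is exactly 0 even
    under noise (the lane at t = 0 defines the normalization).
    """
    if k0 < 0 or k_hyd < 0:
        raise DomainError("rate constants must be non-negative")
    if not 0 < plateau_cap <= 1:
        raise DomainError("plateau_cap must be in (0, 1]")
    t = np.asarray(times, dtype=float)
    if len(t) == 0 or t[0] != 0:
        raise DomainError("time grid must start at 0")
    remaining_cf, _ = closed_form_competing(k0, k_hyd, t)
    remaining_cf = np.asarray(remaining_cf)
    if noise is not None and noise.sd > 0:
        product = noise.apply(plateau_cap * (1.0 - remaining_cf))
        product[0] = 0.0
        remaining = 1.0 - product
    else:
        # keep full floating-point precision in the remaining fraction
        # (1 - (1 - x) destroys it once x < machine epsilon)
        remaining = (1.0 - plateau_cap) + plateau_cap * remaining_cf
        product = plateau_cap * (1.0 - remaining_cf)
    return TimeCourse(
        times=t,
        frac_amino_remaining=remaining,
        frac_product=product,
        provenance="synthetic_fixture",
        meta={"k0": k0, "k_hyd": k_hyd, "plateau_cap": plateau_cap},
    )


def gen_decay_timecourse(
    half_life_min: float,
    times: np.ndarray,
    noise: NoiseSpec | None = None,
) -> TimeCourse:
    """Generate an electrophile stability curve with the given half-life."""
    if not half_life_min > 0:
        raise DomainError("half_life must be positive")
    t = np.asarray(times, dtype=float)
    k_hyd = np.log(2.0) / half_life_min
    frac = np.exp(-k_hyd * t)
    if noise is not None and noise.sd > 0:
        frac = noise.apply(frac)
    return TimeCourse(
        times=t,
        frac_ept_active=frac,
        provenance="synthetic_fixture",
        meta={"half_life_min": half_life_min, "k_hyd": k_hyd},
    )


def draw_stability_half_life(seed: int, lo_h: float = 6.4, hi_h: float = 8.9) -> float:
    """A random electrophile half-life (minutes) from the observed
    hours-scale stability range."""
    rng = np.random.default_rng(seed)
    return float(rng.uniform(lo_h, hi_h) * 60.0)


def gen_melting_curve(
    thermo: DuplexThermo,
    conc: float,
    t_grid: np.ndarray,
    noise: NoiseSpec | None = None,
) -> MeltingCurve:
    """Generate a two-state melting curve theta(T) at per-strand total
    ``conc`` (M) on the Celsius grid ``t_grid``."""
    if not conc > 0:
        raise DomainError("conc must be positive")
    t = np.asarray(t_grid, dtype=float)
    theta = predicted_theta(thermo, t, conc)
    if noise is not None and noise.sd > 0:
        theta = noise.apply(theta)
    return MeltingCurve(temperatures=t, theta=theta, total_conc=conc)


def gen_gel_table(
    true_yields: np.ndarray,
    total_intensity: float = 1000.0,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Generate a gel lane table of (i_remaining, i_product) band pairs.

    Each lane's intensity ratio i_product/(i_remaining + i_product) is
    centred on its true yield; noise perturbs the two band intensities
    independently (per-band multiplicative noise models integration error).
    """
    y = np.asarray(true_yields, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise DomainError("yields must lie in [0, 1]")
    if not total_intensity > 0:
        raise DomainError("total_intensity must be positive")
    i_prod = y * total_intensity
    i_rem = (1.0 - y) * total_intensity
    if noise is not None and noise.sd > 0:
        rng = noise.rng()
        i_rem = noise.apply(i_rem, rng=rng, clip=(0.0, np.inf))
        i_prod = noise.apply(i_prod, rng=rng, clip=(0.0, np.inf))
    return pd.DataFrame(
        {"lane": np.arange(1, len(y) + 1), "i_remaining": i_rem, "i_product": i_prod}
    )
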