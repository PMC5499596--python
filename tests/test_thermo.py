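"""Duplex thermodynamics: NN prediction, van't Hoff K, melt fitting, Tm."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eptlig import (
    DuplexThermo,
    MeltingCurve,
    NNParameterTable,
    fit_two_state_melt,
    melting_temperature,
    nn_duplex_thermo,
    vant_hoff_K,
)
from eptlig.errors import (
    AlphabetError,
    ComplementarityError,
    DomainError,
    NonIdentifiabilityError,
    RangeError,
)
from eptlig.strands import reverse_complement
from eptlig.synthetic import gen_melting_curve
from eptlig.thermo import R_KCAL, predicted_theta

# Independent copy of the unified DNA/DNA dinucleotide parameters used as
# the hand-summation oracle (dH kcal/mol, dS cal/(mol K)).
ORACLE_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2), "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3), "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0), "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4), "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
ORACLE_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def oracle_nn_sum(seq: str):
    dH = dS = 0.0
    for i in range(len(seq) - 1):
        h, s = ORACLE_NN[seq[i : i + 2]]
        dH += h
        dS += s
    for base in (seq[0], seq[-1]):
        h, s = ORACLE_INIT[base]
        dH += h
        dS += s
    return dH, dS


class TestNNDuplexThermo:
    def test_single_step_two_mer(self):
        # GC step plus two G/C initiations
        t = nn_duplex_thermo("GC", reverse_complement("GC"))
        assert t.dH == pytest.approx(-9.8 + 0.1 + 0.1, abs=1e-12)
        assert t.dS == pytest.approx(-24.4 - 2.8 - 2.8, abs=1e-12)
        assert t.source == "nearest_neighbor"

    @pytest.mark.parametrize("probe", ["GCGTACGTAC", "ATGCATTTGC", "CCCGGGAATT"])
    def test_ten_mer_matches_hand_summation(self, probe):
        template = "AAAA" + reverse_complement(probe) + "TTTT"
        t = nn_duplex_thermo(probe, template)
        dH, dS = oracle_nn_sum(probe)
        assert t.dH == pytest.approx(dH, abs=1e-12)
        assert t.dS == pytest.approx(dS, abs=1e-12)

    def test_additivity_over_shared_step_decomposition(self):
        # halves overlapping by one base partition the steps exactly; the
        # split only introduces two spurious inner initiation terms
        probe = "GATCGCGTAC"
        left, right = probe[:5], probe[4:]
        full = nn_duplex_thermo(probe, reverse_complement(probe))
        lt = nn_duplex_thermo(left, reverse_complement(left))
        rt = nn_duplex_thermo(right, reverse_complement(right))
        extra_init = [ORACLE_INIT[left[-1]], ORACLE_INIT[right[0]]]
        assert lt.dH + rt.dH - sum(h for h, _ in extra_init) == pytest.approx(
            full.dH, abs=1e-10
        )
        assert lt.dS + rt.dS - sum(s for _, s in extra_init) == pytest.approx(
            full.dS, abs=1e-10
        )

    def test_mismatch_raises_with_position(self):
        probe = "GCGTACGTAC"
        template = reverse_complement(probe)
        bad = template[:3] + ("A" if template[3] != "A" else "C") + template[4:]
        with pytest.raises(ComplementarityError) as exc:
            nn_duplex_thermo(probe, bad)
        assert exc.value.position is not None
        assert str(exc.value.position) in str(exc.value)

    def test_window_match_inside_longer_template(self):
        probe = "GCGTACGTAC"
        template = "TTTT" + reverse_complement(probe) + "GGGG"
        t1 = nn_duplex_thermo(probe, template)
        t2 = nn_duplex_thermo(probe, reverse_complement(probe))
        assert t1.dH == t2.dH and t1.dS == t2.dS

    def test_rejects_ambiguous_and_rna(self):
        with pytest.raises(AlphabetError):
            nn_duplex_thermo("GCNT", "AAGC")
        with pytest.raises(AlphabetError):
            nn_duplex_thermo("GCAU", "AUGC")


class TestVantHoff:
    def test_zero_free_energy_gives_unit_K(self):
        # pick dH, dS with dH = T*dS/1000 at 25 C
        t_k = 298.15
        dS = -100.0
        thermo = DuplexThermo(t_k * dS / 1000.0, dS)
        assert vant_hoff_K(thermo, 25.0) == pytest.approx(1.0, rel=1e-12)

    def test_printed_association_constant_from_free_energy(self):
        # dG(25 C) = -13.57 kcal/mol corresponds to K ~ 8.82e9 M^-1
        t_k = 298.15
        dS = -189.3
        dH = -13.57 + t_k * dS / 1000.0
        thermo = DuplexThermo(dH, dS)
        oracle = np.exp(13.57 / (R_KCAL * t_k))
        K = vant_hoff_K(thermo, 25.0)
        assert K == pytest.approx(oracle, rel=1e-12)
        assert K == pytest.approx(8.82e9, rel=5e-3)

    def test_monotone_decreasing_in_temperature(self, example_thermo):
        temps = np.linspace(0.0, 90.0, 40)
        Ks = [vant_hoff_K(example_thermo, t) for t in temps]
        assert all(a > b for a, b in zip(Ks, Ks[1:]))
        assert min(Ks) > 0

    def test_ln_K_affine_in_inverse_temperature(self, example_thermo):
        t_c = np.array([10.0, 40.0, 70.0])
        inv_t = 1.0 / (t_c + 273.15)
        lnK = np.log([vant_hoff_K(example_thermo, t) for t in t_c])
        # second difference along 1/T vanishes for an affine relation
        slope01 = (lnK[1] - lnK[0]) / (inv_t[1] - inv_t[0])
        slope12 = (lnK[2] - lnK[1]) / (inv_t[2] - inv_t[1])
        assert slope01 == pytest.approx(slope12, rel=1e-9)

    def test_rejects_nonfinite(self, example_thermo):
        with pytest.raises(DomainError):
            vant_hoff_K(example_thermo, float("nan"))
        with pytest.raises(DomainError):
            DuplexThermo(float("inf"), -100.0)

    def test_forming_duplex_signs_enforced(self):
        with pytest.raises(DomainError):
            DuplexThermo(10.0, -100.0)
        with pytest.raises(DomainError):
            DuplexThermo(-10.0, 100.0)


class TestMeltFit:
    def test_noiseless_round_trip(self, example_thermo):
        grid = np.arange(10.0, 90.5, 1.0)
        curve = gen_melting_curve(example_thermo, 4e-6, grid)
        fit = fit_two_state_melt(curve)
        assert fit.dH == pytest.approx(example_thermo.dH, rel=1e-3)
        assert fit.dS == pytest.approx(example_thermo.dS, rel=1e-3)
        assert fit.source == "melt_fit"

    def test_fit_K_consistent_with_generating_K(self, example_thermo):
        grid = np.arange(10.0, 90.5, 1.0)
        curve = gen_melting_curve(example_thermo, 4e-6, grid)
        fit = fit_two_state_melt(curve)
        assert vant_hoff_K(fit, 25.0) == pytest.approx(
            vant_hoff_K(example_thermo, 25.0), rel=0.02
        )

    def test_noisy_fit_recovers_K_within_tolerance(self, example_thermo):
        # 0.25 C sampling emulates continuous instrument acquisition
        from eptlig.synthetic import NoiseSpec

        grid = np.arange(10.0, 90.1, 0.25)
        true_K = vant_hoff_K(example_thermo, 25.0)
        rel_errors = []
        for rep in range(100):
            curve = gen_melting_curve(
                example_thermo, 4e-6, grid, noise=NoiseSpec(sd=0.01, seed=1000 + rep)
            )
            fit = fit_two_state_melt(curve)
            rel_errors.append(vant_hoff_K(fit, 25.0) / true_K - 1.0)
        rel_errors = np.array(rel_errors)
        assert np.all(np.abs(rel_errors) < 0.25)
        assert abs(np.median(rel_errors)) < 0.10

    def test_fully_duplexed_curve_not_identifiable(self):
        grid = np.linspace(10, 40, 10)
        curve = MeltingCurve(grid, np.ones_like(grid), 4e-6)
        with pytest.raises(NonIdentifiabilityError):
            fit_two_state_melt(curve)

    def test_fully_melted_curve_not_identifiable(self):
        grid = np.linspace(60, 90, 10)
        curve = MeltingCurve(grid, np.full_like(grid, 0.01), 4e-6)
        with pytest.raises(NonIdentifiabilityError):
            fit_two_state_melt(curve)

    def test_too_few_points_rejected(self, example_thermo):
        grid = np.array([20.0, 40.0, 60.0, 80.0])
        curve = gen_melting_curve(example_thermo, 4e-6, grid)
        with pytest.raises(DomainError):
            fit_two_state_melt(curve)


class TestMeltingTemperature:
    def test_theta_is_half_at_tm(self, example_thermo):
        conc = 4e-6
        tm = melting_temperature(example_thermo, conc)
        theta = predicted_theta(example_thermo, np.array([tm]), conc)[0]
        assert theta == pytest.approx(0.5, abs=1e-9)

    def test_tm_increases_with_concentration(self, example_thermo):
        tms = [melting_temperature(example_thermo, c) for c in (1e-7, 1e-6, 1e-5)]
        assert tms[0] < tms[1] < tms[2]

    def test_round_trip_through_melt_fit(self, example_thermo):
        conc = 4e-6
        grid = np.arange(10.0, 90.5, 1.0)
        fit = fit_two_state_melt(gen_melting_curve(example_thermo, conc, grid))
        assert melting_temperature(fit, conc) == pytest.approx(
            melting_temperature(example_thermo, conc), abs=0.1
        )

    def test_out_of_range_raises(self):
        # an extremely stable duplex has no melting transition below 120 C
        stable = DuplexThermo(-300.0, -500.0)
        with pytest.raises(RangeError):
            melting_temperature(stable, 1e-6)


class TestNNParameterTable:
    def test_default_table_complete(self):
        table = NNParameterTable.default_dna()
        for step in NNParameterTable.STEPS:
            dH, dS = table[step]
            assert dH < 0 and dS < 0

    def test_missing_entry_rejected(self):
        table = NNParameterTable.default_dna()
        steps = dict(table._steps)
        steps.pop("AA")
        with pytest.raises(DomainError):
            NNParameterTable(steps)

    def test_positive_step_enthalpy_rejected(self):
        steps = dict(NNParameterTable.default_dna()._steps)
        steps["AA"] = (1.0, -22.2)
        with pytest.raises(DomainError):
            NNParameterTable(steps)


@given(st.floats(min_value=-120.0, max_value=-20.0),
       st.floats(min_value=-400.0, max_value=-80.0))
def test_K_always_positive(dH, dS):
    thermo = DuplexThermo(dH, dS)
    assert vant_hoff_K(thermo, 25.0) > 0
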