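"""Binding generators and fits against closed-form and numerical oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from myxoquant import (
    ITCSimConfig,
    SPRSimConfig,
    affinity_ratio,
    fit_itc_one_site,
    fit_spr_steady_state,
    generate_itc_dataset,
    generate_spr_dataset,
    subtract_dilution,
)
from myxoquant.datatypes import ITCDataset, SPRDataset
from myxoquant.simulate import TWOFOLD_LADDER_M


# ------------------------------------------------------------ SPR generator

def test_spr_half_saturation_point():
    cfg = SPRSimConfig(Rmax=80.0, K_D=2e-4, concentrations=[2e-4, 4e-4, 8e-4, 1.6e-3],
                       noise_sd=0.0)
    data = generate_spr_dataset(cfg)
    assert data.response_RU[0] == pytest.approx(40.0, abs=1e-12)


def test_spr_low_concentration_limit_vanishes():
    cfg = SPRSimConfig(Rmax=100.0, K_D=1e-4,
                       concentrations=[1e-10, 1e-9, 1e-8, 1e-7], noise_sd=0.0)
    data = generate_spr_dataset(cfg)
    assert np.all(data.response_RU < 0.11)


def test_spr_noiseless_ladder_equals_closed_form():
    cfg = SPRSimConfig(Rmax=100.0, K_D=1.5e-4, concentrations=TWOFOLD_LADDER_M,
                       noise_sd=0.0)
    data = generate_spr_dataset(cfg)
    c = np.asarray(TWOFOLD_LADDER_M)
    expected = 100.0 * c / (1.5e-4 + c)  # direct formula evaluation
    assert np.allclose(data.response_RU, expected, atol=1e-12)


# ------------------------------------------------------------ ITC generator

def itc_oracle(n, kd, dh, v0_uL, inj_uL, m0, x0, dilution=0.0):
    """Independent cumulative-heat oracle.

    Solves the binding equilibrium per injection by bracketing the free
    ligand concentration numerically (no closed-form quadratic), then
    takes displacement-corrected finite differences of the cumulative
    heat.
    """
    inj = np.asarray(inj_uL, float)
    dv = np.cumsum(inj) / v0_uL
    mt = m0 * (1 - dv / 2) / (1 + dv / 2)
    xt = x0 * dv / (1 + dv / 2)
    v0_L = v0_uL * 1e-6
    q = np.empty(len(inj))
    for i, (m, x) in enumerate(zip(mt, xt)):
        free = brentq(lambda L: L + n * m * L / (kd + L) - x, 0.0, x, xtol=1e-18,
                      rtol=1e-15)
        theta = free / (kd + free)
        q[i] = n * theta * m * v0_L * dh
    qp = np.concatenate([[0.0], q[:-1]])
    dq = q - qp + (inj / v0_uL) * (q + qp) / 2.0
    return dq / (x0 * inj * 1e-6) + dilution


def test_itc_zero_enthalpy_gives_zero_heats():
    cfg = ITCSimConfig(dH=0.0, dilution_heat=0.0, noise_sd=0.0)
    data = generate_itc_dataset(cfg)
    assert np.allclose(data.heats_kcal_mol, 0.0, atol=1e-15)


def test_itc_noiseless_matches_independent_oracle():
    cfg = ITCSimConfig(n=1.3, K_D=5e-5, dH=-8.0, cell_conc=5e-4, syringe_conc=1e-2,
                       dilution_heat=0.2, noise_sd=0.0)
    data = generate_itc_dataset(cfg)
    expected = itc_oracle(1.3, 5e-5, -8.0, 300.0, data.injection_volumes_uL,
                          5e-4, 1e-2, dilution=0.2)
    assert np.allclose(data.heats_kcal_mol, expected, atol=1e-9)


def test_itc_tight_binding_stoichiometric_limit():
    cfg = ITCSimConfig(n=1.0, K_D=1e-9, dH=-10.0, cell_conc=1e-4,
                       syringe_conc=2.5e-3, dilution_heat=0.3, noise_sd=0.0)
    data = generate_itc_dataset(cfg)
    ratio = data.molar_ratios()
    early = data.heats_kcal_mol[ratio < 0.8]
    late = data.heats_kcal_mol[ratio > 1.2]
    assert np.allclose(early, -10.0 + 0.3, atol=0.05)
    assert np.allclose(late, 0.3, atol=0.05)


def test_itc_undersaturating_syringe_warns(caplog):
    with caplog.at_level("WARNING", logger="myxoquant.simulate.binding"):
        generate_itc_dataset(ITCSimConfig(cell_conc=1e-3, syringe_conc=2e-3))
    assert any("equivalence" in r.message for r in caplog.records)


# ------------------------------------------------------------------ SPR fit

def test_spr_fit_recovers_noiseless_parameters_to_4_sig_figs():
    conc = [c for c in TWOFOLD_LADDER_M] + [2e-3, 4e-3]
    data = generate_spr_dataset(SPRSimConfig(Rmax=100.0, K_D=1e-4,
                                             concentrations=conc, noise_sd=0.0))
    fit = fit_spr_steady_state(data)
    assert fit.K_D == pytest.approx(1e-4, rel=1e-4)
    assert fit.Rmax == pytest.approx(100.0, rel=1e-4)
    assert fit.converged and not fit.flags


def test_spr_half_saturation_identity():
    data = generate_spr_dataset(SPRSimConfig(Rmax=60.0, K_D=2.5e-4,
                                             concentrations=[2.5e-4, 5e-4, 1e-3,
                                                             2e-3, 4e-3],
                                             noise_sd=0.0))
    fit = fit_spr_steady_state(data)
    # the concentration whose response is half the fitted Rmax is K_D itself
    assert data.response_RU[0] == pytest.approx(fit.Rmax / 2, rel=1e-6)
    assert fit.K_D == pytest.approx(2.5e-4, rel=1e-6)


@pytest.mark.parametrize("rmax", [10.0, 100.0, 1000.0])
@pytest.mark.parametrize("kd", [1e-6, 1e-4, 1e-2])
def test_spr_fit_residuals_vanish_across_parameter_space(rmax, kd):
    conc = np.geomspace(kd / 10, kd * 10, 8)
    data = generate_spr_dataset(SPRSimConfig(Rmax=rmax, K_D=kd,
                                             concentrations=conc, noise_sd=0.0))
    fit = fit_spr_steady_state(data)
    assert fit.rss < 1e-12 * rmax ** 2


def test_spr_fit_flags_kd_outside_measured_window():
    # essentially linear response: true Kd far above every concentration
    conc = np.array([1e-8, 2e-8, 4e-8, 8e-8, 1.6e-7])
    data = generate_spr_dataset(SPRSimConfig(Rmax=1000.0, K_D=1.0,
                                             concentrations=conc, noise_sd=0.0))
    fit = fit_spr_steady_state(data)
    assert "unreliable" in fit.flags


def test_spr_fit_order_invariance():
    rng = np.random.default_rng(2)
    data = generate_spr_dataset(SPRSimConfig(Rmax=100.0, K_D=3e-4,
                                             concentrations=TWOFOLD_LADDER_M,
                                             noise_sd=2.0, seed=5))
    perm = rng.permutation(len(data))
    shuffled = SPRDataset(concentration_M=data.concentration_M[perm],
                          response_RU=data.response_RU[perm])
    assert fit_spr_steady_state(shuffled).K_D == pytest.approx(
        fit_spr_steady_state(data).K_D, rel=1e-9)


def test_spr_fit_requires_enough_points_and_range():
    with pytest.raises(ValueError):
        fit_spr_steady_state(SPRDataset(np.array([1e-4, 2e-4, 3e-4]),
                                        np.array([1.0, 2.0, 3.0])))
    with pytest.raises(ValueError):
        fit_spr_steady_state(SPRDataset(np.array([1e-4, 1.2e-4, 1.4e-4, 1.6e-4]),
                                        np.array([1.0, 2.0, 3.0, 4.0])))


# ------------------------------------------------------- dilution subtraction

def test_subtract_zero_control_is_identity():
    data = generate_itc_dataset(ITCSimConfig(noise_sd=0.0, dilution_heat=0.0))
    corrected = subtract_dilution(data)
    assert np.allclose(corrected.heats_kcal_mol, data.heats_kcal_mol)


def test_subtract_equal_control_yields_zero():
    data = generate_itc_dataset(ITCSimConfig(noise_sd=0.0, dilution_heat=0.5))
    clone = ITCDataset(heats_kcal_mol=data.heats_kcal_mol.copy(),
                       cell_volume_uL=data.cell_volume_uL,
                       injection_volumes_uL=data.injection_volumes_uL,
                       cell_conc_M=data.cell_conc_M,
                       syringe_conc_M=data.syringe_conc_M,
                       control_heats_kcal_mol=data.heats_kcal_mol.copy())
    assert np.allclose(subtract_dilution(clone).heats_kcal_mol, 0.0)


def test_dilution_decomposition_recovers_pure_binding_series():
    pure = generate_itc_dataset(ITCSimConfig(noise_sd=0.0, dilution_heat=0.0))
    offset = generate_itc_dataset(ITCSimConfig(noise_sd=0.0, dilution_heat=0.3))
    corrected = subtract_dilution(offset)
    assert np.allclose(corrected.heats_kcal_mol, pure.heats_kcal_mol, atol=1e-9)


def test_subtract_without_control_raises():
    data = generate_itc_dataset(ITCSimConfig(noise_sd=0.0))
    data.control_heats_kcal_mol = None
    with pytest.raises(ValueError):
        subtract_dilution(data)


# ------------------------------------------------------------------ ITC fit

def test_itc_fit_recovers_noiseless_parameters_within_1_percent():
    cfg = ITCSimConfig(n=1.0, K_D=1e-5, dH=-10.0, cell_conc=2e-4,
                       syringe_conc=4e-3, dilution_heat=0.0, noise_sd=0.0)
    fit = fit_itc_one_site(generate_itc_dataset(cfg))
    assert fit.n == pytest.approx(1.0, rel=0.01)
    assert fit.K_D == pytest.approx(1e-5, rel=0.01)
    assert fit.dH == pytest.approx(-10.0, rel=0.01)


def test_itc_fit_zero_enthalpy_is_degenerate():
    data = generate_itc_dataset(ITCSimConfig(dH=0.0, dilution_heat=0.0,
                                             noise_sd=0.0))
    with pytest.raises(ValueError, match="identifiable"):
        fit_itc_one_site(data)


def test_itc_fit_flags_low_c_regime():
    cfg = ITCSimConfig(n=1.0, K_D=5e-2, dH=-10.0, cell_conc=1e-4,
                       syringe_conc=5e-1, noise_sd=0.0)
    fit = fit_itc_one_site(generate_itc_dataset(cfg))
    assert "low_confidence" in fit.flags


def test_itc_fit_bias_shrinks_with_noise():
    """Consistency: parameter errors decrease to zero as noise → 0."""
    errors = []
    for noise in (0.3, 0.03, 0.0):
        cfg = ITCSimConfig(n=1.47, K_D=3e-4, dH=-5.0, cell_conc=1e-3,
                           syringe_conc=2.2e-2, noise_sd=noise, seed=6)
        fit = fit_itc_one_site(generate_itc_dataset(cfg))
        errors.append(abs(fit.K_D / 3e-4 - 1) + abs(fit.n / 1.47 - 1)
                      + abs(fit.dH / -5.0 - 1))
    assert errors[2] < 1e-6
    assert errors[2] <= errors[1] <= errors[0]


def test_itc_fit_validated_against_oracle_curve():
    """Fitting heats produced by the independent numerical oracle (not the
    generator) recovers the oracle's parameters."""
    inj = np.full(19, 2.0)
    heats = itc_oracle(1.2, 8e-5, -6.0, 300.0, inj, 6e-4, 1.4e-2)
    data = ITCDataset(heats_kcal_mol=heats, cell_volume_uL=300.0,
                      injection_volumes_uL=inj, cell_conc_M=6e-4,
                      syringe_conc_M=1.4e-2)
    fit = fit_itc_one_site(data)
    assert fit.n == pytest.approx(1.2, rel=1e-3)
    assert fit.K_D == pytest.approx(8e-5, rel=1e-3)
    assert fit.dH == pytest.approx(-6.0, rel=1e-3)


def test_itc_exclude_first_injection_flag():
    cfg = ITCSimConfig(n=1.0, K_D=1e-5, dH=-10.0, cell_conc=2e-4,
                       syringe_conc=4e-3, noise_sd=0.0)
    data = generate_itc_dataset(cfg)
    data.heats_kcal_mol[0] = -3.0  # corrupt the first shot
    fit = fit_itc_one_site(data, exclude_first=True)
    assert fit.n == pytest.approx(1.0, rel=0.01)


# ------------------------------------------------------------ affinity ratio

@pytest.mark.parametrize("a,b,expected", [
    (1.040e-2, 1.055e-3, 9.86),
    (3e-4, 3e-4, 1.0),
    (2e-3, 1e-3, 2.0),
])
def test_affinity_ratio(a, b, expected):
    assert affinity_ratio(a, b) == pytest.approx(expected, abs=0.005)


def test_affinity_ratio_rejects_nonpositive():
    with pytest.raises(ValueError):
        affinity_ratio(0.0, 1e-3)
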