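"""Synthetic SPR equilibrium series and ITC thermograms."""

from __future__ import annotations

import logging

import numpy as np

from ..binding import itc_injection_heats, langmuir_response
from ..datatypes import ITCDataset, SPRDataset
from .config import ITCSimConfig, SPRSimConfig

__all__ = ["generate_spr_dataset", "generate_itc_dataset", "TWOFOLD_LADDER_M"]

log = logging.getLogger(__name__)

#: the standard twofold analyte dilution ladder, 31.25–1,000 µM, in molar
TWOFOLD_LADDER_M = tuple(31.25e-6 * 2 ** k for k in range(6))


def generate_spr_dataset(config: SPRSimConfig) -> SPRDataset:
    """Equilibrium responses ``Rmax·C/(K_D + C)`` plus Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations, dtype=float)
    resp = langmuir_response(conc, config.Rmax, config.K_D)
    if config.noise_sd > 0:
        resp = resp + rng.normal(0.0, config.noise_sd, size=conc.shape)
    return SPRDataset(concentration_M=conc, response_RU=resp)


def generate_itc_dataset(config: ITCSimConfig) -> ITCDataset:
    """One-set-of-sites injection heats plus dilution offset and noise.

    The paired buffer-only control series (``dilution_heat`` plus the same
    noise model) is attached so that the dilution-subtraction step can be
    exercised end to end.
    """
    rng = np.random.default_rng(config.seed)
    inj = np.full(config.n_injections, config.injection_volume, dtype=float)

    heats = itc_injection_heats(config.n, config.K_D, config.dH,
                                config.cell_volume, inj,
                                config.cell_conc, config.syringe_conc)

    # saturation check: molar ratio reached by the final injection
    from ..binding import itc_cell_concentrations

    mt, xt = itc_cell_concentrations(config.cell_conc, config.syringe_conc,
                                     config.cell_volume, inj)
    final_ratio = xt[-1] / (config.n * mt[-1])
    if final_ratio < 1.5:
        log.warning(
            "syringe concentration %.3g M reaches only %.2f× the binding "
            "equivalence point by the final injection; the fitted ΔH and n "
            "will be poorly constrained", config.syringe_conc, final_ratio)

    heats = heats + config.dilution_heat
    control = np.full(config.n_injections, config.dilution_heat)
    if config.noise_sd > 0:
        heats = heats + rng.normal(0.0, config.noise_sd, size=heats.shape)
        control = control + rng.normal(0.0, config.noise_sd, size=control.shape)

    return ITCDataset(
        heats_kcal_mol=heats,
        cell_volume_uL=config.cell_volume,
        injection_volumes_uL=inj,
        cell_conc_M=config.cell_conc,
        syringe_conc_M=config.syringe_conc,
        control_heats_kcal_mol=control,
    )
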