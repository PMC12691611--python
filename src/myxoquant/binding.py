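"""Equilibrium binding models: SPR steady-state and ITC one-set-of-sites fits.

Two 1:1 binding descriptions are implemented:

* **SPR steady state** — the equilibrium response of an analyte at
  concentration ``C`` flowing over an immobilized ligand follows the
  Langmuir isotherm ``Req = Rmax·C / (K_D + C)``; a nonlinear
  least-squares fit recovers the maximal response ``Rmax`` (RU) and the
  dissociation constant ``K_D`` (M).

* **ITC one set of sites** — a macromolecule at total concentration
  ``M_t`` in a cell of volume ``V0`` binds ligand at ``n`` identical,
  independent sites with association constant ``K_A = 1/K_D`` and molar
  enthalpy ``ΔH``.  The cumulative heat after reaching total ligand
  concentration ``X_t`` is

  ``Q = (n·M_t·ΔH·V0 / 2) · [ 1 + X_t/(n·M_t) + K_D/(n·M_t)
        − sqrt( (1 + X_t/(n·M_t) + K_D/(n·M_t))² − 4·X_t/(n·M_t) ) ]``

  and the heat of injection *i* is the finite difference of ``Q``
  corrected for the liquid displaced from the (constant-volume)
  perfusion cell:  ``ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2``.
  Normalizing by the moles of injectant delivered gives the per-injection
  molar heats that calorimetry software plots against the molar ratio.

Both fits use positivity-enforcing log parameterizations and report
convergence diagnostics and reliability flags rather than silently
returning implausible constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import ITCDataset, SPRDataset

__all__ = [
    "SPRFit",
    "ITCFit",
    "langmuir_response",
    "itc_cell_concentrations",
    "itc_total_heat",
    "itc_injection_heats",
    "fit_spr_steady_state",
    "subtract_dilution",
    "fit_itc_one_site",
    "affinity_ratio",
]


# --------------------------------------------------------------------------
# model functions
# --------------------------------------------------------------------------

def langmuir_response(conc_M: np.ndarray, Rmax: float, K_D: float) -> np.ndarray:
    """Steady-state 1:1 Langmuir binding response (RU)."""
    conc_M = np.asarray(conc_M, dtype=float)
    return Rmax * conc_M / (K_D + conc_M)


def itc_cell_concentrations(cell_conc_M: float, syringe_conc_M: float,
                            cell_volume_uL: float,
                            injection_volumes_uL: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Total macromolecule and ligand concentrations after each injection.

    Uses the standard perfusion-displacement correction for an overfilled
    constant-volume cell: after a cumulative injected volume ``ΔV``,

    ``M_t = M0·(1 − ΔV/2V0)/(1 + ΔV/2V0)``,
    ``X_t = X0·(ΔV/V0)/(1 + ΔV/2V0)``.
    """
    dv = np.cumsum(np.asarray(injection_volumes_uL, dtype=float)) / cell_volume_uL
    mt = cell_conc_M * (1 - dv / 2) / (1 + dv / 2)
    xt = syringe_conc_M * dv / (1 + dv / 2)
    return mt, xt


def itc_total_heat(n: float, K_D: float, dH: float, cell_volume_uL: float,
                   mt: np.ndarray, xt: np.ndarray) -> np.ndarray:
    """Cumulative heat content (kcal) of the cell for the one-set-of-sites model."""
    nm = n * mt
    b = 1.0 + xt / nm + K_D / nm
    v0_L = cell_volume_uL * 1e-6
    return nm * dH * v0_L / 2.0 * (b - np.sqrt(b * b - 4.0 * xt / nm))


def itc_injection_heats(n: float, K_D: float, dH: float, cell_volume_uL: float,
                        injection_volumes_uL: np.ndarray, cell_conc_M: float,
                        syringe_conc_M: float) -> np.ndarray:
    """Per-injection heats normalized to kcal per mole of injectant."""
    inj = np.asarray(injection_volumes_uL, dtype=float)
    mt, xt = itc_cell_concentrations(cell_conc_M, syringe_conc_M, cell_volume_uL, inj)
    q = itc_total_heat(n, K_D, dH, cell_volume_uL, mt, xt)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (inj / cell_volume_uL) * (q + q_prev) / 2.0
    moles = syringe_conc_M * inj * 1e-6  # mol injected per shot
    return dq / moles


# --------------------------------------------------------------------------
# fit results
# --------------------------------------------------------------------------

@dataclass
class SPRFit:
    """Result of a steady-state affinity fit."""

    K_D: float  # M
    Rmax: float  # RU
    rss: float
    stderr_K_D: float
    stderr_Rmax: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def predict(self, conc_M: np.ndarray) -> np.ndarray:
        return langmuir_response(conc_M, self.Rmax, self.K_D)


@dataclass
class ITCFit:
    """Result of a one-set-of-sites thermogram fit."""

    n: float
    K_D: float  # M
    dH: float  # kcal/mol
    offset: float  # kcal/mol baseline
    rss: float
    c_value: float  # n·M_t/K_D at the start of the titration
    converged: bool
    flags: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_spr_steady_state(data: SPRDataset) -> SPRFit:
    """Fit ``Req = Rmax·C/(K_D + C)`` by nonlinear least squares.

    Positivity of both parameters is enforced by fitting in log space.
    Initialization: ``Rmax₀ = 1.1 × max(Req)``, ``K_D₀ = median(C)``.  A
    fitted ``K_D`` outside ``[min(C)/100, 100·max(C)]`` is flagged
    ``"unreliable"``: the data do not constrain an affinity that far
    outside the measured concentration window.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 concentration points to fit")
    conc = data.concentration_M
    resp = data.response_RU
    span = conc.max() / conc.min()
    if span < 4:
        raise ValueError("concentration series must span at least a 4-fold range")

    rmax0 = 1.1 * float(np.max(resp))
    if rmax0 <= 0:
        rmax0 = 1.0
    kd0 = float(np.median(conc))

    def residuals(p):
        rmax, kd = np.exp(p)
        return langmuir_response(conc, rmax, kd) - resp

    sol = least_squares(residuals, x0=np.log([rmax0, kd0]), method="lm")
    rmax, kd = np.exp(sol.x)
    rss = float(np.sum(sol.fun ** 2))

    # delta-method standard errors mapped back from log space
    dof = max(len(conc) - 2, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_rmax, se_kd = rmax * se_log[0], kd * se_log[1]
    except np.linalg.LinAlgError:
        se_rmax = se_kd = np.nan

    flags = []
    if not sol.success:
        flags.append("no_convergence")
    if not (conc.min() / 100 <= kd <= 100 * conc.max()):
        flags.append("unreliable")
    return SPRFit(K_D=float(kd), Rmax=float(rmax), rss=rss,
                  stderr_K_D=float(se_kd), stderr_Rmax=float(se_rmax),
                  converged=bool(sol.success), flags=flags)


def subtract_dilution(data: ITCDataset) -> ITCDataset:
    """Subtract the buffer-only control titration from the sample heats."""
    if data.control_heats_kcal_mol is None:
        raise ValueError("no control titration present to subtract")
    return ITCDataset(
        heats_kcal_mol=data.heats_kcal_mol - data.control_heats_kcal_mol,
        cell_volume_uL=data.cell_volume_uL,
        injection_volumes_uL=data.injection_volumes_uL.copy(),
        cell_conc_M=data.cell_conc_M,
        syringe_conc_M=data.syringe_conc_M,
        control_heats_kcal_mol=None,
    )


def fit_itc_one_site(data: ITCDataset, exclude_first: bool = False) -> ITCFit:
    """Fit the one-set-of-sites model to dilution-corrected injection heats.

    Free parameters: stoichiometry ``n``, ``K_D``, molar enthalpy ``ΔH``
    and a constant baseline offset (residual mixing heat).  ``n`` and
    ``K_D`` are fitted in log space; several ``K_D`` starting values
    spanning weak to tight binding are tried and the best-cost solution
    kept.  A Wiseman ``c = n·M_t/K_D < 0.1`` flags the result
    ``"low_confidence"`` (the isotherm is then too shallow to pin down
    ``n`` and ``ΔH`` separately).

    Parameters
    ----------
    exclude_first : drop the first injection from the fit (common practice
        for diffusion across the syringe tip; off by default).
    """
    heats = data.heats_kcal_mol
    inj = data.injection_volumes_uL
    mask = np.ones(len(heats), dtype=bool)
    if exclude_first:
        mask[0] = False
    if np.ptp(heats[mask]) < 1e-9:
        raise ValueError("injection heats are constant; binding enthalpy is "
                         "not identifiable (ΔH ≈ 0 or no binding)")

    offset0 = float(heats[mask][-1])
    dh0 = float(heats[mask][0]) - offset0
    if dh0 == 0:
        dh0 = float(np.ptp(heats[mask])) or -1.0

    def residuals(p):
        n, kd = np.exp(p[0]), np.exp(p[1])
        dh, off = p[2], p[3]
        model = itc_injection_heats(n, kd, dh, data.cell_volume_uL, inj,
                                    data.cell_conc_M, data.syringe_conc_M) + off
        return (model - heats)[mask]

    best = None
    for c0 in (0.5, 2.0, 10.0, 50.0):
        kd0 = data.cell_conc_M / c0
        sol = least_squares(residuals, x0=[0.0, np.log(kd0), dh0, offset0],
                            method="trf", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol

    n_fit, kd_fit = np.exp(best.x[0]), np.exp(best.x[1])
    dh_fit, off_fit = best.x[2], best.x[3]
    rss = float(np.sum(best.fun ** 2))
    c_value = float(n_fit * data.cell_conc_M / kd_fit)

    flags = []
    if not best.success:
        flags.append("no_convergence")
    if c_value < 0.1:
        flags.append("low_confidence")
    return ITCFit(n=float(n_fit), K_D=float(kd_fit), dH=float(dh_fit),
                  offset=float(off_fit), rss=rss, c_value=c_value,
                  converged=bool(best.success), flags=flags)


def affinity_ratio(kd_a: float, kd_b: float) -> float:
    """Fold difference between two dissociation constants (``kd_a / kd_b``)."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_a / kd_b
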