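"""Seawater CO2-system solver for bench-top fertilization treatments.

Given pH on the total hydrogen-ion scale, total alkalinity, salinity and
temperature, the solver returns the full carbonate state (DIC, pCO2,
carbonate ion, aragonite saturation state) at 0 dbar.  Carbonic-acid
dissociation constants are the Mehrbach et al. measurements as refit by
Dickson & Millero (1987); ancillary constants follow the de-facto CO2SYS
defaults (Weiss K0; Dickson KB and KS; Millero KW; Perez & Fraga KF; Mucci
aragonite Ksp; Uppstrom borate).  All constants are reported on the total
scale where applicable; no nutrient alkalinity terms and no pressure
correction (bench-top vials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


class CarbonateError(ValueError):
    pass


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants (mol/kg-SW, total scale unless noted) at (S, T, 0 dbar)."""

    K0: float  # CO2 solubility, mol/kg/atm (Weiss 1974)
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float  # bisulfate, free scale
    KF: float  # hydrogen fluoride, free scale
    Ksp_aragonite: float
    total_borate: float
    total_sulfate: float
    total_fluoride: float
    calcium: float
    sws_to_total: float
    S: float
    T: float

    def __post_init__(self) -> None:
        for name in (
            "K0", "K1", "K2", "KB", "KW", "KS", "KF", "Ksp_aragonite",
            "total_borate", "total_sulfate", "total_fluoride", "calcium",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CarbonateError(f"constant {name} not finite positive: {v}")
        if self.K1 <= self.K2:
            raise CarbonateError("expected K1 > K2")


@dataclass(frozen=True)
class CarbonateState:
    """Full CO2-system state; concentrations in umol/kg-SW, pCO2 in uatm."""

    ph_T: float
    A_T: float
    DIC: float
    pCO2: float
    omega_a: float
    co3: float
    hco3: float
    co2_aq: float
    S: float
    T: float
    P: float = 0.0


def constants(S: float, T: float) -> ConstantSet:
    """Equilibrium constants at salinity ``S`` and temperature ``T`` (deg C)."""
    if not (0.0 < S < 45.0):
        raise CarbonateError(f"salinity {S} outside (0, 45)")
    if not (-2.0 < T < 40.0):
        raise CarbonateError(f"temperature {T} C outside (-2, 40)")

    TK = T + 273.15
    lnTK = np.log(TK)
    sqS = np.sqrt(S)

    # Salinity-proportional totals (mol/kg-SW)
    TB = 0.000232 / 10.811 * S / 1.80655  # Uppstrom 1974
    TS = 0.14 / 96.062 * S / 1.80655      # Morris & Riley 1966
    TFl = 0.000067 / 18.998 * S / 1.80655  # Riley 1965
    Ca = 0.02128 / 40.087 * S / 1.80655   # Riley & Tongudai 1967

    ion_s = 19.924 * S / (1000.0 - 1.005 * S)

    # Bisulfate, Dickson (1990), free scale
    lnKS = (
        -4276.1 / TK + 141.328 - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * np.sqrt(ion_s)
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * ion_s
        - 2698.0 / TK * ion_s**1.5
        + 1776.0 / TK * ion_s**2
    )
    KS = np.exp(lnKS) * (1.0 - 0.001005 * S)

    # Hydrogen fluoride, Perez & Fraga (1987), free scale
    KF = np.exp(874.0 / TK - 9.68 + 0.111 * sqS)

    sws_to_total = (1.0 + TS / KS) / (1.0 + TS / KS + TFl / KF)

    # CO2 solubility, Weiss (1974)
    lnK0 = (
        -60.2409 + 93.4517 * (100.0 / TK) + 23.3585 * np.log(TK / 100.0)
        + S * (0.023517 - 0.023656 * (TK / 100.0) + 0.0047036 * (TK / 100.0) ** 2)
    )
    K0 = np.exp(lnK0)

    # Mehrbach et al. (1973) refit by Dickson & Millero (1987); seawater scale
    pK1_sws = 3670.7 / TK - 62.008 + 9.7944 * lnTK - 0.0118 * S + 0.000116 * S**2
    pK2_sws = 1394.7 / TK + 4.777 - 0.0184 * S + 0.000118 * S**2
    K1 = 10.0 ** (-pK1_sws) * sws_to_total
    K2 = 10.0 ** (-pK2_sws) * sws_to_total

    # Boric acid, Dickson (1990b), total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / TK
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        - (24.4344 + 25.085 * sqS + 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    KB = np.exp(lnKB)

    # Water, Millero (1995), seawater scale -> total
    lnKW = (
        148.9802 - 13847.26 / TK - 23.6521 * lnTK
        + (118.67 / TK - 5.977 + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    KW = np.exp(lnKW) * sws_to_total

    # Aragonite solubility, Mucci (1983); mol^2/kg^2
    log10Kar = (
        -171.945 - 0.077993 * TK + 2903.293 / TK + 71.595 * np.log10(TK)
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
        - 0.10018 * S + 0.0059415 * S**1.5
    )
    Ksp_ar = 10.0**log10Kar

    return ConstantSet(
        K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
        Ksp_aragonite=Ksp_ar, total_borate=TB, total_sulfate=TS,
        total_fluoride=TFl, calcium=Ca, sws_to_total=sws_to_total, S=S, T=T,
    )


def _alkalinity_from_ph_dic(h: float, dic: float, k: ConstantSet) -> float:
    """Total alkalinity (mol/kg) from total-scale [H+] and DIC (mol/kg)."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    calk = dic * (k.K1 * h + 2.0 * k.K1 * k.K2) / denom
    h_free = h / (1.0 + k.total_sulfate / k.KS)
    balk = k.total_borate * k.KB / (k.KB + h)
    oh = k.KW / h
    hso4 = k.total_sulfate * h_free / (k.KS + h_free)
    hf = k.total_fluoride * h_free / (k.KF + h_free)
    return calk + balk + oh - h_free - hso4 - hf


def solve_carbonate(ph_T: float, A_T: float, S: float, T: float) -> CarbonateState:
    """Solve the CO2 system from (pH_T, total alkalinity).

    Parameters
    ----------
    ph_T : pH, total hydrogen-ion scale, at (S, T).
    A_T : total alkalinity, umol/kg-SW.
    S, T : practical salinity and temperature in deg C.
    """
    if not (6.0 < ph_T < 9.5):
        raise CarbonateError(f"pH {ph_T} outside plausible seawater range (6, 9.5)")
    if not (1000.0 < A_T < 4000.0):
        raise CarbonateError(f"alkalinity {A_T} umol/kg outside (1000, 4000)")
    k = constants(S, T)
    ta = A_T * 1e-6
    h = 10.0 ** (-ph_T)

    h_free = h / (1.0 + k.total_sulfate / k.KS)
    balk = k.total_borate * k.KB / (k.KB + h)
    oh = k.KW / h
    hso4 = k.total_sulfate * h_free / (k.KS + h_free)
    hf = k.total_fluoride * h_free / (k.KF + h_free)
    calk = ta - balk - oh + h_free + hso4 + hf
    if calk <= 0:
        raise CarbonateError("carbonate alkalinity non-positive; inputs inconsistent")

    denom = h * h + k.K1 * h + k.K1 * k.K2
    dic = calk * denom / (k.K1 * h + 2.0 * k.K1 * k.K2)
    co2_aq = dic * h * h / denom
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    pco2 = co2_aq / k.K0
    omega_a = k.calcium * co3 / k.Ksp_aragonite

    return CarbonateState(
        ph_T=ph_T, A_T=A_T, DIC=dic * 1e6, pCO2=pco2 * 1e6,
        omega_a=omega_a, co3=co3 * 1e6, hco3=hco3 * 1e6,
        co2_aq=co2_aq * 1e6, S=S, T=T,
    )


def ph_from_dic_alk(DIC: float, A_T: float, S: float, T: float) -> float:
    """pH (total scale) from DIC and total alkalinity (both umol/kg-SW).

    Bracketed monotone root solve on pH in [2, 12].
    """
    k = constants(S, T)
    dic = DIC * 1e-6
    ta = A_T * 1e-6

    def resid(ph: float) -> float:
        return _alkalinity_from_ph_dic(10.0**-ph, dic, k) - ta

    lo, hi = 2.0, 12.0
    if resid(lo) * resid(hi) > 0:
        raise CarbonateError(
            f"no pH root in [2, 12] for DIC={DIC}, A_T={A_T}, S={S}, T={T}"
        )
    return brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16)


def adjust_ph_to_insitu(ph_T_25C: float, A_T: float, S: float, T_insitu: float) -> float:
    """Convert a 25 degC spectrophotometric pH_T to in-situ temperature.

    Solves (pH at 25 C, A_T) for DIC, then recomputes pH from the conserved
    (DIC, A_T) pair at ``T_insitu``.
    """
    state_25 = solve_carbonate(ph_T_25C, A_T, S, 25.0)
    if T_insitu == 25.0:
        return ph_T_25C
    return ph_from_dic_alk(state_25.DIC, A_T, S, T_insitu)
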