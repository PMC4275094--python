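"""Seawater carbonate-system solver.

Given any two of {total alkalinity TA, dissolved inorganic carbon DIC,
total-scale pH} together with temperature and salinity, the solver computes
the full carbonate speciation, pCO2 and the calcite/aragonite saturation
states at surface pressure.

Equilibrium constants (all converted to the total hydrogen-ion scale,
concentrations in mol/kg-solution):

* K0  — CO2 solubility, Weiss (1974)
* K1, K2 — carbonic acid, Mehrbach et al. (1973) as refitted by
  Dickson & Millero (1987) (seawater scale, converted to total)
* KB  — boric acid, Dickson (1990)
* KW  — water, Millero (1995) (seawater scale, converted to total)
* KS  — bisulfate, Dickson (1990); KF — hydrogen fluoride,
  Dickson & Riley (1979): used for pH-scale conversions
* Ksp(calcite), Ksp(aragonite) — Mucci (1983)
* total boron from salinity, Uppstrom (1974); sulfate Morris & Riley
  (1966); fluoride Riley (1965); calcium Riley & Tongudai (1967)

The alkalinity balance includes carbonate, borate, water and the free
proton: TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]_free.
Phosphate and silicate are taken as zero.  pH measured on the NIST scale is
accepted only with an explicit user-supplied offset to the total scale,
because the liquid-junction correction is apparatus dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["ConstantsSet", "SeawaterState", "constants", "solve"]


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants on the total scale plus salinity-derived totals."""

    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    Ksp_calcite: float
    Ksp_aragonite: float
    total_boron: float
    total_sulfate: float
    total_fluoride: float
    calcium: float
    sws_to_total: float


def constants(temperature: float, salinity: float) -> ConstantsSet:
    """Evaluate the constant set at one temperature (Celsius) and salinity."""
    if not (0.0 <= temperature <= 45.0) or not (15.0 <= salinity <= 45.0):
        raise ValueError("temperature/salinity outside supported range")
    T = temperature + 273.15
    S = salinity
    lnT = np.log(T)
    sqS = np.sqrt(S)

    # salinity-proportional totals, mol/kg-SW
    TB = 0.000416 * S / 35.0                       # Uppstrom (1974)
    TS = (0.14 / 96.062) * (S / 1.80655)           # Morris & Riley (1966)
    TF = (0.000067 / 18.998) * (S / 1.80655)       # Riley (1965)
    Ca = (0.02128 / 40.087) * (S / 1.80655)        # Riley & Tongudai (1967)

    # bisulfate (free scale) — Dickson (1990a)
    I = 19.924 * S / (1000 - 1.005 * S)
    lnKS = (-4276.1 / T + 141.328 - 23.093 * lnT
            + (-13856 / T + 324.57 - 47.986 * lnT) * np.sqrt(I)
            + (35474 / T - 771.54 + 114.723 * lnT) * I
            - 2698 / T * I ** 1.5 + 1776 / T * I ** 2
            + np.log(1 - 0.001005 * S))
    KS = np.exp(lnKS)

    # hydrogen fluoride (free scale) — Dickson & Riley (1979)
    lnKF = 1590.2 / T - 12.641 + 1.525 * np.sqrt(I) + np.log(1 - 0.001005 * S)
    KF = np.exp(lnKF)

    free_to_total = 1.0 + TS / KS
    sws_to_total = free_to_total / (1.0 + TS / KS + TF / KF)

    # CO2 solubility, mol/kg-atm — Weiss (1974)
    lnK0 = (-60.2409 + 93.4517 * (100 / T) + 23.3585 * np.log(T / 100)
            + S * (0.023517 - 0.023656 * (T / 100)
                   + 0.0047036 * (T / 100) ** 2))
    K0 = np.exp(lnK0)

    # carbonic acid, Mehrbach refit by Dickson & Millero (1987), SWS scale
    pK1 = 3670.7 / T - 62.008 + 9.7944 * lnT - 0.0118 * S + 0.000116 * S ** 2
    pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S ** 2
    K1 = 10.0 ** -pK1 * sws_to_total
    K2 = 10.0 ** -pK2 * sws_to_total

    # boric acid, total scale — Dickson (1990b)
    lnKB = ((-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5
             - 0.0996 * S ** 2) / T
            + 148.0248 + 137.1942 * sqS + 1.62142 * S
            - (24.4344 + 25.085 * sqS + 0.2474 * S) * lnT
            + 0.053105 * sqS * T)
    KB = np.exp(lnKB)

    # water, SWS scale — Millero (1995)
    lnKW = (148.9802 - 13847.26 / T - 23.6521 * lnT
            + (-5.977 + 118.67 / T + 1.0495 * lnT) * sqS - 0.01615 * S)
    KW = np.exp(lnKW) * sws_to_total

    # calcite/aragonite solubility — Mucci (1983)
    logKspC = (-171.9065 - 0.077993 * T + 2839.319 / T + 71.595 * np.log10(T)
               + (-0.77712 + 0.0028426 * T + 178.34 / T) * sqS
               - 0.07711 * S + 0.0041249 * S ** 1.5)
    logKspA = (-171.945 - 0.077993 * T + 2903.293 / T + 71.595 * np.log10(T)
               + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
               - 0.10018 * S + 0.0059415 * S ** 1.5)
    return ConstantsSet(K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
                        Ksp_calcite=10.0 ** logKspC,
                        Ksp_aragonite=10.0 ** logKspA,
                        total_boron=TB, total_sulfate=TS, total_fluoride=TF,
                        calcium=Ca, sws_to_total=sws_to_total)


@dataclass(frozen=True)
class SeawaterState:
    """Solved carbonate system at surface pressure."""

    temperature: float           # Celsius
    salinity: float              # practical salinity
    ta: float                    # total alkalinity, umol/kg
    dic: float                   # dissolved inorganic carbon, umol/kg
    ph_total: float              # total-scale pH
    pco2: float                  # uatm
    co2: float                   # [CO2*], umol/kg
    hco3: float                  # umol/kg
    co3: float                   # umol/kg
    omega_calcite: float
    omega_aragonite: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in (
            "temperature", "salinity", "ta", "dic", "ph_total", "pco2",
            "co2", "hco3", "co3", "omega_calcite", "omega_aragonite")}


def _speciate(dic: float, h: float, k: ConstantsSet):
    """Carbonate species (mol/kg) from DIC (mol/kg) and [H+] total."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    co2 = dic * h * h / denom
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    return co2, hco3, co3


def _alkalinity(dic: float, h: float, k: ConstantsSet) -> float:
    """Total alkalinity (mol/kg) of the carbonate/borate/water system."""
    _, hco3, co3 = _speciate(dic, h, k)
    boh4 = k.total_boron * k.KB / (k.KB + h)
    oh = k.KW / h
    h_free = h / (1.0 + k.total_sulfate / k.KS)
    return hco3 + 2.0 * co3 + boh4 + oh - h_free


def solve(temperature: float, salinity: float,
          ta: float | None = None, dic: float | None = None,
          ph: float | None = None,
          ph_nist: float | None = None,
          nist_to_total_offset: float | None = None) -> SeawaterState:
    """Solve the carbonate system from exactly two of TA, DIC and pH (total).

    TA and DIC are in umol/kg.  A NIST-scale pH may be supplied instead of
    a total-scale pH, but only together with an explicit
    ``nist_to_total_offset`` (pH_total = pH_NIST + offset), since no
    universal electrode-independent conversion exists.
    """
    if ph_nist is not None:
        if ph is not None:
            raise ValueError("give either ph (total scale) or ph_nist, not both")
        if nist_to_total_offset is None:
            raise ValueError("ph_nist requires an explicit nist_to_total_offset")
        ph = ph_nist + nist_to_total_offset
    known = [name for name, v in (("ta", ta), ("dic", dic), ("ph", ph))
             if v is not None]
    if len(known) != 2:
        raise ValueError(f"exactly two carbonate parameters required, got "
                         f"{known or 'none'}")
    k = constants(temperature, salinity)

    if ph is not None:
        h = 10.0 ** -ph
        if ta is not None:
            # invert the alkalinity balance, linear in DIC at fixed H+
            ta_mol = ta * 1e-6
            alk0 = _alkalinity(0.0, h, k)
            per_dic = _alkalinity(1.0, h, k) - alk0
            dic_mol = (ta_mol - alk0) / per_dic
            if dic_mol <= 0:
                raise ValueError("no positive DIC is consistent with the "
                                 "supplied TA and pH")
        else:
            dic_mol = dic * 1e-6
            ta_mol = _alkalinity(dic_mol, h, k)
    else:
        ta_mol = ta * 1e-6
        dic_mol = dic * 1e-6

        def resid(ph_try: float) -> float:
            return _alkalinity(dic_mol, 10.0 ** -ph_try, k) - ta_mol

        lo, hi = 2.0, 12.0
        if resid(lo) * resid(hi) > 0:
            raise ValueError("alkalinity balance has no root in pH [2, 12] "
                             "for the supplied TA and DIC")
        ph = brentq(resid, lo, hi, xtol=1e-10)
        h = 10.0 ** -ph

    co2, hco3, co3 = _speciate(dic_mol, h, k)
    pco2 = co2 / k.K0 * 1e6
    omega_ca = k.calcium * co3 / k.Ksp_calcite
    omega_ar = k.calcium * co3 / k.Ksp_aragonite
    return SeawaterState(temperature=temperature, salinity=salinity,
                         ta=ta_mol * 1e6, dic=dic_mol * 1e6, ph_total=ph,
                         pco2=pco2, co2=co2 * 1e6, hco3=hco3 * 1e6,
                         co3=co3 * 1e6, omega_calcite=omega_ca,
                         omega_aragonite=omega_ar)
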