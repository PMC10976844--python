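"""Doubly-labelled water (DLW) energetics.

The DLW method doses an animal with water enriched in the stable isotopes
18O and 2H.  Oxygen leaves the body as both water and CO2 while hydrogen
leaves only as water, so the divergence of the two exponential washout
rates measures CO2 production.  This module implements the field-side
calculations: dose mass, pooled background enrichment, per-isotope
elimination rates and dilution spaces from plateau samples, single-pool
CO2 production, conversion to daily energy expenditure (DEE, kJ/day), and
the quality-control filters that decide which dosings are analysable.

The single-pool model is

    rCO2 = (N / 2.078) * (k_o - k_d) - 0.0062 * k_d * N      [mol/day]

with N the oxygen dilution space (mol body water), k_o and k_d the 18O and
2H elimination rates (/day).  It is the recommended model for animals
below ~10 kg body mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

__all__ = [
    "DlwDosing",
    "DeeResult",
    "QcThresholds",
    "dose_mass",
    "pooled_background",
    "elimination_rate",
    "dilution_space",
    "rco2_single_pool",
    "dee_from_rco2",
    "estimate_dee",
    "qc_filter",
    "delta_to_ppm",
]

Isotope = Literal["18O", "2H"]

#: molar mass (g/mol) of labelled water, per isotope of the label
WATER_MOLAR_MASS = {"18O": 20.015, "2H": 19.017}

#: VSMOW isotope ratios, used by the optional delta -> ppm converter
VSMOW_RATIO_PPM = {"18O": 2005.20, "2H": 155.76}

#: conversion defaults (configurable in every caller)
MOLAR_VOLUME_L = 22.414          # L CO2 per mol at STP
ENERGY_EQUIV_KJ_PER_L = 24.03    # kJ per L CO2 at RQ 0.8


class BelowBackgroundError(ValueError):
    """Final enrichment at or below background: washout rate undefined."""


@dataclass
class DlwDosing:
    """One DLW dosing record: dose, enrichments (ppm) and sample times (days).

    Times are measured in days since dosing; ``t_initial`` is the plateau
    (equilibration) sample, ``t_final`` the recapture sample.
    """

    individual_id: str
    season: str
    weight_kg: float
    dose_g: float
    ie_18o: float
    ie_2h: float
    bg_18o: float
    bg_2h: float
    e0_18o: float
    e0_2h: float
    ef_18o: float
    ef_2h: float
    t_initial: float
    t_final: float
    year: int = 0

    def __post_init__(self) -> None:
        if self.dose_g <= 0:
            raise ValueError("dose mass must be > 0")
        if self.t_final <= self.t_initial:
            raise ValueError("sample times must be strictly increasing")
        for name in ("ie_18o", "ie_2h", "bg_18o", "bg_2h",
                     "e0_18o", "e0_2h", "ef_18o", "ef_2h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"enrichment {name} must be > 0")

    @property
    def elapsed_days(self) -> float:
        return self.t_final - self.t_initial


@dataclass
class DeeResult:
    """Derived DLW quantities and QC flags for one dosing."""

    individual_id: str
    season: str
    year: int = 0
    k_o: Optional[float] = None
    k_d: Optional[float] = None
    n_o: Optional[float] = None
    n_d: Optional[float] = None
    dilution_space_ratio: Optional[float] = None
    rco2: Optional[float] = None
    dee_kj_day: Optional[float] = None
    body_water_fraction: Optional[float] = None
    qc_flags: list = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return not self.qc_flags and self.dee_kj_day is not None


@dataclass
class QcThresholds:
    """Validity filters applied to each dosing.

    background_margin_ppm : minimum final excess (Ef - E_bg) for either
        isotope, default twice the analytical sd of the isotope analysis.
    ratio_low/high : accepted dilution-space ratio N_d/N_o window; values
        outside indicate improper dosing.
    window_days : valid recapture window after dosing.
    body_water_low/high : sanity band on N_o expressed as a fraction of
        body weight.
    """

    background_margin_ppm: float = 2.0
    ratio_low: float = 1.00
    ratio_high: float = 1.10
    window_days: tuple[float, float] = (6.0, 10.0)
    body_water_low: float = 0.40
    body_water_high: float = 0.80


def dose_mass(weight_kg: float, die_ppm: float, ie_ppm: float) -> float:
    """Field dose mass (g): ``0.65 * W * DIE / IE``.

    W is the (estimated) body weight in kg, DIE the desirable initial
    enrichment and IE the injectate enrichment, both in ppm.
    """
    if weight_kg <= 0 or die_ppm < 0 or ie_ppm <= 0:
        raise ValueError("weight and enrichments must be positive")
    if die_ppm >= ie_ppm:
        raise ValueError(
            "desired initial enrichment cannot reach the injectate enrichment"
        )
    return 0.65 * weight_kg * die_ppm / ie_ppm


def pooled_background(samples: Iterable[float]) -> float:
    """Arithmetic mean background enrichment over 5-9 unlabelled individuals.

    Background samples come from other animals trapped at the same social
    groups in the same session, because dosed animals cannot be bled before
    injection.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one background sample required")
    return float(arr.mean())


def elimination_rate(e0: float, ef: float, e_bg: float, t_days: float) -> float:
    """Exponential washout rate k = [ln(E0 - E_bg) - ln(Ef - E_bg)] / t."""
    if t_days <= 0:
        raise ValueError("elapsed time must be > 0")
    if ef <= e_bg:
        raise BelowBackgroundError(
            "final enrichment too close to background to calculate a rate"
        )
    if e0 <= ef:
        raise ValueError("no isotope decay between samples (E0 <= Ef)")
    return (math.log(e0 - e_bg) - math.log(ef - e_bg)) / t_days


def dilution_space(
    dose_g: float, ie: float, e0: float, e_bg: float, isotope: Isotope
) -> float:
    """Plateau-method dilution space N (mol body water).

    ``N = dose_moles * (IE - E0) / (E0 - E_bg)`` with dose moles from the
    labelled water's molar mass.
    """
    if dose_g <= 0:
        raise ValueError("dose mass must be > 0")
    if e0 <= e_bg:
        raise ValueError("plateau enrichment must exceed background")
    if e0 >= ie:
        raise ValueError("plateau enrichment cannot reach injectate enrichment")
    dose_moles = dose_g / WATER_MOLAR_MASS[isotope]
    return dose_moles * (ie - e0) / (e0 - e_bg)


def rco2_single_pool(n_mol: float, k_o: float, k_d: float) -> float:
    """Single-pool CO2 production (mol/day).

    ``rCO2 = (N / 2.078) * (k_o - k_d) - 0.0062 * k_d * N``; N is the
    oxygen dilution space.  A non-positive rate divergence (k_o <= k_d)
    is unphysical and yields a negative value; callers flag it as a
    dosing discrepancy rather than raising.
    """
    if n_mol <= 0:
        raise ValueError("dilution space must be > 0")
    return (n_mol / 2.078) * (k_o - k_d) - 0.0062 * k_d * n_mol


def dee_from_rco2(
    rco2_mol_day: float,
    energy_equivalent: float = ENERGY_EQUIV_KJ_PER_L,
    molar_volume: float = MOLAR_VOLUME_L,
) -> float:
    """DEE (kJ/day) = rCO2 * molar volume (L/mol) * energy equivalent (kJ/L)."""
    return rco2_mol_day * molar_volume * energy_equivalent


def estimate_dee(
    dosing: DlwDosing,
    thresholds: QcThresholds | None = None,
    energy_equivalent: float = ENERGY_EQUIV_KJ_PER_L,
    molar_volume: float = MOLAR_VOLUME_L,
) -> DeeResult:
    """Full single-pool DLW workup for one dosing, with QC flags.

    Flags (``below_background``, ``dosing_discrepancy``, ``window_invalid``,
    ``body_water_implausible``) are data outcomes, not errors; a flagged
    record carries no DEE value.
    """
    thresholds = thresholds or QcThresholds()
    result = DeeResult(
        individual_id=dosing.individual_id,
        season=dosing.season,
        year=dosing.year,
    )

    lo, hi = thresholds.window_days
    if not (lo <= dosing.t_final <= hi):
        result.qc_flags.append("window_invalid")

    margin = thresholds.background_margin_ppm
    if (dosing.ef_18o - dosing.bg_18o) < margin or (
        dosing.ef_2h - dosing.bg_2h
    ) < margin:
        result.qc_flags.append("below_background")
        return result

    t = dosing.elapsed_days
    try:
        result.k_o = elimination_rate(
            dosing.e0_18o, dosing.ef_18o, dosing.bg_18o, t
        )
        result.k_d = elimination_rate(
            dosing.e0_2h, dosing.ef_2h, dosing.bg_2h, t
        )
        result.n_o = dilution_space(
            dosing.dose_g, dosing.ie_18o, dosing.e0_18o, dosing.bg_18o, "18O"
        )
        result.n_d = dilution_space(
            dosing.dose_g, dosing.ie_2h, dosing.e0_2h, dosing.bg_2h, "2H"
        )
    except BelowBackgroundError:
        result.qc_flags.append("below_background")
        return result

    result.dilution_space_ratio = result.n_d / result.n_o
    # N_o in kg of water over body weight: plausibility band on body water
    result.body_water_fraction = (
        result.n_o * 18.015e-3 / dosing.weight_kg
    )

    if not (
        thresholds.ratio_low
        <= result.dilution_space_ratio
        <= thresholds.ratio_high
    ):
        result.qc_flags.append("dosing_discrepancy")
    if not (
        thresholds.body_water_low
        <= result.body_water_fraction
        <= thresholds.body_water_high
    ):
        result.qc_flags.append("body_water_implausible")
    if result.k_o <= result.k_d:
        result.qc_flags.append("dosing_discrepancy")

    if result.qc_flags:
        return result

    result.rco2 = rco2_single_pool(result.n_o, result.k_o, result.k_d)
    if result.rco2 <= 0:
        result.qc_flags.append("dosing_discrepancy")
        result.rco2 = None
        return result
    result.dee_kj_day = dee_from_rco2(
        result.rco2, energy_equivalent, molar_volume
    )
    return result


def qc_filter(
    results: Iterable[DeeResult],
) -> tuple[list[DeeResult], list[DeeResult]]:
    """Split workups into (retained, excluded); exclusions keep their flags."""
    retained, excluded = [], []
    for r in results:
        (retained if r.retained else excluded).append(r)
    return retained, excluded


def delta_to_ppm(delta_permil: float, isotope: Isotope) -> float:
    """Convert a delta value (per mil vs VSMOW) to ppm of the heavy isotope."""
    ratio = VSMOW_RATIO_PPM[isotope] * 1e-6 * (1.0 + delta_permil / 1000.0)
    return ratio / (1.0 + ratio) * 1e6
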