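"""Gestational scaling of plasma protein binding and enzyme activities.

Fraction unbound follows a 1:1 albumin-association model,
``fu(FW) = 1 / (1 + KA * P(FW) / MW_albumin)``, with the association
constant KA pre-solved so the model reproduces the measured non-pregnant
fu at the calibration week.  Enzyme activities follow published
probe-substrate trajectories of fertilization week:

* CYP1A2 — quadratic percent change fitted to caffeine apparent clearance,
  ``0.0291 FW^2 - 2.77 FW`` (a decline);
* UGT1A4 — cubic percent change fitted to lamotrigine apparent clearance,
  ``8.669 FW - 0.339 FW^2 + 0.00462 FW^3`` (an induction);
* CYP3A4 — cubic activity multiplier from midazolam modelling,
  ``1.00736 + 0.00564 FW + 0.00172 FW^2 - 0.00003 FW^3``;
* FMO3 — a late-pregnancy step (third trimester) inferred from nicotine
  N'-oxidation; CYP2C8 is assumed unchanged.

A canonical trimester parameter table (FW 6/20/34) is shipped verbatim;
the equation-generated mode covers arbitrary FW and is continuous, but
deviates a few percent from the canonical table for CYP1A2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compound import ENZYMES, CompoundParameters
from .physiology import albumin_concentration

__all__ = [
    "MW_ALBUMIN",
    "TABLE_TRIMESTER",
    "UGT1A4_CUBIC",
    "PlasmaBindingModel",
    "EnzymeActivityProfile",
    "fraction_unbound",
    "cyp1a2_activity_change",
    "ugt1a4_activity_change",
    "cyp3a4_activity",
    "fmo3_activity",
    "pregnant_compound_params",
    "fit_ugt1a4_cubic",
]

logger = logging.getLogger(__name__)

MW_ALBUMIN = 66_500.0  # g/mol

#: Canonical trimester parameter sets at the representative weeks.
TABLE_TRIMESTER: dict[int, dict] = {
    6: {"fu": 0.075, "CLint": {"CYP1A2": 22.40, "CYP3A4": 0.89,
                               "CYP2C8": 2.14, "FMO3": 4.05, "UGT1A4": 28.24}},
    20: {"fu": 0.085, "CLint": {"CYP1A2": 14.13, "CYP3A4": 1.28,
                                "CYP2C8": 2.14, "FMO3": 4.05, "UGT1A4": 35.04}},
    34: {"fu": 0.091, "CLint": {"CYP1A2": 9.87, "CYP3A4": 1.64,
                                "CYP2C8": 2.14, "FMO3": 7.11, "UGT1A4": 36.91}},
}

#: Published cubic coefficients of the UGT1A4 activity change (percent).
UGT1A4_CUBIC = (8.669, -0.339, 0.00462)

#: Third-trimester onset of the FMO3 activity step (start of trimester 3).
FMO3_ONSET_FW = 27.0
#: Canonical third-trimester FMO3 multiplier (7.11 / 4.05).
FMO3_CANONICAL_MULTIPLIER = 7.11 / 4.05
#: Literature multiplier: +58% in late pregnancy.
FMO3_LITERATURE_MULTIPLIER = 1.58


class UncalibratedModelError(RuntimeError):
    pass


@dataclass
class PlasmaBindingModel:
    """1:1 drug-albumin association model calibrated to a measured fu."""

    KA: float                   # per-umol association constant
    MW_albumin: float = MW_ALBUMIN
    fu_ref: float | None = None
    calibration_FW: float = 0.0

    @classmethod
    def calibrate(cls, fu_ref: float, calibration_FW: float = 0.0,
                  MW_albumin: float = MW_ALBUMIN) -> "PlasmaBindingModel":
        """Solve KA so that fu(calibration_FW) equals the measured value."""
        p_umol = albumin_concentration(calibration_FW) / MW_albumin * 1e6
        ka = (1.0 / fu_ref - 1.0) / p_umol
        return cls(KA=ka, MW_albumin=MW_albumin, fu_ref=fu_ref,
                   calibration_FW=calibration_FW)


def fraction_unbound(fw: float, binding: PlasmaBindingModel) -> float:
    """fu at fertilization week ``fw`` under the albumin binding model."""
    if fw < 0:
        raise ValueError("fertilization week must be >= 0")
    if binding.KA is None or binding.KA <= 0:
        raise UncalibratedModelError("binding model is not calibrated")
    p_umol = albumin_concentration(fw) / binding.MW_albumin * 1e6
    return 1.0 / (1.0 + binding.KA * p_umol)


# ---------------------------------------------------------------------------
# enzyme activity trajectories

def cyp1a2_activity_change(fw: float) -> float:
    """Percent change in CYP1A2 activity (negative during pregnancy)."""
    if fw < 0:
        raise ValueError("fertilization week must be >= 0")
    return 0.0291 * fw ** 2 - 2.77 * fw


def ugt1a4_activity_change(fw: float) -> float:
    """Percent change in UGT1A4 activity (positive during pregnancy)."""
    if fw < 0:
        raise ValueError("fertilization week must be >= 0")
    a1, a2, a3 = UGT1A4_CUBIC
    return a1 * fw + a2 * fw ** 2 + a3 * fw ** 3


def cyp3a4_activity(fw: float) -> float:
    """CYP3A4 activity multiplier (applied raw; 1.00736 at FW 0)."""
    if fw < 0:
        raise ValueError("fertilization week must be >= 0")
    return 1.00736 + 0.00564 * fw + 0.00172 * fw ** 2 - 0.00003 * fw ** 3


def fmo3_activity(fw: float, mode: str = "table_canonical") -> float:
    """FMO3 activity multiplier: 1.0 until the third trimester, then a step.

    ``table_canonical`` uses the canonical trimester-table step (+75.6%);
    ``literature`` uses the published late-pregnancy +58%.
    """
    if fw < 0:
        raise ValueError("fertilization week must be >= 0")
    step = {"table_canonical": FMO3_CANONICAL_MULTIPLIER,
            "literature": FMO3_LITERATURE_MULTIPLIER}[mode]
    return step if fw >= FMO3_ONSET_FW else 1.0


@dataclass
class EnzymeActivityProfile:
    """Activity multiplier of one enzyme as a function of FW."""

    enzyme: str

    def multiplier(self, fw: float) -> float:
        if self.enzyme == "CYP1A2":
            return 1.0 + cyp1a2_activity_change(fw) / 100.0
        if self.enzyme == "UGT1A4":
            return 1.0 + ugt1a4_activity_change(fw) / 100.0
        if self.enzyme == "CYP3A4":
            return cyp3a4_activity(fw)
        if self.enzyme == "FMO3":
            return fmo3_activity(fw)
        if self.enzyme == "CYP2C8":
            return 1.0
        raise ValueError(f"unknown enzyme: {self.enzyme}")

    @property
    def canonical_trimester_values(self) -> dict[int, float]:
        return {fw: TABLE_TRIMESTER[fw]["CLint"][self.enzyme]
                for fw in (6, 20, 34)}


def activity_profile_frame(fw_grid=None):
    """Activity multipliers on an FW grid (for CSV export / plotting)."""
    import pandas as pd

    if fw_grid is None:
        fw_grid = np.arange(0.0, 38.5, 0.5)
    rows = {"FW": np.asarray(fw_grid, dtype=float)}
    for enz in ENZYMES:
        prof = EnzymeActivityProfile(enz)
        rows[enz] = [prof.multiplier(fw) for fw in rows["FW"]]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pregnant parameter assembly

def pregnant_compound_params(base: CompoundParameters, fw: float,
                             mode: str = "table2_canonical",
                             binding: PlasmaBindingModel | None = None
                             ) -> CompoundParameters:
    """Gestational-week-specific compound parameters.

    ``table2_canonical`` returns the canonical trimester table verbatim at
    FW 6/20/34 and falls back to equation mode (with a logged warning) at
    other weeks; ``equation_generated`` evaluates the activity trajectories
    at any FW and is continuous.  CYP2C8 is never changed.
    """
    if fw < 0:
        raise ValueError("fertilization week must be >= 0")
    if mode not in ("table2_canonical", "equation_generated"):
        raise ValueError(f"unknown mode: {mode}")
    if binding is None:
        binding = PlasmaBindingModel.calibrate(base.fu, calibration_FW=0.0)

    if mode == "table2_canonical":
        key = int(fw) if float(fw).is_integer() else None
        if key in TABLE_TRIMESTER:
            row = TABLE_TRIMESTER[key]
            return base.with_updates(fu=row["fu"], CLint=dict(row["CLint"]))
        logger.warning(
            "canonical trimester table has no entry at FW=%s; "
            "falling back to equation-generated parameters", fw)

    fu = fraction_unbound(fw, binding)
    clint = {
        enz: base.CLint[enz] * EnzymeActivityProfile(enz).multiplier(fw)
        for enz in base.CLint
    }
    return base.with_updates(fu=fu, CLint=clint)


def fit_ugt1a4_cubic(points) -> tuple[float, float, float]:
    """Weighted least-squares cubic through the origin.

    ``points`` is an iterable of ``(FW, percent_change, weight)``; weights
    are typically clinical study sizes.  Returns the coefficients
    ``(a1, a2, a3)`` of ``a1*FW + a2*FW^2 + a3*FW^3``.
    """
    pts = np.asarray([(fw, y, w) for fw, y, w in points], dtype=float)
    if len(pts) < 4:
        raise ValueError("at least 4 points are required for a cubic fit")
    if np.any(pts[:, 2] <= 0):
        raise ValueError("weights must be positive")
    fw, y, w = pts.T
    design = np.column_stack([fw, fw ** 2, fw ** 3])
    sw = np.sqrt(w)
    a, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient design for cubic fit")
    return tuple(a)
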