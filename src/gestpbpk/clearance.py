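"""Elimination processes and fraction-metabolized bookkeeping.

Hepatic metabolism is first-order in the unbound hepatic concentration,
one process per enzyme.  Because the published whole-body intrinsic
clearances were fitted inside a platform whose enzymes carry individual
expression scalings, the raw CLint values alone do not reproduce the
published in-vivo dose fractions (f_m).  The engine therefore applies
per-enzyme activity scalings calibrated analytically, once, at the
non-pregnant reference so that the simulated baseline dose fractions equal
the in-vivo anchors (mass balance and DDI derived) — a middle-out
parameterization.  Renal elimination is passive: glomerular filtration of
unbound drug plus kidney-volume-normalized tubular secretion of unbound
drug.

The competitive-inhibition AUC-ratio algebra (Rowland-Matin relation) used
to derive the CYP1A2 contribution from a DDI study is implemented with its
exact inverse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .compound import ENZYMES, CompoundParameters, ConfigurationError
from .physiology import PhysiologyState

__all__ = [
    "RowlandMartinInputs",
    "ClearanceBreakdown",
    "rowland_matin_aucr",
    "solve_fm_from_aucr",
    "renal_clearance",
    "hepatic_activity_scalings",
    "clearance_breakdown",
    "apply_static_inhibition",
]


@dataclass(frozen=True)
class RowlandMartinInputs:
    """Inputs of the competitive-inhibition AUC-ratio relation."""

    fm_total: float        # total hepatically metabolized fraction
    fm_cyp1a2: float       # within-metabolism CYP1A2 share
    inhibition_ratio: float  # unbound inhibitor conc / Ki
    Fg_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fm_total <= 1.0:
            raise ValueError("fm_total must be in [0, 1]")
        if not 0.0 <= self.fm_cyp1a2 <= 1.0:
            raise ValueError("fm_cyp1a2 must be in [0, 1]")
        if self.inhibition_ratio < 0:
            raise ValueError("inhibition ratio must be >= 0")
        if self.Fg_ratio <= 0:
            raise ValueError("Fg_ratio must be positive")


def rowland_matin_aucr(x: RowlandMartinInputs) -> float:
    """AUC ratio under competitive inhibition of one enzyme."""
    q = x.fm_total * x.fm_cyp1a2
    r = x.inhibition_ratio
    inhibited = 0.0 if math.isinf(r) else q / (1.0 + r)
    return x.Fg_ratio / (inhibited + (1.0 - q))


def solve_fm_from_aucr(aucr: float, r: float, Fg_ratio: float = 1.0) -> float:
    """Invert the AUC-ratio relation for the inhibited-pathway fraction.

    Returns ``fm_total * fm_cyp1a2``.  Requires ``aucr >= 1`` (an
    inhibitor cannot decrease exposure in this model) and, for a finite
    solution, ``r > 0`` whenever ``aucr > 1``.
    """
    if aucr < 1.0:
        raise ValueError(f"AUC ratio must be >= 1, got {aucr}")
    if r < 0:
        raise ValueError("inhibition ratio must be >= 0")
    base = 1.0 - Fg_ratio / aucr
    if math.isinf(r):
        q = base
    else:
        if r == 0.0:
            if base > 1e-12:
                raise ValueError("aucr > 1 has no solution with r = 0")
            return 0.0
        q = base * (1.0 + r) / r
    if not -1e-12 <= q <= 1.0 + 1e-12:
        raise ValueError(f"no solution in [0, 1]: fm product = {q:.4f}")
    return min(max(q, 0.0), 1.0)


# ---------------------------------------------------------------------------
# renal and hepatic elimination

def renal_clearance(cp: CompoundParameters, phys: PhysiologyState) -> float:
    """Renal plasma clearance (L/h) referenced to unbound-equilibrated kidney.

    Passive filtration of unbound drug (``GFR_fraction * GFR * fu``) plus
    passive tubular secretion of unbound drug normalized to kidney volume
    (``CL_TSspec * V_kidney * 60 * fu``).  Both terms scale with fu and the
    secretion term with kidney volume, so pregnancy acts only through
    those quantities.
    """
    filtration = cp.GFR_fraction * phys.gfr * cp.fu
    secretion = cp.CL_TSspec * phys.kidney_volume * 60.0 * cp.fu
    return filtration + secretion


def hepatic_activity_scalings(cp_ref: CompoundParameters,
                              phys_ref: PhysiologyState) -> dict[str, float]:
    """Per-enzyme activity scalings from the in-vivo dose-fraction anchors.

    Solves, in closed form, for dimensionless factors ``A_E`` such that the
    plasma-referenced hepatic clearance of enzyme E at the reference state,
    ``A_E * CLint_E * fu``, stands in the published in-vivo proportion to
    the renal clearance: ``CL_E / CL_R = fm_E / fR``.  The factors are
    fixed thereafter; gestational change enters only through CLint(FW) and
    fu(FW).
    """
    if not cp_ref.fm_targets or cp_ref.fR_target <= 0:
        raise ConfigurationError(
            "compound lacks fm/fR anchors required for hepatic calibration")
    cl_r = renal_clearance(cp_ref, phys_ref)
    scalings = {}
    for enz in ENZYMES:
        clint = cp_ref.CLint.get(enz, 0.0)
        fm = cp_ref.fm_targets.get(enz, 0.0)
        if clint <= 0 or fm <= 0:
            scalings[enz] = 0.0
            continue
        cl_e = fm / cp_ref.fR_target * cl_r
        scalings[enz] = cl_e / (clint * cp_ref.fu)
    return scalings


def apply_static_inhibition(cp: CompoundParameters, enzyme: str,
                            r: float) -> CompoundParameters:
    """Competitive inhibition as a static CLint scaling by 1/(1+r)."""
    if enzyme not in ENZYMES:
        raise ConfigurationError(f"unknown enzyme: {enzyme}")
    if r < 0:
        raise ValueError("inhibition ratio must be >= 0")
    factor = 0.0 if math.isinf(r) else 1.0 / (1.0 + r)
    clint = dict(cp.CLint)
    clint[enzyme] = clint.get(enzyme, 0.0) * factor
    return cp.with_updates(CLint=clint)


# ---------------------------------------------------------------------------
# breakdown of eliminated dose

@dataclass(frozen=True)
class ClearanceBreakdown:
    """Fractions of the eliminated dose per pathway (sum to 1)."""

    fractions: dict[str, float]   # enzyme names + "renal"

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {total:.8f}")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def renal(self) -> float:
        return self.fractions["renal"]

    def enzyme_fraction(self, enzyme: str) -> float:
        return self.fractions[enzyme]


def clearance_breakdown(sim) -> ClearanceBreakdown:
    """Fractions of eliminated dose per pathway from a simulation.

    Uses the cumulative per-pathway eliminated amounts at the end of the
    trajectory.  If less than 95% of the absorbed dose has been eliminated
    the simulated span was short of the recommended >= 7 terminal
    half-lives; the (asymptotically constant) flux proportions are still
    returned, with a warning.
    """
    eliminated = {k: v[-1] for k, v in sim.eliminated.items()
                  if k != "feces"}
    total = sum(eliminated.values())
    if total <= 0:
        raise ValueError("no drug eliminated in the simulation")
    absorbed = sim.absorbed_amount()
    if absorbed > 0 and total < 0.95 * absorbed:
        warnings.warn(
            "simulation covers < 95% of absorbed dose elimination; "
            "breakdown uses the cumulative proportions to date",
            RuntimeWarning, stacklevel=2)
    return ClearanceBreakdown({k: v / total for k, v in eliminated.items()})
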