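"""Compound parameters and composition-based tissue partitioning.

The drug is described by its published physicochemical/ADME parameter set
(lipophilicity, monoprotic-base ionization, plasma protein binding,
dissolution, transcellular permeability, per-enzyme whole-body intrinsic
clearances and renal terms).  Tissue-to-plasma partition coefficients are
computed with a Schmitt-type composition scheme: the drug distributes into
tissue water (with pH-driven ion accumulation of the protonated base),
neutral lipid, phospholipid (with an electrostatic enhancement for the
cation) and tissue protein.  The tissue protein affinity is back-calculated
from the measured plasma fraction unbound, so a tissue whose composition
equals plasma has Kp = 1 exactly.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ENZYMES",
    "CompoundParameters",
    "TissueComposition",
    "default_olanzapine",
    "load_compound",
    "load_tissue_compositions",
    "ionized_fraction",
    "tissue_protein_affinity",
    "partition_coefficients",
]

ENZYMES = ("CYP1A2", "CYP3A4", "CYP2C8", "FMO3", "UGT1A4")

PLASMA_PH = 7.4
#: log10 attenuation of lipid partitioning for the ionized species.
ION_LOGP_SHIFT = 3.5
#: Electrostatic enhancement of cation binding to (acidic) phospholipids.
CATION_PHOSPHOLIPID_FACTOR = 20.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TissueComposition:
    """Volume-fraction composition of one tissue plus its water pH."""

    water: float
    neutral_lipid: float
    phospholipid: float
    protein: float
    pH: float

    def __post_init__(self) -> None:
        for name in ("water", "neutral_lipid", "phospholipid", "protein"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fraction out of [0, 1]: {v}")
        if self.water + self.neutral_lipid + self.phospholipid + self.protein > 1.0 + 1e-9:
            raise ValueError("composition fractions exceed 1")


@dataclass
class CompoundParameters:
    """Physicochemical/ADME parameter set of a monoprotic base.

    ``CLint`` entries are whole-body-normalized first-order intrinsic
    clearances (L/h) acting on the unbound hepatic concentration.
    ``fm_targets``/``fR_target`` are in-vivo anchors for the fraction of
    dose eliminated per pathway; they calibrate enzyme activity scalings
    and serve as checks, not as direct rate inputs.
    """

    name: str
    logP: float
    MW: float                   # g/mol
    pKa: float
    fu: float                   # fraction unbound in plasma
    solubility: float           # ug/mL
    dissolution_t50: float      # min
    transcellular_permeability: float  # cm/min
    CLint: dict[str, float]     # enzyme -> L/h
    GFR_fraction: float = 1.0
    CL_TSspec: float = 0.0      # L/min per L kidney (tubular secretion)
    fR_target: float = 0.07
    fm_targets: dict[str, float] = field(default_factory=dict)
    blood_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fu <= 1.0:
            raise ValueError(f"fu must be in (0, 1], got {self.fu}")
        if self.MW <= 0:
            raise ValueError("MW must be positive")
        for enz, cl in self.CLint.items():
            if enz not in ENZYMES:
                raise ConfigurationError(f"unknown enzyme: {enz}")
            if cl < 0:
                raise ValueError(f"CLint must be >= 0: {enz}={cl}")

    @property
    def total_CLint(self) -> float:
        return sum(self.CLint.values())

    def with_updates(self, **kwargs) -> "CompoundParameters":
        """Return a copy with the given fields replaced."""
        out = replace(self, **{k: v for k, v in kwargs.items() if k != "CLint"})
        if "CLint" in kwargs:
            out.CLint = dict(kwargs["CLint"])
        else:
            out.CLint = dict(self.CLint)
        out.fm_targets = dict(self.fm_targets)
        return out

    def copy(self) -> "CompoundParameters":
        return copy.deepcopy(self)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gestpbpk").joinpath("data", name)))


def load_compound(path: str | Path) -> CompoundParameters:
    """Read a compound parameter file (structured text mirroring the
    published input-parameter table)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw.get("dissociation_type", "monoprotic_base") != "monoprotic_base":
        raise ConfigurationError("only monoprotic bases are supported")
    return CompoundParameters(
        name=raw["name"],
        logP=float(raw["logP"]),
        MW=float(raw["MW_g_per_mol"]),
        pKa=float(raw["pKa"]),
        fu=float(raw["fu_fraction"]),
        solubility=float(raw["solubility_ug_per_mL"]),
        dissolution_t50=float(raw["dissolution_t50_min"]),
        transcellular_permeability=float(raw["transcellular_permeability_cm_per_min"]),
        CLint={k: float(v) for k, v in raw["CLint_L_per_h"].items()},
        GFR_fraction=float(raw.get("GFR_fraction", 1.0)),
        CL_TSspec=float(raw.get("CL_TSspec_L_per_min", 0.0)),
        fR_target=float(raw.get("fR_target", 0.0)),
        fm_targets={k: float(v) for k, v in raw.get("fm_targets", {}).items()},
        blood_plasma_ratio=float(raw.get("blood_plasma_ratio", 1.0)),
    )


def default_olanzapine() -> CompoundParameters:
    """The packaged olanzapine parameter set."""
    return load_compound(_data_path("olanzapine.yaml"))


def load_tissue_compositions(path: str | Path | None = None
                             ) -> dict[str, TissueComposition]:
    if path is None:
        path = _data_path("tissue_composition.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        organ: TissueComposition(**{k: float(v) for k, v in comp.items()})
        for organ, comp in raw["compositions"].items()
    }


# ---------------------------------------------------------------------------
# partitioning

def ionized_fraction(pKa: float, pH: float) -> float:
    """Henderson-Hasselbalch protonated fraction of a monoprotic base."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH out of range: {pH}")
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def _alpha(pKa: float, pH: float) -> float:
    """Total-to-neutral concentration ratio in water for a monoprotic base."""
    return 1.0 + 10.0 ** (pKa - pH)


def _tissue_water_affinity(cp: CompoundParameters, tc: TissueComposition,
                           protein_affinity: float) -> float:
    """Tissue concentration per unit neutral-species water concentration."""
    p = 10.0 ** cp.logP
    p_ion = p * 10.0 ** (-ION_LOGP_SHIFT)
    alpha_t = _alpha(cp.pKa, tc.pH)
    cation = alpha_t - 1.0
    return (
        alpha_t * tc.water
        + (p + cation * p_ion) * tc.neutral_lipid
        + (p + cation * p_ion * CATION_PHOSPHOLIPID_FACTOR) * tc.phospholipid
        + protein_affinity * tc.protein
    )


def tissue_protein_affinity(cp: CompoundParameters,
                            plasma: TissueComposition | None = None) -> float:
    """Protein partition coefficient back-calculated from plasma binding.

    Solves the plasma composition balance so that the composition-based
    plasma affinity reproduces the measured fu exactly; the same protein
    affinity is then assumed for tissue proteins.  Clamped at zero when
    lipid partitioning alone would exceed the measured binding.
    """
    if plasma is None:
        plasma = load_tissue_compositions()["plasma"]
    lipid_and_water = _tissue_water_affinity(
        cp, replace(plasma, protein=0.0), protein_affinity=0.0
    )
    target = _alpha(cp.pKa, plasma.pH) / cp.fu
    return max((target - lipid_and_water) / plasma.protein, 0.0)


def partition_coefficients(cp: CompoundParameters,
                           compositions: dict[str, TissueComposition],
                           organs: list[str] | None = None,
                           protein_affinity: float | None = None
                           ) -> dict[str, float]:
    """Tissue-to-plasma partition coefficients (total tissue / total plasma).

    ``protein_affinity`` may be supplied to pin the tissue protein binding
    at a reference value (used when fu itself changes, e.g. in pregnancy,
    so that only the plasma side of the equilibrium moves).
    """
    if "plasma" not in compositions:
        raise ConfigurationError("compositions must include a 'plasma' entry")
    plasma = compositions["plasma"]
    if protein_affinity is None:
        protein_affinity = tissue_protein_affinity(cp, plasma)
    if organs is None:
        organs = [o for o in compositions if o != "plasma"]
    plasma_affinity = _alpha(cp.pKa, plasma.pH) / cp.fu
    kps: dict[str, float] = {}
    for organ in organs:
        if organ not in compositions:
            raise ConfigurationError(f"missing tissue composition: {organ}")
        k = _tissue_water_affinity(cp, compositions[organ], protein_affinity)
        kps[organ] = k / plasma_affinity
    return kps
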