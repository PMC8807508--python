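"""Reference adult physiology and its gestational transformation.

The body is represented by the standard 18-compartment small-molecule
layout (14 perfused organs, portal vein, arterial and venous blood, and a
gut lumen handled by the absorption sub-model).  Pregnancy adds perfused
gestational compartments (placenta, uterus, mammary glands) plus two inert
volumes (a lumped fetal mass and amniotic fluid) that carry no drug.

All pregnancy scaling is driven by the fertilization week FW (gestational
age minus two weeks).  Plasma albumin follows the published exponential
decline ``P(FW) = 14.7 exp(-0.0454 FW) + 31.7`` g/L, which anchors the
gestational change in plasma protein binding.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "PERFUSED_ORGANS",
    "SPLANCHNIC_ORGANS",
    "GESTATIONAL_PERFUSED",
    "GESTATIONAL_INERT",
    "PhysiologyState",
    "albumin_concentration",
    "reference_physiology",
    "pregnancy_physiology",
]

#: Perfused maternal organs (lung is perfused by the full cardiac output).
PERFUSED_ORGANS = (
    "lung", "brain", "heart", "kidney", "liver", "gut_wall", "stomach",
    "spleen", "pancreas", "muscle", "adipose", "skin", "bone", "gonads",
)

#: Organs draining into the portal vein (pre-hepatic).
SPLANCHNIC_ORGANS = ("stomach", "gut_wall", "spleen", "pancreas")

#: Gestational compartments that exchange drug with arterial blood.
GESTATIONAL_PERFUSED = ("placenta", "uterus", "mammary")

#: Gestational volumes that carry no drug (no placental transfer modelled).
GESTATIONAL_INERT = ("fetus", "amniotic_fluid")

_ALBUMIN_AMPLITUDE = 14.7   # g/L
_ALBUMIN_RATE = 0.0454      # 1/week
_ALBUMIN_ASYMPTOTE = 31.7   # g/L

_FLOW_BALANCE_RTOL = 1e-6


class ConfigurationError(ValueError):
    """Raised for unsupported or inconsistent physiological configuration."""


def albumin_concentration(fw: float) -> float:
    """Plasma albumin (g/L) at fertilization week ``fw``.

    Exponential decline from 46.4 g/L at FW 0 toward a 31.7 g/L asymptote.
    """
    if fw < 0:
        raise ValueError(f"fertilization week must be >= 0, got {fw}")
    return _ALBUMIN_AMPLITUDE * math.exp(-_ALBUMIN_RATE * fw) + _ALBUMIN_ASYMPTOTE


@dataclass
class PhysiologyState:
    """Snapshot of anatomy/physiology at a given fertilization week.

    ``blood_flows`` holds the arterial draw of every perfused organ (the
    ``liver`` entry is the hepatic-arterial flow only); their sum equals the
    cardiac output.  Total liver perfusion additionally receives the portal
    drainage of the splanchnic organs (see :meth:`liver_blood_flow`).
    """

    fertilization_week: float
    organ_volumes: dict[str, float]     # L
    blood_flows: dict[str, float]       # L/h, arterial draws
    cardiac_output: float               # L/h
    gfr: float                          # L/h
    albumin: float                      # g/L
    hematocrit: float                   # fraction
    body_weight: float                  # kg
    sex: str = "female"
    lumen_volume_mL: float = 250.0
    intestinal_surface_area_m2: float = 50.0
    intestinal_transit_h: float = 3.3
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def kidney_volume(self) -> float:
        return self.organ_volumes["kidney"]

    @property
    def liver_volume(self) -> float:
        return self.organ_volumes["liver"]

    @property
    def liver_blood_flow(self) -> float:
        """Total liver perfusion: hepatic artery plus portal drainage (L/h)."""
        return self.blood_flows["liver"] + sum(
            self.blood_flows[o] for o in SPLANCHNIC_ORGANS
        )

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.fertilization_week < 0:
            raise ValueError("fertilization_week must be >= 0")
        for name, v in self.organ_volumes.items():
            if v <= 0 and name not in GESTATIONAL_INERT + GESTATIONAL_PERFUSED:
                raise ValueError(f"organ volume must be positive: {name}={v}")
        for name, q in self.blood_flows.items():
            if q < 0:
                raise ValueError(f"blood flow must be non-negative: {name}={q}")
        total = sum(self.blood_flows.values())
        if not math.isclose(total, self.cardiac_output,
                            rel_tol=_FLOW_BALANCE_RTOL):
            raise ValueError(
                f"organ blood flows ({total:.6f} L/h) do not balance cardiac "
                f"output ({self.cardiac_output:.6f} L/h)"
            )
        expected_albumin = albumin_concentration(self.fertilization_week)
        if not math.isclose(self.albumin, expected_albumin, rel_tol=1e-9):
            raise ValueError(
                f"albumin {self.albumin} g/L inconsistent with FW "
                f"{self.fertilization_week} (expected {expected_albumin:.4f})"
            )
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must be a fraction in (0, 1)")

    def copy(self) -> "PhysiologyState":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# constants loading

def _data_path(name: str) -> Path:
    return Path(str(resources.files("gestpbpk").joinpath("data", name)))


def load_reference_constants(sex: str = "female",
                             path: str | Path | None = None) -> dict:
    """Load the versioned reference-physiology constants file.

    A user file given by ``path`` overrides the packaged tables.
    """
    if path is None:
        if sex not in ("female", "male"):
            raise ConfigurationError(f"unsupported sex: {sex!r}")
        path = _data_path(f"reference_physiology_{sex}.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def reference_physiology(sex: str = "female", age: float = 30.0,
                         constants_path: str | Path | None = None
                         ) -> PhysiologyState:
    """Reference non-pregnant adult at FW 0.

    Organ volumes and flows come from the versioned ICRP-style constants
    file; albumin is set to the FW-0 value of the gestational albumin
    trajectory so that pregnancy scaling is the identity at baseline.
    """
    consts = load_reference_constants(sex, constants_path)
    lo, hi = consts["age_range_years"]
    if not lo <= age <= hi:
        raise ConfigurationError(
            f"age {age} outside supported range [{lo}, {hi}]"
        )
    co = float(consts["cardiac_output_L_per_h"])
    fractions = consts["blood_flow_fraction_of_CO"]
    flows = {organ: frac * co for organ, frac in fractions.items()}
    # Force exact balance against rounding in the fractions.
    total = sum(flows.values())
    flows = {o: q * co / total for o, q in flows.items()}
    return PhysiologyState(
        fertilization_week=0.0,
        organ_volumes={k: float(v) for k, v in consts["organ_volumes_L"].items()},
        blood_flows=flows,
        cardiac_output=co,
        gfr=float(consts["gfr_L_per_h"]),
        albumin=albumin_concentration(0.0),
        hematocrit=float(consts["hematocrit_fraction"]),
        body_weight=float(consts["body_weight_kg"]),
        sex=consts["sex"],
        lumen_volume_mL=float(consts["lumen_volume_mL"]),
        intestinal_surface_area_m2=float(consts["effective_intestinal_surface_area_m2"]),
        intestinal_transit_h=float(consts["absorbable_gut_residence_h"]),
        meta={"constants_version": consts.get("version"),
              "gestation": consts.get("gestation")},
    )


# ---------------------------------------------------------------------------
# gestational trajectories

def pregnancy_physiology(base: PhysiologyState, fw: float) -> PhysiologyState:
    """Apply gestational trajectories to a female reference state.

    At ``fw = 0`` the input state is returned unchanged.  Cardiac output,
    GFR, kidney and blood volumes, hematocrit and body weight follow smooth
    documented trajectories; gestational compartments grow from zero.  The
    absolute liver perfusion (hepatic artery + portal drainage) is held at
    its non-pregnant value; the cardiac-output increment is allocated to
    the utero-placental unit, kidneys, mammary glands, skin and adipose.
    """
    if base.sex != "female":
        raise ConfigurationError("pregnancy scaling requires a female state")
    if not 0.0 <= fw <= 40.0:
        raise ValueError(f"fertilization week out of range [0, 40]: {fw}")
    if fw == 0.0:
        return base.copy()
    g = base.meta.get("gestation")
    if g is None:
        raise ConfigurationError("reference state lacks gestational constants")

    term = float(g["term_fw"])
    s = min(fw, term) / term

    co0 = base.cardiac_output
    s_co = min(fw, g["cardiac_output_rise_end_fw"]) / g["cardiac_output_rise_end_fw"]
    co = co0 * (1.0 + g["cardiac_output_rise_fraction"] * s_co)
    delta_co = co - co0

    x = min(fw, g["gfr_rise_end_fw"]) / g["gfr_rise_end_fw"]
    gfr = base.gfr * (1.0 + g["gfr_rise_fraction"] * x * (2.0 - x))

    volumes = dict(base.organ_volumes)
    volumes["kidney"] *= 1.0 + g["kidney_volume_rise_fraction"] * s
    volumes["adipose"] += g["adipose_gain_L_at_term"] * s
    volumes["arterial_blood"] *= 1.0 + g["blood_volume_rise_fraction"] * s
    volumes["venous_blood"] *= 1.0 + g["blood_volume_rise_fraction"] * s
    volumes["placenta"] = g["placenta_L_at_term"] * s ** 2
    volumes["uterus"] = g["uterus_L_at_term"] * s ** 2
    volumes["mammary"] = g["mammary_L_at_term"] * s
    volumes["fetus"] = g["fetus_kg_at_term"] * s ** 3
    volumes["amniotic_fluid"] = g["amniotic_fluid_L_at_term"] * s ** 2

    flows = dict(base.blood_flows)
    shares = g["extra_co_shares"]
    flows["placenta"] = shares["placenta"] * delta_co * 0.85
    flows["uterus"] = shares["placenta"] * delta_co * 0.15
    flows["mammary"] = shares["mammary"] * delta_co
    flows["kidney"] += shares["kidney"] * delta_co
    flows["skin"] += shares["skin"] * delta_co
    flows["adipose"] += shares["adipose"] * delta_co

    gained = (
        volumes["placenta"] + volumes["uterus"] + volumes["mammary"]
        + volumes["fetus"] + volumes["amniotic_fluid"]
        + g["adipose_gain_L_at_term"] * s
        + (volumes["arterial_blood"] + volumes["venous_blood"]
           - base.organ_volumes["arterial_blood"]
           - base.organ_volumes["venous_blood"])
        + g["other_gain_kg_at_term"] * s
    )

    return PhysiologyState(
        fertilization_week=fw,
        organ_volumes=volumes,
        blood_flows=flows,
        cardiac_output=co,
        gfr=gfr,
        albumin=albumin_concentration(fw),
        hematocrit=base.hematocrit - g["hematocrit_drop"] * s,
        body_weight=base.body_weight + gained,
        sex=base.sex,
        lumen_volume_mL=base.lumen_volume_mL,
        intestinal_surface_area_m2=base.intestinal_surface_area_m2,
        intestinal_transit_h=base.intestinal_transit_h,
        meta=copy.deepcopy(base.meta),
    )
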