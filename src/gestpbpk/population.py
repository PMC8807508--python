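"""Seeded virtual populations and trajectory summaries.

Individuals vary in body size (log-normal weight factor scaling organ
volumes linearly and flows/GFR allometrically with exponent 0.75), in
fertilization week (uniform within the trimester range) and in clearance
terms (log-normal multipliers on each hepatic CLint and on the tubular
secretion term).  The pregnancy equation mode supplies each individual's
fu and enzyme activities at her sampled FW.  All sampling is reproducible
from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compound import CompoundParameters
from .engine import SimulationResult
from .physiology import PhysiologyState, pregnancy_physiology
from .pk_metrics import PKMetrics

__all__ = ["PopulationSpec", "generate_population", "population_summary",
           "summary_bands", "geometric_mean_metrics"]

DEFAULT_CLINT_CV = 0.35
DEFAULT_SECRETION_CV = 0.25
DEFAULT_WEIGHT_CV = 0.15
ALLOMETRIC_FLOW_EXPONENT = 0.75


@dataclass
class PopulationSpec:
    """Description of one virtual population."""

    n: int
    seed: int
    fw_range: tuple[float, float] | None = None   # None = non-pregnant
    age_range: tuple[float, float] = (20.0, 40.0)
    variability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if any(cv < 0 for cv in self.variability.values()):
            raise ValueError("CVs must be >= 0")

    def cv(self, key: str, default: float) -> float:
        return self.variability.get(key, default)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def _scale_body(phys: PhysiologyState, factor: float) -> PhysiologyState:
    volumes = {k: v * factor for k, v in phys.organ_volumes.items()}
    flow_factor = factor ** ALLOMETRIC_FLOW_EXPONENT
    flows = {k: q * flow_factor for k, q in phys.blood_flows.items()}
    return PhysiologyState(
        fertilization_week=phys.fertilization_week,
        organ_volumes=volumes, blood_flows=flows,
        cardiac_output=phys.cardiac_output * flow_factor,
        gfr=phys.gfr * flow_factor,
        albumin=phys.albumin, hematocrit=phys.hematocrit,
        body_weight=phys.body_weight * factor, sex=phys.sex,
        lumen_volume_mL=phys.lumen_volume_mL,
        intestinal_surface_area_m2=phys.intestinal_surface_area_m2,
        intestinal_transit_h=phys.intestinal_transit_h,
        meta=phys.meta,
    )


def generate_population(spec: PopulationSpec, base_phys: PhysiologyState,
                        base_cp: CompoundParameters
                        ) -> list[tuple[PhysiologyState, CompoundParameters]]:
    """Sample ``spec.n`` individuals from the reference pair.

    Pregnant individuals get their physiology and compound parameters
    evaluated at an FW drawn uniformly from ``fw_range`` (equation mode);
    the non-pregnant reference population keeps FW = 0.
    """
    from .pregnancy import pregnant_compound_params

    rng = np.random.default_rng(spec.seed)
    cv_cl = spec.cv("CLint", DEFAULT_CLINT_CV)
    cv_ts = spec.cv("CL_TSspec", DEFAULT_SECRETION_CV)
    cv_bw = spec.cv("body_weight", DEFAULT_WEIGHT_CV)

    individuals = []
    for _ in range(spec.n):
        # FW quantile is always drawn so that paired populations generated
        # from the same seed share their downstream variability draws.
        u = rng.uniform()
        fw = (spec.fw_range[0] + u * (spec.fw_range[1] - spec.fw_range[0])
              if spec.fw_range is not None else 0.0)
        phys = pregnancy_physiology(base_phys, fw)
        phys = _scale_body(phys, float(_lognormal_factor(rng, cv_bw)))
        cp = pregnant_compound_params(base_cp, fw, mode="equation_generated")
        clint = {enz: cl * float(_lognormal_factor(rng, cv_cl))
                 for enz, cl in cp.CLint.items()}
        cp = cp.with_updates(
            CLint=clint,
            CL_TSspec=cp.CL_TSspec * float(_lognormal_factor(rng, cv_ts)),
        )
        individuals.append((phys, cp))
    return individuals


def individuals_frame(individuals) -> pd.DataFrame:
    """Sampled individual parameters as one row per individual."""
    rows = []
    for phys, cp in individuals:
        row = {"FW": phys.fertilization_week,
               "body_weight_kg": phys.body_weight, "fu": cp.fu,
               "CL_TSspec": cp.CL_TSspec}
        row.update({f"CLint_{e}": v for e, v in cp.CLint.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries

def summary_bands(results: list[SimulationResult]) -> pd.DataFrame:
    """Per-time median and 5th-95th percentile band of plasma profiles."""
    if len(results) < 2:
        raise ValueError("at least 2 results are required")
    t0 = results[0].time
    for r in results[1:]:
        if len(r.time) != len(t0) or not np.allclose(r.time, t0):
            raise ValueError("simulation results are not on a common grid")
    conc = np.vstack([r.plasma_concentration for r in results])
    p05, p50, p95 = np.percentile(conc, [5, 50, 95], axis=0)
    return pd.DataFrame({"time_h": t0, "p05": p05, "p50": p50, "p95": p95})


def geometric_mean_metrics(metrics: list[PKMetrics]) -> PKMetrics:
    """Geometric means of per-individual PK metrics."""
    def gmean(vals):
        return float(np.exp(np.mean(np.log(vals))))

    mode = metrics[0].mode
    troughs = [m.c_trough for m in metrics]
    return PKMetrics(
        cmax=gmean([m.cmax for m in metrics]),
        tmax=gmean([m.tmax for m in metrics]),
        auc=gmean([m.auc for m in metrics]),
        t_half=gmean([m.t_half for m in metrics]),
        cl_over_f=gmean([m.cl_over_f for m in metrics]),
        c_trough=gmean(troughs) if all(t is not None for t in troughs) else None,
        mode=mode,
    )


def population_summary(results: list[SimulationResult],
                       metrics: list[PKMetrics] | None = None):
    """Bands plus (optionally) geometric-mean metrics."""
    bands = summary_bands(results)
    gm = geometric_mean_metrics(metrics) if metrics else None
    return bands, gm
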