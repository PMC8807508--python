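"""Synthetic inputs: noisy observed profiles, gestational clearance-change
points, and the packaged validation-study fold-error fixture.

All generators are pure functions of their inputs and a seed.  Observation
noise is multiplicative log-normal (concentrations are positive and study
variability is reported on the relative scale), with the mean-one
parameterization so that sampled means are unbiased estimators of the
underlying profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import FoldErrorTable, fold_error_table

__all__ = ["ObservedProfile", "generate_observed_profile",
           "generate_lamotrigine_points", "table4_fixture"]

#: Sample sizes of the three lamotrigine apparent-clearance studies.
DEFAULT_LAMOTRIGINE_STUDY_SIZES = (7, 11, 53)


@dataclass
class ObservedProfile:
    """Mean +/- SD concentration profile of one synthetic study."""

    study_id: str
    times: np.ndarray          # h
    mean_conc: np.ndarray      # ng/mL
    sd_conc: np.ndarray        # ng/mL
    n_subjects: int
    dose: float                # mg

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_conc < 0) or np.any(self.sd_conc < 0):
            raise ValueError("means and SDs must be >= 0")


def generate_observed_profile(truth, sample_times, cv: float,
                              n_subjects: int, seed: int,
                              study_id: str = "synthetic",
                              dose: float | None = None) -> ObservedProfile:
    """Emulate a digitized mean +/- SD study profile from a simulation.

    Per-subject multiplicative log-normal noise with the given CV is drawn
    around the true profile at ``sample_times``; the per-time mean and SD
    of the ``n_subjects`` draws are returned.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    times = np.asarray(sample_times, dtype=float)
    if times.min() < truth.time.min() - 1e-9 or times.max() > truth.time.max() + 1e-9:
        raise ValueError("sample times outside the simulated grid")
    true_conc = np.interp(times, truth.time, truth.plasma_concentration)
    rng = np.random.default_rng(seed)
    if cv == 0:
        draws = np.tile(true_conc, (n_subjects, 1))
    else:
        sigma = np.sqrt(np.log1p(cv ** 2))
        factors = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                                size=(n_subjects, len(times)))
        draws = true_conc[None, :] * factors
    return ObservedProfile(
        study_id=study_id, times=times,
        mean_conc=draws.mean(axis=0),
        sd_conc=draws.std(axis=0, ddof=1) if n_subjects > 1
        else np.zeros_like(times),
        n_subjects=n_subjects,
        dose=dose if dose is not None else truth.dosing_events[0][1],
    )


def generate_lamotrigine_points(coeffs, study_sizes=None, fw_values=None,
                                noise_sd: float = 0.0, seed: int = 0
                                ) -> list[tuple[float, float, float]]:
    """Synthetic gestational clearance-change points with study weights.

    Evaluates the cubic percent-change curve at ``fw_values`` and adds
    Gaussian noise scaled by 1/sqrt(weight) (larger studies are more
    precise).  Defaults emulate the three published lamotrigine studies.
    """
    if study_sizes is None:
        study_sizes = DEFAULT_LAMOTRIGINE_STUDY_SIZES
    if any(w <= 0 for w in study_sizes):
        raise ValueError("study sizes must be positive")
    if fw_values is None:
        fw_values = np.linspace(4.0, 38.0, 3 * len(study_sizes))
    fw_values = np.asarray(fw_values, dtype=float)
    weights = np.resize(np.asarray(study_sizes, dtype=float), len(fw_values))
    a1, a2, a3 = coeffs
    truth = a1 * fw_values + a2 * fw_values ** 2 + a3 * fw_values ** 3
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(fw_values)) / np.sqrt(weights)
    return [(float(fw), float(y), float(w))
            for fw, y, w in zip(fw_values, truth + noise, weights)]


def _fixture_path() -> Path:
    return Path(str(resources.files("gestpbpk").joinpath(
        "data", "table4_validation.csv")))


def table4_fixture() -> FoldErrorTable:
    """Packaged predicted/observed PK pairs of the ten validation studies
    (Cmax, AUC and tmax per study) with recomputed fold errors."""
    frame = pd.read_csv(_fixture_path())
    return fold_error_table(frame)
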