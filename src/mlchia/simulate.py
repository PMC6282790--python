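"""Synthetic MLC data with known ground truth.

Three generators cover every input of the pipeline:

* retention tables from the binding law k' = k'0 / (1 + K_AM * C_M)
  with multiplicative retention-time noise (antibinding via negative
  K_AM, restricted to K_AM * C_M > -1);
* Gaussian-peak chromatogram traces with optional solvent-front peak,
  linear baseline drift and additive detector noise;
* compound tables from the logit-linear absorption model
  logit(%HIA) = b0 + b1 * logP_mw + b2 * PSA + eps.

Defaults mirror the physiological experiment shape: six micellar levels
from 5-17 mM total surfactant (0.0046 M mixture CMC), three replicate
injections per level, and noise at the scale of the fitted residual
standard error.  All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hia import inverse_logit_hia
from .retention import Chromatogram

__all__ = [
    "RetentionSimSpec",
    "ChromatogramSimSpec",
    "CompoundSimSpec",
    "SimulationError",
    "DEFAULT_CM_LEVELS",
    "simulate_retention_table",
    "simulate_chromatogram",
    "simulate_compound_table",
]


class SimulationError(ValueError):
    """Non-physical or inconsistent simulation parameters."""


#: Micellar concentrations (M) for six total-surfactant levels evenly
#: spanning 5-17 mM, less the 0.0046 M mixture CMC.
DEFAULT_CM_LEVELS: tuple[float, ...] = tuple(
    round(total * 1e-3 - 0.0046, 7) for total in (5.0, 7.4, 9.8, 12.2, 14.6, 17.0)
)


@dataclass(frozen=True)
class RetentionSimSpec:
    """Ground truth and noise model for one drug's retention series."""

    drug: str = "synthetic"
    k_prime_0: float = 10.0
    k_am: float = 40.0
    t0: float = 1.5
    concentration_levels: tuple[float, ...] = DEFAULT_CM_LEVELS
    replicates: int = 3
    rt_noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_prime_0 <= 0:
            raise SimulationError("k_prime_0 must be > 0")
        if self.t0 <= 0:
            raise SimulationError("t0 must be > 0")
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")
        if self.rt_noise_cv < 0:
            raise SimulationError("rt_noise_cv must be >= 0")
        if any(c < 0 for c in self.concentration_levels):
            raise SimulationError("concentration levels must be >= 0 M")
        object.__setattr__(
            self, "concentration_levels", tuple(self.concentration_levels)
        )


@dataclass(frozen=True)
class ChromatogramSimSpec:
    """Trace-level parameters layered on a retention spec."""

    retention: RetentionSimSpec = field(default_factory=RetentionSimSpec)
    peak_width_sd: float = 0.08
    peak_height: float = 1.0
    baseline_noise_sd: float = 0.0
    baseline_drift_slope: float = 0.0
    sampling_interval: float = 0.01
    duration: float | None = None
    solvent_front: bool = True

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise SimulationError("sampling_interval must be > 0")
        if self.peak_width_sd <= 0:
            raise SimulationError("peak_width_sd must be > 0")


@dataclass(frozen=True)
class CompoundSimSpec:
    """Generating model for synthetic compound tables.

    Default coefficients and noise follow the published absorption
    model (intercept 4.103, -0.939 per log P_mw unit, -0.02218 per A^2,
    residual SD 0.247 logit units) with predictor ranges covering the
    18 studied drugs.
    """

    n_compounds: int = 50
    beta: tuple[float, float, float] = (4.103, -0.939, -0.02218)
    log_pmw_range: tuple[float, float] = (0.9, 3.0)
    psa_range: tuple[float, float] = (37.0, 89.0)
    noise_sd: float = 0.247
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 5:
            raise SimulationError("n_compounds must be >= 5")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        for lo, hi in (self.log_pmw_range, self.psa_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise SimulationError("predictor ranges must be finite with min < max")
        if not 0 <= self.validation_fraction < 1:
            raise SimulationError("validation_fraction must be in [0, 1)")


def _true_k_prime(spec: RetentionSimSpec, cm: float) -> float:
    denom = 1.0 + spec.k_am * cm
    if denom <= 0:
        raise SimulationError(
            f"k_am*C_M = {spec.k_am * cm:.3g} <= -1 at C_M={cm}; retention undefined"
        )
    return spec.k_prime_0 / denom


def simulate_retention_table(spec: RetentionSimSpec) -> pd.DataFrame:
    """Replicate retention times per micellar level.

    Retention time for level c, replicate r is
    t0 * (1 + k'(c)) * (1 + eps) with eps ~ N(0, rt_noise_cv).
    Columns: drug, c_m_M, replicate, retention_time_min.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cm in spec.concentration_levels:
        kp = _true_k_prime(spec, cm)
        clean = spec.t0 * (1.0 + kp)
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.rt_noise_cv) if spec.rt_noise_cv > 0 else 0.0
            rows.append(
                {
                    "drug": spec.drug,
                    "c_m_M": cm,
                    "replicate": rep,
                    "retention_time_min": clean * (1.0 + noise),
                }
            )
    return pd.DataFrame(rows)


def simulate_chromatogram(spec: ChromatogramSimSpec, level: float) -> Chromatogram:
    """One detector trace at micellar concentration ``level`` (M).

    Gaussian analyte peak at the (noisy) simulated retention time, an
    optional solvent-front Gaussian at t0, linear baseline drift and
    additive Gaussian detector noise.
    """
    ret = spec.retention
    rng = np.random.default_rng(ret.seed)
    kp = _true_k_prime(ret, level)
    rt = ret.t0 * (1.0 + kp)
    if ret.rt_noise_cv > 0:
        rt *= 1.0 + rng.normal(0.0, ret.rt_noise_cv)

    duration = spec.duration or rt + 6.0 * spec.peak_width_sd
    if duration <= rt + 3.0 * spec.peak_width_sd:
        raise SimulationError(
            f"duration {duration} min truncates the analyte peak at {rt:.2f} min"
        )
    t = np.arange(0.0, duration, spec.sampling_interval)
    sig = spec.peak_height * np.exp(-0.5 * ((t - rt) / spec.peak_width_sd) ** 2)
    if spec.solvent_front:
        front_width = spec.peak_width_sd / 2.0
        sig += 0.5 * spec.peak_height * np.exp(-0.5 * ((t - ret.t0) / front_width) ** 2)
    sig += spec.baseline_drift_slope * t
    if spec.baseline_noise_sd > 0:
        sig += rng.normal(0.0, spec.baseline_noise_sd, size=t.shape)
    return Chromatogram(time=t, signal=sig, drug=ret.drug, total_surfactant=level)


def simulate_compound_table(spec: CompoundSimSpec) -> pd.DataFrame:
    """Synthetic compound records from the logit-linear absorption model.

    Predictors are uniform over their ranges; %HIA is the inverse logit
    of b0 + b1*logP_mw + b2*PSA + N(0, noise_sd).  Records whose %HIA
    rounds to 0 or 100 at double precision are redrawn so every record
    has a defined logit.  A ``validation_fraction`` of the records is
    flagged role=validation, the rest train.
    """
    rng = np.random.default_rng(spec.seed)
    b0, b1, b2 = spec.beta
    rows: list[dict] = []
    while len(rows) < spec.n_compounds:
        lp = rng.uniform(*spec.log_pmw_range)
        psa = rng.uniform(*spec.psa_range)
        L = b0 + b1 * lp + b2 * psa
        if spec.noise_sd > 0:
            L += rng.normal(0.0, spec.noise_sd)
        hia = inverse_logit_hia(L)
        if hia <= 0.0 or hia >= 100.0:
            continue  # redraw: logit undefined at the boundaries
        rows.append(
            {
                "name": f"cpd{len(rows) + 1:03d}",
                "log_pmw": lp,
                "psa": psa,
                "hia_percent": hia,
                "role": "train",
                "hia_reference": "synthetic",
            }
        )
    df = pd.DataFrame(rows)
    n_val = int(round(spec.validation_fraction * spec.n_compounds))
    if n_val:
        val_idx = rng.choice(spec.n_compounds, size=n_val, replace=False)
        df.loc[val_idx, "role"] = "validation"
    return df
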