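"""Spike-in simulation of CNV intensity data and phenotypes.

The generative model: a latent Bernoulli carrier indicator per subject, an
LRR matrix equal to measurement noise plus a constant shift (SNR x noise
SD) over the CNV window in carrier rows, and a phenotype that depends on
the data only through carrier status -- phenotype and LRR are conditionally
independent given the latent copy-number state.

Two study designs are supported:

* cohort: carriers drawn Bernoulli(q); continuous phenotype
  y_i ~ Normal(effect_size * carrier_i, 1), i.e. effect_size is the
  carrier mean shift in phenotype-SD units.
* case_control: case status fixed at half cases / half controls; carrier
  status drawn per subject with the Bayes-rule probabilities implied by
  population frequency q, baseline prevalence f0 and penetrance
  f1 = relative_risk * f0.

Noise comes either from a synthetic model (scaled heavy-tailed draws with
lognormal per-marker and per-subject scale factors, emulating the outliers,
skewness and variance heterogeneity of real SNP-array residuals) or by
resampling a user-supplied residual matrix: per replicate a random subset
of marker columns is drawn, and each simulated subject receives one source
subject's residuals at those columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "SimulationConfig",
    "NoiseModel",
    "SimulatedDataset",
    "carrier_cohort",
    "phenotype_cohort",
    "case_control_probabilities",
    "carrier_case_control",
    "spike_in",
    "sample_noise",
    "generate",
]

RngLike = Union[int, np.random.Generator]


def _rng(seed_or_rng: RngLike) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for LRR residuals.

    synthetic mode draws a unit-variance Student-t base (tail_df degrees of
    freedom, rescaled), multiplied by lognormal per-marker and per-subject
    scale factors (sigma of the logs = marker_sd_spread / subject_sd_spread)
    and calibrated so the marginal SD is ~base_sd (0.2, a typical LRR noise
    level).  residual_resample mode draws noise rows from a real residual
    matrix as described in the module docstring.
    """

    mode: str = "synthetic"  # "synthetic" | "residual_resample"
    tail_df: float = 5.0
    marker_sd_spread: float = 0.25
    subject_sd_spread: float = 0.25
    base_sd: float = 0.2
    residual_matrix: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "residual_resample"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.mode == "synthetic" and self.tail_df <= 2:
            raise ValueError("tail_df must exceed 2 for finite variance")
        if self.mode == "residual_resample":
            if self.residual_matrix is None:
                raise ValueError("residual_resample mode needs residual_matrix")
            r = np.asarray(self.residual_matrix, dtype=float)
            if r.ndim != 2:
                raise ValueError("residual_matrix must be subjects x markers")
            object.__setattr__(self, "residual_matrix", r)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one spike-in scenario.

    Defaults are the simulation study's conditions: 200 markers, SNR 0.8,
    cohort effect size 0.4 phenotype SDs, case-control baseline prevalence
    0.01 with relative risk 2, and a centered CNV window.  n_subjects
    defaults to 1000, reconstructed from the study's power tables (see
    docs/methods.md).
    """

    n_subjects: int = 1000
    n_markers: int = 200
    cnv_length: int = 30
    cnv_frequency: float = 0.1
    snr: float = 0.8
    design: str = "cohort"  # "cohort" | "case_control"
    effect_size: float = 0.4
    prevalence_f0: float = 0.01
    relative_risk: float = 2.0
    cnv_window: Optional[tuple[int, int]] = None
    sign: int = 1  # +1 duplication, -1 deletion
    sd_mode: str = "global"  # "global" | "per_marker"
    rng_seed: int = 0

    def __post_init__(self):
        if self.design not in ("cohort", "case_control"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 < self.cnv_frequency < 1:
            raise ValueError("cnv_frequency must be in (0, 1)")
        if self.cnv_length > self.n_markers:
            raise ValueError("cnv_length cannot exceed n_markers")
        if not 0 < self.prevalence_f0 < 1:
            raise ValueError("prevalence_f0 must be in (0, 1)")
        if self.relative_risk * self.prevalence_f0 > 1:
            raise ValueError("penetrance relative_risk * prevalence_f0 exceeds 1")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 (duplication) or -1 (deletion)")

    def window(self) -> tuple[int, int]:
        """CNV window; defaults to centered in the marker range."""
        if self.cnv_window is not None:
            s, e = self.cnv_window
            if not (0 <= s < e <= self.n_markers):
                raise ValueError("cnv_window out of range")
            return int(s), int(e)
        s = (self.n_markers - self.cnv_length) // 2
        return s, s + self.cnv_length


@dataclass(frozen=True)
class SimulatedDataset:
    """Latent truth plus observables for one simulated replicate."""

    carrier: np.ndarray  # 0/1, length n_subjects
    lrr: np.ndarray  # n_subjects x n_markers
    phenotype: np.ndarray  # continuous (cohort) or 0/1 case status
    truth_window: tuple[int, int]
    config: SimulationConfig

    @property
    def case_status(self) -> Optional[np.ndarray]:
        return self.phenotype if self.config.design == "case_control" else None


def carrier_cohort(q: float, n: int, rng_seed: RngLike = 0) -> np.ndarray:
    """i.i.d. Bernoulli(q) carrier indicators for a cohort design."""
    if not 0 < q < 1:
        raise ValueError("carrier frequency q must be in (0, 1)")
    rng = _rng(rng_seed)
    return (rng.random(n) < q).astype(np.int8)


def phenotype_cohort(carrier, effect_size: float, rng_seed: RngLike = 0) -> np.ndarray:
    """Continuous phenotype y_i ~ Normal(effect_size * carrier_i, 1)."""
    if not np.isfinite(effect_size):
        raise ValueError("effect_size must be finite")
    carrier = np.asarray(carrier)
    rng = _rng(rng_seed)
    return effect_size * carrier + rng.standard_normal(carrier.size)


def case_control_probabilities(q: float, f0: float, rr: float) -> tuple[float, float]:
    """Bayes-rule carrier probabilities (P(carrier|case), P(carrier|control)).

    With penetrance f1 = rr * f0:
        P(carrier | case)    = q f1 / (q f1 + (1 - q) f0)
        P(carrier | control) = q (1 - f1) / (q (1 - f1) + (1 - q)(1 - f0))
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    f1 = rr * f0
    if f1 > 1:
        raise ValueError("penetrance f1 = rr * f0 exceeds 1")
    p_case = q * f1 / (q * f1 + (1 - q) * f0)
    p_control = q * (1 - f1) / (q * (1 - f1) + (1 - q) * (1 - f0))
    return p_case, p_control


def carrier_case_control(
    q: float, f0: float, rr: float, case_status, rng_seed: RngLike = 0
) -> np.ndarray:
    """Carrier indicators for fixed case/control labels, via Bayes' rule."""
    p_case, p_control = case_control_probabilities(q, f0, rr)
    case_status = np.asarray(case_status)
    rng = _rng(rng_seed)
    p = np.where(case_status == 1, p_case, p_control)
    return (rng.random(case_status.size) < p).astype(np.int8)


def spike_in(
    noise: np.ndarray,
    carrier,
    window: tuple[int, int],
    snr: float,
    sd_mode: str = "global",
    sign: int = 1,
) -> np.ndarray:
    """Add a constant CNV signal to carrier rows over a marker window.

    The shift is snr * SD(noise) (global SD of the whole noise matrix by
    default; ``sd_mode='per_marker'`` scales each column by its own SD),
    positive for a duplication, negated for a deletion.
    """
    noise = np.asarray(noise, dtype=float)
    carrier = np.asarray(carrier)
    s, e = window
    if not (0 <= s < e <= noise.shape[1]):
        raise ValueError("empty or out-of-range CNV window")
    if sd_mode == "global":
        shift = sign * snr * noise.std()
    elif sd_mode == "per_marker":
        shift = sign * snr * noise[:, s:e].std(axis=0)
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    lrr = noise.copy()
    lrr[carrier == 1, s:e] += shift
    return lrr


def sample_noise(model: NoiseModel, n: int, m: int, rng_seed: RngLike = 0) -> np.ndarray:
    """Draw an n x m noise matrix from a NoiseModel."""
    rng = _rng(rng_seed)
    if model.mode == "synthetic":
        df = model.tail_df
        base = rng.standard_t(df, size=(n, m)) * np.sqrt((df - 2.0) / df)
        marker_scale = np.exp(rng.normal(0.0, model.marker_sd_spread, size=m))
        subject_scale = np.exp(rng.normal(0.0, model.subject_sd_spread, size=n))
        # keep the marginal SD at base_sd despite the lognormal factors
        c = model.base_sd * np.exp(
            -(model.marker_sd_spread**2 + model.subject_sd_spread**2)
        )
        return c * base * subject_scale[:, None] * marker_scale[None, :]
    r = model.residual_matrix
    n_src, m_src = r.shape
    if m > m_src:
        raise ValueError("residual matrix has fewer markers than requested")
    cols = rng.choice(m_src, size=m, replace=False)
    rows = rng.integers(0, n_src, size=n)
    return r[np.ix_(rows, cols)].astype(float)


def generate(
    config: SimulationConfig, noise_model: Optional[NoiseModel] = None
) -> SimulatedDataset:
    """Compose carrier, noise, spike-in and phenotype into one dataset.

    Case-control designs require an even n_subjects (half cases, half
    controls, cases first).  With snr = 0 the result is a null dataset
    (used for type-I calibration).
    """
    noise_model = noise_model or NoiseModel()
    rng = _rng(config.rng_seed)
    n, m = config.n_subjects, config.n_markers
    noise = sample_noise(noise_model, n, m, rng)
    if config.design == "cohort":
        carrier = carrier_cohort(config.cnv_frequency, n, rng)
        phenotype = phenotype_cohort(carrier, config.effect_size, rng)
    else:
        if n % 2:
            raise ValueError("case_control design needs an even n_subjects")
        case_status = np.repeat(np.array([1, 0], dtype=np.int8), n // 2)
        carrier = carrier_case_control(
            config.cnv_frequency, config.prevalence_f0, config.relative_risk,
            case_status, rng,
        )
        phenotype = case_status.astype(float)
    window = config.window()
    lrr = spike_in(noise, carrier, window, config.snr, config.sd_mode, config.sign)
    return SimulatedDataset(carrier, lrr, phenotype, window, config)
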