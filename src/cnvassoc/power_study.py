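"""Monte-Carlo estimation of power and type-I error for both pipelines.

Each grid cell is (design, CNV frequency, CNV length, method); a cell's
power is the fraction of independent spike-in replicates on which the
method declares a CNV-phenotype association.  Replicate data seeds depend
only on (base_seed, design, q, length, replicate) -- not on the method --
so different methods analyse identical datasets and head-to-head power
differences benefit from common random numbers.  The spiked window is
placed uniformly at random on each replicate.

Methods
-------
``marker``          per-marker tests -> p-value transform -> CBS pooling
``marker_nopool``   Bonferroni-corrected minimum p (no pooling comparator)
``cnv``             per-sample CBS calling -> detection -> t/Fisher test
``oracle``          test on the true latent carrier status (upper bound)
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cnv_level, marker_level
from .simulate import NoiseModel, SimulationConfig, SimulatedDataset, generate

__all__ = [
    "PowerGridSpec",
    "PowerEstimate",
    "make_replicate",
    "analysis_seed",
    "run_replicate",
    "run_cell_outcomes",
    "run_cell",
    "run_grid",
    "oracle_power_cohort",
]

_DESIGN_CODE = {"cohort": 1, "case_control": 2}


@dataclass(frozen=True)
class PowerGridSpec:
    """Design grid for a power study.

    ``methods`` is a list of (pipeline, settings) pairs, e.g.
    ``[("marker", {"transform": "probit"}), ("cnv", {"alpha_call": 0.01})]``.
    ``n_permutations`` applies inside every CBS run of the grid.
    """

    designs: tuple[str, ...] = ("cohort",)
    frequencies: tuple[float, ...] = (0.05, 0.1, 0.2)
    cnv_lengths: tuple[int, ...] = (10, 30, 50)
    methods: tuple[tuple[str, dict], ...] = (
        ("marker", {"transform": "probit"}),
        ("cnv", {"alpha_call": 0.01}),
    )
    n_replicates: int = 1000
    base_seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 200
    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass(frozen=True)
class PowerEstimate:
    design: str
    q: float
    cnv_length: int
    method: str
    setting: dict
    power: float
    mc_se: float
    n_replicates: int


def _method_tag(method: str, setting: dict) -> int:
    key = method + "|" + "|".join(f"{k}={setting[k]}" for k in sorted(setting))
    return zlib.crc32(key.encode())


def _cell_entropy(base_seed: int, design: str, q: float, length: int, rep: int):
    return [int(base_seed), _DESIGN_CODE[design], int(round(q * 1e6)),
            int(length), int(rep)]


def make_replicate(
    base_seed: int,
    design: str,
    q: float,
    cnv_length: int,
    rep: int,
    base_config: SimulationConfig,
    noise: NoiseModel,
) -> SimulatedDataset:
    """Generate the dataset for one replicate of one cell (method-blind)."""
    ss = np.random.SeedSequence(_cell_entropy(base_seed, design, q, cnv_length, rep))
    win_ss, data_ss = ss.spawn(2)
    win_rng = np.random.default_rng(win_ss)
    m = base_config.n_markers
    start = int(win_rng.integers(0, m - cnv_length + 1))
    cfg = replace(
        base_config,
        design=design,
        cnv_frequency=q,
        cnv_length=cnv_length,
        cnv_window=(start, start + cnv_length),
        rng_seed=int(data_ss.generate_state(1)[0] % 2**31),
    )
    return generate(cfg, noise)


def run_replicate(
    data: SimulatedDataset,
    method: str,
    setting: dict,
    alpha: float,
    n_permutations: int,
    rng_seed: int,
) -> bool:
    """Apply one pipeline end to end; True iff an association is declared."""
    design = "continuous" if data.config.design == "cohort" else "binary"
    if method == "marker":
        p = marker_level.marker_tests(data.lrr, data.phenotype, design=design)
        track = marker_level.MarkerTestTrack.from_pvalues(
            p, setting.get("transform", "probit")
        )
        regions = marker_level.pool_and_detect(
            track, alpha=alpha, n_permutations=n_permutations, rng_seed=rng_seed
        )
        return len(regions) > 0
    if method == "marker_nopool":
        p = marker_level.marker_tests(data.lrr, data.phenotype, design=design)
        return marker_level.no_pooling_test(p, alpha)
    if method == "cnv":
        alpha_call = setting.get("alpha_call", 0.01)
        rng = np.random.default_rng(rng_seed)
        detected = np.zeros(data.lrr.shape[0], dtype=bool)
        for i in range(data.lrr.shape[0]):
            calls = cnv_level.call_sample(
                data.lrr[i], alpha_call=alpha_call,
                n_permutations=n_permutations,
                rng_seed=int(rng.integers(2**31)), sample=str(i),
            )
            detected[i] = cnv_level.detect_in_simulation(calls, data.truth_window)
        res = cnv_level.associate(detected, data.phenotype, design)
        return res.p < alpha
    if method == "oracle":
        res = cnv_level.associate(data.carrier, data.phenotype, design)
        return res.p < alpha
    raise ValueError(f"unknown method {method!r}")


def analysis_seed(
    base_seed: int, design: str, q: float, cnv_length: int, rep: int,
    method: str, setting: dict,
) -> int:
    """Deterministic per-replicate seed for a pipeline's own randomness.

    Unlike the dataset seed it also hashes the method, so pipelines do not
    share permutation streams even when they share data.
    """
    tag = _method_tag(method, setting)
    ss = np.random.SeedSequence(
        _cell_entropy(base_seed, design, q, cnv_length, rep) + [tag]
    )
    return int(ss.generate_state(1)[0] % 2**31)


def run_cell_outcomes(
    spec: PowerGridSpec,
    design: str,
    q: float,
    cnv_length: int,
    method: str,
    setting: dict,
) -> np.ndarray:
    """Per-replicate rejection outcomes (bool array) for one grid cell."""
    out = np.zeros(spec.n_replicates, dtype=bool)
    for rep in range(spec.n_replicates):
        data = make_replicate(
            spec.base_seed, design, q, cnv_length, rep, spec.base_config, spec.noise
        )
        aseed = analysis_seed(spec.base_seed, design, q, cnv_length, rep,
                              method, setting)
        out[rep] = run_replicate(data, method, setting, spec.alpha,
                                 spec.n_permutations, aseed)
    return out


def run_cell(
    spec: PowerGridSpec,
    design: str,
    q: float,
    cnv_length: int,
    method: str,
    setting: dict,
) -> PowerEstimate:
    """Estimate one cell's power over spec.n_replicates fresh datasets."""
    outcomes = run_cell_outcomes(spec, design, q, cnv_length, method, setting)
    power = float(outcomes.mean())
    mc_se = float(np.sqrt(power * (1 - power) / spec.n_replicates))
    return PowerEstimate(design, q, cnv_length, method, dict(setting),
                         power, mc_se, spec.n_replicates)


def run_grid(spec: PowerGridSpec) -> pd.DataFrame:
    """All cells of the grid as a tidy table.

    Deterministic given spec and base_seed, and order-independent: each
    replicate's seeds derive from its cell coordinates, not from execution
    order.
    """
    rows = []
    for design in spec.designs:
        for q in spec.frequencies:
            for length in spec.cnv_lengths:
                for method, setting in spec.methods:
                    est = run_cell(spec, design, q, length, method, setting)
                    rows.append(
                        {
                            "design": est.design,
                            "q": est.q,
                            "cnv_length": est.cnv_length,
                            "method": est.method,
                            "setting": ";".join(
                                f"{k}={v}" for k, v in sorted(est.setting.items())
                            ),
                            "power": est.power,
                            "mc_se": est.mc_se,
                            "n_replicates": est.n_replicates,
                        }
                    )
    return pd.DataFrame(rows)


def oracle_power_cohort(
    n: int, q: float, effect_size: float, alpha: float = 0.05
) -> float:
    """Analytic power of the oracle two-sample t-test in a cohort design.

    The oracle knows the true carrier status; with K ~ Binomial(n, q)
    carriers the test is a pooled t-test with noncentrality
    effect / sqrt(1/K + 1/(n-K)).  Averages the noncentral-t rejection
    probability over K, counting splits with fewer than 2 per group as
    non-rejections (matching the degenerate-split rule).
    """
    df = n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ks = np.arange(2, n - 1)
    w = stats.binom.pmf(ks, n, q)
    ncp = effect_size / np.sqrt(1.0 / ks + 1.0 / (n - ks))
    power_k = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    return float(np.sum(w * power_k))
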