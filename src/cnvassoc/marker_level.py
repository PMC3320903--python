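"""Marker-level association testing with CBS pooling of p-values.

Stage I tests phenotype against the raw LRR intensity at every marker
(linear regression for a continuous outcome, Welch t-test between cases
and controls for a binary one).  Stage II transforms the resulting
p-values -- the probit transform z = Phi^{-1}(1 - p) maps null p-values to
standard normals, which suits the t-statistics CBS computes -- and runs
circular binary segmentation on the transformed track.  Any segment whose
mean transformed value exceeds that of the remaining markers is a region
where low p-values have aggregated; the CBS permutation test at level
alpha is the single significance gate, so the procedure controls the
family-wise error rate in the weak sense.

A "no pooling" comparator (Bonferroni-corrected minimum p) is provided to
quantify the power gained by pooling across neighboring markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .segmentation import segment

__all__ = [
    "MarkerTestTrack",
    "DetectedRegion",
    "marker_tests",
    "transform_pvalues",
    "pool_and_detect",
    "no_pooling_test",
]

P_FLOOR = 1e-300
# keeps Phi^{-1}(1 - p) finite when a discrete test returns p = 1
P_CEIL = 1.0 - 1e-16

_TRANSFORMS = ("none", "probit", "neglog10")


@dataclass(frozen=True)
class MarkerTestTrack:
    """Per-marker association p-values and their transformed track.

    ``transformed`` is oriented so that larger means more significant for
    every transform: probit z = Phi^{-1}(1-p), neglog10 = -log10(p), and
    ``none`` stores 1 - p.
    """

    pvalues: np.ndarray
    transformed: np.ndarray
    transform: str
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.pvalues.shape != self.transformed.shape:
            raise ValueError("pvalues and transformed must align")

    @classmethod
    def from_pvalues(cls, pvalues, transform: str = "probit", positions=None):
        p = np.asarray(pvalues, dtype=float)
        return cls(p, transform_pvalues(p, transform), transform, positions)


@dataclass(frozen=True)
class DetectedRegion:
    """Half-open marker interval where low p-values have aggregated."""

    start: int
    end: int
    mean_transformed: float
    background_mean: float
    significant: bool


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    z = np.column_stack([np.ones(y.size), covariates])
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    return y - z @ beta


def marker_tests(
    lrr: np.ndarray,
    phenotype,
    covariates=None,
    design: str = "continuous",
) -> np.ndarray:
    """Two-sided per-marker association p-values of phenotype vs LRR.

    continuous: simple linear regression of phenotype on each marker's LRR
    (t-test on the slope).  Covariates, if given, are removed from the
    phenotype by a single least-squares residualization first.
    binary: Welch two-sample t-test of LRR between cases and controls.

    Markers with constant LRR are untestable and get p = 1 (with a
    warning).
    """
    x = np.asarray(lrr, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise ValueError("lrr must be subjects x markers, phenotype length subjects")
    n, m = x.shape
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        k = cov.shape[1]
        y = _residualize(y, cov)
    if n <= k + 2:
        raise ValueError("too few subjects for the requested model")

    if design == "continuous":
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        degenerate = sx <= 0
        sx_safe = np.where(degenerate, 1.0, sx)
        r = np.clip((xc.T @ yc) / (sx_safe * sy), -1.0, 1.0)
        df = n - 2 - k
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif design == "binary":
        yb = y.astype(int)
        if set(np.unique(yb)) - {0, 1}:
            raise ValueError("binary design needs a 0/1 phenotype")
        res = stats.ttest_ind(x[yb == 1], x[yb == 0], axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = ~np.isfinite(p)
    else:
        raise ValueError(f"unknown design {design!r}")

    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant/untestable marker(s); p set to 1",
            stacklevel=2,
        )
        p = np.where(degenerate, 1.0, p)
    return np.minimum(p, 1.0)


def transform_pvalues(pvalues, method: str = "probit") -> np.ndarray:
    """Transform p-values to a uniformly oriented track (larger = stronger).

    p is clipped to [1e-300, 1 - 1e-16] before transforming so the probit
    and -log10 maps stay finite; exact zeros trigger a warning.
    """
    if method not in _TRANSFORMS:
        raise ValueError(f"unknown transform {method!r}")
    p = np.asarray(pvalues, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p <= 0):
        warnings.warn("p-values of 0 clipped to 1e-300 before transform", stacklevel=2)
    p = np.clip(p, P_FLOOR, P_CEIL)
    if method == "probit":
        # Phi^{-1}(1 - p) computed as -Phi^{-1}(p) for precision at small p
        return -special.ndtri(p)
    if method == "neglog10":
        return -np.log10(p)
    return 1.0 - p


def pool_and_detect(
    track: MarkerTestTrack,
    alpha: float = 0.05,
    n_permutations: int = 500,
    min_width: int = 2,
    rng_seed: int = 0,
) -> list[DetectedRegion]:
    """Pool marker-level tests by CBS and return elevated segments.

    Runs CBS on the transformed track at level alpha; if any split is
    significant, every segment whose mean transformed value exceeds the
    mean of the complementary markers is reported (significant = True).
    The split test is the one significance gate, so on global-null data
    the probability of reporting anything is ~alpha (weak FWER control).
    """
    tr = track.transformed
    res = segment(tr, alpha=alpha, n_permutations=n_permutations,
                  min_width=min_width, rng_seed=rng_seed)
    if len(res) <= 1:
        return []
    m = tr.size
    total = float(tr.sum())
    regions = []
    for s in res.segments:
        seg_sum = s.mean * s.n_markers
        background = (total - seg_sum) / (m - s.n_markers)
        if s.mean > background:
            regions.append(
                DetectedRegion(s.start, s.end, s.mean, background, True)
            )
    return regions


def no_pooling_test(pvalues, alpha: float = 0.05) -> bool:
    """Bonferroni-corrected minimum-p test: reject iff min p < alpha / m."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    return bool(p.min() < alpha / p.size)
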