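"""CNV-level testing: call CNVs per sample, then test carriers vs phenotype.

Stage I segments each sample's intensity series by CBS at a calling
threshold alpha_call and turns every non-baseline segment into a gain or
loss call (baseline = the sample's widest segment, a proxy for the
copy-neutral level).  Stage II tests association between detection status
and phenotype: a two-sample t-test for a continuous outcome, Fisher's
exact test for a binary one.  For multi-sample (real-data) analyses,
partially overlapping calls are reduced to minimal common regions shared
by at least ``min_share`` samples before testing, and Benjamini-Hochberg
FDR adjustment is applied across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .segmentation import segment

__all__ = [
    "CnvCall",
    "CommonRegion",
    "AssociationResult",
    "call_sample",
    "detect_in_simulation",
    "associate",
    "minimal_common_regions",
    "fdr_adjust",
]


@dataclass(frozen=True)
class CnvCall:
    """One sample's called copy-number change over [start, end) markers."""

    sample: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    segment_mean: float


@dataclass(frozen=True)
class CommonRegion:
    """Maximal interval shared by an identical carrier set of calls."""

    start: int
    end: int
    carriers: frozenset[str]
    direction: str

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class AssociationResult:
    """Association test outcome for one region or truth window."""

    region: Optional[CommonRegion]
    statistic: float
    p: float
    q: Optional[float] = None


def call_sample(
    series,
    alpha_call: float = 0.01,
    n_permutations: int = 500,
    min_width: int = 2,
    rng_seed: int = 0,
    sample: str = "sample",
) -> list[CnvCall]:
    """Segment one sample and emit gain/loss calls.

    alpha_call is the CBS split-test level and therefore the per-sample
    false-call threshold; 0.01 is robust over a realistic range of CNV
    frequencies.  The widest segment's mean is the copy-neutral baseline;
    every other segment becomes a call, gain if its mean is above baseline.
    """
    res = segment(series, alpha=alpha_call, n_permutations=n_permutations,
                  min_width=min_width, rng_seed=rng_seed)
    if len(res) <= 1:
        return []
    baseline = max(res.segments, key=lambda s: s.n_markers)
    calls = []
    for s in res.segments:
        if s is baseline:
            continue
        direction = "gain" if s.mean > baseline.mean else "loss"
        calls.append(CnvCall(sample, s.start, s.end, direction, s.mean))
    return calls


def detect_in_simulation(calls: Sequence[CnvCall], truth_window: tuple[int, int]) -> bool:
    """True iff any gain call overlaps the spiked window by >= 1 marker.

    Simulated CNVs are duplications, so only gain calls count; overlap of
    a single marker suffices (detection is yes/no, boundary accuracy is
    deliberately not scored).
    """
    s, e = truth_window
    return any(c.direction == "gain" and c.start < e and c.end > s for c in calls)


def associate(detected, phenotype, design: str = "continuous",
              region: Optional[CommonRegion] = None) -> AssociationResult:
    """Test phenotype against detection status.

    continuous: two-sided pooled two-sample t-test of phenotype by detected
    status; binary: two-sided Fisher's exact test of the detected x case
    2x2 table.  Degenerate splits (a t-test group below 2, or a zero
    margin) return p = 1.
    """
    detected = np.asarray(detected).astype(bool)
    phenotype = np.asarray(phenotype, dtype=float)
    if detected.size != phenotype.size:
        raise ValueError("detected and phenotype must align")
    if design == "continuous":
        a, b = phenotype[detected], phenotype[~detected]
        if a.size < 2 or b.size < 2:
            warnings.warn("degenerate detection split; p = 1", stacklevel=2)
            return AssociationResult(region, float("nan"), 1.0)
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return AssociationResult(region, float(stat), float(p))
    if design == "binary":
        case = phenotype.astype(int)
        table = np.array(
            [
                [int((detected & (case == 1)).sum()), int((detected & (case == 0)).sum())],
                [int((~detected & (case == 1)).sum()), int((~detected & (case == 0)).sum())],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            warnings.warn("degenerate 2x2 margin; p = 1", stacklevel=2)
            return AssociationResult(region, float("nan"), 1.0)
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return AssociationResult(region, float(odds), float(p))
    raise ValueError(f"unknown design {design!r}")


def minimal_common_regions(
    calls: Sequence[CnvCall], min_share: int = 3
) -> list[CommonRegion]:
    """Reduce overlapping calls to minimal common regions.

    A sweep over breakpoint-induced atomic intervals merges maximal runs of
    adjacent atoms covered (in the same direction) by an identical set of
    samples; runs whose carrier set has at least ``min_share`` members are
    emitted.  This turns arbitrarily overlapping per-sample calls into
    well-defined testable loci.
    """
    out: list[CommonRegion] = []
    for direction in ("gain", "loss"):
        sub = [c for c in calls if c.direction == direction]
        if not sub:
            continue
        cuts = sorted({c.start for c in sub} | {c.end for c in sub})
        run_start = None
        run_set: frozenset[str] = frozenset()
        prev_end = None
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            carriers = frozenset(c.sample for c in sub if c.start <= lo and c.end >= hi)
            if run_start is not None and (carriers != run_set or lo != prev_end):
                if len(run_set) >= min_share:
                    out.append(CommonRegion(run_start, prev_end, run_set, direction))
                run_start = None
            if run_start is None and carriers:
                run_start, run_set = lo, carriers
            prev_end = hi
        if run_start is not None and len(run_set) >= min_share:
            out.append(CommonRegion(run_start, prev_end, run_set, direction))
    out.sort(key=lambda r: (r.start, r.end, r.direction))
    return out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")
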