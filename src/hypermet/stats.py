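"""Degree distributions, replica ensembles and power-law tail fitting.

The degree distribution of a graph abstraction is summarized as exact
per-degree counts and frequencies p(k) = count / n.  Replica ensembles
(e.g. 200 rewired networks) are reduced to per-degree order statistics
-- median and a percentile band -- keeping only degrees present in a
minimum number of replicas, since rare degrees carry no reliable
frequency information.

Power-law tails p(k) = beta * k^-alpha are fit by ordinary least
squares on log-log axes, the conventional procedure in the metabolic
network literature (deliberately not maximum-likelihood fitting).  The
fitting region can be supplied manually or selected from an ensemble
summary by two rules: the region ends where the percentile band falls
to the single-node frequency floor 1/n (below which a log-log plot
carries no signal), and starts -- scanning down from the end -- at the
first pair of neighboring degrees whose log-log median slope magnitude
drops below a threshold (default 4.0), which marks the crossover from
tail to head.

``degree_mod_classes`` partitions observed degrees into residue classes
mod (k - 1): in the primal of a sparse cardinality-k hypergraph each
hyperedge adds k - 1 to a member's degree, so degrees pile up at
multiples of k - 1 (the "zig-zag" head) and the classes decompose the
distribution into smooth strands.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import HypergraphError, SimpleGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeDistribution",
    "EnsembleSummary",
    "PowerLawFit",
    "degree_distribution",
    "ensemble_summary",
    "select_fit_region",
    "fit_power_law",
    "degree_mod_classes",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Exact degree histogram of a graph: degree -> count, p(k) = count/n."""

    n: int
    degrees: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if sum(self.counts) != self.n:
            raise HypergraphError("degree counts must sum to the node count")
        if any(k < 0 for k in self.degrees):
            raise HypergraphError("degrees must be non-negative")
        if len(self.degrees) != len(set(self.degrees)):
            raise HypergraphError("duplicate degree rows")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.n for c in self.counts)

    def freq(self, k: int) -> float:
        """p(k); 0.0 for unobserved degrees."""
        try:
            return self.counts[self.degrees.index(k)] / self.n
        except ValueError:
            return 0.0

    def as_points(self) -> list[tuple[int, float]]:
        return list(zip(self.degrees, self.frequencies))


def degree_distribution(G: SimpleGraph) -> DegreeDistribution:
    """Per-degree counts over all nodes of G, including degree 0."""
    if G.n == 0:
        raise HypergraphError("degree distribution of an empty graph is undefined")
    counter = Counter(G.degrees().values())
    degrees = tuple(sorted(counter))
    return DegreeDistribution(G.n, degrees, tuple(counter[k] for k in degrees))


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-degree order statistics over an ensemble of replica distributions.

    A degree is reported only when present (count > 0) in at least
    ``min_replicas`` replicas; statistics are taken over the replicas
    that contain the degree.
    """

    degrees: tuple[int, ...]
    n_replicas: tuple[int, ...]
    median: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    percentiles: tuple[float, float]
    min_replicas: int
    total_replicas: int

    def __post_init__(self):
        for lo, med, hi in zip(self.lower, self.median, self.upper):
            if not (lo <= med <= hi):
                raise HypergraphError("percentile bands must satisfy lower <= median <= upper")


def ensemble_summary(
    distributions: Sequence[DegreeDistribution],
    percentiles: tuple[float, float] = (5.0, 95.0),
    min_replicas: int = 10,
) -> EnsembleSummary:
    """Summarize replica degree distributions by median and percentile band."""
    if not distributions:
        raise HypergraphError("ensemble_summary requires at least one distribution")
    lo_p, hi_p = percentiles
    if not 0 <= lo_p <= hi_p <= 100:
        raise HypergraphError("percentiles must satisfy 0 <= lower <= upper <= 100")
    by_degree: dict[int, list[float]] = {}
    for dist in distributions:
        for k, c in zip(dist.degrees, dist.counts):
            if c > 0:
                by_degree.setdefault(k, []).append(c / dist.n)
    degrees = tuple(sorted(k for k, v in by_degree.items() if len(v) >= min_replicas))
    med, lo, hi, nrep = [], [], [], []
    for k in degrees:
        vals = np.asarray(by_degree[k])
        nrep.append(len(vals))
        med.append(float(np.median(vals)))
        lo.append(float(np.percentile(vals, lo_p)))
        hi.append(float(np.percentile(vals, hi_p)))
    return EnsembleSummary(
        degrees, tuple(nrep), tuple(med), tuple(lo), tuple(hi),
        (float(lo_p), float(hi_p)), min_replicas, len(distributions),
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of p(k) = beta * k^-alpha on log-log axes."""

    alpha: float
    beta: float
    region: tuple[int, int]
    rss: float
    n_points: int

    def __post_init__(self):
        if self.region[0] > self.region[1]:
            raise HypergraphError("fit region must satisfy k_start <= k_end")
        if not math.isfinite(self.alpha):
            raise HypergraphError("fitted exponent must be finite")

    def predict(self, k) -> np.ndarray:
        return self.beta * np.asarray(k, dtype=float) ** (-self.alpha)


def select_fit_region(
    summary: EnsembleSummary,
    n: int,
    slope_threshold: float = 4.0,
    end_rule: str = "upper",
) -> tuple[int, int]:
    """Choose the [k_start, k_end] tail-fitting region from an ensemble summary.

    End rule: scanning degrees upward, the region ends at the last
    degree before the chosen percentile first fails to exceed the
    single-node frequency floor 1/n.  ``end_rule`` picks the percentile:
    "upper" compares the upper percentile (e.g. the 95th), "lower" the
    lower one (equivalent to requiring that almost all replicas have
    more than one node at the degree).  Start rule: moving from the end
    toward degree 1, the region starts at the first pair of neighboring
    degrees whose log-log median slope magnitude falls below
    ``slope_threshold``; if no pair does, the smallest reported degree
    starts the region.
    """
    if end_rule not in ("upper", "lower"):
        raise ValueError("end_rule must be 'upper' or 'lower'")
    if not summary.degrees:
        raise HypergraphError("empty ensemble summary")
    floor = 1.0 / n
    band = summary.upper if end_rule == "upper" else summary.lower
    k_end = None
    for k, b in zip(summary.degrees, band):
        if b > floor:
            k_end = k
        else:
            break
    if k_end is None:
        raise HypergraphError(
            "no degree satisfies the end-of-region rule (percentile never exceeds 1/n); "
            "supply a manual fitting region"
        )
    ks = [k for k in summary.degrees if k <= k_end]
    med = {k: m for k, m in zip(summary.degrees, summary.median)}
    k_start = ks[0]
    for i in range(len(ks) - 1, 0, -1):
        k_hi, k_lo = ks[i], ks[i - 1]
        slope = (math.log(med[k_hi]) - math.log(med[k_lo])) / (
            math.log(k_hi) - math.log(k_lo)
        )
        if abs(slope) < slope_threshold:
            k_start = k_hi
            break
    return (k_start, k_end)


def fit_power_law(
    points: Iterable[tuple[float, float]], region: tuple[int, int]
) -> PowerLawFit:
    """OLS fit of log p(k) on log k restricted to ``region``.

    alpha is minus the slope and beta = exp(intercept).  Points with
    zero frequency inside the region are excluded with a warning (they
    have no log image); at least two usable points are required.
    """
    k_start, k_end = region
    if k_start > k_end:
        raise HypergraphError("fit region must satisfy k_start <= k_end")
    xs, ys, dropped = [], [], []
    for k, p in points:
        if not k_start <= k <= k_end:
            continue
        if p <= 0:
            dropped.append(k)
            continue
        xs.append(math.log(k))
        ys.append(math.log(p))
    if dropped:
        logger.warning("fit_power_law: dropped %d zero-frequency degrees %s", len(dropped), dropped)
    if len(xs) < 2:
        raise HypergraphError(
            f"need >= 2 points with positive frequency in region [{k_start}, {k_end}], "
            f"got {len(xs)}"
        )
    slope, intercept = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
    resid = np.asarray(ys) - (slope * np.asarray(xs) + intercept)
    return PowerLawFit(
        alpha=float(-slope),
        beta=float(math.exp(intercept)),
        region=(int(k_start), int(k_end)),
        rss=float(resid @ resid),
        n_points=len(xs),
    )


def degree_mod_classes(
    distribution: DegreeDistribution, k: int
) -> dict[int, tuple[int, ...]]:
    """Partition observed degrees into k-1 residue classes mod (k-1).

    For a cardinality-k hypergraph each hyperedge contributes k-1 to a
    member's primal degree, so each residue class traces one smooth
    strand of the zig-zag distribution.  Requires k >= 3 (for k = 2 the
    single class is the whole degree set and the decomposition is
    vacuous).
    """
    if k < 3:
        raise HypergraphError(f"degree classes need cardinality k >= 3, got {k}")
    classes: dict[int, list[int]] = {r: [] for r in range(k - 1)}
    for d in distribution.degrees:
        classes[d % (k - 1)].append(d)
    return {r: tuple(ds) for r, ds in classes.items()}
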