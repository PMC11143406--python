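"""Survey design: sample-size calculation and two-stage cluster sampling.

The design is a classic two-stage cluster sample: census enumeration areas
(primary sampling units, PSUs) are drawn with probability proportional to
their all-age population, and within each selected PSU a population-equal
segment is chosen at random and enrolled door-to-door until the cluster size
is reached. Because the second-stage inclusion probability is inversely
proportional to PSU size, the design is approximately self-weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

Z_95 = 1.96  # fixed: 95% confidence level

#: Design effect by cluster size, from analysis of early surveys.
DEFF_BY_CLUSTER_SIZE = {35: 1.4, 40: 1.4, 50: 1.5, 60: 1.6}

VALID_CLUSTER_SIZES = tuple(sorted(DEFF_BY_CLUSTER_SIZE))


class ParameterError(ValueError):
    """A design parameter outside its allowed range."""


def deff_for_cluster_size(cluster_size: int) -> float:
    """Design effect used by the sample-size calculator for a cluster size.

    1.4 for cluster sizes 35 and 40, 1.5 for 50, 1.6 for 60.
    """
    try:
        return DEFF_BY_CLUSTER_SIZE[cluster_size]
    except KeyError:
        raise ParameterError(
            f"cluster size must be one of {VALID_CLUSTER_SIZES}, got {cluster_size}"
        ) from None


@dataclass
class SurveyDesign:
    """Design parameters for the sample-size calculator and sampling plan.

    Parameters
    ----------
    prevalence :
        Anticipated prevalence of blindness among people 50+ (fraction).
    precision :
        Desired precision of the estimate, 0.10–0.30. Under the default
        ``precision_mode="relative"`` the confidence half-width is
        ``precision × prevalence``; under ``"absolute"`` it is ``precision``
        itself (the literal closed form).
    nonresponse :
        Anticipated non-response rate, 0–0.20.
    cluster_size :
        Participants enrolled per cluster; one of 35, 40, 50, 60. Fixes the
        design effect.
    proportion_50plus :
        Fraction of the all-age population aged 50 and older; drives the
        segmentation arithmetic.
    deff :
        Override the design effect (default: looked up from cluster size).
    """

    prevalence: float
    precision: float = 0.20
    nonresponse: float = 0.10
    cluster_size: int = 50
    proportion_50plus: float = 0.20
    precision_mode: str = "relative"
    deff: Optional[float] = None
    z: float = Z_95

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError("prevalence must lie strictly in (0, 1)")
        if self.precision_mode == "relative":
            if not 0.10 <= self.precision <= 0.30:
                raise ParameterError("relative precision must lie in [0.10, 0.30]")
        elif not 0.0 < self.precision < 1.0:
            raise ParameterError("absolute precision must lie in (0, 1)")
        if not 0.0 <= self.nonresponse <= 0.20:
            raise ParameterError("nonresponse must lie in [0, 0.20]")
        if self.cluster_size not in DEFF_BY_CLUSTER_SIZE:
            raise ParameterError(
                f"cluster size must be one of {VALID_CLUSTER_SIZES}"
            )
        if not 0.0 < self.proportion_50plus <= 1.0:
            raise ParameterError("proportion_50plus must lie in (0, 1]")
        if self.precision_mode not in ("relative", "absolute"):
            raise ParameterError("precision_mode must be 'relative' or 'absolute'")
        if self.deff is None:
            self.deff = deff_for_cluster_size(self.cluster_size)

    @property
    def half_width(self) -> float:
        """Absolute confidence half-width implied by the precision setting."""
        if self.precision_mode == "relative":
            return self.precision * self.prevalence
        return self.precision


@dataclass(frozen=True)
class SampleSizeResult:
    n_raw: float
    n_individuals: int
    n_clusters: int
    deff_used: float


def compute_sample_size(design: SurveyDesign) -> SampleSizeResult:
    """Required sample size, rounded up to whole clusters.

    n_raw = Z² · P(1−P) / h² · DEFF / (1−d), with half-width h = D·P in
    relative mode (D in absolute mode), inflated for non-response d; field
    teams survey whole clusters, so the recruited size is
    ceil(n_raw / cluster_size) clusters of cluster_size.
    """
    h = design.half_width
    n_srs = design.z**2 * design.prevalence * (1.0 - design.prevalence) / h**2
    n_raw = n_srs * design.deff / (1.0 - design.nonresponse)
    n_clusters = math.ceil(n_raw / design.cluster_size)
    return SampleSizeResult(
        n_raw=n_raw,
        n_individuals=n_clusters * design.cluster_size,
        n_clusters=n_clusters,
        deff_used=design.deff,
    )


@dataclass
class SamplingFrame:
    """List of PSUs with all-age population counts."""

    psus: list[tuple[str, int]]

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.psus]
        if len(set(ids)) != len(ids):
            raise ParameterError("PSU ids must be unique")
        if any(pop <= 0 for _, pop in self.psus):
            raise ParameterError("PSU populations must be positive")

    @property
    def total_population(self) -> int:
        return sum(pop for _, pop in self.psus)

    def __len__(self) -> int:
        return len(self.psus)


def select_psus_pps(
    frame: SamplingFrame,
    n_clusters: int,
    rng: np.random.Generator,
) -> list[str]:
    """Systematic probability-proportional-to-size PSU selection.

    Cumulates PSU populations, draws a random start in the first sampling
    interval and steps through at a fixed interval; a large PSU may be hit
    more than once and then receives several clusters. Because multiple hits
    are allowed, a PSU spanning k sampling intervals is selected with
    certainty at least k times, so no per-hit probability ever exceeds one
    and no separate certainty step is needed.
    """
    if n_clusters < 1:
        raise ParameterError("n_clusters must be at least 1")
    if not frame.psus:
        raise ParameterError("sampling frame is empty")
    total = frame.total_population
    sizes = np.array([pop for _, pop in frame.psus], dtype=float)
    cum = np.cumsum(sizes)
    interval = total / n_clusters
    start = rng.uniform(0.0, interval)
    points = start + interval * np.arange(n_clusters)
    idx = np.searchsorted(cum, points, side="right")
    return [frame.psus[i][0] for i in idx]


@dataclass(frozen=True)
class SegmentPlan:
    """Second-stage segmentation plan for one selected PSU."""

    segment_size: int      # target all-age persons per segment
    n_segments: int
    chosen_segment: int
    segmented: bool


def plan_segmentation(
    psu_population: int,
    proportion_50plus: float,
    cluster_size: int,
    rng: Optional[np.random.Generator] = None,
) -> SegmentPlan:
    """Plan the sketch-map segmentation of one PSU.

    The segment must hold about ``cluster_size / proportion_50plus`` people of
    all ages so that one segment yields a full cluster of people 50 and
    older (e.g. 50 / 0.20 = 250). A PSU smaller than two target segments is
    surveyed whole, without segmentation; otherwise it is divided into
    ``round(population / segment_size)`` population-equal segments and one is
    chosen at random.
    """
    if psu_population <= 0:
        raise ParameterError("PSU population must be positive")
    if not 0.0 < proportion_50plus <= 1.0:
        raise ParameterError("proportion_50plus must lie in (0, 1]")
    segment_size = round(cluster_size / proportion_50plus)
    segmented = psu_population >= 2 * segment_size
    n_segments = max(1, round(psu_population / segment_size)) if segmented else 1
    if n_segments > 1:
        if rng is None:
            rng = np.random.default_rng()
        chosen = int(rng.integers(0, n_segments))
    else:
        chosen = 0
    return SegmentPlan(
        segment_size=segment_size,
        n_segments=n_segments,
        chosen_segment=chosen,
        segmented=segmented,
    )
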