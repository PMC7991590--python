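"""Rescaling of raw effect scores to [-1, 0] and per-position averaging.

The anchors are the 5th percentile of all scores (maps to -1) and the
wild-type peak of the score histogram (maps to 0).  The wild-type peak is
estimated as the median of the scores in the most-populated of ``n_bins``
equal-width bins; ties between bins break toward the bin with the larger
midpoint, since near-neutral scores sit at the high end of the distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from mutsense.dms_io import MutEffectRecord, MutEffectTable
from mutsense.errors import DegenerateDataError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RescaleParams:
    """Anchors of the linear map: ``min_M`` -> ``a`` (-1), ``max_M`` -> ``b`` (0)."""

    min_M: float
    max_M: float
    a: float = -1.0
    b: float = 0.0
    percentile: float = 5.0
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not self.min_M < self.max_M:
            raise DegenerateDataError(f"min_M ({self.min_M}) must be < max_M ({self.max_M})")
        if not self.a < self.b:
            raise ValueError(f"a ({self.a}) must be < b ({self.b})")


@dataclass(frozen=True)
class PositionProfile:
    """Averaged rescaled score at one position; sensitivity = -mean_rescaled."""

    position: int
    mean_rescaled: float
    n_mutants: int

    @property
    def sensitivity(self) -> float:
        return -self.mean_rescaled


def fit_rescale_params(
    scores,
    percentile: float = 5.0,
    n_bins: int = 100,
    a: float = -1.0,
    b: float = 0.0,
) -> RescaleParams:
    """Estimate rescaling anchors from the raw score distribution.

    ``min_M`` is the ``percentile``-th percentile (linear interpolation
    between order statistics).  ``max_M`` is the wild-type peak: the median
    of the scores in the modal histogram bin.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise InsufficientDataError(f"need >= 20 finite scores to fit anchors, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all scores equal; distribution is degenerate")

    min_m = float(np.percentile(x, percentile))  # linear-interpolation definition

    counts, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    modal = int(np.flatnonzero(counts == counts.max())[-1])  # tie -> larger midpoint
    lo, hi = edges[modal], edges[modal + 1]
    in_bin = x[(x >= lo) & (x <= hi)] if modal == n_bins - 1 else x[(x >= lo) & (x < hi)]
    max_m = float(np.median(in_bin))

    if min_m >= max_m:
        raise DegenerateDataError(
            f"fitted anchors collapsed (min_M={min_m:.4g} >= max_M={max_m:.4g}); "
            "the score distribution is pathological — supply manual anchors"
        )
    return RescaleParams(min_M=min_m, max_M=max_m, a=a, b=b, percentile=percentile, n_bins=n_bins)


def rescale_scores(table: MutEffectTable, params: RescaleParams, clamp: bool = True) -> MutEffectTable:
    """Apply ``M -> (b-a)*(M-min_M)/(max_M-min_M) + a`` to every record.

    With ``clamp`` on (default) outputs are forced into [a, b], so scores
    below the 5th-percentile anchor saturate at -1 and scores above the
    wild-type peak saturate at 0.
    """
    span = params.max_M - params.min_M
    gain = (params.b - params.a) / span
    out: list[MutEffectRecord] = []
    for rec in table.records:
        value = gain * (rec.raw_score - params.min_M) + params.a
        if clamp:
            value = min(max(value, params.a), params.b)
        out.append(replace(rec, raw_score=value))
    return MutEffectTable(dataset_id=table.dataset_id, records=out)


def average_by_position(rescaled: MutEffectTable, min_mutants: int = 10) -> list[PositionProfile]:
    """Arithmetic mean of rescaled scores per position, keeping positions with
    at least ``min_mutants`` observed mutants.  Dropped positions are logged.
    """
    if not rescaled.records:
        raise InsufficientDataError("cannot average an empty mutation table")
    profiles: list[PositionProfile] = []
    dropped: list[int] = []
    for pos, recs in sorted(rescaled.by_position().items()):
        if len(recs) < min_mutants:
            dropped.append(pos)
            continue
        mean = float(np.mean([r.raw_score for r in recs]))
        profiles.append(PositionProfile(position=pos, mean_rescaled=mean, n_mutants=len(recs)))
    if dropped:
        logger.info("dropped %d position(s) with < %d mutants: %s", len(dropped), min_mutants, dropped)
    if not profiles:
        raise InsufficientDataError(f"no position has >= {min_mutants} mutants")
    return profiles
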