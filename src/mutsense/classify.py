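"""Combined Z-score computation and three-class residue calling.

Sign convention
---------------
Per-position sensitivity is oriented *positive* (sensitivity = -mean
rescaled score, so 1 = fully mutation-sensitive, 0 = neutral).  With that
orientation the two combined scores are mutually consistent:

* ``score_active = z_sens + z_acc`` — sensitive AND exposed both push the
  active-site score up;
* ``score_buried = z_sens - z_acc`` — sensitive AND inaccessible both push
  the buried score up;

and both classes use the single one-sided rule *score > mean + k.SD* with
k = 1.  Residues exceeding neither cutoff are exposed non-active-site;
residues exceeding both are assigned the class whose score sits more SDs
above its own mean and flagged ``ambiguous_dual_call``.

Standardization uses the population SD (no degrees-of-freedom correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from mutsense.dms_io import AccessibilityTable
from mutsense.errors import DegenerateDataError, InsufficientDataError
from mutsense.rescale_aggregate import PositionProfile

FLAG_AMBIGUOUS = "ambiguous_dual_call"
FLAG_EXCLUDED = "excluded_by_list"


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-scores: subtract the mean, divide by the population SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need >= 2 values to standardize")
    sd = float(x.std())  # population SD, ddof=0
    if sd == 0:
        raise DegenerateDataError("cannot standardize constant values (SD = 0)")
    return (x - x.mean()) / sd


@dataclass
class CombinedScoreTable:
    """Per-residue standardized scores over the positions common to both inputs."""

    positions: np.ndarray  # int, sorted
    z_sens: np.ndarray
    z_acc: np.ndarray

    @property
    def score_active(self) -> np.ndarray:
        return self.z_sens + self.z_acc

    @property
    def score_buried(self) -> np.ndarray:
        return self.z_sens - self.z_acc


@dataclass
class PredictionTable:
    """Three-class calls with per-residue scores, flags, and thresholds used."""

    positions: np.ndarray
    z_sens: np.ndarray
    z_acc: np.ndarray
    score_active: np.ndarray
    score_buried: np.ndarray
    predicted_class: list[str]
    flags: list[set[str]]
    thresholds: dict = field(default_factory=dict)

    def rows(self) -> list[tuple]:
        return [
            (int(p), float(zs), float(za), float(sa), float(sb), cls, ";".join(sorted(fl)))
            for p, zs, za, sa, sb, cls, fl in zip(
                self.positions, self.z_sens, self.z_acc, self.score_active,
                self.score_buried, self.predicted_class, self.flags
            )
        ]

    @classmethod
    def from_rows(cls, rows: list[tuple]) -> "PredictionTable":
        rows = sorted(rows)
        return cls(
            positions=np.array([r[0] for r in rows], dtype=int),
            z_sens=np.array([r[1] for r in rows]),
            z_acc=np.array([r[2] for r in rows]),
            score_active=np.array([r[3] for r in rows]),
            score_buried=np.array([r[4] for r in rows]),
            predicted_class=[r[5] for r in rows],
            flags=[set(f for f in r[6].split(";") if f) for r in rows],
        )

    def as_dict(self) -> dict[int, str]:
        return {int(p): c for p, c in zip(self.positions, self.predicted_class)}


def combine(profiles: Iterable[PositionProfile], acc: AccessibilityTable) -> CombinedScoreTable:
    """Standardize sensitivity and predicted accessibility over shared positions.

    Only positions present in both the (filtered) mutational profiles and the
    sequence-predicted accessibility table enter the combined table; the
    Z-scores are computed over exactly that intersection.
    """
    if acc.source != "sequence_predicted":
        raise ValueError("combine() requires sequence-predicted accessibility (structure values are for truth only)")
    prof_map = {p.position: p.sensitivity for p in profiles}
    acc_map = acc.as_dict()
    common = sorted(set(prof_map) & set(acc_map))
    if len(common) < 3:
        raise InsufficientDataError(f"only {len(common)} residue(s) shared between profiles and accessibility")
    sens = [prof_map[p] for p in common]
    rel = [acc_map[p] for p in common]
    return CombinedScoreTable(
        positions=np.array(common, dtype=int),
        z_sens=standardize(sens),
        z_acc=standardize(rel),
    )


def call_class(scores: Sequence[float], k: float = 1.0) -> np.ndarray:
    """Indices of scores more than ``k`` population SDs above their mean."""
    x = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 scores to derive a cutoff")
    sd = float(x.std())
    if sd == 0:
        raise DegenerateDataError("all combined scores equal (SD = 0)")
    return np.flatnonzero(x > x.mean() + k * sd)


def assign_classes(
    combined: CombinedScoreTable,
    k: float = 1.0,
    exclusions: Iterable[int] = (),
) -> PredictionTable:
    """Call every residue as active_site, buried, or exposed_nonactive.

    ``exclusions`` (structure-coordinate special cases, e.g. metal-binding
    cysteines) are removed from the buried call set only.  Dual calls are
    tie-broken by the larger SD-normalized margin above the mean and flagged.
    """
    excl = set(int(p) for p in exclusions)
    sa, sb = combined.score_active, combined.score_buried
    active_idx = set(call_class(sa, k).tolist())
    buried_idx = set(call_class(sb, k).tolist())
    margin_a = (sa - sa.mean()) / sa.std()
    margin_b = (sb - sb.mean()) / sb.std()

    n = len(combined.positions)
    classes: list[str] = []
    flags: list[set[str]] = [set() for _ in range(n)]
    for i in range(n):
        pos = int(combined.positions[i])
        is_active = i in active_idx
        is_buried = i in buried_idx
        if is_buried and pos in excl:
            is_buried = False
            flags[i].add(FLAG_EXCLUDED)
        if is_active and is_buried:
            flags[i].add(FLAG_AMBIGUOUS)
            classes.append("active_site" if margin_a[i] >= margin_b[i] else "buried")
        elif is_active:
            classes.append("active_site")
        elif is_buried:
            classes.append("buried")
        else:
            classes.append("exposed_nonactive")

    thresholds = {
        "active": {"mean": float(sa.mean()), "sd": float(sa.std()), "k": k},
        "buried": {"mean": float(sb.mean()), "sd": float(sb.std()), "k": k},
    }
    return PredictionTable(
        positions=combined.positions.copy(),
        z_sens=combined.z_sens.copy(),
        z_acc=combined.z_acc.copy(),
        score_active=sa,
        score_buried=sb,
        predicted_class=classes,
        flags=flags,
        thresholds=thresholds,
    )


def burial_truth_from_structure(acc: AccessibilityTable, cutoff: float = 5.0) -> dict[int, str]:
    """Binary burial labels from structure accessibility: <= cutoff% is buried."""
    if acc.source != "structure":
        raise ValueError("burial truth requires structure-calculated accessibility")
    return {pos: ("buried" if rel <= cutoff else "exposed") for pos, rel in acc.records}
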