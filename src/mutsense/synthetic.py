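"""Synthetic saturation-mutagenesis data with realistic class structure.

Generates, from one seeded config: three-class residue truth labels,
structure-style accessibility consistent with those labels, a noisy
sequence-predicted accessibility table tuned to a target Pearson r, and a
raw DMS score table in which active-site positions are uniformly
mutation-sensitive, buried positions tolerate aliphatic substitutions with
some probability (never when the wild type is Ala/Gly), and exposed
non-active-site positions are neutral.  Raw scores live on a log-ratio-like
scale with the wild-type peak near 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mutsense.dms_io import AMINO_ACIDS, AccessibilityTable, MutEffectRecord, MutEffectTable, ResidueTruth
from mutsense.errors import ValidationError

# Substitution categories.  H is grouped with the aromatics, C with the
# polars; membership is a calibration choice, not a physical constant.
ALIPHATIC = frozenset("AVLIMG")
AROMATIC = frozenset("FWYH")
POLAR = frozenset("STNQC")
CHARGED = frozenset("DEKR")

#: Residues favoured (4:1) as wild type at buried positions.
HYDROPHOBIC = frozenset("AVLIMGFWY")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator; defaults give the well-behaved benchmark regime."""

    n_positions: int = 200
    class_fractions: tuple[float, float, float] = (0.10, 0.25, 0.65)  # active, buried, exposed
    wt_score_sd: float = 0.3
    deleterious_mean: float = -4.0
    deleterious_sd: float = 1.0
    aliphatic_tolerance: float = 0.7
    target_r: float = 0.9
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.class_fractions
        if len(f) != 3 or any(x < 0 or x > 1 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValidationError(f"class fractions must lie in [0,1] and sum to 1, got {f}")
        if not (0.0 < self.target_r <= 1.0):
            raise ValidationError(f"target_r must be in (0, 1], got {self.target_r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (0.0 <= self.aliphatic_tolerance <= 1.0):
            raise ValidationError(f"aliphatic_tolerance must be in [0, 1], got {self.aliphatic_tolerance}")


def _largest_remainder_counts(fractions, n: int) -> list[int]:
    """Integer class counts summing to n, by largest-remainder rounding."""
    raw = [f * n for f in fractions]
    counts = [math.floor(r) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def generate_truth(cfg: SyntheticConfig) -> tuple[ResidueTruth, AccessibilityTable]:
    """Residue labels plus consistent structure-source accessibility.

    Buried residues draw relative accessibility uniformly from [0, 5],
    everything else from (5, 100].  Class counts follow largest-remainder
    rounding of the configured fractions.
    """
    if cfg.n_positions < 10:
        raise ValidationError(f"need >= 10 positions, got {cfg.n_positions}")
    rng = np.random.default_rng([cfg.seed, 0])
    n_active, n_buried, n_exposed = _largest_remainder_counts(cfg.class_fractions, cfg.n_positions)
    labels = (["active_site"] * n_active + ["buried"] * n_buried + ["exposed_nonactive"] * n_exposed)
    rng.shuffle(labels)

    records, acc_records = [], []
    for pos, cls in enumerate(labels, start=1):
        if cls == "buried":
            rel = float(rng.uniform(0.0, 5.0))
        else:
            rel = float(rng.uniform(np.nextafter(5.0, 100.0), 100.0))
        records.append((pos, cls))
        acc_records.append((pos, rel))
    truth = ResidueTruth(records=records)
    acc = AccessibilityTable(records=acc_records, source="structure", method="synthetic")
    return truth, acc


def _draw_wt(cls: str, rng: np.random.Generator) -> str:
    if cls == "buried" and rng.random() < 0.8:  # 4:1 odds toward hydrophobic wt
        return rng.choice(sorted(HYDROPHOBIC))
    return rng.choice(AMINO_ACIDS)


def generate_dms(truth: ResidueTruth, cfg: SyntheticConfig) -> MutEffectTable:
    """Raw effect scores for up to 19 substitutions per position.

    Score model: neutral ~ N(0, wt_score_sd); deleterious ~
    N(deleterious_mean, deleterious_sd).  Active-site positions are
    deleterious for every substitution category; buried positions are
    deleterious except for aliphatic substitutions, which stay neutral with
    probability ``aliphatic_tolerance`` unless the wild type is Ala or Gly;
    exposed non-active-site positions are neutral throughout.  Each mutant
    is dropped independently with probability ``missing_rate``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    records: list[MutEffectRecord] = []
    for pos, cls in truth.records:
        wt = str(_draw_wt(cls, rng))
        for mut in AMINO_ACIDS:
            if mut == wt:
                continue
            if rng.random() < cfg.missing_rate:
                continue
            if cls == "exposed_nonactive":
                deleterious = False
            elif cls == "active_site":
                deleterious = True
            else:  # buried
                tolerated = (mut in ALIPHATIC and wt not in "AG"
                             and rng.random() < cfg.aliphatic_tolerance)
                deleterious = not tolerated
            if deleterious:
                score = rng.normal(cfg.deleterious_mean, cfg.deleterious_sd)
            else:
                score = rng.normal(0.0, cfg.wt_score_sd)
            records.append(MutEffectRecord(pos, wt, mut, float(score)))
    return MutEffectTable(dataset_id=f"synthetic-seed{cfg.seed}", records=records)


def generate_predicted_accessibility(
    true_acc: AccessibilityTable, target_r: float, seed: int
) -> AccessibilityTable:
    """Noisy predictor emulation with expected Pearson r ~ target_r.

    The true values are standardized, Gaussian noise of variance
    (1/target_r**2 - 1) is added, and the result is mapped back to the
    percent scale and floored at 0.  r = 1 reproduces the truth exactly.
    """
    if not (0.0 < target_r <= 1.0):
        raise ValidationError(f"target_r must be in (0, 1], got {target_r}")
    rng = np.random.default_rng([seed, 2])
    positions = [p for p, _ in true_acc.records]
    x = np.array([v for _, v in true_acc.records], dtype=float)
    z = (x - x.mean()) / x.std()
    sigma = math.sqrt(1.0 / target_r**2 - 1.0)
    noisy = z + rng.normal(0.0, sigma, size=z.size) if sigma > 0 else z
    pred = np.maximum(noisy * x.std() + x.mean(), 0.0)
    return AccessibilityTable(
        records=[(p, float(v)) for p, v in zip(positions, pred)],
        source="sequence_predicted",
        method="synthetic",
    )


def generate_all(cfg: SyntheticConfig):
    """Convenience: (truth, structure acc, predicted acc, DMS table) in one call."""
    truth, struct_acc = generate_truth(cfg)
    pred_acc = generate_predicted_accessibility(struct_acc, cfg.target_r, cfg.seed)
    dms = generate_dms(truth, cfg)
    return truth, struct_acc, pred_acc, dms
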