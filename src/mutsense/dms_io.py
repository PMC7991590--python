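"""Readers/writers for mutational-effect tables, accessibility tables and truth labels.

All tables use 1-based residue indices in the coordinate system of the DMS
dataset.  An integer ``offset`` on the accessibility readers maps structure
numbering onto DMS numbering.  Missing mutants are represented by absence of
a record, never by sentinel scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from mutsense.errors import FormatError, ValidationError

#: The 20 canonical one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: The three residue classes called by the pipeline.
RESIDUE_CLASSES: tuple[str, ...] = ("active_site", "buried", "exposed_nonactive")


@dataclass(frozen=True)
class MutEffectRecord:
    """One mutant: wild-type residue ``wt_aa`` at ``position`` replaced by ``mut_aa``."""

    position: int
    wt_aa: str
    mut_aa: str
    raw_score: float


@dataclass
class MutEffectTable:
    """Per-mutation effect scores keyed by (position, wt_aa, mut_aa).

    Invariants (enforced by :meth:`validate`): positions >= 1, no
    self-substitutions, no duplicate (position, mut_aa) pairs, and a single
    wild-type identity per position.
    """

    dataset_id: str
    records: list[MutEffectRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[int, str]] = set()
        wt_at: dict[int, str] = {}
        for rec in self.records:
            if rec.position < 1:
                raise ValidationError(f"position {rec.position} is not a 1-based index")
            if rec.wt_aa not in AMINO_ACIDS:
                raise ValidationError(f"unknown wild-type residue {rec.wt_aa!r} at position {rec.position}")
            if rec.mut_aa not in AMINO_ACIDS:
                raise ValidationError(f"unknown substitution {rec.mut_aa!r} at position {rec.position}")
            if rec.wt_aa == rec.mut_aa:
                raise ValidationError(f"self-substitution {rec.wt_aa}->{rec.mut_aa} at position {rec.position}")
            if not math.isfinite(rec.raw_score):
                raise ValidationError(f"non-finite score at position {rec.position} ({rec.mut_aa})")
            key = (rec.position, rec.mut_aa)
            if key in seen:
                raise ValidationError(f"duplicate mutant at position {rec.position} ({rec.mut_aa})")
            seen.add(key)
            prev = wt_at.setdefault(rec.position, rec.wt_aa)
            if prev != rec.wt_aa:
                raise ValidationError(
                    f"inconsistent wild type at position {rec.position}: {prev} vs {rec.wt_aa}"
                )

    @property
    def positions(self) -> list[int]:
        return sorted({r.position for r in self.records})

    def scores(self) -> list[float]:
        return [r.raw_score for r in self.records]

    def by_position(self) -> dict[int, list[MutEffectRecord]]:
        out: dict[int, list[MutEffectRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.position, []).append(rec)
        return out


@dataclass
class AccessibilityTable:
    """Per-residue relative side-chain accessibility (percent).

    ``source`` records provenance: ``"structure"`` for values calculated from
    coordinates, ``"sequence_predicted"`` for predictor output.  Values above
    100 are permitted (extended conformations exceed the reference state).
    """

    records: list[tuple[int, float]]
    source: str
    method: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("structure", "sequence_predicted"):
            raise ValidationError(f"unknown accessibility source {self.source!r}")
        seen: set[int] = set()
        for pos, acc in self.records:
            if pos in seen:
                raise ValidationError(f"duplicate position {pos} in accessibility table")
            seen.add(pos)
            if not math.isfinite(acc) or acc < 0:
                raise ValidationError(f"relative accessibility at position {pos} must be >= 0, got {acc}")

    @property
    def positions(self) -> list[int]:
        return sorted(p for p, _ in self.records)

    def as_dict(self) -> dict[int, float]:
        return dict(self.records)


@dataclass
class ResidueTruth:
    """Curated residue labels plus positions excluded from buried-class evaluation."""

    records: list[tuple[int, str]]
    exclusions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pos, cls in self.records:
            if pos in seen:
                raise ValidationError(f"duplicate position {pos} in truth table")
            seen.add(pos)
            if cls not in RESIDUE_CLASSES:
                raise ValidationError(f"unknown residue class {cls!r} at position {pos}")

    def as_dict(self) -> dict[int, str]:
        return dict(self.records)


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, accepting tab or comma separation."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _to_float(value: str, context: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric score {value!r} {context}") from None


def read_mut_effect_table(path: str | Path, dialect: str = "long", dataset_id: str | None = None) -> MutEffectTable:
    """Read a per-mutation score table.

    ``dialect="long"`` expects columns ``position, wt_aa, mut_aa, score``;
    ``dialect="matrix"`` expects ``position, wt_aa`` followed by the 20
    amino-acid columns, with empty cells marking unobserved mutants.
    """
    if dialect not in ("long", "matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path)
    name = dataset_id if dataset_id is not None else Path(path).stem
    records: list[MutEffectRecord] = []
    if dialect == "long":
        required = {"position", "wt_aa", "mut_aa", "score"}
        if not required.issubset(df.columns):
            raise FormatError(f"long-format table must have columns {sorted(required)}, got {list(df.columns)}")
        for row in df.itertuples(index=False):
            pos = int(row.position)
            records.append(
                MutEffectRecord(pos, str(row.wt_aa).strip().upper(), str(row.mut_aa).strip().upper(),
                                _to_float(row.score, f"at position {pos} ({row.mut_aa})"))
            )
    else:
        aa_cols = [c for c in df.columns if c.upper() in AMINO_ACIDS and len(c) == 1]
        if "position" not in df.columns or "wt_aa" not in df.columns or not aa_cols:
            raise FormatError("matrix-format table must have columns position, wt_aa and amino-acid columns")
        for row in df.itertuples(index=False):
            d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
            pos = int(d["position"])
            wt = str(d["wt_aa"]).strip().upper()
            for col in aa_cols:
                cell = d[col]
                if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                    continue
                mut = col.upper()
                records.append(MutEffectRecord(pos, wt, mut, _to_float(cell, f"at position {pos} ({mut})")))
    return MutEffectTable(dataset_id=name, records=records)


def write_mut_effect_table(table: MutEffectTable, path: str | Path) -> None:
    """Write a table in the long dialect (TSV, sorted by position then substitution)."""
    rows = sorted(table.records, key=lambda r: (r.position, r.mut_aa))
    df = pd.DataFrame(
        {"position": [r.position for r in rows], "wt_aa": [r.wt_aa for r in rows],
         "mut_aa": [r.mut_aa for r in rows], "score": [r.raw_score for r in rows]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_rsa(path: str | Path, chain: str | None = None, offset: int = 0) -> AccessibilityTable:
    """Parse a NACCESS ``.rsa`` file into a structure-source accessibility table.

    Uses the *side-chain relative* column (the burial rule operates on
    side-chain accessibility, not all-atom).  ``chain`` selects one chain;
    with ``chain=None`` all chains are kept, which fails on duplicate residue
    numbers.  ``offset`` is added to every residue number to reconcile
    structure numbering with DMS numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records: list[tuple[int, float]] = []
    chains_seen: set[str] = set()
    for line in path.read_text().splitlines():
        if not line.startswith("RES"):
            continue
        # Fixed layout: RES <resname:3> <chain:1> <resnum:4> then 10 floats
        # (all-atom abs/rel, side-chain abs/rel, main-chain, non-polar, polar).
        chain_id = line[8].strip()
        chains_seen.add(chain_id)
        if chain is not None and chain_id != chain:
            continue
        try:
            resnum = int(line[9:14])
            values = [float(tok) for tok in line[14:].split()]
            sidechain_rel = values[3]
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed RES line in {path}: {line!r}") from exc
        records.append((resnum + offset, max(sidechain_rel, 0.0)))
    if not chains_seen:
        raise FormatError(f"{path} contains no RES lines")
    if chain is not None and chain not in chains_seen:
        raise LookupError(f"chain {chain!r} not found in {path} (chains: {sorted(chains_seen)})")
    return AccessibilityTable(records=records, source="structure", method="naccess")


def read_accessibility_table(path: str | Path, offset: int = 0) -> AccessibilityTable:
    """Read a generic predictor export with columns ``position, rel_acc[, method]``."""
    df = _read_table(path)
    if not {"position", "rel_acc"}.issubset(df.columns):
        raise FormatError(f"accessibility table must have columns position, rel_acc; got {list(df.columns)}")
    method = ""
    if "method" in df.columns and len(df):
        method = str(df["method"].iloc[0])
    records = []
    for row in df.itertuples(index=False):
        pos = int(row.position)
        acc = _to_float(row.rel_acc, f"at position {pos}")
        records.append((pos + offset, acc))
    return AccessibilityTable(records=records, source="sequence_predicted", method=method)


def write_accessibility_table(acc: AccessibilityTable, path: str | Path) -> None:
    df = pd.DataFrame(sorted(acc.records), columns=["position", "rel_acc"])
    if acc.method:
        df["method"] = acc.method
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_truth(path: str | Path, exclusions: Iterable[int] = ()) -> ResidueTruth:
    """Read truth labels: TSV with columns ``position, true_class``."""
    df = _read_table(path)
    if not {"position", "true_class"}.issubset(df.columns):
        raise FormatError(f"truth table must have columns position, true_class; got {list(df.columns)}")
    records = [(int(r.position), str(r.true_class).strip()) for r in df.itertuples(index=False)]
    return ResidueTruth(records=records, exclusions=set(exclusions))


def write_truth(truth: ResidueTruth, path: str | Path) -> None:
    df = pd.DataFrame(sorted(truth.records), columns=["position", "true_class"])
    df.to_csv(path, sep="\t", index=False)


def write_predictions(predictions, path: str | Path) -> None:
    """Write a prediction table as TSV, one row per residue sorted by position.

    Columns: position, z_mut_sens, z_acc, score_active, score_buried,
    predicted_class, flags (semicolon-joined, empty when none).
    """
    rows = predictions.rows()
    if not rows:
        raise ValidationError("refusing to write an empty prediction table")
    df = pd.DataFrame(rows, columns=["position", "z_mut_sens", "z_acc", "score_active",
                                     "score_buried", "predicted_class", "flags"])
    df = df.sort_values("position")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path: str | Path):
    """Re-read a file written by :func:`write_predictions`."""
    from mutsense.classify import PredictionTable  # local import avoids a cycle

    df = _read_table(path)
    required = {"position", "z_mut_sens", "z_acc", "score_active", "score_buried", "predicted_class"}
    if not required.issubset(df.columns):
        raise FormatError(f"prediction table missing columns {sorted(required - set(df.columns))}")
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    return PredictionTable.from_rows(
        [
            (int(r.position), float(r.z_mut_sens), float(r.z_acc), float(r.score_active),
             float(r.score_buried), str(r.predicted_class), str(r.flags))
            for r in df.itertuples(index=False)
        ]
    )
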