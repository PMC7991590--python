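"""Transcribed published benchmark tables for the twelve curated DMS datasets.

These are reference values reported in the literature for this prediction
task: per-protein Pearson correlations between sequence-predicted and
structure-calculated accessibility, and per-dataset classification metrics
for each residue class.  They let the summary machinery be checked against
published cross-dataset aggregates without re-running any external predictor.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLES = {
    "accessibility_correlations": "accessibility_correlations.tsv",
    "active_site": "active_site_benchmark.tsv",
    "buried": "buried_benchmark.tsv",
    "exposed": "exposed_benchmark.tsv",
}


def available() -> list[str]:
    return sorted(_TABLES)


def load_benchmark(name: str) -> pd.DataFrame:
    """Load one of the checked-in benchmark tables as a DataFrame."""
    try:
        filename = _TABLES[name]
    except KeyError:
        raise KeyError(f"unknown benchmark {name!r}; available: {available()}") from None
    ref = resources.files("mutsense").joinpath("data", filename)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
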