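import numpy as np
import pytest

from mutsense.classify import assign_classes, combine
from mutsense.dms_io import MutEffectRecord, MutEffectTable
from mutsense.rescale_aggregate import average_by_position, fit_rescale_params, rescale_scores
from mutsense.synthetic import SyntheticConfig, generate_all


def make_table(records, dataset_id="test"):
    return MutEffectTable(dataset_id=dataset_id, records=[MutEffectRecord(*r) for r in records])


def scores_at_position(values, position=1, wt="A"):
    """Spread arbitrary score values over distinct substitutions at one position."""
    muts = [aa for aa in "CDEFGHIKLMNPQRSTVWY" if aa != wt]
    assert len(values) <= len(muts)
    return [(position, wt, mut, float(v)) for mut, v in zip(muts, values)]


def run_pipeline(cfg: SyntheticConfig, **predict_kwargs):
    """Synthetic data -> predictions, returning (truth, prediction table)."""
    truth, _struct_acc, pred_acc, dms = generate_all(cfg)
    params = fit_rescale_params(dms.scores())
    profiles = average_by_position(rescale_scores(dms, params))
    pred = assign_classes(combine(profiles, pred_acc), **predict_kwargs)
    return truth, pred


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synthetic():
    cfg = SyntheticConfig(n_positions=60, seed=7)
    return cfg, generate_all(cfg)
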