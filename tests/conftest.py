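"""Shared fixtures: synthetic benchmarks and screen-structure builders.

All fixtures are generated programmatically at test time; nothing is read
from disk except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import pytest

import rlooppred as rp

# Venn-region counts emulating the published five-screen family:
# three IP-MS studies (totals 469/313/364; three-way core 49 including a
# 12-member core shared with both Prox-MS studies; pairwise-only regions
# 100/80/63 so the any-two union is 292) and two Prox-MS studies (totals
# 660/440 with a 101-member intersection containing the same 12-core).
SCREEN_REGIONS = {
    ("cristini", "wang", "wu", "mosler", "yan"): 12,
    ("cristini", "wang", "wu"): 37,          # three-way core totals 49
    ("cristini", "wang"): 100,
    ("cristini", "wu"): 80,
    ("wang", "wu"): 63,
    ("cristini",): 240,                       # 469 - 49 - 100 - 80
    ("wang",): 101,                           # 313 - 49 - 100 - 63
    ("wu",): 172,                             # 364 - 49 - 80 - 63
    ("mosler", "yan"): 89,                    # 101 intersection incl. 12-core
    ("mosler",): 559,                         # 660 - 101
    ("yan",): 339,                            # 440 - 101
}

IPMS_STUDIES = ("cristini", "wang", "wu")
PROXMS_STUDIES = ("mosler", "yan")


@pytest.fixture(scope="session")
def screen_family():
    """Five hit lists with the exact published overlap structure."""
    lists = rp.make_hit_lists(SCREEN_REGIONS)
    return {hl.study_name: hl for hl in lists}


@pytest.fixture(scope="session")
def separable_benchmark():
    """Strongly separated synthetic feature table (effect size 2)."""
    spec = rp.SyntheticSpec(n_pos=60, n_neg=400, effect_size=2.0,
                            nucleic_binding_rates=(0.8, 0.1), seed=11)
    table, labels = rp.make_benchmark(spec)
    return table, labels


@pytest.fixture(scope="session")
def null_benchmark():
    """Exchangeable-class synthetic table (effect size 0, equal rates)."""
    spec = rp.SyntheticSpec(n_pos=60, n_neg=400, effect_size=0.0,
                            nucleic_binding_rates=(0.3, 0.3), seed=12)
    table, labels = rp.make_benchmark(spec)
    return table, labels


@pytest.fixture(scope="session")
def small_config():
    """Small but structurally faithful ensemble configuration."""
    return rp.EnsembleConfig(n_models=3, n_negatives_per_model=60,
                             n_trees=50, cv_folds=5, mtry_grid=(2, 5, 10),
                             base_seed=5)


@pytest.fixture(scope="session")
def trained_ensemble(separable_benchmark, small_config):
    table, labels = separable_benchmark
    positives = set(labels.index[labels == 1])
    return rp.train_ensemble(table, positives, small_config)
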