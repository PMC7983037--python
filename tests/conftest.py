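"""Shared fixtures: synthetic worlds generated once per session.

All heavy pipeline runs (registry generation + full CCS calling) are
session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clipmeta as cm
from clipmeta.harmonize import binarize_cnv
from clipmeta.tas import compute_tas


def harmonized(registry, truth):
    """Binarize CNV and project DSS to TAS, in place."""
    for ds in list(registry):
        if ds.modality == "CNV" and not ds.is_binary:
            gain, loss = binarize_cnv(ds)
            registry.remove(ds.dataset_id)
            registry.add(gain)
            registry.add(loss)
        elif ds.modality == "DSS":
            registry.add(compute_tas(ds, truth.drug_targets))
            registry.remove(ds.dataset_id)
    return registry


@pytest.fixture(scope="session")
def default_world():
    """The default stated world: 2,000 genes x 120 lines x 3 partially
    overlapping sites, with planted drivers and SL pairs."""
    cfg = cm.default_config(20240901)
    registry, truth = cm.generate(cfg)
    return cfg, harmonized(registry, truth), truth


@pytest.fixture(scope="session")
def default_clip(default_world):
    cfg, registry, truth = default_world
    result = cm.run_clip(registry, cm.ClipConfig(seed=20240901, n_perm=100))
    return registry, truth, result


@pytest.fixture(scope="session")
def recovery_world():
    """High-reliability full-coverage scenario with subtype-recurrent drivers."""
    from clipmeta.synthdata import recovery_config

    cfg = recovery_config(20240902)
    registry, truth = cm.generate(cfg)
    return cfg, harmonized(registry, truth), truth


@pytest.fixture(scope="session")
def recovery_clip(recovery_world):
    cfg, registry, truth = recovery_world
    result = cm.run_clip(registry, cm.ClipConfig(seed=20240902, n_perm=100))
    return registry, truth, result


@pytest.fixture(scope="session")
def small_world():
    """A fast small panel for structural/CLI tests."""
    cfg = cm.default_config(7, n_genes=300, n_cell_lines=36)
    registry, truth = cm.generate(cfg)
    return cfg, harmonized(registry, truth), truth


def make_dataset(values, dataset_id="D1", site="BROAD", modality="GEXP", **kw):
    return cm.OmicsDataset(dataset_id, site, modality, pd.DataFrame(values), **kw)
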