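import numpy as np
import pandas as pd
import pytest

from cohortscreen.screen_data import META_COLUMNS, WellFeatureTable
from cohortscreen.synthetic import ScreenSimConfig, generate_screen


def make_table(records, feature_names, level="well"):
    """Build a WellFeatureTable from (meta dict, feature values) tuples."""
    rows = []
    for meta, feats in records:
        base = {
            "run_id": "r1",
            "plate_id": "p1",
            "well": "A01",
            "donor_id": "d1",
            "drug_id": "DMSO",
            "dose_uM": 0.0,
            "bioreplicate": 1,
            "tech_replicate": 1,
            "n_cells": 100,
        }
        base.update(meta)
        base.update(dict(zip(feature_names, feats)))
        rows.append(base)
    data = pd.DataFrame(rows, columns=META_COLUMNS + list(feature_names))
    return WellFeatureTable(data, list(feature_names), level=level)


@pytest.fixture(scope="session")
def small_screen():
    """One small synthetic run with ground truth, shared across tests."""
    cfg = ScreenSimConfig(
        n_donors=6,
        n_drugs=8,
        n_features=150,
        n_moa_classes=4,
        wells_per_condition=3,
        bioreplicates=2,
        dmso_wells_per_plate=8,
        cells_per_well=(50, 80),
        seed=11,
    )
    table, truth = generate_screen(cfg)
    return cfg, table, truth
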