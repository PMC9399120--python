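import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mitofusion import profiles, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


SMALL_CONFIG = synthetic.SyntheticConfig(
    n_compounds=120, n_cp_features=120, n_ge_features=80,
    n_planted_cp=12, n_planted_ge=10, n_inconclusive=4,
    n_scaffolds=8, fp_bits=256, seed=3)


def fingerprint_frame(ds: synthetic.SyntheticDataset) -> pd.DataFrame:
    return pd.DataFrame(
        ds.fingerprints.bits,
        index=pd.Index(ds.fingerprints.compound_ids, name="compound_id"),
        columns=[f"bit_{i}" for i in range(ds.fingerprints.n_bits)])


def pipeline_tables(ds: synthetic.SyntheticDataset):
    """Consensus profiles -> cytotoxicity filter -> modeling tables.

    Returns (tables, labels) restricted to retained, conclusive compounds.
    """
    cons = profiles.consensus(profiles.subtract_plate_control(ds.well_table))
    pset = profiles.filter_low_cellcount(cons)
    labels = ds.labels.set_index("compound_id")["label"]
    kept = pset.retained.index
    kept = kept[labels.reindex(kept) != "inconclusive"]
    tables = {"cp": pset.retained.loc[kept],
              "ge": ds.ge_table.loc[kept],
              "fp": fingerprint_frame(ds).loc[kept]}
    return tables, labels.loc[kept]


@pytest.fixture(scope="session")
def small_dataset():
    return synthetic.generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    return pipeline_tables(small_dataset)
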