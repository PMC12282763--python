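"""Shared fixtures: simulated reference, reads, and trained classifiers.

Heavy artifacts are session-scoped so the suite stays fast; everything is
generated programmatically with fixed seeds.
"""

import numpy as np
import pytest

from chipcall.classifier import VariantClassifier
from chipcall.spike_sim import make_reference, simulate_reads, synthetic_feature_table


@pytest.fixture(scope="session")
def sim_ref():
    return make_reference(seed=11)


@pytest.fixture(scope="session")
def sim_reads(sim_ref):
    reads, germline = simulate_reads(sim_ref, mean_depth=80, seed=11, err_rate=0.001)
    return reads, germline


@pytest.fixture(scope="session")
def snv_model():
    X, y = synthetic_feature_table(n=3000, separation=1.0, seed=1)
    return VariantClassifier("gbt", "SNV", "WGS", random_state=1).fit(X, y)


@pytest.fixture(scope="session")
def indel_model():
    X, y = synthetic_feature_table(n=1500, separation=1.0, seed=2, variant_type="INDEL")
    return VariantClassifier("gbt", "INDEL", "WGS", random_state=2).fit(X, y)
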