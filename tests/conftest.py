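import numpy as np
import pandas as pd
import pytest

import fshdsig as fs


@pytest.fixture
def tiny_counts() -> fs.CountMatrix:
    """3 genes x 2 samples with hand-computable size factors (0.5, 2.0)."""
    values = pd.DataFrame(
        [[2.0, 8.0], [3.0, 12.0], [4.0, 16.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2"],
    )
    return fs.CountMatrix(values=values, scale="raw")


@pytest.fixture
def small_gene_sets() -> fs.SignatureGeneSets:
    return fs.SignatureGeneSets(
        dux4_targets=frozenset({"D1", "D2", "D3"}),
        pax7_induced=frozenset({"I1", "I2", "I3"}),
        pax7_repressed=frozenset({"R1", "R2", "R3"}),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    cfg = fs.CohortConfig(seed=11)
    counts, records, gt = fs.generate_cohort(cfg)
    return cfg, counts, records, gt


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    cfg, counts, records, gt = default_cohort
    sets = fs.signature_gene_sets(cfg)
    meta = fs.metadata_frame(records)
    scores = fs.compute_signature_scores(
        counts, sets, fshd_biopsies=meta.index[meta["group"] == "FSHD"]
    )
    return cfg, meta, gt, scores
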