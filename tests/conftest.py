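import numpy as np
import pandas as pd
import pytest

from metabograd import MetaboliteAnnotation, MetaboliteMatrix, SampleMetadata
from metabograd.synth import SynthConfig


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 metabolites, one missing cell."""
    df = pd.DataFrame(
        {"m1": [5.0, np.nan, 7.0], "m2": [1.0, 2.0, 3.0]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return MetaboliteMatrix(data=df)


@pytest.fixture
def tiny_metadata():
    df = pd.DataFrame(
        {
            "subject_id": [f"subj{i}" for i in range(5)],
            "group": ["HC", "HC", "CTEPH", "CTEPH", "DC"],
            "cohort": ["discovery"] * 4 + ["none"],
            "batch": "batch_0",
            "timepoint": "none",
            "site": "none",
            "age": [50.0, 52.0, 65.0, 70.0, 60.0],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"),
    )
    return SampleMetadata(data=df)


@pytest.fixture
def tiny_annotation():
    df = pd.DataFrame(
        {
            "subpathway": ["Sphingomyelins", "TCA cycle"],
            "superpathway": ["Lipid", "Energy"],
            "identity_confirmed": [True, False],
            "xenobiotic": [False, False],
        },
        index=pd.Index(["m1", "m2"], name="metabolite_id"),
    )
    return MetaboliteAnnotation(data=df)


@pytest.fixture
def small_config():
    """Scaled-down study for fast end-to-end runs."""
    return SynthConfig(
        seed=7, m_metabolites=60, n_subpathways=10,
        n_hc_discovery=30, n_hc_replication=30,
        n_cteph_discovery=40, n_cteph_replication=40,
        n_dc=30, n_cted=20, n_ipah=40,
        n_paired=25, n_pre_unpaired=30, n_post_unpaired=30,
        n_trisite_cteph=40, n_trisite_ipah=10,
        n_twin_pairs=3,
    )
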