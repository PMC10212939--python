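import numpy as np
import pandas as pd
import pytest

import donorscreen as ds


@pytest.fixture(scope="session")
def small_cohort():
    """A quick synthetic cohort with enough donors in every partition."""
    return ds.generate_cohort(
        ds.SimConfig(n_patients=300, donor_prevalence=0.10, n_analytes=20,
                     seed=42)
    )


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """Hand-written three-table cohort for exact-value ingestion tests."""
    d = tmp_path_factory.mktemp("tiny")
    (d / "labs.csv").write_text(
        "patient_id,analyte_code,charttime,value\n"
        "p1,NA,2020-01-01T00:00:00,140\n"
        "p1,NA,2020-01-02T12:00:00,138\n"
        "p1,K,2020-01-02T06:00:00,4.1\n"
        "p2,NA,2020-01-05T00:00:00,151\n"
    )
    (d / "stays.csv").write_text(
        "patient_id,stay_start,stay_end,specialty,head_imaging,label,subtype,died_in_icu\n"
        "p1,2020-01-01T00:00:00,2020-01-03T00:00:00,neurosurgery,1,1,local_donor,1\n"
        "p2,2020-01-04T00:00:00,2020-01-06T00:00:00,,0,0,non_donor,0\n"
    )
    (d / "panel.csv").write_text(
        "analyte_code,units,normal_low,normal_high\n"
        "NA,mmol/L,135,145\n"
        "K,mmol/L,3.5,5.0\n"
    )
    return d


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """One fitted pipeline on the small cohort, shared across tests."""
    cfg = ds.RunConfig(
        seed=5,
        bootstrap_B=200,
        ae=ds.AEConfig(epochs=4, seed=5),
        clf=ds.ClassifierConfig(epochs=40, seed=5),
    )
    return ds.DonorScreeningModel(small_cohort, cfg).fit()
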