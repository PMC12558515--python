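import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epihotspot as eh
from epihotspot import datasets as ds

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def thresholds():
    return eh.BinderThresholds()


@pytest.fixture(scope="session")
def rhd_scaffold():
    return ds.synthetic_rhd_scaffold()


@pytest.fixture(scope="session")
def small_panel():
    """Three deterministic synthetic DRB-like alleles."""
    return [eh.make_synthetic_allele(seed=100 + i) for i in range(3)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, k=9):
    return "".join(rng.choice(list(AA), size=k))


def random_record(rng, allele, antigen_id="ag", start=None, rank=None):
    return eh.BindingRecord(
        allele=allele,
        antigen_id=antigen_id,
        start=int(rng.integers(1, 400)) if start is None else start,
        core=random_peptide(rng),
        percent_rank=round(float(rng.uniform(0.01, 100)), 4) if rank is None else rank,
        score=round(float(rng.uniform(-5, 15)), 4),
    )
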