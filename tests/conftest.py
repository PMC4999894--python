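import numpy as np
import pytest

from readthrough.config import PredictorConfig
from readthrough.datasets import Proteome, TRCandidate


@pytest.fixture
def pcfg():
    return PredictorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_proteome(n=30, seed=0, min_len=40, max_len=400, species="fly"):
    """Small random proteome over the 20-letter alphabet."""
    r = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for i in range(n):
        ln = int(r.integers(min_len, max_len))
        records.append((f"P{i:03d}", "".join(r.choice(aas, ln))))
    return Proteome(records=records, species=species)


def make_candidate(pid="C001", cds_len=100, ext_len=20, seed=0, **kwargs):
    r = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    cds = "".join(r.choice(aas, cds_len))
    ext = "X" + "".join(r.choice(aas, ext_len - 1))
    return TRCandidate(id=pid, cds_protein=cds, extension=ext, **kwargs)


@pytest.fixture
def toy_proteome():
    return make_proteome()
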