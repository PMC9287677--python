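import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from miraxis import MirnaRecord, UtrSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# mature miR-139-5p, the MN-enriched miRNA the analyses centre on
MIR139_SEQ = "UCUACAGUGCACGUGUCUCCAGU"


@pytest.fixture
def mir139() -> MirnaRecord:
    return MirnaRecord(mir_id="miR-139-5p", sequence=MIR139_SEQ)


@pytest.fixture
def small_utrs() -> UtrSet:
    return UtrSet.from_pairs(
        [
            ("gA", "ACGT" * 10),
            ("gB", "ACTGTAG" + "C" * 30),  # carries the miR-139 seed site
            ("gC", "N" * 20 + "ACGT" * 5),
        ]
    )


@pytest.fixture
def simple_de() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    n = 40
    return pd.DataFrame(
        dict(
            feature_id=[f"g{i:03d}" for i in range(n)],
            log2fc=rng.normal(0, 1, n),
            pvalue=rng.uniform(0, 1, n),
        )
    )
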