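import numpy as np
import pytest
from hypothesis import settings

from numtscape.aligner import (ScoringScheme, SearchParams, calibrate_evalue)
from numtscape.pipeline import discover_numts
from numtscape.simulate import SimParams, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def evalue_model(scheme):
    return calibrate_evalue(scheme, 400, 4000, n_shuffles=40, seed=1)


@pytest.fixture(scope="session")
def flagship(scheme, evalue_model):
    """The reference simulation study: 2 Mb genome, 30 implanted events,
    300-3000 bp fragments at 5-15% divergence, plus its discovered calls."""
    params = SimParams(seed=7)
    mito, genome, truths = simulate_dataset(params)
    hits = discover_numts(mito, genome, scheme, SearchParams(), evalue_model)
    return {"params": params, "mito": mito, "genome": genome,
            "truths": truths, "hits": hits}
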