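import numpy as np
import pytest

from starrpairs import (CandidateSequence, Pool, SimulationConfig, TrueActivityModel,
                        simulate_dataset)


def make_candidate(cid: str, seq: str, cls: str = "enhancer", **kw) -> CandidateSequence:
    """Candidate of arbitrary length for compact test fixtures."""
    return CandidateSequence(cid, seq, cls=cls, variant_length=True, **kw)


def random_pool(n_enh: int, n_ctl: int, length: int = 249, seed: int = 0) -> Pool:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    cands = [CandidateSequence(f"E{i:03d}", "".join(rng.choice(bases, length)),
                               cls="enhancer", variant_length=length != 249)
             for i in range(n_enh)]
    cands += [CandidateSequence(f"C{i:03d}", "".join(rng.choice(bases, length)),
                                cls="control", variant_length=length != 249)
              for i in range(n_ctl)]
    return Pool(cands)


@pytest.fixture(scope="session")
def multiplicative_dataset():
    """A mid-sized multiplicative-regime screen shared across read-only tests."""
    config = SimulationConfig(n_enhancers=60, n_controls=40, mean_input_depth=100.0,
                              nb_dispersion=0.1, seed=42)
    model = TrueActivityModel(regime="multiplicative", noise_sd=0.1)
    return simulate_dataset(config, model)
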