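import numpy as np
import pandas as pd
import pytest

from omixnet.containers import CountMatrix
from omixnet.simulate import DESpec, ModuleSpec, PeakSpecEntry, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A compact two-module study for fast unit tests."""
    return SimulationConfig(
        n_genes=300,
        samples_per_group=6,
        modules=[
            ModuleSpec(1, 40, True, 0.8, trait_shift=1.5),
            ModuleSpec(2, 30, False, 0.8, condition="exposure", trait_shift=-1.5),
        ],
        de=[DESpec("g200", ("exposure", "disease"), 2.0),
            DESpec("g201", ("exposure", "disease"), -2.0),
            DESpec("g202", ("exposure",), 2.0)],
        peaks=[PeakSpecEntry("g210", "promoter", "gain", "exposure"),
               PeakSpecEntry("g211", "promoter", "loss", "exposure"),
               PeakSpecEntry("g212", "promoter", "gain", "disease")],
        seed=11,
    )


def make_count_matrix(counts: np.ndarray, conditions, dataset="ds1",
                      genes=None, samples=None) -> CountMatrix:
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame({"condition": conditions, "dataset": dataset},
                        index=pd.Index(samples, name="sample"))
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


@pytest.fixture
def nb_sampler():
    def draw(rng, mu, alpha):
        r = 1.0 / alpha
        return rng.negative_binomial(r, r / (r + mu))
    return draw
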