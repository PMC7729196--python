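import numpy as np
import pandas as pd
import pytest

from chromaproteo import enrichment, synthetic


def make_quant(rows):
    """Build a QuantTable frame from (pid, exp, frac, rep, intensity, pep, spc) tuples."""
    return pd.DataFrame(
        rows,
        columns=["protein_id", "experiment", "fraction", "replicate",
                 "intensity", "peptides", "spectral_count"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A shared 300-protein synthetic experiment (seed 7)."""
    cfg = synthetic.SimConfig(n_proteins=300, seed=7)
    records, truth, pwms = synthetic.generate_proteome(cfg)
    quant = synthetic.generate_quant(truth, cfg)
    return cfg, records, truth, pwms, quant


@pytest.fixture(scope="session")
def small_sim_norm(small_sim):
    _, _, _, _, quant = small_sim
    return enrichment.normalize(quant)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
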