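import numpy as np
import pytest

from swdl.acsd import run_acsd
from swdl.experiment import ExperimentConfig
from swdl.framework import assemble_bases
from swdl.ssbss import run_ssbss
from swdl.swbdl import SwbdlParams, run_swbdl
from swdl.swsdl import SwsdlParams, run_swsdl
from swdl.synthgen import SynthConfig, make_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default four-subject benchmark realisation (seed 0)."""
    return make_dataset(SynthConfig(), seed=0)


@pytest.fixture(scope="session")
def default_bases(default_dataset):
    """ssBSS results and assembled base matrices for the default dataset."""
    cfg = ExperimentConfig()
    rng = np.random.default_rng(0)
    results = [run_ssbss(s.data, cfg.ssbss, rng) for s in default_dataset.subjects]
    return results, assemble_bases(results)


@pytest.fixture(scope="session")
def default_fits(default_dataset, default_bases):
    """All four learners fitted to the default dataset with benchmark defaults."""
    _, bases = default_bases
    Ys = [s.data for s in default_dataset.subjects]
    return {
        "ssbss": default_bases[0],
        "acsd": [run_acsd(Y, 9, 12.0, 15) for Y in Ys],
        "swbdl": [
            run_swbdl(Y, bases.D_q, bases.X_q, SwbdlParams(), n_atoms=9) for Y in Ys
        ],
        "swsdl": [
            run_swsdl(Y, bases.D_q, bases.X_q, SwsdlParams(), n_atoms=9) for Y in Ys
        ],
    }
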