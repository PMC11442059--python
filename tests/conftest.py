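import numpy as np
import pytest

import rnlpipe as r
from rnlpipe.spectra import average_replicates, preprocess


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, seed 1 (288 frog reads, 162 substrate reads)."""
    return r.generate_study(r.StudyDesign(seed=1))


@pytest.fixture(scope="session")
def systems():
    return {
        "bird": r.build_bird_system(),
        "lizard": r.build_lizard_system(),
        "crab": r.build_crab_system(),
    }


@pytest.fixture(scope="session")
def averaged(study):
    """Preprocessed and averaged frogs (per individual) and substrates (per type)."""
    frogs, subs, illum = study
    frogs_avg = average_replicates(preprocess(frogs), by=["individual"])
    subs_avg = average_replicates(preprocess(subs), by=["type"])
    return frogs_avg, subs_avg, illum


@pytest.fixture(scope="session")
def contrast_records(averaged, systems):
    frogs_avg, subs_avg, illum = averaged
    return r.contrast_table(frogs_avg, subs_avg, illum, list(systems.values()))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
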