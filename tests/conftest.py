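import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mirkit import build_reference_set, default_library_configs, run_simulated_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def refs():
    """Default synthetic reference set (genome, genes, planted loci)."""
    return build_reference_set(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_configs(refs):
    """Default study design: 12 libraries, 4 profiles x 3 replicates, 50k reads."""
    return default_library_configs(refs, n_libraries=12, n_reads=50_000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(refs, study_configs):
    """Full pipeline run over the default simulated study (computed once)."""
    return run_simulated_study(refs, study_configs, seed=STUDY_SEED)
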