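import numpy as np
import pandas as pd
import pytest

from updtrio.annotation import AnnotationSimConfig, simulate_annotated_variants
from updtrio.containers import TrioGenotypeSet
from updtrio.pipeline import emulate_family6, run_pipeline
from updtrio.simulate import TrioSimConfig, UPDSegmentSpec, simulate_trio

# compact genomes used by most simulation-driven tests
THREE_CHROMS = {"1": 248_956_422, "2": 242_193_529, "6": 170_805_979}
CHR6_LEN = 170_805_979


def make_trio_sim(seed=0, upd=(), **overrides):
    defaults = dict(chrom_lengths=dict(THREE_CHROMS), sites_per_chrom=2500)
    defaults.update(overrides)
    return simulate_trio(TrioSimConfig(seed=seed, **defaults), upd)


def full_chr6_spec(parent="mother", mode="isodisomy"):
    return UPDSegmentSpec("6", 1, CHR6_LEN, parent, mode)


@pytest.fixture(scope="session")
def family6_config():
    return emulate_family6(seed=0)


@pytest.fixture(scope="session")
def family6_report(family6_config):
    return run_pipeline(family6_config)


@pytest.fixture(scope="session")
def annotation_table():
    """The packaged exome-scale fixture: 90,000 rows, four engineered survivors."""
    return simulate_annotated_variants(AnnotationSimConfig())


@pytest.fixture
def toy_trio():
    """Ten hand-written sites on two chromosomes."""
    sites = pd.DataFrame(
        {
            "chrom": ["1"] * 6 + ["2"] * 4,
            "pos": [100, 200, 300, 400, 500, 600, 50, 150, 250, 350],
            "ref": list("ACGTACGTAC"),
            "alt": list("GTACGTACGT"),
        }
    )
    gts = np.array(
        [
            # child, mother, father
            [0, 0, 0],
            [1, 1, 0],
            [2, 1, 1],
            [1, 0, 1],
            [2, 1, 0],   # maternal iso-informative pattern
            [0, 2, 2],   # mendelian error (other)
            [1, 1, 1],
            [-1, 0, 0],
            [2, 2, 0],   # maternal evidence pattern
            [0, 0, 2],   # maternal evidence pattern (child/mother 0/0, father 1/1)
        ],
        dtype=np.int8,
    )
    return TrioGenotypeSet(sites, gts)
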