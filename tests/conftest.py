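import pandas as pd
import pytest

from m5ckit import site_calling as sc
from m5ckit import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_config():
    return sd.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def genome(sim_config):
    return sd.generate_genome(sim_config)


@pytest.fixture(scope="session")
def transcriptome(genome, sim_config):
    return sd.generate_transcriptome(genome, sim_config)


@pytest.fixture(scope="session")
def truth(transcriptome, genome, sim_config):
    return sd.plant_methylation(transcriptome, genome, sim_config)


@pytest.fixture(scope="session")
def pileups(truth, transcriptome, genome, sim_config):
    return sd.simulate_pileups(truth, transcriptome, genome, sim_config)


@pytest.fixture(scope="session")
def called(pileups, transcriptome):
    return sc.call_sites(pileups, transcriptome=transcriptome)


def make_pileup(rows):
    """Build a pileup DataFrame from (chrom,pos,strand,rep,cond,c,t) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "replicate", "condition",
                 "c_count", "t_count"],
    )
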