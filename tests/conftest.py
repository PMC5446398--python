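import numpy as np
import pytest

from mitocleave.genomes import Genome
from mitocleave.guides import (
    GuideSite,
    build_offtarget_index,
    design_tiling_panel,
    scan_pam_sites,
    score_guide,
)
from mitocleave.simulate import SimConfig, simulate_genomes


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def synthetic_genomes(sim_cfg):
    """A mitochondrial-sized circular chromosome, a 1-Mb nuclear background
    and truth peaks, fixed seed."""
    return simulate_genomes(sim_cfg, np.random.default_rng(sim_cfg.seed))


@pytest.fixture(scope="session")
def mito(synthetic_genomes):
    return synthetic_genomes[0]


@pytest.fixture(scope="session")
def nuclear(synthetic_genomes):
    return synthetic_genomes[1]


@pytest.fixture(scope="session")
def scored_sites(mito, nuclear):
    index = build_offtarget_index([nuclear])
    return [score_guide(s, index) for s in scan_pam_sites(mito)]


@pytest.fixture(scope="session")
def panel(mito, scored_sites):
    return design_tiling_panel(mito, scored_sites, target_n=100)


def make_site(cut_pos, chrom="chrM", strand="+", seed="ACGTACGTACGTACGTACGT",
              pam="AGG", flags=frozenset()):
    """A synthetic GuideSite with a prescribed cut position (coordinates
    need not be sequence-consistent; used where only cut_pos matters)."""
    proto = cut_pos - 17 if strand == "+" else cut_pos - 6
    return GuideSite(chrom=chrom, strand=strand, proto_start=proto,
                     seed=seed, pam=pam, cut_pos=cut_pos, quality_flags=flags)
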