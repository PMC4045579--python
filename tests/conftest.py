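import numpy as np
import pytest

from srvscan import codon_engine as ce
from srvscan import synthetic_data as sd
from srvscan.codes import standard_code
from srvscan.seqio import parse_newick


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def small_family():
    """A 4-taxon, 20-codon simulated family (alignment, tree, truth)."""
    spec = sd.SimulationSpec(n_taxa=4, n_codons=20, seed=101, mean_branch_length=0.2)
    aln, truth = sd.simulate_alignment(spec)
    return aln, parse_newick(truth.tree_newick), truth


@pytest.fixture(scope="session")
def medium_family():
    """An 8-taxon, 200-codon family simulated under constant dS."""
    spec = sd.SimulationSpec(n_taxa=8, n_codons=200, seed=202)
    aln, truth = sd.simulate_alignment(spec)
    return aln, parse_newick(truth.tree_newick), truth


@pytest.fixture(scope="session")
def medium_fits(medium_family):
    """M0/M3/DUAL fits of the medium family, shared across tests."""
    aln, tree, _ = medium_family
    m0 = ce.fit_M0(aln, tree, n_restarts=1, seed=1)
    m3 = ce.fit_M3(aln, m0.tree, n_restarts=1, seed=2)
    dual = ce.fit_DUAL(aln, m0.tree, n_restarts=1, seed=3, start_from=m3, kappa=m3.kappa)
    return {"M0": m0, "M3": m3, "DUAL": dual}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
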