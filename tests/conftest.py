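import numpy as np
import pandas as pd
import pytest

from endotol import simulate
from endotol.io import write_fasta


@pytest.fixture(scope="session")
def small_methylome():
    """2,000-probe paired methylome with 50 planted hypomethylation events."""
    return simulate.simulate_methylome(n_probes=2000, n_dmp=50, n_donors=3, seed=11)


@pytest.fixture(scope="session")
def small_counts():
    """2,000-gene paired count matrix with 100 planted fold changes."""
    return simulate.simulate_counts(n_genes=2000, n_de=100, seed=11)


@pytest.fixture(scope="session")
def regions_sim(tmp_path_factory):
    """Toy contig (0.5 Mb, 40 target / 400 background CpGs) with FASTA on disk."""
    seq, annot, peaks, tss, truth = simulate.simulate_regions(
        n_target_cpgs=40,
        n_background_cpgs=400,
        contig_length=500_000,
        seed=7,
    )
    fasta = tmp_path_factory.mktemp("regions") / "genome.fa"
    write_fasta({"chrS": seq}, fasta)
    return {
        "seq": seq,
        "annot": annot,
        "peaks": peaks,
        "tss": tss,
        "truth": truth,
        "fasta": str(fasta),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
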