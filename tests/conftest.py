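import numpy as np
import pandas as pd
import pytest

from cinsig.catalog import proxy_catalog
from cinsig.simdata import CloneSpec, SimConfig, make_reference


@pytest.fixture(scope="session")
def catalog():
    return proxy_catalog()


@pytest.fixture(scope="session")
def tiny_reference():
    """Two 20 kb contigs; large enough that every pyrimidine-centered
    trinucleotide occurs."""
    return make_reference(seed=7, n_contigs=2, contig_length=20_000, gc_fraction=0.45)


def small_sim_config(seed=0, **overrides):
    """A fast two-clone configuration used across tests: 1 Mb contigs, dense
    coverage so per-variant statistics are informative."""
    lengths = {f"chr{i+1}": 1_000_000 for i in range(2)}
    diploid = [(c, 0, lengths[c], 2) for c in lengths]
    cin = [("chr1", 0, lengths["chr1"], 2), ("chr2", 0, lengths["chr2"], 1)]
    defaults = dict(
        seed=seed,
        n_contigs=2,
        contig_length=1_000_000,
        bin_size=100_000,
        clones=[
            CloneSpec("CS", diploid, n_somatic=200,
                      signature_mixture={"clocklike-proxy": 0.7, "flat-proxy": 0.3}),
            CloneSpec("CIN", cin, n_somatic=400,
                      signature_mixture={"SBS17a-proxy": 0.45, "SBS17b-proxy": 0.45,
                                         "flat-proxy": 0.10}),
        ],
        n_cells_per_clone=[25, 25],
        mean_reads_per_cell=50_000,
        coverage_fraction_range=(0.4, 0.6),
        n_germline=100,
        # moderate overdispersion: the whole-contig CN difference separates the
        # clones cleanly, so cluster contamination does not confound the
        # CS-overlap filter assertions downstream
        overdispersion=40.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture()
def small_config():
    return small_sim_config()


def make_flat_ref(seq: str, name: str = "chr1") -> dict:
    return {name: seq}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
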