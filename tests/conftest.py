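import numpy as np
import pytest

from m7gflow.reference import Interval, TRNAGene
from m7gflow.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """Scaled-down simulation for fast unit tests."""
    cfg = SimulationConfig(seed=11, n_isotypes=10,
                           n_isodecoders_per_isotype=1, fraction_m7g=0.4)
    cfg.trac.library_reads = 50_000
    cfg.mrna.n_genes = 200
    cfg.mrna.min_codons = 50
    cfg.mrna.max_codons = 150
    cfg.ribo.n_genes = 50
    return cfg


@pytest.fixture
def loop_gene():
    """A 76-nt gene whose fallback variable loop is [49, 64)."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=76))
    return TRNAGene(
        id="tRNA-Val-AAC-1-1", amino_acid="Val", anticodon="AAC",
        sequence=seq, variable_loop=Interval(49, 64),
    )
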