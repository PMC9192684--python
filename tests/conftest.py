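import numpy as np
import pandas as pd
import pytest

from efficow.simulate import (
    HerdSimConfig,
    ProteomeSimConfig,
    QpcrSimConfig,
    simulate_ct,
    simulate_herd,
    simulate_peptides,
)


@pytest.fixture(scope="session")
def small_herd():
    """20-cow herd with default noise, plus truth offsets."""
    return simulate_herd(HerdSimConfig(n_cows=20, seed=11))


@pytest.fixture(scope="session")
def small_proteome():
    """300-protein 5v5 peptide table with 20 spikes, plus sample sheet and truth."""
    cfg = ProteomeSimConfig(n_proteins=300, n_spike_up=10, n_spike_down=10,
                            seed=7)
    return simulate_peptides(cfg)


@pytest.fixture(scope="session")
def clean_ct():
    """Noise-free Ct table: ddCt must recover the configured ratios exactly."""
    cfg = QpcrSimConfig(ct_noise_sd=0.0, sample_shift_sd=0.0, seed=5,
                        reference_sds={"GAPDH": 0.0, "ACTB": 0.4})
    return simulate_ct(cfg)


@pytest.fixture
def toy_peptides():
    """Hand-written 2-protein table: protA has 5 peptides, protB has 2."""
    rows = [
        # peptide, protein, s1, s2
        ("p1", "protA", 10.0, 12.0),
        ("p2", "protA", 8.0, 9.0),
        ("p3", "protA", 6.0, 7.0),
        ("p4", "protA", 4.0, 3.0),
        ("p5", "protA", 1.0, 2.0),
        ("p6", "protB", 100.0, 90.0),
        ("p7", "protB", 50.0, np.nan),
    ]
    return pd.DataFrame(rows, columns=["peptide_id", "protein_id", "s1", "s2"])
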