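import numpy as np
import pytest

from cavepopgen.panel import AlleleFrequencyPanel, Population


@pytest.fixture(scope="session")
def small_neutral_panel():
    """A 2000-SNP neutral panel shared by read-only tests."""
    from cavepopgen import synthdata as sd

    config = sd.DemographyConfig(snp_count=2000, chrom_length=1_000_000, seed=11)
    panel, _ = sd.simulate_neutral_panel(config, draw_haplotypes=False)
    return panel, config


def make_panel(freq, pos=None, chrom="chr1", n_hap=20, pops=None):
    """Hand-built frequency panel for unit tests."""
    freq = np.asarray(freq, dtype=float)
    k, m = freq.shape
    if pops is None:
        roles = [("surface", 1), ("cave", 1), ("surface", 2), ("cave", 2),
                 ("cave", 2), ("cave", 1), ("cave", 2)]
        pops = [Population(f"pop{i}", roles[i % len(roles)][0],
                           roles[i % len(roles)][1]) for i in range(k)]
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    return AlleleFrequencyPanel(
        populations=pops,
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos),
        freq=freq,
        n=np.full((k, m), n_hap, dtype=np.int64),
    )
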