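import numpy as np
import pytest

from popdiff import GenotypePanel, Locus, MISSING, SimConfig, simulate_panel


def make_panel(dosage, populations=None, chrom=None, pos=None):
    """Build a small panel from a samples x loci dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    samples = [f"s{i}" for i in range(n)]
    if populations is None:
        populations = {s: "A" for s in samples}
    elif isinstance(populations, (list, tuple)):
        populations = dict(zip(samples, populations))
    chrom = chrom or ["1"] * L
    pos = pos or list(range(1, L + 1))
    bases = ["A", "C", "G", "T"]
    loci = [
        Locus(f"m{l}", str(chrom[l]), int(pos[l]), bases[l % 4], bases[(l + 1) % 4])
        for l in range(L)
    ]
    return GenotypePanel(loci, samples, populations, dosage)


@pytest.fixture
def tiny_panel():
    """4 samples x 3 loci with one missing call and two populations."""
    dosage = [
        [0, 1, 2],
        [1, 2, MISSING],
        [2, 0, 0],
        [0, 0, 1],
    ]
    return make_panel(dosage, populations=["A", "A", "B", "B"])


@pytest.fixture(scope="session")
def sim_panel():
    """Session-wide two-population simulation at reduced size."""
    cfg = SimConfig(
        n1=60, n2=60, n_loci=600, n_chrom=5, background_F=0.1933,
        n_selected=6, selected_F=0.8, inbreeding=0.95,
        admixed_fraction=0.05, missing_rate=0.02, seed=42,
    )
    panel, truth = simulate_panel(cfg)
    return panel, truth, cfg
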