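import numpy as np
import pandas as pd
import pytest

from eigensel.io import GenotypeMatrix, variant_frame


def make_matrix(dosages, chroms=None, positions=None, ref="A", alt="G", groups=None, samples=None):
    """Build a GenotypeMatrix from a raw dosage array for fixtures."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if chroms is None:
        chroms = ["1A"] * m
    if positions is None:
        positions = list(range(1000, 1000 + 1000 * m, 1000))
    refs = [ref] * m if isinstance(ref, str) else list(ref)
    alts = [alt] * m if isinstance(alt, str) else list(alt)
    variants = variant_frame(zip(chroms, positions, refs, alts))
    if samples is None:
        samples = np.array([f"S{i}" for i in range(n)], dtype=object)
    else:
        samples = np.array(samples, dtype=object)
    g = None
    if groups is not None:
        g = pd.Series(list(groups), index=samples)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages, groups=g)


def hwe_matrix(n, m, seed=0, groups=None):
    """Panmictic Hardy-Weinberg genotypes (outbred), for GRM identities."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return make_matrix(dos, groups=groups)


@pytest.fixture
def two_pop_sim():
    """Small two-subpopulation Balding-Nichols panel with selected loci."""
    from eigensel.simulate import SimulationConfig, simulate_balding_nichols

    cfg = SimulationConfig(
        n_per_subpop=(40, 40),
        n_snps=800,
        fst_drift=0.05,
        n_selected=5,
        selected_delta=0.5,
        seed=42,
    )
    return simulate_balding_nichols(cfg)
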