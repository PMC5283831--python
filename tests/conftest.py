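import numpy as np
import pandas as pd
import pytest

from proxscreen.synthetic import (
    GenomeConfig,
    ProximityScenario,
    gen_genome,
    gen_de_table,
    gen_peaks,
)


def small_prox_scenario(fold: float, seed: int, n_genes: int = 300,
                        n_down: int = 40, n_up: int = 40,
                        chrom_len: int = 10_000_000,
                        n_peaks: int = 300) -> ProximityScenario:
    """A fast proximity scenario for unit/property tests (one 10-Mb
    chromosome, 300 genes): calibration and testing run in well under a
    second per seed."""
    genome = GenomeConfig({"chr1": chrom_len}, n_genes, seed=seed)
    return ProximityScenario(
        genome=genome, n_down=n_down, n_up=n_up,
        n_unchanged=n_genes - n_down - n_up,
        n_background_peaks=n_peaks, planted_fold=fold, peak_len=200, seed=seed,
    )


def simulate_prox(fold: float, seed: int, **kw):
    """Generate (tss, de, peaks, metadata) for a small proximity scenario."""
    sc = small_prox_scenario(fold, seed, **kw)
    tss = gen_genome(sc.genome)
    de = gen_de_table(tss, sc)
    peaks, meta = gen_peaks(tss, de, sc)
    return tss, de, peaks, meta


@pytest.fixture(scope="session")
def null_prox_dataset():
    """One realisation of the exact-null scenario (planted fold 1)."""
    return simulate_prox(1.0, seed=42)


@pytest.fixture(scope="session")
def enriched_prox_dataset():
    """One realisation of a moderately enriched scenario (planted fold 2)."""
    return simulate_prox(2.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_tss_peaks(rng):
    """Unstructured random TSSs and peaks on two chromosomes, for
    oracle-equivalence checks."""
    chroms = {"chr1": 5_000_000, "chr2": 2_000_000}
    n_tss, n_peaks = 200, 300
    tss_chrom = rng.choice(list(chroms), size=n_tss)
    tss = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_tss)],
        "chrom": tss_chrom,
        "tss": [rng.integers(0, chroms[c]) for c in tss_chrom],
        "strand": rng.choice(["+", "-"], size=n_tss),
        "expression": 10.0 ** rng.normal(1.5, 0.75, size=n_tss),
    })
    pk_chrom = rng.choice(list(chroms), size=n_peaks)
    start = np.array([rng.integers(0, chroms[c] - 200) for c in pk_chrom])
    peaks = pd.DataFrame({
        "chrom": pk_chrom, "start": start, "end": start + 200,
        "summit_offset": rng.integers(0, 200, size=n_peaks),
    })
    return tss, peaks
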