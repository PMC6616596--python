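import numpy as np
import pandas as pd
import pytest

from popscan import GenotypePanel


def make_panel(dosage, positions=None, chroms=None, populations=None,
               alleles=None, ids=None, id_prefix="ind"):
    """Build a panel from a dosage matrix with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = positions if positions is not None else \
        (np.arange(m) + 1) * 1000
    chroms = chroms if chroms is not None else ["1"] * m
    populations = populations if populations is not None else ["POP"] * n
    if alleles is None:
        alleles = [("A", "G")] * m
    markers = pd.DataFrame({
        "id": ids if ids is not None else [f"snp{j}" for j in range(m)],
        "chromosome": chroms,
        "position": positions,
        "allele_a": [a for a, _ in alleles],
        "allele_b": [b for _, b in alleles],
    })
    samples = pd.DataFrame({
        "individual_id": [f"{id_prefix}{i}" for i in range(n)],
        "population": populations,
        "sex": ["unknown"] * n,
    })
    return GenotypePanel(markers, samples, dosage)


def random_panel(rng, n=20, m=50, missing_rate=0.05, n_pops=1,
                 n_chroms=1):
    """Random panel with Hardy-Weinberg-ish genotypes and missingness."""
    p = rng.uniform(0.05, 0.95, size=m)
    dosage = (rng.random((n, m)) < p).astype(np.int8) + \
        (rng.random((n, m)) < p).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random((n, m)) < missing_rate] = -1
    # guarantee each marker has at least one called genotype
    for j in range(m):
        if (dosage[:, j] == -1).all():
            dosage[int(rng.integers(n)), j] = 1
    chroms = [str(1 + (j % n_chroms)) for j in range(m)]
    positions = np.zeros(m, dtype=int)
    for c in range(n_chroms):
        idx = [j for j in range(m) if chroms[j] == str(c + 1)]
        positions[idx] = np.sort(
            rng.choice(np.arange(1, 10_000_000), len(idx), replace=False))
    pops = [f"P{(i % n_pops) + 1}" for i in range(n)]
    return make_panel(dosage, positions=positions, chroms=chroms,
                      populations=pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
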