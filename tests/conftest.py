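import itertools

import numpy as np
import pytest

from mnpkit.marker_screen import MISSING, SnpMatrix
from mnpkit.simulate import SimConfig, simulate_cohort


def make_matrix(rows: list[str], positions: list[int] | None = None,
                contig: str = "chr1", samples: list[str] | None = None) -> SnpMatrix:
    """Build a SnpMatrix from strings like 'AACG' (one string per position,
    one character per sample; '.' = missing)."""
    n = len(rows[0]) if rows else 0
    if positions is None:
        positions = list(range(len(rows)))
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    alleles = np.array([list(r) for r in rows], dtype="<U1") if rows else \
        np.empty((0, len(samples)), dtype="<U1")
    return SnpMatrix(contig=contig, positions=np.array(positions), alleles=alleles,
                     samples=samples)


def brute_force_dp(matrix: SnpMatrix, window: tuple[int, int],
                   min_separation: int = 1) -> tuple[int, float]:
    """Independent all-pairs re-count of the distinguishing-pair statistic."""
    n = matrix.n_samples
    in_window = [k for k, p in enumerate(matrix.positions)
                 if window[0] <= p < window[1]]
    t = 0
    for i, j in itertools.combinations(range(n), 2):
        diffs = [matrix.positions[k] for k in in_window
                 if matrix.alleles[k, i] != MISSING
                 and matrix.alleles[k, j] != MISSING
                 and matrix.alleles[k, i] != matrix.alleles[k, j]]
        if len(diffs) >= 2 and max(diffs) - min(diffs) >= min_separation:
            t += 1
    return t, t / (n * (n - 1) // 2)


SMALL_SIM = SimConfig(seed=7, genome_length=40_000, n_pedigrees=3,
                      strains_per_pedigree=3, n_wild=3, n_clone_pairs=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort reused across tests (fast to genotype and screen)."""
    return simulate_cohort(SMALL_SIM)
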