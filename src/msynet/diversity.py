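"""Paternal-lineage diversity: Watterson's theta and nucleotide diversity pi.

Both estimators are per-site rates over a fixed denominator L, the length of
the single-copy Y sequence in which variants could have been called — not
the number of segregating sites. theta = S / (a_n * L) with
a_n = sum_{i=1}^{n-1} 1/i; pi is the mean pairwise Hamming distance between
the n haploid sequences divided by L (the plain pairwise mean, no n/(n-1)
correction). Samples sharing a haplotype contribute zero-distance pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DiversityResult:
    subset: str
    n: int
    S: int
    L: int
    theta: float
    pi: float


def _subset_calls(matrix: GenotypeMatrix, sample_ids: Sequence[str], L: float) -> np.ndarray:
    if len(sample_ids) < 2:
        raise ValueError("diversity requires n >= 2 samples")
    if L <= 0:
        raise ValueError("denominator L must be positive")
    sub = matrix.calls[[matrix.sample_index(s) for s in sample_ids]]
    if (sub == MISSING).any():
        raise ValueError("subset contains MISSING calls; impute first")
    return sub


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(matrix: GenotypeMatrix, sample_ids: Sequence[str], L: float) -> float:
    sub = _subset_calls(matrix, sample_ids, L)
    S = int(((sub == 0).any(axis=0) & (sub == 1).any(axis=0)).sum())
    return S / (harmonic(len(sample_ids)) * L)


def nucleotide_diversity_pi(matrix: GenotypeMatrix, sample_ids: Sequence[str], L: float) -> float:
    sub = _subset_calls(matrix, sample_ids, L)
    dists = [int((sub[i] != sub[j]).sum()) for i, j in combinations(range(len(sub)), 2)]
    return float(np.mean(dists)) / L


def diversity_table(
    matrix: GenotypeMatrix,
    subsets: dict[str, Sequence[str]],
    L: float,
) -> pd.DataFrame:
    """Theta and pi for each named sample subset, one row per subset."""
    rows = []
    for name, sample_ids in subsets.items():
        sub = _subset_calls(matrix, sample_ids, L)
        S = int(((sub == 0).any(axis=0) & (sub == 1).any(axis=0)).sum())
        rows.append(
            DiversityResult(
                subset=name,
                n=len(sample_ids),
                S=S,
                L=int(L),
                theta=watterson_theta(matrix, sample_ids, L),
                pi=nucleotide_diversity_pi(matrix, sample_ids, L),
            ).__dict__
        )
    return pd.DataFrame(rows, columns=["subset", "n", "S", "L", "theta", "pi"])
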