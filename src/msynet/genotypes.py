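"""Haploid genotype matrix: samples x biallelic SNV sites.

Cells take one of three states: REF (0), ALT (1) or MISSING (-1). Per-cell
read depth (DP) and genotype quality (GQ) are carried for audit when known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

REF: int = 0
ALT: int = 1
MISSING: int = -1


@dataclass(frozen=True, order=True)
class Site:
    """A biallelic SNV site (1-based position, as in VCF)."""

    contig: str
    pos: int
    ref: str = "A"
    alt: str = "G"

    def label(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @staticmethod
    def from_label(label: str) -> "Site":
        contig, pos, ref, alt = label.rsplit(":", 3)
        return Site(contig, int(pos), ref, alt)


@dataclass
class GenotypeMatrix:
    """Samples x sites haploid allele matrix with optional DP/GQ audit arrays."""

    samples: list[str]
    sites: list[Site]
    calls: np.ndarray  # int8, shape (n_samples, n_sites)
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    outgroup: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise ValueError("genotype cells must be REF (0), ALT (1) or MISSING (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def ingroup(self) -> list[str]:
        return [s for s in self.samples if s not in self.outgroup]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return replace(
            self,
            samples=list(sample_ids),
            calls=self.calls[idx].copy(),
            dp=None if self.dp is None else self.dp[idx].copy(),
            gq=None if self.gq is None else self.gq[idx].copy(),
            outgroup=frozenset(s for s in sample_ids if s in self.outgroup),
        )

    def n_missing(self) -> int:
        return int((self.calls == MISSING).sum())

    def segregating_sites(self, sample_ids: Iterable[str] | None = None) -> int:
        """Count sites carrying both alleles among the given samples (MISSING ignored)."""
        sub = self.calls if sample_ids is None else self.calls[[self.sample_index(s) for s in sample_ids]]
        has_ref = (sub == REF).any(axis=0)
        has_alt = (sub == ALT).any(axis=0)
        return int((has_ref & has_alt).sum())
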