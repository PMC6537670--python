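"""Variant filter cascade and missing-call imputation for haploid Y variants.

Variants are kept only when they fall in single-copy Y (scY) regions and
survive an ordered cascade: biallelic SNV, no heterozygous or phased call
(impossible states on a haploid chromosome), not an apparent reference
error, not all-missing, and supported by at least one sample with adequate
depth and genotype quality. Each dropped site is logged with the first rule
it violated. Because the reference assembly is one individual's consensus,
a site at which every called ingroup sample carries the alternate allele is
read as an error in the reference base, not a polymorphism.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import ALT, MISSING, REF, GenotypeMatrix, Site
from .io import Interval, VariantRecord

REASONS = (
    "not_scY",
    "indel",
    "multiallelic",
    "heterozygous",
    "phased",
    "reference_error",
    "empty",
    "below_thresholds",
)


@dataclass
class FilterLog:
    frame: pd.DataFrame  # contig, pos, reason

    def counts(self) -> dict[str, int]:
        return self.frame["reason"].value_counts().to_dict()


class _RegionIndex:
    """Membership test for 1-based positions against sorted BED intervals."""

    def __init__(self, intervals: list[Interval]):
        self.by_contig: dict[str, tuple[list[int], list[int]]] = {}
        for contig, start, end in sorted(intervals):
            starts, ends = self.by_contig.setdefault(contig, ([], []))
            if starts and start < ends[-1]:
                raise ValueError(f"overlapping scY intervals on {contig}")
            starts.append(start)
            ends.append(end)

    def contains(self, contig: str, pos: int) -> bool:
        if contig not in self.by_contig:
            return False
        starts, ends = self.by_contig[contig]
        i = bisect_right(starts, pos - 1)
        return i > 0 and pos - 1 < ends[i - 1]


def filter_variants(
    records: list[VariantRecord],
    scy_intervals: list[Interval],
    samples: list[str],
    dp_min: int = 3,
    gq_min_exclusive: int = 9,
    outgroup_ids: tuple[str, ...] = (),
    reference_sample: str | None = None,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Apply the ordered filter cascade; return the haploid matrix and drop log.

    Per-sample cells failing DP >= ``dp_min`` or GQ > ``gq_min_exclusive``
    are demoted to MISSING; a site survives only if at least one cell passes
    both. The reference-error test uses ingroup samples only; when
    ``reference_sample`` is given, that individual must itself carry ALT for
    a unanimous-ALT site to count as a reference error.
    """
    if not samples:
        raise ValueError("no samples given")
    index = _RegionIndex(scy_intervals)
    known_contigs = set(index.by_contig)
    ingroup = [s for s in samples if s not in outgroup_ids]
    if not ingroup:
        raise ValueError("all samples are outgroup")

    kept: list[tuple[Site, np.ndarray, np.ndarray, np.ndarray]] = []
    dropped: list[tuple[str, int, str]] = []

    vcf_contigs = {r.contig for r in records}
    if records and known_contigs and not (vcf_contigs & known_contigs):
        raise ValueError(
            f"no shared contig names between VCF ({sorted(vcf_contigs)[:3]}...) "
            f"and scY BED ({sorted(known_contigs)[:3]}...)"
        )

    for i, r in enumerate(records):
        if r.pos < 1 or not r.ref:
            raise ValueError(f"malformed VCF record at index {i}: {r.contig}:{r.pos}")

        def drop(reason: str) -> None:
            dropped.append((r.contig, r.pos, reason))

        if not index.contains(r.contig, r.pos):
            drop("not_scY")
            continue
        if len(r.ref) != 1 or any(len(a) != 1 for a in r.alts):
            drop("indel")
            continue
        if len(r.alts) != 1:
            drop("multiallelic" if r.alts else "empty")
            continue
        if any(r.is_het(s) for s in samples):
            drop("heterozygous")
            continue
        if any(r.phased.get(s, False) for s in samples):
            drop("phased")
            continue
        calls_in = [r.allele(s) for s in ingroup]
        called = [c for c in calls_in if c != MISSING]
        # a single called sample cannot establish that the reference base is
        # wrong; unanimity needs at least two independent observations
        unanimous_alt = len(called) >= 2 and all(c == ALT for c in called)
        if unanimous_alt and (
            reference_sample is None or r.allele(reference_sample) == ALT
        ):
            drop("reference_error")
            continue
        if not called:
            drop("empty")
            continue

        alleles = np.array([r.allele(s) for s in samples], dtype=np.int8)
        dp = np.array([-1 if r.dp.get(s) is None else r.dp[s] for s in samples])
        gq = np.array([-1 if r.gq.get(s) is None else r.gq[s] for s in samples])
        passing = (dp >= dp_min) & (gq > gq_min_exclusive)
        if not (passing & (alleles != MISSING))[np.isin(samples, ingroup)].any():
            drop("below_thresholds")
            continue
        alleles = np.where(passing, alleles, MISSING).astype(np.int8)
        kept.append((Site(r.contig, r.pos, r.ref, r.alts[0]), alleles, dp, gq))

    kept.sort(key=lambda t: t[0])
    n = len(samples)
    if kept:
        calls = np.stack([k[1] for k in kept], axis=1)
        dp_mat = np.stack([k[2] for k in kept], axis=1)
        gq_mat = np.stack([k[3] for k in kept], axis=1)
    else:
        calls = np.zeros((n, 0), dtype=np.int8)
        dp_mat = np.zeros((n, 0), dtype=int)
        gq_mat = np.zeros((n, 0), dtype=int)
    matrix = GenotypeMatrix(
        samples=list(samples),
        sites=[k[0] for k in kept],
        calls=calls,
        dp=dp_mat,
        gq=gq_mat,
        outgroup=frozenset(outgroup_ids),
    )
    log = FilterLog(
        pd.DataFrame(sorted(dropped), columns=["contig", "pos", "reason"])
    )
    return matrix, log


# ---------------------------------------------------------------------------
# Imputation


def _clusters(samples: list[str], dist: np.ndarray) -> dict[str, int]:
    """Two-way clustering by cutting the unique longest MST edge, else one cluster."""
    n = len(samples)
    if n < 3:
        return {s: 0 for s in samples}
    # Prim MST on the complete graph
    in_tree = [0]
    edges: list[tuple[int, int, int]] = []
    best = {j: (dist[0, j], 0) for j in range(1, n)}
    while len(in_tree) < n:
        j = min(best, key=lambda j: (best[j][0], j))
        w, i = best[j]
        edges.append((int(w), i, j))
        in_tree.append(j)
        del best[j]
        for k in best:
            if dist[j, k] < best[k][0]:
                best[k] = (dist[j, k], j)
    longest = max(e[0] for e in edges)
    top = [e for e in edges if e[0] == longest]
    if len(top) != 1 or longest == 0:
        return {s: 0 for s in samples}
    cut = top[0]
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for w, i, j in edges:
        if (w, i, j) != cut:
            adj[i].append(j)
            adj[j].append(i)
    comp = {cut[1]}
    stack = [cut[1]]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in comp:
                comp.add(v)
                stack.append(v)
    return {s: (0 if i in comp else 1) for i, s in enumerate(samples)}


def impute_missing(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Fill MISSING cells from each sample's nearest neighbour in the network.

    Distances are Hamming distances over complete sites (no MISSING in any
    sample). Ties among equidistant donors resolve to their shared allele if
    unanimous, otherwise to the majority allele within the recipient's
    cluster (the two sides of the longest edge of a provisional
    minimum-spanning network), and finally to REF. Every imputed cell is
    logged with its donor and distance.
    """
    calls = matrix.calls.copy()
    n, m = calls.shape
    all_missing = (calls == MISSING).all(axis=1)
    if m and all_missing.any():
        bad = [matrix.samples[i] for i in np.where(all_missing)[0]]
        raise ValueError(f"samples with 100% missing calls cannot be placed: {bad}")
    complete = ~(calls == MISSING).any(axis=0)
    if m and not complete.any():
        raise ValueError("no complete site available to anchor imputation")

    core = calls[:, complete]
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        dist[i] = (core != core[i]).sum(axis=1)
    cluster = _clusters(matrix.samples, dist)

    log_rows = []
    miss_i, miss_j = np.where(calls == MISSING)
    for i, j in zip(miss_i, miss_j):
        donors = [k for k in range(n) if k != i and calls[k, j] != MISSING]
        if not donors:
            raise ValueError(f"site {matrix.sites[j].label()} has no called sample")
        dmin = min(dist[i, k] for k in donors)
        nearest = [k for k in donors if dist[i, k] == dmin]
        alleles = {int(calls[k, j]) for k in nearest}
        if len(alleles) == 1:
            value = alleles.pop()
            how = "nearest" if len(nearest) == 1 else "tie_unanimous"
            donor = matrix.samples[min(nearest)]
        else:
            members = [
                k for k in range(n)
                if cluster[matrix.samples[k]] == cluster[matrix.samples[i]]
                and calls[k, j] != MISSING
            ]
            votes = [int(calls[k, j]) for k in members]
            n_alt = sum(v == ALT for v in votes)
            if 2 * n_alt > len(votes):
                value, how = ALT, "cluster_majority"
            elif 2 * n_alt < len(votes):
                value, how = REF, "cluster_majority"
            else:
                value, how = REF, "tie_to_ref"
            donor = "cluster"
        calls[i, j] = value
        log_rows.append(
            {
                "sample": matrix.samples[i],
                "site": matrix.sites[j].label(),
                "value": value,
                "donor": donor,
                "distance": dmin,
                "rule": how,
            }
        )
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        sites=list(matrix.sites),
        calls=calls,
        dp=matrix.dp,
        gq=matrix.gq,
        outgroup=matrix.outgroup,
    )
    log = pd.DataFrame(log_rows, columns=["sample", "site", "value", "donor", "distance", "rule"])
    return out, log
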