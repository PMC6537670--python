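"""Readers and writers for the pipeline's on-disk formats.

Coordinate conventions: BED intervals are 0-based half-open; VCF positions
are 1-based. All conversions go through the single function pair
:func:`pos_to_bed_start` / :func:`bed_start_to_pos`.

VCF access is backed by :mod:`pysam`; tables by :mod:`pandas`. Output files
written by pipeline stages carry a ``#`` header comment naming the producing
stage and configuration hash, which all readers here skip.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .genotypes import ALT, MISSING, REF, GenotypeMatrix, Site
from .window_classification import WINDOW_COLS, WindowDepthTable

Interval = tuple[str, int, int]


def pos_to_bed_start(pos: int) -> int:
    """1-based VCF position -> 0-based BED start."""
    return pos - 1


def bed_start_to_pos(start: int) -> int:
    """0-based BED start -> 1-based VCF position."""
    return start + 1


def stage_comment(stage: str, config_hash: str | None = None) -> str:
    tag = f"# msynet stage={stage}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VariantRecord:
    """One VCF site with the per-sample fields the pipeline consumes."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    gts: dict[str, tuple[int | None, ...]] = field(default_factory=dict)
    phased: dict[str, bool] = field(default_factory=dict)
    dp: dict[str, int | None] = field(default_factory=dict)
    gq: dict[str, int | None] = field(default_factory=dict)

    def is_missing(self, sample: str) -> bool:
        gt = self.gts.get(sample, (None,))
        return all(a is None for a in gt)

    def is_het(self, sample: str) -> bool:
        gt = [a for a in self.gts.get(sample, ()) if a is not None]
        return len(set(gt)) > 1

    def allele(self, sample: str) -> int:
        """Collapse a (possibly diploid-homozygous) GT to a haploid state."""
        gt = [a for a in self.gts.get(sample, ()) if a is not None]
        if not gt:
            return MISSING
        if len(set(gt)) > 1:
            raise ValueError(f"heterozygous call for {sample} at {self.contig}:{self.pos}")
        return ALT if gt[0] > 0 else REF


_FORMAT_FIELDS = ("GT", "DP", "GQ")


def read_vcf(path: str | os.PathLike) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF into neutral records; haploid and diploid GT both accepted."""
    with pysam.VariantFile(str(path)) as vf:
        for f in _FORMAT_FIELDS:
            if f not in vf.header.formats:
                raise ValueError(f"VCF {path} lacks required FORMAT field {f}")
        samples = list(vf.header.samples)
        records = []
        for rec in vf:
            r = VariantRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
            )
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                r.gts[s] = tuple(gt) if gt is not None else (None,)
                # htslib flags single-allele GTs as phased; phase is only
                # meaningful for ploidy >= 2
                r.phased[s] = bool(call.phased) and len(r.gts[s]) > 1
                r.dp[s] = call.get("DP")
                r.gq[s] = call.get("GQ")
            records.append(r)
    return samples, records


def write_vcf(
    path: str | os.PathLike,
    samples: list[str],
    records: list[VariantRecord],
    contig_lengths: dict[str, int],
    extra_header_lines: tuple[str, ...] = (),
) -> None:
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for line in extra_header_lines:
        header.add_line(line)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda x: (x.contig, x.pos)):
            rec = vf.new_record(
                contig=r.contig,
                start=pos_to_bed_start(r.pos),
                alleles=(r.ref, *r.alts),
            )
            for s in samples:
                call = rec.samples[s]
                call["GT"] = r.gts.get(s, (None,))
                call.phased = r.phased.get(s, False)
                if r.dp.get(s) is not None:
                    call["DP"] = r.dp[s]
                if r.gq.get(s) is not None:
                    call["GQ"] = r.gq[s]
            vf.write(rec)


# ---------------------------------------------------------------------------
# BED


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals per contig."""
    out: list[Interval] = []
    for iv in sorted(intervals):
        if out and out[-1][0] == iv[0] and iv[1] <= out[-1][2]:
            out[-1] = (iv[0], out[-1][1], max(out[-1][2], iv[2]))
        else:
            out.append(iv)
    return out


def read_bed(path: str | os.PathLike, merge: bool = False) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED line with fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end < 0:
                raise ValueError(f"{path}:{i}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{i}: start must be < end")
            intervals.append((contig, start, end))
    if merge:
        return merge_intervals(intervals)
    s = sorted(intervals)
    for a, b in zip(s, s[1:]):
        if a[0] == b[0] and b[1] < a[2]:
            raise ValueError(f"{path}: overlapping intervals {a} and {b}")
    return s


def write_bed(path: str | os.PathLike, intervals: list[Interval], comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment + "\n")
        for contig, start, end in sorted(intervals):
            fh.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Tables


def read_fai(path: str | os.PathLike) -> dict[str, int]:
    """Contig lengths from a FASTA index (.fai): first two tab columns."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            lengths[parts[0]] = int(parts[1])
    if not lengths:
        raise ValueError(f"no contigs in index {path}")
    return lengths


def write_sample_sheet(path: str | os.PathLike, sexes: dict[str, str], comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment + "\n")
        fh.write("sample_id\tsex\n")
        for s, sex in sexes.items():
            fh.write(f"{s}\t{sex}\n")


def read_sample_sheet(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise ValueError(f"sample sheet {path} needs columns sample_id and sex")
    return dict(zip(df["sample_id"], df["sex"]))


def write_depth_table(table: WindowDepthTable, path: str | os.PathLike, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment + "\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def read_depth_table(depths_path: str | os.PathLike, sample_sheet_path: str | os.PathLike) -> WindowDepthTable:
    frame = pd.read_csv(depths_path, sep="\t", comment="#")
    sexes = read_sample_sheet(sample_sheet_path)
    sample_cols = [c for c in frame.columns if c not in WINDOW_COLS]
    return WindowDepthTable(frame=frame, sexes={s: sexes[s] for s in sample_cols})


# ---------------------------------------------------------------------------
# Genotype matrix


def write_matrix(matrix: GenotypeMatrix, path: str | os.PathLike, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment + "\n")
        if matrix.outgroup:
            fh.write("# outgroup=" + ",".join(sorted(matrix.outgroup)) + "\n")
        fh.write("sample\t" + "\t".join(s.label() for s in matrix.sites) + "\n")
        for i, s in enumerate(matrix.samples):
            cells = ["." if c == MISSING else str(int(c)) for c in matrix.calls[i]]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


def read_matrix(path: str | os.PathLike) -> GenotypeMatrix:
    outgroup: frozenset = frozenset()
    header = None
    rows: list[tuple[str, list[int]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# outgroup="):
                outgroup = frozenset(line.split("=", 1)[1].split(","))
                continue
            if line.startswith("#") or not line:
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            rows.append((parts[0], [MISSING if c == "." else int(c) for c in parts[1:]]))
    if header is None:
        raise ValueError(f"empty matrix file {path}")
    sites = [Site.from_label(lbl) for lbl in header[1:]]
    import numpy as np

    calls = np.array([r[1] for r in rows], dtype="int8").reshape(len(rows), len(sites))
    return GenotypeMatrix(
        samples=[r[0] for r in rows], sites=sites, calls=calls, outgroup=outgroup
    )
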