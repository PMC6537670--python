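"""Generators for every input the MSY pipeline consumes, with full ground truth.

Two simulators cover the two data streams of the analysis:

* sexed read-depth profiles over a genome template whose segments carry a
  known copy class (single-copy Y, multi-copy Y, or non-Y), for testing
  window classification. Depth is Poisson: a male's haploid Y attracts half
  his autosomal coverage per copy, a female only a small mismapping leak.
* haploid genotype matrices from haplotypes evolved on a known rooted tree
  under the infinite-sites model (each mutation strikes a fresh site), for
  testing filtering, network building, diversity and dating.

The bundled reference tree mimics a two-haplogroup camel Y genealogy:
three domestic lineages of 13/14/15 mutations plus one wild-sampled lineage
of 12 on the domestic side, a 536-step inter-haplogroup edge, and wild
lineages of 0/2/4 mutations (596 variants in total, two of eight samples
sharing a haplotype).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import substream
from .genotypes import ALT, MISSING, REF, GenotypeMatrix, Site
from .io import VariantRecord, write_bed, write_depth_table, write_matrix, write_sample_sheet, write_vcf
from .window_classification import MCY, NONMSY, SCY, WindowDepthTable, tile_windows

# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class Segment:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    copy_class: str  # scY | mcY | nonMSY
    copy_number: int = 1


@dataclass
class GenomeTemplate:
    """Labeled segments tiling a set of contigs; the simulation ground truth."""

    contigs: list[tuple[str, int]]
    segments: list[Segment]

    def __post_init__(self) -> None:
        lengths = dict(self.contigs)
        by_contig: dict[str, list[Segment]] = {}
        for seg in self.segments:
            if seg.contig not in lengths:
                raise ValueError(f"segment on unknown contig {seg.contig!r}")
            if not 0 <= seg.start < seg.end <= lengths[seg.contig]:
                raise ValueError(f"segment out of bounds: {seg}")
            if seg.copy_class not in (SCY, MCY, NONMSY):
                raise ValueError(f"unknown copy class {seg.copy_class!r}")
            if seg.copy_class == SCY and seg.copy_number != 1:
                raise ValueError("scY segments must have copy_number 1")
            if seg.copy_class == MCY and seg.copy_number < 2:
                raise ValueError("mcY segments must have copy_number >= 2")
            by_contig.setdefault(seg.contig, []).append(seg)
        for contig, length in self.contigs:
            segs = sorted(by_contig.get(contig, []), key=lambda s: s.start)
            if not segs or segs[0].start != 0 or segs[-1].end != length:
                raise ValueError(f"segments do not tile contig {contig!r}")
            for a, b in zip(segs, segs[1:]):
                if a.end != b.start:
                    raise ValueError(f"gap or overlap between segments on {contig!r}")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    def class_intervals(self, copy_class: str) -> list[tuple[str, int, int]]:
        return sorted(
            (s.contig, s.start, s.end) for s in self.segments if s.copy_class == copy_class
        )

    def scy_length(self) -> int:
        return sum(s.end - s.start for s in self.segments if s.copy_class == SCY)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    sex: str  # male | female
    mean_autosomal_depth: float


@dataclass
class CohortSpec:
    samples: list[SampleSpec]
    window_size: int = 50
    female_leak_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        sexes = {s.sex for s in self.samples}
        if "male" not in sexes or "female" not in sexes:
            raise ValueError("cohort needs at least one male and one female")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.female_leak_rate < 0:
            raise ValueError("female_leak_rate must be non-negative")
        for s in self.samples:
            if s.mean_autosomal_depth <= 0:
                raise ValueError(f"sample {s.sample_id}: depth must be positive")

    @property
    def sexes(self) -> dict[str, str]:
        return {s.sample_id: s.sex for s in self.samples}


@dataclass
class TreeSpec:
    """Rooted tree as parent links, mutations per edge (or durations + rate)."""

    parent: dict[str, str | None]
    mutations: dict[str, int] | None = None
    durations: dict[str, float] | None = None
    mu: float | None = None
    L_sites: int | None = None
    tip_samples: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for n, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"node {n!r} has unknown parent {p!r}")
            seen = {n}
            while p is not None:  # acyclicity via parent walk
                if p in seen:
                    raise ValueError(f"cycle through node {p!r}")
                seen.add(p)
                p = self.parent[p]
        if self.mutations is None and self.durations is None:
            raise ValueError("provide per-edge mutations or durations")
        if self.mutations is not None:
            for n, m in self.mutations.items():
                if n not in self.parent or self.parent[n] is None:
                    raise ValueError(f"mutation count on non-edge node {n!r}")
                if not (isinstance(m, (int, np.integer)) and m >= 0):
                    raise ValueError(f"edge {n!r}: mutation count must be a nonnegative integer")
        if self.durations is not None and (self.mu is None or self.L_sites is None):
            raise ValueError("durations require mu and L_sites")
        for tip in self.tip_samples:
            if tip not in self.parent:
                raise ValueError(f"tip {tip!r} not in tree")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    def preorder(self) -> list[str]:
        children: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                children[p].append(n)
        order, stack = [], [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(sorted(children[n], reverse=True))
        return order


# ---------------------------------------------------------------------------
# Depth simulation


def window_truth(template: GenomeTemplate, window_size: int) -> pd.DataFrame:
    """Majority-class truth per fixed-width window (ties -> earlier segment)."""
    windows = tile_windows(template.contig_lengths, window_size)
    segs: dict[str, list[Segment]] = {}
    for s in template.segments:
        segs.setdefault(s.contig, []).append(s)
    for v in segs.values():
        v.sort(key=lambda s: s.start)

    classes, copies = [], []
    for contig, grp in windows.groupby("contig", sort=False):
        slist = segs[contig]
        si = 0
        for start, end in zip(grp["start"], grp["end"]):
            while slist[si].end <= start:
                si += 1
            best, best_ov = None, -1
            j = si
            while j < len(slist) and slist[j].start < end:
                ov = min(end, slist[j].end) - max(start, slist[j].start)
                if ov > best_ov:  # strict: ties keep the earlier segment
                    best, best_ov = slist[j], ov
                j += 1
            classes.append(best.copy_class)
            copies.append(best.copy_number if best.copy_class != NONMSY else 0)
    windows = windows.copy()
    windows["copy_class"] = classes
    windows["copy_number"] = copies
    return windows


def simulate_depths(template: GenomeTemplate, cohort: CohortSpec) -> WindowDepthTable:
    """Draw Poisson window depths conditioned on sex and window copy class.

    Expected depth = mean_autosomal_depth x factor with factor 1.0 on nonMSY
    for both sexes, 0.5 x copy_number for males on Y windows, and the female
    leak rate for females on Y windows.
    """
    shortest = min(length for _, length in template.contigs)
    if cohort.window_size > shortest:
        raise ValueError(
            f"window_size {cohort.window_size} exceeds shortest contig ({shortest} bp)"
        )
    truth = window_truth(template, cohort.window_size)
    is_y = truth["copy_class"].isin([SCY, MCY]).to_numpy()
    cn = truth["copy_number"].to_numpy()

    frame = truth[["contig", "start", "end"]].copy()
    for spec in cohort.samples:
        if spec.sex == "male":
            factor = np.where(is_y, 0.5 * np.maximum(cn, 1), 1.0)
        else:
            factor = np.where(is_y, cohort.female_leak_rate, 1.0)
        rng = substream(cohort.seed, "depths", spec.sample_id)
        frame[spec.sample_id] = rng.poisson(spec.mean_autosomal_depth * factor)
    return WindowDepthTable(frame=frame, sexes=cohort.sexes)


# ---------------------------------------------------------------------------
# Haplotype simulation


def simulate_haplotypes(tree: TreeSpec, seed: int = 0) -> tuple[GenotypeMatrix, dict[str, list[int]]]:
    """Evolve haplotypes on the tree under infinite sites.

    The root carries all-REF; each edge toggles a fresh block of sites equal
    to its mutation count. Returns the tip genotype matrix (columns are
    exactly the mutated sites, in edge-preorder) and the per-edge truth site
    lists keyed by the edge's child node.
    """
    order = tree.preorder()
    counts: dict[str, int] = {}
    for node in order:
        if tree.parent[node] is None:
            continue
        if tree.mutations is not None:
            counts[node] = int(tree.mutations.get(node, 0))
        else:
            lam = tree.mu * tree.L_sites * tree.durations.get(node, 0.0)
            if not np.isfinite(lam):
                raise ValueError(f"edge {node!r}: non-finite expected mutation count")
            counts[node] = int(substream(seed, "haplotypes", node).poisson(lam))
    total = sum(counts.values())
    if tree.L_sites is not None and total > tree.L_sites:
        raise ValueError(
            f"requested {total} mutations exceed the {tree.L_sites}-site pool"
        )

    edge_sites: dict[str, list[int]] = {}
    nxt = 0
    vectors: dict[str, np.ndarray] = {tree.root: np.zeros(total, dtype=np.int8)}
    for node in order:
        p = tree.parent[node]
        if p is None:
            continue
        k = counts[node]
        edge_sites[node] = list(range(nxt, nxt + k))
        nxt += k
        v = vectors[p].copy()
        v[edge_sites[node]] ^= 1
        vectors[node] = v

    samples: list[str] = []
    rows: list[np.ndarray] = []
    for tip in order:
        for sample in tree.tip_samples.get(tip, ()):
            samples.append(sample)
            rows.append(vectors[tip])
    calls = np.array(rows, dtype=np.int8) if rows else np.zeros((0, total), dtype=np.int8)
    sites = [Site("Ysim", i + 1) for i in range(total)]
    matrix = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    return matrix, edge_sites


def matrix_to_records(
    matrix: GenotypeMatrix,
    dp: np.ndarray | int = 30,
    gq: np.ndarray | int = 99,
) -> list[VariantRecord]:
    """Express a genotype matrix as VCF-style records (haploid GT)."""
    n, m = matrix.calls.shape
    dp_arr = np.broadcast_to(np.asarray(dp), (n, m))
    gq_arr = np.broadcast_to(np.asarray(gq), (n, m))
    records = []
    for j, site in enumerate(matrix.sites):
        r = VariantRecord(contig=site.contig, pos=site.pos, ref=site.ref, alts=(site.alt,))
        for i, s in enumerate(matrix.samples):
            c = matrix.calls[i, j]
            r.gts[s] = (None,) if c == MISSING else (int(c),)
            r.phased[s] = False
            r.dp[s] = int(dp_arr[i, j])
            r.gq[s] = int(gq_arr[i, j])
        records.append(r)
    return records


def cleanable_contigs(
    template: GenomeTemplate,
    window_size: int = 50,
    min_length: int = 200,
    min_fraction: float = 0.5,
) -> set[str]:
    """Contigs that survive contig cleanup under the template's own truth labels."""
    truth = window_truth(template, window_size)
    kept = set()
    lengths = template.contig_lengths
    for contig, grp in truth.groupby("contig"):
        y_frac = grp["copy_class"].isin([SCY, MCY]).mean()
        if lengths[contig] >= min_length and y_frac >= min_fraction:
            kept.add(contig)
    return kept


def place_sites(
    matrix: GenotypeMatrix,
    template: GenomeTemplate,
    seed: int = 0,
    restrict_contigs: set[str] | None = None,
) -> GenotypeMatrix:
    """Relocate matrix columns to distinct random positions inside scY segments.

    Column order is preserved (column j receives the j-th smallest genomic
    position) and REF/ALT nucleotides are drawn per site. Placement can be
    restricted to a contig subset — typically the contigs that survive
    cleanup, since on real data variants are called against the cleaned
    assembly only.
    """
    intervals = template.class_intervals(SCY)
    if restrict_contigs is not None:
        intervals = [iv for iv in intervals if iv[0] in restrict_contigs]
    total = sum(e - s for _, s, e in intervals)
    if matrix.n_sites > total:
        raise ValueError(f"{matrix.n_sites} sites do not fit in {total} bp of scY sequence")
    rng = substream(seed, "fixture", "positions")
    offsets = np.sort(rng.choice(total, size=matrix.n_sites, replace=False))
    bases = np.array(list("ACGT"))
    sites: list[Site] = []
    bounds = np.cumsum([e - s for _, s, e in intervals])
    for off in offsets:
        k = int(np.searchsorted(bounds, off, side="right"))
        contig, s0, _ = intervals[k]
        pos = s0 + int(off) - (int(bounds[k - 1]) if k else 0) + 1  # 1-based
        ref, alt = rng.choice(bases, size=2, replace=False)
        sites.append(Site(contig, pos, str(ref), str(alt)))
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        sites=sites,
        calls=matrix.calls.copy(),
        outgroup=matrix.outgroup,
    )
    return out


def inject_missing(matrix: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set exactly floor(rate x cells) cells to MISSING, chosen uniformly."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    n_cells = matrix.calls.size
    k = int(np.floor(rate * n_cells))
    calls = matrix.calls.copy()
    if k:
        rng = substream(seed, "fixture", "missing")
        flat = rng.choice(n_cells, size=k, replace=False)
        calls.flat[flat] = MISSING
    return GenotypeMatrix(
        samples=list(matrix.samples), sites=list(matrix.sites), calls=calls,
        outgroup=matrix.outgroup,
    )


# ---------------------------------------------------------------------------
# Fixture writing


def write_fixture(
    template: GenomeTemplate,
    depths: WindowDepthTable,
    genotypes: GenotypeMatrix,
    outdir: str | os.PathLike,
    overwrite: bool = False,
    mean_dp: float = 30.0,
    gq: int = 99,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the complete on-disk fixture: truth BEDs, depth TSV, VCF, sample sheet.

    Genotype columns are placed at random scY positions on contigs that
    survive cleanup (variants on real data are called against the cleaned
    assembly); per-cell DP is drawn Poisson around ``mean_dp`` and GQ is
    constant, so threshold behaviour can be probed by configuration. Fails
    rather than overwrite unless asked.
    """
    if not genotypes.samples:
        raise ValueError("empty cohort: genotype matrix has no samples")
    unknown = set(genotypes.samples) - set(depths.samples)
    if unknown:
        raise ValueError(f"genotype samples absent from depth table: {sorted(unknown)}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scY_bed": outdir / "truth_scY.bed",
        "mcY_bed": outdir / "truth_mcY.bed",
        "nonMSY_bed": outdir / "truth_nonMSY.bed",
        "depths": outdir / "depths.tsv",
        "samples": outdir / "samples.tsv",
        "vcf": outdir / "variants.vcf",
        "truth_matrix": outdir / "truth_genotypes.tsv",
    }
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite without overwrite=True: {existing}")

    placed = place_sites(
        genotypes, template, seed=seed, restrict_contigs=cleanable_contigs(template)
    )
    observed = inject_missing(placed, missing_rate, seed=seed)
    rng_dp = substream(seed, "fixture", "dp")
    dp = rng_dp.poisson(mean_dp, size=observed.calls.shape)
    records = matrix_to_records(observed, dp=dp, gq=gq)

    for cname, key in ((SCY, "scY_bed"), (MCY, "mcY_bed"), (NONMSY, "nonMSY_bed")):
        write_bed(paths[key], template.class_intervals(cname), comment=f"# msynet truth class={cname}")
    write_depth_table(depths, paths["depths"], comment="# msynet synthetic depths")
    write_sample_sheet(paths["samples"], depths.sexes, comment="# msynet synthetic cohort")
    write_vcf(paths["vcf"], observed.samples, records, template.contig_lengths)
    write_matrix(placed, paths["truth_matrix"], comment="# msynet truth genotypes (pre-missingness)")
    return paths


# ---------------------------------------------------------------------------
# Reference fixtures


def two_haplogroup_tree() -> TreeSpec:
    """The bundled two-haplogroup reference genealogy (596 mutations, 8 samples).

    Domestic-side basal node roots three domestic lineages (13/14/15
    mutations) and one wild-sampled lineage (12); a 536-step edge reaches the
    wild basal node, which carries one sampled haplotype directly plus
    lineages of 2 (shared by a father-sharing sample pair) and 4 mutations.
    """
    parent = {
        "D_basal": None,
        "DC269": "D_basal",
        "DC101": "D_basal",
        "DC102": "D_basal",
        "WC305": "D_basal",
        "W_basal": "D_basal",
        "WC302": "W_basal",
        "WC214": "W_basal",
        "WC304": "W_basal",
    }
    mutations = {
        "DC269": 13,
        "DC101": 14,
        "DC102": 15,
        "WC305": 12,
        "W_basal": 536,
        "WC302": 0,
        "WC214": 2,
        "WC304": 4,
    }
    tips = {
        "DC269": ("DC269",),
        "DC101": ("DC101",),
        "DC102": ("DC102",),
        "WC305": ("WC305",),
        "WC302": ("WC302",),
        "WC214": ("WC214", "WC218"),
        "WC304": ("WC304",),
    }
    return TreeSpec(parent=parent, mutations=mutations, tip_samples=tips)


DOMESTIC_SAMPLES = ("DC269", "DC101", "DC102")
WILD_SAMPLES = ("WC302", "WC304", "WC214", "WC218", "WC305")
WILD_IN_DOMESTIC = "WC305"


def example_template(seed: int = 0, n_contigs: int = 8, mean_contig_length: int = 30_000) -> GenomeTemplate:
    """A random labeled template with mixed-class segments on each contig."""
    rng = substream(seed, "template")
    contigs, segments = [], []
    for i in range(n_contigs):
        length = int(rng.integers(mean_contig_length // 2, mean_contig_length * 3 // 2))
        contig = f"ctg{i + 1}"
        contigs.append((contig, length))
        pos = 0
        while pos < length:
            seg_len = min(int(rng.integers(50, 400)) * 10, length - pos)
            if length - (pos + seg_len) < 500:
                seg_len = length - pos
            cls = str(rng.choice([SCY, MCY, NONMSY], p=[0.35, 0.25, 0.40]))
            cn = int(rng.integers(2, 6)) if cls == MCY else 1
            segments.append(Segment(contig, pos, pos + seg_len, cls, cn))
            pos += seg_len
    return GenomeTemplate(contigs=contigs, segments=segments)


def example_cohort(seed: int = 0, window_size: int = 50, female_leak_rate: float = 0.02) -> CohortSpec:
    """Eight sequenced males (the genotyped samples) and six females."""
    male_depths = (20.0, 12.0, 15.0, 18.0, 10.0, 14.0, 22.0, 16.0)
    female_depths = (11.0, 13.0, 17.0, 19.0, 12.0, 15.0)
    males = DOMESTIC_SAMPLES + WILD_SAMPLES
    samples = [SampleSpec(m, "male", d) for m, d in zip(males, male_depths)]
    samples += [SampleSpec(f"F{i + 1}", "female", d) for i, d in enumerate(female_depths)]
    return CohortSpec(samples=samples, window_size=window_size,
                      female_leak_rate=female_leak_rate, seed=seed)


def write_example_fixture(
    outdir: str | os.PathLike,
    seed: int = 0,
    missing_rate: float = 0.0,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Simulate and write the full reference fixture into ``outdir``."""
    template = example_template(seed=seed)
    cohort = example_cohort(seed=seed)
    depths = simulate_depths(template, cohort)
    matrix, _ = simulate_haplotypes(two_haplogroup_tree(), seed=seed)
    return write_fixture(
        template, depths, matrix, outdir,
        overwrite=overwrite, missing_rate=missing_rate, seed=seed,
    )
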