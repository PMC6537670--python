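"""Classification of assembly windows into scY / mcY / nonMSY from sexed read depth.

The male-specific region of the Y chromosome (MSY) is haploid in males and
absent in females, so on a correctly assembled single-copy Y segment a male
shows roughly half his autosomal coverage and a female shows (near) zero.
Multi-copy Y segments collapse in assembly and attract proportionally more
male reads. Fixed-width windows are scored per copy class with a Poisson
likelihood on normalized depth, and contigs are then cleaned by minimum
length and Y-specific window content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCY = "scY"
MCY = "mcY"
NONMSY = "nonMSY"
NOCALL = "nocall"
CLASSES = (SCY, MCY, NONMSY)

WINDOW_COLS = ["contig", "start", "end"]


def tile_windows(contig_lengths: dict[str, int], window_size: int) -> pd.DataFrame:
    """Tile each contig with fixed-width windows; the final window may be short."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    rows = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length {length}")
        starts = np.arange(0, length, window_size)
        ends = np.minimum(starts + window_size, length)
        rows.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class WindowDepthTable:
    """Per-sample mean read depth on fixed-width windows, with sample sex labels.

    ``frame`` holds columns contig/start/end plus one column per sample;
    ``norm_factors`` is set once :func:`normalize_depths` has rescaled each
    sample to genome-wide mean 1.0 and remembers the per-sample divisor.
    """

    frame: pd.DataFrame
    sexes: dict[str, str]
    norm_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in WINDOW_COLS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"depth table lacks columns {missing}")
        for s in self.samples:
            if s not in self.sexes:
                raise ValueError(f"sample {s!r} has no sex label")
            if self.sexes[s] not in ("male", "female"):
                raise ValueError(f"sample {s!r} has invalid sex {self.sexes[s]!r}")
        if (self.frame[self.samples].to_numpy() < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.frame.columns if c not in WINDOW_COLS]

    def males(self) -> list[str]:
        return [s for s in self.samples if self.sexes[s] == "male"]

    def females(self) -> list[str]:
        return [s for s in self.samples if self.sexes[s] == "female"]


def normalize_depths(table: WindowDepthTable, exclude: tuple[str, ...] = ()) -> WindowDepthTable:
    """Scale each sample's depths to genome-wide mean 1.0, optionally dropping samples.

    The per-sample divisor is its mean window depth over the whole table (the
    normalizer a sequencing-depth difference between individuals cancels
    against). Samples listed in ``exclude`` — typically the individual the
    reference assembly is built from, whose reads match the reference
    perfectly and would bias the comparison — are removed from the output.
    """
    keep = [s for s in table.samples if s not in exclude]
    if not keep:
        raise ValueError("no samples left after exclusions")
    out = table.frame[WINDOW_COLS + keep].copy()
    factors: dict[str, float] = {}
    for s in keep:
        mean = float(out[s].mean())
        if mean <= 0:
            raise ValueError(f"sample {s!r} has zero total depth; cannot normalize")
        out[s] = out[s] / mean
        factors[s] = mean
    return WindowDepthTable(
        frame=out,
        sexes={s: table.sexes[s] for s in keep},
        norm_factors=factors,
    )


@dataclass
class WindowClassification:
    """Per-window class assignment with per-class log-likelihood scores."""

    frame: pd.DataFrame  # contig,start,end,assigned,copy_number,ll_nonMSY,ll_scY,ll_mcY
    epsilon: float
    excluded_samples: tuple[str, ...] = ()


def classify_windows(
    norm: WindowDepthTable,
    epsilon: float = 0.02,
    k_max: int = 20,
    ref_depth: float | None = None,
) -> WindowClassification:
    """Assign each window the copy class maximizing a Poisson likelihood.

    Expected normalized depth per class: nonMSY male=female=1; scY male=0.5,
    female=epsilon (mismapping floor); mcY with copy number k>=2 male=0.5*k,
    female=epsilon. Normalized depths are rescaled to count scale by a common
    reference depth (default: mean of the per-sample normalizers) before the
    Poisson score x*log(lam) - lam is summed over samples; the common rescale
    preserves the argmax, making assignments invariant to any per-sample
    depth rescaling.
    """
    males, females = norm.males(), norm.females()
    if not males or not females:
        raise ValueError("need at least one male and one female after exclusions")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if ref_depth is None:
        if norm.norm_factors:
            ref_depth = float(np.mean(list(norm.norm_factors.values())))
        else:
            ref_depth = 1.0

    xm = norm.frame[males].to_numpy(dtype=float) * ref_depth
    xf = norm.frame[females].to_numpy(dtype=float) * ref_depth
    sum_m, sum_f = xm.sum(axis=1), xf.sum(axis=1)
    n_m, n_f = len(males), len(females)
    D = ref_depth

    def score(ratio_m: float, ratio_f: float) -> np.ndarray:
        lam_m, lam_f = D * ratio_m, D * ratio_f
        return (
            sum_m * math.log(lam_m)
            - n_m * lam_m
            + sum_f * math.log(lam_f)
            - n_f * lam_f
        )

    ll_non = score(1.0, 1.0)
    ll_scy = score(0.5, epsilon)
    ks = np.arange(2, k_max + 1)
    ll_mcy_all = np.stack([score(0.5 * k, epsilon) for k in ks], axis=1)
    best_k_idx = np.argmax(ll_mcy_all, axis=1)
    ll_mcy = ll_mcy_all[np.arange(len(best_k_idx)), best_k_idx]
    best_k = ks[best_k_idx]

    scores = np.stack([ll_non, ll_scy, ll_mcy], axis=1)
    # ties break toward the earlier class in (nonMSY, scY, mcY) order
    assigned_idx = np.argmax(scores, axis=1)
    names = np.array([NONMSY, SCY, MCY])
    assigned = names[assigned_idx]
    copy_number = np.where(assigned == MCY, best_k, np.where(assigned == SCY, 1, 0))

    zero = (sum_m + sum_f) == 0
    assigned = np.where(zero, NOCALL, assigned)

    out = norm.frame[WINDOW_COLS].copy()
    out["assigned"] = assigned
    out["copy_number"] = copy_number
    out["ll_nonMSY"] = ll_non
    out["ll_scY"] = ll_scy
    out["ll_mcY"] = ll_mcy
    return WindowClassification(frame=out, epsilon=epsilon)


@dataclass
class ContigReport:
    frame: pd.DataFrame  # contig,length,n_windows,n_scY,n_mcY,n_nonMSY,y_fraction,kept


def _merge_windows(rows: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Merge adjacent/contiguous same-contig windows into maximal intervals."""
    merged: list[tuple[str, int, int]] = []
    for _, r in rows.sort_values(["contig", "start"]).iterrows():
        if merged and merged[-1][0] == r["contig"] and merged[-1][2] == r["start"]:
            merged[-1] = (merged[-1][0], merged[-1][1], int(r["end"]))
        else:
            merged.append((r["contig"], int(r["start"]), int(r["end"])))
    return merged


def clean_contigs(
    cls: WindowClassification,
    contig_lengths: dict[str, int],
    min_length: int = 200,
    min_fraction: float = 0.5,
) -> tuple[ContigReport, dict[str, list[tuple[str, int, int]]]]:
    """Discard contigs that are short or not Y-specific; emit per-class intervals.

    A contig is kept iff its length >= ``min_length`` AND the fraction of its
    windows classified scY or mcY >= ``min_fraction``. No-call windows count
    against the Y fraction (conservative). Adjacent same-class windows on
    kept contigs are merged into maximal BED intervals.
    """
    df = cls.frame
    unknown = set(df["contig"]) - set(contig_lengths)
    if unknown:
        raise ValueError(f"windows on contigs with no length entry: {sorted(unknown)}")

    recs = []
    for contig, grp in df.groupby("contig", sort=True):
        counts = grp["assigned"].value_counts()
        n = len(grp)
        n_y = int(counts.get(SCY, 0) + counts.get(MCY, 0))
        frac = n_y / n
        length = contig_lengths[contig]
        recs.append(
            {
                "contig": contig,
                "length": length,
                "n_windows": n,
                "n_scY": int(counts.get(SCY, 0)),
                "n_mcY": int(counts.get(MCY, 0)),
                "n_nonMSY": int(counts.get(NONMSY, 0) + counts.get(NOCALL, 0)),
                "y_fraction": frac,
                "kept": bool(length >= min_length and frac >= min_fraction),
            }
        )
    report = pd.DataFrame(recs)
    kept_contigs = set(report.loc[report["kept"], "contig"])

    beds: dict[str, list[tuple[str, int, int]]] = {}
    for cname in (SCY, MCY):
        rows = df[(df["assigned"] == cname) & df["contig"].isin(kept_contigs)]
        beds[cname] = _merge_windows(rows)
    return ContigReport(frame=report), beds


def assembly_stats(contig_lengths: dict[str, int] | list[int]) -> dict[str, int]:
    """Total length, contig count and N50 of a set of contig lengths.

    N50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the total.
    """
    lengths = sorted(
        contig_lengths.values() if isinstance(contig_lengths, dict) else contig_lengths,
        reverse=True,
    )
    if not lengths:
        raise ValueError("empty contig length set")
    if min(lengths) <= 0:
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for ln in lengths:
        cum += ln
        if cum * 2 >= total:
            n50 = ln
            break
    return {"total_bp": total, "n_contigs": len(lengths), "n50": n50}
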