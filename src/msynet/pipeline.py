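"""End-to-end pipeline: classify -> filter -> impute -> network -> diversity -> dating.

Configuration lives in a single mapping (YAML file or dict), every output
file carries the producing stage and a hash of the configuration, and a
JSON manifest records parameter values, seeds and per-stage record counts.
Reruns with the same configuration are byte-identical; each stage can be
resumed from the on-disk intermediates of the previous ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .diversity import diversity_table
from .haplotype_network import (
    HaploNetwork,
    assign_haplogroups,
    collapse_haplotypes,
    median_joining,
    network_from_tables,
    network_tables,
    to_dot,
)
from .rho_dating import DatingConfig, date_node
from .variant_filtering import filter_variants, impute_missing
from .window_classification import (
    assembly_stats,
    classify_windows,
    clean_contigs,
    normalize_depths,
)

log = logging.getLogger("msynet")

STAGES = ("classify", "filter", "impute", "network", "diversity", "dating")

#: scY length of the reference MSY assembly the defaults are tuned to (bp)
DEFAULT_SCY_LENGTH = 2_390_000


@dataclass
class PipelineConfig:
    depths: str = ""
    sample_sheet: str = ""
    vcf: str = ""
    contig_lengths: str = ""  # optional .fai; else inferred from window ends
    window_size: int = 50
    exclude_samples: tuple[str, ...] = ()
    epsilon: float = 0.02
    k_max: int = 20
    min_contig_length: int = 200
    min_y_fraction: float = 0.5
    dp_min: int = 3
    gq_min_exclusive: int = 9
    outgroup_ids: tuple[str, ...] = ()
    reference_sample: str | None = None
    epsilon_mj: int = 0
    haplogroup_seeds: dict[str, str] = field(default_factory=dict)  # sample -> label
    subsets: dict[str, list[str]] = field(default_factory=dict)
    diversity_length: float = DEFAULT_SCY_LENGTH
    mu: float = 1.68e-8
    dating_length: float = DEFAULT_SCY_LENGTH
    generation_years: float = 6.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 <= self.min_y_fraction <= 1):
            raise ValueError("min_y_fraction must be in [0, 1]")
        if self.epsilon < 0 or self.epsilon_mj < 0:
            raise ValueError("epsilon values must be non-negative")

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        cfg = PipelineConfig(**{k: v for k, v in d.items()})
        cfg.exclude_samples = tuple(cfg.exclude_samples)
        cfg.outgroup_ids = tuple(cfg.outgroup_ids)
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_samples"] = list(self.exclude_samples)
        d["outgroup_ids"] = list(self.outgroup_ids)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _setup_logging(level: str) -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[msynet:%(stage)s] %(message)s"))
        log.addHandler(h)
    log.setLevel(level.upper())


def _stage_log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    resume_from: str | None = None,
) -> dict:
    """Run (or resume) all stages; return the manifest written to manifest.json."""
    _setup_logging(cfg.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest: dict = {"config": cfg.to_dict(), "config_hash": chash, "stages": {}}
    if resume_from is not None and resume_from not in STAGES:
        raise ValueError(f"unknown stage {resume_from!r}; stages are {STAGES}")
    start = STAGES.index(resume_from) if resume_from else 0

    def fresh(stage: str) -> bool:
        return STAGES.index(stage) >= start

    def comment(stage: str) -> str:
        return mio.stage_comment(stage, chash)

    # -- classify ----------------------------------------------------------
    scy_path = outdir / "scY.bed"
    if fresh("classify"):
        table = mio.read_depth_table(cfg.depths, cfg.sample_sheet)
        norm = normalize_depths(table, exclude=cfg.exclude_samples)
        cls = classify_windows(norm, epsilon=cfg.epsilon, k_max=cfg.k_max)
        if cfg.contig_lengths:
            lengths = mio.read_fai(cfg.contig_lengths)
        else:
            lengths = {
                c: int(g["end"].max()) for c, g in cls.frame.groupby("contig", sort=True)
            }
        report, beds = clean_contigs(
            cls, lengths, min_length=cfg.min_contig_length, min_fraction=cfg.min_y_fraction
        )
        mio.write_bed(scy_path, beds["scY"], comment=comment("classify"))
        mio.write_bed(outdir / "mcY.bed", beds["mcY"], comment=comment("classify"))
        with open(outdir / "contig_report.tsv", "w") as fh:
            fh.write(comment("classify") + "\n")
            report.frame.to_csv(fh, sep="\t", index=False)
        stats = assembly_stats(lengths)
        (outdir / "assembly_stats.json").write_text(
            json.dumps({"stage": "classify", "config": chash, **stats}, sort_keys=True) + "\n"
        )
        manifest["stages"]["classify"] = {
            "n_windows": int(len(cls.frame)),
            "n_contigs_kept": int(report.frame["kept"].sum()),
            "scY_bp": int(sum(e - s for _, s, e in beds["scY"])),
        }
        _stage_log("classify", f"{len(cls.frame)} windows, {manifest['stages']['classify']}")

    # -- filter ------------------------------------------------------------
    matrix_path = outdir / "matrix.tsv"
    if fresh("filter"):
        scy = mio.read_bed(scy_path)
        samples, records = mio.read_vcf(cfg.vcf)
        try:
            matrix, flog = filter_variants(
                records,
                scy,
                samples,
                dp_min=cfg.dp_min,
                gq_min_exclusive=cfg.gq_min_exclusive,
                outgroup_ids=cfg.outgroup_ids,
                reference_sample=cfg.reference_sample,
            )
        except Exception as exc:
            raise RuntimeError(f"stage filter failed: {exc}") from exc
        if matrix.n_sites == 0:
            raise RuntimeError("stage filter failed: no sites retained in scY regions")
        mio.write_matrix(matrix, matrix_path, comment=comment("filter"))
        with open(outdir / "filter_log.tsv", "w") as fh:
            fh.write(comment("filter") + "\n")
            flog.frame.to_csv(fh, sep="\t", index=False)
        manifest["stages"]["filter"] = {
            "n_input": len(records),
            "n_retained": matrix.n_sites,
            "dropped": flog.counts(),
        }
        _stage_log("filter", str(manifest["stages"]["filter"]))
    else:
        matrix = mio.read_matrix(matrix_path)

    # -- impute ------------------------------------------------------------
    imputed_path = outdir / "matrix_imputed.tsv"
    if fresh("impute"):
        imputed, ilog = impute_missing(matrix)
        mio.write_matrix(imputed, imputed_path, comment=comment("impute"))
        with open(outdir / "impute_log.tsv", "w") as fh:
            fh.write(comment("impute") + "\n")
            ilog.to_csv(fh, sep="\t", index=False)
        manifest["stages"]["impute"] = {"n_imputed": int(len(ilog))}
        _stage_log("impute", f"{len(ilog)} cells imputed")
    else:
        imputed = mio.read_matrix(imputed_path)

    # -- network -----------------------------------------------------------
    if fresh("network"):
        ingroup = imputed.subset_samples(imputed.ingroup())
        ht = collapse_haplotypes(ingroup)
        net = median_joining(ht, epsilon=cfg.epsilon_mj)
        labels: dict[str, str] = {}
        partition = None
        if cfg.haplogroup_seeds:
            seeds = {
                net.node_of_sample(sample): label
                for sample, label in cfg.haplogroup_seeds.items()
            }
            partition = assign_haplogroups(net, seeds)
            labels = partition.labels
        nodes, edges = network_tables(net, labels)
        for name, df in (("nodes.tsv", nodes), ("edges.tsv", edges)):
            with open(outdir / name, "w") as fh:
                fh.write(comment("network") + "\n")
                df.to_csv(fh, sep="\t", index=False)
        (outdir / "network.dot").write_text(to_dot(net, labels) + "\n")
        manifest["stages"]["network"] = {
            "n_haplotypes": ht.n_haplotypes,
            "n_medians": len(net.medians()),
            "n_haplogroups": len(set(labels.values())) if labels else 0,
            "total_length": net.total_length(),
            "split_edge": list(partition.split_edge) if partition else None,
            "split_length": partition.split_length if partition else None,
            "n_constant_dropped": ht.n_constant_dropped,
        }
        _stage_log("network", str(manifest["stages"]["network"]))
    else:
        nodes = pd.read_csv(outdir / "nodes.tsv", sep="\t", comment="#", dtype={"vector": str})
        edges = pd.read_csv(outdir / "edges.tsv", sep="\t", comment="#")
        net = network_from_tables(nodes, edges)
        labels = {
            r["node"]: r["haplogroup"]
            for _, r in nodes.iterrows()
            if isinstance(r["haplogroup"], str) and r["haplogroup"]
        }
        imputed = mio.read_matrix(imputed_path)

    # -- diversity ---------------------------------------------------------
    if fresh("diversity") and cfg.subsets:
        ingroup = imputed.subset_samples(imputed.ingroup())
        div = diversity_table(ingroup, cfg.subsets, cfg.diversity_length)
        with open(outdir / "diversity.tsv", "w") as fh:
            fh.write(comment("diversity") + "\n")
            div.to_csv(fh, sep="\t", index=False)
        manifest["stages"]["diversity"] = {
            row["subset"]: {"theta": row["theta"], "pi": row["pi"]}
            for _, row in div.iterrows()
        }
        _stage_log("diversity", str(manifest["stages"]["diversity"]))

    # -- dating ------------------------------------------------------------
    if fresh("dating") and labels:
        dating_cfg = DatingConfig(
            mu=cfg.mu, L_sites=cfg.dating_length, generation_years=cfg.generation_years
        )
        rows = []
        observed = set(net.observed())
        split = manifest["stages"].get("network", {}).get("split_edge")
        if split is None:  # resumed run: recover split edge from labels
            split = [
                e for e in net.graph.edges
                if labels.get(e[0]) != labels.get(e[1])
            ]
            split = list(split[0]) if split else None
        if split:
            for endpoint in split:
                side = labels.get(endpoint, "")
                tips_side = sorted(n for n in observed if labels.get(n) == side)
                for scope, tips in (
                    (f"{side}_members", tips_side),
                    ("all_members", sorted(observed)),
                ):
                    res = date_node(net, tips, endpoint, dating_cfg)
                    rows.append(
                        {
                            "node": endpoint,
                            "haplogroup": side,
                            "tips": scope,
                            "n": res.n_tips,
                            "rho": res.rho,
                            "sigma": res.sigma,
                            "t_years": res.t_years,
                            "t_sd_years": res.t_sd_years,
                            "mu": cfg.mu,
                            "L": cfg.dating_length,
                            "generation_years": cfg.generation_years,
                        }
                    )
        dating = pd.DataFrame(rows)
        with open(outdir / "dating.tsv", "w") as fh:
            fh.write(comment("dating") + "\n")
            dating.to_csv(fh, sep="\t", index=False)
        manifest["stages"]["dating"] = {"n_rows": len(rows)}
        _stage_log("dating", f"{len(rows)} dated (node, tip-set) pairs")

    from . import __version__

    manifest["version"] = __version__
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
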