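"""End-to-end orchestration: simulate or load -> merge -> CpG-filter ->
LD-prune -> cFDR both orderings -> conjunction -> MR both directions ->
QTL annotation -> plot data, with a row-count ledger at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cfdr_core, ld_prune, mr, sumstats_io
from .cfdr_core import CFDRResult, StratumSpec
from .ld_prune import GenotypePanel
from .sumstats_io import MergedPanel, SumstatTable

logger = logging.getLogger(__name__)

QTL_CLASSES = frozenset({"eQTL", "meQTL", "metaQTL"})


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    sumstats1: str
    sumstats2: str
    genotypes: str
    cpg_catalog: str | None = None
    known_loci: str | None = None
    qtl_tables: list[str] = field(default_factory=list)
    trait1: str = "trait1"
    trait2: str = "trait2"
    strata: tuple[float, ...] = cfdr_core.DEFAULT_STRATA
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    alphas: tuple[float, float] = (0.05, 0.01)
    mr_p_threshold: float = mr.GWAS_SIG
    mr_r2: float = mr.CLUMP_R2
    mr_action: int = 2
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.prune_r2 <= 1) or not (0 < self.mr_r2 <= 1):
            raise ValueError("r2 thresholds must lie in (0, 1]")
        if any(not (0 < a < 1) for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        for p in (self.sumstats1, self.sumstats2, self.genotypes):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["strata"] = tuple(raw.get("strata", cfdr_core.DEFAULT_STRATA))
        raw["alphas"] = tuple(raw.get("alphas", (0.05, 0.01)))
        return cls(**raw)


def annotate_qtl(result: CFDRResult, tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Left-join QTL annotation tables (snp_id, qtl_class, target, tissue,
    p) onto the result and add per-class presence flags."""
    out = result.df.copy()
    hits: dict[str, set[str]] = {c: set() for c in QTL_CLASSES}
    for tab in tables:
        bad = set(tab["qtl_class"]) - QTL_CLASSES
        if bad:
            raise ValueError(f"unknown qtl_class values: {sorted(bad)}")
        for cls_name, grp in tab.groupby("qtl_class"):
            hits[str(cls_name)].update(grp["snp_id"].astype(str))
    out["has_eqtl"] = out["snp_id"].isin(hits["eQTL"])
    out["has_meqtl"] = out["snp_id"].isin(hits["meQTL"])
    out["has_metaqtl"] = out["snp_id"].isin(hits["metaQTL"])
    out["any_qtl"] = out[["has_eqtl", "has_meqtl", "has_metaqtl"]].any(axis=1)
    return out


def render_plots(bundle: dict, outdir: str | Path) -> list[Path]:
    """Write stratified Q-Q, fold-enrichment and Manhattan figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    qq = bundle.get("qq")
    if qq is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        for label, df in qq.strata.items():
            ax.plot(df["nominal"], df["empirical"], label=label, lw=1)
        lim = max((df["empirical"].max() for df in qq.strata.values()), default=1)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
        ax.set_xlabel("nominal -log10(p1)")
        ax.set_ylabel("empirical -log10(q)")
        ax.legend(fontsize=7)
        path = outdir / "conditional_qq.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    fe = bundle.get("enrichment")
    if fe is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, vals in fe.strata.items():
            ax.plot(fe.grid_neglog10, vals, label=label, lw=1)
        ax.axhline(1.0, color="k", ls="--", lw=0.8)
        ax.set_xlabel("nominal -log10(p1)")
        ax.set_ylabel("fold enrichment")
        ax.legend(fontsize=7)
        path = outdir / "fold_enrichment.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    man = bundle.get("manhattan")
    if man is not None:
        fig, ax = plt.subplots(figsize=(7, 3))
        for chrom, grp in man.groupby("chrom", sort=False):
            ax.scatter(grp["cum_pos"], grp["neglog10"], s=3)
        ax.axhline(man.attrs.get("sig_line", cfdr_core.SIG_LINE), color="red", lw=0.8)
        ax.set_xlabel("cumulative position")
        ax.set_ylabel("-log10(cFDR)")
        path = outdir / "manhattan.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_pipeline(config: RunConfig, make_plots: bool = False) -> dict:
    """Execute the full analysis; returns a result bundle and writes the
    result tables under ``config.outdir``.

    The bundle's ``counts`` entry records the row funnel
    (merged >= cpg_filtered >= pruned >= calls).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    t1 = sumstats_io.read_sumstats(config.sumstats1, trait_label=config.trait1)
    t2 = sumstats_io.read_sumstats(config.sumstats2, trait_label=config.trait2)
    counts["input_trait1"] = len(t1)
    counts["input_trait2"] = len(t2)

    panel = _stage("merge", lambda: sumstats_io.merge_traits(t1, t2))
    counts["merged"] = len(panel)

    if config.cpg_catalog:
        catalog = _stage("read_catalog", lambda: sumstats_io.read_catalog(config.cpg_catalog))
        panel = _stage("cpg_filter", lambda: sumstats_io.filter_cpg(panel, catalog))
    counts["cpg_filtered"] = len(panel)

    vm_full = pd.concat([t1.df, t2.df])[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
    geno = _stage("load_genotypes", lambda: GenotypePanel.from_tsv(config.genotypes, vm_full))
    in_panel = [s for s in geno.snp_ids if s in set(panel.df["snp_id"])]
    geno_panel = geno.subset(in_panel)  # prune only the CpG-filtered SNPs
    pvals = dict(zip(panel.df["snp_id"], panel.df["p1"]))
    prune = _stage(
        "prune",
        lambda: ld_prune.indep_pairwise(
            geno_panel,
            window_snps=config.prune_window,
            step_snps=config.prune_step,
            r2_max=config.prune_r2,
            pvals=pvals,
        ),
    )
    kept = set(prune.kept) & set(panel.df["snp_id"])
    pruned_panel = MergedPanel(
        panel.trait1, panel.trait2, panel.df[panel.df["snp_id"].isin(kept)].reset_index(drop=True)
    )
    counts["pruned"] = len(pruned_panel)

    strata = StratumSpec(config.strata)
    qq = _stage("conditional_qq", lambda: cfdr_core.conditional_qq(pruned_panel, strata))
    enrich = _stage("fold_enrichment", lambda: cfdr_core.fold_enrichment(pruned_panel, strata))
    result = _stage("cfdr", lambda: cfdr_core.compute_cfdr(pruned_panel, config.alphas))
    counts["calls_sig05"] = int(result.df["sig05"].sum())
    counts["calls_pleio05"] = int(result.df["pleio05"].sum())

    if config.known_loci:
        known = pd.read_csv(config.known_loci, sep="\t").iloc[:, 0].astype(str).tolist()
        result = _stage("novelty", lambda: cfdr_core.exclude_known(result, known, geno))

    if config.qtl_tables:
        tables = [pd.read_csv(p, sep="\t") for p in config.qtl_tables]
        annotated = _stage("annotate_qtl", lambda: annotate_qtl(result, tables))
    else:
        annotated = result.df

    mr_report = _stage(
        "mr",
        lambda: mr.run_bidirectional(
            t1,
            t2,
            geno,
            p_threshold=config.mr_p_threshold,
            r2_max=config.mr_r2,
            action=config.mr_action,
            seed=config.seed if config.seed else 20210404,
        ),
    )

    manhattan = cfdr_core.manhattan_data(result, "ccfdr")

    annotated.to_csv(outdir / "cfdr_results.tsv", sep="\t", index=False)
    mr_report.to_csv(outdir / "mr_report.tsv", sep="\t", index=False)
    manhattan.to_csv(outdir / "manhattan_data.tsv", sep="\t", index=False)
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump({"counts": counts}, fh, sort_keys=False)

    bundle = {
        "counts": counts,
        "panel": pruned_panel,
        "qq": qq,
        "enrichment": enrich,
        "cfdr": result,
        "annotated": annotated,
        "mr": mr_report,
        "manhattan": manhattan,
        "prune": prune,
    }
    if make_plots:
        bundle["figures"] = render_plots(bundle, outdir)
    return bundle


def _stage(name: str, fn):
    try:
        out = fn()
    except Exception as exc:  # re-raise with stage context per the contract
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    size = len(out) if hasattr(out, "__len__") else "n/a"
    logger.info("stage %s complete (rows: %s)", name, size)
    return out
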