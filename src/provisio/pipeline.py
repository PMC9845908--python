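"""End-to-end pipeline driver.

Reproduces the analysis order of the study on synthetic (or user) data:
per-tissue expression filtering -> TMM normalization -> precision-weighted
differential expression; per-tissue coexpression network -> module-trait
correlation -> cross-tissue module correspondence with hypergeometric and
bootstrap nulls; miRNA curation -> miRNA differential expression; consensus
target calling and reciprocal-best-hit orthology.  Each stage writes
plain-text artifacts and the run log records config, versions, and
before/after feature counts for every filtering step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, correspondence, de, io, mirna, network, normalization, synthetic
from . import targets as targets_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds in one place (YAML-loadable).

    Defaults follow the study's analysis settings: expression filtering by
    CPM with min_count 10 / min_total 15, TMM trims 0.30/0.05, non-intercept
    group model with season/condition/interaction contrasts, soft power 4,
    min module size 30, deep split 2, merge cut height 0.25, bootstrap null
    with 10,000 iterations, miRNA read floor 5 with randfold alpha 0.05,
    consensus-target p < 0.01, and RBH e-value cutoff 1e-5.
    """

    seed: int = 0
    simulate: bool = True
    out_dir: str = "provisio_run"
    # synthetic scale (desk-scale defaults; the full design is 12,770 genes)
    n_genes: int = 2000
    n_mirna_loci: int = 75
    # normalization / DE
    min_count: float = 10.0
    min_total: float = 15.0
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    trend_span: float = 0.5  # lowess span for the mean-variance trend
    alphas: tuple[float, float] = (0.05, 0.1)
    drop_samples: tuple[str, ...] = ()
    # network
    beta: float = 4.0
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    trait_alpha: float = 0.05
    # correspondence
    n_iter: int = 10_000
    include_unassigned: bool = False
    # miRNA curation
    min_reads: int = 5
    randfold_alpha: float = 0.05
    homolog_identity: float = 0.90
    homolog_max_mismatches: int = 2
    # targets / orthology
    target_p_max: float = 0.01
    rbh_evalue_max: float = 1e-5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alphas"] = list(self.alphas)
        d["drop_samples"] = list(self.drop_samples)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunLog:
    config: dict
    config_hash: str
    version: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.perf_counter() - _T0, 3)}
        entry.update(info)
        self.stages.append(entry)
        logger.info("stage %s: %s", stage, info)


_T0 = time.perf_counter()


def _tissue_de(counts: pd.DataFrame, meta: pd.DataFrame, cfg: RunConfig,
               log: RunLog, tag: str, out: Path) -> de.DEResult:
    """Filter -> TMM -> log-CPM -> precision weights -> moderated contrasts."""
    keep = normalization.filter_by_expression(
        counts, meta["group"], min_count=cfg.min_count, min_total=cfg.min_total
    )
    log.record(f"filter_{tag}", before=counts.shape[0], after=len(keep),
               fraction=round(len(keep) / counts.shape[0], 4))
    filtered = counts.loc[keep]
    factors = normalization.tmm_factors(
        filtered, logratio_trim=cfg.logratio_trim, abs_trim=cfg.abs_trim
    )
    logcpm = normalization.log_cpm(filtered, factors)
    design = de.build_design(meta)
    weights = de.precision_weights(logcpm, design, span=cfg.trend_span)
    result = de.fit_moderated(logcpm, design, weights=weights)
    for cname, tab in result.tables.items():
        io.write_table(tab.reset_index(names="feature"), out / f"de_{tag}_{cname}.tsv")
    return result


def _tissue_network(logcpm_t: pd.DataFrame, meta_t: pd.DataFrame, cfg: RunConfig,
                    log: RunLog, tag: str, out: Path):
    """Outliers -> scale-free scan -> adjacency/TOM -> modules -> traits."""
    outliers = network.detect_sample_outliers(logcpm_t)
    expr = logcpm_t.drop(index=outliers)
    meta_t = meta_t.drop(index=outliers)
    log.record(f"network_outliers_{tag}", flagged=outliers)

    good = network.good_genes_filter(expr)
    log.record(f"network_good_genes_{tag}", before=expr.shape[1], after=len(good))
    expr = expr[good]

    scan = network.scale_free_scan(expr, betas=range(1, 11))
    io.write_table(scan, out / f"scale_free_{tag}.tsv")

    ncfg = network.NetworkConfig(
        beta=cfg.beta, min_module_size=cfg.min_module_size,
        deep_split=cfg.deep_split, merge_cut_height=cfg.merge_cut_height,
    )
    adj = network.adjacency(expr, beta=ncfg.beta)
    tom = network.tom_similarity(adj)
    part = network.cut_modules(tom, ncfg, genes=expr.columns)
    part = network.merge_similar_modules(part, expr, cut_height=ncfg.merge_cut_height)
    log.record(f"network_modules_{tag}", n_modules=int(part.labels.max()),
               unassigned=int((part.labels == 0).sum()))

    io.write_partition(part.labels, out / f"partition_{tag}.tsv")
    traits = pd.DataFrame(
        {
            "season": (meta_t["season"] == "late").astype(int),
            "condition": (meta_t["condition"] == "poor").astype(int),
            "cage": (meta_t["cage"] == meta_t["cage"].iloc[0]).astype(int),
        },
        index=meta_t.index,
    )
    if part.eigengenes is not None and not part.eigengenes.empty:
        io.write_table(part.eigengenes.reset_index(names="sample"),
                       out / f"eigengenes_{tag}.tsv")
        mt = network.module_trait_correlation(part.eigengenes, traits,
                                              alpha=cfg.trait_alpha)
        io.write_table(mt, out / f"module_trait_{tag}.tsv")
    else:
        mt = pd.DataFrame(columns=["module", "trait", "r", "p", "significant"])
    return part, mt


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on synthetic data; returns the artifact directory."""
    global _T0
    _T0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(config=config.to_dict(), config_hash=config.config_hash(),
                 version=__version__)

    if not config.simulate:
        raise NotImplementedError(
            "only --simulate runs are wired into the driver; use the library "
            "functions or per-stage CLI subcommands on user data"
        )

    design = synthetic.DesignSpec(n_genes=config.n_genes,
                                  n_mirna_loci=config.n_mirna_loci)
    counts, meta, truth = synthetic.generate_counts(design=design, seed=config.seed)
    if config.drop_samples:
        counts = counts.drop(columns=list(config.drop_samples))
        meta = meta.drop(index=list(config.drop_samples))
    io.write_counts(counts, out / "counts.tsv")
    io.write_metadata(meta, out / "metadata.tsv")
    io.write_json({t: truth.modules[t].to_dict() for t in truth.modules},
                  out / "truth_modules.json")
    log.record("simulate", n_genes=counts.shape[0], n_samples=counts.shape[1])

    # ---- per-tissue mRNA differential expression (tissues never pooled)
    de_results = {}
    logcpms = {}
    metas = {}
    for tissue in synthetic.TISSUES:
        m = meta[meta["tissue"] == tissue]
        c = counts[m.index]
        de_results[tissue] = _tissue_de(c, m, config, log, tissue, out)
        keep = normalization.filter_by_expression(
            c, m["group"], min_count=config.min_count, min_total=config.min_total)
        factors = normalization.tmm_factors(c.loc[keep])
        logcpms[tissue] = normalization.log_cpm(c.loc[keep], factors).T  # samples x genes
        metas[tissue] = m

    # ---- per-tissue networks and module-trait correlation
    partitions = {}
    interesting = {}
    for tissue in synthetic.TISSUES:
        part, mt = _tissue_network(logcpms[tissue], metas[tissue], config, log,
                                   tissue, out)
        partitions[tissue] = part
        sig = mt[(mt["significant"]) & (mt["trait"].isin(["season", "condition"]))]
        interesting[tissue] = sorted(
            {int(str(m).removeprefix("ME")) for m in sig["module"]}
        )

    # ---- cross-tissue module correspondence
    egg_relab = correspondence.match_labels(partitions["egg"].labels,
                                            partitions["oocyte"].labels)
    moi = interesting["oocyte"]
    table, flow = correspondence.overlap_table(
        partitions["oocyte"].labels, egg_relab, modules_of_interest=moi,
        include_unassigned=config.include_unassigned,
        n_iter=config.n_iter, seed=config.seed,
    )
    io.write_table(table, out / "module_overlap.tsv")
    io.write_json({"modules_of_interest": moi, **flow}, out / "module_flow.json")
    log.record("correspondence", modules_of_interest=moi)

    # ---- miRNA curation and differential expression
    records, mirna_truth = synthetic.generate_mirna_records(
        n_loci=config.n_mirna_loci, seed=config.seed,
        sample_ids=list(meta.index),
    )
    passing = mirna.filter_precursor_pairs(records, min_reads=config.min_reads,
                                           randfold_alpha=config.randfold_alpha)
    log.record("mirna_filter", before=int(records["precursor"].nunique()),
               after=int(passing["precursor"].nunique()))
    loci = mirna.merge_loci(passing)
    mir_counts = mirna.mirna_count_table(loci, passing)
    io.write_gff3(
        pd.DataFrame(
            {
                "chrom": [l.chrom for l in loci],
                "start": [l.start for l in loci],
                "end": [l.end for l in loci],
                "strand": [l.strand for l in loci],
                "id": [l.locus_id for l in loci],
                "mature": [l.mature_seq for l in loci],
            }
        ),
        out / "curated_loci.gff3",
    )
    io.write_counts(mir_counts, out / "mirna_counts.tsv")
    log.record("mirna_merge", loci=len(loci))
    mirna_de = {}
    for tissue in synthetic.TISSUES:
        m = metas[tissue]
        mirna_de[tissue] = _tissue_de(mir_counts[m.index], m, config, log,
                                      f"mirna_{tissue}", out)

    # ---- consensus targets / RBH orthologs / overlap statistics
    mature_ids = [l.locus_id for l in loci]
    preds_a, preds_b, target_truth = synthetic.generate_target_tables(
        mature_ids, list(counts.index[: max(200, config.n_genes // 10)]),
        seed=config.seed,
    )
    called = targets_mod.consensus_targets(preds_a, preds_b,
                                           p_max=config.target_p_max)
    io.write_table(
        pd.DataFrame(sorted(called), columns=["mirna", "gene"]),
        out / "consensus_targets.tsv",
    )
    hits_ab, hits_ba, hit_truth = synthetic.generate_hit_tables(seed=config.seed)
    pairs = targets_mod.rbh_orthologs(hits_ab, hits_ba,
                                      evalue_max=config.rbh_evalue_max)
    io.write_table(
        pd.DataFrame(
            [(p.gene_a, p.gene_b, p.evalue_ab, p.evalue_ba) for p in pairs],
            columns=["gene_a", "gene_b", "evalue_ab", "evalue_ba"],
        ),
        out / "rbh_pairs.tsv",
    )
    log.record("targets", consensus=len(called), rbh=len(pairs))

    # DE-set vs target-set intersection (oocyte season, adjusted p < 0.1)
    season_tab = de_results["oocyte"].tables["season"]
    de_set = set(season_tab.index[season_tab["padj"] < 0.1])
    target_genes = {g for _, g in called}
    universe = set(season_tab.index) | target_genes
    overlap_stats = targets_mod.set_overlap_test(
        de_set & universe, target_genes & universe, universe
    )
    io.write_json(overlap_stats, out / "de_target_overlap.json")

    # ---- Table-1-style summary: up/down per contrast per tissue per assay
    summary_rows = []
    for assay, res_by_tissue in (("mRNA", de_results), ("miRNA", mirna_de)):
        for tissue in synthetic.TISSUES:
            res = res_by_tissue[tissue]
            s = de.de_summary(res, alphas=config.alphas)
            for contrast, row in s.iterrows():
                summary_rows.append({"assay": assay, "tissue": tissue,
                                     "contrast": contrast, **row.to_dict()})
    io.write_table(pd.DataFrame(summary_rows), out / "de_summary.tsv")

    log.record("done")
    io.write_json(
        {"config": log.config, "config_hash": log.config_hash,
         "version": log.version, "stages": log.stages},
        out / "run_log.json",
    )
    return out
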