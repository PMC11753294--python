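"""Config-driven end-to-end pipeline over a file-based workspace.

Stages (simulate -> de -> der -> integrate -> enrich -> network ->
preserve -> hubs) each read their inputs from, and write their outputs to,
a workspace directory, so any stage can be re-run in isolation and two runs
with the same config and seed produce byte-identical tables.  A global seed
fans out to per-stage seeds through a stable hash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chipder, diffexpr, enrichment, integration, io, network, preservation
from .containers import CountMatrix, PeakSet
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    _spawn,
    default_config,
    simulate_peak_counts,
    simulate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "omixnet_run"
    seed: int = 0
    p_de: float = 0.05
    fdr_der: float = 0.05
    min_correlation: float = 0.8
    promoter_halfwidth: int = 3000
    min_count: int = 15
    min_module_size: int = 30
    merge_height: float = 0.25
    min_coherence: float = 0.3
    target_r2: float = 0.8
    n_perm: int = 1000
    kme_min: float = 0.8
    degree_quantile: float = 0.9
    top_n: int = 5
    gsea_n_perm: int = 1000
    soft_powers: dict = field(default_factory=dict)  # condition -> pinned beta
    count_mode_conditions: tuple = ("disease",)
    discovery_condition: str = "exposure"
    test_condition: str = "disease"
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        for name in ("p_de", "fdr_der", "merge_height", "target_r2",
                     "kme_min", "degree_quantile", "min_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_module_size < 2 or self.top_n < 1 or self.promoter_halfwidth < 0:
            raise ValueError("invalid size/threshold parameter")

    def stage_seed(self, stage: str) -> int:
        return int(_spawn(self.seed, f"stage:{stage}").integers(0, 2**31))

    def content_hash(self) -> str:
        # the output location is not part of the analysis configuration
        return io.config_hash(dataclasses.replace(self, outdir=""))


def _ws(config: PipelineConfig) -> Path:
    ws = Path(config.outdir)
    for sub in ("inputs", "inputs/peaks", "de", "der", "integrate",
                "enrich", "network", "preserve", "hubs"):
        (ws / sub).mkdir(parents=True, exist_ok=True)
    return ws


def _list_datasets(ws: Path) -> list[str]:
    return sorted(p.stem.removeprefix("counts_") for p in (ws / "inputs").glob("counts_*.tsv"))


def _load_dataset(ws: Path, ds: str) -> CountMatrix:
    meta = io.read_sample_meta(ws / "inputs" / f"meta_{ds}.tsv")
    return io.read_counts(ws / "inputs" / f"counts_{ds}.tsv", meta)


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic study and write every pipeline input."""
    ws = _ws(config)
    sim = config.simulation or default_config(config.stage_seed("simulate"))
    datasets, truth, annotation, db, peaksets, gene_sets = simulate_study(sim)
    sim.to_yaml(ws / "inputs" / "sim_config.yaml")
    for (cond, ds), cm in datasets.items():
        io.write_counts(cm, ws / "inputs" / f"counts_{ds}.tsv")
        io.write_sample_meta(cm.meta, ws / "inputs" / f"meta_{ds}.tsv")
    io.write_annotation(annotation, ws / "inputs" / "annotation.tsv")
    io.write_enhancers(db, ws / "inputs" / "enhancers.tsv")
    io.write_gmt(gene_sets, ws / "inputs" / "gene_sets.gmt")
    for cond, groups in peaksets.items():
        for group, reps in groups.items():
            for i, ps in enumerate(reps):
                io.write_bed(ps, ws / "inputs" / "peaks" / f"{cond}_{group}_rep{i + 1}.bed")
    # consensus + simulated read counts for count-mode conditions
    for cond in config.count_mode_conditions:
        reps = peaksets[cond]["case"] + peaksets[cond]["control"]
        consensus = chipder.consensus_peaks(reps, min_replicates=2)
        io.write_bed(consensus, ws / "inputs" / f"consensus_{cond}.bed")
        pc = simulate_peak_counts(consensus, truth, sim, cond)
        io.write_counts(pc, ws / "inputs" / f"peak_counts_{cond}.tsv")
        io.write_sample_meta(pc.meta, ws / "inputs" / f"peak_meta_{cond}.tsv")
    # truth tables
    truth.modules.rename("module").to_csv(ws / "inputs" / "truth_modules.tsv", sep="\t")
    truth.de.to_csv(ws / "inputs" / "truth_de.tsv", sep="\t", index=False)
    truth.peaks.to_csv(ws / "inputs" / "truth_peaks.tsv", sep="\t", index=False)
    truth.module_info.to_csv(ws / "inputs" / "truth_module_info.tsv", sep="\t")
    return {"datasets": len(datasets), "genes": sim.n_genes}


def stage_de(config: PipelineConfig) -> dict:
    """Per-dataset QC, balancing and NB-LRT differential expression."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    tallies = {}
    for ds in _list_datasets(ws):
        cm = _load_dataset(ws, ds)
        result, qc = diffexpr.run_de(
            cm, seed=config.stage_seed(f"de:{ds}"),
            min_correlation=config.min_correlation, p_threshold=config.p_de,
        )
        io.write_result_table(result, ws / "de" / f"de_{ds}.tsv", cfg_hash)
        tallies[ds] = {
            "samples_removed_qc": len(qc.removed),
            "genes_tested": len(result),
            "degs": int(result["deg"].sum()),
        }
        for name, r in qc.removed:
            logger.info("de[%s]: removed sample %s (mean r=%.3f)", ds, name, r)
    return tallies


def stage_der(config: PipelineConfig) -> dict:
    """Differential H3K27ac regions per condition, annotated to genes."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    annotation = io.read_annotation(ws / "inputs" / "annotation.tsv")
    db = io.read_enhancers(ws / "inputs" / "enhancers.tsv")
    filtered = chipder.filter_enhancer_associations(db)
    tallies = {}
    for cond in CONDITIONS:
        if cond in config.count_mode_conditions:
            meta = io.read_sample_meta(ws / "inputs" / f"peak_meta_{cond}.tsv")
            pc = io.read_counts(ws / "inputs" / f"peak_counts_{cond}.tsv", meta)
            table = chipder.differential_regions_counts(pc, fdr=config.fdr_der)
            consensus = io.read_bed(ws / "inputs" / f"consensus_{cond}.bed")
            ders = chipder.annotate_der_counts(table, consensus)
        else:
            reps = {g: [io.read_bed(p) for p in sorted(
                        (ws / "inputs" / "peaks").glob(f"{cond}_{g}_rep*.bed"))]
                    for g in ("case", "control")}
            case_cons = chipder.consensus_peaks(reps["case"], min_replicates=2)
            ctrl_cons = chipder.consensus_peaks(reps["control"], min_replicates=2)
            ders = chipder.differential_regions_presence(case_cons, ctrl_cons)
        gaders = chipder.annotate_peaks(
            ders, annotation, filtered, promoter_halfwidth=config.promoter_halfwidth
        )
        io.write_result_table(ders, ws / "der" / f"der_{cond}.tsv", cfg_hash, index=False)
        io.write_result_table(gaders, ws / "der" / f"gader_{cond}.tsv", cfg_hash, index=False)
        tallies[cond] = {"ders": len(ders), "gader_genes": int(gaders["gene"].nunique())}
    return tallies


def _de_signature_from_file(path) -> dict[str, int]:
    df = io.read_result_table(path, index_col="gene")
    called = df[df["deg"]]
    return dict(zip(called.index, called["direction"].astype(int)))


def _gader_signature_from_file(path) -> dict[str, int]:
    df = io.read_result_table(path)
    if not len(df):
        return {}
    return chipder.gader_signature(df)


def stage_integrate(config: PipelineConfig) -> dict:
    """Merge RNA + ChIP evidence per condition, then intersect conditions."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    signatures = {}
    tallies = {}
    for cond in CONDITIONS:
        lists = []
        for ds in _list_datasets(ws):
            if ds.startswith(cond):
                lists.append((ds, "rna", _de_signature_from_file(ws / "de" / f"de_{ds}.tsv")))
        lists.append((f"{cond}_chip", "chip",
                      _gader_signature_from_file(ws / "der" / f"gader_{cond}.tsv")))
        sig = integration.merge_condition_signature(lists, condition=cond)
        signatures[cond] = sig
        table = pd.DataFrame(
            sorted(sig.directions.items()), columns=["gene", "direction"]
        )
        io.write_result_table(table, ws / "integrate" / f"signature_{cond}.tsv",
                              cfg_hash, index=False)
        excl = pd.DataFrame({"gene": sorted(sig.excluded_discordant)})
        io.write_result_table(excl, ws / "integrate" / f"excluded_{cond}.tsv",
                              cfg_hash, index=False)
        tallies[cond] = sig.tally()
    common = integration.intersect_conditions(signatures[CONDITIONS[0]], signatures[CONDITIONS[1]])
    rows = [(g, common.concordant.get(g, 0), g in common.concordant) for g in sorted(common.common)]
    table = pd.DataFrame(rows, columns=["gene", "direction", "concordant"])
    io.write_result_table(table, ws / "integrate" / "common.tsv", cfg_hash, index=False)
    tallies["common"] = common.tally()
    return tallies


def stage_enrich(config: PipelineConfig) -> dict:
    """ORA + GSEA on the concordant signature, plus term clustering."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    sets = io.read_gmt(ws / "inputs" / "gene_sets.gmt")
    common = io.read_result_table(ws / "integrate" / "common.tsv")
    query = set(common.loc[common["concordant"], "gene"])

    # universe + per-condition mean log2FC over all genes tested for DE
    per_cond_fc: dict[str, pd.Series] = {}
    for cond in CONDITIONS:
        frames = []
        for ds in _list_datasets(ws):
            if ds.startswith(cond):
                df = io.read_result_table(ws / "de" / f"de_{ds}.tsv", index_col="gene")
                frames.append(df["log2fc"])
        per_cond_fc[cond] = pd.concat(frames, axis=1).mean(axis=1)
    universe = set().union(*(s.index for s in per_cond_fc.values()))
    query &= universe

    ora_res = enrichment.ora(query, universe, sets)
    io.write_result_table(ora_res, ws / "enrich" / "ora.tsv", cfg_hash, index=False)

    ranking = pd.concat(per_cond_fc.values(), axis=1).mean(axis=1).dropna()
    gsea_res = enrichment.gsea(ranking, sets, n_perm=config.gsea_n_perm,
                               seed=config.stage_seed("gsea"))
    io.write_result_table(gsea_res, ws / "enrich" / "gsea.tsv", cfg_hash, index=False)

    sig_terms = ora_res[ora_res["significant"]]
    k = 5
    if len(sig_terms) >= k:
        clusters = enrichment.term_similarity_clusters(sig_terms, sets, k=k)
        io.write_result_table(clusters.to_frame(), ws / "enrich" / "term_clusters.tsv", cfg_hash)
        n_clusters = int(clusters.nunique())
    else:
        logger.info("fewer than %d significant terms; clustering skipped", k)
        n_clusters = 0
    return {
        "ora_significant": int(ora_res["significant"].sum()) if len(ora_res) else 0,
        "gsea_significant": int(gsea_res["significant"].sum()) if len(gsea_res) else 0,
        "term_clusters": n_clusters,
    }


def _network_universe(config: PipelineConfig, ws: Path) -> list[str]:
    """Union of DEGs and GADER genes, filtered for low counts per dataset."""
    selected: set[str] = set()
    for ds in _list_datasets(ws):
        selected |= set(_de_signature_from_file(ws / "de" / f"de_{ds}.tsv"))
    for cond in CONDITIONS:
        selected |= set(_gader_signature_from_file(ws / "der" / f"gader_{cond}.tsv"))
    datasets = [_load_dataset(ws, ds) for ds in _list_datasets(ws)]
    kept = set(network.low_count_filter(datasets, min_count=config.min_count))
    return sorted(selected & kept)


def _condition_expression(config: PipelineConfig, ws: Path, cond: str,
                          genes: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Merged, VST-transformed, batch-adjusted expression for one condition."""
    from .containers import concat_count_matrices

    mats = [_load_dataset(ws, ds) for ds in _list_datasets(ws) if ds.startswith(cond)]
    merged = concat_count_matrices(mats)
    sf = diffexpr.size_factors(merged)
    expr = network.vst(merged, sf)
    expr = network.batch_adjust(expr, merged.meta["dataset"], merged.meta["condition"])
    trait = (merged.meta["condition"] == "case").astype(int)
    return expr.loc[genes], trait


def stage_network(config: PipelineConfig) -> dict:
    """Per-condition signed network, modules, eigengenes, trait correlation."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    genes = _network_universe(config, ws)
    tallies = {"network_genes": len(genes)}
    betas = {}
    for cond in CONDITIONS:
        expr, trait = _condition_expression(config, ws, cond, genes)
        expr.to_csv(ws / "network" / f"expr_{cond}.tsv", sep="\t")
        trait.rename("trait").to_csv(ws / "network" / f"trait_{cond}.tsv", sep="\t")
        if cond in config.soft_powers:
            beta = int(config.soft_powers[cond])
            fit_table = pd.DataFrame()
        else:
            beta, fit_table = network.pick_soft_threshold(expr, target_r2=config.target_r2)
        betas[cond] = beta
        if len(fit_table):
            io.write_result_table(fit_table, ws / "network" / f"soft_threshold_{cond}.tsv",
                                  cfg_hash, index=False)
        net = network.build_network(expr, beta)
        labels = network.detect_modules(
            net, expr, min_module_size=config.min_module_size,
            merge_height=config.merge_height, min_coherence=config.min_coherence,
        )
        io.write_result_table(labels.to_frame(), ws / "network" / f"modules_{cond}.tsv", cfg_hash)
        me = network.module_eigengenes(expr, labels)
        me.eigengenes.to_csv(ws / "network" / f"eigengenes_{cond}.tsv", sep="\t")
        io.write_result_table(me.kme, ws / "network" / f"kme_{cond}.tsv", cfg_hash)
        if len(me.eigengenes.columns):
            trait_corr = network.module_trait_correlation(me, trait)
            io.write_result_table(trait_corr, ws / "network" / f"module_trait_{cond}.tsv", cfg_hash)
            n_sig = int(trait_corr["significant"].sum())
        else:
            n_sig = 0
        tallies[cond] = {
            "beta": beta,
            "modules": int(labels.max()),
            "trait_correlated": n_sig,
        }
    io.write_json(betas, ws / "network" / "betas.json")
    return tallies


def _load_network(ws: Path, cond: str) -> tuple[pd.DataFrame, network.Network, pd.Series]:
    expr = pd.read_csv(ws / "network" / f"expr_{cond}.tsv", sep="\t", index_col=0)
    betas = json.loads((ws / "network" / "betas.json").read_text())
    net = network.build_network(expr, int(betas[cond]))
    labels = io.read_result_table(ws / "network" / f"modules_{cond}.tsv", index_col=0)["module"]
    return expr, net, labels


def stage_preserve(config: PipelineConfig) -> dict:
    """Preservation of discovery-condition modules in the test network."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    disc_expr, disc_net, disc_labels = _load_network(ws, config.discovery_condition)
    test_expr, test_net, _ = _load_network(ws, config.test_condition)
    modules = {
        int(m): sorted(disc_labels.index[disc_labels == m])
        for m in sorted(set(disc_labels) - {0})
    }
    if not modules:
        io.write_result_table(pd.DataFrame(), ws / "preserve" / "preservation.tsv", cfg_hash)
        return {"modules_tested": 0, "preserved": 0}
    report = preservation.preservation_permutation(
        disc_expr, disc_net, test_expr, test_net, modules,
        n_perm=config.n_perm, seed=config.stage_seed("preserve"),
    )
    trait_path = ws / "network" / f"module_trait_{config.discovery_condition}.tsv"
    if trait_path.exists():
        trait_corr = io.read_result_table(trait_path, index_col="module")
        report["trait_correlated"] = report["module"].map(trait_corr["significant"])
    else:
        report["trait_correlated"] = False
    io.write_result_table(report, ws / "preserve" / "preservation.tsv", cfg_hash, index=False)
    preserved = report.groupby("module")["preserved"].first()
    return {"modules_tested": len(modules), "preserved": int(preserved.sum())}


def stage_hubs(config: PipelineConfig) -> dict:
    """Hub genes in preserved, trait-correlated discovery modules."""
    ws = _ws(config)
    cfg_hash = config.content_hash()
    path = ws / "preserve" / "preservation.tsv"
    report = io.read_result_table(path)
    if not len(report):
        io.write_result_table(pd.DataFrame(), ws / "hubs" / "hubs.tsv", cfg_hash)
        return {"hub_modules": 0, "hubs": 0}
    flags = report.groupby("module")[["preserved", "trait_correlated"]].first()
    target_modules = set(flags.index[flags["preserved"] & flags["trait_correlated"]])
    expr, net, labels = _load_network(ws, config.discovery_condition)
    me = network.module_eigengenes(expr, labels)
    hub_report = preservation.hub_genes(
        net, labels.where(labels.isin(target_modules), 0), me,
        degree_quantile=config.degree_quantile, kme_min=config.kme_min,
        top_n=config.top_n,
    )
    io.write_result_table(hub_report, ws / "hubs" / "hubs.tsv", cfg_hash, index=False)
    top = preservation.top_hubs(hub_report, config.top_n)
    io.write_result_table(top, ws / "hubs" / "top_hubs.tsv", cfg_hash, index=False)
    return {"hub_modules": len(target_modules), "hubs": int(hub_report["hub"].sum()) if len(hub_report) else 0}


STAGES = ("simulate", "de", "der", "integrate", "enrich", "network", "preserve", "hubs")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the run report."""
    config.validate()
    ws = _ws(config)
    report: dict = {"config_hash": config.content_hash(), "seed": config.seed}
    for stage in STAGES:
        fn = globals()[f"stage_{stage}"]
        try:
            report[stage] = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    tally = report["integrate"]["common"]
    assert tally["common"] == tally["concordant"] + tally["discordant"]
    io.write_json(report, ws / "run_report.json")
    return report
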