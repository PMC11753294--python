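"""Synthetic multi-dataset study generator with planted ground truth.

Emulates the structure of a two-condition integrative study: per condition
several RNA-seq count datasets (case vs control, with dataset batch
effects), one H3K27ac ChIP-seq dataset (replicated peak sets per group),
a gene annotation, and an enhancer-gene association table.

The expression model is a latent-factor model on the log scale:

    log mu_gj = baseline_g + batch_{g,d} + ln(2) * log2FC_gc * 1[j in case]
                + loading_m * f_{mj}           (gene g in module m)

with counts drawn NB(mu, alpha), Var = mu + alpha * mu^2.  One latent
factor per module per sample creates WGCNA-detectable correlation blocks;
modules flagged ``shared`` receive a factor in both conditions,
condition-specific modules only in their own condition's samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, EnhancerDB, PeakSet

CONDITIONS = ("exposure", "disease")


@dataclass
class ModuleSpec:
    module_id: int
    size: int
    shared: bool
    loading: float
    condition: str = "exposure"  # host condition when not shared
    trait_shift: float = 0.0  # latent-factor mean shift in case samples

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("module loading must lie in [0, 1]")
        if self.size < 2:
            raise ValueError("module size must be >= 2")

    @property
    def member_log2fc(self) -> float:
        """Expected member log2 fold change induced by the factor shift."""
        return self.loading * self.trait_shift / np.log(2.0)


@dataclass
class DESpec:
    gene: str
    conditions: tuple[str, ...]
    log2fc: float

    @property
    def direction(self) -> int:
        return 1 if self.log2fc > 0 else -1


@dataclass
class PeakSpecEntry:
    gene: str
    element: str  # promoter | enhancer
    direction: str  # gain | loss
    condition: str

    def __post_init__(self) -> None:
        if self.element not in ("promoter", "enhancer"):
            raise ValueError(f"unknown element type {self.element!r}")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"unknown peak direction {self.direction!r}")


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_datasets_per_condition: int = 2
    samples_per_group: int = 10
    modules: list[ModuleSpec] = field(default_factory=list)
    de: list[DESpec] = field(default_factory=list)
    peaks: list[PeakSpecEntry] = field(default_factory=list)
    nb_dispersion: float = 0.1
    baseline_mean_log_range: tuple[float, float] = (3.0, 8.0)
    batch_effect_sd: float = 0.5
    n_chip_replicates: int = 3
    promoter_halfwidth: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch effect SD must be non-negative")
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        ids = [m.module_id for m in self.modules]
        if len(ids) != len(set(ids)):
            raise ValueError("module ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def to_yaml(self, path) -> None:
        def _plain(x):
            if isinstance(x, dict):
                return {str(k): _plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_plain(v) for v in x]
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            if isinstance(x, (np.str_, str)):
                return str(x)
            return x

        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["modules"] = [ModuleSpec(**m) for m in raw.get("modules", [])]
        raw["de"] = [DESpec(gene=d["gene"], conditions=tuple(d["conditions"]),
                            log2fc=d["log2fc"]) for d in raw.get("de", [])]
        raw["peaks"] = [PeakSpecEntry(**p) for p in raw.get("peaks", [])]
        raw["baseline_mean_log_range"] = tuple(raw["baseline_mean_log_range"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure: module labels, DE directions, peak assignments."""

    modules: pd.Series  # gene -> module id (0 = background)
    module_info: pd.DataFrame  # module_id-indexed: size, shared, loading, condition
    de: pd.DataFrame  # rows (gene, condition, log2fc, direction)
    peaks: pd.DataFrame  # rows (condition, chrom, start, end, gene, element, direction)
    gene_loadings: pd.Series | None = None  # per-gene effective factor loading

    def module_labels(self, condition: str) -> pd.Series:
        """Planted labels restricted to modules active in `condition`."""
        active = set(
            self.module_info.index[
                self.module_info["shared"] | (self.module_info["condition"] == condition)
            ]
        )
        return self.modules.where(self.modules.isin(active), 0)

    def de_directions(self, condition: str) -> dict[str, int]:
        sub = self.de[self.de["condition"] == condition]
        return dict(zip(sub["gene"], sub["direction"]))


def _spawn(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose)."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _module_membership(config: SimulationConfig) -> pd.Series:
    genes = config.gene_ids
    labels = np.zeros(config.n_genes, dtype=int)
    cursor = 0
    for mod in config.modules:
        labels[cursor:cursor + mod.size] = mod.module_id
        cursor += mod.size
    return pd.Series(labels, index=genes, name="module")


def build_truth(config: SimulationConfig) -> GroundTruth:
    membership = _module_membership(config)
    # heterogeneous connectivity: each member's effective loading is the
    # module loading scaled by a per-gene multiplier in [0.5, 1]
    load_rng = _spawn(config.seed, "gene-loadings")
    multipliers = load_rng.uniform(0.5, 1.0, size=config.n_genes)
    gene_loadings = pd.Series(0.0, index=membership.index, name="loading")
    for mod in config.modules:
        members = membership.index[membership == mod.module_id]
        gene_loadings.loc[members] = mod.loading * multipliers[
            membership.to_numpy() == mod.module_id
        ]
    info = pd.DataFrame(
        {
            "size": [m.size for m in config.modules],
            "shared": [m.shared for m in config.modules],
            "loading": [m.loading for m in config.modules],
            "condition": [m.condition for m in config.modules],
            "trait_shift": [m.trait_shift for m in config.modules],
        },
        index=pd.Index([m.module_id for m in config.modules], name="module_id"),
    )
    de_rows = []
    for spec in config.de:
        for cond in spec.conditions:
            de_rows.append((spec.gene, cond, spec.log2fc, spec.direction))
    # module members are differentially expressed through the factor shift
    for mod in config.modules:
        if mod.trait_shift == 0.0:
            continue
        conds = CONDITIONS if mod.shared else (mod.condition,)
        for gene in membership.index[membership == mod.module_id]:
            lfc = float(gene_loadings[gene] * mod.trait_shift / np.log(2.0))
            for cond in conds:
                de_rows.append((gene, cond, lfc, 1 if lfc > 0 else -1))
    de = pd.DataFrame(de_rows, columns=["gene", "condition", "log2fc", "direction"])
    peaks = pd.DataFrame(columns=["condition", "chrom", "start", "end", "gene", "element", "direction"])
    return GroundTruth(membership, info, de, peaks, gene_loadings)


def simulate_counts(config: SimulationConfig) -> tuple[dict[tuple[str, str], CountMatrix], GroundTruth]:
    """Draw NB count matrices for every (condition, dataset) pair.

    Returns a dict keyed by (condition, dataset id) and the planted truth.
    All randomness derives from ``config.seed``.
    """
    truth = build_truth(config)
    genes = config.gene_ids
    if truth.de.size and not set(truth.de["gene"]) <= set(genes):
        raise ValueError("DE spec references unknown genes")

    base_rng = _spawn(config.seed, "baseline")
    lo, hi = config.baseline_mean_log_range
    baseline = base_rng.uniform(lo, hi, size=config.n_genes)

    module_rows = {m.module_id: np.flatnonzero(truth.modules.to_numpy() == m.module_id)
                   for m in config.modules}

    datasets: dict[tuple[str, str], CountMatrix] = {}
    gene_index = pd.Index(genes)
    for cond in CONDITIONS:
        # per-gene shifts for standalone DE entries; module members get their
        # condition effect through the factor mean shift instead
        de_shift = np.zeros(config.n_genes)
        for spec in config.de:
            if cond in spec.conditions:
                de_shift[gene_index.get_loc(spec.gene)] = spec.log2fc * np.log(2.0)
        active = [m for m in config.modules if m.shared or m.condition == cond]
        for d in range(config.n_datasets_per_condition):
            ds_id = f"{cond}_ds{d + 1}"
            rng = _spawn(config.seed, f"counts:{ds_id}")
            batch = rng.normal(0.0, config.batch_effect_sd, size=config.n_genes)
            n = 2 * config.samples_per_group
            is_case = np.array([1] * config.samples_per_group + [0] * config.samples_per_group)
            logmu = (baseline[:, None] + batch[:, None]
                     + de_shift[:, None] * is_case[None, :])
            for mod in active:
                factor = rng.normal(0.0, 1.0, size=n) + mod.trait_shift * is_case
                rows = module_rows[mod.module_id]
                gl = truth.gene_loadings.to_numpy()[rows]
                logmu[rows, :] += gl[:, None] * factor[None, :]
            mu = np.exp(logmu)
            r = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            sample_ids = [f"{ds_id}_{'case' if c else 'ctrl'}{i % config.samples_per_group + 1}"
                          for i, c in enumerate(is_case)]
            meta = pd.DataFrame(
                {
                    "condition": np.where(is_case == 1, "case", "control"),
                    "dataset": ds_id,
                    "study_condition": cond,
                },
                index=pd.Index(sample_ids, name="sample"),
            )
            datasets[(cond, ds_id)] = CountMatrix(
                pd.DataFrame(counts, index=genes, columns=sample_ids), meta
            )
    return datasets, truth


# ---------------------------------------------------------------------------
# annotation + enhancers


def simulate_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, EnhancerDB]:
    """Place genes on synthetic chromosomes and enhancers between them.

    Gene bodies never overlap; each enhancer lies strictly intergenic and at
    least ``promoter_halfwidth`` away from every TSS so planted enhancer
    peaks are never reclassified as promoter peaks.
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = _spawn(config.seed, "annotation")
    genes = config.gene_ids
    per_chrom = 500
    margin = config.promoter_halfwidth + 100

    ann_rows = []
    enh_rows = []
    assoc_rows = []
    enh_counter = 0
    for ci in range(0, config.n_genes, per_chrom):
        chrom = f"chr{ci // per_chrom + 1}"
        pos = 10_000
        chrom_genes = genes[ci:ci + per_chrom]
        placed = []
        for g in chrom_genes:
            body = int(rng.integers(2_000, 8_000))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + body
            tss = start if strand == "+" else end
            ann_rows.append((g, chrom, start, end, strand, tss))
            placed.append((g, start, end))
            gap = int(rng.integers(2 * margin + 2_000, 2 * margin + 10_000))
            # enhancer candidate in the middle of the gap, clear of both TSSs
            if rng.random() < 0.7:
                width = int(rng.integers(400, 1_200))
                centre = end + gap // 2 + int(rng.integers(-400, 401))
                e_start = centre - width // 2
                e_end = e_start + width
                if e_start > end + margin and e_end < end + gap - margin:
                    enh_rows.append((f"E{enh_counter:05d}", chrom, e_start, e_end,
                                     float(rng.uniform(0.1, 2.5))))
                    enh_counter += 1
            pos = end + gap
    annotation = pd.DataFrame(
        ann_rows, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    ).set_index("gene")

    enhancers = pd.DataFrame(
        enh_rows, columns=["enhancer_id", "chrom", "start", "end", "enhancer_score"]
    ).set_index("enhancer_id")

    # associate each enhancer with 1-8 nearby genes
    by_chrom = {c: sub.sort_values("tss") for c, sub in annotation.groupby("chrom")}
    for eid, row in enhancers.iterrows():
        sub = by_chrom[row["chrom"]]
        centre = (row["start"] + row["end"]) // 2
        order = (sub["tss"] - centre).abs().sort_values()
        k = int(min(1 + rng.poisson(2.0), 8, len(order)))
        for g in order.index[:k]:
            assoc_rows.append((eid, g, float(rng.uniform(0.5, 30.0))))
    associations = pd.DataFrame(assoc_rows, columns=["enhancer_id", "gene", "association_score"])
    return annotation, EnhancerDB(enhancers, associations)


# ---------------------------------------------------------------------------
# peaks


def _jitter(rng: np.random.Generator, start: int, end: int) -> tuple[int, int]:
    s = start + int(rng.integers(-50, 51))
    e = end + int(rng.integers(-50, 51))
    return max(0, s), max(max(0, s) + 1, e)


def simulate_peaks(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    db: EnhancerDB | None = None,
) -> tuple[dict[str, dict[str, list[PeakSet]]], GroundTruth]:
    """Replicated case/control peak sets per condition with planted DERs.

    ``gain`` entries put a peak only in case replicates; ``loss`` only in
    control replicates; background peaks appear in both with <=50 bp
    replicate jitter.  Enhancer entries are resolved against ``db`` (after
    the default association filter) and rejected when the gene has no
    surviving enhancer.  Updates and returns ``truth`` with the planted
    peak table.
    """
    unknown = {p.gene for p in config.peaks} - set(annotation.index)
    if unknown:
        raise ValueError(f"peak spec references unknown genes: {sorted(unknown)[:5]}")
    rng = _spawn(config.seed, "peaks")
    spec_genes = {(p.condition, p.gene) for p in config.peaks}

    filtered = None
    if any(p.element == "enhancer" for p in config.peaks):
        if db is None:
            raise ValueError("enhancer peak entries require an EnhancerDB")
        from .chipder import filter_enhancer_associations  # deferred: avoids cycle

        filtered = filter_enhancer_associations(db)

    planted_rows = []
    for entry in config.peaks:
        ann = annotation.loc[entry.gene]
        if entry.element == "promoter":
            tss = int(ann["tss"])
            width = int(rng.integers(800, 2_000))
            start = max(0, tss - width // 2)
            planted_rows.append((entry.condition, ann["chrom"], start, start + width,
                                 entry.gene, "promoter", entry.direction))
        else:
            assoc = filtered.associations
            mine = assoc[assoc["gene"] == entry.gene]
            if not len(mine):
                raise ValueError(
                    f"gene {entry.gene} has no enhancer surviving the association filter"
                )
            eid = mine.sort_values(["association_score", "enhancer_id"],
                                   ascending=[False, True]).iloc[0]["enhancer_id"]
            enh = filtered.enhancers.loc[eid]
            planted_rows.append((entry.condition, enh["chrom"], int(enh["start"]),
                                 int(enh["end"]), entry.gene, "enhancer", entry.direction))
    peak_truth = pd.DataFrame(
        planted_rows,
        columns=["condition", "chrom", "start", "end", "gene", "element", "direction"],
    )
    truth.peaks = peak_truth

    # background promoter peaks away from planted genes
    out: dict[str, dict[str, list[PeakSet]]] = {}
    for cond in CONDITIONS:
        cond_truth = peak_truth[peak_truth["condition"] == cond]
        bg_rows = []
        for g, ann in annotation.iterrows():
            if (cond, g) in spec_genes or g in set(cond_truth["gene"]):
                continue
            if rng.random() < 0.25:
                tss = int(ann["tss"])
                width = int(rng.integers(800, 2_000))
                start = max(0, tss - width // 2)
                bg_rows.append((ann["chrom"], start, start + width))
        out[cond] = {"case": [], "control": []}
        for group in ("case", "control"):
            for rep in range(config.n_chip_replicates):
                rows = []
                for chrom, s, e in bg_rows:
                    js, je = _jitter(rng, s, e)
                    rows.append((chrom, js, je))
                for _, p in cond_truth.iterrows():
                    present = (p["direction"] == "gain") == (group == "case")
                    if present:
                        js, je = _jitter(rng, int(p["start"]), int(p["end"]))
                        rows.append((p["chrom"], js, je))
                df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
                df["name"] = [f"{cond}_{group}_r{rep + 1}_p{i}" for i in range(len(df))]
                out[cond][group].append(PeakSet(df, label=f"{cond}:{group}:rep{rep + 1}"))
    return out, truth


def plant_enhancer_peaks(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    db: EnhancerDB,
    n_per_condition: int = 10,
) -> SimulationConfig:
    """Append enhancer gain/loss entries on genes with filter-surviving enhancers.

    Enhancer targets can only be chosen once the annotation exists, so the
    bundled study plants them here rather than in the static config.
    """
    from .chipder import filter_enhancer_associations

    filtered = filter_enhancer_associations(db)
    used = {p.gene for p in config.peaks}
    rng = _spawn(config.seed, "enhancer-plant")
    assoc = filtered.associations
    candidates = assoc[~assoc["gene"].isin(used)].drop_duplicates("gene")
    for cond in CONDITIONS:
        n = min(n_per_condition, len(candidates))
        idx = rng.choice(len(candidates), size=n, replace=False)
        for _, row in candidates.iloc[sorted(idx)].iterrows():
            direction = "gain" if rng.random() < 0.6 else "loss"
            config.peaks.append(PeakSpecEntry(row["gene"], "enhancer", direction, cond))
        candidates = candidates.drop(candidates.index[sorted(idx)])
    return config


def simulate_peak_counts(
    consensus: PeakSet,
    truth: GroundTruth,
    config: SimulationConfig,
    condition: str,
    log2fc: float = 2.0,
) -> CountMatrix:
    """NB read counts under consensus peaks with planted 4-fold shifts.

    Peaks overlapping a planted gain get +log2fc in case samples; losses get
    +log2fc in control samples.
    """
    rng = _spawn(config.seed, f"peakcounts:{condition}")
    n_rep = config.n_chip_replicates
    df = consensus.df
    base = rng.uniform(4.0, 7.0, size=len(df))
    shift = np.zeros(len(df))
    cond_truth = truth.peaks[truth.peaks["condition"] == condition]
    for i, row in df.iterrows():
        hits = cond_truth[
            (cond_truth["chrom"] == row["chrom"])
            & (cond_truth["start"] < row["end"])
            & (cond_truth["end"] > row["start"])
        ]
        if len(hits):
            shift[i] = log2fc * np.log(2) * (1 if hits.iloc[0]["direction"] == "gain" else -1)
    is_case = np.array([1] * n_rep + [0] * n_rep)
    logmu = base[:, None] + shift[:, None] * is_case[None, :]
    mu = np.exp(logmu)
    alpha = 0.05
    r = 1.0 / alpha
    counts = rng.negative_binomial(r, r / (r + mu))
    ids = [f"{condition}_chip_{'case' if c else 'ctrl'}{i % n_rep + 1}" for i, c in enumerate(is_case)]
    names = df["name"].tolist()  # consensus peak ids
    meta = pd.DataFrame(
        {"condition": np.where(is_case == 1, "case", "control"),
         "dataset": f"{condition}_chip"},
        index=pd.Index(ids, name="sample"),
    )
    return CountMatrix(pd.DataFrame(counts, index=names, columns=ids), meta)


# ---------------------------------------------------------------------------
# gene sets for the enrichment stage


def simulate_gene_sets(
    truth: GroundTruth,
    config: SimulationConfig,
    n_random: int = 40,
    set_size_range: tuple[int, int] = (15, 120),
) -> dict[str, tuple[str, list[str]]]:
    """Term collection: one term per planted module + DE terms + random terms."""
    rng = _spawn(config.seed, "genesets")
    genes = np.array(config.gene_ids)
    sets: dict[str, tuple[str, list[str]]] = {}
    for mid, row in truth.module_info.iterrows():
        members = list(truth.modules.index[truth.modules == mid])
        extra = list(rng.choice(genes, size=max(3, len(members) // 10), replace=False))
        sets[f"MODULE_{mid}"] = (f"planted module {mid} programme", sorted(set(members + extra)))
    for cond in CONDITIONS:
        up = [g for g, d in truth.de_directions(cond).items() if d == 1]
        down = [g for g, d in truth.de_directions(cond).items() if d == -1]
        if up:
            sets[f"DE_UP_{cond.upper()}"] = (f"{cond} induced genes", sorted(up))
        if down:
            sets[f"DE_DOWN_{cond.upper()}"] = (f"{cond} repressed genes", sorted(down))
    lo, hi = set_size_range
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_{i:03d}"] = (f"random set {i}", sorted(rng.choice(genes, size=size, replace=False)))
    return sets


# ---------------------------------------------------------------------------
# the bundled study


def default_config(seed: int = 0) -> SimulationConfig:
    """The bundled two-condition synthetic study.

    2 conditions x 2 datasets, 2000 genes, 40 samples per condition,
    5 planted modules (3 shared across conditions, 2 exposure-specific)
    at loading 0.8, planted DE genes at |log2FC| = 2, and planted
    promoter/enhancer peak gains and losses.
    """
    # factor shift chosen so |member log2FC| = 2 at loading 0.8
    shift = 2.0 * float(np.log(2.0)) / 0.8
    modules = [
        ModuleSpec(1, 200, True, 0.8, trait_shift=shift),
        ModuleSpec(2, 150, True, 0.8, trait_shift=-shift),
        ModuleSpec(3, 120, True, 0.8, trait_shift=shift),
        ModuleSpec(4, 80, False, 0.8, condition="exposure", trait_shift=-shift),
        ModuleSpec(5, 50, False, 0.8, condition="exposure", trait_shift=shift),
    ]
    width = len(str(2000 - 1))
    gid = lambda i: f"g{i:0{width}d}"

    de: list[DESpec] = []
    rng = _spawn(seed, "default-de")
    cursor = sum(m.size for m in modules)
    background = list(range(cursor, 2000))
    standalone = rng.choice(background, size=170, replace=False)
    both_up, both_down, disc, exp_only, dis_only = np.split(standalone, [40, 80, 110, 140])
    for i in both_up:
        de.append(DESpec(gid(i), CONDITIONS, 2.0))
    for i in both_down:
        de.append(DESpec(gid(i), CONDITIONS, -2.0))
    for i in disc:  # opposite directions: populates the discordant bin
        de.append(DESpec(gid(i), ("exposure",), 2.0))
        de.append(DESpec(gid(i), ("disease",), -2.0))
    for i in exp_only:
        de.append(DESpec(gid(i), ("exposure",), 2.0))
    for i in dis_only:
        de.append(DESpec(gid(i), ("disease",), -2.0))

    # promoter peaks: some on DE genes (matching sign), some ChIP-only
    peaks: list[PeakSpecEntry] = []
    de_by_cond = {c: {} for c in CONDITIONS}
    for spec in de:
        for c in spec.conditions:
            de_by_cond[c][spec.gene] = spec.direction
    chip_only = [i for i in background if gid(i) not in {s.gene for s in de}]
    rng2 = _spawn(seed, "default-peaks")
    mod_cursor = 0
    mod_ranges = {}
    for mod in modules:
        mod_ranges[mod.module_id] = (mod_cursor, mod_cursor + mod.size, mod)
        mod_cursor += mod.size
    for cond in CONDITIONS:
        on_de = rng2.choice(sorted(de_by_cond[cond]), size=25, replace=False)
        for g in on_de:
            peaks.append(PeakSpecEntry(g, "promoter",
                                       "gain" if de_by_cond[cond][g] == 1 else "loss", cond))
        # acetylation changes on module-member promoters, matching the
        # module's expression direction in this condition
        for lo, hi, mod in mod_ranges.values():
            if not (mod.shared or mod.condition == cond):
                continue
            for i in rng2.choice(range(lo, hi), size=3, replace=False):
                peaks.append(PeakSpecEntry(
                    gid(i), "promoter",
                    "gain" if mod.member_log2fc > 0 else "loss", cond))
        extra = rng2.choice(chip_only, size=15, replace=False)
        chip_only = [i for i in chip_only if i not in set(extra)]
        for i in extra:
            peaks.append(PeakSpecEntry(gid(i), "promoter",
                                       "gain" if rng2.random() < 0.5 else "loss", cond))
    return SimulationConfig(modules=modules, de=de, peaks=peaks, seed=seed)


def simulate_study(config: SimulationConfig):
    """Generate every input of the bundled study from one config.

    Returns (datasets, truth, annotation, enhancer_db, peaksets, gene_sets).
    Enhancer peak entries are auto-planted on genes whose enhancers survive
    the default association filter.
    """
    datasets, truth = simulate_counts(config)
    annotation, db = simulate_annotation(config)
    if not any(p.element == "enhancer" for p in config.peaks):
        plant_enhancer_peaks(config, annotation, db)
    peaksets, truth = simulate_peaks(annotation, truth, config, db=db)
    gene_sets = simulate_gene_sets(truth, config)
    return datasets, truth, annotation, db, peaksets, gene_sets
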