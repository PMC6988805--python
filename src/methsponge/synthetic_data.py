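"""Synthetic multi-omics generator with planted ground truth.

Emulates the input shapes of a tumor/normal multi-omics sponge-circRNA
study — miRNA and gene expression matrices, 450K-style probe methylation
with annotation, circRNA coordinates, circRNA-miRNA and site-resolved
miRNA-gene interactions, a driver-gene list, and clinical survival — and
plants the structure every downstream stage is meant to recover:

* differentially expressed miRNAs and genes (tumor/normal fold change
  ``effect_fc``),
* co-methylated, differentially methylated circRNA host-gene modules
  (a shared per-module latent factor),
* true sponge circRNA-driver pairs: >= 8 unique shared target sites,
  positively correlated host/promoter methylation, and promoter methylation
  negatively coupled (strength ``coupling_rho``) to driver expression,
* decoy circRNA-driver pairs capped at <= 3 unique shared sites,
* survival times with hazard proportional to exp(beta . x) over the sponge
  host-gene methylation.

Everything is deterministic under ``SimulationConfig.rng_seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .types import (
    CircRNAAnnotation,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    GroundTruth,
    InteractionTables,
    MethylationProfile,
    NORMAL,
    ProbeAnnotation,
    SEED_ALPHABET,
    SEED_LENGTH,
    SimulationConfig,
    TUMOR,
    ValidationError,
)

N_SPONGE_MIRNAS = 10  # shared miRNAs (and unique sites) per planted pair
N_DECOY_MIRNAS_PER_DRIVER = 3  # caps decoy pairs at 3 unique sites
N_MODULE_MIRNAS = 3  # common DE miRNAs gluing each module into a CC clique
DECOY_DRIVERS_PER_CIRC = 4
SMALL_SEED_POOL = 20  # decoy/background seeds drawn from a small pool


def _sub_seed(cfg: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, tag)))


def sample_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], pd.Series]:
    tumor = [f"T{i:03d}" for i in range(1, cfg.n_tumor + 1)]
    normal = [f"N{i:03d}" for i in range(1, cfg.n_normal + 1)]
    groups = pd.Series(
        [TUMOR] * len(tumor) + [NORMAL] * len(normal), index=tumor + normal,
        name="group",
    )
    return tumor, normal, groups


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


def _draw_seed(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(SEED_ALPHABET), size=SEED_LENGTH))


@dataclass
class _Plan:
    """Deterministic layout shared between the generator stages."""

    mirnas: list[str]
    circs: list[str]
    genes: list[str]
    drivers: list[str]
    module_circs: list[list[str]]  # per planted module
    sponge_pairs: list[tuple[str, str]]
    decoy_pairs: list[tuple[str, str]]
    sponge_mirnas: dict[tuple[str, str], list[str]]
    decoy_mirnas: dict[str, list[str]]  # per driver
    module_mirnas: list[list[str]]
    background_mirnas: list[str]
    de_mirnas: set[str]
    de_genes: set[str]
    host_of: dict[str, str]
    module_of_circ: dict[str, int]


def _layout(cfg: SimulationConfig) -> _Plan:
    cfg.validate()
    mirnas = _ids("miR-", cfg.n_mirna)
    circs = _ids("circ_", cfg.n_circ)
    genes = _ids("G", cfg.n_gene)
    drivers = genes[: cfg.n_driver]

    n_module_circ = cfg.n_planted_modules * cfg.module_size
    module_circs = [
        circs[m * cfg.module_size : (m + 1) * cfg.module_size]
        for m in range(cfg.n_planted_modules)
    ]
    module_of_circ = {
        c: m for m, members in enumerate(module_circs) for c in members
    }
    # planted pairs: module circRNAs round-robin over modules, matched with
    # the first drivers
    flat = list(
        itertools.chain.from_iterable(
            itertools.zip_longest(*module_circs)
        )
    ) if module_circs else list(circs)
    flat = [c for c in flat if c is not None]
    sponge_circs = flat[: cfg.n_planted_pairs]
    sponge_pairs = list(zip(sponge_circs, drivers[: cfg.n_planted_pairs]))

    # dedicated miRNA blocks, in deterministic id order
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        if cursor + k > len(mirnas):
            raise ValidationError(
                "n_mirna too small for the planted interaction structure"
            )
        block = mirnas[cursor : cursor + k]
        cursor += k
        return block

    sponge_mirnas = {pair: take(N_SPONGE_MIRNAS) for pair in sponge_pairs}
    decoy_mirnas = {g: take(N_DECOY_MIRNAS_PER_DRIVER) for g in drivers}
    module_mirnas = [take(N_MODULE_MIRNAS) for _ in range(cfg.n_planted_modules)]
    background_mirnas = mirnas[cursor:]

    # decoy pairs: each module circRNA interacts with the decoy miRNAs of a
    # fixed rotation of drivers (its planted partner excluded)
    planted = set(sponge_pairs)
    decoy_pairs = []
    mod_circ_list = [c for members in module_circs for c in members]
    for i, c in enumerate(mod_circ_list):
        picked = 0
        j = 0
        while picked < min(DECOY_DRIVERS_PER_CIRC, len(drivers)) and j < len(drivers):
            g = drivers[(i + j) % len(drivers)]
            j += 1
            if (c, g) in planted:
                continue
            decoy_pairs.append((c, g))
            picked += 1

    de_mirnas = (
        set(itertools.chain.from_iterable(sponge_mirnas.values()))
        | set(itertools.chain.from_iterable(decoy_mirnas.values()))
        | set(itertools.chain.from_iterable(module_mirnas))
        | set(background_mirnas[: len(background_mirnas) // 3])
    )
    # all drivers plus a slice of other genes are differentially expressed
    other = [g for g in genes if g not in drivers]
    de_genes = set(drivers) | set(other[: len(other) // 3])

    host_of = {c: f"HOST{c[-3:]}" for c in circs}
    return _Plan(
        mirnas=mirnas, circs=circs, genes=genes, drivers=drivers,
        module_circs=module_circs, sponge_pairs=sponge_pairs,
        decoy_pairs=decoy_pairs, sponge_mirnas=sponge_mirnas,
        decoy_mirnas=decoy_mirnas, module_mirnas=module_mirnas,
        background_mirnas=background_mirnas, de_mirnas=de_mirnas,
        de_genes=de_genes, host_of=host_of, module_of_circ=module_of_circ,
    )


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def simulate_interactions(
    cfg: SimulationConfig,
) -> tuple[InteractionTables, GroundTruth]:
    """Bipartite circRNA-miRNA edges and site-resolved miRNA-gene edges.

    Each planted sponge pair shares ``N_SPONGE_MIRNAS`` miRNAs with distinct
    seeds, hence >= 8 unique sites on its driver; decoy pairs share at most
    3 miRNAs whose (gene, seed)-determined sites cap them at 3 unique
    positions.  Same-seed miRNAs targeting the same gene always hit the
    same site position.
    """
    plan = _layout(cfg)
    rng = _sub_seed(cfg, 1)

    seeds: dict[str, str] = {}
    # sponge miRNAs: seeds distinct within a pair (guarantees >= 8 sites)
    for pair, block in plan.sponge_mirnas.items():
        used: set[str] = set()
        for m in block:
            s = _draw_seed(rng)
            while s in used:
                s = _draw_seed(rng)
            used.add(s)
            seeds[m] = s
    # everything else draws from a small pool -> exercises seed collisions
    pool = []
    while len(pool) < SMALL_SEED_POOL:
        s = _draw_seed(rng)
        if s not in pool:
            pool.append(s)
    for m in plan.mirnas:
        if m not in seeds:
            seeds[m] = pool[int(rng.integers(len(pool)))]

    # site positions: one per (gene, seed)
    site_counter: dict[str, int] = {}
    site_of: dict[tuple[str, str], int] = {}

    def site(gene: str, seed: str) -> int:
        key = (gene, seed)
        if key not in site_of:
            site_counter[gene] = site_counter.get(gene, 0) + 1
            site_of[key] = 100 * site_counter[gene]
        return site_of[key]

    cm_edges: set[tuple[str, str]] = set()
    mg_edges: set[tuple[str, str, int, str]] = set()

    for (circ, driver), block in plan.sponge_mirnas.items():
        for m in block:
            cm_edges.add((circ, m))
            mg_edges.add((m, driver, site(driver, seeds[m]), seeds[m]))
    for circ, driver in plan.decoy_pairs:
        for m in plan.decoy_mirnas[driver]:
            cm_edges.add((circ, m))
            mg_edges.add((m, driver, site(driver, seeds[m]), seeds[m]))
    for mod, members in enumerate(plan.module_circs):
        for m in plan.module_mirnas[mod]:
            for circ in members:
                cm_edges.add((circ, m))
    # background: non-module circRNAs pick up a few background miRNAs so the
    # CC network has sparse structure outside the planted modules
    non_module = [c for c in plan.circs if c not in plan.module_of_circ]
    for circ in non_module:
        k = int(rng.integers(1, 4))
        for m in rng.choice(plan.background_mirnas, size=min(k, len(plan.background_mirnas)), replace=False):
            cm_edges.add((circ, str(m)))
    # background miRNAs also target a few non-driver genes
    non_driver = [g for g in plan.genes if g not in plan.drivers]
    for m in plan.background_mirnas:
        k = int(rng.integers(0, 3))
        for g in rng.choice(non_driver, size=min(k, len(non_driver)), replace=False):
            mg_edges.add((m, str(g), site(str(g), seeds[m]), seeds[m]))

    circ_mirna = pd.DataFrame(
        sorted(cm_edges), columns=["circ_id", "mirna_id"]
    )
    mirna_gene = pd.DataFrame(
        sorted(mg_edges), columns=["mirna_id", "gene_id", "site_pos", "seed"]
    )
    tables = InteractionTables(circ_mirna, mirna_gene).validate()
    truth = GroundTruth(
        true_de_mirnas=set(plan.de_mirnas),
        true_dm_circ_hosts={plan.host_of[c] for c in plan.module_of_circ},
        true_modules=[set(members) for members in plan.module_circs],
        true_sponge_pairs=list(plan.sponge_pairs),
        true_decoy_pairs=list(plan.decoy_pairs),
    )
    return tables, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

#: magnitudes of the methylation model (beta-value scale)
HOST_BASE_LO, HOST_BASE_HI = 0.30, 0.40  # normal-group host-gene baseline
DM_SHIFT = 0.28  # tumor shift of module host genes (fold change ~ 1.7)
MODULE_LOADING = 0.15  # loading on the shared per-module factor
LATENT_SD = 0.05  # residual sd of the gene-level latent
PROMOTER_LOADING = 0.15  # planted-driver promoter loading on its module factor


@dataclass
class MethylationOutput:
    probes: MethylationProfile
    annotation: ProbeAnnotation
    circ_annotation: CircRNAAnnotation
    gene_annotation: GeneAnnotation
    host_latent: pd.DataFrame  # gene-level latent betas, hosts x samples
    promoter_latent: pd.DataFrame  # drivers x samples


def simulate_methylation(
    cfg: SimulationConfig, truth: GroundTruth
) -> MethylationOutput:
    """Probe-level betas plus annotation, with planted structure.

    Per gene, a latent beta per sample; probes of the gene are the latent
    plus N(0, ``meth_noise_sd``) noise, clipped to [0, 1] — multiple
    adjacent CpGs share one pattern.  Module host genes load on a shared
    per-module factor (pairwise latent r > 0.6) and are shifted in tumor
    samples; planted drivers' promoter latents load on the same factor as
    their partner circRNA's module.  The annotation carries deliberately
    bad probes (missing values, multi-gene, sex-chromosome, SNP) for the
    filter chain.
    """
    plan = _layout(cfg)
    rng = _sub_seed(cfg, 2)
    tumor, normal, groups = sample_ids(cfg)
    samples = tumor + normal
    n_s = len(samples)
    is_tumor = np.array([s in set(tumor) for s in samples], dtype=float)

    factors = rng.normal(size=(cfg.n_planted_modules, n_s))

    host_latent = {}
    for circ in plan.circs:
        host = plan.host_of[circ]
        base = rng.uniform(HOST_BASE_LO, HOST_BASE_HI)
        lat = base + LATENT_SD * rng.normal(size=n_s)
        mod = plan.module_of_circ.get(circ)
        if mod is not None:
            lat = lat + DM_SHIFT * is_tumor + MODULE_LOADING * factors[mod]
        host_latent[host] = np.clip(lat, 0.01, 0.99)
    host_latent = pd.DataFrame(host_latent, index=samples).T

    sponge_module = {g: plan.module_of_circ[c] for c, g in plan.sponge_pairs}
    promoter_latent = {}
    gene_body_latent = {}
    for g in plan.drivers:
        base = rng.uniform(0.30, 0.50)
        lat = base + LATENT_SD * rng.normal(size=n_s)
        if g in sponge_module:
            lat = lat + PROMOTER_LOADING * factors[sponge_module[g]]
        promoter_latent[g] = np.clip(lat, 0.01, 0.99)
        gene_body_latent[g] = np.clip(
            rng.uniform(0.3, 0.7) + LATENT_SD * rng.normal(size=n_s), 0.01, 0.99
        )
    promoter_latent = pd.DataFrame(promoter_latent, index=samples).T

    # ---- genomic layout -------------------------------------------------
    circ_rows, gene_rows, probe_rows, beta_rows = [], [], [], []
    autosomes = [f"chr{i}" for i in range(1, 23)]
    probe_idx = 0

    def add_probe(chrom, pos, genes_tuple, snp, betas):
        nonlocal probe_idx
        probe_idx += 1
        pid = f"cg{probe_idx:08d}"
        probe_rows.append((pid, chrom, pos, genes_tuple, snp))
        beta_rows.append((pid, betas))

    for i, circ in enumerate(plan.circs):
        host = plan.host_of[circ]
        chrom = autosomes[i % len(autosomes)]
        start = 100_000 + 50_000 * i
        end = start + 2_000
        circ_rows.append((circ, host, chrom, start + 200, end - 200, "+"))
        lat = host_latent.loc[host].to_numpy()
        for k in range(3):  # 3 body probes per host gene
            betas = np.clip(lat + cfg.meth_noise_sd * rng.normal(size=n_s), 0, 1)
            add_probe(chrom, start + 400 + 400 * k, (host,), False, betas)

    for j, g in enumerate(plan.drivers):
        chrom = autosomes[j % len(autosomes)]
        tss = 5_000_000 + 100_000 * j
        strand = "+" if j % 2 == 0 else "-"
        gene_rows.append((g, chrom, strand, tss))
        sgn = 1 if strand == "+" else -1
        lat_p = promoter_latent.loc[g].to_numpy()
        # promoter probes inside [TSS-1500, TSS+500] (strand-mirrored)
        for off in (-1_000, -200, 300):
            betas = np.clip(lat_p + cfg.meth_noise_sd * rng.normal(size=n_s), 0, 1)
            add_probe(chrom, tss + sgn * off, (g,), False, betas)
        # gene-body probes outside the window, distinct signal
        lat_b = gene_body_latent[g]
        for off in (3_000, 5_000):
            betas = np.clip(lat_b + cfg.meth_noise_sd * rng.normal(size=n_s), 0, 1)
            add_probe(chrom, tss + sgn * off, (g,), False, betas)

    # ---- deliberately bad probes ---------------------------------------
    filler = np.clip(0.5 + 0.1 * rng.normal(size=n_s), 0, 1)
    na_betas = filler.copy()
    na_betas[0] = np.nan
    add_probe("chr1", 10_000, (plan.host_of[plan.circs[0]],), False, na_betas)
    add_probe("chr1", 11_000,
              (plan.host_of[plan.circs[0]], plan.host_of[plan.circs[1]]),
              False, filler)
    add_probe("chrX", 12_000, (plan.host_of[plan.circs[0]],), False, filler)
    add_probe("chrY", 13_000, (plan.host_of[plan.circs[1]],), False, filler)
    add_probe("chr2", 14_000, (plan.host_of[plan.circs[2]],), True, filler)

    probes_df = pd.DataFrame(
        {pid: b for pid, b in beta_rows}, index=samples
    ).T
    probes_df.index.name = "feature"
    ann = ProbeAnnotation(
        pd.DataFrame(
            [(p, c, pos, g, s) for p, c, pos, g, s in probe_rows],
            columns=["probe_id", "chrom", "pos", "genes", "snp_overlap"],
        ).set_index("probe_id")
    ).validate()
    circ_ann = CircRNAAnnotation(
        pd.DataFrame(
            circ_rows,
            columns=["circ_id", "host_gene", "chrom", "start", "end", "strand"],
        )
    ).validate()
    gene_ann = GeneAnnotation(
        pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss"])
        .set_index("gene_id")
    ).validate()
    profile = MethylationProfile(probes_df, "probe", groups).validate()
    return MethylationOutput(
        probes=profile, annotation=ann, circ_annotation=circ_ann,
        gene_annotation=gene_ann, host_latent=host_latent,
        promoter_latent=promoter_latent,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

EXPR_LOG2_SD = 0.5  # within-group sd on the log2 scale
EXPR_BASE_LO, EXPR_BASE_HI = 4.0, 8.0  # log2 baseline abundance


def simulate_expression(
    cfg: SimulationConfig,
    truth: GroundTruth,
    promoter_latent: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """miRNA and gene expression matrices with planted fold changes.

    Log-normal counts: value = 2 ** (base + log2(effect_fc) * tumor +
    EXPR_LOG2_SD * noise).  Planted differential features alternate between
    up- and down-regulation.  Planted drivers' log2 expression mixes in the
    standardised promoter latent with weight ``-coupling_rho`` so promoter
    methylation and expression are negatively correlated in tumor samples.
    """
    plan = _layout(cfg)
    rng = _sub_seed(cfg, 3)
    tumor, normal, groups = sample_ids(cfg)
    samples = tumor + normal
    n_s = len(samples)
    is_tumor = np.array([s in set(tumor) for s in samples], dtype=float)
    log_fc = np.log2(cfg.effect_fc)
    rho = cfg.coupling_rho

    def expr_rows(features, de_set, coupled: dict[str, np.ndarray]):
        rows = {}
        for i, f in enumerate(features):
            base = rng.uniform(EXPR_BASE_LO, EXPR_BASE_HI)
            noise = rng.normal(size=n_s)
            if f in coupled:
                w = coupled[f]
                w = (w - w.mean()) / (w.std() if w.std() > 0 else 1.0)
                noise = -rho * w + np.sqrt(max(0.0, 1 - rho**2)) * noise
            shift = 0.0
            if f in de_set:
                shift = log_fc if i % 2 == 0 else -log_fc
            rows[f] = 2.0 ** (base + shift * is_tumor + EXPR_LOG2_SD * noise)
        return pd.DataFrame(rows, index=samples).T

    mirna_values = expr_rows(plan.mirnas, truth.true_de_mirnas, {})
    coupled = {}
    if promoter_latent is not None:
        for _, g in plan.sponge_pairs:
            if g in promoter_latent.index:
                coupled[g] = promoter_latent.loc[g].to_numpy()
    gene_values = expr_rows(plan.genes, plan.de_genes, coupled)
    mirna_values.index.name = "feature"
    gene_values.index.name = "feature"
    return (
        ExpressionMatrix(mirna_values, groups).validate(),
        ExpressionMatrix(gene_values, groups).validate(),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

BASELINE_HAZARD = 1.0 / 1500.0  # exponential baseline, per day


def simulate_survival(
    cfg: SimulationConfig,
    meth: MethylationProfile,
    covariates: list[str] | None = None,
) -> tuple[ClinicalTable, pd.Series]:
    """Tumor-sample survival with hazard exp(beta . x) over methylation.

    Event times are exponential with per-sample rate
    ``BASELINE_HAZARD * exp(sum_i beta_i x_i)`` (centred covariates);
    censoring is independent per sample with probability ``censor_rate``
    (competing exponential censor time).  Returns the clinical table and
    the true per-sample linear predictor (risk ordering).
    """
    cfg.validate()
    rng = _sub_seed(cfg, 4)
    tumor, _, _ = sample_ids(cfg)
    cols = [s for s in meth.values.columns if s in set(tumor)]
    if not cols:
        raise ValidationError("simulate_survival needs tumor samples in the profile")
    covariates = covariates or list(meth.values.index)
    beta = np.asarray(cfg.survival_beta, float)[: len(covariates)]
    if len(beta) < len(covariates):
        covariates = covariates[: len(beta)]
    x = meth.values.loc[covariates, cols].to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    lp = beta @ xc
    rate = BASELINE_HAZARD * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    if cfg.censor_rate >= 1.0:
        time = rng.exponential(1.0 / rate)
        event = np.zeros_like(time, dtype=int)
    elif cfg.censor_rate <= 0.0:
        time, event = event_time, np.ones_like(event_time, dtype=int)
    else:
        c_rate = rate * cfg.censor_rate / (1.0 - cfg.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-3)
    table = pd.DataFrame({"time": time, "event": event}, index=cols)
    table.index.name = "sample"
    clinical = ClinicalTable(table).validate()
    risk = pd.Series(lp, index=cols, name="linear_predictor")
    return clinical, risk


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    truth: GroundTruth
    interactions: InteractionTables
    mirna_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    meth_probes: MethylationProfile
    probe_annotation: ProbeAnnotation
    circ_annotation: CircRNAAnnotation
    gene_annotation: GeneAnnotation
    driver_list: set[str]
    clinical: ClinicalTable
    groups: pd.Series


def simulate_all(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate every pipeline input in dependency order."""
    cfg.validate()
    plan = _layout(cfg)
    interactions, truth = simulate_interactions(cfg)
    meth = simulate_methylation(cfg, truth)
    mirna_expr, gene_expr = simulate_expression(
        cfg, truth, promoter_latent=meth.promoter_latent
    )
    sponge_hosts = [plan.host_of[c] for c, _ in plan.sponge_pairs]
    host_profile = MethylationProfile(
        meth.host_latent.loc[sponge_hosts], "gene"
    ).validate() if sponge_hosts else MethylationProfile(
        meth.host_latent.iloc[:1], "gene"
    ).validate()
    clinical, risk = simulate_survival(cfg, host_profile)
    truth.true_pi_ranks = risk
    _, _, groups = sample_ids(cfg)
    return SyntheticDataset(
        cfg=cfg, truth=truth, interactions=interactions,
        mirna_expr=mirna_expr, gene_expr=gene_expr,
        meth_probes=meth.probes, probe_annotation=meth.annotation,
        circ_annotation=meth.circ_annotation,
        gene_annotation=meth.gene_annotation,
        driver_list=set(plan.drivers), clinical=clinical, groups=groups,
    )


def write_dataset(data: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every table in the io module's formats; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "groups": out / "groups.tsv",
        "mirna_expr": out / "mirna_expression.tsv",
        "gene_expr": out / "gene_expression.tsv",
        "meth_probes": out / "methylation_probes.tsv",
        "probe_annotation": out / "probe_annotation.tsv",
        "circ_annotation": out / "circ_annotation.bed",
        "gene_annotation": out / "gene_annotation.tsv",
        "circ_mirna": out / "circ_mirna.tsv",
        "mirna_gene": out / "mirna_gene.tsv",
        "driver_list": out / "driver_genes.txt",
        "clinical": out / "clinical.tsv",
    }
    msio.write_groups(data.groups, paths["groups"])
    msio.write_matrix(data.mirna_expr, paths["mirna_expr"])
    msio.write_matrix(data.gene_expr, paths["gene_expr"])
    msio.write_matrix(data.meth_probes, paths["meth_probes"])
    msio.write_probe_annotation(data.probe_annotation, paths["probe_annotation"])
    msio.write_bed_like(data.circ_annotation, paths["circ_annotation"])
    msio.write_gene_annotation(data.gene_annotation, paths["gene_annotation"])
    msio.write_interactions(data.interactions, paths["circ_mirna"], paths["mirna_gene"])
    msio.write_driver_list(data.driver_list, paths["driver_list"])
    msio.write_clinical(data.clinical, paths["clinical"])
    return paths
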