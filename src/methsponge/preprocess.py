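"""Probe filtering and methylation aggregation.

The 450K-style probe matrix is reduced to analysable features in two steps:
a hard filter (drop probes with any missing value, probes annotated to more
than one gene, probes on sex chromosomes, and probes overlapping SNPs),
then averaging of the surviving probes per host gene, or per promoter
window (TSS-1500 .. TSS+500, strand-aware) for driver genes.  Expression is
log2(x + 1) transformed for display and correlation work.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    CircRNAAnnotation,
    ExpressionMatrix,
    GeneAnnotation,
    MethylationProfile,
    ProbeAnnotation,
    SEX_CHROMOSOMES,
    ValidationError,
)

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500  # bp upstream of TSS (inclusive endpoint)
PROMOTER_DOWNSTREAM = 500  # bp downstream of TSS (inclusive endpoint)


def filter_probes(
    probes: MethylationProfile, ann: ProbeAnnotation
) -> MethylationProfile:
    """Keep only clean probes: complete, single-gene, autosomal, SNP-free.

    Row order of the surviving probes is preserved.  Probes present in the
    profile but absent from the annotation are an error (the filter cannot
    judge them).
    """
    if probes.resolution != "probe":
        raise ValidationError("filter_probes expects a probe-resolution profile")
    unknown = probes.values.index.difference(ann.table.index)
    if len(unknown):
        raise ValidationError(
            f"probes missing from annotation: {list(unknown[:10])}"
        )
    sub = ann.table.loc[probes.values.index]
    complete = ~probes.values.isna().any(axis=1)
    single_gene = sub["genes"].map(len) == 1
    autosomal = ~sub["chrom"].isin(SEX_CHROMOSOMES)
    no_snp = ~sub["snp_overlap"]
    keep = complete & single_gene & autosomal & no_snp
    dropped = probes.values.index[~keep]
    if len(dropped):
        log.info(
            "filter_probes dropped %d/%d probes (missing=%d, multigene=%d, "
            "sex-chrom=%d, snp=%d)",
            len(dropped), len(keep),
            int((~complete).sum()), int((~single_gene).sum()),
            int((~autosomal).sum()), int((~no_snp).sum()),
        )
    if not keep.any():
        log.warning("filter_probes: no probes survived the filter chain")
    return MethylationProfile(
        probes.values.loc[keep], "probe", probes.groups
    ).validate()


def _aggregate(values: pd.DataFrame, probe_gene: pd.Series,
               resolution: str, groups) -> MethylationProfile:
    gene_means = values.groupby(probe_gene).mean()
    gene_means.index.name = "feature"
    return MethylationProfile(gene_means, resolution, groups).validate()


def aggregate_gene_methylation(
    probes: MethylationProfile,
    ann: ProbeAnnotation,
    regions: CircRNAAnnotation | GeneAnnotation | None = None,
) -> MethylationProfile:
    """Average member-probe betas per gene (unweighted mean).

    A gene's methylation is the mean beta of the probes annotated to it.
    If ``regions`` is given, output is restricted to its gene universe;
    genes with no surviving probe are dropped and reported.
    """
    sub = ann.table.loc[probes.values.index]
    probe_gene = sub["genes"].map(lambda g: g[0] if len(g) == 1 else None)
    usable = probe_gene.notna()
    out = _aggregate(probes.values.loc[usable], probe_gene[usable],
                     "gene", probes.groups)
    if regions is not None:
        if isinstance(regions, CircRNAAnnotation):
            wanted = pd.Index(sorted(set(regions.table["host_gene"])))
        else:
            wanted = regions.table.index.sort_values()
        lost = wanted.difference(out.values.index)
        if len(lost):
            log.warning(
                "aggregate_gene_methylation: %d genes with no surviving probe: %s",
                len(lost), list(lost[:10]),
            )
        out = MethylationProfile(
            out.values.loc[wanted.intersection(out.values.index)],
            "gene", probes.groups,
        ).validate()
    return out


def promoter_methylation(
    probes: MethylationProfile,
    ann: ProbeAnnotation,
    genes: GeneAnnotation,
) -> MethylationProfile:
    """Average betas over the promoter window of each gene.

    The window is [TSS-1500, TSS+500] on the + strand (both endpoints
    inclusive) and its mirror [TSS-500, TSS+1500] on the - strand, so that
    "upstream" always means against the direction of transcription.  Genes
    whose window contains no surviving probe are dropped and reported.
    """
    sub = ann.table.loc[probes.values.index]
    rows = {}
    empty = []
    for gene_id, rec in genes.table.iterrows():
        tss, strand, chrom = rec["tss"], rec["strand"], rec["chrom"]
        if strand == "+":
            lo, hi = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
        else:
            lo, hi = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
        in_window = (
            (sub["chrom"] == chrom) & (sub["pos"] >= lo) & (sub["pos"] <= hi)
        )
        if not in_window.any():
            empty.append(gene_id)
            continue
        rows[gene_id] = probes.values.loc[in_window].mean(axis=0)
    if empty:
        log.warning(
            "promoter_methylation: %d genes with empty promoter window: %s",
            len(empty), empty[:10],
        )
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "feature"
    if values.empty:
        values = pd.DataFrame(
            index=pd.Index([], name="feature"), columns=probes.values.columns
        ).astype(float)
    return MethylationProfile(values, "promoter", probes.groups).validate()


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) on every cell; the pseudo-count keeps zeros finite."""
    if (expr.values.values < 0).any():
        raise ValidationError("log_transform requires non-negative values")
    return ExpressionMatrix(np.log2(expr.values + 1.0), expr.groups).validate()
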