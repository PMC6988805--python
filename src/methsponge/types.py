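"""Typed in-memory containers shared across the pipeline.

All tabular payloads are pandas objects; the dataclasses add the domain
invariants (group labels, beta ranges, resolution flags) that plain frames
cannot express.  Validation happens at construction via ``validate()`` so
that malformed data fails close to where it entered the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
GROUPS = (TUMOR, NORMAL)

#: chromosomes accepted in probe annotation; sex chromosomes are listed so
#: the preprocessing filter can remove them explicitly.
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
SEX_CHROMOSOMES = ("chrX", "chrY")

SEED_LENGTH = 7  # miRNA seed: nucleotides 2-8
SEED_ALPHABET = "ACGU"


class ValidationError(ValueError):
    """A typed table violated one of its invariants."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Non-negative feature x sample abundance matrix with group labels."""

    values: pd.DataFrame
    groups: pd.Series  # index = sample ids, values in {tumor, normal}

    def validate(self) -> "ExpressionMatrix":
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        if (self.values.values < 0).any():
            bad = self.values.lt(0).any(axis=1)
            raise ValidationError(
                f"negative expression values, e.g. feature {self.values.index[bad][0]!r}"
            )
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValidationError(f"samples without group label: {list(missing[:5])}")
        bad_labels = set(self.groups.loc[self.values.columns]) - set(GROUPS)
        if bad_labels:
            raise ValidationError(f"unknown group labels: {sorted(bad_labels)}")
        return self

    def samples_in(self, group: str) -> list[str]:
        labels = self.groups.loc[self.values.columns]
        return list(labels.index[labels == group])


@dataclass
class MethylationProfile:
    """Beta-value matrix in [0, 1] at probe, gene or promoter resolution.

    Missing values (NA) are representable only at probe resolution, mirroring
    upstream array data before the filtering step removes them.
    """

    values: pd.DataFrame
    resolution: str  # probe | gene | promoter
    groups: pd.Series | None = None

    def validate(self) -> "MethylationProfile":
        if self.resolution not in ("probe", "gene", "promoter"):
            raise ValidationError(f"unknown resolution {self.resolution!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.values.astype(float)
        if np.isnan(arr).any() and self.resolution != "probe":
            raise ValidationError(
                f"NA values not allowed at {self.resolution} resolution"
            )
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            rows, cols = np.where((arr < 0) | (arr > 1))
            r, c = rows[0], cols[0]
            raise ValidationError(
                f"beta value {arr[r, c]} out of [0,1] at "
                f"feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if self.groups is not None:
            missing = self.values.columns.difference(self.groups.index)
            if len(missing):
                raise ValidationError(
                    f"samples without group label: {list(missing[:5])}"
                )
        return self

    def samples_in(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValidationError("profile carries no group labels")
        labels = self.groups.loc[self.values.columns]
        return list(labels.index[labels == group])


@dataclass
class ProbeAnnotation:
    """450K-style probe annotation: position, gene assignment, SNP flag.

    ``genes`` holds a tuple of gene ids per probe; probes mapping to more
    than one gene are removed by the preprocessing filter.
    """

    table: pd.DataFrame  # index probe id; columns: chrom, pos, genes, snp_overlap

    def validate(self) -> "ProbeAnnotation":
        _check_unique(self.table.index, "probe ids")
        required = {"chrom", "pos", "genes", "snp_overlap"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"probe annotation missing columns: {sorted(missing)}")
        bad_chrom = set(self.table["chrom"]) - set(CHROMOSOMES)
        if bad_chrom:
            raise ValidationError(f"unknown chromosomes: {sorted(bad_chrom)[:5]}")
        if (self.table["pos"] < 1).any():
            raise ValidationError("probe positions must be >= 1 (1-based)")
        return self


@dataclass
class CircRNAAnnotation:
    """circRNA genomic intervals (BED convention: 0-based, half-open)."""

    table: pd.DataFrame  # columns: circ_id, host_gene, chrom, start, end, strand

    def validate(self) -> "CircRNAAnnotation":
        _check_unique(pd.Index(self.table["circ_id"]), "circRNA ids")
        bad = self.table["start"] >= self.table["end"]
        if bad.any():
            rec = self.table[bad].iloc[0]
            raise ValidationError(
                f"circRNA {rec['circ_id']!r}: start {rec['start']} >= end {rec['end']}"
            )
        if not set(self.table["strand"]) <= {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")
        return self

    def host_of(self) -> dict[str, str]:
        return dict(zip(self.table["circ_id"], self.table["host_gene"]))


@dataclass
class GeneAnnotation:
    """Gene TSS positions (1-based) with strand, for promoter windows."""

    table: pd.DataFrame  # index gene id; columns: chrom, strand, tss

    def validate(self) -> "GeneAnnotation":
        _check_unique(self.table.index, "gene ids")
        if not set(self.table["strand"]) <= {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")
        if (self.table["tss"] < 1).any():
            raise ValidationError("TSS positions must be >= 1")
        return self


@dataclass
class InteractionTables:
    """Bipartite circRNA-miRNA edges and site-resolved miRNA-gene edges."""

    circ_mirna: pd.DataFrame  # columns: circ_id, mirna_id
    mirna_gene: pd.DataFrame  # columns: mirna_id, gene_id, site_pos, seed

    def validate(self) -> "InteractionTables":
        if self.circ_mirna.duplicated(["circ_id", "mirna_id"]).any():
            raise ValidationError("duplicate circRNA-miRNA edges")
        if self.mirna_gene.duplicated(["mirna_id", "gene_id", "site_pos"]).any():
            raise ValidationError("duplicate miRNA-gene site records")
        seeds = self.mirna_gene["seed"]
        bad = ~seeds.str.fullmatch(f"[{SEED_ALPHABET}]{{{SEED_LENGTH}}}")
        if bad.any():
            raise ValidationError(
                f"malformed seed sequences, e.g. {seeds[bad].iloc[0]!r} "
                f"(expected {SEED_LENGTH}-mer over {SEED_ALPHABET})"
            )
        # one miRNA, one seed
        per_mirna = self.mirna_gene.groupby("mirna_id")["seed"].nunique()
        if (per_mirna > 1).any():
            raise ValidationError(
                f"miRNA with inconsistent seed: {per_mirna[per_mirna > 1].index[0]!r}"
            )
        return self

    def mirnas_of_circ(self, circ_id: str) -> set[str]:
        sub = self.circ_mirna[self.circ_mirna["circ_id"] == circ_id]
        return set(sub["mirna_id"])

    def mirnas_of_gene(self, gene_id: str) -> set[str]:
        sub = self.mirna_gene[self.mirna_gene["gene_id"] == gene_id]
        return set(sub["mirna_id"])


@dataclass
class ClinicalTable:
    """Per-sample survival time (days) and event indicator."""

    table: pd.DataFrame  # index sample id; columns: time, event

    def validate(self) -> "ClinicalTable":
        _check_unique(self.table.index, "sample ids")
        if (self.table["time"] <= 0).any():
            bad = self.table.index[self.table["time"] <= 0][0]
            raise ValidationError(f"non-positive survival time for sample {bad!r}")
        if not set(self.table["event"].astype(int)) <= {0, 1}:
            raise ValidationError("event indicator must be 0/1")
        return self


@dataclass
class SimulationConfig:
    """Knobs of the synthetic multi-omics generator.

    The defaults are the study conditions every acceptance experiment runs
    under; see the methods note for the rationale behind each magnitude.
    """

    n_tumor: int = 60
    n_normal: int = 30
    n_mirna: int = 150
    n_circ: int = 40
    n_gene: int = 60
    n_driver: int = 15
    n_planted_pairs: int = 5
    n_planted_modules: int = 2
    module_size: int = 8
    effect_fc: float = 4.0
    meth_noise_sd: float = 0.05
    coupling_rho: float = 0.7
    survival_beta: tuple[float, ...] = (1.5, -1.5, 1.0, -1.0, 0.8)
    censor_rate: float = 0.3
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        counts = {
            "n_tumor": self.n_tumor, "n_normal": self.n_normal,
            "n_mirna": self.n_mirna, "n_circ": self.n_circ,
            "n_gene": self.n_gene, "n_driver": self.n_driver,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.n_planted_pairs < 0 or self.n_planted_modules < 0:
            raise ValidationError("planted counts must be non-negative")
        if self.n_planted_pairs > min(self.n_circ, self.n_driver):
            raise ValidationError(
                "n_planted_pairs exceeds available circRNAs or driver genes"
            )
        if self.n_planted_modules * self.module_size > self.n_circ:
            raise ValidationError("planted modules do not fit into n_circ circRNAs")
        if not (0 < self.meth_noise_sd < 1):
            raise ValidationError("meth_noise_sd must lie in (0, 1)")
        if not (-1 <= self.coupling_rho <= 1):
            raise ValidationError("coupling_rho must lie in [-1, 1]")
        if not (0 <= self.censor_rate <= 1):
            raise ValidationError("censor_rate must lie in [0, 1]")
        if self.effect_fc <= 0:
            raise ValidationError("effect_fc must be positive")
        return self


@dataclass
class GroundTruth:
    """Planted structure the generator guarantees, for parameter recovery."""

    true_de_mirnas: set[str] = field(default_factory=set)
    true_dm_circ_hosts: set[str] = field(default_factory=set)
    true_modules: list[set[str]] = field(default_factory=list)
    true_sponge_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_pi_ranks: pd.Series | None = None  # per-sample linear-predictor risk
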