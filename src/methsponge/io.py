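"""Tab-delimited readers and writers for every file shape the pipeline touches.

Formats
-------
* matrices: TSV, first column feature id, header row of sample ids
* group labels: two-column TSV ``sample<TAB>group``
* circRNA annotation: 6-column BED-like (chrom start end circ_id strand host_gene)
* gene annotation: TSV (gene_id chrom strand tss)
* probe annotation: TSV (probe_id chrom pos genes snp_overlap), genes ';'-joined
* interaction edge lists: 2-column circRNA-miRNA; 4-column miRNA-gene with
  site position and seed
* clinical: TSV (sample time event)

Everything is UTF-8, ``NA`` encodes missingness (probe-level methylation
only), and writes use a deterministic row order so reruns are
byte-comparable.  ``write . read`` is the identity on all typed tables.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CircRNAAnnotation,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    InteractionTables,
    MethylationProfile,
    ProbeAnnotation,
    ValidationError,
)

log = logging.getLogger(__name__)

NA = "NA"
# full float round-trip
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file failed structural validation; message names the offending cell."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", header=0, dtype=str,
                           na_values=[], keep_default_na=False)
    except Exception as exc:  # malformed TSV
        raise ParseError(f"{path}: cannot parse as TSV ({exc})") from exc


def _values_frame(raw: pd.DataFrame, path: Path, allow_na: bool) -> pd.DataFrame:
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: matrix needs a feature column and >=1 sample")
    feat_col = raw.columns[0]
    frame = raw.set_index(feat_col)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    if pd.Index(frame.columns).has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids in header")
    out = {}
    for col in frame.columns:
        s = frame[col].mask(frame[col] == NA)
        try:
            # astype(float) is correctly rounded (unlike pandas' fast parser),
            # which the full-precision round-trip contract needs
            out[col] = s.astype(float)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col!r}: {exc}")
    values = pd.DataFrame(out, index=frame.index)
    values.index.name = "feature"
    if not allow_na and values.isna().any().any():
        col = values.columns[values.isna().any()][0]
        row = values.index[values[col].isna()][0]
        raise ParseError(f"{path}: NA not permitted here (row {row!r}, column {col!r})")
    return values


def read_groups(path: str | Path) -> pd.Series:
    """Read the sample -> {tumor, normal} label map."""
    raw = _read_table(path)
    if raw.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns (sample, group)")
    s = pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values, name="group")
    if s.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    return s


def write_groups(groups: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"sample": groups.index, "group": groups.values})
    frame.to_csv(path, sep="\t", index=False)


def read_matrix(
    path: str | Path,
    kind: str,
    groups: pd.Series | str | Path | None = None,
    resolution: str = "probe",
) -> ExpressionMatrix | MethylationProfile:
    """Read a feature x sample TSV as a typed, validated matrix.

    Parameters
    ----------
    kind
        ``"expression"`` or ``"methylation"``.
    groups
        Sample group labels (Series or path to a groups TSV); required for
        expression, optional for methylation.
    resolution
        Methylation resolution flag; NA cells are accepted only at
        ``"probe"`` resolution.
    """
    path = Path(path)
    if isinstance(groups, (str, Path)):
        groups = read_groups(groups)
    if kind == "expression":
        if groups is None:
            raise ValueError("expression matrices require group labels")
        values = _values_frame(_read_table(path), path, allow_na=False)
        try:
            return ExpressionMatrix(values, groups).validate()
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if kind == "methylation":
        allow_na = resolution == "probe"
        values = _values_frame(_read_table(path), path, allow_na=allow_na)
        try:
            return MethylationProfile(values, resolution, groups).validate()
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(mat: ExpressionMatrix | MethylationProfile, path: str | Path) -> None:
    """Write a typed matrix as TSV (features sorted, ``NA`` for missing)."""
    values = mat.values.sort_index()
    values.to_csv(path, sep="\t", index_label="feature",
                  na_rep=NA, float_format=_FLOAT_FMT)


def read_bed_like(path: str | Path) -> CircRNAAnnotation:
    """Read circRNA intervals from a 6-column BED-like file.

    Columns: chrom, start, end, circ_id, strand, host_gene.  Coordinates are
    0-based half-open (BED convention); records with start >= end are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, start, end, circ_id, strand, host = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if start_i >= end_i:
                raise ParseError(
                    f"{path}:{lineno}: start {start_i} >= end {end_i} for {circ_id!r}"
                )
            rows.append((circ_id, host, chrom, start_i, end_i, strand))
    table = pd.DataFrame(
        rows, columns=["circ_id", "host_gene", "chrom", "start", "end", "strand"]
    )
    try:
        return CircRNAAnnotation(table).validate()
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed_like(ann: CircRNAAnnotation, path: str | Path) -> None:
    t = ann.table.sort_values("circ_id")
    bed = t[["chrom", "start", "end", "circ_id", "strand", "host_gene"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    raw = _read_table(path)
    required = ["gene_id", "chrom", "strand", "tss"]
    if list(raw.columns) != required:
        raise ParseError(f"{path}: expected columns {required}")
    table = raw.set_index("gene_id")
    table["tss"] = pd.to_numeric(table["tss"]).astype(int)
    try:
        return GeneAnnotation(table).validate()
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.sort_index().to_csv(path, sep="\t", index_label="gene_id")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    raw = _read_table(path)
    required = ["probe_id", "chrom", "pos", "genes", "snp_overlap"]
    if list(raw.columns) != required:
        raise ParseError(f"{path}: expected columns {required}")
    table = raw.set_index("probe_id")
    table["pos"] = pd.to_numeric(table["pos"]).astype(int)
    table["genes"] = [
        tuple(g for g in str(cell).split(";") if g) for cell in table["genes"]
    ]
    table["snp_overlap"] = table["snp_overlap"].map({"0": False, "1": True})
    if table["snp_overlap"].isna().any():
        raise ParseError(f"{path}: snp_overlap must be 0/1")
    try:
        return ProbeAnnotation(table).validate()
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    t = ann.table.sort_index().copy()
    t["genes"] = [";".join(g) for g in t["genes"]]
    t["snp_overlap"] = t["snp_overlap"].astype(int)
    t.to_csv(path, sep="\t", index_label="probe_id")


def read_interactions(circ_mirna_path: str | Path,
                      mirna_gene_path: str | Path) -> InteractionTables:
    cm = _read_table(circ_mirna_path)
    if list(cm.columns) != ["circ_id", "mirna_id"]:
        raise ParseError(f"{circ_mirna_path}: expected columns circ_id, mirna_id")
    mg = _read_table(mirna_gene_path)
    if list(mg.columns) != ["mirna_id", "gene_id", "site_pos", "seed"]:
        raise ParseError(
            f"{mirna_gene_path}: expected columns mirna_id, gene_id, site_pos, seed"
        )
    mg = mg.copy()
    mg["site_pos"] = pd.to_numeric(mg["site_pos"]).astype(int)
    try:
        return InteractionTables(cm, mg).validate()
    except ValidationError as exc:
        raise ParseError(f"{circ_mirna_path} / {mirna_gene_path}: {exc}") from exc


def write_interactions(tables: InteractionTables,
                       circ_mirna_path: str | Path,
                       mirna_gene_path: str | Path) -> None:
    cm = tables.circ_mirna.sort_values(["circ_id", "mirna_id"])
    cm.to_csv(circ_mirna_path, sep="\t", index=False)
    mg = tables.mirna_gene.sort_values(["mirna_id", "gene_id", "site_pos"])
    mg.to_csv(mirna_gene_path, sep="\t", index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    raw = _read_table(path)
    if list(raw.columns) != ["sample", "time", "event"]:
        raise ParseError(f"{path}: expected columns sample, time, event")
    table = raw.set_index("sample")
    table["time"] = table["time"].astype(float)
    table["event"] = table["event"].astype(float).astype(int)
    try:
        return ClinicalTable(table).validate()
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.sort_index().to_csv(
        path, sep="\t", index_label="sample", float_format=_FLOAT_FMT
    )


def read_driver_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line driver gene list; blanks skipped, de-duplicated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            gene = line.strip()
            if gene:
                genes.add(gene)
    if not genes:
        warnings.warn(f"driver list {path} is empty", stacklevel=2)
        log.warning("driver list %s is empty", path)
    return genes


def write_driver_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")
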