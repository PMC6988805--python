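"""circRNA-miRNA-driver (CMD) tripartite network and candidate pairs.

Driver genes are the intersection of the differentially expressed genes
with a curated cancer-driver list.  The CMD network keeps a miRNA iff it is
differentially expressed, touches at least one candidate circRNA and at
least one driver; every (circRNA, driver) pair connected through at least
one retained miRNA is a candidate sponge pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .types import InteractionTables

log = logging.getLogger(__name__)


@dataclass
class CandidatePair:
    circ_id: str
    gene_id: str
    shared_mirnas: set[str]


def select_driver_genes(de_genes: set[str], driver_list: set[str]) -> set[str]:
    """Differentially expressed driver genes: the exact set intersection."""
    drivers = de_genes & driver_list
    if not drivers:
        warnings.warn("no differentially expressed driver genes", stacklevel=2)
        log.warning("select_driver_genes: empty intersection")
    return drivers


def build_cmd_network(
    candidate_circ: set[str],
    drivers: set[str],
    interactions: InteractionTables,
    de_mirnas: set[str] | None = None,
) -> tuple[list[CandidatePair], pd.DataFrame]:
    """Assemble the tripartite CMD network.

    Parameters
    ----------
    de_mirnas
        If given, only differentially expressed miRNAs mediate edges
        (the default pipeline behavior); pass ``None`` to admit all shared
        miRNAs.

    Returns the candidate pair list plus a typed tripartite edge list
    (columns: source, source_type, target, target_type).  miRNAs of degree
    zero on either side never appear.
    """
    cm = interactions.circ_mirna
    cm = cm[cm["circ_id"].isin(candidate_circ)]
    mg = interactions.mirna_gene[["mirna_id", "gene_id"]].drop_duplicates()
    mg = mg[mg["gene_id"].isin(drivers)]
    circ_side = cm.groupby("mirna_id")["circ_id"].agg(set)
    gene_side = mg.groupby("mirna_id")["gene_id"].agg(set)
    retained = set(circ_side.index) & set(gene_side.index)
    if de_mirnas is not None:
        retained &= de_mirnas
    pairs: dict[tuple[str, str], set[str]] = {}
    for m in sorted(retained):
        for c in circ_side[m]:
            for g in gene_side[m]:
                pairs.setdefault((c, g), set()).add(m)
    pair_list = [
        CandidatePair(c, g, ms) for (c, g), ms in sorted(pairs.items())
    ]
    edge_rows = []
    for m in sorted(retained):
        for c in sorted(circ_side[m]):
            edge_rows.append((c, "circRNA", m, "miRNA"))
        for g in sorted(gene_side[m]):
            edge_rows.append((m, "miRNA", g, "driver"))
    edges = pd.DataFrame(
        edge_rows, columns=["source", "source_type", "target", "target_type"]
    )
    return pair_list, edges


def cmd_mirna_universe(pairs: list[CandidatePair], edges: pd.DataFrame) -> set[str]:
    """All miRNAs participating in the CMD network (the Fisher-test universe)."""
    return set(edges.loc[edges["source_type"] == "miRNA", "source"]) | set(
        edges.loc[edges["target_type"] == "miRNA", "target"]
    )


def write_candidate_pairs(pairs: list[CandidatePair], path) -> None:
    rows = [
        {
            "circ_id": p.circ_id,
            "gene_id": p.gene_id,
            "shared_mirnas": ";".join(sorted(p.shared_mirnas)),
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=["circ_id", "gene_id", "shared_mirnas"]).to_csv(
        path, sep="\t", index=False
    )
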