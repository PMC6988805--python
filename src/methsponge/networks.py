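"""circRNA crosstalk networks and dense-module mining.

Three steps: (1) project the circRNA-miRNA bipartite graph onto circRNAs
through differentially expressed miRNAs (CC network; edge weight = number
of shared miRNAs); (2) keep only CC edges whose two host genes are
differentially methylated AND co-methylated — sample Pearson r above
``r_min`` and significant against a sample-permutation null (DMCC network;
edge weight = r); (3) mine dense modules with an MCODE-style procedure
(k-core vertex weighting, greedy seed expansion, haircut) and take module
members as candidate circRNAs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import InteractionTables, MethylationProfile, ValidationError

log = logging.getLogger(__name__)


@dataclass
class Module:
    """A mined dense module: member circRNAs, its seed node and score."""

    members: set[str]
    seed: str
    score: float


def build_cc_network(
    interactions: InteractionTables, de_mirnas: set[str]
) -> nx.Graph:
    """circRNA crosstalk graph: edge iff two circRNAs share a DE miRNA.

    Nodes are circRNAs interacting with at least one differentially
    expressed miRNA; the edge weight counts the shared DE miRNAs.
    """
    if not de_mirnas:
        raise ValidationError("build_cc_network needs a non-empty DE miRNA set")
    edges = interactions.circ_mirna
    sub = edges[edges["mirna_id"].isin(de_mirnas)]
    net = nx.Graph()
    net.add_nodes_from(sorted(sub["circ_id"].unique()))
    for _, circs in sub.groupby("mirna_id")["circ_id"]:
        for u, v in itertools.combinations(sorted(circs.unique()), 2):
            if net.has_edge(u, v):
                net[u][v]["weight"] += 1
            else:
                net.add_edge(u, v, weight=1)
    return net


def degree_summary(net: nx.Graph) -> dict:
    """Degree distribution plus a descriptive power-law tail slope.

    The slope is the log-log least-squares fit of the degree survival
    function P(D >= d) over positive degrees — a descriptive statistic,
    not a fitted power-law model.
    """
    if net.number_of_nodes() < 2:
        raise ValidationError("degree_summary needs >= 2 nodes")
    degrees = pd.Series(dict(net.degree()), name="degree").sort_index()
    pos = np.sort(degrees[degrees > 0].unique())
    slope = float("nan")
    if len(pos) >= 2:
        surv = np.array([(degrees >= d).mean() for d in pos])
        slope = float(np.polyfit(np.log(pos), np.log(surv), 1)[0])
    return {
        "degrees": degrees,
        "max_degree": int(degrees.max()),
        "mean_degree": float(degrees.mean()),
        "tail_slope": slope,
    }


def _perm_pearson_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed r and one-sided permutation p (r greater than random).

    Permutes the sample order of ``y``; p = (1 + #{r_perm >= r_obs}) /
    (n_perm + 1).
    """
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("constant profile: correlation undefined")
    r_obs = float(xc @ yc / denom)
    perms = np.stack([rng.permutation(len(y)) for _ in range(n_perm)])
    r_null = (yc[perms] @ xc) / denom
    p = (1.0 + int((r_null >= r_obs).sum())) / (n_perm + 1.0)
    return r_obs, p


def build_dmcc_network(
    cc: nx.Graph,
    meth: MethylationProfile,
    dm_hosts: set[str],
    host_of: dict[str, str],
    r_min: float = 0.6,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> nx.Graph:
    """Co-methylation subgraph of the CC network.

    A CC edge survives iff both endpoints' host genes are differentially
    methylated, their gene-level methylation correlates with r > ``r_min``,
    and the correlation beats a one-sided sample-permutation null at
    ``alpha``.  Edge weight becomes r.  ``host_of`` maps circRNA id to host
    gene id; both endpoints must resolve to a methylation row.
    """
    if meth.resolution != "gene":
        raise ValidationError("build_dmcc_network expects gene-resolution methylation")
    rng = np.random.default_rng(rng_seed)
    values = meth.values
    dmcc = nx.Graph()
    for u, v in sorted(map(tuple, map(sorted, cc.edges()))):
        hu, hv = host_of.get(u), host_of.get(v)
        if hu not in dm_hosts or hv not in dm_hosts:
            continue
        if hu not in values.index or hv not in values.index:
            continue
        x = values.loc[hu].to_numpy(float)
        y = values.loc[hv].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            log.warning("dmcc: pair (%s, %s) skipped, <3 shared samples", u, v)
            continue
        r, p = _perm_pearson_pvalue(x[ok], y[ok], n_perm, rng)
        if r > r_min and p < alpha:
            dmcc.add_edge(u, v, weight=r)
    return dmcc


# ---------------------------------------------------------------------------
# MCODE-style module mining
# ---------------------------------------------------------------------------

def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(net: nx.Graph, degree_cutoff: int, k_core: int) -> dict[str, float]:
    """MCODE vertex weighting.

    weight(v) = (highest k-core number of v's closed neighborhood) x
    (density of that highest core).  Nodes with degree below the cutoff
    weight zero.
    """
    weights: dict[str, float] = {}
    for v in net.nodes():
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = net.subgraph(list(net.neighbors(v)) + [v])
        cores = nx.core_number(nbhd)
        k_max = max(cores.values())
        if k_max < k_core:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, k in cores.items() if k >= k_max]
        weights[v] = k_max * _density(nbhd.subgraph(core_nodes))
    return weights


def mine_modules(
    net: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    min_size: int = 3,
) -> list[Module]:
    """MCODE-style dense-module mining.

    Seeds are taken in decreasing vertex weight (ties broken by node id);
    each seed greedily absorbs unassigned neighbors whose weight is at
    least ``(1 - node_score_cutoff)`` times the seed weight, breadth-first.
    The haircut removes members with fewer than 2 connections inside the
    module.  Modules are ranked by score = density x size; every node
    belongs to at most one module.
    """
    if net.number_of_nodes() == 0 or net.number_of_edges() == 0:
        return []
    weights = _vertex_weights(net, degree_cutoff, k_core)
    assigned: set[str] = set()
    modules: list[Module] = []
    order = sorted(weights, key=lambda v: (-weights[v], v))
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in sorted(net.neighbors(node)):
                    if nb in members or nb in assigned:
                        continue
                    if weights[nb] >= threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
        if haircut:
            while True:
                sub = net.subgraph(members)
                trim = {v for v in members if sub.degree(v) < 2}
                if not trim or len(members) - len(trim) == 0:
                    members -= trim
                    break
                members -= trim
        if len(members) < min_size or seed not in members:
            continue
        sub = net.subgraph(members)
        if not nx.is_connected(sub):
            members = set(nx.node_connected_component(sub, seed))
            sub = net.subgraph(members)
        score = _density(sub) * len(members)
        modules.append(Module(set(members), seed, score))
        assigned |= members
    modules.sort(key=lambda m: (-m.score, m.seed))
    return modules


def candidate_circrnas(modules: list[Module]) -> set[str]:
    """Union of module members — the candidate circRNAs for the CMD step."""
    out: set[str] = set()
    for m in modules:
        out |= m.members
    return out


def write_network(net: nx.Graph, edge_path, graphml_path=None) -> None:
    """Write a weighted edge list TSV (and optionally GraphML)."""
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1)}
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)


def write_modules(modules: list[Module], path) -> None:
    rows = []
    for i, m in enumerate(modules, 1):
        for member in sorted(m.members):
            rows.append(
                {
                    "module": i,
                    "member": member,
                    "is_seed": int(member == m.seed),
                    "score": m.score,
                }
            )
    pd.DataFrame(rows, columns=["module", "member", "is_seed", "score"]).to_csv(
        path, sep="\t", index=False
    )
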