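"""Four-condition sponge circRNA-driver gene prediction.

Each candidate pair from the CMD network is scored with:

* ``P1`` — one-sided Fisher/hypergeometric enrichment of the shared miRNAs
  against the CMD miRNA universe.  With ``a`` shared miRNAs, ``b`` miRNAs
  of the circRNA shared only with other drivers, ``c`` miRNAs of the driver
  shared only with other circRNAs, and ``d = n - a - b - c`` remaining
  miRNAs, the point probability of a table is

      (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!)

  and P1 sums the point terms over a' >= a at fixed margins.
* ``P2`` / ``r_meth`` — sample Pearson correlation (1/(n-1) normalisation)
  between the circRNA host-gene methylation and the driver promoter
  methylation in tumor samples, with its two-sided t-test p-value.
* permutation check — the observed r must beat a one-sided sample-
  permutation null (r greater than random).
* unique seed sites — the shared miRNAs must hit >= 8 distinct target-site
  positions on the driver; miRNAs with the same seed can occupy the same
  site, so distinctness is by site position.
* methylation-expression anticorrelation — driver promoter methylation must
  correlate negatively (p < 0.05) with driver expression in tumor samples.

A pair is emitted as predicted iff all four conditions hold; the full score
table (passing and failing pairs, with per-condition flags) is kept for
audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cmd_network import CandidatePair
from .types import (
    ExpressionMatrix,
    InteractionTables,
    MethylationProfile,
    TUMOR,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Shared-miRNA 2x2 table with margins fixed by the CMD universe."""

    a: int  # shared miRNAs of the pair
    b: int  # circRNA's miRNAs shared with other drivers only
    c: int  # driver's miRNAs shared with other circRNAs only
    d: int  # remaining miRNAs in the universe
    n: int  # total miRNAs in the universe

    def validate(self) -> "ContingencyTable":
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d != self.n:
            raise ValidationError(
                f"margin inconsistency: a+b+c+d={self.a+self.b+self.c+self.d} != n={self.n}"
            )
        return self


@dataclass
class PredictionConfig:
    p1_max: float = 0.05
    p2_max: float = 0.05
    perm_alpha: float = 0.05
    min_sites: int = 8
    meth_expr_alpha: float = 0.05
    n_perm: int = 1000
    min_shared_samples: int = 10
    rng_seed: int = 0


def shared_mirna_test(tbl: ContingencyTable) -> float:
    """One-sided Fisher enrichment p-value for the shared-miRNA count.

    P1 = sum over a' >= a of the hypergeometric point probability with the
    table's margins held fixed.
    """
    tbl.validate()
    if tbl.a == 0:
        return 1.0
    # drawing (a+b) circRNA-miRNAs from n, counting hits among (a+c) driver-miRNAs
    return float(stats.hypergeom.sf(tbl.a - 1, tbl.n, tbl.a + tbl.c, tbl.a + tbl.b))


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with its two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_correlation needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def permutation_positive_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """One-sided permutation p-value that r is greater than random.

    Permutes the sample order of ``y``; p = (1 + #{r_perm >= r_obs}) /
    (n_perm + 1).  Deterministic for a fixed seed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("permutation test needs equal-length vectors, n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("constant vector: correlation undefined")
    r_obs = xc @ yc / denom
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    perms = np.stack([rng.permutation(len(y)) for _ in range(n_perm)])
    r_null = (yc[perms] @ xc) / denom
    return float((1.0 + (r_null >= r_obs).sum()) / (n_perm + 1.0))


def count_unique_seed_sites(
    pair: CandidatePair, interactions: InteractionTables
) -> int:
    """Distinct target-site positions on the driver hit by shared miRNAs.

    Sites occupied only by same-seed miRNA copies collapse to one because
    distinctness is by position on the gene.
    """
    mg = interactions.mirna_gene
    sub = mg[(mg["gene_id"] == pair.gene_id) & (mg["mirna_id"].isin(pair.shared_mirnas))]
    if sub.empty:
        log.warning(
            "count_unique_seed_sites: no site records for driver %s", pair.gene_id
        )
        return 0
    return int(sub["site_pos"].nunique())


def contingency_for_pair(
    pair: CandidatePair,
    interactions: InteractionTables,
    universe: set[str],
    candidate_circ: set[str],
    drivers: set[str],
) -> ContingencyTable:
    """Build the pair's 2x2 table from the CMD miRNA universe.

    a = miRNAs shared by the pair; b = the circRNA's universe miRNAs that
    also hit some other driver but not this one; c = the driver's universe
    miRNAs shared with some other candidate circRNA but not this one;
    d = the rest of the universe.
    """
    circ_m = interactions.mirnas_of_circ(pair.circ_id) & universe
    gene_m = interactions.mirnas_of_gene(pair.gene_id) & universe
    a = len(circ_m & gene_m)
    b = len(circ_m - gene_m)
    c = len(gene_m - circ_m)
    n = len(universe)
    d = n - a - b - c
    return ContingencyTable(a, b, c, d, n).validate()


def _tumor_columns(*mats) -> list[str]:
    cols = None
    for mat in mats:
        tumor = set(mat.samples_in(TUMOR))
        cols = tumor if cols is None else cols & tumor
    return sorted(cols)


def predict_sponge_pairs(
    candidates: list[CandidatePair],
    meth_host: MethylationProfile,
    meth_promoter: MethylationProfile,
    expr: ExpressionMatrix,
    interactions: InteractionTables,
    host_of: dict[str, str],
    universe: set[str],
    candidate_circ: set[str],
    drivers: set[str],
    cfg: PredictionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every candidate pair and emit those passing all four conditions.

    All correlations are computed on tumor samples only, on the sample
    intersection of the three profiles.  Returns ``(predicted, scores)``
    where ``scores`` holds one audit row per candidate with every statistic
    and pass/fail flag.
    """
    cfg = cfg or PredictionConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    shared = _tumor_columns(meth_host, meth_promoter, expr)
    if len(shared) < cfg.min_shared_samples:
        raise ValidationError(
            f"only {len(shared)} shared tumor samples; "
            f"need >= {cfg.min_shared_samples}"
        )
    host_vals = meth_host.values[shared]
    prom_vals = meth_promoter.values[shared]
    expr_vals = expr.values[shared]
    rows = []
    for pair in candidates:
        host = host_of.get(pair.circ_id)
        row = {
            "circ_id": pair.circ_id,
            "gene_id": pair.gene_id,
            "n_shared_mirnas": len(pair.shared_mirnas),
        }
        tbl = contingency_for_pair(pair, interactions, universe,
                                   candidate_circ, drivers)
        row["p1"] = shared_mirna_test(tbl)
        row["n_unique_sites"] = count_unique_seed_sites(pair, interactions)
        scorable = (
            host in host_vals.index
            and pair.gene_id in prom_vals.index
            and pair.gene_id in expr_vals.index
        )
        if scorable:
            x = host_vals.loc[host].to_numpy(float)
            y = prom_vals.loc[pair.gene_id].to_numpy(float)
            e = expr_vals.loc[pair.gene_id].to_numpy(float)
            r_meth, p2 = pearson_correlation(x, y)
            perm_p = permutation_positive_test(x, y, cfg.n_perm, rng)
            r_me, p_me = pearson_correlation(y, e)
        else:
            log.warning(
                "pair (%s, %s): missing methylation/expression rows; "
                "correlation conditions fail",
                pair.circ_id, pair.gene_id,
            )
            r_meth = p2 = perm_p = r_me = p_me = np.nan
        row.update(
            r_meth=r_meth, p2=p2, perm_p=perm_p,
            r_meth_expr=r_me, p_meth_expr=p_me,
        )
        row["pass_p1"] = row["p1"] <= cfg.p1_max
        row["pass_p2"] = bool(np.nan_to_num(p2, nan=1.0) <= cfg.p2_max)
        row["pass_perm"] = bool(
            np.nan_to_num(r_meth, nan=-1.0) > 0
            and np.nan_to_num(perm_p, nan=1.0) < cfg.perm_alpha
        )
        row["pass_sites"] = row["n_unique_sites"] >= cfg.min_sites
        row["pass_meth_expr"] = bool(
            np.nan_to_num(r_me, nan=1.0) < 0
            and np.nan_to_num(p_me, nan=1.0) < cfg.meth_expr_alpha
        )
        row["predicted"] = (
            row["pass_p1"] and row["pass_p2"] and row["pass_perm"]
            and row["pass_sites"] and row["pass_meth_expr"]
        )
        rows.append(row)
    scores = pd.DataFrame(rows)
    if scores.empty:
        scores = pd.DataFrame(
            columns=["circ_id", "gene_id", "n_shared_mirnas", "p1",
                     "n_unique_sites", "r_meth", "p2", "perm_p",
                     "r_meth_expr", "p_meth_expr", "pass_p1", "pass_p2",
                     "pass_perm", "pass_sites", "pass_meth_expr", "predicted"]
        )
    predicted = scores[scores["predicted"]].reset_index(drop=True)
    return predicted, scores
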