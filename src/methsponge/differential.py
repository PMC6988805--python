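"""SAM-style two-group differential screening.

Features (miRNAs, genes, or methylation levels) are compared between tumor
and normal groups with a moderated t statistic

    d_i = (mean_tumor_i - mean_normal_i) / (s_i + s0)

where ``s_i`` is the usual two-sample standard error and the fudge factor
``s0`` (5th percentile of the ``s_i``) stabilises low-variance features.
False-discovery q-values come from group-label permutations: the null
distribution of |d| is pooled over permutations, the FDR at each observed
|d| is the expected null exceedance count over the observed exceedance
count, and q-values are the monotone envelope of those FDRs.

A feature passes the screen iff its raw fold change clears the gate
(FC > fc_up or FC < fc_down) and q <= q_max.  Fold changes are computed on
raw group means with a +1 pseudo-count in the denominator guard, matching
the pipeline's log-transform convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, MethylationProfile, NORMAL, TUMOR, ValidationError

#: default gates: expression uses FC>2 / FC<0.5 with q<0.01; methylation
#: uses FC>1.5 / FC<2/3 with q<0.05.
EXPRESSION_GATES = dict(fc_up=2.0, fc_down=0.5, q_max=0.01)
METHYLATION_GATES = dict(fc_up=1.5, fc_down=2.0 / 3.0, q_max=0.05)


@dataclass
class ScreenResult:
    """Per-feature outcome of the differential screen."""

    table: pd.DataFrame  # index feature; columns: tumor_mean, normal_mean,
    #                      fold_change, d_stat, q_value, passed

    @property
    def passed_ids(self) -> set[str]:
        return set(self.table.index[self.table["passed"]])


def _group_split(mat: ExpressionMatrix | MethylationProfile) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    values = mat.values
    tumor = mat.samples_in(TUMOR)
    normal = mat.samples_in(NORMAL)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError(
            f"differential screen needs >=2 samples per group "
            f"(tumor={len(tumor)}, normal={len(normal)})"
        )
    return values[tumor].to_numpy(float), values[normal].to_numpy(float), values.index


def _d_statistic(x_t: np.ndarray, x_n: np.ndarray, s0: float | None = None):
    """Moderated t over rows; returns (d, s, s0)."""
    n1, n2 = x_t.shape[1], x_n.shape[1]
    m1, m2 = x_t.mean(axis=1), x_n.mean(axis=1)
    ss = ((x_t - m1[:, None]) ** 2).sum(axis=1) + ((x_n - m2[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    s = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.percentile(s, 5))
    d = (m1 - m2) / (s + s0)
    return d, s, s0


def _permutation_q(
    x: np.ndarray,
    n_tumor: int,
    d_obs: np.ndarray,
    s0: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """q-values from pooled permutation null of |d|.

    For each observed |d| threshold t: FDR(t) = E_perm[#{|d*|>=t}] / #{|d|>=t};
    q is the running minimum of FDR over decreasing t (so q is monotone
    non-increasing in |d|), clipped to [0, 1].
    """
    m, n = x.shape
    abs_obs = np.abs(d_obs)
    null_pool = np.empty((n_perm, m))
    cols = np.arange(n)
    for p in range(n_perm):
        perm = rng.permutation(cols)
        xt, xn = x[:, perm[:n_tumor]], x[:, perm[n_tumor:]]
        d_null, _, _ = _d_statistic(xt, xn, s0=s0)
        null_pool[p] = np.abs(d_null)
    flat = np.sort(null_pool.ravel())
    order = np.argsort(-abs_obs, kind="stable")  # descending |d|
    sorted_abs = abs_obs[order]
    # expected null count >= threshold, averaged over permutations
    exceed = (flat.size - np.searchsorted(flat, sorted_abs, side="left")) / n_perm
    observed = np.arange(1, m + 1)
    fdr = np.clip(exceed / observed, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]  # q_i = min_{j>=i} fdr_j
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_screen(
    mat: ExpressionMatrix | MethylationProfile,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    q_max: float = 0.01,
    n_perm: int = 200,
    rng_seed: int = 0,
) -> ScreenResult:
    """Screen features for tumor/normal differences.

    Returns a full per-feature table; ``passed`` marks features clearing
    both the fold-change gate and the q-value gate.  Deterministic for a
    fixed ``rng_seed``.
    """
    x_t, x_n, index = _group_split(mat)
    m1, m2 = x_t.mean(axis=1), x_n.mean(axis=1)
    # +1 pseudo-count guards a zero denominator, consistent with log2(x+1)
    fold_change = np.where(m2 > 0, m1 / np.where(m2 > 0, m2, 1.0), (m1 + 1) / 1.0)
    d, _, s0 = _d_statistic(x_t, x_n)
    rng = np.random.default_rng(rng_seed)
    x = np.concatenate([x_t, x_n], axis=1)
    q = _permutation_q(x, x_t.shape[1], d, s0, n_perm, rng)
    passed = ((fold_change > fc_up) | (fold_change < fc_down)) & (q <= q_max)
    table = pd.DataFrame(
        {
            "tumor_mean": m1,
            "normal_mean": m2,
            "fold_change": fold_change,
            "d_stat": d,
            "q_value": q,
            "passed": passed,
        },
        index=index,
    )
    return ScreenResult(table)
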