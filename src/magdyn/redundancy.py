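"""Community functional redundancy from abundances and trait distances.

Functional uniqueness Ustar is the ratio of Rao's quadratic entropy
Q = sum_ij p_i p_j d_ij to the Gini-Simpson index D = 1 - sum_i p_i^2;
redundancy is Rstar = 1 - Ustar.  With trait distances bounded in [0, 1]
(as Gower distances are) the ratio itself lies in [0, 1]: Rstar = 1 means
every MAG is functionally interchangeable, Rstar = 0 a community of
maximally distinct MAGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import _align_distance, hill_neutral

__all__ = [
    "RedundancyResult",
    "rao_quadratic",
    "gini_simpson",
    "uniqueness_redundancy",
    "redundancy_table",
    "redundancy_diversity_relation",
]


@dataclass(frozen=True)
class RedundancyResult:
    sample_id: str
    rao_q: float
    simpson: float
    ustar: float
    rstar: float
    defined: bool = True


def _clean(p, d, mag_ids=None):
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid abundance vector")
    p = p / p.sum()
    index = list(mag_ids) if mag_ids is not None else list(range(len(p)))
    D = _align_distance(index, d)
    if (D < -1e-12).any() or (D > 1 + 1e-12).any():
        raise ValueError("trait distances must lie in [0, 1]")
    keep = p > 0
    return p[keep], D[np.ix_(keep, keep)]


def rao_quadratic(p, d, mag_ids=None) -> float:
    """Rao's quadratic entropy: expected trait distance between two random reads."""
    p, D = _clean(p, d, mag_ids)
    return float(p @ D @ p)


def gini_simpson(p) -> float:
    """Gini-Simpson index: probability two random reads come from different MAGs."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid abundance vector")
    p = p / p.sum()
    return float(1.0 - np.sum(p**2))


def uniqueness_redundancy(p, d, sample_id: str = "", mag_ids=None) -> RedundancyResult:
    """Ustar = Q/D and Rstar = 1 - Ustar for one community.

    A single-MAG community has D = 0; the result is flagged undefined and
    should be excluded from summaries.
    """
    q_val = rao_quadratic(p, d, mag_ids)
    simpson = gini_simpson(p)
    if simpson <= 0:
        return RedundancyResult(sample_id, q_val, simpson, np.nan, np.nan, defined=False)
    ustar = q_val / simpson
    if ustar > 1.0 + 1e-9:
        raise AssertionError(
            f"Ustar = {ustar} > 1 with distances in [0, 1]; inputs are inconsistent"
        )
    ustar = float(np.clip(ustar, 0.0, 1.0))
    return RedundancyResult(sample_id, q_val, simpson, ustar, 1.0 - ustar)


def redundancy_table(abund_df: pd.DataFrame, d) -> pd.DataFrame:
    """Per-sample redundancy table over a relative-abundance DataFrame."""
    rows = []
    for sample_id, p in abund_df.iterrows():
        vec = p.to_numpy(dtype=float)
        if vec.sum() <= 0:
            continue
        r = uniqueness_redundancy(vec, d, sample_id=sample_id, mag_ids=list(abund_df.columns))
        rows.append(
            {
                "sample_id": sample_id,
                "rao_q": r.rao_q,
                "simpson": r.simpson,
                "ustar": r.ustar,
                "rstar": r.rstar,
                "defined": r.defined,
            }
        )
    return pd.DataFrame(rows)


def redundancy_diversity_relation(
    abund_df: pd.DataFrame,
    d,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Relationship between log neutral diversity and redundancy across samples.

    Returns the paired per-sample values plus Pearson and Spearman
    correlations with permutation p-values (two-sided, label permutation of
    one margin, observed labelling included in the reference set).
    """
    table = redundancy_table(abund_df, d)
    table = table[table["defined"]]
    if len(table) < 3:
        raise ValueError("need >= 3 defined samples for the relation")
    log_div = np.array(
        [
            np.log(hill_neutral(abund_df.loc[s].to_numpy(float) / abund_df.loc[s].sum(), 1.0))
            for s in table["sample_id"]
        ]
    )
    rstar = table["rstar"].to_numpy()
    pairs = pd.DataFrame(
        {"sample_id": table["sample_id"], "log_neutral_diversity": log_div, "rstar": rstar}
    )
    out = {"pairs": pairs}
    if np.std(log_div) == 0 or np.std(rstar) == 0:
        out.update(
            pearson_r=np.nan, pearson_p=np.nan, spearman_rho=np.nan, spearman_p=np.nan,
            defined=False,
        )
        return out
    rng = np.random.default_rng(seed)
    pear = stats.pearsonr(log_div, rstar).statistic
    spear = stats.spearmanr(log_div, rstar).statistic
    hits_p = hits_s = 1
    for _ in range(n_permutations):
        perm = rng.permutation(rstar)
        if abs(stats.pearsonr(log_div, perm).statistic) >= abs(pear) - 1e-12:
            hits_p += 1
        if abs(stats.spearmanr(log_div, perm).statistic) >= abs(spear) - 1e-12:
            hits_s += 1
    out.update(
        pearson_r=float(pear),
        pearson_p=hits_p / (n_permutations + 1),
        spearman_rho=float(spear),
        spearman_p=hits_s / (n_permutations + 1),
        defined=True,
    )
    return out
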