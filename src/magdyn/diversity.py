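"""Hill-number diversities of order q and their alpha/beta/gamma partitioning.

Three diversity components are supported over the same sample x MAG
abundance table:

* ``neutral`` — relative abundances only; at q = 1 the exponential of
  Shannon entropy (effective number of equally abundant MAGs).
* ``phylogenetic`` — branch-length weighted Hill numbers: each branch
  contributes its length times the summed relative abundance of its
  descendant tips; values are normalised by the abundance-weighted mean
  tree depth T, giving an effective number of equally divergent lineages.
* ``functional`` — attribute diversity built on a pairwise trait distance
  matrix (Gower distance over metabolic capacity indices); single-sample
  values are effective numbers of equally distinct MAGs, while the
  alpha/beta/gamma partition works on the total attribute diversity whose
  beta component ranges over [1, N^2] for N samples.

All orders q are available; the q -> 1 limit is evaluated analytically.
Beta diversity is reported as Sørensen-type turnover, rescaled to [0, 1]
by (beta - 1)/(N - 1) for neutral/phylogenetic components and by
(beta - 1)/(N^2 - 1) (default) for the functional component.

Partitions use equal sample weights.  MAGs with zero abundance in every
sample of a computation are ignored by it; they are never removed from
the table globally.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .io import AbundanceTable, Phylogeny

__all__ = [
    "COMPONENTS",
    "hill_neutral",
    "hill_phylo",
    "hill_func",
    "gower_distance",
    "beta_partition",
    "sorensen_turnover",
    "turnover_series",
    "turnover_distance_matrix",
    "alpha_diversity_table",
]

COMPONENTS = ("neutral", "phylogenetic", "functional")

_Q1_TOL = 1e-10


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector is all zero")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {total})")
    return p


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * ln(x) with the 0 ln 0 = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * np.log(x[mask])
    return out


def hill_neutral(p, q: float = 1.0) -> float:
    """Effective number of MAGs at order q from a relative-abundance vector."""
    p = _check_simplex(p)
    p = p[p > 0]
    if abs(q - 1.0) < _Q1_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _branch_profile(p: np.ndarray, lengths: np.ndarray, incidence: np.ndarray):
    """Per-branch abundances a_b and lengths, dropping zero-abundance branches."""
    a = incidence @ p
    keep = (a > 0) & (lengths > 0)
    return lengths[keep], a[keep]


def hill_phylo(
    p,
    phylogeny: Phylogeny,
    q: float = 1.0,
    mag_ids: list | None = None,
    normalized: bool = True,
) -> float:
    """Phylogenetic Hill number of order q.

    With branch abundances a_b, lengths L_b and T = sum(L_b a_b), the
    normalised q = 1 value is exp(-sum((L_b/T) a_b ln a_b)): the effective
    number of equally divergent lineages.  ``normalized=False`` multiplies
    by T, returning the effective total branch length instead.
    """
    p = _check_simplex(p)
    if mag_ids is None:
        mag_ids = phylogeny.tip_labels
        if len(mag_ids) != len(p):
            raise ValueError("abundance vector length does not match tip count")
    lengths, incidence = phylogeny.branch_arrays(list(mag_ids))
    L, a = _branch_profile(p, lengths, incidence)
    T = float(L @ a)
    if T <= 0:
        raise ValueError("abundance-weighted tree depth is zero")
    w = L / T
    if abs(q - 1.0) < _Q1_TOL:
        value = float(np.exp(-np.sum(w * a * np.log(a))))
    else:
        value = float(np.sum(w * a**q) ** (1.0 / (1.0 - q)))
    return value if normalized else value * T


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Gower distance between MAG trait rows, in [0, 1].

    Each trait is scaled by its observed range; constant traits carry no
    information and are excluded from the mean.  All-constant input is an
    error.
    """
    if traits.shape[0] < 2:
        raise ValueError("Gower distance needs at least 2 MAGs")
    X = traits.to_numpy(dtype=float)
    ranges = X.max(axis=0) - X.min(axis=0)
    usable = ranges > 0
    if not usable.any():
        raise ValueError("all traits are constant; Gower distance undefined")
    Xs = X[:, usable] / ranges[usable]
    diff = np.abs(Xs[:, None, :] - Xs[None, :, :]).mean(axis=2)
    return pd.DataFrame(diff, index=traits.index, columns=traits.index)


def _align_distance(p_index, d: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(d, pd.DataFrame):
        missing = [m for m in p_index if m not in d.index]
        if missing:
            raise ValueError(f"MAGs absent from distance matrix: {missing}")
        d = d.loc[p_index, p_index].to_numpy(dtype=float)
    else:
        d = np.asarray(d, dtype=float)
        if d.shape != (len(p_index), len(p_index)):
            raise ValueError("distance matrix does not match abundance vector")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return d


def hill_func(p, d, q: float = 1.0, mag_ids=None) -> float:
    """Functional Hill number: effective number of equally distinct MAGs.

    Uses the attribute-diversity formulation with Rao quadratic entropy
    Q = sum_ij d_ij p_i p_j; the q = 1 value is
    exp(-1/2 sum_ij (d_ij/Q) p_i p_j ln(p_i p_j)).
    """
    p = _check_simplex(p)
    index = list(mag_ids) if mag_ids is not None else list(range(len(p)))
    D = _align_distance(index, d)
    keep = p > 0
    p, D = p[keep], D[np.ix_(keep, keep)]
    Q = float(p @ D @ p)
    if Q <= 0:
        raise ValueError(
            "Rao quadratic entropy is zero: community is functionally uniform, "
            "functional Hill number undefined"
        )
    if abs(q - 1.0) < _Q1_TOL:
        # -1/2 sum (d/Q) p_i p_j (ln p_i + ln p_j) collapses by symmetry
        return float(np.exp(-(_xlogx(p) @ D @ p) / Q))
    total = float(np.sum((D / Q) * np.outer(p, p) ** q))
    return float(total ** (1.0 / (2.0 * (1.0 - q))))


# ---------------------------------------------------------------------------
# alpha / beta / gamma partitioning (equal sample weights)
# ---------------------------------------------------------------------------


def _partition_profile(X: np.ndarray, L: np.ndarray, q: float):
    """Partition over a unit x sample abundance profile.

    X is (n_samples, n_units) with rows summing to 1 over the tree/tip
    expansion implied by L (unit lengths for the neutral case); returns
    (alpha, gamma).  Equal weights; q -> 1 handled analytically.
    """
    N = X.shape[0]
    abar = X.mean(axis=0)
    T = float(L @ abar)
    if T <= 0:
        raise ValueError("pooled abundance profile is empty")
    w = L / T
    Z = X / N
    if abs(q - 1.0) < _Q1_TOL:
        gamma = float(np.exp(-np.sum(w * _xlogx(abar))))
        alpha = float(np.exp(-np.sum(w * _xlogx(Z).sum(axis=0)))) / N
    else:
        gamma = float(np.sum(w * abar**q) ** (1.0 / (1.0 - q)))
        alpha = float(np.sum(w * (Z**q).sum(axis=0)) ** (1.0 / (1.0 - q))) / N
    return alpha, gamma


def _partition_functional(P: np.ndarray, D: np.ndarray, q: float):
    """Attribute-diversity partition; returns (alpha, gamma) total diversities.

    Both use the pooled-assemblage Rao Q so that beta = gamma/alpha lies in
    [1, N^2].
    """
    N = P.shape[0]
    pbar = P.mean(axis=0)
    Q = float(pbar @ D @ pbar)
    if Q <= 0:
        raise ValueError("pooled Rao quadratic entropy is zero")
    Z = P / N
    if abs(q - 1.0) < _Q1_TOL:
        gamma = float(np.exp(-2.0 * (_xlogx(pbar) @ D @ pbar) / Q))
        u = _xlogx(Z).sum(axis=0)
        v = Z.sum(axis=0)
        alpha = float(np.exp(-2.0 * (u @ D @ v) / Q)) / N**2
    else:
        gamma = float(np.sum((D / Q) * np.outer(pbar, pbar) ** q) ** (1.0 / (1.0 - q)))
        zq = (Z**q).sum(axis=0)
        alpha = float(np.sum((D / Q) * np.outer(zq, zq)) ** (1.0 / (1.0 - q))) / N**2
    return alpha, gamma


class _PartitionContext:
    """Precomputed backbone (branch incidence or distances) for one MAG set.

    Avoids re-deriving the tree's branch arrays or re-aligning the distance
    matrix for every pair in a pairwise turnover matrix.
    """

    def __init__(self, component, mag_ids, tree=None, distances=None):
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        self.component = component
        self.mag_ids = list(mag_ids)
        if component == "phylogenetic":
            if tree is None:
                raise ValueError("phylogenetic partition requires a tree")
            self.lengths, incidence = tree.branch_arrays(self.mag_ids)
            self.incidence = incidence.astype(float)
        elif component == "functional":
            if distances is None:
                raise ValueError("functional partition requires a distance matrix")
            self.D = _align_distance(self.mag_ids, distances)

    def partition(self, X: np.ndarray, q: float):
        if self.component == "neutral":
            return _partition_profile(X, np.ones(X.shape[1]), q)
        if self.component == "phylogenetic":
            return _partition_profile(X @ self.incidence.T, self.lengths, q)
        return _partition_functional(X, self.D, q)

    def beta(self, X: np.ndarray, q: float) -> float:
        alpha, gamma = self.partition(X, q)
        N = X.shape[0]
        upper = N**2 if self.component == "functional" else N
        beta = gamma / alpha
        if beta < 1.0 - 1e-6 or beta > upper * (1 + 1e-6):
            raise AssertionError(f"beta {beta} outside [1, {upper}]")
        return float(np.clip(beta, 1.0, upper))


def _as_rows(samples) -> np.ndarray:
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("beta partition needs >= 2 aligned abundance vectors")
    sums = X.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every sample in a partition must have positive abundance")
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("abundance vectors must each sum to 1")
    return X


def beta_partition(
    samples,
    component: str = "neutral",
    q: float = 1.0,
    tree: Phylogeny | None = None,
    distances=None,
    mag_ids=None,
) -> tuple[float, float, float]:
    """Partition N samples into (alpha, gamma, beta = gamma/alpha).

    ``samples`` is an (N, S) array of aligned relative-abundance vectors (or
    a DataFrame whose columns are MAG ids).  ``tree`` is required for the
    phylogenetic component and ``distances`` for the functional one.
    Beta lies in [1, N] (neutral/phylogenetic) or [1, N^2] (functional).
    """
    if isinstance(samples, pd.DataFrame):
        mag_ids = list(samples.columns)
        samples = samples.to_numpy(dtype=float)
    X = _as_rows(samples)
    N = X.shape[0]
    if mag_ids is None:
        mag_ids = tree.tip_labels if component == "phylogenetic" and tree is not None else list(range(X.shape[1]))
    ctx = _PartitionContext(component, mag_ids, tree=tree, distances=distances)
    alpha, gamma = ctx.partition(X, q)
    beta = gamma / alpha
    # guard against floating-point undershoot below the theoretical floor
    upper = N**2 if component == "functional" else N
    if beta < 1.0 - 1e-6 or beta > upper * (1 + 1e-6):
        raise AssertionError(f"beta {beta} outside [1, {upper}]")
    return alpha, gamma, float(np.clip(beta, 1.0, upper))


def sorensen_turnover(
    beta: float,
    n: int,
    component: str = "neutral",
    functional_normalization: str = "squared",
) -> float:
    """Rescale a beta diversity to Sørensen-type turnover in [0, 1].

    Neutral and phylogenetic betas range over [1, N] and are rescaled by
    (beta - 1)/(N - 1).  Functional beta from the attribute-diversity
    partition ranges over [1, N^2]; the default normalisation divides by
    N^2 - 1 (``functional_normalization="linear"`` selects N - 1 instead).
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if n < 2:
        raise ValueError("turnover needs at least 2 samples")
    if component == "functional" and functional_normalization == "squared":
        upper = n**2
    else:
        upper = n
    if not (1.0 - 1e-9 <= beta <= upper * (1 + 1e-9)):
        raise ValueError(f"beta {beta} outside its legal range [1, {upper}]")
    return float(np.clip((beta - 1.0) / (upper - 1.0), 0.0, 1.0))


def turnover_series(
    samples: pd.DataFrame,
    component: str = "neutral",
    q: float = 1.0,
    tree: Phylogeny | None = None,
    distances=None,
    functional_normalization: str = "squared",
) -> dict:
    """Within-individual turnover along an ordered time series.

    ``samples`` rows must be ordered by time.  Returns consecutive pairwise
    turnovers, the overall N-sample turnover, and (for reference) the mean
    of all pairwise turnovers.
    """
    n = samples.shape[0]
    if n < 2:
        warnings.warn("turnover series skipped: fewer than 2 time points")
        return {"consecutive": [], "overall": np.nan, "pairwise_mean": np.nan}
    X = _as_rows(samples.to_numpy(dtype=float))
    ctx = _PartitionContext(component, list(samples.columns), tree=tree, distances=distances)

    def pair(i, j):
        beta = ctx.beta(X[[i, j]], q)
        return sorensen_turnover(
            beta, 2, component, functional_normalization=functional_normalization
        )

    consecutive = [pair(i, i + 1) for i in range(n - 1)]
    overall = sorensen_turnover(
        ctx.beta(X, q), n, component, functional_normalization=functional_normalization
    )
    pairwise = [pair(i, j) for i, j in itertools.combinations(range(n), 2)]
    return {
        "consecutive": consecutive,
        "overall": overall,
        "pairwise_mean": float(np.mean(pairwise)),
    }


def turnover_distance_matrix(
    abund: AbundanceTable | pd.DataFrame,
    component: str = "neutral",
    q: float = 1.0,
    tree: Phylogeny | None = None,
    distances=None,
    functional_normalization: str = "squared",
) -> pd.DataFrame:
    """Sample x sample pairwise Sørensen-turnover dissimilarity matrix."""
    df = abund.to_relative().df if isinstance(abund, AbundanceTable) else abund
    X = df.to_numpy(dtype=float)
    sums = X.sum(axis=1)
    if (sums <= 0).any():
        bad = [df.index[i] for i in np.flatnonzero(sums <= 0)]
        warnings.warn(f"all-zero samples excluded from turnover matrix: {bad}")
        df = df.loc[sums > 0]
        X = df.to_numpy(dtype=float)
    ctx = _PartitionContext(component, list(df.columns), tree=tree, distances=distances)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        beta = ctx.beta(X[[i, j]], q)
        out[i, j] = out[j, i] = sorensen_turnover(
            beta, 2, component, functional_normalization=functional_normalization
        )
    return pd.DataFrame(out, index=df.index, columns=df.index)


def alpha_diversity_table(
    abund: AbundanceTable | pd.DataFrame,
    components=COMPONENTS,
    q: float = 1.0,
    tree: Phylogeny | None = None,
    distances=None,
) -> pd.DataFrame:
    """Long-format per-sample alpha diversities for the requested components."""
    df = abund.to_relative().df if isinstance(abund, AbundanceTable) else abund
    ids = list(df.columns)
    rows = []
    for sample_id, p in df.iterrows():
        vec = p.to_numpy(dtype=float)
        if vec.sum() <= 0:
            warnings.warn(f"all-zero sample excluded from alpha diversity: {sample_id}")
            continue
        for component in components:
            if component == "neutral":
                value = hill_neutral(vec, q)
            elif component == "phylogenetic":
                value = hill_phylo(vec, tree, q, mag_ids=ids)
            elif component == "functional":
                value = hill_func(vec, distances, q, mag_ids=ids)
            else:
                raise ValueError(f"unknown component {component!r}")
            rows.append(
                {"sample_id": sample_id, "component": component, "q": q, "alpha": value}
            )
    return pd.DataFrame(rows)
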