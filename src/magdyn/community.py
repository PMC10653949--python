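"""Directional treatment effects on community composition.

Two distance-based procedures over a sample dissimilarity matrix (by
default the pairwise Sørensen-turnover matrices produced by
:mod:`magdyn.diversity`):

* :class:`Permanova` — one-way permutational multivariate ANOVA with the
  unadjusted R^2 as the effect-size of interest.  Repeated-measures designs
  are honoured by restricted permutations: treatment labels are shuffled
  only within each stratum (typically the individual), so the permutation
  null preserves the block structure.
* :class:`Cap` — canonical analysis of principal coordinates: a principal
  coordinate decomposition of the dissimilarity matrix followed by linear
  discriminant analysis of group membership on the first m coordinate axes,
  with m chosen by leave-one-out allocation success when not supplied.

Both are Model classes whose ``fit()`` returns a Results object with a
``summary()`` table.  Negative eigenvalues from non-Euclidean
dissimilarities are dropped (with a warning) in CAP; PERMANOVA sums of
squares use the raw Gower-centered matrix, where they cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["gower_center", "Permanova", "PermanovaResults", "permanova", "Cap", "CapResults", "cap"]


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        if list(d.columns) != ids:
            raise ValueError("distance matrix index and columns must match")
        d = d.to_numpy(dtype=float)
    else:
        d = np.asarray(d, dtype=float)
        ids = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return d, ids


def gower_center(d) -> np.ndarray:
    """Gower's double-centering: G = -1/2 J A J with A the squared distances."""
    d, _ = _as_square(d)
    A = -0.5 * d**2
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _group_ss(G: np.ndarray, labels: np.ndarray) -> float:
    """Among-group sum of squares tr(H G) for a doubly centered G."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss += G[np.ix_(idx, idx)].sum() / len(idx)
    return ss


@dataclass
class PermanovaResults:
    """PERMANOVA fit: pseudo-F, unadjusted R^2 and the permutation p-value."""

    term: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int
    ss_among: float
    ss_resid: float
    ss_total: float
    permuted_f: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        a, n = self.n_groups, self.n_samples
        return pd.DataFrame(
            {
                "df": [a - 1, n - a, n - 1],
                "sum_of_squares": [self.ss_among, self.ss_resid, self.ss_total],
                "pseudo_F": [self.pseudo_f, np.nan, np.nan],
                "R2": [self.r_squared, self.ss_resid / self.ss_total, 1.0],
                "p_value": [self.p_value, np.nan, np.nan],
            },
            index=[self.term, "Residual", "Total"],
        )

    def __str__(self):
        return (
            f"PERMANOVA ({self.term}): pseudo-F = {self.pseudo_f:.4f}, "
            f"R2 = {self.r_squared:.4f}, p = {self.p_value:.4g} "
            f"({self.n_permutations} restricted permutations)"
        )


class Permanova:
    """One-way PERMANOVA on a dissimilarity matrix with optional strata.

    Parameters
    ----------
    distance : DataFrame or ndarray
        Symmetric sample dissimilarity matrix.
    groups : Series or sequence
        Group label (e.g. treatment) per sample, aligned with the matrix.
    strata : Series or sequence, optional
        Block label per sample (e.g. individual); permutations shuffle group
        labels only within blocks.  ``None`` permutes freely.
    term : str
        Name of the tested factor, used in summaries.
    """

    def __init__(self, distance, groups, strata=None, term: str = "treatment"):
        self.D, self.ids = _as_square(distance)
        self.groups = self._aligned(groups, "groups")
        if len(np.unique(self.groups)) < 2:
            raise ValueError("groups must have at least 2 levels")
        self.strata = self._aligned(strata, "strata") if strata is not None else None
        self.term = term
        self.G = gower_center(self.D)

    def _aligned(self, values, what) -> np.ndarray:
        if isinstance(values, pd.Series):
            values = values.reindex(self.ids) if set(self.ids) <= set(values.index) else values
        arr = np.asarray(values)
        if len(arr) != len(self.ids):
            raise ValueError(f"{what} length does not match the distance matrix")
        return arr

    def _permuted_labels(self, rng) -> np.ndarray:
        labels = self.groups.copy()
        if self.strata is None:
            return rng.permutation(labels)
        for block in np.unique(self.strata):
            idx = np.flatnonzero(self.strata == block)
            if len(idx) > 1:
                labels[idx] = labels[idx[rng.permutation(len(idx))]]
        return labels

    def fit(self, n_permutations: int = 999, seed=None) -> PermanovaResults:
        rng = np.random.default_rng(seed)
        n = len(self.ids)
        a = len(np.unique(self.groups))
        ss_total = float(np.trace(self.G))
        ss_among = _group_ss(self.G, self.groups)
        ss_resid = ss_total - ss_among
        # ss_resid can be exactly 0 under complete separation: F is then +inf
        with np.errstate(divide="ignore"):
            f_obs = (ss_among / (a - 1)) / (ss_resid / (n - a))
        if self.strata is not None:
            singles = [
                b for b in np.unique(self.strata) if (self.strata == b).sum() == 1
            ]
            if singles:
                warnings.warn(
                    f"strata blocks with a single sample contribute no permutation: {singles}"
                )
        perm_f = np.empty(n_permutations)
        with np.errstate(divide="ignore"):
            for k in range(n_permutations):
                labels = self._permuted_labels(rng)
                ss_a = _group_ss(self.G, labels)
                perm_f[k] = (ss_a / (a - 1)) / ((ss_total - ss_a) / (n - a))
        p = (1 + np.sum(perm_f >= f_obs - 1e-12)) / (1 + n_permutations)
        return PermanovaResults(
            term=self.term,
            pseudo_f=float(f_obs),
            r_squared=float(ss_among / ss_total),
            p_value=float(p),
            n_permutations=n_permutations,
            n_samples=n,
            n_groups=a,
            ss_among=float(ss_among),
            ss_resid=float(ss_resid),
            ss_total=float(ss_total),
            permuted_f=perm_f,
        )


def permanova(d, groups, strata=None, n_perm: int = 999, seed=None, term="treatment"):
    """Convenience wrapper: fit a one-way PERMANOVA in one call."""
    return Permanova(d, groups, strata=strata, term=term).fit(n_permutations=n_perm, seed=seed)


@dataclass
class CapResults:
    """CAP fit: canonical site scores, PCoA eigenvalues and the retained m."""

    site_scores: pd.DataFrame
    eigenvalues: np.ndarray
    m: int
    loo_success: float
    groups: pd.Series

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [self.m, self.loo_success, self.site_scores.shape[1]],
            },
            index=["pcoa_axes_retained_m", "loo_allocation_success", "canonical_axes"],
        )

    def __str__(self):
        return (
            f"CAP: m = {self.m} PCo axes, LOO allocation success = "
            f"{self.loo_success:.3f}, {self.site_scores.shape[1]} canonical axes"
        )


class Cap:
    """Canonical analysis of principal coordinates for group separation."""

    def __init__(self, distance, groups):
        self.D, self.ids = _as_square(distance)
        groups = pd.Series(np.asarray(groups), index=self.ids)
        if groups.nunique() < 2:
            raise ValueError("CAP needs at least 2 groups")
        self.groups = groups
        G = gower_center(self.D)
        eigval, eigvec = linalg.eigh(G)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        tol = max(1e-10, 1e-8 * max(abs(eigval[0]), 1.0))
        negative = eigval < -tol
        if negative.any():
            warnings.warn(
                f"dropping {negative.sum()} negative-eigenvalue axes "
                "(non-Euclidean dissimilarity)"
            )
        keep = eigval > tol
        self.eigenvalues = eigval[keep]
        self.coordinates = eigvec[:, keep] * np.sqrt(self.eigenvalues)

    def _loo_success(self, m: int) -> float:
        X = self.coordinates[:, :m]
        y = self.groups.to_numpy()
        n = len(y)
        hits = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < 2:
                continue
            lda = LinearDiscriminantAnalysis()
            lda.fit(X[mask], y[mask])
            hits += lda.predict(X[i:i + 1])[0] == y[i]
        return hits / n

    def fit(self, m: int | None = None) -> CapResults:
        n_axes = self.coordinates.shape[1]
        if m is not None:
            if not 1 <= m <= n_axes:
                raise ValueError(f"m must be in [1, {n_axes}]")
            loo = self._loo_success(m)
        else:
            # smallest m maximizing leave-one-out allocation success
            best_m, loo = 1, -1.0
            upper = min(n_axes, len(self.ids) - 2)
            for cand in range(1, upper + 1):
                s = self._loo_success(cand)
                if s > loo + 1e-12:
                    best_m, loo = cand, s
            m = best_m
        lda = LinearDiscriminantAnalysis()
        lda.fit(self.coordinates[:, :m], self.groups.to_numpy())
        scores = lda.transform(self.coordinates[:, :m])
        n_canon = min(m, self.groups.nunique() - 1)
        scores = scores[:, :n_canon]
        site_scores = pd.DataFrame(
            scores,
            index=self.ids,
            columns=[f"CAP{i + 1}" for i in range(scores.shape[1])],
        )
        return CapResults(
            site_scores=site_scores,
            eigenvalues=self.eigenvalues,
            m=m,
            loo_success=loo,
            groups=self.groups,
        )


def cap(d, groups, m: int | None = None) -> CapResults:
    """Convenience wrapper: fit CAP in one call."""
    return Cap(d, groups).fit(m=m)
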