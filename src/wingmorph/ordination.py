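"""Ordination of tangent-space shape data.

PCA for exploratory structure, canonical variate analysis (CVA) across
groups with pairwise Mahalanobis distances and permutation tests, and the
centroid-size / altitude bivariate correlation.

Tangent shape data are rank-deficient (2k coordinates, 2k - 4 shape
dimensions) and group sizes can be smaller than the variable count, so the
within-group covariance is regularized by a PCA pre-reduction retaining a
fixed fraction of total variance, capped at n - g components.  Canonical
axes are eigenvectors of W^{-1}B scaled so the pooled within-group variance
along each axis is one; Euclidean distance between group means in that
space is then the Mahalanobis distance D, and the implementation
cross-checks this against the direct quadratic form on every fit.

Distances are reported on the D scale with D^2 alongside, both labelled,
because conventions differ between software packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .errors import AnalysisError

__all__ = [
    "PcaResult",
    "pca",
    "CanonicalVariates",
    "CVAResults",
    "two_group_permutation",
    "CorrelationResult",
    "size_covariate_correlation",
]

_RANK_TOL = 1e-12


@dataclass
class PcaResult:
    """Spectral decomposition of the sample covariance matrix.

    Loadings are columns; sign convention: the largest-magnitude element of
    each loading vector is positive.
    """

    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    mean: np.ndarray

    def n_components_for(self, fraction: float) -> int:
        """Smallest number of leading components whose cumulative variance
        proportion reaches `fraction`."""
        return int(np.searchsorted(self.cumulative, fraction - 1e-12) + 1)

    def summary(self) -> str:
        lines = ["Principal Component Analysis", "=" * 44,
                 f"{'PC':>4} {'eigenvalue':>12} {'prop':>8} {'cum':>8}"]
        for i, (ev, p, c) in enumerate(
            zip(self.eigenvalues, self.proportion, self.cumulative)
        ):
            lines.append(f"{i + 1:>4} {ev:>12.6g} {p:>8.4f} {c:>8.4f}")
            if i >= 14:
                lines.append(f"  ... ({len(self.eigenvalues) - 15} more)")
                break
        return "\n".join(lines)


def pca(x: np.ndarray) -> PcaResult:
    """PCA of a data matrix (rows = specimens) via SVD of the centred data;
    eigenvalues are those of the sample covariance (n - 1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise AnalysisError("pca requires an (n, p) matrix with n >= 3")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (x.shape[0] - 1)
    # fixed sign: largest-|.| element of each loading positive
    loadings = vt.T
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    scores = u * s
    total = eigenvalues.sum()
    if total <= 0:
        raise AnalysisError("data matrix has zero total variance")
    proportion = eigenvalues / total
    return PcaResult(
        eigenvalues=eigenvalues,
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        scores=scores,
        loadings=loadings,
        mean=mean,
    )


def _validate_groups(labels: pd.Series | Sequence, n: int) -> pd.Series:
    labels = pd.Series(list(labels))
    if len(labels) != n:
        raise AnalysisError("group labels length does not match data")
    return labels


def _group_indices(labels: pd.Series) -> dict[str, np.ndarray]:
    valid = labels.notna().to_numpy()
    names = sorted(labels[valid].unique())
    return {g: np.flatnonzero((labels == g).to_numpy()) for g in names}


@dataclass
class CVAResults:
    """Canonical variate analysis results.

    eigenvalues: canonical eigenvalues (at most g-1 nonzero);
    scores: specimen scores on the canonical axes, scaled so the pooled
    within-group variance along each axis is 1;
    mahalanobis_d / mahalanobis_d2: pairwise distances between group means
    on the D and D^2 scales (both labelled; D^2 is what some packages print);
    perm_pvalues: filled by permutation_test().
    """

    group_names: list[str]
    group_sizes: pd.Series
    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    scores: np.ndarray
    score_labels: pd.Series
    mean_scores: pd.DataFrame
    mahalanobis_d: pd.DataFrame
    mahalanobis_d2: pd.DataFrame
    n_components_retained: int
    var_retain: float
    perm_pvalues: Optional[pd.DataFrame] = None
    n_permutations: Optional[int] = None
    rng_seed: Optional[int] = None
    _model: "CanonicalVariates" = field(default=None, repr=False)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def n_axes_for(self, fraction: float) -> int:
        """Number of leading canonical variables needed to reach a given
        fraction of the among-group variation."""
        return int(np.searchsorted(self.cumulative, fraction - 1e-12) + 1)

    def permutation_test(
        self, n_perm: int = 1000, seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Pairwise permutation tests of the Mahalanobis distance between
        every pair of groups; stores and returns the p-value matrix."""
        g = self.n_groups
        pvals = np.ones((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                pair_seed = None if seed is None else (seed + 1000003 * i + j) % (2**31)
                p = self._model.pairwise_permutation(
                    self.group_names[i], self.group_names[j],
                    n_perm=n_perm, seed=pair_seed,
                )
                pvals[i, j] = pvals[j, i] = p
        self.perm_pvalues = pd.DataFrame(
            pvals, index=self.group_names, columns=self.group_names
        )
        self.n_permutations = n_perm
        self.rng_seed = seed
        return self.perm_pvalues

    def plot(self, ax=None, ellipse_prob: float = 0.90):
        from .plotting import cva_scatter

        return cva_scatter(self, ax=ax, ellipse_prob=ellipse_prob)

    def summary(self) -> str:
        lines = [
            "Canonical Variate Analysis",
            "=" * 46,
            f"groups: {self.n_groups}   specimens: {len(self.scores)}   "
            f"components retained: {self.n_components_retained}",
            "",
            f"{'CV':>4} {'eigenvalue':>12} {'prop':>8} {'cum':>8}",
        ]
        for i, (ev, p, c) in enumerate(
            zip(self.eigenvalues, self.proportion, self.cumulative)
        ):
            lines.append(f"{i + 1:>4} {ev:>12.6g} {p:>8.4f} {c:>8.4f}")
        lines += ["", "Mahalanobis distances D (lower triangle):"]
        with pd.option_context("display.float_format", "{:.3f}".format):
            lines.append(str(self.mahalanobis_d.where(
                np.tril(np.ones(self.mahalanobis_d.shape, bool), -1)
            ).fillna("")))
        if self.perm_pvalues is not None:
            lines += ["", f"permutation p-values ({self.n_permutations} permutations):"]
            with pd.option_context("display.float_format", "{:.4f}".format):
                lines.append(str(self.perm_pvalues))
        return "\n".join(lines)


class CanonicalVariates:
    """CVA model over tangent coordinates and a group partition.

    Parameters
    ----------
    x : (n, p) matrix of tangent coordinates.
    groups : per-specimen labels; NaN rows are excluded.
    var_retain : fraction of total variance kept by the PCA pre-reduction
        (capped at n - g components) that regularizes the within-group
        covariance.
    """

    def __init__(self, x: np.ndarray, groups, var_retain: float = 0.99):
        self.x = np.asarray(x, dtype=float)
        if self.x.ndim != 2:
            raise AnalysisError("x must be a 2-D matrix")
        self.groups = _validate_groups(groups, self.x.shape[0])
        if not (0 < var_retain <= 1):
            raise AnalysisError("var_retain must be in (0, 1]")
        self.var_retain = var_retain

        self._indices = _group_indices(self.groups)
        if len(self._indices) < 2:
            raise AnalysisError("CVA requires at least 2 groups")
        for g, idx in self._indices.items():
            if len(idx) < 2:
                raise AnalysisError(f"group {g!r} has fewer than 2 specimens")

    # -- shared reduction ---------------------------------------------------
    def _reduce(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """PCA pre-reduction of the grouped rows; returns (z, labels_idx,
        names).  Basis is fitted on the grouped specimens only."""
        names = list(self._indices)
        used = np.concatenate([self._indices[g] for g in names])
        used.sort()
        xg = self.x[used]
        n, g = len(used), len(names)
        if n - g < 1:
            raise AnalysisError("need n - g >= 1 specimens beyond group count")
        p = pca(xg)
        rank = int(np.sum(p.eigenvalues > _RANK_TOL * max(p.eigenvalues[0], 1e-300)))
        m = min(p.n_components_for(self.var_retain), n - g, rank)
        z = p.scores[:, :m]
        lab = self.groups.iloc[used].reset_index(drop=True)
        return z, lab, names

    @staticmethod
    def _scatter(z: np.ndarray, lab: pd.Series, names: list[str]):
        """Group means, pooled within-group covariance W and between-group
        covariance B of the reduced data."""
        n, m = z.shape
        g = len(names)
        means = np.stack([z[(lab == name).to_numpy()].mean(axis=0) for name in names])
        sizes = np.array([(lab == name).sum() for name in names])
        sw = np.zeros((m, m))
        for name, mu in zip(names, means):
            zg = z[(lab == name).to_numpy()] - mu
            sw += zg.T @ zg
        w = sw / (n - g)
        grand = (sizes[:, None] * means).sum(axis=0) / sizes.sum()
        dm = means - grand
        b = (sizes[:, None] * dm).T @ dm / (g - 1)
        return means, sizes, w, b

    def fit(self) -> CVAResults:
        z, lab, names = self._reduce()
        means, sizes, w, b = self._scatter(z, lab, names)
        g = len(names)

        try:
            evals, vecs = scipy.linalg.eigh(b, w)
        except scipy.linalg.LinAlgError as exc:
            raise AnalysisError(
                "within-group covariance is singular after reduction; "
                "lower var_retain"
            ) from exc
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        vecs = vecs[:, order]  # eigh(b, w): vecs.T @ w @ vecs = I

        n_axes = min(g - 1, z.shape[1])
        canonical_evals = evals[:n_axes]
        total = canonical_evals.sum()
        proportion = canonical_evals / total if total > 0 else np.zeros(n_axes)

        scores_all = z @ vecs
        mean_scores_all = means @ vecs
        # Mahalanobis distances use the full W-whitened space, which equals
        # the direct quadratic form (mi-mj)' W^{-1} (mi-mj)
        d2 = _pairwise_sq(mean_scores_all)
        d2_direct = _direct_mahalanobis_sq(means, w)
        if not np.allclose(d2, d2_direct, rtol=0, atol=1e-8 * max(1.0, d2.max())):
            raise AnalysisError(
                "internal cross-check failed: canonical-space distances do "
                "not match the direct Mahalanobis computation"
            )

        d2_df = pd.DataFrame(d2, index=names, columns=names)
        res = CVAResults(
            group_names=names,
            group_sizes=pd.Series(sizes, index=names),
            eigenvalues=canonical_evals,
            proportion=proportion,
            cumulative=np.cumsum(proportion),
            scores=scores_all[:, :n_axes],
            score_labels=lab,
            mean_scores=pd.DataFrame(
                mean_scores_all[:, :n_axes], index=names,
                columns=[f"CV{i + 1}" for i in range(n_axes)],
            ),
            mahalanobis_d=np.sqrt(d2_df),
            mahalanobis_d2=d2_df,
            n_components_retained=z.shape[1],
            var_retain=self.var_retain,
            _model=self,
        )
        return res

    def pairwise_permutation(
        self, group_a: str, group_b: str, n_perm: int = 1000,
        seed: Optional[int] = None,
    ) -> float:
        """Permutation test for one pair of groups (labels shuffled between
        the two groups only); statistic is the Mahalanobis distance between
        the two group means."""
        ia, ib = self._indices[group_a], self._indices[group_b]
        return two_group_permutation(
            self.x[ia], self.x[ib], n_perm=n_perm, seed=seed,
            var_retain=self.var_retain,
        )


def _pairwise_sq(m: np.ndarray) -> np.ndarray:
    diff = m[:, None, :] - m[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _direct_mahalanobis_sq(means: np.ndarray, w: np.ndarray) -> np.ndarray:
    g = means.shape[0]
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = means[i] - means[j]
            out[i, j] = out[j, i] = d @ np.linalg.solve(w, d)
    return out


def _two_group_d(z: np.ndarray, na: int) -> float:
    """Mahalanobis D between the first na rows and the rest of z."""
    za, zb = z[:na], z[na:]
    ma, mb = za.mean(axis=0), zb.mean(axis=0)
    sa = za - ma
    sb = zb - mb
    w = (sa.T @ sa + sb.T @ sb) / (len(z) - 2)
    d = ma - mb
    return float(np.sqrt(d @ np.linalg.solve(w, d)))


def two_group_permutation(
    xa: np.ndarray,
    xb: np.ndarray,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    var_retain: float = 0.99,
) -> float:
    """Permutation p-value for the Mahalanobis distance between two group
    means.  Specimen labels are shuffled between the two groups only and
    the statistic (including the pooled within-group covariance) is
    recomputed each time.  p = (1 + #{perm >= obs}) / (1 + n_perm), the
    add-one convention, so p is never zero."""
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    if len(xa) < 2 or len(xb) < 2:
        raise AnalysisError("both groups need at least 2 specimens")
    if n_perm < 99:
        raise AnalysisError("n_perm must be at least 99")
    pooled = np.vstack([xa, xb])
    n, na = len(pooled), len(xa)
    # joint reduction so W is invertible for every relabelling
    p = pca(pooled)
    rank = int(np.sum(p.eigenvalues > _RANK_TOL * max(p.eigenvalues[0], 1e-300)))
    m = min(p.n_components_for(var_retain), n - 2, rank)
    z = p.scores[:, :m]

    observed = _two_group_d(z, na)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(idx)
        if _two_group_d(z[idx], na) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class CorrelationResult:
    """Pearson correlation with a two-sided p-value from the t transform
    with n - 2 degrees of freedom."""

    r: float
    n: int
    pvalue: float
    var_x: str = "x"
    var_y: str = "y"

    def summary(self) -> str:
        stars = "**" if self.pvalue < 0.01 else ("*" if self.pvalue < 0.05 else "")
        return (
            f"Pearson correlation {self.var_x} ~ {self.var_y}: "
            f"r = {self.r:.3f}{stars} (n = {self.n}, p = {self.pvalue:.3g})"
        )


def size_covariate_correlation(
    centroid_sizes, altitudes, var_x: str = "altitude_masl",
    var_y: str = "centroid_size",
) -> CorrelationResult:
    """Bivariate Pearson correlation between centroid size and altitude
    (or any paired covariate)."""
    y = np.asarray(centroid_sizes, dtype=float)
    x = np.asarray(altitudes, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise AnalysisError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance in one of the variables")
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), pvalue=float(p),
                             var_x=var_x, var_y=var_y)
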