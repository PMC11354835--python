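"""Linear discriminant classification against reference groups.

The discriminant is the classical linear one: in the PCA-reduced tangent
subspace (same regularization policy as the CVA), each group scores a
query x as

    score_g(x) = m_g' W^{-1} x  -  1/2 m_g' W^{-1} m_g  +  log prior_g

with m_g the group mean and W the pooled within-group covariance; the
specimen is assigned to the argmax.  Priors default to equal because the
reference panels are balanced.  Leave-one-out cross-validation refits the
discriminant (including the subspace reduction) for every held-out
specimen; the superimposition itself is not redone, a standard and
documented approximation (GPA on n-1 vs n shapes is essentially
identical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .ordination import pca, _RANK_TOL

logger = logging.getLogger(__name__)

__all__ = [
    "LinearDiscriminant",
    "DiscriminantResults",
    "ClassificationResult",
    "loocv_accuracy",
    "frequency_table",
    "africanized_table",
]


def _fit_lda_arrays(x, labels, priors, var_retain):
    """Core LDA fit; returns (names, grand mean, basis, group means in the
    subspace, W^-1, log priors)."""
    labels = pd.Series(list(labels))
    valid = labels.notna().to_numpy()
    x = np.asarray(x, dtype=float)[valid]
    labels = labels[valid].reset_index(drop=True)
    names = sorted(labels.unique())
    g = len(names)
    if g < 2:
        raise AnalysisError("need at least 2 reference groups")
    sizes = np.array([(labels == name).sum() for name in names])
    if sizes.min() < 2:
        raise AnalysisError("every reference group needs at least 2 specimens")
    n = len(x)

    p = pca(x)
    rank = int(np.sum(p.eigenvalues > _RANK_TOL * max(p.eigenvalues[0], 1e-300)))
    m = min(p.n_components_for(var_retain), n - g, rank)
    basis = p.loadings[:, :m]
    z = (x - p.mean) @ basis

    means = np.stack([z[(labels == name).to_numpy()].mean(axis=0) for name in names])
    sw = np.zeros((m, m))
    for name, mu in zip(names, means):
        zg = z[(labels == name).to_numpy()] - mu
        sw += zg.T @ zg
    w = sw / (n - g)
    try:
        winv = np.linalg.inv(w)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError(
            "pooled within-group covariance is singular; lower var_retain"
        ) from exc

    if priors == "equal":
        log_priors = np.full(g, -np.log(g))
    elif priors == "proportional":
        log_priors = np.log(sizes / sizes.sum())
    else:
        raise AnalysisError("priors must be 'equal' or 'proportional'")
    return names, p.mean, basis, means, winv, log_priors


@dataclass
class ClassificationResult:
    """Assignments of query specimens to reference groups.

    scores: per-specimen discriminant scores for every group;
    weights: posterior-like normalized weights (softmax of the scores);
    assigned: the argmax group per specimen (ties broken toward the
    lexicographically first group name, with a logged warning).
    """

    assigned: pd.Series
    scores: pd.DataFrame
    weights: pd.DataFrame

    def confusion_matrix(self, true_labels) -> pd.DataFrame:
        """Known group x assigned group counts; rows sum to group sizes."""
        true = pd.Series(list(true_labels), index=self.assigned.index)
        groups = sorted(set(true.dropna()) | set(self.scores.columns))
        tab = pd.crosstab(true, self.assigned)
        return tab.reindex(index=sorted(set(true.dropna())),
                           columns=groups, fill_value=0)

    def accuracy(self, true_labels) -> float:
        true = pd.Series(list(true_labels), index=self.assigned.index)
        return float((self.assigned == true).mean())


@dataclass
class DiscriminantResults:
    """Fitted linear discriminant: group means, pooled-covariance inverse
    and the subspace basis, plus resubstitution diagnostics."""

    group_names: list[str]
    grand_mean: np.ndarray
    basis: np.ndarray
    means: np.ndarray
    winv: np.ndarray
    log_priors: np.ndarray
    provenance: Optional[str]
    resub: ClassificationResult
    accuracy_resub: float
    confusion_resub: pd.DataFrame
    _model: "LinearDiscriminant" = field(default=None, repr=False)

    def discriminant_scores(self, x: np.ndarray) -> pd.DataFrame:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.grand_mean) @ self.basis
        a = self.means @ self.winv  # (g, m)
        const = -0.5 * np.einsum("gm,gm->g", a, self.means) + self.log_priors
        return pd.DataFrame(z @ a.T + const, columns=self.group_names)

    def classify(
        self,
        x: np.ndarray,
        ids: Optional[Sequence[str]] = None,
        provenance: Optional[str] = None,
    ) -> ClassificationResult:
        """Assign query specimens to reference groups.

        Queries must be expressed in the same tangent basis as the training
        data (joint superimposition); when both the model and the call
        carry a provenance token they must match.
        """
        if (
            provenance is not None
            and self.provenance is not None
            and provenance != self.provenance
        ):
            raise AnalysisError(
                "query tangent coordinates come from a different "
                "superimposition than the training data"
            )
        scores = self.discriminant_scores(x)
        if ids is not None:
            scores.index = list(ids)
        s = scores.to_numpy()
        best = s.max(axis=1)
        assigned = []
        for row, b in zip(s, best):
            winners = [g for g, v in zip(self.group_names, row) if v >= b - 1e-10]
            if len(winners) > 1:
                logger.warning(
                    "tied discriminant scores among %s; assigning to %r",
                    winners, winners[0],
                )
            assigned.append(winners[0])
        shifted = np.exp(s - best[:, None])
        weights = pd.DataFrame(
            shifted / shifted.sum(axis=1, keepdims=True),
            index=scores.index, columns=self.group_names,
        )
        return ClassificationResult(
            assigned=pd.Series(assigned, index=scores.index, name="assigned"),
            scores=scores,
            weights=weights,
        )

    def loocv_accuracy(self) -> float:
        """Leave-one-out cross-validated accuracy on the reference data
        (the discriminant, including the subspace reduction, is refit for
        each held-out specimen)."""
        return loocv_accuracy(
            self._model.x, self._model.labels,
            priors=self._model.priors, var_retain=self._model.var_retain,
        )

    def summary(self) -> str:
        lines = [
            "Linear Discriminant Analysis",
            "=" * 40,
            f"reference groups: {len(self.group_names)}",
            f"subspace dimensions: {self.basis.shape[1]}",
            f"resubstitution accuracy: {100 * self.accuracy_resub:.2f}%",
            "",
            "confusion matrix (resubstitution):",
            str(self.confusion_resub),
        ]
        return "\n".join(lines)


class LinearDiscriminant:
    """Discriminant model over tangent coordinates and reference labels.

    Rows whose label is NaN are ignored at fit time (they are the queries).
    """

    def __init__(self, x, labels, priors: str = "equal",
                 var_retain: float = 0.99, provenance: Optional[str] = None):
        self.x = np.asarray(x, dtype=float)
        self.labels = pd.Series(list(labels))
        self.priors = priors
        self.var_retain = var_retain
        self.provenance = provenance

    def fit(self) -> DiscriminantResults:
        names, grand, basis, means, winv, log_priors = _fit_lda_arrays(
            self.x, self.labels, self.priors, self.var_retain
        )
        res = DiscriminantResults(
            group_names=names, grand_mean=grand, basis=basis, means=means,
            winv=winv, log_priors=log_priors, provenance=self.provenance,
            resub=None, accuracy_resub=np.nan, confusion_resub=None,
            _model=self,
        )
        valid = self.labels.notna().to_numpy()
        resub = res.classify(self.x[valid])
        true = self.labels[valid].reset_index(drop=True)
        res.resub = resub
        res.accuracy_resub = resub.accuracy(true)
        res.confusion_resub = resub.confusion_matrix(true)
        return res


def loocv_accuracy(x, labels, priors: str = "equal",
                   var_retain: float = 0.99) -> float:
    """Leave-one-out cross-validated classification accuracy.

    For every labelled specimen, the discriminant (subspace reduction
    included) is refit on the remaining specimens and the held-out one is
    classified; returns the fraction classified into its own group.
    """
    labels = pd.Series(list(labels))
    valid = labels.notna().to_numpy()
    x = np.asarray(x, dtype=float)[valid]
    labels = labels[valid].reset_index(drop=True)
    counts = labels.value_counts()
    if counts.min() < 3:
        raise AnalysisError("LOO cross-validation needs >= 3 specimens per group")
    n = len(x)
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        names, grand, basis, means, winv, log_priors = _fit_lda_arrays(
            x[mask], labels[mask], priors, var_retain
        )
        z = (x[i] - grand) @ basis
        a = means @ winv
        scores = a @ z - 0.5 * np.einsum("gm,gm->g", a, means) + log_priors
        if names[int(np.argmax(scores))] == labels.iloc[i]:
            correct += 1
        mask[i] = True
    return correct / n


def frequency_table(assigned, populations) -> pd.DataFrame:
    """Percentage of each population's specimens assigned to each
    reference group; rows sum to 100."""
    assigned = pd.Series(list(assigned), name="assigned")
    populations = pd.Series(list(populations), name="population")
    tab = pd.crosstab(populations, assigned)
    return tab.div(tab.sum(axis=1), axis=0) * 100


def africanized_table(
    assigned,
    floors,
    africanized_classes: Sequence[str] = ("A. m. scutellata", "AB"),
) -> pd.DataFrame:
    """Two-row Africanized / European percentage table by altitudinal
    floor.  A specimen counts as Africanized when assigned to the
    scutellata-like reference or to a hybrid (AB) class."""
    assigned = pd.Series(list(assigned))
    floors = pd.Series(list(floors), name="floor")
    if floors.isna().any():
        raise AnalysisError("missing altitudinal floor for some specimens")
    status = pd.Series(
        np.where(assigned.isin(list(africanized_classes)), "Africanized", "European"),
        name="morphotype",
    )
    tab = pd.crosstab(status, floors)
    tab = tab.reindex(index=["Africanized", "European"], fill_value=0)
    return tab.div(tab.sum(axis=0), axis=1) * 100
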