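"""Generalized Procrustes analysis and tangent-space projection.

Superimposition removes the nuisance variation (position, size,
orientation) from raw landmark configurations, leaving only shape.  The
convention used throughout is *partial* Procrustes: every configuration is
centred and scaled to unit centroid size, and only a proper rotation
(determinant +1; wings are all digitized on the same side, so reflections
are disallowed) is fitted.  Aligned shapes are then projected orthogonally
onto the linear tangent space at the consensus, where standard multivariate
statistics are valid.

Centroid sizes reported for the size–altitude analysis are taken from the
raw (pre-scaling) coordinates; after superimposition every shape has unit
centroid size by construction.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AnalysisError, DatasetError
from .tps import Dataset

__all__ = [
    "centroid_size",
    "procrustes_fit",
    "GeneralizedProcrustes",
    "GPAResults",
]


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of the summed squared deviations of the
    landmarks from their centroid.  Invariant to translation and rotation;
    scales linearly under isotropic scaling."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise AnalysisError("centroid_size requires a (k, 2) array with k >= 3")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0 or not np.isfinite(cs):
        raise AnalysisError("degenerate configuration: all landmarks coincide")
    return cs


def _center_scale(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs <= 0:
        raise AnalysisError("degenerate configuration: all landmarks coincide")
    return centered / cs


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R (2x2, det +1) minimizing ||a @ R - b||_F for
    centred configurations a, b, via SVD of the cross-covariance."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_fit(
    target: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Superimpose target onto reference (both (k, 2)): centre, scale to
    unit centroid size, and rotate (no reflection) to minimize the summed
    squared landmark distances.  Returns the aligned target and the partial
    Procrustes distance (root-sum-of-squares residual) to the centred,
    unit-scaled reference."""
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape:
        raise AnalysisError(
            f"landmark count mismatch: {target.shape} vs {reference.shape}"
        )
    a = _center_scale(target)
    b = _center_scale(reference)
    r = _optimal_rotation(a, b)
    aligned = a @ r
    residual = float(np.sqrt(np.sum((aligned - b) ** 2)))
    return aligned, residual


@dataclass
class GPAResults:
    """Superimposed dataset: aligned shapes, consensus, raw centroid
    sizes, and tangent-space coordinates.

    shapes: (n, k, 2) Procrustes coordinates, each centred with unit
    centroid size; consensus: (k, 2) mean shape (unit centroid size);
    tangent: (n, 2k) deviations from the consensus projected orthogonally
    onto the tangent space.  provenance identifies the superimposition so
    discriminant models can refuse queries aligned separately.
    """

    ids: list[str]
    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    tangent: np.ndarray
    n_iter: int
    converged: bool
    metadata: Optional[pd.DataFrame] = None
    provenance: str = field(default_factory=lambda: uuid.uuid4().hex)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Export specimen_id, centroid size and the 2k tangent coordinates
        (x1, y1, x2, y2, ...) as a DataFrame for external tools."""
        cols = [f"{axis}{i + 1}" for i in range(self.k) for axis in ("x", "y")]
        df = pd.DataFrame(self.tangent, columns=cols)
        df.insert(0, "centroid_size", self.centroid_sizes)
        df.insert(0, "specimen_id", self.ids)
        return df

    def summary(self) -> str:
        lines = [
            "Generalized Procrustes Analysis",
            "=" * 37,
            f"specimens:        {self.n}",
            f"landmarks:        {self.k}",
            f"iterations:       {self.n_iter}{'' if self.converged else ' (not converged)'}",
            f"mean centroid CS: {self.centroid_sizes.mean():.4f}",
            f"tangent variance: {self.tangent.var(axis=0).sum():.6g}",
        ]
        return "\n".join(lines)


class GeneralizedProcrustes:
    """Iterative GPA model over a landmark Dataset (or (n, k, 2) array).

    fit() centres and unit-scales every configuration, iteratively rotates
    all of them to the running consensus until the consensus stabilizes,
    aligns the final consensus to its principal axes for a deterministic
    orientation, and projects the aligned shapes into the tangent space.
    """

    def __init__(self, data: "Dataset | np.ndarray", ids: Optional[list[str]] = None):
        if isinstance(data, Dataset):
            self._coords = data.coords_array()
            self._ids = data.ids
            self._metadata = data.metadata_frame()
        else:
            self._coords = np.asarray(data, dtype=float)
            if self._coords.ndim != 3 or self._coords.shape[2] != 2:
                raise DatasetError("expected an (n, k, 2) coordinate array")
            self._ids = ids if ids is not None else [str(i) for i in range(len(self._coords))]
            self._metadata = None
        if self._coords.shape[0] < 2:
            raise DatasetError("GPA requires at least 2 configurations")
        if self._coords.shape[1] < 3:
            raise DatasetError("GPA requires at least 3 landmarks")

    def fit(self, tol: float = 1e-10, max_iter: int = 100) -> GPAResults:
        coords = self._coords
        n = coords.shape[0]
        sizes = np.array([centroid_size(c) for c in coords])
        shapes = np.stack([_center_scale(c) for c in coords])

        # start from the mean of the centred, scaled shapes: on data that
        # are already mutually aligned this is the fixed point, so refits
        # converge immediately; fall back to the first specimen if the
        # mean degenerates (arbitrary orientations can cancel out)
        mean0 = shapes.mean(axis=0)
        if np.sqrt(np.sum((mean0 - mean0.mean(axis=0)) ** 2)) > 1e-6:
            consensus = _center_scale(mean0)
        else:
            consensus = shapes[0].copy()
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            for i in range(n):
                shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
            new_consensus = shapes.mean(axis=0)
            new_consensus = _center_scale(new_consensus)
            # movement measured modulo rotation: the whole set's global
            # orientation is gauge freedom fixed later by the principal axes
            rot = _optimal_rotation(new_consensus, consensus)
            delta = np.sqrt(np.sum((new_consensus @ rot - consensus) ** 2))
            consensus = new_consensus
            if delta < tol:
                converged = True
                break
        if not converged:
            import warnings

            warnings.warn(
                f"GPA did not converge in {max_iter} iterations", stacklevel=2
            )

        # deterministic orientation: rotate the whole set so the consensus
        # lies along its principal axes, with a fixed sign convention
        u, _, vt = np.linalg.svd(consensus, full_matrices=False)
        rot = vt.T
        if np.linalg.det(rot) < 0:
            rot[:, 1] *= -1
        consensus = consensus @ rot
        shapes = shapes @ rot
        if consensus[0, 0] < 0:  # 180-degree rotation, still det +1
            consensus = -consensus
            shapes = -shapes

        flat = shapes.reshape(n, -1)
        c = consensus.reshape(-1)  # unit norm: consensus has unit CS
        tangent = flat - np.outer(flat @ c, c)

        return GPAResults(
            ids=list(self._ids),
            shapes=shapes,
            consensus=consensus,
            centroid_sizes=sizes,
            tangent=tangent,
            n_iter=n_iter,
            converged=converged,
            metadata=self._metadata,
        )


def tangent_project(aligned: GPAResults) -> GPAResults:
    """Recompute the orthogonal tangent-space projection of the aligned
    shapes at the consensus (idempotent; fit() already stores it)."""
    flat = aligned.shapes.reshape(aligned.n, -1)
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    aligned.tangent = flat - np.outer(flat @ c, c)
    return aligned
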