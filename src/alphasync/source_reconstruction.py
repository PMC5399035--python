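"""Source space, leadfields and the LCMV beamformer.

The spatial filter for source s with (orientation-resolved) leadfield
column l_s and regularized sensor covariance C is the linearly constrained
minimum-variance solution

    w_s = (l_sᵀ C⁻¹ l_s)⁻¹ l_sᵀ C⁻¹

which has unit gain at the source (w_s·l_s = 1) and minimum output
variance otherwise.  With free orientations, the scalar orientation per
source is the max-power direction: the generalized eigenvector minimising
lᵀC⁻¹l within the non-silent subspace of the local leadfield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .preprocessing import SensorEpochs

DEFAULT_REGULARIZATION = 0.05


class SingularCovarianceError(np.linalg.LinAlgError):
    """Regularized covariance not invertible; increase regularization."""


@dataclass
class SourceSpace:
    """Grid of candidate sources with atlas labels.

    Sources that fall outside every atlas area are masked out and excluded
    from leadfield and beamformer computation (white-matter analogue).
    """

    positions: np.ndarray
    orientations: np.ndarray | str
    atlas_labels: np.ndarray
    retained_mask: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.atlas_labels = np.asarray(self.atlas_labels, object)
        self.retained_mask = np.asarray(self.retained_mask, bool)
        if isinstance(self.orientations, str):
            if self.orientations != "free":
                raise ValueError("orientations must be an array or 'free'")
        else:
            self.orientations = np.asarray(self.orientations, float)
        labels = self.atlas_labels[self.retained_mask]
        if any(lab is None for lab in labels):
            raise ValueError("every retained source needs an atlas label")

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def retained_labels(self) -> np.ndarray:
        return self.atlas_labels[self.retained_mask]

    def area_table(self) -> pd.DataFrame:
        labs, counts = np.unique(self.retained_labels.astype(str),
                                 return_counts=True)
        return pd.DataFrame({"area": labs, "n_sources": counts})


@dataclass
class Leadfield:
    """channels × sources (fixed orientation) or channels × sources × 3."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield must be finite")
        if self.matrix.ndim not in (2, 3):
            raise ValueError("leadfield must be 2-D or 3-D")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BeamformerFilter:
    """LCMV weights (sources × channels) plus the covariance they solve."""

    weights: np.ndarray
    covariance_used: np.ndarray
    regularization: float
    orientations: np.ndarray | None = None


def label_sources(positions: np.ndarray, atlas) -> SourceSpace:
    """Assign each grid point to an atlas area.

    ``atlas`` maps a (3,) point to an area name or None; it may be a
    callable or an object with a ``label(point)`` method.  Unlabelled
    points are masked out.
    """
    lab_fn = atlas.label if hasattr(atlas, "label") else atlas
    if hasattr(atlas, "__len__") and len(atlas) == 0:
        raise ValueError("empty atlas")
    positions = np.asarray(positions, float)
    labels = np.array([lab_fn(p) for p in positions], object)
    mask = np.array([lab is not None for lab in labels])
    return SourceSpace(positions=positions, orientations="free",
                       atlas_labels=labels, retained_mask=mask)


def epoch_covariance(epochs: SensorEpochs) -> np.ndarray:
    """Average of per-epoch (demeaned) sample covariances."""
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    x = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    cov = np.einsum("ecs,eds->cd", x, x) / (epochs.n_epochs * epochs.n_samples)
    return 0.5 * (cov + cov.T)


def _regularize(cov: np.ndarray, fraction: float) -> np.ndarray:
    n = cov.shape[0]
    return cov + fraction * np.trace(cov) / n * np.eye(n)


def _max_power_orientation(local_lf: np.ndarray, cinv: np.ndarray) -> np.ndarray:
    """Orientation maximising LCMV output power, restricted to the subspace
    where the leadfield is non-silent (the radial direction of a spherical
    conductor carries no signal and must not be selected)."""
    u, s, _ = np.linalg.svd(local_lf, full_matrices=False)
    keep = s > max(1e-12, 1e-8 * s[0])
    basis = (u[:, keep] * s[keep])  # channels × k, leadfield restricted
    g = basis.T @ cinv @ basis
    _, vecs = np.linalg.eigh(g)
    # min lᵀC⁻¹l  <=>  max output power 1/(lᵀC⁻¹l)
    v = vecs[:, 0]
    ori, *_ = np.linalg.lstsq(local_lf, basis @ v, rcond=None)
    ori /= np.linalg.norm(ori)
    return ori


def lcmv_weights(leadfield: Leadfield, covariance: np.ndarray,
                 regularization_fraction: float = DEFAULT_REGULARIZATION
                 ) -> BeamformerFilter:
    """Unit-gain LCMV spatial filters for every source.

    Covariance is diagonally loaded by ``regularization_fraction`` of its
    mean eigenvalue.  A 3-D leadfield triggers max-power scalar orientation
    selection per source; a 2-D leadfield is used as-is.
    """
    if regularization_fraction < 0:
        raise ValueError("regularization_fraction must be >= 0")
    cov = _regularize(np.asarray(covariance, float), regularization_fraction)
    try:
        cho = linalg.cho_factor(cov)
    except np.linalg.LinAlgError as err:
        raise SingularCovarianceError(
            "regularized covariance is singular; increase "
            "regularization_fraction") from err
    cinv = linalg.cho_solve(cho, np.eye(cov.shape[0]))

    lf = leadfield.matrix
    orientations = None
    if lf.ndim == 3:
        orientations = np.empty((lf.shape[1], 3))
        cols = np.empty(lf.shape[:2])
        for s in range(lf.shape[1]):
            ori = _max_power_orientation(lf[:, s, :], cinv)
            orientations[s] = ori
            cols[:, s] = lf[:, s, :] @ ori
        lf = cols

    ci_l = cinv @ lf                      # channels × sources
    denom = np.einsum("cs,cs->s", lf, ci_l)
    if np.any(denom <= 0):
        raise SingularCovarianceError(
            "zero or negative source power denominator; leadfield column "
            "may be null — increase regularization or drop the source")
    weights = (ci_l / denom).T            # sources × channels
    return BeamformerFilter(weights=weights, covariance_used=cov,
                            regularization=regularization_fraction,
                            orientations=orientations)


def apply_weights(filt: BeamformerFilter, epochs: SensorEpochs) -> np.ndarray:
    """Project sensor epochs to source space: (n_epochs, n_sources, n_samples)."""
    if epochs.n_channels != filt.weights.shape[1]:
        raise ValueError(
            f"filter expects {filt.weights.shape[1]} channels, "
            f"epochs have {epochs.n_channels}")
    return np.einsum("sc,ecn->esn", filt.weights, epochs.data)


def weight_correlation_matrix(filt: BeamformerFilter,
                              labels: np.ndarray | list[str]) -> pd.DataFrame:
    """Source-leakage diagnostic: Pearson correlation of beamformer weight
    vectors, averaged over cross-area source pairs.

    High weight correlation between two sources means their reconstructed
    series share sensor-level mixing, so PLV between them is suspect.
    Group differences in these correlations (tested with the same edge-wise
    machinery as PLV) would indicate leakage-driven connectivity effects.
    Values lie in [−1, 1]; returned as a symmetric area × area DataFrame.
    """
    w = np.asarray(filt.weights, float)
    sd = w.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-norm weight vector for source "
                         f"{int(np.argmax(sd == 0))}: correlation undefined")
    wc = np.corrcoef(w)
    labels = np.asarray(labels)
    area_names = sorted(set(labels.tolist()))
    groups = {a: np.flatnonzero(labels == a) for a in area_names}
    n = len(area_names)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            block = wc[np.ix_(groups[area_names[i]], groups[area_names[j]])]
            out[i, j] = out[j, i] = block.mean()
    return pd.DataFrame(out, index=area_names, columns=area_names)
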