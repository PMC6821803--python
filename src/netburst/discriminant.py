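"""Canonical discriminant analysis of well-level feature vectors.

Fisher's canonical discriminant functions: with between-group scatter B and
pooled within-group covariance W (computed on internally standardized
features), the canonical axes solve the generalized eigenproblem
B v = λ W v, ordered by decreasing λ, at most min(g − 1, p) of them. Axes
are scaled so the canonical variates have unit pooled within-group variance.
Group membership is re-assigned by nearest group centroid in canonical space
(equal priors by default), and the resubstitution accuracy — the fraction of
training wells assigned back to their own group — is the reported
"percent correct classification". Resubstitution is the SPSS-style
convention; a leave-one-out flag provides the honest estimate. Group
envelopes are chi-square confidence ellipses of the canonical scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .core import ValidationError

#: ridge added to the pooled covariance, as a fraction of its trace
RIDGE = 1e-8


@dataclass
class FeatureMatrix:
    """Rows = wells, columns = named features, one group label per row."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (wells × features)")
        if self.X.shape[0] != self.labels.size:
            raise ValidationError("one label per row required")
        if self.X.shape[1] != len(self.feature_names):
            raise ValidationError("one name per feature column required")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains missing/non-finite values")
        groups, counts = np.unique(self.labels, return_counts=True)
        if groups.size < 2:
            raise ValidationError("need at least 2 groups")
        if np.any(counts < 2):
            small = groups[counts < 2]
            raise ValidationError(f"groups with fewer than 2 rows: {list(small)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_names, label_column: str = "group_label") -> "FeatureMatrix":
        return cls(
            df.loc[:, list(feature_names)].to_numpy(float),
            df[label_column].to_numpy(),
            tuple(feature_names),
        )


@dataclass
class DiscriminantModel:
    feature_names: tuple[str, ...]
    feature_mean: np.ndarray  # standardization offsets
    feature_scale: np.ndarray  # standardization scales
    coefficients: np.ndarray  # (p × k) canonical coefficient vectors
    eigenvalues: np.ndarray  # (k,) between/within eigenvalues
    group_names: np.ndarray
    centroids: np.ndarray  # (g × k) group centroids in canonical space
    priors: np.ndarray

    @property
    def n_functions(self) -> int:
        return self.coefficients.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Canonical scores of raw feature rows."""
        Z = (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale
        return Z @ self.coefficients


def fit_discriminant(data: FeatureMatrix, priors: str = "equal") -> DiscriminantModel:
    """Fit canonical discriminant functions to labeled feature vectors.

    Features are standardized internally, so the analysis is invariant to
    affine rescaling of any feature column. The pooled within-group
    covariance gets a small ridge (1e-8 × trace) before inversion; a matrix
    singular beyond that raises with advice to drop a redundant feature.
    """
    X, labels = data.X, data.labels
    groups = np.unique(labels)
    g, p = groups.size, X.shape[1]
    k = min(g - 1, p)

    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        dead = [data.feature_names[i] for i in np.flatnonzero(scale == 0)]
        raise ValidationError(f"constant feature column(s) {dead}: remove them")
    Z = (X - mean) / scale

    overall = Z.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in groups:
        Zi = Z[labels == grp]
        mi = Zi.mean(axis=0)
        W += (Zi - mi).T @ (Zi - mi)
        B += Zi.shape[0] * np.outer(mi - overall, mi - overall)
    n = Z.shape[0]
    W /= n - g  # pooled within-group covariance

    W_reg = W + RIDGE * np.trace(W) / p * np.eye(p)
    try:
        eigvals, eigvecs = linalg.eigh(B, W_reg)
    except linalg.LinAlgError as exc:
        raise ValidationError(
            "pooled within-group covariance is singular beyond ridge "
            "regularization; remove collinear features"
        ) from exc
    order = np.argsort(eigvals)[::-1][:k]
    vals = np.clip(eigvals[order], 0.0, None)
    vecs = eigvecs[:, order]
    # unit pooled within-group variance along each canonical axis
    within_var = np.einsum("ij,jk,ki->i", vecs.T, W, vecs)
    vecs = vecs / np.sqrt(np.clip(within_var, 1e-300, None))

    scores = Z @ vecs
    centroids = np.vstack([scores[labels == grp].mean(axis=0) for grp in groups])
    if priors == "equal":
        pr = np.full(g, 1.0 / g)
    elif priors == "proportional":
        pr = np.array([(labels == grp).mean() for grp in groups])
    else:
        raise ValidationError("priors must be 'equal' or 'proportional'")
    return DiscriminantModel(
        feature_names=data.feature_names,
        feature_mean=mean,
        feature_scale=scale,
        coefficients=vecs,
        eigenvalues=vals,
        group_names=groups,
        centroids=centroids,
        priors=pr,
    )


def reclassify(model: DiscriminantModel, data: FeatureMatrix) -> tuple[np.ndarray, float]:
    """Assign each row to its nearest centroid; return labels and % correct.

    Distances in canonical space are Euclidean (the canonical variates are
    whitened within groups), adjusted by −2·log(prior) for unequal priors.
    Applied to the training data this is the resubstitution accuracy.
    """
    if tuple(model.feature_names) != tuple(data.feature_names):
        raise ValidationError("feature columns do not match the fitted model")
    scores = model.transform(data.X)
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    d2 = d2 - 2.0 * np.log(model.priors)[None, :]
    predicted = model.group_names[np.argmin(d2, axis=1)]
    pct_correct = 100.0 * float(np.mean(predicted == data.labels))
    return predicted, pct_correct


def leave_one_out_accuracy(data: FeatureMatrix, priors: str = "equal") -> float:
    """Honest (leave-one-out) counterpart of the resubstitution accuracy."""
    n = data.X.shape[0]
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = FeatureMatrix(data.X[keep], data.labels[keep], data.feature_names)
        model = fit_discriminant(train, priors=priors)
        score = model.transform(data.X[i:i + 1])
        d2 = ((score - model.centroids) ** 2).sum(axis=1) - 2.0 * np.log(model.priors)
        pred = model.group_names[np.argmin(d2)]
        correct += int(pred == data.labels[i])
    return 100.0 * correct / n


@dataclass(frozen=True)
class Ellipse:
    """A confidence ellipse in canonical (function 1, function 2) space."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float
    group: str


def group_envelopes(
    model: DiscriminantModel, data: FeatureMatrix, confidence: float = 0.95
) -> list[Ellipse]:
    """Per-group confidence ellipses of canonical scores.

    Ellipses are centered on the group centroids; axes come from the
    eigendecomposition of each group's 2-D score covariance scaled by the
    chi-square quantile (2 df). A single canonical function is padded with a
    zero second dimension; a degenerate covariance collapses to a zero-radius
    circle with a warning.
    """
    import warnings

    scores = model.transform(data.X)
    if scores.shape[1] == 1:
        scores = np.hstack([scores, np.zeros_like(scores)])
    scores2 = scores[:, :2]
    q = chi2.ppf(confidence, df=2)
    ellipses = []
    for grp in model.group_names:
        s = scores2[data.labels == grp]
        if s.shape[0] < 3:
            raise ValidationError(f"group {grp}: need >= 3 rows for an envelope")
        center = s.mean(axis=0)
        cov = np.cov(s, rowvar=False)
        vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
        if np.any(vals <= 0):
            warnings.warn(f"group {grp}: degenerate score covariance", stacklevel=2)
            vals = np.clip(vals, 0.0, None)
        semi = np.sqrt(vals * q)
        angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
        ellipses.append(
            Ellipse(
                center=(float(center[0]), float(center[1])),
                semi_axes=(float(semi[-1]), float(semi[0])),  # major, minor
                angle_deg=angle,
                group=str(grp),
            )
        )
    return ellipses
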