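"""delta13C essential-amino-acid fingerprinting via linear discriminant analysis.

Metazoans cannot synthesize essential amino acids de novo, so a
consumer's eAA delta13C pattern is inherited from the basal resource
that produced them. After removing per-sample baseline offsets by
mean-centering, the multivariate pattern ("fingerprint") separates
plant-, bacteria- and fungus-derived carbon. This module classifies
consumers against an endmember training library with LDA built from
first principles (pooled within-class covariance, generalized
eigenproblem), plus leave-one-out cross-validation and confidence
ellipses for the discriminant plane.

Determinism conventions: discriminant axes are ordered by decreasing
eigenvalue with the largest-magnitude loading made positive; class
order is the order of first appearance in the library, and posterior
ties break to the earliest class in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DomainError, SchemaError, ValidationError

DEFAULT_PANEL = ("Ile", "Leu", "Phe", "Thr", "Val")


def mean_center(values: pd.DataFrame, panel: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Subtract each row's mean over ``panel`` from that row's panel entries.

    The centering mean defaults to all columns present (for the
    standard workflow: the full five-eAA panel, even when downstream
    analyses use a subset). Rows become zero-mean, removing per-sample
    baseline delta13C offsets so only the fingerprint pattern remains.
    Centering is idempotent and invariant to adding a per-row constant.
    """
    panel = tuple(panel) if panel is not None else tuple(values.columns)
    missing_cols = [c for c in panel if c not in values.columns]
    if missing_cols:
        raise SchemaError(f"panel columns not in matrix: {missing_cols}")
    sub = values[list(panel)]
    na = sub.isna()
    if na.any().any():
        cells = [(idx, col) for idx, row in na.iterrows() for col in panel if row[col]]
        raise ValidationError(f"missing cells in centering panel: {cells[:10]}")
    return sub.sub(sub.mean(axis=1), axis=0)


@dataclass
class SourceLibrary:
    """Endmember training specimens for the basal-resource classes.

    ``values`` holds one row per specimen (delta13C per panel eAA, no
    missing cells); ``labels`` the class of each specimen. Each class
    needs at least ``len(panel) + 2`` specimens so the pooled
    within-class covariance is nonsingular.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, index=self.values.index, dtype=object)
        if self.values.isna().any().any():
            raise ValidationError("source library must have no missing cells in the panel")
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValidationError("source library needs at least 2 classes")
        need = len(self.values.columns) + 2
        small = counts[counts < need]
        if len(small):
            raise ValidationError(
                f"classes with fewer than panel_size + 2 = {need} specimens: "
                f"{dict(small)} (pooled covariance would be singular)"
            )

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def classes(self) -> list[str]:
        # order of first appearance: the documented deterministic class order
        return list(dict.fromkeys(self.labels))

    def centered(self, panel: tuple[str, ...] | None = None) -> "SourceLibrary":
        return SourceLibrary(mean_center(self.values, panel), self.labels)

    def drop_specimen(self, idx) -> "SourceLibrary":
        return SourceLibrary(self.values.drop(index=idx), self.labels.drop(index=idx))


@dataclass
class LDAModel:
    """A fitted linear discriminant classifier.

    ``scalings`` projects centered-panel rows onto the discriminant
    axes; its columns are orthonormal under the within-covariance
    metric (v' W v = I). ``class_means`` live in the centered-eAA
    space the model was fitted in.
    """

    classes: list[str]
    class_means: np.ndarray        # (k, p), centered-panel space
    pooled_cov: np.ndarray         # (p, p), may be singular for centered data
    scalings: np.ndarray           # (p, r), r <= k-1
    eigenvalues: np.ndarray        # (r,)
    priors: np.ndarray             # (k,)
    panel: tuple[str, ...]
    basis: np.ndarray = None       # (p, r0) orthonormal basis of the data subspace
    _means_b: np.ndarray = None    # class means in basis coordinates
    _cov_b: np.ndarray = None      # pooled covariance in basis coordinates


def fit_lda(
    library: SourceLibrary,
    priors: str = "equal",
    ridge: float = 0.0,
    center: bool = True,
) -> LDAModel:
    """Fit LDA on the (centered) endmember library.

    Solves the generalized eigenproblem B v = lambda W v of
    between-class vs pooled within-class scatter. Mean-centered data
    live on the zero-sum hyperplane, so the problem is solved in the
    orthonormal basis of the data's own subspace (total-scatter range)
    and the scalings mapped back — the covariance is nonsingular
    there. ``priors`` is ``"equal"`` (default: library sizes are
    compilation artifacts, not prevalence) or ``"proportional"``. A
    ridge term ``ridge * I`` additionally regularizes genuinely
    degenerate within-class structure.
    """
    if priors not in ("equal", "proportional"):
        raise DomainError(f"priors must be 'equal' or 'proportional', got {priors!r}")
    lib = library.centered() if center else library
    X = lib.values.to_numpy(dtype=float)
    classes = lib.classes
    k, p = len(classes), X.shape[1]
    n = X.shape[0]

    means = np.vstack([X[(lib.labels == c).to_numpy()].mean(axis=0) for c in classes])
    counts = np.array([(lib.labels == c).sum() for c in classes], dtype=float)

    W = np.zeros((p, p))
    for ci, c in enumerate(classes):
        D = X[(lib.labels == c).to_numpy()] - means[ci]
        W += D.T @ D
    W /= n - k

    grand = (counts[:, None] * means).sum(axis=0) / counts.sum()
    Dm = means - grand
    B = (counts[:, None] * Dm).T @ Dm / (k - 1)

    # orthonormal basis of the subspace the data actually occupy
    tvals, tvecs = linalg.eigh(W + B)
    keep = tvals > max(tvals.max(), 1.0) * 1e-10
    Q = tvecs[:, keep]
    Wb = Q.T @ W @ Q + ridge * np.eye(Q.shape[1])
    Bb = Q.T @ B @ Q
    if np.linalg.matrix_rank(Wb, tol=1e-10 * max(np.abs(Wb).max(), 1.0)) < Wb.shape[0]:
        raise DomainError(
            "pooled within-class covariance is singular; pass ridge > 0 to regularize"
        )
    try:
        evals, evecs_b = linalg.eigh(Bb, Wb)
    except linalg.LinAlgError as exc:
        raise DomainError(
            "pooled within-class covariance is singular; pass ridge > 0 to regularize"
        ) from exc
    order = np.argsort(evals)[::-1][: min(k - 1, Q.shape[1])]
    evals = evals[order]
    evecs = Q @ evecs_b[:, order]
    # deterministic sign: make the largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    pri = np.full(k, 1.0 / k) if priors == "equal" else counts / counts.sum()
    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_cov=W,
        scalings=evecs,
        eigenvalues=evals,
        priors=pri,
        panel=lib.panel,
        basis=Q,
        _means_b=means @ Q,
        _cov_b=Wb,
    )


def classify(model: LDAModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Classify centered samples under the shared-covariance Gaussian model.

    Returns a DataFrame (index = sample index) with the predicted
    class, one posterior column per class (``post_<class>``), and the
    discriminant coordinates (``LD1``, ``LD2``, ...). Posterior ties
    break to the earliest class in the model's class order.
    """
    missing = [a for a in model.panel if a not in samples.columns]
    if missing:
        raise SchemaError(f"samples missing panel eAAs: {missing}")
    X = samples[list(model.panel)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("samples contain missing panel values")

    # work in the model's data-subspace basis (covariance nonsingular there)
    Xb = X @ model.basis
    Winv = linalg.inv(model._cov_b)
    # linear discriminant scores: x' W^-1 mu_c - mu_c' W^-1 mu_c / 2 + log pi_c
    A = Winv @ model._means_b.T                          # (r0, k)
    const = -0.5 * np.einsum("kp,pk->k", model._means_b, A) + np.log(model.priors)
    scores = Xb @ A + const                              # (n, k)
    scores -= scores.max(axis=1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(axis=1, keepdims=True)

    # earliest class within numerical tie of the max
    winners = [int(np.flatnonzero(row >= row.max() - 1e-12)[0]) for row in post]
    coords = X @ model.scalings

    out = pd.DataFrame(index=samples.index)
    out["predicted"] = [model.classes[w] for w in winners]
    for ci, c in enumerate(model.classes):
        out[f"post_{c}"] = post[:, ci]
    for j in range(coords.shape[1]):
        out[f"LD{j + 1}"] = coords[:, j]
    return out


def loocv_accuracy(
    library: SourceLibrary, priors: str = "equal", ridge: float = 0.0
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated accuracy plus the confusion matrix.

    Refits the LDA once per specimen with that specimen held out and
    predicts it; accuracy = correct / n. The confusion matrix is
    indexed true class x predicted class.
    """
    lib = library.centered()
    classes = lib.classes
    need = len(lib.panel) + 2
    counts = lib.labels.value_counts()
    small = counts[counts < need + 1]
    if len(small):
        raise ValidationError(
            f"LOOCV needs every class to keep >= {need} specimens after removal; "
            f"too small: {dict(small)}"
        )
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    correct = 0
    for idx in lib.values.index:
        model = fit_lda(lib.drop_specimen(idx), priors=priors, ridge=ridge, center=False)
        pred = classify(model, lib.values.loc[[idx]])["predicted"].iloc[0]
        truth = lib.labels.loc[idx]
        confusion.loc[truth, pred] += 1
        correct += pred == truth
    return correct / len(lib.values), confusion


@dataclass(frozen=True)
class ConfidenceEllipse:
    """A bivariate normal confidence ellipse in the discriminant plane."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]   # major, minor
    rotation: float                  # radians, angle of the major axis
    level: float
    degenerate: bool


def confidence_ellipse(coords, level: float = 0.95) -> ConfidenceEllipse:
    """Confidence ellipse of a 2-D point cloud.

    The sample covariance is scaled by the chi-square(2 df) quantile at
    ``level``; semi-axes are the square roots of the scaled
    eigenvalues. A zero-variance cloud yields a degenerate (flagged)
    ellipse with zero axes.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise DomainError(f"coords must be n x 2, got shape {X.shape}")
    if X.shape[0] < 3:
        raise DomainError(f"need >= 3 points for an ellipse, got {X.shape[0]}")
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1), got {level}")

    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    evals, evecs = linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    q = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(q * evals)[::-1]          # major first
    major_vec = evecs[:, -1]
    rotation = float(np.arctan2(major_vec[1], major_vec[0]))
    degenerate = bool(np.all(evals < 1e-14))
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        rotation=rotation,
        level=level,
        degenerate=degenerate,
    )
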