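"""Bayesian green/yellow pixel classification and digital-biomass counting.

After segmentation, the candidate plant pixels still mix green leaves,
senescent yellow leaves and occasionally soil.  A per-class color density
model separates them: each class (green = 1, yellow = 2) gets a full-
covariance multivariate Gaussian fitted to labelled training pixels in raw
RGB, and every masked pixel is assigned to the class maximising
``log pi_c + log N(color; mu_c, Sigma_c)``.  The result is the 0/1/2 label
image — 0 background, 1 green leaf, 2 yellow leaf — whose histogram yields
the green-pixel count used as digital biomass.

The classifier follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_log_proba``), so it composes with sklearn pipelines
and model selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

GREEN, YELLOW = 1, 2
CLASS_NAMES = {GREEN: "green", YELLOW: "yellow"}

__all__ = [
    "GREEN",
    "YELLOW",
    "LabeledPixelSample",
    "BiomassRecord",
    "GaussianPixelClassifier",
    "fit_pixel_classifier",
    "classify_pixels",
    "count_labels",
    "pixels_to_area",
    "sum_views",
    "load_training_csv",
]


@dataclass(frozen=True)
class LabeledPixelSample:
    """One labelled training pixel: an (r, g, b) triple and its class."""

    color: tuple[int, int, int]
    label: int

    def __post_init__(self):
        if self.label not in (GREEN, YELLOW):
            raise ValueError(f"label must be {GREEN} (green) or {YELLOW} (yellow)")


@dataclass(frozen=True)
class BiomassRecord:
    """Per-(pot, day) pixel counts; ``green_pixels`` is the digital biomass."""

    pot_id: str
    day: int
    green_pixels: int
    yellow_pixels: int

    @property
    def total_pixels(self) -> int:
        return self.green_pixels + self.yellow_pixels


class GaussianPixelClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-posterior Gaussian color classifier for leaf pixels.

    Parameters
    ----------
    epsilon : float, default 1.0
        Ridge added to each class covariance diagonal; keeps the densities
        well-defined when a training class is nearly monochrome.
    equal_priors : bool, default False
        Use uniform class priors instead of empirical class frequencies.

    Attributes (after ``fit``)
    --------------------------
    classes_ : (k,) sorted class labels
    means_ : (k, 3) per-class mean RGB
    covariances_ : (k, 3, 3) per-class sample covariance (ddof=1) + epsilon*I
    priors_ : (k,) class priors summing to 1
    """

    MIN_SAMPLES_PER_CLASS = 4

    def __init__(self, epsilon: float = 1.0, equal_priors: bool = False):
        self.epsilon = epsilon
        self.equal_priors = equal_priors

    def fit(self, X, y):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_samples, 3) RGB triples")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes of training pixels")
        means, covs, priors = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < self.MIN_SAMPLES_PER_CLASS:
                name = CLASS_NAMES.get(int(c), str(c))
                raise ValueError(
                    f"class {name!r} has only {len(Xc)} training pixels "
                    f"(need >= {self.MIN_SAMPLES_PER_CLASS})"
                )
            means.append(Xc.mean(axis=0))
            covs.append(np.cov(Xc, rowvar=False, ddof=1) + self.epsilon * np.eye(3))
            priors.append(len(Xc) / len(X))
        self.means_ = np.array(means)
        self.covariances_ = np.array(covs)
        if self.equal_priors:
            self.priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
        else:
            self.priors_ = np.array(priors)
        # cache Cholesky factors for the log-density
        self._chol_ = np.array([np.linalg.cholesky(S) for S in self.covariances_])
        self._logdet_ = np.array(
            [2.0 * np.log(np.diag(L)).sum() for L in self._chol_]
        )
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        """(n, k) matrix of log pi_c + log N(x; mu_c, Sigma_c)."""
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for j in range(len(self.classes_)):
            d = X - self.means_[j]
            z = np.linalg.solve(self._chol_[j], d.T)  # whiten
            maha = np.einsum("ij,ij->j", z, z)
            out[:, j] = (
                np.log(self.priors_[j])
                - 0.5 * (3 * np.log(2 * np.pi) + self._logdet_[j] + maha)
            )
        return out

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        norm = np.logaddexp.reduce(jll, axis=1, keepdims=True)
        return jll - norm

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        # argmax takes the first maximum, so exact ties go to the smaller
        # label — green (1) before yellow (2)
        return self.classes_[np.argmax(jll, axis=1)]

    # --- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "means_")
        return {
            "epsilon": self.epsilon,
            "equal_priors": self.equal_priors,
            "classes": self.classes_.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covariances_.tolist(),
            "priors": self.priors_.tolist(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianPixelClassifier":
        model = cls(epsilon=d.get("epsilon", 1.0), equal_priors=d.get("equal_priors", False))
        model.classes_ = np.array(d["classes"])
        model.means_ = np.array(d["means"], dtype=float)
        model.covariances_ = np.array(d["covariances"], dtype=float)
        model.priors_ = np.array(d["priors"], dtype=float)
        model._chol_ = np.array([np.linalg.cholesky(S) for S in model.covariances_])
        model._logdet_ = np.array([2.0 * np.log(np.diag(L)).sum() for L in model._chol_])
        return model

    @classmethod
    def load_json(cls, path) -> "GaussianPixelClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_pixel_classifier(
    samples, epsilon: float = 1.0, equal_priors: bool = False
) -> GaussianPixelClassifier:
    """Fit the Gaussian color model from labelled pixel samples.

    ``samples`` may be a list of :class:`LabeledPixelSample` or any iterable
    of ``(r, g, b, label)`` rows.
    """
    colors, labels = [], []
    for s in samples:
        if isinstance(s, LabeledPixelSample):
            colors.append(s.color)
            labels.append(s.label)
        else:
            r, g, b, lab = s
            colors.append((r, g, b))
            labels.append(int(lab))
    return GaussianPixelClassifier(epsilon=epsilon, equal_priors=equal_priors).fit(
        np.asarray(colors, dtype=float), np.asarray(labels)
    )


def load_training_csv(path):
    """Read a training table with columns r, g, b, label into (X, y)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"r", "g", "b", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"training CSV missing columns: {sorted(missing)}")
    return df[["r", "g", "b"]].to_numpy(dtype=float), df["label"].to_numpy(dtype=int)


def classify_pixels(img, mask, model: GaussianPixelClassifier) -> np.ndarray:
    """Label every masked pixel green (1) or yellow (2); background stays 0."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape[:2] != mask.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {img.shape[:2]}")
    labels = np.zeros(mask.shape, dtype=np.uint8)
    if mask.any():
        labels[mask] = model.predict(img[mask].astype(float)).astype(np.uint8)
    return labels


def count_labels(label_img, pot_id: str, day: int) -> BiomassRecord:
    """Histogram a 0/1/2 label image into a per-(pot, day) biomass record."""
    lbl = np.asarray(label_img)
    bad = np.setdiff1d(np.unique(lbl), [0, GREEN, YELLOW])
    if bad.size:
        raise ValueError(f"label image contains values outside {{0,1,2}}: {bad.tolist()}")
    return BiomassRecord(
        pot_id=pot_id,
        day=int(day),
        green_pixels=int((lbl == GREEN).sum()),
        yellow_pixels=int((lbl == YELLOW).sum()),
    )


def pixels_to_area(count: float, scale: float) -> float:
    """Convert a pixel count to mm^2 given a scale in pixels per mm.

    A 300 mm reference ruler spanning 3000 px gives scale = 10 px/mm, so one
    pixel covers 1/100 mm^2.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0 pixels per mm")
    return count / scale**2


def sum_views(areas) -> float:
    """Total projected area over multiple views (e.g. one top + four sides)."""
    areas = list(areas)
    if not areas:
        raise ValueError("need at least one view")
    return float(np.sum(areas))
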