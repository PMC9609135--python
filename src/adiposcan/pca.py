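"""Per-part principal component models.

For one part and sex, the height-normalized variable matrix is (by
default) z-standardized per column — the variable sets mix length,
circumference, area and volume ratios whose raw variances differ by
orders of magnitude — then the sample covariance

    C = 1/(n-1) * sum_i (x_i - x_bar)(x_i - x_bar)^T

is formed explicitly and eigendecomposed. Eigenvalues are sorted in
non-increasing order; each eigenvalue's share of the total variance is
reported as a percentage. At least two components are always retained
(the downstream classifier lives in the Comp1-Comp2 plane); more are kept
if needed to reach the configured explained-variance target. Loadings are
sign-fixed (largest-magnitude element positive) so serialized models are
reproducible across runs and platforms.

Every training subject is stored as a labeled point in the Comp1-Comp2
plane; per-class summaries (mean/median/min/max of both components)
describe the class clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import linalg

from .errors import DegenerateVarianceError, DomainError, SchemaError
from .preprocess import PartDataset
from .reference import FatClass


@dataclass
class PartPCAModel:
    part: str
    sex: str
    variable_names: tuple[str, ...]
    mean: np.ndarray  # per-variable mean on the input scale
    scale: np.ndarray  # per-variable sd used for standardization (ones if raw)
    loadings: np.ndarray  # p x p, column j = eigenvector of component j+1
    eigenvalues: np.ndarray  # non-increasing
    variance_shares: np.ndarray  # percent, sums to 100
    n_retained: int
    scores: np.ndarray  # n x 2, training subjects in the Comp1-Comp2 plane
    labels: list[FatClass]
    subject_ids: list[str]
    standardized: bool = True
    class_summaries: dict = field(default_factory=dict)

    # -- projection ---------------------------------------------------------

    def _vector(self, measurements: Mapping[str, float]) -> np.ndarray:
        try:
            return np.array([measurements[v] for v in self.variable_names], dtype=float)
        except KeyError as exc:
            raise SchemaError(
                f"{self.part}/{self.sex} model: missing variable {exc.args[0]!r}"
            ) from None

    def transform(self, x: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Project centered/standardized input onto the leading components."""
        t = n_components if n_components is not None else 2
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.mean) / self.scale
        return z @ self.loadings[:, :t]

    def project(self, measurements: Mapping[str, float]) -> tuple[float, float]:
        """(Comp1, Comp2) coordinates of one measurement map."""
        scores = self.transform(self._vector(measurements))
        return float(scores[0, 0]), float(scores[0, 1])

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Map full-dimensional component scores back to the input scale."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != len(self.variable_names):
            raise DomainError("inverse transform needs scores for every component")
        return scores @ self.loadings.T * self.scale + self.mean

    @property
    def training_points(self) -> list[tuple[float, float, FatClass, str]]:
        return [
            (float(c1), float(c2), label, sid)
            for (c1, c2), label, sid in zip(self.scores, self.labels, self.subject_ids)
        ]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "part": self.part,
            "sex": self.sex,
            "variable_names": list(self.variable_names),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_shares": self.variance_shares.tolist(),
            "n_retained": self.n_retained,
            "scores": self.scores.tolist(),
            "labels": [str(c) for c in self.labels],
            "subject_ids": list(self.subject_ids),
            "standardized": self.standardized,
            "class_summaries": self.class_summaries,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PartPCAModel":
        return cls(
            part=data["part"],
            sex=data["sex"],
            variable_names=tuple(data["variable_names"]),
            mean=np.asarray(data["mean"], dtype=float),
            scale=np.asarray(data["scale"], dtype=float),
            loadings=np.asarray(data["loadings"], dtype=float),
            eigenvalues=np.asarray(data["eigenvalues"], dtype=float),
            variance_shares=np.asarray(data["variance_shares"], dtype=float),
            n_retained=int(data["n_retained"]),
            scores=np.asarray(data["scores"], dtype=float),
            labels=[FatClass.from_label(c) for c in data["labels"]],
            subject_ids=list(data["subject_ids"]),
            standardized=bool(data["standardized"]),
            class_summaries=dict(data["class_summaries"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PartPCAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def covariance_eigendecomposition(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose the explicitly formed sample covariance of a
    subjects x variables matrix; returns (eigenvalues, eigenvectors) in
    non-increasing eigenvalue order, sign-fixed."""
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    values, vectors = linalg.eigh(cov)
    order = np.argsort(values)[::-1]
    values = np.clip(values[order], 0.0, None)
    vectors = vectors[:, order]
    flip = vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])] < 0
    vectors[:, flip] *= -1.0
    return values, vectors


def fit_part_pca(
    dataset: PartDataset,
    fv_target: float = 0.8,
    standardize: bool = True,
) -> PartPCAModel:
    """Fit the per-part component model on labeled training subjects.

    fv_target is the fraction of total variance the retained components
    must explain; at least two components are always kept.
    """
    x = dataset.matrix
    n, p = x.shape
    if n < 2:
        raise DomainError(f"{dataset.part}/{dataset.sex}: need >= 2 subjects, got {n}")
    if not 0.0 < fv_target <= 1.0:
        raise DomainError(f"fv_target must be in (0, 1], got {fv_target}")
    sd = x.std(axis=0, ddof=1)
    degenerate = [dataset.variable_names[j] for j in np.flatnonzero(sd <= 1e-12 * np.maximum(np.abs(x).max(axis=0), 1.0))]
    if degenerate:
        raise DegenerateVarianceError(
            f"{dataset.part}/{dataset.sex}: variable(s) with zero variance: {degenerate}"
        )
    mean = x.mean(axis=0)
    scale = sd if standardize else np.ones(p)
    z = (x - mean) / scale
    eigenvalues, loadings = covariance_eigendecomposition(z)
    total = eigenvalues.sum()
    shares = 100.0 * eigenvalues / total
    cumulative = np.cumsum(shares)
    n_retained = max(2, int(np.searchsorted(cumulative, 100.0 * fv_target - 1e-9) + 1))
    n_retained = min(n_retained, p)
    scores = z @ loadings[:, :2]
    model = PartPCAModel(
        part=dataset.part,
        sex=dataset.sex,
        variable_names=tuple(dataset.variable_names),
        mean=mean,
        scale=scale,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_shares=shares,
        n_retained=n_retained,
        scores=scores,
        labels=list(dataset.labels),
        subject_ids=list(dataset.subject_ids),
        standardized=standardize,
    )
    model.class_summaries = _class_summaries(model)
    return model


def _class_summaries(model: PartPCAModel) -> dict:
    """Per class, mean/median/min/max of each retained component."""
    summaries: dict[str, dict] = {}
    labels = np.array([int(c) for c in model.labels])
    for cls in FatClass:
        mask = labels == int(cls)
        if not mask.any():
            continue
        entry = {}
        for j, comp in enumerate(("comp1", "comp2")):
            col = model.scores[mask, j]
            entry[comp] = {
                "mean": float(col.mean()),
                "median": float(np.median(col)),
                "min": float(col.min()),
                "max": float(col.max()),
            }
        entry["n"] = int(mask.sum())
        summaries[str(cls)] = entry
    return summaries


def two_component_share(model: PartPCAModel) -> float:
    """Summed percentage variance share of Comp1 and Comp2."""
    return float(model.variance_shares[:2].sum())
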