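"""Neural surrogate for pose-change deformation.

Per-patient FE reposing is too slow for the clinic, so a feed-forward
network is trained on an FE-simulated cohort to map source-pose skin
landmarks (plus the source/target gravity directions) directly to the
target-pose skin landmark positions and the tumor-centroid dislocation.

Features: K skin landmarks chosen by farthest-point sampling seeded at the
breast apex (a deterministic, canonical ordering), flattened, plus the two
gravity unit vectors: 3K + 6 numbers.  The network predicts landmark
*displacements* and the tumor dislocation vector (3K + 3 numbers); absolute
target positions are recovered by adding the source landmarks back.  Loss
is squared error, i.e. the RMSE objective up to a monotone transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .geometry import GeometryError, TriMesh
from .phantom import Corpus
from .poses import PoseCase

__all__ = [
    "FeatureVector",
    "SurrogateModel",
    "Prediction",
    "farthest_point_landmarks",
    "make_features",
    "train",
    "predict",
    "accuracy_within",
]

DEFAULT_HIDDEN = (128, 128, 128)
DEFAULT_EPOCHS = 500
DEFAULT_DELTA_MM = 5.0  # surgical-margin-scale tolerance for "accuracy"


@dataclass(frozen=True)
class FeatureVector:
    """Flattened landmark coordinates plus the gravity pair; one subject."""

    landmarks: np.ndarray  # (K, 3) source-pose skin landmarks, mm
    gravity_source: np.ndarray  # unit 3-vector
    gravity_target: np.ndarray
    landmark_indices: np.ndarray  # (K,) vertex ids into the source skin mesh

    @property
    def k(self) -> int:
        return len(self.landmarks)

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.landmarks.ravel(), self.gravity_source, self.gravity_target]
        )


def farthest_point_landmarks(vertices: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point sampling seeded at the breast apex.

    The apex is the vertex of largest z (most anterior point); each further
    landmark maximises the distance to those already chosen.  Returns vertex
    indices in selection order (a canonical parameterization of the skin).
    """
    v = np.asarray(vertices, dtype=np.float64)
    if len(v) < k:
        raise GeometryError(f"mesh has {len(v)} vertices, fewer than K={k}")
    chosen = np.empty(k, dtype=np.int64)
    chosen[0] = int(np.argmax(v[:, 2]))
    dist = np.linalg.norm(v - v[chosen[0]], axis=1)
    for i in range(1, k):
        chosen[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(v - v[chosen[i]], axis=1))
    return chosen


def _canonical_order(vertices: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Order landmarks by a canonical surface parameterization.

    Spherical coordinates about the breast axis (through the base centroid,
    along +z): landmarks are binned into 22.5-degree polar bands from the
    apex outwards and sorted by azimuth within each band.  This makes
    landmark i refer to roughly the same anatomical region on every subject,
    which is what lets one network generalise across subjects.
    """
    # base-plane centre, phrased translation-equivariantly (min z ~ chest wall)
    centre = np.array(
        [vertices[:, 0].mean(), vertices[:, 1].mean(), vertices[:, 2].min()]
    )
    r = vertices[idx] - centre
    rn = np.linalg.norm(r, axis=1)
    rn[rn < 1e-12] = 1.0
    polar = np.arccos(np.clip(r[:, 2] / rn, -1.0, 1.0))
    azimuth = np.arctan2(r[:, 1], r[:, 0])
    band = np.floor(polar / (np.pi / 8.0)).astype(int)
    return idx[np.lexsort((azimuth, band))]


def make_features(
    skin_mesh_source: TriMesh,
    pose_pair: tuple[PoseCase, PoseCase],
    k: int = 64,
) -> FeatureVector:
    """Canonical K-landmark feature vector for one subject."""
    if k < 8:
        raise ValueError("K must be >= 8")
    src, tgt = pose_pair
    idx = farthest_point_landmarks(skin_mesh_source.vertices, k)
    idx = _canonical_order(skin_mesh_source.vertices, idx)
    return FeatureVector(
        landmarks=skin_mesh_source.vertices[idx].copy(),
        gravity_source=src.gravity.copy(),
        gravity_target=tgt.gravity.copy(),
        landmark_indices=idx,
    )


class LearningFailureWarning(UserWarning):
    """Training loss failed to decrease early in training."""


@dataclass
class SurrogateModel:
    """Trained deformation surrogate: weights plus normalisation constants."""

    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    k: int
    seed: int
    hidden: tuple[int, ...]
    train_loss: tuple[float, ...] = ()
    validation_rmse: float = float("nan")

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = (x - self.x_mean) / self.x_scale
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        h = h @ self.coefs[-1] + self.intercepts[-1]
        return h * self.y_scale + self.y_mean

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Network outputs (landmark displacements + tumor dislocation), mm."""
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        expected = 3 * self.k + 6
        if x.shape[1] != expected:
            raise ValueError(
                f"feature length {x.shape[1]} does not match model K={self.k} "
                f"(expected {expected})"
            )
        return self._forward(x)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single portable .npz file: weights plus a JSON metadata blob."""
        path = Path(path)
        meta = {
            "k": self.k,
            "seed": self.seed,
            "hidden": list(self.hidden),
            "n_layers": len(self.coefs),
            "train_loss": list(self.train_loss),
            "validation_rmse": self.validation_rmse,
        }
        arrays = {
            "x_mean": self.x_mean,
            "x_scale": self.x_scale,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        }
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            coefs = [data[f"W{i}"] for i in range(meta["n_layers"])]
            intercepts = [data[f"b{i}"] for i in range(meta["n_layers"])]
            return cls(
                coefs=coefs,
                intercepts=intercepts,
                x_mean=data["x_mean"],
                x_scale=data["x_scale"],
                y_mean=data["y_mean"],
                y_scale=data["y_scale"],
                k=meta["k"],
                seed=meta["seed"],
                hidden=tuple(meta["hidden"]),
                train_loss=tuple(meta["train_loss"]),
                validation_rmse=meta["validation_rmse"],
            )


def corpus_design(
    corpus: Corpus, k: int = 64
) -> tuple[np.ndarray, np.ndarray, list[FeatureVector]]:
    """Feature matrix X (n, 3K+6) and target matrix Y (n, 3K+3) for a corpus.

    Targets are landmark displacements (source -> target pose) followed by
    the tumor-centroid dislocation vector.
    """
    pose_pair = (corpus.pose_source, corpus.pose_target)
    X, Y, feats = [], [], []
    for rec in corpus.successful():
        fv = make_features(rec.skin_mesh_source, pose_pair, k)
        disp = rec.skin_vertices_target[fv.landmark_indices] - fv.landmarks
        X.append(fv.flatten())
        Y.append(np.concatenate([disp.ravel(), rec.tumor_dislocation]))
        feats.append(fv)
    if not X:
        raise ValueError("corpus has no successful records")
    return np.asarray(X), np.asarray(Y), feats


def train(
    corpus: Corpus,
    k: int = 64,
    hidden: tuple[int, ...] = DEFAULT_HIDDEN,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    holdout_fraction: float = 0.2,
    batch_size: int = 8,
    learning_rate: float = 1e-3,
    l2_alpha: float = 0.1,
) -> tuple[SurrogateModel, dict]:
    """Train the deformation surrogate on an FE corpus.

    Deterministic under fixed seed.  Returns (model, info) where info carries
    the train/validation split indices, loss trace and held-out RMSE.
    """
    n_ok = len(corpus.successful())
    if n_ok < 20:
        raise ValueError(f"corpus must have >= 20 successful subjects, got {n_ok}")
    if holdout_fraction < 0.2:
        raise ValueError("held-out split must be at least 20%")
    X, Y, _ = corpus_design(corpus, k)
    n = len(X)
    rng = np.random.default_rng([int(seed), 13])
    perm = rng.permutation(n)
    n_val = max(int(round(holdout_fraction * n)), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    x_mean, x_scale = X[train_idx].mean(axis=0), X[train_idx].std(axis=0)
    y_mean, y_scale = Y[train_idx].mean(axis=0), Y[train_idx].std(axis=0)
    x_scale[x_scale < 1e-8] = 1.0
    y_scale[y_scale < 1e-8] = 1.0

    Xn = (X - x_mean) / x_scale
    Yn = (Y - y_mean) / y_scale

    net = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        max_iter=epochs,
        random_state=int(seed) % (2**31),
        tol=0.0,
        n_iter_no_change=epochs + 1,
        early_stopping=False,
        batch_size=min(batch_size, len(train_idx)),
        learning_rate_init=learning_rate,
        alpha=l2_alpha,  # strong L2 suits the small-cohort regime
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        net.fit(Xn[train_idx], Yn[train_idx])

    loss_curve = tuple(float(v) for v in net.loss_curve_)
    head = max(int(0.1 * epochs), 2)
    if len(loss_curve) >= head and loss_curve[head - 1] >= loss_curve[0]:
        warnings.warn(
            "training loss did not decrease over the first 10% of epochs",
            LearningFailureWarning,
        )

    model = SurrogateModel(
        coefs=[np.asarray(w) for w in net.coefs_],
        intercepts=[np.asarray(b) for b in net.intercepts_],
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        k=k,
        seed=int(seed),
        hidden=tuple(hidden),
        train_loss=loss_curve,
    )
    pred_val = model.predict_raw(X[val_idx])
    val_rmse = float(np.sqrt(np.mean((pred_val - Y[val_idx]) ** 2)))
    model.validation_rmse = val_rmse
    info = {
        "train_indices": train_idx,
        "validation_indices": val_idx,
        "loss_curve": loss_curve,
        "validation_rmse": val_rmse,
    }
    return model, info


@dataclass(frozen=True)
class Prediction:
    """Surrogate output for one subject, in the SS reference frame (mm)."""

    landmarks_target: np.ndarray  # (K, 3) predicted target-pose skin landmarks
    tumor_dislocation: np.ndarray  # (3,) centroid displacement source -> target
    tumor_centroid_target: np.ndarray | None  # absolute, if source centroid known


def predict(
    model: SurrogateModel,
    features: FeatureVector,
    tumor_centroid_source: np.ndarray | None = None,
) -> Prediction:
    """Deterministic forward pass for one subject.

    If the source-pose tumor centroid is supplied (it is known from the
    fused MRI segmentation), the absolute target-pose centroid is returned
    alongside the dislocation vector.
    """
    if features.k != model.k:
        raise ValueError(f"feature K={features.k} does not match model K={model.k}")
    out = model.predict_raw(features.flatten())[0]
    disp = out[: 3 * model.k].reshape(-1, 3)
    dislocation = out[3 * model.k :]
    centroid = (
        None
        if tumor_centroid_source is None
        else np.asarray(tumor_centroid_source, dtype=np.float64) + dislocation
    )
    return Prediction(
        landmarks_target=features.landmarks + disp,
        tumor_dislocation=dislocation,
        tumor_centroid_target=centroid,
    )


def accuracy_within(
    predicted: np.ndarray, truth: np.ndarray, delta: float = DEFAULT_DELTA_MM
) -> float:
    """Fraction of matched points whose Euclidean error is <= delta (mm)."""
    p = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    t = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("point sets must be non-empty")
    err = np.linalg.norm(p - t, axis=1)
    return float(np.mean(err <= delta))
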