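"""PCA reduction of TFPSSM vectors and the Euclidean metric on the scores.

Components are fit on training data only and applied to both training and
test vectors; the protein-protein distance used by all neighbor selection
is the Euclidean distance in this projected space.  The number of retained
components is the smallest count whose cumulative explained-variance ratio
reaches the requested target; whitening (on by default) rescales each
retained component to unit variance on the training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .features import TfpssmVector

__all__ = [
    "PcaModel",
    "ReducedVector",
    "fit_pca",
    "transform",
    "transform_many",
    "euclidean_distance",
    "apply_cluster_representatives",
    "read_cluster_table",
    "DEFAULT_TARGET_RATIO",
]

#: explained-variance target used by default; whitening defaults on
DEFAULT_TARGET_RATIO = 0.96

_VAR_FLOOR = 1e-15


@dataclass
class PcaModel:
    """A fitted PCA projection.

    ``components`` rows are orthonormal principal axes (sign-fixed so each
    row's largest-magnitude entry is positive); ``explained_variance`` are
    the per-component training variances (ddof=1).
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    whiten: bool
    target_ratio: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def input_dim(self) -> int:
        return self.components.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "whiten": self.whiten,
            "target_ratio": self.target_ratio,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(d["mean"]),
            components=np.array(d["components"]),
            explained_variance=np.array(d["explained_variance"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            whiten=bool(d["whiten"]),
            target_ratio=float(d["target_ratio"]),
        )


@dataclass
class ReducedVector:
    protein_id: str
    coordinates: np.ndarray


def select_n_components(ratios: Sequence[float], target_ratio: float) -> int:
    """Smallest component count whose cumulative ratio reaches the target."""
    cumulative = np.cumsum(ratios)
    # tiny slack so an exact hit is not lost to rounding
    reached = np.nonzero(cumulative >= target_ratio - 1e-12)[0]
    if reached.size == 0:
        return len(ratios)
    return int(reached[0]) + 1


def fit_pca(
    train: Sequence[TfpssmVector] | np.ndarray,
    target_ratio: float = DEFAULT_TARGET_RATIO,
    whiten: bool = True,
) -> PcaModel:
    """Fit PCA on training feature vectors.

    Raises ``ValueError`` for fewer than 2 rows or a target ratio outside
    (0, 1].  Deterministic given row order: the full SVD is computed and
    each component's sign is fixed by its largest-magnitude entry.
    """
    if not 0 < target_ratio <= 1:
        raise ValueError(f"target_ratio must be in (0, 1], got {target_ratio}")
    X = _as_matrix(train)
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 training rows, got {X.shape[0]}")
    pca = PCA(svd_solver="full").fit(X)
    n = select_n_components(pca.explained_variance_ratio_, target_ratio)
    components = pca.components_[:n].copy()
    # sign convention: largest-magnitude entry of each axis is positive
    flip = np.sign(components[np.arange(n), np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    components *= flip[:, None]
    return PcaModel(
        mean=pca.mean_,
        components=components,
        explained_variance=pca.explained_variance_[:n].copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:n].copy(),
        whiten=whiten,
        target_ratio=target_ratio,
    )


def transform(model: PcaModel, v: TfpssmVector) -> ReducedVector:
    """Project one feature vector into the model's component space."""
    coords = _project(model, v.values[None, :])[0]
    return ReducedVector(protein_id=v.protein_id, coordinates=coords)


def transform_many(
    model: PcaModel, vectors: Iterable[TfpssmVector]
) -> list[ReducedVector]:
    vectors = list(vectors)
    if not vectors:
        return []
    coords = _project(model, _as_matrix(vectors))
    return [
        ReducedVector(v.protein_id, c) for v, c in zip(vectors, coords)
    ]


def euclidean_distance(a: ReducedVector, b: ReducedVector) -> float:
    """L2 distance in the projected space."""
    if a.coordinates.shape != b.coordinates.shape:
        raise ValueError(
            f"dimension mismatch: {a.coordinates.shape} vs {b.coordinates.shape}"
        )
    return float(np.linalg.norm(a.coordinates - b.coordinates))


def _as_matrix(vectors: Sequence[TfpssmVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return vectors
    return np.stack([v.values for v in vectors])


def _project(model: PcaModel, X: np.ndarray) -> np.ndarray:
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"input dimension {X.shape[1]} != model dimension {model.input_dim}"
        )
    coords = (X - model.mean) @ model.components.T
    if model.whiten:
        coords = coords / np.sqrt(np.maximum(model.explained_variance, _VAR_FLOOR))
    return coords


def read_cluster_table(stream) -> dict[str, str]:
    """Read protein_id TAB cluster_id; '#' comment lines skipped."""
    import io

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    table: dict[str, str] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"cluster TSV line {lineno}: expected 2 columns")
        table[fields[0]] = fields[1]
    return table


def apply_cluster_representatives(
    vectors: Sequence[TfpssmVector], clusters: dict[str, str]
) -> list[TfpssmVector]:
    """Keep one representative per sequence-identity cluster.

    Stands in for upstream redundancy reduction: the first member of each
    cluster (ascending protein id) is retained; proteins absent from the
    table are kept as singletons.
    """
    seen: set[str] = set()
    kept = []
    for v in sorted(vectors, key=lambda v: v.protein_id):
        cluster = clusters.get(v.protein_id, v.protein_id)
        if cluster in seen:
            continue
        seen.add(cluster)
        kept.append(v)
    return kept
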