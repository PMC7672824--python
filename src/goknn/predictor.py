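"""KNN-voting GO predictors: neighbor selection, vote weighting, hierarchical
score propagation, plus the Naive and BLAST-transfer baselines.

Four neighbor-selection strategies operate in the PCA-projected feature
space:

* ``one_nn``  — the single nearest training protein; its closed GO set is
  transferred with confidence 1.00.
* ``fixed``   — the k nearest training proteins.
* ``dynamic`` — every training protein strictly closer than a trained
  distance threshold (a quartile of the training set's nearest-neighbor
  distance distribution); queries with no such neighbor are unpredicted.
* ``hybrid``  — dynamic, falling back to fixed-k when dynamic is empty, so
  every query is covered.

Selected neighbors vote for their (ancestor-closed) GO terms with a weight
of 1 (equal), 1/d (inverse), sqrt(1/d), or the FunFam-overlap proportion.
Raw votes are propagated child-to-parent through the ontology (Sum or Max
merge), root terms are dropped, and scores are max-normalized to (0, 1].
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .ontology import GoDag
from .reduction import ReducedVector

__all__ = [
    "KnnConfig",
    "Neighbor",
    "TermScores",
    "TrainingIndex",
    "nearest_neighbors_fixed",
    "dynamic_distance_threshold",
    "nearest_neighbors_dynamic",
    "hybrid_neighbors",
    "voting_weight",
    "funoverlap_weight",
    "read_funfam_assignments",
    "vote",
    "propagate_scores",
    "normalize_scores",
    "predict",
    "predict_all",
    "naive_baseline",
    "blast_baseline",
    "read_cafa_predictions",
    "write_cafa_predictions",
    "FUNFAM_EVALUE_THRESHOLD",
]

#: FunFam assignments above this E-value are discarded before overlap weighting
FUNFAM_EVALUE_THRESHOLD = 1e-5

#: clamp for inverse-distance weights at d == 0 (exact duplicate proteins)
_DISTANCE_EPSILON = 1e-9

_MODES = ("one_nn", "fixed", "dynamic", "hybrid")
_SCHEMES = ("equal", "inverse", "sqrt_inverse", "funoverlap")
_QUARTILES = {"Q1": 0.25, "Q2": 0.50, "Q3": 0.75}


@dataclass
class KnnConfig:
    """Neighbor-selection and voting configuration.

    ``funoverlap`` weighting is only meaningful for ``dynamic`` mode, where
    a neighbor with no usable FunFam overlap can simply be dropped; the
    fixed modes guarantee k voters and would break that contract.
    """

    mode: str = "fixed"
    k: int = 3
    quartile: str = "Q2"
    weight_scheme: str = "inverse"
    propagation: str = "sum"
    funoverlap_asymmetric: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.weight_scheme not in _SCHEMES:
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.propagation not in ("sum", "max"):
            raise ValueError(f"propagation must be 'sum' or 'max'")
        if self.mode in ("fixed", "hybrid") and self.k < 1:
            raise ValueError("k must be >= 1 for fixed/hybrid modes")
        if self.mode in ("dynamic", "hybrid") and self.quartile not in _QUARTILES:
            raise ValueError(f"quartile must be one of {sorted(_QUARTILES)}")
        if self.weight_scheme == "funoverlap" and self.mode != "dynamic":
            raise ValueError("funoverlap weighting requires dynamic mode")


@dataclass(frozen=True)
class Neighbor:
    protein_id: str
    distance: float
    weight: float


@dataclass
class TermScores:
    """Map of GO id to non-negative vote score."""

    scores: dict[str, float] = field(default_factory=dict)
    normalized: bool = False

    def __getitem__(self, term: str) -> float:
        return self.scores[term]

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def items(self):
        return self.scores.items()


class TrainingIndex:
    """Reduced training vectors, stacked for vectorized distance queries."""

    def __init__(self, vectors: Sequence[ReducedVector]):
        if not vectors:
            raise ValueError("empty training set")
        order = np.argsort([v.protein_id for v in vectors], kind="stable")
        self.ids = [vectors[i].protein_id for i in order]
        self.matrix = np.stack([vectors[i].coordinates for i in order])

    def __len__(self) -> int:
        return len(self.ids)

    def distances_to(self, query: ReducedVector) -> np.ndarray:
        if query.coordinates.shape[0] != self.matrix.shape[1]:
            raise ValueError("query dimension does not match training index")
        return np.linalg.norm(self.matrix - query.coordinates, axis=1)


def _sorted_neighbors(index: TrainingIndex, dist: np.ndarray) -> list[tuple[float, str]]:
    # index.ids is already ascending, so a stable sort on distance breaks
    # ties by ascending protein_id
    order = np.argsort(dist, kind="stable")
    return [(float(dist[i]), index.ids[i]) for i in order]


def nearest_neighbors_fixed(
    query: ReducedVector, index: TrainingIndex, k: int
) -> list[Neighbor]:
    """The k training proteins nearest to the query.

    Ties in distance are broken by ascending protein id; the result is
    sorted by (distance, protein_id).  Weights are left at 1 for the caller
    to overwrite.
    """
    if not 1 <= k <= len(index):
        raise ValueError(f"k={k} outside [1, {len(index)}]")
    pairs = _sorted_neighbors(index, index.distances_to(query))[:k]
    return [Neighbor(pid, d, 1.0) for d, pid in pairs]


def dynamic_distance_threshold(index: TrainingIndex, quartile: str) -> float:
    """Quartile of the training set's nearest-neighbor distance distribution.

    For each training protein, the distance to its nearest *other* training
    protein is computed; the requested quartile (Q1/Q2/Q3, linear
    interpolation) of that distribution is the dynamic selection radius.
    """
    if quartile not in _QUARTILES:
        raise ValueError(f"quartile must be one of {sorted(_QUARTILES)}")
    if len(index) < 2:
        raise ValueError("need at least 2 training proteins")
    diff = index.matrix[:, None, :] - index.matrix[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(d, np.inf)
    nn_dist = d.min(axis=1)
    return float(np.quantile(nn_dist, _QUARTILES[quartile], method="linear"))


def nearest_neighbors_dynamic(
    query: ReducedVector, index: TrainingIndex, threshold: float
) -> list[Neighbor]:
    """All training proteins strictly closer than the threshold.

    May be empty, in which case dynamic mode leaves the query unpredicted.
    """
    dist = index.distances_to(query)
    pairs = [(d, pid) for d, pid in _sorted_neighbors(index, dist) if d < threshold]
    return [Neighbor(pid, d, 1.0) for d, pid in pairs]


def hybrid_neighbors(
    query: ReducedVector, index: TrainingIndex, k: int, threshold: float
) -> list[Neighbor]:
    """Dynamic selection with a fixed-k fallback: every query gets neighbors."""
    selected = nearest_neighbors_dynamic(query, index, threshold)
    if selected:
        return selected
    return nearest_neighbors_fixed(query, index, k)


def voting_weight(distance: float, scheme: str) -> float:
    """Distance-based vote weight: 1, 1/d, or sqrt(1/d) (d clamped at 1e-9)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if scheme == "equal":
        return 1.0
    d = max(distance, _DISTANCE_EPSILON)
    if scheme == "inverse":
        return 1.0 / d
    if scheme == "sqrt_inverse":
        return math.sqrt(1.0 / d)
    raise ValueError(f"unknown distance weight scheme {scheme!r}")


def funoverlap_weight(
    query_funfams: set[str],
    neighbor_funfams: set[str],
    asymmetric: bool = False,
) -> float | None:
    """Overlap proportion between query and neighbor FunFam assignments.

    Jaccard (|intersection| / |union|) by default; the asymmetric variant
    divides by the query's set size instead.  Returns ``None`` — neighbor
    excluded from voting — when either set is empty or the overlap is zero.
    """
    if not query_funfams or not neighbor_funfams:
        return None
    inter = len(query_funfams & neighbor_funfams)
    if inter == 0:
        return None
    denom = len(query_funfams) if asymmetric else len(query_funfams | neighbor_funfams)
    return inter / denom


def read_funfam_assignments(
    stream: IO[str] | str, evalue_threshold: float = FUNFAM_EVALUE_THRESHOLD
) -> dict[str, set[str]]:
    """Read protein_id TAB funfam_id TAB e_value; keep rows with E <= threshold."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"FunFam TSV line {lineno}: expected 3 columns")
        pid, funfam, evalue = fields
        if float(evalue) <= evalue_threshold:
            out.setdefault(pid, set()).add(funfam)
    return out


def _weight_neighbors(
    neighbors: list[Neighbor],
    cfg: KnnConfig,
    query_id: str,
    funfams: Mapping[str, set[str]] | None,
) -> list[Neighbor]:
    if cfg.weight_scheme == "funoverlap":
        if funfams is None:
            raise ValueError("funoverlap weighting requires FunFam assignments")
        weighted = []
        qff = funfams.get(query_id, set())
        for nb in neighbors:
            w = funoverlap_weight(
                qff, funfams.get(nb.protein_id, set()), cfg.funoverlap_asymmetric
            )
            if w is not None:
                weighted.append(Neighbor(nb.protein_id, nb.distance, w))
        return weighted
    return [
        Neighbor(nb.protein_id, nb.distance, voting_weight(nb.distance, cfg.weight_scheme))
        for nb in neighbors
    ]


def vote(neighbors: Sequence[Neighbor], annotations: Mapping[str, set[str]]) -> TermScores:
    """Accumulate each neighbor's weight onto every term it is annotated with."""
    scores: dict[str, float] = {}
    for nb in neighbors:
        if nb.protein_id not in annotations:
            raise KeyError(f"neighbor {nb.protein_id} has no annotation record")
        for term in annotations[nb.protein_id]:
            scores[term] = scores.get(term, 0.0) + nb.weight
    return TermScores(scores)


def propagate_scores(
    raw: TermScores, dag: GoDag, mode: str = "sum", unique_descendants: bool = False
) -> TermScores:
    """Propagate votes child-to-parent through the ontology.

    Terms are processed children-before-parents; each term's propagated
    score merges its own direct votes with its direct children's propagated
    scores — ``max`` takes the maximum, ``sum`` adds every child's
    propagated score.  In a diamond-shaped region the recursive sum counts
    a descendant once per path; with ``unique_descendants`` each
    descendant's direct votes are counted once instead (irrelevant for
    trees and for ``max``).
    """
    if mode not in ("sum", "max"):
        raise ValueError("mode must be 'sum' or 'max'")
    for term in raw:
        if term not in dag:
            raise KeyError(f"scored term {term} absent from ontology")
    if mode == "sum" and unique_descendants:
        return _propagate_sum_unique(raw, dag)
    out: dict[str, float] = {}
    for term in dag.topological_order():
        own = raw.scores.get(term, 0.0)
        child_scores = [out[c] for c in dag.children(term) if c in out]
        if mode == "max":
            merged = max([own, *child_scores])
        else:
            merged = own + sum(child_scores)
        if merged > 0:
            out[term] = merged
    return TermScores(out)


def _propagate_sum_unique(raw: TermScores, dag: GoDag) -> TermScores:
    """Sum propagation counting each voted descendant once per ancestor."""
    from .ontology import ancestors as _ancestors

    out: dict[str, float] = {}
    for term, score in raw.items():
        if score <= 0:
            continue
        out[term] = out.get(term, 0.0) + score
        for anc in _ancestors(dag, term):
            out[anc] = out.get(anc, 0.0) + score
    return TermScores(out)


def normalize_scores(s: TermScores) -> TermScores:
    """Divide every score by the maximum, mapping scores into (0, 1]."""
    if not s.scores or max(s.scores.values()) <= 0:
        import warnings

        warnings.warn("all-zero scores: empty prediction", stacklevel=2)
        return TermScores({}, normalized=True)
    top = max(s.scores.values())
    return TermScores({t: v / top for t, v in s.items() if v > 0}, normalized=True)


def _select_neighbors(
    query: ReducedVector,
    index: TrainingIndex,
    cfg: KnnConfig,
    threshold: float | None,
) -> list[Neighbor]:
    if cfg.mode == "one_nn":
        return nearest_neighbors_fixed(query, index, 1)
    if cfg.mode == "fixed":
        return nearest_neighbors_fixed(query, index, cfg.k)
    if threshold is None:
        raise ValueError(f"{cfg.mode} mode needs a distance threshold")
    if cfg.mode == "dynamic":
        return nearest_neighbors_dynamic(query, index, threshold)
    return hybrid_neighbors(query, index, cfg.k, threshold)


def predict(
    query: ReducedVector,
    index: TrainingIndex,
    annotations: Mapping[str, set[str]],
    dag: GoDag,
    cfg: KnnConfig,
    threshold: float | None = None,
    funfams: Mapping[str, set[str]] | None = None,
) -> TermScores | None:
    """Predict GO term confidences for one query protein.

    ``annotations`` must already be ancestor-closed.  Returns ``None`` when
    dynamic mode finds no neighbor within the threshold (the query is
    unpredicted).  1NN transfers the nearest neighbor's closed term set
    with confidence 1.00; the voting modes run
    vote -> propagate -> drop roots -> max-normalize.
    """
    neighbors = _select_neighbors(query, index, cfg, threshold)
    if cfg.mode == "one_nn":
        nearest = neighbors[0]
        terms = annotations.get(nearest.protein_id)
        if terms is None:
            raise KeyError(f"neighbor {nearest.protein_id} has no annotation record")
        return TermScores({t: 1.0 for t in terms if t not in dag.root_ids}, normalized=True)
    neighbors = _weight_neighbors(neighbors, cfg, query.protein_id, funfams)
    if not neighbors:
        return None
    raw = vote(neighbors, annotations)
    propagated = propagate_scores(raw, dag, cfg.propagation)
    non_root = TermScores(
        {t: v for t, v in propagated.items() if t not in dag.root_ids}
    )
    return normalize_scores(non_root)


def predict_all(
    queries: Sequence[ReducedVector],
    index: TrainingIndex,
    annotations: Mapping[str, set[str]],
    dag: GoDag,
    cfg: KnnConfig,
    funfams: Mapping[str, set[str]] | None = None,
) -> dict[str, TermScores]:
    """Predict every query; the dynamic threshold is fit once on the index.

    Unpredicted queries (dynamic mode, empty neighborhood) are absent from
    the result — the partial-evaluation case.
    """
    threshold = None
    if cfg.mode in ("dynamic", "hybrid"):
        threshold = dynamic_distance_threshold(index, cfg.quartile)
    out: dict[str, TermScores] = {}
    for q in queries:
        scores = predict(q, index, annotations, dag, cfg, threshold, funfams)
        if scores is not None and len(scores):
            out[q.protein_id] = scores
    return out


def naive_baseline(annotations: Mapping[str, set[str]]) -> TermScores:
    """Background term frequencies: every query gets this same prediction.

    score(term) = fraction of training proteins annotated (after closure)
    with the term.
    """
    if not annotations:
        raise ValueError("empty training annotation set")
    n = len(annotations)
    counts: dict[str, int] = {}
    for terms in annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return TermScores({t: c / n for t, c in counts.items()}, normalized=True)


_EVALUE_FLOOR = 1e-180


def blast_baseline(
    hits: IO[str] | str, annotations: Mapping[str, set[str]]
) -> dict[str, TermScores]:
    """Homology-transfer baseline from a 12-column BLAST tabular hit file.

    Each hit's weight is -log10(E) (E clamped at 1e-180); a term's raw
    score is the best weight among hits whose subject carries the term
    (after closure), then scores are max-normalized per query.  Queries
    with no usable hit are absent from the result.
    """
    if isinstance(hits, str):
        hits = io.StringIO(hits)
    raw: dict[str, dict[str, float]] = {}
    for lineno, line in enumerate(hits, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"BLAST tabular line {lineno}: expected 12 columns, got {len(fields)}"
            )
        query, subject = fields[0], fields[1]
        try:
            evalue = float(fields[10])
        except ValueError:
            raise ValueError(f"BLAST tabular line {lineno}: bad E-value") from None
        if subject not in annotations:
            continue
        w = -math.log10(max(evalue, _EVALUE_FLOOR))
        if w <= 0:
            continue
        scores = raw.setdefault(query, {})
        for term in annotations[subject]:
            scores[term] = max(scores.get(term, 0.0), w)
    return {q: normalize_scores(TermScores(s)) for q, s in raw.items() if s}


_CAFA_LINE_RE = re.compile(r"^(\S+)\s+(GO:\d{7})\s+([01]\.\d{2})$")


def write_cafa_predictions(
    predictions: Mapping[str, TermScores],
    stream: IO[str],
    author: str = "goknn",
    model: int = 1,
    keywords: str = "sequence properties",
) -> None:
    """Write predictions in CAFA submission format (scores in [0.01, 1.00])."""
    stream.write(f"AUTHOR {author}\n")
    stream.write(f"MODEL {model}\n")
    stream.write(f"KEYWORDS {keywords}.\n")
    for protein in sorted(predictions):
        for term in sorted(predictions[protein]):
            score = min(1.0, max(0.01, predictions[protein][term]))
            stream.write(f"{protein}\t{term}\t{score:.2f}\n")
    stream.write("END\n")


def read_cafa_predictions(stream: IO[str] | str) -> dict[str, TermScores]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, dict[str, float]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.split()[0] in ("AUTHOR", "MODEL", "KEYWORDS", "END"):
            continue
        m = _CAFA_LINE_RE.match(line)
        if not m:
            raise ValueError(f"prediction line {lineno}: malformed: {line!r}")
        out.setdefault(m.group(1), {})[m.group(2)] = float(m.group(3))
    return {p: TermScores(s, normalized=True) for p, s in out.items()}
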