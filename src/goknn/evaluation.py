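"""Protein-centric precision/recall evaluation and cross-validation splits.

For each protein i and decision threshold tau, the predicted set
P_i(tau) = {terms with confidence >= tau} is compared against the
experimentally determined (ancestor-closed) set T_i:

    pr_i(tau) = |P_i(tau) & T_i| / |P_i(tau)|
    rc_i(tau) = |P_i(tau) & T_i| / |T_i|

Precision is averaged over m(tau), the proteins with a non-empty P_i(tau);
recall is averaged over n_e — every benchmark protein in *full* mode, only
the proteins the method attempted (m(0)) in *partial* mode.  Fmax is the
maximum harmonic mean of the averaged precision and recall over the tau
grid (0.00 to 1.00 in steps of 0.01 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np

from .ontology import GoDag, close_annotations
from .predictor import TermScores

__all__ = [
    "EvalMode",
    "PrPoint",
    "EvalResult",
    "FoldSplit",
    "default_tau_grid",
    "protein_pr",
    "aggregate_pr",
    "evaluate",
    "coverage_table",
    "five_fold_split",
]


def default_tau_grid() -> np.ndarray:
    """Thresholds 0.00, 0.01, ..., 1.00."""
    return np.round(np.arange(0, 101) / 100, 2)


@dataclass(frozen=True)
class EvalMode:
    """Evaluation denominator policy: 'full' (all proteins) or 'partial' (m(0))."""

    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "partial"):
            raise ValueError("mode must be 'full' or 'partial'")


@dataclass(frozen=True)
class PrPoint:
    tau: float
    pr: float
    rc: float
    m_tau: int


@dataclass
class EvalResult:
    curve: list[PrPoint]
    fmax: float
    tau_at_fmax: float
    coverage: float
    n_benchmark: int
    n_predicted: int

    def save(self, json_path: str | Path, curve_path: str | Path | None = None) -> None:
        payload = {
            "fmax": self.fmax,
            "tau_at_fmax": self.tau_at_fmax,
            "coverage": self.coverage,
            "n_benchmark": self.n_benchmark,
            "n_predicted": self.n_predicted,
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))
        if curve_path is not None:
            with Path(curve_path).open("w") as fh:
                fh.write("tau\tpr\trc\tm_tau\n")
                for p in self.curve:
                    fh.write(f"{p.tau:.2f}\t{p.pr:.6f}\t{p.rc:.6f}\t{p.m_tau}\n")


@dataclass
class FoldSplit:
    assignments: dict[str, int]
    seed: int
    n_folds: int = 5

    def fold(self, index: int) -> set[str]:
        return {p for p, f in self.assignments.items() if f == index}

    def train_validation(self, index: int) -> tuple[set[str], set[str]]:
        validation = self.fold(index)
        train = {p for p in self.assignments if p not in validation}
        return train, validation


def protein_pr(
    pred: TermScores, truth: set[str], tau: float
) -> tuple[float | None, float]:
    """Per-protein precision and recall at threshold tau.

    Precision is ``None`` when no term reaches tau (the protein then does
    not count toward m(tau)); recall is 0 in that case.
    """
    if not truth:
        raise ValueError("empty truth set: protein should have been skipped")
    predicted = {t for t, s in pred.items() if s >= tau}
    if not predicted:
        return None, 0.0
    hits = len(predicted & truth)
    return hits / len(predicted), hits / len(truth)


def aggregate_pr(
    per_protein: Sequence[tuple[float | None, float]],
    mode: EvalMode,
    tau: float,
    n_full: int,
) -> PrPoint | None:
    """Average per-protein precision over m(tau) and recall over n_e.

    ``per_protein`` holds one (pr_i, rc_i) pair per *attempted* protein
    (those with any prediction at tau=0); ``n_full`` is the benchmark size.
    Returns ``None`` when m(tau) is empty (precision undefined).
    """
    m_tau = [p for p, _ in per_protein if p is not None]
    if not m_tau:
        return None
    n_e = n_full if mode.mode == "full" else len(per_protein)
    if n_e < 1:
        raise ValueError("evaluation denominator must be >= 1")
    pr = sum(m_tau) / len(m_tau)
    rc = sum(r for _, r in per_protein) / n_e
    return PrPoint(tau=tau, pr=pr, rc=rc, m_tau=len(m_tau))


def evaluate(
    predictions: Mapping[str, TermScores],
    truth: Mapping[str, set[str]],
    dag: GoDag,
    mode: EvalMode = EvalMode("full"),
    tau_grid: Sequence[float] | None = None,
    close_inputs: bool = True,
) -> EvalResult:
    """Protein-centric PR curve, Fmax, and coverage for a prediction set.

    Both predictions and truth are ancestor-closed (roots dropped) before
    counting unless ``close_inputs`` is false (for inputs already closed).
    Proteins with empty truth after closure are excluded with a warning.
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    closed_truth = close_annotations(dag, truth) if close_inputs else dict(truth)
    benchmark = {p for p, t in closed_truth.items() if t}
    skipped = set(closed_truth) - benchmark
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} protein(s) with empty truth after closure",
            stacklevel=2,
        )
    if benchmark and not any(p in benchmark for p in predictions):
        raise ValueError("prediction and truth protein sets are disjoint")

    closed_preds: dict[str, TermScores] = {}
    for protein, scores in predictions.items():
        if protein not in benchmark:
            continue
        if close_inputs:
            closed_preds[protein] = _close_scores(scores, dag)
        else:
            closed_preds[protein] = scores
    attempted = {p: s for p, s in closed_preds.items() if len(s)}

    n_full = len(benchmark)
    curve: list[PrPoint] = []
    best: PrPoint | None = None
    fmax, tau_at = 0.0, 0.0
    for tau in tau_grid:
        per = [protein_pr(s, closed_truth[p], tau) for p, s in attempted.items()]
        point = aggregate_pr(per, mode, float(tau), n_full)
        if point is None:
            continue
        curve.append(point)
        if point.pr + point.rc > 0:
            f = 2 * point.pr * point.rc / (point.pr + point.rc)
            if f > fmax:
                fmax, tau_at, best = f, point.tau, point
    coverage = len(attempted) / n_full if n_full else 0.0
    return EvalResult(
        curve=curve,
        fmax=fmax,
        tau_at_fmax=tau_at,
        coverage=coverage,
        n_benchmark=n_full,
        n_predicted=len(attempted),
    )


def _close_scores(scores: TermScores, dag: GoDag) -> TermScores:
    """Ancestor-close a prediction: each ancestor gets its best descendant score."""
    from .ontology import ancestors

    closed: dict[str, float] = {}
    roots = dag.root_ids
    for term, s in scores.items():
        for t in (term, *ancestors(dag, term)):
            if t not in roots:
                closed[t] = max(closed.get(t, 0.0), s)
    return TermScores(closed, normalized=scores.normalized)


def coverage_table(
    predictions_per_config: Mapping[str, Mapping[str, TermScores]],
    dataset: Sequence[str],
) -> list[tuple[str, int, float]]:
    """Per-configuration count and percentage of proteins with a prediction."""
    total = len(dataset)
    rows = []
    for config, preds in predictions_per_config.items():
        n = sum(1 for p in dataset if p in preds and len(preds[p]))
        rows.append((config, n, 100.0 * n / total if total else 0.0))
    return rows


def five_fold_split(
    protein_ids: Sequence[str],
    seed: int,
    cluster_table: Mapping[str, str] | None = None,
    n_folds: int = 5,
) -> FoldSplit:
    """Seeded shuffle + round-robin assignment into five folds.

    With a sequence-identity cluster table, whole clusters go to one fold
    (largest clusters first, to the currently smallest fold) so redundant
    sequences never straddle the train/validation boundary.
    """
    ids = sorted(set(protein_ids))
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} proteins, got {len(ids)}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    if cluster_table is None:
        order = list(rng.permutation(ids))
        for i, pid in enumerate(order):
            assignments[pid] = i % n_folds
    else:
        clusters: dict[str, list[str]] = {}
        for pid in ids:
            clusters.setdefault(cluster_table.get(pid, pid), []).append(pid)
        names = list(rng.permutation(sorted(clusters)))
        names.sort(key=lambda c: -len(clusters[c]))
        sizes = [0] * n_folds
        for name in names:
            fold = int(np.argmin(sizes))
            for pid in clusters[name]:
                assignments[pid] = fold
            sizes[fold] += len(clusters[name])
    return FoldSplit(assignments=assignments, seed=seed, n_folds=n_folds)
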