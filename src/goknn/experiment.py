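"""Run configuration and cross-validated experiment grids.

``RunConfig`` captures one grid run: the feature max gap, PCA target
ratio/whitening, the neighbor-mode x weight-scheme x propagation grid, and
the evaluation mode.  ``run_experiment_grid`` evaluates every cell by
five-fold cross-validation and reports per-cell mean Fmax and coverage,
so the best (mode, k or quartile, weighting, propagation) combination per
ontology namespace can be read off the table.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

from .evaluation import EvalMode, evaluate, five_fold_split
from .features import DEFAULT_MAX_GAP, Pssm, compute_tfpssm
from .ontology import GoDag, close_annotations
from .predictor import KnnConfig, TrainingIndex, predict_all
from .reduction import DEFAULT_TARGET_RATIO, fit_pca, transform_many

__all__ = ["RunConfig", "GridCell", "run_experiment_grid", "featurize_benchmark"]

log = logging.getLogger("goknn")


@dataclass
class RunConfig:
    """Serializable description of one experiment-grid run."""

    max_gap: int = DEFAULT_MAX_GAP
    target_ratio: float = DEFAULT_TARGET_RATIO
    whiten: bool = True
    modes: tuple[str, ...] = ("one_nn", "fixed", "dynamic", "hybrid")
    k_values: tuple[int, ...] = tuple(range(1, 11))
    quartiles: tuple[str, ...] = ("Q1", "Q2", "Q3")
    weight_schemes: tuple[str, ...] = ("equal", "inverse", "sqrt_inverse")
    propagations: tuple[str, ...] = ("sum", "max")
    eval_mode: str = "full"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("modes", "k_values", "quartiles", "weight_schemes", "propagations"):
            if not getattr(self, name):
                raise ValueError(f"{name} grid must be non-empty")

    def knn_grid(self) -> list[KnnConfig]:
        """Expand the grid into concrete KNN configurations."""
        cells: list[KnnConfig] = []
        for mode in self.modes:
            for prop in self.propagations:
                if mode == "one_nn":
                    cells.append(KnnConfig(mode="one_nn", propagation=prop))
                    continue
                for scheme in self.weight_schemes:
                    if mode == "fixed":
                        cells += [
                            KnnConfig(mode=mode, k=k, weight_scheme=scheme,
                                      propagation=prop)
                            for k in self.k_values
                        ]
                    elif mode == "dynamic":
                        cells += [
                            KnnConfig(mode=mode, quartile=q, weight_scheme=scheme,
                                      propagation=prop)
                            for q in self.quartiles
                        ]
                    else:  # hybrid
                        cells += [
                            KnnConfig(mode=mode, k=k, quartile=q,
                                      weight_scheme=scheme, propagation=prop)
                            for k in self.k_values
                            for q in self.quartiles
                        ]
        # one_nn ignores propagation; drop the duplicate cells
        seen, unique = set(), []
        for c in cells:
            key = (c.mode, c.k, c.quartile, c.weight_scheme,
                   c.propagation if c.mode != "one_nn" else "-")
            if key not in seen:
                seen.add(key)
                unique.append(c)
        return unique

    def save(self, stream: IO[str]) -> None:
        cp = configparser.ConfigParser()
        cp["features"] = {"max_gap": str(self.max_gap)}
        cp["pca"] = {"target_ratio": str(self.target_ratio),
                     "whiten": str(self.whiten).lower()}
        cp["knn"] = {
            "modes": ",".join(self.modes),
            "k_values": ",".join(map(str, self.k_values)),
            "quartiles": ",".join(self.quartiles),
            "weight_schemes": ",".join(self.weight_schemes),
            "propagations": ",".join(self.propagations),
        }
        cp["evaluation"] = {"mode": self.eval_mode,
                            "n_folds": str(self.n_folds),
                            "seed": str(self.seed)}
        cp.write(stream)

    @classmethod
    def load(cls, stream: IO[str] | str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if isinstance(stream, (str, Path)):
            with open(stream) as fh:
                cp.read_file(fh)
        else:
            cp.read_file(stream)
        def split(section: str, key: str, fallback: str) -> tuple[str, ...]:
            return tuple(cp.get(section, key, fallback=fallback).split(","))
        return cls(
            max_gap=cp.getint("features", "max_gap", fallback=DEFAULT_MAX_GAP),
            target_ratio=cp.getfloat("pca", "target_ratio",
                                     fallback=DEFAULT_TARGET_RATIO),
            whiten=cp.getboolean("pca", "whiten", fallback=True),
            modes=split("knn", "modes", "one_nn,fixed,dynamic,hybrid"),
            k_values=tuple(int(k) for k in split("knn", "k_values",
                                                 "1,2,3,4,5,6,7,8,9,10")),
            quartiles=split("knn", "quartiles", "Q1,Q2,Q3"),
            weight_schemes=split("knn", "weight_schemes",
                                 "equal,inverse,sqrt_inverse"),
            propagations=split("knn", "propagations", "sum,max"),
            eval_mode=cp.get("evaluation", "mode", fallback="full"),
            n_folds=cp.getint("evaluation", "n_folds", fallback=5),
            seed=cp.getint("evaluation", "seed", fallback=0),
        )


@dataclass
class GridCell:
    config: KnnConfig
    mean_fmax: float
    mean_coverage: float
    fold_fmax: list[float] = field(default_factory=list)

    def label(self) -> str:
        c = self.config
        if c.mode == "one_nn":
            return "1NN"
        param = f"k={c.k}" if c.mode == "fixed" else (
            c.quartile if c.mode == "dynamic" else f"k={c.k},{c.quartile}")
        return f"{c.mode}({param},{c.weight_scheme},{c.propagation})"


def featurize_benchmark(
    pssms: Sequence[Pssm], max_gap: int = DEFAULT_MAX_GAP
):
    """TFPSSM vectors for a list of PSSMs."""
    return [compute_tfpssm(p, max_gap) for p in pssms]


def run_experiment_grid(
    cfg: RunConfig,
    features: Sequence,
    annotations: Mapping[str, set[str]],
    dag: GoDag,
    cluster_table: Mapping[str, str] | None = None,
) -> list[GridCell]:
    """Cross-validated Fmax for every cell of the configuration grid.

    Features are raw TFPSSM vectors; within each fold, PCA is fit on the
    training portion only and applied to both portions, annotations are
    closed once, and every grid cell is predicted and evaluated on the
    held-out fold.  Cells are returned sorted by descending mean Fmax.
    """
    closed = close_annotations(dag, annotations)
    ids = sorted(v.protein_id for v in features)
    split = five_fold_split(ids, cfg.seed, cluster_table, cfg.n_folds)
    by_id = {v.protein_id: v for v in features}
    cells = cfg.knn_grid()
    fmax: dict[int, list[float]] = {i: [] for i in range(len(cells))}
    cov: dict[int, list[float]] = {i: [] for i in range(len(cells))}
    for fold in range(cfg.n_folds):
        train_ids, valid_ids = split.train_validation(fold)
        train_feats = [by_id[p] for p in sorted(train_ids)]
        valid_feats = [by_id[p] for p in sorted(valid_ids)]
        model = fit_pca(train_feats, cfg.target_ratio, cfg.whiten)
        index = TrainingIndex(transform_many(model, train_feats))
        queries = transform_many(model, valid_feats)
        truth = {p: closed[p] for p in valid_ids if closed.get(p)}
        for i, cell in enumerate(cells):
            preds = predict_all(queries, index, closed, dag, cell)
            if not any(p in truth for p in preds):
                fmax[i].append(0.0)
                cov[i].append(0.0)
                continue
            result = evaluate(preds, truth, dag, EvalMode(cfg.eval_mode),
                              close_inputs=False)
            fmax[i].append(result.fmax)
            cov[i].append(result.coverage)
        log.info("fold %d/%d done (train=%d, valid=%d)",
                 fold + 1, cfg.n_folds, len(train_ids), len(valid_ids))
    out = [
        GridCell(
            config=cells[i],
            mean_fmax=sum(fmax[i]) / len(fmax[i]),
            mean_coverage=sum(cov[i]) / len(cov[i]),
            fold_fmax=fmax[i],
        )
        for i in range(len(cells))
    ]
    out.sort(key=lambda c: -c.mean_fmax)
    for cell in out[:3]:
        log.info("grid: %s fmax=%.3f coverage=%.1f%%",
                 cell.label(), cell.mean_fmax, 100 * cell.mean_coverage)
    return out
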