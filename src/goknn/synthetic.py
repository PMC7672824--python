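"""Synthetic benchmark generator: random PSSMs, toy GO DAGs, and clustered
annotation structure.

The generator emulates the shape of a real GO-prediction study without any
downloads: proteins fall into functional clusters; all members of a cluster
share one coherent (ancestor-closed) GO term set and a common PSSM score
profile, perturbed by Gaussian noise.  At zero noise every member of a
cluster has an identical profile — and hence identical TFPSSM features —
so nearest-neighbor transfer is exact by construction.  What this does not
emulate: real PSSM score statistics, sequence-length/annotation-depth
correlations, and the long-tailed term frequencies of curated corpora.

All randomness flows through one ``numpy`` generator seeded from
``SyntheticSpec.seed``; identical seeds give identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .features import AMINO_ACIDS, Pssm, write_ascii_pssm
from .ontology import GoDag, GoTerm, write_annotations, write_obo

__all__ = ["SyntheticSpec", "SyntheticBenchmark", "generate_synthetic_benchmark"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark.

    Defaults give 5 well-separated clusters of 8 proteins, sequences of
    40-60 residues, a depth-3 branching-3 toy ontology, and 3 leaf terms
    per cluster — small enough for exhaustive checking, structured enough
    that neighbor voting has signal to find.
    """

    seed: int = 0
    n_proteins: int = 40
    seq_length: tuple[int, int] = (40, 60)
    n_clusters: int = 5
    intra_cluster_noise: float = 0.5
    dag_depth: int = 3
    dag_branching: int = 3
    terms_per_cluster: int = 3
    profile_scale: float = 6.0
    namespace: str = "BPO"

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_clusters", "dag_depth", "dag_branching",
                     "terms_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.intra_cluster_noise < 0:
            raise ValueError("intra_cluster_noise must be >= 0")
        if self.seq_length[0] < 2 or self.seq_length[1] < self.seq_length[0]:
            raise ValueError("seq_length range must satisfy 2 <= lo <= hi")


@dataclass
class SyntheticBenchmark:
    spec: SyntheticSpec
    pssms: list[Pssm]
    dag: GoDag
    annotations: dict[str, set[str]]
    cluster_of: dict[str, int] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.pssms]

    def write(self, outdir: str | Path) -> None:
        """Write every artifact in the standard text formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pssm_dir = outdir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for pssm in self.pssms:
            with (pssm_dir / f"{pssm.protein_id}.pssm").open("w") as fh:
                write_ascii_pssm(pssm, fh)
        with (outdir / "ontology.obo").open("w") as fh:
            write_obo(self.dag, fh)
        with (outdir / "annotations.tsv").open("w") as fh:
            write_annotations(self.annotations, fh)
        with (outdir / "clusters.tsv").open("w") as fh:
            for pid in sorted(self.cluster_of):
                fh.write(f"{pid}\tC{self.cluster_of[pid]:03d}\n")
        with (outdir / "sequences.fasta").open("w") as fh:
            for pssm in self.pssms:
                fh.write(f">{pssm.protein_id}\n{pssm.sequence}\n")


def _random_dag(rng: np.random.Generator, spec: SyntheticSpec) -> GoDag:
    """A rooted DAG of the requested depth/branching, with occasional
    second parents within the same level to exercise multi-parent merges."""
    counter = 1
    levels: list[list[str]] = [["GO:0000001"]]
    terms = [GoTerm(id="GO:0000001", name="root", namespace=spec.namespace)]
    for depth in range(1, spec.dag_depth + 1):
        level: list[str] = []
        for parent in levels[-1]:
            for _ in range(spec.dag_branching):
                counter += 1
                tid = f"GO:{counter:07d}"
                parents = {parent}
                # ~20% of non-top-level nodes get a second parent (DAG, not tree)
                if depth > 1 and len(levels[-1]) > 1 and rng.random() < 0.2:
                    other = rng.choice([p for p in levels[-1] if p != parent])
                    parents.add(str(other))
                terms.append(
                    GoTerm(
                        id=tid,
                        name=f"synthetic term {counter}",
                        namespace=spec.namespace,
                        parents=frozenset(parents),
                    )
                )
                level.append(tid)
        levels.append(level)
    return GoDag(terms)


def _cluster_profile(
    rng: np.random.Generator, length: int, scale: float
) -> tuple[str, np.ndarray]:
    """A consensus sequence and its idealized PSSM score profile."""
    idx = rng.integers(0, 20, size=length)
    sequence = "".join(AMINO_ACIDS[i] for i in idx)
    scores = np.full((length, 20), -scale / 2)
    scores[np.arange(length), idx] = scale
    return sequence, scores


def generate_synthetic_benchmark(spec: SyntheticSpec) -> SyntheticBenchmark:
    """Deterministically generate a clustered GO-prediction benchmark.

    Each cluster draws ``terms_per_cluster`` distinct non-root leaf-ward
    terms from the toy DAG as its annotation (shared by every member) and a
    consensus PSSM profile; members add independent Gaussian score noise of
    standard deviation ``intra_cluster_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    dag = _random_dag(rng, spec)
    candidates = sorted(set(dag.terms) - dag.root_ids)
    if spec.terms_per_cluster > len(candidates):
        raise ValueError(
            f"terms_per_cluster={spec.terms_per_cluster} exceeds the "
            f"{len(candidates)} non-root terms in the ontology"
        )
    pssms: list[Pssm] = []
    annotations: dict[str, set[str]] = {}
    cluster_of: dict[str, int] = {}
    profiles = []
    for c in range(spec.n_clusters):
        length = int(rng.integers(spec.seq_length[0], spec.seq_length[1] + 1))
        profiles.append(_cluster_profile(rng, length, spec.profile_scale))
    cluster_terms = [
        set(str(t) for t in rng.choice(candidates, spec.terms_per_cluster, replace=False))
        for _ in range(spec.n_clusters)
    ]
    for i in range(spec.n_proteins):
        c = i % spec.n_clusters
        pid = f"P{i:04d}"
        sequence, base = profiles[c]
        noise = rng.normal(0.0, spec.intra_cluster_noise, size=base.shape)
        pssms.append(Pssm(protein_id=pid, sequence=sequence, scores=base + noise))
        annotations[pid] = set(cluster_terms[c])
        cluster_of[pid] = c
    return SyntheticBenchmark(
        spec=spec, pssms=pssms, dag=dag, annotations=annotations, cluster_of=cluster_of
    )
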