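import numpy as np
import pytest

from goknn.ontology import GoDag, GoTerm

GO = [f"GO:{i:07d}" for i in range(8)]  # GO[1]..GO[7]


@pytest.fixture(scope="session")
def toy_dag() -> GoDag:
    """Seven-term toy ontology: one root, two mid-level terms, four leaves.

    GO:2 and GO:3 are children of the root GO:1; GO:4/GO:5 hang under GO:2
    and GO:6/GO:7 under GO:3.
    """
    ns = "BPO"
    return GoDag(
        [
            GoTerm(id=GO[1], name="root", namespace=ns),
            GoTerm(id=GO[2], name="mid a", namespace=ns, parents=frozenset({GO[1]})),
            GoTerm(id=GO[3], name="mid b", namespace=ns, parents=frozenset({GO[1]})),
            GoTerm(id=GO[4], name="leaf a1", namespace=ns, parents=frozenset({GO[2]})),
            GoTerm(id=GO[5], name="leaf a2", namespace=ns, parents=frozenset({GO[2]})),
            GoTerm(id=GO[6], name="leaf b1", namespace=ns, parents=frozenset({GO[3]})),
            GoTerm(id=GO[7], name="leaf b2", namespace=ns, parents=frozenset({GO[3]})),
        ]
    )


def random_dag(rng: np.random.Generator, n_terms: int, namespace: str = "BPO") -> GoDag:
    """Random single-root DAG: term i picks 1-2 parents among terms < i."""
    terms = [GoTerm(id="GO:0000001", name="root", namespace=namespace)]
    for i in range(2, n_terms + 1):
        n_parents = 1 if i == 2 else int(rng.integers(1, 3))
        choices = rng.choice(i - 1, size=min(n_parents, i - 1), replace=False) + 1
        parents = frozenset(f"GO:{int(c):07d}" for c in choices)
        terms.append(
            GoTerm(id=f"GO:{i:07d}", name=f"t{i}", namespace=namespace, parents=parents)
        )
    return GoDag(terms)


def raw_edge_list(dag: GoDag) -> list[tuple[str, str]]:
    """(child, parent) pairs straight from the term records."""
    return [(t.id, p) for t in dag.terms.values() for p in t.parents]
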