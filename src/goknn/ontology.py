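"""Gene Ontology DAG parsing, validation, and true-path annotation closure.

The GO vocabulary is a directed acyclic graph in three namespaces
(biological process, cellular component, molecular function).  Annotation
to a term implies annotation to every ancestor ("true-path rule"), so
annotation sets are closed under the ancestor relation before any counting.
Namespace roots are excluded from closed sets: predicting a root is vacuous.

Propagation follows both ``is_a`` and ``part_of`` edges, the GO-consortium
convention; other relationship types are ignored.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "GoTerm",
    "GoDag",
    "OboError",
    "parse_obo",
    "write_obo",
    "ancestors",
    "close_annotations",
    "read_annotations",
    "write_annotations",
]

#: canonical long namespace names mapped to the three-letter codes used here
NAMESPACE_CODES = {
    "biological_process": "BPO",
    "cellular_component": "CCO",
    "molecular_function": "MFO",
}

_GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: edge types followed for ancestor computation and propagation
PROPAGATION_RELATIONS = ("is_a", "part_of")


class OboError(ValueError):
    """Raised for structural defects in an ontology file (cycles, dangling ids)."""


@dataclass(frozen=True)
class GoTerm:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not _GO_ID_RE.match(self.id):
            raise OboError(f"malformed GO accession: {self.id!r}")
        if self.id in self.parents:
            raise OboError(f"{self.id} lists itself as a parent")


class GoDag:
    """A validated GO directed acyclic graph.

    Parameters
    ----------
    terms
        Iterable of :class:`GoTerm`.  Parents of non-obsolete terms must
        exist, edges must stay within one namespace, and the graph spanned
        by ``is_a``/``part_of`` edges must be acyclic.
    """

    def __init__(self, terms: Iterable[GoTerm]):
        self.terms: dict[str, GoTerm] = {t.id: t for t in terms}
        # edges point child -> parent
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            if t.obsolete:
                continue
            for p in t.parents:
                if p not in self.terms:
                    raise OboError(f"term {t.id} references unknown parent {p}")
                parent = self.terms[p]
                if parent.obsolete:
                    raise OboError(f"term {t.id} has obsolete parent {p}")
                if t.namespace != parent.namespace:
                    raise OboError(
                        f"cross-namespace edge {t.id} ({t.namespace}) -> "
                        f"{p} ({parent.namespace})"
                    )
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            u, v, *_ = next(iter(nx.find_cycle(g)))
            raise OboError(f"ontology contains a cycle through edge {u} -> {v}")
        self._graph = g
        self.roots: dict[str, set[str]] = {}
        for t in self.terms.values():
            if not t.obsolete and not t.parents:
                self.roots.setdefault(t.namespace, set()).add(t.id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def root_ids(self) -> set[str]:
        """Union of the per-namespace root ids."""
        return set().union(*self.roots.values()) if self.roots else set()

    def children(self, term_id: str) -> set[str]:
        """Direct children (terms whose parent set contains *term_id*)."""
        self._check(term_id)
        return set(self._graph.predecessors(term_id))

    def parents(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self._graph.successors(term_id))

    def topological_order(self) -> list[str]:
        """Term ids ordered children-before-parents (leaves first)."""
        return list(nx.topological_sort(self._graph))

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise KeyError(f"unknown GO term: {term_id}")


def ancestors(dag: GoDag, term_id: str) -> set[str]:
    """All transitive parents of *term_id* via is_a/part_of, excluding itself."""
    dag._check(term_id)
    return nx.descendants(dag._graph, term_id)


def parse_obo(stream: IO[str] | str) -> GoDag:
    """Parse an OBO 1.2 stream into a validated :class:`GoDag`.

    Only the tags ``id``, ``name``, ``namespace``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete`` are interpreted; obsolete
    terms are retained but flagged and carry no edges.  Long namespace names
    are mapped to BPO/CCO/MFO.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=False)
    terms = []
    for node, data in graph.nodes(data=True):
        if not data:
            # obonet materializes dangling parent references as bare nodes
            child = next(iter(graph.predecessors(node)), None)
            raise OboError(f"term {child} references unknown parent {node}")
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: set[str] = set()
        if not obsolete:
            for _, parent, rel in graph.out_edges(node, keys=True):
                if rel in PROPAGATION_RELATIONS:
                    parents.add(parent)
        ns = data.get("namespace", "")
        terms.append(
            GoTerm(
                id=node,
                name=data.get("name", ""),
                namespace=NAMESPACE_CODES.get(ns, ns),
                parents=frozenset(parents),
                obsolete=obsolete,
            )
        )
    return GoDag(terms)


_NAMESPACE_LONG = {v: k for k, v in NAMESPACE_CODES.items()}


def write_obo(dag: GoDag, stream: IO[str]) -> None:
    """Write the OBO subset this package reads (fixture round-trips)."""
    stream.write("format-version: 1.2\n")
    stream.write("ontology: go-subset\n")
    for term_id in sorted(dag.terms):
        t = dag.terms[term_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {t.id}\n")
        stream.write(f"name: {t.name or t.id}\n")
        if t.namespace:
            stream.write(f"namespace: {_NAMESPACE_LONG.get(t.namespace, t.namespace)}\n")
        for p in sorted(t.parents):
            stream.write(f"is_a: {p}\n")
        if t.obsolete:
            stream.write("is_obsolete: true\n")


def close_annotations(
    dag: GoDag, annotations: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Close each protein's term set under the true-path rule.

    Every annotated term is replaced by its union with all ancestors;
    namespace roots are then removed.  Annotations to obsolete terms are
    dropped with a warning.  Idempotent.
    """
    roots = dag.root_ids
    closed: dict[str, set[str]] = {}
    for protein, terms in annotations.items():
        out: set[str] = set()
        for term in terms:
            if term not in dag.terms:
                raise KeyError(f"protein {protein} annotated to unknown term {term}")
            if dag.terms[term].obsolete:
                warnings.warn(
                    f"protein {protein}: dropping annotation to obsolete term {term}",
                    stacklevel=2,
                )
                continue
            out.add(term)
            out |= ancestors(dag, term)
        closed[protein] = out - roots
    return closed


def read_annotations(stream: IO[str] | str) -> dict[str, set[str]]:
    """Read a two-column (protein_id TAB go_id) TSV; '#' lines are comments."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ann: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"annotation TSV line {lineno}: expected 2 columns")
        ann.setdefault(fields[0], set()).add(fields[1])
    return ann


def write_annotations(annotations: Mapping[str, set[str]], stream: IO[str]) -> None:
    for protein in sorted(annotations):
        for term in sorted(annotations[protein]):
            stream.write(f"{protein}\t{term}\n")
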