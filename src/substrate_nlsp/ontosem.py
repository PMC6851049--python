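"""Chemical-ontology semantic similarity features.

A ChEBI-style ontology is a rooted DAG of terms connected by ``is_a``
edges.  Given a corpus of compound→term annotations, each term gets an
information content IC(c) = −log p(c), where p(c) is the propagated
annotation frequency of the term (GO-style: an annotation to a term counts
for all its ancestors).  The semantic similarity of two terms is Lin's
measure

    sim(c1, c2) = 2·IC(MICA) / (IC(c1) + IC(c2))

with MICA the most informative common ancestor.  A compound is featurized
against the transporter classes by its maximum Lin similarity to the
members of each class.

ChEBI has three disjoint subontologies ("chemical entity", "role",
"subatomic particle"); terms from different subontologies share no
ancestor and get similarity 0.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import obonet

from .chemstruct import ClassSubsets, CompoundRecord

logger = logging.getLogger(__name__)


class OboFormatError(ValueError):
    """Raised for malformed or cyclic OBO input."""


@dataclass
class OntologyDAG:
    """Terms plus directed ``is_a`` parent edges.

    ``parents[t]`` is the set of direct is_a parents of ``t``; roots are
    the terms with no parents.  ``alt_ids`` maps secondary ids to their
    primary term.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.terms:
            self.parents.setdefault(t, set())
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (child, par) for child, ps in self.parents.items() for par in ps
        )
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OboFormatError(
                f"is_a graph contains a cycle through term {cyc[0][0]!r}"
            )
        self._graph = g
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents[t]}

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary term id (identity for primary ids)."""
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive ancestor set of ``term`` (includes itself)."""
        term = self.resolve(term)
        if term not in self.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term) | {term})
            self._anc_cache[term] = cached
        return cached

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                kids[p].add(child)
        return kids


def parse_obo(source, relations: tuple[str, ...] = ()) -> OntologyDAG:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas are interpreted; obsolete terms are dropped and
    ``alt_id`` aliases recorded.  Hierarchy edges come from ``is_a`` lines;
    additional relationship types may be admitted via ``relations`` (e.g.
    ``("part_of",)``), but the default is the plain is_a hierarchy.

    ``source`` may be a path, a file object, or an OBO document string.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        graph = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # malformed stanzas surface as parse errors
        raise OboFormatError(f"unreadable OBO input: {exc}") from exc

    terms = set(graph.nodes)
    parents: dict[str, set[str]] = {t: set() for t in terms}
    keep = {"is_a", *relations}
    for child, parent, rel in graph.edges(keys=True):
        if rel in keep and parent in terms:
            parents[child].add(parent)
    alt_ids: dict[str, str] = {}
    for t, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = t
    return OntologyDAG(terms=terms, parents=parents, alt_ids=alt_ids)


def ancestors(dag: OntologyDAG, term: str) -> frozenset[str]:
    """Reflexive-transitive closure over parent edges."""
    return dag.ancestors(term)


def write_obo(dag: OntologyDAG, path=None, ontology_name: str = "synthetic") -> str:
    """Serialize a DAG to OBO 1.2 text; :func:`parse_obo` round-trips it."""
    primary_of_alt: dict[str, list[str]] = {}
    for alt, primary in dag.alt_ids.items():
        primary_of_alt.setdefault(primary, []).append(alt)
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {term}")
        for alt in sorted(primary_of_alt.get(term, [])):
            lines.append(f"alt_id: {alt}")
        for parent in sorted(dag.parents[term]):
            lines.append(f"is_a: {parent}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@dataclass
class ICTable:
    """Per-term information content (in nats) from a propagated-count corpus."""

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def get(self, term: str, default: float = 0.0) -> float:
        return self.ic.get(term, default)


def compute_ic(
    dag: OntologyDAG,
    annotations: dict[str, str],
    log_base: float = math.e,
    unseen_cap: float | None = None,
) -> ICTable:
    """Information content from compound annotations with ancestor propagation.

    Each compound annotated to a term contributes one count to that term
    and to every ancestor.  ``p(c)`` is the propagated count divided by the
    count of ``c``'s root (the number of corpus compounds in the same
    subontology), and IC(c) = −log p(c).  Terms never reached by the
    corpus get a capped IC (default: max observed IC + 1 nat, the
    increment expressed in the chosen base so the whole table still
    scales uniformly with the base).

    Lin similarity is invariant to ``log_base``; it only rescales the table.
    """
    if not annotations:
        raise ValueError("need at least one annotation to build an IC table")
    counts: dict[str, int] = {t: 0 for t in dag.terms}
    for comp, term in annotations.items():
        term = dag.resolve(term)
        if term not in dag.terms:
            raise KeyError(
                f"compound {comp!r} annotated to unknown term {term!r}"
            )
        for anc in dag.ancestors(term):
            counts[anc] += 1

    log = lambda x: math.log(x) / math.log(log_base)  # noqa: E731
    roots = dag.roots
    ic: dict[str, float] = {}
    observed: list[float] = []
    for t in dag.terms:
        if counts[t] == 0:
            continue
        denom = max(counts[r] for r in dag.ancestors(t) & roots)
        ic[t] = -log(counts[t] / denom)
        observed.append(ic[t])
    if unseen_cap is not None:
        cap = unseen_cap
    else:
        cap = max(observed) + 1.0 / math.log(log_base)
    for t in dag.terms:
        ic.setdefault(t, cap)
    return ICTable(ic=ic, corpus_size=len(annotations))


def lin_similarity(dag: OntologyDAG, ic: ICTable, c1: str, c2: str) -> float:
    """Lin semantic similarity 2·IC(MICA)/(IC(c1)+IC(c2)) in [0, 1].

    Terms with no common ancestor (different subontologies), or two roots
    with zero IC, score 0 by convention.
    """
    c1, c2 = dag.resolve(c1), dag.resolve(c2)
    common = dag.ancestors(c1) & dag.ancestors(c2)
    if not common:
        return 0.0
    denom = ic.get(c1) + ic.get(c2)
    if denom <= 0:
        return 0.0
    mica_ic = max(ic.get(t) for t in common)
    return (2.0 * mica_ic) / denom


def encode_semantic(
    query: CompoundRecord,
    subsets: ClassSubsets,
    dataset: dict[str, CompoundRecord],
    dag: OntologyDAG,
    ic: ICTable,
    exclude_self: bool = True,
) -> np.ndarray:
    """Per-class maximum Lin similarity feature vector.

    Component *i* is the maximum Lin similarity between the query's
    ontology term and the terms of the members of class *i*.  Unannotated
    members contribute 0, and an unannotated query yields the zero vector
    (the structural feature block still informs the classifier).
    """
    return encode_semantic_many(
        [query], subsets, dataset, dag, ic, exclude_self=exclude_self
    )[0]


def encode_semantic_many(
    queries: list[CompoundRecord],
    subsets: ClassSubsets,
    dataset: dict[str, CompoundRecord],
    dag: OntologyDAG,
    ic: ICTable,
    exclude_self: bool = True,
) -> np.ndarray:
    """Vectorised :func:`encode_semantic` for many queries (rows)."""
    for ids in subsets.members.values():
        for mid in ids:
            if mid not in dataset:
                raise KeyError(f"class member {mid!r} not found in dataset")

    @lru_cache(maxsize=None)
    def pair_sim(t1: str, t2: str) -> float:
        return lin_similarity(dag, ic, t1, t2)

    out = np.zeros((len(queries), len(subsets.labels)))
    for qi, q in enumerate(queries):
        if q.ontology_term is None:
            continue
        for i, lab in enumerate(subsets.labels):
            ids = subsets.members[lab]
            if exclude_self:
                ids = ids - {q.id}
            if not ids:
                logger.warning(
                    "class %r empty%s for query %r; semantic feature set to 0",
                    lab,
                    " after self-exclusion" if exclude_self else "",
                    q.id,
                )
                continue
            best = 0.0
            for mid in ids:
                term = dataset[mid].ontology_term
                if term is None:
                    continue
                a, b = sorted((dag.resolve(q.ontology_term), dag.resolve(term)))
                s = pair_sim(a, b)
                if s > best:
                    best = s
            out[qi, i] = best
    return out
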