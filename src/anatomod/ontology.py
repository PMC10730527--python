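"""Anatomy-ontology handling: OBO parsing, closures, information content and
term/protein semantic similarity.

The ontology is modelled as a DAG of terms connected by typed child→parent
edges (``is_a``, ``part_of``, ``develops_from``), the subset of relations an
anatomy ontology such as Uberon uses to relate a structure to what it is, what
it belongs to and what it develops from.  Annotation-based information content
(IC) follows the classic definition

    IC(t) = -ln( (count(t) + c) / total )

where ``count(t)`` is the number of proteins annotated to ``t`` or any of its
descendants (true-path propagation), ``total`` the number of distinct proteins
annotated anywhere in the ontology, and ``c`` a pseudocount guarding against
log(0).  Term similarity maximises over the common-ancestor set S(t1, t2):

    lin(t1, t2)       = max_{t in S} 2 IC(t) / (IC(t1) + IC(t2))
    schlicker(t1, t2) = max_{t in S} [2 IC(t) / (IC(t1) + IC(t2))] * (1 + IC(t))

The ``schlicker_printed`` form multiplies the Lin term by ``(1 + IC(t))`` and
is therefore unbounded above; downstream network construction min–max rescales
such scores into [0, 1].  A ``schlicker_classic`` variant using the original
relevance factor ``(1 - p(t))`` is also provided.
"""

from __future__ import annotations

import io
import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of", "develops_from")
#: relations that constitute subsumption/partonomy, used for IC and similarity
SIMILARITY_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised for malformed OBO input (missing ids, cyclic relations)."""


class UndefinedSimilarity(Exception):
    """Signals that a protein pair has no defined semantic similarity
    (at least one protein carries no ontology annotation)."""


@dataclass
class OntologyGraph:
    """Typed-relation DAG of ontology terms.

    ``graph`` is a :class:`networkx.MultiDiGraph` with child→parent edges
    keyed by relation type, the orientation obonet uses.
    """

    graph: nx.MultiDiGraph
    names: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str, relations: Iterable[str] = RELATIONS) -> set[str]:
        rels = set(relations)
        return {
            parent
            for _, parent, rel in self.graph.out_edges(term, keys=True)
            if rel in rels
        }

    def children(self, term: str, relations: Iterable[str] = RELATIONS) -> set[str]:
        rels = set(relations)
        return {
            child
            for child, _, rel in self.graph.in_edges(term, keys=True)
            if rel in rels
        }


def parse_obo(text: str) -> OntologyGraph:
    """Parse an OBO 1.2 document (the ``is_a`` / ``part_of`` /
    ``develops_from`` subset) into an :class:`OntologyGraph`.

    Obsolete terms are dropped, unknown relationship types are ignored with a
    warning, and cyclic relations raise :class:`OboParseError`.
    """
    _check_term_stanzas_have_ids(text)
    multi = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)

    graph = nx.MultiDiGraph()
    names: dict[str, str] = {}
    # obonet may create bare nodes for referenced-but-undeclared parents;
    # every node it kept is treated as a term.
    for node, data in multi.nodes(data=True):
        graph.add_node(node)
        if data.get("name"):
            names[node] = data["name"]

    for child, parent, rel in multi.edges(keys=True):
        if rel not in RELATIONS:
            logger.warning("ignoring unsupported relationship type %r (%s -> %s)",
                           rel, child, parent)
            continue
        graph.add_edge(child, parent, key=rel)

    plain = nx.DiGraph(graph)
    if not nx.is_directed_acyclic_graph(plain):
        cycle = nx.find_cycle(plain)
        raise OboParseError(f"ontology relations contain a cycle: {cycle}")
    return OntologyGraph(graph=graph, names=names)


def _check_term_stanzas_have_ids(text: str) -> None:
    stanza_no = 0
    in_term = False
    has_id = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            if in_term and not has_id:
                raise OboParseError(f"[Term] stanza #{stanza_no} has no id: line")
            in_term = line == "[Term]"
            if in_term:
                stanza_no += 1
                has_id = False
        elif in_term and line.startswith("id:"):
            has_id = True
    if in_term and not has_id:
        raise OboParseError(f"[Term] stanza #{stanza_no} has no id: line")


@dataclass
class AnnotationTable:
    """Protein→term annotation pairs with a term→protein-set view."""

    df: pd.DataFrame  # columns: protein_id, term_id (deduplicated)

    def __post_init__(self) -> None:
        self.df = (
            self.df[["protein_id", "term_id"]]
            .astype(str)
            .drop_duplicates()
            .reset_index(drop=True)
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationTable":
        return cls(pd.DataFrame(list(pairs), columns=["protein_id", "term_id"]))

    @classmethod
    def read_tsv(cls, path_or_buffer) -> "AnnotationTable":
        df = pd.read_csv(
            path_or_buffer,
            sep="\t",
            comment="#",
            header=None,
            names=["protein_id", "term_id"],
            dtype=str,
        )
        return cls(df)

    def write_tsv(self, path) -> None:
        out = self.df.sort_values(["protein_id", "term_id"])
        out.to_csv(path, sep="\t", header=False, index=False)

    @property
    def proteins(self) -> set[str]:
        return set(self.df["protein_id"])

    def terms_of(self, protein: str) -> set[str]:
        return set(self.df.loc[self.df["protein_id"] == protein, "term_id"])

    def term_to_proteins(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for protein, term in self.df.itertuples(index=False):
            out.setdefault(term, set()).add(protein)
        return out

    def protein_to_terms(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for protein, term in self.df.itertuples(index=False):
            out.setdefault(protein, set()).add(term)
        return out

    def restrict_to(self, g: OntologyGraph) -> "AnnotationTable":
        mask = self.df["term_id"].isin(g.terms)
        return AnnotationTable(self.df[mask])


def ancestors(
    g: OntologyGraph, term: str, relations: Iterable[str] = SIMILARITY_RELATIONS
) -> set[str]:
    """Reflexive-transitive ancestor closure of ``term`` over the chosen
    relation types (always contains ``term`` itself)."""
    if term not in g:
        raise KeyError(term)
    rels = set(relations)
    seen = {term}
    queue = deque([term])
    while queue:
        current = queue.popleft()
        for _, parent, rel in g.graph.out_edges(current, keys=True):
            if rel in rels and parent not in seen:
                seen.add(parent)
                queue.append(parent)
    return seen


def descendants(
    g: OntologyGraph, term: str, relations: Iterable[str] = SIMILARITY_RELATIONS
) -> set[str]:
    """Reflexive-transitive descendant closure (terms whose ancestor closure
    reaches ``term``)."""
    if term not in g:
        raise KeyError(term)
    rels = set(relations)
    seen = {term}
    queue = deque([term])
    while queue:
        current = queue.popleft()
        for child, _, rel in g.graph.in_edges(current, keys=True):
            if rel in rels and child not in seen:
                seen.add(child)
                queue.append(child)
    return seen


def collect_original_annotations(
    g: OntologyGraph,
    ann: AnnotationTable,
    target: str,
    relations: Iterable[str] = RELATIONS,
) -> set[str]:
    """Proteins annotated to ``target`` or to any of its parts/precursors.

    A protein counts as "originally annotated" to an anatomical entity when
    its annotation term reaches the entity through the ``is_a`` / ``part_of``
    / ``develops_from`` closure — e.g. a protein annotated to a fin's radial
    skeleton (a part) or to the fin bud (a developmental precursor) belongs to
    the fin's original set.
    """
    if target not in g:
        raise KeyError(target)
    reach = descendants(g, target, relations)
    t2p = ann.term_to_proteins()
    out: set[str] = set()
    for term in reach:
        out |= t2p.get(term, set())
    return out


def collect_original_annotations_labeled(
    g: OntologyGraph,
    ann: AnnotationTable,
    target: str,
    relations: Iterable[str] = RELATIONS,
) -> dict[str, str]:
    """Like :func:`collect_original_annotations` but labels each protein
    ``original_direct`` (annotated to the target itself) or
    ``original_part_or_precursor``. Direct annotation wins on conflict."""
    if target not in g:
        raise KeyError(target)
    t2p = ann.term_to_proteins()
    labels: dict[str, str] = {}
    for term in descendants(g, target, relations):
        if term == target:
            continue
        for protein in t2p.get(term, set()):
            labels[protein] = "original_part_or_precursor"
    for protein in t2p.get(target, set()):
        labels[protein] = "original_direct"
    return labels


@dataclass
class ICTable:
    """Per-term information content in natural-log units.

    ``counts`` holds the propagated annotation counts used to compute the IC;
    ``total`` is the number of distinct proteins annotated anywhere in the
    ontology and ``constant`` the pseudocount added to each count.
    """

    ic: dict[str, float]
    counts: dict[str, int]
    total: int
    constant: float

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def p_raw(self, term: str) -> float:
        """Raw annotation probability count(t)/total (no pseudocount),
        capped at 1; used by the classic Schlicker relevance factor."""
        return min(self.counts.get(term, 0) / self.total, 1.0)


def compute_ic(
    g: OntologyGraph,
    ann: AnnotationTable,
    constant: float = 1.0,
    relations: Iterable[str] = SIMILARITY_RELATIONS,
    zero_count: str = "error",
) -> ICTable:
    """Annotation-frequency information content for every ontology term.

    Counts are propagated up the hierarchy (a protein annotated to a term is
    implicitly annotated to all its ancestors), which makes IC anti-monotone
    along the DAG. ``constant`` is the pseudocount of the probability
    numerator; with ``constant=0`` an unannotated term has p=0 and either
    raises (``zero_count='error'``) or gets IC=+inf (``zero_count='inf'``).
    """
    if constant < 0:
        raise ValueError("constant must be non-negative")
    ann = ann.restrict_to(g)
    if ann.df.empty:
        raise ValueError("annotation table is empty (total protein count would be 0)")

    t2p = ann.term_to_proteins()
    total = len(ann.proteins)

    # propagate protein sets bottom-up in reverse topological order
    order = list(nx.topological_sort(nx.DiGraph(g.graph)))  # children first? no:
    # edges run child -> parent, so topological order puts children before
    # parents; accumulate each node's set into its parents as we go.
    propagated: dict[str, set[str]] = {t: set(t2p.get(t, set())) for t in g.terms}
    for term in order:
        for parent in g.parents(term, relations):
            propagated[parent] |= propagated[term]

    ic: dict[str, float] = {}
    counts: dict[str, int] = {}
    for term in g.terms:
        count = len(propagated[term])
        counts[term] = count
        numerator = count + constant
        if numerator == 0:
            if zero_count == "error":
                raise ValueError(
                    f"term {term} has zero annotations and constant=0; "
                    "p(t)=0 is undefined under -log"
                )
            ic[term] = math.inf
            continue
        p = min(numerator / total, 1.0)
        ic[term] = -math.log(p)
    return ICTable(ic=ic, counts=counts, total=total, constant=constant)


SIMILARITY_METHODS = ("lin", "schlicker_printed", "schlicker_classic")


def term_similarity(
    g: OntologyGraph,
    ic: ICTable,
    t1: str,
    t2: str,
    method: str = "lin",
    relations: Iterable[str] = SIMILARITY_RELATIONS,
) -> float:
    """Semantic similarity of two terms, maximised over common ancestors.

    ``lin`` is bounded in [0, 1]; ``schlicker_printed`` multiplies each
    candidate by (1 + IC(t)) and can exceed 1; ``schlicker_classic`` uses the
    (1 - p(t)) relevance factor instead and stays within [0, 1].
    """
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown similarity method {method!r}")
    common = ancestors(g, t1, relations) & ancestors(g, t2, relations)
    if not common:
        raise ValueError(
            f"terms {t1} and {t2} share no ancestor; "
            "a rooted ontology always provides one"
        )
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    best = 0.0
    for t in common:
        base = 2.0 * ic[t] / denom
        if method == "schlicker_printed":
            value = base * (1.0 + ic[t])
        elif method == "schlicker_classic":
            value = base * (1.0 - ic.p_raw(t))
        else:
            value = base
        best = max(best, value)
    return best


def protein_similarity(
    g: OntologyGraph,
    ic: ICTable,
    ann: AnnotationTable | Mapping[str, set[str]],
    protein_a: str,
    protein_b: str,
    method: str = "lin",
    aggregate: str = "max",
    relations: Iterable[str] = SIMILARITY_RELATIONS,
    _term_cache: dict | None = None,
) -> float:
    """Aggregate term similarity over the two proteins' annotation sets.

    ``aggregate='max'`` takes the best term pair; ``'bma'`` the best-match
    average (mean of each term's best partner, averaged over both sides).
    Raises :class:`UndefinedSimilarity` if either protein is unannotated.
    """
    p2t = ann if isinstance(ann, Mapping) else ann.protein_to_terms()
    terms_a = p2t.get(protein_a, set())
    terms_b = p2t.get(protein_b, set())
    if not terms_a or not terms_b:
        raise UndefinedSimilarity(
            f"protein pair ({protein_a}, {protein_b}) has an unannotated member"
        )
    if aggregate not in ("max", "bma"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    cache = _term_cache if _term_cache is not None else {}

    def sim(t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key not in cache:
            cache[key] = term_similarity(g, ic, t1, t2, method, relations)
        return cache[key]

    if aggregate == "max":
        return max(sim(t1, t2) for t1 in terms_a for t2 in terms_b)

    best_a = [max(sim(t1, t2) for t2 in terms_b) for t1 in terms_a]
    best_b = [max(sim(t1, t2) for t1 in terms_a) for t2 in terms_b]
    return 0.5 * (sum(best_a) / len(best_a) + sum(best_b) / len(best_b))
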