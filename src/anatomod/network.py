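"""Weighted protein networks: STRING-style input, anatomy-semantic networks,
network integration, weighted degree and export.

The integrated network combines a PPI backbone (interaction-confidence
weights, e.g. STRING combined scores rescaled to [0, 1]) with an
anatomy-based semantic network (pairwise protein similarity from shared
ontology annotations).  Integration is a convex combination on the PPI edge
set:

    w(u, v) = alpha * w_ppi(u, v) + (1 - alpha) * w_sem(u, v)

PPI edges whose endpoints carry no defined semantic score keep their PPI
weight; pairs that are similar only semantically are not added as edges (the
PPI network is the backbone, semantic evidence re-weights it). A
``min_weight`` cutoff then removes low-confidence edges.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

from .ontology import (
    AnnotationTable,
    ICTable,
    OntologyGraph,
    SIMILARITY_RELATIONS,
    UndefinedSimilarity,
    protein_similarity,
)

logger = logging.getLogger(__name__)

PROVENANCES = ("ppi", "semantic", "integrated")


@dataclass
class WeightedNetwork:
    """Undirected protein graph with edge weights in [0, 1] and a provenance
    tag (``ppi`` / ``semantic`` / ``integrated``) per edge."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, u: str, v: str, weight: float, provenance: str = "ppi") -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        self.graph.add_edge(u, v, weight=float(weight), provenance=provenance)

    def weight(self, u: str, v: str) -> float | None:
        data = self.graph.get_edge_data(u, v)
        return None if data is None else data["weight"]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["weight"]

    def sorted_edges(self) -> list[tuple[str, str, float]]:
        """Edges with endpoints in lexicographic order — for stable output."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, d["weight"]))
        return sorted(out)


def read_string_links(source) -> WeightedNetwork:
    """Read a STRING protein-links style table (``protein1 protein2
    combined_score``, whitespace- or tab-delimited, optional header).

    Scores in the 0–1000 integer dialect are divided by 1000; files whose
    maximum score is <= 1 are taken to be in the real [0, 1] dialect already.
    Duplicate pairs keep the maximum score; self-loops are dropped with a
    warning.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source
        and Path(source).exists()
    ):
        text = Path(source).read_text()
    elif isinstance(source, io.IOBase):
        text = source.read()
    else:
        text = str(source)

    rows: list[tuple[int, str, str, float]] = []  # (lineno, u, v, score)
    seen_data = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        u, v, raw = parts[0], parts[1], parts[2]
        try:
            score = float(raw)
        except ValueError:
            if not seen_data:  # header row
                continue
            raise ValueError(f"line {lineno}: non-numeric score {raw!r}") from None
        seen_data = True
        rows.append((lineno, u, v, score))

    if not rows:
        logger.warning("no interaction rows found")
        return WeightedNetwork()

    max_score = max(r[3] for r in rows)
    thousand_mode = max_score > 1.0
    limit = 1000.0 if thousand_mode else 1.0

    net = WeightedNetwork()
    for lineno, u, v, score in rows:
        if not (0.0 <= score <= limit):
            raise ValueError(
                f"line {lineno}: score {score} outside [0, {limit:g}]"
            )
        if u == v:
            logger.warning("line %d: dropping self-loop on %r", lineno, u)
            continue
        w = score / 1000.0 if thousand_mode else score
        prev = net.weight(u, v)
        if prev is None or w > prev:
            net.add_edge(u, v, w, provenance="ppi")
    return net


def build_semantic_network(
    g: OntologyGraph,
    ic: ICTable,
    ann: AnnotationTable,
    proteins: Iterable[str],
    method: str = "lin",
    aggregate: str = "max",
    relations: Iterable[str] = SIMILARITY_RELATIONS,
) -> WeightedNetwork:
    """Anatomy-based protein network: an edge for every annotated pair with
    positive similarity.

    When the similarity method can exceed 1 (``schlicker_printed``), edge
    scores are min–max rescaled into [0, 1] across the network.
    """
    p2t = ann.protein_to_terms()
    annotated = sorted(p for p in proteins if p2t.get(p))
    net = WeightedNetwork()
    if len(annotated) < 2:
        logger.warning("fewer than 2 annotated proteins; semantic network is empty")
        return net

    cache: dict = {}
    raw: list[tuple[str, str, float]] = []
    for i, pa in enumerate(annotated):
        for pb in annotated[i + 1:]:
            s = protein_similarity(
                g, ic, p2t, pa, pb, method, aggregate, relations, _term_cache=cache
            )
            if s > 0:
                raw.append((pa, pb, s))

    if raw and method == "schlicker_printed":
        values = [s for _, _, s in raw]
        lo, hi = min(values), max(values)
        if hi > 1.0:
            if hi == lo:
                raw = [(u, v, 1.0) for u, v, _ in raw]
            else:
                raw = [(u, v, (s - lo) / (hi - lo)) for u, v, s in raw]

    for u, v, s in raw:
        net.add_edge(u, v, s, provenance="semantic")
    for p in annotated:  # annotated-but-dissimilar proteins stay as nodes
        net.graph.add_node(p)
    return net


def integrate_networks(
    ppi: WeightedNetwork,
    sem: WeightedNetwork,
    alpha: float = 0.5,
    min_weight: float = 0.0,
) -> WeightedNetwork:
    """Convex combination of PPI and semantic scores on the PPI edge set.

    A semantic score is *defined* for a pair when both endpoints are nodes of
    the semantic network (annotated proteins); a defined-but-absent edge
    contributes similarity 0. Edges with final weight < ``min_weight`` are
    removed to filter spurious interactions.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    sem_nodes = sem.nodes
    out = WeightedNetwork()
    for u, v, w_ppi in ppi.edges():
        if u in sem_nodes and v in sem_nodes:
            w_sem = sem.weight(u, v) or 0.0
            w = alpha * w_ppi + (1.0 - alpha) * w_sem
            prov = "integrated"
        else:
            w = w_ppi
            prov = "ppi"
        if w >= min_weight:
            out.add_edge(u, v, w, provenance=prov)
    for node in ppi.nodes:
        out.graph.add_node(node)
    return out


def weighted_degree(net: WeightedNetwork, u: str) -> float:
    """Sum of edge weights incident to ``u`` (0 for isolated nodes)."""
    if u not in net.graph:
        raise KeyError(u)
    return float(sum(d["weight"] for _, _, d in net.graph.edges(u, data=True)))


def weighted_degrees(net: WeightedNetwork) -> dict[str, float]:
    return {u: weighted_degree(net, u) for u in net.graph.nodes}


def induced_subgraph(net: WeightedNetwork, nodes: Iterable[str]) -> WeightedNetwork:
    """Subgraph on ``nodes ∩ net.nodes`` with internal edges and weights
    preserved; missing nodes are silently excluded."""
    keep = set(nodes) & net.nodes
    out = WeightedNetwork()
    out.graph.add_nodes_from(keep)
    for u, v, d in net.graph.subgraph(keep).edges(data=True):
        out.graph.add_edge(u, v, **d)
    return out


EXPORT_FORMATS = ("sif", "graphml", "tsv")


def export_network(
    net: WeightedNetwork,
    prefix,
    format: str = "sif",
    node_attrs: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the network as SIF (``A pp B`` lines), GraphML (with a ``weight``
    edge attribute) or an edge-list TSV; a node-attribute table, when given,
    is written alongside as ``<prefix>.nodes.tsv``."""
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "sif":
        path = prefix.with_suffix(".sif")
        lines = [f"{u} pp {v}" for u, v, _ in net.sorted_edges()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(path)
    elif format == "graphml":
        path = prefix.with_suffix(".graphml")
        ordered = nx.Graph()
        ordered.add_nodes_from(sorted(net.graph.nodes))
        for u, v, _ in net.sorted_edges():
            ordered.add_edge(u, v, **net.graph.edges[u, v])
        nx.write_graphml(ordered, path)
        written.append(path)
    else:
        path = prefix.with_suffix(".edges.tsv")
        with open(path, "w") as fh:
            fh.write("protein1\tprotein2\tweight\tprovenance\n")
            for u, v, w in net.sorted_edges():
                prov = net.graph.edges[u, v].get("provenance", "")
                fh.write(f"{u}\t{v}\t{w:.6g}\t{prov}\n")
        written.append(path)

    if node_attrs is not None:
        npath = prefix.parent / (prefix.name + ".nodes.tsv")
        node_attrs.to_csv(npath, sep="\t", index=False)
        written.append(npath)
    return written
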