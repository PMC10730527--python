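"""Seeded synthetic two-species worlds for exercising the whole pipeline.

A world emulates the statistical structure the analysis assumes, without any
real downloads: a small rooted anatomy ontology (an ``is_a`` tree plus a
``part_of`` part and a ``develops_from`` precursor for each of two target
entities, mirroring the fin / fin-bud pattern), per-species protein sets with
one planted module each, STRING-style weighted networks built as planted
partitions (dense well-weighted edges inside the module, sparse weak edges
outside), an ortholog map linking the two species with one-to-many
duplicates (emulating the teleost whole-genome duplication), and full ground
truth for every planted label.

Key knobs and what they emulate:

* ``conserved_fraction`` (rho) — fraction of each module shared across
  species through the ortholog map.
* ``hub_bias`` — extra within-module attachment probability for edges
  touching a conserved member; makes conserved proteins hubs *by
  construction*, so the conserved-vs-specific weighted-degree inference can
  be tested as a recoverable planted effect.
* ``annotated_fraction`` — fraction of module members given "original"
  annotations; the remainder are hidden ground truth that candidate
  prediction should recover.
* ``duplication_rate`` (delta) — fraction of species-B genes carrying two
  species-A ortholog copies.

Identical seeds give byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import WeightedNetwork
from .comparison import OrthologMap
from .ontology import AnnotationTable, OntologyGraph

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard study conditions."""

    seed: int = 0
    depth: int = 3              # is_a tree depth (root = level 0)
    branching: int = 2          # children per internal term
    n_proteins: int = 500       # per species
    module_size: int = 60
    conserved_fraction: float = 0.3   # rho
    duplication_rate: float = 0.25    # delta
    p_in: float = 0.3
    p_out: float = 0.01
    w_in: tuple[float, float] = (0.6, 0.9)
    w_out: tuple[float, float] = (0.05, 0.2)
    hub_bias: float = 0.1
    annotated_fraction: float = 0.75
    noise_edges: float = 0.01   # epsilon: spurious edges per real edge

    def __post_init__(self) -> None:
        for name in ("conserved_fraction", "duplication_rate", "p_in", "p_out",
                     "hub_bias", "annotated_fraction", "noise_edges"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth < 2:
            raise ValueError("ontology depth must be >= 2")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.module_size > self.n_proteins:
            raise ValueError("module_size cannot exceed n_proteins")
        for name in ("w_in", "w_out"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered range within [0, 1]")

    @property
    def n_tree_terms(self) -> int:
        b, d = self.branching, self.depth
        return (b ** (d + 1) - 1) // (b - 1)


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


@dataclass
class EntityTerms:
    """The designated anatomical target of one species plus its typed
    satellites (a part_of part and a develops_from precursor)."""

    target: str
    part: str
    precursor: str


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    ontology: OntologyGraph
    entity_a: EntityTerms
    entity_b: EntityTerms
    ann_a: AnnotationTable
    ann_b: AnnotationTable
    net_a: WeightedNetwork
    net_b: WeightedNetwork
    orthologs: OrthologMap
    module_a: set[str]
    module_b: set[str]
    conserved_a: set[str]
    conserved_b: set[str]
    original_a: set[str]   # module members with original annotations
    original_b: set[str]
    hidden_a: set[str]     # module members to be recovered by prediction
    hidden_b: set[str]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for species, module, conserved, original in (
            ("a", self.module_a, self.conserved_a, self.original_a),
            ("b", self.module_b, self.conserved_b, self.original_b),
        ):
            proteins = (
                sorted(self.net_a.nodes) if species == "a"
                else sorted(self.net_b.nodes)
            )
            for p in proteins:
                in_module = p in module
                label = (
                    "original" if p in original
                    else "hidden" if in_module
                    else "background"
                )
                rows.append((species, p, in_module, p in conserved, label))
        return pd.DataFrame(
            rows,
            columns=["species", "protein_id", "in_module", "conserved", "origin"],
        )


def generate_ontology(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[OntologyGraph, EntityTerms, EntityTerms]:
    """Rooted is_a tree with two designated target entities, each given a
    part (part_of) and a developmental precursor (develops_from, itself
    is_a an embryonic-structure term)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    b, d = cfg.branching, cfg.depth
    n_tree = cfg.n_tree_terms

    graph = nx.MultiDiGraph()
    names: dict[str, str] = {}
    for i in range(n_tree):
        t = _term_id(i)
        graph.add_node(t)
        names[t] = "anatomical structure" if i == 0 else f"structure {i}"
        if i > 0:
            parent = _term_id((i - 1) // b)
            graph.add_edge(t, parent, key="is_a")

    first_leaf = (b ** d - 1) // (b - 1)
    leaves = [_term_id(i) for i in range(first_leaf, n_tree)]
    pick = rng.choice(len(leaves), size=2, replace=False)
    target_a, target_b = leaves[pick[0]], leaves[pick[1]]
    names[target_a] = "paired appendage A"
    names[target_b] = "paired appendage B"

    nxt = n_tree
    embryo = _term_id(nxt)
    graph.add_node(embryo)
    names[embryo] = "embryonic structure"
    graph.add_edge(embryo, _term_id(0), key="is_a")
    nxt += 1

    entities = []
    for target, tag in ((target_a, "A"), (target_b, "B")):
        part = _term_id(nxt)
        graph.add_node(part)
        names[part] = f"appendage {tag} skeleton"
        graph.add_edge(part, target, key="part_of")
        nxt += 1
        precursor = _term_id(nxt)
        graph.add_node(precursor)
        names[precursor] = f"appendage {tag} bud"
        graph.add_edge(precursor, embryo, key="is_a")
        graph.add_edge(precursor, target, key="develops_from")
        nxt += 1
        entities.append(EntityTerms(target=target, part=part, precursor=precursor))

    return OntologyGraph(graph=graph, names=names), entities[0], entities[1]


def generate_annotations(
    cfg: SyntheticConfig,
    g: OntologyGraph,
    proteins: list[str],
    members: list[str],
    entity: EntityTerms,
    rng: np.random.Generator,
) -> tuple[AnnotationTable, set[str], set[str]]:
    """Annotate one species.

    ``annotated_fraction`` of module members get an "original" annotation to
    the target, its part or its precursor (equal odds). The remaining members
    are hidden ground truth: they carry only a coarser annotation to the
    target's is_a parent — a term that does NOT reach the target through the
    part/precursor closure, but that a correctly predicted candidate shares
    with the seed proteins once annotations are propagated (emulating the
    coarse-granularity annotations real unstudied proteins tend to have).
    Background proteins carry one off-target annotation each.
    """
    entity_terms = [entity.target, entity.part, entity.precursor]
    coarse = sorted(g.parents(entity.target, ("is_a",)))[0]
    avoid = set(entity_terms) | {coarse} | {
        t for t in g.terms if g.names.get(t, "").startswith(("appendage", "paired"))
    } | {_term_id(0)}
    off_target = sorted(g.terms - avoid)

    n_original = int(round(cfg.annotated_fraction * len(members)))
    order = list(rng.permutation(len(members)))
    original = {members[i] for i in order[:n_original]}
    hidden = set(members) - original

    pairs: list[tuple[str, str]] = []
    for p in sorted(original):
        term = entity_terms[rng.integers(0, len(entity_terms))]
        pairs.append((p, term))
    for p in sorted(hidden):
        pairs.append((p, coarse))
    for p in sorted(set(proteins) - original - hidden):
        term = off_target[rng.integers(0, len(off_target))]
        pairs.append((p, term))
    return AnnotationTable.from_pairs(pairs), original, hidden


def generate_species_network(
    cfg: SyntheticConfig,
    members: list[str],
    conserved_members: set[str],
    proteins: list[str],
    rng: np.random.Generator,
) -> WeightedNetwork:
    """Planted-partition network: module pairs connect with
    ``p_in + hub_bias`` when either endpoint is conserved (``p_in``
    otherwise) and draw weights from ``w_in``; all other pairs connect with
    ``p_out`` and draw from ``w_out``; ``noise_edges`` spurious edges per
    real edge are sprinkled uniformly over the non-edges."""
    if cfg.p_in <= cfg.p_out:
        logger.warning(
            "p_in (%g) <= p_out (%g): the planted module is undetectable",
            cfg.p_in, cfg.p_out,
        )
    n = len(proteins)
    index = {p: i for i, p in enumerate(proteins)}
    member_mask = np.zeros(n, dtype=bool)
    member_mask[[index[p] for p in members]] = True
    cons_mask = np.zeros(n, dtype=bool)
    cons_mask[[index[p] for p in conserved_members]] = True

    iu, jv = np.triu_indices(n, k=1)
    in_module = member_mask[iu] & member_mask[jv]
    boosted = in_module & (cons_mask[iu] | cons_mask[jv])
    prob = np.where(in_module, cfg.p_in, cfg.p_out)
    prob = np.where(boosted, np.minimum(cfg.p_in + cfg.hub_bias, 1.0), prob)

    keep = rng.random(iu.size) < prob
    lo = np.where(in_module, cfg.w_in[0], cfg.w_out[0])
    hi = np.where(in_module, cfg.w_in[1], cfg.w_out[1])
    weights = lo + (hi - lo) * rng.random(iu.size)

    net = WeightedNetwork()
    net.graph.add_nodes_from(proteins)
    kept = np.flatnonzero(keep)
    for idx in kept:
        net.add_edge(proteins[iu[idx]], proteins[jv[idx]],
                     float(weights[idx]), provenance="ppi")

    n_noise = int(round(cfg.noise_edges * kept.size))
    if n_noise:
        open_pairs = np.flatnonzero(~keep)
        chosen = rng.choice(open_pairs.size, size=min(n_noise, open_pairs.size),
                            replace=False)
        wlo, whi = cfg.w_out
        noise_w = wlo + (whi - wlo) * rng.random(chosen.size)
        for c, w in zip(open_pairs[chosen], noise_w):
            net.add_edge(proteins[iu[c]], proteins[jv[c]], float(w),
                         provenance="ppi")
    return net


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Generate a complete seeded two-species world."""
    ss = np.random.SeedSequence(cfg.seed)
    (s_onto, s_membership, s_ann_a, s_ann_b,
     s_net_a, s_net_b, s_orth) = ss.spawn(7)

    g, entity_a, entity_b = generate_ontology(cfg, np.random.default_rng(s_onto))

    proteins_a = [f"A_P{i:04d}" for i in range(cfg.n_proteins)]
    proteins_b = [f"B_P{i:04d}" for i in range(cfg.n_proteins)]

    rng_m = np.random.default_rng(s_membership)
    module_a = sorted(rng_m.choice(proteins_a, cfg.module_size, replace=False))
    module_b = sorted(rng_m.choice(proteins_b, cfg.module_size, replace=False))
    n_cons = int(round(cfg.conserved_fraction * cfg.module_size))
    conserved_a = sorted(rng_m.choice(module_a, n_cons, replace=False))
    conserved_b = sorted(rng_m.choice(module_b, n_cons, replace=False))

    orth = _generate_orthologs(
        cfg, proteins_a, proteins_b, module_a, module_b,
        conserved_a, conserved_b, np.random.default_rng(s_orth),
    )

    ann_a, original_a, hidden_a = generate_annotations(
        cfg, g, proteins_a, module_a, entity_a, np.random.default_rng(s_ann_a)
    )
    ann_b, original_b, hidden_b = generate_annotations(
        cfg, g, proteins_b, module_b, entity_b, np.random.default_rng(s_ann_b)
    )

    net_a = generate_species_network(
        cfg, module_a, set(conserved_a), proteins_a, np.random.default_rng(s_net_a)
    )
    net_b = generate_species_network(
        cfg, module_b, set(conserved_b), proteins_b, np.random.default_rng(s_net_b)
    )

    return SyntheticWorld(
        config=cfg, ontology=g, entity_a=entity_a, entity_b=entity_b,
        ann_a=ann_a, ann_b=ann_b, net_a=net_a, net_b=net_b,
        orthologs=orth,
        module_a=set(module_a), module_b=set(module_b),
        conserved_a=set(conserved_a), conserved_b=set(conserved_b),
        original_a=original_a, original_b=original_b,
        hidden_a=hidden_a, hidden_b=hidden_b,
    )


def _generate_orthologs(
    cfg: SyntheticConfig,
    proteins_a: list[str],
    proteins_b: list[str],
    module_a: list[str],
    module_b: list[str],
    conserved_a: list[str],
    conserved_b: list[str],
    rng: np.random.Generator,
) -> OrthologMap:
    """Backbone bijection plus duplicates.

    Conserved pairs are wired module-to-module; module-specific members map
    only to the other species' background so that planted conserved labels
    are exactly the ortholog-recoverable ones. Each B gene then gains a
    second A copy with probability ``duplication_rate``, drawn from the A
    background (duplicate copies sit outside the module)."""
    pairs: set[tuple[str, str]] = set()
    pairs |= {(a, b) for a, b in zip(conserved_a, conserved_b)}

    rest_a = sorted(set(proteins_a) - set(module_a))
    rest_b = sorted(set(proteins_b) - set(module_b))
    specific_a = sorted(set(module_a) - set(conserved_a))
    specific_b = sorted(set(module_b) - set(conserved_b))

    perm_rest_b = list(rng.permutation(rest_b))
    perm_rest_a = list(rng.permutation(rest_a))
    # A-specific members pair with B background, B-specific with A background
    used_b = []
    for a, b in zip(specific_a, perm_rest_b):
        pairs.add((a, b))
        used_b.append(b)
    used_a = []
    for b, a in zip(specific_b, perm_rest_a):
        pairs.add((a, b))
        used_a.append(a)
    remaining_a = [a for a in perm_rest_a if a not in set(used_a)]
    remaining_b = [b for b in perm_rest_b if b not in set(used_b)]
    pairs |= set(zip(remaining_a, remaining_b))

    background_a = rest_a  # duplicate copies are drawn from outside module A
    b_of_pairs = sorted({b for _, b in pairs})
    dup_draws = rng.random(len(b_of_pairs)) < cfg.duplication_rate
    copy_idx = rng.integers(0, len(background_a), size=len(b_of_pairs))
    for b, dup, ci in zip(b_of_pairs, dup_draws, copy_idx):
        if dup:
            pairs.add((background_a[ci], b))
    return OrthologMap(pairs)


# ---------------------------------------------------------------------------
# file output

def write_obo(g: OntologyGraph, path) -> None:
    """Serialise the ontology in the OBO 1.2 subset the parser reads."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(g.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        name = g.names.get(term)
        if name:
            lines.append(f"name: {name}")
        for _, parent, rel in sorted(g.graph.out_edges(term, keys=True),
                                     key=lambda e: (e[2], e[1])):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_string_links(net: WeightedNetwork, path) -> None:
    """Write STRING-style links with integer 0–1000 combined scores."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, w in net.sorted_edges():
            fh.write(f"{u}\t{v}\t{int(round(w * 1000))}\n")


def write_world(world: SyntheticWorld, outdir) -> dict[str, Path]:
    """Write every standard-format input file plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations_a": outdir / "annotations_a.tsv",
        "annotations_b": outdir / "annotations_b.tsv",
        "links_a": outdir / "links_a.tsv",
        "links_b": outdir / "links_b.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_obo(world.ontology, paths["ontology"])
    world.ann_a.write_tsv(paths["annotations_a"])
    world.ann_b.write_tsv(paths["annotations_b"])
    write_string_links(world.net_a, paths["links_a"])
    write_string_links(world.net_b, paths["links_b"])
    world.orthologs.write_tsv(paths["orthologs"])
    world.truth_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
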