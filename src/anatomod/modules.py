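"""Assembly of anatomical-entity modules from original + predicted proteins.

A module is an anatomical entity's protein set — the originally annotated
proteins (directly, or via a part / developmental-precursor term) plus the
network-predicted candidates — together with the weighted edges they induce
in the integrated network. Members are ranked by weighted degree within the
module's induced subgraph (hub-ness is treated as a modular property; a
configuration flag switches to whole-network degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import (
    WeightedNetwork,
    export_network,
    induced_subgraph,
    weighted_degree,
)

ORIGIN_DIRECT = "original_direct"
ORIGIN_PART = "original_part_or_precursor"
ORIGIN_PREDICTED = "predicted"


@dataclass
class Module:
    """An anatomical entity's protein module.

    ``origin`` labels every member ``original_direct`` /
    ``original_part_or_precursor`` / ``predicted``; ``lost`` lists originally
    annotated proteins absent from the network (and therefore from the
    module).
    """

    entity: str
    subgraph: WeightedNetwork
    origin: dict[str, str]
    lost: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return self.subgraph.nodes

    def original_nodes(self) -> set[str]:
        return {p for p, o in self.origin.items() if o != ORIGIN_PREDICTED}

    def predicted_nodes(self) -> set[str]:
        return {p for p, o in self.origin.items() if o == ORIGIN_PREDICTED}


def assemble_module(
    net: WeightedNetwork,
    entity: str,
    original: Mapping[str, str] | Iterable[str],
    predicted: Iterable[str] = (),
) -> Module:
    """Build the module for ``entity`` from originally annotated proteins
    (with origin labels; a plain iterable is labelled ``original_direct``) and
    predicted candidates. Raises on overlap between the two sets."""
    if not isinstance(original, Mapping):
        original = {p: ORIGIN_DIRECT for p in original}
    predicted = set(predicted)
    overlap = set(original) & predicted
    if overlap:
        raise ValueError(
            f"original and predicted sets overlap: {sorted(overlap)[:5]}"
        )
    members = (set(original) | predicted) & net.nodes
    lost = set(original) - net.nodes
    origin = {p: original[p] for p in set(original) & members}
    origin.update({p: ORIGIN_PREDICTED for p in predicted & members})
    return Module(
        entity=entity,
        subgraph=induced_subgraph(net, members),
        origin=origin,
        lost=lost,
    )


def module_weighted_degrees(
    m: Module, net: WeightedNetwork | None = None
) -> dict[str, float]:
    """Weighted degree of each member — within the module's induced subgraph
    by default, or in the full network when ``net`` is given."""
    source = m.subgraph if net is None else net
    return {p: weighted_degree(source, p) for p in m.nodes}


def rank_by_weighted_degree(
    m: Module, net: WeightedNetwork | None = None
) -> pd.DataFrame:
    """Members ranked by descending weighted degree (ties broken
    lexicographically by protein id); rank 1 is the top hub."""
    wdeg = module_weighted_degrees(m, net)
    ordered = sorted(wdeg.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        (p, m.origin[p], w, w / len(m.nodes), i + 1)
        for i, (p, w) in enumerate(ordered)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "origin",
            "weighted_degree",
            "normalized_weighted_degree",
            "rank",
        ],
    )


def compare_degree_distributions(
    m: Module, net: WeightedNetwork | None = None
) -> dict:
    """Compare predicted vs. originally annotated members' weighted-degree
    distributions (five-number summaries, means and a Wilcoxon rank-sum
    p-value). A higher predicted distribution suggests the candidates are at
    least as central as the seed proteins."""
    from .comparison import wilcoxon_rank_sum  # deferred: avoids cycle

    original = m.original_nodes()
    predicted = m.predicted_nodes()
    if not original:
        raise ValueError("module has no originally annotated members")
    if not predicted:
        raise ValueError("module has no predicted members")

    wdeg = module_weighted_degrees(m, net)
    groups = {
        "original": np.array(sorted(wdeg[p] for p in original)),
        "predicted": np.array(sorted(wdeg[p] for p in predicted)),
    }
    summary: dict = {}
    for name, values in groups.items():
        q = np.percentile(values, [0, 25, 50, 75, 100])
        summary[name] = {
            "n": int(values.size),
            "min": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "max": float(q[4]),
            "mean": float(values.mean()),
        }
    stat, p = wilcoxon_rank_sum(groups["predicted"], groups["original"])
    summary["wilcoxon"] = {"statistic": float(stat), "p_value": float(p)}
    return summary


def degree_distribution_frame(m: Module, net: WeightedNetwork | None = None) -> pd.DataFrame:
    """Boxplot-ready long table of per-member weighted degrees by group."""
    wdeg = module_weighted_degrees(m, net)
    rows = [
        (p, "predicted" if m.origin[p] == ORIGIN_PREDICTED else "original", wdeg[p])
        for p in sorted(m.nodes)
    ]
    return pd.DataFrame(rows, columns=["protein_id", "group", "weighted_degree"])


def export_module(m: Module, prefix, net: WeightedNetwork | None = None) -> list[Path]:
    """Write SIF + GraphML + node-attribute TSV + lost-protein TSV."""
    prefix = Path(prefix)
    ranks = rank_by_weighted_degree(m, net)
    files = export_network(m.subgraph, prefix, "sif", node_attrs=ranks)
    files += export_network(m.subgraph, prefix, "graphml")
    lost_path = prefix.parent / (prefix.name + ".lost.tsv")
    with open(lost_path, "w") as fh:
        fh.write("protein_id\n")
        for p in sorted(m.lost):
            fh.write(p + "\n")
    files.append(lost_path)
    return files
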