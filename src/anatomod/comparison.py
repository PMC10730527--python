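"""Cross-species module comparison.

Two homologous modules (one per species) are compared through an ortholog
map: a protein is *conserved* when at least one of its orthologs lies in the
other species' module — all such orthologs are retained, so a gene duplicated
in one lineage (e.g. after a whole-genome duplication) can contribute several
conserved copies — and *module-specific* otherwise. Because module sizes
differ between species, each protein's weighted degree is normalised by its
module's size before distributions are compared; Wilcoxon rank-sum tests
contrast conserved vs. module-specific members within each species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .modules import Module, module_weighted_degrees, rank_by_weighted_degree
from .network import WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Cross-species gene/protein correspondences; one-to-many and
    many-to-one pairs are allowed (teleost duplicates map one B gene to two A
    copies)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def b_to_a(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out

    def reversed(self) -> "OrthologMap":
        return OrthologMap({(b, a) for a, b in self.pairs})

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in sorted(self.pairs):
                fh.write(f"{a}\t{b}\n")


def read_ortholog_table(source, columns: tuple[int, int] = (0, 1)) -> OrthologMap:
    """Read a two-species ortholog table (TSV; ``#`` comments and a header
    line skipped; duplicate pairs collapse). ``columns`` selects the A- and
    B-species columns by index."""
    from io import IOBase

    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source
        and Path(source).exists()
    ):
        text = Path(source).read_text()
    elif isinstance(source, IOBase):
        text = source.read()
    else:
        text = str(source)

    ia, ib = columns
    pairs: set[tuple[str, str]] = set()
    seen_data = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) <= max(ia, ib):
            raise ValueError(
                f"line {lineno}: expected >= {max(ia, ib) + 1} columns, "
                f"got {len(parts)}"
            )
        a, b = parts[ia].strip(), parts[ib].strip()
        if not seen_data and (a.lower() in ("protein_a", "protein1", "gene_a")
                              or lineno == 1 and _looks_like_header(parts)):
            seen_data = True
            continue
        if not a or not b:
            raise ValueError(f"line {lineno}: empty protein id")
        pairs.add((a, b))
        seen_data = True
    if not pairs:
        logger.warning("ortholog table is empty")
    return OrthologMap(pairs)


def _looks_like_header(parts: list[str]) -> bool:
    lowered = [p.lower() for p in parts]
    keywords = ("protein", "gene", "ortholog", "symbol", "id")
    return any(any(k in p for k in keywords) for p in lowered)


@dataclass
class ComparisonResult:
    """Outcome of a two-module comparison.

    Partitions are exhaustive and disjoint per species; ``matched_pairs``
    lists ortholog pairs with both ends in-module (their endpoints are exactly
    the conserved proteins); ``tests`` maps species ('a'/'b') to
    (statistic, p_value) of the conserved-vs-specific Wilcoxon rank-sum test,
    or None when a side has an empty group.
    """

    conserved_a: set[str]
    specific_a: set[str]
    conserved_b: set[str]
    specific_b: set[str]
    matched_pairs: list[tuple[str, str]]
    nwd_a: dict[str, float]
    nwd_b: dict[str, float]
    tests: dict[str, tuple[float, float] | None]
    rank_table: pd.DataFrame | None = None

    def partition_frame(self) -> pd.DataFrame:
        rows = []
        for species, conserved, specific, nwd in (
            ("a", self.conserved_a, self.specific_a, self.nwd_a),
            ("b", self.conserved_b, self.specific_b, self.nwd_b),
        ):
            for p in sorted(conserved):
                rows.append((species, p, "conserved", nwd[p]))
            for p in sorted(specific):
                rows.append((species, p, "specific", nwd[p]))
        return pd.DataFrame(
            rows,
            columns=["species", "protein_id", "category",
                     "normalized_weighted_degree"],
        )


def classify_conserved(
    module_a: Module, module_b: Module, orth: OrthologMap
) -> tuple[set[str], set[str], set[str], set[str], list[tuple[str, str]]]:
    """Partition both modules into conserved / module-specific proteins.

    A member of module A is conserved iff at least one ortholog lies in
    module B (and symmetrically); with one-to-many orthology every in-module
    ortholog is retained as conserved.
    """
    nodes_a, nodes_b = module_a.nodes, module_b.nodes
    matched = sorted(
        (a, b) for a, b in orth.pairs if a in nodes_a and b in nodes_b
    )
    conserved_a = {a for a, _ in matched}
    conserved_b = {b for _, b in matched}
    return (
        conserved_a,
        nodes_a - conserved_a,
        conserved_b,
        nodes_b - conserved_b,
        matched,
    )


def normalized_weighted_degree(
    m: Module, net: WeightedNetwork | None = None
) -> dict[str, float]:
    """Weighted degree divided by module size, for every module member."""
    if not m.nodes:
        raise ValueError("module is empty")
    size = len(m.nodes)
    return {p: w / size for p, w in module_weighted_degrees(m, net).items()}


def wilcoxon_rank_sum(
    x: Iterable[float],
    y: Iterable[float],
    alternative: str = "two_sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) test.

    ``method='auto'`` uses the exact rank-sum distribution when the combined
    sample is small (n1+n2 <= 14) and tie-free, otherwise the normal
    approximation with tie and continuity corrections. Returns
    (U statistic of x, p-value).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(
        alternative
    )
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:  # every value identical: no evidence either way
        return float(x.size * y.size / 2.0), 1.0

    if method == "auto":
        scipy_method = (
            "exact" if (x.size + y.size <= 14 and not has_ties) else "asymptotic"
        )
    elif method == "exact":
        if has_ties:
            logger.warning("ties present; falling back to normal approximation")
            scipy_method = "asymptotic"
        else:
            scipy_method = "exact"
    else:
        scipy_method = "asymptotic"

    res = stats.mannwhitneyu(
        x, y, alternative=alt, method=scipy_method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_modules(
    module_a: Module,
    module_b: Module,
    orth: OrthologMap,
    alternative: str = "two_sided",
) -> ComparisonResult:
    """Full cross-species comparison: conserved/specific partitions,
    normalised weighted degrees, per-species Wilcoxon tests and a matched
    ortholog-rank table."""
    if not module_a.nodes or not module_b.nodes:
        raise ValueError("both modules must be nonempty")
    conserved_a, specific_a, conserved_b, specific_b, matched = classify_conserved(
        module_a, module_b, orth
    )
    nwd_a = normalized_weighted_degree(module_a)
    nwd_b = normalized_weighted_degree(module_b)

    tests: dict[str, tuple[float, float] | None] = {}
    for species, conserved, specific, nwd in (
        ("a", conserved_a, specific_a, nwd_a),
        ("b", conserved_b, specific_b, nwd_b),
    ):
        if not conserved or not specific:
            logger.warning(
                "species %s: conserved or specific group empty; test skipped",
                species,
            )
            tests[species] = None
            continue
        tests[species] = wilcoxon_rank_sum(
            [nwd[p] for p in sorted(conserved)],
            [nwd[p] for p in sorted(specific)],
            alternative=alternative,
        )

    ranks_a = rank_by_weighted_degree(module_a).set_index("protein_id")["rank"]
    ranks_b = rank_by_weighted_degree(module_b).set_index("protein_id")["rank"]
    rank_rows = [
        (a, b, int(ranks_a[a]), int(ranks_b[b])) for a, b in matched
    ]
    rank_table = pd.DataFrame(
        rank_rows, columns=["protein_a", "protein_b", "rank_a", "rank_b"]
    )
    return ComparisonResult(
        conserved_a=conserved_a,
        specific_a=specific_a,
        conserved_b=conserved_b,
        specific_b=specific_b,
        matched_pairs=matched,
        nwd_a=nwd_a,
        nwd_b=nwd_b,
        tests=tests,
        rank_table=rank_table,
    )


def validate_predictions_by_homology(
    predicted_a: Iterable[str], module_b: Module, orth: OrthologMap
) -> pd.DataFrame:
    """Homology check of predicted proteins: for each predicted protein of
    species A, report whether >= 1 ortholog lies in module B and the origin
    labels of those in-module orthologs (a predicted protein whose ortholog
    was independently annotated in the other species is corroborated)."""
    fwd = orth.a_to_b()
    rows = []
    for p in sorted(set(predicted_a)):
        in_module = sorted(fwd.get(p, set()) & module_b.nodes)
        origins = ";".join(module_b.origin[b] for b in in_module)
        rows.append((p, len(in_module) > 0, ",".join(in_module), origins))
    return pd.DataFrame(
        rows,
        columns=["protein_id", "validated", "orthologs_in_module", "origins"],
    )


def homology_validation_summary(report: pd.DataFrame) -> dict:
    """Counts for a homology-validation report: total predictions, how many
    were validated, and a breakdown by the origin label of the supporting
    in-module orthologs."""
    by_origin: dict[str, int] = {}
    for origins in report.loc[report["validated"], "origins"]:
        for label in set(origins.split(";")):
            if label:
                by_origin[label] = by_origin.get(label, 0) + 1
    return {
        "total_predicted": int(len(report)),
        "validated": int(report["validated"].sum()),
        "by_origin": dict(sorted(by_origin.items())),
    }
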