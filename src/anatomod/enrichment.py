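"""Ontology-term over-representation analysis (Fisher's exact test).

A study protein set is tested term-by-term against a background: with N
background proteins of which K carry the term, and a study of size n with k
carriers, the one-sided p-value is the hypergeometric upper tail
P(X >= k). Annotations are propagated up the ontology (is_a / part_of) before
counting, so a protein annotated to a fin's part also counts for the fin. The
``enriched`` flag uses the raw p-value at ``alpha`` (over-representation
convention); Benjamini–Hochberg-adjusted p-values are reported alongside.
The same engine serves anatomy-ontology and GO-BP-style annotation tables —
a GO table is simply another ontology + annotation pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparison import OrthologMap
from .ontology import AnnotationTable, OntologyGraph, SIMILARITY_RELATIONS, descendants

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 enrichment table: k of n study proteins carry a term that K of N
    background proteins carry."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.n, self.K)
            and self.k <= self.n <= self.N
            and 0 <= self.K <= self.N
            and self.n - self.k <= self.N - self.K
        )
        if not ok:
            raise ValueError(
                f"invalid contingency table k={self.k} n={self.n} "
                f"K={self.K} N={self.N}"
            )


def fisher_exact_one_sided(t: ContingencyTable) -> float:
    """One-sided (over-representation) Fisher exact p-value: the
    hypergeometric upper tail P(X >= k)."""
    return float(stats.hypergeom.sf(t.k - 1, t.N, t.K, t.n))


def _propagated_term_proteins(
    ann: AnnotationTable,
    g: OntologyGraph,
    relations: Iterable[str] = SIMILARITY_RELATIONS,
) -> dict[str, set[str]]:
    direct = ann.restrict_to(g).term_to_proteins()
    out: dict[str, set[str]] = {}
    for term in g.terms:
        proteins: set[str] = set()
        for d in descendants(g, term, relations):
            proteins |= direct.get(d, set())
        if proteins:
            out[term] = proteins
    return out


def enrich_terms(
    study: set[str],
    ann: AnnotationTable,
    g: OntologyGraph,
    background: set[str] | None = None,
    alpha: float = 0.05,
    relations: Iterable[str] = SIMILARITY_RELATIONS,
) -> pd.DataFrame:
    """Term-by-term Fisher enrichment of ``study`` against ``background``
    (default: all annotated proteins).

    Returns a frame sorted by ascending p-value with columns term_id,
    term_name, k, n, K, N, odds_ratio, p_value, p_adjusted, enriched.
    """
    if background is None:
        background = ann.proteins
    if not study:
        raise ValueError("study set is empty")
    if not background:
        raise ValueError("background set is empty")
    stray = study - background
    if stray:
        raise ValueError(
            f"study proteins missing from background: {sorted(stray)[:5]}"
        )

    term_proteins = _propagated_term_proteins(ann, g, relations)
    N = len(background)
    n = len(study)
    rows = []
    for term in sorted(term_proteins):
        carriers = term_proteins[term] & background
        K = len(carriers)
        if K == 0:
            continue
        k = len(carriers & study)
        p = fisher_exact_one_sided(ContingencyTable(k=k, n=n, K=K, N=N))
        a, b = k, n - k
        c, d = K - k, (N - n) - (K - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((term, g.names.get(term, ""), k, n, K, N, odds, p))

    frame = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "n", "K", "N",
                 "odds_ratio", "p_value"],
    )
    if frame.empty:
        frame["p_adjusted"] = []
        frame["enriched"] = []
        return frame
    frame["p_adjusted"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    frame["enriched"] = frame["p_value"] < alpha
    frame = frame.sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def enriched_term_set(result: pd.DataFrame) -> set[str]:
    return set(result.loc[result["enriched"], "term_id"])


def shared_enriched_terms(
    set_a: set[str],
    set_b: set[str],
    ann: AnnotationTable,
    g: OntologyGraph,
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> set[str]:
    """Terms enriched in both protein sets — e.g. predicted proteins vs. the
    originally annotated proteins of the same module."""
    ea = enriched_term_set(enrich_terms(set_a, ann, g, background, alpha))
    eb = enriched_term_set(enrich_terms(set_b, ann, g, background, alpha))
    return ea & eb


def fate_report(
    specific: set[str],
    orth: OrthologMap,
    ann_other: AnnotationTable,
    g_other: OntologyGraph,
    background_other: set[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """What became of one species' module-specific proteins in the other
    species: map them through the ortholog table (all targets retained) and
    run enrichment against the other species' annotations.

    Returns (enrichment frame, number of unmapped proteins).
    """
    if not specific:
        raise ValueError("module-specific protein set is empty")
    fwd = orth.a_to_b()
    mapped: set[str] = set()
    unmapped = 0
    for p in specific:
        targets = fwd.get(p, set())
        if targets:
            mapped |= targets
        else:
            unmapped += 1
    if unmapped:
        logger.info("%d of %d specific proteins had no ortholog",
                    unmapped, len(specific))
    if background_other is None:
        background_other = ann_other.proteins
    mapped &= background_other
    if not mapped:
        raise ValueError("no module-specific protein maps into the background")
    frame = enrich_terms(mapped, ann_other, g_other, background_other, alpha)
    return frame, unmapped
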