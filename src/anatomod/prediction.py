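"""Network-based candidate-protein prediction.

Guilt-by-association scoring follows the Hishigaki chi-square statistic: for
a protein ``u`` and an annotated set ``A``, compare the observed amount of
annotation in u's neighbourhood, ``n``, with its expectation ``e`` under the
background annotation frequency ``f = |A ∩ V| / |V|``:

    score(u) = sign(n - e) * (n - e)^2 / e

In the weighted mode (the default, appropriate for integrated networks where
edge weights carry confidence) ``n`` is the summed weight of edges to
annotated neighbours and ``e`` is u's total incident weight times ``f``; the
count mode uses neighbour counts, recovering the original formulation. The
statistic is signed so that annotation-depleted neighbourhoods rank below
neutral ones.

Performance per anatomical entity is estimated by leave-one-out
cross-validation: each annotated protein is scored with its own annotation
hidden (removed from both the neighbourhood and the background frequency),
every non-annotated node is scored against the full set, and ROC /
precision-recall curves are computed over the pooled ranking. A precision
threshold applied to the cross-validated PR curve yields a score cutoff for
calling new candidate proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .network import WeightedNetwork


def hishigaki_score(
    net: WeightedNetwork,
    annotated: set[str],
    u: str,
    mode: str = "weighted",
) -> float:
    """Signed chi-square enrichment of annotated proteins in u's
    neighbourhood; 0 when the expectation is 0 (no neighbours or empty
    background)."""
    if u not in net.graph:
        raise KeyError(u)
    if mode not in ("weighted", "count"):
        raise ValueError(f"unknown mode {mode!r}")

    n_nodes = net.graph.number_of_nodes()
    freq = len(annotated & net.nodes) / n_nodes

    observed = 0.0
    exposure = 0.0  # neighbour count (count mode) or total incident weight
    for _, v, d in net.graph.edges(u, data=True):
        w = d["weight"] if mode == "weighted" else 1.0
        exposure += w
        if v in annotated:
            observed += w

    expected = exposure * freq
    if expected == 0.0:
        return 0.0
    diff = observed - expected
    return math.copysign(diff * diff / expected, diff) if diff != 0 else 0.0


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome for one anatomical entity.

    ``positives``/``negatives`` map protein ids to their LOO scores; ``roc``
    is the (fpr, tpr) polyline from (0,0) to (1,1); ``pr`` holds
    (recall, precision, score_cutoff) triples, one per distinct score
    threshold, in order of decreasing cutoff; ``auc`` is the trapezoidal area
    under the ROC curve.
    """

    positives: dict[str, float]
    negatives: dict[str, float]
    roc: list[tuple[float, float]]
    pr: list[tuple[float, float, float]]
    auc: float

    def score_frame(self) -> pd.DataFrame:
        rows = [
            (p, s, True, True) for p, s in sorted(self.positives.items())
        ] + [
            (p, s, False, False) for p, s in sorted(self.negatives.items())
        ]
        return pd.DataFrame(
            rows, columns=["protein_id", "score", "is_annotated", "held_out"]
        )

    def write(self, prefix) -> list[Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        scores = prefix.parent / (prefix.name + ".scores.tsv")
        self.score_frame().to_csv(
            scores, sep="\t", index=False, float_format="%.10g"
        )
        roc_path = prefix.parent / (prefix.name + ".roc.tsv")
        pd.DataFrame(self.roc, columns=["fpr", "tpr"]).to_csv(
            roc_path, sep="\t", index=False, float_format="%.10g"
        )
        pr_path = prefix.parent / (prefix.name + ".pr.tsv")
        pd.DataFrame(
            self.pr, columns=["recall", "precision", "score_cutoff"]
        ).to_csv(pr_path, sep="\t", index=False, float_format="%.10g")
        return [scores, roc_path, pr_path]


def loo_cross_validate(
    net: WeightedNetwork,
    annotated: set[str],
    mode: str = "weighted",
) -> CVResult:
    """Leave-one-out cross-validation of Hishigaki prediction for one
    annotated set; requires at least two annotated proteins in the network."""
    in_net = annotated & net.nodes
    if len(in_net) < 2:
        raise ValueError(
            f"need >= 2 annotated proteins in the network, found {len(in_net)}"
        )

    positives: dict[str, float] = {}
    for p in sorted(in_net):
        positives[p] = hishigaki_score(net, in_net - {p}, p, mode)
    negatives: dict[str, float] = {}
    for p in sorted(net.nodes - annotated):
        negatives[p] = hishigaki_score(net, in_net, p, mode)
    if not negatives:
        raise ValueError("every network node is annotated; nothing to rank against")

    roc, pr, auc_value = score_curves(
        list(positives.values()), list(negatives.values())
    )
    return CVResult(
        positives=positives, negatives=negatives, roc=roc, pr=pr, auc=auc_value
    )


def score_curves(
    pos_scores: list[float], neg_scores: list[float]
) -> tuple[list[tuple[float, float]], list[tuple[float, float, float]], float]:
    """ROC and PR curves over a pooled score ranking (descending score, tied
    scores grouped) and the trapezoidal ROC AUC.

    Returns (roc, pr, auc) with roc as (fpr, tpr) points from (0,0) to (1,1)
    and pr as (recall, precision, score_cutoff) triples in order of
    decreasing cutoff.
    """
    labels = np.array([1] * len(pos_scores) + [0] * len(neg_scores))
    scores = np.array(list(pos_scores) + list(neg_scores), dtype=float)

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    roc = list(zip(fpr.tolist(), tpr.tolist()))
    auc_value = float(_trapezoid_auc(fpr, tpr))

    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # the final (recall=0, precision=1) sentinel carries no threshold
    pr = [
        (float(recall[i]), float(precision[i]), float(thresholds[i]))
        for i in range(len(thresholds))
    ]
    pr.sort(key=lambda t: -t[2])
    return roc, pr, auc_value


def select_score_cutoff(cv: CVResult, precision_threshold: float) -> float | None:
    """Lowest score cutoff (maximal recall) whose cross-validated precision
    meets the threshold; ``None`` when the precision is never reached."""
    if not (0.0 < precision_threshold <= 1.0):
        raise ValueError(
            f"precision threshold must lie in (0, 1], got {precision_threshold}"
        )
    if not cv.pr:
        raise ValueError("CV result has no precision-recall points")
    eligible = [cutoff for _, prec, cutoff in cv.pr if prec >= precision_threshold]
    return min(eligible) if eligible else None


def predict_candidates(
    net: WeightedNetwork,
    annotated: set[str],
    cutoff: float,
    mode: str = "weighted",
) -> set[str]:
    """All non-annotated network nodes whose full-annotation Hishigaki score
    reaches the cutoff."""
    if cutoff is None:
        raise ValueError("cutoff is None (precision threshold was never reached)")
    if cutoff == math.inf:
        return set()
    in_net = annotated & net.nodes
    out = set()
    for p in net.nodes - annotated:
        if hishigaki_score(net, in_net, p, mode) >= cutoff:
            out.add(p)
    return out
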