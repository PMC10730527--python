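"""Ontology parsing, closures, information content and semantic similarity."""

import math

import numpy as np
import pytest

from anatomod.ontology import (
    AnnotationTable,
    ICTable,
    OboParseError,
    UndefinedSimilarity,
    ancestors,
    collect_original_annotations,
    collect_original_annotations_labeled,
    compute_ic,
    parse_obo,
    protein_similarity,
    term_similarity,
)

from conftest import (
    dfs_ancestors_oracle,
    make_ontology,
    random_annotations,
    random_dag,
)

TWO_TERM_OBO = """\
format-version: 1.2

[Term]
id: X:0001
name: organ

[Term]
id: X:0002
name: sub-organ
is_a: X:0001
"""


class TestParseObo:
    def test_is_a_edge(self):
        g = parse_obo(TWO_TERM_OBO)
        assert g.terms == {"X:0001", "X:0002"}
        assert ("X:0002", "X:0001", "is_a") in g.graph.edges(keys=True)
        assert g.names["X:0002"] == "sub-organ"

    def test_typed_part_of_relationship(self):
        doc = TWO_TERM_OBO + (
            "\n[Term]\nid: X:0003\nrelationship: part_of X:0001\n"
        )
        g = parse_obo(doc)
        assert ("X:0003", "X:0001", "part_of") in g.graph.edges(keys=True)

    def test_develops_from_relationship(self):
        doc = TWO_TERM_OBO + (
            "\n[Term]\nid: X:0004\nrelationship: develops_from X:0002\n"
        )
        g = parse_obo(doc)
        assert ("X:0004", "X:0002", "develops_from") in g.graph.edges(keys=True)

    def test_cycle_raises(self):
        doc = (
            "[Term]\nid: A\nis_a: B\n\n[Term]\nid: B\nis_a: A\n"
        )
        with pytest.raises(OboParseError, match="cycle"):
            parse_obo(doc)

    def test_stanza_without_id_raises(self):
        doc = "[Term]\nname: nameless\n\n[Term]\nid: A\n"
        with pytest.raises(OboParseError, match="no id"):
            parse_obo(doc)

    def test_obsolete_terms_dropped(self):
        doc = TWO_TERM_OBO + "\n[Term]\nid: X:0009\nis_obsolete: true\n"
        g = parse_obo(doc)
        assert "X:0009" not in g.terms

    def test_unknown_relationship_ignored(self, caplog):
        doc = TWO_TERM_OBO + (
            "\n[Term]\nid: X:0005\nrelationship: adjacent_to X:0001\n"
        )
        g = parse_obo(doc)
        assert not any(
            rel == "adjacent_to" for *_, rel in g.graph.edges(keys=True)
        )


class TestAncestors:
    def test_root_is_reflexive(self, chain_ontology):
        assert ancestors(chain_ontology, "root") == {"root"}

    def test_chain_closure(self, chain_ontology):
        assert ancestors(chain_ontology, "B") == {"B", "A", "root"}

    def test_unknown_term_raises(self, chain_ontology):
        with pytest.raises(KeyError):
            ancestors(chain_ontology, "missing")

    def test_relation_filtering(self):
        g = make_ontology([
            ("part", "whole", "part_of"),
            ("whole", "root", "is_a"),
            ("bud", "whole", "develops_from"),
        ])
        assert ancestors(g, "part", ("is_a",)) == {"part"}
        assert ancestors(g, "part", ("is_a", "part_of")) == {
            "part", "whole", "root"
        }
        assert ancestors(g, "bud", ("is_a", "part_of")) == {"bud"}

    def test_matches_dfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(42)
        relations = ("is_a", "part_of", "develops_from")
        for _ in range(1000):
            g = random_dag(rng, int(rng.integers(2, 31)), relations)
            term = f"T{int(rng.integers(0, len(g.terms)))}"
            subset = tuple(
                r for r in relations if rng.random() < 0.7
            ) or ("is_a",)
            assert ancestors(g, term, subset) == dfs_ancestors_oracle(
                g, term, subset
            )


class TestCollectOriginalAnnotations:
    @pytest.fixture
    def fin_like(self):
        # target with a part (part_of) and a precursor chain (develops_from)
        g = make_ontology([
            ("fin", "appendage", "is_a"),
            ("radials", "fin", "part_of"),
            ("fin_bud", "fin", "develops_from"),
            ("other", "appendage", "is_a"),
        ])
        ann = AnnotationTable.from_pairs([
            ("p_direct", "fin"),
            ("p_part", "radials"),
            ("p_bud", "fin_bud"),
            ("p_other", "other"),
        ])
        return g, ann

    def test_part_and_precursor_included(self, fin_like):
        g, ann = fin_like
        result = collect_original_annotations(g, ann, "fin")
        assert result == {"p_direct", "p_part", "p_bud"}

    def test_unrelated_excluded(self, fin_like):
        g, ann = fin_like
        assert "p_other" not in collect_original_annotations(g, ann, "fin")

    def test_missing_target_raises(self, fin_like):
        g, ann = fin_like
        with pytest.raises(KeyError):
            collect_original_annotations(g, ann, "tail")

    def test_labels(self, fin_like):
        g, ann = fin_like
        labels = collect_original_annotations_labeled(g, ann, "fin")
        assert labels == {
            "p_direct": "original_direct",
            "p_part": "original_part_or_precursor",
            "p_bud": "original_part_or_precursor",
        }


class TestComputeIc:
    def test_direct_evaluation(self, chain_ontology):
        # 9 proteins on B, 91 elsewhere: count(B)=9, total=100, constant=1
        pairs = [(f"p{i}", "B") for i in range(9)]
        pairs += [(f"q{i}", "C") for i in range(91)]
        ic = compute_ic(chain_ontology, AnnotationTable.from_pairs(pairs),
                        constant=1.0)
        assert ic["B"] == pytest.approx(-math.log(0.1), abs=1e-6)
        assert ic["B"] == pytest.approx(2.302585, abs=1e-6)

    def test_fully_annotated_term_has_zero_ic(self, chain_ontology):
        # count(B) = total - constant -> numerator = total -> p = 1 -> IC = 0
        pairs = [(f"p{i}", "B") for i in range(4)] + [("q", "C")]
        ic = compute_ic(chain_ontology, AnnotationTable.from_pairs(pairs),
                        constant=1.0)
        assert ic["B"] == 0.0
        assert ic["root"] == 0.0

    def test_pseudocount_caps_probability_at_one(self, chain_ontology):
        pairs = [("p0", "B")]
        ic = compute_ic(chain_ontology, AnnotationTable.from_pairs(pairs),
                        constant=1.0)
        assert all(v >= 0.0 for v in ic.ic.values())

    def test_empty_table_raises(self, chain_ontology):
        with pytest.raises(ValueError):
            compute_ic(chain_ontology,
                       AnnotationTable.from_pairs([("p", "nope")]))

    def test_zero_count_zero_constant(self, chain_ontology):
        pairs = [("p0", "B")]
        with pytest.raises(ValueError):
            compute_ic(chain_ontology, AnnotationTable.from_pairs(pairs),
                       constant=0.0, zero_count="error")
        ic = compute_ic(chain_ontology, AnnotationTable.from_pairs(pairs),
                        constant=0.0, zero_count="inf")
        assert ic["C"] == math.inf

    def test_anti_monotone_in_count(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_dag(rng, 15)
            ann = random_annotations(rng, g)
            ic = compute_ic(g, ann)
            for t1 in g.terms:
                for t2 in g.terms:
                    if ic.counts[t1] <= ic.counts[t2]:
                        assert ic[t1] >= ic[t2] - 1e-12


def brute_force_similarity(g, ic, t1, t2, method, relations):
    """Independent enumeration over the full common-ancestor set."""
    common = dfs_ancestors_oracle(g, t1, relations) & dfs_ancestors_oracle(
        g, t2, relations
    )
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    values = []
    for t in common:
        base = 2 * ic[t] / denom
        if method == "schlicker_printed":
            values.append(base * (1 + ic[t]))
        elif method == "schlicker_classic":
            values.append(base * (1 - ic.p_raw(t)))
        else:
            values.append(base)
    return max(values) if values else 0.0


class TestTermSimilarity:
    def test_self_similarity_is_one(self, chain_ontology, chain_ic):
        assert term_similarity(
            chain_ontology, chain_ic, "B", "B", "lin"
        ) == pytest.approx(1.0)

    def test_lin_on_injected_chain(self, chain_ontology, chain_ic):
        # S(B,C) = {root, A}: max(0, 2*1.0/3.5) = 0.5714...
        assert term_similarity(
            chain_ontology, chain_ic, "B", "C", "lin"
        ) == pytest.approx(2 * 1.0 / 3.5, abs=1e-4)

    def test_schlicker_printed_exceeds_one(self, chain_ontology, chain_ic):
        value = term_similarity(
            chain_ontology, chain_ic, "B", "C", "schlicker_printed"
        )
        assert value == pytest.approx(2 * 1.0 / 3.5 * 2.0, abs=1e-4)
        assert value > 1.0

    def test_zero_ic_denominator(self, chain_ontology):
        ic = ICTable(ic={t: 0.0 for t in chain_ontology.terms},
                     counts={}, total=1, constant=1.0)
        assert term_similarity(chain_ontology, ic, "B", "C", "lin") == 0.0

    def test_unknown_method(self, chain_ontology, chain_ic):
        with pytest.raises(ValueError):
            term_similarity(chain_ontology, chain_ic, "B", "C", "resnik")

    @pytest.mark.parametrize("method", ["lin", "schlicker_printed",
                                        "schlicker_classic"])
    def test_matches_brute_force_on_random_dags(self, method):
        rng = np.random.default_rng(11)
        relations = ("is_a", "part_of")
        for _ in range(200):
            g = random_dag(rng, int(rng.integers(3, 31)), relations)
            ann = random_annotations(rng, g)
            ic = compute_ic(g, ann)
            terms = sorted(g.terms)
            t1 = terms[int(rng.integers(0, len(terms)))]
            t2 = terms[int(rng.integers(0, len(terms)))]
            got = term_similarity(g, ic, t1, t2, method, relations)
            want = brute_force_similarity(g, ic, t1, t2, method, relations)
            assert got == pytest.approx(want, abs=1e-12)

    def test_lin_symmetry_and_bounds(self):
        rng = np.random.default_rng(23)
        g = random_dag(rng, 30)
        ann = random_annotations(rng, g, 40)
        ic = compute_ic(g, ann)
        terms = sorted(g.terms)
        for _ in range(1000):
            t1 = terms[int(rng.integers(0, len(terms)))]
            t2 = terms[int(rng.integers(0, len(terms)))]
            s12 = term_similarity(g, ic, t1, t2, "lin")
            s21 = term_similarity(g, ic, t2, t1, "lin")
            assert s12 == pytest.approx(s21, abs=1e-12)
            assert 0.0 <= s12 <= 1.0 + 1e-12


class TestProteinSimilarity:
    @pytest.fixture
    def annotated(self, chain_ontology):
        return AnnotationTable.from_pairs([
            ("pa", "B"), ("pb", "C"), ("pc", "B"),
        ])

    def test_identical_annotations(self, chain_ontology, chain_ic, annotated):
        assert protein_similarity(
            chain_ontology, chain_ic, annotated, "pa", "pc", "lin"
        ) == pytest.approx(1.0)

    def test_reduces_to_term_similarity(self, chain_ontology, chain_ic,
                                        annotated):
        assert protein_similarity(
            chain_ontology, chain_ic, annotated, "pa", "pb", "lin", "max"
        ) == pytest.approx(2 * 1.0 / 3.5, abs=1e-4)

    def test_unannotated_protein_signals(self, chain_ontology, chain_ic,
                                         annotated):
        with pytest.raises(UndefinedSimilarity):
            protein_similarity(
                chain_ontology, chain_ic, annotated, "pa", "ghost", "lin"
            )

    def test_bma_equals_max_for_single_annotations(self, chain_ontology,
                                                   chain_ic, annotated):
        m = protein_similarity(
            chain_ontology, chain_ic, annotated, "pa", "pb", "lin", "max"
        )
        b = protein_similarity(
            chain_ontology, chain_ic, annotated, "pa", "pb", "lin", "bma"
        )
        assert m == pytest.approx(b)
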