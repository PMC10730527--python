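"""End-to-end workflow orchestration.

The pipeline mirrors the two-species comparative workflow: for each species
it integrates a PPI network with an anatomy-semantic network, evaluates
guilt-by-association prediction by leave-one-out cross-validation, calls
candidate proteins at a precision threshold, assembles the anatomical
entity's module, and finally compares the two species' modules through an
ortholog map (conserved vs. module-specific proteins, normalised
weighted-degree tests, homology validation, ontology enrichment).

Configuration is one YAML file; every stage writes plain-text tables into the
output directory plus a ``manifest.json`` recording the configuration,
package version, seed and headline counts. Given identical inputs and
configuration the output tree is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .comparison import (
    OrthologMap,
    compare_modules,
    homology_validation_summary,
    read_ortholog_table,
    validate_predictions_by_homology,
)
from .enrichment import enrich_terms, enriched_term_set, fate_report
from .modules import (
    Module,
    assemble_module,
    compare_degree_distributions,
    degree_distribution_frame,
    export_module,
)
from .network import (
    WeightedNetwork,
    build_semantic_network,
    export_network,
    integrate_networks,
    read_string_links,
)
from .ontology import (
    AnnotationTable,
    OntologyGraph,
    collect_original_annotations_labeled,
    compute_ic,
    parse_obo,
)
from .prediction import (
    CVResult,
    loo_cross_validate,
    predict_candidates,
    select_score_cutoff,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class SpeciesConfig:
    annotations: Path
    network: Path
    entity: str
    precision_threshold: float = 0.7

    def validate(self, label: str) -> None:
        if not (0.0 < self.precision_threshold <= 1.0):
            raise ConfigError(
                f"{label}: precision_threshold must lie in (0, 1], "
                f"got {self.precision_threshold}"
            )


@dataclass
class PipelineConfig:
    ontology: Path
    orthologs: Path
    species_a: SpeciesConfig
    species_b: SpeciesConfig
    output_dir: Path
    similarity_method: str = "lin"
    similarity_aggregate: str = "max"
    alpha: float = 0.5
    min_weight: float = 0.0
    ic_constant: float = 1.0
    hishigaki_mode: str = "weighted"
    enrichment_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        base = path.parent

        def resolve(p) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            species = {}
            for key in ("species_a", "species_b"):
                s = raw[key]
                species[key] = SpeciesConfig(
                    annotations=resolve(s["annotations"]),
                    network=resolve(s["network"]),
                    entity=str(s["entity"]),
                    precision_threshold=float(s.get("precision_threshold", 0.7)),
                )
            sim = raw.get("similarity", {})
            integ = raw.get("integration", {})
            cfg = cls(
                ontology=resolve(raw["ontology"]),
                orthologs=resolve(raw["orthologs"]),
                species_a=species["species_a"],
                species_b=species["species_b"],
                output_dir=resolve(raw.get("output_dir", "results")),
                similarity_method=sim.get("method", "lin"),
                similarity_aggregate=sim.get("aggregate", "max"),
                alpha=float(integ.get("alpha", 0.5)),
                min_weight=float(integ.get("min_weight", 0.0)),
                ic_constant=float(raw.get("ic_constant", 1.0)),
                hishigaki_mode=raw.get("hishigaki_mode", "weighted"),
                enrichment_alpha=float(raw.get("enrichment_alpha", 0.05)),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.species_a.validate("species_a")
        self.species_b.validate("species_b")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError(f"integration alpha must lie in [0, 1], got {self.alpha}")
        if self.hishigaki_mode not in ("weighted", "count"):
            raise ConfigError(f"unknown hishigaki_mode {self.hishigaki_mode!r}")
        if not (0.0 < self.enrichment_alpha <= 1.0):
            raise ConfigError("enrichment_alpha must lie in (0, 1]")

    def check_inputs_exist(self) -> None:
        for p in (self.ontology, self.orthologs,
                  self.species_a.annotations, self.species_a.network,
                  self.species_b.annotations, self.species_b.network):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def echo(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return plain(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, Path):
                return str(obj)
            return obj
        return plain(self)


@dataclass
class SpeciesState:
    """Everything computed for one species along the way."""

    label: str
    cfg: SpeciesConfig
    ann: AnnotationTable = None
    ppi: WeightedNetwork = None
    integrated: WeightedNetwork = None
    originals: dict[str, str] = None
    cv: CVResult = None
    cutoff: float | None = None
    predicted: set[str] = None
    module: Module = None


class Pipeline:
    """Stage-by-stage runner; later stages compute earlier ones on demand."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.manifest: dict = {
            "anatomod_version": __version__,
            "seed": config.seed,
            "config": config.echo(),
            "counts": {},
        }
        self._loaded = False
        self.species: dict[str, SpeciesState] = {}
        self.ontology: OntologyGraph | None = None
        self.orthologs: OrthologMap | None = None
        self.comparison = None

    # -- stages -------------------------------------------------------------

    def load_inputs(self) -> None:
        if self._loaded:
            return
        cfg = self.config
        cfg.check_inputs_exist()
        self.outdir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        self.ontology = parse_obo(Path(cfg.ontology).read_text())
        self.orthologs = read_ortholog_table(cfg.orthologs)
        for label, scfg in (("a", cfg.species_a), ("b", cfg.species_b)):
            state = SpeciesState(label=label, cfg=scfg)
            state.ann = AnnotationTable.read_tsv(scfg.annotations)
            state.ppi = read_string_links(scfg.network)
            self.species[label] = state
        self._loaded = True
        logger.info("inputs loaded in %.2fs", time.perf_counter() - t0)

    def stage_integrate(self) -> None:
        self.load_inputs()
        cfg = self.config
        for label, state in self.species.items():
            if state.integrated is not None:
                continue
            t0 = time.perf_counter()
            ic = compute_ic(self.ontology, state.ann, constant=cfg.ic_constant)
            sem = build_semantic_network(
                self.ontology, ic, state.ann,
                proteins=state.ppi.nodes,
                method=cfg.similarity_method,
                aggregate=cfg.similarity_aggregate,
            )
            state.integrated = integrate_networks(
                state.ppi, sem, alpha=cfg.alpha, min_weight=cfg.min_weight
            )
            export_network(state.integrated, self.outdir / f"integrated_{label}",
                           format="tsv")
            self.manifest["counts"][f"network_{label}"] = {
                "ppi_nodes": len(state.ppi.nodes),
                "ppi_edges": state.ppi.n_edges(),
                "semantic_edges": sem.n_edges(),
                "integrated_edges": state.integrated.n_edges(),
            }
            logger.info("species %s integrated in %.2fs",
                        label, time.perf_counter() - t0)

    def stage_cv(self) -> None:
        self.stage_integrate()
        for label, state in self.species.items():
            if state.cv is not None:
                continue
            t0 = time.perf_counter()
            state.originals = collect_original_annotations_labeled(
                self.ontology, state.ann, state.cfg.entity
            )
            in_net = set(state.originals) & state.integrated.nodes
            if len(in_net) < 2:
                raise RuntimeError(
                    f"entity {state.cfg.entity} (species {label}): fewer than 2 "
                    "annotated proteins in the network; cannot cross-validate"
                )
            state.cv = loo_cross_validate(
                state.integrated, set(state.originals),
                mode=self.config.hishigaki_mode,
            )
            state.cv.write(self.outdir / f"cv_{label}")
            self.manifest["counts"][f"cv_{label}"] = {
                "n_original": len(state.originals),
                "n_original_in_network": len(in_net),
                "auc": round(state.cv.auc, 6),
            }
            logger.info("species %s LOO-CV in %.2fs (AUC %.3f)",
                        label, time.perf_counter() - t0, state.cv.auc)

    def stage_predict(self) -> None:
        self.stage_cv()
        for label, state in self.species.items():
            if state.predicted is not None:
                continue
            state.cutoff = select_score_cutoff(
                state.cv, state.cfg.precision_threshold
            )
            if state.cutoff is None:
                logger.warning(
                    "species %s: precision %.2f never reached; no candidates",
                    label, state.cfg.precision_threshold,
                )
                state.predicted = set()
            else:
                state.predicted = predict_candidates(
                    state.integrated, set(state.originals), state.cutoff,
                    mode=self.config.hishigaki_mode,
                )
            frame = pd.DataFrame(
                {"protein_id": sorted(state.predicted)}
            )
            frame.to_csv(self.outdir / f"predicted_{label}.tsv",
                         sep="\t", index=False)
            self.manifest["counts"][f"prediction_{label}"] = {
                "precision_threshold": state.cfg.precision_threshold,
                "score_cutoff": None if state.cutoff is None
                else round(state.cutoff, 6),
                "n_predicted": len(state.predicted),
            }

    def stage_module(self) -> None:
        self.stage_predict()
        for label, state in self.species.items():
            if state.module is not None:
                continue
            state.module = assemble_module(
                state.integrated, state.cfg.entity,
                state.originals, state.predicted,
            )
            export_module(state.module, self.outdir / f"module_{label}")
            degree_distribution_frame(state.module).to_csv(
                self.outdir / f"module_{label}.degree_groups.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
            counts = {
                "entity": state.cfg.entity,
                "n_members": len(state.module.nodes),
                "n_original": len(state.module.original_nodes()),
                "n_predicted": len(state.module.predicted_nodes()),
                "n_lost": len(state.module.lost),
            }
            if state.module.predicted_nodes() and state.module.original_nodes():
                summary = compare_degree_distributions(state.module)
                counts["predicted_vs_original_wilcoxon_p"] = round(
                    summary["wilcoxon"]["p_value"], 8
                )
                counts["predicted_median_wdeg"] = round(
                    summary["predicted"]["median"], 6
                )
                counts["original_median_wdeg"] = round(
                    summary["original"]["median"], 6
                )
            self.manifest["counts"][f"module_{label}"] = counts

    def stage_compare(self) -> None:
        self.stage_module()
        if self.comparison is not None:
            return
        module_a = self.species["a"].module
        module_b = self.species["b"].module
        result = compare_modules(module_a, module_b, self.orthologs)
        self.comparison = result
        result.partition_frame().to_csv(
            self.outdir / "comparison.partitions.tsv",
            sep="\t", index=False, float_format="%.10g",
        )
        result.rank_table.to_csv(
            self.outdir / "comparison.matched_ranks.tsv", sep="\t", index=False
        )
        test_rows = []
        for species in ("a", "b"):
            t = result.tests[species]
            test_rows.append(
                (species, "skipped" if t is None else "wilcoxon_rank_sum",
                 "" if t is None else f"{t[0]:.10g}",
                 "" if t is None else f"{t[1]:.10g}")
            )
        pd.DataFrame(
            test_rows, columns=["species", "test", "statistic", "p_value"]
        ).to_csv(self.outdir / "comparison.tests.tsv", sep="\t", index=False)

        reports = {}
        for direction, pred, module, orth in (
            ("a_in_b", self.species["a"].predicted, module_b, self.orthologs),
            ("b_in_a", self.species["b"].predicted, module_a,
             self.orthologs.reversed()),
        ):
            report = validate_predictions_by_homology(pred, module, orth)
            report.to_csv(self.outdir / f"homology_validation_{direction}.tsv",
                          sep="\t", index=False)
            reports[direction] = homology_validation_summary(report)
        self.manifest["counts"]["comparison"] = {
            "conserved_a": len(result.conserved_a),
            "specific_a": len(result.specific_a),
            "conserved_b": len(result.conserved_b),
            "specific_b": len(result.specific_b),
            "matched_pairs": len(result.matched_pairs),
            "tests": {
                s: (None if result.tests[s] is None
                    else {"statistic": round(result.tests[s][0], 6),
                          "p_value": float(f"{result.tests[s][1]:.6g}")})
                for s in ("a", "b")
            },
            "homology_validation": reports,
        }

    def stage_enrich(self) -> None:
        self.stage_compare()
        cfg = self.config
        enr_counts = {}
        for label, state in self.species.items():
            background = state.ann.proteins
            enriched_sets: list[set[str]] = []
            for group, proteins in (
                ("original", set(state.originals) & state.module.nodes),
                ("predicted", state.predicted),
            ):
                if not proteins:
                    logger.warning("species %s: %s set empty; enrichment skipped",
                                   label, group)
                    continue
                frame = enrich_terms(
                    proteins, state.ann, self.ontology,
                    background=background, alpha=cfg.enrichment_alpha,
                )
                frame.to_csv(
                    self.outdir / f"enrichment_{label}_{group}.tsv",
                    sep="\t", index=False, float_format="%.10g",
                )
                enriched = enriched_term_set(frame)
                enriched_sets.append(enriched)
                enr_counts[f"{label}_{group}_enriched_terms"] = len(enriched)
            shared = set.intersection(*enriched_sets) if len(enriched_sets) == 2 else set()
            pd.DataFrame({"term_id": sorted(shared)}).to_csv(
                self.outdir / f"shared_terms_{label}.tsv", sep="\t", index=False
            )
            enr_counts[f"{label}_shared_terms"] = len(shared)

        for direction, specific, orth, other in (
            ("a_specific_in_b", self.comparison.specific_a,
             self.orthologs, self.species["b"]),
            ("b_specific_in_a", self.comparison.specific_b,
             self.orthologs.reversed(), self.species["a"]),
        ):
            try:
                frame, unmapped = fate_report(
                    specific, orth, other.ann, self.ontology,
                    alpha=cfg.enrichment_alpha,
                )
            except ValueError as exc:
                logger.warning("fate report %s skipped: %s", direction, exc)
                continue
            frame.to_csv(self.outdir / f"fate_{direction}.tsv",
                         sep="\t", index=False, float_format="%.10g")
            enr_counts[f"fate_{direction}_enriched_terms"] = int(
                frame["enriched"].sum()
            )
            enr_counts[f"fate_{direction}_unmapped"] = unmapped
        self.manifest["counts"]["enrichment"] = enr_counts

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return path

    def run_all(self) -> dict:
        self.stage_enrich()
        self.write_manifest()
        return self.manifest
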