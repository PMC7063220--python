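"""End-to-end two-module workflow: screen, network, enrich, overlap, chemo.

``run_pipeline`` executes the full analysis the way the individual stage
functions would be called by hand: ADMET-screen the compound table, filter
the target predictions, split targets into the hemorheology and coagulopathy
modules, build one herb-compound-target network per module, rank nodes by
degree and betweenness, run pathway over-representation per module, compute
the cross-module overlaps, and -- when a cohort file is configured -- fit
the PLS-DA pharmacodynamic evaluation.  Every run writes intermediate TSVs,
a single deterministic ``summary.json`` and a ``manifest.json`` (config
hash, seed, package version) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, chemometrics, enrichment, io, network, screening
from .screening import COAGULOPATHY, HEMORHEOLOGY, ScreenConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and options of one pipeline run."""

    compounds: str
    predictions: str
    module_annotations: str
    gmt: str
    outdir: str
    cohort: str | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    species: str = "Homo sapiens"
    prune_isolated: bool = True
    normalized_betweenness: bool = True
    top_k: int = 10
    enrichment_mode: str = "standard"
    alpha: float = 0.05
    n_components: int = 2
    cv_folds: int = 7
    n_perm: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        screen = ScreenConfig(**raw.pop("screen", {}))
        cfg = cls(screen=screen, **raw)
        for p in (cfg.compounds, cfg.predictions, cfg.module_annotations, cfg.gmt, cfg.cohort):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg


def _centrality_records(table, k, net):
    top_deg = network.rank_top_k(table, "degree", k, node_type=network.NODE_COMPOUND)
    top_bet = network.rank_top_k(table, "betweenness", k, node_type=network.NODE_COMPOUND)
    top_tdeg = network.rank_top_k(table, "degree", k, node_type=network.NODE_TARGET)
    return {
        "counts": net.counts(),
        "top_compounds_by_degree": top_deg[["node", "degree"]].to_dict("records"),
        "top_compounds_by_betweenness": top_bet[["node", "betweenness"]].to_dict("records"),
        "top_targets_by_degree": top_tdeg[["node", "degree"]].to_dict("records"),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the summary dictionary (also written out)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    stage = "setup"
    try:
        stage = "screen"
        records = io.read_compounds(cfg.compounds)
        screened = screening.apply_admet_filter(records, cfg.screen)
        frame = [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "herbs": ";".join(sorted(r.herb_ids)),
                "ob": r.ob, "caco2": r.caco2, "dl": r.dl,
                "pass_reason": screened.reasons[r.compound_id],
            }
            for r in screened.retained
        ]
        import pandas as pd

        pd.DataFrame(frame).to_csv(outdir / "screened_compounds.tsv", sep="\t", index=False)
        summary["screen"] = {
            "n_input": len(records),
            "n_retained": len(screened.retained),
            "n_whitelisted": sum(v == "whitelist" for v in screened.reasons.values()),
            "n_errors": len(screened.errors),
        }

        stage = "targets"
        preds = io.read_predictions(cfg.predictions)
        retained_ids = set(screened.retained_ids)
        edges = screening.filter_predictions(preds, species=cfg.species)
        edges = edges[edges["compound_id"].isin(retained_ids)]
        edges.to_csv(outdir / "filtered_edges.tsv", sep="\t", index=False)
        all_targets = sorted(set(edges["target"]))
        annotations = io.read_module_annotations(cfg.module_annotations)
        assignment = screening.assign_modules(all_targets, annotations)
        summary["targets"] = {
            "n_targets": len(all_targets),
            "n_hemorheology": len(assignment.hemorheology),
            "n_coagulopathy": len(assignment.coagulopathy),
            "n_shared": len(assignment.shared),
        }

        stage = "network"
        herbs = sorted({h for r in screened.retained for h in r.herb_ids})
        herb_by_compound = {r.compound_id: sorted(r.herb_ids) for r in screened.retained}
        nets, tables = {}, {}
        for mod, mod_targets in (
            (HEMORHEOLOGY, assignment.hemorheology),
            (COAGULOPATHY, assignment.coagulopathy),
        ):
            mod_edges = edges[edges["target"].isin(mod_targets)]
            mod_compounds = sorted(set(mod_edges["compound_id"]))
            attribution = [
                (h, c) for c in mod_compounds for h in herb_by_compound[c]
            ]
            net = network.build_network(
                mod, herbs, mod_compounds, sorted(mod_targets),
                attribution, list(mod_edges[["compound_id", "target"]].itertuples(index=False)),
                prune_isolated=cfg.prune_isolated,
            )
            table = network.centrality_table(net, normalized=cfg.normalized_betweenness)
            table.to_csv(outdir / f"centrality_{mod}.tsv", sep="\t", index=False)
            network.export_sif(net, outdir / f"network_{mod}.sif")
            nets[mod], tables[mod] = net, table
            summary[f"network_{mod}"] = _centrality_records(table, cfg.top_k, net)

        stage = "enrichment"
        collection = enrichment.AnnotationCollection("pathways", io.read_gmt(cfg.gmt))
        enriched_sets = {}
        for mod in (HEMORHEOLOGY, COAGULOPATHY):
            res = enrichment.enrich(
                getattr(assignment, mod), collection,
                mode=cfg.enrichment_mode, alpha=cfg.alpha,
            )
            res.to_csv(outdir / f"enrichment_{mod}.tsv", sep="\t", index=False)
            enriched_sets[mod] = set(res.loc[res["significant"], "category"])
            summary[f"enrichment_{mod}"] = {
                "n_tested": len(res),
                "n_significant": len(enriched_sets[mod]),
                "top_categories": res.head(cfg.top_k)[["category", "p", "q"]].to_dict("records"),
            }

        stage = "overlap"
        ov_compounds = network.overlap(
            set(nets[HEMORHEOLOGY].nodes_of_type(network.NODE_COMPOUND)),
            set(nets[COAGULOPATHY].nodes_of_type(network.NODE_COMPOUND)),
        )
        ov_targets = network.overlap(assignment.hemorheology, assignment.coagulopathy)
        ov_pathways = network.overlap(enriched_sets[HEMORHEOLOGY], enriched_sets[COAGULOPATHY])
        summary["overlap"] = {
            kind: {
                "size_a": ov.size_a, "size_b": ov.size_b,
                "size_union": ov.size_union, "size_intersection": ov.size_intersection,
            }
            for kind, ov in (
                ("compounds", ov_compounds), ("targets", ov_targets), ("pathways", ov_pathways),
            )
        }

        stage = "herb_contribution"
        contrib = network.herb_contribution(
            nets[HEMORHEOLOGY], nets[COAGULOPATHY], herb_by_compound
        )
        contrib.to_csv(outdir / "herb_contribution.tsv", sep="\t", index=False)

        if cfg.cohort:
            stage = "chemometrics"
            cohort = io.read_cohort(cfg.cohort)
            x = cohort.drop(columns="group")
            groups = cohort["group"].to_numpy()
            model = chemometrics.plsda(
                x, groups, n_components=cfg.n_components, cv_folds=cfg.cv_folds
            )
            chem = {
                "r2x": model.r2x, "r2y": model.r2y, "q2": model.q2,
                "classes": list(model.classes),
            }
            if "control" in model.classes:
                dist = chemometrics.group_distance_ranking(model.T, groups, "control")
                chem["distance_to_control"] = dist.to_dict("records")
            if {"control", "model"} <= set(model.classes):
                sub = cohort[cohort["group"].isin(["control", "model"])]
                m2 = chemometrics.plsda(
                    sub.drop(columns="group"), sub["group"].to_numpy(),
                    n_components=cfg.n_components, cv_folds=cfg.cv_folds,
                )
                vips = chemometrics.vip(m2)
                vips.to_frame().to_csv(outdir / "vip_control_vs_model.tsv", sep="\t")
                chem["vip_control_vs_model"] = vips.to_dict()
                perm = chemometrics.permutation_validate(
                    sub.drop(columns="group"), sub["group"].to_numpy(),
                    n_components=cfg.n_components, n_perm=cfg.n_perm,
                    seed=cfg.seed, cv_folds=cfg.cv_folds,
                )
                chem["permutation"] = {
                    "r2_intercept": perm.r2_intercept,
                    "q2_intercept": perm.q2_intercept,
                    "valid": perm.valid,
                }
            summary["chemometrics"] = chem

        stage = "report"
        io.write_json_report(summary, outdir / "summary.json")
        manifest = {
            "seed": cfg.seed,
            "netpharm_version": __version__,
            "config": dataclasses.asdict(cfg),
            "input_sha256": {
                name: io.file_sha256(p)
                for name, p in (
                    ("compounds", cfg.compounds), ("predictions", cfg.predictions),
                    ("module_annotations", cfg.module_annotations), ("gmt", cfg.gmt),
                    ("cohort", cfg.cohort),
                )
                if p
            },
        }
        io.write_json_report(manifest, outdir / "manifest.json")
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return summary
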