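"""End-to-end orchestration with a single config, run manifest and logging.

Stages communicate only through files written under the output directory;
the manifest records the effective configuration, seeds, row counts and
sha256 checksums of every written file, which suffices to reproduce the run.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from pathlib import Path

import yaml

from . import cnv as cnv_mod
from . import diffstats, enrichment, network, preprocess, signature, summarize, tables_io

logger = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict = {
    "inputs": {
        "evidence": None,
        "spikeins": None,
        "classes": None,  # JSON: sample -> class
        "gmt": None,
        "mouse_edges": None,
        "human_edges": None,
        "ks_edges": None,
        "orthologues": None,
        "kinase_classes": None,
        "probes": None,
    },
    "preprocess": {
        "min_loc_prob": 0.75,
        "presence_fraction": 0.75,
        "k": 10,
        "fallback": "row_min",
        "aggregate": "sum",
    },
    "diff": {
        "q_threshold": 0.05,
        "require_omnibus": True,
    },
    "signature": {
        "threshold": 1.2,
        "n_trees": 2000,
        "seed": 0,
        "importance_scale": "raw",
    },
    "enrichment": {
        "background": "detected",  # or "gmt_union"
    },
    "cnv": {
        "alpha": 0.01,
        "n_permutations": 1000,
        "min_width": 2,
        "trim_sd": 3.0,
        "smooth_window": 5,
        "merge_delta": 0.2,
        "deletion_threshold": -0.5,
        "amplification_threshold": 0.5,
        "high_amplification_threshold": 1.5,
        "seed": 0,
    },
    "summarize": {
        "top_variable_k": 150,
        "variability_method": "variance",
    },
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return resolve_config(user)


def resolve_config(user: dict) -> dict:
    """Merge user config over defaults; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, over: dict, trail: str) -> None:
        for key, value in over.items():
            if key not in base:
                raise ConfigValidationError(f"unknown config key: {trail}{key}")
            if isinstance(base[key], dict) and isinstance(value, dict):
                merge(base[key], value, f"{trail}{key}.")
            else:
                base[key] = value

    if not isinstance(user, dict):
        raise ConfigValidationError("config root must be a mapping")
    merge(cfg, user, "")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: dict, out_dir: str | Path) -> Path:
    """Execute every configured stage; returns the run directory.

    Re-running with the same config and inputs reproduces all outputs
    bit-identically (stochastic stages are governed by the configured seeds).
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}, "files": {}}
    inputs = cfg["inputs"]

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage=%s %s", stage, counts)

    def finish(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    try:
        stage = "preprocess"
        records = tables_io.read_evidence(inputs["evidence"])
        amounts = tables_io.read_spikeins(inputs["spikeins"])
        class_of = tables_io.read_json(inputs["classes"])
        pp = cfg["preprocess"]
        full, imputed, factors = preprocess.preprocess_evidence(
            records, amounts, class_of,
            min_loc_prob=pp["min_loc_prob"],
            presence_fraction=pp["presence_fraction"],
            k=pp["k"], fallback=pp["fallback"], aggregate=pp["aggregate"],
        )
        full.write(out / "matrix_full.tsv", out / "matrix_full.json")
        imputed.write(out / "matrix_imputed.tsv", out / "matrix_imputed.json")
        tables_io.write_json(
            {"factors": factors.factors, "expected_amounts": factors.expected_amounts},
            out / "normalisation.json",
        )
        for name in ("matrix_full.tsv", "matrix_full.json", "matrix_imputed.tsv",
                     "matrix_imputed.json", "normalisation.json"):
            finish(out / name)
        record(stage, n_evidence=len(records), n_sites_full=len(full.sites),
               n_sites_reproducible=len(imputed.sites), n_samples=len(full.samples))

        stage = "diffstats"
        table = diffstats.fit_moderated_contrasts(imputed)
        calls = diffstats.call_class_specific(
            table,
            q_threshold=cfg["diff"]["q_threshold"],
            require_omnibus=cfg["diff"]["require_omnibus"],
        )
        diffstats.results_frame(table).to_csv(out / "contrasts.csv", index_label="site")
        tables_io.write_json(calls, out / "class_specific_calls.json")
        finish(out / "contrasts.csv")
        finish(out / "class_specific_calls.json")
        record(stage, **{f"n_{c}_specific": len(v) for c, v in calls.items()})

        stage = "signature"
        sig_cfg = cfg["signature"]
        model = signature.train_two_step(
            imputed,
            threshold=sig_cfg["threshold"],
            n_trees=sig_cfg["n_trees"],
            seed=sig_cfg["seed"],
            importance_scale=sig_cfg["importance_scale"],
        )
        model.save(out / "signature.json")
        finish(out / "signature.json")
        record(stage, n_selected=len(model.selected_sites),
               step1_oob_error=model.step1_oob_error,
               step2_oob_error=model.step2_oob_error)

        # foreground/background for enrichment and networks: genes of called sites
        gene_by_protein = {
            r.protein_id: r.gene_symbol for r in records if not r.is_spikein
        }
        background = sorted(
            {
                gene_by_protein.get(tables_io.parse_site_key(s)[0], "").upper()
                for s in full.sites
            }
            - {""}
        )
        called_sites = sorted({s for v in calls.values() for s in v})
        foreground = sorted(
            {
                gene_by_protein.get(tables_io.parse_site_key(s)[0], "").upper()
                for s in called_sites
            }
            - {""}
        )

        if inputs["gmt"]:
            stage = "enrichment"
            sets = tables_io.read_gmt(inputs["gmt"])
            if cfg["enrichment"]["background"] == "gmt_union":
                bg = sorted(set(background) | {g for s in sets for g in s.members})
            else:
                bg = background
            results = enrichment.hypergeom_enrich(foreground, bg, sets)
            enrichment.results_frame(results).to_csv(out / "enrichment.csv", index=False)
            finish(out / "enrichment.csv")
            record(stage, n_sets_tested=len(results), n_foreground=len(foreground))

        if inputs["mouse_edges"]:
            stage = "network"
            mouse_edges = tables_io.read_edges(inputs["mouse_edges"])
            human_edges = (
                tables_io.read_edges(inputs["human_edges"]) if inputs["human_edges"] else []
            )
            ks_edges = (
                tables_io.read_edges(inputs["ks_edges"]) if inputs["ks_edges"] else []
            )
            ortho = (
                tables_io.read_orthologues(inputs["orthologues"])
                if inputs["orthologues"] else None
            )
            net = network.build_network(
                foreground, mouse_edges, human_edges, ortho, ks_edges
            )
            network.write_edge_list(net, out / "network_edges.tsv")
            finish(out / "network_edges.tsv")
            tables_io.write_json(
                {"hubs": network.rank_hubs(net, top_n=20)}, out / "network_hubs.json"
            )
            finish(out / "network_hubs.json")
            record(stage, n_nodes=net.graph.number_of_nodes(),
                   n_edges=net.graph.number_of_edges())

        stage = "summarize"
        clustering = summarize.hcluster(imputed)
        tables_io.write_json(
            {
                "row_order": clustering.row_order,
                "col_order": clustering.col_order,
                "row_linkage": clustering.row_linkage.tolist(),
                "col_linkage": clustering.col_linkage.tolist(),
            },
            out / "clustering.json",
        )
        finish(out / "clustering.json")
        per_class_sets = {
            cls: {
                s for s in full.sites
                if full.observed.loc[s, full.samples_of(cls)].any()
            }
            for cls in full.classes()
        }
        ov = summarize.overlap_counts(per_class_sets)
        tables_io.write_json(
            {
                "names": list(ov.names),
                "regions": {"".join("ABC"[i] for i, f in enumerate(k) if f): v
                            for k, v in ov.regions.items()},
            },
            out / "overlap_counts.json",
        )
        finish(out / "overlap_counts.json")
        record(stage, union=ov.union_size, common_all=ov.common_all())

        if inputs["probes"]:
            stage = "cnv"
            probes = tables_io.read_probes(inputs["probes"])
            params = cnv_mod.CnvParams(**{
                k: v for k, v in cfg["cnv"].items()
            })
            segs, level_means = cnv_mod.call_copy_number(probes, params=params)
            tables_io.write_segments(segs, out / "segments.tsv")
            finish(out / "segments.tsv")
            tables_io.write_json({"level_means": level_means}, out / "cnv_levels.json")
            finish(out / "cnv_levels.json")
            record(stage, n_segments=len(segs), n_levels=len(level_means))

    except (ConfigValidationError,):
        raise
    except Exception as exc:  # annotate with the failing stage, keep partial outputs
        tables_io.write_json(manifest, out / "manifest.json")
        raise StageError(stage, exc) from exc

    tables_io.write_json(manifest, out / "manifest.json")
    return out


def write_default_config(path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)
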