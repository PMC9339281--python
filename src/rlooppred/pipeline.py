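"""End-to-end orchestration: consensus → features → ensemble → calls → enrichment.

One config drives a reproducible run.  Every filtering decision is counted
in the run manifest because the headline set sizes are all downstream of
silent filters (ID normalization, nonstandard-letter rejection,
complete-case dropping); the manifest reconciles parsed = kept + dropped.
Identical config + inputs + seed gives byte-identical prediction tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import consensus as cs
from . import ensemble as es
from . import features as ft
from . import stats

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def reconciles(self) -> bool:
        feats = self.stage_counts.get("featurize", {})
        if not feats:
            return False
        return feats["parsed"] == (feats["kept"] + feats["dropped_incomplete"]
                                   + feats["dropped_nonstandard"])

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config {path} is not a mapping")
    return config


def _resolve(base: Path, value: str) -> Path:
    path = Path(value)
    return path if path.is_absolute() else base / path


def _ensemble_config(section: dict, seed: int) -> es.EnsembleConfig:
    section = dict(section or {})
    preset = section.pop("preset", None)
    if "mtry_grid" in section:
        section["mtry_grid"] = tuple(section["mtry_grid"])
    section.setdefault("base_seed", seed)
    if preset:
        return es.EnsembleConfig.preset(preset, **section)
    return es.EnsembleConfig(**section)


def run_pipeline(config: dict | str | Path,
                 base_dir: str | Path | None = None) -> RunManifest:
    """Execute the full pipeline described by ``config``.

    Config keys: ``seed``; ``output_dir``; ``consensus`` (``lists``,
    ``rule``, optional ``k``, ``id_mode``); ``inputs`` (``proteome``,
    ``annotations`` mapping, ``nucleic_acid_list``, optional ``domains``);
    ``ensemble`` (EnsembleConfig fields or ``preset``); optional
    ``enrichment.background_size``.  Relative paths resolve against the
    config file's directory (or ``base_dir``).
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        base = config_path.parent if base_dir is None else Path(base_dir)
        config = load_config(config_path)
    else:
        base = Path(base_dir) if base_dir else Path.cwd()

    seed = int(config.get("seed", 0))
    outdir = _resolve(base, config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seeds={"base_seed": seed},
                           started=datetime.now(timezone.utc).isoformat())

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- consensus -------------------------------------------------------
    try:
        csec = config["consensus"]
        id_mode = csec.get("id_mode", "uppercase")
        list_paths = [_resolve(base, p) for p in csec["lists"]]
        for p in list_paths:
            if not p.exists():
                raise FileNotFoundError(f"hit list not found: {p}")
            manifest.input_digests[str(p)] = _digest(p)
        hit_lists = [cs.HitList.from_file(p, mode=id_mode) for p in list_paths]
        consensus = cs.intersect_consensus(
            hit_lists, rule=csec.get("rule", "any_pair"), k=csec.get("k"))
        consensus_path = outdir / "consensus.tsv"
        consensus.to_tsv(consensus_path)
        manifest.outputs["consensus"] = str(consensus_path)
        manifest.stage_counts["consensus"] = {
            "n_lists": len(hit_lists), "n_members": len(consensus)}
    except PipelineError:
        raise
    except Exception as exc:
        fail("consensus", exc)

    # --- featurize -------------------------------------------------------
    try:
        inputs = config["inputs"]
        proteome_path = _resolve(base, inputs["proteome"])
        if not proteome_path.exists():
            raise FileNotFoundError(f"proteome not found: {proteome_path}")
        manifest.input_digests[str(proteome_path)] = _digest(proteome_path)
        records = ft.read_fasta(proteome_path)
        n_parsed = len(records)
        n_nonstandard = sum(r.nonstandard for r in records)
        lengths = {r.id: r.length for r in records}
        ann_paths = {name: _resolve(base, p)
                     for name, p in inputs["annotations"].items()}
        for p in ann_paths.values():
            if not p.exists():
                raise FileNotFoundError(f"annotation table not found: {p}")
            manifest.input_digests[str(p)] = _digest(p)
        na_path = _resolve(base, inputs["nucleic_acid_list"])
        if not na_path.exists():
            raise FileNotFoundError(f"nucleic-acid list not found: {na_path}")
        manifest.input_digests[str(na_path)] = _digest(na_path)
        na_list = [ln for ln in na_path.read_text().splitlines() if ln.strip()]
        annotations = ft.ingest_annotations(
            ann_paths, na_list, lengths,
            phosphosite_encoding=inputs.get("phosphosite_encoding", "density"))
        table = ft.build_feature_table(records, annotations, consensus.members)
        features_path = outdir / "features.tsv"
        ft.write_feature_table(table, features_path)
        manifest.outputs["features"] = str(features_path)
        manifest.stage_counts["featurize"] = {
            "parsed": n_parsed,
            "dropped_nonstandard": n_nonstandard,
            "dropped_incomplete": n_parsed - n_nonstandard - len(table),
            "kept": len(table),
            "n_positives": int(table["label"].sum()),
        }
    except PipelineError:
        raise
    except Exception as exc:
        fail("featurize", exc)

    # --- train -----------------------------------------------------------
    try:
        ens_config = _ensemble_config(config.get("ensemble", {}), seed)
        manifest.seeds["model_seeds_first_last"] = [
            ens_config.base_seed,
            ens_config.base_seed + ens_config.n_models - 1]
        ensemble = es.train_ensemble(table, consensus.members, ens_config)
        ensemble.save(outdir)
        metrics_path = outdir / "model_metrics.tsv"
        summary_path = outdir / "metrics_summary.tsv"
        ensemble.summary().to_csv(summary_path, sep="\t",
                                  float_format="%.10g")
        manifest.outputs["model_metrics"] = str(metrics_path)
        manifest.outputs["metrics_summary"] = str(summary_path)
        manifest.stage_counts["train"] = {"n_models": ens_config.n_models}
    except PipelineError:
        raise
    except Exception as exc:
        fail("train", exc)

    # --- predict ---------------------------------------------------------
    try:
        predictions = es.predict_proteome(ensemble, table)
        pred_path = outdir / "predictions.tsv"
        predictions.to_tsv(pred_path)
        manifest.outputs["predictions"] = str(pred_path)
        manifest.stage_counts["predict"] = {
            "n_proteins": len(predictions.mean_probability),
            "n_candidate": int(predictions.candidate.sum()),
            "n_high_confidence": int(predictions.high_confidence.sum()),
        }
    except PipelineError:
        raise
    except Exception as exc:
        fail("predict", exc)

    # --- enrich ----------------------------------------------------------
    try:
        background = int(config.get("enrichment", {}).get(
            "background_size", len(table)))
        screens = {hl.study_name: hl.members for hl in hit_lists}
        enrich = es.compare_to_screens(predictions, screens, background)
        enrich_path = outdir / "screen_enrichment.tsv"
        enrich.to_csv(enrich_path, sep="\t", float_format="%.6g")
        manifest.outputs["screen_enrichment"] = str(enrich_path)
        if "domains" in inputs:
            dom_path = _resolve(base, inputs["domains"])
            manifest.input_digests[str(dom_path)] = _digest(dom_path)
            hits = ft.read_domain_hits(dom_path)
            counts = ft.filter_domain_hits(hits, lengths)
            all_counts = counts["n_domains"].reindex(
                [r.id for r in records]).fillna(0).astype(int)
            in_set = all_counts[all_counts.index.isin(consensus.members)]
            in_bg = all_counts[~all_counts.index.isin(consensus.members)]
            dom_rows = []
            for bin_label, res in stats.domain_count_classes(
                    in_set, in_bg, correction="bonferroni").items():
                dom_rows.append({
                    "bin": bin_label,
                    "set_proportion": res["set_proportion"],
                    "background_proportion": res["background_proportion"],
                    "p_value": res["fisher"].p_value,
                    "adjusted_p": res["fisher"].adjusted_p,
                })
            dom_out = outdir / "domain_enrichment.tsv"
            pd.DataFrame(dom_rows).to_csv(dom_out, sep="\t", index=False,
                                          float_format="%.6g")
            manifest.outputs["domain_enrichment"] = str(dom_out)
    except PipelineError:
        raise
    except Exception as exc:
        fail("enrich", exc)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest_path = outdir / "manifest.json"
    manifest.save(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    if not manifest.reconciles():
        raise PipelineError("stage 'manifest' failed: row counts do not reconcile")
    return manifest


def intersect_model_outputs(pred_a: es.PredictionResult | str | Path,
                            pred_b: es.PredictionResult | str | Path) -> dict[str, Any]:
    """Intersect the high-confidence call sets of two prediction runs.

    Mirrors combining the IP-MS-trained and Prox-MS-trained model outputs
    into one final candidate set.  Returns the overlap ids plus a-only and
    b-only counts.
    """
    if not isinstance(pred_a, es.PredictionResult):
        pred_a = es.PredictionResult.from_tsv(pred_a)
    if not isinstance(pred_b, es.PredictionResult):
        pred_b = es.PredictionResult.from_tsv(pred_b)
    a = pred_a.high_confidence_ids
    b = pred_b.high_confidence_ids
    return {"overlap": sorted(a & b), "n_overlap": len(a & b),
            "n_a_only": len(a - b), "n_b_only": len(b - a)}
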