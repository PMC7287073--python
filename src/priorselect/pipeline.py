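"""End-to-end orchestration: simulate -> score signatures -> model -> report.

A single YAML config drives the whole experiment.  Results are written as
TSV tables plus a JSON manifest recording the config hash, the seed, the
package version and a checksum per output file, so a finished run can be
verified and an interrupted one resumed (completed stages whose checksums
still match are skipped).

Config schema (all blocks optional unless noted)::

    seed: 0
    data:                    # required: exactly one of the two keys
      synthetic: {...}       # SyntheticConfig fields
      directory: path/to/bundle
    signatures:
      threshold: 0.1
      scope: global          # global | train_only
    strategies: [OT, PG, OT+S, PG+S, GW, GW_SEL_EN, GW_SEL_RF]
    model_families: [en, rf] # families for the non-SEL strategies
    protocol: {...}          # ExperimentProtocol fields
    evaluation:
      exclusion_epsilon: 0.01
      top_drugs: 50
      k_values: [1, 5, 10]
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .datatypes import GeneSetCollection
from .evaluation import (
    aggregate_records,
    best_model_per_drug,
    evaluate_fit,
    exclude_drugs,
    feature_type_frequencies,
    pathway_comparison,
    records_frame,
)
from .features import BIO_STRATEGIES, STRATEGIES, IneligibleDrug
from .modeling import ExperimentProtocol, run_drug
from .signatures import score_signatures
from .synthetic import SyntheticBundle, SyntheticConfig, generate, read_bundle

logger = logging.getLogger(__name__)

__all__ = ["run_all", "validate_config", "load_config"]

DEFAULT_STRATEGIES = ["OT", "PG", "OT+S", "PG+S", "GW", "GW_SEL_EN", "GW_SEL_RF"]

RESULT_FILES = [
    "records.tsv",
    "records_aggregated.tsv",
    "best_models.tsv",
    "excluded_drugs.tsv",
    "pathway_tests.tsv",
    "feature_type_frequencies.tsv",
    "feature_effects.tsv",
]


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(source) -> list[str]:
    """Schema and cross-reference checks; returns a list of findings.

    Findings are prefixed ``error:`` or ``warning:``; an empty list means the
    config is clean.
    """
    findings: list[str] = []
    try:
        cfg = load_config(source)
    except Exception as exc:
        return [f"error: config does not parse: {exc}"]

    data = cfg.get("data")
    if not isinstance(data, dict) or not ({"synthetic", "directory"} & set(data)):
        findings.append("error: config requires a 'data' block with 'synthetic' or 'directory'")
        data = {}
    if "synthetic" in data:
        try:
            SyntheticConfig.from_dict(data["synthetic"]).validate()
        except (TypeError, ValueError) as exc:
            findings.append(f"error: invalid synthetic config: {exc}")
    if "directory" in data:
        base = Path(data["directory"])
        for name in ("expression.tsv", "responses.tsv", "drug_annotations.tsv"):
            if not (base / name).exists():
                findings.append(f"error: data directory is missing {name}")
        strategies = cfg.get("strategies", DEFAULT_STRATEGIES)
        needs_omics = any(s in BIO_STRATEGIES for s in strategies)
        for name in ("mutation.tsv", "cnv.tsv", "segment_genes.tsv", "tissue.tsv"):
            if needs_omics and not (base / name).exists():
                findings.append(
                    f"error: strategy requiring all modalities requested but {name} is absent"
                )

    for s in cfg.get("strategies", DEFAULT_STRATEGIES):
        if s not in STRATEGIES:
            findings.append(f"error: unknown strategy {s!r}; valid: {sorted(STRATEGIES)}")
    for fam in cfg.get("model_families", ["en", "rf"]):
        if fam not in ("en", "rf"):
            findings.append(f"error: unknown model family {fam!r}")
    if "protocol" in cfg:
        try:
            proto = ExperimentProtocol(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in cfg["protocol"].items()
            })
            if proto.test_fraction != 0.3 or proto.cv_folds != 3 or proto.n_repetitions != 5:
                findings.append(
                    "warning: protocol deviates from the default 0.3 test fraction / "
                    "3 folds / 5 repetitions"
                )
        except (TypeError, ValueError) as exc:
            findings.append(f"error: invalid protocol: {exc}")
    sig = cfg.get("signatures", {})
    if sig.get("scope", "global") not in ("global", "train_only"):
        findings.append("error: signatures.scope must be 'global' or 'train_only'")
    return findings


def _load_data(cfg: dict, seed: int) -> SyntheticBundle:
    data = cfg["data"]
    if "synthetic" in data:
        syn = dict(data["synthetic"])
        syn.setdefault("seed", seed)
        return generate(SyntheticConfig.from_dict(syn))
    return read_bundle(data["directory"])


def _run_one(drug, strategy, family, bundle, protocol, sig_scores):
    fits = run_drug(
        drug, strategy, bundle.dataset, bundle.responses, protocol,
        model_family=family, pathways=bundle.pathways, signature_scores=sig_scores,
    )
    return drug.drug_id, strategy, family, fits


def run_all(
    config,
    out_dir: str | Path,
    seed: int | None = None,
    resume: bool = False,
    n_jobs: int = 1,
) -> dict:
    """Execute every stage for every drug x strategy x family; returns the manifest."""
    cfg = load_config(config)
    findings = validate_config(cfg)
    errors = [f for f in findings if f.startswith("error:")]
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    cfg_hash = _config_hash(cfg)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash and all(
            (out / f).exists() and _checksum(out / f) == old["files"].get(f)
            for f in RESULT_FILES
        ):
            logger.info("resume: all outputs verified, skipping recompute")
            return old

    t0 = time.time()
    bundle = _load_data(cfg, cfg["seed"])
    if cfg.get("drug_subset"):
        wanted = set(cfg["drug_subset"])
        bundle.drugs = [d for d in bundle.drugs if d.drug_id in wanted]
    logger.info("data stage: %d cell lines, %d genes, %d drugs",
                len(bundle.dataset.cell_lines), bundle.dataset.expression.shape[1],
                len(bundle.drugs))

    sig_cfg = cfg.get("signatures", {})
    sig_scores = score_signatures(
        bundle.dataset.expression,
        bundle.signatures,
        threshold=sig_cfg.get("threshold", 0.1),
        scope=sig_cfg.get("scope", "global"),
    )
    logger.info("signature stage: %d/%d signatures retained",
                len(sig_scores.retained), len(bundle.signatures))

    proto_kwargs = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in cfg.get("protocol", {}).items()
    }
    proto_kwargs["seed"] = cfg["seed"]
    protocol = ExperimentProtocol(**proto_kwargs)
    strategies = cfg.get("strategies", DEFAULT_STRATEGIES)
    families = cfg.get("model_families", ["en", "rf"])

    jobs = []
    for drug in bundle.drugs:
        for strategy in strategies:
            fams = ["en"] if strategy == "GW_SEL_EN" else ["rf"] if strategy == "GW_SEL_RF" else families
            for family in fams:
                jobs.append((drug, strategy, family))
    outputs = Parallel(n_jobs=n_jobs)(
        delayed(_run_one)(drug, strategy, family, bundle, protocol, sig_scores)
        for drug, strategy, family in jobs
    )

    rows, effect_rows, model_effects = [], [], []
    skipped = []
    for drug_id, strategy, family, fits in outputs:
        if isinstance(fits, IneligibleDrug):
            skipped.append({"drug_id": drug_id, "strategy": strategy, "reason": fits.reason})
            logger.info("skipped %s / %s: %s", drug_id, strategy, fits.reason)
            continue
        y = bundle.responses.for_drug(drug_id)
        mean_effects = None
        types = None
        for rep, fit in enumerate(fits):
            rows.append(evaluate_fit(fit, y, drug_id, strategy, rep))
            if mean_effects is None:
                mean_effects = fit.feature_effects.astype(float).copy()
            else:
                mean_effects = mean_effects.add(fit.feature_effects, fill_value=0.0)
        mean_effects /= len(fits)
        drug_obj = next(d for d in bundle.drugs if d.drug_id == drug_id)
        if strategy in BIO_STRATEGIES:
            from .features import build_strategy  # metadata for the same columns
            matrix = build_strategy(
                strategy, drug_obj, bundle.dataset,
                pathways=bundle.pathways, signature_scores=sig_scores, response=y,
            )
            types = matrix.feature_meta["type"].reindex(mean_effects.index)
            model_effects.append(
                {
                    "drug_id": drug_id, "strategy": strategy, "model_family": family,
                    "effects": mean_effects, "types": types,
                }
            )
            for col, eff in mean_effects.items():
                effect_rows.append(
                    {
                        "drug_id": drug_id, "strategy": strategy, "model_family": family,
                        "feature": col, "type": types.loc[col], "mean_effect": eff,
                    }
                )

    records = records_frame(rows)
    aggregated = aggregate_records(records)
    eval_cfg = cfg.get("evaluation", {})
    excluded = exclude_drugs(aggregated, epsilon=eval_cfg.get("exclusion_epsilon", 0.01))
    retained = aggregated[~aggregated["drug_id"].isin(excluded)]
    best = best_model_per_drug(retained) if len(retained) else pd.DataFrame(
        columns=["drug_id", "strategy", "model_family", "pearson_r", "rel_rmse", "n_features"]
    )
    pathway_tests = pathway_comparison(aggregated, bundle.drugs, excluded=excluded)
    freq = feature_type_frequencies(
        model_effects,
        aggregated,
        top_drugs=eval_cfg.get("top_drugs", 50),
        k_values=tuple(eval_cfg.get("k_values", [1, 5, 10])),
    )

    records.to_csv(out / "records.tsv", sep="\t", index=False)
    aggregated.to_csv(out / "records_aggregated.tsv", sep="\t", index=False)
    best.to_csv(out / "best_models.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(excluded), columns=["drug_id"]).to_csv(
        out / "excluded_drugs.tsv", sep="\t", index=False
    )
    pathway_tests.to_csv(out / "pathway_tests.tsv", sep="\t", index=False)
    freq.to_csv(out / "feature_type_frequencies.tsv", sep="\t")
    pd.DataFrame(
        effect_rows,
        columns=["drug_id", "strategy", "model_family", "feature", "type", "mean_effect"],
    ).to_csv(out / "feature_effects.tsv", sep="\t", index=False)

    manifest = {
        "config": cfg,
        "config_hash": cfg_hash,
        "seed": cfg["seed"],
        "version": __version__,
        "n_models": int(len(aggregated)),
        "n_excluded_drugs": int(len(excluded)),
        "skipped": skipped,
        "files": {f: _checksum(out / f) for f in RESULT_FILES},
        "elapsed_seconds": round(time.time() - t0, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
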