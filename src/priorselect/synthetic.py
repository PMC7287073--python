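"""Synthetic multi-omic drug-screen generator with planted response mechanisms.

Emulates the structure of a large cancer cell-line screen -- continuous
log-scale expression, binary mutation calls on a gene subset, binary
copy-number calls on contiguous genomic segments, tissue labels, per-drug
target annotations drawn from planted pathways, and AUC dose-response values
in [0, 1] -- at a configurable reduced scale, so every downstream stage can
be tested against a known ground truth.

Each drug is assigned one of four mechanisms:

``target_expression``
    AUC decreases with the (standardized) expression of one annotated target
    gene; lower AUC = stronger efficacy, so over-expressing lines respond.
``target_mutation``
    mutated lines respond: AUC drops by the effect size in carriers.
``polygenic``
    a broad signal spread over many expression features with small weights.
``null``
    AUC is baseline plus noise; no feature carries signal.

Responses follow ``AUC = clip(base - sum_j w_j * driver_j + eps, 0, 1)`` with
standardized drivers and Gaussian noise.  In the ``narrow`` regime the
expression driver acts only in a small outlier subpopulation (mimicking a
receptor over-expressed in a handful of lines), producing the
narrow-with-outliers response distributions seen for many targeted agents.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DrugAnnotation,
    GeneSetCollection,
    OmicsDataset,
    ResponseTable,
)
from . import io as psio

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticBundle", "generate", "write_dataset", "read_bundle"]

MECHANISMS = ("target_expression", "target_mutation", "polygenic", "null")


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are a ~1/10-scale screen.

    The full-scale study exposes ~17,737 expression features, 310 mutation
    genes, 425 CNV segments, 13 tissues and ~250 drugs across 24 target
    pathways; defaults here keep the same shape at a tractable size.
    """

    n_cell_lines: int = 500
    n_genes: int = 2000
    n_mutation_genes: int = 150
    n_cnv_segments: int = 60
    segment_size: int = 5
    n_pathways: int = 24
    pathway_size_range: tuple[int, int] = (10, 50)
    n_signatures: int = 20
    signature_size_range: tuple[int, int] = (5, 15)
    signature_rho: float = 0.5
    n_tissues: int = 13
    n_drugs: int = 20
    mechanism_mix: dict[str, float] = field(
        default_factory=lambda: {
            "target_expression": 0.3,
            "target_mutation": 0.2,
            "polygenic": 0.2,
            "null": 0.3,
        }
    )
    effect_size: float = 0.3
    noise_sd: float = 0.05
    regime: str = "wide"  # wide | narrow
    outlier_fraction: float = 0.1
    polygenic_n_drivers: int = 20
    missing_mutation_rate: float = 0.1
    missing_cnv_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not math.isclose(sum(self.mechanism_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("mechanism_mix proportions must sum to 1")
        unknown = set(self.mechanism_mix) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms {sorted(unknown)}")
        for name in (
            "n_cell_lines", "n_genes", "n_mutation_genes", "n_cnv_segments",
            "segment_size", "n_pathways", "n_signatures", "n_tissues", "n_drugs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.regime not in ("wide", "narrow"):
            raise ValueError("regime must be 'wide' or 'narrow'")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway sizes exceed n_genes")
        if self.signature_size_range[1] > self.n_genes:
            raise ValueError("signature sizes exceed n_genes")
        if not 0 <= self.signature_rho <= 1:
            raise ValueError("signature_rho must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_size_range"] = list(self.pathway_size_range)
        d["signature_size_range"] = list(self.signature_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("pathway_size_range", "signature_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted mechanism per drug: driver features and their true weights.

    ``drivers[drug]`` is a list of ``(feature_type, source_gene, weight)``
    triples; null drugs have an empty list.
    """

    mechanism: dict[str, str]
    drivers: dict[str, list[tuple[str, str, float]]]
    base_auc: dict[str, float]

    def driver_features(self, drug_id: str) -> list[tuple[str, str]]:
        return [(t, s) for t, s, _ in self.drivers[drug_id]]

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "drivers": {d: [list(t) for t in v] for d, v in self.drivers.items()},
            "base_auc": self.base_auc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            mechanism=dict(d["mechanism"]),
            drivers={k: [tuple(t) for t in v] for k, v in d["drivers"].items()},
            base_auc={k: float(v) for k, v in d["base_auc"].items()},
        )


@dataclass
class SyntheticBundle:
    dataset: OmicsDataset
    pathways: GeneSetCollection
    signatures: GeneSetCollection
    drugs: list[DrugAnnotation]
    responses: ResponseTable
    truth: GroundTruth
    config: SyntheticConfig


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a full synthetic screen; deterministic given ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("expression", "mutation", "cnv", "tissue", "sets", "drugs", "response", "mask"),
            root.spawn(8),
        )
    }

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    n, p = config.n_cell_lines, config.n_genes

    # --- gene sets -------------------------------------------------------
    rng = streams["sets"]
    lo, hi = config.pathway_size_range
    pathway_sets = {
        f"PW{i:03d}": sorted(rng.choice(p, size=int(rng.integers(lo, hi + 1)), replace=False))
        for i in range(config.n_pathways)
    }
    pathways = GeneSetCollection(
        sets={name: [genes[j] for j in idx] for name, idx in pathway_sets.items()},
        kind="pathway",
    )
    # signatures are disjoint so each planted co-expression block is clean
    lo, hi = config.signature_size_range
    pool = list(range(p))
    signature_sets = {}
    for i in range(config.n_signatures):
        size = int(rng.integers(lo, hi + 1))
        if size > len(pool):
            raise ValueError("signature sizes exhaust the gene pool; reduce n_signatures")
        picked = rng.choice(len(pool), size=size, replace=False)
        signature_sets[f"SIG{i:03d}"] = sorted(pool[j] for j in picked)
        pool = [g for j, g in enumerate(pool) if j not in set(picked)]
    signatures = GeneSetCollection(
        sets={name: [genes[j] for j in idx] for name, idx in signature_sets.items()},
        kind="signature",
    )

    # --- expression: block-correlated within signatures ------------------
    rng = streams["expression"]
    base_mean = rng.uniform(3.0, 11.0, size=p)
    expr = rng.standard_normal((n, p))
    rho = config.signature_rho
    for name, idx in signature_sets.items():
        factor = rng.standard_normal(n)
        expr[:, idx] = (
            math.sqrt(rho) * factor[:, None]
            + math.sqrt(1.0 - rho) * rng.standard_normal((n, len(idx)))
        )
    expression = pd.DataFrame(expr + base_mean, index=lines, columns=genes)
    expression.index.name = "cell_line"

    # --- drugs: mechanism, pathway, targets ------------------------------
    rng = streams["drugs"]
    mech_names = list(config.mechanism_mix)
    mech_probs = np.array([config.mechanism_mix[m] for m in mech_names])
    # deterministic counts: largest-remainder apportionment of the mix
    raw = mech_probs * config.n_drugs
    counts = np.floor(raw).astype(int)
    remainder = config.n_drugs - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    mechanisms = [m for m, c in zip(mech_names, counts) for _ in range(c)]
    rng.shuffle(mechanisms)

    pathway_names = list(pathway_sets)
    drug_ids = [f"D{i:03d}" for i in range(config.n_drugs)]
    drug_pathway = {d: pathway_names[rng.integers(len(pathway_names))] for d in drug_ids}
    drug_targets: dict[str, list[str]] = {}
    for d in drug_ids:
        members = pathways.members(drug_pathway[d])
        k = int(rng.integers(1, min(3, len(members)) + 1))
        drug_targets[d] = sorted(rng.choice(members, size=k, replace=False))

    # --- mutations: panel covers all drug targets plus random genes -------
    rng = streams["mutation"]
    target_pool = sorted({g for t in drug_targets.values() for g in t})
    extra_needed = max(config.n_mutation_genes - len(target_pool), 0)
    non_targets = [g for g in genes if g not in set(target_pool)]
    extra = sorted(
        rng.choice(non_targets, size=min(extra_needed, len(non_targets)), replace=False)
    )
    mutation_genes = sorted(set(target_pool) | set(extra))
    prevalence = rng.uniform(0.01, 0.2, size=len(mutation_genes))
    mut = (rng.random((n, len(mutation_genes))) < prevalence).astype(np.int8)
    mutation = pd.DataFrame(mut, index=lines, columns=mutation_genes)
    mutation.index.name = "cell_line"

    # --- CNV: contiguous gene blocks --------------------------------------
    rng = streams["cnv"]
    seg_names = [f"SEG{i:03d}" for i in range(config.n_cnv_segments)]
    max_start = max(p - config.segment_size, 1)
    starts = sorted(rng.choice(max_start, size=config.n_cnv_segments, replace=False))
    segment_genes = {
        name: frozenset(genes[s : s + config.segment_size])
        for name, s in zip(seg_names, starts)
    }
    seg_prev = rng.uniform(0.01, 0.2, size=config.n_cnv_segments)
    cnv = pd.DataFrame(
        (rng.random((n, config.n_cnv_segments)) < seg_prev).astype(np.int8),
        index=lines,
        columns=seg_names,
    )
    cnv.index.name = "cell_line"

    # --- tissue ------------------------------------------------------------
    rng = streams["tissue"]
    tissue_levels = [f"tissue_{i:02d}" for i in range(config.n_tissues)]
    weights = rng.dirichlet(np.full(config.n_tissues, 5.0))
    tissue = pd.Series(
        rng.choice(tissue_levels, size=n, p=weights), index=lines, name="tissue"
    )
    tissue.index.name = "cell_line"

    # --- availability masks -------------------------------------------------
    rng = streams["mask"]
    availability = pd.DataFrame(True, index=lines, columns=["expression", "mutation", "cnv"])
    availability["mutation"] = rng.random(n) >= config.missing_mutation_rate
    availability["cnv"] = rng.random(n) >= config.missing_cnv_rate
    mutation.loc[~availability["mutation"], :] = 0
    cnv.loc[~availability["cnv"], :] = 0

    # --- responses -----------------------------------------------------------
    rng = streams["response"]
    mechanism: dict[str, str] = {}
    drivers: dict[str, list[tuple[str, str, float]]] = {}
    base_auc: dict[str, float] = {}
    records = []
    expr_values = expression  # includes base_mean
    for d, mech in zip(drug_ids, mechanisms):
        mechanism[d] = mech
        base = float(rng.uniform(0.55, 0.9))
        base_auc[d] = base
        signal = np.zeros(n)
        drug_drivers: list[tuple[str, str, float]] = []
        if mech == "target_expression":
            target = drug_targets[d][int(rng.integers(len(drug_targets[d])))]
            x = expr_values[target].to_numpy().copy()
            if config.regime == "narrow":
                # over-express the target in a small outlier subpopulation
                n_out = max(int(round(config.outlier_fraction * n)), 1)
                out_idx = rng.choice(n, size=n_out, replace=False)
                x[out_idx] += 6.0
                expression[target] = x
            w = config.effect_size
            signal = w * _standardize(x)
            drug_drivers.append(("expression", target, w))
        elif mech == "target_mutation":
            candidates = [g for g in drug_targets[d] if g in mutation.columns]
            target = candidates[int(rng.integers(len(candidates)))]
            calls = mutation[target].to_numpy().astype(float)
            if calls.std() == 0:  # ensure a usable carrier frequency
                flip = rng.choice(n, size=max(int(0.05 * n), 2), replace=False)
                calls[flip] = 1.0
                mutation[target] = calls.astype(np.int8)
            w = config.effect_size
            signal = w * _standardize(calls)
            drug_drivers.append(("mutation", target, w))
        elif mech == "polygenic":
            k = min(config.polygenic_n_drivers, p)
            idx = rng.choice(p, size=k, replace=False)
            w_each = config.effect_size / math.sqrt(k)
            for j in idx:
                g = genes[j]
                signal += w_each * _standardize(expr_values[g].to_numpy())
                drug_drivers.append(("expression", g, w_each))
        drivers[d] = drug_drivers
        eps = rng.normal(0.0, config.noise_sd, size=n)
        auc = np.clip(base - signal + eps, 0.0, 1.0)
        records.append(
            pd.DataFrame({"drug_id": d, "cell_line": lines, "auc": auc})
        )

    responses = ResponseTable(records=pd.concat(records, ignore_index=True))
    dataset = OmicsDataset(
        expression=expression,
        mutation=mutation,
        cnv=cnv,
        segment_genes=segment_genes,
        tissue=tissue,
        availability=availability,
    )
    annotations = [
        DrugAnnotation(
            drug_id=d,
            targets=frozenset(drug_targets[d]),
            target_pathway=drug_pathway[d],
        )
        for d in drug_ids
    ]
    truth = GroundTruth(mechanism=mechanism, drivers=drivers, base_auc=base_auc)
    return SyntheticBundle(
        dataset=dataset,
        pathways=pathways,
        signatures=signatures,
        drugs=annotations,
        responses=responses,
        truth=truth,
        config=config,
    )


def write_dataset(bundle: SyntheticBundle, out_dir: str | os.PathLike, overwrite: bool = False) -> dict:
    """Write every bundle component in the exchange formats plus a manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is non-empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)
    files = psio.write_dataset_tables(bundle.dataset, out)
    psio.write_gmt(bundle.pathways, out / "pathways.gmt")
    psio.write_gmt(bundle.signatures, out / "signatures.gmt")
    psio.write_drug_annotations(bundle.drugs, out / "drug_annotations.tsv")
    psio.write_response_table(bundle.responses, out / "responses.tsv")
    manifest = {
        "config": bundle.config.to_dict(),
        "seed": bundle.config.seed,
        "ground_truth": bundle.truth.to_dict(),
        "files": {
            **files,
            "pathways": "pathways.gmt",
            "signatures": "signatures.gmt",
            "drug_annotations": "drug_annotations.tsv",
            "responses": "responses.tsv",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_bundle(in_dir: str | os.PathLike) -> SyntheticBundle:
    """Load a written bundle back; inverse of :func:`write_dataset`."""
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    return SyntheticBundle(
        dataset=psio.read_dataset_tables(in_dir),
        pathways=psio.read_gmt(in_dir / "pathways.gmt", kind="pathway"),
        signatures=psio.read_gmt(in_dir / "signatures.gmt", kind="signature"),
        drugs=psio.read_drug_annotations(in_dir / "drug_annotations.tsv"),
        responses=psio.read_response_table(in_dir / "responses.tsv"),
        truth=GroundTruth.from_dict(manifest["ground_truth"]),
        config=SyntheticConfig.from_dict(manifest["config"]),
    )
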