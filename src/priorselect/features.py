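"""Per-drug feature-space construction.

Five feature-set strategies are supported, ordered from most to least
restricted:

* ``OT`` (only targets): expression, mutation and copy-number features of the
  drug's annotated target genes, plus a full one-hot encoding of tissue.
* ``PG`` (pathway genes): as OT, but over the union of the targets with all
  members of every pathway containing at least one target.
* ``OT+S`` / ``PG+S``: the above extended with retained signature-activity
  columns.
* ``GW`` (genome-wide): every expression feature, no tissue columns -- the
  unrestricted baseline.  The two data-driven strategies (``GW_SEL_EN``,
  ``GW_SEL_RF``) reuse the GW matrix; selection happens at modeling time.

A copy-number segment contributes a column when it covers at least one gene
of the strategy's gene universe.  Samples are restricted to cell lines that
have a response for the drug and every modality that actually contributes a
column; genome-wide matrices therefore typically keep more samples than the
biologically driven ones, whose mutation/CNV requirements drop masked lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DrugAnnotation, FeatureMatrix, GeneSetCollection, OmicsDataset
from .signatures import SignatureScores

__all__ = [
    "StrategySpec",
    "STRATEGIES",
    "IneligibleDrug",
    "build_ot",
    "build_pg",
    "build_gw",
    "add_signatures",
    "build_strategy",
]


@dataclass(frozen=True)
class StrategySpec:
    name: str
    uses_targets: bool
    uses_pathways: bool
    uses_signatures: bool
    modalities: frozenset[str]  # modalities the strategy may draw on


STRATEGIES: dict[str, StrategySpec] = {
    "OT": StrategySpec("OT", True, False, False, frozenset({"expression", "mutation", "cnv", "tissue"})),
    "PG": StrategySpec("PG", True, True, False, frozenset({"expression", "mutation", "cnv", "tissue"})),
    "OT+S": StrategySpec("OT+S", True, False, True, frozenset({"expression", "mutation", "cnv", "tissue"})),
    "PG+S": StrategySpec("PG+S", True, True, True, frozenset({"expression", "mutation", "cnv", "tissue"})),
    "GW": StrategySpec("GW", False, False, False, frozenset({"expression"})),
    "GW_SEL_EN": StrategySpec("GW_SEL_EN", False, False, False, frozenset({"expression"})),
    "GW_SEL_RF": StrategySpec("GW_SEL_RF", False, False, False, frozenset({"expression"})),
}

BIO_STRATEGIES = ("OT", "PG", "OT+S", "PG+S")
GW_STRATEGIES = ("GW", "GW_SEL_EN", "GW_SEL_RF")


@dataclass(frozen=True)
class IneligibleDrug:
    """Typed result for a drug that cannot form the requested feature space."""

    drug_id: str
    strategy: str
    reason: str


def _assemble(
    drug: DrugAnnotation,
    data: OmicsDataset,
    gene_universe: set[str],
    response: pd.Series | None,
    strategy: str,
) -> FeatureMatrix | IneligibleDrug:
    """Extract expression/mutation/CNV/tissue columns for a gene universe."""
    expr_genes = sorted(gene_universe & set(data.expression.columns))
    mut_genes = sorted(gene_universe & set(data.mutation.columns))
    segments = sorted(
        s for s, covered in data.segment_genes.items() if covered & gene_universe
    )
    if not (expr_genes or mut_genes or segments):
        return IneligibleDrug(
            drug.drug_id, strategy,
            "no feature beyond tissue type available for the drug's gene universe",
        )

    required = set()
    if expr_genes:
        required.add("expression")
    if mut_genes:
        required.add("mutation")
    if segments:
        required.add("cnv")
    samples = data.available_lines(required)
    if response is not None:
        samples = samples.intersection(response.dropna().index, sort=False)
    samples = pd.Index([s for s in data.cell_lines if s in set(samples)])

    blocks: list[pd.DataFrame] = []
    meta_rows: list[tuple[str, str, str]] = []  # (column, type, source)
    if expr_genes:
        block = data.expression.loc[samples, expr_genes]
        block.columns = [f"expr:{g}" for g in expr_genes]
        blocks.append(block)
        meta_rows += [(f"expr:{g}", "expression", g) for g in expr_genes]
    if mut_genes:
        block = data.mutation.loc[samples, mut_genes].astype(float)
        block.columns = [f"mut:{g}" for g in mut_genes]
        blocks.append(block)
        meta_rows += [(f"mut:{g}", "mutation", g) for g in mut_genes]
    if segments:
        block = data.cnv.loc[samples, segments].astype(float)
        block.columns = [f"cnv:{s}" for s in segments]
        blocks.append(block)
        meta_rows += [(f"cnv:{s}", "cnv", s) for s in segments]
    # full one-hot over the declared tissue vocabulary (no reference drop)
    levels = data.tissue_levels
    tissue = pd.DataFrame(
        {f"tissue:{lv}": (data.tissue.loc[samples] == lv).astype(float) for lv in levels},
        index=samples,
    )
    blocks.append(tissue)
    meta_rows += [(f"tissue:{lv}", "tissue", lv) for lv in levels]

    values = pd.concat(blocks, axis=1)
    meta = pd.DataFrame(
        [(t, s) for _, t, s in meta_rows],
        index=pd.Index([c for c, _, _ in meta_rows]),
        columns=["type", "source"],
    )
    return FeatureMatrix(values=values, feature_meta=meta)


def build_ot(
    drug: DrugAnnotation, data: OmicsDataset, response: pd.Series | None = None
) -> FeatureMatrix | IneligibleDrug:
    """Only-targets feature space: direct target genes plus tissue one-hots."""
    if not drug.targets:
        return IneligibleDrug(drug.drug_id, "OT", "drug has no annotated targets")
    return _assemble(drug, data, set(drug.targets), response, "OT")


def build_pg(
    drug: DrugAnnotation,
    data: OmicsDataset,
    pathways: GeneSetCollection,
    response: pd.Series | None = None,
) -> FeatureMatrix | IneligibleDrug:
    """Pathway-genes feature space: targets united with every pathway hit.

    The gene universe is the union of the drug's targets with all members of
    every pathway containing at least one target; targets stay in the
    universe even when no pathway contains them.
    """
    if not drug.targets:
        return IneligibleDrug(drug.drug_id, "PG", "drug has no annotated targets")
    hits = pathways.sets_containing(drug.targets)
    universe = set(drug.targets) | pathways.union(hits)
    return _assemble(drug, data, universe, response, "PG")


def build_gw(
    drug: DrugAnnotation, data: OmicsDataset, response: pd.Series | None = None
) -> FeatureMatrix:
    """Genome-wide feature space: all expression columns, expression-only samples."""
    samples = data.available_lines(["expression"])
    if response is not None:
        keep = set(response.dropna().index)
        samples = pd.Index([s for s in samples if s in keep])
    values = data.expression.loc[samples].copy()
    values.columns = [f"expr:{g}" for g in data.expression.columns]
    meta = pd.DataFrame(
        {"type": "expression", "source": list(data.expression.columns)},
        index=values.columns,
    )
    return FeatureMatrix(values=values, feature_meta=meta)


def add_signatures(base: FeatureMatrix, scores: SignatureScores) -> FeatureMatrix:
    """Append one activity column per retained signature to a base matrix."""
    missing = [s for s in base.sample_ids if s not in scores.activity.index]
    if missing:
        raise ValueError(f"no signature activity for sample {missing[0]!r}")
    if not scores.retained:
        return base
    clash = set(f"sig:{s}" for s in scores.retained) & set(base.values.columns)
    if clash:
        raise ValueError(f"signature column already present: {sorted(clash)[0]!r}")
    block = scores.activity.loc[base.sample_ids, scores.retained]
    block.columns = [f"sig:{s}" for s in scores.retained]
    values = pd.concat([base.values, block], axis=1)
    meta = pd.concat(
        [
            base.feature_meta,
            pd.DataFrame(
                {"type": "signature", "source": scores.retained},
                index=block.columns,
            ),
        ]
    )
    return FeatureMatrix(values=values, feature_meta=meta)


def build_strategy(
    name: str,
    drug: DrugAnnotation,
    data: OmicsDataset,
    pathways: GeneSetCollection | None = None,
    signature_scores: SignatureScores | None = None,
    response: pd.Series | None = None,
) -> FeatureMatrix | IneligibleDrug:
    """Dispatch a strategy name to its builder."""
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}; valid: {sorted(STRATEGIES)}")
    if name in ("GW", "GW_SEL_EN", "GW_SEL_RF"):
        return build_gw(drug, data, response)
    if name in ("PG", "PG+S"):
        if pathways is None:
            raise ValueError(f"strategy {name} requires a pathway collection")
        base = build_pg(drug, data, pathways, response)
    else:
        base = build_ot(drug, data, response)
    if isinstance(base, IneligibleDrug):
        return IneligibleDrug(base.drug_id, name, base.reason)
    if name.endswith("+S"):
        if signature_scores is None:
            raise ValueError(f"strategy {name} requires signature scores")
        base = add_signatures(base, signature_scores)
    return base
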