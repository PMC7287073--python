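"""Core in-memory containers for the drug-sensitivity pipeline.

The study setting is a panel of cancer cell lines characterized by four data
modalities -- continuous gene expression, binary coding-variant (mutation)
calls, binary copy-number-variant calls on genomic segments, and a tissue
label -- screened against a library of compounds whose efficacy is summarized
as the area under the dose-response curve (AUC, in [0, 1], lower = stronger
effect).  All containers are thin validated wrappers around pandas objects so
the rest of the pipeline can rely on label alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OmicsDataset",
    "GeneSetCollection",
    "DrugAnnotation",
    "ResponseTable",
    "FeatureMatrix",
    "FormatError",
]

MODALITIES = ("expression", "mutation", "cnv")

FEATURE_TYPES = ("expression", "mutation", "cnv", "tissue", "signature")


class FormatError(ValueError):
    """Raised when an input file or matrix violates its declared format."""


def _check_binary(df: pd.DataFrame, name: str) -> None:
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{name} matrix must be binary; found {values[i, j]!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )


@dataclass
class OmicsDataset:
    """Aligned multi-modal cell-line data with per-modality availability masks.

    All matrices are indexed by one shared, ordered cell-line universe (the
    index of ``expression``).  A cell line missing a modality keeps its row
    (zero-filled for binary modalities) but is flagged unavailable in
    ``availability``; downstream feature construction drops such samples
    rather than imputing them.

    Parameters
    ----------
    expression : DataFrame, cell lines x genes, continuous log-scale units.
    mutation : DataFrame, cell lines x genes, binary calls.
    cnv : DataFrame, cell lines x segments, binary calls.
    segment_genes : mapping of segment id to the set of gene ids it covers.
    tissue : Series mapping cell line to a tissue label from a finite
        vocabulary (13 sites in the motivating dataset).
    availability : DataFrame, cell lines x {expression, mutation, cnv},
        boolean; defaults to everything available.
    """

    expression: pd.DataFrame
    mutation: pd.DataFrame
    cnv: pd.DataFrame
    segment_genes: dict[str, frozenset[str]]
    tissue: pd.Series
    availability: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        lines = self.expression.index
        if self.availability is None:
            self.availability = pd.DataFrame(
                True, index=lines, columns=list(MODALITIES)
            )
        self.segment_genes = {s: frozenset(g) for s, g in self.segment_genes.items()}
        for name in ("mutation", "cnv", "availability"):
            df = getattr(self, name)
            if not df.index.equals(lines):
                raise ValueError(
                    f"{name} index must match the expression cell-line universe "
                    "in the same order"
                )
        if not self.tissue.index.equals(lines):
            raise ValueError("tissue index must match the cell-line universe")
        _check_binary(self.mutation, "mutation")
        _check_binary(self.cnv, "cnv")
        missing = set(self.cnv.columns) - set(self.segment_genes)
        if missing:
            raise ValueError(
                f"cnv segments without a segment_genes entry: {sorted(missing)[:5]}"
            )

    @property
    def cell_lines(self) -> pd.Index:
        return self.expression.index

    @property
    def tissue_levels(self) -> list[str]:
        return sorted(self.tissue.unique())

    def available_lines(self, modalities: Iterable[str]) -> pd.Index:
        """Cell lines for which every listed modality is present."""
        mask = np.ones(len(self.cell_lines), dtype=bool)
        for m in modalities:
            mask &= self.availability[m].to_numpy()
        return self.cell_lines[mask]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsDataset):
            return NotImplemented
        return (
            self.expression.equals(other.expression)
            and self.mutation.equals(other.mutation)
            and self.cnv.equals(other.cnv)
            and self.segment_genes == other.segment_genes
            and self.tissue.equals(other.tissue)
            and self.availability.equals(other.availability)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or expression signatures).

    ``sets`` maps a unique set name to an ordered, de-duplicated list of gene
    ids.  ``kind`` records whether the collection holds pathway membership or
    expression signatures; the distinction only matters for reporting.
    """

    sets: dict[str, list[str]]
    kind: str = "pathway"

    def __post_init__(self) -> None:
        if self.kind not in ("pathway", "signature"):
            raise ValueError(f"unknown collection kind {self.kind!r}")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return self.sets[name]

    def sets_containing(self, genes: Iterable[str]) -> list[str]:
        """Names of sets whose membership intersects ``genes``."""
        genes = set(genes)
        return [name for name, members in self.sets.items() if genes & set(members)]

    def union(self, names: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for n in names:
            out |= set(self.sets[n])
        return out


@dataclass(frozen=True)
class DrugAnnotation:
    """Per-drug target genes and the drug's target-pathway class.

    Targets are the union of the screening resource's own annotation and an
    optional secondary drug database; ``target_sources`` records which
    contributed.  ``targets`` may be empty, in which case the drug is only
    eligible for genome-wide strategies.
    """

    drug_id: str
    targets: frozenset[str]
    target_pathway: str
    target_sources: frozenset[str] = frozenset({"gdsc"})

    def __post_init__(self) -> None:
        if not self.target_pathway:
            raise ValueError(f"drug {self.drug_id!r} has an empty target pathway")
        unknown = self.target_sources - {"gdsc", "drugbank"}
        if unknown:
            raise ValueError(f"unknown target sources {sorted(unknown)}")


@dataclass
class ResponseTable:
    """Long-format drug response: one AUC record per (drug, cell line)."""

    records: pd.DataFrame  # columns: drug_id, cell_line, auc

    def __post_init__(self) -> None:
        required = ["drug_id", "cell_line", "auc"]
        if list(self.records.columns) != required:
            self.records = self.records[required]
        auc = self.records["auc"].to_numpy()
        if ((auc < 0) | (auc > 1)).any():
            bad = self.records[(self.records["auc"] < 0) | (self.records["auc"] > 1)]
            raise FormatError(
                f"AUC outside [0,1] for drug {bad.iloc[0]['drug_id']!r}, "
                f"cell line {bad.iloc[0]['cell_line']!r}"
            )
        if self.records.duplicated(["drug_id", "cell_line"]).any():
            raise FormatError("duplicate (drug, cell line) response records")

    def drugs(self) -> list[str]:
        return list(dict.fromkeys(self.records["drug_id"]))

    def for_drug(self, drug_id: str) -> pd.Series:
        """AUC indexed by cell line for one drug."""
        sub = self.records[self.records["drug_id"] == drug_id]
        return pd.Series(
            sub["auc"].to_numpy(), index=pd.Index(sub["cell_line"], name="cell_line"),
            name=drug_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseTable):
            return NotImplemented
        return self.records.reset_index(drop=True).equals(
            other.records.reset_index(drop=True)
        )


@dataclass
class FeatureMatrix:
    """A per-drug design matrix whose every column carries provenance.

    ``values`` is samples x features; ``feature_meta`` is indexed by the
    column names of ``values`` and carries ``type`` (one of expression,
    mutation, cnv, tissue, signature) and ``source`` (the gene, segment,
    tissue label, or signature name the column came from).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame  # columns: type, source

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.feature_meta.index):
            raise ValueError("feature_meta must be indexed by the value columns")
        bad = set(self.feature_meta["type"]) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature types {sorted(bad)}")
        pairs = list(zip(self.feature_meta["type"], self.feature_meta["source"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (type, source) feature pairs")
        if len(self.values) and self.values.isna().all(axis=0).any():
            col = self.values.columns[self.values.isna().all(axis=0)][0]
            raise ValueError(f"feature column {col!r} is entirely missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def of_type(self, feature_type: str) -> list[str]:
        meta = self.feature_meta
        return list(meta.index[meta["type"] == feature_type])
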