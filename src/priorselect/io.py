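"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV matrices (header row of feature ids, first
column of cell-line ids), GMT gene-set files, TSV drug-annotation tables and
a long-format TSV response table.  Readers validate on load and raise
:class:`~priorselect.datatypes.FormatError` naming the offending location.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DrugAnnotation,
    FormatError,
    GeneSetCollection,
    OmicsDataset,
    ResponseTable,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# matrices

def read_matrix(path: str | os.PathLike, value_kind: str = "continuous") -> pd.DataFrame:
    """Read a labeled TSV matrix (rows = cell lines, columns = features).

    ``value_kind='binary'`` additionally validates that every entry is 0 or 1.
    """
    if value_kind not in ("continuous", "binary"):
        raise ValueError(f"value_kind must be continuous or binary, got {value_kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature column {dup!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at row "
                f"{bad.index[0]!r}, column {col!r}"
            )
    if value_kind == "binary":
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"{path}: binary matrix contains {values[i, j]!r} at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
        df = df.astype(np.int8)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "cell_line"
    return df


# shortest decimal representation that parses back to the identical float
_FLOAT_FMT = lambda x: repr(float(x))  # noqa: E731


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df = df.copy()
    df.index.name = "cell_line"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | os.PathLike, kind: str = "pathway") -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``.

    The description field is discarded; duplicate genes within a set are
    dropped keeping the first occurrence.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT "
                    "requires name, description and at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = [g for g in fields[2:] if g]
            sets[name] = list(dict.fromkeys(genes))
    return GeneSetCollection(sets=sets, kind=kind)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# drug annotations

def _parse_targets(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text:
        return frozenset()
    return frozenset(t.strip() for t in text.split(";") if t.strip())


def read_drug_annotations(
    path_gdsc: str | os.PathLike,
    path_drugbank: str | os.PathLike | None = None,
) -> list[DrugAnnotation]:
    """Read drug annotations, merging targets from a secondary database.

    The primary table carries ``drug_id``, semicolon-separated ``targets`` and
    the ``target_pathway`` class; the optional secondary table carries
    ``drug_id`` and ``targets``.  Per drug the target set is the union over
    the two sources; the pathway class always comes from the primary table.
    Drugs present only in the secondary table are skipped with a warning.
    """
    gdsc = pd.read_csv(path_gdsc, sep="\t", dtype=str)
    for col in ("drug_id", "targets", "target_pathway"):
        if col not in gdsc.columns:
            raise FormatError(f"{path_gdsc}: missing required column {col!r}")
    drugbank: dict[str, frozenset[str]] = {}
    if path_drugbank is not None:
        db = pd.read_csv(path_drugbank, sep="\t", dtype=str)
        for col in ("drug_id", "targets"):
            if col not in db.columns:
                raise FormatError(f"{path_drugbank}: missing required column {col!r}")
        drugbank = {
            row["drug_id"]: _parse_targets(row["targets"]) for _, row in db.iterrows()
        }
    annotations: list[DrugAnnotation] = []
    seen: set[str] = set()
    for _, row in gdsc.iterrows():
        drug = row["drug_id"]
        if drug in seen:
            raise FormatError(f"{path_gdsc}: duplicate drug id {drug!r}")
        seen.add(drug)
        targets = _parse_targets(row["targets"])
        sources = {"gdsc"}
        if drug in drugbank:
            targets = targets | drugbank[drug]
            sources.add("drugbank")
        annotations.append(
            DrugAnnotation(
                drug_id=drug,
                targets=frozenset(targets),
                target_pathway=row["target_pathway"],
                target_sources=frozenset(sources),
            )
        )
    orphans = set(drugbank) - seen
    for drug in sorted(orphans):
        logger.warning("drug %r present only in the secondary target table; skipped", drug)
    return annotations


def write_drug_annotations(
    annotations: list[DrugAnnotation],
    path_gdsc: str | os.PathLike,
    path_drugbank: str | os.PathLike | None = None,
) -> None:
    """Write annotations back to the two-table layout read_drug_annotations expects.

    Targets sourced from both databases cannot be un-merged, so the primary
    table receives the full union and the secondary table (if requested) the
    same targets for drugs flagged with a drugbank source.
    """
    rows = [
        {
            "drug_id": a.drug_id,
            "targets": ";".join(sorted(a.targets)),
            "target_pathway": a.target_pathway,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["drug_id", "targets", "target_pathway"]).to_csv(
        path_gdsc, sep="\t", index=False
    )
    if path_drugbank is not None:
        db_rows = [
            {"drug_id": a.drug_id, "targets": ";".join(sorted(a.targets))}
            for a in annotations
            if "drugbank" in a.target_sources
        ]
        pd.DataFrame(db_rows, columns=["drug_id", "targets"]).to_csv(
            path_drugbank, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# responses

def read_response_table(path: str | os.PathLike) -> ResponseTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"drug_id": str, "cell_line": str},
        float_precision="round_trip",
    )
    for col in ("drug_id", "cell_line", "auc"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return ResponseTable(records=df[["drug_id", "cell_line", "auc"]])


def write_response_table(table: ResponseTable, path: str | os.PathLike) -> None:
    table.records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# datasets

_SEGMENT_MAP_COLS = ["segment", "genes"]


def write_dataset_tables(dataset: OmicsDataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the four modality tables plus the segment map; returns file map."""
    out = Path(out_dir)
    files = {
        "expression": "expression.tsv",
        "mutation": "mutation.tsv",
        "cnv": "cnv.tsv",
        "segment_genes": "segment_genes.tsv",
        "tissue": "tissue.tsv",
        "availability": "availability.tsv",
    }
    write_matrix(dataset.expression, out / files["expression"])
    write_matrix(dataset.mutation, out / files["mutation"])
    write_matrix(dataset.cnv, out / files["cnv"])
    seg = pd.DataFrame(
        [
            {"segment": s, "genes": ";".join(sorted(g))}
            for s, g in dataset.segment_genes.items()
        ],
        columns=_SEGMENT_MAP_COLS,
    )
    seg.to_csv(out / files["segment_genes"], sep="\t", index=False)
    tissue = dataset.tissue.rename("tissue").to_frame()
    tissue.index.name = "cell_line"
    tissue.to_csv(out / files["tissue"], sep="\t")
    avail = dataset.availability.astype(int)
    avail.index.name = "cell_line"
    avail.to_csv(out / files["availability"], sep="\t")
    return files


def read_dataset_tables(in_dir: str | os.PathLike) -> OmicsDataset:
    in_dir = Path(in_dir)
    expression = read_matrix(in_dir / "expression.tsv", "continuous")
    mutation = read_matrix(in_dir / "mutation.tsv", "binary")
    cnv = read_matrix(in_dir / "cnv.tsv", "binary")
    seg = pd.read_csv(in_dir / "segment_genes.tsv", sep="\t", dtype=str)
    segment_genes = {
        row["segment"]: frozenset(_parse_targets(row["genes"]))
        for _, row in seg.iterrows()
    }
    tissue_df = pd.read_csv(in_dir / "tissue.tsv", sep="\t", index_col=0, dtype=str)
    tissue = tissue_df["tissue"]
    tissue.index = tissue.index.astype(str)
    avail_path = in_dir / "availability.tsv"
    availability = None
    if avail_path.exists():
        availability = read_matrix(avail_path, "binary").astype(bool)
    return OmicsDataset(
        expression=expression,
        mutation=mutation,
        cnv=cnv,
        segment_genes=segment_genes,
        tissue=tissue,
        availability=availability,
    )
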