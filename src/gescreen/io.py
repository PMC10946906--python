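"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column ``gene_id``, one column per
sample) with a companion design TSV (``sample_id``, ``label``); plate
libraries as a long CSV (``plate_id, well_id, role, compound_id, gene,
value``) plus an annotation CSV; ground truth and fitted signature models as
JSON.  All writes use full float precision (shortest round-tripping repr),
so ``read(write(x))`` recovers ``x`` exactly and outputs are deterministic
given the data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PlateLibrary
from .signature import DLDAModel
from .synthetic_data import GroundTruth

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_plate_csv", "write_plate_csv",
    "read_annotations_csv", "write_annotations_csv",
    "read_ground_truth", "write_ground_truth",
    "read_model_json", "write_model_json", "write_signature_tsv",
    "write_ranking_tsv", "write_trend_tsv", "write_gene_list",
]


def read_expression_tsv(matrix_path, design_path) -> ExpressionMatrix:
    """Read a genes x samples TSV and its sample design TSV."""
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ValueError(f"{matrix_path}: first column must be 'gene_id', "
                         f"got {raw.columns[0]!r}")
    dup = raw["gene_id"][raw["gene_id"].duplicated()]
    if len(dup):
        line = dup.index[0] + 2  # header is line 1
        raise ValueError(f"{matrix_path}:{line}: duplicate gene id {dup.iloc[0]!r}")
    body = raw.set_index("gene_id")
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(
                f"{matrix_path}:{row + 2}: non-numeric value in column {col!r}")
    # astype goes through numpy's correctly-rounded strtod so that
    # write -> read -> write is byte-identical
    values = body.astype(float)
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if list(design.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(f"{design_path}: expected columns sample_id, label")
    design = design.set_index("sample_id")["label"]
    missing = values.columns.difference(design.index)
    if len(missing):
        raise ValueError(f"{design_path}: design missing sample {missing[0]!r}")
    return ExpressionMatrix(values, design)


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path,
                         design_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    design = matrix.design.rename("label")
    design.index.name = "sample_id"
    design.to_csv(design_path, sep="\t")


def read_plate_csv(path, annotations_path=None) -> PlateLibrary:
    """Read the long-format plate CSV (and optionally the annotation CSV)."""
    long = pd.read_csv(path, dtype={"plate_id": str, "well_id": str,
                                    "role": str, "compound_id": str,
                                    "gene": str})
    expected = ["plate_id", "well_id", "role", "compound_id", "gene", "value"]
    if list(long.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    long["compound_id"] = long["compound_id"].fillna("")
    wells = (long[["plate_id", "well_id", "role", "compound_id"]]
             .drop_duplicates(ignore_index=True))
    dup = wells.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        w = wells.loc[dup.idxmax()]
        raise ValueError(f"{path}: well {w['well_id']!r} on plate "
                         f"{w['plate_id']!r} has conflicting role/compound rows")
    annotations = (read_annotations_csv(annotations_path)
                   if annotations_path is not None else None)
    kwargs = {} if annotations is None else {"annotations": annotations}
    return PlateLibrary(wells=wells,
                        measurements=long[["plate_id", "well_id", "gene", "value"]],
                        **kwargs)


def write_plate_csv(lib: PlateLibrary, path) -> None:
    long = lib.measurements.merge(lib.wells, on=["plate_id", "well_id"])
    long = long[["plate_id", "well_id", "role", "compound_id", "gene", "value"]]
    long.to_csv(path, index=False)


def read_annotations_csv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype={"compound_id": str, "name": str})
    expected = ["compound_id", "name", "approved", "withdrawn", "black_box"]
    if list(ann.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    for col in ("approved", "withdrawn", "black_box"):
        if ann[col].dtype != bool:
            mapped = ann[col].map({"True": True, "False": False,
                                   "true": True, "false": False,
                                   1: True, 0: False})
            if mapped.isna().any():
                raise ValueError(f"{path}: column {col!r} must be boolean")
            ann[col] = mapped
    return ann


def write_annotations_csv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_model_json(model: DLDAModel, path) -> None:
    doc = {
        "genes": model.genes,
        "classes": list(model.classes),
        "class_means": {c: model.class_means[c].tolist()
                        for c in model.classes},
        "pooled_var": model.pooled_var.tolist(),
        "loocv_accuracy": model.loocv_accuracy,
        "selection_trace": model.selection_trace,
        "divergence_warning": model.divergence_warning,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model_json(path) -> DLDAModel:
    doc = json.loads(Path(path).read_text())
    idx = pd.Index(doc["genes"], name="gene_id")
    classes = tuple(doc["classes"])
    return DLDAModel(
        genes=list(doc["genes"]),
        classes=classes,
        class_means=pd.DataFrame(
            {c: doc["class_means"][c] for c in classes}, index=idx),
        pooled_var=pd.Series(doc["pooled_var"], index=idx),
        loocv_accuracy=doc.get("loocv_accuracy"),
        selection_trace=list(doc.get("selection_trace", [])),
        divergence_warning=bool(doc.get("divergence_warning", False)),
    )


def write_signature_tsv(model: DLDAModel, snr_table: pd.DataFrame,
                        path) -> None:
    """Signature summary: gene, direction, SNR, class means, pooled variance."""
    directions = model.directions
    rows = []
    for g in model.genes:
        rows.append({
            "gene_id": g,
            "direction": "up" if directions[g] > 0 else "down",
            "snr": snr_table.at[g, "snr"],
            f"mean_{model.classes[0]}": model.class_means.at[g, model.classes[0]],
            f"mean_{model.classes[1]}": model.class_means.at[g, model.classes[1]],
            "pooled_variance": model.pooled_var[g],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ranking_tsv(ranking: pd.DataFrame, path) -> None:
    out = ranking.copy()
    out.index.name = "compound_id"
    out.to_csv(path, sep="\t")


def write_trend_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
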