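"""Readers and writers for the pipeline's delimited-text formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import METADATA_COLUMNS, ExpressionDataset
from .errors import ValidationError
from .simulate import SyntheticTruth
from .targets import DrugTargetCatalog, load_catalog


def read_expression(
    expression_path: str | Path,
    metadata_path: str | Path,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Load one dataset from its expression and metadata TSVs.

    The expression TSV has gene ids in the first column and one column per
    sample; the metadata TSV has columns sample_id, condition_id, arm,
    dose_gray, time_hours. Validation (duplicates, missing samples,
    non-numeric cells) is delegated to :class:`ExpressionDataset`.
    """
    expression_path = Path(expression_path)
    # round_trip parsing restores the exact written doubles
    raw = pd.read_csv(expression_path, sep="\t", index_col=0, float_precision="round_trip")
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene rows in {expression_path}: {dupes[:5]}")
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[converted.isna() & raw[col].notna()]
        if len(bad):
            raise ValidationError(
                f"non-numeric cell at gene {bad[0]!r}, sample {col!r} in {expression_path}"
            )
        raw[col] = converted
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"{metadata_path} missing metadata columns: {missing}")
    if dataset_id is None:
        dataset_id = expression_path.stem.removesuffix("_expression")
    return ExpressionDataset(dataset_id, raw, meta)


def read_collection(
    manifest_path: str | Path,
) -> tuple[list[ExpressionDataset], SyntheticTruth | None, DrugTargetCatalog]:
    """Load a written collection back from its manifest.

    Returns the datasets, the planted truth if truth tables are present
    (None otherwise), and the drug catalog.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    files = manifest["files"]

    datasets = [
        read_expression(root / expr, root / files["metadata"][ds], dataset_id=ds)
        for ds, expr in sorted(files["datasets"].items())
    ]
    catalog = load_catalog(root / files["catalog"])

    truth = None
    truth_files = files.get("truth") or {}
    if "genes" in truth_files:
        genes_tab = pd.read_csv(root / truth_files["genes"], sep="\t", dtype={"gene_id": str})
        de_tab = pd.read_csv(root / truth_files["de"], sep="\t", dtype=str)
        module_of_gene = dict(
            zip(genes_tab["gene_id"], genes_tab["module"].astype(int))
        )
        truth = SyntheticTruth(
            module_of_gene=module_of_gene,
            hub_genes=frozenset(genes_tab.loc[genes_tab["is_hub"] == 1, "gene_id"]),
            de_direction={
                (str(r.gene_id), str(r.condition_id)): str(r.direction)
                for r in de_tab.itertuples()
            },
            consistent_direction=dict(
                zip(genes_tab["gene_id"], genes_tab["consistent_direction"].astype(str))
            ),
            druggable_genes=frozenset(genes_tab.loc[genes_tab["is_druggable"] == 1, "gene_id"]),
            condition_ids=tuple(manifest.get("condition_ids", ())),
            min_sig_fraction=float(manifest.get("min_sig_fraction", 0.25)),
        )
    return datasets, truth, catalog


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
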