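"""Reading and writing volumes, atlases, phenotype tables and graphs.

Formats: NIfTI-1 (``.nii``/``.nii.gz``) for intensity, label and saliency
volumes; TSV with a mandatory header for region and phenotype tables (and a
``#``-comment vocabulary block for controlled columns); GraphML plus a flat
TSV edge list for correlation graphs; JSON for configs and reports.

On read, every volume is reoriented to the package's fixed axis order
``(sagittal, coronal, axial)`` with index 0 of the sagittal axis on the
*right* hemisphere, using the file's affine; files whose orientation cannot
be determined are rejected rather than silently guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    GROUPS,
    HEMISPHERES,
    SUBSCORES,
    BrainVolume,
    ParcellationAtlas,
    SubjectRecord,
    ValidationError,
)

__all__ = [
    "read_volume", "write_volume", "read_atlas", "write_atlas",
    "read_phenotypes", "write_phenotypes", "write_graph", "read_json", "write_json",
]


def _canonical_data(img, path):
    if len(img.shape) != 3:
        raise ValidationError(
            f"{path}: expected a 3D image, got {len(img.shape)}D"
        )
    try:
        ornt = nib.orientations.io_orientation(img.affine)
        if np.any(np.isnan(ornt)):
            raise ValueError("degenerate affine")
        can = nib.as_closest_canonical(img)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot determine orientation: {exc}") from exc
    zooms = can.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-4 * max(zooms):
        raise ValidationError(f"{path}: anisotropic voxels {zooms} are unsupported")
    data = np.asanyarray(can.dataobj)
    # canonical is RAS (+x toward the left-to-right direction increasing);
    # flip so that sagittal index 0 is the rightmost slice
    return np.flip(data, axis=0).copy(), float(zooms[0])


def read_volume(path) -> BrainVolume:
    """Read a 3D NIfTI volume, normalising orientation and axis order."""
    img = nib.load(str(path))
    data, vs = _canonical_data(img, path)
    return BrainVolume(data=np.asarray(data, dtype=np.float32), voxel_size=vs)


def _write_nifti(data: np.ndarray, voxel_size: float, path) -> None:
    vs = float(voxel_size)
    # +x is "right" in RAS; our index 0 is the rightmost slice, so the
    # sagittal axis direction is -x
    affine = np.diag([-vs, vs, vs, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_volume(volume: BrainVolume, path) -> None:
    _write_nifti(volume.data.astype(np.float32), volume.voxel_size, path)


# ---------------------------------------------------------------------------
# region tables / atlases

_VOCAB = {"hemisphere": HEMISPHERES}


def _write_table(df: pd.DataFrame, path, vocab_cols=()) -> None:
    with open(path, "w") as fh:
        for col in vocab_cols:
            values = _VOCAB.get(col) or sorted(set(df[col]))
            fh.write(f"# {col}: {','.join(str(v) for v in values)}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_atlas(atlas: ParcellationAtlas, label_path, table_path) -> None:
    _write_nifti(atlas.labels.astype(np.int32), 1.0, label_path)
    _write_table(atlas.regions, table_path, vocab_cols=("hemisphere", "lobe", "network"))


def read_atlas(label_path, table_path) -> ParcellationAtlas:
    """Read a label volume + region table; cross-validates ids."""
    img = nib.load(str(label_path))
    data, _ = _canonical_data(img, label_path)
    labels = np.asarray(np.rint(data), dtype=np.int32)
    table = pd.read_csv(table_path, sep="\t", comment="#")
    missing = {"region_id", "name", "hemisphere", "lobe", "is_cortical", "network"} \
        - set(table.columns)
    if missing:
        raise ValidationError(f"{table_path}: missing columns {sorted(missing)}")
    table["is_cortical"] = table["is_cortical"].astype(bool)
    table["network"] = table["network"].fillna("none")
    return ParcellationAtlas(labels=labels, regions=table)


# ---------------------------------------------------------------------------
# phenotypes

_PHENO_COLS = ("subject_id", "group", "srs_total") + SUBSCORES


def write_phenotypes(records, path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group,
               "srs_total": r.srs_total if r.srs_total is not None else ""}
        for s in SUBSCORES:
            row[s] = r.subscores[s] if r.subscores else ""
        rows.append(row)
    _write_table(pd.DataFrame(rows, columns=list(_PHENO_COLS)), path, vocab_cols=("group",))


def read_phenotypes(path):
    """Read and validate a phenotype TSV into SubjectRecords."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PHENO_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"{path}: unknown groups {sorted(bad)}")
    records = []
    for _, row in df.iterrows():
        if row["group"] == "control":
            scores = [row["srs_total"]] + [row[s] for s in SUBSCORES]
            if any(v == v and str(v) != "" for v in scores):  # NaN-safe non-blank
                raise ValidationError(
                    f"{path}: control subject {row['subject_id']} carries SRS scores"
                )
            records.append(SubjectRecord(str(row["subject_id"]), "control"))
        else:
            if row[["srs_total", *SUBSCORES]].isna().any():
                raise ValidationError(
                    f"{path}: scored subject {row['subject_id']} has blank SRS fields"
                )
            records.append(SubjectRecord(
                str(row["subject_id"]), str(row["group"]),
                srs_total=float(row["srs_total"]),
                subscores={s: float(row[s]) for s in SUBSCORES},
            ))
    return records


# ---------------------------------------------------------------------------
# graphs / json

def write_graph(graph, graphml_path=None, edge_tsv_path=None) -> None:
    """Export a correlation graph as GraphML and/or a flat TSV edge list."""
    G = graph.graph if hasattr(graph, "graph") and isinstance(graph.graph, nx.Graph) else graph
    if graphml_path is not None:
        nx.write_graphml(G, str(graphml_path))
    if edge_tsv_path is not None:
        rows = [{"region_a": a, "region_b": b,
                 "tau": d.get("tau"), "p": d.get("p")}
                for a, b, d in sorted(G.edges(data=True))]
        pd.DataFrame(rows, columns=["region_a", "region_b", "tau", "p"]) \
            .to_csv(edge_tsv_path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
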