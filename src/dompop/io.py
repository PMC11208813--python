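"""Readers and writers for the pipeline's delimited-text formats.

Dialect: comma-separated, "." decimal mark, UTF-8.  Marker matrices carry
locus ids either in a ``PRIMER:LOCUS`` convention or alongside a sidecar
primer map.  Reports are JSON with deterministic key order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BinaryMarkerMatrix,
    DiasporeRecord,
    FruitRecord,
    TreeRecord,
    ValidationError,
)

log = logging.getLogger("dompop")


def _primer_from_locus_id(locus_id: str) -> str | None:
    if ":" in locus_id:
        return locus_id.split(":", 1)[0]
    return None


def read_marker_matrix(path, primer_map_path=None) -> BinaryMarkerMatrix:
    """Read an individuals x loci 0/1 band matrix from CSV.

    Header row holds locus ids, first column individual ids.  Primer
    grouping comes from a two-column sidecar CSV (locus, primer) if given,
    otherwise from a ``PRIMER:LOCUS`` id convention; failing both, every
    locus is assigned to a single ``"P0"`` primer.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    individual_ids = [str(i) for i in df.index]
    locus_ids = [str(c) for c in df.columns]
    scores = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            cell = str(raw).strip()
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"non-binary cell at row {individual_ids[i]!r}, "
                    f"column {locus_ids[j]!r}: {raw!r}"
                )
            scores[i, j] = int(cell)
    if pd.isna(df.values).any():
        raise ValidationError("marker matrix contains missing cells")

    if primer_map_path is not None:
        pm = pd.read_csv(primer_map_path, dtype=str)
        primer_of_locus = dict(zip(pm.iloc[:, 0], pm.iloc[:, 1]))
    else:
        primer_of_locus = {}
        for locus in locus_ids:
            primer = _primer_from_locus_id(locus)
            primer_of_locus[locus] = primer if primer is not None else "P0"
    matrix = BinaryMarkerMatrix(individual_ids, locus_ids, primer_of_locus, scores)
    log.info("read marker matrix: %d individuals x %d loci", *matrix.scores.shape)
    return matrix


def write_marker_matrix(matrix: BinaryMarkerMatrix, path, primer_map_path=None) -> None:
    df = pd.DataFrame(
        matrix.scores, index=matrix.individual_ids, columns=matrix.locus_ids
    )
    df.to_csv(path)
    if primer_map_path is not None:
        pd.DataFrame(
            {
                "locus": matrix.locus_ids,
                "primer": [matrix.primer_of_locus[l] for l in matrix.locus_ids],
            }
        ).to_csv(primer_map_path, index=False)


_TREE_COLUMNS = ["id", "x", "y", "circumferences", "height", "crown_area", "fruiting"]


def read_tree_table(path) -> list[TreeRecord]:
    """Read the tree survey table (one row per tree, circumferences ';'-joined)."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValidationError(f"no trees in {path}")
    missing = [c for c in _TREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"tree table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        circs = [float(c) for c in str(row["circumferences"]).split(";") if c.strip()]
        records.append(
            TreeRecord(
                tree_id=str(row["id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                stem_circumferences=circs,
                total_height=float(row["height"]),
                crown_area=float(row["crown_area"]),
                fruiting=str(row["fruiting"]).strip().lower() in ("true", "1", "yes"),
            )
        )
    log.info("read %d tree records (%d fruiting)", len(records),
             sum(r.fruiting for r in records))
    return records


def write_tree_table(trees: list[TreeRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [t.tree_id for t in trees],
            "x": [t.x for t in trees],
            "y": [t.y for t in trees],
            "circumferences": [";".join(f"{c:g}" for c in t.stem_circumferences)
                               for t in trees],
            "height": [t.total_height for t in trees],
            "crown_area": [t.crown_area for t in trees],
            "fruiting": [t.fruiting for t in trees],
        }
    ).to_csv(path, index=False)


def read_fruit_table(path) -> list[FruitRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        pulp = row.get("pulp_yield")
        records.append(
            FruitRecord(
                tree_id=str(row["tree_id"]),
                length=float(row["length"]),
                diameter=float(row["diameter"]),
                fresh_mass=float(row["fresh_mass"]),
                pulp_yield=None if pulp is None or pd.isna(pulp) else float(pulp),
            )
        )
    return records


def write_fruit_table(fruits: list[FruitRecord], path) -> None:
    pd.DataFrame(
        {
            "tree_id": [f.tree_id for f in fruits],
            "length": [f.length for f in fruits],
            "diameter": [f.diameter for f in fruits],
            "fresh_mass": [f.fresh_mass for f in fruits],
            "pulp_yield": [f.pulp_yield for f in fruits],
        }
    ).to_csv(path, index=False)


def read_diaspore_table(path) -> list[DiasporeRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        rec = DiasporeRecord(
            tree_id=str(row["tree_id"]),
            length=float(row["length"]),
            diameter=float(row["diameter"]),
            thickness=float(row["thickness"]),
            fresh_mass=float(row["fresh_mass"]),
        )
        if not rec.thickness <= rec.diameter <= rec.length:
            # measurement axes are operator conventions; warn, do not reject
            log.warning("diaspore of %s: axes not ordered thickness<=diameter<=length",
                        rec.tree_id)
        records.append(rec)
    return records


def write_diaspore_table(diaspores: list[DiasporeRecord], path) -> None:
    pd.DataFrame(
        {
            "tree_id": [d.tree_id for d in diaspores],
            "length": [d.length for d in diaspores],
            "diameter": [d.diameter for d in diaspores],
            "thickness": [d.thickness for d in diaspores],
            "fresh_mass": [d.fresh_mass for d in diaspores],
        }
    ).to_csv(path, index=False)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, tuple)):
            return list(o)
        return super().default(o)


def write_results(report: dict, path) -> None:
    """Write a nested report as JSON with deterministic key order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_ReportEncoder)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
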