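"""Plain-text readers/writers for every pipeline stage.

Genotypes travel in a rotated r/qtl-style CSV: trait columns first, then one
column per marker, with rows 2-3 carrying chromosome and cM position.
Physical (bp) positions live in a separate marker-map TSV.  Expression and
detection matrices are probes x samples TSVs.  All floats are written with a
fixed format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GenotypeMatrix, MarkerMap

FLOAT_FMT = "%.10g"


def write_marker_map(markers: MarkerMap, path) -> None:
    markers.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_genotypes_csv(geno: GenotypeMatrix, traits: pd.DataFrame, path) -> None:
    """Rotated r/qtl CSV: id + trait columns, then markers with chr/cM rows."""
    traits = traits.loc[geno.individuals]
    marker_ids = geno.markers.marker_ids
    header = ["id"] + list(traits.columns) + marker_ids
    row_chr = [""] * (1 + traits.shape[1]) + [geno.markers.chromosome] * len(marker_ids)
    row_cm = [""] * (1 + traits.shape[1]) + [FLOAT_FMT % c for c in geno.markers.cm]
    letters = geno.to_frame()
    lines = [",".join(header), ",".join(row_chr), ",".join(row_cm)]
    for ind in geno.individuals:
        vals = [ind] + [FLOAT_FMT % v for v in traits.loc[ind]] + list(letters.loc[ind])
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_csv(path, markers: MarkerMap) -> tuple[GenotypeMatrix, pd.DataFrame]:
    raw = pd.read_csv(path, header=0, dtype=str)
    chrom_row = raw.iloc[0]
    marker_cols = [c for c in raw.columns if str(chrom_row[c]).strip() not in ("", "nan")]
    trait_cols = [c for c in raw.columns if c not in marker_cols and c != "id"]
    body = raw.iloc[2:].reset_index(drop=True)
    individuals = body["id"].astype(str).tolist()
    geno_frame = body[marker_cols].copy()
    geno_frame.index = individuals
    if marker_cols != markers.marker_ids:
        raise ValueError("marker columns do not match marker map")
    geno = GenotypeMatrix.from_frame(geno_frame, markers)
    traits = body[trait_cols].astype(float)
    traits.index = individuals
    return geno, traits


def write_expression(expr: ExpressionMatrix, out_dir, prefix: str = "expression") -> None:
    out = Path(out_dir)
    expr.intensities.rename_axis("probe_id").to_csv(
        out / f"{prefix}.tsv", sep="\t", float_format=FLOAT_FMT
    )
    expr.detection_p.rename_axis("probe_id").to_csv(
        out / f"{prefix}_detection.tsv", sep="\t", float_format=FLOAT_FMT
    )
    expr.annotation.rename_axis("probe_id").to_csv(
        out / "annotation.tsv", sep="\t", float_format=FLOAT_FMT
    )


def read_expression(
    expr_path, detection_path, annotation_path, stage: str = "raw"
) -> ExpressionMatrix:
    intens = pd.read_csv(expr_path, sep="\t", index_col="probe_id")
    det = pd.read_csv(detection_path, sep="\t", index_col="probe_id")
    ann = pd.read_csv(annotation_path, sep="\t", index_col="probe_id",
                      dtype={"chromosome": str})
    intens.index = intens.index.astype(str)
    det.index = det.index.astype(str)
    ann.index = ann.index.astype(str)
    return ExpressionMatrix(intens, det, ann, stage=stage)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("sample").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_json(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
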