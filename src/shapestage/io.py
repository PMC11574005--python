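"""Table serialization: cohort CSV, thickness TSV, effect-map TSV, spheres.

All numeric output uses a fixed "%.10g" float format so that re-running a
seeded analysis reproduces files byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, ThicknessMatrix
from .errors import ValidationError
from .massuni import EffectMap
from .mesh import MeshAtlas, SphericalParam

FLOAT_FMT = "%.10g"

__all__ = [
    "write_cohort", "read_cohort",
    "write_thickness", "read_thickness",
    "write_effect_map", "read_effect_map",
    "write_sphere", "read_sphere",
    "write_json",
]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table lacks columns {sorted(missing)}")
    return df


def write_thickness(tm: ThicknessMatrix, path: str | Path, atlas: MeshAtlas | None = None) -> None:
    """TSV with subjects in rows; a sidecar ``<path>.cols.tsv`` maps columns
    to (structure, local vertex) when an atlas is given."""
    path = Path(path)
    df = pd.DataFrame(tm.values)
    df.insert(0, "subject_id", tm.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if atlas is not None:
        rows = []
        for key in atlas.structure_keys:
            start, stop = atlas.vertex_offsets[key]
            for local, g in enumerate(range(start, stop)):
                rows.append((g, key, local))
        pd.DataFrame(rows, columns=["global_vertex", "structure", "local_vertex"]).to_csv(
            path.with_suffix(path.suffix + ".cols.tsv"), sep="\t", index=False
        )


def read_thickness(path: str | Path) -> ThicknessMatrix:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValidationError("thickness TSV lacks subject_id column")
    sids = df["subject_id"].to_numpy()
    return ThicknessMatrix(df.drop(columns="subject_id").to_numpy(float), sids)


def write_effect_map(m: EffectMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "vertex": np.arange(len(m.beta)),
            "beta": m.beta,
            "se": m.se,
            "p": m.p,
            "sig": (m.sig_mask.astype(int) if m.sig_mask is not None else np.zeros(len(m.beta), int)),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_effect_map(path: str | Path) -> EffectMap:
    df = pd.read_csv(path, sep="\t")
    return EffectMap(
        df["beta"].to_numpy(float),
        df["se"].to_numpy(float),
        df["p"].to_numpy(float),
        df["sig"].to_numpy(bool),
    )


def write_sphere(sphere: SphericalParam, path: str | Path) -> None:
    """Plain CSV (vertex, x, y, z) of the unit registration coordinates."""
    df = pd.DataFrame(sphere.unit_coords, columns=["x", "y", "z"])
    df.insert(0, "vertex", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.17g")


def read_sphere(path: str | Path) -> SphericalParam:
    df = pd.read_csv(path)
    return SphericalParam(df[["x", "y", "z"]].to_numpy(float))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
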