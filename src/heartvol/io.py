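"""Schema-validated readers and writers.

Contour sets travel as JSON (one record per contour: plane geometry,
vertex array, chamber/layer/phase labels, slice index or plane angle)
with a version tag; a flat CSV export (one vertex per row) is provided
for interoperability. Results are plain CSV/JSON with a fixed column
order and deterministic number formatting, so identical inputs produce
identical bytes. All serialized lengths are mm, volumes ml, masses g,
angles degrees; numbers carry no unit suffixes — units live here, in the
schema.

No standard bioimaging format (DICOM, NIfTI) is consumed or produced:
inputs are contours, not pixels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import Contour, LaxSet, Line3, Plane, SaxStack, ValidationError

__all__ = [
    "SCHEMA_VERSION",
    "write_contours",
    "read_contours",
    "contours_to_csv",
    "write_results",
]

SCHEMA_VERSION = "1.0"


class _PlaneModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    origin: list[float] = Field(min_length=3, max_length=3)
    normal: list[float] = Field(min_length=3, max_length=3)
    basis: list[list[float]]  # two 3-vectors

    @field_validator("basis")
    @classmethod
    def _two_vectors(cls, v):
        if len(v) != 2 or any(len(b) != 3 for b in v):
            raise ValueError("basis must hold two 3-vectors")
        return v

    def build(self) -> Plane:
        return Plane(np.array(self.origin), np.array(self.normal),
                     np.array(self.basis).T)

    @classmethod
    def dump(cls, p: Plane) -> dict:
        return {"origin": p.origin.tolist(), "normal": p.normal.tolist(),
                "basis": p.basis.T.tolist()}


class _ContourModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    plane: _PlaneModel
    vertices: list[list[float]] = Field(min_length=3)
    chamber: Literal["LV", "LA"]
    layer: Literal["endo", "epi"]
    phase: Literal["ED", "ES"]
    index_or_angle: float

    @field_validator("vertices")
    @classmethod
    def _pairs(cls, v):
        if any(len(p) != 2 for p in v):
            raise ValueError("vertices must be 2-D points")
        return v

    def build(self) -> Contour:
        return Contour(self.plane.build(), np.array(self.vertices),
                       self.chamber, self.layer, self.phase, self.index_or_angle)

    @classmethod
    def dump(cls, c: Contour) -> dict:
        return {"plane": _PlaneModel.dump(c.plane),
                "vertices": c.vertices.tolist(), "chamber": c.chamber,
                "layer": c.layer, "phase": c.phase,
                "index_or_angle": float(c.index_or_angle)}


class _LineModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    point: list[float] = Field(min_length=3, max_length=3)
    direction: list[float] = Field(min_length=3, max_length=3)

    def build(self) -> Line3:
        return Line3(np.array(self.point), np.array(self.direction))

    @classmethod
    def dump(cls, ln: Line3) -> dict:
        return {"point": ln.point.tolist(), "direction": ln.direction.tolist()}


class _ContourSetModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: str
    kind: Literal["sax", "lax"]
    long_axis: _LineModel
    contours: list[_ContourModel]
    thickness: float | None = None
    gap: float | None = None
    mitral_plane: _PlaneModel | None = None
    extra_basal: list[_ContourModel] = Field(default_factory=list)
    plane_angles: list[float] | None = None


def write_contours(obj: SaxStack | LaxSet, path: str | Path) -> Path:
    """Serialize a contour set to schema-versioned JSON."""
    path = Path(path)
    if isinstance(obj, SaxStack):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": "sax",
            "thickness": obj.thickness,
            "gap": obj.gap,
            "mitral_plane": _PlaneModel.dump(obj.mitral_plane),
            "long_axis": _LineModel.dump(obj.long_axis),
            "contours": [_ContourModel.dump(c) for c in obj.contours],
            "extra_basal": [_ContourModel.dump(c) for c in obj.extra_basal],
        }
    elif isinstance(obj, LaxSet):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": "lax",
            "plane_angles": list(obj.plane_angles),
            "long_axis": _LineModel.dump(obj.long_axis),
            "contours": [_ContourModel.dump(c) for c in obj.contours],
        }
    else:
        raise ValidationError("write_contours expects a SaxStack or LaxSet")
    path.write_text(json.dumps(doc, sort_keys=True) + "\n")
    return path


def read_contours(path: str | Path) -> SaxStack | LaxSet:
    """Read and invariant-check a contour set written by ``write_contours``.

    Schema violations raise with the offending field/record named;
    unknown schema versions are rejected explicitly.
    """
    raw = json.loads(Path(path).read_text())
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported contour-set schema version {version!r} "
            f"(this build reads {SCHEMA_VERSION!r})")
    try:
        model = _ContourSetModel.model_validate(raw)
    except Exception as exc:  # pydantic error already names field + index
        raise ValidationError(f"contour-set schema violation in {path}: {exc}") from exc
    if model.kind == "sax":
        if model.thickness is None or model.mitral_plane is None or model.gap is None:
            raise ValidationError("SAX contour set requires thickness, gap and mitral_plane")
        return SaxStack(
            tuple(c.build() for c in model.contours),
            model.thickness, model.gap, model.mitral_plane.build(),
            model.long_axis.build(),
            tuple(c.build() for c in model.extra_basal))
    if model.plane_angles is None:
        raise ValidationError("LAX contour set requires plane_angles")
    return LaxSet(tuple(c.build() for c in model.contours),
                  tuple(model.plane_angles), model.long_axis.build())


def contours_to_csv(obj: SaxStack | LaxSet, path: str | Path) -> Path:
    """Flat CSV export: one vertex per row."""
    rows = []
    for ci, c in enumerate(obj.contours):
        for vi, (u, v) in enumerate(c.vertices):
            rows.append((ci, c.chamber, c.layer, c.phase,
                         float(c.index_or_angle), vi, u, v))
    df = pd.DataFrame(rows, columns=["contour_id", "chamber", "layer", "phase",
                                     "index_or_angle", "vertex_index",
                                     "u_mm", "v_mm"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path,
                  reports: dict[str, dict] | None = None) -> list[Path]:
    """Write result tables as CSV (and reports as JSON) deterministically.

    Column order is taken from each frame as-is; floats are rendered with
    ``%.10g`` and a fixed line terminator so two runs over identical
    inputs produce identical bytes. An empty table yields a header-only
    CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
        written.append(p)
    for name, doc in (reports or {}).items():
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(doc, sort_keys=True, indent=2,
                                allow_nan=True) + "\n")
        written.append(p)
    return written
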