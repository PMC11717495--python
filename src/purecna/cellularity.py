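"""Cell-count tumour purity from nucleus detections inside pathologist ROIs.

The detector output side of a computational-pathology pipeline is consumed
here: a table of detected nuclei (planar coordinates in microns, class
tumour/background, detection confidence) plus region-of-interest polygons in
the same coordinate frame. Purity is the tumour fraction of counted cells,
reported on a 0–100% scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape
from shapely.ops import unary_union

from purecna.stats import PearsonResult, pearson_ci

__all__ = [
    "CellDetection", "RoiSet", "SlideCellSummary", "PurityEstimate",
    "count_cells_in_roi", "tumour_purity", "paired_slide_concordance",
    "read_detections", "write_detections", "read_roi_geojson",
    "write_roi_geojson", "read_purity_table", "write_purity_table",
]

MICRONS_PER_MM = 1000.0

#: accepted synonyms for the two detection classes (case-insensitive)
_CLASS_SYNONYMS = {
    "tumour": "tumour", "tumor": "tumour", "tc": "tumour",
    "background": "background", "bc": "background",
}

PURITY_METHODS = ("softctm", "softctm_he2", "cp", "estimate", "infiniumpurify", "truth")


def normalise_class(label: str) -> str:
    try:
        return _CLASS_SYNONYMS[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown detection class {label!r}") from None


@dataclass(frozen=True)
class CellDetection:
    """One detected nucleus: position (microns), class and confidence."""

    x: float
    y: float
    cls: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cls", normalise_class(self.cls))
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class RoiSet:
    """Union of region-of-interest polygons (micron coordinate frame)."""

    def __init__(self, polygons: Sequence[Polygon]):
        if not polygons:
            raise ValueError("empty RoiSet")
        for p in polygons:
            if not p.is_valid:
                raise ValueError("ROI polygon is not simple/valid")
        self.polygons = list(polygons)
        # overlapping polygons are merged so points are counted once
        self._union = unary_union(self.polygons)
        if self._union.area <= 0:
            raise ValueError("ROI area must be positive")

    @property
    def area_mm2(self) -> float:
        return self._union.area / MICRONS_PER_MM**2

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Inclusive containment (boundary points count as inside)."""
        return shapely.intersects_xy(self._union, x, y)


@dataclass(frozen=True)
class SlideCellSummary:
    """Tumour/background cell counts of one slide within its ROI."""

    slide_id: str
    TC: int
    BC: int
    area_mm2: float

    def __post_init__(self) -> None:
        if self.TC < 0 or self.BC < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def density(self) -> float:
        """Cells per mm² over the ROI."""
        return (self.TC + self.BC) / self.area_mm2


@dataclass(frozen=True)
class PurityEstimate:
    """A tumour purity value (percent) for one sample by one method."""

    sample_id: str
    method: str
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"purity {self.value} outside [0, 100]")


def count_cells_in_roi(
    detections: Iterable[CellDetection],
    rois: RoiSet,
    slide_id: str,
    min_confidence: float = 0.0,
) -> SlideCellSummary:
    """Count tumour and background cells falling inside the ROI union.

    Detections below ``min_confidence`` are discarded first (default 0: no
    filtering, matching detectors whose post-processing already thresholds).
    """
    dets = [d for d in detections if d.confidence >= min_confidence]
    if dets:
        x = np.array([d.x for d in dets])
        y = np.array([d.y for d in dets])
        inside = rois.contains_points(x, y)
        tc = int(sum(1 for d, i in zip(dets, inside) if i and d.cls == "tumour"))
        bc = int(sum(1 for d, i in zip(dets, inside) if i and d.cls == "background"))
    else:
        tc = bc = 0
    if tc + bc == 0:
        warnings.warn(f"slide {slide_id}: no detections inside ROI", stacklevel=2)
    return SlideCellSummary(slide_id=slide_id, TC=tc, BC=bc, area_mm2=rois.area_mm2)


def tumour_purity(summary: SlideCellSummary) -> float:
    """Tumour purity in percent: 100 · TC / (TC + BC).

    0% means no tumour cells, 100% pure tumour. A slide with no counted
    cells has undefined purity and raises (flagged, never silently 0).
    """
    total = summary.TC + summary.BC
    if total == 0:
        raise ValueError(f"slide {summary.slide_id}: no cells counted, purity undefined")
    return 100.0 * summary.TC / total


def paired_slide_concordance(
    values_a: Mapping[str, float] | Sequence[float],
    values_b: Mapping[str, float] | Sequence[float],
) -> PearsonResult:
    """Pearson correlation of purity between paired (serial-section) slides.

    Mapping inputs are matched by sample ID; an ID present on one side only
    is an error listing the missing pairs.
    """
    if isinstance(values_a, Mapping) != isinstance(values_b, Mapping):
        raise TypeError("both inputs must be mappings or both sequences")
    if isinstance(values_a, Mapping):
        only_a = sorted(set(values_a) - set(values_b))
        only_b = sorted(set(values_b) - set(values_a))
        if only_a or only_b:
            raise ValueError(
                f"unmatched sample IDs: only in first={only_a}, only in second={only_b}"
            )
        keys = sorted(values_a)
        a = [values_a[k] for k in keys]
        b = [values_b[k] for k in keys]
    else:
        if len(values_a) != len(values_b):
            raise ValueError("paired lists must have equal length")
        a, b = list(values_a), list(values_b)
    if len(a) < 3:
        raise ValueError("need at least 3 matched pairs")
    # identical or perfectly anti-ordered lists short-circuit the CI machinery
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) == 1.0 or len(a) == 3:
        return PearsonResult(r=r, ci_low=r, ci_high=r, n=len(a), p_value=0.0)
    return pearson_ci(a, b)


# ---------------------------------------------------------------------------
# I/O dialects

def read_detections(path: str | Path) -> list[CellDetection]:
    """CSV with header x,y,class,confidence; class synonyms are normalised."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"x", "y", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: detections CSV needs columns {sorted(required)}")
    conf = df["confidence"] if "confidence" in df.columns else np.ones(len(df))
    return [
        CellDetection(x=float(x), y=float(y), cls=str(c), confidence=float(p))
        for x, y, c, p in zip(df["x"], df["y"], df["class"], conf)
    ]


def write_detections(detections: Iterable[CellDetection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,class,confidence\n")
        for d in detections:
            fh.write(f"{d.x:.3f},{d.y:.3f},{d.cls},{d.confidence:.4f}\n")


def read_roi_geojson(path: str | Path) -> RoiSet:
    """GeoJSON FeatureCollection of Polygon/MultiPolygon features."""
    with open(path) as fh:
        gj = json.load(fh)
    polygons: list[Polygon] = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            polygons.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polygons.extend(geom.geoms)
        else:
            raise ValueError(f"{path}: unsupported geometry {geom.geom_type}")
    return RoiSet(polygons)


def write_roi_geojson(rois: RoiSet, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {},
         "geometry": json.loads(shapely.to_geojson(p))}
        for p in rois.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_purity_table(path: str | Path) -> list[PurityEstimate]:
    """TSV with header sample_id, method, value (percent)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "method": str})
    return [
        PurityEstimate(sample_id=str(r.sample_id), method=str(r.method), value=float(r.value))
        for r in df.itertuples()
    ]


def write_purity_table(estimates: Iterable[PurityEstimate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmethod\tvalue\n")
        for e in estimates:
            fh.write(f"{e.sample_id}\t{e.method}\t{e.value:.4f}\n")
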