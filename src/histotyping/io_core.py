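"""Readers/writers, domain containers, configuration and logging.

Coordinate convention: real-valued microns, origin at the image top-left,
x rightward, y downward.  Pixel (i, j) has its center at
((j + 0.5) * mpp, (i + 0.5) * mpp).  All geometry downstream of IO is in
micron coordinates so features are resolution independent.

Formats: PNG/TIFF for images, single-channel 16-bit label TIFF/PNG for
masks (0 = background, k = lumen k), GeoJSON for annotations and lumen
sets, CSV for feature/clinical/score tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon

logger = logging.getLogger("histotyping")

#: Missing-value sentinel for degenerate regions (e.g. < 3 glands); excluded
#: pairwise in downstream statistics.
SENTINEL = float("nan")


class InputError(ValueError):
    """Unreadable or malformed input file."""


class ValidationError(ValueError):
    """Input readable but violating a contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RegionImage:
    """An RGB region-of-interest raster with physical resolution.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    microns_per_pixel : physical size of one pixel in micrometers (> 0)
    region_id : identifier of the region / patient
    site : contributing-site label (scanner/stain batch)
    """

    pixels: np.ndarray
    microns_per_pixel: float
    region_id: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("RegionImage.pixels must be (H, W, 3) RGB")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValidationError("RegionImage must be at least 32x32 px")
        if not self.microns_per_pixel > 0:
            raise ValidationError("microns_per_pixel must be > 0")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def size_um(self) -> tuple[float, float]:
        """(height, width) in microns."""
        h, w = self.shape_px
        return h * self.microns_per_pixel, w * self.microns_per_pixel


@dataclass
class AnnotationPolygon:
    """Tumor-region annotation: a simple closed polygon in microns."""

    vertices: np.ndarray  # (N, 2) [x, y] in um
    region_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be (N, 2)")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("annotation must be a simple polygon of positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class LumenSet:
    """A tumor-region annotation plus per-lumen boundary polygons (um)."""

    region: AnnotationPolygon
    lumens: list[Polygon]
    source: str = "mask"  # {"mask", "segmenter", "generator"}

    def __len__(self) -> int:
        return len(self.lumens)

    @property
    def centroids(self) -> np.ndarray:
        if not self.lumens:
            return np.empty((0, 2))
        return np.array([[p.centroid.x, p.centroid.y] for p in self.lumens])


# ---------------------------------------------------------------------------
# Image / annotation IO
# ---------------------------------------------------------------------------

def px_to_um(ij: np.ndarray, mpp: float) -> np.ndarray:
    """Pixel indices (i, j) -> micron coordinates (x, y) of pixel centers."""
    ij = np.asarray(ij, dtype=float)
    return np.stack([(ij[..., 1] + 0.5) * mpp, (ij[..., 0] + 0.5) * mpp], axis=-1)


def um_to_px(xy: np.ndarray, mpp: float) -> np.ndarray:
    """Micron coordinates (x, y) -> fractional pixel indices (i, j)."""
    xy = np.asarray(xy, dtype=float)
    return np.stack([xy[..., 1] / mpp - 0.5, xy[..., 0] / mpp - 0.5], axis=-1)


def read_image(path: str | Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 16-bit label mask (0 = background, k = lumen k)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise InputError(f"cannot read mask {path}: {exc}") from exc
    return np.asarray(arr).astype(np.uint16)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask, dtype=np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask)
    else:
        iio.imwrite(path, mask)


def _polygon_to_geojson(vertices: np.ndarray) -> dict:
    ring = [[float(x), float(y)] for x, y in np.asarray(vertices)]
    if ring[0] != ring[-1]:
        ring.append(ring[0])
    return {"type": "Polygon", "coordinates": [ring]}


def _geojson_to_vertices(geom: Mapping) -> np.ndarray:
    if geom.get("type") != "Polygon":
        raise InputError(f"expected GeoJSON Polygon, got {geom.get('type')}")
    ring = np.asarray(geom["coordinates"][0], dtype=float)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    return ring


def read_annotation(path: str | Path, region_id: str = "") -> AnnotationPolygon:
    """Read a tumor-region annotation from a GeoJSON file (coords in um)."""
    try:
        with open(path) as fh:
            gj = json.load(fh)
    except Exception as exc:
        raise InputError(f"cannot read annotation {path}: {exc}") from exc
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
        props = gj["features"][0].get("properties") or {}
        region_id = region_id or str(props.get("region_id", ""))
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    return AnnotationPolygon(_geojson_to_vertices(geom), region_id=region_id)


def write_annotation(path: str | Path, ann: AnnotationPolygon) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"region_id": ann.region_id},
                "geometry": _polygon_to_geojson(ann.vertices),
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_region(
    image_path: str | Path,
    annotation_path: str | Path,
    metadata: Mapping[str, Any],
) -> tuple[RegionImage, AnnotationPolygon]:
    """Read an ROI image + tumor annotation.

    ``metadata`` must carry ``microns_per_pixel``; ``region_id`` and ``site``
    are optional.  The annotation is validated to lie within the image bounds
    after the um->px conversion; a violation reports the offending vertex.
    """
    mpp = float(metadata["microns_per_pixel"])
    img = RegionImage(
        read_image(image_path),
        microns_per_pixel=mpp,
        region_id=str(metadata.get("region_id", "")),
        site=str(metadata.get("site", "")),
    )
    ann = read_annotation(annotation_path, region_id=img.region_id)
    h_um, w_um = img.size_um
    for idx, (x, y) in enumerate(ann.vertices):
        if not (0 <= x <= w_um and 0 <= y <= h_um):
            raise ValidationError(
                f"annotation vertex {idx} at ({x:g}, {y:g}) um lies outside "
                f"the image bounds ({w_um:g} x {h_um:g} um)"
            )
    return img, ann


def write_lumen_set(path: str | Path, ls: LumenSet) -> None:
    """Write a LumenSet as a GeoJSON FeatureCollection (region + lumens)."""
    features = [
        {
            "type": "Feature",
            "properties": {"role": "region", "region_id": ls.region.region_id,
                           "source": ls.source},
            "geometry": _polygon_to_geojson(ls.region.vertices),
        }
    ]
    for k, poly in enumerate(ls.lumens, start=1):
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "lumen", "label": k},
                "geometry": _polygon_to_geojson(
                    np.asarray(poly.exterior.coords)[:-1]
                ),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_lumen_set(path: str | Path) -> LumenSet:
    with open(path) as fh:
        gj = json.load(fh)
    region = None
    lumens: list[Polygon] = []
    source = "mask"
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        verts = _geojson_to_vertices(feat["geometry"])
        if props.get("role") == "region":
            region = AnnotationPolygon(verts, region_id=str(props.get("region_id", "")))
            source = str(props.get("source", "mask"))
        else:
            lumens.append(Polygon(verts))
    if region is None:
        raise InputError(f"{path}: no region feature found")
    return LumenSet(region=region, lumens=lumens, source=source)


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

def write_feature_table(
    records: Sequence[tuple[str, "FeatureVector"]], path: str | Path
) -> None:
    """Write (region_id, FeatureVector) records as a CSV.

    One header row of feature names, one row per region; all vectors must
    share a single catalog ordering.
    """
    from .graph_texture_features import FeatureVector  # local: avoid cycle

    names = None
    rows = {}
    for region_id, vec in records:
        if not isinstance(vec, FeatureVector):
            raise ValidationError("records must contain FeatureVector values")
        if names is None:
            names = list(vec.names)
        elif list(vec.names) != names:
            raise ValidationError("mixed feature catalogs in one table")
        rows[region_id] = np.asarray(vec.values, dtype=float)
    if names is None:
        from .graph_texture_features import catalog_names

        names = catalog_names()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "region_id"
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="region_id")
    df.index = df.index.astype(str)
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical/survival CSV into a validated DataFrame."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValidationError("clinical table requires a patient_id column")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id {dup!r}")
    if "time" in df.columns and (df["time"] < 0).any():
        raise ValidationError("negative follow-up time")
    if "event" in df.columns and not df["event"].dropna().isin([0, 1]).all():
        raise ValidationError("event flag must be 0/1")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationConfig:
    min_area_um2: float = 40.0
    opening_radius_px: int = 2
    boundary_samples: int = 128


@dataclass
class FeatureConfig:
    boundary_samples: int = 128
    n_fourier: int = 10
    hu_log_compress: bool = True
    p5_p95_as_ratio: bool = True  # False -> p95 - p5 range
    subgraph_epsilon_factor: float = 2.0  # x median 1-NN distance
    glcm_levels: int = 32
    glcm_distance: int = 1
    density_radii_um: tuple[float, float] = (50.0, 100.0)


@dataclass
class StabilityConfig:
    ks_threshold: float = 0.4
    min_regions_per_site: int = 10


@dataclass
class ModelConfig:
    alpha: float = 0.5  # elastic-net mixing
    n_folds: int = 10
    threshold_rule: str = "logrank"  # or "median"


@dataclass
class Config:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    model: ModelConfig = field(default_factory=ModelConfig)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config with sections mirroring module names.

    Every numeric constant in the defaults above is overridable; unknown
    keys raise so typos do not silently fall back to defaults.
    """
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for section, values in data.items():
        if not hasattr(cfg, section):
            raise ValidationError(f"unknown config section {section!r}")
        sub = getattr(cfg, section)
        for key, val in (values or {}).items():
            if not hasattr(sub, key):
                raise ValidationError(f"unknown config key {section}.{key}")
            current = getattr(sub, key)
            if isinstance(current, tuple):
                val = tuple(val)
            setattr(sub, key, val)
    return cfg


def config_to_dict(cfg: Config) -> dict:
    return dataclasses.asdict(cfg)
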