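"""Standalone synthetic-region builder used by the acceptance script."""

from __future__ import annotations

import numpy as np
from shapely import affinity
from shapely.geometry import box

from histotyping.io_core import AnnotationPolygon, LumenSet
from histotyping.synthetic_data import ShapeParams, make_lumen, place_glands


def build_region(
    seed: int,
    n_glands: int = 20,
    canvas: float = 512.0,
    shape_class: str = "disk",
    size: float = 35.0,
    boundary_noise: float = 0.0,
    density_heterogeneity: float = 0.4,
    mixed: bool = False,
) -> LumenSet:
    """A ground-truth region of synthetic gland lumens."""
    rng = np.random.default_rng(seed)
    region = box(8.0, 8.0, canvas - 8.0, canvas - 8.0)
    centers = place_glands(region, n_glands, size, density_heterogeneity, rng)
    lumens = []
    for i, ctr in enumerate(centers):
        cls = shape_class
        if mixed:
            cls = ("disk", "ellipse", "crescent")[i % 3]
        poly = make_lumen(
            ShapeParams(cls, size, aspect=2.0, notch_depth=0.4,
                        boundary_noise=boundary_noise),
            rng,
        )
        lumens.append(affinity.translate(poly, ctr[0], ctr[1]))
    ann = AnnotationPolygon(np.asarray(region.exterior.coords)[:-1],
                            region_id=f"R{seed}")
    return LumenSet(region=ann, lumens=lumens, source="generator")
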