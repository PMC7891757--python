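"""Planar AOI world model.

The analysis discretizes gaze position into a small set of named areas of
interest (AOIs) — here the ten instrument regions of an airliner cockpit
panel plus the windshield.  The world model is an ordered registry of those
regions: its region order fixes the row/column order of every transition
matrix downstream, and its centroid geometry supplies the transition
amplitudes used by the ambient/focal coefficient K.

Samples that fall inside no region are given the reserved sentinel id
``OUTSIDE_AOI`` (0); they are excluded from all metrics but their time share
is reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from shapely.geometry import Point, Polygon, box

from .errors import ConfigurationError, UnknownAOIError

#: Reserved AOI id for gaze that hits no defined region.
OUTSIDE_AOI = 0


@dataclass(frozen=True)
class AOIRegion:
    """One named region of the panel.

    Parameters
    ----------
    id
        1-based index; the default model numbers regions the way cockpit
        panels are conventionally read (PFD sub-regions first, windshield
        last).
    label
        Short instrument name, e.g. ``ATT`` or ``OTW``.
    shape
        Planar polygon in the model's declared units.
    """

    id: int
    label: str
    shape: Polygon

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ConfigurationError(f"AOI id must be >= 1, got {self.id}")
        if not self.shape.is_valid or self.shape.area <= 0:
            raise ConfigurationError(
                f"AOI {self.id} ({self.label!r}) has a degenerate shape"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.shape.centroid
        return (c.x, c.y)

    def contains(self, x: float, y: float) -> bool:
        # boundary points count as inside so adjacent rectangles tile cleanly
        return bool(self.shape.intersects(Point(x, y)))


@dataclass(frozen=True)
class WorldModel:
    """Ordered registry of AOI regions plus the coordinate-unit declaration."""

    regions: tuple[AOIRegion, ...]
    units: str = "mm"
    _by_id: Mapping[int, AOIRegion] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(self.regions) < 2:
            raise ConfigurationError("a world model needs at least 2 regions")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate AOI ids: {dupes}")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ConfigurationError(
                f"AOI ids must be contiguous from 1, got {sorted(ids)}"
            )
        object.__setattr__(
            self, "regions", tuple(sorted(self.regions, key=lambda r: r.id))
        )
        object.__setattr__(self, "_by_id", {r.id: r for r in self.regions})

    @property
    def m(self) -> int:
        """Number of AOIs (transition matrices are m x m)."""
        return len(self.regions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)

    def region(self, aoi_id: int) -> AOIRegion:
        try:
            return self._by_id[aoi_id]
        except KeyError:
            raise UnknownAOIError(f"unknown AOI id {aoi_id}") from None

    def distance(self, i: int, j: int) -> float:
        """Euclidean centroid distance between AOIs *i* and *j* (model units)."""
        if i == j:
            self.region(i)  # still validate the id
            return 0.0
        return float(math.dist(self.region(i).centroid, self.region(j).centroid))

    def distance_matrix(self) -> np.ndarray:
        """(m x m) centroid-distance table in region order."""
        cents = np.array([r.centroid for r in self.regions])
        diff = cents[:, None, :] - cents[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def locate(self, x: float, y: float) -> int:
        """AOI id containing point (x, y), or ``OUTSIDE_AOI``.

        Regions are probed in id order, so where shapes share a boundary the
        lower id wins.
        """
        for r in self.regions:
            if r.contains(x, y):
                return r.id
        return OUTSIDE_AOI

    def to_config(self) -> dict:
        """JSON/YAML-compatible configuration that round-trips via
        :func:`load_world_model`."""
        return {
            "units": self.units,
            "regions": [
                {
                    "id": r.id,
                    "label": r.label,
                    "polygon": [list(p) for p in r.shape.exterior.coords[:-1]],
                }
                for r in self.regions
            ],
        }


def _region_from_config(entry: Mapping) -> AOIRegion:
    try:
        rid = int(entry["id"])
        label = str(entry["label"])
    except KeyError as exc:
        raise ConfigurationError(f"region entry missing key {exc}") from None
    if "rect" in entry:
        x0, y0, x1, y1 = map(float, entry["rect"])
        if not (x1 > x0 and y1 > y0):
            raise ConfigurationError(
                f"AOI {rid}: rect must satisfy x1 > x0 and y1 > y0"
            )
        shape = box(x0, y0, x1, y1)
    elif "polygon" in entry:
        shape = Polygon([tuple(map(float, p)) for p in entry["polygon"]])
    else:
        raise ConfigurationError(f"AOI {rid}: needs a 'rect' or 'polygon' key")
    return AOIRegion(id=rid, label=label, shape=shape)


def load_world_model(config: str | Mapping) -> WorldModel:
    """Build a :class:`WorldModel` from a YAML/JSON text or a parsed mapping.

    The document declares ``units`` and a ``regions`` list; each region has
    an ``id``, a ``label`` and either a ``rect`` ``[x0, y0, x1, y1]`` or a
    ``polygon`` vertex list.  Regions are returned sorted by id.
    """
    if isinstance(config, str):
        try:
            parsed = yaml.safe_load(config)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"unparseable world-model config: {exc}")
    else:
        parsed = config
    if not isinstance(parsed, Mapping) or "regions" not in parsed:
        raise ConfigurationError("world-model config must define 'regions'")
    regions = tuple(_region_from_config(e) for e in parsed["regions"])
    return WorldModel(regions=regions, units=str(parsed.get("units", "mm")))


def default_world_model() -> WorldModel:
    """The bundled ten-AOI cockpit model (schematic planar coordinates)."""
    text = (
        resources.files("aoiscan.data")
        .joinpath("default_world_model.yaml")
        .read_text()
    )
    return load_world_model(text)
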