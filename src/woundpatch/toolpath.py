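"""Minimal scaffold slicer: planar slicing, perimeters, rectilinear infill
with regional density/angle control, and volumetric G-code.

Conventions follow common slicer practice: layers are cut at mid-layer
heights (z_min + (k + 0.5) * layer_height); the i-th perimeter is the slice
polygon inset by (i + 0.5) widths; rectilinear infill lines are spaced
``width / density`` apart (0.4 mm lines at 40 % density -> 1.0 mm pitch),
clipped to the innermost perimeter minus the infill-overlap band, with their
phase anchored to the world origin so output is deterministic.  The extruder
axis E carries *cumulative extruded volume* in mm^3:
``dE = length * width * layer_height * flow``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import (GeometryCollection, LineString, MultiLineString,
                              MultiPolygon, Polygon, box)

from .core import GeometryError, SurfaceMesh


class ConfigError(ValueError):
    """Raised for inconsistent print settings or region modifiers."""


@dataclass
class PrintSettings:
    """Print parameters (defaults are the bioprinted-patch settings)."""

    layer_height: float = 0.16          # mm
    speed: float = 20.0                 # mm/s
    travel_speed: float = 100.0         # mm/s, non-extruding moves
    perimeters: int = 2
    top_bottom_layers: int = 2
    infill_density: float = 0.40        # fraction of solid
    infill_angle: float | None = None   # None -> alternate 0/90 per layer
    extrusion_width: float = 0.4        # mm
    flow: float = 1.0
    infill_overlap: float = 0.5         # fraction of width
    connect_infill: bool = True

    def validate(self) -> None:
        if not 0 < self.infill_density <= 1:
            raise ConfigError("infill_density must be in (0, 1]")
        if self.layer_height >= self.extrusion_width:
            raise ConfigError("layer_height must be smaller than extrusion_width")
        if self.perimeters < 0 or self.top_bottom_layers < 0:
            raise ConfigError("counts must be >= 0")
        if self.layer_height <= 0 or self.speed <= 0 or self.extrusion_width <= 0:
            raise ConfigError("layer_height, speed, extrusion_width must be positive")

    def angle_for_layer(self, k: int) -> float:
        if self.infill_angle is not None:
            return self.infill_angle
        return 0.0 if k % 2 == 0 else 90.0

    def header(self) -> dict:
        return {
            "layer_height_mm": self.layer_height, "speed_mm_s": self.speed,
            "perimeters": self.perimeters, "top_bottom_layers": self.top_bottom_layers,
            "infill_density": self.infill_density,
            "infill_angle": "alternating 0/90" if self.infill_angle is None
                            else self.infill_angle,
            "extrusion_width_mm": self.extrusion_width, "flow": self.flow,
            "infill_overlap": self.infill_overlap, "connect_infill": self.connect_infill,
        }


@dataclass
class RegionModifier:
    """Override infill density/angle inside a region.

    The region is either a fractional ``span`` along ``axis`` (0 = x, 1 = y,
    2 = z) of the model's bounding box, or an absolute world-space ``bounds``
    box ``[[x0,y0,z0],[x1,y1,z1]]``.  Regions of different modifiers may not
    overlap.
    """

    density: float
    angle: float | None = None
    axis: int = 0
    span: tuple = (0.0, 1.0)
    bounds: np.ndarray | None = None

    def absolute_bounds(self, model_bounds: np.ndarray) -> np.ndarray:
        if self.bounds is not None:
            return np.asarray(self.bounds, dtype=float).reshape(2, 3)
        lo, hi = np.asarray(model_bounds, dtype=float)
        out = np.array([lo.copy(), hi.copy()])
        a0, a1 = self.span
        if not (0.0 <= a0 < a1 <= 1.0):
            raise ConfigError(f"fractional span must satisfy 0 <= a < b <= 1, got {self.span}")
        width = hi[self.axis] - lo[self.axis]
        out[0, self.axis] = lo[self.axis] + a0 * width
        out[1, self.axis] = lo[self.axis] + a1 * width
        return out


@dataclass
class Polyline:
    """One extrusion path within a layer."""

    points: np.ndarray              # (n, 2) xy mm
    role: str                       # perimeter | solid | infill
    width: float

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Layer:
    z: float
    polylines: list = field(default_factory=list)


@dataclass
class ToolPath:
    layers: list
    settings: PrintSettings

    def total_length(self, roles: tuple | None = None) -> float:
        return sum(p.length for layer in self.layers for p in layer.polylines
                   if roles is None or p.role in roles)


@dataclass
class Move:
    x: float
    y: float
    z: float
    e: float       # cumulative extruded volume, mm^3
    feed: float    # mm/min
    travel: bool


@dataclass
class GCodeProgram:
    moves: list
    settings_header: dict

    @property
    def total_extruded_mm3(self) -> float:
        return self.moves[-1].e if self.moves else 0.0


@dataclass
class PrintEstimate:
    bioink_volume_ml: float       # everything extruded
    infill_volume_ml: float       # infill roads only
    perimeter_volume_ml: float
    solid_volume_ml: float
    print_time_s: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# slicing


def _as_polygons(geom) -> list:
    if geom is None or geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        return [g for g in geom.geoms if isinstance(g, Polygon) and not g.is_empty]
    return []


def slice_mesh(mesh: SurfaceMesh, layer_height: float) -> list:
    """Cut a watertight mesh into per-layer cross-sections.

    Returns ``[(z, [shapely Polygon, ...]), ...]`` with cuts at mid-layer
    heights, so a slicing plane never coincides with a flat face of a
    grid-aligned mesh.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise GeometryError("slicing requires a watertight mesh")
    z_min, z_max = tm.bounds[0][2], tm.bounds[1][2]
    n_layers = int(math.floor((z_max - z_min) / layer_height))
    if n_layers == 0:
        return []
    zs = z_min + (np.arange(n_layers) + 0.5) * layer_height
    sections = tm.section_multiplane(plane_origin=[0, 0, z_min],
                                     plane_normal=[0, 0, 1], heights=zs - z_min)
    from .patch_design import path2d_polygons

    out = []
    for z, path in zip(zs, sections):
        polys = [] if path is None else path2d_polygons(path)
        out.append((float(z), polys))
    return out


def make_perimeters(polygon: Polygon, count: int, width: float) -> list:
    """Inset perimeter loops: the i-th loop at (i + 0.5) * width inside the slice."""
    loops = []
    for i in range(count):
        inset = polygon.buffer(-(i + 0.5) * width, join_style="mitre")
        for poly in _as_polygons(inset):
            rings = [poly.exterior] + list(poly.interiors)
            for ring in rings:
                pts = np.asarray(ring.coords)
                if len(pts) >= 4:
                    loops.append(Polyline(points=pts, role="perimeter", width=width))
    return loops


def _as_lines(geom) -> list:
    if geom is None or geom.is_empty:
        return []
    if isinstance(geom, LineString):
        return [geom]
    if isinstance(geom, (MultiLineString, GeometryCollection)):
        out = []
        for g in geom.geoms:
            out.extend(_as_lines(g))
        return out
    return []


def rectilinear_infill(polygon: Polygon, density: float, angle: float, width: float,
                       overlap: float = 0.5, connect: bool = True,
                       inset: float = 0.0) -> list:
    """Parallel infill lines at ``angle`` with pitch ``width / density``.

    ``inset`` is the total perimeter wall thickness (perimeter count x width);
    lines are clipped to the slice polygon inset by ``inset - overlap * width``
    so they fuse with the innermost perimeter.  Line phase is anchored to the
    world origin.  With ``connect``, consecutive lines are joined into
    serpentine paths whenever the short connector stays inside the region.
    """
    if not 0 < density <= 1:
        raise ConfigError("infill density must be in (0, 1]")
    clip_inset = max(inset - overlap * width, 0.0)
    region = polygon.buffer(-clip_inset, join_style="mitre") if clip_inset > 0 else polygon
    if region.is_empty:
        return []
    pitch = width / density
    theta = math.radians(angle)
    u = np.array([math.cos(theta), math.sin(theta)])   # along lines
    m = np.array([-math.sin(theta), math.cos(theta)])  # across lines
    corners = np.array(box(*region.bounds).exterior.coords)[:4]
    t_lo, t_hi = (corners @ m).min(), (corners @ m).max()
    s_lo, s_hi = (corners @ u).min() - 1.0, (corners @ u).max() + 1.0
    k_lo = math.ceil((t_lo + 1e-9) / pitch)
    k_hi = math.floor((t_hi - 1e-9) / pitch)
    shapely.prepare(region)
    rows = []  # one entry per scan line: list of (n, 2) arrays ordered along u
    for k in range(k_lo, k_hi + 1):
        base = k * pitch * m
        line = LineString([base + s_lo * u, base + s_hi * u])
        segs = _as_lines(region.intersection(line))
        pieces = []
        for seg in segs:
            pts = np.asarray(seg.coords)
            if len(pts) >= 2 and LineString(pts).length > 1e-9:
                pieces.append(pts)
        pieces.sort(key=lambda p: float(p.mean(axis=0) @ u))
        if pieces:
            rows.append(pieces)
    polylines: list = []
    current: np.ndarray | None = None
    forward = True
    for pieces in rows:
        ordered = pieces if forward else [p[::-1] for p in reversed(pieces)]
        for pts in ordered:
            if current is not None and connect:
                joint = LineString([current[-1], pts[0]])
                if (joint.length <= 2.0 * pitch
                        and region.buffer(0.51 * width).covers(joint)):
                    current = np.vstack([current, pts])
                    continue
            if current is not None:
                polylines.append(Polyline(current, role="infill", width=width))
            current = pts
        forward = not forward
    if current is not None:
        polylines.append(Polyline(current, role="infill", width=width))
    return polylines


def _check_modifiers(modifiers, model_bounds) -> list:
    boxes = [mod.absolute_bounds(model_bounds) for mod in modifiers]
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            lo = np.maximum(boxes[i][0], boxes[j][0])
            hi = np.minimum(boxes[i][1], boxes[j][1])
            if np.all(hi - lo > 1e-9):
                raise ConfigError(f"region modifiers {i} and {j} overlap")
    return boxes


def apply_region_modifiers(layer_polygons: list, modifiers: list,
                           model_bounds: np.ndarray,
                           default_density: float,
                           default_angle_for_layer) -> list:
    """Partition each layer's polygons into (polygon, density, angle) pieces.

    ``layer_polygons`` is the output of :func:`slice_mesh`.  Every infill
    region inherits the density/angle of the modifier whose box contains it;
    leftovers keep the per-layer defaults.  Overlapping modifiers are a
    configuration error.
    """
    boxes = _check_modifiers(modifiers, model_bounds)
    out = []
    for k, (z, polys) in enumerate(layer_polygons):
        default_angle = default_angle_for_layer(k)
        pieces = []
        for poly in polys:
            remainder = poly
            for mod, bnds in zip(modifiers, boxes):
                if not (bnds[0][2] - 1e-9 <= z <= bnds[1][2] + 1e-9):
                    continue
                cut = box(bnds[0][0], bnds[0][1], bnds[1][0], bnds[1][1])
                inside = remainder.intersection(cut)
                for p in _as_polygons(inside):
                    angle = default_angle if mod.angle is None else mod.angle
                    pieces.append((p, poly, mod.density, angle))
                remainder = remainder.difference(cut)
            for p in _as_polygons(remainder):
                pieces.append((p, poly, default_density, default_angle))
        out.append((z, pieces))
    return out


def generate_toolpath(mesh: SurfaceMesh, settings: PrintSettings,
                      modifiers: list = ()) -> ToolPath:
    """Slice a mesh into perimeters + rectilinear infill, honouring modifiers.

    The first and last ``top_bottom_layers`` layers are filled solid
    (density 1); elsewhere the infill density/angle come from the settings or
    the region modifier containing the area.
    """
    settings.validate()
    sliced = slice_mesh(mesh, settings.layer_height)
    n = len(sliced)
    tm_bounds = mesh.to_trimesh().bounds
    partitioned = apply_region_modifiers(
        sliced, list(modifiers), tm_bounds,
        default_density=settings.infill_density,
        default_angle_for_layer=settings.angle_for_layer)
    w = settings.extrusion_width
    inset = settings.perimeters * w
    layers = []
    for k, ((z, polys), (_, pieces)) in enumerate(zip(sliced, partitioned)):
        layer = Layer(z=z)
        for poly in polys:
            layer.polylines.extend(make_perimeters(poly, settings.perimeters, w))
        solid = k < settings.top_bottom_layers or k >= n - settings.top_bottom_layers
        if solid:
            for poly in polys:
                lines = rectilinear_infill(poly, 1.0, settings.angle_for_layer(k), w,
                                           settings.infill_overlap,
                                           settings.connect_infill, inset)
                for p in lines:
                    p.role = "solid"
                layer.polylines.extend(lines)
        else:
            for piece, parent, density, angle in pieces:
                # clip relative to the parent slice polygon so the perimeter
                # inset is measured from the true outline, not the region cut
                lines = rectilinear_infill(parent, density, angle, w,
                                           settings.infill_overlap,
                                           settings.connect_infill, inset)
                layer.polylines.extend(_clip_polylines_to_piece(lines, piece, parent,
                                                                len(modifiers) > 0))
        layers.append(layer)
    return ToolPath(layers=layers, settings=settings)


def _clip_polylines_to_piece(lines, piece, parent, has_modifiers: bool) -> list:
    if not has_modifiers or piece.equals(parent):
        return lines
    out = []
    # shrink by an epsilon so a line lying exactly on a shared region edge is
    # claimed by neither piece (instead of being extruded twice)
    clip = piece.buffer(-1e-9)
    for p in lines:
        geom = clip.intersection(LineString(p.points)) if len(p.points) >= 2 else None
        for seg in _as_lines(geom):
            pts = np.asarray(seg.coords)
            if len(pts) >= 2 and LineString(pts).length > 1e-9:
                out.append(Polyline(pts, role=p.role, width=p.width))
    return out


def plan_gcode(toolpath: ToolPath, settings: PrintSettings | None = None
               ) -> tuple[GCodeProgram, PrintEstimate]:
    """Turn a toolpath into moves with cumulative volumetric E and estimates.

    ``dE = length * width * layer_height * flow`` per extruding segment;
    print time covers extruding moves at ``speed`` and travels at
    ``travel_speed``.
    """
    settings = settings or toolpath.settings
    h, flow = settings.layer_height, settings.flow
    feed_print = settings.speed * 60.0
    feed_travel = settings.travel_speed * 60.0
    moves: list = []
    e = 0.0
    time_s = 0.0
    vol_by_role = {"perimeter": 0.0, "solid": 0.0, "infill": 0.0}
    pos: np.ndarray | None = None
    for layer in toolpath.layers:
        z = layer.z
        if not layer.polylines:
            ref = pos if pos is not None else np.zeros(2)
            moves.append(Move(float(ref[0]), float(ref[1]), z, e, feed_travel, True))
            continue
        for p in layer.polylines:
            start = p.points[0]
            if pos is None or not np.allclose(start, pos) or \
                    (moves and moves[-1].z != z):
                dist = 0.0 if pos is None else float(np.linalg.norm(start - pos))
                time_s += dist / settings.travel_speed
                moves.append(Move(float(start[0]), float(start[1]), z, e,
                                  feed_travel, True))
            for a, b in zip(p.points[:-1], p.points[1:]):
                seg = float(np.linalg.norm(b - a))
                if seg <= 0:
                    continue
                de = seg * p.width * h * flow
                e += de
                vol_by_role[p.role] += de
                time_s += seg / settings.speed
                moves.append(Move(float(b[0]), float(b[1]), z, e, feed_print, False))
            pos = p.points[-1]
    program = GCodeProgram(moves=moves, settings_header=settings.header())
    estimate = PrintEstimate(
        bioink_volume_ml=e / 1000.0,
        infill_volume_ml=vol_by_role["infill"] / 1000.0,
        perimeter_volume_ml=vol_by_role["perimeter"] / 1000.0,
        solid_volume_ml=vol_by_role["solid"] / 1000.0,
        print_time_s=time_s,
    )
    return program, estimate
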