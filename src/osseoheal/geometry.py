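"""Parametric implant profiles, layered bone domain, and quad meshing.

The model lives in the axisymmetric half-plane: ``x`` is the radial
coordinate (x >= 0, symmetry axis at x = 0) and ``y`` the axial coordinate.
The implant hangs from the top of a rectangular domain; a cortical stratum
caps the bone, a callus band of configurable width wraps the threaded part
of the implant, and the remainder is cancellous bone.

The implant outer boundary is described as a single-valued radius function
r(y), which lets the mesher produce a boundary-fitted tensor-product grid of
quadrilaterals: element faces coincide exactly with the implant profile and
with every region boundary, so per-region mesh areas match the region
polygons to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

__all__ = [
    "ChamberParams",
    "ImplantProfile",
    "DomainLayout",
    "Mesh",
    "build_chamber_profile",
    "build_domain",
    "generate_mesh",
    "rect_mesh",
    "catalog_implants",
    "ImplantSpec",
]

PROFILE_STYLES = ("v_thread", "trapezoid", "eagle_beak", "inverse_eagle_beak")

#: fraction of the nominal depth used for the shallow half of an
#: (inverse) eagle-beak chamber; the deep half uses the full depth.
EAGLE_SHALLOW_FRACTION = 0.6


@dataclass(frozen=True)
class ChamberParams:
    """Parametric description of one healing-chamber (thread) unit.

    Flank angles are measured between the flank orientation and the applied
    force direction (the implant axis): a *smaller* angle means a *steeper*
    flank.  ``depth_d`` is the radial depth of the chamber cut below the
    thread crest; ``root_length_r`` / ``crest_length_c`` are the axial
    lengths of the flat root and (minimum) crest land.
    """

    depth_d: float  # mm
    upper_flank_angle_phi: float  # degrees from the axial (force) direction
    lower_flank_angle: float  # degrees
    root_length_r: float  # mm
    crest_length_c: float  # mm
    pitch: float  # mm
    n_threads: int
    profile_style: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.depth_d < 0:
            raise ValueError("depth_d must be >= 0")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if self.n_threads < 1:
            raise ValueError("n_threads must be >= 1")
        if self.profile_style not in PROFILE_STYLES:
            raise ValueError(f"profile_style must be one of {PROFILE_STYLES}")
        for name in ("upper_flank_angle_phi", "lower_flank_angle"):
            ang = getattr(self, name)
            if not (0.0 < ang < 90.0):
                raise ValueError(f"{name} must lie in (0, 90) degrees, got {ang}")
        if self.root_length_r < 0 or self.crest_length_c < 0:
            raise ValueError("root/crest lengths must be >= 0")

    @property
    def flank_depths(self) -> tuple[float, float]:
        """(upper, lower) radial depths of the two flanks."""
        d = self.depth_d
        if self.profile_style == "eagle_beak":
            return EAGLE_SHALLOW_FRACTION * d, d
        if self.profile_style == "inverse_eagle_beak":
            return d, EAGLE_SHALLOW_FRACTION * d
        return d, d

    def axial_extents(self) -> tuple[float, float]:
        """Axial lengths of the upper and lower flanks."""
        du, dl = self.flank_depths
        dyu = du / math.tan(math.radians(self.upper_flank_angle_phi))
        dyl = dl / math.tan(math.radians(self.lower_flank_angle))
        return dyu, dyl

    def validate_closure(self) -> None:
        dyu, dyl = self.axial_extents()
        used = dyu + self.root_length_r + dyl + self.crest_length_c
        if used > self.pitch + 1e-12:
            raise ValueError(
                "chamber unit does not close within one pitch: flank extents "
                f"({dyu:.4g} + {dyl:.4g}) + root ({self.root_length_r:.4g}) + "
                f"crest ({self.crest_length_c:.4g}) = {used:.4g} > pitch {self.pitch:.4g}"
            )


@dataclass
class ImplantProfile:
    """Half-plane outline of the implant plus the r(y) radius function.

    ``segments`` lists (y_lo, y_hi, kind, r_lo, r_hi) pieces in ascending y;
    kinds are collar/crest/flank_upper/flank_lower/root/tip.  ``polyline``
    is the closed outer boundary (simple polygon, all radii >= 0).
    """

    polyline: np.ndarray  # (M, 2) closed outline, first point not repeated
    core_radius: float  # crest (outer) radius, mm
    length_total: float  # mm
    segments: list[tuple[float, float, str, float, float]]
    y_tip: float = 0.0  # axial coordinate of the implant tip
    chamber_spans: list[tuple[float, float]] = field(default_factory=list)

    @property
    def y_top(self) -> float:
        return self.y_tip + self.length_total

    def radius_at(self, y) -> np.ndarray:
        """Outer radius r(y); crest radius outside the threaded span."""
        ys = np.array([s[0] for s in self.segments] + [self.segments[-1][1]])
        rs = np.array([s[3] for s in self.segments] + [self.segments[-1][4]])
        return np.interp(np.asarray(y, dtype=float), ys, rs)

    def segment_kind(self, y: float) -> str:
        if y < self.y_tip - 1e-12:
            return "below_tip"
        for y_lo, y_hi, kind, _, _ in self.segments:
            if y_lo - 1e-12 <= y <= y_hi + 1e-12:
                return kind
        return "collar"

    def shifted(self, dy: float) -> "ImplantProfile":
        poly = self.polyline.copy()
        poly[:, 1] += dy
        segs = [(a + dy, b + dy, k, rl, rh) for a, b, k, rl, rh in self.segments]
        spans = [(a + dy, b + dy) for a, b in self.chamber_spans]
        return ImplantProfile(poly, self.core_radius, self.length_total, segs,
                              self.y_tip + dy, spans)

    def polygon(self) -> Polygon:
        return Polygon(self.polyline)

    def area(self) -> float:
        return self.polygon().area


def build_chamber_profile(params: ChamberParams, core_radius: float = 2.0,
                          collar_length: float = 1.0, tip_length: float = 0.5,
                          ) -> ImplantProfile:
    """Construct the implant outline with ``n_threads`` repeated chambers.

    The profile is built tip-down at y=0, collar at the top.  Eagle-beak
    chambers deepen the lower half of each chamber relative to the upper
    half; inverse eagle-beak the converse.
    """
    params.validate_closure()
    R = core_radius
    du, dl = params.flank_depths
    if max(du, dl) >= R:
        raise ValueError(
            f"depth_d {params.depth_d} does not leave a positive root radius "
            f"for core_radius {R}"
        )
    dyu, dyl = params.axial_extents()
    L = collar_length + params.n_threads * params.pitch + tip_length

    # segments in *descending* y, then reversed
    segs_desc: list[tuple[float, float, str, float, float]] = []
    y = L
    if collar_length > 0:
        segs_desc.append((y - collar_length, y, "collar", R, R))
        y -= collar_length
    spans = []
    for _ in range(params.n_threads):
        y0 = y
        if dyu > 0:
            segs_desc.append((y - dyu, y, "flank_upper", R - du, R))
            y -= dyu
        if params.root_length_r > 0:
            # a zero-depth "root" is just more crest land
            kind = "root" if params.depth_d > 0 else "crest"
            segs_desc.append((y - params.root_length_r, y, kind, R - dl, R - du))
            y -= params.root_length_r
        if dyl > 0:
            segs_desc.append((y - dyl, y, "flank_lower", R, R - dl))
            y -= dyl
        spans.append((y, y0))  # chamber cut span (flanks + root)
        crest = y0 - params.pitch
        if y - crest > 1e-12:
            segs_desc.append((crest, y, "crest", R, R))
            y = crest
    if tip_length > 0:
        segs_desc.append((0.0, y, "tip", R, R))

    segments = list(reversed(segs_desc))

    # outer-boundary vertices top -> bottom
    pts: list[tuple[float, float]] = [(0.0, L), (R, L)]
    for y_lo, y_hi, kind, r_lo, r_hi in segs_desc:
        pts.append((r_lo, y_lo))
    pts.append((0.0, 0.0))

    poly = _clean_polyline(np.array(pts, dtype=float))
    profile = ImplantProfile(poly, R, L, segments, 0.0,
                             spans if params.depth_d > 0 else [])
    if not profile.polygon().is_valid or not profile.polygon().is_simple:
        raise ValueError("generated profile polyline self-intersects")
    if np.any(poly[:, 0] < -1e-12):
        raise ValueError("profile has negative radial coordinates")
    return profile


def _clean_polyline(pts: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates and merge exactly collinear runs."""
    keep = [pts[0]]
    for p in pts[1:]:
        if not np.allclose(p, keep[-1], atol=1e-12):
            keep.append(p)
    if np.allclose(keep[-1], keep[0], atol=1e-12):
        keep.pop()
    out = []
    m = len(keep)
    for i in range(m):
        a, b, c = keep[i - 1], keep[i], keep[(i + 1) % m]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) > 1e-12:
            out.append(b)
    return np.array(out)


@dataclass
class DomainLayout:
    """Region polygons and named boundaries of the axisymmetric model."""

    regions: dict[str, Polygon]
    boundaries: dict[str, list[tuple[tuple[float, float], tuple[float, float]]]]
    profile: ImplantProfile  # shifted into domain coordinates
    extent: tuple[float, float]  # (R_dom, H_dom)
    r_callus: float
    y_callus_bottom: float
    cortical_thickness: float


def build_domain(profile: ImplantProfile, cortical_thickness: float = 1.5,
                 callus_margin: float = 0.5,
                 domain_extent: tuple[float, float] = (6.0, 14.0)) -> DomainLayout:
    """Assemble implant / callus / cortical / cancellous region polygons.

    The callus is the lateral band of width ``callus_margin`` beyond the
    thread crest, wrapping the implant flanks down to the tip level (the
    tip itself seats on host bone, as in a drilled osteotomy); the
    cells-origin boundary is the callus outer edge facing the host bone.
    """
    if callus_margin <= 0:
        raise ValueError("callus_margin must be > 0")
    R_dom, H_dom = domain_extent
    prof = profile.shifted(H_dom - profile.length_total - profile.y_tip)
    R = prof.core_radius
    r_cal = R + callus_margin
    y_cb = prof.y_tip
    if r_cal >= R_dom or y_cb <= 0:
        raise ValueError(
            "callus band extends outside the domain: need "
            f"r_callus {r_cal} < {R_dom} and implant tip above the base "
            f"(y_tip = {y_cb})"
        )
    implant = prof.polygon()
    callus_box = box(0.0, y_cb, r_cal, H_dom)
    callus = callus_box.difference(implant)
    regions = {"implant": implant, "callus": callus}
    t = cortical_thickness
    if t > 0:
        cortical = box(0.0, H_dom - t, R_dom, H_dom).difference(callus_box)
        if cortical.area > 1e-12:
            regions["cortical"] = cortical
    whole = box(0.0, 0.0, R_dom, H_dom)
    cancellous = whole.difference(implant).difference(callus_box)
    if t > 0:
        cancellous = cancellous.difference(regions.get("cortical", Polygon()))
    regions["cancellous"] = cancellous

    r_top = float(prof.radius_at(H_dom))
    boundaries = {
        "axis": [((0.0, 0.0), (0.0, H_dom))],
        "load_surface": [((0.0, H_dom), (r_top, H_dom))],
        "fixed_base": [((0.0, 0.0), (R_dom, 0.0))],
        "cells_origin": [((r_cal, y_cb), (r_cal, H_dom)),
                         ((R, y_cb), (r_cal, y_cb))],
        "implant_callus_interface": [
            ((prof.polyline[i][0], prof.polyline[i][1]),
             (prof.polyline[(i + 1) % len(prof.polyline)][0],
              prof.polyline[(i + 1) % len(prof.polyline)][1]))
            for i in range(len(prof.polyline))
        ],
    }
    return DomainLayout(regions, boundaries, prof, (R_dom, H_dom), r_cal, y_cb, t)


@dataclass
class Mesh:
    """Quadrilateral mesh with region tags and named boundary sets."""

    node_coords: np.ndarray  # (N, 2) mm
    elements: np.ndarray  # (E, 4) CCW connectivity
    element_region: np.ndarray  # (E,) region tag strings
    boundary_sets: dict[str, np.ndarray]  # name -> node indices
    edge_sets: dict[str, np.ndarray]  # name -> (K, 2) node-index pairs
    element_size_target: float = 0.05

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_corner_coords(self) -> np.ndarray:
        return self.node_coords[self.elements]  # (E, 4, 2)

    def element_centroids(self) -> np.ndarray:
        return self.element_corner_coords().mean(axis=1)

    def element_areas(self) -> np.ndarray:
        c = self.element_corner_coords()
        x, y = c[..., 0], c[..., 1]
        xr, yr = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.abs(np.sum(x * yr - xr * y, axis=1))

    def min_jacobian(self) -> float:
        """Smallest bilinear-map Jacobian over the 2x2 Gauss points."""
        from .fem import GAUSS_POINTS, shape_gradients

        c = self.element_corner_coords()
        best = np.inf
        for xi, eta in GAUSS_POINTS:
            dN = shape_gradients(xi, eta)
            J = np.einsum("eai,aj->eij", c, dN)
            det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            best = min(best, det.min())
        return float(best)

    def edge_lengths(self) -> np.ndarray:
        c = self.element_corner_coords()
        d = np.roll(c, -1, axis=1) - c
        return np.linalg.norm(d, axis=2).ravel()

    def elements_in_region(self, name: str) -> np.ndarray:
        return np.nonzero(self.element_region == name)[0]


def rect_mesh(width: float, height: float, element_size: float,
              region: str = "callus", origin: tuple[float, float] = (0.0, 0.0),
              nx: int | None = None, ny: int | None = None) -> Mesh:
    """Structured rectangle mesh (the mesher's structured fallback path)."""
    x0, y0 = origin
    nx = nx or max(1, round(width / element_size))
    ny = ny or max(1, round(height / element_size))
    xs = x0 + np.linspace(0.0, width, nx + 1)
    ys = y0 + np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    coords = np.column_stack([X.ravel(), Y.ravel()])
    elems = []
    for j in range(ny):
        for i in range(nx):
            n0 = j * (nx + 1) + i
            elems.append([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    elements = np.array(elems, dtype=int)
    tol = 1e-9 * max(width, height, 1.0)
    bsets = {
        "left": np.nonzero(np.abs(coords[:, 0] - x0) < tol)[0],
        "right": np.nonzero(np.abs(coords[:, 0] - (x0 + width)) < tol)[0],
        "bottom": np.nonzero(np.abs(coords[:, 1] - y0) < tol)[0],
        "top": np.nonzero(np.abs(coords[:, 1] - (y0 + height)) < tol)[0],
    }
    return Mesh(coords, elements, np.full(len(elements), region, dtype="<U16"),
                bsets, {}, element_size)


def generate_mesh(layout: DomainLayout, element_size: float = 0.05,
                  implant_element_factor: float = 1.0,
                  far_field_growth: float = 1.0) -> Mesh:
    """Boundary-fitted tensor-product quad mesh of the full domain.

    Horizontal grid lines are snapped to every profile breakpoint and region
    boundary; the radial coordinates of each row are mapped so that element
    columns follow the implant profile exactly.  ``implant_element_factor``
    coarsens the (stiff, nearly rigid) implant interior;
    ``far_field_growth`` > 1 grades the host-bone region away from the
    callus geometrically while the callus band keeps the target size.
    """
    if element_size <= 0:
        raise ValueError("element_size must be > 0")
    h = element_size
    prof = layout.profile
    R_dom, H_dom = layout.extent
    R = prof.core_radius
    r_cal, y_cb = layout.r_callus, layout.y_callus_bottom
    t_cor = layout.cortical_thickness

    # --- horizontal grid lines -------------------------------------------
    breaks = {0.0, H_dom, y_cb, prof.y_tip}
    if t_cor > 0:
        breaks.add(H_dom - t_cor)
    for y_lo, y_hi, _, _, _ in prof.segments:
        breaks.update((y_lo, y_hi))
    fine = sorted(b for b in breaks if y_cb - 1e-12 <= b <= H_dom + 1e-12)
    ylines_fine = _fill_lines(fine, h)
    below = _graded_steps(y_cb, h, far_field_growth)
    ylines = np.concatenate([y_cb - below[::-1], ylines_fine])

    # --- radial column template ------------------------------------------
    depth_max = max((R - min(s[3], s[4]) for s in prof.segments), default=0.0)
    n_in = max(2, round(R / (h * implant_element_factor)))
    n_cal = max(2, round((r_cal - R + 0.5 * depth_max) / h))
    s_in = np.linspace(0.0, 1.0, n_in + 1)
    s_cal = np.linspace(0.0, 1.0, n_cal + 1)[1:]
    out_steps = _graded_steps(R_dom - r_cal, h, far_field_growth)
    s_out = out_steps / (R_dom - r_cal)

    rv = np.where(ylines >= prof.y_tip - 1e-12, prof.radius_at(ylines), R)
    ncols = n_in + n_cal + len(s_out) + 1
    nrows = len(ylines)
    coords = np.empty((nrows * ncols, 2))
    for j, y in enumerate(ylines):
        xs = np.concatenate([
            s_in * rv[j],
            rv[j] + s_cal * (r_cal - rv[j]),
            r_cal + s_out * (R_dom - r_cal),
        ])
        base = j * ncols
        coords[base:base + ncols, 0] = xs
        coords[base:base + ncols, 1] = y

    elems = np.empty(((nrows - 1) * (ncols - 1), 4), dtype=int)
    k = 0
    for j in range(nrows - 1):
        for i in range(ncols - 1):
            n0 = j * ncols + i
            elems[k] = (n0, n0 + 1, n0 + ncols + 1, n0 + ncols)
            k += 1

    # --- region tags by centroid containment ------------------------------
    cent = coords[elems].mean(axis=1)
    xc, yc = cent[:, 0], cent[:, 1]
    region = np.full(len(elems), "cancellous", dtype="<U16")
    in_implant = (yc > prof.y_tip) & (xc < prof.radius_at(yc) - 1e-12)
    in_callus = ~in_implant & (xc < r_cal) & (yc > y_cb)
    region[in_callus] = "callus"
    if t_cor > 0:
        in_cort = ~in_implant & ~in_callus & (yc > H_dom - t_cor)
        region[in_cort] = "cortical"
    region[in_implant] = "implant"

    mesh = Mesh(coords, elems, region, {}, {}, h)
    if mesh.min_jacobian() <= 0:
        raise RuntimeError("mesher produced non-positive Jacobian elements")

    # --- boundary node sets ----------------------------------------------
    tol = 1e-9 * max(R_dom, H_dom)
    x, y = coords[:, 0], coords[:, 1]
    axis = np.nonzero(np.abs(x) < tol)[0]
    base_nodes = np.nonzero(np.abs(y) < tol)[0]
    top = np.abs(y - H_dom) < tol
    r_top = float(prof.radius_at(H_dom))
    load_surface = np.nonzero(top & (x < r_top + tol))[0]
    cells_origin = np.nonzero(
        ((np.abs(x - r_cal) < tol) & (y > y_cb - tol))
        | ((np.abs(y - y_cb) < tol) & (x > R - tol) & (x < r_cal + tol))
    )[0]
    drained = np.nonzero(
        (np.abs(x - R_dom) < tol) | (np.abs(y) < tol) | (top & (x > r_top - tol))
    )[0]
    mesh.boundary_sets = {
        "axis": axis,
        "fixed_base": base_nodes,
        "load_surface": load_surface,
        "cells_origin": cells_origin,
        "drained": drained,
    }
    mesh.edge_sets = {"implant_callus_interface": _interface_edges(mesh)}
    return mesh


def _graded_steps(total: float, h: float, growth: float) -> np.ndarray:
    """Cumulative node offsets covering ``total`` starting at size h."""
    if total <= 1e-12:
        return np.zeros(0)
    if growth <= 1.0 + 1e-9:
        n = max(2, round(total / h))
        return np.linspace(0.0, total, n + 1)[1:]
    steps = []
    size, pos = h, 0.0
    while pos + size < total:
        pos += size
        steps.append(pos)
        size *= growth
    return np.array(steps + [total])


def _fill_lines(breaks: list[float], h: float) -> np.ndarray:
    out = [breaks[0]]
    for a, b in zip(breaks, breaks[1:]):
        gap = b - a
        if gap < 1e-12:
            continue
        n = max(1, round(gap / h))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.array(out)


def _interface_edges(mesh: Mesh) -> np.ndarray:
    """Element edges shared between implant and non-implant elements."""
    edge_owner: dict[tuple[int, int], list[int]] = {}
    for e, conn in enumerate(mesh.elements):
        for i in range(4):
            a, b = int(conn[i]), int(conn[(i + 1) % 4])
            edge_owner.setdefault((min(a, b), max(a, b)), []).append(e)
    out = []
    for (a, b), owners in edge_owner.items():
        if len(owners) == 2:
            tags = {mesh.element_region[o] for o in owners}
            if "implant" in tags and len(tags) > 1:
                out.append((a, b))
    return np.array(sorted(out), dtype=int).reshape(-1, 2)


@dataclass(frozen=True)
class ImplantSpec:
    """Catalog entry: chamber parameters plus body/domain dimensions."""

    params: ChamberParams
    core_radius: float = 2.0
    collar_length: float = 1.2
    tip_length: float = 0.8
    cortical_thickness: float = 1.5
    callus_margin: float = 0.5
    domain_extent: tuple[float, float] = (6.0, 14.0)

    def profile(self) -> ImplantProfile:
        return build_chamber_profile(self.params, self.core_radius,
                                     self.collar_length, self.tip_length)

    def layout(self) -> DomainLayout:
        return build_domain(self.profile(), self.cortical_thickness,
                            self.callus_margin, self.domain_extent)


def catalog_implants() -> dict[str, ImplantSpec]:
    """Eight labelled healing-chamber designs A-H.

    Absolute dimensions are documented approximations (4 mm diameter, 10 mm
    length, 0.8 mm pitch); the designs encode the published ordering
    relations: upper-flank angle A > E > F (F steepest), root/crest length
    B < G, chamber depth C < H, D an eagle-beak modification of C and H its
    inverse (deep upper half).
    """

    def cp(d, phi_u, phi_l, r, c, style="trapezoid"):
        return ChamberParams(depth_d=d, upper_flank_angle_phi=phi_u,
                             lower_flank_angle=phi_l, root_length_r=r,
                             crest_length_c=c, pitch=0.8, n_threads=10,
                             profile_style=style)

    return {
        "A": ImplantSpec(cp(0.40, 75.0, 75.0, 0.05, 0.05)),
        "B": ImplantSpec(cp(0.45, 70.0, 70.0, 0.05, 0.05)),
        "C": ImplantSpec(cp(0.15, 60.0, 60.0, 0.05, 0.05)),
        "D": ImplantSpec(cp(0.30, 60.0, 60.0, 0.05, 0.05, "eagle_beak")),
        "E": ImplantSpec(cp(0.40, 60.0, 60.0, 0.05, 0.05)),
        "F": ImplantSpec(cp(0.40, 45.0, 60.0, 0.05, 0.05)),
        "G": ImplantSpec(cp(0.45, 70.0, 70.0, 0.20, 0.20)),
        "H": ImplantSpec(cp(0.30, 60.0, 60.0, 0.05, 0.05, "inverse_eagle_beak")),
    }


def analog_implants(n_threads: int = 3) -> dict[str, ImplantSpec]:
    """Scaled-down analogs of the catalog designs for regression studies.

    Same chamber parameters per label, fewer threads, a 2 mm-diameter body
    and a compact bone section, so design comparisons (flank slope, root
    and crest length, chamber depth) run at identical mesh density in
    seconds rather than hours.
    """
    import dataclasses

    out = {}
    for label, spec in catalog_implants().items():
        params = dataclasses.replace(spec.params, n_threads=n_threads)
        out[label] = ImplantSpec(params, core_radius=1.0, collar_length=0.8,
                                 tip_length=1.0, cortical_thickness=0.8,
                                 callus_margin=0.5, domain_extent=(2.8, 5.0))
    return out
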