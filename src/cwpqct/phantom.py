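"""Synthetic CT phantoms: airway tube trees, vessel trees and HU mixtures.

A phantom is built from analytic tube segments (known centerline, inner
radius and wall thickness), rasterized onto a voxel grid, so every
downstream measurement (skeleton topology, cross-section geometry, HU
class fractions, vessel CSA binning) can be checked against ground truth.

Conventions: mm coordinates with the voxel center of index ``i`` at
``(i + 0.5) * spacing``; x = patient-left, y = anterior, z = superior.
The airway mask stored on the output is lumen plus wall (the full tube),
the ground-truth label grid distinguishes lumen (1), wall (2), vessel (3)
and parenchymal class ``10 + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import (
    LABEL_LUMEN,
    LABEL_PARENCHYMA_BASE,
    LABEL_VESSEL,
    LABEL_WALL,
    VolumeGrid,
)

#: order of the five mutually exclusive parenchymal classes in label codes
PARENCHYMA_CLASSES = ("emphysema", "normal", "ggo", "semi_consolidation", "consolidation")

#: tissue HU levels: air lumen, soft-tissue wall, contrast-free vessel, and
#: parenchymal classes at (or near) their HU-interval midpoints
DEFAULT_HU = {
    "lumen": -1000.0,
    "wall": 0.0,
    "vessel": 100.0,
    "emphysema": -1000.0,
    "normal": -825.0,
    "ggo": -600.0,
    "semi_consolidation": -350.0,
    "consolidation": -70.0,
}

DEFAULT_NOISE_SD = 20.0


@dataclass(frozen=True)
class TubeSpec:
    """One straight tube segment of an airway or vessel tree.

    ``start`` is optional: branches with a parent begin at the parent's end
    point; a parentless branch without ``start`` begins at the default root
    position (top-center of the grid).
    """

    name: str
    parent: str | None
    direction: tuple[float, float, float]
    length: float          # mm
    r_in: float            # inner (lumen) radius, mm
    wall: float = 0.0      # wall thickness, mm (0 for vessels)
    start: tuple[float, float, float] | None = None

    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError(f"branch {self.name!r} has zero direction")
        return d / n


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.75, 0.75, 0.75)
    airway_branches: list[TubeSpec] = field(default_factory=list)
    vessel_branches: list[TubeSpec] = field(default_factory=list)
    mixture: dict[str, float] = field(
        default_factory=lambda: {"normal": 1.0})
    hu_levels: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd: float | dict[str, float] = DEFAULT_NOISE_SD
    seed: int = 0
    allow_overlap: bool = False
    lung_margin_vox: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for b in self.airway_branches + self.vessel_branches:
            if b.r_in <= 0:
                raise ValueError(f"branch {b.name!r} has nonpositive radius")
            if b.length <= 0:
                raise ValueError(f"branch {b.name!r} has nonpositive length")
            if b.wall < 0:
                raise ValueError(f"branch {b.name!r} has negative wall thickness")
        bad = set(self.mixture) - set(PARENCHYMA_CLASSES)
        if bad:
            raise ValueError(f"unknown parenchymal classes in mixture: {sorted(bad)}")
        fracs = np.array(list(self.mixture.values()), dtype=float)
        if (fracs < 0).any() or fracs.sum() > 1 + 1e-9:
            raise ValueError("mixture fractions must be nonnegative and sum to <= 1")

    def sd_for(self, tissue: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(tissue, DEFAULT_NOISE_SD))
        return float(self.noise_sd)


# --------------------------------------------------------------- geometry

def cone_directions(parent_dir, half_angle_deg: float, azimuths_deg,
                    ref=None) -> list[np.ndarray]:
    """Unit vectors at ``half_angle_deg`` from ``parent_dir``, one per azimuth.

    Used to build daughters with a known included angle: two azimuths 180
    degrees apart give an included angle of ``2 * half_angle_deg``; three
    azimuths 120 degrees apart give pairwise included angles of
    ``arccos(cos^2 a - sin^2 a / 2)``.
    """
    d = np.asarray(parent_dir, dtype=float)
    d = d / np.linalg.norm(d)
    if ref is None:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, d)) > 0.95:
            ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    a = np.deg2rad(half_angle_deg)
    out = []
    for az in np.atleast_1d(azimuths_deg):
        phi = np.deg2rad(az)
        w = np.cos(a) * d + np.sin(a) * (np.cos(phi) * u + np.sin(phi) * v)
        out.append(w / np.linalg.norm(w))
    return out


def resolve_endpoints(branches: list[TubeSpec], extent: np.ndarray,
                      default_root: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Start/end points (mm) for every branch; parents must precede children."""
    pts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for b in branches:
        if b.parent is None:
            p0 = np.asarray(b.start, dtype=float) if b.start is not None else default_root.copy()
        else:
            if b.parent not in pts:
                raise ValueError(f"branch {b.name!r} listed before its parent {b.parent!r}")
            p0 = pts[b.parent][1]
        p1 = p0 + b.unit_direction() * b.length
        pts[b.name] = (p0, p1)
    return pts


def _paint_tube(p0, p1, radius, spacing, shape):
    """Voxel indices within ``radius`` of segment p0-p1 and their distances.

    Flat-capped: only voxels whose axial projection falls inside [p0, p1]
    count, so an isolated tube has the exact analytic cylinder volume up
    to surface quantization.  Junction elbows are filled separately with
    joint balls.
    """
    spacing = np.asarray(spacing)
    lo = np.minimum(p0, p1) - radius - spacing
    hi = np.maximum(p0, p1) + radius + spacing
    i0 = np.maximum(np.floor(lo / spacing - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing - 0.5).astype(int) + 1, shape)
    if (i0 >= i1).any():
        return None, None
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(i0, i1)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    pts = (idx + 0.5) * spacing
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    t = ((pts - p0) @ seg) / seg_len2
    proj = p0 + np.clip(t, 0.0, 1.0)[:, None] * seg
    dist = np.linalg.norm(pts - proj, axis=1)
    keep = (dist < radius) & (t >= 0.0) & (t <= 1.0)
    return idx[keep], dist[keep]


def _paint_ball(center, radius, spacing, shape):
    """Voxel indices within ``radius`` of a point and their distances."""
    spacing = np.asarray(spacing)
    i0 = np.maximum(np.floor((center - radius) / spacing - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil((center + radius) / spacing - 0.5).astype(int) + 1, shape)
    if (i0 >= i1).any():
        return None, None
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(i0, i1)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.linalg.norm((idx + 0.5) * spacing - center, axis=1)
    keep = dist < radius
    return idx[keep], dist[keep]


def _exact_class_counts(mixture: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so class counts hit fractions exactly."""
    fracs = {c: mixture.get(c, 0.0) for c in PARENCHYMA_CLASSES}
    leftover = 1.0 - sum(fracs.values())
    if leftover > 1e-12:  # unassigned mass defaults to normal lung
        fracs["normal"] = fracs.get("normal", 0.0) + leftover
    raw = {c: f * n for c, f in fracs.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(PARENCHYMA_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_volume(spec: PhantomSpec) -> VolumeGrid:
    """Rasterize a phantom spec into a labelled HU volume.

    Deterministic for a fixed seed: the random stream is consumed in a
    documented order (1. parenchymal class placement permutation, 2. one
    Gaussian noise field for the whole grid).
    """
    spec.validate()
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = shape * spacing
    rng = np.random.default_rng(spec.seed)

    default_root = np.array([extent[0] / 2, extent[1] / 2, extent[2] - 2.0])
    airway_pts = resolve_endpoints(spec.airway_branches, extent, default_root)
    vessel_root = np.array([extent[0] / 2, extent[1] / 2, extent[2] - 2.0])
    vessel_pts = resolve_endpoints(spec.vessel_branches, extent, vessel_root)

    # bounds check, naming the offending branch: a flat-capped tube spans
    # only its perpendicular half-width along each axis; the joint ball at
    # a child's start needs the parent's full outer radius
    all_branches = {b.name: b for b in spec.airway_branches + spec.vessel_branches}
    for b in all_branches.values():
        pts = airway_pts.get(b.name) or vessel_pts.get(b.name)
        r_out = b.r_in + b.wall
        d = b.unit_direction()
        hw = r_out * np.sqrt(np.maximum(0.0, 1.0 - d**2))
        lo = np.minimum(*pts) - hw
        hi = np.maximum(*pts) + hw
        if b.parent is not None:
            pr = all_branches[b.parent]
            pr_out = pr.r_in + pr.wall
            lo = np.minimum(lo, pts[0] - pr_out)
            hi = np.maximum(hi, pts[0] + pr_out)
        if (lo < 0).any() or (hi > extent).any():
            raise ValueError(
                f"branch {b.name!r} extends outside the grid "
                f"(span {np.round(lo, 1).tolist()}..{np.round(hi, 1).tolist()} mm, "
                f"extent {np.round(extent, 1).tolist()} mm)")

    labels = np.zeros(tuple(shape), dtype=np.int16)
    lumen = np.zeros(tuple(shape), dtype=bool)
    wall = np.zeros(tuple(shape), dtype=bool)
    airway_by_name = {b.name: b for b in spec.airway_branches}
    for b in spec.airway_branches:
        p0, p1 = airway_pts[b.name]
        idx, dist = _paint_tube(p0, p1, b.r_in + b.wall, spacing, shape)
        if idx is None:
            continue
        inner = dist < b.r_in
        lumen[tuple(idx[inner].T)] = True
        wall[tuple(idx[~inner].T)] = True
        if b.parent is not None:
            # joint ball with the parent's radii fills the junction elbow
            par = airway_by_name[b.parent]
            idx, dist = _paint_ball(p0, par.r_in + par.wall, spacing, shape)
            if idx is not None:
                inner = dist < par.r_in
                lumen[tuple(idx[inner].T)] = True
                wall[tuple(idx[~inner].T)] = True
    wall &= ~lumen  # lumen wins at junction overlaps

    vessel = np.zeros(tuple(shape), dtype=bool)
    vessel_by_name = {b.name: b for b in spec.vessel_branches}
    for b in spec.vessel_branches:
        p0, p1 = vessel_pts[b.name]
        idx, dist = _paint_tube(p0, p1, b.r_in, spacing, shape)
        if idx is not None:
            vessel[tuple(idx.T)] = True
        if b.parent is not None:
            par = vessel_by_name[b.parent]
            idx, _ = _paint_ball(p0, par.r_in, spacing, shape)
            if idx is not None:
                vessel[tuple(idx.T)] = True
    overlap = vessel & (lumen | wall)
    if overlap.any():
        if not spec.allow_overlap:
            raise ValueError(
                f"airway and vessel tubes overlap on {int(overlap.sum())} voxels; "
                "set allow_overlap=True to let airways take precedence")
        vessel &= ~(lumen | wall)

    m = spec.lung_margin_vox
    lung = np.zeros(tuple(shape), dtype=bool)
    if m > 0:
        lung[m:-m, m:-m, m:-m] = True
    else:
        lung[:] = True

    paren = lung & ~lumen & ~wall & ~vessel
    paren_idx = np.flatnonzero(paren.ravel())
    counts = _exact_class_counts(spec.mixture, paren_idx.size)
    perm = rng.permutation(paren_idx.size)
    class_codes = np.empty(paren_idx.size, dtype=np.int16)
    pos = 0
    for k, cname in enumerate(PARENCHYMA_CLASSES):
        c = counts.get(cname, 0)
        class_codes[perm[pos:pos + c]] = LABEL_PARENCHYMA_BASE + k
        pos += c

    labels.ravel()[paren_idx] = class_codes
    labels[lumen] = LABEL_LUMEN
    labels[wall] = LABEL_WALL
    labels[vessel] = LABEL_VESSEL

    hu = np.full(tuple(shape), spec.hu_levels["normal"], dtype=np.float32)
    sd = np.zeros(tuple(shape), dtype=np.float32)
    for tissue, lab in (("lumen", LABEL_LUMEN), ("wall", LABEL_WALL), ("vessel", LABEL_VESSEL)):
        sel = labels == lab
        hu[sel] = spec.hu_levels[tissue]
        sd[sel] = spec.sd_for(tissue)
    for k, cname in enumerate(PARENCHYMA_CLASSES):
        sel = labels == LABEL_PARENCHYMA_BASE + k
        hu[sel] = spec.hu_levels[cname]
        sd[sel] = spec.sd_for(cname)
    if np.any(sd > 0):
        hu = hu + sd * rng.standard_normal(tuple(shape)).astype(np.float32)

    return VolumeGrid(
        hu=hu,
        spacing=tuple(spacing),
        lung_mask=lung,
        airway_mask=lumen | wall,
        vessel_mask=vessel,
        labels=labels,
        meta={
            "seed": spec.seed,
            "branch_endpoints_mm": {k: (tuple(v[0]), tuple(v[1]))
                                    for k, v in {**airway_pts, **vessel_pts}.items()},
            "n_airway_branches": len(spec.airway_branches),
        },
    )


# ----------------------------------------------------------------- presets

def cylinder_phantom(r_in: float = 4.0, wall: float = 1.0, length: float = 40.0,
                     spacing: float = 0.5, pad_mm: float = 8.0, seed: int = 0,
                     noise_sd: float = 0.0, direction=(0.0, 0.0, -1.0),
                     mixture: dict[str, float] | None = None) -> PhantomSpec:
    """A single straight airway tube, centered, along ``direction``."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    r_out = r_in + wall
    half = (length / 2) * np.abs(d) + r_out + pad_mm
    extent = 2 * half
    shape = tuple(int(np.ceil(e / spacing)) for e in extent)
    center = np.array(shape) * spacing / 2
    start = center - d * length / 2
    tube = TubeSpec("cyl", None, tuple(d), length, r_in, wall, start=tuple(start))
    return PhantomSpec(shape=shape, spacing=(spacing,) * 3,
                       airway_branches=[tube], seed=seed, noise_sd=noise_sd,
                       mixture=mixture or {"normal": 1.0})


def y_phantom(included_angle_deg: float = 70.0, r_parent: float = 2.5,
              r_daughter: float = 1.5, wall: float = 0.8,
              parent_len: float = 18.0, daughter_len: float = 24.0,
              spacing: float = 0.5, seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """A parent tube splitting into two daughters with a known included angle.

    Daughters are long and thin relative to the parent so their tubes
    separate quickly below the junction and the direction fit sees a long
    straight centerline segment.
    """
    half = included_angle_deg / 2.0
    parent_dir = (0.0, 0.0, -1.0)
    d1, d2 = cone_directions(parent_dir, half, [0.0, 180.0])
    margin = r_parent + wall + 6.0
    span = daughter_len * np.sin(np.deg2rad(half))
    extent = np.array([2 * (span + margin), 2 * (span + margin),
                       parent_len + daughter_len + 2 * margin])
    shape = tuple(int(np.ceil(e / spacing)) for e in extent)
    ext = np.array(shape) * spacing
    start = (ext[0] / 2, ext[1] / 2, ext[2] - margin)
    branches = [
        TubeSpec("parent", None, parent_dir, parent_len, r_parent, wall, start=start),
        TubeSpec("d1", "parent", tuple(d1), daughter_len, r_daughter, wall),
        TubeSpec("d2", "parent", tuple(d2), daughter_len, r_daughter, wall),
    ]
    return PhantomSpec(shape=shape, spacing=(spacing,) * 3,
                       airway_branches=branches, seed=seed, noise_sd=noise_sd)


def trifurcation_phantom(half_angle_deg: float = 35.0, r_parent: float = 2.5,
                         r_daughter: float = 1.5, wall: float = 0.8,
                         parent_len: float = 18.0, daughter_len: float = 24.0,
                         spacing: float = 0.5, seed: int = 0,
                         noise_sd: float = 0.0) -> PhantomSpec:
    """A parent tube splitting into three daughters on a 120-degree cone.

    The pairwise included angle of the daughters is
    ``arccos(cos^2 a - sin^2 a / 2)`` for half-angle ``a`` (59.57 degrees
    at the default 35).
    """
    parent_dir = (0.0, 0.0, -1.0)
    ds = cone_directions(parent_dir, half_angle_deg, [0.0, 120.0, 240.0])
    span = daughter_len * np.sin(np.deg2rad(half_angle_deg)) + 10.0
    ext = np.array([2 * span, 2 * span, parent_len + daughter_len + 16.0])
    shape = tuple(int(np.ceil(e / spacing)) for e in ext)
    extent = np.array(shape) * spacing
    branches = [TubeSpec("parent", None, parent_dir, parent_len, r_parent, wall,
                         start=(extent[0] / 2, extent[1] / 2, extent[2] - 8.0))]
    for i, d in enumerate(ds):
        branches.append(TubeSpec(f"d{i}", "parent", tuple(d), daughter_len,
                                 r_daughter, wall))
    return PhantomSpec(shape=shape, spacing=(spacing,) * 3,
                       airway_branches=branches, seed=seed, noise_sd=noise_sd)


def trifurcation_pairwise_angle(half_angle_deg: float) -> float:
    """Analytic pairwise included angle of a symmetric trifurcation."""
    a = np.deg2rad(half_angle_deg)
    return float(np.degrees(np.arccos(np.cos(a)**2 - 0.5 * np.sin(a)**2)))


def default_airway_tree() -> list[TubeSpec]:
    """The 26-branch bronchial tree preset.

    Trachea, left/right main bronchi, Bronint, the four lobar trifurcations
    (TriRUL, TriRLL, TriLUL, TriLLB) and 18 segmental branches grouped into
    the five lobe subgroups (sRUL x3, sRML x2, sRLL x5, sLUL x3, sLLL x5).
    Geometry is scaled to fit a 96 mm cube; radii taper from 4.5 mm
    (trachea) to ~1 mm (segmental airways).
    """

    def n(v):
        v = np.asarray(v, dtype=float)
        return tuple(v / np.linalg.norm(v))

    br: list[TubeSpec] = []
    add = br.append
    add(TubeSpec("Trachea", None, (0, 0, -1), 22.0, 4.5, 1.3))
    add(TubeSpec("RMB", "Trachea", n((-0.50, 0.05, -0.87)), 13.0, 3.2, 1.0))
    add(TubeSpec("LMB", "Trachea", n((0.64, 0.08, -0.77)), 18.0, 2.9, 1.0))
    # right upper lobe
    add(TubeSpec("TriRUL", "RMB", n((-0.75, 0.15, 0.64)), 9.0, 1.9, 0.8))
    for i, d in enumerate(cone_directions(n((-0.75, 0.15, 0.64)), 35.0, [0, 120, 240])):
        add(TubeSpec(f"sRUL_{i + 1}", "TriRUL", tuple(d), 7.0, 1.2, 0.7))
    # bronchus intermedius and its three daughters (two RML segmentals + TriRLL)
    add(TubeSpec("Bronint", "RMB", n((-0.12, -0.05, -0.99)), 12.0, 2.4, 0.9))
    add(TubeSpec("sRML_1", "Bronint", n((-0.30, 0.75, -0.59)), 8.0, 1.2, 0.7))
    add(TubeSpec("sRML_2", "Bronint", n((-0.70, 0.40, -0.59)), 8.0, 1.2, 0.7))
    add(TubeSpec("TriRLL", "Bronint", n((-0.15, -0.35, -0.92)), 8.0, 1.8, 0.8))
    rll = cone_directions(n((-0.15, -0.35, -0.92)), 35.0, [0, 120, 240])
    for i, d in enumerate(rll):
        add(TubeSpec(f"sRLL_{i + 1}", "TriRLL", tuple(d), 7.0, 1.2, 0.7))
    for i, d in enumerate(cone_directions(rll[1], 30.0, [90, 270])):
        add(TubeSpec(f"sRLL_{i + 4}", "sRLL_2", tuple(d), 6.0, 1.0, 0.6))
    # left upper lobe
    add(TubeSpec("TriLUL", "LMB", n((0.62, 0.20, 0.76)), 9.0, 1.9, 0.8))
    for i, d in enumerate(cone_directions(n((0.62, 0.20, 0.76)), 35.0, [0, 120, 240])):
        add(TubeSpec(f"sLUL_{i + 1}", "TriLUL", tuple(d), 7.0, 1.2, 0.7))
    # left lower lobe
    add(TubeSpec("TriLLB", "LMB", n((0.30, -0.25, -0.92)), 9.0, 2.0, 0.8))
    lll = cone_directions(n((0.30, -0.25, -0.92)), 35.0, [0, 120, 240])
    for i, d in enumerate(lll):
        add(TubeSpec(f"sLLL_{i + 1}", "TriLLB", tuple(d), 7.0, 1.2, 0.7))
    for i, d in enumerate(cone_directions(lll[1], 30.0, [90, 270])):
        add(TubeSpec(f"sLLL_{i + 4}", "sLLL_2", tuple(d), 6.0, 1.0, 0.6))
    return br


def truncate_tree(branches: list[TubeSpec], keep: set[str]) -> list[TubeSpec]:
    """Keep only branches whose full ancestor chain is inside ``keep``."""
    out, names = [], set()
    for b in branches:
        if b.name in keep and (b.parent is None or b.parent in names):
            out.append(b)
            names.add(b.name)
    return out


def rotate_tree(branches: list[TubeSpec], rotation: np.ndarray,
                root_start: tuple[float, float, float]) -> list[TubeSpec]:
    """Rigidly rotate every branch direction; the root is re-anchored."""
    out = []
    for b in branches:
        d = rotation @ b.unit_direction()
        start = root_start if b.parent is None else None
        out.append(replace(b, direction=tuple(d), start=start))
    return out


def mirror_tree_x(branches: list[TubeSpec]) -> list[TubeSpec]:
    """Flip the tree left-right (negate the x component of every direction)."""
    out = []
    for b in branches:
        d = b.unit_direction() * np.array([-1.0, 1.0, 1.0])
        start = b.start
        out.append(replace(b, direction=tuple(d), start=start))
    return out


def default_phantom_spec(seed: int = 0, noise_sd: float = 10.0,
                         spacing: float = 0.75,
                         shape: tuple[int, int, int] = (128, 128, 128)) -> PhantomSpec:
    """The standard unit-test phantom: full 26-branch tree, mild mixture."""
    return PhantomSpec(
        shape=shape,
        spacing=(spacing,) * 3,
        airway_branches=default_airway_tree(),
        mixture={"emphysema": 0.08, "normal": 0.78, "ggo": 0.04,
                 "semi_consolidation": 0.05, "consolidation": 0.05},
        seed=seed,
        noise_sd=noise_sd,
    )


def table1_phantom_spec(seed: int = 0, noise_sd: float = 10.0) -> PhantomSpec:
    """Thick-slice acquisition preset: 0.75 mm in-plane, 3 mm slices.

    Mirrors a 16-detector spiral protocol with 3 mm reconstructed slice
    thickness; volumes from this preset are resampled to isotropic spacing
    before geometry extraction.
    """
    spec = default_phantom_spec(seed=seed, noise_sd=noise_sd)
    spec.spacing = (0.75, 0.75, 3.0)
    spec.shape = (128, 128, 32)
    return spec


def random_vessel_tree(rng: np.random.Generator, extent_mm: float = 30.0,
                       n_branches: int = 5) -> list[TubeSpec]:
    """A random chained vessel tree for property tests, kept inside the grid.

    Candidate directions whose endpoint would leave the safe interior are
    re-aimed at the grid center, so the tubes never hit the bounds check.
    """
    branches: list[TubeSpec] = []
    center = np.full(3, extent_mm / 2)
    pos = np.array([extent_mm / 2, extent_mm / 2, extent_mm - 6.0])
    start = tuple(pos)
    parent = None
    margin = 4.0
    for i in range(n_branches):
        r = float(rng.uniform(0.4, 1.6))
        length = float(rng.uniform(3.0, 6.0))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        end = pos + d * length
        if (end < margin).any() or (end > extent_mm - margin).any():
            d = center - pos
            d /= np.linalg.norm(d)
            end = pos + d * length
        branches.append(TubeSpec(f"v{i}", parent, tuple(d), length, r,
                                 start=start if parent is None else None))
        parent = f"v{i}"
        pos = end
    return branches
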