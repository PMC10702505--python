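"""Anatomical branch labeling and airway structural variables.

Implements the four per-branch structural measures used to stage airway
involvement: the bifurcation angle theta (degrees, between daughter
directions), the hydraulic diameter D_h = 4A/Pe of the lumen, the mean
radial wall thickness WT, and the circularity Cr = 4*pi*A/Pe^2 (1 for a
circle).  Cross-sections are sampled on planes perpendicular to the local
centerline over the middle third of each branch, away from junction flare;
the lumen contour is found per radial ray at the -500 HU crossing of the
intensity profile and the outer wall contour at the half-maximum descent
of the wall peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VolumeGrid
from .skeleton import AirwayTree, Branch

#: the five lobe subgroups; member branches are labeled ``<subgroup>_<i>``
LOBE_SUBGROUPS = ("sRUL", "sRML", "sRLL", "sLUL", "sLLL")

#: branches for which theta, D_h, WT and Cr are all reported
NAMED_BRANCHES = ("Trachea", "LMB", "RMB", "Bronint",
                  "TriLUL", "TriLLB", "TriRUL", "TriRLL")


# ------------------------------------------------------------- angles

def bifurcation_angle(d1, d2) -> float:
    """Included angle (degrees) between two daughter direction vectors."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("bifurcation angle of a zero vector is undefined")
    c = np.clip(np.dot(a / na, b / nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def branch_theta(tree: AirwayTree, idx: int) -> float:
    """Theta of a branch: the included angle of its daughters.

    Two daughters give their included angle; three (a trifurcation) give
    the mean of the three pairwise angles.  Any other daughter count has
    no defined theta (NaN).
    """
    kids = tree.branches[idx].children
    if len(kids) not in (2, 3):
        return float("nan")
    dirs = [tree.branches[k].direction() for k in kids]
    pairs = [(i, j) for i in range(len(dirs)) for j in range(i + 1, len(dirs))]
    return float(np.mean([bifurcation_angle(dirs[i], dirs[j]) for i, j in pairs]))


# ------------------------------------------------------------- labeling

def _subtree_mean_x(tree: AirwayTree, idx: int) -> float:
    pts = np.vstack([tree.branches[i].points for i in tree.subtree(idx)])
    return float(pts[:, 0].mean())


def _dz(tree: AirwayTree, idx: int) -> float:
    return float(tree.branches[idx].direction()[2])


def _canon_order(tree: AirwayTree, ids: list[int]) -> list[int]:
    """Deterministic ordering of sibling branches by direction vector."""
    def keyf(i):
        d = tree.branches[i].direction()
        return (round(-d[2], 3), round(d[0], 3), round(d[1], 3))
    return sorted(ids, key=keyf)


def label_branches(tree: AirwayTree) -> AirwayTree:
    """Assign the 26-label anatomical scheme by generation and laterality.

    The root branch is the trachea; its daughters split into left and right
    main bronchi by the mean x (patient-left) of their subtrees.  On the
    right, the daughter heading superior is the upper-lobe trifurcation
    (TriRUL) and the inferior one the bronchus intermedius, whose most
    inferior daughter is TriRLL and remaining daughters the middle-lobe
    segmentals.  On the left, the superior daughter of the LMB is TriLUL
    and the inferior TriLLB.  All descendants of a lobar trifurcation get
    that lobe's subgroup label; anything unassignable is labeled
    ``unlabeled`` but never dropped.
    """
    for b in tree.branches:
        b.label = None
    br = tree.branches
    br[tree.root].label = "Trachea"
    kids = br[tree.root].children
    if len(kids) < 2:
        if len(kids) == 1:
            _mark_unlabeled(tree)
            raise ValueError("cannot orient the tree: trachea has a single "
                             "daughter (missing LMB or RMB)")
        for b in br:
            if b.label is None:
                b.label = "unlabeled"
        return tree
    if len(kids) > 2:
        raise ValueError(f"trachea has {len(kids)} daughters; expected LMB and RMB")

    a, b_ = kids
    lmb, rmb = (a, b_) if _subtree_mean_x(tree, a) > _subtree_mean_x(tree, b_) else (b_, a)
    br[lmb].label = "LMB"
    br[rmb].label = "RMB"

    def _canon_dfs(root_idx: int) -> list[int]:
        out = []
        stack = list(reversed(_canon_order(tree, br[root_idx].children)))
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(reversed(_canon_order(tree, br[i].children)))
        return out

    def label_subgroup(root_idx: int, prefix: str) -> None:
        for k, i in enumerate(_canon_dfs(root_idx), start=1):
            br[i].label = f"{prefix}_{k}"

    # right side
    rkids = br[rmb].children
    if len(rkids) == 2:
        up, down = sorted(rkids, key=lambda i: -_dz(tree, i))
        br[up].label = "TriRUL"
        br[down].label = "Bronint"
        label_subgroup(up, "sRUL")
        bkids = br[down].children
        if len(bkids) >= 2:
            tri_rll = min(bkids, key=lambda i: _dz(tree, i))
            br[tri_rll].label = "TriRLL"
            rml = _canon_order(tree, [i for i in bkids if i != tri_rll])
            for k, i in enumerate(rml, start=1):
                br[i].label = f"sRML_{k}"
            label_subgroup(tri_rll, "sRLL")
    # left side
    lkids = br[lmb].children
    if len(lkids) == 2:
        up, down = sorted(lkids, key=lambda i: -_dz(tree, i))
        br[up].label = "TriLUL"
        br[down].label = "TriLLB"
        label_subgroup(up, "sLUL")
        label_subgroup(down, "sLLL")

    for b in br:
        if b.label is None:
            b.label = "unlabeled"
    return tree


def _mark_unlabeled(tree: AirwayTree) -> None:
    for b in tree.branches:
        if b.label is None:
            b.label = "unlabeled"


# ------------------------------------------------------- cross-sections

@dataclass
class CrossSection:
    origin: np.ndarray          # mm
    normal: np.ndarray          # unit
    area: float                 # luminal area A, mm^2
    pe_in: float                # inner perimeter, mm
    pe_out: float               # outer perimeter, mm (NaN if incomplete)
    r_in: np.ndarray            # per-ray inner radius, mm
    r_out: np.ndarray           # per-ray outer radius, mm (NaN where invalid)

    def check(self) -> None:
        assert self.area > 0 and self.pe_in > 0
        assert self.pe_in**2 >= 4 * np.pi * self.area * (1 - 1e-9), \
            "isoperimetric bound violated"


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """D_h = 4A/Pe; equals the diameter for a circular section."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * area / perimeter


def circularity(area: float, perimeter: float) -> float:
    """Cr = 4*pi*A/Pe^2; 1 for a circle, < 1 for any other exact shape."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def wall_thickness(section: CrossSection, min_rays: int = 8) -> float:
    """Mean radial wall thickness over valid rays of one cross-section.

    Rays whose outer radius is missing or smaller than the inner radius are
    discarded; fewer than ``min_rays`` surviving rays is an error.
    """
    valid = np.isfinite(section.r_out) & (section.r_out >= section.r_in)
    if valid.sum() < min_rays:
        raise ValueError(
            f"only {int(valid.sum())} valid wall rays (need >= {min_rays})")
    return float(np.mean(section.r_out[valid] - section.r_in[valid]))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def _circular_smooth(r: np.ndarray) -> np.ndarray:
    """Light periodic smoothing of a radial contour (1/4, 1/2, 1/4 kernel).

    Suppresses the azimuthal partial-volume jitter of sub-voxel boundary
    estimates, which otherwise inflates the polygon perimeter and biases
    circularity low; the kernel is mean-preserving so radii are unbiased.
    """
    if not np.isfinite(r).all():
        return r
    return 0.25 * np.roll(r, 1) + 0.5 * r + 0.25 * np.roll(r, -1)


def _polygon_area_perimeter(radii: np.ndarray, angles: np.ndarray) -> tuple[float, float]:
    x = radii * np.cos(angles)
    y = radii * np.sin(angles)
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    per = float(np.sum(np.hypot(np.diff(np.append(x, x[0])),
                                np.diff(np.append(y, y[0])))))
    return float(area), per


def extract_cross_sections(volume: VolumeGrid, tree: AirwayTree, branch: int | Branch,
                           n_rays: int = 64, inner_hu: float = -500.0,
                           wall_search_mm: float = 5.0,
                           max_radius_mm: float = 20.0) -> list[CrossSection]:
    """Luminal/wall cross-sections over the middle third of a branch.

    Sections lie on planes perpendicular to the local centerline tangent,
    one per skeleton point in the middle third.  Sections whose rays leave
    the grid, or whose lumen contour is not closed (a ray never crosses
    ``inner_hu``), are skipped.
    """
    b = tree.branches[branch] if isinstance(branch, int) else branch
    pts = b.points
    if len(pts) < 3:
        raise ValueError("branch has fewer than 3 skeleton points")
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    mid = (s >= total / 3.0) & (s <= 2.0 * total / 3.0)
    if not mid.any():
        mid[len(pts) // 2] = True
    sp = np.asarray(volume.spacing)
    dt = 0.25 * float(sp.min())
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    extent = np.asarray(volume.shape) * sp

    sections: list[CrossSection] = []
    for i in np.flatnonzero(mid):
        lo, hi = max(i - 1, 0), min(i + 1, len(pts) - 1)
        normal = pts[hi] - pts[lo]
        nn = np.linalg.norm(normal)
        if nn == 0:
            continue
        normal = normal / nn
        # rays stop one voxel short of the grid boundary
        border = float(min(pts[i].min(), (extent - pts[i]).min()) - sp.max())
        t_max = min(max_radius_mm, border)
        if t_max < 4 * dt:
            continue  # plane effectively exits the grid
        t = np.arange(0.0, t_max, dt)
        sec = _measure_section(volume, pts[i], normal, t, angles, inner_hu,
                               wall_search_mm)
        if sec is not None:
            sections.append(sec)
    return sections


def _measure_section(volume: VolumeGrid, origin, normal, t, angles,
                     inner_hu, wall_search_mm) -> CrossSection | None:
    sp = np.asarray(volume.spacing)
    u, v = _plane_basis(normal)
    dirs = np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * v  # (K,3)
    # sample points: (K, T, 3)
    pos = origin + dirs[:, None, :] * t[None, :, None]
    ijk = pos / sp - 0.5
    if (ijk < 0).any() or (ijk >= (np.array(volume.shape) - 1)).any():
        return None  # plane exits the grid
    prof = ndimage.map_coordinates(volume.hu, ijk.reshape(-1, 3).T, order=1,
                                   mode="nearest").reshape(len(angles), len(t))
    if prof[:, 0].max() >= inner_hu:
        return None  # origin not inside an open lumen

    K = len(angles)
    r_in = np.full(K, np.nan)
    r_out = np.full(K, np.nan)
    dt = t[1] - t[0]
    for k in range(K):
        f = prof[k]
        above = np.flatnonzero(f >= inner_hu)
        if above.size == 0:
            return None  # lumen not closed along this ray
        j = above[0]
        # sub-sample linear interpolation of the -500 HU crossing
        f0, f1 = f[j - 1], f[j]
        frac = (inner_hu - f0) / (f1 - f0) if f1 != f0 else 0.0
        r_in[k] = t[j - 1] + frac * dt
        # wall peak and half-maximum descent
        j_hi = min(j + int(wall_search_mm / dt), len(t) - 1)
        if j_hi <= j:
            continue
        seg = f[j:j_hi + 1]
        pk = int(np.argmax(seg))
        f_pk = seg[pk]
        if f_pk < inner_hu:
            continue  # no wall contrast on this ray
        tail = f[j + pk:min(j + pk + int(wall_search_mm / dt), len(t))]
        f_bg = float(tail.min()) if tail.size else f_pk
        half = 0.5 * (f_pk + f_bg)
        after = f[j + pk:]
        below = np.flatnonzero(after <= half)
        if below.size == 0:
            continue
        m = below[0]
        if m == 0:
            r_out[k] = t[j + pk]
        else:
            g0, g1 = after[m - 1], after[m]
            frac = (half - g0) / (g1 - g0) if g1 != g0 else 0.0
            r_out[k] = t[j + pk + m - 1] + frac * dt

    r_in = _circular_smooth(r_in)
    r_out = _circular_smooth(r_out)
    area, pe_in = _polygon_area_perimeter(r_in, angles)
    if area <= 0:
        return None
    if np.isfinite(r_out).all():
        _, pe_out = _polygon_area_perimeter(r_out, angles)
    else:
        pe_out = float("nan")
    sec = CrossSection(origin=np.asarray(origin, dtype=float), normal=normal,
                       area=area, pe_in=pe_in, pe_out=pe_out,
                       r_in=r_in, r_out=r_out)
    sec.check()
    return sec


# ------------------------------------------------------------- metrics

@dataclass
class BranchGeometry:
    label: str
    theta_deg: float
    dh_mm: float
    wt_mm: float
    cr: float
    n_sections: int


def branch_metrics(volume: VolumeGrid, tree: AirwayTree,
                   n_rays: int = 64) -> pd.DataFrame:
    """Per-branch structural variables and lobe-subgroup aggregates.

    One row per branch (labeled or not) with the mean over its valid
    cross-sections of D_h, WT and Cr, plus theta where the branch has two
    or three daughters; additional rows aggregate each lobe subgroup by
    the mean of its member branches.  A branch with no valid section keeps
    its row with missing metrics, feeding the downstream imputation stage.
    """
    rows: list[BranchGeometry] = []
    per_branch: dict[int, BranchGeometry] = {}
    for i, b in enumerate(tree.branches):
        label = b.label or f"branch_{i}"
        theta = branch_theta(tree, i)
        try:
            secs = extract_cross_sections(volume, tree, i, n_rays=n_rays)
        except ValueError:
            secs = []
        if secs:
            dh = float(np.mean([hydraulic_diameter(s.area, s.pe_in) for s in secs]))
            cr = float(np.mean([circularity(s.area, s.pe_in) for s in secs]))
            wts = []
            for s in secs:
                try:
                    wts.append(wall_thickness(s))
                except ValueError:
                    pass
            wt = float(np.mean(wts)) if wts else float("nan")
        else:
            dh = cr = wt = float("nan")
        geo = BranchGeometry(label, theta, dh, wt, cr, len(secs))
        per_branch[i] = geo
        rows.append(geo)

    # lobe subgroup aggregates (D_h, WT, Cr only; theta is junction-specific)
    for sub in LOBE_SUBGROUPS:
        members = [per_branch[i] for i, b in enumerate(tree.branches)
                   if b.label and b.label.startswith(sub + "_")]
        if not members:
            continue
        rows.append(BranchGeometry(
            label=sub,
            theta_deg=float("nan"),
            dh_mm=float(np.nanmean([m.dh_mm for m in members]))
            if any(np.isfinite(m.dh_mm) for m in members) else float("nan"),
            wt_mm=float(np.nanmean([m.wt_mm for m in members]))
            if any(np.isfinite(m.wt_mm) for m in members) else float("nan"),
            cr=float(np.nanmean([m.cr for m in members]))
            if any(np.isfinite(m.cr) for m in members) else float("nan"),
            n_sections=int(sum(m.n_sections for m in members)),
        ))

    return pd.DataFrame([r.__dict__ for r in rows])
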