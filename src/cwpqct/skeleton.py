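"""1-D airway skeleton extraction and rooted-tree construction.

The centerline is extracted by medially-penalized geodesic path tracing:
Dijkstra runs over the mask voxel graph with edge costs discounted by the
distance-transform value (paths hug the medial axis), branch tips are
found iteratively as the unclaimed voxel farthest (in true geodesic
length) from the root, each tip's path back to the existing skeleton is
appended, and the tube around every traced path is claimed until the mask
is covered.  The resulting centerline voxels are connected into a graph
(26-neighbourhood, physical edge lengths), residual cycles are removed
with a minimum spanning tree, and the graph is rooted at the most
superior endpoint (the top of the trachea).  Maximal junction-to-junction
paths become branches; short terminal spurs are pruned against the local
tube radius, and junction nodes closer than the local radius are merged
so a trifurcation does not read as two stacked bifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra
from scipy.spatial import cKDTree

from .grid import VolumeGrid

_NEIGHBOURS = np.array([(i, j, k)
                        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                        if (i, j, k) != (0, 0, 0)])


@dataclass
class Branch:
    """A maximal centerline path between junctions (or junction and tip).

    ``points`` are mm coordinates ordered proximal to distal; the first
    point is the parent junction (shared with sibling branches).
    """

    points: np.ndarray
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    label: str | None = None
    mean_radius: float = 0.0   # mean inscribed radius along the branch, mm
    start_radius: float = 0.0  # inscribed radius at the parent junction, mm

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def direction(self, flare_exclude_mm: float | None = None) -> np.ndarray:
        """Unit direction, proximal to distal.

        Principal direction of the centerline points after dropping the
        junction-flare region (within 1.5 x the junction radius of the
        proximal end, where the centerline still curves into the parent)
        and the distal cap region (within one local radius of the tip).
        Falls back to less exclusion, then to the chord, when a short
        branch leaves too few points.
        """
        pts = self.points
        if flare_exclude_mm is None:
            flare_exclude_mm = 2.0 * (self.start_radius or self.mean_radius)
        d0 = np.linalg.norm(pts - pts[0], axis=1)
        d1 = np.linalg.norm(pts - pts[-1], axis=1)
        sel = (d0 >= flare_exclude_mm) & (d1 >= self.mean_radius)
        chord = pts[-1] - pts[0]
        if sel.sum() >= 4:
            kept = pts[sel]
            centered = kept - kept.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            v = vt[0]
            if np.dot(v, chord) < 0:
                v = -v
        else:
            # short branch: chord from the first junction-free point to the
            # tip — junction flare would rotate a PCA fit toward the parent
            past = np.flatnonzero(d0 >= min(flare_exclude_mm, d0[-1] / 2))
            v = pts[-1] - pts[past[0]] if len(past) and past[0] < len(pts) - 1 else chord
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("degenerate branch: zero direction")
        return v / n


@dataclass
class AirwayTree:
    branches: list[Branch]
    root: int
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def children_of(self, idx: int) -> list[int]:
        return self.branches[idx].children

    def subtree(self, idx: int) -> list[int]:
        out, stack = [], [idx]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.branches[i].children)
        return out

    def labels(self) -> dict[str, int]:
        return {b.label: i for i, b in enumerate(self.branches) if b.label}

    def check(self) -> None:
        roots = [i for i, b in enumerate(self.branches) if b.parent is None]
        assert roots == [self.root], "tree must have a single root"
        labs = [b.label for b in self.branches if b.label and b.label != "unlabeled"]
        assert len(labs) == len(set(labs)), "assigned labels must be unique"


def _mask_components(mask: np.ndarray) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    lab, n = ndimage.label(mask, structure=struct)
    if n > 1:
        sizes = sorted(np.bincount(lab.ravel())[1:], reverse=True)
        raise ValueError(
            f"airway mask has {n} connected components (sizes {sizes}); "
            "expected a single 6-connected component")
    return mask


def _voxel_graph(mask: np.ndarray, sp: np.ndarray, edt: np.ndarray):
    """26-connectivity sparse graphs over mask voxels.

    Returns (index array (n,3), physical-length graph, medially-penalized
    graph).  The penalized cost of stepping onto voxel v divides by its
    distance-transform value, so shortest paths run along the medial axis.
    """
    idx = np.argwhere(mask)
    n = len(idx)
    node = np.full(mask.shape, -1, dtype=np.int64)
    node[tuple(idx.T)] = np.arange(n)
    rows, cols, w_len, w_med = [], [], [], []
    eps = 0.25 * float(sp.min())
    r = edt[tuple(idx.T)]
    for off in _NEIGHBOURS:
        nb = idx + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        src = np.flatnonzero(ok)
        dst = node[tuple(nb[ok].T)]
        hit = dst >= 0
        src, dst = src[hit], dst[hit]
        if src.size == 0:
            continue
        d = float(np.linalg.norm(off * sp))
        rows.append(src)
        cols.append(dst)
        w_len.append(np.full(src.size, d))
        # centrality: cheap through the medial axis, dear near the surface
        w_med.append(d / (0.5 * (r[src] + r[dst]) + eps))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g_len = coo_matrix((np.concatenate(w_len), (rows, cols)), shape=(n, n)).tocsr()
    g_med = coo_matrix((np.concatenate(w_med), (rows, cols)), shape=(n, n)).tocsr()
    return idx, g_len, g_med


def centerline_mask(mask: np.ndarray, spacing, coverage_factor: float = 1.8,
                    max_paths: int = 2000) -> np.ndarray:
    """Boolean centerline of a (possibly multi-component) tubular mask.

    Each 26-connected component is traced independently (vessel masks are
    naturally split between the lungs); see :func:`_centerline_component`
    for the per-component algorithm.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(mask, structure=struct)
    if n <= 1:
        return _centerline_component(mask, spacing, coverage_factor, max_paths)
    out = np.zeros(mask.shape, dtype=bool)
    for k in range(1, n + 1):
        out |= _centerline_component(lab == k, spacing, coverage_factor, max_paths)
    return out


def _centerline_component(mask: np.ndarray, spacing, coverage_factor: float = 1.8,
                          max_paths: int = 2000) -> np.ndarray:
    """Centerline of one connected component by geodesic path tracing.

    The root is the most central voxel of the topmost occupied slice.
    Repeatedly, the unclaimed voxel with the largest true geodesic distance
    from the root seeds a path traced back (along medially-penalized
    shortest paths) until it meets the existing skeleton; the tube around
    the path — every voxel within ``coverage_factor`` x the local radius
    of its nearest path point — is claimed.  Terminates when the mask is
    covered.
    """
    sp = np.asarray(spacing, dtype=float)
    edt = ndimage.distance_transform_edt(mask, sampling=sp)
    idx, g_len, g_med = _voxel_graph(mask, sp, edt)
    n = len(idx)
    if n == 1:
        return mask.copy()
    r = edt[tuple(idx.T)]

    mm = idx * sp
    # root: superior AND medial — a pure topmost-voxel root would sit on
    # the cap surface and seed degenerate stubs along the cap face
    root = int(np.argmax(mm[:, 2] + 2.0 * r))

    d_med, pred = _dijkstra(g_med, directed=False, indices=root,
                            return_predecessors=True)
    d_len = _dijkstra(g_len, directed=False, indices=root)
    d_len[~np.isfinite(d_len)] = -np.inf  # unreachable: never chosen as a tip
    tip_score = d_len

    in_skel = np.zeros(n, dtype=bool)
    halo = np.zeros(n, dtype=bool)      # 26-neighbourhood of the skeleton
    claimed = np.zeros(n, dtype=bool)
    in_skel[root] = True
    indptr, indices = g_len.indptr, g_len.indices

    for _ in range(max_paths):
        if claimed.all():
            break
        tip = int(np.argmax(np.where(claimed, -np.inf, tip_score)))
        if not np.isfinite(tip_score[tip]):
            break
        # trace tip -> root; stop on reaching the skeleton or any voxel
        # adjacent to it (adjacency keeps the skeleton graph connected and
        # prevents near-parallel duplicate paths whose predecessor chains
        # would only merge near the root)
        path = [tip]
        cur = tip
        while not in_skel[cur] and not halo[cur]:
            cur = pred[cur]
            if cur < 0:
                break
            path.append(cur)
        path = np.array(path)
        in_skel[path] = True
        for v in path:
            halo[indices[indptr[v]:indptr[v + 1]]] = True
        # claim the tube around the new path; the effective radius at each
        # path point is propagated from nearby fat points, so end caps and
        # junction elbows (where the raw distance value collapses) are
        # still claimed and do not seed spurious tips
        r_path = r[path]
        r_eff = r_path.copy()
        pm = mm[path]
        for j in np.argsort(r_path)[::-1][:max(8, len(path) // 4)]:
            near = np.linalg.norm(pm - pm[j], axis=1) <= 1.5 * r_path[j]
            r_eff[near] = np.maximum(r_eff[near], r_path[j])
        unclaimed = np.flatnonzero(~claimed)
        tree = cKDTree(pm)
        dist, nearest = tree.query(mm[unclaimed], k=1)
        cover = dist <= coverage_factor * r_eff[nearest] + sp.max()
        claimed[unclaimed[cover]] = True
        claimed[path] = True

    out = np.zeros(mask.shape, dtype=bool)
    out[tuple(idx[in_skel].T)] = True
    return out


def skeletonize(airway: VolumeGrid | np.ndarray,
                spacing: tuple[float, float, float] | None = None,
                prune_factor: float = 2.0,
                merge_factor: float = 1.5) -> AirwayTree:
    """Extract the rooted centerline tree of an airway mask.

    Parameters
    ----------
    airway:
        A :class:`VolumeGrid` carrying ``airway_mask`` or a boolean array
        (then ``spacing`` is required).
    prune_factor:
        Terminal spurs shorter than ``prune_factor x`` the local inscribed
        radius are removed (thinning artefacts at tube ends/junctions).
    merge_factor:
        Internal junction-to-junction paths shorter than ``merge_factor x``
        the local radius are contracted into their parent, merging junction
        clusters produced by thinning at trifurcations.
    """
    if isinstance(airway, VolumeGrid):
        mask = airway.airway_mask
        if mask is None:
            raise ValueError("VolumeGrid has no airway mask")
        spacing = airway.spacing
    else:
        mask = np.asarray(airway, dtype=bool)
        if spacing is None:
            raise ValueError("spacing is required when passing a bare mask")
    if not mask.any():
        raise ValueError("airway mask is empty")
    _mask_components(mask)
    sp = np.asarray(spacing, dtype=float)
    return _component_tree(mask, sp, prune_factor, merge_factor)


def _component_tree(mask: np.ndarray, sp: np.ndarray,
                    prune_factor: float = 2.0,
                    merge_factor: float = 1.5) -> AirwayTree:
    """Rooted centerline tree of one connected tubular component."""
    skel = centerline_mask(mask, sp)
    edt = ndimage.distance_transform_edt(mask, sampling=sp)

    idx = np.argwhere(skel)
    key = {tuple(v): i for i, v in enumerate(idx)}
    g = nx.Graph()
    g.add_nodes_from(range(len(idx)))
    for off in _NEIGHBOURS:
        nb = idx + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        w = float(np.linalg.norm(off * sp))
        for a, b in zip(idx[ok], nb[ok]):
            j = key.get(tuple(b))
            if j is not None:
                g.add_edge(key[tuple(a)], j, weight=w)

    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) > 1:
        g = g.subgraph(comps[0]).copy()  # thinning crumbs; keep the main body
    tree_g = nx.minimum_spanning_tree(g, weight="weight")

    # root: most superior endpoint (degree 1), ties broken by centrality
    deg1 = [n for n in tree_g.nodes if tree_g.degree[n] == 1]
    if not deg1:
        deg1 = list(tree_g.nodes)
    root_node = max(deg1, key=lambda n: (idx[n][2], edt[tuple(idx[n])]))

    parent = {root_node: None}
    children: dict[int, list[int]] = {n: [] for n in tree_g.nodes}
    for u, v in nx.bfs_edges(tree_g, root_node):
        parent[v] = u
        children[u].append(v)

    mm = (idx + 0.5) * sp
    branches = _build_branches(root_node, children, mm, edt, idx, sp, mask)
    branches = _prune_and_merge(branches, prune_factor, merge_factor)

    root_idx = next(i for i, b in enumerate(branches) if b.parent is None)
    tree = AirwayTree(branches=branches, root=root_idx, spacing=tuple(sp),
                      meta={"n_skeleton_points": len(idx),
                            "n_cycle_edges_removed": g.number_of_edges() - tree_g.number_of_edges()})
    tree.check()
    return tree


def centerline_points(mask: np.ndarray, spacing):
    """Sub-voxel centerline of a tubular mask, with per-point arc lengths.

    Runs the full tree pipeline (path tracing, recentering, smoothing,
    spur pruning) on every 26-connected component and concatenates the
    branch chains; shared junction points are emitted once.  Returns
    ``(points, tangents, lengths, outward)`` where ``lengths`` is the
    centerline arc length owned by each point (half the distance to each
    chain neighbour) and ``outward`` is the outward unit tangent for free
    chain ends (rows of zeros elsewhere) — the tube overhangs its last
    centerline point there, which callers may account for.
    """
    mask = np.asarray(mask, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    struct = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(mask, structure=struct)
    pts, tans, lens, outs = [], [], [], []
    h = float(sp.min())
    for k in range(1, n + 1):
        comp = lab == k
        if comp.sum() < 3:
            p = (np.argwhere(comp) + 0.5) * sp
            pts.append(p)
            tans.append(np.tile([0.0, 0.0, 1.0], (len(p), 1)))
            lens.append(np.full(len(p), h))
            outs.append(np.zeros((len(p), 3)))
            continue
        tree = _component_tree(comp, sp)
        for b in tree.branches:
            bp = b.points
            seg = np.linalg.norm(np.diff(bp, axis=0), axis=1)
            own = np.empty(len(bp))
            own[0] = seg[0] / 2
            own[-1] = seg[-1] / 2
            if len(bp) > 2:
                own[1:-1] = (seg[:-1] + seg[1:]) / 2
            grad = np.gradient(bp, axis=0)
            norms = np.linalg.norm(grad, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            tan = grad / norms
            out = np.zeros((len(bp), 3))
            if b.parent is None:
                out[0] = -tan[0]          # free proximal end (tree root)
            if not b.children:
                out[-1] = tan[-1]         # free distal end (branch tip)
            s = 0 if b.parent is None else 1
            pts.append(bp[s:])
            tans.append(tan[s:])
            lens.append(np.maximum(own[s:], 0.25 * h))
            outs.append(out[s:])
    return np.vstack(pts), np.vstack(tans), np.concatenate(lens), np.vstack(outs)


def _recenter_disc(chain_mm: np.ndarray, radii: np.ndarray,
                   mask_tree: "cKDTree", mask_mm: np.ndarray,
                   sp: np.ndarray) -> np.ndarray:
    """Sub-voxel recentering of a centerline chain onto the tube axis.

    Each point moves to the centroid of the in-mask voxels inside its
    perpendicular disc slab (radius = local inscribed radius, thickness
    about one voxel).  The voxelized lumen disc is symmetric about the
    true axis, so the centroid removes the half-voxel jogs a discrete
    path must make when the axis runs between voxel columns.
    """
    n = len(chain_mm)
    if n < 3:
        return chain_mm.copy()
    out = chain_mm.copy()
    h = float(sp.max())
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        t = chain_mm[hi] - chain_mm[lo]
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t /= norm
        # capture must exceed the tube radius from an off-center point, or
        # the captured disc is symmetric about the point instead of the axis
        R = max(float(radii[i]) + 2.0 * h, 2.0 * float(sp.min()))
        cand = mask_tree.query_ball_point(chain_mm[i], r=R + h)
        if not cand:
            continue
        rel = mask_mm[cand] - chain_mm[i]
        axial = rel @ t
        in_disc = (np.abs(axial) <= 0.75 * h) & \
                  (np.linalg.norm(rel - np.outer(axial, t), axis=1) <= R)
        if in_disc.sum() >= 3:
            out[i] = mask_mm[cand][in_disc].mean(axis=0)
    return out


def smooth_chain(points: np.ndarray, window: int = 5, passes: int = 2) -> np.ndarray:
    """Moving-average smoothing of an ordered point chain, endpoints fixed.

    The traced centerline wanders within the half-voxel-wide medial
    plateau; smoothing removes that jitter so directions and tangents are
    stable, without moving the junction endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3 or window < 3:
        return pts
    half = window // 2
    for _ in range(passes):
        out = pts.copy()
        for i in range(1, len(pts) - 1):
            lo, hi = max(0, i - half), min(len(pts), i + half + 1)
            out[i] = pts[lo:hi].mean(axis=0)
        pts = out
    return pts


def _build_branches(root_node, children, mm, edt, idx, sp, mask) -> list[Branch]:
    mask_mm = (np.argwhere(mask) + 0.5) * sp
    mask_tree = cKDTree(mask_mm)
    branches: list[Branch] = []
    stack: list[tuple[int, int | None]] = [(root_node, None)]
    while stack:
        start, pb = stack.pop()
        for child in children[start]:
            chain = [start, child]
            cur = child
            while len(children[cur]) == 1:
                cur = children[cur][0]
                chain.append(cur)
            bi = len(branches)
            radii = edt[tuple(idx[chain].T)]
            pts = _recenter_disc(mm[chain], radii, mask_tree, mask_mm, sp)
            branches.append(Branch(points=smooth_chain(pts), parent=pb,
                                   mean_radius=float(radii.mean()),
                                   start_radius=float(radii[0])))
            if pb is not None:
                branches[pb].children.append(bi)
            stack.append((cur, bi))
    return branches


def _prune_and_merge(branches: list[Branch], prune_factor: float,
                     merge_factor: float) -> list[Branch]:
    """Iteratively drop short terminal spurs and contract junction clusters."""
    alive = {i for i in range(len(branches))}
    n_root = sum(1 for b in branches if b.parent is None)

    def _remove(i: int) -> None:
        alive.discard(i)
        p = branches[i].parent
        if p is not None:
            branches[p].children.remove(i)

    changed = True
    while changed:
        changed = False
        # terminal spur pruning (never remove the only branch)
        for i in sorted(alive):
            if i not in alive:
                continue
            b = branches[i]
            if b.children or b.parent is None or len(alive) <= 1:
                continue
            # the local tube radius at the attachment governs spur scale;
            # the parent's mean radius covers attachments on end caps where
            # the junction-voxel distance value is unrepresentatively small
            local_r = max(b.mean_radius, b.start_radius,
                          0.8 * branches[b.parent].mean_radius)
            if b.length < prune_factor * local_r:
                _remove(i)
                changed = True
        # pass-through merge: a branch with exactly one child is one branch
        for i in sorted(alive):
            if i not in alive:
                continue
            b = branches[i]
            while len(b.children) == 1:
                c = b.children[0]
                cb = branches[c]
                n0, n1 = len(b.points), len(cb.points)
                b.mean_radius = (b.mean_radius * n0 + cb.mean_radius * n1) / (n0 + n1)
                b.points = np.vstack([b.points, cb.points[1:]])
                b.children = cb.children
                for gc in cb.children:
                    branches[gc].parent = i
                alive.discard(c)
                changed = True
        # junction-cluster contraction: short internal branch folds into parent
        for i in sorted(alive):
            if i not in alive:
                continue
            b = branches[i]
            if b.parent is None or not b.children:
                continue
            if len(b.children) >= 2 and \
                    b.length < merge_factor * max(b.mean_radius, b.start_radius):
                p = b.parent
                pb = branches[p]
                pb.points = np.vstack([pb.points, b.points[1:]])
                pb.children.remove(i)
                pb.children.extend(b.children)
                for c in b.children:
                    branches[c].parent = p
                alive.discard(i)
                changed = True

    old_to_new = {old: new for new, old in enumerate(sorted(alive))}
    out = []
    for old in sorted(alive):
        b = branches[old]
        out.append(Branch(
            points=b.points,
            parent=None if b.parent is None else old_to_new[b.parent],
            children=[old_to_new[c] for c in b.children],
            label=b.label,
            mean_radius=b.mean_radius,
            start_radius=b.start_radius,
        ))
    return out
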