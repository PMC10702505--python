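"""Airway structural variables: angles, D_h, WT, Cr, labeling, metrics."""


import numpy as np
import pytest
from scipy.special import ellipe

from cwpqct import (
    bifurcation_angle,
    branch_metrics,
    circularity,
    cylinder_phantom,
    extract_cross_sections,
    generate_volume,
    hydraulic_diameter,
    label_branches,
    skeletonize,
    wall_thickness,
)
from cwpqct.airway import CrossSection, branch_theta
from cwpqct.phantom import (
    default_airway_tree,
    mirror_tree_x,
    trifurcation_pairwise_angle,
    trifurcation_phantom,
    truncate_tree,
)
from cwpqct.phantom import PhantomSpec
from cwpqct.skeleton import AirwayTree, Branch


# ---------------------------------------------------------- pure formulas

@pytest.mark.parametrize("d1, d2, expected", [
    ((1, 0, 0), (0, 1, 0), 90.0),
    ((1, 0, 0), (1 / np.sqrt(2), 1 / np.sqrt(2), 0), 45.0),
    ((0, 0, 1), (0, 0, -1), 180.0),
    ((0, 0, 1), (0, 0, 1), 0.0),
])
def test_bifurcation_angle_closed_forms(d1, d2, expected):
    assert bifurcation_angle(d1, d2) == pytest.approx(expected, abs=1e-9)


def test_bifurcation_angle_zero_vector_rejected():
    with pytest.raises(ValueError):
        bifurcation_angle((0, 0, 0), (1, 0, 0))


def _ellipse_area_perimeter(a, b, n=200_000):
    """Independent oracle: polygonal arc length at very fine resolution."""
    t = np.linspace(0, 2 * np.pi, n)
    x, y = a * np.cos(t), b * np.sin(t)
    per = np.hypot(np.diff(x), np.diff(y)).sum()
    return np.pi * a * b, per


@pytest.mark.parametrize("area, per, dh, cr", [
    (np.pi, 2 * np.pi, 2.0, 1.0),          # unit circle
    (4.0, 8.0, 2.0, np.pi / 4),            # square side 2
])
def test_dh_cr_closed_forms(area, per, dh, cr):
    assert hydraulic_diameter(area, per) == pytest.approx(dh)
    assert circularity(area, per) == pytest.approx(cr)


def test_dh_cr_ellipse_against_numeric_perimeter():
    a, b = 2.0, 1.0
    area, per = _ellipse_area_perimeter(a, b)
    # cross-check the oracle itself against the complete elliptic integral
    assert per == pytest.approx(4 * a * ellipe(1 - b**2 / a**2), rel=1e-6)
    assert hydraulic_diameter(area, per) == pytest.approx(4 * area / per)
    assert circularity(area, per) == pytest.approx(4 * np.pi * area / per**2)
    assert circularity(area, per) < 1.0


@pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
def test_dh_cr_nonpositive_rejected(bad):
    with pytest.raises(ValueError):
        hydraulic_diameter(*bad)
    with pytest.raises(ValueError):
        circularity(*bad)


def _section(r_in, r_out, n=16):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return CrossSection(origin=np.zeros(3), normal=np.array([0, 0, 1.0]),
                        area=np.pi * np.mean(r_in) ** 2,
                        pe_in=2 * np.pi * np.mean(r_in), pe_out=float("nan"),
                        r_in=np.asarray(r_in, float) * np.ones(n),
                        r_out=np.asarray(r_out, float) * np.ones(n))


def test_wall_thickness_concentric_circles():
    assert wall_thickness(_section(2.0, 3.0)) == pytest.approx(1.0)
    assert wall_thickness(_section(2.0, 2.0)) == pytest.approx(0.0)


def test_wall_thickness_discards_inverted_rays():
    sec = _section(2.0, 3.0)
    sec.r_out[:4] = 1.0  # outer < inner: discarded
    assert wall_thickness(sec) == pytest.approx(1.0)
    sec.r_out[:] = np.nan
    with pytest.raises(ValueError):
        wall_thickness(sec)


# ----------------------------------------------------- measured sections

def test_cylinder_section_area_and_perimeter(cylinder_volume, cylinder_tree):
    secs = extract_cross_sections(cylinder_volume, cylinder_tree, cylinder_tree.root)
    assert len(secs) >= 5
    areas = np.array([s.area for s in secs])
    pes = np.array([s.pe_in for s in secs])
    assert abs(areas.mean() - np.pi * 16) / (np.pi * 16) < 0.05
    assert abs(pes.mean() - 2 * np.pi * 4) / (2 * np.pi * 4) < 0.05
    for s in secs:
        assert s.pe_out >= s.pe_in or np.isnan(s.pe_out)


def test_isoperimetric_bound_on_all_sections(full_phantom):
    vol, tree = full_phantom
    checked = 0
    for i in range(len(tree.branches)):
        try:
            secs = extract_cross_sections(vol, tree, i)
        except ValueError:
            continue
        for s in secs:
            assert circularity(s.area, s.pe_in) <= 1.0 + 0.05
            checked += 1
    assert checked > 10


def test_tilted_cylinder_same_area():
    """The section plane follows the axis, not the grid."""
    d = np.array([np.sin(np.radians(30)), 0.05, -np.cos(np.radians(30))])
    d /= np.linalg.norm(d)
    vol = generate_volume(cylinder_phantom(r_in=4.0, wall=1.0, length=40.0,
                                           spacing=0.5, direction=tuple(d)))
    tree = skeletonize(vol)
    secs = extract_cross_sections(vol, tree, tree.root)
    areas = np.array([s.area for s in secs])
    assert abs(areas.mean() - np.pi * 16) / (np.pi * 16) < 0.05


def test_rotation_invariance_of_metrics(cylinder_volume, cylinder_tree):
    base = branch_metrics(cylinder_volume, cylinder_tree).iloc[0]
    d = np.array([0.4, -0.3, -0.85])
    d /= np.linalg.norm(d)
    vol = generate_volume(cylinder_phantom(r_in=4.0, wall=1.0, length=40.0,
                                           spacing=0.5, direction=tuple(d)))
    rot = branch_metrics(vol, skeletonize(vol)).iloc[0]
    for k in ("dh_mm", "cr"):
        assert abs(rot[k] - base[k]) / base[k] < 0.05
    # WT is quantization-limited, so compare on the half-voxel scale
    assert abs(rot.wt_mm - base.wt_mm) < 0.125


def test_resolution_convergence_cylinder():
    """|measured - truth| for D_h and WT shrinks as voxels halve."""
    errs = {}
    for h in (0.75, 0.375):
        vol = generate_volume(cylinder_phantom(r_in=4.0, wall=1.5, length=40.0,
                                               spacing=h, noise_sd=0.0))
        row = branch_metrics(vol, skeletonize(vol)).iloc[0]
        errs[h] = (abs(row.dh_mm - 8.0), abs(row.wt_mm - 1.5))
    assert errs[0.375][0] <= errs[0.75][0]
    assert errs[0.375][1] <= errs[0.75][1]


# -------------------------------------------------------------- labeling

def test_labels_match_generator_ground_truth(full_phantom):
    _, tree = full_phantom
    truth = {b.name: b for b in default_airway_tree()}
    labels = tree.labels()
    named = ["Trachea", "LMB", "RMB", "Bronint", "TriLUL", "TriLLB", "TriRUL", "TriRLL"]
    for name in named:
        assert name in labels
        measured = tree.branches[labels[name]].direction()
        true_dir = np.asarray(truth[name].direction) / np.linalg.norm(truth[name].direction)
        assert bifurcation_angle(measured, true_dir) < 15.0
    # subgroup membership counts match the generator
    for sub, n in (("sRUL", 3), ("sRML", 2), ("sRLL", 5), ("sLUL", 3), ("sLLL", 5)):
        members = [b for b in tree.branches if b.label and b.label.startswith(sub + "_")]
        assert len(members) == n
    assert not any(b.label == "unlabeled" for b in tree.branches)


def test_mirrored_phantom_swaps_left_right():
    spec = PhantomSpec(shape=(128, 128, 128), spacing=(0.75,) * 3,
                       airway_branches=mirror_tree_x(default_airway_tree()),
                       noise_sd=0.0)
    tree = label_branches(skeletonize(generate_volume(spec)))
    labels = tree.labels()
    # the mirrored RMB subtree sits on the patient-left side, so it is
    # labeled as the left main bronchus and vice versa
    rmb_dir = tree.branches[labels["RMB"]].direction()
    lmb_dir = tree.branches[labels["LMB"]].direction()
    assert lmb_dir[0] > 0 > rmb_dir[0]
    for sub in ("sRUL", "sRML", "sRLL", "sLUL", "sLLL"):
        assert any(b.label and b.label.startswith(sub + "_") for b in tree.branches)


def test_truncated_tree_labels_main_bronchi_only():
    spec = PhantomSpec(shape=(96, 96, 96), spacing=(0.75,) * 3,
                       airway_branches=truncate_tree(default_airway_tree(),
                                                     {"Trachea", "LMB", "RMB"}),
                       noise_sd=0.0)
    tree = label_branches(skeletonize(generate_volume(spec)))
    labs = sorted(b.label for b in tree.branches)
    assert labs == ["LMB", "RMB", "Trachea"]


def test_unorientable_tree_rejected():
    pts = np.array([[0, 0, 10.0], [0, 0, 5.0]])
    root = Branch(points=pts, parent=None, children=[1], mean_radius=2.0)
    child = Branch(points=np.array([[0, 0, 5.0], [1, 0, 1.0]]), parent=0,
                   mean_radius=1.0)
    tree = AirwayTree(branches=[root, child], root=0, spacing=(1, 1, 1))
    with pytest.raises(ValueError, match="missing LMB or RMB"):
        label_branches(tree)


# ---------------------------------------------------------------- angles

def test_y_phantom_angle_recovery(y70_tree):
    assert branch_theta(y70_tree, y70_tree.root) == pytest.approx(70.0, abs=2.0)


def test_trifurcation_pairwise_mean_angle():
    vol = generate_volume(trifurcation_phantom(half_angle_deg=35.0))
    tree = skeletonize(vol)
    junctions = [i for i, b in enumerate(tree.branches) if len(b.children) == 3]
    assert len(junctions) == 1
    truth = trifurcation_pairwise_angle(35.0)
    assert branch_theta(tree, junctions[0]) == pytest.approx(truth, abs=2.0)


# --------------------------------------------------------------- metrics

def test_single_cylinder_metrics_row(cylinder_volume, cylinder_tree):
    df = branch_metrics(cylinder_volume, cylinder_tree)
    assert len(df) == 1
    row = df.iloc[0]
    assert np.isnan(row.theta_deg)  # no daughters, no bifurcation angle
    assert row.dh_mm == pytest.approx(8.0, rel=0.05)
    assert row.wt_mm == pytest.approx(1.0, abs=0.25)  # half a voxel
    assert row.cr >= 0.95


def test_full_phantom_metric_recovery(full_phantom):
    """Named-branch recovery at the 0.75 mm default: D_h within 10%, WT
    within one voxel (sub-voxel walls read at the PSF width), theta of the
    long-daughter junctions within 10 degrees."""
    vol, tree = full_phantom
    df = branch_metrics(vol, tree).set_index("label")
    truth = {b.name: b for b in default_airway_tree()}
    for name in ("Trachea", "LMB", "RMB", "Bronint", "TriLUL", "TriLLB",
                 "TriRUL", "TriRLL"):
        row = df.loc[name]
        assert row.dh_mm == pytest.approx(2 * truth[name].r_in, rel=0.10)
        assert abs(row.wt_mm - truth[name].wall) <= 0.75
        assert 0 < row.cr <= 1.05
    lmb_kids = [np.asarray(truth[k].direction) for k in ("TriLUL", "TriLLB")]
    lmb_truth = bifurcation_angle(*lmb_kids)
    assert df.loc["LMB"].theta_deg == pytest.approx(lmb_truth, abs=10.0)
    tr_kids = [np.asarray(truth[k].direction) for k in ("LMB", "RMB")]
    assert df.loc["Trachea"].theta_deg == pytest.approx(
        bifurcation_angle(*tr_kids), abs=10.0)
    # lobe-subgroup aggregate rows exist
    for sub in ("sRUL", "sRML", "sRLL", "sLUL", "sLLL"):
        assert sub in df.index


def test_occluded_branch_reports_missing_metrics(y70_volume, y70_tree):
    """A daughter flooded by opacity keeps its row with NaN metrics."""
    vol = y70_volume
    hu = vol.hu.copy()
    d1 = y70_tree.branches[y70_tree.root].children[0]
    pts = y70_tree.branches[d1].points
    sp = np.asarray(vol.spacing)
    for p in pts:
        i, j, k = np.round(p / sp - 0.5).astype(int)
        sl = (slice(max(i - 8, 0), i + 9), slice(max(j - 8, 0), j + 9),
              slice(max(k - 8, 0), k + 9))
        hu[sl] = -100.0  # consolidation-level opacity fills the lumen
    occluded = type(vol)(hu=hu, spacing=vol.spacing, lung_mask=vol.lung_mask,
                         airway_mask=vol.airway_mask, labels=vol.labels)
    df = branch_metrics(occluded, y70_tree)
    assert len(df) == 3
    assert df.dh_mm.isna().any() and df.dh_mm.notna().any()
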