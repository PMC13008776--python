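"""Nuclear segmentation, consensus reconciliation, RBC filter, cytoplasm."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from msq.core_io import RunConfig
from msq.segmentation import (CompositeCell, NucleusObject,
                              consensus_support, expand_cytoplasm,
                              filter_rbc, reconcile_composite,
                              segment_nuclei)


def _disc_image(centres, radius=5.0, shape=(200, 200), od=0.8):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cx, cy in centres:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = od
    return img


class TestSegmentNuclei:
    def test_blank_raster_no_objects(self):
        assert segment_nuclei(np.zeros((64, 64))) == []

    def test_planted_discs_recovered_with_subpixel_centroids(self, rng):
        centres = [(15 + 21 * c, 20 + 25 * r)
                   for r in range(5) for c in range(10)]
        img = _disc_image(centres, radius=5.0, shape=(150, 230))
        objs = segment_nuclei(img)
        assert len(objs) == 50
        d, _ = cKDTree([o.centroid for o in objs]).query(centres)
        assert (d < 1.0).all()

    def test_touching_discs_split_by_watershed(self):
        img = _disc_image([(40, 50), (52, 50)], radius=6.0, shape=(100, 100))
        objs = segment_nuclei(img)
        assert len(objs) == 2

    def test_unavailable_backend_named_in_error(self):
        with pytest.raises(RuntimeError, match="stardist"):
            segment_nuclei(np.zeros((32, 32)), backend="stardist")

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.full((8, 8), -1.0))


def _obj(stain, label, x, y, area=50.0):
    return NucleusObject(stain=stain, label=label, centroid=(x, y),
                         area=area, polygon=np.array([[x, y]]))


def _consensus_oracle(per_stain, radius, consensus_frac):
    """Exhaustive O(n^2) oracle: union-find over all cross-stain detection
    pairs within the match radius; support = distinct stains per component.
    Exact on fixtures whose cells are separated by > 2*radius."""
    flat = [(s, i, o.centroid) for s, objs in enumerate(per_stain)
            for i, o in enumerate(objs)]
    parent = list(range(len(flat)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(flat)):
        for b in range(a + 1, len(flat)):
            if flat[a][0] == flat[b][0]:
                continue
            (ax, ay), (bx, by) = flat[a][2], flat[b][2]
            if np.hypot(ax - bx, ay - by) <= radius:
                parent[find(a)] = find(b)
    comps = {}
    for k in range(len(flat)):
        comps.setdefault(find(k), []).append(flat[k])
    need = consensus_support(len(per_stain), consensus_frac)
    kept = [c for c in comps.values() if len({s for s, _, _ in c}) >= need]
    return kept


class TestReconcileComposite:
    def test_consensus_support_is_inclusive_rational(self):
        assert consensus_support(5, 0.60) == 3   # 3/5 = 0.6 passes
        assert consensus_support(3, 0.60) == 2
        assert consensus_support(10, 0.60) == 6
        assert consensus_support(1, 0.60) == 1

    def test_three_of_five_stains_retained(self):
        cfg = RunConfig(stains=tuple("abcde"))
        per_stain = [[_obj(s, 1, 50.0, 50.0)] for s in range(3)] + [[], []]
        cells = reconcile_composite(per_stain, cfg)
        assert len(cells) == 1
        assert cells[0].support == 3

    def test_two_of_five_dropped(self):
        cfg = RunConfig(stains=tuple("abcde"))
        per_stain = [[_obj(s, 1, 50.0, 50.0)] for s in range(2)] + [[], [], []]
        assert reconcile_composite(per_stain, cfg) == []

    def test_single_stain_keeps_everything(self):
        cfg = RunConfig(stains=("only",))
        per_stain = [[_obj(0, i, 10.0 * i, 5.0) for i in range(1, 6)]]
        cells = reconcile_composite(per_stain, cfg)
        assert len(cells) == 5
        assert all(c.support == 1 for c in cells)

    def test_match_radius_respected(self):
        cfg = RunConfig(stains=("a", "b"))  # radius 6 px at mpp 0.5
        near = [[_obj(0, 1, 50, 50)], [_obj(1, 1, 54, 50)]]
        far = [[_obj(0, 1, 50, 50)], [_obj(1, 1, 58, 50)]]
        assert reconcile_composite(near, cfg)[0].support == 2
        assert all(c.support == 1 for c in reconcile_composite(far, cfg))

    def test_matches_exhaustive_oracle_on_random_instance(self, rng):
        cfg = RunConfig(stains=tuple("abcde"))
        n_stains, n_cells = 5, 100
        pts = rng.uniform(30, 970, (n_cells + 20, 2))
        # enforce separation > 2*radius so the oracle is exact
        keep = []
        for p in pts:
            if all(np.hypot(*(p - pts[k])) > 15 for k in keep):
                keep.append(len(keep))
        pts = pts[:len(keep)]
        truth_n = len(pts) - 20
        per_stain = [[] for _ in range(n_stains)]
        for i, (x, y) in enumerate(pts[:truth_n]):
            for s in range(n_stains):
                jitter = rng.uniform(-1, 1, 2)
                per_stain[s].append(_obj(s, len(per_stain[s]) + 1,
                                         x + jitter[0], y + jitter[1]))
        for i, (x, y) in enumerate(pts[truth_n:]):  # single-stain artefacts
            s = int(rng.integers(0, n_stains))
            per_stain[s].append(_obj(s, len(per_stain[s]) + 1, x, y))
        cells = reconcile_composite(per_stain, cfg)
        oracle = _consensus_oracle(per_stain, cfg.match_radius_px,
                                   cfg.consensus_frac)
        assert len(cells) == len(oracle) == truth_n

    def test_consensus_monotonicity(self, rng):
        """Raising consensus_frac never increases the composite count."""
        per_stain = [[] for _ in range(4)]
        for i in range(30):
            x, y = rng.uniform(20, 480, 2)
            for s in range(4):
                if rng.random() > 0.3:
                    per_stain[s].append(_obj(s, len(per_stain[s]) + 1, x, y))
        counts = []
        for frac in (0.25, 0.5, 0.75, 1.0):
            cfg = RunConfig(stains=tuple("abcd"), consensus_frac=frac)
            counts.append(len(reconcile_composite(per_stain, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_no_stains_rejected(self):
        with pytest.raises(ValueError):
            reconcile_composite([], RunConfig())


class TestFilterRbc:
    def _cells(self, n):
        return [CompositeCell(cell_id=i, centroid=(0, 0), centroid_um=(0, 0),
                              polygon=np.empty((0, 2)), support=1, members=[])
                for i in range(n)]

    def test_planted_anucleate_high_residual_flagged(self, rng):
        n_true, n_rbc = 200, 10
        nuc = np.concatenate([rng.uniform(0.5, 1.0, n_true),
                              rng.uniform(0.05, 0.2, n_rbc)])
        res = np.concatenate([rng.uniform(0.0, 0.05, n_true),
                              rng.uniform(0.4, 0.8, n_rbc)])
        cells = filter_rbc(self._cells(n_true + n_rbc), nuc, res)
        flags = np.array([c.rbc_flag for c in cells])
        assert flags[n_true:].sum() >= 9
        assert flags[:n_true].sum() <= 2

    def test_no_anucleate_objects_no_flags(self, rng):
        nuc = rng.uniform(0.5, 1.0, 50)
        res = rng.uniform(0.0, 0.01, 50)  # residual is pure noise
        cells = filter_rbc(self._cells(50), nuc, res)
        assert not any(c.rbc_flag for c in cells)

    def test_small_cohort_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            cells = filter_rbc(self._cells(5), np.ones(5), np.zeros(5))
        assert not any(c.rbc_flag for c in cells)

    def test_hit_miss_report_on_planted_panel(self, small_panel_result):
        """Pathologist-marked RBC points inside retained nuclei are misses,
        outside are hits (successful filtering)."""
        result, truth, cfg = small_panel_result
        f = result.features
        kept = f[~f["rbc_flag"].astype(bool)]
        pts = kept[["x_px", "y_px"]].to_numpy()
        rbc = truth.cells[truth.cells["is_rbc"]][["x", "y"]].to_numpy()
        d, _ = cKDTree(pts).query(rbc)
        hits = int((d >= cfg.match_radius_px).sum())
        assert hits >= int(0.7 * len(rbc))


class TestExpandCytoplasm:
    def test_zero_pixels_no_cytoplasm(self):
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[8:12, 8:12] = True
        n, cyt, whole = expand_cytoplasm(nuc, 0)
        assert not cyt.any()
        np.testing.assert_array_equal(whole, nuc)

    def test_disc_expansion_area(self):
        yy, xx = np.mgrid[0:40, 0:40]
        nuc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 5 ** 2
        n, cyt, whole = expand_cytoplasm(nuc, 3)
        assert whole.sum() == pytest.approx(np.pi * 8 ** 2, rel=0.10)
        assert not (n & cyt).any()
        np.testing.assert_array_equal(n | cyt, whole)

    def test_default_expansion_is_three_pixels(self):
        assert RunConfig().cytoplasm_px == 3
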