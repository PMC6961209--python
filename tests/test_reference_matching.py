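"""Projection-matching classifier: recovery, oracle equivalence, unification."""

import numpy as np
import pandas as pd
import pytest

from mtpipe import helical_geometry as hg
from mtpipe import reference_matching as rm
from mtpipe import synthetic_data as sd
from mtpipe.star_io import make_table


@pytest.fixture(scope="module")
def decorated13():
    return hg.build_lattice(hg.helical_table(13, 3), 900.0, decorated=True,
                            seam_pf=0)


def _ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())


class TestMatchAlign:
    def test_self_match_recovers_grid_parameters(self, decorated13):
        """A noiseless projection at grid-point parameters comes back with
        its own class, Rot, and shift."""
        t = make_table(1)
        t.df["psi_prior"] = 0.0
        img = hg.project_lattice(decorated13, 36.0, 90.0, 0.0, 11.12, -5.56,
                                 pixel_size=5.56, box_px=108).data
        refs = rm.ReferenceSet([decorated13], ["13-3"], 5.56, 108)
        res = rm.match(np.array([img]), t, refs,
                       rm.SearchGrid(max_shift=30.0), align=True)
        row = res.df.iloc[0]
        assert row["class_index"] == 0
        assert row["rot"] == pytest.approx(36.0)
        assert row["origin_x"] == pytest.approx(11.12)
        assert row["origin_y"] == pytest.approx(-5.56)
        assert row["score"] > 0.99

    def test_score_invariant_to_intensity_scaling(self, decorated13):
        t = make_table(1)
        img = hg.project_lattice(decorated13, 10.0, 90.0, 0.0,
                                 pixel_size=5.56, box_px=108).data
        refs = rm.ReferenceSet([decorated13], ["13-3"], 5.56, 108)
        grid = rm.SearchGrid(rot_step=5.0, rot_local_range=10.0,
                             max_shift=10.0)
        a = rm.match(np.array([img]), t, refs, grid, align=True)
        b = rm.match(np.array([7.5 * img]), t, refs, grid, align=True)
        assert a.df["score"].iloc[0] == pytest.approx(b.df["score"].iloc[0])
        assert a.df["rot"].iloc[0] == b.df["rot"].iloc[0]

    def test_align_true_never_scores_below_align_false(self, decorated13):
        """When the current parameters lie on the search grid, searching
        can only help."""
        t = make_table(1)
        t.df[["rot", "tilt", "psi"]] = [18.0, 90.0, 0.0]
        rng = np.random.default_rng(1)
        img = hg.project_lattice(decorated13, 18.0, 90.0, 0.0,
                                 pixel_size=5.56, box_px=108).data
        img = img + 0.5 * img.std() * rng.standard_normal(img.shape)
        refs = rm.ReferenceSet([decorated13], ["13-3"], 5.56, 108)
        fixed = rm.match(np.array([img]), t, refs, align=False)
        searched = rm.match(np.array([img]), t, refs,
                            rm.SearchGrid(rot_step=1.8, rot_local_range=3.6,
                                          max_shift=15.0), align=True)
        assert searched.df["score"].iloc[0] >= fixed.df["score"].iloc[0] - 1e-9

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rm.ReferenceSet([], [], 5.56, 108)


@pytest.fixture(scope="module")
def toy():
    apix, box = 7.0, 48
    lat13 = hg.build_lattice(hg.helical_table(13, 3), 500.0,
                             decorated=True, seam_pf=0)
    lat14 = hg.build_lattice(hg.helical_table(14, 3), 500.0,
                             decorated=True, seam_pf=0)
    refs = rm.ReferenceSet([lat13, lat14], ["13-3", "14-3"], apix, box)
    rots = np.array([0.0, 10.0, 20.0])
    shifts_px = [(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    return apix, box, refs, rots, shifts_px


class TestBruteForceOracle:
    """match() against an independent double-loop enumeration."""

    def _oracle(self, img, refs, rots, shifts_px, apix, box, limit=12.0):
        """Naive enumeration: render every candidate projection (shift
        applied analytically), mask, band-limit, and take the best NCC."""
        circ = rm._circular_mask(box, apix)
        band = rm._band_mask(box, apix, limit)
        ib = np.fft.irfft2(np.fft.rfft2(img) * band, s=img.shape)
        best = (-np.inf, None)
        for c in range(len(refs)):
            for rot in rots:
                for dx, dy in shifts_px:
                    p = hg.project_lattice(
                        refs.lattices[c], rot, 90.0, 0.0, dx * apix,
                        dy * apix, pixel_size=apix, box_px=box,
                        lowpass=refs.lowpass).data
                    pb = np.fft.irfft2(np.fft.rfft2(p) * band, s=p.shape)
                    a = circ * np.roll(ib, (-dy, -dx), axis=(0, 1))
                    b = circ * np.roll(pb, (-dy, -dx), axis=(0, 1))
                    s = (a * b).sum() / (np.linalg.norm(a)
                                         * np.linalg.norm(b))
                    if s > best[0]:
                        best = (s, (c, rot, dx * apix, dy * apix))
        return best[1]

    @pytest.mark.parametrize("true_c,true_rot,true_shift", [
        (0, 10.0, (7.0, -7.0)),
        (1, 20.0, (0.0, 7.0)),
        (0, 0.0, (-7.0, 0.0)),
    ])
    def test_argmax_agrees_with_oracle(self, toy, true_c, true_rot,
                                       true_shift):
        apix, box, refs, rots, shifts_px = toy
        img = hg.project_lattice(
            refs.lattices[true_c], true_rot, 90.0, 0.0, *true_shift,
            pixel_size=apix, box_px=box, lowpass=refs.lowpass).data
        t = make_table(1)
        t.df[["rot", "psi_prior"]] = [10.0, 0.0]
        grid = rm.SearchGrid(rot_step=10.0, rot_local_range=10.0,
                             max_shift=10.5, shift_step=1)
        res = rm.match(np.array([img]), t, refs, grid, align=True)
        row = res.df.iloc[0]
        got = (int(row["class_index"]), float(row["rot"]),
               float(row["origin_x"]), float(row["origin_y"]))
        want = self._oracle(img, refs, rots, shifts_px, apix, box)
        assert got == (want[0], want[1], want[2], want[3])
        assert got == (true_c, true_rot, true_shift[0], true_shift[1])


class TestPfSort:
    def test_reference_set_spans_six_architectures(self):
        labels = [p.label for p in hg.all_architectures()]
        assert labels == ["11-3", "12-3", "13-3", "14-3", "15-4", "16-4"]

    def test_noiseless_13pf_tube_fully_classified(self):
        cfg = sd.SimConfig(seed=9, n_tubes=1, segments_per_tube=(5, 5),
                           arch_mix={"13-3": 1.0}, noise_sigma=0.0,
                           p_register_jump=0.0, p_rot_misregister=0.0,
                           sigma_rot=0.0, sigma_psi=0.0, sigma_tilt=0.0)
        ds = sd.simulate_dataset(cfg)
        from mtpipe.star_io import set_priors_and_reset
        t = set_priors_and_reset(ds.table)
        res = rm.pf_sort(ds.stack, t)
        assert all(res.labels[c] == "13-3"
                   for c in res.df["class_index"])


class TestSeamClassify:
    def test_generated_offset_recovered(self, decorated13):
        """A tube generated at (k=+2, reg=0) with current parameters at the
        k=0 convention classifies as (k=+2, reg=0)."""
        params = hg.helical_table(13, 3)
        moved = hg.transform_lattice(decorated13, 2 * params.twist,
                                     2 * params.rise)
        t = make_table(3)
        t.df[["rot", "tilt", "psi"]] = [25.0, 90.0, 40.0]
        imgs = np.stack([
            hg.project_lattice(moved, 25.0, 90.0, 40.0,
                               pixel_size=5.56, box_px=108).data
            for _ in range(3)])
        res = rm.seam_classify(imgs, t, params, base_lattice=decorated13)
        assert all(res.labels[c] == (2, 0) for c in res.df["class_index"])

    def test_register_shift_recovered(self, decorated13):
        params = hg.helical_table(13, 3)
        moved = hg.transform_lattice(decorated13, 0.0, params.monomer_repeat)
        t = make_table(1)
        t.df[["rot", "tilt", "psi"]] = [25.0, 90.0, 0.0]
        img = hg.project_lattice(moved, 25.0, 90.0, 0.0,
                                 pixel_size=5.56, box_px=108).data
        res = rm.seam_classify(np.array([img]), t, params,
                               base_lattice=decorated13)
        assert res.labels[res.df["class_index"].iloc[0]] == (0, 1)


class TestUnifyAndConfidence:
    def test_modal_class_and_confidence(self):
        t = make_table(10)
        df = pd.DataFrame({"class_index": [13] * 9 + [14]})
        unified, per_tube = rm.unify_class_per_tube(df, t)
        assert set(unified) == {13}
        assert per_tube["confidence"].iloc[0] == pytest.approx(90.0)

    def test_unanimous_is_100(self):
        t = make_table(4)
        df = pd.DataFrame({"class_index": [2, 2, 2, 2]})
        _, per_tube = rm.unify_class_per_tube(df, t)
        assert per_tube["confidence"].iloc[0] == 100.0

    def test_tie_goes_to_lower_class(self):
        t = make_table(4)
        df = pd.DataFrame({"class_index": [5, 2, 5, 2]})
        unified, per_tube = rm.unify_class_per_tube(df, t)
        assert per_tube["modal_class"].iloc[0] == 2
        assert per_tube["confidence"].iloc[0] == pytest.approx(50.0)

    def test_confidence_histogram(self):
        per_tube = pd.DataFrame({"confidence": [100.0, 100.0, 100.0, 50.0]})
        hist = rm.confidence_report(per_tube)
        assert hist.loc[hist["bin"] == "100", "percent_of_tubes"].iloc[0] == 75.0
        assert hist.loc[hist["bin"] == "50-60", "percent_of_tubes"].iloc[0] == 25.0
        assert hist["percent_of_tubes"].sum() == pytest.approx(100.0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="no tubes"):
            rm.confidence_report(pd.DataFrame({"confidence": []}))
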