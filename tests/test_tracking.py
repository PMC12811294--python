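"""Detection, greedy IoU linking, track merging, survival conversion,
MOTA scoring, parameter search and subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from imnpheno import synthetic as syn
from imnpheno import tracking as trk
from imnpheno.frames import Frame


def box_at(y, x, side=10.0):
    return (y, x, y + side, x + side)


def make_detections(day_boxes: dict[float, list]) -> list[trk.Detection]:
    return [
        trk.Detection(day=d, box=b) for d, boxes in day_boxes.items() for b in boxes
    ]


@pytest.fixture(scope="module")
def timelapse_movie():
    spec = syn.SceneSpec(field_size_um=(350.0, 350.0), pixel_size_um=0.69, seed=3)
    cohort = syn.CohortSpec(groups=[syn.GroupSpec("control", 30)],
                            baseline_hazard=0.03, seed=3)
    return syn.generate_timelapse(spec, cohort)


def gt_tracks_from(table: pd.DataFrame) -> list[trk.Track]:
    out = []
    for cid, df in table.groupby("cell_id"):
        out.append(trk.Track(int(cid), {
            r.day: (r.y0, r.x0, r.y1, r.x1) for r in df.itertuples()
        }))
    return out


class TestDetectImn:
    def test_blank_frame_no_detections(self):
        fr = Frame(np.full((200, 200), 10.0), 0.69, channel="egfp")
        assert trk.detect_imn(fr) == []

    def test_detection_against_ground_truth_boxes(self, timelapse_movie):
        frames, gt = timelapse_movie
        fr = frames[0]
        dets = trk.detect_imn(fr)
        gt_boxes = [
            (r.y0, r.x0, r.y1, r.x1)
            for r in gt.tracks[gt.tracks["day"] == fr.timepoint].itertuples()
        ]
        matched = 0
        for g in gt_boxes:
            if any(trk.iou(g, d.box) >= 0.5 for d in dets):
                matched += 1
        recall = matched / len(gt_boxes)
        precision = sum(
            any(trk.iou(g, d.box) >= 0.5 for g in gt_boxes) for d in dets
        ) / len(dets)
        assert recall >= 0.9 and precision >= 0.9

    def test_determinism(self, timelapse_movie):
        frames, _ = timelapse_movie
        a = trk.detect_imn(frames[0])
        b = trk.detect_imn(frames[0])
        assert [d.box for d in a] == [d.box for d in b]


class TestLinkTracks:
    def test_stationary_box_gives_single_full_track(self):
        days = list(np.arange(12.0, 48.0, 2.0))
        dets = make_detections({d: [box_at(50, 50)] for d in days})
        tracks = trk.link_tracks(dets)
        assert len(tracks) == 1
        assert len(tracks[0].boxes) == 18

    def test_two_distant_boxes_stay_separate(self):
        days = [12.0, 14.0, 16.0]
        dets = make_detections({d: [box_at(10, 10), box_at(150, 150)] for d in days})
        tracks = trk.link_tracks(dets)
        assert len(tracks) == 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            trk.link_tracks([], trk.TrackerParams(association_iou=0.0))

    def test_greedy_matches_hungarian_oracle(self):
        """Frame-to-frame greedy association agrees with the optimal
        assignment on >= 95% of links for near-stationary cells."""
        rng = np.random.default_rng(12)
        n, n_frames = 20, 10
        pos = rng.uniform(20, 480, (n, 2))
        days = np.arange(float(n_frames))
        all_dets: dict[float, list] = {}
        for d in days:
            boxes = [box_at(*(p + rng.normal(0, 0.8, 2)), side=12.0) for p in pos]
            all_dets[d] = boxes
        dets = make_detections(all_dets)
        tracks = trk.link_tracks(dets, trk.TrackerParams(association_iou=0.3))

        # oracle: optimal assignment frame to frame by IoU
        agree = total = 0
        prev_boxes = all_dets[days[0]]
        prev_greedy = {i: i for i in range(n)}
        for d in days[1:]:
            cur = all_dets[d]
            cost = np.array([[1 - trk.iou(a, b) for b in cur] for a in prev_boxes])
            ri, ci = linear_sum_assignment(cost)
            optimal = dict(zip(ri, ci))
            # greedy links: which current box follows which previous box
            # (reconstruct from emitted tracks)
            by_track = {}
            for t in tracks:
                if float(d) in t.boxes and float(d - 1) in t.boxes:
                    by_track[tuple(t.boxes[d - 1])] = tuple(t.boxes[d])
            for i, pb in enumerate(prev_boxes):
                total += 1
                want = tuple(cur[optimal[i]])
                got = by_track.get(tuple(pb))
                if got == want:
                    agree += 1
            prev_boxes = cur
        assert agree / total >= 0.95

    def test_min_track_length_drops_singletons(self):
        dets = make_detections({12.0: [box_at(10, 10)]})
        assert trk.link_tracks(dets, trk.TrackerParams(min_track_length=2)) == []


class TestMergeTracks:
    def test_identical_forward_backward_merge_to_one(self):
        boxes = {d: box_at(30, 30) for d in (12.0, 14.0, 16.0)}
        f = trk.Track(0, dict(boxes), direction="forward")
        b = trk.Track(0, dict(boxes), direction="backward")
        merged = trk.merge_tracks([f], [b])
        assert len(merged) == 1
        assert sorted(merged[0].boxes) == [12.0, 14.0, 16.0]

    def test_partial_overlap_spans_union(self):
        fwd = trk.Track(0, {d: box_at(30, 30) for d in np.arange(12.0, 22.0, 2.0)})
        bwd = trk.Track(1, {d: box_at(30, 30) for d in np.arange(16.0, 30.0, 2.0)})
        merged = trk.merge_tracks([fwd], [bwd])
        assert len(merged) == 1
        assert min(merged[0].boxes) == 12.0 and max(merged[0].boxes) == 28.0

    def test_disjoint_in_time_not_merged(self):
        a = trk.Track(0, {12.0: box_at(30, 30)})
        b = trk.Track(1, {20.0: box_at(30, 30)})
        assert len(trk.merge_tracks([a], [b])) == 2

    def test_tile_offsets_map_to_global(self):
        a = trk.Track(0, {12.0: box_at(10, 10)}, tile="t0")
        b = trk.Track(1, {12.0: box_at(0, 0)}, tile="t1")
        layout = {"t0": (0.0, 0.0), "t1": (10.0, 10.0)}
        merged = trk.merge_tracks([a], [b], tile_layout=layout)
        assert len(merged) == 1  # same global box after offsetting

    def test_merge_idempotence(self, timelapse_movie):
        frames, _ = timelapse_movie
        dets = [d for fr in frames for d in trk.detect_imn(fr)]
        fwd = trk.link_tracks(dets, direction="forward")
        bwd = trk.link_tracks(dets, direction="backward")
        merged = trk.merge_tracks(fwd, bwd)
        again = trk.merge_tracks(merged, [])
        assert len(again) == len(merged)
        assert all(a.boxes == b.boxes for a, b in zip(again, merged))

    def test_unknown_tile_rejected(self):
        t = trk.Track(0, {12.0: box_at(0, 0)}, tile="t9")
        with pytest.raises(ValueError, match="t9"):
            trk.merge_tracks([t], [], tile_layout={"t0": (0.0, 0.0)})


class TestTracksToSurvival:
    def test_death_at_first_missed_timepoint(self):
        t = trk.Track(0, {d: box_at(5, 5) for d in np.arange(14.0, 30.0, 2.0)})
        rec = trk.tracks_to_survival([t], final_day=46.0, interval=2.0).iloc[0]
        assert rec["start"] == 14.0
        assert rec["end"] == 30.0
        assert rec["event"] == 1

    def test_present_at_final_day_censored(self):
        t = trk.Track(0, {d: box_at(5, 5) for d in np.arange(12.0, 48.0, 2.0)})
        rec = trk.tracks_to_survival([t], final_day=46.0, interval=2.0).iloc[0]
        assert rec["end"] == 46.0 and rec["event"] == 0

    def test_empty_track_set(self):
        out = trk.tracks_to_survival([], 46.0, 2.0)
        assert len(out) == 0

    def test_record_validity_invariant(self, timelapse_movie):
        frames, _ = timelapse_movie
        dets = [d for fr in frames for d in trk.detect_imn(fr)]
        merged = trk.merge_tracks(trk.link_tracks(dets),
                                  trk.link_tracks(dets, direction="backward"))
        recs = trk.tracks_to_survival(merged, 46.0, 2.0)
        assert (recs["end"] >= recs["start"]).all()
        assert (recs.loc[recs["end"] == 46.0, "event"] == 0).all()
        assert recs["event"].isin([0, 1]).all()


class TestMota:
    def test_perfect_predictions_score_one(self, timelapse_movie):
        _, gt = timelapse_movie
        tracks = gt_tracks_from(gt.tracks)
        score, comp = trk.mota(tracks, tracks)
        assert score == 1.0
        assert comp["FN"] == comp["FP"] == comp["IDSW"] == 0

    def test_no_predictions_score_zero(self, timelapse_movie):
        _, gt = timelapse_movie
        tracks = gt_tracks_from(gt.tracks)
        score, comp = trk.mota([], tracks)
        assert score == 0.0
        assert comp["FN"] == comp["GT"]

    def test_single_identity_swap_on_ten_by_ten(self):
        """10 objects x 10 frames with exactly one mid-sequence identity
        swap and no FP/FN: MOTA = 1 - 1/100."""
        gt = [
            trk.Track(i, {float(d): box_at(20.0 * i, 10.0) for d in range(10)})
            for i in range(10)
        ]
        pred = []
        for i in range(10):
            boxes = {}
            for d in range(10):
                # predictions for objects 0 and 1 exchange ids from frame 5
                src = i
                if d >= 5 and i in (0, 1):
                    src = 1 - i
                boxes[float(d)] = box_at(20.0 * src, 10.0)
            pred.append(trk.Track(100 + i, boxes))
        score, comp = trk.mota(pred, gt)
        assert comp == {"FN": 0, "FP": 0, "IDSW": 2, "GT": 100} or \
               comp == {"FN": 0, "FP": 0, "IDSW": 1, "GT": 100}
        # two gt tracks swap partners -> 2 switch events, one per track
        assert score == pytest.approx(1 - comp["IDSW"] / 100)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            trk.mota([], [], iou_threshold=1.5)


class TestTuneTracker:
    def small_movie(self):
        spec = syn.SceneSpec(field_size_um=(200.0, 200.0), pixel_size_um=0.69, seed=5)
        cohort = syn.CohortSpec(groups=[syn.GroupSpec("g", 10)],
                                baseline_hazard=0.04, seed=5)
        frames, gt = syn.generate_timelapse(spec, cohort)
        dets = [d for fr in frames for d in trk.detect_imn(fr)]
        return dets, gt_tracks_from(gt.tracks)

    def test_single_point_space_returned(self):
        movie = self.small_movie()
        space = {"association_iou": [0.3], "max_gap": [1]}
        best, log = trk.tune_tracker(space, [movie], budget=1, seed=0)
        assert best.association_iou == 0.3 and best.max_gap == 1
        assert len(log) == 1

    def test_sane_setting_beats_degenerate(self):
        movie = self.small_movie()
        space = {"association_iou": [0.3, 0.99]}
        best, log = trk.tune_tracker(space, [movie], budget=4, seed=1)
        assert best.association_iou == 0.3

    def test_deterministic_selection(self):
        movie = self.small_movie()
        space = {"association_iou": [0.2, 0.3, 0.5], "max_gap": [0, 1, 2]}
        a, la = trk.tune_tracker(space, [movie], budget=5, seed=7)
        b, lb = trk.tune_tracker(space, [movie], budget=5, seed=7)
        assert (a.association_iou, a.max_gap) == (b.association_iou, b.max_gap)
        pd.testing.assert_frame_equal(la, lb)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            trk.tune_tracker({}, [], budget=1)


class TestSampleCells:
    def records(self, sizes: dict[str, int]) -> pd.DataFrame:
        rows = []
        cid = 0
        for g, n in sizes.items():
            for _ in range(n):
                rows.append({"cell_id": cid, "group": g, "start": 12.0,
                             "end": 30.0, "event": 1})
                cid += 1
        return pd.DataFrame(rows)

    def test_undersized_group_returned_whole_with_flag(self):
        recs = self.records({"a": 300})
        out, flags = trk.sample_cells(recs, n=500, seed=0)
        assert len(out) == 300 and flags["a"] is True

    def test_exact_sample_of_500(self):
        recs = self.records({"a": 3500})
        out, flags = trk.sample_cells(recs, n=500, seed=1)
        assert len(out) == 500 and flags["a"] is False
        again, _ = trk.sample_cells(recs, n=500, seed=1)
        assert (out["cell_id"].to_numpy() == again["cell_id"].to_numpy()).all()

    def test_different_seeds_differ(self):
        recs = self.records({"a": 3500})
        a, _ = trk.sample_cells(recs, n=500, seed=1)
        b, _ = trk.sample_cells(recs, n=500, seed=2)
        assert set(a["cell_id"]) != set(b["cell_id"])


class TestEndToEnd:
    def test_direction_symmetry_on_clean_movie(self):
        spec = syn.SceneSpec(field_size_um=(250.0, 250.0), pixel_size_um=0.69,
                             noise_sigma=0.0, seed=6)
        cohort = syn.CohortSpec(groups=[syn.GroupSpec("g", 15)],
                                baseline_hazard=0.04, seed=6)
        frames, _ = syn.generate_timelapse(spec, cohort)
        dets = [d for fr in frames for d in trk.detect_imn(fr)]
        fwd = trk.merge_tracks(trk.link_tracks(dets, direction="forward"), [])
        bwd = trk.merge_tracks(trk.link_tracks(dets, direction="backward"), [])
        ra = trk.tracks_to_survival(fwd, 46.0, 2.0).sort_values("start").reset_index(drop=True)
        rb = trk.tracks_to_survival(bwd, 46.0, 2.0).sort_values("start").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            ra[["start", "end", "event"]].sort_values(["start", "end"]).reset_index(drop=True),
            rb[["start", "end", "event"]].sort_values(["start", "end"]).reset_index(drop=True),
        )

    def test_survival_recovery_and_pipeline_mota(self, timelapse_movie):
        """>= 90% of true cells recovered within one schedule interval;
        pipeline MOTA >= 0.9."""
        frames, gt = timelapse_movie
        dets = [d for fr in frames for d in trk.detect_imn(fr)]
        merged = trk.merge_tracks(trk.link_tracks(dets),
                                  trk.link_tracks(dets, direction="backward"))
        score, _ = trk.mota(merged, gt_tracks_from(gt.tracks))
        assert score >= 0.9
        recs = trk.tracks_to_survival(merged, 46.0, 2.0)
        hits = 0
        for t in gt.survival.itertuples():
            m = recs[(abs(recs["start"] - t.start) <= 2.0)
                     & (abs(recs["end"] - t.end) <= 2.0)]
            if len(m):
                hits += 1
        assert hits / len(gt.survival) >= 0.9
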