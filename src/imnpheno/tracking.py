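"""Longitudinal iMN viability tracking: detection, greedy IoU linking,
tile/direction track merging, start-end-censor conversion, and MOTA.

Converted cultures are imaged every second day from D12 to D46; each
neuron is detected per frame, detections are linked into tracks both
forward and backward in time, tracks from overlapping tiles and both
directions are merged, and each merged track becomes one survival
record: entry at first sighting, death at the first missed scheduled
timepoint after the last sighting, censoring at the final day.

Cells in these cultures are nearly stationary, so association is a
deterministic greedy intersection-over-union matcher with a small gap
tolerance; the tracker interface is pluggable for motion-model trackers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import Frame
from .segmentation import ANY_OBJECT_PARAMS, DetectionParams, detect_blobs

Box = tuple[float, float, float, float]  # half-open (y0, x0, y1, x1), px


@dataclass
class Detection:
    """One per-frame detection: day, half-open box, score, source tile."""

    day: float
    box: Box
    score: float = 1.0
    tile: str = "t0"


@dataclass
class Track:
    """Ordered day -> box map from one tile and time direction."""

    track_id: int
    boxes: dict[float, Box]
    scores: dict[float, float] = field(default_factory=dict)
    tile: str = "t0"
    direction: str = "forward"

    @property
    def days(self) -> list[float]:
        return sorted(self.boxes)


@dataclass
class TrackerParams:
    """Greedy-association tracker parameters."""

    association_iou: float = 0.3
    max_gap: int = 1
    min_track_length: int = 2
    score_cutoff: float = 0.0

    def validate(self) -> None:
        if not (0 < self.association_iou <= 1):
            raise ValueError("association_iou must be in (0, 1]")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open boxes."""
    iy = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    ix = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = iy * ix
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

#: detection preset for 10x viability frames: compact bright somata
IMN_DETECTION_PARAMS = DetectionParams(
    sigma_um=2.0, min_area_um2=40.0, max_area_um2=500.0, min_roundness=0.6
)


def detect_imn(
    frame: Frame,
    model=None,
    params: DetectionParams = IMN_DETECTION_PARAMS,
    tile: str = "t0",
) -> list[Detection]:
    """Detect neurons (small bright round somata) in one eGFP frame.

    Classical stand-in for a learned detector: blob detection with
    size/roundness criteria encoding the neuronal-morphology rule. When
    a fitted classifier ``model`` is given, each blob's features are
    extracted and only blobs classified iMN are kept.
    """
    labels = detect_blobs(frame, params)
    dets: list[Detection] = []
    if labels.max() == 0:
        return dets
    from skimage.measure import regionprops

    regions = regionprops(labels)
    if model is not None:
        from .classify import extract_cell_features
        from .synthetic import CLASS_IMN

        rows = []
        for r in regions:
            m = labels == r.label
            rows.append(extract_cell_features(m, m, frame))
        feats = pd.DataFrame(rows)
        keep = [k == CLASS_IMN for k in model.predict(feats)]
        regions = [r for r, k in zip(regions, keep) if k]
    for r in regions:
        y0, x0, y1, x1 = r.bbox
        dets.append(
            Detection(day=frame.timepoint, box=(float(y0), float(x0), float(y1), float(x1)),
                      score=1.0, tile=tile)
        )
    return dets


# --------------------------------------------------------------------------
# greedy linking
# --------------------------------------------------------------------------

def link_tracks(
    detections: list[Detection],
    params: TrackerParams = TrackerParams(),
    direction: str = "forward",
) -> list[Track]:
    """Link detections into tracks by greedy one-to-one IoU association.

    Frames are processed in day order (reversed for the backward
    direction); at each frame every (track, detection) pair above the
    IoU minimum competes, highest IoU first (ties: smaller track id).
    Unmatched detections open new tracks; tracks missing more than
    ``max_gap`` consecutive frames close; tracks with fewer than
    ``min_track_length`` detections are dropped.
    """
    params.validate()
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    dets = [d for d in detections if d.score >= params.score_cutoff]
    days = sorted({d.day for d in dets}, reverse=(direction == "backward"))
    by_day: dict[float, list[Detection]] = {}
    for d in dets:
        by_day.setdefault(d.day, []).append(d)

    next_id = itertools.count()
    active: list[dict] = []
    done: list[dict] = []
    for day in days:
        frame_dets = by_day[day]
        pairs = []
        for ti, tr in enumerate(active):
            for di, det in enumerate(frame_dets):
                v = iou(tr["last_box"], det.box)
                if v >= params.association_iou:
                    pairs.append((-v, tr["id"], ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, _, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            tr = active[ti]
            det = frame_dets[di]
            tr["boxes"][day] = det.box
            tr["scores"][day] = det.score
            tr["last_box"] = det.box
            tr["misses"] = 0
            used_t.add(ti)
            used_d.add(di)
        still = []
        for ti, tr in enumerate(active):
            if ti not in used_t:
                tr["misses"] += 1
            (still if tr["misses"] <= params.max_gap else done).append(tr)
        active = still
        for di, det in enumerate(frame_dets):
            if di not in used_d:
                active.append(
                    {"id": next(next_id), "boxes": {day: det.box},
                     "scores": {day: det.score}, "last_box": det.box, "misses": 0,
                     "tile": det.tile}
                )
    done.extend(active)
    out = []
    for tr in done:
        if len(tr["boxes"]) < params.min_track_length:
            continue
        out.append(
            Track(track_id=tr["id"], boxes=dict(tr["boxes"]), scores=dict(tr["scores"]),
                  tile=tr.get("tile", "t0"), direction=direction)
        )
    out.sort(key=lambda t: (min(t.boxes), t.track_id))
    for i, t in enumerate(out):
        t.track_id = i
    return out


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------

def _to_global(track: Track, tile_layout: dict[str, tuple[float, float]] | None) -> Track:
    if not tile_layout:
        return track
    if track.tile not in tile_layout:
        raise ValueError(f"tile {track.tile!r} missing from layout {sorted(tile_layout)}")
    oy, ox = tile_layout[track.tile]
    boxes = {d: (b[0] + oy, b[1] + ox, b[2] + oy, b[3] + ox) for d, b in track.boxes.items()}
    return replace(track, boxes=boxes)


def merge_tracks(
    forward: list[Track],
    backward: list[Track],
    tile_layout: dict[str, tuple[float, float]] | None = None,
    merge_iou: float = 0.5,
) -> list[Track]:
    """Combine overlapping tracks across tiles and time directions.

    Tracks are first mapped to global pixel coordinates via the tile
    layout (tile id -> (y, x) offset). Two tracks merge iff they share
    at least one day and their mean IoU over shared days reaches
    ``merge_iou``; merging is transitive (connected components). The
    merged track's box on each day comes from the highest-score source
    covering that day.
    """
    tracks = [_to_global(t, tile_layout) for t in forward + backward]
    n = len(tracks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            shared = set(tracks[i].boxes) & set(tracks[j].boxes)
            if not shared:
                continue
            mean_iou = np.mean([iou(tracks[i].boxes[d], tracks[j].boxes[d]) for d in shared])
            if mean_iou >= merge_iou:
                union(i, j)

    groups: dict[int, list[Track]] = {}
    for i, t in enumerate(tracks):
        groups.setdefault(find(i), []).append(t)
    merged = []
    for k, (root, members) in enumerate(sorted(groups.items())):
        boxes: dict[float, Box] = {}
        scores: dict[float, float] = {}
        for t in members:
            for d, b in t.boxes.items():
                s = t.scores.get(d, 1.0)
                if d not in boxes or s > scores[d]:
                    boxes[d] = b
                    scores[d] = s
        merged.append(
            Track(track_id=k, boxes=boxes, scores=scores, tile="global",
                  direction="merged")
        )
    merged.sort(key=lambda t: (min(t.boxes), sorted(t.boxes.values())[0]))
    for i, t in enumerate(merged):
        t.track_id = i
    return merged


# --------------------------------------------------------------------------
# survival conversion
# --------------------------------------------------------------------------

def tracks_to_survival(
    tracks: list[Track],
    final_day: float,
    interval: float,
    group: str = "",
) -> pd.DataFrame:
    """Convert merged tracks to start-end-censor survival records.

    Start is the first detection day. A track that disappears before the
    final day dies at the first missed scheduled timepoint (last
    sighting + interval, event = 1); a track still present at the final
    day is censored there (event = 0). A track last seen one interval
    before the final day would place its death exactly on the final
    day, where a disappearance cannot be told apart from the end of
    observation; such records are censored, so event = 0 holds for
    every record with end = final day.
    """
    rows = []
    for t in tracks:
        days = t.days
        if not days:
            raise ValueError(f"track {t.track_id} has no detections")
        start = days[0]
        last = days[-1]
        if last + interval >= final_day:
            end, event = float(final_day), 0
        else:
            end, event = float(last + interval), 1
        rows.append(
            {"cell_id": t.track_id, "group": group, "start": float(start),
             "end": end, "event": event}
        )
    return pd.DataFrame(rows, columns=["cell_id", "group", "start", "end", "event"])


# --------------------------------------------------------------------------
# MOTA
# --------------------------------------------------------------------------

def mota(
    predicted: list[Track],
    ground_truth: list[Track],
    iou_threshold: float = 0.5,
) -> tuple[float, dict[str, int]]:
    """Multi-object tracking accuracy against ground-truth tracks.

    Per frame, surviving (gt, pred) matches from the previous frame are
    kept when still above the IoU threshold; remaining objects are
    matched greedily by descending IoU. MOTA = 1 - (FN + FP + IDSW) /
    total ground-truth objects; the components are returned alongside.
    """
    if not (0 < iou_threshold <= 1):
        raise ValueError("iou_threshold must be in (0, 1]")
    days = sorted({d for t in ground_truth for d in t.boxes} | {d for t in predicted for d in t.boxes})
    fn = fp = idsw = 0
    total_gt = 0
    last_match: dict[int, int] = {}  # gt id -> pred id
    for day in days:
        gts = {t.track_id: t.boxes[day] for t in ground_truth if day in t.boxes}
        preds = {t.track_id: t.boxes[day] for t in predicted if day in t.boxes}
        total_gt += len(gts)
        matches: dict[int, int] = {}
        # persist previous matches still valid
        for g, p in last_match.items():
            if g in gts and p in preds and iou(gts[g], preds[p]) >= iou_threshold:
                matches[g] = p
        free_g = [g for g in gts if g not in matches]
        free_p = [p for p in preds if p not in matches.values()]
        cands = sorted(
            ((iou(gts[g], preds[p]), g, p) for g in free_g for p in free_p),
            key=lambda x: (-x[0], x[1], x[2]),
        )
        for v, g, p in cands:
            if v < iou_threshold:
                break
            if g in matches or p in matches.values():
                continue
            matches[g] = p
        fn += len(gts) - len(matches)
        fp += len(preds) - len(matches)
        for g, p in matches.items():
            if g in last_match and last_match[g] != p:
                idsw += 1
        last_match.update(matches)
    score = 1.0 - (fn + fp + idsw) / total_gt if total_gt else 1.0
    return score, {"FN": fn, "FP": fp, "IDSW": idsw, "GT": total_gt}


# --------------------------------------------------------------------------
# parameter search
# --------------------------------------------------------------------------

def tune_tracker(
    param_space: dict[str, list],
    gt_movies: list[tuple[list[Detection], list[Track]]],
    budget: int = 20,
    seed: int = 0,
    iou_threshold: float = 0.5,
) -> tuple[TrackerParams, pd.DataFrame]:
    """Seeded random search over tracker parameters, maximizing mean MOTA.

    ``param_space`` maps TrackerParams field names to candidate values;
    ``gt_movies`` pairs per-movie detections with ground-truth tracks.
    Returns the best-evaluated parameters and the full evaluation log.
    The search hook is deliberately simple and swappable: the objective
    (MOTA) and the space define the optimization, not the strategy.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not param_space or any(len(v) == 0 for v in param_space.values()):
        raise ValueError("empty parameter space")
    rng = np.random.default_rng(seed)
    names = sorted(param_space)
    n_combos = int(np.prod([len(param_space[k]) for k in names]))
    tried: set[tuple] = set()
    log = []
    best = None
    for _ in range(budget):
        if len(tried) == n_combos:
            break
        while True:
            combo = tuple(param_space[k][rng.integers(len(param_space[k]))] for k in names)
            if combo not in tried:
                tried.add(combo)
                break
        params = TrackerParams(**dict(zip(names, combo)))
        try:
            params.validate()
        except ValueError:
            continue
        scores = []
        for dets, gt in gt_movies:
            tracks = link_tracks(dets, params)
            scores.append(mota(tracks, gt, iou_threshold)[0])
        mean_score = float(np.mean(scores)) if scores else math.nan
        log.append({**dict(zip(names, combo)), "mean_mota": mean_score})
        if best is None or mean_score > best[0]:
            best = (mean_score, params)
    if best is None:
        raise ValueError("no valid parameter combination evaluated")
    return best[1], pd.DataFrame(log)


# --------------------------------------------------------------------------
# subsampling
# --------------------------------------------------------------------------

def sample_cells(
    records: pd.DataFrame,
    n: int = 500,
    seed: int = 0,
    group_col: str = "group",
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Uniformly sample ``n`` survival records per group, without
    replacement (deterministic under the seed).

    Groups with fewer than ``n`` records are returned whole and flagged
    in the returned dict (group -> True when undersized).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    parts, flags = [], {}
    for g, df in records.groupby(group_col, sort=True):
        if len(df) <= n:
            parts.append(df)
            flags[g] = len(df) < n
        else:
            idx = rng.choice(len(df), size=n, replace=False)
            parts.append(df.iloc[np.sort(idx)])
            flags[g] = False
    return pd.concat(parts, ignore_index=True), flags
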