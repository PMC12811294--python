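"""Synthetic microscopy, trace and cohort generators with ground truth.

Every input the analysis pipeline consumes can be generated here:
multichannel culture images, longitudinal viability movies, neurite
kymograph stacks, extracellular-flux plates, biosensor time series and
survival cohorts. Each generator is deterministic under a fixed seed and
returns, alongside the rendered data, a ground-truth table keyed to it,
so every downstream stage can be benchmarked without any real data.

The cell archetypes encode the morphological criteria that distinguish
the three classes in converted cultures: induced motor neurons (iMN) are
small bright round somata (radius 5-10 µm) with 1-5 thin neurites;
non-neuronal cells are large flat dim ellipses (major axis >= 30 µm,
eccentricity >= 0.7); dead cells are 2-4 small bright fragments
(<= 4 µm) of condensed debris.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import Frame, PIXEL_SIZE_BY_MAGNIFICATION

DEFAULT_SCHEDULE = (12, 46, 2)  # first day, last day, interval (days)
MOTILITY_THRESHOLD_UM = 12.5
MOTILITY_DURATION_MIN = 10.0
KYMO_FRAME_RATE_HZ = 0.33

CLASS_IMN = "iMN"
CLASS_NON_IMN = "non-iMN"
CLASS_DEAD = "dead"


class SpecificationError(ValueError):
    """A generator spec is internally inconsistent."""


class PlacementError(RuntimeError):
    """Requested cells cannot be placed without exceeding the overlap bound."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Parameters of one synthetic culture field.

    Lengths are µm, areas µm², intensities arbitrary units on the same
    scale as the rendered frames.
    """

    field_size_um: tuple[float, float] = (250.0, 250.0)
    pixel_size_um: float = PIXEL_SIZE_BY_MAGNIFICATION[20]
    n_imn: int = 10
    n_non_imn: int = 5
    n_dead: int = 5
    soma_radius_um: tuple[float, float] = (5.0, 10.0)
    neurite_count: tuple[int, int] = (1, 5)
    neurite_length_um: tuple[float, float] = (20.0, 60.0)
    mito_count: tuple[int, int] = (8, 20)
    mito_area_um2: tuple[float, float] = (0.3, 0.8)
    mito_intensity: tuple[float, float] = (120.0, 220.0)
    tdp43_ratio: tuple[float, float] = (0.2, 1.2)
    background: float = 10.0
    noise_sigma: float = 2.0
    overlap_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_imn", "n_non_imn", "n_dead"):
            if getattr(self, name) < 0:
                raise SpecificationError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0:
            raise SpecificationError("pixel_size_um must be > 0")
        if self.noise_sigma < 0:
            raise SpecificationError("noise_sigma must be >= 0")
        if not (0 <= self.overlap_fraction <= 1):
            raise SpecificationError("overlap_fraction must be in [0, 1]")
        if self.soma_radius_um[0] <= 0 or self.soma_radius_um[1] < self.soma_radius_um[0]:
            raise SpecificationError("soma_radius_um must be an increasing positive range")


@dataclass
class GroupSpec:
    """One cohort arm: name, size and true log hazard ratio vs control."""

    name: str
    n_cells: int
    log_hr: float = 0.0


@dataclass
class CohortSpec:
    """Survival-cohort parameters for longitudinal viability imaging.

    ``baseline_hazard`` is the control-arm event rate in events/day; each
    group's rate is ``baseline_hazard * exp(log_hr)``. ``entry_day`` may
    be a single day (all cells recognized then) or a ``(lo, hi)`` range
    sampled uniformly and snapped to the imaging schedule.
    """

    groups: list[GroupSpec] = field(default_factory=lambda: [GroupSpec("control", 100)])
    baseline_hazard: float = 0.05
    entry_day: float | tuple[float, float] = 12.0
    final_day: float = 46.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard < 0:
            raise SpecificationError("baseline_hazard must be >= 0")
        entries = self.entry_day if isinstance(self.entry_day, tuple) else (self.entry_day,)
        if any(e >= self.final_day for e in entries):
            raise SpecificationError("final_day must exceed all entry days")
        for g in self.groups:
            if g.n_cells < 0:
                raise SpecificationError("group sizes must be >= 0")


@dataclass
class GroundTruth:
    """Ground-truth record bundle emitted next to every generated output."""

    cells: pd.DataFrame | None = None
    cell_labels: np.ndarray | None = None
    soma_labels: np.ndarray | None = None
    nucleus_labels: np.ndarray | None = None
    mitochondria: pd.DataFrame | None = None
    tracks: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    motility: pd.DataFrame | None = None
    motility_positions: np.ndarray | None = None  # (n_mito, n_frames) µm
    flux: pd.DataFrame | None = None
    series: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# rendering helpers
# --------------------------------------------------------------------------

def _paint_disk(img: np.ndarray, cy: float, cx: float, r_px: float, value: float) -> None:
    y0 = max(int(cy - r_px) - 1, 0)
    y1 = min(int(cy + r_px) + 2, img.shape[0])
    x0 = max(int(cx - r_px) - 1, 0)
    x1 = min(int(cx + r_px) + 2, img.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    img[y0:y1, x0:x1][m] = np.maximum(img[y0:y1, x0:x1][m], value)


def _paint_ellipse(img, cy, cx, ry, rx, theta, value) -> None:
    ext = max(ry, rx)
    y0 = max(int(cy - ext) - 1, 0)
    y1 = min(int(cy + ext) + 2, img.shape[0])
    x0 = max(int(cx - ext) - 1, 0)
    x1 = min(int(cx + ext) + 2, img.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dy * math.cos(theta) + dx * math.sin(theta)
    v = -dy * math.sin(theta) + dx * math.cos(theta)
    m = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    img[y0:y1, x0:x1][m] = np.maximum(img[y0:y1, x0:x1][m], value)


def _paint_gaussian_spot(img, cy, cx, sigma_px, amplitude) -> None:
    ext = max(int(4 * sigma_px) + 1, 2)
    y0 = max(int(cy) - ext, 0)
    y1 = min(int(cy) + ext + 1, img.shape[0])
    x0 = max(int(cx) - ext, 0)
    x1 = min(int(cx) + ext + 1, img.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)
    )


def _paint_polyline(img, pts_px: np.ndarray, half_width_px: float, value: float) -> None:
    """Paint a polyline with given half width by stamping disks per step."""
    for i in range(len(pts_px) - 1):
        p, q = pts_px[i], pts_px[i + 1]
        seg = np.linalg.norm(q - p)
        n = max(int(seg / 0.5), 1)
        for t in np.linspace(0, 1, n + 1):
            c = p + t * (q - p)
            _paint_disk(img, c[0], c[1], max(half_width_px, 0.7), value)


def _disk_overlap_area(r1: float, r2: float, d: float) -> float:
    """Area of the intersection of two disks with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    tri = 0.5 * math.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    return a1 + a2 - tri


def _place_cells(
    rng: np.random.Generator,
    field_um: tuple[float, float],
    radii_um: Sequence[float],
    overlap_fraction: float,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Rejection-sample soma centers (µm) honoring the disk-overlap bound."""
    placed: list[tuple[float, float, float]] = []
    out: list[tuple[float, float]] = []
    h, w = field_um
    for r in radii_um:
        if 2 * r > min(h, w):
            raise PlacementError(
                f"field {field_um} µm too small for a cell of radius {r:.1f} µm"
            )
        for _ in range(max_tries):
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            ok = True
            for (py, px, pr) in placed:
                d = math.hypot(cy - py, cx - px)
                lim = overlap_fraction * math.pi * min(r, pr) ** 2
                if _disk_overlap_area(r, pr, d) > lim:
                    ok = False
                    break
            if ok:
                placed.append((cy, cx, r))
                out.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place {len(radii_um)} cells in a {h:.0f}x{w:.0f} µm field "
                f"within the {overlap_fraction:.0%} soma-overlap bound"
            )
    return out


def _random_walk_path(
    rng: np.random.Generator,
    start_um: np.ndarray,
    length_um: float,
    step_um: float = 2.0,
    heading: float | None = None,
    jitter: float = 0.35,
) -> np.ndarray:
    """Random-walk polyline of the given arc length, points in µm (y, x)."""
    if heading is None:
        heading = rng.uniform(0, 2 * math.pi)
    pts = [start_um.astype(float)]
    travelled = 0.0
    while travelled < length_um:
        step = min(step_um, length_um - travelled)
        heading += rng.normal(0.0, jitter)
        pts.append(pts[-1] + step * np.array([math.sin(heading), math.cos(heading)]))
        travelled += step
    return np.array(pts)


def _bbox_of_mask(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1


# --------------------------------------------------------------------------
# culture image
# --------------------------------------------------------------------------

def generate_culture_image(spec: SceneSpec) -> tuple[dict[str, Frame], GroundTruth]:
    """Render one multichannel culture field with per-cell ground truth.

    Returns co-registered channels ``egfp`` (cytoplasm + neurites),
    ``hoechst`` (nuclei), ``tmrm`` (mitochondrial puncta) and ``tdp43``
    (antibody-like stain painted at each cell's true cytoplasm/nucleus
    intensity ratio), plus a :class:`GroundTruth` with labeled masks and
    one row per rendered cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    shape = (
        int(round(spec.field_size_um[0] / px)),
        int(round(spec.field_size_um[1] / px)),
    )
    egfp = np.zeros(shape)
    hoechst = np.zeros(shape)
    tmrm = np.zeros(shape)
    tdp43 = np.zeros(shape)
    cell_labels = np.zeros(shape, dtype=np.int32)
    soma_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)

    classes = (
        [CLASS_IMN] * spec.n_imn
        + [CLASS_NON_IMN] * spec.n_non_imn
        + [CLASS_DEAD] * spec.n_dead
    )
    # effective placement radius: soma for iMN, semi-major for flat cells,
    # debris-cluster radius for dead cells
    radii, cell_params = [], []
    for klass in classes:
        if klass == CLASS_IMN:
            r = rng.uniform(*spec.soma_radius_um)
            radii.append(r)
            cell_params.append({"r": r})
        elif klass == CLASS_NON_IMN:
            major = rng.uniform(16.0, 25.0)  # semi-major >= 15 µm -> axis >= 30 µm
            ecc = rng.uniform(0.72, 0.9)
            minor = major * math.sqrt(1 - ecc**2)
            radii.append(major)
            cell_params.append({"ry": major, "rx": minor, "theta": rng.uniform(0, math.pi)})
        else:
            radii.append(4.0)
            cell_params.append({})
    centers = _place_cells(rng, spec.field_size_um, radii, spec.overlap_fraction)

    rows = []
    mito_rows = []
    pending_cell_masks: list[tuple[int, np.ndarray]] = []
    for cid, (klass, (cy_um, cx_um), params) in enumerate(
        zip(classes, centers, cell_params), start=1
    ):
        cy, cx = cy_um / px, cx_um / px
        cell_m = np.zeros(shape, dtype=bool)
        soma_m = np.zeros(shape, dtype=bool)
        nuc_m = np.zeros(shape, dtype=bool)
        n_neurites = 0
        soma_r_um = np.nan
        if klass == CLASS_IMN:
            soma_r_um = params["r"]
            _paint_disk(soma_m, cy, cx, soma_r_um / px, True)
            cell_m |= soma_m
            n_neurites = int(rng.integers(spec.neurite_count[0], spec.neurite_count[1] + 1))
            base_angle = rng.uniform(0, 2 * math.pi)
            for k in range(n_neurites):
                ang = base_angle + 2 * math.pi * k / max(n_neurites, 1) + rng.normal(0, 0.3)
                start = np.array([cy_um, cx_um]) + soma_r_um * np.array(
                    [math.sin(ang), math.cos(ang)]
                )
                path = _random_walk_path(
                    rng, start, rng.uniform(*spec.neurite_length_um), heading=ang
                )
                path = np.clip(path, 1.0, np.array(spec.field_size_um) - 1.0)
                _paint_polyline(cell_m, path / px, 0.5 / px, True)
            _paint_disk(nuc_m, cy, cx, 0.55 * soma_r_um / px, True)
            amp_soma, amp_neurite = 200.0, 120.0
            egfp[soma_m] = np.maximum(egfp[soma_m], amp_soma)
            neur = cell_m & ~soma_m
            egfp[neur] = np.maximum(egfp[neur], amp_neurite)
        elif klass == CLASS_NON_IMN:
            _paint_ellipse(
                soma_m, cy, cx, params["ry"] / px, params["rx"] / px, params["theta"], True
            )
            cell_m |= soma_m
            _paint_ellipse(
                nuc_m, cy, cx, 0.35 * params["ry"] / px, 0.35 * params["rx"] / px,
                params["theta"], True,
            )
            egfp[soma_m] = np.maximum(egfp[soma_m], 60.0)
        else:  # dead: 2-4 fragments <= 4 µm across, within a ~8 µm cluster
            n_frag = int(rng.integers(2, 5))
            for _ in range(n_frag):
                fr = rng.uniform(0.8, 2.0)  # radius -> diameter <= 4 µm
                off = rng.uniform(-4.0, 4.0, size=2)
                _paint_disk(soma_m, cy + off[0] / px, cx + off[1] / px, fr / px, True)
            cell_m |= soma_m
            _paint_disk(nuc_m, cy, cx, 1.8 / px, True)  # condensed (pyknotic) nucleus
            egfp[soma_m] = np.maximum(egfp[soma_m], 180.0)

        hoechst[nuc_m] = np.maximum(hoechst[nuc_m], 150.0)
        ratio = rng.uniform(*spec.tdp43_ratio)
        nuc_level = 120.0
        tdp43[cell_m & ~nuc_m] = np.maximum(tdp43[cell_m & ~nuc_m], ratio * nuc_level)
        tdp43[nuc_m] = np.maximum(tdp43[nuc_m], nuc_level)

        n_mito = 0
        if klass == CLASS_IMN:
            n_mito = int(rng.integers(spec.mito_count[0], spec.mito_count[1] + 1))
            ys, xs = np.nonzero(soma_m)
            for mid in range(n_mito):
                j = rng.integers(len(ys))
                area = rng.uniform(*spec.mito_area_um2)
                inten = rng.uniform(*spec.mito_intensity)
                sigma_um = math.sqrt(area / math.pi) / 1.5
                _paint_gaussian_spot(tmrm, ys[j], xs[j], sigma_um / px, inten)
                mito_rows.append(
                    {"cell_id": cid, "mito_id": mid, "cy": ys[j], "cx": xs[j],
                     "area_um2": area, "intensity": inten}
                )

        # somata claim their pixels first (a neurite passing another
        # cell's body lies under it); neurites claim leftovers below
        soma_labels[soma_m & (soma_labels == 0)] = cid
        nucleus_labels[nuc_m & (nucleus_labels == 0)] = cid
        pending_cell_masks.append((cid, cell_m))
        y0, x0, y1, x1 = _bbox_of_mask(soma_m)
        rows.append(
            {"cell_id": cid, "klass": klass, "cy": cy, "cx": cx,
             "soma_radius_um": soma_r_um, "n_neurites": n_neurites,
             "n_mitochondria": n_mito, "tdp43_ratio": ratio,
             "y0": y0, "x0": x0, "y1": y1, "x1": x1}
        )

    cell_labels = soma_labels.copy()
    for cid, cell_m in pending_cell_masks:
        cell_labels[cell_m & (cell_labels == 0)] = cid

    frames = {}
    for name, img in [("egfp", egfp), ("hoechst", hoechst), ("tmrm", tmrm), ("tdp43", tdp43)]:
        noisy = img + spec.background + rng.normal(0, spec.noise_sigma, shape)
        frames[name] = Frame(np.clip(noisy, 0, None), px, channel=name, timepoint=0.0)

    columns = ["cell_id", "klass", "cy", "cx", "soma_radius_um", "n_neurites",
               "n_mitochondria", "tdp43_ratio", "y0", "x0", "y1", "x1"]
    gt = GroundTruth(
        cells=pd.DataFrame(rows, columns=columns),
        cell_labels=cell_labels,
        soma_labels=soma_labels,
        nucleus_labels=nucleus_labels,
        mitochondria=pd.DataFrame(
            mito_rows, columns=["cell_id", "mito_id", "cy", "cx", "area_um2", "intensity"]
        ),
    )
    return frames, gt


# --------------------------------------------------------------------------
# time-lapse viability movie
# --------------------------------------------------------------------------

def imaging_days(schedule: tuple[float, float, float] = DEFAULT_SCHEDULE) -> np.ndarray:
    """Scheduled imaging days: first to last inclusive at the given interval."""
    first, last, step = schedule
    return np.arange(first, last + 0.5 * step, step)


def generate_timelapse(
    spec: SceneSpec,
    cohort: CohortSpec,
    schedule: tuple[float, float, float] = DEFAULT_SCHEDULE,
) -> tuple[list[Frame], GroundTruth]:
    """Render a longitudinal viability movie of appearing/dying iMN.

    Each simulated cell appears at its entry day and, if it dies on day
    ``d``, is present only in frames with day < d (half-open presence),
    so the observed duration is exactly death day minus entry day. Cells
    surviving past the final frame are censored there. Ground truth
    carries per-frame bounding boxes (``tracks``) and start-end-censor
    survival records (``survival``).
    """
    spec.validate()
    cohort.validate()
    days = imaging_days(schedule)
    first, last, step = schedule
    rng = np.random.default_rng(cohort.seed)
    px = spec.pixel_size_um
    shape = (
        int(round(spec.field_size_um[0] / px)),
        int(round(spec.field_size_um[1] / px)),
    )

    radii, groups = [], []
    for g in cohort.groups:
        for _ in range(g.n_cells):
            radii.append(rng.uniform(*spec.soma_radius_um))
            groups.append(g)
    centers = _place_cells(rng, spec.field_size_um, radii, spec.overlap_fraction)

    surv_rows, track_rows = [], []
    cells = []
    for cid, (r_um, g, (cy_um, cx_um)) in enumerate(zip(radii, groups, centers), start=1):
        if isinstance(cohort.entry_day, tuple):
            raw = rng.uniform(*cohort.entry_day)
            entry = float(days[np.searchsorted(days, raw, side="left").clip(0, len(days) - 1)])
        else:
            entry = float(cohort.entry_day)
        rate = cohort.baseline_hazard * math.exp(g.log_hr)
        death_time = entry + (rng.exponential(1.0 / rate) if rate > 0 else math.inf)
        if death_time <= last:
            # snap the (unobserved) death to the first scheduled day after
            # the last sighting: the day the cell is first absent
            later = days[days > entry]
            death_day = float(later[np.searchsorted(later, death_time, side="left")
                                    .clip(0, len(later) - 1)])
            if death_time > later[-1]:
                death_day = math.inf
        else:
            death_day = math.inf
        # a death falling on the final scheduled day is indistinguishable
        # from the end of observation, so it is censored there
        event = 0 if (math.isinf(death_day) or death_day >= last) else 1
        end = float(last) if event == 0 else death_day
        surv_rows.append(
            {"cell_id": cid, "group": g.name, "start": entry, "end": end, "event": event}
        )
        r_px = r_um / px
        cy, cx = cy_um / px, cx_um / px
        box = (cy - r_px, cx - r_px, cy + r_px + 1, cx + r_px + 1)
        for d in days:
            if entry <= d and d < death_day:
                track_rows.append(
                    {"cell_id": cid, "day": float(d), "y0": box[0], "x0": box[1],
                     "y1": box[2], "x1": box[3]}
                )
        cells.append((cid, cy, cx, r_px, entry, death_day))

    frames = []
    for d in days:
        img = np.zeros(shape)
        for cid, cy, cx, r_px, entry, death_day in cells:
            if entry <= d < death_day:
                _paint_disk(img, cy, cx, r_px, 200.0)
        img += spec.background + rng.normal(0, spec.noise_sigma, shape)
        frames.append(
            Frame(np.clip(img, 0, None), px, channel="egfp", timepoint=float(d))
        )

    gt = GroundTruth(
        tracks=pd.DataFrame(track_rows, columns=["cell_id", "day", "y0", "x0", "y1", "x1"]),
        survival=pd.DataFrame(surv_rows, columns=["cell_id", "group", "start", "end", "event"]),
    )
    return frames, gt


# --------------------------------------------------------------------------
# kymograph stack
# --------------------------------------------------------------------------

def n_frames_for(duration_s: float, frequency_hz: float) -> int:
    """Frame count for a duration at a frame rate: floor(D·f) + 1 (t=0 included)."""
    return int(math.floor(duration_s * frequency_hz)) + 1


def generate_kymo_stack(
    n_mito: int = 20,
    motile_fraction: float = 0.4,
    speed_range_um_min: tuple[float, float] = (1.5, 3.0),
    duration_min: float = MOTILITY_DURATION_MIN,
    frequency_hz: float = KYMO_FRAME_RATE_HZ,
    path_length_um: float = 80.0,
    pixel_size_um: float = PIXEL_SIZE_BY_MAGNIFICATION[40],
    background: float = 10.0,
    noise_sigma: float = 2.0,
    jitter_um: float = 0.02,
    reversal_prob: float = 0.005,
    seed: int = 0,
) -> tuple[list[Frame], np.ndarray, GroundTruth]:
    """Render a neurite time-lapse with mitochondria moving along a path.

    Returns the frame stack, the neurite path polyline (µm, soma end
    first) and a per-mitochondrion ground-truth motility table. Motile
    mitochondria move at a fixed speed drawn from ``speed_range_um_min``
    with rare direction reversals; stationary ones jitter with standard
    deviation ``jitter_um``, far below the motility threshold.
    """
    if not (0 <= motile_fraction <= 1):
        raise SpecificationError("motile_fraction must be in [0, 1]")
    if duration_min <= 0:
        raise SpecificationError("duration must be > 0")
    n_motile = int(round(n_mito * motile_fraction))
    if n_motile > 0 and speed_range_um_min[1] * duration_min < MOTILITY_THRESHOLD_UM:
        raise SpecificationError(
            f"max speed {speed_range_um_min[1]} µm/min cannot exceed the "
            f"{MOTILITY_THRESHOLD_UM} µm motility threshold within {duration_min} min"
        )
    rng = np.random.default_rng(seed)
    nT = n_frames_for(duration_min * 60.0, frequency_hz)
    dt_min = (1.0 / frequency_hz) / 60.0

    # gently curved path, points every 1 µm, arc-length parametrized
    n_pts = int(path_length_um) + 1
    headings = np.cumsum(rng.normal(0, 0.03, n_pts))
    steps = np.stack([np.sin(headings), np.cos(headings)], axis=1)
    path = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])[:n_pts]
    path -= path.min(axis=0)
    margin = 4.0
    path += margin

    labels = np.array([True] * n_motile + [False] * (n_mito - n_motile))
    s0 = rng.uniform(2.0, path_length_um - 2.0, n_mito)
    amps = rng.uniform(150.0, 250.0, n_mito)
    positions = np.zeros((n_mito, nT))
    gt_rows = []
    for i in range(n_mito):
        s = np.empty(nT)
        s[0] = s0[i]
        if labels[i]:
            speed = rng.uniform(*speed_range_um_min)
            direction = rng.choice([-1.0, 1.0])
            for t in range(1, nT):
                if rng.random() < reversal_prob:
                    direction = -direction
                nxt = s[t - 1] + direction * speed * dt_min
                if nxt < 2.0 or nxt > path_length_um - 2.0:
                    direction = -direction
                    nxt = s[t - 1] + direction * speed * dt_min
                s[t] = nxt
        else:
            s[1:] = s0[i] + rng.normal(0, jitter_um, nT - 1)
        positions[i] = s
        ds = np.diff(s)
        total = float(np.abs(ds).sum())
        antero = float(ds[ds > 0].sum())
        retro = float(-ds[ds < 0].sum())
        gt_rows.append(
            {"mito_id": i, "motile": bool(total >= MOTILITY_THRESHOLD_UM),
             "total_um": total, "antero_um": antero, "retro_um": retro,
             "mean_speed_um_min": total / ((nT - 1) * dt_min),
             "max_speed_um_min": float(np.abs(ds).max() / dt_min), "s0_um": s0[i]}
        )

    extent = path.max(axis=0) + margin
    shape = (int(round(extent[0] / pixel_size_um)), int(round(extent[1] / pixel_size_um)))
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])
    frames = []
    for t in range(nT):
        img = np.zeros(shape)
        for i in range(n_mito):
            yx = np.array(
                [np.interp(positions[i, t], arc, path[:, 0]),
                 np.interp(positions[i, t], arc, path[:, 1])]
            )
            _paint_gaussian_spot(
                img, yx[0] / pixel_size_um, yx[1] / pixel_size_um,
                0.3 / pixel_size_um, amps[i],
            )
        img += background + rng.normal(0, noise_sigma, shape)
        frames.append(
            Frame(np.clip(img, 0, None), pixel_size_um, channel="tmrm",
                  timepoint=t / frequency_hz, time_unit="s")
        )
    gt = GroundTruth(motility=pd.DataFrame(gt_rows), motility_positions=positions)
    return frames, path, gt


# --------------------------------------------------------------------------
# flux plate
# --------------------------------------------------------------------------

FLUX_PHASES = ("baseline", "post-oligomycin", "post-FCCP", "post-inhibitors")


@dataclass
class LineFluxParams:
    """True bioenergetic parameters of one cell line (raw, pre-normalization)."""

    line: str
    basal_ocr: float = 80.0
    maximal_ocr: float = 130.0
    atp_linked_ocr: float = 60.0
    baseline_ecar: float = 40.0
    non_mito_ocr: float = 20.0
    non_glyc_ecar: float = 10.0
    cells_per_well: int = 2000


def generate_flux_plate(
    lines: Sequence[LineFluxParams],
    wells_per_line: int = 6,
    cycles_per_phase: int = 3,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a mito-stress-test plate as a long-format measurement table.

    Phase layout follows the injection protocol (baseline, oligomycin,
    FCCP, antimycin A + rotenone + 2-DG); per-phase plateau means equal
    the true values before additive Gaussian noise. Columns: well, line,
    cycle, phase, ocr, ecar, cell_count.
    """
    if cycles_per_phase < 2:
        raise SpecificationError("need >= 2 measurement cycles per phase")
    rng = np.random.default_rng(seed)
    rows = []
    for lp in lines:
        if lp.cells_per_well <= 0:
            raise SpecificationError("cells_per_well must be > 0")
        phase_ocr = {
            "baseline": lp.basal_ocr + lp.non_mito_ocr,
            "post-oligomycin": lp.basal_ocr - lp.atp_linked_ocr + lp.non_mito_ocr,
            "post-FCCP": lp.maximal_ocr + lp.non_mito_ocr,
            "post-inhibitors": lp.non_mito_ocr,
        }
        phase_ecar = {
            "baseline": lp.baseline_ecar + lp.non_glyc_ecar,
            "post-oligomycin": lp.baseline_ecar + lp.non_glyc_ecar,
            "post-FCCP": lp.baseline_ecar + lp.non_glyc_ecar,
            "post-inhibitors": lp.non_glyc_ecar,
        }
        for w in range(wells_per_line):
            well = f"{lp.line}_w{w}"
            cyc = 0
            for phase in FLUX_PHASES:
                for _ in range(cycles_per_phase):
                    rows.append(
                        {"well": well, "line": lp.line, "cycle": cyc, "phase": phase,
                         "ocr": phase_ocr[phase] + rng.normal(0, noise_sigma),
                         "ecar": phase_ecar[phase] + rng.normal(0, noise_sigma),
                         "cell_count": lp.cells_per_well}
                    )
                    cyc += 1
    truth = pd.DataFrame(
        [{"line": lp.line, "basal_ocr": lp.basal_ocr, "maximal_ocr": lp.maximal_ocr,
          "atp_linked_ocr": lp.atp_linked_ocr, "baseline_ecar": lp.baseline_ecar,
          "non_mito_ocr": lp.non_mito_ocr, "non_glyc_ecar": lp.non_glyc_ecar,
          "cells_per_well": lp.cells_per_well} for lp in lines]
    )
    return pd.DataFrame(rows), GroundTruth(flux=truth)


# --------------------------------------------------------------------------
# intensity time series (MitoSOX / PercevalHR)
# --------------------------------------------------------------------------

PERCEVAL_INJECTIONS_MIN = (5.0, 15.0)  # oligomycin, 2-deoxy-D-glucose


def generate_intensity_series(
    kind: str,
    *,
    slope_per_h: float = 2.0,
    phase_ratios: tuple[float, float, float] = (1.0, 0.7, 0.4),
    timestep_min: float | None = None,
    duration_min: float | None = None,
    noise_sigma: float = 0.0,
    n_cells: int = 1,
    baseline: float = 100.0,
    slope_sd_per_h: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-cell biosensor traces.

    ``kind="mitosox"``: linear intensity increase (default sampled every
    10 min for 3 h, the ROS-imaging schedule); per-cell true slopes are
    drawn N(slope, slope_sd) and recorded. ``kind="perceval"``: 490/405
    excitation-ratio traces, piecewise constant at ``phase_ratios`` with
    transitions at the oligomycin (5 min) and 2-DG (15 min) injections.
    """
    rng = np.random.default_rng(seed)
    if kind == "mitosox":
        timestep_min = 10.0 if timestep_min is None else timestep_min
        duration_min = 180.0 if duration_min is None else duration_min
        if duration_min <= 0:
            raise SpecificationError("duration must be > 0")
        t = np.arange(0.0, duration_min + 0.5 * timestep_min, timestep_min)
        rows, truth = [], []
        for c in range(n_cells):
            sl = slope_per_h + rng.normal(0, slope_sd_per_h)
            vals = baseline + sl * t / 60.0 + rng.normal(0, noise_sigma, t.size)
            rows.append(pd.DataFrame({"cell_id": c, "t_min": t, "intensity": vals}))
            truth.append({"cell_id": c, "slope_per_h": sl})
        return pd.concat(rows, ignore_index=True), GroundTruth(series=pd.DataFrame(truth))
    if kind == "perceval":
        timestep_min = 5.0 / 60.0 if timestep_min is None else timestep_min  # 0.2 Hz
        duration_min = 25.0 if duration_min is None else duration_min
        if duration_min <= 0:
            raise SpecificationError("duration must be > 0")
        if duration_min < PERCEVAL_INJECTIONS_MIN[1]:
            raise SpecificationError("duration must cover both injection times")
        t = np.arange(0.0, duration_min + 0.5 * timestep_min, timestep_min)
        ratio = np.where(
            t < PERCEVAL_INJECTIONS_MIN[0], phase_ratios[0],
            np.where(t < PERCEVAL_INJECTIONS_MIN[1], phase_ratios[1], phase_ratios[2]),
        )
        rows, truth = [], []
        for c in range(n_cells):
            ch405 = np.full(t.size, baseline) + rng.normal(0, noise_sigma, t.size)
            ch490 = ratio * baseline + rng.normal(0, noise_sigma, t.size)
            rows.append(
                pd.DataFrame({"cell_id": c, "t_min": t, "ch490": ch490, "ch405": ch405})
            )
            truth.append(
                {"cell_id": c, "ratio_steady": phase_ratios[0],
                 "ratio_oligo": phase_ratios[1], "ratio_2dg": phase_ratios[2]}
            )
        return pd.concat(rows, ignore_index=True), GroundTruth(series=pd.DataFrame(truth))
    raise SpecificationError(f"unknown series kind: {kind!r}")


# --------------------------------------------------------------------------
# survival cohort
# --------------------------------------------------------------------------

def generate_survival_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Draw start-end-censor survival records from the cohort's hazards.

    Event times are exponential with rate ``baseline_hazard * exp(log_hr)``
    from each cell's entry day; times beyond the final observation day
    are censored there. Columns: cell_id, group, log_hr, start, end, event.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    rows = []
    cid = 1
    for g in cohort.groups:
        rate = cohort.baseline_hazard * math.exp(g.log_hr)
        for _ in range(g.n_cells):
            if isinstance(cohort.entry_day, tuple):
                entry = rng.uniform(*cohort.entry_day)
            else:
                entry = float(cohort.entry_day)
            dt = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            end = entry + dt
            if end >= cohort.final_day:
                end, event = cohort.final_day, 0
            else:
                event = 1
            rows.append(
                {"cell_id": cid, "group": g.name, "log_hr": g.log_hr,
                 "start": entry, "end": float(end), "event": event}
            )
            cid += 1
    return pd.DataFrame(rows, columns=["cell_id", "group", "log_hr", "start", "end", "event"])
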