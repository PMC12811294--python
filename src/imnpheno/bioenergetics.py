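"""Extracellular-flux corrections, respiratory/glycolytic parameters,
PercevalHR ratios and MitoSOX slopes.

Flux wells follow the mito-stress-test injection protocol: baseline,
oligomycin (blocks ATP synthase), FCCP (uncouples, maximal respiration),
then antimycin A + rotenone + 2-deoxy-D-glucose (stops mitochondrial
respiration and glycolysis). The post-inhibitors plateau defines
non-mitochondrial oxygen consumption and non-glycolytic acidification;
both are subtracted from every OCR/ECAR value, wells with any negative
corrected phase mean are discarded, and surviving rates are normalized
by the well's cell count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FLUX_PHASES, PERCEVAL_INJECTIONS_MIN


class ProtocolError(ValueError):
    """A well is missing one of the protocol phases."""


@dataclass
class BioenergeticParams:
    """Per-line respiratory/glycolytic parameters, cell-count normalized.

    The algebraic identities hold exactly: spare = maximal - basal and
    oligomycin-sensitive = basal - post-oligomycin mean.
    """

    line: str
    basal_ocr: float
    maximal_ocr: float
    oligo_sensitive_ocr: float
    spare_capacity: float
    baseline_ecar: float
    ocr_ecar_ratio: float
    n_wells: int
    sem: dict[str, float] | None = None


def _phase_means(well: pd.DataFrame, col: str) -> dict[str, float]:
    means = {}
    for phase in FLUX_PHASES:
        vals = well.loc[well["phase"] == phase, col]
        if len(vals) == 0:
            raise ProtocolError(f"missing phase {phase!r}")
        means[phase] = float(vals.mean())
    return means


def correct_flux(well: pd.DataFrame) -> tuple[pd.DataFrame | None, str | None]:
    """Correct one well's OCR/ECAR series, or reject it.

    Subtracts the post-inhibitors phase mean from every OCR value (and
    the analogous non-glycolytic term from every ECAR value), rejects
    the well when any corrected phase mean is negative, then divides the
    surviving values by the well's cell count. Returns (corrected, None)
    or (None, reason).
    """
    well = well.copy()
    cells = float(well["cell_count"].iloc[0])
    if cells <= 0:
        raise ValueError("cell count must be > 0")
    ocr_means = _phase_means(well, "ocr")
    ecar_means = _phase_means(well, "ecar")
    non_mito = ocr_means["post-inhibitors"]
    non_glyc = ecar_means["post-inhibitors"]
    well["ocr"] = well["ocr"] - non_mito
    well["ecar"] = well["ecar"] - non_glyc
    for col in ("ocr", "ecar"):
        for phase in FLUX_PHASES[:-1]:
            if well.loc[well["phase"] == phase, col].mean() < 0:
                return None, f"negative corrected {col.upper()} rate in {phase}"
    well["ocr"] /= cells
    well["ecar"] /= cells
    return well, None


def derive_params(
    wells: list[pd.DataFrame],
    line: str = "",
    phase_stat: str = "mean",
) -> BioenergeticParams:
    """Derive respiratory/glycolytic parameters from corrected wells.

    Per well: basal = baseline-phase mean OCR; maximal = post-FCCP mean;
    oligomycin-sensitive = basal - post-oligomycin mean; spare = maximal
    - basal; baseline ECAR mean; OCR/ECAR = basal OCR / baseline ECAR
    computed per well (respecting well pairing), then averaged across
    wells with SEM. ``phase_stat="last"`` uses each phase's final cycle
    instead of its mean.
    """
    if not wells:
        raise ValueError("zero surviving wells: parameters undefined")

    def stat(w: pd.DataFrame, phase: str, col: str) -> float:
        vals = w.loc[w["phase"] == phase, col]
        if len(vals) == 0:
            raise ProtocolError(f"missing phase {phase!r}")
        return float(vals.iloc[-1] if phase_stat == "last" else vals.mean())

    rows = []
    for w in wells:
        basal = stat(w, "baseline", "ocr")
        maximal = stat(w, "post-FCCP", "ocr")
        post_oligo = stat(w, "post-oligomycin", "ocr")
        ecar = stat(w, "baseline", "ecar")
        rows.append(
            {"basal": basal, "maximal": maximal,
             "oligo_sensitive": basal - post_oligo, "spare": maximal - basal,
             "ecar": ecar, "ratio": basal / ecar if ecar != 0 else math.nan}
        )
    df = pd.DataFrame(rows)
    n = len(df)
    sem = {
        k: float(df[k].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0 for k in df.columns
    }
    basal = float(df["basal"].mean())
    maximal = float(df["maximal"].mean())
    return BioenergeticParams(
        line=line,
        basal_ocr=basal,
        maximal_ocr=maximal,
        oligo_sensitive_ocr=float(df["oligo_sensitive"].mean()),
        spare_capacity=maximal - basal,
        baseline_ecar=float(df["ecar"].mean()),
        ocr_ecar_ratio=float(df["ratio"].mean()),
        n_wells=n,
        sem=sem,
    )


def analyze_plate(plate: pd.DataFrame) -> tuple[dict[str, BioenergeticParams], pd.DataFrame]:
    """Correct every well of a long-format plate table and derive
    per-line parameters; rejected wells are returned with reasons."""
    params: dict[str, BioenergeticParams] = {}
    rejected = []
    for line, line_df in plate.groupby("line", sort=True):
        surviving = []
        for well, wdf in line_df.groupby("well", sort=True):
            corrected, reason = correct_flux(wdf)
            if corrected is None:
                rejected.append({"well": well, "line": line, "reason": reason})
            else:
                surviving.append(corrected)
        if surviving:
            params[str(line)] = derive_params(surviving, line=str(line))
    return params, pd.DataFrame(rejected, columns=["well", "line", "reason"])


# --------------------------------------------------------------------------
# PercevalHR
# --------------------------------------------------------------------------

def perceval_ratio(
    series490: np.ndarray,
    series405: np.ndarray,
    t_min: np.ndarray,
    injections_min: tuple[float, float] = PERCEVAL_INJECTIONS_MIN,
) -> tuple[np.ndarray, dict[str, float]]:
    """Pointwise 490/405 excitation ratio with per-phase means.

    The 490/405 ratio reports the intracellular ATP/ADP ratio; phases
    are split at the oligomycin and 2-deoxy-D-glucose injection times.
    Returns the ratio trace and means for steady-state, post-oligomycin
    and post-2DG phases.
    """
    s490 = np.asarray(series490, float)
    s405 = np.asarray(series405, float)
    t = np.asarray(t_min, float)
    if s490.shape != s405.shape or s490.shape != t.shape:
        raise ValueError("series must be aligned with equal lengths")
    if np.any(s405 <= 0):
        raise ValueError("non-positive 405 nm values: ratio undefined")
    ratio = s490 / s405
    t1, t2 = injections_min
    phases = {
        "steady_state": ratio[t < t1],
        "post_oligomycin": ratio[(t >= t1) & (t < t2)],
        "post_2dg": ratio[t >= t2],
    }
    means = {k: float(v.mean()) if len(v) else math.nan for k, v in phases.items()}
    return ratio, means


# --------------------------------------------------------------------------
# MitoSOX
# --------------------------------------------------------------------------

def mitosox_slope(intensity: np.ndarray, t_min: np.ndarray) -> float:
    """OLS slope of MitoSOX intensity vs time, in intensity units per hour.

    The signal-increase rate proxies mitochondrial superoxide
    production. Needs >= 3 timepoints; negative slopes are legitimate
    output (flagged downstream as possible photobleaching).
    """
    y = np.asarray(intensity, float)
    t = np.asarray(t_min, float)
    if y.size < 3:
        raise ValueError("need >= 3 timepoints for a slope")
    t_h = t / 60.0
    slope = np.polyfit(t_h, y, 1)[0]
    return float(slope)


def mitosox_slopes(series: pd.DataFrame) -> pd.DataFrame:
    """Per-cell MitoSOX slopes from a long-format (cell_id, t_min,
    intensity) table."""
    rows = [
        {"cell_id": cid, "slope_per_h": mitosox_slope(df["intensity"], df["t_min"])}
        for cid, df in series.groupby("cell_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=["cell_id", "slope_per_h"])
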