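"""Three-class morphological cell classification and transformation efficiency.

Each segmented cell is labelled iMN, non-iMN or dead from seven
morphological features of its soma and neurites. The default model is a
multinomial logistic regression on standardized features (trained on
labelled synthetic archetypes); a thresholds-only rule classifier with
the same 3-class contract is available where no training data exists.
An external learned classifier can be plugged in through the same
``predict(features) -> labels`` interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.linear_model import LogisticRegression

from .frames import Frame
from .morphometry import skeletonize_cell
from .segmentation import crop_centered, roundness_of
from .synthetic import CLASS_DEAD, CLASS_IMN, CLASS_NON_IMN

FEATURE_COLUMNS = [
    "soma_area_um2", "roundness", "fragment_count", "neurite_count",
    "skeleton_length_um", "mean_intensity", "max_intensity",
]

#: exact posterior ties are broken against inflating efficiency
CLASS_PRIORITY = {CLASS_DEAD: 0, CLASS_NON_IMN: 1, CLASS_IMN: 2}

DEFAULT_CROP_SIDE_UM = 27.6


class DegenerateTrainingError(ValueError):
    """Training table holds fewer than two classes."""


def extract_cell_features(
    soma_mask: np.ndarray,
    cell_mask: np.ndarray,
    frame: Frame,
    crop_side_um: float = DEFAULT_CROP_SIDE_UM,
) -> dict[str, float]:
    """Morphological feature vector of one segmented cell.

    Features: soma area (µm²), soma roundness, fragment count inside a
    centre crop (thresholded connected components — separates condensed
    debris from intact somata), neurite count (skeleton branches leaving
    the soma), total neurite skeleton length (µm), and mean/max
    intensity over the cell region.
    """
    soma = np.asarray(soma_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not soma.any() or not cell.any():
        raise ValueError("empty mask")
    px = frame.pixel_size_um
    area = float(soma.sum()) * px**2
    rnd = roundness_of(soma)

    cy, cx = ndi.center_of_mass(soma)
    crop = crop_centered(frame, (cy, cx), crop_side_um).data
    if np.ptp(crop) > 0:
        thr = threshold_otsu(crop)
        lab, _ = ndi.label(crop > thr)
        sizes = np.bincount(lab.ravel())[1:]
        fragments = int((sizes * px**2 >= 1.0).sum())
    else:
        fragments = 0

    # neurites: connected components of the cell mask outside the
    # (slightly dilated) soma that touch the soma rim
    dil = ndi.binary_dilation(soma, iterations=2)
    outside = cell & ~dil
    lab, n = ndi.label(outside, structure=np.ones((3, 3)))
    rim = ndi.binary_dilation(dil, iterations=2) & ~dil
    touching = np.unique(lab[rim & (lab > 0)])
    min_px = max(int(2.0 / px), 2)
    sizes = np.bincount(lab.ravel())
    neurites = int(sum(1 for t in touching if sizes[t] >= min_px))

    if outside.any():
        skel_len = skeletonize_cell(cell, px, soma_mask=dil).total_length_um
    else:
        skel_len = 0.0
    vals = frame.data[cell]
    return {
        "soma_area_um2": area,
        "roundness": rnd,
        "fragment_count": float(fragments),
        "neurite_count": float(neurites),
        "skeleton_length_um": float(skel_len),
        "mean_intensity": float(vals.mean()),
        "max_intensity": float(vals.max()),
    }


@dataclass
class ClassifierModel:
    """Serializable multinomial-logistic cell classifier.

    Stores standardization constants and fitted weights, so predictions
    are deterministic and the model round-trips through JSON.
    """

    classes: list[str]
    coef: np.ndarray
    intercept: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    validation_accuracy: float = math.nan
    n_train: int = 0
    n_validation: int = 0
    seed: int = 0

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = (features[FEATURE_COLUMNS].to_numpy(float) - self.feature_mean) / self.feature_std
        z = X @ self.coef.T + self.intercept
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, features: pd.DataFrame) -> list[str]:
        if len(features) == 0:
            return []
        proba = self.predict_proba(features)
        out = []
        for row in proba:
            best = row.max()
            tied = [self.classes[i] for i in range(len(row)) if row[i] == best]
            out.append(min(tied, key=lambda c: CLASS_PRIORITY[c]))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "validation_accuracy": self.validation_accuracy,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassifierModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            classes=d["classes"], coef=np.array(d["coef"]),
            intercept=np.array(d["intercept"]),
            feature_mean=np.array(d["feature_mean"]),
            feature_std=np.array(d["feature_std"]),
            validation_accuracy=d["validation_accuracy"],
            n_train=d["n_train"], n_validation=d["n_validation"], seed=d["seed"],
        )


def fit_classifier(
    labelled: pd.DataFrame,
    seed: int = 0,
    validation_fraction: float = 0.25,
) -> ClassifierModel:
    """Fit the multinomial-logistic classifier on a labelled feature table.

    ``labelled`` must carry the seven feature columns plus a ``klass``
    column. A seeded random split holds out ``validation_fraction`` of
    the rows; validation accuracy is stored on the model.
    """
    classes = sorted(labelled["klass"].unique())
    if len(classes) < 2:
        raise DegenerateTrainingError("training table holds a single class")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(labelled))
    n_val = max(int(round(validation_fraction * len(labelled))), 1)
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        train_idx = idx
    train = labelled.iloc[train_idx]
    val = labelled.iloc[val_idx]

    X = train[FEATURE_COLUMNS].to_numpy(float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    clf = LogisticRegression(max_iter=2000, C=10.0, random_state=seed)
    clf.fit((X - mean) / std, train["klass"])
    coef, intercept = clf.coef_, clf.intercept_
    if len(clf.classes_) == 2:  # expand binary form to one row per class
        coef = np.vstack([-coef, coef]) / 2
        intercept = np.array([-intercept[0], intercept[0]]) / 2
    model = ClassifierModel(
        classes=list(clf.classes_), coef=coef, intercept=intercept,
        feature_mean=mean, feature_std=std,
        n_train=len(train_idx), n_validation=len(val_idx), seed=seed,
    )
    pred = model.predict(val)
    model.validation_accuracy = float(np.mean(np.array(pred) == val["klass"].to_numpy()))
    return model


class RuleClassifier:
    """Thresholds-only fallback with the same 3-class contract.

    Encodes the archetype criteria directly: dead cells are small
    fragmented debris; non-neuronal cells are large and flat; everything
    else with a compact soma is an iMN.
    """

    def __init__(
        self,
        dead_max_area_um2: float = 60.0,
        non_imn_min_area_um2: float = 330.0,
        min_roundness: float = 0.6,
    ) -> None:
        self.dead_max_area_um2 = dead_max_area_um2
        self.non_imn_min_area_um2 = non_imn_min_area_um2
        self.min_roundness = min_roundness

    def predict(self, features: pd.DataFrame) -> list[str]:
        out = []
        for _, r in features.iterrows():
            if r["soma_area_um2"] <= self.dead_max_area_um2 or (
                r["fragment_count"] >= 2 and r["soma_area_um2"] < 100.0
            ):
                out.append(CLASS_DEAD)
            elif (
                r["soma_area_um2"] >= self.non_imn_min_area_um2
                or r["roundness"] < self.min_roundness
            ):
                out.append(CLASS_NON_IMN)
            else:
                out.append(CLASS_IMN)
        return out


def classify_cells(features: pd.DataFrame, model) -> pd.DataFrame:
    """Attach one class label per row, preserving input order."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise KeyError(f"feature schema mismatch, missing columns: {missing}")
    out = features.copy()
    out["klass"] = model.predict(features)
    return out


def transformation_efficiency(
    records: pd.DataFrame,
    by: list[str] | None = None,
    denominator: str = "all",
) -> tuple[float, pd.DataFrame]:
    """Fraction of detected cells exhibiting neuronal morphology.

    Default denominator counts all three classes (dead cells included);
    ``denominator="alive"`` restricts to iMN + non-iMN. When ``by``
    names grouping columns (e.g. line and batch), a per-group table with
    the across-batch SEM is returned alongside the overall proportion.
    """
    if len(records) == 0:
        raise ValueError("cannot compute efficiency of zero records")

    def _eff(df: pd.DataFrame) -> float:
        denom = df if denominator == "all" else df[df["klass"] != CLASS_DEAD]
        if len(denom) == 0:
            return math.nan
        return float((denom["klass"] == CLASS_IMN).sum() / len(denom))

    overall = _eff(records)
    if by:
        rows = []
        group_cols = by[:-1] if len(by) > 1 else by
        for key, df in records.groupby(by):
            key = key if isinstance(key, tuple) else (key,)
            rows.append({**dict(zip(by, key)), "efficiency": _eff(df), "n_cells": len(df)})
        per_batch = pd.DataFrame(rows)
        summary = (
            per_batch.groupby(group_cols)["efficiency"]
            .agg(mean="mean", sem=lambda s: s.std(ddof=1) / math.sqrt(len(s)) if len(s) > 1 else 0.0,
                 n_batches="count")
            .reset_index()
        )
        return overall, summary
    return overall, pd.DataFrame(
        [{"efficiency": overall, "n_cells": len(records)}]
    )
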