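"""Shared fixtures: one mixed culture scene, its segmentation, and a
labelled feature table, generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from imnpheno import classify as cls
from imnpheno import segmentation as seg
from imnpheno import synthetic as syn


@pytest.fixture(scope="session")
def mixed_scene():
    """Default-noise culture with 20 iMN, 10 non-iMN, 10 dead cells."""
    spec = syn.SceneSpec(
        field_size_um=(400.0, 400.0), n_imn=20, n_non_imn=10, n_dead=10, seed=21
    )
    frames, gt = syn.generate_culture_image(spec)
    return spec, frames, gt


@pytest.fixture(scope="session")
def mixed_segmentation(mixed_scene):
    _, frames, _ = mixed_scene
    return seg.segment_culture(frames["egfp"], frames["hoechst"])


def features_with_truth(seed: int, n=(20, 10, 10), field=(400.0, 400.0)) -> pd.DataFrame:
    """Segment a generated scene and label each detected cell's features
    with the true class of the cell whose nucleus seeded its region."""
    spec = syn.SceneSpec(
        field_size_um=field, n_imn=n[0], n_non_imn=n[1], n_dead=n[2], seed=seed
    )
    frames, gt = syn.generate_culture_image(spec)
    masks = seg.segment_culture(frames["egfp"], frames["hoechst"])
    lut = gt.cells.set_index("cell_id")["klass"]
    rows = []
    for cid in np.unique(masks["cells"]):
        if cid == 0:
            continue
        soma_m = masks["soma"] == cid
        if not soma_m.any():
            continue
        f = cls.extract_cell_features(soma_m, masks["cells"] == cid, frames["egfp"])
        nuc_m = masks["nuclei"] == cid
        cy, cx = ndi.center_of_mass(nuc_m if nuc_m.any() else soma_m)
        true_id = (
            gt.nucleus_labels[int(cy), int(cx)]
            or gt.soma_labels[int(cy), int(cx)]
            or gt.cell_labels[int(cy), int(cx)]
        )
        rows.append({**f, "klass": lut.get(true_id, "bg") if true_id else "bg"})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def labelled_features():
    """Training features from three scenes (seeds 31-33), truth-labelled."""
    df = pd.concat([features_with_truth(s) for s in (31, 32, 33)], ignore_index=True)
    return df[df["klass"] != "bg"].reset_index(drop=True)


@pytest.fixture(scope="session")
def fitted_model(labelled_features):
    return cls.fit_classifier(labelled_features, seed=0)
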