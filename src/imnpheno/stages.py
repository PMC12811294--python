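"""Registered pipeline stages for :func:`imnpheno.io.run_stage`.

Each stage is a thin, validated wrapper over one library operation so
runs can be orchestrated from configuration with uniform logging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .frames import Frame
from .io import RunConfig, StageError, register_stage
from .segmentation import roundness_of, segment_culture
from .synthetic import SceneSpec, generate_culture_image


@register_stage("simulate-culture")
def _simulate_culture(config: RunConfig, inputs: dict) -> dict:
    spec = inputs.get("spec") or SceneSpec(seed=config.seed)
    frames, gt = generate_culture_image(spec)
    return {"frames": frames, "cells": gt.cells, "ground_truth": gt}


@register_stage("segment")
def _segment(config: RunConfig, inputs: dict) -> dict:
    frames: dict[str, Frame] = inputs.get("frames", {})
    for chan in ("egfp", "hoechst"):
        if chan not in frames:
            raise StageError(f"segment stage requires channel {chan!r}")
    masks = segment_culture(frames["egfp"], frames["hoechst"])
    px = frames["egfp"].pixel_size_um
    rows = []
    for cid in np.unique(masks["soma"]):
        if cid == 0:
            continue
        m = masks["soma"] == cid
        cy, cx = ndi.center_of_mass(m)
        rows.append(
            {"label": int(cid), "cy": float(cy), "cx": float(cx),
             "area_um2": float(m.sum()) * px**2, "roundness": roundness_of(m)}
        )
    cells = pd.DataFrame(rows, columns=["label", "cy", "cx", "area_um2", "roundness"])
    return {"cells": cells, "masks": masks}
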