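"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: overlap
counting is a literal triple loop over voxels, and scoring is a literal
transcription of the deduction rules, so they can serve as an oracle for
the production implementations.
"""

from __future__ import annotations

import numpy as np


def brute_force_overlaps(mask_data: np.ndarray, atlas) -> dict:
    """Per-(code, hemisphere) lesion/region voxel counts via explicit loops."""
    label_of = {r.label: r.key for r in atlas.regions}
    region_voxels = {r.key: 0 for r in atlas.regions}
    lesion_voxels = {r.key: 0 for r in atlas.regions}
    labels = atlas.labels.data
    nx, ny, nz = labels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lab = int(labels[i, j, k])
                if lab == 0:
                    continue
                key = label_of[lab]
                region_voxels[key] += 1
                if mask_data[i, j, k] > 0:
                    lesion_voxels[key] += 1
    return {
        key: (lesion_voxels[key], region_voxels[key])
        for key in region_voxels
    }


def brute_force_score(mask_data: np.ndarray, atlas,
                      cortical_threshold: float = 1.0 / 3.0) -> dict:
    """Literal application of the ASPECTS deduction rules."""
    overlaps = brute_force_overlaps(mask_data, atlas)
    nuclear = {"CA", "LE", "IC", "IN"}
    deductions = set()
    for (code, hemi), (les, reg) in overlaps.items():
        if code in nuclear:
            if les >= 1:
                deductions.add((code, hemi))
        else:
            if les / reg >= cortical_threshold:
                deductions.add((code, hemi))
    score = {}
    for hemi in ("left", "right"):
        score[hemi] = 10 - sum(1 for (_, h) in deductions if h == hemi)
    lesion_in = {
        hemi: any(les > 0 for (c, h), (les, _) in overlaps.items() if h == hemi)
        for hemi in ("left", "right")
    }
    if lesion_in["left"] and lesion_in["right"]:
        reported = min(score.values())
    elif lesion_in["left"]:
        reported = score["left"]
    elif lesion_in["right"]:
        reported = score["right"]
    else:
        reported = 10
    fractions = {key: les / reg for key, (les, reg) in overlaps.items()}
    return {"fractions": fractions, "deductions": deductions,
            "score_left": score["left"], "score_right": score["right"],
            "reported": reported}
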