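"""End-to-end helpers tying the pipeline stages together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import median_grid, resample_inplane
from .pet_metrics import compute_metrics
from .table import FeatureTable, assemble
from .texture import extract_all

__all__ = ["resample_cohort", "cohort_to_table", "clinical_frame"]


def resample_cohort(patients):
    """Resample every patient in-plane to the cohort's median grid.

    Returns new patient objects; patients already on the median grid are
    passed through unchanged (copied).
    """
    from dataclasses import replace

    target = median_grid([p.volumes.ct.shape[:2] for p in patients])
    out = []
    for p in patients:
        pair, mask = resample_inplane(p.volumes, p.mask, target)
        out.append(replace(p, volumes=pair, mask=mask))
    return out


def clinical_frame(patients) -> pd.DataFrame:
    """Clinical covariates + label, id-indexed."""
    rows = {
        p.id: {
            "age": p.clinical.age,
            "sex": p.clinical.sex,
            "location": p.clinical.location,
            "ca199": p.clinical.ca199,
            "resectability": p.clinical.resectability,
            "label": p.label,
        }
        for p in patients
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def cohort_to_table(patients, ng: int = 32, resample_to_median: bool = False) -> FeatureTable:
    """Extract all features for a cohort and assemble the unified table."""
    if resample_to_median:
        patients = resample_cohort(patients)
    img = {}
    met = {}
    with np.errstate(all="ignore"):
        for p in patients:
            img[p.id] = extract_all(p.volumes, p.mask, ng=ng)
            m = compute_metrics(p.volumes.pet, p.mask, p.volumes.spacing_mm)
            met[p.id] = {"suvmax": m.suvmax, "mtv_cc": m.mtv_cc, "tlg": m.tlg}
    image_features = pd.DataFrame.from_dict(img, orient="index")
    pet_metrics = pd.DataFrame.from_dict(met, orient="index")
    return assemble(image_features, pet_metrics, clinical_frame(patients))
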