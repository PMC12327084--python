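"""JHU ICBM-DTI-81 white-matter atlas label fixture.

The 48 deep-white-matter labels of the JHU ICBM-DTI-81 parcellation:
6 midline structures plus 21 left/right homologous pairs.  Merging each
hemisphere pair into one region yields the 27 ROIs used throughout the
cohort pipeline.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["JHU_MIDLINE", "JHU_PAIRED", "jhu_labels", "jhu_pairing", "merged_roi_names"]

JHU_MIDLINE: tuple[str, ...] = (
    "Middle cerebellar peduncle",
    "Pontine crossing tract",
    "Genu of corpus callosum",
    "Body of corpus callosum",
    "Splenium of corpus callosum",
    "Fornix (column and body)",
)

JHU_PAIRED: tuple[str, ...] = (
    "Corticospinal tract",
    "Medial lemniscus",
    "Inferior cerebellar peduncle",
    "Superior cerebellar peduncle",
    "Cerebral peduncle",
    "Anterior limb of internal capsule",
    "Posterior limb of internal capsule",
    "Retrolenticular part of internal capsule",
    "Anterior corona radiata",
    "Superior corona radiata",
    "Posterior corona radiata",
    "Posterior thalamic radiation",
    "Sagittal stratum",
    "External capsule",
    "Cingulum (cingulate gyrus)",
    "Cingulum (hippocampus)",
    "Fornix (cres) / Stria terminalis",
    "Superior longitudinal fasciculus",
    "Superior fronto-occipital fasciculus",
    "Uncinate fasciculus",
    "Tapetum",
)


def jhu_labels() -> list[str]:
    """All 48 atlas labels (midline + left/right of each pair)."""
    labels = list(JHU_MIDLINE)
    for name in JHU_PAIRED:
        labels.append(f"{name} L")
        labels.append(f"{name} R")
    return labels


def jhu_pairing() -> pd.DataFrame:
    """Pairing table mapping each of the 48 labels to its merged ROI name.

    Columns: ``label``, ``merged_name``, ``hemisphere`` (L/R/M).  Midline
    labels map to themselves.
    """
    rows = [(m, m, "M") for m in JHU_MIDLINE]
    for name in JHU_PAIRED:
        rows.append((f"{name} L", name, "L"))
        rows.append((f"{name} R", name, "R"))
    return pd.DataFrame(rows, columns=["label", "merged_name", "hemisphere"])


def merged_roi_names() -> list[str]:
    """The 27 merged ROI names (6 midline + 21 hemisphere-merged)."""
    return list(JHU_MIDLINE) + list(JHU_PAIRED)
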