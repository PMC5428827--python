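"""The fixed registry of the 65 base features.

Category counts are the contract: 16 shape, 11 intensity-histogram, 22
co-occurrence (GLCM), 5 NGTDM and 11 run-length (RLM). Non-shape features
("texture" in the screening sense, 49 of them) are computed under all four
preprocessing variants during screening; shape features are computed once per
scan from the contour, so a screening pass yields 49*4 + 16 = 212
feature/preprocessing combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .glcm import GLCM_FEATURE_NAMES
from .intensity import INTENSITY_FEATURE_NAMES
from .ngtdm import NGTDM_FEATURE_NAMES
from .rlm import RLM_FEATURE_NAMES
from .shape import SHAPE_FEATURE_NAMES

_FORMULA_REFS = {
    "shape": "mesh/PCA geometry (see shape module)",
    "intensity": "first-order statistics (see intensity module)",
    "COM": "Haralick co-occurrence statistics (see glcm module)",
    "NGTDM": "Amadasun-King neighborhood difference statistics (see ngtdm module)",
    "RLM": "Galloway/Chu run-length statistics (see rlm module)",
}


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    category: str  # shape | intensity | COM | NGTDM | RLM
    formula_ref: str


def _entries():
    out = []
    for n in SHAPE_FEATURE_NAMES:
        out.append(RegistryEntry(f"shape_{n}", "shape", _FORMULA_REFS["shape"]))
    for n in INTENSITY_FEATURE_NAMES:
        out.append(RegistryEntry(f"int_{n}", "intensity", _FORMULA_REFS["intensity"]))
    for n in GLCM_FEATURE_NAMES:
        out.append(RegistryEntry(f"glcm_{n}", "COM", _FORMULA_REFS["COM"]))
    for n in NGTDM_FEATURE_NAMES:
        out.append(RegistryEntry(f"ngtdm_{n}", "NGTDM", _FORMULA_REFS["NGTDM"]))
    for n in RLM_FEATURE_NAMES:
        out.append(RegistryEntry(f"rlm_{n}", "RLM", _FORMULA_REFS["RLM"]))
    return tuple(out)


FEATURE_REGISTRY: tuple[RegistryEntry, ...] = _entries()

CATEGORY_COUNTS = {"shape": 16, "intensity": 11, "COM": 22, "NGTDM": 5, "RLM": 11}

SHAPE_FEATURES = tuple(e.name for e in FEATURE_REGISTRY if e.category == "shape")
TEXTURE_FEATURES = tuple(e.name for e in FEATURE_REGISTRY if e.category != "shape")


def registry_frame() -> pd.DataFrame:
    """Registry as a DataFrame (exportable to CSV)."""
    return pd.DataFrame(
        [(e.name, e.category, e.formula_ref) for e in FEATURE_REGISTRY],
        columns=["feature", "category", "formula_ref"],
    )
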