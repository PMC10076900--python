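"""Shared containers for per-point thickness measurements."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Samples above this are considered runaway measurements, discarded, counted.
MAX_PLAUSIBLE_THICKNESS_MM = 15.0

METHODS = ("3D-MN", "3D-NN", "3D-RT", "2D-CN", "2D-SN")


@dataclass
class ThicknessMap:
    """Per-point thickness samples of one method on one structure.

    ``origins`` are the physical points (mm) each sample is anchored to (and
    by which it was allocated to a subregion); ``values`` are thicknesses in
    mm; ``counts`` records failed/skipped measurements by cause.
    """

    method: str
    structure: str
    origins: np.ndarray
    values: np.ndarray
    subregions: np.ndarray
    counts: dict = field(default_factory=dict)
    knee_id: str = ""

    def __post_init__(self):
        self.origins = np.asarray(self.origins, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        self.subregions = np.asarray(self.subregions, dtype="<U4")
        if not (len(self.origins) == len(self.values) == len(self.subregions)):
            raise ValueError("inconsistent sample array lengths")
        if len(self.values) and self.values.min() < 0:
            raise ValueError("negative thickness sample")

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "knee_id": self.knee_id,
                "method": self.method,
                "structure": self.structure,
                "subregion": self.subregions,
                "x_mm": self.origins[:, 0],
                "y_mm": self.origins[:, 1],
                "z_mm": self.origins[:, 2],
                "thickness_mm": self.values,
            }
        )


def apply_thickness_cap(
    values: np.ndarray, counts: dict, cap: float = MAX_PLAUSIBLE_THICKNESS_MM
) -> np.ndarray:
    """Mask of samples passing the plausibility cap; over-cap ones counted."""
    keep = values <= cap
    n_over = int((~keep).sum())
    if n_over:
        counts["over_cap"] = counts.get("over_cap", 0) + n_over
    return keep
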