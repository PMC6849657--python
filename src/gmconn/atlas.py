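"""Atlas definitions: a labeled volume partitioning the template frame into
90 named cortical/subcortical regions, AAL-style.

The bundled synthetic atlas partitions the template grid into 90 rectangular
blocks carrying the standard 90 AAL region names — enough structure for
region aggregation without shipping (or downloading) the real atlas, which
can be supplied from NIfTI + TSV files instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["AtlasDefinition", "bundled_atlas", "load_atlas", "AAL90_NAMES"]

N_REGIONS = 90

_AAL45 = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid", "Frontal_Mid_Orb",
    "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Inf_Orb", "Rolandic_Oper",
    "Supp_Motor_Area", "Olfactory", "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus",
    "Insula", "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual", "Occipital_Sup",
    "Occipital_Mid", "Occipital_Inf", "Fusiform", "Postcentral", "Parietal_Sup",
    "Parietal_Inf", "SupraMarginal", "Angular", "Precuneus", "Paracentral_Lobule",
    "Caudate", "Putamen", "Pallidum", "Thalamus", "Heschl", "Temporal_Sup",
    "Temporal_Pole_Sup", "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]
#: The 90 region names in conventional order (left/right interleaved).
AAL90_NAMES = [f"{name}_{side}" for name in _AAL45 for side in ("L", "R")]


@dataclass
class AtlasDefinition:
    """Label volume + region lookup table (exactly 90 nonzero region ids)."""

    label_volume: np.ndarray  # 3-D int grid, 0 = background
    affine: np.ndarray
    region_table: pd.DataFrame  # columns: region_id, region_name

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        self.affine = np.asarray(self.affine, dtype=float)
        ids = self.region_table["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids) or np.any(ids == 0):
            raise ValueError("region_table ids must be distinct and nonzero")
        if len(ids) != N_REGIONS:
            raise ValueError(f"atlas must define exactly {N_REGIONS} regions, got {len(ids)}")
        present = np.setdiff1d(np.unique(self.label_volume), [0])
        unknown = np.setdiff1d(present, ids)
        if unknown.size:
            raise ValueError(f"label volume contains ids not in the region table: {unknown[:5]}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.region_table["region_id"].to_numpy()


def bundled_atlas(
    shape: tuple[int, int, int] = (30, 30, 30),
    affine: np.ndarray | None = None,
) -> AtlasDefinition:
    """Synthetic 90-region atlas: a 5 x 6 x 3 rectangular partition of the
    template grid, labeled 1..90 with AAL-style names."""
    factors = (5, 6, 3)
    if any(s < f for s, f in zip(shape, factors)):
        raise ValueError(f"shape {shape} too small for a {factors} partition")
    labels = np.zeros(shape, dtype=np.int16)
    xs = np.array_split(np.arange(shape[0]), factors[0])
    ys = np.array_split(np.arange(shape[1]), factors[1])
    zs = np.array_split(np.arange(shape[2]), factors[2])
    rid = 1
    for x in xs:
        for y in ys:
            for z in zs:
                labels[np.ix_(x, y, z)] = rid
                rid += 1
    table = pd.DataFrame(
        {"region_id": np.arange(1, N_REGIONS + 1), "region_name": AAL90_NAMES}
    )
    return AtlasDefinition(
        label_volume=labels,
        affine=np.eye(4) if affine is None else affine,
        region_table=table,
    )


def load_atlas(label_path: str | Path, table_path: str | Path) -> AtlasDefinition:
    """Load an atlas from a NIfTI label volume and a TSV region table."""
    img = nib.load(str(label_path))
    table = pd.read_csv(table_path, sep="\t")
    if not {"region_id", "region_name"} <= set(table.columns):
        raise ValueError("region table must have columns region_id, region_name")
    return AtlasDefinition(
        label_volume=np.asarray(img.get_fdata()).round().astype(int),
        affine=np.asarray(img.affine, dtype=float),
        region_table=table[["region_id", "region_name"]].copy(),
    )
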