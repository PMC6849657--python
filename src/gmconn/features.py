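"""Feature assembly: collapse cube-level efficiencies onto the 90 atlas
regions and build each subject's 93-feature vector (90 regional mean
efficiencies + brain volume + network size + mean degree), optionally
extended with clinical covariates (age, tumor hemisphere, tumor lobe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

from .atlas import AtlasDefinition
from .metrics import GlobalMetrics, global_metrics, nodal_efficiency
from .network import CubeNodeSet, parcellate_cubes, compute_similarity, threshold_network
from .volume import GrayMatterVolume

__all__ = [
    "ClinicalCovariates",
    "GLOBAL_FEATURES",
    "CLINICAL_FEATURES",
    "LOBE_CATEGORIES",
    "assign_regions",
    "aggregate_efficiency",
    "assemble_features",
    "extract_features",
    "core_feature_names",
]

logger = logging.getLogger(__name__)

GLOBAL_FEATURES = ["brain_volume", "network_size", "mean_degree"]
LOBE_CATEGORIES = ["frontal", "insular", "occipital", "parietal", "temporal", "multifocal"]
CLINICAL_FEATURES = ["age", "hemisphere_left"] + [f"lobe_{c}" for c in LOBE_CATEGORIES]


@dataclass(frozen=True)
class ClinicalCovariates:
    age: float
    hemisphere: str  # "left" / "right"
    lobe: str  # one of LOBE_CATEGORIES

    def encode(self) -> pd.Series:
        """Fixed encoding: age, left=1 indicator, lobe one-hot (6 columns)."""
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.lobe not in LOBE_CATEGORIES:
            raise ValueError(f"unknown lobe {self.lobe!r}")
        vals = [float(self.age), 1.0 if self.hemisphere == "left" else 0.0]
        vals += [1.0 if self.lobe == c else 0.0 for c in LOBE_CATEGORIES]
        return pd.Series(vals, index=CLINICAL_FEATURES)


def core_feature_names(atlas: AtlasDefinition) -> list[str]:
    """The documented, stable 93-column ordering."""
    return [f"eff_{n}" for n in atlas.region_table["region_name"]] + GLOBAL_FEATURES


def assign_regions(centroids: np.ndarray, atlas: AtlasDefinition) -> np.ndarray:
    """Atlas region id of the voxel containing each world-mm centroid
    (nearest-voxel rounding); 0 = background or outside the atlas grid."""
    vox = apply_affine(np.linalg.inv(atlas.affine), np.atleast_2d(centroids))
    idx = np.rint(vox).astype(int)
    shape = atlas.label_volume.shape
    inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    region = np.zeros(len(idx), dtype=int)
    ii = idx[inside]
    region[inside] = atlas.label_volume[ii[:, 0], ii[:, 1], ii[:, 2]]
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d node centroids fall outside the atlas grid", n_out)
    return region


def aggregate_efficiency(
    nodal_eff: np.ndarray,
    region_ids: np.ndarray,
    atlas: AtlasDefinition,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean nodal efficiency per atlas region.

    Nodes with region id 0 (unassigned) are excluded; a region containing no
    node gets efficiency 0 and is reported in the returned ``empty_regions``
    mask (aligned with the atlas region-table order).
    """
    nodal_eff = np.asarray(nodal_eff, dtype=float)
    region_ids = np.asarray(region_ids)
    if nodal_eff.shape != region_ids.shape:
        raise ValueError("nodal efficiencies and region ids must have equal length")
    ids = atlas.region_ids
    means = np.zeros(len(ids))
    empty = np.zeros(len(ids), dtype=bool)
    for k, rid in enumerate(ids):
        sel = region_ids == rid
        if sel.any():
            means[k] = nodal_eff[sel].mean()
        else:
            empty[k] = True
    if empty.any():
        logger.warning(
            "%d atlas regions contain no network node; imputed efficiency 0",
            int(empty.sum()),
        )
    return means, empty


def assemble_features(
    regional: np.ndarray,
    global_m: GlobalMetrics,
    clinical: ClinicalCovariates | None = None,
    atlas: AtlasDefinition | None = None,
) -> pd.Series:
    """Build the subject's feature vector in the documented fixed order:
    90 regional efficiencies, brain_volume, network_size, mean_degree, then
    (optionally) age, hemisphere indicator and the 6-lobe one-hot block."""
    regional = np.asarray(regional, dtype=float)
    if regional.shape != (90,):
        raise ValueError(f"expected 90 regional efficiencies, got {regional.shape}")
    if atlas is not None:
        names = core_feature_names(atlas)
    else:
        names = [f"eff_region_{i:02d}" for i in range(1, 91)] + GLOBAL_FEATURES
    vals = np.concatenate(
        [regional, [global_m.brain_volume, float(global_m.network_size), global_m.mean_degree]]
    )
    out = pd.Series(vals, index=names)
    if clinical is not None:
        out = pd.concat([out, clinical.encode()])
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("feature vector contains non-finite values")
    return out


def extract_features(
    volume: GrayMatterVolume,
    atlas: AtlasDefinition,
    *,
    min_gm: float = 0.1,
    threshold_method: str = "permutation_fpr",
    threshold_param: float = 0.05,
    n_permutations: int = 20,
    rotation_invariant: bool = False,
    clinical: ClinicalCovariates | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Full per-subject chain: cubes → similarity → threshold → efficiency
    → regional aggregation → feature vector."""
    nodes = parcellate_cubes(volume, min_gm=min_gm)
    sim = compute_similarity(nodes, rotation_invariant=rotation_invariant)
    net = threshold_network(
        sim, threshold_method, threshold_param,
        nodes=nodes, n_permutations=n_permutations, seed=seed,
    )
    eff = nodal_efficiency(net)
    region_ids = assign_regions(nodes.centroids, atlas)
    regional, _ = aggregate_efficiency(eff, region_ids, atlas)
    gm = global_metrics(net, nodes, volume)
    return assemble_features(regional, gm, clinical=clinical, atlas=atlas)
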