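"""Synthetic cohorts of post-VBM-like gray-matter maps.

Real gray-matter covariance connectomes are built from patient MRI that is
not publicly deposited, so this module generates stand-in cohorts whose
*statistical* structure matches what the downstream pipeline needs to see:
volumes in a common template frame whose cube-to-cube correlation pattern
differs between two classes with a controllable effect size, plus clinical
covariates (age, tumor hemisphere, tumor lobe) whose association with the
class label is itself controllable.

Generative model
----------------
The volume interior (a one-cube background shell is left at exactly zero) is
tiled into 3x3x3-voxel cubes, and the cubes are partitioned into
``n_latent_regions`` contiguous blocks.  Each subject draws one latent score
per block from an equicorrelated multivariate normal whose inter-block
correlation is ``rho0`` for wild-type-like subjects and
``rho0 + 0.3 * effect_size`` (capped) for mutant-like subjects.  A fixed
zero-mean spatial motif, replicated in every cube, is scaled by the block's
latent score and added to a shared smooth baseline template together with
voxelwise noise.  Within a subject, two cubes from blocks b and b' then
correlate roughly like the product of their latent scores, so the more
strongly the latent scores co-vary (mutant-like class), the denser and more
efficient the thresholded network — which is exactly the kind of
class-informative regional-efficiency difference the classifier stage is
meant to recover.  At ``effect_size = 0`` the two classes are exchangeable
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import GrayMatterVolume, save_volume

__all__ = ["LesionSpec", "CohortSpec", "SyntheticSubject", "generate_subject", "generate_cohort", "write_cohort"]

CUBE_EDGE = 3

# Baseline inter-block latent correlation (both classes) and the increment
# applied to the mutant-like class per unit effect_size.
_RHO_BASE = 0.05
_RHO_PER_EFFECT = 0.3
_RHO_MAX = 0.95

# Amplitude of the block-score x motif signal relative to the baseline
# template jitter (sd 0.1) and voxel noise; chosen so that cube pairs with
# aligned latent scores correlate strongly while misaligned pairs do not.
_SIGNAL_AMPLITUDE = 1.0
_TEMPLATE_MEAN = 0.5
_TEMPLATE_JITTER_SD = 0.1

LOBES = ["frontal", "insular", "occipital", "parietal", "temporal", "multifocal"]
# Primary-site frequencies of diffuse glioma (normalized); frontal dominates.
_LOBE_BASE_P = np.array([0.42, 0.06, 0.03, 0.12, 0.23, 0.14])
_P_LEFT = 0.72
_AGE_MEAN_WT = 48.0
_AGE_SD = 13.0
_AGE_SHIFT_PER_ASSOC = 12.0  # mutant-like subjects younger on average
_FRONTAL_TILT_PER_ASSOC = 0.20  # mutant-like tumors more often frontal
_HEMI_TILT_PER_ASSOC = 0.12


@dataclass(frozen=True)
class LesionSpec:
    """Optional focal lesion: voxels within ``radius`` of the center of the
    block ``block_index`` are multiplied by ``1 - intensity_reduction``."""

    block_index: int
    radius: float
    intensity_reduction: float

    def validate(self) -> None:
        if not 0.0 <= self.intensity_reduction <= 1.0:
            raise ValueError("lesion intensity_reduction must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``volume_shape`` dimensions must each be a multiple of 3 so the cube
    tiling is exact.  ``effect_size`` controls the between-class difference
    in inter-block latent coupling (0 = exchangeable classes);
    ``clinical_assoc`` in [0, 1] controls how strongly age/hemisphere/lobe
    associate with the class label.
    """

    n_subjects: int = 60
    class_balance: float = 0.63
    volume_shape: tuple[int, int, int] = (30, 30, 30)
    n_latent_regions: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.1
    lesion: LesionSpec | None = None
    clinical_assoc: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        shape = tuple(self.volume_shape)
        if len(shape) != 3 or any(int(s) != s or s <= 0 for s in shape):
            raise ValueError("volume_shape must be a triple of positive integers")
        if any(s % CUBE_EDGE != 0 for s in shape):
            raise ValueError(
                f"volume_shape {shape} must have every dimension divisible by "
                f"{CUBE_EDGE} so the cube tiling is exact"
            )
        if any(s < 3 * CUBE_EDGE for s in shape):
            raise ValueError(
                f"volume_shape {shape} too small: need at least one interior cube "
                f"inside the one-cube background shell"
            )
        if self.n_latent_regions < 1:
            raise ValueError("n_latent_regions must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.clinical_assoc <= 1.0:
            raise ValueError("clinical_assoc must lie in [0, 1]")
        if self.lesion is not None:
            self.lesion.validate()
        n_cubes = int(np.prod([s // CUBE_EDGE - 2 for s in shape]))
        if self.n_latent_regions > n_cubes:
            raise ValueError(
                f"n_latent_regions={self.n_latent_regions} exceeds the "
                f"{n_cubes} interior cubes of shape {shape}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if d.get("lesion") is not None:
            d["lesion"] = LesionSpec(**d["lesion"])
        if "volume_shape" in d:
            d["volume_shape"] = tuple(d["volume_shape"])
        return cls(**d)


@dataclass
class SyntheticSubject:
    """One generated subject: the volume, its label and clinical covariates.

    ``latent_scores`` exposes the per-block latent draws so the generative
    covariance structure can be checked directly against sample correlations.
    """

    subject_id: str
    volume: GrayMatterVolume
    label: int
    age: float
    tumor_hemisphere: str
    tumor_lobe: str
    latent_scores: np.ndarray


def _class_rho(spec: CohortSpec, label: int) -> float:
    rho = _RHO_BASE + (_RHO_PER_EFFECT * spec.effect_size if label else 0.0)
    return min(rho, _RHO_MAX)


class _CohortTemplate:
    """Structures shared by every subject of a cohort: the baseline template,
    the cube→block partition and the spatial motif.  Deterministic given the
    spec seed."""

    def __init__(self, spec: CohortSpec):
        spec.validate()
        self.spec = spec
        shape = tuple(spec.volume_shape)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E]))

        # Interior mask: drop a one-cube shell so background voxels are 0.
        grid = tuple(s // CUBE_EDGE for s in shape)
        inner = tuple(g - 2 for g in grid)
        cube_ix = np.stack(
            np.meshgrid(*[np.arange(1, g - 1) for g in grid], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        self.cube_index = cube_ix  # (n_cubes, 3) cube-grid coordinates
        self.n_cubes = cube_ix.shape[0]
        assert self.n_cubes == int(np.prod(inner))

        # Contiguous blocks: split the lexicographically ordered cube list
        # into near-equal runs (slab-like, hence contiguous).
        splits = np.array_split(np.arange(self.n_cubes), spec.n_latent_regions)
        self.block_of_cube = np.empty(self.n_cubes, dtype=int)
        for b, ix in enumerate(splits):
            self.block_of_cube[ix] = b

        self.template = np.zeros(shape)
        jitter = rng.normal(0.0, _TEMPLATE_JITTER_SD, size=shape)
        lo = CUBE_EDGE
        hi = tuple(CUBE_EDGE * (g - 1) for g in grid)
        sl = tuple(slice(lo, h) for h in hi)
        self.interior_slices = sl
        self.template[sl] = np.clip(_TEMPLATE_MEAN + jitter[sl], 0.05, None)

        motif = rng.normal(size=CUBE_EDGE**3)
        motif -= motif.mean()
        motif /= motif.std()
        self.motif = motif.reshape((CUBE_EDGE,) * 3)

        # Per-voxel block label (-1 background) for building subject volumes.
        self.block_volume = np.full(shape, -1, dtype=int)
        for (cx, cy, cz), b in zip(cube_ix, self.block_of_cube):
            self.block_volume[
                cx * CUBE_EDGE : (cx + 1) * CUBE_EDGE,
                cy * CUBE_EDGE : (cy + 1) * CUBE_EDGE,
                cz * CUBE_EDGE : (cz + 1) * CUBE_EDGE,
            ] = b

    def block_center_voxel(self, block_index: int) -> np.ndarray:
        """Voxel coordinates of the centroid of a block's cubes."""
        cubes = self.cube_index[self.block_of_cube == block_index]
        if cubes.size == 0:
            raise ValueError(f"block {block_index} is empty")
        return cubes.mean(axis=0) * CUBE_EDGE + (CUBE_EDGE - 1) / 2.0


def _draw_latents(spec: CohortSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    """Equicorrelated normal scores: z_b = sqrt(rho)*g + sqrt(1-rho)*e_b."""
    rho = _class_rho(spec, label)
    k = spec.n_latent_regions
    shared = rng.normal()
    indiv = rng.normal(size=k)
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv


def _draw_clinical(spec: CohortSpec, label: int, rng: np.random.Generator):
    a = spec.clinical_assoc
    age = float(
        np.clip(rng.normal(_AGE_MEAN_WT - _AGE_SHIFT_PER_ASSOC * a * label, _AGE_SD), 18, 85)
    )
    p_left = np.clip(_P_LEFT + _HEMI_TILT_PER_ASSOC * a * (1 if label else -1), 0.05, 0.95)
    hemisphere = "left" if rng.random() < p_left else "right"
    p = _LOBE_BASE_P.copy()
    if label:
        p[0] += _FRONTAL_TILT_PER_ASSOC * a
    p /= p.sum()
    lobe = LOBES[rng.choice(len(LOBES), p=p)]
    return age, hemisphere, lobe


def generate_subject(
    spec: CohortSpec,
    label: int,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    template: _CohortTemplate | None = None,
) -> SyntheticSubject:
    """Generate one subject with the given class label.

    ``rng`` supplies all subject-level randomness; the cohort-level template
    (baseline volume, block partition, motif) depends only on ``spec.seed``.
    """
    tpl = template or _CohortTemplate(spec)
    spec = tpl.spec
    z = _draw_latents(spec, int(bool(label)), rng)

    values = tpl.template.copy()
    inside = tpl.block_volume >= 0
    motif_tile = np.tile(tpl.motif, tuple(s // CUBE_EDGE for s in values.shape))
    values[inside] += _SIGNAL_AMPLITUDE * z[tpl.block_volume[inside]] * motif_tile[inside]
    values[inside] += rng.normal(0.0, spec.noise_sd, size=int(inside.sum()))
    np.clip(values, 0.0, None, out=values)

    if spec.lesion is not None:
        center = tpl.block_center_voxel(spec.lesion.block_index)
        grids = np.ogrid[tuple(slice(0, s) for s in values.shape)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sphere = dist2 <= spec.lesion.radius**2
        values[sphere] *= 1.0 - spec.lesion.intensity_reduction

    age, hemisphere, lobe = _draw_clinical(spec, int(bool(label)), rng)
    vol = GrayMatterVolume(values=values, affine=np.eye(4), subject_id=subject_id)
    return SyntheticSubject(
        subject_id=subject_id,
        volume=vol,
        label=int(bool(label)),
        age=age,
        tumor_hemisphere=hemisphere,
        tumor_lobe=lobe,
        latent_scores=z,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate the full cohort and its subject table.

    Exactly ``n_subjects`` subjects; the number of label-1 subjects is
    ``round(n_subjects * class_balance)`` (within one subject of the exact
    fraction).  Deterministic given the spec, including its seed.
    """
    spec.validate()
    tpl = _CohortTemplate(spec)
    n_pos = int(round(spec.n_subjects * spec.class_balance))
    n_pos = min(max(n_pos, 1), spec.n_subjects - 1) if spec.n_subjects > 1 else n_pos
    labels = np.zeros(spec.n_subjects, dtype=int)
    labels[:n_pos] = 1
    order_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA1]))
    order_rng.shuffle(labels)

    streams = np.random.SeedSequence([spec.seed, 0xB2]).spawn(spec.n_subjects)
    subjects = []
    for i, (lab, ss) in enumerate(zip(labels, streams)):
        sid = f"sub-{i:03d}"
        subjects.append(
            generate_subject(spec, int(lab), np.random.default_rng(ss), sid, template=tpl)
        )
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "label": [s.label for s in subjects],
            "age": [s.age for s in subjects],
            "hemisphere": [s.tumor_hemisphere for s in subjects],
            "lobe": [s.tumor_lobe for s in subjects],
        }
    )
    return subjects, table


def write_cohort(
    subjects: list[SyntheticSubject], table: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write volumes as .nii.gz plus the subject table CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        save_volume(s.volume, out_dir / f"{s.subject_id}_gm.nii.gz")
    table.to_csv(out_dir / "subjects.csv", index=False)
    return out_dir
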