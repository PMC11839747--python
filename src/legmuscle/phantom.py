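"""Seeded synthetic Dixon leg phantoms, perturbed "rater" masks and
covariate-linked cohorts.

The phantom emulates a two-leg axial fat-water stack: each slice holds two
circular legs, each leg a ring of subcutaneous fat (high fat fraction)
around a muscle annulus partitioned into five angular sectors (the five
muscle groups: anterior compartment, deep posterior compartment, lateral
compartment, soleus, gastrocnemius) surrounding a central bone signal void.
In a voxel of tissue with true fat fraction ff the noiseless signals are
F = S0*ff/100 and W = S0 - F, so the measured fat fraction 100*F/(F+W)
recovers ff exactly; optional Gaussian noise (clipped at zero) is added per
channel. Geometry is deliberately schematic — only the topology matters for
testing (adjacent labels, a fat ring hugging the muscle boundary, signal
voids), not anatomical shape.

Cohorts are generated from standardized linear models: per-muscle volume
and IMF are linear in z-scored age, BMI and sex with Gaussian residuals,
and plantarflexion force is linear in age, BMI, sex and plantarflexor
muscle volume, matching the structure assumed by the downstream
association models. Effects are specified and applied on standardized
scales; defaults mirror the covariate distributions of a mid-adult cohort
(age 34.2 (11.2) years, BMI 25.1 (4.5) kg/m², 73.7% female) with
volume ~ BMI and sex but not age, IMF ~ age and BMI, and a soleus-volume
contribution to force of about six percent unique variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import (FatWaterVolume, LabelMap, MEASURE_COLUMNS,
                      MUSCLE_LABELS, MUSCLE_NAMES, VoxelGeometry)

logger = logging.getLogger(__name__)

#: Angular width (radians) of a muscle sector at area scale 1.0. Five
#: sectors at scale 1 cover 75% of the annulus; the remainder is unlabeled
#: muscle tissue, as not every leg muscle belongs to a segmented group.
BASE_ANGLE = 2.0 * math.pi * 0.15

DEFAULT_MUSCLE_FF = {
    "anterior_compartment": 5.0,
    "deep_posterior_compartment": 8.0,
    "lateral_compartment": 12.0,
    "soleus": 15.0,
    "gastrocnemius": 20.0,
}

MIN_MUSCLE_VOXELS = 27


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and noise parameters of one synthetic leg stack."""

    dims: tuple[int, int, int] = (96, 64, 10)
    voxel_size: tuple[float, float, float] = (0.71, 0.71, 5.0)
    leg_radius: float = 20.0          # outer radius incl. fat ring (voxels)
    ring_thickness: float = 3.0       # subcutaneous fat ring (voxels)
    bone_radius: float = 4.0          # central signal void (voxels)
    muscle_ff: dict = field(default_factory=lambda: dict(DEFAULT_MUSCLE_FF))
    area_scale: dict = field(default_factory=dict)   # name -> scale, default 1.0
    taper: float = 0.85               # leg radius multiplier at the last slice
    twist_per_slice: float = 0.02     # sector rotation (rad) per slice
    n_empty_slices: int = 0           # air-only superior slices (no legs)
    other_tissue_ff: float = 10.0     # unlabeled muscle tissue
    subcut_ff: float = 90.0
    s0: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name, ff in {**self.muscle_ff, "subcut": self.subcut_ff,
                         "other": self.other_tissue_ff}.items():
            if not (0.0 <= ff <= 100.0):
                raise ValueError(f"fat fraction for {name!r} must be in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.muscle_ff) - set(MUSCLE_NAMES)
        unknown |= set(self.area_scale) - set(MUSCLE_NAMES)
        if unknown:
            raise ValueError(f"unknown muscle names: {sorted(unknown)}")

    def geometry(self) -> VoxelGeometry:
        affine = np.diag([*self.voxel_size, 1.0])
        return VoxelGeometry(affine=affine, dims=self.dims)


def _leg_centers(dims) -> list[tuple[float, float]]:
    nx, ny = dims[0], dims[1]
    return [(0.27 * nx, 0.5 * ny), (0.73 * nx, 0.5 * ny)]


def _sector_angles(spec: PhantomSpec) -> dict[str, tuple[float, float]]:
    """Contiguous angular intervals per muscle name; error if they overflow."""
    start = 0.0
    out = {}
    for name in MUSCLE_NAMES:
        width = BASE_ANGLE * spec.area_scale.get(name, 1.0)
        out[name] = (start, start + width)
        start += width
    if start > 2.0 * math.pi + 1e-9:
        raise ValueError(
            f"muscle sectors overflow the annulus: total angle {start:.3f} rad "
            f"> 2*pi; reduce area scales {spec.area_scale}")
    return out


def _radius_scale(spec: PhantomSpec, z: int) -> float:
    nz = spec.dims[2]
    frac = z / (nz - 1) if nz > 1 else 0.0
    return 1.0 + (spec.taper - 1.0) * frac


def make_leg_phantom(spec: PhantomSpec) -> tuple[FatWaterVolume, LabelMap]:
    """Build one two-leg Dixon phantom and its exact truth label map.

    The leg radius tapers linearly toward the inferior slices and the
    sector layout rotates slightly slice to slice, so a stack provides
    distinct (but smoothly related) cross sections, as a real calf does.
    """
    nx, ny, nz = spec.dims
    geom = spec.geometry()
    name_to_label = {(name, side): lab for lab, (name, side) in MUSCLE_LABELS.items()}
    sectors = _sector_angles(spec)

    r_m0 = spec.leg_radius - spec.ring_thickness
    r_m_last = spec.leg_radius * min(1.0, spec.taper) - spec.ring_thickness
    if not (0 < spec.bone_radius < min(r_m0, r_m_last) < spec.leg_radius):
        raise ValueError("require 0 < bone_radius < leg_radius*taper - ring_thickness")

    xs, ys = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
    labels = np.zeros(spec.dims, dtype=np.int16)
    ff = np.zeros(spec.dims, dtype=float)
    tissue = np.zeros(spec.dims, dtype=bool)

    if spec.n_empty_slices >= nz:
        raise ValueError("n_empty_slices must leave at least one leg slice")
    for z in range(spec.n_empty_slices, nz):
        scale = _radius_scale(spec, z)
        r_leg = spec.leg_radius * scale
        r_muscle = r_leg - spec.ring_thickness
        twist = spec.twist_per_slice * z
        for side, (cx, cy) in zip(("left", "right"), _leg_centers(spec.dims)):
            dx, dy = xs - cx, ys - cy
            r = np.hypot(dx, dy)
            theta = np.mod(np.arctan2(dy, dx) - twist, 2.0 * math.pi)
            leg = r <= r_leg
            bone = r <= spec.bone_radius
            ring = leg & (r > r_muscle)
            annulus = leg & ~bone & ~ring
            tissue[:, :, z] |= leg & ~bone
            ff[:, :, z][ring] = spec.subcut_ff
            ff[:, :, z][annulus] = spec.other_tissue_ff
            for name in MUSCLE_NAMES:
                a0, a1 = sectors[name]
                sect = annulus & (theta >= a0) & (theta < a1)
                labels[:, :, z][sect] = name_to_label[(name, side)]
                ff[:, :, z][sect] = spec.muscle_ff.get(name, DEFAULT_MUSCLE_FF[name])

    for lab in range(1, 11):
        n = int((labels == lab).sum())
        if n < MIN_MUSCLE_VOXELS:
            name, side = MUSCLE_LABELS[lab]
            raise ValueError(
                f"compartment {side} {name} has only {n} voxels "
                f"(< {MIN_MUSCLE_VOXELS}); enlarge dims or area scale")

    fat = np.where(tissue, spec.s0 * (ff / 100.0), 0.0)
    water = np.where(tissue, spec.s0 - fat, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        fat = np.clip(fat + rng.normal(0.0, spec.noise_sd, fat.shape), 0.0, None)
        water = np.clip(water + rng.normal(0.0, spec.noise_sd, water.shape), 0.0, None)

    vol = FatWaterVolume(fat=fat, water=water, geometry=geom)
    truth = LabelMap(labels=labels, geometry=geom)
    return vol, truth


@dataclass(frozen=True)
class RaterJitter:
    """Boundary perturbation model for a simulated human rater."""

    boundary_op_prob: float = 0.5
    max_shift_voxels: int = 1
    ops: tuple[str, ...] = ("dilate", "erode")

    def __post_init__(self):
        if not (0.0 <= self.boundary_op_prob <= 1.0):
            raise ValueError("boundary_op_prob must be in [0, 1]")
        bad = set(self.ops) - {"dilate", "erode"}
        if bad:
            raise ValueError(f"unknown ops {sorted(bad)}")


def simulate_rater(truth: LabelMap, jitter: RaterJitter, seed: int = 0) -> LabelMap:
    """Perturb a truth label map the way an independent human rater might.

    Per slice and per label, with probability ``boundary_op_prob`` one 2D
    3x3 dilation or erosion is applied, plus an integer in-plane shift of at
    most ``max_shift_voxels``. Labels are re-painted in a seed-randomized
    order and never overwrite one another, so the output stays disjoint.
    """
    rng = np.random.default_rng(seed)
    src = truth.labels
    out = np.zeros_like(src)
    struct2d = np.ones((3, 3), dtype=bool)
    present = truth.present_labels
    for z in range(src.shape[2]):
        sl = src[:, :, z]
        order = rng.permutation(present)
        new_sl = out[:, :, z]
        for lab in order:
            mask = sl == lab
            if not mask.any():
                continue
            if jitter.boundary_op_prob > 0 and rng.random() < jitter.boundary_op_prob:
                op = jitter.ops[rng.integers(len(jitter.ops))]
                if op == "dilate":
                    mask = ndimage.binary_dilation(mask, structure=struct2d)
                else:
                    mask = ndimage.binary_erosion(mask, structure=struct2d,
                                                  border_value=0)
                if jitter.max_shift_voxels > 0:
                    shift = rng.integers(-jitter.max_shift_voxels,
                                         jitter.max_shift_voxels + 1, size=2)
                    mask = ndimage.shift(mask.astype(np.uint8), shift, order=0,
                                         cval=0).astype(bool)
            new_sl[mask & (new_sl == 0)] = lab
    return LabelMap(labels=out, geometry=truth.geometry,
                    label_table=truth.label_table)


def benchmark_stacks(n: int, seed: int = 42,
                     noise_sd: float = 0.0) -> list[tuple[FatWaterVolume, LabelMap]]:
    """The desk-scale segmentation benchmark cohort: n noiseless two-leg
    stacks (96 x 64 x 24, two air-only superior slices) whose leg radius
    and per-muscle area shares vary stack to stack, with the five sectors
    tiling the whole muscle annulus the way the real compartments tile the
    leg. Used to train and hold out phantoms for the U-Net harness."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        raw = {m: float(rng.uniform(0.9, 1.1)) for m in MUSCLE_NAMES}
        norm = 2.0 * math.pi / (BASE_ANGLE * sum(raw.values()))
        scales = {m: v * norm * 0.9999 for m, v in raw.items()}
        spec = PhantomSpec(dims=(96, 64, 24), noise_sd=noise_sd,
                           seed=seed + 100 + i, area_scale=scales,
                           twist_per_slice=0.05, n_empty_slices=2,
                           leg_radius=float(rng.uniform(19, 21)))
        out.append(make_leg_phantom(spec))
    return out


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

DEFAULT_VOLUME_MEAN = {  # mL per side, mid-adult leg
    "anterior_compartment": 270.0,
    "deep_posterior_compartment": 110.0,
    "lateral_compartment": 110.0,
    "soleus": 450.0,
    "gastrocnemius": 250.0,
}
DEFAULT_VOLUME_SD = {k: 0.2 * v for k, v in DEFAULT_VOLUME_MEAN.items()}
DEFAULT_IMF_MEAN = {
    "anterior_compartment": 6.0,
    "deep_posterior_compartment": 7.0,
    "lateral_compartment": 8.0,
    "soleus": 9.0,
    "gastrocnemius": 10.0,
}
DEFAULT_IMF_SD = {k: 2.0 for k in DEFAULT_IMF_MEAN}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a synthetic cohort of leg phantoms.

    Effect sizes are standardized (per SD of the covariate, in SDs of the
    outcome); sex is coded female=0/male=1 and standardized with the
    population split. Residual SDs default to sqrt(1 - sum of squared
    effects) so every outcome has unit variance on the z scale.
    """

    n: int = 95
    female_fraction: float = 0.737
    age_mean: float = 34.2
    age_sd: float = 11.2
    bmi_mean: float = 25.1
    bmi_sd: float = 4.5

    vol_age: float = 0.0
    vol_bmi: float = 0.4
    vol_sex: float = 0.5
    vol_resid_sd: float | None = None
    volume_mean: dict = field(default_factory=lambda: dict(DEFAULT_VOLUME_MEAN))
    volume_sd: dict = field(default_factory=lambda: dict(DEFAULT_VOLUME_SD))

    imf_age: float = 0.3
    imf_bmi: float = 0.25
    imf_sex: float = -0.15
    imf_resid_sd: float | None = None
    imf_mean: dict = field(default_factory=lambda: dict(DEFAULT_IMF_MEAN))
    imf_sd: dict = field(default_factory=lambda: dict(DEFAULT_IMF_SD))

    pf_age: float = -0.15
    pf_bmi: float = 0.15
    pf_sex: float = 0.4
    pf_volume_effects: dict = field(default_factory=lambda: {"soleus": 0.32})
    pf_resid_sd: float | None = None
    pf_mean: float = 122.5
    pf_sd: float = 30.0
    pf_fraction: float = 1.0   # fraction of participants with force data

    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("cohort needs n >= 3")
        for name in ("vol_resid_sd", "imf_resid_sd", "pf_resid_sd"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.female_fraction < 1.0):
            raise ValueError("female_fraction must be in (0, 1)")

    def _resid(self, explicit, betas) -> float:
        if explicit is not None:
            return explicit
        return math.sqrt(max(1.0 - sum(b * b for b in betas), 1e-4))


def simulate_cohort(cspec: CohortSpec, pspec: PhantomSpec | None = None,
                    with_images: bool = False):
    """Draw a cohort: covariates, exact generating muscle measures, and
    (optionally) one phantom image pair + truth mask per participant.

    Returns ``(cohort, truth_measures, images)`` where ``images`` is a list
    of (FatWaterVolume, LabelMap) or None when ``with_images`` is False.
    Images are scaled so each participant's sector areas and fat fractions
    reproduce the generated volumes and IMF; a requested volume the phantom
    annulus cannot hold raises with the participant and muscle named.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n
    male = (rng.random(n) >= cspec.female_fraction).astype(float)
    p_male = 1.0 - cspec.female_fraction
    z_sex = (male - p_male) / math.sqrt(p_male * (1.0 - p_male))
    z_age = rng.standard_normal(n)
    z_bmi = rng.standard_normal(n)
    age = np.clip(cspec.age_mean + cspec.age_sd * z_age, 18.0, 90.0)
    bmi = np.clip(cspec.bmi_mean + cspec.bmi_sd * z_bmi, 15.0, 55.0)

    cohort = pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(n)],
        "age": age, "bmi": bmi,
        "sex": np.where(male > 0, "male", "female"),
    })

    vol_resid = cspec._resid(cspec.vol_resid_sd,
                             (cspec.vol_age, cspec.vol_bmi, cspec.vol_sex))
    imf_resid = cspec._resid(cspec.imf_resid_sd,
                             (cspec.imf_age, cspec.imf_bmi, cspec.imf_sex))

    rows = []
    z_vol = {}  # (name, side) -> standardized volume scores
    for name in MUSCLE_NAMES:
        for side in ("left", "right"):
            zv = (cspec.vol_age * z_age + cspec.vol_bmi * z_bmi
                  + cspec.vol_sex * z_sex + vol_resid * rng.standard_normal(n))
            zi = (cspec.imf_age * z_age + cspec.imf_bmi * z_bmi
                  + cspec.imf_sex * z_sex + imf_resid * rng.standard_normal(n))
            z_vol[(name, side)] = zv
            vol = np.clip(cspec.volume_mean[name] + cspec.volume_sd[name] * zv,
                          1.0, None)
            imf = np.clip(cspec.imf_mean[name] + cspec.imf_sd[name] * zi,
                          0.5, 60.0)
            for i in range(n):
                rows.append({
                    "participant_id": cohort.participant_id[i],
                    "source": "truth", "muscle": name, "side": side,
                    "volume_ml": vol[i], "imf_pct": imf[i],
                    "n_voxels": np.nan, "n_voxels_eroded": np.nan,
                    "eroded_flag": False,
                })
    truth = pd.DataFrame(rows, columns=list(MEASURE_COLUMNS))

    pf_betas = [cspec.pf_age, cspec.pf_bmi, cspec.pf_sex,
                *cspec.pf_volume_effects.values()]
    pf_resid = cspec._resid(cspec.pf_resid_sd, pf_betas)
    for side in ("left", "right"):
        z_pf = (cspec.pf_age * z_age + cspec.pf_bmi * z_bmi
                + cspec.pf_sex * z_sex + pf_resid * rng.standard_normal(n))
        for mname, beta in cspec.pf_volume_effects.items():
            z_pf = z_pf + beta * z_vol[(mname, side)]
        pf = np.clip(cspec.pf_mean + cspec.pf_sd * z_pf, 5.0, None)
        if cspec.pf_fraction < 1.0:
            drop = rng.random(n) >= cspec.pf_fraction
            pf = np.where(drop, np.nan, pf)
        cohort[f"pf_{side}"] = pf

    images = None
    if with_images:
        if pspec is None:
            pspec = PhantomSpec()
        images = []
        for i in range(n):
            images.append(_participant_phantom(
                pspec, truth, cohort.participant_id[i], seed=cspec.seed + 1000 + i))
    return cohort, truth, images


def _participant_phantom(pspec: PhantomSpec, truth: pd.DataFrame,
                         pid: str, seed: int):
    """Phantom whose sector areas/ff match one participant's truth row."""
    sub = truth[truth.participant_id == pid]
    geom = pspec.geometry()
    voxvol = geom.voxel_volume_mm3
    area_per_radian = 0.0  # voxels per radian summed over leg-bearing slices
    for z in range(pspec.n_empty_slices, pspec.dims[2]):
        r_m = pspec.leg_radius * _radius_scale(pspec, z) - pspec.ring_thickness
        area_per_radian += 0.5 * (r_m ** 2 - pspec.bone_radius ** 2)
    ml_per_radian = area_per_radian * voxvol / 1000.0

    scales, ffs = {}, {}
    for name in MUSCLE_NAMES:
        # left/right volumes may differ; the cylindrical phantom has one
        # sector layout, so use the side mean for geometry and exact ff per
        # muscle (sides share ff in the image; truth table keeps both).
        v = float(sub[sub.muscle == name].volume_ml.mean())
        angle = v / ml_per_radian
        scales[name] = angle / BASE_ANGLE
        ffs[name] = float(sub[sub.muscle == name].imf_pct.mean())
    total = sum(BASE_ANGLE * s for s in scales.values())
    if total > 2.0 * math.pi:
        over = max(scales, key=scales.get)
        raise ValueError(
            f"participant {pid}: requested volumes exceed the phantom annulus "
            f"(total sector angle {total:.2f} rad > 2*pi; largest: {over}); "
            f"reduce volume means or enlarge the phantom")
    spec = replace(pspec, area_scale=scales, muscle_ff=ffs, seed=seed)
    return make_leg_phantom(spec)
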