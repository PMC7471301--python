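"""Synthetic orbital CT phantoms and synthetic measurement-study tables.

Phantoms emulate the features of orbital CT that the measurement pipeline
relies on: one filled sphere per eyeball at soft-tissue HU, small cubic bone
blocks marking the orbital-rim landmarks, orbital-fat background and
additive Gaussian HU noise, on a 1 mm isotropic grid by default.  The true
proptosis of a spherical eyeball against the landmark plane has the closed
form d + r (signed center-to-plane distance along the anterior normal plus
the radius), which serves as the analytic oracle for the whole pipeline.

The study generator emulates the structure of a clinical method-comparison
study: per-eye true proptosis values read by three methods (Hertel
exophthalmometer, single-slice CT, 3-D software) with method-specific
additive bias and noise, repeated readings, multiple raters with additive
rater effects, and a strabismus subgroup with inflated noise.  Hertel
readings are recorded to the nearest 0.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import fit_plane
from .segmentation import SeedSet
from .volume_io import BinaryMask, CTVolume

__all__ = [
    "EyeSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "true_proptosis",
    "truth_mask",
    "suggest_seeds",
    "random_phantom_spec",
    "StudySpec",
    "generate_study",
    "METHODS",
]

METHODS = ("hertel", "ct2d", "software3d")


@dataclass
class EyeSpec:
    """One spherical eyeball: world-mm center and radius."""

    center: tuple
    radius: float


@dataclass
class PhantomSpec:
    """Geometry and intensity recipe for one synthetic orbital CT volume.

    The three ``landmarks`` are the rim reference points defining the true
    interzygomatic plane; ``anterior_axis`` orients its normal.  HU levels
    follow the ordering of real orbital tissues (air < fat < eyeball <
    bone); eyeball and fat must differ by at least 20 HU so seed histograms
    can separate them.
    """

    shape: tuple = (64, 64, 48)
    spacing: tuple = (1.0, 1.0, 1.0)
    eyes: dict = field(
        default_factory=lambda: {
            "right": EyeSpec(center=(18.0, 32.0, 24.0), radius=12.0),
            "left": EyeSpec(center=(46.0, 32.0, 24.0), radius=12.0),
        }
    )
    landmarks: tuple = ((4.0, 24.0, 24.0), (60.0, 24.0, 24.0), (8.0, 22.0, 36.0))
    anterior_axis: tuple = (0.0, 1.0, 0.0)
    hu_eyeball: float = 20.0
    hu_fat: float = -80.0
    hu_bone: float = 700.0
    hu_air: float = -1000.0
    hu_lens: float = 100.0
    lens_cap: bool = False
    bone_size: float = 5.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for side, eye in self.eyes.items():
            if eye.radius <= 0:
                raise ValueError(f"{side} eyeball radius must be > 0")
            c = np.asarray(eye.center)
            extent = np.asarray(self.shape) * np.asarray(self.spacing)
            if np.any(c - eye.radius < 0) or np.any(c + eye.radius > extent):
                raise ValueError(f"{side} eyeball sphere extends outside the grid")
        if abs(self.hu_eyeball - self.hu_fat) < 20:
            raise ValueError("eyeball and fat HU must differ by at least 20")
        # raises on collinear landmarks
        fit_plane(np.asarray(self.landmarks, float), self.anterior_axis)


@dataclass
class PhantomTruth:
    """Exact generating parameters: the analytic ground truth of a phantom."""

    eyes: dict
    landmarks: np.ndarray
    anterior_axis: np.ndarray
    true_proptosis: dict  # side -> mm
    seed: int

    def to_dict(self) -> dict:
        return {
            "eyes": {s: {"center": list(map(float, e.center)), "radius": float(e.radius)}
                     for s, e in self.eyes.items()},
            "landmarks": np.asarray(self.landmarks, float).tolist(),
            "anterior_axis": np.asarray(self.anterior_axis, float).tolist(),
            "true_proptosis": {s: float(v) for s, v in self.true_proptosis.items()},
            "seed": int(self.seed),
        }


def true_proptosis(spec: PhantomSpec, side: str) -> float:
    """Closed-form proptosis of one spherical eyeball, mm.

    Signed distance from the landmark plane to the sphere center along the
    anterior unit normal, plus the radius.  No voxelization enters.
    """
    eye = spec.eyes[side]
    plane = fit_plane(np.asarray(spec.landmarks, float), spec.anterior_axis)
    d = float(plane.signed_distance(np.asarray(eye.center, float)))
    return d + eye.radius


def _world_grid(spec: PhantomSpec) -> tuple:
    idx = np.indices(spec.shape, dtype=float)
    sp = np.asarray(spec.spacing)
    # identity orientation, origin at 0: world = index * spacing
    return idx[0] * sp[0], idx[1] * sp[1], idx[2] * sp[2]


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render the phantom volume and return it with its ground truth."""
    x, y, z = _world_grid(spec)
    data = np.full(spec.shape, spec.hu_fat, dtype=float)

    half = spec.bone_size / 2.0
    for lm in spec.landmarks:
        in_block = (
            (np.abs(x - lm[0]) <= half)
            & (np.abs(y - lm[1]) <= half)
            & (np.abs(z - lm[2]) <= half)
        )
        data[in_block] = spec.hu_bone

    anterior = np.asarray(spec.anterior_axis, float)
    anterior = anterior / np.linalg.norm(anterior)
    for eye in spec.eyes.values():
        c = np.asarray(eye.center, float)
        r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        inside = r2 <= eye.radius**2
        data[inside] = spec.hu_eyeball
        if spec.lens_cap:
            # brighter spherical cap on the anterior pole, mimicking the lens
            ant_coord = (x - c[0]) * anterior[0] + (y - c[1]) * anterior[1] + (z - c[2]) * anterior[2]
            data[inside & (ant_coord > 0.8 * eye.radius)] = spec.hu_lens

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    volume = CTVolume(data=data, spacing=np.asarray(spec.spacing, float))
    truth = PhantomTruth(
        eyes=spec.eyes,
        landmarks=np.asarray(spec.landmarks, float),
        anterior_axis=anterior,
        true_proptosis={s: true_proptosis(spec, s) for s in spec.eyes},
        seed=spec.seed,
    )
    return volume, truth


def truth_mask(spec: PhantomSpec, side: str) -> BinaryMask:
    """Analytic digitization of one eyeball sphere (voxel-center rule)."""
    x, y, z = _world_grid(spec)
    eye = spec.eyes[side]
    c = np.asarray(eye.center, float)
    inside = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= eye.radius**2
    vol = CTVolume(data=np.zeros(spec.shape), spacing=np.asarray(spec.spacing, float))
    return BinaryMask.from_volume(vol, inside.astype(np.uint8))


def suggest_seeds(spec: PhantomSpec, side: str, margin: float = 3.0) -> SeedSet:
    """Seed set on the axial slice through the eyeball center.

    Foreground: voxels within half the radius of the center, on that slice.
    Background: a sparse grid of voxels on the same slice farther than
    radius + ``margin`` from the center (fat and, where present, bone).
    """
    eye = spec.eyes[side]
    sp = np.asarray(spec.spacing)
    c_vox = np.asarray(eye.center) / sp
    k = int(round(c_vox[2]))
    nx, ny = spec.shape[0], spec.shape[1]
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = (ii - c_vox[0]) * sp[0]
    dy = (jj - c_vox[1]) * sp[1]
    dist = np.hypot(dx, dy)
    fg = np.argwhere(dist <= eye.radius / 2.0)
    bg = np.argwhere((dist >= eye.radius + margin) & (ii % 3 == 0) & (jj % 3 == 0))
    fg3 = np.column_stack([fg, np.full(len(fg), k)])
    bg3 = np.column_stack([bg, np.full(len(bg), k)])
    return SeedSet(foreground=fg3, background=bg3, slice_index=k)


def random_phantom_spec(rng: np.random.Generator, noise_sigma: float = 10.0) -> PhantomSpec:
    """Randomized single-eye phantom for validation sweeps.

    Radius uniform on 10–14 mm, plane offset (sphere center anterior of the
    landmark plane) uniform on 2–10 mm, plane tilted obliquely by up to
    ~15 degrees, 1 mm isotropic voxels.
    """
    shape = (64, 64, 48)
    radius = float(rng.uniform(10.0, 14.0))
    offset = float(rng.uniform(2.0, 10.0))

    # oblique anterior-pointing plane normal
    tilt = rng.uniform(-0.25, 0.25, size=2)
    normal = np.array([tilt[0], 1.0, tilt[1]])
    normal /= np.linalg.norm(normal)
    anchor = np.array([32.0, 18.0, 24.0])
    # in-plane basis
    u = np.cross(normal, [0.0, 0.0, 1.0])
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    lms = (
        anchor - 24.0 * u + rng.uniform(-2, 2) * v,
        anchor + 24.0 * u + rng.uniform(-2, 2) * v,
        anchor - 20.0 * u + 10.0 * v,
    )
    center = anchor + offset * normal + rng.uniform(-2, 2) * u
    return PhantomSpec(
        shape=shape,
        eyes={"right": EyeSpec(center=tuple(center), radius=radius)},
        landmarks=tuple(tuple(p) for p in lms),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# -- synthetic measurement study ----------------------------------------


@dataclass
class StudySpec:
    """Recipe for a synthetic subject x method x repeat x rater table.

    Defaults emulate the structure of a 126-subject method-comparison study
    of Graves orbitopathy: latent per-eye proptosis ~ N(17.78, 3.2^2) mm;
    method biases 0 / +1.43 / +0.78 mm (Hertel / single-slice CT / 3-D
    software) so the between-method mean differences match the reported
    Hertel-vs-CT and Hertel-vs-software gaps; per-method noise sigmas chosen
    to reproduce the reported Bland-Altman limits of agreement; a strabismus
    subgroup (fraction 21/126) with inflated Hertel and CT noise; three
    repeats and three raters with a 1.5 mm rater-effect sigma.
    """

    n_subjects: int = 126
    eyes_per_subject: int = 2
    truth_mean: float = 17.78
    truth_sd: float = 3.2
    method_bias: dict = field(
        default_factory=lambda: {"hertel": 0.0, "ct2d": 1.43, "software3d": 0.78}
    )
    method_noise_sd: dict = field(
        default_factory=lambda: {"hertel": 1.8, "ct2d": 1.1, "software3d": 0.2}
    )
    n_repeats: int = 3
    n_raters: int = 3
    rater_sd: float = 1.5
    strabismus_fraction: float = 21.0 / 126.0
    strabismus_extra_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats for reliability statistics")
        sds = [self.truth_sd, self.rater_sd, self.strabismus_extra_sd, *self.method_noise_sd.values()]
        if any(s < 0 for s in sds):
            raise ValueError("all sigmas must be >= 0")
        if not 0 <= self.strabismus_fraction <= 1:
            raise ValueError("strabismus fraction must be in [0, 1]")


def generate_study(spec: StudySpec) -> pd.DataFrame:
    """Draw a synthetic measurement table.

    Per eye, a latent true proptosis is drawn once; each reading is
    truth + method bias + rater effect + fresh Gaussian noise.  Repeats
    share truth, bias and rater effect but redraw the noise.  Strabismus
    eyes add ``strabismus_extra_sd`` (in quadrature conceptually: as an
    additional independent noise term) to Hertel and CT readings.  Hertel
    values are rounded to the nearest 0.5 mm.  Deterministic under ``seed``.

    Returns a long-format DataFrame with columns subject_id, eye, method,
    repeat, rater, value_mm, group.
    """
    rng = np.random.default_rng(spec.seed)
    n_strab = int(round(spec.strabismus_fraction * spec.n_subjects))
    strab = np.zeros(spec.n_subjects, dtype=bool)
    strab[:n_strab] = True

    # rater effects: one offset per (rater, method)
    rater_eff = rng.normal(0.0, spec.rater_sd, size=(spec.n_raters, len(METHODS)))

    rows = []
    eye_labels = ["right", "left"][: spec.eyes_per_subject]
    for s in range(spec.n_subjects):
        group = "strabismus" if strab[s] else "non_strabismus"
        for eye in eye_labels:
            truth = rng.normal(spec.truth_mean, spec.truth_sd)
            for mi, method in enumerate(METHODS):
                sd = spec.method_noise_sd[method]
                if strab[s] and method in ("hertel", "ct2d"):
                    sd = float(np.hypot(sd, spec.strabismus_extra_sd))
                for rater in range(spec.n_raters):
                    for rep in range(spec.n_repeats):
                        value = (
                            truth
                            + spec.method_bias[method]
                            + rater_eff[rater, mi]
                            + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                        )
                        if method == "hertel":
                            value = np.round(value * 2.0) / 2.0
                        rows.append(
                            (f"S{s:04d}", eye, method, rep + 1, f"R{rater + 1}", value, group)
                        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "eye", "method", "repeat", "rater", "value_mm", "group"],
    )
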