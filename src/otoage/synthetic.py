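"""Synthetic otolith populations.

Generates annotated otolith-like images whose morphology encodes fish age the
way Greenland halibut sagittae do: juveniles are near-circular blobs without
marginal protrusions ("fingers"), fingers develop on the upper margin from a
configurable onset age and grow in number and length, and the dark core sits
at a relative vertical position that moves downward as the upper part of the
otolith outgrows the lower part.  Images are standardized to a fixed vertical
foreground extent at render time, mirroring the height standardization used
for real images, so absolute size is deliberately *not* an age cue.

Population structure follows the study system: three sex groups
(male / female / unknown) with distinct truncated-normal age distributions,
group proportions of roughly 34.5 / 48.9 / 16.6 %, and a linear sex-dependent
age-length relation with a shared intercept (male and female fish have the
same expected length at birth).

Sex does not alter the rendered morphology: the group differences live in the
age distributions, which is exactly the setting needed to test whether a
sex-conditional regression head can exploit sex as prior information when the
image itself carries no sex cue.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, signal
from scipy.stats import truncnorm

SEXES = ("male", "female", "unknown")

# Group proportions, age means (yr) and SDs (yr) for male/female/unknown fish,
# and the 1-26 yr age range of the study population.
DEFAULT_PROPORTIONS = (0.345, 0.489, 0.166)
DEFAULT_AGE_MEANS = (10.0, 12.0, 11.0)
DEFAULT_AGE_SDS = (3.3, 4.4, 5.4)
DEFAULT_AGE_RANGE = (1, 26)


class LengthParams(NamedTuple):
    """Linear age->length model: length = intercept + slope(sex) * age + noise.

    The intercept (expected length at age 0) is shared between sexes; the male
    slope is ``female_slope + male_slope_delta`` (negative delta: males grow
    slower and stay smaller, as in halibut).
    """

    intercept: float = 8.0        # cm
    female_slope: float = 4.5     # cm / yr
    male_slope_delta: float = -1.0  # cm / yr
    noise_sd: float = 7.0         # cm


@dataclasses.dataclass(frozen=True)
class RenderParams:
    """Geometry of the procedural otolith renderer (pixels unless noted)."""

    canvas_size: int = 128
    target_height_fraction: float = 0.8   # foreground vertical extent / canvas
    base_radius_per_year: float = 2.5     # pre-standardization growth, px/yr
    finger_onset_age: float = 5.0         # yr; no fingers below this age
    fingers_per_year: float = 0.5         # new fingers per year past onset
    finger_length_per_year: float = 1.0   # protrusion length growth, px/yr
    finger_length_max: float = 12.0       # protrusion length cap, px
    core_diameter: float = 12.0           # dark core diameter, px
    core_drift_per_year: float = 0.02     # downward drift of core, fraction/yr
    width_growth_per_year: float = 0.03   # horizontal/vertical ratio growth /yr
    texture_noise_sd: float = 0.05        # intensity units

    max_fingers: int = 6
    core_top_fraction: float = 0.30       # core position at age 0, from top

    def __post_init__(self):
        if not 0.0 < self.target_height_fraction <= 1.0:
            raise ValueError("target_height_fraction must be in (0, 1]")
        for name in ("base_radius_per_year", "fingers_per_year",
                     "finger_length_per_year", "core_drift_per_year",
                     "width_growth_per_year", "texture_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass(frozen=True)
class PopulationConfig:
    n_total: int
    group_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    age_means: tuple[float, float, float] = DEFAULT_AGE_MEANS
    age_sds: tuple[float, float, float] = DEFAULT_AGE_SDS
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE
    length_params: LengthParams = LengthParams()
    render: RenderParams = RenderParams()
    seed: int = 0
    unknown_sex_lengths: bool = False

    def __post_init__(self):
        p = np.asarray(self.group_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"group_proportions must sum to 1, got {p.sum()!r}")
        if (p < 0).any():
            raise ValueError("group_proportions must be non-negative")
        if self.age_range[0] < 1:
            raise ValueError("age_range lower bound must be >= 1")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be a non-empty interval")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")


@dataclasses.dataclass
class OtolithRecord:
    """One annotated image: (X_i, y_i, z_i) plus optional length."""

    sample_id: str
    image: np.ndarray | None   # (H, W, 3) float in [0, 1]; None if not rendered
    read_age: int              # yr
    sex: str                   # male | female | unknown
    length: float | None = None  # cm


def expected_finger_count(age: float, params: RenderParams) -> int:
    """Deterministic finger count used by the renderer (monotone in age)."""
    if age < params.finger_onset_age:
        return 0
    n = int(np.floor(params.fingers_per_year * (age - params.finger_onset_age))) + 1
    return min(n, params.max_fingers)


def _radial_profile(age: float, params: RenderParams,
                    rng: np.random.Generator, n_theta: int = 1024):
    """Boundary radius r(theta) in pre-standardization pixels.

    theta is the mathematical polar angle; theta in (0, pi) is the *upper*
    margin of the otolith where fingers develop.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r0 = 10.0 + params.base_radius_per_year * age
    # vertical semi-axis fixed at r0; horizontal semi-axis widens with age
    ax = r0 * min(1.6, 0.62 + params.width_growth_per_year * age)
    ay = r0
    r = ax * ay / np.sqrt((ay * np.cos(theta)) ** 2 + (ax * np.sin(theta)) ** 2)
    # mild low-order irregularity so same-age fish differ
    ph = rng.uniform(0.0, 2.0 * np.pi, size=2)
    r = r * (1.0 + 0.02 * np.sin(2 * theta + ph[0]) + 0.015 * np.sin(3 * theta + ph[1]))
    n_fingers = expected_finger_count(age, params)
    if n_fingers > 0:
        amp = min(params.finger_length_max,
                  params.finger_length_per_year
                  * (age - params.finger_onset_age + 1.0))
        centers = np.linspace(np.deg2rad(35), np.deg2rad(145), n_fingers)
        centers = centers + rng.uniform(-np.deg2rad(3), np.deg2rad(3), size=n_fingers)
        widths = np.deg2rad(4.5) * (1.0 + rng.uniform(-0.10, 0.10, size=n_fingers))
        for c, w in zip(centers, widths):
            r = r + amp * np.exp(-0.5 * ((theta - c) / w) ** 2)
    return theta, r


def render_otolith(age: float, sex: str, params: RenderParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one otolith image as an (S, S, 3) float array in [0, 1].

    The rendered foreground's vertical extent equals
    ``target_height_fraction * canvas_size`` to within a pixel (height
    standardization is built into the renderer).  ``sex`` is accepted for
    interface symmetry but does not alter the morphology.
    """
    if age < 1:
        raise ValueError(f"age must be >= 1, got {age}")
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    s = params.canvas_size
    theta, r = _radial_profile(age, params, rng)

    up = r * np.sin(theta)
    v_extent = up.max() - up.min()
    target = params.target_height_fraction * s
    scale = target / v_extent
    r = r * scale
    up_max, up_min = up.max() * scale, up.min() * scale

    # place the blob so its vertical span is centred on the canvas
    cy = (s - 1) / 2.0 + (up_max + up_min) / 2.0
    cx = (s - 1) / 2.0
    rows = np.arange(s)[:, None] - cy          # +down
    cols = np.arange(s)[None, :] - cx
    rho = np.hypot(rows, cols)
    ang = np.arctan2(-rows, cols) % (2.0 * np.pi)   # up is positive angle side
    r_at = np.interp(ang, theta, r, period=2.0 * np.pi)
    alpha = np.clip(r_at - rho + 0.5, 0.0, 1.0)     # antialiased membership

    base = 0.85 + rng.normal(0.0, params.texture_noise_sd, size=(s, s))
    intensity = alpha * base

    # dark core on the vertical axis; its relative position (from the top of
    # the foreground) drifts downward with age
    rel = np.clip(params.core_top_fraction + params.core_drift_per_year * age,
                  0.05, 0.80)
    top_row = cy - up_max
    core_row = top_row + rel * target
    core_r = params.core_diameter / 2.0
    core_dist = np.hypot(np.arange(s)[:, None] - core_row,
                         np.arange(s)[None, :] - cx)
    core_alpha = np.clip(core_r - core_dist + 0.5, 0.0, 1.0) * (alpha > 0.5)
    intensity = intensity * (1.0 - 0.75 * core_alpha)

    tint = np.array([1.0, 0.96, 0.88])
    img = np.clip(intensity[:, :, None] * tint[None, None, :], 0.0, 1.0)
    return img.astype(np.float64)


def sample_length(age: float, sex: str, length_params: LengthParams,
                  rng: np.random.Generator) -> float:
    """Draw a length (cm) from the linear sex-dependent growth model."""
    if sex not in ("male", "female"):
        raise ValueError(f"sample_length requires a known sex, got {sex!r}")
    slope = length_params.female_slope
    if sex == "male":
        slope += length_params.male_slope_delta
    value = length_params.intercept + slope * age
    if length_params.noise_sd > 0:
        value += rng.normal(0.0, length_params.noise_sd)
    return float(max(value, 1.0))


def _sample_age(sex_idx: int, config: PopulationConfig,
                rng: np.random.Generator) -> int:
    lo, hi = config.age_range
    mu = config.age_means[sex_idx]
    sd = config.age_sds[sex_idx]
    a, b = (lo - mu) / sd, (hi - mu) / sd
    x = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    return int(np.clip(np.rint(x), lo, hi))


def sample_population(config: PopulationConfig,
                      with_images: bool = True) -> list[OtolithRecord]:
    """Draw a full annotated population.

    Each record uses its own counter-derived random substream, so record ``i``
    is identical no matter how many other records are drawn.  With
    ``with_images=False`` only the metadata are sampled (record images are
    ``None``), which is convenient for large distributional checks.
    """
    records = []
    cum = np.cumsum(config.group_proportions)
    for i in range(config.n_total):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,)))
        u = rng.random()
        sex_idx = int(np.searchsorted(cum, u, side="right"))
        sex_idx = min(sex_idx, 2)
        sex = SEXES[sex_idx]
        age = _sample_age(sex_idx, config, rng)
        if sex in ("male", "female"):
            length = sample_length(age, sex, config.length_params, rng)
        elif config.unknown_sex_lengths:
            latent = "male" if rng.random() < 0.5 else "female"
            length = sample_length(age, latent, config.length_params, rng)
        else:
            length = None
        image = (render_otolith(age, sex, config.render, rng)
                 if with_images else None)
        records.append(OtolithRecord(sample_id=f"oto{i:05d}", image=image,
                                     read_age=age, sex=sex, length=length))
    return records


def tiny_study_config(n_total: int = 600, seed: int = 0,
                      canvas_size: int = 64) -> PopulationConfig:
    """Desk-scale study population: small images, ages 1-16, well-separated
    male/female age means (6 vs 10 yr) and a strong morphological age signal.

    This is the configuration used by the model-recovery experiments and the
    worked examples.
    """
    return PopulationConfig(
        n_total=n_total,
        age_means=(6.0, 10.0, 8.0),
        age_sds=(2.5, 2.5, 3.0),
        age_range=(1, 16),
        render=RenderParams(canvas_size=canvas_size, core_diameter=7.0),
        seed=seed,
    )


def write_dataset(records: Sequence[OtolithRecord], out_dir: str | Path) -> Path:
    """Write one PNG per record plus a CSV manifest; returns the CSV path.

    Images are quantized to 8-bit on write; the manifest columns are
    ``sample_id,filename,read_age,sex,length`` with an empty length field for
    records without a length.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.sample_id}.png"
        arr = np.clip(np.rint(rec.image * 255.0), 0, 255).astype(np.uint8)
        try:
            Image.fromarray(arr).save(out_dir / fname)
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
        rows.append({"sample_id": rec.sample_id, "filename": fname,
                     "read_age": rec.read_age, "sex": rec.sex,
                     "length": rec.length})
    manifest = out_dir / "metadata.csv"
    pd.DataFrame(rows, columns=["sample_id", "filename", "read_age", "sex",
                                "length"]).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# measurement helpers (independent of the renderer's construction; used by the
# test-suite oracles and the examples)

def foreground_mask(image: np.ndarray, threshold: float = 0.35) -> np.ndarray:
    """Foreground = pixels whose green channel exceeds ``threshold``."""
    return image[..., 1] > threshold


def measure_vertical_extent(image: np.ndarray) -> int:
    """Vertical extent (px) of the foreground."""
    rows = np.flatnonzero(foreground_mask(image).any(axis=1))
    if rows.size == 0:
        raise ValueError("image has no foreground")
    return int(rows[-1] - rows[0] + 1)


def count_fingers(image: np.ndarray, prominence_px: float = 2.0) -> int:
    """Count marginal protrusions on the upper half of the otolith boundary.

    Works from the image alone: takes the polar boundary-radius profile about
    the foreground centroid over the upper margin, smooths it, removes the
    broad trend with a median filter, and counts residual peaks of at least
    ``prominence_px`` pixels.  Reliable from ~128 px canvases upward; at very
    small canvases raster noise can masquerade as a protrusion.
    """
    mask = foreground_mask(image)
    if not mask.any():
        raise ValueError("image has no foreground")
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    ang = np.arctan2(-(rr - cy), cc - cx)
    rho = np.hypot(rr - cy, cc - cx)
    upper = (ang > np.deg2rad(15)) & (ang < np.deg2rad(165))
    if not upper.any():
        return 0
    nbins = 150
    bins = np.linspace(np.deg2rad(15), np.deg2rad(165), nbins + 1)
    idx = np.clip(np.digitize(ang[upper], bins) - 1, 0, nbins - 1)
    profile = np.full(nbins, -np.inf)
    np.maximum.at(profile, idx, rho[upper])
    good = np.isfinite(profile)
    profile = np.interp(np.arange(nbins), np.flatnonzero(good), profile[good])
    profile = ndimage.gaussian_filter1d(profile, 2.0, mode="nearest")
    trend = ndimage.median_filter(profile, size=41, mode="nearest")
    peaks, _ = signal.find_peaks(profile - trend, prominence=prominence_px)
    return int(len(peaks))


def measure_core_row(image: np.ndarray) -> float:
    """Centroid row of the dark core, measured as the darkest interior region."""
    mask = ndimage.binary_fill_holes(foreground_mask(image))
    interior = ndimage.binary_erosion(mask, iterations=2)
    dark = interior & (image[..., 1] < 0.3)
    if not dark.any():
        raise ValueError("no core found")
    rr = np.nonzero(dark)[0]
    return float(rr.mean())
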