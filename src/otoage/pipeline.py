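"""Image and metadata ingestion, standardization and train-time augmentation.

The reader consumes the PNG + CSV layout written by
:func:`otoage.synthetic.write_dataset` (and any real dataset exported in the
same dialect).  Preprocessing mirrors the study protocol: images are
standardized so every otolith has the same maximum vertical extent — which
forces the model to read growth pattern rather than absolute size — and
downsampled to the square model input.  Augmentation is train-time only:
horizontal translation within a fraction of the width (no vertical shifts,
since height carries the standardization) and rotation within a fraction of a
full turn.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage import transform
from skimage.filters import threshold_otsu

SEX_ORDER = ("male", "female", "unknown")


def encode_sex(sex: str) -> np.ndarray:
    """One-hot encode sex: male -> [1,0,0], female -> [0,1,0], unknown -> [0,0,1].

    Strings are normalized case-insensitively with surrounding whitespace
    stripped; anything else is an error.
    """
    key = str(sex).strip().lower()
    if key not in SEX_ORDER:
        raise ValueError(f"sex must be one of {SEX_ORDER}, got {sex!r}")
    code = np.zeros(3, dtype=np.float32)
    code[SEX_ORDER.index(key)] = 1.0
    return code


@dataclasses.dataclass(frozen=True)
class AugmentSpec:
    """Train-time augmentation: shifts as a fraction of image width,
    rotations as a fraction of a full turn (0.1 -> up to 36 deg either way)."""

    horizontal_translation_range: float = 0.1
    rotation_factor: float = 0.1

    def __post_init__(self):
        if self.horizontal_translation_range < 0 or self.rotation_factor < 0:
            raise ValueError("augmentation factors must be >= 0")

    @property
    def max_rotation_deg(self) -> float:
        return self.rotation_factor * 360.0


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file into an (H, W, 3) float array in [0, 1].

    Grayscale inputs are replicated across the three channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("RGB", "L"):
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr


def _foreground_rows(image: np.ndarray) -> np.ndarray:
    green = image[..., 1]
    if green.max() - green.min() < 1e-3:
        raise ValueError("image has no foreground (constant intensity)")
    mask = green > threshold_otsu(green)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("image has no foreground above the Otsu threshold")
    return rows


def standardize_height(image: np.ndarray, target_height: int) -> np.ndarray:
    """Rescale so the foreground's vertical extent equals ``target_height``.

    The otolith is segmented by Otsu thresholding of the green channel, the
    whole image is rescaled isotropically (aspect preserved) and the blob is
    re-centred on a canvas of the original size.
    """
    h, w = image.shape[:2]
    rows = _foreground_rows(image)
    extent = rows[-1] - rows[0] + 1
    scale = target_height / extent
    zoomed = transform.rescale(image, scale, channel_axis=2, order=1,
                               anti_aliasing=scale < 1, preserve_range=True)
    zrows = _foreground_rows(zoomed)
    zcols = np.flatnonzero(
        (zoomed[..., 1] > threshold_otsu(zoomed[..., 1])).any(axis=0))
    cy = (zrows[0] + zrows[-1]) / 2.0
    cx = (zcols[0] + zcols[-1]) / 2.0
    out = np.zeros((h, w, image.shape[2]), dtype=image.dtype)
    # paste zoomed so that (cy, cx) lands at the canvas centre
    top = int(round(h / 2 - cy))
    left = int(round(w / 2 - cx))
    zs = zoomed.shape
    src_r0, src_c0 = max(0, -top), max(0, -left)
    dst_r0, dst_c0 = max(0, top), max(0, left)
    nr = min(zs[0] - src_r0, h - dst_r0)
    nc = min(zs[1] - src_c0, w - dst_c0)
    if nr <= 0 or nc <= 0:
        raise ValueError("foreground does not fit on the canvas after scaling")
    out[dst_r0:dst_r0 + nr, dst_c0:dst_c0 + nc] = \
        zoomed[src_r0:src_r0 + nr, src_c0:src_c0 + nc]
    return np.clip(out, 0.0, 1.0)


def resize(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to a ``side x side`` square (e.g. 600 -> 256)."""
    if image.shape[0] == side and image.shape[1] == side:
        return image.copy()
    down = side < image.shape[0]
    out = transform.resize(image, (side, side), order=1,
                           anti_aliasing=down, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, spec: AugmentSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Random rotation then horizontal translation; nearest-edge fill.

    Bilinear interpolation with edge fill keeps intensities inside the input
    range; there is no vertical translation.
    """
    out = image
    if spec.rotation_factor > 0:
        angle = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
    if spec.horizontal_translation_range > 0:
        dx = rng.uniform(-spec.horizontal_translation_range,
                         spec.horizontal_translation_range) * image.shape[1]
        out = ndimage.shift(out, (0.0, dx, 0.0), order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0) if out is not image else image.copy()


class DatasetTable:
    """Aligned images + metadata used for training and evaluation.

    Holds sample ids, read ages (yr), one-hot sex codes, optional lengths
    (NaN when absent) and, optionally, the image stack itself.
    """

    def __init__(self, sample_ids: np.ndarray, read_ages: np.ndarray,
                 sex: np.ndarray, lengths: np.ndarray,
                 images: np.ndarray | None = None,
                 allow_age_zero: bool = False):
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        self.read_ages = np.asarray(read_ages, dtype=float)
        self.sex = np.asarray(sex, dtype=object)
        self.lengths = np.asarray(lengths, dtype=float)
        self.images = None if images is None else np.asarray(images)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        min_age = 0 if allow_age_zero else 1
        if (self.read_ages < min_age).any():
            raise ValueError(f"read ages must be >= {min_age}")
        for s in self.sex:
            encode_sex(s)  # validates
        n = len(self.sample_ids)
        if not (len(self.read_ages) == len(self.sex) == len(self.lengths) == n):
            raise ValueError("metadata columns must have equal length")
        if self.images is not None and len(self.images) != n:
            raise ValueError("images and metadata must have equal length")
        self._allow_age_zero = allow_age_zero

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def sex_codes(self) -> np.ndarray:
        return np.stack([encode_sex(s) for s in self.sex])

    @property
    def known_sex_mask(self) -> np.ndarray:
        return np.array([s in ("male", "female") for s in self.sex])

    def subset(self, index) -> "DatasetTable":
        index = np.asarray(index)
        return DatasetTable(
            self.sample_ids[index], self.read_ages[index], self.sex[index],
            self.lengths[index],
            None if self.images is None else self.images[index],
            allow_age_zero=self._allow_age_zero)

    @classmethod
    def from_records(cls, records) -> "DatasetTable":
        have_images = all(r.image is not None for r in records)
        return cls(
            sample_ids=np.array([r.sample_id for r in records], dtype=object),
            read_ages=np.array([r.read_age for r in records], dtype=float),
            sex=np.array([r.sex for r in records], dtype=object),
            lengths=np.array([np.nan if r.length is None else r.length
                              for r in records], dtype=float),
            images=np.stack([r.image for r in records]) if have_images else None)

    @classmethod
    def from_manifest(cls, manifest_csv: str | Path,
                      load_images: bool = True) -> "DatasetTable":
        """Read the ``sample_id,filename,read_age,sex,length`` CSV layout."""
        manifest_csv = Path(manifest_csv)
        frame = pd.read_csv(manifest_csv)
        required = {"sample_id", "filename", "read_age", "sex", "length"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"manifest {manifest_csv} lacks columns {sorted(missing)}")
        images = None
        if load_images:
            images = np.stack([load_image(manifest_csv.parent / f)
                               for f in frame["filename"]])
        return cls(sample_ids=frame["sample_id"].astype(str).to_numpy(dtype=object),
                   read_ages=frame["read_age"].to_numpy(dtype=float),
                   sex=np.array([str(s).strip().lower() for s in frame["sex"]],
                                dtype=object),
                   lengths=frame["length"].to_numpy(dtype=float),
                   images=images)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "read_age": self.read_ages,
                             "sex": self.sex,
                             "length": self.lengths})
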