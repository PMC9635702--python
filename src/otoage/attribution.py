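"""Pixel-relevance heatmaps for a trained age regressor.

Five gradient-based attribution methods, all targeting the sex-selected
output node (the quantity the model actually predicts):

* gradient saliency — |d f / d pixel| at the input;
* baseline gradients — |(x - baseline) * d f / d x| at the input, the
  single-point version of the path methods;
* integrated gradients — (x - baseline) times the path-averaged gradient
  along the straight line from baseline to input; its raw signed
  attributions satisfy the completeness identity
  sum(attributions) ~= f(x) - f(baseline);
* guided backpropagation — gradients where every ReLU passes back only
  positive gradients at positively-activated units;
* integrated guided gradients — the path average computed with guided
  gradients.

A non-informative baseline (default all-black) anchors the path methods.
Because a naively trained regressor assigns a black image an age near the
mean response, the training device :func:`add_baseline_class` appends black
images labelled age 0 to the training set, pushing the model output at the
baseline toward zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .pipeline import DatasetTable

METHODS = ("saliency", "baseline_gradients", "integrated_gradients",
           "guided_backprop", "integrated_guided_gradients")


@dataclasses.dataclass
class Heatmap:
    """Nonnegative relevance map in [0, 1] over the input's spatial grid.

    ``raw`` keeps the signed per-channel attributions (path methods only);
    it is what the completeness check sums.
    """

    values: np.ndarray          # (H, W)
    method: str
    sex: str
    raw: np.ndarray | None = None  # (H, W, 3) signed, before abs/reduce

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if v.min() < 0 or v.max() > 1 + 1e-9:
            raise ValueError("heatmap values must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class AttributionConfig:
    method: str = "integrated_gradients"
    steps: int = 64
    baseline: str | np.ndarray = "black"
    absolute: bool = True

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method in ("integrated_gradients", "integrated_guided_gradients") \
                and self.steps < 2:
            raise ValueError("path methods require steps >= 2")


def _reduce(att: np.ndarray, absolute: bool = True) -> np.ndarray:
    """abs (optional) -> max over channels -> normalize to [0, 1]."""
    a = np.abs(att) if absolute else np.maximum(att, 0.0)
    a = a.max(axis=2)
    peak = a.max()
    return a / peak if peak > 0 else a


def _resolve_baseline(baseline, image: np.ndarray) -> np.ndarray:
    if isinstance(baseline, str):
        if baseline != "black":
            raise ValueError(f"unknown baseline spec {baseline!r}")
        return np.zeros_like(image)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != image.shape:
        raise ValueError("baseline shape must match the image")
    return baseline


def gradient_saliency(model, image: np.ndarray, sex) -> Heatmap:
    """|gradient of the sex-selected output w.r.t. each input pixel|."""
    _, grad = model.predict_with_gradient(image, sex)
    return Heatmap(values=_reduce(grad), method="saliency", sex=str(sex))


def baseline_gradients(model, image: np.ndarray, sex,
                       baseline="black") -> Heatmap:
    """|(x - baseline) * gradient| at the input (one-point path method)."""
    base = _resolve_baseline(baseline, image)
    _, grad = model.predict_with_gradient(image, sex)
    raw = (image - base) * grad
    return Heatmap(values=_reduce(raw), method="baseline_gradients",
                   sex=str(sex), raw=raw)


def _clamp_onset(model, image, base, sex, probes: int = 257) -> float:
    """Largest alpha below which the model output is identically zero.

    With a ReLU output and a black baseline, a model trained with the
    baseline class is clamped at zero on an initial stretch of the path;
    the gradient vanishes there, so that stretch contributes nothing to the
    path integral and the quadrature budget can be spent on the active
    segment.  Detection uses forward passes only; models without a batch
    ``predict`` fall back to the full path.
    """
    predict = getattr(model, "predict", None)
    if predict is None:
        return 0.0
    from .pipeline import encode_sex as _enc
    code = _enc(sex) if isinstance(sex, str) else np.asarray(sex)
    alphas = np.linspace(0.0, 1.0, probes)
    batch = base[None] + alphas[:, None, None, None] * (image - base)[None]
    f = np.asarray(predict(batch, np.repeat(code[None], probes, axis=0)))
    active = np.flatnonzero(f > 0)
    if active.size == 0 or active[0] == 0:
        return 0.0
    return float(alphas[active[0] - 1])


def _path_average_gradient(model, image, base, steps, sex, guided):
    """Midpoint-rule path-averaged gradient along baseline -> image.

    The average is taken over the active segment [alpha*, 1] (see
    :func:`_clamp_onset`) and scaled by its length, which equals the full
    path integral because the gradient is zero on the clamped stretch.
    """
    alpha0 = _clamp_onset(model, image, base, sex)
    alphas = alpha0 + (1.0 - alpha0) * (np.arange(steps) + 0.5) / steps
    total = np.zeros_like(image)
    chunk = 32
    for start in range(0, steps, chunk):
        a = alphas[start:start + chunk]
        batch = base[None] + a[:, None, None, None] * (image - base)[None]
        _, grads = model.predict_batch_with_gradients(batch, sex, guided=guided)
        total += grads.sum(axis=0)
    return (1.0 - alpha0) * total / steps


def integrated_gradients(model, image: np.ndarray, sex, steps: int = 64,
                         baseline="black") -> Heatmap:
    """(x - baseline) times the path-averaged gradient (midpoint rule)."""
    if steps < 2:
        raise ValueError("integrated gradients requires steps >= 2")
    base = _resolve_baseline(baseline, image)
    avg = _path_average_gradient(model, image, base, steps, sex, guided=False)
    raw = (image - base) * avg
    return Heatmap(values=_reduce(raw), method="integrated_gradients",
                   sex=str(sex), raw=raw)


def completeness_gap(model, heatmap: Heatmap, image: np.ndarray, sex,
                     baseline="black") -> tuple[float, float]:
    """(sum of raw attributions, f(x) - f(baseline)) for an IG heatmap."""
    if heatmap.raw is None:
        raise ValueError("heatmap carries no raw attributions")
    base = _resolve_baseline(baseline, image)
    fx, _ = model.predict_with_gradient(image, sex)
    fb, _ = model.predict_with_gradient(base, sex)
    return float(heatmap.raw.sum()), float(fx - fb)


def guided_backprop(model, image: np.ndarray, sex) -> Heatmap:
    """Gradient with only positive gradients passed through active ReLUs."""
    _, grad = model.predict_with_gradient(image, sex, guided=True)
    return Heatmap(values=_reduce(grad), method="guided_backprop", sex=str(sex))


def integrated_guided_gradients(model, image: np.ndarray, sex,
                                steps: int = 64, baseline="black") -> Heatmap:
    """Integrated-gradients path average computed with guided gradients."""
    if steps < 2:
        raise ValueError("integrated guided gradients requires steps >= 2")
    base = _resolve_baseline(baseline, image)
    avg = _path_average_gradient(model, image, base, steps, sex, guided=True)
    raw = (image - base) * avg
    return Heatmap(values=_reduce(raw), method="integrated_guided_gradients",
                   sex=str(sex), raw=raw)


def compute_heatmap(model, image: np.ndarray, sex,
                    config: AttributionConfig = AttributionConfig()) -> Heatmap:
    """Dispatch on :class:`AttributionConfig`."""
    if config.method == "saliency":
        return gradient_saliency(model, image, sex)
    if config.method == "baseline_gradients":
        return baseline_gradients(model, image, sex, baseline=config.baseline)
    if config.method == "integrated_gradients":
        return integrated_gradients(model, image, sex, steps=config.steps,
                                    baseline=config.baseline)
    if config.method == "guided_backprop":
        return guided_backprop(model, image, sex)
    return integrated_guided_gradients(model, image, sex, steps=config.steps,
                                       baseline=config.baseline)


def add_baseline_class(table: DatasetTable, n: int = 50, label: float = 0.0,
                       seed: int = 0) -> DatasetTable:
    """Append ``n`` all-black images labelled ``label`` (age 0) for training.

    Sexes are drawn uniformly so every head sees baseline examples.  The
    returned table relaxes the age >= 1 invariant explicitly; it must only be
    used as a *training* set — baseline rows never belong in validation or
    test folds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if table.images is None:
        raise ValueError("table must carry images")
    rng = np.random.default_rng(seed)
    shape = table.images.shape[1:]
    black = np.zeros((n,) + shape, dtype=table.images.dtype)
    sexes = rng.choice(["male", "female", "unknown"], size=n)
    ids = np.array([f"baseline{i:04d}" for i in range(n)], dtype=object)
    return DatasetTable(
        sample_ids=np.concatenate([table.sample_ids, ids]),
        read_ages=np.concatenate([table.read_ages, np.full(n, float(label))]),
        sex=np.concatenate([table.sex, sexes.astype(object)]),
        lengths=np.concatenate([table.lengths, np.full(n, np.nan)]),
        images=np.concatenate([table.images, black]),
        allow_age_zero=True)


def save_heatmap(heatmap: Heatmap, png_path, raw_path=None,
                 cmap: str = "viridis") -> None:
    """Render to PNG with a perceptually uniform colormap; optionally save the
    raw relevance array as .npy for downstream analysis."""
    import matplotlib.pyplot as plt
    from PIL import Image
    mapper = plt.get_cmap(cmap)
    rgb = (mapper(heatmap.values)[:, :, :3] * 255).astype(np.uint8)
    Image.fromarray(rgb).save(png_path)
    if raw_path is not None:
        np.save(raw_path, heatmap.raw if heatmap.raw is not None
                else heatmap.values)
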