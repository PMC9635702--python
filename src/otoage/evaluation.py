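"""Splitting, exhaustive cross-validation and ageing-precision metrics.

The cross-validation scheme is the early-stopping variant of k*l-fold CV:
the known-sex samples are dealt into k folds by proportionate stratified
allocation on read age; trial i then tests on fold i, early-stops on fold
i+1 (cyclic), and trains on the remaining k-2 folds plus the unknown-sex
pool, so every known-sex sample is tested exactly once and unknown-sex
samples are never tested.

Metrics are those used for ageing precision in fisheries work: RMSE in
years; the two-reading coefficient of variation

    CV_i = sqrt((yhat_i - ybar_i)^2 + (y_i - ybar_i)^2) / ybar_i,
    ybar_i = (y_i + yhat_i) / 2,

equivalently |yhat_i - y_i| / (sqrt(2) * ybar_i), averaged over samples;
0-off / 1-off agreement percentages of the rounded prediction; and the
KL divergence between Gaussian-KDE estimates of the predicted-age and
read-age distributions, computed by trapezoidal integration.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .model import ModelConfig, build_model, train_with_early_stopping
from .pipeline import AugmentSpec, DatasetTable

logger = logging.getLogger(__name__)

KDE_GRID_POINTS = 512
KDE_DENSITY_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# fold construction

@dataclasses.dataclass
class FoldAssignment:
    """Fold index (1..k) per known-sex sample; unknown-sex ids pooled apart."""

    k: int
    known_ids: np.ndarray       # sample ids, known sex
    folds: np.ndarray           # same length, values in 1..k
    unknown_ids: np.ndarray     # train-only pool

    def fold_ids(self, fold: int) -> np.ndarray:
        return self.known_ids[self.folds == fold]


@dataclasses.dataclass(frozen=True)
class CVTrial:
    index: int                  # 1..k
    test_ids: tuple
    val_ids: tuple
    train_ids: tuple            # k-2 folds plus the unknown-sex pool


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    trials: tuple[CVTrial, ...]


def stratified_split(table: DatasetTable, k: int, seed: int = 0) -> FoldAssignment:
    """Proportionate age-stratified allocation of known-sex samples to k folds.

    Within each read-age stratum the samples are shuffled and dealt
    round-robin; the dealing pointer carries over between strata, so overall
    fold sizes differ by at most one (exactly equal when k divides n).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    known = np.flatnonzero(table.known_sex_mask)
    if k > known.size:
        raise ValueError(f"k={k} exceeds the {known.size} known-sex samples")
    rng = np.random.default_rng(seed)
    ids = table.sample_ids[known]
    ages = table.read_ages[known].astype(int)
    folds = np.zeros(known.size, dtype=int)
    pointer = 0
    for age in np.unique(ages):
        stratum = np.flatnonzero(ages == age)
        stratum = stratum[rng.permutation(stratum.size)]
        for j, pos in enumerate(stratum):
            folds[pos] = (pointer + j) % k + 1
        pointer += stratum.size
    unknown_ids = table.sample_ids[~table.known_sex_mask]
    return FoldAssignment(k=k, known_ids=ids, folds=folds,
                          unknown_ids=np.asarray(unknown_ids, dtype=object))


def make_fold_plan(assignment: FoldAssignment) -> FoldPlan:
    """k trials: test fold i, validation fold i+1 (wrapping k+1 -> 1),
    training on the other k-2 folds plus the unknown-sex pool."""
    k = assignment.k
    trials = []
    for i in range(1, k + 1):
        val_fold = i % k + 1
        train_folds = [f for f in range(1, k + 1) if f not in (i, val_fold)]
        train_ids = np.concatenate(
            [assignment.fold_ids(f) for f in train_folds]
            + [assignment.unknown_ids])
        trials.append(CVTrial(index=i,
                              test_ids=tuple(assignment.fold_ids(i)),
                              val_ids=tuple(assignment.fold_ids(val_fold)),
                              train_ids=tuple(train_ids)))
    return FoldPlan(trials=tuple(trials))


# ---------------------------------------------------------------------------
# prediction container

class PredictionSet:
    """Paired (read age, predicted age, sex) rows with trial provenance."""

    COLUMNS = ["sample_id", "trial", "read_age", "predicted_age", "sex"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"PredictionSet frame lacks columns {sorted(missing)}")
        if (frame["predicted_age"] < 0).any():
            raise ValueError("predicted ages must be >= 0")
        self.frame = frame.reset_index(drop=True)[self.COLUMNS]

    def __len__(self):
        return len(self.frame)

    @property
    def read_ages(self) -> np.ndarray:
        return self.frame["read_age"].to_numpy(dtype=float)

    @property
    def predicted_ages(self) -> np.ndarray:
        return self.frame["predicted_age"].to_numpy(dtype=float)

    @property
    def residuals(self) -> np.ndarray:
        """epsilon_i = y_i - yhat_i."""
        return self.read_ages - self.predicted_ages

    def for_sex(self, sex: str) -> "PredictionSet":
        return PredictionSet(self.frame[self.frame["sex"] == sex])

    def for_trial(self, trial: int) -> "PredictionSet":
        return PredictionSet(self.frame[self.frame["trial"] == trial])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, sample_ids, read_ages, predicted_ages, sex, trial=0):
        n = len(sample_ids)
        trials = np.full(n, trial) if np.isscalar(trial) else np.asarray(trial)
        return cls(pd.DataFrame({
            "sample_id": sample_ids, "trial": trials, "read_age": read_ages,
            "predicted_age": predicted_ages, "sex": sex}))


# ---------------------------------------------------------------------------
# metrics

def rmse(pred_set) -> float:
    """Root mean squared error, years."""
    y, yhat = _pairs(pred_set)
    if y.size == 0:
        raise ValueError("rmse requires at least one sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def cv_single(y: float, yhat: float) -> float:
    """Two-reading ageing-precision CV for one (read, predicted) pair."""
    ybar = (y + yhat) / 2.0
    if ybar <= 0:
        raise ValueError("CV undefined for mean age <= 0")
    return float(np.sqrt((yhat - ybar) ** 2 + (y - ybar) ** 2) / ybar)


def mean_cv(pred_set) -> float:
    """Mean of per-sample CVs, as a fraction (multiply by 100 to report %)."""
    y, yhat = _pairs(pred_set)
    if y.size == 0:
        raise ValueError("mean_cv requires at least one sample")
    ybar = (y + yhat) / 2.0
    if (ybar <= 0).any():
        raise ValueError("CV undefined for mean age <= 0")
    cvs = np.sqrt((yhat - ybar) ** 2 + (y - ybar) ** 2) / ybar
    return float(cvs.mean())


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def off_percentage(pred_set, tolerance: int) -> float:
    """Percent of samples with |round(yhat) - y| <= tolerance (0-off / 1-off).

    Rounding is half-away-from-zero.
    """
    if tolerance not in (0, 1):
        raise ValueError("tolerance must be 0 or 1")
    y, yhat = _pairs(pred_set)
    if y.size == 0:
        raise ValueError("off_percentage requires at least one sample")
    return float(100.0 * np.mean(np.abs(_round_half_away(yhat) - y) <= tolerance))


def _pairs(pred_set):
    if isinstance(pred_set, PredictionSet):
        return pred_set.read_ages, pred_set.predicted_ages
    y, yhat = pred_set
    return np.asarray(y, dtype=float), np.asarray(yhat, dtype=float)


def residual_sd_by_age(pred_set: PredictionSet) -> pd.Series:
    """Empirical SD (ddof=1) of residuals grouped by read age.

    Ages with fewer than two residuals are omitted (and logged).
    """
    y = pred_set.read_ages.astype(int)
    res = pred_set.residuals
    out = {}
    for age in np.unique(y):
        sample = res[y == age]
        if sample.size < 2:
            logger.info("residual_sd_by_age: age %d has %d sample(s); omitted",
                        age, sample.size)
            continue
        out[int(age)] = float(np.std(sample, ddof=1))
    return pd.Series(out, name="residual_sd", dtype=float).rename_axis("read_age")


# ---------------------------------------------------------------------------
# density estimation and KL divergence

@dataclasses.dataclass(frozen=True)
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(trapezoid(self.density, self.grid))


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    sd = samples.std(ddof=1)
    q75, q25 = np.percentile(samples, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        spread = max(abs(samples.mean()), 1.0) * 1e-2
    return float(0.9 * spread * n ** (-0.2))


def default_grid(samples, bandwidth: float | None = None,
                 n_points: int = KDE_GRID_POINTS) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    bw = silverman_bandwidth(samples) if bandwidth is None else bandwidth
    return np.linspace(samples.min() - 3 * bw, samples.max() + 3 * bw, n_points)


def shared_grid(*sample_sets, n_points: int = KDE_GRID_POINTS) -> np.ndarray:
    """A grid wide enough for KDEs of several samples on a common support."""
    lo, hi = np.inf, -np.inf
    for s in sample_sets:
        s = np.asarray(s, dtype=float)
        bw = silverman_bandwidth(s)
        lo = min(lo, s.min() - 3 * bw)
        hi = max(hi, s.max() + 3 * bw)
    return np.linspace(lo, hi, n_points)


def kde(samples, grid: np.ndarray | None = None) -> DensityEstimate:
    """Gaussian-kernel density estimate with Silverman bandwidth."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("kde requires at least two samples")
    bw = silverman_bandwidth(samples)
    if grid is None:
        grid = default_grid(samples, bw)
    grid = np.asarray(grid, dtype=float)
    dens = np.zeros_like(grid)
    # chunk over samples to bound memory at large n
    for start in range(0, samples.size, 4096):
        chunk = samples[start:start + 4096]
        z = (grid[:, None] - chunk[None, :]) / bw
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens /= samples.size * bw * np.sqrt(2.0 * np.pi)
    return DensityEstimate(grid=grid, density=dens, bandwidth=bw)


def kl_divergence(p: DensityEstimate, q: DensityEstimate,
                  floor: float = KDE_DENSITY_FLOOR) -> float:
    """KL(P || Q) = integral of P (log P - log Q) by the trapezoidal rule.

    Q is floored at ``floor`` before taking logs; grid points where P = 0
    contribute nothing.
    """
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("kl_divergence requires a common evaluation grid")
    pd_ = np.maximum(p.density, 0.0)
    qd = np.maximum(q.density, floor)
    integrand = np.where(pd_ > 0, pd_ * (np.log(np.maximum(pd_, floor)) - np.log(qd)), 0.0)
    return float(trapezoid(integrand, p.grid))


def kl_between_samples(p_samples, q_samples) -> float:
    """KL divergence between the KDEs of two samples on a shared grid."""
    grid = shared_grid(p_samples, q_samples)
    return kl_divergence(kde(p_samples, grid), kde(q_samples, grid))


# ---------------------------------------------------------------------------
# report

@dataclasses.dataclass
class MetricsReport:
    """RMSE (yr), mean CV (fraction), 0-off/1-off (%), KL per sex;
    overall plus per-sex blocks."""

    rmse: float
    mean_cv: float
    off0_pct: float
    off1_pct: float
    kl_by_sex: dict
    per_sex: dict
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_metrics(pred_set: PredictionSet) -> MetricsReport:
    """Score a prediction set overall and per sex.

    The per-sex KL divergence compares the KDE of predicted ages against the
    KDE of read ages within that sex (requires >= 2 samples of each).
    """
    per_sex, kl_by_sex = {}, {}
    for sex in ("male", "female"):
        sub = pred_set.for_sex(sex)
        if len(sub) >= 2:
            kl_by_sex[sex] = kl_between_samples(sub.read_ages, sub.predicted_ages)
            per_sex[sex] = {"rmse": rmse(sub), "mean_cv": mean_cv(sub),
                            "off0_pct": off_percentage(sub, 0),
                            "off1_pct": off_percentage(sub, 1), "n": len(sub)}
    return MetricsReport(rmse=rmse(pred_set), mean_cv=mean_cv(pred_set),
                         off0_pct=off_percentage(pred_set, 0),
                         off1_pct=off_percentage(pred_set, 1),
                         kl_by_sex=kl_by_sex, per_sex=per_sex, n=len(pred_set))


# ---------------------------------------------------------------------------
# cross-validation runner

def _group_mean_bias(table: DatasetTable) -> tuple[float, float, float]:
    out = []
    for sex in ("male", "female", "unknown"):
        mask = np.array([s == sex for s in table.sex])
        out.append(float(table.read_ages[mask].mean()) if mask.any()
                   else float(table.read_ages.mean()))
    return tuple(out)


def run_cross_validation(plan: FoldPlan, table: DatasetTable,
                         model_config: ModelConfig,
                         augment_spec: AugmentSpec | None = None,
                         seed: int = 0, patience: int = 20,
                         max_epochs: int = 100):
    """Train one fresh model per trial and score its test-fold predictions.

    Output biases are initialized at the per-group mean read ages of each
    trial's training set.  Returns the pooled :class:`PredictionSet` and the
    list of per-trial :class:`MetricsReport`.
    """
    id_to_pos = {sid: i for i, sid in enumerate(table.sample_ids)}
    frames, reports = [], []
    for trial in plan.trials:
        def sub(ids):
            return table.subset(np.array([id_to_pos[s] for s in ids], dtype=int))
        t_train, t_val, t_test = sub(trial.train_ids), sub(trial.val_ids), sub(trial.test_ids)
        cfg = dataclasses.replace(model_config,
                                  output_bias_init=_group_mean_bias(t_train))
        model = build_model(cfg, seed=seed + trial.index)
        try:
            model, _ = train_with_early_stopping(
                model, t_train, t_val, augment_spec=augment_spec,
                patience=patience, max_epochs=max_epochs,
                seed=seed + trial.index)
        except Exception as exc:
            raise RuntimeError(f"cross-validation trial {trial.index} failed: "
                               f"{exc}") from exc
        preds = model.predict(t_test.images, t_test.sex_codes)
        ps = PredictionSet.from_arrays(t_test.sample_ids, t_test.read_ages,
                                       preds, t_test.sex, trial=trial.index)
        frames.append(ps.frame)
        reports.append(compute_metrics(ps))
    pooled = PredictionSet(pd.concat(frames, ignore_index=True))
    return pooled, reports
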