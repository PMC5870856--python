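"""Tail-contrast solubility model: fitting, feature elimination, prediction.

Model
-----
Training records are ranked by measured solubility; the bottom and top
``ceil(tail_fraction * n)`` records (default 5% tails) form the contrast
classes.  For each feature, the standardized difference between the
high-tail and low-tail means,

    z = (mean_high - mean_low) / sd(tail union),

is recorded; the feature's weight is |z| normalised so weights sum to 1
over the active features.  A query feature value x contributes

    s = clamp((x - mean_low) / (mean_high - mean_low), 0, 1)

(a linear scaling anchored at the tail means; for solubility-lowering
features mean_high < mean_low and the map reverses automatically), and the
predicted scaled solubility is the weight-convex combination of the
contributions — guaranteed to lie in [0, 1].  Percent solubility is the
affine map of the scaled value onto the interval between the mean measured
solubilities of the two tails.

Backward feature elimination repeatedly drops the lowest-weight active
feature (renormalising the remaining weights) while the Pearson correlation
between scaled predictions and measured solubility over the full (non-TM)
training population does not fall, and returns the best model seen.
"Fall" is judged against a small tolerance (``elimination_tol``): a dip
smaller than the sampling fluctuation of r is not evidence that
performance has dropped, and treating it as such would stop the
elimination almost immediately on any realistic data.

Proteins with a predicted transmembrane segment are excluded from training
and flagged, but still scored, at prediction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .features import FEATURE_NAMES, feature_table, feature_vector, isoelectric_point
from .profiles import detect_tm
from .seqio import ProteinSequence, TrainingRecord

MODEL_FORMAT = "seqsol-model"
MODEL_VERSION = 1

SequenceLike = ProteinSequence | str


@dataclass(frozen=True)
class FeatureStats:
    """Tail statistics for one feature."""

    feature: str
    mean_low: float
    mean_high: float
    pooled_sd: float
    z: float
    weight: float


@dataclass(frozen=True)
class PredictionResult:
    """Prediction plus per-feature diagnostics for one sequence.

    ``deviations`` holds, for each of the 35 features, the signed distance
    of the sequence's value from the training-population mean in units of
    the population SD — the quantities a user inspects to decide which
    features to target when engineering solubility.
    """

    id: str
    scaled: float
    percent: float
    pI: float
    tm_flag: bool
    deviations: Mapping[str, float]


def _as_feature_frame(X) -> pd.DataFrame | None:
    """Return X as a 35-column feature frame if it already is one, else None."""
    if isinstance(X, pd.DataFrame):
        missing = set(FEATURE_NAMES) - set(X.columns)
        if missing:
            raise ValueError(f"feature frame is missing columns: {sorted(missing)}")
        return X[list(FEATURE_NAMES)].astype(float)
    return None


class SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from protein sequences to the 35-feature table.

    Accepts an iterable of sequences (strings or :class:`ProteinSequence`)
    and returns a ``(n, 35)`` DataFrame; composes with sklearn pipelines.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = _as_feature_frame(X)
        return frame if frame is not None else feature_table(X)


class TailContrastRegressor(RegressorMixin, BaseEstimator):
    """Solubility predictor weighted by low/high solubility-tail contrast.

    Parameters
    ----------
    tail_fraction : float, default 0.05
        Fraction of the (TM-excluded) training population in each tail.
    select_features : bool, default True
        Run backward feature elimination after fitting the 35-feature
        model, keeping the feature subset with the best training
        correlation.
    exclude_tm : bool, default True
        Drop training records with a predicted transmembrane segment
        before ranking (only possible when sequences, not a precomputed
        feature frame, are supplied to :meth:`fit`).

    Attributes
    ----------
    stats_ : pandas.DataFrame
        Per-feature ``mean_low``, ``mean_high``, ``pooled_sd``, ``z``,
        ``weight`` (index: the 35 feature names; weights of inactive
        features are 0).
    active_ : list of str
        Features currently contributing to predictions.
    percent_low_, percent_high_ : float
        Mean measured solubility (percent) of the low and high tails;
        anchors of the scaled-to-percent calibration.
    population_means_, population_sds_ : pandas.Series
        Feature means and SDs over the TM-excluded training population,
        used for the deviation diagnostics.
    population_mean_scaled_ : float
        Mean scaled prediction over the training population.
    """

    def __init__(self, tail_fraction: float = 0.05, select_features: bool = True,
                 exclude_tm: bool = True, elimination_tol: float = 0.01):
        self.tail_fraction = tail_fraction
        self.select_features = select_features
        self.exclude_tm = exclude_tm
        self.elimination_tol = elimination_tol

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        """Fit tail statistics (and optionally eliminate features).

        X may be a sequence of protein sequences or a precomputed
        ``(n, 35)`` feature DataFrame; y are measured solubilities in
        percent (values above 100 are legitimate).
        """
        if not 0.0 < self.tail_fraction <= 0.5:
            raise ValueError(f"tail_fraction must lie in (0, 0.5], got {self.tail_fraction}")
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("solubility values must be non-negative")
        frame = _as_feature_frame(X)
        if frame is None:
            seqs = list(X)
            if len(seqs) != len(y):
                raise ValueError("X and y have different lengths")
            if self.exclude_tm:
                keep = np.array([not detect_tm(s).flag for s in seqs])
                seqs = [s for s, k in zip(seqs, keep) if k]
                y = y[keep]
            frame = feature_table(seqs)
        elif len(frame) != len(y):
            raise ValueError("X and y have different lengths")

        n = len(frame)
        if n < 40:
            raise ValueError(f"need at least 40 records after TM exclusion, got {n}")
        if np.ptp(y) == 0.0:
            raise ValueError("solubility values are all equal; tails are undefined")

        k = math.ceil(self.tail_fraction * n)
        order = np.argsort(y, kind="stable")
        low_idx, high_idx = order[:k], order[n - k:]

        Xm = frame.to_numpy()
        low, high = Xm[low_idx], Xm[high_idx]
        mean_low = low.mean(axis=0)
        mean_high = high.mean(axis=0)
        pooled_sd = np.concatenate([low, high]).std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(pooled_sd > 0, (mean_high - mean_low) / pooled_sd, 0.0)

        stats_frame = pd.DataFrame(
            {"mean_low": mean_low, "mean_high": mean_high,
             "pooled_sd": pooled_sd, "z": z, "weight": 0.0},
            index=list(FEATURE_NAMES),
        )
        self.feature_names_ = list(FEATURE_NAMES)
        self.stats_ = stats_frame
        if not np.any(z != 0.0):
            raise ValueError("no feature separates the solubility tails")
        self.active_ = list(FEATURE_NAMES)
        self._renormalize_weights()

        self.percent_low_ = float(y[low_idx].mean())
        self.percent_high_ = float(y[high_idx].mean())
        self.population_means_ = frame.mean(axis=0)
        self.population_sds_ = frame.std(axis=0, ddof=1)
        self.n_features_in_ = len(FEATURE_NAMES)

        if self.select_features:
            self._eliminate(frame, y)
        self.population_mean_scaled_ = float(np.mean(self._scaled(frame)))
        return self

    def _renormalize_weights(self) -> None:
        w = self.stats_["z"].abs().where(self.stats_.index.isin(self.active_), 0.0)
        total = w.sum()
        if total == 0.0:
            raise ValueError("active features all have zero contrast")
        w = w / total
        # nudge the largest weight so the active-weight vector sums to
        # exactly 1.0 in float: anchors at the tail means then score an
        # exact 0 or 1 and the convex combination cannot leave [0, 1]
        wa = w.loc[self.active_].to_numpy().copy()
        for _ in range(4):
            s = np.sum(wa)
            if s == 1.0:
                break
            wa[int(np.argmax(wa))] += 1.0 - s
        w.loc[self.active_] = wa
        self.stats_["weight"] = w

    # -------------------------------------------------------------- predict

    def _scaled(self, frame: pd.DataFrame) -> np.ndarray:
        """Scaled predictions in [0, 1] for a feature frame."""
        active = self.active_
        s = self.stats_.loc[active]
        x = frame[active].to_numpy()
        low = s["mean_low"].to_numpy()
        high = s["mean_high"].to_numpy()
        span = high - low
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(span != 0.0, (x - low) / np.where(span != 0.0, span, 1.0), 0.5)
        contrib = np.clip(contrib, 0.0, 1.0)
        # np.sum reproduces the exact pairwise summation used to normalise
        # the weights, so anchor inputs hit 0.0 and 1.0 exactly
        return np.clip(np.sum(contrib * s["weight"].to_numpy(), axis=1), 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        """Scaled solubility in [0, 1] for each input sequence (or feature row)."""
        self._check_fitted()
        frame = _as_feature_frame(X)
        if frame is None:
            frame = feature_table(X)
        return self._scaled(frame)

    def predict_percent(self, X) -> np.ndarray:
        """Percent solubility via the tail-anchored affine calibration."""
        scaled = self.predict(X)
        return self.percent_low_ + scaled * (self.percent_high_ - self.percent_low_)

    def predict_result(self, seqs: Iterable[SequenceLike]) -> list[PredictionResult]:
        """Full per-sequence results: scaled, percent, pI, TM flag, deviations."""
        self._check_fitted()
        results = []
        for i, seq in enumerate(seqs):
            fv = pd.Series(feature_vector(seq), dtype=float)
            frame = fv.to_frame().T
            scaled = float(self._scaled(frame)[0])
            sds = self.population_sds_
            with np.errstate(divide="ignore", invalid="ignore"):
                dev = (fv - self.population_means_) / sds.where(sds > 0, np.inf)
            results.append(PredictionResult(
                id=seq.id if isinstance(seq, ProteinSequence) else str(i),
                scaled=scaled,
                percent=self.percent_low_ + scaled * (self.percent_high_ - self.percent_low_),
                pI=isoelectric_point(seq),
                tm_flag=detect_tm(seq).flag,
                deviations=dev.to_dict(),
            ))
        return results

    # ---------------------------------------------------------- elimination

    def _eliminate(self, frame: pd.DataFrame, y: np.ndarray) -> None:
        """Greedy backward elimination on training correlation.

        Repeatedly drops the lowest-weight active feature (ties broken by
        dropping the one later in the canonical ordering) and renormalises.
        Elimination stops when the correlation between scaled predictions
        and y falls more than ``elimination_tol`` below the best value seen
        so far — a decrease smaller than the sampling fluctuation of r is
        not evidence that performance has fallen — and the best-so-far
        model is restored.
        """
        best_active = list(self.active_)
        best_weights = self.stats_["weight"].copy()
        best_r = self._train_correlation(frame, y)
        while len(self.active_) > 1:
            weights = self.stats_.loc[self.active_, "weight"]
            min_w = weights.min()
            # ties: drop the candidate later in canonical feature order
            candidate = [f for f in self.active_ if weights[f] == min_w][-1]
            self.active_ = [f for f in self.active_ if f != candidate]
            self._renormalize_weights()
            r = self._train_correlation(frame, y)
            if r < best_r - self.elimination_tol:
                break
            if r >= best_r:
                best_active = list(self.active_)
                best_weights = self.stats_["weight"].copy()
                best_r = r
        self.active_ = best_active
        self.stats_["weight"] = best_weights
        self.train_correlation_ = best_r

    def _train_correlation(self, frame: pd.DataFrame, y: np.ndarray) -> float:
        pred = self._scaled(frame)
        if np.ptp(pred) == 0.0:
            return -np.inf
        return float(stats.pearsonr(pred, y)[0])

    def _check_fitted(self) -> None:
        if not hasattr(self, "stats_"):
            raise RuntimeError("model is not fitted; call fit() first")


# ---------------------------------------------------------------- wrappers


def _split_records(records: Sequence[TrainingRecord]):
    seqs = [r.sequence for r in records]
    y = np.array([r.solubility for r in records], dtype=float)
    return seqs, y


def fit(records: Sequence[TrainingRecord], tail_fraction: float = 0.05) -> TailContrastRegressor:
    """Fit the 35-feature tail-contrast model (no elimination) on records."""
    seqs, y = _split_records(records)
    return TailContrastRegressor(
        tail_fraction=tail_fraction, select_features=False
    ).fit(seqs, y)


def eliminate_features(
    model: TailContrastRegressor, records: Sequence[TrainingRecord]
) -> TailContrastRegressor:
    """Backward-eliminate features of a fitted model using the same records.

    Returns the model (mutated in place and returned for convenience) with
    the feature subset whose training correlation was best before the
    first decrease.
    """
    model._check_fitted()
    seqs, y = _split_records(records)
    if model.exclude_tm:
        keep = np.array([not detect_tm(s).flag for s in seqs])
        seqs = [s for s, k in zip(seqs, keep) if k]
        y = y[keep]
    frame = feature_table(seqs)
    model._eliminate(frame, y)
    model.population_mean_scaled_ = float(np.mean(model._scaled(frame)))
    return model


def scale_feature(x: float, stats: FeatureStats) -> float:
    """Linear scaling of one feature value onto [0, 1] between its tail means."""
    span = stats.mean_high - stats.mean_low
    if span == 0.0:
        return 0.5
    return float(np.clip((x - stats.mean_low) / span, 0.0, 1.0))


def predict(seq: SequenceLike, model: TailContrastRegressor) -> PredictionResult:
    """Predict one sequence, returning the full diagnostic result."""
    return model.predict_result([seq])[0]


# ------------------------------------------------------------- persistence


def save_model(model: TailContrastRegressor, path: str | Path) -> None:
    """Write a fitted model as a versioned key-value text file."""
    model._check_fitted()
    lines = [f"{MODEL_FORMAT}\t{MODEL_VERSION}"]
    for key in ("tail_fraction", "percent_low_", "percent_high_", "population_mean_scaled_"):
        lines.append(f"{key.rstrip('_')}\t{getattr(model, key)!r}")
    lines.append("active\t" + ",".join(model.active_))
    for f in FEATURE_NAMES:
        s = model.stats_.loc[f]
        lines.append(
            "feature\t" + "\t".join([
                f, repr(float(s["mean_low"])), repr(float(s["mean_high"])),
                repr(float(s["pooled_sd"])), repr(float(s["z"])), repr(float(s["weight"])),
                repr(float(model.population_means_[f])), repr(float(model.population_sds_[f])),
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> TailContrastRegressor:
    """Read a model written by :func:`save_model`; lossless round trip."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty model file: {path}")
    head = lines[0].split("\t")
    if len(head) != 2 or head[0] != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
    version = int(head[1])
    if version != MODEL_VERSION:
        raise ValueError(
            f"{path}: model file version {version} is not supported "
            f"(this build reads version {MODEL_VERSION})"
        )
    scalars: dict[str, str] = {}
    active: list[str] | None = None
    rows: dict[str, list[float]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        if parts[0] == "active":
            active = parts[1].split(",") if len(parts) > 1 and parts[1] else []
        elif parts[0] == "feature":
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed feature line: {line!r}")
            rows[parts[1]] = [float(v) for v in parts[2:]]
        elif len(parts) == 2:
            scalars[parts[0]] = parts[1]
        else:
            raise ValueError(f"{path}: malformed line: {line!r}")
    required = {"tail_fraction", "percent_low", "percent_high", "population_mean_scaled"}
    if active is None or not required <= set(scalars) or set(rows) != set(FEATURE_NAMES):
        raise ValueError(f"{path}: truncated or incomplete model file")

    model = TailContrastRegressor(tail_fraction=float(scalars["tail_fraction"]))
    model.feature_names_ = list(FEATURE_NAMES)
    mat = np.array([rows[f] for f in FEATURE_NAMES])
    model.stats_ = pd.DataFrame(
        mat[:, :5], index=list(FEATURE_NAMES),
        columns=["mean_low", "mean_high", "pooled_sd", "z", "weight"],
    )
    model.population_means_ = pd.Series(mat[:, 5], index=list(FEATURE_NAMES))
    model.population_sds_ = pd.Series(mat[:, 6], index=list(FEATURE_NAMES))
    model.active_ = active
    model.percent_low_ = float(scalars["percent_low"])
    model.percent_high_ = float(scalars["percent_high"])
    model.population_mean_scaled_ = float(scalars["population_mean_scaled"])
    model.n_features_in_ = len(FEATURE_NAMES)
    return model
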