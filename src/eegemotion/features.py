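"""The ten time-domain features and feature-matrix assembly.

Each segment is standardized to zero mean and unit variance (see
:func:`build_feature_matrix` for where the normalization can be placed),
decomposed into subband reconstructions, and each reconstruction is
reduced to ten scalars:

f1  average amplitude change   (1/C) sum |s[i+1] - s[i]|
f2  activity (Hjorth)          population variance sigma_a^2
f3  absolute square-root sum   sum sqrt|s_i|
f4  clearance factor           peak / (mean sqrt|s_i|)^2
f5  root mean square           sqrt(mean s_i^2)
f6  crest factor               peak / RMS
f7  shape factor               RMS / mean|s_i|
f8  log detector               exp(mean log|s_i|)
f9  mobility (Hjorth)          sigma_d / sigma_a  (d = first difference)
f10 absolute sum               sum |s_i|

with peak = (max(s) - min(s)) / 2.  Conventions, fixed once and recorded:

* absolute values are taken under the square roots and the logarithm, so
  every feature stays real on standardized (signed) signals;
* variance is the population variance (divide by C), matching the "mean
  power" reading of activity;
* the first derivative is the forward difference s[i+1] - s[i] (length
  C-1), the same differences f1 averages — but note f1's divisor is C,
  not C-1;
* samples with |s_i| < 1e-12 are clamped to 1e-12 before the logarithm
  (a single exact zero would otherwise force f8 to 0).

The assembled matrix is min-max scaled to [0, 1] per column.  By default
the scaling statistics come from the training split only (no leakage); a
``full-data`` mode that scales before splitting is also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .errors import DegenerateSignalError, InputError
from .subband import BRAINWAVE_LEVELS, Segment, decompose_matrix

LOG_EPS = 1e-12

FEATURE_COLUMNS = tuple(f"f{i}" for i in range(1, 11))
FEATURE_NAMES = (
    "aac",
    "activity",
    "abs_sqrt_sum",
    "clearance_factor",
    "rms",
    "crest_factor",
    "shape_factor",
    "log_detector",
    "mobility",
    "abs_sum",
)
PROVENANCE_COLUMNS = ("subject", "emotion", "video", "segment", "channel", "band")
BAND_SORT_ORDER = ("delta", "theta", "alpha", "beta", "gamma")


def standardize(signal: np.ndarray) -> np.ndarray:
    """Scale a signal to zero mean and unit (population) variance."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise InputError("standardize needs at least 2 samples")
    std = x.std()
    if std == 0.0:
        raise DegenerateSignalError(
            "cannot standardize a constant signal (zero variance)"
        )
    return (x - x.mean()) / std


# -- individual features ----------------------------------------------------

def aac(x: np.ndarray) -> float:
    """f1: mean consecutive-sample change, with divisor C."""
    x = np.asarray(x, float)
    return float(np.abs(np.diff(x)).sum() / x.size)


def activity(x: np.ndarray, ddof: int = 0) -> float:
    """f2: variance (Hjorth activity / mean power); population by default."""
    return float(np.var(np.asarray(x, float), ddof=ddof))


def abs_sqrt_sum(x: np.ndarray) -> float:
    """f3: sum of the square roots of the absolute sample values."""
    return float(np.sqrt(np.abs(np.asarray(x, float))).sum())


def _peak(x: np.ndarray) -> float:
    return float((x.max() - x.min()) / 2.0)


def clearance_factor(x: np.ndarray) -> float:
    """f4: peak over the squared mean of root absolute values."""
    x = np.asarray(x, float)
    denom = float(np.sqrt(np.abs(x)).mean()) ** 2
    if denom == 0.0:
        return 0.0
    return _peak(x) / denom


def rms(x: np.ndarray) -> float:
    """f5: root mean square."""
    x = np.asarray(x, float)
    return float(np.sqrt(np.mean(x**2)))


def crest_factor(x: np.ndarray) -> float:
    """f6: peak over RMS; 0 for the all-zero signal."""
    x = np.asarray(x, float)
    r = rms(x)
    if r == 0.0:
        return 0.0
    return _peak(x) / r


def shape_factor(x: np.ndarray) -> float:
    """f7: RMS over mean absolute value; 0 for the all-zero signal."""
    x = np.asarray(x, float)
    denom = float(np.abs(x).mean())
    if denom == 0.0:
        return 0.0
    return rms(x) / denom


def log_detector(x: np.ndarray) -> float:
    """f8: exp of the mean log absolute value, zeros clamped to 1e-12."""
    x = np.abs(np.asarray(x, float))
    return float(np.exp(np.mean(np.log(np.maximum(x, LOG_EPS)))))


def mobility(x: np.ndarray, ddof: int = 0) -> float:
    """f9: Hjorth mobility, std(first difference) / std(signal)."""
    x = np.asarray(x, float)
    sa = x.std(ddof=ddof)
    if sa == 0.0:
        raise DegenerateSignalError("mobility undefined for a zero-variance signal")
    return float(np.diff(x).std(ddof=ddof) / sa)


def abs_sum(x: np.ndarray) -> float:
    """f10: sum of absolute sample values."""
    return float(np.abs(np.asarray(x, float)).sum())


_FEATURE_FUNCS = (
    aac,
    activity,
    abs_sqrt_sum,
    clearance_factor,
    rms,
    crest_factor,
    shape_factor,
    log_detector,
    mobility,
    abs_sum,
)


@dataclass(frozen=True)
class FeatureVector:
    """The ten named feature values of one (segment, subband) pair."""

    aac: float
    activity: float
    abs_sqrt_sum: float
    clearance_factor: float
    rms: float
    crest_factor: float
    shape_factor: float
    log_detector: float
    mobility: float
    abs_sum: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_features(signal: np.ndarray, ddof: int = 0) -> FeatureVector:
    """Compute all ten features of one signal.

    ``ddof`` selects the variance convention for activity and mobility
    (0 = population, the default; 1 = sample).  Raises
    :class:`DegenerateSignalError` on zero-variance input, where mobility
    is undefined.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise InputError("feature extraction needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise InputError("feature extraction requires finite sample values")
    if x.std() == 0.0:
        raise DegenerateSignalError(
            "zero-variance signal: mobility (f9) is undefined"
        )
    values = {}
    for name, f in zip(FEATURE_NAMES, _FEATURE_FUNCS):
        values[name] = f(x, ddof) if name in ("activity", "mobility") else f(x)
    return FeatureVector(**values)


def _features_block(X: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Vectorised feature bank: rows of X -> rows of a (n, 10) matrix."""
    X = np.asarray(X, float)
    n = X.shape[-1]
    absx = np.abs(X)
    sqrtx = np.sqrt(absx)
    d = np.diff(X, axis=-1)
    sa = X.std(axis=-1, ddof=ddof)
    if np.any(sa == 0.0):
        raise DegenerateSignalError("zero-variance signal in feature batch")
    peak = (X.max(axis=-1) - X.min(axis=-1)) / 2.0
    r = np.sqrt(np.mean(X**2, axis=-1))
    out = np.empty((X.shape[0], 10))
    out[:, 0] = np.abs(d).sum(axis=-1) / n
    out[:, 1] = sa**2
    out[:, 2] = sqrtx.sum(axis=-1)
    out[:, 3] = peak / sqrtx.mean(axis=-1) ** 2
    out[:, 4] = r
    out[:, 5] = peak / r
    out[:, 6] = r / absx.mean(axis=-1)
    out[:, 7] = np.exp(np.mean(np.log(np.maximum(absx, LOG_EPS)), axis=-1))
    out[:, 8] = d.std(axis=-1, ddof=ddof) / sa
    out[:, 9] = absx.sum(axis=-1)
    return out


def build_feature_matrix(
    dataset: Iterable[Segment],
    channels: Sequence[str] | None = None,
    bands: Sequence[str] | None = None,
    wavelet: str = "db8",
    levels: int = 6,
    standardize_mode: str = "segment",
    variance_ddof: int = 0,
) -> pd.DataFrame:
    """Decompose every retained segment and extract one row per subband.

    Rows carry provenance columns (subject, emotion, video, segment,
    channel, band) followed by ``f1`` ... ``f10``, in deterministic order
    sorted by (subject, emotion, video, segment, channel, band).
    ``channels`` and ``bands`` filter to subsets of the known names.

    ``standardize_mode`` places the zero-mean/unit-variance normalization:

    * ``"segment"`` (default) — standardize each raw segment before
      decomposition.  Overall amplitude is removed but each rhythm's
      *share* of the signal power survives into its reconstruction, so
      band-power contrasts remain visible to the feature bank.
    * ``"subband"`` — standardize each band reconstruction immediately
      before feature extraction.  This also erases relative band power;
      only within-band spectral shape is left.
    * ``"none"`` — no normalization (absolute microvolt features).
    """
    dataset = list(dataset)
    if bands is None:
        bands = list(BRAINWAVE_LEVELS)
    unknown = set(bands) - set(BRAINWAVE_LEVELS)
    if unknown:
        raise InputError(f"unknown band name(s): {sorted(unknown)}")
    if channels is not None:
        known = {s.channel for s in dataset}
        missing = set(channels) - known
        if missing:
            raise InputError(f"channel(s) {sorted(missing)} not present in dataset")
        dataset = [s for s in dataset if s.channel in set(channels)]
    if not dataset:
        raise InputError("empty selection: no segments match the requested filters")

    lengths = {len(s) for s in dataset}
    if len(lengths) != 1:
        raise InputError("all segments must share one length")

    if standardize_mode not in ("segment", "subband", "none"):
        raise InputError(f"unknown standardize_mode {standardize_mode!r}")
    levels_needed = [BRAINWAVE_LEVELS[b] for b in bands]
    frames = []
    chunk = 2048  # bounds peak memory: one chunk's reconstructions at a time
    for start in range(0, len(dataset), chunk):
        part = dataset[start : start + chunk]
        X = np.stack([s.samples for s in part])
        if standardize_mode == "segment":
            sd = X.std(axis=-1, keepdims=True)
            if np.any(sd == 0.0):
                raise DegenerateSignalError("constant segment; cannot standardize")
            X = (X - X.mean(axis=-1, keepdims=True)) / sd
        recs = decompose_matrix(X, wavelet=wavelet, levels=levels, names=levels_needed)
        meta = pd.DataFrame(
            {
                "subject": [s.subject for s in part],
                "emotion": [s.label for s in part],
                "video": [s.video for s in part],
                "segment": [s.index for s in part],
                "channel": [s.channel for s in part],
            }
        )
        for band in bands:
            B = recs[BRAINWAVE_LEVELS[band]]
            if standardize_mode == "subband":
                sd = B.std(axis=-1, keepdims=True)
                if np.any(sd == 0.0):
                    raise DegenerateSignalError(
                        f"constant {band} reconstruction; cannot standardize"
                    )
                B = (B - B.mean(axis=-1, keepdims=True)) / sd
            feats = _features_block(B, ddof=variance_ddof)
            df = meta.copy()
            df["band"] = band
            for j, col in enumerate(FEATURE_COLUMNS):
                df[col] = feats[:, j]
            frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out["band"] = pd.Categorical(out["band"], categories=BAND_SORT_ORDER, ordered=True)
    out = out.sort_values(list(PROVENANCE_COLUMNS), kind="mergesort").reset_index(drop=True)
    out["band"] = out["band"].astype(str)
    return out


def minmax_fit_transform(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    mode: str = "train-only",
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Min-max scale the feature columns to [0, 1].

    ``train-only`` (default) fits the per-column min/max on the training
    rows and applies them to both splits, so test values may fall outside
    [0, 1].  ``full-data`` fits on train and test pooled, reproducing the
    scale-then-split ordering.  A constant column maps to 0.  Returns
    (scaled train, scaled test, per-column stats frame with rows
    ``min``/``max``).
    """
    if len(train) == 0:
        raise InputError("training matrix is empty")
    if mode not in ("train-only", "full-data"):
        raise InputError(f"unknown scaling mode {mode!r}")
    cols = [c for c in FEATURE_COLUMNS if c in train.columns]
    if len(cols) != len(FEATURE_COLUMNS):
        raise InputError("feature columns f1..f10 missing from matrix")
    if mode == "full-data" and test is not None:
        fit_on = np.vstack([train[cols].to_numpy(), test[cols].to_numpy()])
    else:
        fit_on = train[cols].to_numpy()
    scaler = MinMaxScaler().fit(fit_on)
    stats = pd.DataFrame(
        [scaler.data_min_, scaler.data_max_], index=["min", "max"], columns=cols
    )
    train = train.copy()
    train[cols] = scaler.transform(train[cols].to_numpy())
    if test is not None:
        test = test.copy()
        test[cols] = scaler.transform(test[cols].to_numpy())
    return train, test, stats
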