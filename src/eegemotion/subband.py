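"""Wavelet subband decomposition of fixed-length EEG segments.

A 6-level Daubechies-8 (db8) discrete wavelet transform splits a segment
sampled at 256 Hz into six detail levels and one approximation level.  With
dyadic halving the levels map onto the classical EEG rhythms:

====== ==================== =====================
level  nominal label        nominal range (Hz)
====== ==================== =====================
D1     noise                125-256
D2     noise                63-125
D3     gamma                30-63
D4     beta                 13-30
D5     alpha                8-13
D6     theta                4-7
A6     delta                0-4
====== ==================== =====================

The nominal Hz labels above are the source convention's display metadata:
they describe a 512 Hz record and are only realizable at that rate.  At
the 256 Hz this pipeline processes (Nyquist 128 Hz) the levels actually
resolve one octave lower — see ``DYADIC_RANGES``: D1 64-128, D2 32-64,
D3 16-32, D4 8-16, D5 4-8, D6 2-4, A6 0-2 Hz — and db8 filters have
finite transition bands besides.  The labels are documented, not
"corrected": band names follow the table above throughout.

Each subband is returned as a *time-domain reconstruction* at the
original length (all other levels zeroed before inverting the transform),
so the seven reconstructions sum back to the input signal exactly (up to
floating-point round-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pywt

from .errors import InputError

WAVELET = "db8"
LEVELS = 6
BOUNDARY_MODE = "symmetric"

#: nominal (display) ranges of the levels, Hz, in the source convention
SUBBAND_RANGES: dict[str, tuple[float, float]] = {
    "D1": (125.0, 256.0),
    "D2": (63.0, 125.0),
    "D3": (30.0, 63.0),
    "D4": (13.0, 30.0),
    "D5": (8.0, 13.0),
    "D6": (4.0, 7.0),
    "A6": (0.0, 4.0),
}

#: frequency ranges the levels actually resolve at a 256 Hz sampling rate
DYADIC_RANGES: dict[str, tuple[float, float]] = {
    "D1": (64.0, 128.0),
    "D2": (32.0, 64.0),
    "D3": (16.0, 32.0),
    "D4": (8.0, 16.0),
    "D5": (4.0, 8.0),
    "D6": (2.0, 4.0),
    "A6": (0.0, 2.0),
}

#: levels that survive noise removal, keyed by brain-wave name
BRAINWAVE_LEVELS: dict[str, str] = {
    "gamma": "D3",
    "beta": "D4",
    "alpha": "D5",
    "theta": "D6",
    "delta": "A6",
}

NOISE_LEVELS = ("D1", "D2")


@dataclass
class Segment:
    """One channel of one fixed-length EEG window, in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    label: str | None = None
    subject: int | None = None
    video: int | None = None
    index: int | None = None  # window ("page") index within the video
    channel: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("segment samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SubbandSet:
    """The 7 band-limited reconstructions of one segment."""

    bands: dict[str, np.ndarray]
    sampling_rate: float
    wavelet: str = WAVELET
    levels: int = LEVELS
    boundary_mode: str = BOUNDARY_MODE
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(SUBBAND_RANGES))

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.bands.values()}
        if len(lengths) > 1:
            raise InputError("all subband reconstructions must share one length")


def _coeff_names(levels: int) -> list[str]:
    # pywt.wavedec returns [cA_L, cD_L, cD_{L-1}, ..., cD_1]
    return [f"A{levels}"] + [f"D{j}" for j in range(levels, 0, -1)]


def decompose_matrix(
    signals: np.ndarray,
    wavelet: str = WAVELET,
    levels: int = LEVELS,
    mode: str = BOUNDARY_MODE,
    names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Decompose a stack of equal-length signals, rows = signals.

    Returns a mapping from level name (``A6``, ``D6`` ... ``D1``) to an array
    of band reconstructions with the same shape as ``signals``.  ``names``
    restricts which levels are reconstructed (all by default).  This is the
    vectorised workhorse behind :func:`decompose`.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n = signals.shape[-1]
    if n < 2**levels:
        raise InputError(
            f"segment length {n} too short for a {levels}-level decomposition "
            f"(need at least {2**levels} samples)"
        )
    coeffs = pywt.wavedec(signals, wavelet, mode=mode, level=levels, axis=-1)
    all_names = _coeff_names(levels)
    if names is None:
        names = all_names
    unknown = set(names) - set(all_names)
    if unknown:
        raise InputError(f"unknown level name(s): {sorted(unknown)}")
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(all_names):
        if name not in names:
            continue
        selected = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        rec = pywt.waverec(selected, wavelet, mode=mode, axis=-1)
        out[name] = rec[..., :n]
    return out


def decompose(
    segment: Segment,
    wavelet: str = WAVELET,
    levels: int = LEVELS,
    mode: str = BOUNDARY_MODE,
) -> SubbandSet:
    """Split one segment into its 7 named band reconstructions.

    The reconstructions are additive: their elementwise sum reproduces the
    input within floating tolerance (perfect-reconstruction property of the
    orthogonal db8 filter bank).
    """
    recs = decompose_matrix(segment.samples, wavelet, levels, mode)
    bands = {name: rec[0] for name, rec in recs.items()}
    return SubbandSet(
        bands=bands,
        sampling_rate=segment.sampling_rate,
        wavelet=wavelet,
        levels=levels,
        boundary_mode=mode,
    )


def retain_brainwaves(subbands: SubbandSet) -> dict[str, np.ndarray]:
    """Drop the two noise levels (D1, D2) and name the remaining five.

    Returns ``{gamma, beta, alpha, theta, delta}`` mapped to the same
    reconstruction arrays held by ``subbands`` (no copy).
    """
    out: dict[str, np.ndarray] = {}
    for wave, level in BRAINWAVE_LEVELS.items():
        if level not in subbands.bands:
            raise InputError(f"subband set is missing level {level} ({wave})")
        out[wave] = subbands.bands[level]
    return out
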