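"""fNIRS signal conversion and conditioning.

Implements the modified Beer-Lambert law (MBLL) linking two-wavelength
optical-density changes to oxy-/deoxy-hemoglobin concentration changes,

    [dHbO; dHbR] = (1/rho) * M^-1 @ [OD_l1; OD_l2],
    M[w][c] = eps_c(lambda_w) * DPF(lambda_w),

together with the band-pass filter and sampling-rate conversions the
pipeline applies to hemodynamic and EEG channels.  The forward map
(concentration -> OD) is the exact matrix inverse of the same relation and
is used by the synthetic generator and in round-trip tests.

Extinction coefficients are in 1/(mM*cm), concentrations in mM, the
source-detector separation ``rho`` in cm, and DPF is dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import InvalidParameterError, ShapeError

__all__ = [
    "MBLLParams",
    "HemoRecording",
    "mbll_forward",
    "mbll_inverse",
    "bandpass",
    "resample",
]

#: Default extinction coefficients eps[wavelength][chromophore], 1/(mM*cm),
#: at 760 and 850 nm (standard tabulated values; configurable).
_DEFAULT_EPS = ((0.5958, 1.6745), (1.0507, 0.7861))


@dataclass(frozen=True)
class MBLLParams:
    """Parameters of the modified Beer-Lambert conversion.

    Attributes
    ----------
    wavelengths : (nm, nm)
        The two measurement wavelengths.
    eps : 2x2 nested tuple
        ``eps[w][c]`` = extinction coefficient of chromophore ``c``
        (0 = HbO, 1 = HbR) at wavelength ``w``, in 1/(mM*cm).
    dpf : (float, float)
        Differential pathlength factor per wavelength (dimensionless).
    rho : float
        Source-detector separation in cm.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    eps: tuple[tuple[float, float], tuple[float, float]] = _DEFAULT_EPS
    dpf: tuple[float, float] = (6.0, 6.0)
    rho: float = 3.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise InvalidParameterError(f"rho must be > 0, got {self.rho}")
        if any(d <= 0 for d in self.dpf):
            raise InvalidParameterError(f"dpf must be > 0, got {self.dpf}")
        m = self.matrix
        if not np.all(np.isfinite(m)) or np.linalg.cond(m) > 1e12:
            raise InvalidParameterError(
                "extinction/DPF matrix is singular or ill-conditioned"
            )

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 map M with M[w][c] = eps_c(lambda_w) * DPF(lambda_w)."""
        e = np.asarray(self.eps, dtype=float)
        return e * np.asarray(self.dpf, dtype=float)[:, None]


@dataclass
class HemoRecording:
    """Per-channel hemoglobin concentration-change series (mM).

    ``hbo`` and ``hbr`` are channels x samples; markers and identifiers are
    inherited from the source optical-density recording.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    pair_ids: list[int]
    markers: list
    subject: int = 0
    session: int = 0

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ShapeError("hbo and hbr must have identical shapes")

    def replace(self, **kw) -> "HemoRecording":
        return dataclasses.replace(self, **kw)


def _as_series_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"series shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mbll_inverse(od1, od2, p: MBLLParams = MBLLParams()):
    """Convert two-wavelength OD changes to (dHbO, dHbR) in mM.

    Applies ``(1/rho) * M^-1`` samplewise; inputs may be 1-D series or
    matching n-D arrays (conversion acts on every element pair).
    """
    od1, od2 = _as_series_pair(od1, od2)
    minv = np.linalg.inv(p.matrix)
    hbo = (minv[0, 0] * od1 + minv[0, 1] * od2) / p.rho
    hbr = (minv[1, 0] * od1 + minv[1, 1] * od2) / p.rho
    return hbo, hbr


def mbll_forward(hbo, hbr, p: MBLLParams = MBLLParams()):
    """Exact forward map (dHbO, dHbR) -> (OD_l1, OD_l2).

    ``mbll_inverse(*mbll_forward(h, r, p), p)`` recovers ``(h, r)`` to
    floating-point precision for any invertible parameter set.
    """
    hbo, hbr = _as_series_pair(hbo, hbr)
    m = p.matrix
    od1 = p.rho * (m[0, 0] * hbo + m[0, 1] * hbr)
    od2 = p.rho * (m[1, 0] * hbo + m[1, 1] * hbr)
    return od1, od2


def bandpass(series, fs, low=0.01, high=0.09, order=3, zero_phase=True):
    """Butterworth band-pass along the last axis.

    Defaults to the hemodynamic band (3rd-order, 0.01-0.09 Hz).  Zero-phase
    (forward-backward) filtering is the default so that epoch timing is not
    phase-shifted; note this doubles the effective magnitude order.  Set
    ``zero_phase=False`` for a causal single pass.
    """
    if fs <= 0:
        raise InvalidParameterError(f"fs must be > 0, got {fs}")
    if not (0 < low < high < fs / 2):
        raise InvalidParameterError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"low={low}, high={high}, fs={fs}"
        )
    if order < 1:
        raise InvalidParameterError(f"order must be >= 1, got {order}")
    x = np.asarray(series, dtype=float)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1, padtype="odd")
    return signal.sosfilt(sos, x, axis=-1)


def resample(series, fs_in, fs_out):
    """Polyphase anti-aliased downsampling along the last axis.

    The ratio ``fs_out/fs_in`` is reduced to a rational number (e.g.
    12.5 -> 10 Hz is 4/5, 1000 -> 200 Hz is 1/5); output length is
    ``round(n * fs_out / fs_in)``.  Upsampling is not supported.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise InvalidParameterError("sampling rates must be > 0")
    if fs_out > fs_in:
        raise InvalidParameterError(
            f"upsampling ({fs_in} -> {fs_out} Hz) is not supported"
        )
    x = np.asarray(series, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(1_000_000)
    # demean first so the channel mean survives the FIR's DC ripple exactly;
    # linear-extension padding keeps slow trends flat at the edges
    m = x.mean(axis=-1, keepdims=True)
    y = signal.resample_poly(x - m, ratio.numerator, ratio.denominator,
                             axis=-1, padtype="line")
    return y + m
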