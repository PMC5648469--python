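"""Saturation-recovery FLASH signal chain for quantitative first-pass CMR.

Converts measured magnitude signal to gadolinium concentration via a
Bloch-simulated look-up table (LUT) of the acquisition protocol:

* :func:`sr_flash_signal` — simulate the normalized SR-FLASH signal for a
  given [Gd], by ideal saturation, free T1 recovery to the first readout
  line, and discrete line-by-line FLASH evolution up to the central
  k-space line, with optional T2* loss at the echo time.
* :func:`build_lut` — tabulate the simulation on a concentration grid and
  locate the monotone (invertible) domain.
* :func:`t2star_correct` — dual-echo mono-exponential extrapolation to TE=0.
* :func:`signal_to_concentration` — proton-density-normalized LUT inversion.
* :func:`extract_aif` — blood-pool mean concentration curve.

Relaxation rates follow the linear fast-exchange model
``R1 = 1/T1_native + r1*[Gd]`` and ``R2* = 1/T2*_native + r2star*[Gd]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "SRProtocol",
    "RelaxationParams",
    "SignalLUT",
    "ConcentrationSeries",
    "sr_flash_signal",
    "build_lut",
    "t2star_correct",
    "signal_to_concentration",
    "extract_aif",
]


@dataclass(frozen=True)
class SRProtocol:
    """Dual-echo saturation-recovery FLASH protocol parameters.

    flip_angle       : readout flip angle, degrees (low for linearity).
    tr_line          : repetition time per phase-encode line, ms.
    te1, te2         : echo times, ms (te1 < te2 < tr_line).
    saturation_delay : saturation pulse to central k-space line, ms.
    n_pe_lines       : phase-encode lines per image (linear ordering).
    pd_flip_angle    : flip angle of the proton-density reference, degrees.
    sat_efficiency   : fraction of Mz destroyed by the saturation pulse
                       (1.0 = ideal saturation).
    """

    flip_angle: float = 8.0
    tr_line: float = 2.0
    te1: float = 0.6
    te2: float = 1.6
    saturation_delay: float = 100.0
    n_pe_lines: int = 48
    pd_flip_angle: float = 5.0
    sat_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.flip_angle < 90:
            raise ValueError(f"flip_angle must be in (0, 90), got {self.flip_angle}")
        if not 0 < self.te1 < self.te2 < self.tr_line:
            raise ValueError("echo times must satisfy 0 < te1 < te2 < tr_line")
        if self.saturation_delay <= 0:
            raise ValueError("saturation_delay must be > 0")
        if self.n_pe_lines < 1:
            raise ValueError("n_pe_lines must be >= 1")
        if not 0 <= self.sat_efficiency <= 1:
            raise ValueError("sat_efficiency must be in [0, 1]")
        if self.saturation_delay <= self.central_line_index * self.tr_line:
            raise ValueError(
                "saturation_delay must exceed the readout time to the central "
                f"line ({self.central_line_index * self.tr_line} ms)"
            )

    @property
    def central_line_index(self) -> int:
        """0-based index of the central k-space line under linear ordering."""
        return self.n_pe_lines // 2

    @classmethod
    def default_myocardial(cls) -> "SRProtocol":
        return cls()

    @classmethod
    def default_aif(cls) -> "SRProtocol":
        """Low-resolution protocol: few lines, very short saturation delay,
        so the signal stays nearly linear at high blood-pool [Gd]."""
        return cls(saturation_delay=30.0, n_pe_lines=12)


@dataclass(frozen=True)
class RelaxationParams:
    """Contrast-agent relaxivities and native tissue relaxation times.

    r1, r2star in L mmol^-1 s^-1; T1_native, T2star_native in ms.
    """

    r1: float = 4.5
    r2star: float = 5.0
    T1_native: float = 1000.0
    T2star_native: float = 30.0

    def __post_init__(self) -> None:
        for name in ("r1", "r2star", "T1_native", "T2star_native"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def myocardium_1p5T(cls) -> "RelaxationParams":
        return cls(T1_native=1000.0, T2star_native=30.0)

    @classmethod
    def blood_1p5T(cls) -> "RelaxationParams":
        return cls(T1_native=1600.0, T2star_native=50.0)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Gadolinium concentration (mmol/L) over time, per pixel or per ROI."""

    times: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != self.concentration.shape[0]:
            raise ValueError("leading axis of concentration must match times")


def sr_flash_signal(gd, protocol: SRProtocol, relax: RelaxationParams,
                    te: float | None = None):
    """Normalized SR-FLASH signal at gadolinium concentration ``gd`` (mmol/L).

    ``te`` is the echo time in ms at which T2* loss is applied; ``None``
    evaluates the signal extrapolated to TE = 0 (no T2* loss), which is the
    form used for the inversion LUT when measurements are dual-echo
    T2*-corrected first.  Returns signal divided by the proton-density
    reference ``sin(pd_flip_angle)``.
    """
    gd = np.asarray(gd, dtype=float)
    if np.any(gd < 0):
        raise ValueError("gd must be >= 0")
    r1_s = 1000.0 / relax.T1_native + relax.r1 * gd      # 1/s
    tr_s = protocol.tr_line / 1000.0
    ic = protocol.central_line_index
    t_free = (protocol.saturation_delay - ic * protocol.tr_line) / 1000.0

    m0 = 1.0
    mz = m0 * (1.0 - protocol.sat_efficiency)            # after saturation
    mz = m0 + (mz - m0) * np.exp(-t_free * r1_s)          # free recovery
    cos_a = np.cos(np.radians(protocol.flip_angle))
    e_tr = np.exp(-tr_s * r1_s)
    for _ in range(ic):                                   # lines before center
        mz = m0 + (mz * cos_a - m0) * e_tr
    signal = mz * np.sin(np.radians(protocol.flip_angle))
    if te is not None:
        r2s_s = 1000.0 / relax.T2star_native + relax.r2star * gd
        signal = signal * np.exp(-(te / 1000.0) * r2s_s)
    return signal / np.sin(np.radians(protocol.pd_flip_angle))


@dataclass(frozen=True)
class SignalLUT:
    """Monotone signal <-> [Gd] map from the Bloch simulation of a protocol."""

    gd_grid: np.ndarray
    normalized_signal: np.ndarray
    valid_max_gd: float

    def __post_init__(self) -> None:
        n_valid = self.n_valid
        if n_valid < 2:
            raise ValueError("LUT must have at least 2 valid points")
        d = np.diff(self.normalized_signal[:n_valid])
        if np.any(d <= 0):
            raise ValueError("LUT must be strictly increasing on [0, valid_max_gd]")

    @property
    def n_valid(self) -> int:
        return int(np.searchsorted(self.gd_grid, self.valid_max_gd, side="right"))

    def forward(self, gd):
        """Interpolated signal on the valid domain (round-trip checks)."""
        n = self.n_valid
        return np.interp(np.asarray(gd, float), self.gd_grid[:n],
                         self.normalized_signal[:n])

    def invert(self, normalized_signal):
        """Invert signal to [Gd]; returns (gd, saturated_mask).

        Signals above the valid range are clipped to ``valid_max_gd`` and
        flagged; signals below the gd=0 signal map to 0.
        """
        s = np.asarray(normalized_signal, float)
        n = self.n_valid
        sig = self.normalized_signal[:n]
        saturated = s > sig[-1]
        gd = np.interp(s, sig, self.gd_grid[:n])
        return gd, saturated


def build_lut(protocol: SRProtocol, relax: RelaxationParams,
              grid_spec=(20.0, 0.01), te: float | None = None) -> SignalLUT:
    """Tabulate :func:`sr_flash_signal` over a [Gd] grid.

    ``grid_spec`` is ``(gd_max, step)`` in mmol/L or an explicit ascending
    grid starting at 0.  ``valid_max_gd`` is set to the largest grid value
    below the first non-monotonicity (T2*-induced signal rollover); a grid
    whose very first step is already non-increasing raises.
    """
    if isinstance(grid_spec, tuple) and len(grid_spec) == 2:
        gd_max, step = grid_spec
        grid = np.arange(0.0, gd_max + 0.5 * step, step)
    else:
        grid = np.asarray(grid_spec, dtype=float)
    if grid.size < 2:
        raise ValueError("LUT grid must contain at least 2 points")
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("LUT grid must be ascending and start at 0")

    sig = np.asarray(sr_flash_signal(grid, protocol, relax, te=te), float)
    d = np.diff(sig)
    bad = np.nonzero(d <= 0)[0]
    if bad.size and bad[0] == 0:
        raise ValueError("signal curve is non-monotone from the first grid step")
    valid_max = grid[bad[0]] if bad.size else grid[-1]
    return SignalLUT(gd_grid=grid, normalized_signal=sig, valid_max_gd=float(valid_max))


class T2StarCorrection(NamedTuple):
    s0: np.ndarray
    r2star_apparent: np.ndarray
    n_flagged: int


def t2star_correct(s1, s2, te1: float, te2: float) -> T2StarCorrection:
    """Dual-echo mono-exponential extrapolation to TE = 0.

    ``R2* = ln(s1/s2)/(te2-te1)`` (1/ms), ``s0 = s1*exp(R2* * te1)``.
    Pixels where noise makes s2 > s1 (negative apparent R2*) are passed
    through unchanged (s0 = s1, R2* = 0) and counted in ``n_flagged``.
    """
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    if te2 <= te1:
        raise ValueError("te2 must exceed te1")
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("signals must be > 0 for log extrapolation")
    r2s = np.log(s1 / s2) / (te2 - te1)
    negative = r2s < 0
    r2s = np.where(negative, 0.0, r2s)
    s0 = np.where(negative, s1, s1 * np.exp(r2s * te1))
    return T2StarCorrection(s0=s0, r2star_apparent=r2s,
                            n_flagged=int(np.count_nonzero(negative)))


class ConversionResult(NamedTuple):
    series: ConcentrationSeries
    n_saturated: int


def signal_to_concentration(times, series, lut: SignalLUT, pd_reference,
                            baseline_frames: int | None = None) -> ConversionResult:
    """Invert a dynamic signal series to gadolinium concentration.

    ``series`` has shape (n_t, *spatial) in raw signal units and is first
    normalized by ``pd_reference`` (same spatial shape); pixels with
    non-positive PD are masked to NaN.  Signals above the LUT range are
    clipped to ``valid_max_gd`` and counted.  If ``baseline_frames`` is
    given, the mean concentration of those leading frames is subtracted
    (Delta[Gd]) and the result floored at zero.
    """
    series = np.asarray(series, float)
    pd_reference = np.asarray(pd_reference, float)
    if series.shape[1:] != pd_reference.shape:
        raise ValueError("pd_reference shape must match the spatial shape")
    valid = pd_reference > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = series / pd_reference
    gd, saturated = lut.invert(norm)
    gd = np.where(valid, gd, np.nan)
    n_sat = int(np.count_nonzero(saturated & valid))
    if baseline_frames:
        base = gd[:baseline_frames].mean(axis=0)
        gd = np.clip(gd - base, 0.0, None)
    return ConversionResult(
        series=ConcentrationSeries(times=np.asarray(times, float), concentration=gd),
        n_saturated=n_sat,
    )


def extract_aif(series: ConcentrationSeries, blood_mask):
    """Mean blood-pool concentration per frame -> arterial input function."""
    from .phantom import AIFCurve

    mask = np.asarray(blood_mask, bool)
    if mask.shape != series.concentration.shape[1:]:
        raise ValueError("blood_mask shape must match the spatial shape")
    if not mask.any():
        raise ValueError("blood_mask is empty")
    vals = series.concentration[:, mask].mean(axis=1)
    return AIFCurve(times=series.times, values=vals, unit="mmol/L")
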