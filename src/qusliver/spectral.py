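"""Block-wise spectral processing of RF ultrasound frames.

Converts RF frames to envelope/B-mode, computes overlapping-block power
spectra and envelope-SNR maps, forms the log spectral ratio Y(f, z) against
a reference phantom, and selects an analysis ROI by proximity of the
envelope SNR to the fully-developed-speckle (Rayleigh) value.

Conventions
-----------
* Arrays are indexed ``(axial, lateral)``; axial index increases with depth.
* Block coordinates are 0-based, half-open pixel intervals.
* Frequencies are carried in MHz on explicit grids.
* Natural logarithms throughout; dB only at reporting boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, resample
from scipy.signal.windows import tukey

logger = logging.getLogger(__name__)

#: Envelope SNR (mean / population sd) of a Rayleigh-distributed envelope,
#: sqrt(pi / (4 - pi)) ~= 1.913 -- the signature of fully developed speckle.
RAYLEIGH_SNR: float = float(np.sqrt(np.pi / (4.0 - np.pi)))

#: Default analysis band, MHz.
DEFAULT_BAND = (4.0, 18.0)


def wavelength_mm(frequency_hz: float, sound_speed_m_s: float = 1540.0) -> float:
    """Acoustic wavelength lambda = c / f, in millimetres."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return sound_speed_m_s / frequency_hz * 1e3


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockGrid:
    """Geometry of overlapping square analysis blocks on one frame.

    The block side spans ``20 * wavelength`` in physical units and
    consecutive blocks overlap by 80 % (step = 20 % of the side).  Rounding:
    the side is rounded to the nearest pixel, the step is floored, and a
    step below one pixel is clamped to one.
    """

    block_axial_px: int
    block_lateral_px: int
    step_axial_px: int
    step_lateral_px: int
    origins_axial: np.ndarray
    origins_lateral: np.ndarray
    wavelength_mm: float
    axial_spacing_mm: float
    lateral_spacing_mm: float

    @property
    def n_axial(self) -> int:
        return len(self.origins_axial)

    @property
    def n_lateral(self) -> int:
        return len(self.origins_lateral)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_axial, self.n_lateral)

    @property
    def axial_step_mm(self) -> float:
        """Physical axial distance between block origins."""
        return self.step_axial_px * self.axial_spacing_mm

    @property
    def block_centers_axial_mm(self) -> np.ndarray:
        return (self.origins_axial + self.block_axial_px / 2.0) * self.axial_spacing_mm


@dataclass
class SpectrumMap:
    """Per-block averaged periodograms sampled on a frequency grid (MHz)."""

    spectra: np.ndarray          # (n_freq, n_axial_blocks, n_lateral_blocks)
    freq_grid_mhz: np.ndarray
    grid: BlockGrid
    band_mhz: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.freq_grid_mhz = np.asarray(self.freq_grid_mhz, dtype=float)
        if self.spectra.shape[0] != self.freq_grid_mhz.size:
            raise ValueError("spectra first axis must match freq_grid")
        if np.any(self.spectra < 0):
            raise ValueError("power spectra must be non-negative")


@dataclass
class SNRMap:
    """Per-block envelope SNR on a :class:`BlockGrid`; NaN marks blocks where
    the envelope is constant and the SNR is undefined."""

    values: np.ndarray
    grid: BlockGrid


@dataclass
class LogRatioVolume:
    """The log spectral ratio Y(f, z) = ln[S_s / S_r * T_m] per block.

    ``Y`` has shape ``(n_freq, n_axial_blocks, n_lateral_blocks)``.
    """

    Y: np.ndarray
    freq_grid_mhz: np.ndarray
    axial_step_cm: float
    lateral_step_cm: float = 0.0
    tm_applied: bool = False
    sample_id: str = ""
    reference_id: str = ""

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.freq_grid_mhz = np.asarray(self.freq_grid_mhz, dtype=float)
        if self.Y.ndim != 3:
            raise ValueError("Y must be (n_freq, n_axial, n_lateral)")
        if self.Y.shape[0] != self.freq_grid_mhz.size:
            raise ValueError("Y first axis must match freq_grid")
        if self.freq_grid_mhz.size == 0:
            raise ValueError("empty frequency grid")
        if self.axial_step_cm <= 0:
            raise ValueError("axial_step_cm must be positive")

    @property
    def map_shape(self) -> tuple[int, int]:
        return self.Y.shape[1:]


@dataclass(frozen=True)
class ROIWindow:
    """Half-open block-index window [axial0, axial0+n_axial) x [lateral0, ...)."""

    axial0: int
    lateral0: int
    n_axial: int
    n_lateral: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.axial0, self.axial0 + self.n_axial),
                slice(self.lateral0, self.lateral0 + self.n_lateral))


# ---------------------------------------------------------------------------
# RF conditioning
# ---------------------------------------------------------------------------

def iq_to_rf(iq: np.ndarray, sampling_frequency_hz: float,
             carrier_frequency_hz: float, upsample_factor: int = 8) -> np.ndarray:
    """Convert complex baseband (IQ) lines to real RF.

    The IQ signal is interpolated by ``upsample_factor`` (Fourier-method
    ideal interpolation) and remodulated at the carrier:
    ``rf(t) = Re{ iq_up(t) * exp(j 2 pi f_c t) }``.

    Parameters
    ----------
    iq : complex array, axial axis first (1-D or 2-D ``(axial, lateral)``).
    sampling_frequency_hz : IQ (baseband) sampling rate.
    carrier_frequency_hz : demodulation carrier; required to remodulate.
    upsample_factor : output has ``upsample_factor * n`` axial samples.
    """
    if carrier_frequency_hz is None or carrier_frequency_hz <= 0:
        raise ValueError("carrier frequency is required and must be positive")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    iq = np.asarray(iq)
    if not np.iscomplexobj(iq):
        iq = iq.astype(complex)
    n_out = iq.shape[0] * upsample_factor
    up = resample(iq, n_out, axis=0)
    fs_out = sampling_frequency_hz * upsample_factor
    t = np.arange(n_out) / fs_out
    phase = np.exp(2j * np.pi * carrier_frequency_hz * t)
    if iq.ndim > 1:
        phase = phase.reshape((-1,) + (1,) * (iq.ndim - 1))
    return np.real(up * phase)


def compute_envelope(rf: np.ndarray) -> np.ndarray:
    """Envelope (analytic-signal magnitude) of real RF, per lateral line."""
    rf = np.asarray(rf, dtype=float)
    return np.abs(hilbert(rf, axis=0))


# ---------------------------------------------------------------------------
# Block geometry
# ---------------------------------------------------------------------------

def block_grid(frame_shape: tuple[int, int], wavelength_mm: float,
               axial_spacing_mm: float, lateral_spacing_mm: float,
               n_wavelengths: float = 20.0,
               overlap: float = 0.8) -> BlockGrid:
    """Lay out square ``n_wavelengths * lambda`` blocks with fractional overlap.

    Block side (pixels) = round(n_wavelengths * lambda / spacing); step =
    max(1, floor((1 - overlap) * side)).  All blocks lie fully inside the
    frame.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    if axial_spacing_mm <= 0 or lateral_spacing_mm <= 0 or wavelength_mm <= 0:
        raise ValueError("spacings and wavelength must be positive")
    side_mm = n_wavelengths * wavelength_mm
    b_ax = int(round(side_mm / axial_spacing_mm))
    b_lat = int(round(side_mm / lateral_spacing_mm))
    if b_ax < 1 or b_lat < 1:
        raise ValueError("block smaller than one pixel")
    if b_ax > frame_shape[0] or b_lat > frame_shape[1]:
        raise ValueError(
            f"frame {frame_shape} smaller than one {b_ax}x{b_lat} block")
    s_ax = max(1, int(np.floor((1.0 - overlap) * b_ax + 1e-9)))
    s_lat = max(1, int(np.floor((1.0 - overlap) * b_lat + 1e-9)))
    origins_ax = np.arange(0, frame_shape[0] - b_ax + 1, s_ax)
    origins_lat = np.arange(0, frame_shape[1] - b_lat + 1, s_lat)
    return BlockGrid(
        block_axial_px=b_ax, block_lateral_px=b_lat,
        step_axial_px=s_ax, step_lateral_px=s_lat,
        origins_axial=origins_ax, origins_lateral=origins_lat,
        wavelength_mm=wavelength_mm,
        axial_spacing_mm=axial_spacing_mm,
        lateral_spacing_mm=lateral_spacing_mm,
    )


# ---------------------------------------------------------------------------
# Spectra and SNR
# ---------------------------------------------------------------------------

def compute_power_spectrum_map(frame: np.ndarray, grid: BlockGrid,
                               freq_grid_mhz: np.ndarray,
                               sampling_frequency_hz: float,
                               tukey_ratio: float = 0.25,
                               nfft: int | None = None) -> SpectrumMap:
    """Average Tukey-windowed periodograms of each block's lateral lines.

    Within a block, every lateral line contributes one zero-padded
    periodogram of its axial segment (Welch-style averaging across lines,
    no axial sub-segmentation); the average is then interpolated onto
    ``freq_grid_mhz``.
    """
    frame = np.asarray(frame, dtype=float)
    freq_grid_mhz = np.asarray(freq_grid_mhz, dtype=float)
    nyq_mhz = sampling_frequency_hz / 2e6
    if freq_grid_mhz.size == 0:
        raise ValueError("empty frequency grid")
    if freq_grid_mhz.max() > nyq_mhz or freq_grid_mhz.min() < 0:
        raise ValueError("freq_grid outside [0, Nyquist]")
    b = grid.block_axial_px
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(4 * b)))
    win = tukey(b, tukey_ratio)
    norm = np.sum(win ** 2)
    f_native_mhz = np.fft.rfftfreq(nfft, d=1.0 / sampling_frequency_hz) / 1e6
    out = np.empty((freq_grid_mhz.size, grid.n_axial, grid.n_lateral))
    for ia, a0 in enumerate(grid.origins_axial):
        seg_all = frame[a0:a0 + b, :] * win[:, None]
        P_all = np.abs(np.fft.rfft(seg_all, n=nfft, axis=0)) ** 2 / norm
        for il, l0 in enumerate(grid.origins_lateral):
            P = P_all[:, l0:l0 + grid.block_lateral_px].mean(axis=1)
            out[:, ia, il] = np.interp(freq_grid_mhz, f_native_mhz, P)
    return SpectrumMap(spectra=out, freq_grid_mhz=freq_grid_mhz, grid=grid)


def envelope_snr(envelope: np.ndarray) -> float:
    """Envelope SNR = <E> / sqrt(<(E - <E>)^2>) (population normalisation).

    Returns NaN for a constant envelope (SNR undefined).
    """
    env = np.asarray(envelope, dtype=float).ravel()
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative")
    sd = env.std()  # population (ddof=0)
    if sd == 0:
        return float("nan")
    return float(env.mean() / sd)


def compute_snr_map(envelope: np.ndarray, grid: BlockGrid) -> SNRMap:
    """Per-block envelope SNR map; constant blocks get NaN, not an error."""
    envelope = np.asarray(envelope, dtype=float)
    out = np.empty(grid.shape)
    for ia, a0 in enumerate(grid.origins_axial):
        for il, l0 in enumerate(grid.origins_lateral):
            blk = envelope[a0:a0 + grid.block_axial_px,
                           l0:l0 + grid.block_lateral_px]
            out[ia, il] = envelope_snr(blk)
    return SNRMap(values=out, grid=grid)


def compute_log_spectral_ratio(sample: SpectrumMap, reference: SpectrumMap,
                               t_m: np.ndarray | float = 1.0) -> LogRatioVolume:
    """Y = ln(S_s / S_r) + ln(T_m), per frequency and block.

    ``t_m`` is the reference phantom's membrane transmission compensation,
    scalar or per-frequency; it must be positive on the band.
    """
    if sample.spectra.shape != reference.spectra.shape:
        raise ValueError("sample and reference maps must share one geometry")
    if not np.array_equal(sample.freq_grid_mhz, reference.freq_grid_mhz):
        raise ValueError("sample and reference must share one frequency grid")
    if np.any(reference.spectra <= 0):
        raise ValueError("reference power must be strictly positive on band")
    t_m = np.asarray(t_m, dtype=float)
    if np.any(t_m <= 0):
        raise ValueError("T_m must be positive on the analysis band")
    if t_m.ndim == 1:
        t_m = t_m[:, None, None]
    Y = np.log(sample.spectra / reference.spectra) + np.log(t_m)
    g = sample.grid
    return LogRatioVolume(
        Y=Y, freq_grid_mhz=sample.freq_grid_mhz,
        axial_step_cm=g.step_axial_px * g.axial_spacing_mm / 10.0,
        lateral_step_cm=g.step_lateral_px * g.lateral_spacing_mm / 10.0,
        tm_applied=bool(np.any(t_m != 1.0)),
    )


def usable_bandwidth(spectrum: SpectrumMap, noise_floor_db: float = -20.0,
                     band_mhz: tuple[float, float] = DEFAULT_BAND,
                     roi: ROIWindow | None = None) -> tuple[float, float]:
    """Largest contiguous band where the ROI-mean spectrum exceeds
    (peak + ``noise_floor_db``), clipped to ``band_mhz``.

    Raises ``ValueError`` when no in-band frequency clears the floor.
    """
    spec = spectrum.spectra
    if roi is not None:
        sa, sl = roi.slices()
        spec = spec[:, sa, sl]
    mean_spec = spec.mean(axis=(1, 2))
    peak = mean_spec.max()
    if peak <= 0:
        raise ValueError("spectrum is identically zero")
    above = mean_spec > peak * 10.0 ** (noise_floor_db / 10.0)
    in_band = ((spectrum.freq_grid_mhz >= band_mhz[0])
               & (spectrum.freq_grid_mhz <= band_mhz[1]))
    ok = above & in_band
    if not ok.any():
        raise ValueError("no usable band above the noise floor")
    # largest contiguous run of True
    idx = np.flatnonzero(ok)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    best = max(splits, key=len)
    f = spectrum.freq_grid_mhz
    return (float(f[best[0]]), float(f[best[-1]]))


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------

def select_roi(snr: SNRMap, fixed_region: ROIWindow | None = None,
               subroi_shape: tuple[int, int] | None = None,
               target_snr: float = RAYLEIGH_SNR) -> ROIWindow:
    """Pick the sub-window whose mean SNR is nearest the Rayleigh value.

    All candidate windows of ``subroi_shape`` inside ``fixed_region``
    (default: the whole map; default sub-window: half the region per axis)
    are scanned exhaustively; NaN blocks (undefined SNR) are excluded from
    the window means.  Ties break toward the smallest (axial, lateral)
    origin.  If every window mean falls below the target a warning is
    logged and the argmin is still returned.
    """
    vals = snr.values
    if fixed_region is None:
        fixed_region = ROIWindow(0, 0, vals.shape[0], vals.shape[1])
    fa, fl = fixed_region.slices()
    region = vals[fa, fl]
    if subroi_shape is None:
        subroi_shape = (max(1, fixed_region.n_axial // 2),
                        max(1, fixed_region.n_lateral // 2))
    wa, wl = subroi_shape
    if wa > fixed_region.n_axial or wl > fixed_region.n_lateral:
        raise ValueError("sub-ROI larger than the fixed region")
    na = fixed_region.n_axial - wa + 1
    nl = fixed_region.n_lateral - wl + 1
    # sliding-window nanmean via cumulative sums of values and counts
    filled = np.nan_to_num(region, nan=0.0)
    counts = (~np.isnan(region)).astype(float)
    def winsum(arr: np.ndarray) -> np.ndarray:
        c = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
        c[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
        return (c[wa:wa + na, wl:wl + nl] - c[0:na, wl:wl + nl]
                - c[wa:wa + na, 0:nl] + c[0:na, 0:nl])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = winsum(filled) / winsum(counts)
    dist = np.abs(means - target_snr)
    dist[np.isnan(dist)] = np.inf
    if not np.isfinite(dist).any():
        raise ValueError("no window with defined SNR")
    # ties (within numerical noise) break toward the smallest (axial,
    # lateral) origin: first flat index among near-minimal windows
    best = dist.min()
    flat = int(np.flatnonzero(dist <= best + 1e-9 * max(best, 1.0))[0])
    ia, il = np.unravel_index(flat, dist.shape)
    if np.nanmax(means) < target_snr:
        logger.warning(
            "all candidate windows have mean SNR below the Rayleigh value "
            "(best %.3f); returning the nearest window anyway",
            float(means[ia, il]))
    return ROIWindow(fixed_region.axial0 + int(ia),
                     fixed_region.lateral0 + int(il), wa, wl)


def fixed_region_from_mm(grid: BlockGrid, axial_mm: float = 8.0,
                         lateral_mm: float = 22.0,
                         axial0: int = 0, lateral0: int = 0) -> ROIWindow:
    """Fixed analysis region expressed in block indices from physical extents."""
    na = max(1, int(round(axial_mm / (grid.step_axial_px * grid.axial_spacing_mm))))
    nl = max(1, int(round(lateral_mm / (grid.step_lateral_px * grid.lateral_spacing_mm))))
    na = min(na, grid.n_axial - axial0)
    nl = min(nl, grid.n_lateral - lateral0)
    return ROIWindow(axial0, lateral0, na, nl)
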