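"""Synthetic data with known ground truth for every pipeline stage.

Emulates (i) block-wise log spectral ratios following the adapted power-law
model Y(f,z) = ln(db) + dn*ln(f) - 4*f*da(z), (ii) fully developed speckle
RF volumes with prescribed backscatter/attenuation patterns, (iii) H&E-like
histology images with bright circular fat vacuoles plus elongated
distractors, and (iv) whole study cohorts whose per-grade feature
distributions emulate a preclinical rodent steatosis cohort (per-grade
medians, spreads and group sizes).

All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .spectral import LogRatioVolume

# Physically sensible parameter ranges for ground-truth maps.
DELTA_B_RANGE = (0.1, 1e5)
DELTA_N_RANGE = (-8.0, 8.0)
DELTA_ALPHA_RANGE = (0.0, 2.0)   # Np / cm / MHz

SOUND_SPEED_M_S = 1540.0

COHORT_COLUMNS = ["subject_id", "grade_true", "fat_fraction_true",
                  "delta_b_db", "delta_n", "delta_alpha", "snr",
                  "delta_bsc_11mhz"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TissueGroundTruth:
    """True relative-coefficient maps on an (axial, lateral) grid.

    delta_b : linear backscatter-amplitude ratio (> 0, dimensionless)
    delta_n : backscatter frequency-dependence difference (dimensionless)
    delta_alpha : attenuation-slope difference (Np cm^-1 MHz^-1)
    """

    delta_b: np.ndarray
    delta_n: np.ndarray
    delta_alpha: np.ndarray
    axial_spacing_mm: float
    lateral_spacing_mm: float

    def __post_init__(self) -> None:
        self.delta_b = np.asarray(self.delta_b, dtype=float)
        self.delta_n = np.asarray(self.delta_n, dtype=float)
        self.delta_alpha = np.asarray(self.delta_alpha, dtype=float)
        if not (self.delta_b.shape == self.delta_n.shape == self.delta_alpha.shape):
            raise ValueError("all ground-truth maps must share one grid shape")
        if np.any(self.delta_b <= 0):
            raise ValueError("delta_b must be strictly positive everywhere")
        if self.axial_spacing_mm <= 0 or self.lateral_spacing_mm <= 0:
            raise ValueError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta_b.shape

    def cumulative_attenuation(self) -> np.ndarray:
        """Cumulative attenuation da(z) in Np/MHz at each block centre.

        Midpoint-rule integral of delta_alpha from depth 0 (the
        transducer-proximal edge of the analysis region): row i integrates
        full steps over rows 0..i-1 plus half a step of row i.
        """
        dz_cm = self.axial_spacing_mm / 10.0
        full = np.cumsum(self.delta_alpha, axis=0) * dz_cm
        return full - self.delta_alpha * dz_cm / 2.0


@dataclass
class PhantomReference:
    """Acoustic parameters of the calibrated reference phantom.

    ``t_m`` is the transmission compensation of the phantom's protective
    membrane, a positive per-frequency curve (default: no compensation).
    The absolute values b_r, n_r, alpha_r are declared synthetic defaults;
    the pipeline only ever uses sample-minus-reference quantities.
    """

    b_r: float = 1.0
    n_r: float = 1.0
    alpha_r: float = 0.1           # Np / cm / MHz
    t_m: np.ndarray | float = 1.0
    sound_speed_m_s: float = SOUND_SPEED_M_S

    def __post_init__(self) -> None:
        if self.b_r <= 0 or self.alpha_r < 0 or self.sound_speed_m_s <= 0:
            raise ValueError("phantom parameters out of range")
        if np.any(np.asarray(self.t_m) <= 0):
            raise ValueError("t_m must be positive on the analysis band")


@dataclass
class RFVolume:
    """A stack of RF frames: samples indexed (frame, axial, lateral)."""

    samples: np.ndarray
    sampling_frequency_hz: float
    center_frequency_hz: float
    axial_spacing_mm: float
    lateral_spacing_mm: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must be (frame, axial, lateral)")
        if self.samples.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.axial_spacing_mm <= 0 or self.lateral_spacing_mm <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


@dataclass
class HistologySpec:
    """Recipe for a synthetic H&E-like image with known vacuole mask."""

    image_shape: tuple[int, int] = (512, 512)
    target_fat_fraction_pct: float = 20.0
    vacuole_radius_px: tuple[int, int] = (5, 15)
    n_distractors: int = 0
    background_gray_level: int = 130
    vacuole_gray_level: int = 235
    binarization_threshold: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fat_fraction_pct < 90.0):
            raise ValueError("target fat fraction must be in [0, 90) %")
        if not (self.vacuole_gray_level > self.binarization_threshold
                > self.background_gray_level):
            raise ValueError(
                "need vacuole level > threshold > background level")
        if self.vacuole_radius_px[0] < 1 or \
                self.vacuole_radius_px[1] < self.vacuole_radius_px[0]:
            raise ValueError("invalid vacuole radius range")


@dataclass
class CohortSpec:
    """Per-grade generative parameters for a synthetic study cohort.

    ``feature_medians``/``feature_iqrs`` map feature name to per-grade
    values; ``fat_fraction_mean_sd`` gives (mean, sd) per grade, truncated
    to the grade's Brunt interval.  ``noise_scale`` multiplies every random
    spread at once: at zero, each subject sits exactly at its grade's
    medians.
    """

    group_sizes: tuple[int, ...] = (24, 15, 16)
    feature_medians: dict = field(default_factory=lambda: {
        "delta_b_db":      (26.72, 27.41, 37.55),
        "delta_n":         (-6.17, -6.17, -6.17),   # grade-independent
        "delta_alpha":     (0.12, 0.26, 0.65),
        "snr":             (1.42, 1.63, 1.70),
        "delta_bsc_11mhz": (2.35e-4, 1.60e-4, 41.95e-4),
    })
    feature_iqrs: dict = field(default_factory=lambda: {
        "delta_b_db":      (6.05, 9.76, 8.18),
        "delta_n":         (0.79, 0.73, 1.02),
        "delta_alpha":     (0.20, 0.14, 0.37),
        "snr":             (0.09, 0.12, 0.08),
        "delta_bsc_11mhz": (5.42e-4, 7.83e-4, 48.62e-4),
    })
    fat_fraction_mean_sd: tuple = ((1.28, 1.26), (20.36, 7.36), (45.23, 9.74))
    fat_fraction_bounds: tuple = ((0.0, 5.0), (5.0, 33.0), (33.0, 66.0))
    noise_scale: float = 1.0
    #: fraction of each printed IQR attributed to fat-independent noise; the
    #: remainder comes from the within-grade fat-fraction variation itself.
    noise_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for g, ((lo, hi), (mean, _sd)) in enumerate(
                zip(self.fat_fraction_bounds, self.fat_fraction_mean_sd)):
            if not (lo <= mean <= hi):
                raise ValueError(
                    f"grade {g}: fat-fraction mean {mean} outside its Brunt "
                    f"interval [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _expand_level(level, shape: tuple[int, int], layout: str) -> np.ndarray:
    """Turn a scalar or (low, high) pair into a map with the given layout."""
    if np.isscalar(level):
        return np.full(shape, float(level))
    lo, hi = float(level[0]), float(level[1])
    if layout == "piecewise":
        out = np.full(shape, lo)
        out[shape[0] // 2:, :] = hi      # axial top/bottom split
        return out
    if layout == "smooth-gradient":
        ramp = np.linspace(lo, hi, shape[0])
        return np.tile(ramp[:, None], (1, shape[1]))
    return np.full(shape, lo)


def make_ground_truth(shape: tuple[int, int], layout: str = "constant",
                      delta_b=1.0, delta_n=0.0, delta_alpha=0.0,
                      axial_spacing_mm: float = 0.56,
                      lateral_spacing_mm: float = 0.56,
                      seed: int | None = None) -> TissueGroundTruth:
    """Build ground-truth maps with a prescribed spatial layout.

    ``layout`` is one of ``constant`` (scalars), ``piecewise`` (axial
    top/bottom split of a 2-level pair, TV-friendly) or ``smooth-gradient``
    (axial linear ramp between a pair).  Levels outside the physically
    sensible ranges are rejected.  ``seed`` is accepted for interface
    symmetry; the layouts here are deterministic.
    """
    if layout not in ("constant", "piecewise", "smooth-gradient"):
        raise ValueError(f"unknown layout {layout!r}")
    maps = {}
    for name, level, (lo, hi) in (
            ("delta_b", delta_b, DELTA_B_RANGE),
            ("delta_n", delta_n, DELTA_N_RANGE),
            ("delta_alpha", delta_alpha, DELTA_ALPHA_RANGE)):
        arr = np.atleast_1d(np.asarray(level, dtype=float))
        if np.any(arr < lo) or np.any(arr > hi):
            raise ValueError(f"{name} level outside [{lo}, {hi}]")
        maps[name] = _expand_level(level, shape, layout)
    return TissueGroundTruth(
        delta_b=maps["delta_b"], delta_n=maps["delta_n"],
        delta_alpha=maps["delta_alpha"],
        axial_spacing_mm=axial_spacing_mm,
        lateral_spacing_mm=lateral_spacing_mm,
    )


# ---------------------------------------------------------------------------
# Forward spectral model
# ---------------------------------------------------------------------------

def simulate_spectra(truth: TissueGroundTruth,
                     phantom: PhantomReference | None = None,
                     freq_grid_mhz: np.ndarray | None = None,
                     noise_sd: float = 0.0,
                     seed: int | None = None) -> LogRatioVolume:
    """Exact forward evaluation of the adapted power-law model plus noise.

    Y(f, z) = ln(db(z)) + dn(z) * ln(f) - 4 * f * da(z), with da the
    midpoint-rule cumulative integral of delta_alpha from depth 0, plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    if phantom is None:
        phantom = PhantomReference()
    if freq_grid_mhz is None:
        freq_grid_mhz = np.linspace(4.0, 18.0, 30)
    f = np.asarray(freq_grid_mhz, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    da = truth.cumulative_attenuation()                      # (nz, nx) Np/MHz
    fcol = f[:, None, None]
    Y = (np.log(truth.delta_b)[None] + truth.delta_n[None] * np.log(fcol)
         - 4.0 * fcol * da[None])
    t_m = np.asarray(phantom.t_m, dtype=float)
    if t_m.ndim == 1:
        Y = Y + np.log(t_m)[:, None, None]
    elif np.any(t_m != 1.0):
        Y = Y + np.log(t_m)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Y = Y + rng.normal(scale=noise_sd, size=Y.shape)
    return LogRatioVolume(
        Y=Y, freq_grid_mhz=f,
        axial_step_cm=truth.axial_spacing_mm / 10.0,
        lateral_step_cm=truth.lateral_spacing_mm / 10.0,
        tm_applied=bool(np.any(t_m != 1.0)),
        sample_id="synthetic", reference_id="synthetic-phantom",
    )


# ---------------------------------------------------------------------------
# Speckle RF
# ---------------------------------------------------------------------------

@dataclass
class Acquisition:
    """Acquisition settings for the speckle simulator."""

    sampling_frequency_hz: float = 120e6
    center_frequency_hz: float = 15e6
    pulse_bandwidth_frac: float = 0.75   # fractional -6 dB-ish Gaussian band
    lateral_spacing_mm: float = 0.1
    sound_speed_m_s: float = SOUND_SPEED_M_S

    @property
    def axial_spacing_mm(self) -> float:
        # pulse-echo depth per sample: c / (2 fs)
        return self.sound_speed_m_s * 1e3 / (2.0 * self.sampling_frequency_hz)


def simulate_rf(truth: TissueGroundTruth,
                acquisition: Acquisition | None = None,
                n_frames: int = 1,
                frame_shape: tuple[int, int] | None = None,
                scatterer_std: float = 1.0,
                seed: int | None = None) -> RFVolume:
    """Convolution speckle model with prescribed coefficient patterns.

    A white Gaussian scatterer field scaled by sqrt(delta_b) is filtered,
    in overlapping axial segments, by a Gaussian-modulated pulse spectrum
    multiplied by the depth-cumulative attenuation e^(-2 a(z) f) and the
    backscatter frequency weighting f^(delta_n / 2) (amplitude filters, so
    the block power spectra follow the power-law model).  The envelope of a
    homogeneous region is Rayleigh to within sampling error.
    """
    if acquisition is None:
        acquisition = Acquisition()
    acq = acquisition
    f0 = acq.center_frequency_hz
    fs = acq.sampling_frequency_hz
    if f0 * (1 + acq.pulse_bandwidth_frac) > fs / 2:
        raise ValueError("pulse band exceeds the sampling constraint")
    if n_frames < 1:
        raise ValueError("need n_frames >= 1")

    if frame_shape is None:
        n_ax = int(round(truth.shape[0] * truth.axial_spacing_mm
                         / acq.axial_spacing_mm))
        n_lat = int(round(truth.shape[1] * truth.lateral_spacing_mm
                          / acq.lateral_spacing_mm))
        frame_shape = (n_ax, n_lat)
    n_ax, n_lat = frame_shape

    seg = 256
    hop = seg // 2
    margin = seg                       # lead-in/out rows cropped after filtering
    nfft = 2 * seg                     # zero-padding: linear, not circular, conv
    n_tot = n_ax + 2 * margin

    # nearest-neighbour lookup of the coarse truth maps on the (extended)
    # RF pixel grid; rows in the margins replicate the edges, and depth 0
    # sits at the first real row so cumulative attenuation is 0 above it
    depth_px = np.clip(np.arange(n_tot) - margin, 0, n_ax - 1)
    iz = np.minimum((depth_px * acq.axial_spacing_mm
                     / truth.axial_spacing_mm).astype(int), truth.shape[0] - 1)
    ix = np.minimum((np.arange(n_lat) * acq.lateral_spacing_mm
                     / truth.lateral_spacing_mm).astype(int), truth.shape[1] - 1)
    amp = np.sqrt(truth.delta_b)[np.ix_(iz, ix)]
    dn = truth.delta_n[np.ix_(iz, ix)]
    # cumulative attenuation at RF axial resolution (Np/MHz)
    dz_cm = acq.axial_spacing_mm / 10.0
    alpha_px = np.where((np.arange(n_tot) >= margin)[:, None],
                        truth.delta_alpha[np.ix_(iz, ix)], 0.0)
    cum_att = np.cumsum(alpha_px, axis=0) * dz_cm - alpha_px * dz_cm / 2.0

    # periodic Hann analysis window: sums to 1 at 50 % overlap, so with a
    # depth-independent filter the overlap-add is exactly the LTI convolution
    win = np.hanning(seg + 1)[:-1]
    f_mhz = np.fft.rfftfreq(nfft, d=1.0 / fs) / 1e6
    sigma_mhz = acq.pulse_bandwidth_frac * (f0 / 1e6) / 2.355
    pulse = np.exp(-0.5 * ((f_mhz - f0 / 1e6) / sigma_mhz) ** 2)
    f_safe = np.maximum(f_mhz, 0.5)    # guard f^(dn/2) near DC

    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, n_ax, n_lat))
    for k in range(n_frames):
        field = rng.normal(scale=scatterer_std, size=(n_tot, n_lat)) * amp
        out = np.zeros((n_tot + nfft, n_lat))
        for start in range(0, n_tot - seg + 1, hop):
            centre = start + seg // 2
            H = (pulse[:, None]
                 * f_safe[:, None] ** (dn[centre][None, :] / 2.0)
                 * np.exp(-2.0 * cum_att[centre][None, :] * f_mhz[:, None]))
            chunk = field[start:start + seg] * win[:, None]
            spec = np.fft.rfft(chunk, n=nfft, axis=0) * H
            out[start:start + nfft] += np.fft.irfft(spec, n=nfft, axis=0)
        frames[k] = out[margin:margin + n_ax]
    return RFVolume(
        samples=frames, sampling_frequency_hz=fs, center_frequency_hz=f0,
        axial_spacing_mm=acq.axial_spacing_mm,
        lateral_spacing_mm=acq.lateral_spacing_mm,
    )


# ---------------------------------------------------------------------------
# Histology
# ---------------------------------------------------------------------------

def _tint_pink(gray: np.ndarray) -> np.ndarray:
    """Map a grayscale field to an eosin-pink RGB image whose luminance
    (0.2125 R + 0.7154 G + 0.0721 B) matches the grayscale values."""
    g = gray.astype(float)
    rgb = np.stack([np.clip(g + 40, 0, 255),
                    np.clip(g - 14, 0, 255),
                    np.clip(g + 20, 0, 255)], axis=-1)
    return rgb.astype(np.uint8)


def make_histology_image(spec: HistologySpec) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize an H&E-like RGB image and its true fat-vacuole mask.

    Non-overlapping bright discs are placed until the disc-area fraction
    reaches the target within +-0.5 percentage points; the sampling radius
    shrinks when placements keep failing, and the final disc's radius is
    capped so the target is not overshot.  Elongated bright distractors
    (aspect ratio >= 3, vessel-like) are drawn but excluded from the true
    mask.  Raises ``RuntimeError`` when the requested fraction cannot be
    placed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    total_px = h * w
    target_px = spec.target_fat_fraction_pct / 100.0 * total_px

    gray = np.clip(rng.normal(spec.background_gray_level, 8.0, (h, w)),
                   0, spec.binarization_threshold - 8)
    mask = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)   # vacuoles + distractors + margin
    yy, xx = np.mgrid[0:h, 0:w]

    def paint_disc(cy, cx, r, into_mask: bool) -> None:
        s = (slice(max(0, cy - r - 1), cy + r + 2),
             slice(max(0, cx - r - 1), cx + r + 2))
        d2 = (yy[s] - cy) ** 2 + (xx[s] - cx) ** 2
        disc = d2 <= r * r
        vals = np.clip(rng.normal(spec.vacuole_gray_level, 3.0, int(disc.sum())),
                       spec.binarization_threshold + 8, 255)
        gray[s][disc] = vals
        if into_mask:
            mask[s][disc] = True
        occupied[s][d2 <= (r + 1) ** 2] = True

    def free_at(cy, cx, r, gap) -> bool:
        # boundary gap >= `gap` px; at 3 px the morphological opening
        # downstream cannot bridge neighbouring discs into one component
        if cy - r < 1 or cy + r >= h - 1 or cx - r < 1 or cx + r >= w - 1:
            return False
        m = r + gap - 1
        s = (slice(max(0, cy - m), cy + m + 1),
             slice(max(0, cx - m), cx + m + 1))
        d2 = (yy[s] - cy) ** 2 + (xx[s] - cx) ** 2
        return not occupied[s][d2 <= m * m].any()

    # elongated distractors first so vacuole placement avoids them;
    # radii below 7 px barely survive the downstream radius-5 opening
    min_r = max(spec.vacuole_radius_px[0], 7)
    for _ in range(spec.n_distractors):
        placed = False
        for _attempt in range(400):
            length = int(rng.integers(30, 60))
            width = max(4, length // max(4, int(rng.integers(4, 7))))
            theta = rng.uniform(0, np.pi)
            cy = int(rng.integers(length, h - length))
            cx = int(rng.integers(length, w - length))
            ca, sa = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ca + (yy - cy) * sa
            v = -(xx - cx) * sa + (yy - cy) * ca
            ell = (u / length) ** 2 + (v / width) ** 2 <= 1.0
            grow = (u / (length + 2)) ** 2 + (v / (width + 2)) ** 2 <= 1.0
            if occupied[grow].any():
                continue
            gray[ell] = np.clip(
                rng.normal(spec.vacuole_gray_level, 3.0, int(ell.sum())),
                spec.binarization_threshold + 8, 255)
            occupied[grow] = True
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a distractor")

    from scipy.ndimage import distance_transform_edt

    lo_r, hi_r = min_r, spec.vacuole_radius_px[1]
    cur_hi = hi_r
    gap = 3
    failures = 0
    while True:
        min_area = np.pi * lo_r ** 2
        remaining = target_px - mask.sum()
        if remaining < min_area / 2.0:
            break
        r = int(rng.integers(lo_r, cur_hi + 1))
        r_cap = int(np.sqrt(max(remaining, min_area) / np.pi))
        r = max(lo_r, min(r, r_cap))
        cy = int(rng.integers(r + 1, h - r - 1))
        cx = int(rng.integers(r + 1, w - r - 1))
        if free_at(cy, cx, r, gap):
            paint_disc(cy, cx, r, into_mask=True)
            failures = 0
            continue
        failures += 1
        if failures <= 60:
            continue
        # blind sampling is jamming: locate genuinely free sites from the
        # Euclidean distance map of the unoccupied space
        failures = 0
        edt = distance_transform_edt(~occupied)
        edt[:lo_r + 1, :] = 0
        edt[-lo_r - 1:, :] = 0
        edt[:, :lo_r + 1] = 0
        edt[:, -lo_r - 1:] = 0
        feasible_r = min(int(edt.max()) - gap, cur_hi, r_cap)
        if feasible_r < lo_r:
            if gap > 1:          # relax the separation before giving up
                gap -= 1
                continue
            if lo_r > 3:         # last resort: tiny gap-filling discs
                lo_r -= 1
                continue
            raise RuntimeError(
                f"target fat fraction {spec.target_fat_fraction_pct}% "
                "infeasible: no free space left for discs")
        cand = np.argwhere(edt > feasible_r + gap - 1)
        cy, cx = cand[rng.integers(len(cand))]
        r = min(feasible_r, min(int(cy), int(cx), h - 1 - int(cy),
                                w - 1 - int(cx)) - 1)
        if free_at(int(cy), int(cx), r, gap):
            paint_disc(int(cy), int(cx), r, into_mask=True)
        cur_hi = max(lo_r, min(cur_hi, feasible_r + 2))
    return _tint_pink(gray), mask


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _interp_extrap(x: np.ndarray, xp: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation that extends the end segments instead
    of clamping, so the monotone feature-fat relationship continues beyond
    the outer grade means (acoustic parameters keep rising with fat content
    at higher steatosis grades)."""
    out = np.interp(x, xp, yp)
    lo = x < xp[0]
    if lo.any():
        s = (yp[1] - yp[0]) / (xp[1] - xp[0])
        out[lo] = yp[0] + s * (x[lo] - xp[0])
    hi = x > xp[-1]
    if hi.any():
        s = (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
        out[hi] = yp[-1] + s * (x[hi] - xp[-1])
    return out


def make_cohort(spec: CohortSpec | None = None, seed: int | None = None):
    """Generate a per-subject feature table with known fat fractions.

    Each subject's fat fraction is drawn from its grade's truncated normal;
    feature locations follow a piecewise-linear interpolation of the grade
    medians against the grade-mean fat fractions (so grade-conditional
    medians match the configured medians while features co-vary with fat
    content, as the underlying acoustics dictates), plus Gaussian noise
    scaled from the configured IQRs.  Bitwise reproducible under the seed.
    """
    import pandas as pd

    if spec is None:
        spec = CohortSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    ff_means = np.array([m for m, _ in spec.fat_fraction_mean_sd])

    rows = []
    sid = 0
    for g, n in enumerate(spec.group_sizes):
        if n == 0:
            continue
        mean, sd = spec.fat_fraction_mean_sd[g]
        lo, hi = spec.fat_fraction_bounds[g]
        sd_eff = sd * spec.noise_scale
        if sd_eff == 0:
            ff = np.full(n, mean)
        else:
            a, b = (lo - mean) / sd_eff, (hi - mean) / sd_eff
            ff = truncnorm.rvs(a, b, loc=mean, scale=sd_eff, size=n,
                               random_state=rng)
        feats = {}
        for name, medians in spec.feature_medians.items():
            centers = _interp_extrap(ff, ff_means, np.asarray(medians))
            noise_sd = (spec.noise_fraction * spec.feature_iqrs[name][g]
                        / 1.349) * spec.noise_scale
            feats[name] = centers + rng.normal(scale=noise_sd, size=n)
        for i in range(n):
            rows.append({
                "subject_id": f"S{sid:03d}",
                "grade_true": g,
                "fat_fraction_true": ff[i],
                **{name: feats[name][i] for name in spec.feature_medians},
            })
            sid += 1
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
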