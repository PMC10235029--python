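"""HDF5 / PNG / CSV serialization of the pipeline's intermediates."""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .rpltv import CoefficientMaps
from .spectral import LogRatioVolume
from .synth import RFVolume


def save_rf(path, rf: RFVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf.samples)
        f.attrs["sampling_frequency_hz"] = rf.sampling_frequency_hz
        f.attrs["center_frequency_hz"] = rf.center_frequency_hz
        f.attrs["axial_spacing_mm"] = rf.axial_spacing_mm
        f.attrs["lateral_spacing_mm"] = rf.lateral_spacing_mm


def load_rf(path) -> RFVolume:
    with h5py.File(path, "r") as f:
        return RFVolume(
            samples=f["rf"][()],
            sampling_frequency_hz=float(f.attrs["sampling_frequency_hz"]),
            center_frequency_hz=float(f.attrs["center_frequency_hz"]),
            axial_spacing_mm=float(f.attrs["axial_spacing_mm"]),
            lateral_spacing_mm=float(f.attrs["lateral_spacing_mm"]),
        )


def save_log_ratio(path, vol: LogRatioVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=vol.Y)
        f.create_dataset("freq_grid", data=vol.freq_grid_mhz)
        f.attrs["axial_step_cm"] = vol.axial_step_cm
        f.attrs["lateral_step_cm"] = vol.lateral_step_cm
        f.attrs["tm_applied"] = vol.tm_applied
        f.attrs["sample_id"] = vol.sample_id
        f.attrs["reference_id"] = vol.reference_id


def load_log_ratio(path) -> LogRatioVolume:
    with h5py.File(path, "r") as f:
        return LogRatioVolume(
            Y=f["Y"][()], freq_grid_mhz=f["freq_grid"][()],
            axial_step_cm=float(f.attrs["axial_step_cm"]),
            lateral_step_cm=float(f.attrs["lateral_step_cm"]),
            tm_applied=bool(f.attrs["tm_applied"]),
            sample_id=str(f.attrs["sample_id"]),
            reference_id=str(f.attrs["reference_id"]),
        )


def save_maps(path, maps: CoefficientMaps, snr: np.ndarray | None = None,
              delta_bsc: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("delta_b", data=maps.delta_b)
        f.create_dataset("delta_n", data=maps.delta_n)
        f.create_dataset("delta_a", data=maps.delta_a)
        f.create_dataset("delta_alpha", data=maps.delta_alpha)
        if snr is not None:
            f.create_dataset("snr", data=snr)
        if delta_bsc is not None:
            f.create_dataset("delta_bsc", data=delta_bsc)
        f.attrs["axial_step_cm"] = maps.axial_step_cm
        f.attrs["converged"] = maps.converged


def load_maps(path) -> CoefficientMaps:
    with h5py.File(path, "r") as f:
        return CoefficientMaps(
            delta_b=f["delta_b"][()], delta_n=f["delta_n"][()],
            delta_a=f["delta_a"][()], delta_alpha=f["delta_alpha"][()],
            axial_step_cm=float(f.attrs["axial_step_cm"]),
            converged=bool(f.attrs["converged"]),
        )


def save_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def load_image(path) -> np.ndarray:
    return iio.imread(Path(path))


def save_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
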