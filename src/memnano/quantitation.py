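"""Surface-density and copy-number quantitation.

Ensemble-fluorescence density estimates divide the background-subtracted
integrated ROI intensity by the single-molecule intensity of the fluorophore
and the ROI area; flow-cytometric copy numbers are obtained from bead
calibration standards (MESF) after correcting for the antibody's degree of
labeling; detergent-resistant-membrane association is expressed as the
percentage of net nuclear-fraction signal over net whole-cell signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("memnano")


@dataclass
class DensityMeasurement:
    integrated_intensity: float  # counts within the ROI
    area_um2: float
    background_per_um2: float = 0.0  # counts per um^2
    single_molecule_intensity: float = 1.0  # counts per molecule

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("ROI area must be > 0")
        if self.single_molecule_intensity <= 0:
            raise ValueError("single-molecule intensity must be > 0")


def density_from_intensity(m: DensityMeasurement) -> float:
    """Molecules per um^2 from ensemble fluorescence:
    (integrated - background*area) / (single-molecule intensity * area).
    Negative net intensities clamp to zero with a warning (background
    overestimation is common at low density)."""
    net = m.integrated_intensity - m.background_per_um2 * m.area_um2
    if net < 0:
        log.warning("net intensity negative (%.3g); density clamped to 0", net)
        return 0.0
    return net / (m.single_molecule_intensity * m.area_um2)


class BeadCalibration:
    """Monotone bead calibration mapping reference intensities to fluorophore
    counts (MESF), fitted by ordinary least squares on log-log pairs."""

    def __init__(self, intensities, mesf_counts):
        i = np.asarray(intensities, float)
        c = np.asarray(mesf_counts, float)
        if len(i) < 2 or len(i) != len(c):
            raise ValueError("need >= 2 matched (intensity, count) pairs")
        if np.any(i <= 0) or np.any(c <= 0):
            raise ValueError("calibration values must be positive")
        order = np.argsort(i)
        self.intensities = i[order]
        self.counts = c[order]
        self.slope, self.intercept = np.polyfit(np.log(self.intensities), np.log(self.counts), 1)
        if self.slope <= 0:
            raise ValueError("calibration map must be monotone increasing")

    def __call__(self, intensity: float) -> float:
        if intensity < self.intensities[0] or intensity > self.intensities[-1]:
            log.warning("MFI %.3g outside calibration range; extrapolating", intensity)
        return float(np.exp(self.intercept + self.slope * np.log(intensity)))


def copies_from_mfi(
    mfi_cells: float,
    mfi_background: float,
    calibration: BeadCalibration,
    degree_of_labeling: float,
) -> float:
    """Copies per cell: calibrated net MFI divided by the antibody's degree
    of fluorophore conjugation."""
    if degree_of_labeling <= 0:
        raise ValueError("degree of labeling must be > 0")
    net = mfi_cells - mfi_background
    if net <= 0:
        raise ValueError("net MFI must be positive")
    return calibration(net) / degree_of_labeling


def drm_fraction(
    mfi_nuclei: float,
    mfi_nuclear_bg: float,
    mfi_cells: float,
    mfi_cell_bg: float,
) -> float:
    """Detergent-resistant membrane association in percent:
    100 * (net nuclear-fraction MFI) / (net whole-cell MFI)."""
    denom = mfi_cells - mfi_cell_bg
    if denom <= 0:
        raise ValueError("net whole-cell MFI must be positive")
    return 100.0 * (mfi_nuclei - mfi_nuclear_bg) / denom
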