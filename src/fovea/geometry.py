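"""Coordinate conventions and axial-length lateral-scale correction.

Commercial OCT devices report scan lengths assuming a schematic eye
(Cirrus HD-OCT: axial length 24.46 mm).  The true lateral extent of a scan
scales linearly with the participant's measured axial length, so every
lateral measurement in this package is corrected by the ratio
``axial_length / device_assumed_axial``.

Conventions used throughout the package:

* image arrays are indexed ``(row, col)`` mapping to ``(y, x)``, 0-based,
  pixel-center; ``y`` increases downward (axial depth on B-scans, vertical
  on en-face maps);
* physical coordinates are micrometres relative to the top-left pixel
  center of the ROI/map.
"""

from __future__ import annotations

from dataclasses import dataclass

DEVICE_ASSUMED_AXIAL_MM: float = 24.46
"""Axial length (mm) of the schematic eye assumed by the Cirrus device."""

AXIAL_LENGTH_WINDOW_MM: tuple[float, float] = (18.0, 32.0)
"""Plausibility window for measured axial length; catches unit errors."""


def correct_lateral_scale(
    nominal_length_mm: float,
    axial_length_mm: float,
    device_assumed_axial_mm: float = DEVICE_ASSUMED_AXIAL_MM,
    axial_length_window_mm: tuple[float, float] = AXIAL_LENGTH_WINDOW_MM,
) -> float:
    """True lateral scan length (mm) for a participant's eye.

    Parameters
    ----------
    nominal_length_mm
        Scan length as reported by the device (e.g. 6 or 9 mm).
    axial_length_mm
        Participant's measured ocular axial length (mm).
    device_assumed_axial_mm
        Axial length assumed by the device (default 24.46 mm, Cirrus).
    axial_length_window_mm
        ``(lo, hi)`` plausibility bounds on ``axial_length_mm``.

    Returns
    -------
    float
        ``nominal_length_mm * axial_length_mm / device_assumed_axial_mm``.
    """
    if nominal_length_mm <= 0:
        raise ValueError(f"nominal_length_mm must be > 0, got {nominal_length_mm}")
    if device_assumed_axial_mm <= 0:
        raise ValueError(
            f"device_assumed_axial_mm must be > 0, got {device_assumed_axial_mm}"
        )
    lo, hi = axial_length_window_mm
    if not (axial_length_mm > 0 and lo <= axial_length_mm <= hi):
        raise ValueError(
            f"axial_length_mm={axial_length_mm} outside plausibility window "
            f"[{lo}, {hi}] mm (check units: mm expected)"
        )
    return nominal_length_mm * axial_length_mm / device_assumed_axial_mm


def um_per_pixel(corrected_length_mm: float, n_pixels: int) -> float:
    """Lateral sampling (µm/pixel) of a scan of known physical length."""
    if corrected_length_mm <= 0:
        raise ValueError(f"corrected_length_mm must be > 0, got {corrected_length_mm}")
    if n_pixels < 2:
        raise ValueError(f"n_pixels must be >= 2, got {n_pixels}")
    return 1000.0 * corrected_length_mm / n_pixels


@dataclass(frozen=True)
class LateralScale:
    """Lateral calibration of one scan: nominal vs. axial-length-corrected."""

    nominal_length_mm: float
    axial_length_mm: float
    device_assumed_axial_mm: float = DEVICE_ASSUMED_AXIAL_MM

    @property
    def corrected_length_mm(self) -> float:
        return correct_lateral_scale(
            self.nominal_length_mm, self.axial_length_mm, self.device_assumed_axial_mm
        )

    def um_per_px(self, n_pixels: int) -> float:
        return um_per_pixel(self.corrected_length_mm, n_pixels)
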