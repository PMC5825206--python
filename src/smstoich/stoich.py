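"""Intensity-calibrated copy numbers and the binomial labeling model.

Copy numbers are estimated by comparing a complex's fluorescence to a
surface-attached dimeric-GFP standard imaged under identical illumination:
``copies = 2 * I_complex / I_ref``. The labeling model treats each subunit
of a monomer/dimer mixture as labeled independently with probability ``p``;
because unlabeled species are invisible, all observable fractions are
conditional on a spot carrying at least one fluorophore. Among visible
spots the two-step (two-fluorophore) fraction is

    f2(d, p) = d * p^2 / (d * p * (2 - p) + (1 - d) * p)
             = d * p / (1 + d * (1 - p)),

with ``d`` the true dimer fraction. ``f2`` increases in both arguments, so
the smallest ``p`` consistent with an observed ``f2`` is attained at
``d = 1``: p_min = 2 * f2 / (1 + f2). This is what turns an observed
two-step fraction into a lower bound on the labeling efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationReference", "LabelingModel", "CopyNumberEstimate",
           "calibrate_reference", "estimate_copy_number",
           "expected_two_step_fraction", "min_labeling_efficiency",
           "classify_super", "surface_density"]


@dataclass(frozen=True)
class CalibrationReference:
    """Intensity distribution of the calibration standard (dimeric GFP:
    two copies per spot). The population mean is the calibration statistic."""

    mean_intensity: float
    sd_intensity: float
    n_reference_spots: int
    copies_in_reference: int = 2

    def __post_init__(self) -> None:
        if not (self.mean_intensity > 0):
            raise ValueError("reference mean intensity must be > 0")
        if self.n_reference_spots < 1:
            raise ValueError("n_reference_spots must be >= 1")
        if self.sd_intensity < 0:
            raise ValueError("sd_intensity must be >= 0")


@dataclass(frozen=True)
class LabelingModel:
    dimer_fraction: float
    labeling_efficiency: float

    def __post_init__(self) -> None:
        for name in ("dimer_fraction", "labeling_efficiency"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class CopyNumberEstimate:
    copies: float
    se: float
    valid: bool = True
    flag: str | None = None


def calibrate_reference(intensities, copies_in_reference: int = 2) -> CalibrationReference:
    """Build a calibration reference from measured standard-spot
    intensities (non-finite values, e.g. border-clipped measurements, are
    excluded)."""
    arr = np.asarray(intensities, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no usable reference intensities")
    return CalibrationReference(
        mean_intensity=float(arr.mean()),
        sd_intensity=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_reference_spots=int(arr.size),
        copies_in_reference=copies_in_reference,
    )


def estimate_copy_number(complex_intensity: float, ref: CalibrationReference,
                         complex_se: float = 0.0) -> CopyNumberEstimate:
    """Copies per complex from the intensity ratio to the standard.

    ``copies = copies_in_reference * I / ref.mean``; the standard error
    combines the SEM of the reference mean with ``complex_se`` (the SE of
    the complex intensity, if known) by first-order propagation. A complex
    three times as bright as the dimeric-GFP standard gives 6 copies.
    """
    if not math.isfinite(complex_intensity) or complex_intensity <= 0:
        return CopyNumberEstimate(0.0, float("nan"), valid=False,
                                  flag="non-positive complex intensity")
    copies = ref.copies_in_reference * complex_intensity / ref.mean_intensity
    ref_sem = ref.sd_intensity / math.sqrt(ref.n_reference_spots)
    rel = (ref_sem / ref.mean_intensity) ** 2 + (complex_se / complex_intensity) ** 2
    return CopyNumberEstimate(copies, copies * math.sqrt(rel))


def expected_two_step_fraction(model: LabelingModel) -> float:
    """Fraction of visible spots showing two bleaching steps under the
    binomial labeling model (see module docstring)."""
    d, p = model.dimer_fraction, model.labeling_efficiency
    if p == 0:
        raise ValueError("labeling_efficiency 0 produces no visible spots")
    return d * p / (1.0 + d * (1.0 - p))


def min_labeling_efficiency(observed_two_step_fraction: float) -> float:
    """Smallest labeling probability consistent with an observed two-step
    fraction over all possible true dimer fractions (bound attained at
    d = 1): ``p_min = 2 f2 / (1 + f2)``, monotone increasing in f2."""
    f2 = observed_two_step_fraction
    if not (0.0 <= f2 < 1.0):
        raise ValueError("two-step fraction must be in [0, 1)")
    return 2.0 * f2 / (1.0 + f2)


def classify_super(complex_intensity: float, single_reference_mean: float | None,
                   tolerance: float = 0.25) -> str:
    """Classify a complex as a single assembly or a 'super' (two coalesced)
    assembly by intensity: super when intensity >= (2 - tolerance) x the
    single-assembly reference mean."""
    if single_reference_mean is None or not math.isfinite(single_reference_mean) \
            or single_reference_mean <= 0:
        return "unclassified"
    return "super" if complex_intensity >= (2.0 - tolerance) * single_reference_mean \
        else "single"


def surface_density(n_tracks_per_cell: float, labeling_efficiency: float,
                    cell_area_um2: float) -> float:
    """Receptors per um^2: observed tracks corrected for partial labeling,
    divided by the cell footprint (40 tracks at 33% labeling over 100 um^2
    is about 1.2 per um^2 — about one receptor per um^2)."""
    if not (labeling_efficiency > 0):
        raise ValueError("labeling_efficiency must be > 0")
    if not (cell_area_um2 > 0):
        raise ValueError("cell_area_um2 must be > 0")
    if n_tracks_per_cell < 0:
        raise ValueError("n_tracks_per_cell must be >= 0")
    return (n_tracks_per_cell / labeling_efficiency) / cell_area_um2
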