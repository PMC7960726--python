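"""Jet-geometry extraction from femtosecond snapshot images.

A gas-dynamic-virtual-nozzle microjet is imaged side-on: the jet appears
as a dark, roughly vertical band on a bright background, with the nozzle
at the top of the frame.  Row index increases downstream.  An XFEL pulse
that hits the jet vaporises a segment, leaving a gap; further downstream
the intact jet eventually breaks up into droplets (Rayleigh break-up).

The features extracted here drive the shot-acceptance rules: gap
positions and sizes (did the pump hit the jet, and where?), the width of
the jet projected onto the horizontal plane (tilt / diameter anomaly
detection), and the break-up point (a pump strike downstream of break-up
cannot launch a shock into the continuous jet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["JetFeatures", "extract_jet_features", "gap_centre", "jet_speed"]


@dataclass
class JetFeatures:
    """Geometry extracted from one jet snapshot.

    Positions are in micrometres measured from the top edge of the frame
    (0-based pixel convention, row index increases downstream).
    """

    projected_width_um: float
    gaps_um: list[tuple[float, float]] = field(default_factory=list)
    breakup_um: float | None = None
    axis_column_um: float | None = None
    no_jet: bool = False

    @property
    def n_gaps(self) -> int:
        return len(self.gaps_um)

    def continuous_upstream_of(self, position_um: float) -> bool:
        """True when no gap or break-up lies upstream of ``position_um``."""
        if self.no_jet:
            return False
        for start, _ in self.gaps_um:
            if start < position_um:
                return False
        if self.breakup_um is not None and self.breakup_um < position_um:
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "projected_width_um": self.projected_width_um,
            "gaps_um": [list(g) for g in self.gaps_um],
            "breakup_um": self.breakup_um,
            "axis_column_um": self.axis_column_um,
            "no_jet": self.no_jet,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs of a boolean array as (start, stop, value)."""
    out: list[tuple[int, int, bool]] = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        out.append((i, j, bool(mask[i])))
        i = j
    return out


def extract_jet_features(
    image: np.ndarray,
    um_per_px: float = 0.11,
    intensity_threshold: float | None = None,
    min_gap_px: int = 2,
    min_segment_px: int = 8,
) -> JetFeatures:
    """Segment a jet snapshot and measure gaps, width and break-up point.

    Parameters
    ----------
    image:
        Single-channel array; dark jet on bright background.
    um_per_px:
        Calibration (default 0.11 um per pixel).
    intensity_threshold:
        Pixels strictly below this value count as jet.  ``None`` selects
        Otsu's threshold on the image histogram.
    min_gap_px:
        Shortest run of jet-free rows counted as a gap (suppresses
        single-row noise).
    min_segment_px:
        Shortest run of jet-present rows counted as continuous jet; runs
        below this, downstream of the last continuous segment, are
        treated as droplets.

    Returns
    -------
    JetFeatures
        With ``no_jet=True`` (and empty gap list) when no pixel is below
        the threshold anywhere — distinguishable from an intact jet.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {img.shape}")
    if not um_per_px > 0:
        raise ValueError(f"um_per_px must be > 0, got {um_per_px}")
    if intensity_threshold is None:
        if img.max() == img.min():
            return JetFeatures(projected_width_um=0.0, no_jet=True)
        intensity_threshold = threshold_otsu(img)

    jet = img < intensity_threshold
    present = jet.any(axis=1)
    if not present.any():
        return JetFeatures(projected_width_um=0.0, no_jet=True)

    runs = _runs(present)
    present_runs = [(a, b) for a, b, v in runs if v]
    long_runs = [(a, b) for a, b in present_runs if b - a >= min_segment_px]
    if not long_runs:
        # nothing but droplets: report no continuous jet
        return JetFeatures(projected_width_um=0.0, no_jet=True)

    # Break-up: droplet-like (short) presence runs downstream of the last
    # long continuous segment.  Two or more of them mark intermittency.
    last_long_end = long_runs[-1][1]
    trailing_droplets = [
        (a, b) for a, b in present_runs if a >= last_long_end and b - a < min_segment_px
    ]
    breakup_um: float | None = None
    if len(trailing_droplets) >= 2:
        breakup_um = last_long_end * um_per_px

    # Gaps: jet-free runs of >= min_gap_px rows bounded by continuous jet
    # on both sides, upstream of the break-up point.
    gaps: list[tuple[float, float]] = []
    long_starts = [a for a, _ in long_runs]
    long_ends = [b for _, b in long_runs]
    for a, b, v in runs:
        if v or b - a < min_gap_px:
            continue
        if a == 0 or b == len(present):  # frame edge, not a gap
            continue
        upstream_is_jet = any(e <= a for e in long_ends)
        downstream_is_jet = any(s >= b for s in long_starts)
        if upstream_is_jet and downstream_is_jet and (breakup_um is None or a * um_per_px < breakup_um):
            gaps.append((a * um_per_px, b * um_per_px))

    # Projected width: median horizontal extent over jet-present rows of
    # the continuous (pre-break-up) segments.
    widths = []
    axis_cols = []
    for a, b in long_runs:
        for r in range(a, b):
            cols = np.flatnonzero(jet[r])
            if cols.size:
                widths.append(cols[-1] - cols[0] + 1)
                axis_cols.append(0.5 * (cols[0] + cols[-1]))
    width_um = float(np.median(widths)) * um_per_px
    axis_um = float(np.median(axis_cols)) * um_per_px

    return JetFeatures(
        projected_width_um=width_um,
        gaps_um=gaps,
        breakup_um=breakup_um,
        axis_column_um=axis_um,
    )


def gap_centre(features: JetFeatures, which: int = 1) -> float:
    """Centre (um) of the ``which``-th gap, ordinals counted downstream from 1."""
    if features.no_jet:
        raise ValueError("no jet detected; gap positions undefined")
    if not 1 <= which <= len(features.gaps_um):
        raise IndexError(
            f"gap ordinal {which} out of range; {len(features.gaps_um)} gap(s) present"
        )
    start, end = features.gaps_um[which - 1]
    return 0.5 * (start + end)


def jet_speed(y1_um: float, t1_ns: float, y2_um: float, t2_ns: float) -> float:
    """Jet speed (m/s) from a gap centre tracked at two imaging delays.

    ``v = (y1 - y2) / (t1 - t2)``; downstream motion (gap centre moving to
    larger y with time) gives a positive speed.  1 um/ns = 1000 m/s.
    """
    if t1_ns == t2_ns:
        raise ValueError("imaging delays are equal; speed undefined")
    return (y1_um - y2_um) / (t1_ns - t2_ns) * 1000.0
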