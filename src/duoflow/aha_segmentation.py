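"""AHA 17-segment bookkeeping on short-axis perfusion maps.

Three short-axis levels are analysed: basal (segments 1-6), mid-ventricular
(7-12) and apical (13-16); the apical cap (segment 17) is excluded, so each
patient contributes 16 segments.  Segment sectors start at the anterior
reference angle (the anterior RV insertion) and proceed counterclockwise in
the standard apex-up display.  Regions of interest are eroded one pixel from
both the endo- and epicardial borders before averaging, global perfusion is
the unweighted mean over the 16 segmental means, myocardial perfusion
reserve (MPR) is stress/rest, and stress positivity uses the strict
< 2.0 ml/min/g cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import N_SEGMENTS

__all__ = [
    "SegmentMap",
    "SLICE_SEGMENTS",
    "STRESS_CUTOFF",
    "erode_roi",
    "build_segment_map",
    "segment_means",
    "global_mp",
    "compute_mpr",
    "classify_stress_positive",
]

#: segment labels per short-axis level (17-segment model, apex excluded)
SLICE_SEGMENTS = {
    "basal": tuple(range(1, 7)),
    "mid": tuple(range(7, 13)),
    "apical": tuple(range(13, 17)),
}

STRESS_CUTOFF = 2.0  # ml/min/g, strict '<' positivity


@dataclass(frozen=True)
class SegmentMap:
    """Per-pixel segment labels for one short-axis slice."""

    labels: np.ndarray
    slice_level: str
    reference_angle: float

    def __post_init__(self) -> None:
        if self.slice_level not in SLICE_SEGMENTS:
            raise ValueError(f"unknown slice level {self.slice_level!r}")
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(SLICE_SEGMENTS[self.slice_level]):
            raise ValueError("labels outside the slice's segment range")


def build_segment_map(shape, center, slice_level: str,
                      reference_angle: float = 90.0) -> SegmentMap:
    """Angular AHA sectors for one slice: 6 x 60 deg (basal, mid) or
    4 x 90 deg (apical), numbered counterclockwise from ``reference_angle``
    (degrees, measured counterclockwise from the +x image axis)."""
    segs = SLICE_SEGMENTS.get(slice_level)
    if segs is None:
        raise ValueError(f"unknown slice level {slice_level!r}")
    h, w = shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("center must lie inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    # +y downward in image coordinates; negate for counterclockwise angles
    theta = np.degrees(np.arctan2(-(yy - cy), xx - cx))
    width = 360.0 / len(segs)
    k = np.floor(((theta - reference_angle) % 360.0) / width).astype(np.int32)
    labels = segs[0] + k
    return SegmentMap(labels=labels, slice_level=slice_level,
                      reference_angle=float(reference_angle % 360.0))


def erode_roi(myocardial_mask, n_pixels: int = 1, segment_labels=None) -> np.ndarray:
    """Erode an annular ROI ``n_pixels`` from both borders.

    Plain morphological erosion recedes the endo- and epicardial borders
    symmetrically.  Raises if the mask vanishes, or — when a segment label
    map is supplied — if any segment present before erosion loses all of
    its pixels, naming that segment.
    """
    mask = np.asarray(myocardial_mask, bool)
    if n_pixels < 0:
        raise ValueError("n_pixels must be >= 0")
    if n_pixels == 0:
        return mask.copy()
    eroded = ndimage.binary_erosion(mask, iterations=n_pixels)
    if segment_labels is not None:
        labels = np.asarray(segment_labels)
        for seg in np.unique(labels[mask & (labels > 0)]):
            if not eroded[labels == seg].any():
                raise ValueError(f"erosion by {n_pixels} px emptied segment {seg}")
    elif not eroded.any():
        raise ValueError(f"erosion by {n_pixels} px emptied the ROI")
    return eroded


def segment_means(perfusion_map, segment_labels, expected_segments=None) -> pd.DataFrame:
    """Mean of unmasked (non-NaN) pixels per segment.

    Returns a DataFrame indexed by segment with columns ``value`` and
    ``n_pixels``; an expected segment with no valid pixels raises.
    """
    pmap = np.asarray(perfusion_map, float)
    labels = np.asarray(segment_labels)
    if pmap.shape != labels.shape:
        raise ValueError("perfusion map and segment labels must align")
    segs = (sorted(set(np.unique(labels)) - {0})
            if expected_segments is None else list(expected_segments))
    rows = []
    for seg in segs:
        vals = pmap[(labels == seg) & ~np.isnan(pmap)]
        if vals.size == 0:
            raise ValueError(f"segment {seg} has no valid pixels")
        rows.append((seg, float(vals.mean()), int(vals.size)))
    return pd.DataFrame(rows, columns=["segment", "value", "n_pixels"]).set_index("segment")


def global_mp(values) -> float:
    """Global MP: unweighted mean over the 16 segmental values."""
    vals = np.asarray(values, float)
    if vals.shape != (N_SEGMENTS,):
        raise ValueError(f"expected {N_SEGMENTS} segmental values, got {vals.shape}")
    if np.any(np.isnan(vals)):
        raise ValueError("missing segmental values")
    return float(vals.mean())


def compute_mpr(stress_table: pd.DataFrame, rest_table: pd.DataFrame) -> pd.DataFrame:
    """Combine per-segment rest/stress means into the segment perfusion table.

    Input tables are :func:`segment_means` outputs; the result has columns
    ``mp_rest``, ``mp_stress``, ``mpr`` (= stress/rest) and ``n_pixels``.
    """
    if not stress_table.index.equals(rest_table.index):
        raise ValueError("stress and rest tables must share segment ids")
    rest = rest_table["value"].to_numpy(float)
    if np.any(rest <= 0):
        bad = rest_table.index[rest <= 0].tolist()
        raise ValueError(f"rest MP must be > 0 for MPR (segments {bad})")
    out = pd.DataFrame(index=stress_table.index)
    out["mp_rest"] = rest
    out["mp_stress"] = stress_table["value"].to_numpy(float)
    out["mpr"] = out["mp_stress"] / out["mp_rest"]
    out["n_pixels"] = stress_table["n_pixels"]
    return out


def classify_stress_positive(stress_values, threshold: float = STRESS_CUTOFF,
                             rule: str = "any", lesion_segments=None):
    """Stress-positivity at the perfusion cut-off (strict inequality).

    A segment is positive iff its stress MP < ``threshold``.  Patient-level
    positivity: ``rule='any'`` — any positive segment; ``rule='territory'``
    — at least one positive segment among ``lesion_segments``.
    Returns ``(segment_flags: pd.Series, patient_positive: bool)``.
    """
    s = pd.Series(stress_values, dtype=float)
    if s.isna().any():
        raise ValueError("stress values must be present")
    flags = s < threshold
    if rule == "any":
        patient = bool(flags.any())
    elif rule == "territory":
        if lesion_segments is None:
            raise ValueError("rule='territory' requires lesion_segments")
        sel = flags.loc[[seg for seg in lesion_segments if seg in flags.index]]
        patient = bool(sel.any())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return flags, patient
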