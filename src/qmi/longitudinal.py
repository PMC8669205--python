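"""Longitudinal lesion-versus-control ROI extraction.

For each lesion a local control region of interest is built by dilating
the lesion mask one voxel in all directions (26-neighbourhood) and
subtracting the lesion itself: a one-voxel shell.  Scanner- and
visit-level intensity biases are spatially smooth, so they affect lesion
and adjacent control shell almost identically and cancel in the
lesion-minus-control difference — the reason a local control is used
instead of, say, a contralateral one.

ROI means are gated by an R2* acceptance window (default 5-30 s^-1,
inclusive) computed from the same visit's R2* map, to exclude voxels
dominated by CSF (very low R2*) or white matter (around 30 s^-1); the
window gates every parameter's mean for that visit.  Per-lesion series
are then temporally realigned so the onset visit sits at offset 0 and
baseline-normalized by subtracting the mean of all pre-onset
differences, which removes any residual static partial-volume offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionRecord",
    "AlignedSeries",
    "LesionExcluded",
    "make_control_roi",
    "roi_mean",
    "extract_series",
    "realign_and_normalize",
    "ACCEPT_RANGE_DEFAULT",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: Inclusive R2* voxel-acceptance window, s^-1.
ACCEPT_RANGE_DEFAULT: Tuple[float, float] = (5.0, 30.0)

#: Stage labels attached to aligned visits.
PRE, LESIONAL, INTERIM, POST = "pre-lesional", "lesional", "interim", "post-lesional"


class LesionExcluded(Exception):
    """Raised when a lesion cannot enter the longitudinal analysis."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class LesionRecord:
    """Lesion mask, its derived control shell, and the onset visit."""

    lesion_mask: np.ndarray
    onset_visit: int
    subject_id: str = ""
    lesion_id: int = 0
    control_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.control_mask is None:
            self.control_mask = make_control_roi(self.lesion_mask)
        else:
            self.control_mask = np.asarray(self.control_mask, dtype=bool)
        if np.any(self.lesion_mask & self.control_mask):
            raise ValueError("lesion and control masks overlap")
        if not self.control_mask.any():
            raise ValueError("control mask is empty")


@dataclass
class AlignedSeries:
    """Per-lesion lesion-minus-control series realigned to onset.

    offsets : visit index minus onset (0 is the lesional visit);
    values : parameter -> normalized differences per offset (NaN where a
    visit had no accepted voxels); stage_labels : pre-lesional for
    offsets < 0, lesional at 0, post-lesional at the last available
    offset, interim in between; accepted_voxel_counts : accepted lesion
    voxels per offset.
    """

    offsets: np.ndarray
    values: Dict[str, np.ndarray]
    stage_labels: List[str]
    accepted_voxel_counts: np.ndarray
    lesion_id: int = 0
    subject_id: str = ""

    def stage_values(self, parameter: str) -> Dict[str, float]:
        """The three values entering inference: the visit immediately
        before onset, the onset visit, and the last available visit."""
        v = self.values[parameter]
        out = {}
        pre_idx = [i for i, o in enumerate(self.offsets)
                   if o < 0 and np.isfinite(v[i])]
        if pre_idx:
            out[PRE] = float(v[pre_idx[-1]])
        les = np.flatnonzero(self.offsets == 0)
        if les.size and np.isfinite(v[les[0]]):
            out[LESIONAL] = float(v[les[0]])
        post_idx = [i for i, o in enumerate(self.offsets)
                    if o > 0 and np.isfinite(v[i])]
        if post_idx:
            out[POST] = float(v[post_idx[-1]])
        return out


def make_control_roi(lesion_mask: np.ndarray) -> np.ndarray:
    """One-voxel control shell: 26-neighbourhood dilation minus the lesion."""
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    on_border = (mask[0].any() or mask[-1].any() or mask[:, 0].any()
                 or mask[:, -1].any() or mask[:, :, 0].any()
                 or mask[:, :, -1].any())
    if on_border:
        warnings.warn("lesion touches the volume border; control ROI truncated")
    control = ndimage.binary_dilation(mask, structure=_STRUCT26) & ~mask
    if not control.any():
        raise ValueError("lesion fills the volume; no control voxels exist")
    return control


def roi_mean(param_map: np.ndarray, roi_mask: np.ndarray,
             r2star_map: np.ndarray,
             accept_range: Tuple[float, float] = ACCEPT_RANGE_DEFAULT,
             ) -> Tuple[float, int]:
    """Mean of ``param_map`` over the ROI, restricted to voxels whose R2*
    lies in ``accept_range`` (inclusive).

    Returns (mean, n_accepted); the mean is NaN (a flagged missing
    value, never a silent zero) when no voxel survives the window.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    r2s = np.asarray(r2star_map, dtype=float)
    lo, hi = accept_range
    sel = roi & (r2s >= lo) & (r2s <= hi)
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(np.asarray(param_map, dtype=float)[sel].mean()), n


def extract_series(maps_by_visit: Sequence[Mapping[str, np.ndarray]],
                   record: LesionRecord,
                   parameters: Sequence[str],
                   accept_range: Tuple[float, float] = ACCEPT_RANGE_DEFAULT,
                   min_lesion_voxels: int = 3,
                   ) -> Dict[str, np.ndarray]:
    """Raw per-visit lesion-minus-control differences for each parameter.

    Every visit's means (lesion and control, every parameter) are gated
    by that visit's own R2* map.  Lesions for which fewer than
    ``min_lesion_voxels`` lesion voxels survive the window at any visit
    are excluded (too close to the pial surface / partial volume), via
    :class:`LesionExcluded`.

    Returns a dict with one array per parameter (indexed by visit) plus
    "_n_lesion" / "_n_control" accepted-voxel counts.
    """
    n_visits = len(maps_by_visit)
    out = {p: np.full(n_visits, np.nan) for p in parameters}
    n_les = np.zeros(n_visits, dtype=int)
    n_ctl = np.zeros(n_visits, dtype=int)
    for v, maps in enumerate(maps_by_visit):
        r2s = np.asarray(maps["r2star"], dtype=float)
        for p in parameters:
            les_mean, nl = roi_mean(maps[p], record.lesion_mask, r2s, accept_range)
            ctl_mean, nc = roi_mean(maps[p], record.control_mask, r2s, accept_range)
            out[p][v] = les_mean - ctl_mean
            n_les[v], n_ctl[v] = nl, nc
        if n_les[v] < min_lesion_voxels:
            raise LesionExcluded(
                f"only {n_les[v]} lesion voxel(s) inside the R2* acceptance "
                f"window at visit {v} (pial-surface / partial-volume exclusion)")
    out["_n_lesion"] = n_les
    out["_n_control"] = n_ctl
    return out


def realign_and_normalize(diffs: Mapping[str, np.ndarray], onset_visit: int,
                          lesion_id: int = 0, subject_id: str = "",
                          ) -> AlignedSeries:
    """Realign a raw difference series to onset and baseline-normalize it.

    Visit indices are re-expressed as offsets from onset (onset -> 0) and
    the mean of all pre-onset differences is subtracted per parameter, so
    pre-lesional entries average to zero by construction.  Lesions with
    no usable pre-onset or no post-onset data are excluded (they appeared
    on the first or last available scan).
    """
    params = [p for p in diffs if not p.startswith("_")]
    n_visits = len(np.asarray(diffs[params[0]]))
    offsets = np.arange(n_visits) - onset_visit

    any_finite = np.zeros(n_visits, dtype=bool)
    for p in params:
        any_finite |= np.isfinite(np.asarray(diffs[p], dtype=float))
    if not np.any(any_finite & (offsets < 0)):
        raise LesionExcluded("no pre-lesional values")
    if not np.any(any_finite & (offsets > 0)):
        raise LesionExcluded("no post-lesional values")

    values = {}
    for p in params:
        x = np.asarray(diffs[p], dtype=float)
        pre = x[(offsets < 0) & np.isfinite(x)]
        if pre.size == 0:
            raise LesionExcluded(f"no pre-lesional values for {p}")
        values[p] = x - pre.mean()

    last = int(np.max(offsets[any_finite]))
    labels = []
    for o in offsets:
        if o < 0:
            labels.append(PRE)
        elif o == 0:
            labels.append(LESIONAL)
        elif o == last:
            labels.append(POST)
        else:
            labels.append(INTERIM)

    counts = np.asarray(diffs.get("_n_lesion", np.zeros(n_visits, dtype=int)))
    return AlignedSeries(offsets=offsets, values=values, stage_labels=labels,
                         accepted_voxel_counts=counts, lesion_id=lesion_id,
                         subject_id=subject_id)
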