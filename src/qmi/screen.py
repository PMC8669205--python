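"""Rule-based screening for acute cortical microinfarcts (A-CMI).

Operationalizes the standard rating criteria — a hyperintense lesion on
the DWI trace, smaller than 5 mm, restricted to the cerebral cortex, with
hypo- or isointense signal on the mean-diffusivity (MD) map — as a
deterministic detector: the DWI trace is z-scored against the cortical
mean and standard deviation, supra-threshold cortical voxels are grouped
into 26-connected components, and each component is accepted or rejected
by size, location and MD criteria.

The visual "hyperintense" / "hypo- or isointense" judgements become
z-score thresholds (defaults: DWI z >= 3, MD z <= +1), deliberately
conservative proxies for visual salience.  A three-voxel size floor
excludes isolated noise voxels and chance-adjacent pairs, whose expected
count under z-scoring is essentially independent of the noise level;
such sub-3-voxel lesions are below the slice thickness and are not
considered detectable anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

__all__ = ["ScreenParams", "CandidateLesion", "detect_acmi", "max_diameter"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ScreenParams:
    """Detector thresholds.

    z_dwi : minimum cortical DWI z-score for lesion voxels.
    md_z_max : maximum mean MD z-score inside the lesion ("hypo- or
        isointense" upper bound).
    max_diameter_mm : lesions must be strictly smaller than this.
    min_voxels : minimum component size in voxels.
    """

    z_dwi: float = 3.0
    md_z_max: float = 1.0
    max_diameter_mm: float = 5.0
    min_voxels: int = 3


@dataclass
class CandidateLesion:
    """One connected DWI-hyperintense candidate with its verdict."""

    mask: np.ndarray
    max_diameter_mm: float
    dwi_z: float
    md_z: float
    verdict: str  # accepted | rejected_size | rejected_md | rejected_location
    n_voxels: int = 0

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def max_diameter(mask: np.ndarray, voxel_size_mm: Sequence[float]) -> float:
    """Maximum lesion diameter in mm.

    Convention: the maximum pairwise Euclidean distance between voxel
    centers plus one mean voxel extent, so that a single voxel has a
    nonzero diameter.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no diameter")
    vox = np.asarray(voxel_size_mm, dtype=float)
    coords = np.argwhere(mask) * vox
    if coords.shape[0] > 400:
        # reduce to the component's boundary voxels first
        boundary = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT26)
        coords = np.argwhere(boundary) * vox
    span = 0.0 if coords.shape[0] < 2 else float(pdist(coords).max())
    return span + float(vox.mean())


def detect_acmi(dwi_trace: np.ndarray, md_map: np.ndarray,
                cortex_mask: np.ndarray,
                params: ScreenParams | None = None,
                voxel_size_mm: Sequence[float] = (0.8, 0.8, 2.0),
                ) -> List[CandidateLesion]:
    """Detect acute-cortical-microinfarct candidates on one visit.

    Returns all candidates (accepted and rejected), deterministically
    ordered by decreasing size then lexicographic seed coordinate.
    """
    if params is None:
        params = ScreenParams()
    dwi = np.asarray(dwi_trace, dtype=float)
    md = np.asarray(md_map, dtype=float)
    cortex = np.asarray(cortex_mask, dtype=bool)
    if dwi.shape != md.shape or dwi.shape != cortex.shape:
        raise ValueError("maps and cortex mask must share one grid")
    if not cortex.any():
        raise ValueError("cortex mask is empty")

    mu, sd = dwi[cortex].mean(), dwi[cortex].std(ddof=1)
    if not sd > 0:
        raise ValueError("degenerate cortical DWI standard deviation (<= 0)")
    zmap = (dwi - mu) / sd
    md_mu, md_sd = md[cortex].mean(), md[cortex].std(ddof=1)
    if not md_sd > 0:
        raise ValueError("degenerate cortical MD standard deviation (<= 0)")
    md_zmap = (md - md_mu) / md_sd

    labels, n = ndimage.label((zmap >= params.z_dwi) & cortex,
                              structure=_STRUCT26)
    comps = []
    for lab in range(1, n + 1):
        mask = labels == lab
        seed = tuple(int(c) for c in np.argwhere(mask)[0])
        comps.append((int(mask.sum()), seed, mask))
    comps.sort(key=lambda t: (-t[0], t[1]))

    out: List[CandidateLesion] = []
    for size, _, mask in comps:
        diam = max_diameter(mask, voxel_size_mm)
        dwi_z = float(zmap[mask].mean())
        md_z = float(md_zmap[mask].mean())
        if np.any(mask & ~cortex):
            verdict = "rejected_location"
        elif size < params.min_voxels or diam >= params.max_diameter_mm:
            verdict = "rejected_size"
        elif md_z > params.md_z_max:
            verdict = "rejected_md"
        else:
            verdict = "accepted"
        out.append(CandidateLesion(mask=mask, max_diameter_mm=diam,
                                   dwi_z=dwi_z, md_z=md_z, verdict=verdict,
                                   n_voxels=size))
    return out
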