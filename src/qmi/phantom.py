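"""Synthetic serial quantitative-MRI studies with stage-evolving cortical lesions.

The generator emulates a monthly serial MRI study of a small-vessel-disease
cohort: each subject-level "study" is a stack of pre-aligned monthly visits
on a common grid, and each visit carries a 6-echo gradient-echo (GRE)
magnitude+phase series, a multi-echo spin-echo series for R2 mapping, and
directly emitted quantitative maps (R1, DWI trace at b=1000 and b=3000, MD,
FA), plus a cortex mask and per-lesion truth masks.

The anatomy is deliberately minimal: a three-compartment ellipsoidal brain
(CSF core, white matter, a cortical grey-matter shell) with typical 3 T
relaxation rates — cortical GM R2* near 15 s^-1, WM near 30 s^-1, CSF much
lower.  Cortical lesions are small spheres (< 5 mm for microinfarct-like
lesions) whose parameter values follow an acute-to-post-lesional
trajectory: at the onset visit the DWI trace rises while MD, R1, R2 and
R2* drop (acute cytotoxic oedema); afterwards everything returns to
baseline except R2*, which overshoots above its pre-lesional level (iron
accumulation).  Ground truth (per-visit parameter maps, per-lesion deltas,
the static field-offset map) is retained for recovery tests.

Signal models:
  GRE        magnitude(TE) = PD exp(-R2* TE), phase(TE) = wrap(2 pi f TE)
  spin echo  magnitude(TE) = PD exp(-R2 TE), zero phase
Complex Gaussian noise of standard deviation ``noise_sd`` is added to the
real and imaginary channels before magnitude/phase extraction (Rician
magnitude statistics); emitted parameter maps get additive Gaussian noise
scaled by ``param_noise_frac`` times the cortical-GM value of each
parameter.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .relaxometry import EchoSeries, QuantitativeMap

__all__ = [
    "TissueParams",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "Study",
    "Visit",
    "DEFAULT_TISSUES",
    "ACUTE_DELTAS",
    "POST_DELTAS",
    "simulate_multiecho_gre",
    "build_phantom",
    "default_cohort_spec",
]

#: Quantitative parameters carried by every visit.
PARAMETERS = ("r1", "r2", "r2star", "dwi_b1000", "dwi_b3000", "md", "fa")

# Compartment labels in the geometry volume.
BACKGROUND, CSF, WM, GM = 0, 1, 2, 3


@dataclass
class TissueParams:
    """True parameter values for one tissue compartment.

    Rates in s^-1, MD in mm^2/s, DWI trace and proton density in
    arbitrary units, FA dimensionless.
    """

    r1: float
    r2: float
    r2star: float
    pd: float
    dwi_b1000: float
    dwi_b3000: float
    md: float
    fa: float


#: Typical 3 T values per compartment.  Cortical GM R2* ~15 s^-1,
#: WM ~30 s^-1, CSF far lower — the ordering the acceptance window
#: (5-30 s^-1) is designed around.
DEFAULT_TISSUES: Dict[str, TissueParams] = {
    "csf": TissueParams(r1=0.25, r2=0.5, r2star=1.0, pd=1.0,
                        dwi_b1000=0.15, dwi_b3000=0.02, md=3.0e-3, fa=0.05),
    "gm": TissueParams(r1=0.83, r2=12.5, r2star=15.0, pd=0.85,
                       dwi_b1000=1.0, dwi_b3000=0.55, md=0.8e-3, fa=0.15),
    "wm": TissueParams(r1=1.2, r2=14.3, r2star=30.0, pd=0.7,
                       dwi_b1000=0.9, dwi_b3000=0.5, md=0.7e-3, fa=0.45),
}

#: Additive offsets applied inside the lesion at the onset visit
#: (acute stage): diffusion restriction raises the DWI trace and lowers
#: MD; R1, R2 and R2* all drop.
ACUTE_DELTAS: Dict[str, float] = {
    "dwi_b1000": +0.30, "dwi_b3000": +0.17, "md": -0.16e-3,
    "r1": -0.12, "r2": -2.0, "r2star": -3.0, "fa": 0.0,
}

#: Additive offsets from the visit after onset onward (post-lesional
#: stage): everything back to baseline except an R2* overshoot.
POST_DELTAS: Dict[str, float] = {
    "dwi_b1000": 0.0, "dwi_b3000": 0.0, "md": 0.0,
    "r1": 0.0, "r2": 0.0, "r2star": +2.0, "fa": 0.0,
}


@dataclass
class LesionSpec:
    """One spherical cortical lesion.

    center : voxel coordinates (may be fractional); diameter_mm : lesion
    diameter (< 5 mm for microinfarct-like lesions); onset_visit : first
    visit at which the lesion is present; stage_deltas : additive offsets
    per stage ("acute", "post") and parameter.
    """

    center: Tuple[float, float, float]
    diameter_mm: float
    onset_visit: int
    stage_deltas: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "acute": dict(ACUTE_DELTAS), "post": dict(POST_DELTAS),
    })

    def delta_at(self, visit: int) -> Dict[str, float]:
        if visit < self.onset_visit:
            return {p: 0.0 for p in PARAMETERS}
        stage = "acute" if visit == self.onset_visit else "post"
        d = self.stage_deltas.get(stage, {})
        return {p: float(d.get(p, 0.0)) for p in PARAMETERS}


@dataclass
class PhantomSpec:
    """Full description of one synthetic serial study."""

    grid_shape: Tuple[int, int, int] = (72, 72, 18)
    voxel_size_mm: Tuple[float, float, float] = (0.8, 0.8, 2.0)
    n_visits: int = 10
    echo_times_ms: Sequence[float] = tuple(4.92 * k for k in range(1, 7))
    se_echo_times_ms: Sequence[float] = tuple(10.0 * k for k in range(1, 11))
    noise_sd: float = 0.01
    param_noise_frac: float = 0.02
    tissue_params: Dict[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES))
    lesion_specs: List[LesionSpec] = field(default_factory=list)
    field_offset_background_hz: float = 5.0
    lesion_field_dip_hz: float = -8.0
    seed: int = 0

    def __post_init__(self):
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 2 or np.any(np.diff(te) <= 0) or te[0] <= 0:
            raise ValueError("echo times must be positive and strictly increasing")
        if self.n_visits < 3:
            raise ValueError("need at least 3 visits (pre / lesional / post)")
        t = self.tissue_params
        if not (t["csf"].r2star < t["gm"].r2star < t["wm"].r2star):
            raise ValueError("tissue R2* must satisfy CSF < GM < WM")
        for les in self.lesion_specs:
            if not (0 <= les.onset_visit < self.n_visits):
                raise ValueError(
                    f"lesion onset_visit {les.onset_visit} outside study")
            if les.diameter_mm <= 0:
                raise ValueError("lesion diameter must be positive")


@dataclass
class Visit:
    """All volumes emitted for one monthly visit."""

    index: int
    gre: EchoSeries
    spin_echo: EchoSeries
    maps: Dict[str, QuantitativeMap]


@dataclass
class Study:
    """A serial study: visits plus static geometry and lesion masks."""

    visits: List[Visit]
    cortex_mask: np.ndarray
    lesion_masks: Dict[int, np.ndarray]
    voxel_size_mm: Tuple[float, float, float]
    onset_visits: Dict[int, int]

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class PhantomTruth:
    """Ground truth retained for recovery tests."""

    parameter_maps: List[Dict[str, np.ndarray]]  # per visit
    compartments: np.ndarray
    field_offset_hz: np.ndarray
    lesion_masks: Dict[int, np.ndarray]
    lesion_deltas: Dict[int, Dict[str, Dict[str, float]]]
    onset_visits: Dict[int, int]


def _voxel_centers_mm(grid_shape, voxel_size_mm):
    axes = [ (np.arange(n) + 0.5) * v for n, v in zip(grid_shape, voxel_size_mm) ]
    return np.meshgrid(*axes, indexing="ij")


def make_compartments(grid_shape, voxel_size_mm) -> np.ndarray:
    """Label volume: ellipsoidal brain with CSF core, WM, cortical GM shell."""
    xm, ym, zm = _voxel_centers_mm(grid_shape, voxel_size_mm)
    extent = [n * v for n, v in zip(grid_shape, voxel_size_mm)]
    center = [e / 2 for e in extent]
    semi = [0.95 * e / 2 for e in extent]
    rho = np.sqrt(((xm - center[0]) / semi[0]) ** 2
                  + ((ym - center[1]) / semi[1]) ** 2
                  + ((zm - center[2]) / semi[2]) ** 2)
    labels = np.full(grid_shape, BACKGROUND, dtype=np.int8)
    labels[rho <= 1.0] = GM
    labels[rho <= 0.75] = WM
    labels[rho <= 0.25] = CSF
    return labels


def sphere_mask(grid_shape, voxel_size_mm, center_voxel, diameter_mm) -> np.ndarray:
    """Voxels whose centers lie within diameter/2 of the lesion center."""
    xm, ym, zm = _voxel_centers_mm(grid_shape, voxel_size_mm)
    c = [(ci + 0.5) * vi for ci, vi in zip(center_voxel, voxel_size_mm)]
    d2 = (xm - c[0]) ** 2 + (ym - c[1]) ** 2 + (zm - c[2]) ** 2
    return d2 <= (diameter_mm / 2.0) ** 2


def cortical_depth_mm(cortex_mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Distance (mm) from each cortical voxel to the nearest non-cortex
    voxel, with out-of-volume treated as non-cortex (zero-padded), so
    border voxels never look artificially deep."""
    padded = np.pad(np.asarray(cortex_mask, dtype=bool), 1)
    edt = ndimage.distance_transform_edt(padded, sampling=voxel_size_mm)
    return edt[1:-1, 1:-1, 1:-1]


def _field_offset_map(spec: PhantomSpec, compartments, lesion_masks) -> np.ndarray:
    """Static field-offset map: smooth background plus localized dips at
    lesion sites (paramagnetic-like perturbations that darken SWI)."""
    nx, ny, nz = spec.grid_shape
    x = np.linspace(0, 1, nx)[:, None, None]
    y = np.linspace(0, 1, ny)[None, :, None]
    z = np.linspace(0, 1, nz)[None, None, :]
    a = spec.field_offset_background_hz
    f = a * (0.6 * np.sin(np.pi * x) * np.cos(np.pi * y)
             + 0.4 * (z - 0.5))
    for les, mask in zip(spec.lesion_specs, lesion_masks.values()):
        if not mask.any():
            continue
        xm, ym, zm = _voxel_centers_mm(spec.grid_shape, spec.voxel_size_mm)
        c = [(ci + 0.5) * vi for ci, vi in zip(les.center, spec.voxel_size_mm)]
        sigma = max(les.diameter_mm / 2.0, 1.0)
        d2 = (xm - c[0]) ** 2 + (ym - c[1]) ** 2 + (zm - c[2]) ** 2
        f = f + spec.lesion_field_dip_hz * np.exp(-d2 / (2 * sigma ** 2))
    return f


def simulate_multiecho_gre(r2star_map, proton_density, field_offset_hz,
                           echo_times_ms, noise_sd=0.0, rng=None,
                           voxel_size_mm=(0.8, 0.8, 2.0)) -> EchoSeries:
    """Simulate a multi-echo GRE magnitude+phase series.

    magnitude(TE) = PD exp(-R2* TE); phase(TE) = 2 pi f TE wrapped to
    (-pi, pi].  Complex Gaussian noise (sd per channel) is added before
    magnitude/phase extraction, yielding Rician magnitude noise.
    """
    r2s = np.asarray(r2star_map, dtype=float)
    pd = np.asarray(proton_density, dtype=float)
    f = np.asarray(field_offset_hz, dtype=float)
    if np.any(r2s < 0):
        raise ValueError("negative R2* in map")
    if r2s.shape != pd.shape or r2s.shape != f.shape:
        raise ValueError("maps must share one grid")
    te_s = np.asarray(echo_times_ms, dtype=float) / 1000.0
    sig = (pd[..., None] * np.exp(-r2s[..., None] * te_s)
           * np.exp(2j * np.pi * f[..., None] * te_s))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        sig = sig + noise_sd * (rng.standard_normal(sig.shape)
                                + 1j * rng.standard_normal(sig.shape))
    return EchoSeries(np.abs(sig), np.angle(sig), np.asarray(echo_times_ms, float),
                      voxel_size_mm=tuple(voxel_size_mm))


def _base_parameter_maps(spec: PhantomSpec, compartments) -> Dict[str, np.ndarray]:
    maps = {}
    comp_of = {"csf": CSF, "gm": GM, "wm": WM}
    for p in PARAMETERS + ("pd",):
        vol = np.zeros(spec.grid_shape)
        for name, label in comp_of.items():
            vol[compartments == label] = getattr(spec.tissue_params[name], p)
        maps[p] = vol
    return maps


def build_phantom(spec: PhantomSpec) -> Tuple[Study, PhantomTruth]:
    """Generate the full serial study and its ground truth.

    Raises ValueError if any lesion extends outside the cortical GM
    compartment or if two lesions overlap.
    """
    compartments = make_compartments(spec.grid_shape, spec.voxel_size_mm)
    cortex = compartments == GM

    lesion_masks: Dict[int, np.ndarray] = {}
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    for i, les in enumerate(spec.lesion_specs):
        mask = sphere_mask(spec.grid_shape, spec.voxel_size_mm,
                           les.center, les.diameter_mm)
        if not mask.any():
            raise ValueError(f"lesion {i} covers no voxel")
        if np.any(mask & ~cortex):
            raise ValueError(
                f"lesion {i} at {les.center} extends outside the cortical "
                "GM compartment")
        if np.any(mask & occupied):
            raise ValueError(f"lesion {i} overlaps another lesion")
        occupied |= mask
        lesion_masks[i] = mask

    field = _field_offset_map(spec, compartments, lesion_masks)
    base = _base_parameter_maps(spec, compartments)
    gm_scale = {p: abs(getattr(spec.tissue_params["gm"], p)) for p in PARAMETERS}

    rng = np.random.default_rng(spec.seed)
    visits: List[Visit] = []
    truth_maps: List[Dict[str, np.ndarray]] = []
    for v in range(spec.n_visits):
        true_v = {p: base[p].copy() for p in PARAMETERS}
        for i, les in enumerate(spec.lesion_specs):
            deltas = les.delta_at(v)
            for p in PARAMETERS:
                if deltas[p]:
                    true_v[p][lesion_masks[i]] += deltas[p]
        truth_maps.append(true_v)

        gre = simulate_multiecho_gre(
            true_v["r2star"], base["pd"], field, spec.echo_times_ms,
            noise_sd=spec.noise_sd, rng=rng, voxel_size_mm=spec.voxel_size_mm)
        se = simulate_multiecho_gre(
            true_v["r2"], base["pd"], np.zeros(spec.grid_shape),
            spec.se_echo_times_ms, noise_sd=spec.noise_sd, rng=rng,
            voxel_size_mm=spec.voxel_size_mm)

        maps = {}
        for p in ("r1", "dwi_b1000", "dwi_b3000", "md", "fa"):
            vol = true_v[p].copy()
            if spec.param_noise_frac > 0:
                vol = vol + (spec.param_noise_frac * gm_scale[p]
                             * rng.standard_normal(spec.grid_shape))
            maps[p] = QuantitativeMap(vol, p, voxel_size_mm=spec.voxel_size_mm)
        visits.append(Visit(index=v, gre=gre, spin_echo=se, maps=maps))

    study = Study(
        visits=visits, cortex_mask=cortex, lesion_masks=lesion_masks,
        voxel_size_mm=spec.voxel_size_mm,
        onset_visits={i: l.onset_visit for i, l in enumerate(spec.lesion_specs)},
    )
    truth = PhantomTruth(
        parameter_maps=truth_maps, compartments=compartments,
        field_offset_hz=field, lesion_masks=lesion_masks,
        lesion_deltas={i: l.stage_deltas for i, l in enumerate(spec.lesion_specs)},
        onset_visits={i: l.onset_visit for i, l in enumerate(spec.lesion_specs)},
    )
    return study, truth


def default_cohort_spec(n_lesions: int = 15, seed: int = 0,
                        diameter_mm: float = 3.0,
                        delta_jitter: float = 0.2,
                        min_separation_mm: float = 8.0,
                        **overrides) -> PhantomSpec:
    """Spec for the default analysis cohort: ``n_lesions`` non-overlapping
    cortical lesions with onsets spread over interior visits.

    Lesion severities vary: each lesion's stage deltas are the defaults
    scaled by a seeded uniform factor in [1 - delta_jitter, 1 + delta_jitter],
    emulating between-lesion variability.  Placement draws from voxels whose
    full lesion sphere fits inside the cortical shell.
    """
    probe = PhantomSpec(seed=seed, **overrides)
    compartments = make_compartments(probe.grid_shape, probe.voxel_size_mm)
    cortex = compartments == GM
    edt = cortical_depth_mm(cortex, probe.voxel_size_mm)
    candidates = np.argwhere(edt > diameter_mm / 2.0)
    if candidates.shape[0] < n_lesions:
        raise ValueError("cortical shell too thin for requested lesions")

    rng = np.random.default_rng(seed)
    order = rng.permutation(candidates.shape[0])
    vox = np.asarray(probe.voxel_size_mm)
    chosen: List[np.ndarray] = []
    for idx in order:
        c = candidates[idx]
        if all(np.linalg.norm((c - prev) * vox) >= min_separation_mm
               for prev in chosen):
            chosen.append(c)
        if len(chosen) == n_lesions:
            break
    if len(chosen) < n_lesions:
        raise ValueError(
            f"could only place {len(chosen)} of {n_lesions} lesions with "
            f"{min_separation_mm} mm separation")

    onset_choices = list(range(2, probe.n_visits - 2))
    lesions = []
    for k, c in enumerate(chosen):
        scale = 1.0 + delta_jitter * (2 * rng.random() - 1)
        deltas = {
            "acute": {p: scale * d for p, d in ACUTE_DELTAS.items()},
            "post": {p: scale * d for p, d in POST_DELTAS.items()},
        }
        lesions.append(LesionSpec(
            center=tuple(int(x) for x in c), diameter_mm=diameter_mm,
            onset_visit=onset_choices[k % len(onset_choices)],
            stage_deltas=deltas))
    return PhantomSpec(seed=seed, lesion_specs=lesions, **overrides)
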