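"""Voxelwise relaxometry from multi-echo magnitude data.

The workhorse estimator is a closed-form trapezoidal-rule R2* map: for a
mono-exponential decay dS/dTE = -R2*.S, integrating from the first to the
last echo gives S_1 - S_N = R2* . integral(S dTE), so

    R2* = (S_1 - S_N) / trapz(S, TE)

with the integral approximated by the trapezoidal rule over the sampled
echoes.  A nonlinear least-squares mono-exponential fit and a log-linear
R2 fit (for spin-echo series) are provided alongside; the nonlinear fit
doubles as an independent oracle for the closed form in the test suite.

Unit convention: echo times are milliseconds at every interface and are
converted to seconds internally, so all relaxation rates come out in s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EchoSeries",
    "QuantitativeMap",
    "r2star_trapz",
    "fit_monoexp_ls",
    "r2_loglinear",
    "PARAMETER_UNITS",
]

#: Canonical units per quantitative parameter.
PARAMETER_UNITS = {
    "r1": "s^-1",
    "r2": "s^-1",
    "r2star": "s^-1",
    "dwi_b1000": "a.u.",
    "dwi_b3000": "a.u.",
    "md": "mm^2/s",
    "fa": "1",
    "swi": "a.u.",
}


@dataclass
class EchoSeries:
    """A multi-echo acquisition for one visit.

    Parameters
    ----------
    magnitude : ndarray, shape (x, y, z, n_echoes)
        Nonnegative magnitude images, arbitrary units.
    phase : ndarray, same shape
        Phase images in radians, wrapped to (-pi, pi].
    echo_times_ms : array-like
        Strictly increasing, positive echo times in milliseconds.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in millimetres.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    echo_times_ms: np.ndarray
    voxel_size_mm: tuple = (0.8, 0.8, 2.0)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.magnitude.ndim != 4:
            raise ValueError("magnitude must be 4D (x, y, z, echo)")
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        n = self.echo_times_ms.size
        if n < 2:
            raise ValueError("an echo series needs at least 2 echoes")
        if self.magnitude.shape[-1] != n:
            raise ValueError(
                f"echo axis length {self.magnitude.shape[-1]} does not match "
                f"{n} echo times"
            )
        if np.any(np.diff(self.echo_times_ms) <= 0) or self.echo_times_ms[0] < 0:
            raise ValueError("echo times must be nonnegative and strictly increasing")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_ms.size)

    @property
    def grid_shape(self) -> tuple:
        return self.magnitude.shape[:3]


@dataclass
class QuantitativeMap:
    """A voxelwise parameter volume with units and a validity mask."""

    values: np.ndarray
    parameter: str
    units: str = ""
    voxel_size_mm: tuple = (0.8, 0.8, 2.0)
    validity_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("QuantitativeMap values must be 3D")
        if not self.units:
            self.units = PARAMETER_UNITS.get(self.parameter, "a.u.")
        if self.validity_mask is None:
            self.validity_mask = np.isfinite(self.values)
        else:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != self.values.shape:
                raise ValueError("validity_mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.validity_mask])):
            raise ValueError("non-finite values inside validity_mask")


def r2star_trapz(series: EchoSeries) -> QuantitativeMap:
    """Closed-form trapezoidal-rule R2* estimate from a multi-echo series.

    Per voxel, R2* = (S_1 - S_N) / sum_i dTE_i (S_i + S_{i+1}) / 2 with
    echo times in seconds, so the output is in s^-1.  Voxels where the
    trapezoidal integral vanishes (e.g. zero signal) are excluded from the
    validity mask; negative estimates (S_N > S_1, noise-driven) are kept
    as values but remain subject to downstream acceptance windows.
    """
    te_s = series.echo_times_ms / 1000.0
    sig = series.magnitude
    numer = sig[..., 0] - sig[..., -1]
    denom = np.trapezoid(sig, x=te_s, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2s = numer / denom
    valid = (denom != 0) & np.isfinite(r2s)
    r2s = np.where(valid, r2s, np.nan)
    return QuantitativeMap(
        r2s, "r2star", voxel_size_mm=series.voxel_size_mm, validity_mask=valid
    )


def fit_monoexp_ls(series: EchoSeries, max_iter: int = 100, tol: float = 1e-12) -> QuantitativeMap:
    """Per-voxel nonlinear least-squares fit of S(TE) = S0 exp(-R TE).

    Gauss-Newton with step halving, initialised from the log-linear
    solution.  Non-converged voxels are dropped from the validity mask
    (counted in a warning).  Intended as an accuracy reference; the
    trapezoidal closed form is the production estimator.
    """
    if series.n_echoes < 3:
        raise ValueError("nonlinear fit needs at least 3 echoes")
    te = series.echo_times_ms / 1000.0
    shape = series.grid_shape
    sig = series.magnitude.reshape(-1, series.n_echoes)

    # Log-linear initialisation on positive signals.
    pos = np.all(sig > 0, axis=1)
    r0 = np.zeros(sig.shape[0])
    s0 = np.maximum(sig[:, 0], 1e-30)
    if pos.any():
        logs = np.log(sig[pos])
        slope, intercept = _lsq_line(te, logs)
        r0[pos] = -slope
        s0[pos] = np.exp(intercept)

    r, a = r0.copy(), s0.copy()
    converged = np.zeros(sig.shape[0], dtype=bool)
    failed = np.zeros(sig.shape[0], dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(~converged & ~failed)
        if idx.size == 0:
            break
        e = np.exp(-np.outer(r[idx], te))
        resid = sig[idx] - a[idx, None] * e
        # Jacobian columns: d/dS0 = e ; d/dR = -S0 * TE * e
        j_r = -a[idx, None] * te[None, :] * e
        g11 = np.einsum("ij,ij->i", e, e)
        g12 = np.einsum("ij,ij->i", e, j_r)
        g22 = np.einsum("ij,ij->i", j_r, j_r)
        b1 = np.einsum("ij,ij->i", e, resid)
        b2 = np.einsum("ij,ij->i", j_r, resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            det = g11 * g22 - g12 * g12
            da = (g22 * b1 - g12 * b2) / det
            dr = (g11 * b2 - g12 * b1) / det
        bad = ~(np.isfinite(da) & np.isfinite(dr))
        da[bad] = 0.0
        dr[bad] = 0.0
        a[idx] += da
        r[idx] += dr
        small = np.hypot(da, dr) < tol * (1.0 + np.abs(r[idx]))
        converged[idx[small & ~bad]] = True
        failed[idx[bad]] = True

    failed |= ~np.isfinite(r)
    n_bad = int(np.sum(failed | (~converged & ~failed)))
    if n_bad:
        warnings.warn(f"monoexp fit: {n_bad} voxel(s) did not converge; dropped")
    valid = converged & np.isfinite(r) & ~failed
    out = np.where(valid, r, np.nan).reshape(shape)
    return QuantitativeMap(
        out, "r2star", units="s^-1", voxel_size_mm=series.voxel_size_mm,
        validity_mask=valid.reshape(shape),
    )


def r2_loglinear(se_series: EchoSeries) -> QuantitativeMap:
    """R2 map as the least-squares slope of -ln S versus TE (s^-1).

    Voxels with any nonpositive magnitude are excluded from the validity
    mask.  This is the default R2 fit for multi-echo spin-echo data; the
    nonlinear mono-exponential fit is available as a cross-check.
    """
    te = se_series.echo_times_ms / 1000.0
    sig = se_series.magnitude.reshape(-1, se_series.n_echoes)
    pos = np.all(sig > 0, axis=1)
    r = np.full(sig.shape[0], np.nan)
    if pos.any():
        slope, _ = _lsq_line(te, np.log(sig[pos]))
        r[pos] = -slope
    shape = se_series.grid_shape
    return QuantitativeMap(
        r.reshape(shape), "r2", voxel_size_mm=se_series.voxel_size_mm,
        validity_mask=pos.reshape(shape),
    )


def _lsq_line(x: np.ndarray, ys: np.ndarray):
    """Closed-form simple linear regression of each row of ys on x."""
    xm = x.mean()
    xc = x - xm
    denom = np.dot(xc, xc)
    slope = ys @ xc / denom
    intercept = ys.mean(axis=1) - slope * xm
    return slope, intercept
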