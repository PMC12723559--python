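"""Analytic four-sphere volume-conductor EEG forward model.

Maps a current dipole inside the innermost (brain) shell to the electric
potential on the scalp surface of a four-shell spherical head model
(gray matter, CSF, skull, scalp). The solution expands the dipole source
in Legendre harmonics and, for each order n, solves the radial two-point
boundary-value problem across the shells (continuity of potential and of
radial current density at each interface, zero radial current at the outer
scalp surface) as a small linear system with per-shell-normalized radial
basis functions, which keeps the system well conditioned at high order.

Conventions
-----------
* Geometry in mm, conductivities in S/m, dipole moments in nA·μm,
  potentials in μV.
* The dipole is split into radial (along its position vector) and
  tangential components; the tangential reference direction is chosen in
  the dipole-electrode plane, so the azimuthal factor is 1.

A closed-form solution for a dipole in a homogeneous conducting sphere
(derived by generating-function summation of the point-source series, with
the dipole obtained as a source-position derivative) is provided as an
independent cross-check: with all four conductivities equal the shell
model must reduce to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, lpmv

__all__ = [
    "FourSphereModel",
    "EEGTrace",
    "scalp_potential",
    "project_dipole",
    "homogeneous_sphere_potential",
]

_MM = 1e-3  # mm → m
_NAUM = 1e-15  # nA·μm → A·m


@dataclass(frozen=True)
class FourSphereModel:
    """Concentric-shell head model (brain, CSF, skull, scalp)."""

    radii_mm: tuple = (79.0, 80.0, 85.0, 90.0)
    conductivities: tuple = (0.047, 1.71, 0.02, 0.41)  # S/m
    max_order: int = 2000
    rtol: float = 1e-12

    def __post_init__(self) -> None:
        r = self.radii_mm
        if not all(r[i] < r[i + 1] for i in range(3)):
            raise ValueError("shell radii must be strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")


@dataclass
class EEGTrace:
    """Scalp-potential time series in μV at one electrode."""

    values: np.ndarray  # μV
    fs: float  # Hz
    electrode_mm: tuple = (0.0, 0.0, 90.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EEG trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


def _shell_transfer(model: FourSphereModel, n_orders: int) -> np.ndarray:
    """Transfer coefficients T_n mapping unit source strength to the
    order-n potential coefficient on the scalp surface.

    For each order n, unknowns are the homogeneous-solution coefficients
    [A1, A2, B2, A3, B3, A4, B4] with shell s potential
    ``A_s (r/r_s)^n + B_s (r_{s-1}/r)^(n+1)`` (shell 1 has no interior
    singular term beyond the source itself, whose boundary trace is
    normalized to 1). Depends only on geometry/conductivity, so results
    are cached on the model instance.
    """
    cache = getattr(model, "_transfer_cache", None)
    if cache is not None and cache.size >= n_orders:
        return cache[:n_orders]
    r1, r2, r3, r4 = (r * _MM for r in model.radii_mm)
    s1, s2, s3, s4 = model.conductivities
    T = np.empty(n_orders)
    for i in range(n_orders):
        n = i + 1
        q12 = (r1 / r2) ** n
        q23 = (r2 / r3) ** n
        q34 = (r3 / r4) ** n
        p12 = (r1 / r2) ** (n + 1)
        p23 = (r2 / r3) ** (n + 1)
        p34 = (r3 / r4) ** (n + 1)
        M = np.zeros((7, 7))
        rhs = np.zeros(7)
        # interface r1: potential continuity, then current continuity
        M[0] = [1.0, -q12, -1.0, 0, 0, 0, 0]
        rhs[0] = -1.0  # unit source boundary trace (rz/r1)^(n+1) := 1
        M[1] = [s1 * n, -s2 * n * q12, s2 * (n + 1), 0, 0, 0, 0]
        rhs[1] = s1 * (n + 1)
        # interface r2
        M[2] = [0, 1.0, p12, -q23, -1.0, 0, 0]
        M[3] = [0, s2 * n, -s2 * (n + 1) * p12, -s3 * n * q23, s3 * (n + 1), 0, 0]
        # interface r3
        M[4] = [0, 0, 0, 1.0, p23, -q34, -1.0]
        M[5] = [0, 0, 0, s3 * n, -s3 * (n + 1) * p23, -s4 * n * q34, s4 * (n + 1)]
        # outer surface r4: zero radial current
        M[6] = [0, 0, 0, 0, 0, n, -(n + 1) * p34]
        sol = np.linalg.solve(M, rhs)
        A4, B4 = sol[5], sol[6]
        T[i] = A4 + B4 * p34
    object.__setattr__(model, "_transfer_cache", T)
    return T


def scalp_potential(
    model: FourSphereModel,
    dipole_moment: np.ndarray,
    dipole_pos_mm: np.ndarray,
    electrode_pos_mm: np.ndarray,
) -> float:
    """Potential (μV) at a scalp electrode from a current dipole.

    Parameters
    ----------
    dipole_moment : length-3 vector, nA·μm.
    dipole_pos_mm : dipole location, mm from the head-model center; must be
        inside the brain shell.
    electrode_pos_mm : electrode location on the scalp surface (radius
        within 1% of the outer shell radius; projected onto it).
    """
    p = np.asarray(dipole_moment, dtype=float) * _NAUM
    rd = np.asarray(dipole_pos_mm, dtype=float) * _MM
    re = np.asarray(electrode_pos_mm, dtype=float) * _MM
    r1 = model.radii_mm[0] * _MM
    r4 = model.radii_mm[3] * _MM
    rz = np.linalg.norm(rd)
    if rz >= r1:
        raise ValueError("dipole must lie strictly inside the brain shell")
    if abs(np.linalg.norm(re) - r4) > 0.01 * r4:
        raise ValueError("electrode must lie on the scalp surface")
    re = re / np.linalg.norm(re) * r4

    # local frame: ẑ' along the dipole position (or along p if centered)
    if rz > 1e-12 * r1:
        zhat = rd / rz
    else:
        rz = 0.0
        norm_p = np.linalg.norm(p)
        zhat = p / norm_p if norm_p > 0 else np.array([0.0, 0.0, 1.0])
    e_hat = re / r4
    cosg = float(np.clip(e_hat @ zhat, -1.0, 1.0))
    tang = e_hat - cosg * zhat
    tnorm = np.linalg.norm(tang)
    xhat = tang / tnorm if tnorm > 1e-12 else np.zeros(3)

    p_rad = float(p @ zhat)
    p_tan = float(p @ xhat)

    sigma1 = model.conductivities[0]
    pref = 1.0 / (4.0 * np.pi * sigma1 * r1**2)
    x = rz / r1  # < 1

    total = 0.0
    block = 50
    n_done = 0
    converged = False
    while n_done < model.max_order:
        n_hi = min(n_done + block, model.max_order)
        T = _shell_transfer(model, n_hi)
        ns = np.arange(n_done + 1, n_hi + 1)
        radial_fac = x ** (ns - 1)  # (rz/r1)^(n-1); 0^0 = 1
        Pn = eval_legendre(ns, cosg)
        Pn1 = lpmv(1, ns, cosg)
        terms = (
            T[n_done:n_hi]
            * radial_fac
            * pref
            * (p_rad * ns * Pn - p_tan * Pn1)
        )
        total += terms.sum()
        n_done = n_hi
        tail = np.abs(terms[-5:]).max() if terms.size >= 5 else np.abs(terms).max()
        if tail <= model.rtol * max(abs(total), 1e-300) and n_done >= 20:
            converged = True
            break
    if not converged and rz > 0:
        raise RuntimeError(
            f"four-sphere series did not converge within {model.max_order} terms"
        )
    return total * 1e6  # V → μV


def project_dipole(
    trace,
    model: FourSphereModel,
    dipole_pos_mm=(0.0, 0.0, 78.0),
    electrode_pos_mm=(0.0, 0.0, 90.0),
    axis=(0.0, 0.0, 1.0),
) -> EEGTrace:
    """Project a scalar dipole-moment time series to a scalp EEG trace.

    The forward model is linear and time-invariant, so the trace maps
    through a single gain: the potential per unit dipole moment along
    ``axis`` at the given position.
    """
    values = np.asarray(trace.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("dipole trace contains non-finite samples")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    gain = scalp_potential(model, axis, dipole_pos_mm, electrode_pos_mm)
    return EEGTrace(values=gain * values, fs=trace.fs, electrode_mm=tuple(electrode_pos_mm))


def homogeneous_sphere_potential(
    dipole_moment,
    dipole_pos_mm,
    electrode_pos_mm,
    sigma: float,
    radius_mm: float,
    h_mm: float = 1e-4,
) -> float:
    """Closed-form potential (μV) of a dipole in a homogeneous sphere.

    For a point current source at radius b inside an insulated sphere of
    radius R, the surface potential series
    ``Σ (2n+1)/n (b/R)^n P_n`` sums in closed form via the Legendre
    generating function to ``2/d + ln(2 / (1 - x c + d))`` with
    ``x = b/R``, ``c = cos γ``, ``d = sqrt(1 - 2 x c + x²)``. The dipole
    potential is the directional derivative with respect to the source
    position (central differences with step ``h_mm``), giving an oracle
    independent of the shell solver.
    """
    p = np.asarray(dipole_moment, dtype=float) * _NAUM
    rd = np.asarray(dipole_pos_mm, dtype=float) * _MM
    re = np.asarray(electrode_pos_mm, dtype=float) * _MM
    R = radius_mm * _MM
    re = re / np.linalg.norm(re) * R
    h = h_mm * _MM

    def G(src: np.ndarray) -> float:
        b = np.linalg.norm(src)
        xf = b / R
        c = float(re @ src / (np.linalg.norm(re) * b)) if b > 0 else 1.0
        d = np.sqrt(max(1.0 - 2.0 * xf * c + xf * xf, 1e-300))
        return (2.0 / d + np.log(2.0 / (1.0 - xf * c + d))) / R

    grad = np.zeros(3)
    for k in range(3):
        dv = np.zeros(3)
        dv[k] = h
        grad[k] = (G(rd + dv) - G(rd - dv)) / (2.0 * h)
    return float(p @ grad) / (4.0 * np.pi * sigma) * 1e6
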