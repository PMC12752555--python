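"""Polymer elasticity models for tethered two-state protein constructs.

The mechanically unfolded polypeptide is described by the Marko-Siggia
worm-like chain (WLC) interpolation formula; the folded domain is treated
as a single rigid freely-jointed-chain (FJC) segment whose length defaults
to the native N-to-C terminal distance.  The unfolding step size observed
in a bead-height trace is the difference between the two extensions,

    delta_x(f) = z_wlc(f; L_contour) - z_fjc(f; b_native),

and the reversible work of stretching, integral of delta_x df, sets the
force dependence of the folding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "KBT_ROOM",
    "ElasticityParams",
    "InvalidParameterError",
    "QuadratureError",
    "wlc_force",
    "wlc_extension",
    "fjc_extension",
    "step_size",
    "stretch_free_energy",
    "StepSizeTable",
]

#: Thermal energy at room temperature, pN*nm.
KBT_ROOM = 4.1


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is outside its admissible range."""


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to converge."""


@dataclass(frozen=True)
class ElasticityParams:
    """Elastic parameters of one tethered construct.

    Parameters
    ----------
    persistence_length : float
        WLC persistence length of the unfolded chain, nm.
    contour_per_residue : float
        Contour length gained per unfolded residue, nm.
    n_released_residues : int
        Number of residues that gain chain contour upon unfolding.
    nc_distance_native : float
        Distance between the terminal alpha-carbons of the folded
        domain, nm.  Also the default FJC segment length.
    kuhn_length_native : float or None
        Length of the single FJC segment representing the folded domain,
        nm.  ``None`` means "use ``nc_distance_native``".
    thermal_energy : float
        k_B T in pN*nm.
    """

    persistence_length: float = 0.8
    contour_per_residue: float = 0.38
    n_released_residues: int = 70
    nc_distance_native: float = 1.3
    kuhn_length_native: float | None = None
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise InvalidParameterError("persistence_length must be > 0")
        if self.contour_per_residue <= 0:
            raise InvalidParameterError("contour_per_residue must be > 0")
        if self.n_released_residues < 1:
            raise InvalidParameterError("n_released_residues must be >= 1")
        if self.nc_distance_native <= 0:
            raise InvalidParameterError("nc_distance_native must be > 0")
        if self.kuhn_length_native is not None and self.kuhn_length_native <= 0:
            raise InvalidParameterError("kuhn_length_native must be > 0")
        if self.thermal_energy <= 0:
            raise InvalidParameterError("thermal_energy must be > 0")
        if self.contour_length <= self.nc_distance_native:
            raise InvalidParameterError(
                "released contour length must exceed the native N-C distance"
            )

    @property
    def contour_length(self) -> float:
        """Contour length released on unfolding, nm."""
        return self.n_released_residues * self.contour_per_residue

    @property
    def native_segment(self) -> float:
        """FJC segment length of the folded domain, nm."""
        if self.kuhn_length_native is not None:
            return self.kuhn_length_native
        return self.nc_distance_native

    def with_(self, **kwargs) -> "ElasticityParams":
        return replace(self, **kwargs)


def wlc_force(extension, contour_length: float, params: ElasticityParams):
    """Marko-Siggia interpolation force law of the WLC.

    f(z) = (kT/Lp) * [ 1/(4 (1 - z/Lc)^2) - 1/4 + z/Lc ]
    """
    if contour_length <= 0:
        raise InvalidParameterError("contour_length must be > 0")
    x = np.asarray(extension, dtype=float) / contour_length
    if np.any(x < 0) or np.any(x >= 1):
        raise InvalidParameterError("extension must lie in [0, contour_length)")
    kbt = params.thermal_energy
    lp = params.persistence_length
    out = (kbt / lp) * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
    return out if out.ndim else float(out)


def _wlc_extension_scalar(force: float, contour_length: float,
                          params: ElasticityParams) -> float:
    if force < 0:
        raise InvalidParameterError("force must be >= 0")
    if force == 0.0:
        return 0.0
    phi = force * params.persistence_length / params.thermal_energy

    def g(x: float) -> float:
        return 0.25 / (1.0 - x) ** 2 - 0.25 + x - phi

    # g is strictly increasing on [0, 1); bracket just below the singularity
    hi = 1.0 - 1e-14
    if g(hi) <= 0:  # force beyond float resolution of the asymptote
        return contour_length * hi
    x = brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return contour_length * x


def wlc_extension(force, contour_length: float, params: ElasticityParams):
    """Extension of a worm-like chain at a given force (inverse Marko-Siggia).

    Strictly increasing in force, 0 at zero force, approaches
    ``contour_length`` from below at large force.  Accepts scalars or
    arrays of forces.
    """
    if params.persistence_length <= 0 or contour_length <= 0:
        raise InvalidParameterError("contour and persistence length must be > 0")
    f = np.asarray(force, dtype=float)
    if f.ndim == 0:
        return _wlc_extension_scalar(float(f), contour_length, params)
    return np.array(
        [_wlc_extension_scalar(fi, contour_length, params) for fi in f.ravel()]
    ).reshape(f.shape)


def fjc_extension(force, segment_length: float, params: ElasticityParams):
    """Extension of a single freely-jointed (rigid) segment under force.

    z(f) = L * [coth(f b / kT) - kT/(f b)] with b = L = segment_length,
    i.e. the Langevin orientation average of one rigid rod.  Continuous at
    f -> 0 with limit 0.
    """
    if segment_length <= 0:
        raise InvalidParameterError("segment_length must be > 0")
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("force must be >= 0")
    a = f * segment_length / params.thermal_energy
    # Langevin function with a small-argument series to avoid 0/0
    small = a < 1e-4
    with np.errstate(over="ignore", invalid="ignore"):
        lang = np.where(small, a / 3.0 - a**3 / 45.0,
                        1.0 / np.tanh(np.where(small, 1.0, a))
                        - 1.0 / np.where(small, 1.0, a))
    out = segment_length * lang
    return float(out) if out.ndim == 0 else out


def step_size(force, params: ElasticityParams):
    """Unfolding step size delta_x(f): unfolded-chain WLC extension minus
    folded-domain FJC extension, nm."""
    f = np.asarray(force, dtype=float)
    z_u = wlc_extension(f, params.contour_length, params)
    z_n = fjc_extension(f, params.native_segment, params)
    out = np.asarray(z_u) - np.asarray(z_n)
    return float(out) if out.ndim == 0 else out


def stretch_free_energy(force: float, params: ElasticityParams) -> float:
    """Reversible stretching work integral_0^f delta_x(f') df', in k_B T.

    This is the amount by which force tilts the unfolded state down
    relative to the folded state; it vanishes at zero force and is
    strictly increasing.
    """
    if force < 0:
        raise InvalidParameterError("force must be >= 0")
    if force == 0.0:
        return 0.0
    val, err = quad(lambda f: step_size(f, params), 0.0, force, limit=200)
    if not np.isfinite(val) or err > max(1e-8, 1e-6 * abs(val)):
        raise QuadratureError(
            f"stretching-energy quadrature did not converge: value={val}, "
            f"abserr={err}, force={force}"
        )
    return val / params.thermal_energy


class StepSizeTable:
    """Fast linear-interpolation table of step_size(f) on a dense grid.

    Used by the trajectory simulator where delta_x must be evaluated at
    every sample of a force ramp; interpolation error on the default
    0.02 pN grid is far below measurement noise.
    """

    def __init__(self, params: ElasticityParams, f_max: float = 65.0,
                 df: float = 0.02):
        self.params = params
        self._grid = np.arange(0.0, f_max + df, df)
        self._vals = step_size(self._grid, params)

    def __call__(self, force):
        return np.interp(force, self._grid, self._vals)
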