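"""Per-construct physical models of the tethered protein.

A ``ConstructModel`` bundles everything the simulator and the landscape
reconstruction need for one protein variant: the Bell rate laws for the
two unfolding regimes (below/above the regime-crossover force) and for
folding, the elasticity block, and the attempt rate used to convert
zero-force rate constants into barrier heights.

Default models for the three engineered variants (LE-CSP-GS, KL-CSP-GS,
KL-CSP-LE) and the untagged protein are built from the published fit
values where available; quantities the source does not state (the
high-force zero-force rate, the folding distance, the folding zero-force
rate) are derived from explicit, documented conventions:

* k_u,1^0 is set by continuity of the piecewise unfolding law at the
  regime-crossover force (10 pN);
* the folding distance x_f defaults to 2.5 nm;
* k_f^0 is chosen so that the coexistence force f_c reproduces the
  construct's equilibrium folding free energy dG0 through the
  stretching-work relation dG0 = G_stretch(f_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .kinetics import FOLD, UNFOLD, BellParams, bell_rate
from .polymer import ElasticityParams, InvalidParameterError, stretch_free_energy

__all__ = [
    "RegimeFits",
    "ConstructModel",
    "REGIME_CROSSOVER_PN",
    "DEFAULT_ATTEMPT_RATE",
    "DEFAULT_FOLDING_X",
    "default_construct",
    "default_constructs",
    "CONSTRUCT_IDS",
]

#: Force separating the low- and high-force unfolding regimes, pN.
REGIME_CROSSOVER_PN = 10.0

#: Intrinsic attempt rate k*, 1/s.
DEFAULT_ATTEMPT_RATE = 1e6

#: Default folding transition distance, nm (declared convention).
DEFAULT_FOLDING_X = 2.5

CONSTRUCT_IDS = ("LE-CSP-GS", "KL-CSP-GS", "KL-CSP-LE", "native")


@dataclass(frozen=True)
class RegimeFits:
    """Bell parameters per force regime for one construct."""

    low_force: BellParams
    high_force: BellParams
    folding: BellParams
    construct_id: str = ""

    def __post_init__(self) -> None:
        if self.low_force.sign != UNFOLD or self.high_force.sign != UNFOLD:
            raise InvalidParameterError("unfolding branches must have sign=+1")
        if self.folding.sign != FOLD:
            raise InvalidParameterError("folding branch must have sign=-1")


@dataclass(frozen=True)
class ConstructModel:
    """Complete kinetic + elastic model of one tethered construct."""

    construct_id: str
    regime_fits: RegimeFits
    elasticity: ElasticityParams
    attempt_rate: float = DEFAULT_ATTEMPT_RATE
    ramp_fit: BellParams | None = None
    regime_crossover: float = REGIME_CROSSOVER_PN

    def __post_init__(self) -> None:
        max_k0 = max(self.regime_fits.low_force.k0,
                     self.regime_fits.high_force.k0,
                     self.regime_fits.folding.k0)
        if self.attempt_rate < max_k0:
            raise InvalidParameterError(
                "attempt_rate must be >= every fitted k0")

    def unfolding_rate(self, force):
        """Piecewise Bell unfolding rate: low-force branch below the
        crossover, high-force branch at and above it."""
        f = np.asarray(force, dtype=float)
        k_lo = bell_rate(f, self.regime_fits.low_force,
                         self.elasticity.thermal_energy)
        k_hi = bell_rate(f, self.regime_fits.high_force,
                         self.elasticity.thermal_energy)
        out = np.where(f < self.regime_crossover, k_lo, k_hi)
        return float(out) if out.ndim == 0 else out

    def folding_rate(self, force):
        return bell_rate(force, self.regime_fits.folding,
                         self.elasticity.thermal_energy)

    def with_(self, **kwargs) -> "ConstructModel":
        return replace(self, **kwargs)


# Published fit values per construct: low-force (k_u,2^0, x_u,2),
# high-force x_u,1, ramp-distribution (k_u^0, x_u), and equilibrium dG0
# (k_B T).  The untagged protein is kinetically indistinguishable from
# LE-CSP-GS and reuses its values with 66 released residues.
_PRINTED = {
    "LE-CSP-GS": dict(k_u2=3.0e-2, x_u2=0.9, x_u1=0.6,
                      ramp_k0=2.4e-2, ramp_x=0.7, dg0=8.9, n_released=70),
    "KL-CSP-GS": dict(k_u2=4.9e-3, x_u2=1.4, x_u1=0.5,
                      ramp_k0=1.2e-2, ramp_x=0.6, dg0=12.4, n_released=70),
    "KL-CSP-LE": dict(k_u2=2.2e-3, x_u2=1.7, x_u1=0.5,
                      ramp_k0=1.2e-2, ramp_x=0.9, dg0=13.6, n_released=70),
    "native": dict(k_u2=3.0e-2, x_u2=0.9, x_u1=0.6,
                   ramp_k0=2.4e-2, ramp_x=0.7, dg0=8.9, n_released=66),
}


def _critical_force_for_dg0(dg0: float, elasticity: ElasticityParams) -> float:
    """Solve G_stretch(f_c) = dG0 (both in k_B T) for f_c."""
    return brentq(lambda f: stretch_free_energy(f, elasticity) - dg0,
                  0.1, 30.0, xtol=1e-10)


def default_construct(construct_id: str,
                      elasticity: ElasticityParams | None = None,
                      folding_x: float = DEFAULT_FOLDING_X,
                      attempt_rate: float = DEFAULT_ATTEMPT_RATE,
                      crossover: float = REGIME_CROSSOVER_PN) -> ConstructModel:
    """Build the default model for one construct id."""
    if construct_id not in _PRINTED:
        raise KeyError(f"unknown construct {construct_id!r}; "
                       f"choose from {CONSTRUCT_IDS}")
    p = _PRINTED[construct_id]
    if elasticity is None:
        elasticity = ElasticityParams(n_released_residues=p["n_released"])
    kbt = elasticity.thermal_energy
    low = BellParams(k0=p["k_u2"], x=p["x_u2"], sign=UNFOLD)
    # high-force k0 by continuity of the piecewise law at the crossover
    k_u1 = p["k_u2"] * float(np.exp(crossover * (p["x_u2"] - p["x_u1"]) / kbt))
    high = BellParams(k0=k_u1, x=p["x_u1"], sign=UNFOLD)
    # folding k0 from the equilibrium free energy via the coexistence force
    f_c = _critical_force_for_dg0(p["dg0"], elasticity)
    k_at_fc = bell_rate(f_c, low, kbt)
    k_f0 = k_at_fc * float(np.exp(f_c * folding_x / kbt))
    fold = BellParams(k0=k_f0, x=folding_x, sign=FOLD)
    return ConstructModel(
        construct_id=construct_id,
        regime_fits=RegimeFits(low_force=low, high_force=high, folding=fold,
                               construct_id=construct_id),
        elasticity=elasticity,
        attempt_rate=attempt_rate,
        ramp_fit=BellParams(k0=p["ramp_k0"], x=p["ramp_x"], sign=UNFOLD),
        regime_crossover=crossover,
    )


def default_constructs() -> dict[str, ConstructModel]:
    """Default models for all four constructs."""
    return {cid: default_construct(cid) for cid in CONSTRUCT_IDS}
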