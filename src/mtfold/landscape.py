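"""Zero-force free-energy landscape along the N-to-C distance coordinate.

The landscape is summarized by its four stationary points: the native
minimum N, the two barriers TS1 (high-force regime) and TS2 (low-force
regime), and the unfolded reference U.  Positions come from the native
N-C distance plus the fitted transition distances; energies come from
the folding free energy dG0 and the barrier heights implied by the
zero-force rate constants and the attempt rate.

Sign convention: U is the zero of energy and N sits at -dG0, so a more
stable construct has a deeper (more negative) native well.

Two independent routes to dG0 are provided: a one-parameter fit of the
force-dependent unfolding probability, and the stretching work at the
coexistence force of the fitted rate laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .constructs import ConstructModel
from .kinetics import BellParams, barrier_height, critical_force
from .polymer import ElasticityParams, InvalidParameterError, stretch_free_energy

__all__ = [
    "LandscapeResult",
    "UnidentifiableError",
    "transition_state_positions",
    "landscape_energies",
    "fit_unfolding_probability",
    "delta_g0_from_rates",
    "nc_distance_from_structure",
    "build_landscape",
]


class UnidentifiableError(RuntimeError):
    """The supplied data cannot pin down the requested parameter."""


@dataclass(frozen=True)
class LandscapeResult:
    """Stationary points of the reconstructed landscape."""

    construct_id: str
    positions: dict  # {"N","TS1","TS2","U"} -> nm
    energies: dict   # {"N","TS1","TS2","U"} -> k_B T (U = 0 reference)
    delta_g0: float
    critical_force: float

    def __post_init__(self) -> None:
        p = self.positions
        if not (p["N"] < p["TS1"] < p["TS2"]):
            raise InvalidParameterError(
                "positions must be ordered N < TS1 < TS2")

    def as_dict(self) -> dict:
        return {
            "construct": self.construct_id,
            "positions_nm": dict(self.positions),
            "energies_kBT": dict(self.energies),
            "delta_g0_kBT": self.delta_g0,
            "critical_force_pN": self.critical_force,
        }


def transition_state_positions(model: ConstructModel) -> dict:
    """N-C distances of N, TS1 and TS2.

    TS1 sits at the native distance plus the high-force transition
    distance; TS2 at the native distance plus the low-force one.
    """
    fits = model.regime_fits
    if fits.low_force is None or fits.high_force is None:
        raise InvalidParameterError("both regime fits are required")
    nc = model.elasticity.nc_distance_native
    return {
        "N": nc,
        "TS1": nc + fits.high_force.x,
        "TS2": nc + fits.low_force.x,
    }


def landscape_energies(model: ConstructModel, delta_g0: float) -> dict:
    """Energies (k_B T, U = 0) of N, TS1 and TS2.

    N sits at -dG0; each barrier sits the corresponding zero-force
    barrier height ln(k*/k_u,i^0) above N.
    """
    fits = model.regime_fits
    e_n = -delta_g0
    return {
        "U": 0.0,
        "N": e_n,
        "TS1": e_n + barrier_height(fits.high_force.k0, model.attempt_rate),
        "TS2": e_n + barrier_height(fits.low_force.k0, model.attempt_rate),
    }


def fit_unfolding_probability(pu_data, elasticity: ElasticityParams,
                              ) -> tuple[float, float]:
    """Fit dG0 to force-dependent unfolding probabilities.

    Model: P_u(f) = 1 / (1 + exp(dG0 - G_stretch(f))), energies in k_B T.
    Returns (delta_g0, critical_force); by construction the fitted curve
    passes through 1/2 at the critical force.
    """
    data = [(float(f), float(p)) for f, p in pu_data]
    if len(data) < 4:
        raise InvalidParameterError("need P_u at >= 4 forces")
    forces = np.array([f for f, _ in data])
    pu = np.array([p for _, p in data])
    if np.all(pu < 0.02) or np.all(pu > 0.98):
        raise UnidentifiableError(
            "P_u data do not span the transition; dG0 is unidentifiable")
    g = np.array([stretch_free_energy(f, elasticity) for f in forces])

    def resid(theta):
        return 1.0 / (1.0 + np.exp(theta[0] - g)) - pu

    res = least_squares(resid, x0=[np.median(g)])
    dg0 = float(res.x[0])
    f_hi = max(forces.max() * 3.0, 30.0)
    fc = brentq(lambda f: stretch_free_energy(f, elasticity) - dg0,
                1e-6, f_hi, xtol=1e-10)
    return dg0, float(fc)


def delta_g0_from_rates(unfold: BellParams, fold: BellParams,
                        elasticity: ElasticityParams) -> float:
    """dG0 as the stretching work at the coexistence force.

    The folding free energy equals the reversible work of holding the
    released chain at the force where folding and unfolding rates cross.
    """
    fc = critical_force(unfold, fold, elasticity.thermal_energy)
    if fc <= 0:
        raise UnidentifiableError(
            "rate laws do not cross at positive force; no dG0")
    return stretch_free_energy(fc, elasticity)


def nc_distance_from_structure(path, chain_id: str = "A",
                               model_index: int = 0) -> float:
    """Terminal CA-to-CA distance of a structure, in nm.

    Uses the first model of multi-model (NMR) entries by default and
    reads both PDB and mmCIF files.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = str(path)
    parser = (MMCIFParser(QUIET=True) if path.endswith((".cif", ".mmcif"))
              else PDBParser(QUIET=True))
    structure = parser.get_structure("s", path)
    model = list(structure)[model_index]
    if chain_id not in model:
        raise InvalidParameterError(f"chain {chain_id!r} not found")
    residues = [r for r in model[chain_id] if r.id[0] == " "]
    if len(residues) < 2:
        raise InvalidParameterError(
            f"chain {chain_id!r} has fewer than 2 residues")
    for res, which in ((residues[0], "first"), (residues[-1], "last")):
        if "CA" not in res:
            raise InvalidParameterError(
                f"{which} residue {res.get_resname()}{res.id[1]} has no CA")
    d_ang = residues[0]["CA"] - residues[-1]["CA"]
    return float(d_ang) / 10.0


def build_landscape(model: ConstructModel,
                    delta_g0: float | None = None) -> LandscapeResult:
    """Assemble the landscape summary for one construct.

    When ``delta_g0`` is not given it is recomputed from the fitted rate
    laws via the coexistence-force route.
    """
    if delta_g0 is None:
        delta_g0 = delta_g0_from_rates(model.regime_fits.low_force,
                                       model.regime_fits.folding,
                                       model.elasticity)
    fc = critical_force(model.regime_fits.low_force,
                        model.regime_fits.folding,
                        model.elasticity.thermal_energy)
    positions = transition_state_positions(model)
    positions["U"] = positions["TS2"] + model.elasticity.contour_length / 4.0
    energies = landscape_energies(model, delta_g0)
    return LandscapeResult(construct_id=model.construct_id,
                           positions=positions, energies=energies,
                           delta_g0=float(delta_g0), critical_force=float(fc))
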