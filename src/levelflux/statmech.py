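"""State functions of the energy-level diagram.

The statistical description assigns every species j a chemical potential

    mu_j = G_j + kT ln N_j,

every transformation r an affinity (driving free energy)

    A_r = -dmu_r + deltaQ_r,   dmu_r = sum_products nu*mu - sum_substrates nu*mu,

and the system an entropy built from the probabilities of existence of its
entities.  All energies are in units set by ``spec.kT`` with k_B = 1.

Two entropy evaluations are provided.  The "stirling" mode follows the
per-population log-probability with the N ln N - N factorial approximation,

    S = sum_j [ N_j ln P1_j - (N_j ln N_j - N_j) ],

where ln P1_j collects, over the transformations producing j, the substrate
log-populations and the energy drop per event.  The "affinity" mode is the
compact per-transformation form

    S = sum_j N_j + (1/kT) sum_r A_r * W_r,

with W_r the product-side population of transformation r (stoichiometry
weighted).  For diagrams in which every species has at most one producing
transformation the two modes coincide identically; at thermodynamic balance
(all affinities zero) the affinity mode reduces to S = sum_j N_j exactly,
Boltzmann's count of entities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram import SystemSpec, SystemState, Transformation

__all__ = [
    "FreeEnergyTerm",
    "PotentialUndefinedError",
    "chemical_potential",
    "chemical_potentials",
    "entity_log_probability",
    "system_entropy",
    "transformation_free_energy",
    "affinities",
    "factor_phi",
]


class PotentialUndefinedError(ValueError):
    """Chemical potential requested for an extinct species (N = 0)."""


@dataclass(frozen=True)
class FreeEnergyTerm:
    """Free-energy bookkeeping of one transformation at one state.

    ``affinity = -delta_mu + deltaQ``: positive values drive net forward
    flux, zero marks thermodynamic balance of the channel.
    """

    transformation: int
    delta_mu: float
    deltaQ: float

    @property
    def affinity(self) -> float:
        return -self.delta_mu + self.deltaQ


def chemical_potential(state: SystemState, spec: SystemSpec, j: int) -> float:
    """mu_j = G_j + kT ln N_j; undefined (diverges) for N_j = 0."""
    N = state.populations[j]
    if N <= 0:
        raise PotentialUndefinedError(
            f"chemical potential of species '{spec.species[j].id}' undefined at N = {N}"
        )
    return spec.species[j].G + spec.kT * float(np.log(N))


def chemical_potentials(state: SystemState, spec: SystemSpec, floor: float = 0.0) -> np.ndarray:
    """Vector of mu_j.  With ``floor > 0`` extinct populations are clipped,
    giving the finite (very negative) potential used by the dynamics near
    N = 0; with floor = 0 extinct species get -inf."""
    N = np.asarray(state.populations, dtype=float)
    if floor > 0:
        N = np.maximum(N, floor)
    with np.errstate(divide="ignore"):
        return spec.energies() + spec.kT * np.log(N)


def _producing(spec: SystemSpec, j: int) -> list[tuple[int, Transformation, int]]:
    """Transformations with species j among their products (index, tr, coeff)."""
    sid = spec.species[j].id
    out = []
    for r, tr in enumerate(spec.transformations):
        if sid in tr.products:
            out.append((r, tr, tr.products[sid]))
    return out


def _delta_G(spec: SystemSpec, tr: Transformation) -> float:
    G = {s.id: s.G for s in spec.species}
    return sum(c * G[sid] for sid, c in tr.products.items()) - sum(
        c * G[sid] for sid, c in tr.substrates.items()
    )


def entity_log_probability(state: SystemState, spec: SystemSpec, j: int) -> float:
    """ln P1_j: the log-probability of existence of one j-entity.

    Summed over the transformations producing j: substrate log-populations
    plus the energy balance (-dG + deltaQ)/kT of the producing event.  A
    species with no producing transformation exists as given: ln P1_j then
    defaults to ln N_j (its own abundance).  Any extinct substrate makes
    existence impossible: -inf.
    """
    producers = _producing(spec, j)
    index = {s.id: i for i, s in enumerate(spec.species)}
    N = state.populations
    if not producers:
        Nj = N[j]
        return float(np.log(Nj)) if Nj > 0 else -np.inf
    total = 0.0
    for r, tr, _coeff in producers:
        for sid, c in tr.substrates.items():
            Nk = N[index[sid]]
            if Nk <= 0:
                return -np.inf  # a vital ingredient is missing: j could not exist
            total += c * float(np.log(Nk))
        total += (-_delta_G(spec, tr) + tr.deltaQ) / spec.kT
    return total


def transformation_free_energy(state: SystemState, spec: SystemSpec, r: int) -> FreeEnergyTerm:
    """Free-energy term of transformation r at the given state.

    delta_mu is products-minus-substrates, stoichiometry weighted; the
    affinity -delta_mu + deltaQ is positive when the channel is driven
    forward.  Extinct participants make the potential undefined.
    """
    tr = spec.transformations[r]
    index = {s.id: i for i, s in enumerate(spec.species)}
    mu = {}
    for sid in list(tr.substrates) + list(tr.products):
        mu[sid] = chemical_potential(state, spec, index[sid])
    delta_mu = sum(c * mu[sid] for sid, c in tr.products.items()) - sum(
        c * mu[sid] for sid, c in tr.substrates.items()
    )
    return FreeEnergyTerm(transformation=r, delta_mu=float(delta_mu), deltaQ=tr.deltaQ)


def affinities(
    state: SystemState,
    spec: SystemSpec,
    floor: float = 0.0,
    deltaQ: np.ndarray | None = None,
) -> np.ndarray:
    """Vector of affinities A_r = -dmu_r + deltaQ_r for all transformations.

    ``deltaQ`` overrides the specs' static quantum couplings (used by driven
    systems); ``floor`` clips populations before taking logs so the result
    stays finite near extinction.
    """
    mu = chemical_potentials(state, spec, floor=floor)
    S = spec.stoichiometry()
    if deltaQ is None:
        deltaQ = np.array([tr.deltaQ for tr in spec.transformations])
    with np.errstate(invalid="ignore"):
        return -(S.T @ mu) + deltaQ


def _product_weight(spec: SystemSpec, state: SystemState) -> np.ndarray:
    """W_r = stoichiometry-weighted product-side population of each channel."""
    index = {s.id: i for i, s in enumerate(spec.species)}
    W = np.zeros(spec.n_transformations)
    for r, tr in enumerate(spec.transformations):
        W[r] = sum(c * state.populations[index[sid]] for sid, c in tr.products.items())
    return W


def system_entropy(state: SystemState, spec: SystemSpec, mode: str = "affinity") -> float:
    """System entropy (k_B = 1) in the requested evaluation mode.

    mode "stirling": S = sum_j [N_j ln P1_j - (N_j ln N_j - N_j)].
    mode "exact":    S = sum_j [N_j ln P1_j - ln N_j!]  (lgamma, no
                     factorial approximation; their gap is the true
                     Stirling error and vanishes relatively as populations
                     grow).
    mode "affinity": S = sum_j N_j + (1/kT) sum_r A_r W_r.

    Extinct populations contribute zero (the N ln N -> 0 limit); a zero
    substrate of a producing channel of a populated species makes the
    stirling mode -inf (that population could not exist).
    """
    N = np.asarray(state.populations, dtype=float)
    if mode == "affinity":
        if not N.any():
            return 0.0
        mu = chemical_potentials(state, spec)
        S_mat = spec.stoichiometry()
        deltaQ = np.array([tr.deltaQ for tr in spec.transformations])
        # A_r * W_r with the 0 * (+-inf) -> 0 limit for extinct products
        total = float(np.sum(N))
        W = _product_weight(spec, state)
        for r in range(spec.n_transformations):
            contrib = 0.0
            dmu = 0.0
            ok = True
            idx = np.nonzero(S_mat[:, r])[0]
            for jj in idx:
                if N[jj] <= 0:
                    # extinct participant: its own weight is zero, but its
                    # divergent potential only matters if the product side
                    # still carries population
                    if W[r] == 0.0:
                        ok = False
                        break
                    dmu += S_mat[jj, r] * (-np.inf if S_mat[jj, r] else 0.0)
                else:
                    dmu += S_mat[jj, r] * mu[jj]
            if not ok or W[r] == 0.0:
                continue
            contrib = (-dmu + deltaQ[r]) * W[r] / spec.kT
            total += contrib
        return total
    if mode in ("stirling", "exact"):
        from scipy.special import gammaln

        total = 0.0
        for j in range(spec.n_species):
            Nj = N[j]
            if Nj <= 0:
                continue
            lnP1 = entity_log_probability(state, spec, j)
            ln_factorial = (
                Nj * np.log(Nj) - Nj if mode == "stirling" else float(gammaln(Nj + 1.0))
            )
            total += Nj * lnP1 - ln_factorial
        return float(total)
    raise ValueError(f"unknown entropy mode '{mode}' (use 'stirling', 'exact' or 'affinity')")


def factor_phi(state: SystemState, spec: SystemSpec, j: int | None = None):
    """phi_j = N_j exp(G_j / kT), the abundance factor of level j.

    With ``j`` omitted, returns the whole vector.  Near balance ln phi_j is
    linear in the composition c_j, the signature of the lognormal pattern.
    """
    N = np.asarray(state.populations, dtype=float)
    phi = N * np.exp(spec.energies() / spec.kT)
    if j is None:
        return phi
    return float(phi[j])
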