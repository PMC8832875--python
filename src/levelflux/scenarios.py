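"""Canonical seeded systems used by every demo and test.

Three named scenarios instantiate the energy-level diagram at increasing
complexity:

``two_level``
    Two species on levels G_A, G_B joined by one quantum-coupled
    isomerization: the minimal diagram, with a closed-form balance ratio.

``chain``
    An assembly cascade: j-mer + monomer -> (j+1)-mer for j = 1..M-1, with
    composition c_j = j.  Each step absorbs a quantum chosen to make
    assembly downhill by a stated margin (standard affinity +1 kT at unit
    populations by default).  Two variants:

    * closed (default): all matter starts in the monomer pool and relaxes
      to balance — the workhorse for conservation/entropy checks;
    * reservoir-fed (``source=True``): a slow elementally-balanced feed
      R -> monomer trickles matter out of a large reservoir while the fast
      assembly steps stay quasi-equilibrated.  Monomers and j-mers then
      co-grow with N_j tracking N_1**j — the regime in which the sigmoid
      cumulative curve, the power-law body and the constant free-energy
      factor alpha_j appear.

``driven``
    The chain with a time-periodic quantum coupling on its first
    transformation; amplitude in units of kT.  Zero amplitude reduces
    exactly to ``chain``.

All generators are deterministic given their parameters; ``make_random_system``
additionally draws valid random diagrams from a seed for property sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram import Species, SystemSpec, Transformation
from .dynamics import DriveSchedule

__all__ = [
    "make_two_level",
    "make_chain",
    "make_driven",
    "make_random_system",
]


def make_two_level(
    G_A: float = 0.0,
    G_B: float = 1.0,
    deltaQ: float = 0.0,
    sigma: float = 1.0,
    N0_A: float = 10.0,
    N0_B: float = 1e-6,
    kT: float = 1.0,
) -> SystemSpec:
    """Minimal diagram: A <-> B through one quantum-coupled channel.

    Closed in matter (the quantum carries only energy); its balance ratio is
    N_B/N_A = exp((G_A - G_B + deltaQ)/kT).
    """
    return SystemSpec(
        species=(
            Species("A", G=G_A, c=1, N0=N0_A),
            Species("B", G=G_B, c=1, N0=N0_B),
        ),
        transformations=(
            Transformation(substrates={"A": 1}, products={"B": 1}, deltaQ=deltaQ, sigma=sigma),
        ),
        kT=kT,
        label="two_level",
    )


def make_chain(
    M: int = 5,
    pool: float = 1000.0,
    G_step: float = 0.0,
    affinity_margin: float = 1.0,
    sigma: float = 1.0,
    kT: float = 1.0,
    source: bool = False,
    sigma_feed_ratio: float = 50.0,
    monomer_seed: float = 0.01,
    polymer_seed: float | None = None,
) -> SystemSpec:
    """Assembly cascade X_j + X_1 -> X_{j+1}, c_j = j, M levels.

    Each assembly step's quantum coupling is set so the step is downhill by
    ``affinity_margin`` (in kT) at unit populations: deltaQ = margin + dG
    with dG = G_{j+1} - G_j - G_1.  ``G_step`` spaces the level energies as
    G_j = (j-1)*G_step.

    Closed variant (default): N0 = [pool, 0, ..., 0] — all matter in
    monomers.  Reservoir variant (``source=True``): a species R (c = 1,
    population ``pool``) feeds monomers through a transformation R -> X_1
    with conductance sigma / ``sigma_feed_ratio``; monomers start at
    ``monomer_seed`` and higher levels at ``polymer_seed``, so the whole
    cascade grows as the reservoir drains.  The feed's own coupling uses the
    same downhill margin.
    """
    if M < 3:
        raise ValueError("chain scenario requires M >= 3 levels")
    if polymer_seed is None:
        polymer_seed = 1e-9 if source else 0.0
    G = [(j - 1) * G_step for j in range(1, M + 1)]
    species = [
        Species(f"X{j}", G=G[j - 1], c=j, N0=monomer_seed if source else 0.0)
        if j == 1
        else Species(f"X{j}", G=G[j - 1], c=j, N0=polymer_seed)
        for j in range(1, M + 1)
    ]
    if not source:
        # monomer pool minus seed matter: total elemental matter is exactly `pool`
        seed_matter = sum(j * polymer_seed for j in range(2, M + 1))
        species[0] = Species("X1", G=G[0], c=1, N0=pool - seed_matter)
    transformations = []
    if source:
        species.append(Species("R", G=G[0], c=1, N0=pool))
        transformations.append(
            Transformation(
                substrates={"R": 1},
                products={"X1": 1},
                deltaQ=affinity_margin,  # dG = 0 between R and X1
                sigma=sigma / sigma_feed_ratio,
                label="feed",
            )
        )
    for j in range(1, M):
        dG = G[j] - G[j - 1] - G[0]
        sub = {"X1": 2} if j == 1 else {f"X{j}": 1, "X1": 1}
        transformations.append(
            Transformation(
                substrates=sub,
                products={f"X{j + 1}": 1},
                deltaQ=affinity_margin + dG,
                sigma=sigma,
                label=f"assemble_{j + 1}",
            )
        )
    return SystemSpec(
        species=tuple(species),
        transformations=tuple(transformations),
        kT=kT,
        label="chain" + ("_sourced" if source else ""),
    )


def make_driven(
    M: int = 5,
    amplitude: float = 0.0,
    period: float = 5.0,
    phase: float = 0.0,
    drive_transformation: int = 0,
    **chain_kwargs,
) -> tuple[SystemSpec, DriveSchedule]:
    """The chain with a periodic quantum drive on one transformation.

    Returns (spec, schedule).  The spec is byte-identical to
    :func:`make_chain` with the same parameters — the drive lives entirely
    in the schedule, so zero amplitude degenerates exactly to the undriven
    chain.
    """
    spec = make_chain(M=M, **chain_kwargs)
    spec = SystemSpec(
        species=spec.species,
        transformations=spec.transformations,
        kT=spec.kT,
        label=spec.label,
    )
    schedule = DriveSchedule(
        transformation=drive_transformation,
        amplitude=amplitude,
        period=period,
        phase=phase,
    )
    return spec, schedule


def make_random_system(
    seed: int,
    max_species: int = 5,
    kT: float = 1.0,
) -> SystemSpec:
    """Draw a random valid diagram (seeded, deterministic).

    Species get compositions from {1, 1, 2, 3}, normal energies and
    log-uniform populations.  Transformations are built only from
    elementally balanced patterns: isomerizations between equal-composition
    species and assemblies a + b -> d with c_a + c_b = c_d.  Every draw
    passes validate_system with zero violations.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_species + 1))
    comps = [1] + [int(rng.choice([1, 1, 2, 3])) for _ in range(n - 1)]
    species = [
        Species(
            id=f"s{i}",
            G=float(rng.normal(0.0, 1.0)),
            c=comps[i],
            N0=float(np.exp(rng.uniform(np.log(0.5), np.log(50.0)))),
        )
        for i in range(n)
    ]
    candidates: list[Transformation] = []
    for i in range(n):
        for j in range(n):
            if i < j and comps[i] == comps[j]:
                candidates.append(
                    Transformation(substrates={f"s{i}": 1}, products={f"s{j}": 1})
                )
            for k in range(n):
                if k != i and k != j and comps[i] + comps[j] == comps[k]:
                    sub = {f"s{i}": 2} if i == j else {f"s{i}": 1, f"s{j}": 1}
                    if i <= j:
                        candidates.append(
                            Transformation(substrates=sub, products={f"s{k}": 1})
                        )
    if not candidates:
        # guaranteed fallback: duplicate-composition isomerization partner
        species.append(Species(id=f"s{n}", G=float(rng.normal()), c=comps[0], N0=5.0))
        candidates.append(Transformation(substrates={"s0": 1}, products={f"s{n}": 1}))
    n_tr = int(rng.integers(1, min(len(candidates), 4) + 1))
    chosen = rng.choice(len(candidates), size=n_tr, replace=False)
    transformations = [
        Transformation(
            substrates=candidates[int(c)].substrates,
            products=candidates[int(c)].products,
            deltaQ=float(rng.normal(0.0, 1.0)),
            sigma=float(rng.uniform(0.1, 2.0)),
        )
        for c in chosen
    ]
    return SystemSpec(
        species=tuple(species),
        transformations=tuple(transformations),
        kT=kT,
        label=f"random_{seed}",
    )
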