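"""Synthetic ground-truth generation for validating pathway inference.

Real untargeted metabolomics sets are never fully annotated, so validation
uses simulated data with known pathway activities: a random fraction of
pathways is activated, each active pathway generates a random fraction of its
member metabolites, present metabolites are detected independently with
probability gamma, and detections are mapped through the mass bins into the
binary observation vector.  The module also builds random test topologies
(with controllable mass collisions) and the small two-pathway worked example
used throughout the documentation and tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .model import MetabolicModel, ObservationVector, build_observation_vector

__all__ = [
    "SyntheticDataset",
    "generate_synthetic_dataset",
    "generate_random_model",
    "benchmark_topology",
    "make_figure1_fixture",
    "round_portion",
]


def round_portion(frac: float, count: int) -> int:
    """Number of items a fraction selects: round-half-up, at least 1 if frac > 0."""
    if not 0.0 <= frac <= 1.0:
        raise InputError(f"fraction must be in [0, 1], got {frac}")
    if count < 0:
        raise InputError("count must be >= 0")
    if frac == 0.0 or count == 0:
        return 0
    return max(1, int(math.floor(frac * count + 0.5)))


@dataclass
class SyntheticDataset:
    """Ground truth and generated observations for one synthetic replicate."""

    true_a: np.ndarray  # (I,) ground-truth pathway activities
    true_z: np.ndarray  # (I, J) which active pathway generated which metabolite
    true_m: np.ndarray  # (J,) metabolite presence (OR over pathways)
    w: ObservationVector
    config: dict

    def validate(self, model: MetabolicModel, gamma: float) -> None:
        """Check the generative invariants linking a, Z, m and w."""
        assert ((self.true_m == 1) == (self.true_z.sum(axis=0) > 0)).all()
        on_active = (self.true_a[:, None] * model.membership) >= self.true_z
        assert on_active.all(), "Z outside active-pathway membership"
        for k in np.flatnonzero(self.w.w == 1):
            cands = model.candidates_of_bin[k]
            assert gamma > 0 and self.true_m[cands].any(), f"spurious observation in bin {k}"
        if gamma == 1.0:
            for k in range(model.n_bins):
                cands = model.candidates_of_bin[k]
                present = bool(self.true_m[cands].any()) if cands.size else False
                assert bool(self.w.w[k]) == present


def generate_synthetic_dataset(
    model: MetabolicModel,
    frac_pathways: float,
    frac_metabolites: float,
    gamma: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> SyntheticDataset:
    """Simulate one ground-truth dataset on the given model.

    ``round(frac_pathways * I)`` pathways are activated uniformly without
    replacement; each active pathway generates ``round(frac_metabolites *
    size)`` of its metabolites uniformly without replacement (a metabolite
    shared by several active pathways may be selected by each independently);
    each present metabolite is detected with probability ``gamma`` and
    detections set the bins of the observation vector.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InputError(f"gamma must be in [0, 1], got {gamma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    I, J = model.n_pathways, model.n_metabolites
    n_active = round_portion(frac_pathways, I)
    active = rng.choice(I, size=n_active, replace=False) if n_active else np.empty(0, int)
    true_a = np.zeros(I, dtype=np.uint8)
    true_a[active] = 1
    true_z = np.zeros((I, J), dtype=np.uint8)
    for i in active:
        members = model.pathway_metabolites[i]
        n_gen = round_portion(frac_metabolites, members.size)
        if n_gen:
            chosen = rng.choice(members, size=n_gen, replace=False)
            true_z[i, chosen] = 1
    true_m = (true_z.sum(axis=0) > 0).astype(np.uint8)
    detected = true_m.astype(bool) & (rng.random(J) < gamma)
    det_masses = model.metabolite_mass[detected & (model.bin_of_metabolite >= 0)]
    w = build_observation_vector(det_masses, model)
    return SyntheticDataset(
        true_a=true_a,
        true_z=true_z,
        true_m=true_m,
        w=w,
        config=dict(
            frac_pathways=frac_pathways,
            frac_metabolites=frac_metabolites,
            gamma=gamma,
            seed=None if isinstance(seed, np.random.Generator) else seed,
        ),
    )


def generate_random_model(
    n_pathways: int,
    n_metabolites: int,
    mean_pathway_size: float = 10.0,
    mass_collision_fraction: float = 0.1,
    seed: int | np.random.Generator | None = None,
    ppm_tol: float = 15.0,
    mass_range: tuple[float, float] = (80.0, 900.0),
    size_dispersion: float = 0.0,
    hub_exponent: float = 0.0,
    family_exponent: float = 0.0,
    ensure_coverage: bool = False,
) -> MetabolicModel:
    """Random bipartite pathway-metabolite topology with mass collisions.

    With the default shape parameters, pathway sizes are
    Poisson(``mean_pathway_size``) clipped to [1, J] and members are drawn
    uniformly, so metabolites may sit on zero, one or many pathways.  A
    ``mass_collision_fraction`` of metabolites is given a mass within a few
    ppm of another metabolite (sharing its bin, like isomers); the remaining
    masses are separated by far more than the tolerance, so with no
    collisions every metabolite gets its own bin.

    The shape parameters emulate the statistical features of genome-scale
    pathway collections, which uniform topologies lack:

    - ``size_dispersion`` > 0 draws pathway sizes from a lognormal with the
      given sigma (mean preserved), giving a few large pathways and many
      small ones.
    - ``hub_exponent`` > 0 samples members with Zipf-like weights, creating
      hub metabolites shared by many pathways (currency compounds and
      central intermediates).
    - ``family_exponent`` > 0 attaches mass colliders preferentially to
      already-popular masses, creating heavy-tailed isobar families (e.g.
      sugar or amino-acid isomers) instead of mere pairs.
    - ``ensure_coverage`` attaches any pathway-less metabolite to one random
      pathway, as in models built *from* pathway databases where every
      metabolite originates in some pathway.
    """
    if n_pathways < 1 or n_metabolites < 1:
        raise InputError("need at least one pathway and one metabolite")
    if not 0.0 <= mass_collision_fraction < 1.0:
        raise InputError("mass_collision_fraction must be in [0, 1)")
    if mean_pathway_size > n_metabolites:
        raise InputError(
            f"mean pathway size {mean_pathway_size} exceeds the number of "
            f"metabolites {n_metabolites}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    I, J = n_pathways, n_metabolites
    if size_dispersion > 0:
        # lognormal with the requested mean: median = mean / exp(sigma^2 / 2)
        mu_log = np.log(mean_pathway_size) - size_dispersion**2 / 2.0
        sizes = np.round(rng.lognormal(mu_log, size_dispersion, I)).astype(int)
    else:
        sizes = rng.poisson(mean_pathway_size, I)
    sizes = np.clip(sizes, 1, J)
    if hub_exponent > 0:
        weights = 1.0 / np.arange(1, J + 1) ** hub_exponent
        weights = weights[rng.permutation(J)]
        weights /= weights.sum()
    else:
        weights = None
    membership = np.zeros((I, J), dtype=np.uint8)
    for i in range(I):
        membership[i, rng.choice(J, size=int(sizes[i]), replace=False, p=weights)] = 1
    if ensure_coverage:
        for j in np.flatnonzero(membership.sum(axis=0) == 0):
            membership[rng.integers(I), j] = 1

    n_coll = int(round(mass_collision_fraction * J))
    n_host = J - n_coll
    # hosts on a geometric grid with 60 ppm steps: >> tolerance, never merged
    lo, hi = mass_range
    step = 60e-6
    max_slots = int(np.floor(np.log(hi / lo) / np.log1p(step)))
    if max_slots < n_host:
        raise InputError("mass range too narrow for the requested model size")
    slots = np.sort(rng.choice(max_slots, size=n_host, replace=False))
    host_masses = lo * np.power(1.0 + step, slots)
    masses = np.empty(J)
    perm = rng.permutation(J)
    host_idx, coll_idx = perm[:n_host], perm[n_host:]
    masses[host_idx] = host_masses
    if n_coll:
        if family_exponent > 0:
            fam_w = 1.0 / np.arange(1, n_host + 1) ** family_exponent
            fam_w = fam_w[rng.permutation(n_host)]
            partners = rng.choice(host_idx, size=n_coll, p=fam_w / fam_w.sum())
        else:
            partners = rng.choice(host_idx, size=n_coll, replace=True)
        jitter = rng.uniform(-5e-6, 5e-6, size=n_coll)
        masses[coll_idx] = masses[partners] * (1.0 + jitter)
    return MetabolicModel.from_masses(
        pathway_ids=[f"pw{i + 1}" for i in range(I)],
        metabolite_ids=[f"m{j + 1}" for j in range(J)],
        metabolite_mass=masses,
        membership=membership,
        ppm_tol=ppm_tol,
    )


def benchmark_topology(
    seed: int | np.random.Generator | None = None,
    n_pathways: int = 50,
    n_metabolites: int = 800,
) -> MetabolicModel:
    """The bundled benchmark topology for synthetic validation.

    A random model whose summary statistics mirror genome-scale metabolic
    models assembled from pathway databases: about two pathway memberships
    per metabolite with strong hubs, lognormal pathway sizes, every
    metabolite on at least one pathway, and half the metabolites isobaric
    with another metabolite (so unique masses number roughly half the
    metabolites), with heavy-tailed isobar families.
    """
    return generate_random_model(
        n_pathways,
        n_metabolites,
        mean_pathway_size=max(4.0, 0.04 * n_metabolites),
        mass_collision_fraction=0.5,
        seed=seed,
        size_dispersion=0.7,
        hub_exponent=0.8,
        family_exponent=1.1,
        ensure_coverage=True,
    )


def make_figure1_fixture() -> tuple[MetabolicModel, ObservationVector]:
    """The packaged two-pathway worked example.

    Pathway 1 has six metabolites, four of them (j3, j4, j5, j6) in observed
    bins; Pathway 2 has eight, three observed (j5, j7, j13).  j5 belongs to
    both pathways; j3, j4 and j5 are isobaric and share one observed bin, one
    observed bin holds the two candidates j6 and j7, and j13 is observed,
    unique to Pathway 2, alone in its bin.  Every observed metabolite of
    Pathway 1 can therefore be explained by Pathway 2's activity, while the
    j13 observation can only be explained by Pathway 2 -- so inference
    concludes Pathway 2 is active with high probability, even though the
    enrichment ratios (4/6 vs 3/8) suggest the opposite ordering.
    """
    met_ids = [f"j{n}" for n in range(1, 14)]
    masses = {
        "j1": 120.0, "j2": 130.0,
        "j3": 150.0, "j4": 150.0005, "j5": 150.001,   # isobaric trio, one bin
        "j6": 180.0, "j7": 180.0009,                   # two-candidate bin
        "j8": 200.0, "j9": 210.0, "j10": 220.0, "j11": 230.0, "j12": 240.0,
        "j13": 250.0,                                  # unique evidence
    }
    pathway1 = {"j1", "j2", "j3", "j4", "j5", "j6"}
    pathway2 = {"j5", "j7", "j8", "j9", "j10", "j11", "j12", "j13"}
    membership = np.array(
        [
            [1 if m in pathway1 else 0 for m in met_ids],
            [1 if m in pathway2 else 0 for m in met_ids],
        ],
        dtype=np.uint8,
    )
    model = MetabolicModel.from_masses(
        pathway_ids=["pathway_1", "pathway_2"],
        metabolite_ids=met_ids,
        metabolite_mass=[masses[m] for m in met_ids],
        membership=membership,
        ppm_tol=15.0,
    )
    observed = [150.0006, 180.0004, 250.0]
    w = build_observation_vector(observed, model)
    assert not w.unmatched_masses
    return model, w
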