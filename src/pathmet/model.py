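"""Core data structures: metabolic model, parameters, mass binning, observations.

A metabolic model reduces each pathway to its metabolite membership set and
each metabolite to a monoisotopic neutral mass.  Metabolite masses are
discretized into bins: each bin is centered at a unique mass value with a
relative tolerance of ``ppm_tol`` parts per million, and every metabolite is
assigned to the single bin whose center is closest to its mass.  Measured m/z
values (singly charged, adduct-corrected upstream) are converted to neutral
masses by adding or subtracting one proton mass according to ionization mode
and then matched against the bins to form the binary observation vector ``w``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .exceptions import InputError, ModelError

logger = logging.getLogger(__name__)

#: Mass of one proton in daltons, used for ionization-mode adjustment.
PROTON_MASS = 1.007276466

#: Sentinel bin index for a metabolite detached from every bin (see
#: :func:`restrict_tau`).
NO_BIN = -1


@dataclass
class Parameters:
    """Model and sampler parameters.

    Attributes
    ----------
    lambda_mode:
        ``"beta"`` places a conjugate Beta(``alpha``, ``beta``) hyperprior on
        the pathway-activity probability ``lambda`` and samples it alongside
        the activities; ``"fixed"`` holds ``lambda_value`` constant.
    lambda_value:
        Prior probability that a pathway is active (fixed mode only).
    alpha, beta:
        Beta hyperprior parameters (beta mode only); the default Beta(1, 1)
        is uniform on [0, 1].
    mu:
        Probability that an active pathway produces any given one of its
        member metabolites.
    gamma:
        Detection probability per present metabolite ("observed accuracy" of
        the instrument).  Use 1.0 for noise-free synthetic validation.
    ppm_tol:
        Relative mass tolerance, in parts per million, used both for bin
        construction and for matching measurements to bins.
    activity_threshold:
        Posterior cutoff at or above which a pathway is called active.
    n_samples:
        Total number of Gibbs sweeps ``T`` (including burn-in).
    n_burn_in:
        Number of initial sweeps discarded before estimating posteriors.
    n_chains:
        Number of independent chains; retained draws are pooled.
    seed:
        Seed for all sampler randomness; identical seeds give bit-identical
        draws.
    """

    lambda_mode: str = "beta"
    lambda_value: float = 0.5
    alpha: float = 1.0
    beta: float = 1.0
    mu: float = 0.5
    gamma: float = 0.9
    ppm_tol: float = 15.0
    activity_threshold: float = 0.5
    n_samples: int = 1000
    n_burn_in: int = 100
    n_chains: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_mode not in ("fixed", "beta"):
            raise InputError(
                f"lambda_mode must be 'fixed' or 'beta', got {self.lambda_mode!r}"
            )
        for name in ("lambda_value", "mu", "activity_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.gamma <= 1.0:
            raise InputError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.alpha <= 0 or self.beta <= 0:
            raise InputError("Beta prior parameters must be positive")
        if self.ppm_tol <= 0:
            raise InputError(f"ppm_tol must be positive, got {self.ppm_tol}")
        if self.n_burn_in < 0 or self.n_samples <= self.n_burn_in:
            raise InputError(
                "need n_samples > n_burn_in >= 0, got "
                f"T={self.n_samples}, burn_in={self.n_burn_in}"
            )
        if self.n_chains < 1:
            raise InputError("n_chains must be >= 1")


@dataclass
class MeasurementRecord:
    """One measured m/z value with its ionization mode."""

    mz: float
    ionization_mode: str = "neutral"

    def __post_init__(self) -> None:
        if not np.isfinite(self.mz) or self.mz <= 0:
            raise InputError(f"measured m/z must be positive and finite, got {self.mz}")
        if self.ionization_mode not in ("positive", "negative", "neutral"):
            raise InputError(
                f"unknown ionization mode {self.ionization_mode!r}; "
                "expected 'positive', 'negative' or 'neutral'"
            )


def adjust_measurement(rec: MeasurementRecord, proton_mass: float = PROTON_MASS) -> float:
    """Convert a measured m/z to a neutral mass.

    Positive-mode ions are protonated ([M+H]+), so one proton mass is
    subtracted; negative-mode ions are deprotonated ([M-H]-), so one proton
    mass is added; neutral masses pass through unchanged.
    """
    if rec.ionization_mode == "positive":
        return rec.mz - proton_mass
    if rec.ionization_mode == "negative":
        return rec.mz + proton_mass
    return rec.mz


def assign_mass_bins(
    masses: Sequence[float], ppm_tol: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize metabolite masses into ppm-tolerance bins.

    Distinct masses are sorted ascending and agglomerated in a single greedy
    pass: a new bin is started whenever the next mass lies more than
    ``ppm_tol`` (relative to the current bin's running mean) above it.  Each
    bin's center is the mean of its member masses, and every metabolite is
    then assigned to the nearest center (ties broken toward the lower-mass
    center).

    Returns
    -------
    bin_centers:
        Strictly increasing array of K center masses.
    bin_of_metabolite:
        For each input mass, the index of its assigned bin.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.ndim != 1 or masses.size == 0:
        raise InputError("masses must be a non-empty 1-D sequence")
    bad = np.flatnonzero(~np.isfinite(masses) | (masses <= 0))
    if bad.size:
        raise InputError(
            f"non-positive or non-finite mass at row(s) {bad.tolist()}: "
            f"{masses[bad].tolist()}"
        )
    if ppm_tol <= 0:
        raise InputError(f"ppm_tol must be positive, got {ppm_tol}")

    distinct = np.unique(masses)
    centers: list[float] = []
    run_sum = distinct[0]
    run_n = 1
    for m in distinct[1:]:
        mean = run_sum / run_n
        if (m - mean) > ppm_tol * 1e-6 * mean:
            centers.append(mean)
            run_sum, run_n = m, 1
        else:
            run_sum += m
            run_n += 1
    centers.append(run_sum / run_n)
    bin_centers = np.asarray(centers)
    bin_of_metabolite = nearest_center(masses, bin_centers)
    return bin_centers, bin_of_metabolite


def nearest_center(masses: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the nearest center for each mass; ties go to the lower center."""
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    idx = np.searchsorted(centers, masses)
    lo = np.clip(idx - 1, 0, len(centers) - 1)
    hi = np.clip(idx, 0, len(centers) - 1)
    # ties (equidistant) resolve to the lower-mass center via <=
    pick_lo = np.abs(masses - centers[lo]) <= np.abs(centers[hi] - masses)
    return np.where(pick_lo, lo, hi)


@dataclass
class MetabolicModel:
    """Pathway-metabolite membership plus the mass-bin discretization.

    The map ``bin_of_metabolite`` is the one-hot-per-row realization of the
    J x K metabolite-to-mass matrix: every metabolite carries exactly one
    mass, so it maps to exactly one bin (or to :data:`NO_BIN` after an
    explicit annotation restriction detaches it).
    """

    pathway_ids: list[str]
    metabolite_ids: list[str]
    metabolite_mass: np.ndarray
    membership: np.ndarray
    bin_centers: np.ndarray
    bin_of_metabolite: np.ndarray
    ppm_tol: float = 15.0
    metabolite_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.metabolite_mass = np.asarray(self.metabolite_mass, dtype=float)
        self.membership = np.asarray(self.membership, dtype=np.uint8)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_of_metabolite = np.asarray(self.bin_of_metabolite, dtype=np.int64)
        self._caches: dict[str, object] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_masses(
        cls,
        pathway_ids: Sequence[str],
        metabolite_ids: Sequence[str],
        metabolite_mass: Sequence[float],
        membership: np.ndarray,
        ppm_tol: float = 15.0,
        metabolite_names: Sequence[str] | None = None,
    ) -> "MetabolicModel":
        """Build a model, constructing the bins from the metabolite masses."""
        centers, assignment = assign_mass_bins(metabolite_mass, ppm_tol)
        model = cls(
            pathway_ids=list(pathway_ids),
            metabolite_ids=list(metabolite_ids),
            metabolite_mass=np.asarray(metabolite_mass, dtype=float),
            membership=np.asarray(membership, dtype=np.uint8),
            bin_centers=centers,
            bin_of_metabolite=assignment,
            ppm_tol=ppm_tol,
            metabolite_names=list(metabolite_names) if metabolite_names else None,
        )
        model.validate()
        return model

    # -- shape shortcuts ---------------------------------------------------

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    # -- derived structure (cached; the model is treated as immutable) -----

    def _cache(self, key, builder):
        if key not in self._caches:
            self._caches[key] = builder()
        return self._caches[key]

    @property
    def candidates_of_bin(self) -> list[np.ndarray]:
        """For each bin k, the indices of metabolites assigned to it (J_k)."""

        def build():
            cands: list[list[int]] = [[] for _ in range(self.n_bins)]
            for j, k in enumerate(self.bin_of_metabolite):
                if k != NO_BIN:
                    cands[k].append(j)
            return [np.asarray(c, dtype=np.int64) for c in cands]

        return self._cache("candidates_of_bin", build)

    @property
    def tau_csc(self) -> sparse.csc_matrix:
        """Sparse J x K metabolite-to-bin indicator (detached rows empty)."""

        def build():
            attached = np.flatnonzero(self.bin_of_metabolite != NO_BIN)
            data = np.ones(attached.size)
            return sparse.csc_matrix(
                (data, (attached, self.bin_of_metabolite[attached])),
                shape=(self.n_metabolites, self.n_bins),
            )

        return self._cache("tau_csc", build)

    @property
    def pathway_metabolites(self) -> list[np.ndarray]:
        """For each pathway i, the indices of its member metabolites."""

        def build():
            return [np.flatnonzero(self.membership[i]) for i in range(self.n_pathways)]

        return self._cache("pathway_metabolites", build)

    @property
    def pathway_size(self) -> np.ndarray:
        return self.membership.sum(axis=1).astype(np.int64)

    def pathway_count_per_metabolite(self, a: np.ndarray) -> np.ndarray:
        """n_j: number of active pathways containing each metabolite."""
        return np.asarray(a, dtype=np.int64) @ self.membership.astype(np.int64)

    # -- validation --------------------------------------------------------

    def validate(self, allow_detached: bool = True) -> None:
        """Check the structural invariants; raise :class:`ModelError` on failure."""
        I, J, K = self.n_pathways, self.n_metabolites, self.n_bins
        if len(set(self.pathway_ids)) != I:
            raise ModelError("pathway_ids are not unique")
        if len(set(self.metabolite_ids)) != J:
            raise ModelError("metabolite_ids are not unique")
        if self.membership.shape != (I, J):
            raise ModelError(
                f"membership shape {self.membership.shape} != ({I}, {J})"
            )
        if not np.isin(self.membership, (0, 1)).all():
            raise ModelError("membership entries must be 0 or 1")
        if self.metabolite_mass.shape != (J,):
            raise ModelError("metabolite_mass length mismatch")
        if (self.metabolite_mass <= 0).any() or ~np.isfinite(self.metabolite_mass).all():
            raise ModelError("metabolite masses must be positive and finite")
        if K == 0 or (np.diff(self.bin_centers) <= 0).any():
            raise ModelError("bin_centers must be non-empty and strictly increasing")
        binof = self.bin_of_metabolite
        if binof.shape != (J,):
            raise ModelError("bin_of_metabolite length mismatch")
        detached = binof == NO_BIN
        if detached.any() and not allow_detached:
            raise ModelError("detached metabolites present")
        if ((binof < 0) & ~detached).any() or (binof >= K).any():
            raise ModelError("bin_of_metabolite indices out of range")
        att = ~detached
        if att.any():
            centers = self.bin_centers[binof[att]]
            rel = np.abs(self.metabolite_mass[att] - centers) / centers
            worst = rel.max()
            if worst > self.ppm_tol * 1e-6 * (1 + 1e-9):
                j = np.flatnonzero(att)[int(np.argmax(rel))]
                raise ModelError(
                    f"metabolite {self.metabolite_ids[j]} lies {worst * 1e6:.2f} ppm "
                    f"from its bin center, beyond the {self.ppm_tol} ppm tolerance"
                )

    def restricted(self) -> bool:
        """True if any metabolite has been detached from its bin."""
        return bool((self.bin_of_metabolite == NO_BIN).any())


@dataclass
class ObservationVector:
    """Binary observation vector over the model's K mass bins.

    ``w[k] = 1`` records that at least one measurement matched bin k;
    ``matched_measurements[k]`` lists the adjusted neutral masses responsible,
    and ``unmatched_masses`` the adjusted masses that matched no bin within
    tolerance (reported, never silently dropped).
    """

    w: np.ndarray
    matched_measurements: list[list[float]]
    unmatched_masses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.uint8)

    @property
    def n_bins(self) -> int:
        return int(self.w.size)

    @property
    def observed_bins(self) -> np.ndarray:
        return np.flatnonzero(self.w == 1)

    def validate(self) -> None:
        if len(self.matched_measurements) != self.n_bins:
            raise ModelError("matched_measurements length != K")
        for k in range(self.n_bins):
            if bool(self.w[k]) != bool(self.matched_measurements[k]):
                raise ModelError(
                    f"w[{k}]={self.w[k]} inconsistent with "
                    f"{len(self.matched_measurements[k])} matched measurements"
                )


def build_observation_vector(
    adjusted_masses: Iterable[float],
    model: MetabolicModel,
    ppm_tol: float | None = None,
) -> ObservationVector:
    """Match adjusted neutral masses against the model's bins.

    Each mass is matched to its nearest bin center and kept only if it lies
    within ``ppm_tol`` of that center (relative to the center).  A mass within
    tolerance of more than one center is assigned to the nearest only, with a
    warning.  An empty measurement list yields an all-zero ``w``.
    """
    if model.n_bins == 0:
        raise InputError("model has no mass bins")
    tol = model.ppm_tol if ppm_tol is None else ppm_tol
    masses = np.atleast_1d(np.asarray(list(adjusted_masses), dtype=float))
    matched: list[list[float]] = [[] for _ in range(model.n_bins)]
    unmatched: list[float] = []
    if masses.size:
        bad = np.flatnonzero(~np.isfinite(masses) | (masses <= 0))
        if bad.size:
            raise InputError(
                f"non-positive or non-finite adjusted mass at row(s) {bad.tolist()}"
            )
        nearest = nearest_center(masses, model.bin_centers)
        centers = model.bin_centers[nearest]
        within = np.abs(masses - centers) <= tol * 1e-6 * centers
        for m, k, ok in zip(masses, nearest, within):
            if ok:
                matched[k].append(float(m))
                # ambiguous match: also within tolerance of a neighboring center
                for other in (k - 1, k + 1):
                    if 0 <= other < model.n_bins and other != k:
                        c = model.bin_centers[other]
                        if abs(m - c) <= tol * 1e-6 * c:
                            logger.warning(
                                "mass %.6f is within %.1f ppm of two bin centers "
                                "(%.6f and %.6f); assigned to the nearest (%.6f)",
                                m, tol, model.bin_centers[k], c, model.bin_centers[k],
                            )
            else:
                unmatched.append(float(m))
    w = np.fromiter((1 if m else 0 for m in matched), dtype=np.uint8, count=model.n_bins)
    return ObservationVector(w=w, matched_measurements=matched, unmatched_masses=unmatched)


def restrict_tau(
    model: MetabolicModel, fixed_annotations: Mapping[int, str]
) -> MetabolicModel:
    """Fix the metabolite identity of selected bins from external annotations.

    For every entry ``bin k -> metabolite j`` the candidate set of bin k is
    reduced to the single named metabolite; every other metabolite previously
    assigned to that bin is detached (its bin becomes :data:`NO_BIN`), so it
    can no longer explain, or be explained by, any observation.  Bins not
    named in ``fixed_annotations`` are unchanged.  Returns a new model; the
    input is not modified.
    """
    if not fixed_annotations:
        return model
    met_index = {m: j for j, m in enumerate(model.metabolite_ids)}
    binof = model.bin_of_metabolite.copy()
    for k, met_id in fixed_annotations.items():
        if not 0 <= k < model.n_bins:
            raise InputError(f"bin index {k} out of range (K={model.n_bins})")
        if met_id not in met_index:
            raise InputError(f"unknown metabolite id {met_id!r} for bin {k}")
        j = met_index[met_id]
        if model.bin_of_metabolite[j] != k:
            raise InputError(
                f"metabolite {met_id!r} is not a candidate of bin {k} "
                f"(its bin is {int(model.bin_of_metabolite[j])})"
            )
        others = np.flatnonzero(binof == k)
        binof[others[others != j]] = NO_BIN
        binof[j] = k
    restricted = replace(model, bin_of_metabolite=binof)
    restricted.validate()
    return restricted


def fixed_annotations_from_masses(
    model: MetabolicModel, pairs: Iterable[tuple[float, str]]
) -> dict[int, str]:
    """Resolve (mass, metabolite_id) pairs to a bin->metabolite restriction map.

    The mass may be a bin center or a measured mass; it is matched to the
    nearest bin center within the model tolerance.
    """
    out: dict[int, str] = {}
    for mass, met_id in pairs:
        k = int(nearest_center(np.array([mass]), model.bin_centers)[0])
        c = model.bin_centers[k]
        if abs(mass - c) > model.ppm_tol * 1e-6 * c:
            raise InputError(
                f"annotation mass {mass} matches no bin within {model.ppm_tol} ppm"
            )
        if k in out and out[k] != met_id:
            raise InputError(
                f"conflicting fixed annotations for bin {k}: {out[k]!r} vs {met_id!r}"
            )
        out[k] = met_id
    return out
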