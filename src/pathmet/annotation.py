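"""Metabolite-presence posteriors and per-bin candidate ranking.

Given retained pathway-state draws from the Gibbs sampler, the posterior
probability that metabolite j is present, p(m_j = 1 | w), is the draw average
of the per-state conditional p(m_j = 1 | a, w).  Conditioned on ``a``, m_j
interacts only with its own bin's observation w_kj, through the joint

    p(m_j=0, w_kj=0 | a) = (1 - phi_j) * P_other
    p(m_j=0, w_kj=1 | a) = (1 - phi_j) * (1 - P_other)
    p(m_j=1, w_kj=0 | a) = phi_j * (1 - gamma) * P_other
    p(m_j=1, w_kj=1 | a) = phi_j * (1 - (1 - gamma) * P_other)

with ``P_other`` the product of survival factors (1 - gamma * phi_j') over
the other candidates j' of the bin.  Normalizing the two cases matching the
observed w_kj gives the conditional presence probability; no re-sampling is
performed.  The resulting posteriors score and rank the candidate set of
each observed bin; all candidates tied at the maximum form the reported
annotation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, PathmetError
from .model import NO_BIN, MetabolicModel, ObservationVector, Parameters
from .inference import PosteriorSamples, _safe_log_factors, phi

__all__ = [
    "AnnotationResult",
    "RankedBin",
    "joint_mj_wk_given_a",
    "presence_given_states",
    "exact_metabolite_posterior",
    "metabolite_posterior",
    "rank_candidates",
]

#: Posteriors within this absolute tolerance of the bin maximum are treated
#: as tied; true ties are exact (identical draw averages), the tolerance only
#: guards float noise.
TIE_TOL = 1e-9


def joint_mj_wk_given_a(
    model: MetabolicModel,
    j: int,
    a: np.ndarray,
    w: np.ndarray | ObservationVector,
    mu: float,
    gamma: float,
) -> np.ndarray:
    """Joint probabilities p(m_j, w_kj | a) as a 2x2 array indexed [m_j, w_kj].

    For a detached metabolite (no bin) the observation column w_kj = 0/1 is
    replaced by the marginal presence prior given ``a``: column 0 holds
    (1 - phi_j, phi_j) and column 1 is zero.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    if not 0 <= j < model.n_metabolites:
        raise InputError(f"metabolite index {j} out of range")
    n = model.pathway_count_per_metabolite(a)
    phis = phi(n, mu)
    pj = phis[j]
    k = int(model.bin_of_metabolite[j])
    if k == NO_BIN:
        return np.array([[1.0 - pj, 0.0], [pj, 0.0]])
    others = model.candidates_of_bin[k]
    others = others[others != j]
    p_other = float(np.prod(1.0 - gamma * phis[others])) if others.size else 1.0
    return np.array(
        [
            [(1.0 - pj) * p_other, (1.0 - pj) * (1.0 - p_other)],
            [pj * (1.0 - gamma) * p_other, pj * (1.0 - (1.0 - gamma) * p_other)],
        ]
    )


def presence_given_states(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    states: np.ndarray,
    mu: float,
    gamma: float,
) -> np.ndarray:
    """Conditional presence probabilities p(m_j = 1 | a, w) for many states.

    ``states`` is an (S, I) binary matrix; the result is (S, J).  This is the
    vectorized form of normalizing :func:`joint_mj_wk_given_a` at the
    observed w_kj; the tests pin its equality with the scalar formula.
    Detached metabolites carry no observational evidence and get phi_j.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    states = np.atleast_2d(np.asarray(states))
    n = states.astype(np.int64) @ model.membership.astype(np.int64)  # (S, J)
    phis = phi(n, mu)
    f = 1.0 - gamma * phis
    logf, zero = _safe_log_factors(f)
    tau = model.tau_csc
    log_prod = np.asarray(logf @ tau)  # (S, K) log prod over candidates
    n_zero = np.asarray(zero.astype(float) @ tau)

    binof = model.bin_of_metabolite
    attached = binof != NO_BIN
    kj = np.where(attached, binof, 0)
    # product over the *other* candidates of j's bin, per state
    other_zero = n_zero[:, kj] - zero[:, :].astype(float) * attached
    with np.errstate(over="ignore"):
        p_other = np.where(
            other_zero > 0, 0.0, np.exp(log_prod[:, kj] - logf * attached)
        )
    w_j = wv[kj] == 1
    p0 = np.where(w_j, (1.0 - phis) * (1.0 - p_other), (1.0 - phis) * p_other)
    p1 = np.where(
        w_j,
        phis * (1.0 - (1.0 - gamma) * p_other),
        phis * (1.0 - gamma) * p_other,
    )
    total = p0 + p1
    impossible = attached & (total <= 0.0)
    if impossible.any():
        s, j = np.argwhere(impossible)[0]
        raise PathmetError(
            f"pathway state {s} assigns zero probability to both presence cases "
            f"of metabolite {model.metabolite_ids[j]} in observed bin "
            f"{int(binof[j])}; the state cannot have generated this observation"
        )
    out = np.where(attached, np.divide(p1, np.where(total > 0, total, 1.0)), phis)
    return out


def exact_metabolite_posterior(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    params: Parameters,
) -> np.ndarray:
    """Exact p(m_j = 1 | w) by enumerating pathway states (verification oracle).

    Weights the conditional presence probabilities by the exact state
    posterior from 2^I enumeration; zero-probability states are excluded
    (they contribute no weight and may be inconsistent with ``w``).
    """
    from .inference import exact_state_distribution

    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    states, logp = exact_state_distribution(model, wv, params)
    keep = np.isfinite(logp)
    per_state = presence_given_states(model, wv, states[keep], params.mu, params.gamma)
    return np.exp(logp[keep]) @ per_state


@dataclass
class RankedBin:
    """Ranked annotation candidates for one observed bin."""

    bin_index: int
    bin_center: float
    metabolite_ids: list[str]  # sorted by posterior descending
    posteriors: list[float]
    top_set: set[str] = field(default_factory=set)


@dataclass
class AnnotationResult:
    """Presence posteriors for all metabolites plus per-bin rankings."""

    metabolite_posterior: np.ndarray  # (J,) p(m_j = 1 | w)
    mc_se: np.ndarray  # (J,) batch-means Monte-Carlo SE
    ranked_bins: dict[int, RankedBin]  # observed bins only
    metabolite_ids: list[str]


def metabolite_posterior(
    samples: PosteriorSamples,
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    params: Parameters,
) -> AnnotationResult:
    """Estimate p(m_j = 1 | w) by averaging over the retained pathway draws."""
    if samples.draws.shape[0] == 0:
        raise InputError("no retained draws to average over")
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    per_draw = presence_given_states(model, wv, samples.draws, params.mu, params.gamma)
    post = per_draw.mean(axis=0)
    n_b = min(20, per_draw.shape[0])
    edges = np.linspace(0, per_draw.shape[0], n_b + 1).astype(int)
    batch = np.stack([per_draw[lo:hi].mean(axis=0) for lo, hi in zip(edges[:-1], edges[1:])])
    mc_se = batch.std(axis=0, ddof=1) / np.sqrt(n_b)
    ranked = {
        int(k): rank_candidates(post, model, wv, int(k))
        for k in np.flatnonzero(wv == 1)
    }
    return AnnotationResult(
        metabolite_posterior=post,
        mc_se=mc_se,
        ranked_bins=ranked,
        metabolite_ids=list(model.metabolite_ids),
    )


def rank_candidates(
    metabolite_post: np.ndarray,
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    k: int,
    tie_tol: float = TIE_TOL,
) -> RankedBin:
    """Rank the candidate set of observed bin ``k`` by presence posterior.

    Candidates are sorted by posterior descending, ties broken by metabolite
    id (lexicographic); the top set contains every candidate within
    ``tie_tol`` of the maximum.  An unobserved bin yields an empty ranking.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    if not 0 <= k < model.n_bins:
        raise InputError(f"bin index {k} out of range")
    if wv[k] != 1:
        return RankedBin(
            bin_index=k, bin_center=float(model.bin_centers[k]),
            metabolite_ids=[], posteriors=[], top_set=set(),
        )
    cands = model.candidates_of_bin[k]
    order = sorted(cands, key=lambda j: (-metabolite_post[j], model.metabolite_ids[j]))
    ids = [model.metabolite_ids[j] for j in order]
    posts = [float(metabolite_post[j]) for j in order]
    top = {i for i, p in zip(ids, posts) if p >= posts[0] - tie_tol} if posts else set()
    return RankedBin(
        bin_index=k, bin_center=float(model.bin_centers[k]),
        metabolite_ids=ids, posteriors=posts, top_set=top,
    )
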