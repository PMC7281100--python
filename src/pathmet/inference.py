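"""Pathway-activity inference: marginalized likelihood, Gibbs sampler, exact oracle.

The latent metabolite-production matrix Z is never sampled: it is summed out
analytically.  With ``n_j`` the number of active pathways containing
metabolite j, the probability that at least one of them produced it is

    phi_j(a) = 1 - (1 - mu)^n_j

and the observation likelihood factorizes over bins,

    p(w_k = 0 | a) = prod_{j in J_k} (1 - gamma * phi_j(a)),
    p(w_k = 1 | a) = 1 - p(w_k = 0 | a),

so only the binary pathway-state vector ``a`` needs to be sampled.  The Gibbs
sweep updates each a_i from its full conditional, recomputing only the bins
whose candidate sets touch pathway i (exactly equivalent to a full
recomputation, which the tests verify), and optionally draws lambda from its
conjugate Beta conditional.  For small models an exact posterior by 2^I
enumeration serves as a verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, logsumexp

from .exceptions import InputError, UnattainableObservationError
from .model import NO_BIN, MetabolicModel, ObservationVector, Parameters

__all__ = [
    "phi",
    "log_likelihood_w_given_a",
    "log_prior_a",
    "gibbs_sample_posterior",
    "exact_posterior",
    "exact_state_distribution",
    "PosteriorSamples",
]


def phi(n_active, mu: float):
    """Probability that >=1 of ``n_active`` active pathways produced a metabolite.

    Accepts a scalar or array count; 0 when no containing pathway is active,
    nondecreasing in both arguments.
    """
    n = np.asarray(n_active)
    if (n < 0).any():
        raise InputError("active-pathway count must be >= 0")
    if not 0.0 <= mu <= 1.0:
        raise InputError(f"mu must be in [0, 1], got {mu}")
    out = -np.expm1(np.log1p(-mu) * n) if mu < 1.0 else (n > 0).astype(float)
    return float(out) if np.isscalar(n_active) else out


def _log1mexp(logp: np.ndarray) -> np.ndarray:
    """log(1 - exp(logp)) for logp <= 0, elementwise and stable.

    logp == 0 maps to -inf; logp == -inf maps to 0.
    """
    logp = np.asarray(logp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        small = logp > -np.log(2.0)  # exp(logp) close to 1
        out = np.where(
            small,
            np.log(-np.expm1(np.where(small, logp, -1.0))),
            np.log1p(-np.exp(np.where(small, -1.0, logp))),
        )
    return out


def _safe_log_factors(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split survival factors into (log of positive part, zero mask)."""
    zero = f <= 0.0
    logf = np.where(zero, 0.0, np.log(np.where(zero, 1.0, f)))
    return logf, zero


def bin_log_probs(
    model: MetabolicModel, a: np.ndarray, mu: float, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin log p(w_k=0|a) and log p(w_k=1|a) for one pathway state."""
    n = model.pathway_count_per_metabolite(a)
    f = 1.0 - gamma * phi(n, mu)
    logf, zero = _safe_log_factors(f)
    tau = model.tau_csc
    log_p0 = np.asarray(logf @ tau).ravel()
    n_zero = np.asarray(zero.astype(float) @ tau).ravel()
    log_p0 = np.where(n_zero > 0, -np.inf, log_p0)
    log_p1 = _log1mexp(log_p0)
    return log_p0, log_p1


def log_likelihood_w_given_a(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    a: np.ndarray,
    mu: float,
    gamma: float,
) -> float:
    """Marginalized log likelihood log p(w | a).

    Returns -inf exactly when some observed bin has zero probability, e.g. no
    active pathway contains any of its candidates.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    if wv.shape != (model.n_bins,):
        raise InputError(f"w has length {wv.shape}, expected ({model.n_bins},)")
    a = np.asarray(a)
    if a.shape != (model.n_pathways,):
        raise InputError(f"a has length {a.shape}, expected ({model.n_pathways},)")
    log_p0, log_p1 = bin_log_probs(model, a, mu, gamma)
    terms = np.where(wv == 1, log_p1, log_p0)
    if np.isneginf(terms).any():
        return -np.inf
    return float(terms.sum())


def log_prior_a(a: np.ndarray, params: Parameters) -> float:
    """Log prior of a pathway-state vector.

    Fixed mode: independent Bernoulli(lambda) terms.  Beta mode: the
    exchangeable Beta-Bernoulli marginal
    ``log B(alpha + s, beta + I - s) - log B(alpha, beta)`` with ``s`` the
    number of active pathways.
    """
    a = np.asarray(a)
    s = int(a.sum())
    n = int(a.size)
    if params.lambda_mode == "beta":
        return float(betaln(params.alpha + s, params.beta + n - s)
                     - betaln(params.alpha, params.beta))
    lam = params.lambda_value
    # lambda in {0, 1} contradicting a gives probability zero, not an exception
    if lam == 0.0:
        return 0.0 if s == 0 else -np.inf
    if lam == 1.0:
        return 0.0 if s == n else -np.inf
    return float(s * np.log(lam) + (n - s) * np.log1p(-lam))


@dataclass
class PosteriorSamples:
    """Retained pathway-state draws and the posterior estimates they support."""

    draws: np.ndarray  # (T_retained, I) binary
    pathway_posterior: np.ndarray  # (I,) column means of draws
    mc_se: np.ndarray  # (I,) batch-means Monte-Carlo standard error
    lambda_draws: np.ndarray | None = None  # (T_retained,) in beta mode
    pathway_ids: list[str] | None = None

    @property
    def n_retained(self) -> int:
        return int(self.draws.shape[0])

    def active_flags(self, threshold: float = 0.5) -> np.ndarray:
        """Binary activity calls at the given posterior threshold (inclusive)."""
        return (self.pathway_posterior >= threshold).astype(np.uint8)


def _batch_means_se(draws: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Monte-Carlo SE of the column means via batch means."""
    t = draws.shape[0]
    n_batches = min(n_batches, t)
    edges = np.linspace(0, t, n_batches + 1).astype(int)
    means = np.stack([draws[lo:hi].mean(axis=0) for lo, hi in zip(edges[:-1], edges[1:])])
    return means.std(axis=0, ddof=1) / np.sqrt(n_batches)


def check_attainable(model: MetabolicModel, w: np.ndarray | ObservationVector) -> None:
    """Raise if some observed bin has no candidate on any pathway."""
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    on_pathway = model.membership.sum(axis=0) > 0
    for k in np.flatnonzero(wv == 1):
        cands = model.candidates_of_bin[k]
        if cands.size == 0 or not on_pathway[cands].any():
            raise UnattainableObservationError(
                f"observed bin {k} (center {model.bin_centers[k]:.6f} Da) has no "
                "candidate metabolite on any pathway; the model assigns it "
                "probability 0.  Check the binning tolerance and model completeness."
            )


class _GibbsWorkspace:
    """Precomputed per-pathway update tables for the collapsed sweep.

    For pathway i the full conditional ratio involves only the bins whose
    candidate sets contain a metabolite of pathway i.  For those bins we store
    the concatenated full candidate lists (``cand``), segment offsets into
    them (``offsets``), whether each candidate is itself on pathway i
    (``on_i``), and the observation value of each affected bin (``w_aff``).
    Every update recomputes the affected bins' terms from the exact integer
    counts ``n_j``, so there is no accumulated floating-point drift.
    """

    def __init__(self, model: MetabolicModel, w: np.ndarray):
        self.model = model
        self.w = np.asarray(w)
        memb = model.membership.astype(bool)
        self.tables = []
        for i in range(model.n_pathways):
            mets = np.flatnonzero(memb[i])
            bins = model.bin_of_metabolite[mets]
            aff_bins = np.unique(bins[bins != NO_BIN])
            cand_lists = [model.candidates_of_bin[k] for k in aff_bins]
            if cand_lists:
                cand = np.concatenate(cand_lists)
                offsets = np.zeros(len(cand_lists), dtype=np.int64)
                np.cumsum([c.size for c in cand_lists[:-1]], out=offsets[1:])
            else:
                cand = np.empty(0, dtype=np.int64)
                offsets = np.empty(0, dtype=np.int64)
            self.tables.append(
                dict(
                    mets=mets,
                    cand=cand,
                    offsets=offsets,
                    on_i=memb[i][cand],
                    w_aff=self.w[aff_bins].astype(bool),
                )
            )

    def conditional_log_odds(
        self, n: np.ndarray, a_i: int, i: int, mu: float, gamma: float
    ) -> float:
        """log p(w | a_i=1, a_-i) - log p(w | a_i=0, a_-i) over affected bins.

        ``n`` holds the current active-pathway counts per metabolite (which
        include pathway i's contribution ``a_i``).
        """
        t = self.tables[i]
        cand, on_i = t["cand"], t["on_i"]
        if cand.size == 0:
            return 0.0
        n_excl = n[cand] - (a_i * on_i)
        f0 = 1.0 - gamma * phi(n_excl, mu)
        f1 = 1.0 - gamma * phi(n_excl + on_i, mu)
        return float(_segment_loglik(f1, t["offsets"], t["w_aff"])
                     - _segment_loglik(f0, t["offsets"], t["w_aff"]))


def _segment_loglik(f: np.ndarray, offsets: np.ndarray, w_aff: np.ndarray) -> float:
    """Sum of per-bin log p(w_k|.) given candidate survival factors ``f``.

    Bins are contiguous segments of ``f`` delimited by ``offsets``.
    """
    logf, zero = _safe_log_factors(f)
    log_p0 = np.add.reduceat(logf, offsets)
    any_zero = np.add.reduceat(zero.astype(float), offsets) > 0
    log_p0 = np.where(any_zero, -np.inf, log_p0)
    terms = np.where(w_aff, _log1mexp(log_p0), log_p0)
    return float(terms.sum())


def gibbs_sample_posterior(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    params: Parameters,
    seed: int | None = None,
) -> PosteriorSamples:
    """Collapsed Gibbs sampler for the pathway-activity posterior p(a | w).

    Runs ``params.n_samples`` systematic sweeps (i = 1..I, then lambda in
    beta mode) per chain, discards the first ``params.n_burn_in``, and pools
    retained draws across chains.  The state is initialized all-active, which
    has positive likelihood whenever ``w`` is attainable.  Identical seeds
    give bit-identical output.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    if wv.shape != (model.n_bins,):
        raise InputError(f"w has length {wv.shape}, expected ({model.n_bins},)")
    check_attainable(model, wv)
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(params.n_chains)
    ws = _GibbsWorkspace(model, wv)
    I = model.n_pathways
    mu, gamma = params.mu, params.gamma
    fixed = params.lambda_mode == "fixed"
    memb64 = model.membership.astype(np.int64)

    all_draws = []
    all_lam = []
    n_retained = params.n_samples - params.n_burn_in
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        a = np.ones(I, dtype=np.int64)
        n = memb64.sum(axis=0)  # counts for the all-active state
        lam = params.lambda_value if fixed else params.alpha / (params.alpha + params.beta)
        draws = np.empty((n_retained, I), dtype=np.uint8)
        lam_draws = np.empty(n_retained) if not fixed else None
        for t in range(params.n_samples):
            for i in range(I):
                if lam <= 0.0:
                    p1 = 0.0
                elif lam >= 1.0:
                    p1 = 1.0
                else:
                    log_odds = (np.log(lam) - np.log1p(-lam)
                                + ws.conditional_log_odds(n, a[i], i, mu, gamma))
                    # p(a_i=1 | rest) through a stable logistic
                    if log_odds >= 0:
                        p1 = 1.0 / (1.0 + np.exp(-log_odds))
                    else:
                        e = np.exp(log_odds)
                        p1 = e / (1.0 + e)
                new = int(rng.random() < p1)
                if new != a[i]:
                    n[ws.tables[i]["mets"]] += new - a[i]
                    a[i] = new
            if not fixed:
                s = int(a.sum())
                lam = rng.beta(params.alpha + s, params.beta + I - s)
            if t >= params.n_burn_in:
                draws[t - params.n_burn_in] = a
                if not fixed:
                    lam_draws[t - params.n_burn_in] = lam
        all_draws.append(draws)
        if not fixed:
            all_lam.append(lam_draws)

    draws = np.concatenate(all_draws, axis=0)
    return PosteriorSamples(
        draws=draws,
        pathway_posterior=draws.mean(axis=0),
        mc_se=_batch_means_se(draws),
        lambda_draws=np.concatenate(all_lam) if all_lam else None,
        pathway_ids=list(model.pathway_ids),
    )


_MAX_ENUM_PATHWAYS = 20


def exact_state_distribution(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    params: Parameters,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all 2^I pathway states and their normalized log posteriors.

    Returns ``(states, log_post)`` where ``states`` is a (2^I, I) binary
    matrix and ``log_post`` the exact log p(a | w) of each row.  Refuses
    models with more than 20 pathways.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    I = model.n_pathways
    if I > _MAX_ENUM_PATHWAYS:
        raise InputError(
            f"exact enumeration over 2^{I} states refused (limit I <= "
            f"{_MAX_ENUM_PATHWAYS}); use the Gibbs sampler instead"
        )
    n_states = 1 << I
    states = ((np.arange(n_states)[:, None] >> np.arange(I)[None, :]) & 1).astype(np.uint8)
    log_joint = np.empty(n_states)
    tau = model.tau_csc
    memb64 = model.membership.astype(np.int64)
    s_active = states.sum(axis=1).astype(int)
    if params.lambda_mode == "beta":
        log_prior = (betaln(params.alpha + s_active, params.beta + I - s_active)
                     - betaln(params.alpha, params.beta))
    else:
        lam = params.lambda_value
        if lam in (0.0, 1.0):
            log_prior = np.array([log_prior_a(s, params) for s in states])
        else:
            log_prior = s_active * np.log(lam) + (I - s_active) * np.log1p(-lam)
    for lo in range(0, n_states, chunk):
        hi = min(lo + chunk, n_states)
        n = states[lo:hi].astype(np.int64) @ memb64  # (c, J) active counts
        f = 1.0 - params.gamma * phi(n, params.mu)
        logf, zero = _safe_log_factors(f)
        log_p0 = np.asarray(logf @ tau)
        n_zero = np.asarray(zero.astype(float) @ tau)
        log_p0 = np.where(n_zero > 0, -np.inf, log_p0)
        with np.errstate(invalid="ignore"):
            terms = np.where(wv[None, :] == 1, _log1mexp(log_p0), log_p0)
        ll = np.where(np.isneginf(terms).any(axis=1), -np.inf, np.nansum(terms, axis=1))
        log_joint[lo:hi] = ll
    log_joint = log_joint + log_prior
    log_z = logsumexp(log_joint)
    if np.isneginf(log_z):
        raise UnattainableObservationError(
            "every pathway state has zero likelihood for this observation vector"
        )
    return states, log_joint - log_z


def exact_posterior(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    params: Parameters,
) -> np.ndarray:
    """Exact marginal posteriors p(a_i = 1 | w) by 2^I enumeration."""
    states, log_post = exact_state_distribution(model, w, params)
    post = np.exp(log_post)
    return states.T.astype(float) @ post
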