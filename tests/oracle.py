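"""Brute-force oracles used only by tests.

Everything here works directly from the generative definitions -- enumerate
the full metabolite-production matrix Z, collapse it to presence m, and sum
probabilities -- with no marginalization tricks, so it is independent of the
library's collapsed likelihood and annotation formulas.
"""

from __future__ import annotations

import itertools

import numpy as np

from pathmet.model import NO_BIN


def _iter_z(model, a):
    """All production matrices Z consistent with membership, with p(Z | a)."""
    I, J = model.n_pathways, model.n_metabolites
    free = [(i, j) for i in range(I) for j in range(J)
            if model.membership[i, j] == 1 and a[i] == 1]
    for bits in itertools.product((0, 1), repeat=len(free)):
        z = np.zeros((I, J), dtype=int)
        for (i, j), b in zip(free, bits):
            z[i, j] = b
        yield z


def _p_z_given_a(z, model, a, mu):
    p = 1.0
    for i in range(model.n_pathways):
        for j in range(model.n_metabolites):
            if model.membership[i, j] == 1 and a[i] == 1:
                p *= mu if z[i, j] else (1.0 - mu)
            elif z[i, j]:
                return 0.0
    return p


def _p_wk_given_m(wk, m, cands, gamma):
    """p(w_k | m_{J_k}): each present candidate detected with prob gamma."""
    p_none = (1.0 - gamma) ** int(m[cands].sum())
    return p_none if wk == 0 else 1.0 - p_none


def brute_likelihood(model, w, a, mu, gamma):
    """p(w | a) by full enumeration of Z."""
    total = 0.0
    for z in _iter_z(model, a):
        pz = _p_z_given_a(z, model, a, mu)
        if pz == 0.0:
            continue
        m = (z.sum(axis=0) > 0).astype(int)
        pw = 1.0
        for k in range(model.n_bins):
            pw *= _p_wk_given_m(w[k], m, model.candidates_of_bin[k], gamma)
        total += pz * pw
    return total


def brute_prior(a, params):
    from scipy.special import beta as beta_fn

    s, n = int(np.sum(a)), len(a)
    if params.lambda_mode == "beta":
        return beta_fn(params.alpha + s, params.beta + n - s) / beta_fn(
            params.alpha, params.beta
        )
    lam = params.lambda_value
    return lam**s * (1.0 - lam) ** (n - s)


def brute_posterior(model, w, params):
    """Exact marginals p(a_i = 1 | w) by enumerating both a and Z."""
    I = model.n_pathways
    states = list(itertools.product((0, 1), repeat=I))
    joint = np.array(
        [
            brute_prior(a, params)
            * brute_likelihood(model, w, np.array(a), params.mu, params.gamma)
            for a in states
        ]
    )
    joint /= joint.sum()
    return np.array(
        [sum(p for a, p in zip(states, joint) if a[i] == 1) for i in range(I)]
    )


def brute_joint_mj_wk(model, j, a, wkj, mj, mu, gamma):
    """p(m_j = mj, w_kj = wkj | a) by full enumeration of Z."""
    k = int(model.bin_of_metabolite[j])
    total = 0.0
    for z in _iter_z(model, a):
        pz = _p_z_given_a(z, model, a, mu)
        if pz == 0.0:
            continue
        m = (z.sum(axis=0) > 0).astype(int)
        if m[j] != mj:
            continue
        if k == NO_BIN:
            total += pz if wkj == 0 else 0.0
        else:
            total += pz * _p_wk_given_m(wkj, m, model.candidates_of_bin[k], gamma)
    return total


def brute_metabolite_posterior(model, w, params):
    """p(m_j = 1 | w) by enumerating a and Z jointly."""
    I, J = model.n_pathways, model.n_metabolites
    num = np.zeros(J)
    den = 0.0
    for a in itertools.product((0, 1), repeat=I):
        a = np.array(a)
        pa = brute_prior(a, params)
        for z in _iter_z(model, a):
            pz = _p_z_given_a(z, model, a, params.mu)
            if pz == 0.0:
                continue
            m = (z.sum(axis=0) > 0).astype(int)
            pw = 1.0
            for k in range(model.n_bins):
                pw *= _p_wk_given_m(w[k], m, model.candidates_of_bin[k], params.gamma)
            weight = pa * pz * pw
            den += weight
            num += weight * m
    return num / den


def pair_count_auc(scores, labels):
    """O(n^2) Mann-Whitney AUC with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def hypergeom_tail_p(k, big_k, n, big_n):
    """One-sided (greater) Fisher p-value by explicit tail summation.

    Probability of drawing >= k marked items when n of big_n items are drawn
    and big_k are marked.
    """
    from math import comb

    total = comb(big_n, n)
    upper = min(big_k, n)
    return sum(
        comb(big_k, x) * comb(big_n - big_k, n - x) for x in range(k, upper + 1)
    ) / total
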