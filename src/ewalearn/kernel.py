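"""Numba likelihood kernel: pointwise log-likelihood and analytic gradients.

The kernel walks the event sequence once, maintaining per-individual
attraction scores ``A`` and their sensitivities ``dA/dphi`` (the attraction
recursion is the only place a learning parameter enters with memory).  It
returns the total and pointwise log-likelihood plus the gradient with respect
to every individual's *natural-scale* parameters; link-function and
hierarchical chain rules are applied by the caller in numpy.

Gradient identities used (I the individual softmax, S the social multinomial,
P = (1-g) I + g S, c the observed choice, p = P_c):

* d log p / d lambda = w I_c (A_c - sum_i I_i A_i) / p           (w = 1-g, or 1
  when no social information is defined for the event)
* d log p / d A_i   = w lambda I_c (delta_ci - I_i) / p, folded into phi via
  the recursion dA'_c = (1-phi) dA_c + (pi - A_c)
* d log p / d gamma = (S_c - I_c) / p
* d log p / d f_c   = g S_c (ln N_c - sum_i S_i ln N_i) / p
* d log p / d beta_k = g S_c (kappa_kc - sum_i S_i kappa_ki) / p
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def ewa_loglik_grad(
    actor,  # int32 [E]
    choice,  # int32 [E]
    payoff,  # float64 [E]
    N,  # float64 [E, K]
    kappa,  # float64 [5, E, K]
    social_any,  # uint8 [E]
    lam,  # float64 [J]
    phi,  # float64 [J]
    gam,  # float64 [J]
    fc,  # float64 [J]
    beta,  # float64 [5, J]
    use_social,  # bool
    fc_free,  # bool
    active,  # uint8 [5]
    want_grad,  # bool
):
    E = actor.shape[0]
    K = N.shape[1]
    J = lam.shape[0]
    A = np.zeros((J, K))
    dA = np.zeros((J, K))
    pointwise = np.empty(E)
    glam = np.zeros(J)
    gphi = np.zeros(J)
    ggam = np.zeros(J)
    gfc = np.zeros(J)
    gbeta = np.zeros((5, J))
    I = np.empty(K)
    S = np.empty(K)
    logN = np.empty(K)

    total = 0.0
    for e in range(E):
        j = actor[e]
        # individual softmax
        zmax = -1e300
        for i in range(K):
            z = lam[j] * A[j, i]
            if z > zmax:
                zmax = z
        ssum = 0.0
        for i in range(K):
            I[i] = np.exp(lam[j] * A[j, i] - zmax)
            ssum += I[i]
        for i in range(K):
            I[i] /= ssum

        social = use_social and social_any[e] == 1
        g = gam[j] if social else 0.0
        if social:
            f = fc[j] if fc_free else 1.0
            wmax = -1e300
            for i in range(K):
                if N[e, i] > 0.0:
                    logN[i] = np.log(N[e, i])
                    b = 0.0
                    for k in range(5):
                        if active[k] == 1:
                            b += beta[k, j] * kappa[k, e, i]
                    S[i] = f * logN[i] + b
                    if S[i] > wmax:
                        wmax = S[i]
                else:
                    logN[i] = 0.0
                    S[i] = -np.inf
            wsum = 0.0
            for i in range(K):
                if N[e, i] > 0.0:
                    S[i] = np.exp(S[i] - wmax)
                    wsum += S[i]
                else:
                    S[i] = 0.0
            for i in range(K):
                S[i] /= wsum

        c = choice[e]
        if social:
            p = (1.0 - g) * I[c] + g * S[c]
            w = 1.0 - g
        else:
            p = I[c]
            w = 1.0
        if p <= 0.0:
            pointwise[e] = -np.inf
            total = -np.inf
            # cannot recover; stop accumulating gradients meaningfully
            for e2 in range(e + 1, E):
                pointwise[e2] = 0.0
            return total, pointwise, glam, gphi, ggam, gfc, gbeta
        lp = np.log(p)
        pointwise[e] = lp
        total += lp

        if want_grad:
            Abar = 0.0
            dAbar = 0.0
            for i in range(K):
                Abar += I[i] * A[j, i]
                dAbar += I[i] * dA[j, i]
            glam[j] += w * I[c] * (A[j, c] - Abar) / p
            gphi[j] += w * lam[j] * I[c] * (dA[j, c] - dAbar) / p
            if social:
                ggam[j] += (S[c] - I[c]) / p
                if S[c] > 0.0:
                    if fc_free:
                        lbar = 0.0
                        for i in range(K):
                            if S[i] > 0.0:
                                lbar += S[i] * logN[i]
                        gfc[j] += g * S[c] * (logN[c] - lbar) / p
                    for k in range(5):
                        if active[k] == 1:
                            kbar = 0.0
                            for i in range(K):
                                if S[i] > 0.0:
                                    kbar += S[i] * kappa[k, e, i]
                            gbeta[k, j] += g * S[c] * (kappa[k, e, c] - kbar) / p

        # attraction update for the chosen technique only
        Aold = A[j, c]
        A[j, c] = (1.0 - phi[j]) * Aold + phi[j] * payoff[e]
        dA[j, c] = (1.0 - phi[j]) * dA[j, c] + (payoff[e] - Aold)

    return total, pointwise, glam, gphi, ggam, gfc, gbeta


@njit(cache=False)
def ewa_choice_probs(
    actor,
    choice,
    payoff,
    N,
    kappa,
    social_any,
    lam,
    phi,
    gam,
    fc,
    beta,
    use_social,
    fc_free,
    active,
):
    """Forward one-step-ahead probability matrix [E, K] (no gradients)."""
    E = actor.shape[0]
    K = N.shape[1]
    J = lam.shape[0]
    A = np.zeros((J, K))
    out = np.empty((E, K))
    I = np.empty(K)
    S = np.empty(K)
    for e in range(E):
        j = actor[e]
        zmax = -1e300
        for i in range(K):
            z = lam[j] * A[j, i]
            if z > zmax:
                zmax = z
        ssum = 0.0
        for i in range(K):
            I[i] = np.exp(lam[j] * A[j, i] - zmax)
            ssum += I[i]
        for i in range(K):
            I[i] /= ssum
        social = use_social and social_any[e] == 1
        if social:
            f = fc[j] if fc_free else 1.0
            wmax = -1e300
            for i in range(K):
                if N[e, i] > 0.0:
                    b = 0.0
                    for k in range(5):
                        if active[k] == 1:
                            b += beta[k, j] * kappa[k, e, i]
                    S[i] = f * np.log(N[e, i]) + b
                    if S[i] > wmax:
                        wmax = S[i]
                else:
                    S[i] = -np.inf
            wsum = 0.0
            for i in range(K):
                if N[e, i] > 0.0:
                    S[i] = np.exp(S[i] - wmax)
                    wsum += S[i]
                else:
                    S[i] = 0.0
            g = gam[j]
            for i in range(K):
                out[e, i] = (1.0 - g) * I[i] + g * S[i] / wsum
        else:
            for i in range(K):
                out[e, i] = I[i]
        c = choice[e]
        A[j, c] = (1.0 - phi[j]) * A[j, c] + phi[j] * payoff[e]
    return out


__all__ = ["ewa_choice_probs", "ewa_loglik_grad"]
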