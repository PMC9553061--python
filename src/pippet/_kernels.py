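"""Numba kernels for the per-dt filter loops.

The loops run at dt = 1 ms over tens of simulated seconds per trial, so the
inner stepping is compiled.  All randomness stays outside: callers pass a
pre-drawn array of standard-normal deviates for the phase-tracking noise.

State convention: ``mu[k]``/``V[k]`` hold the posterior *before* step k is
processed; an event at grid step k is absorbed during step k, so ``mu[k]``
is the left-hand limit mu_t at that event and ``mu[k+1]`` reflects mu_t+.
"""

import numpy as np
from numba import njit

V_FLOOR = 1e-12
_SQRT2PI = np.sqrt(2.0 * np.pi)


@njit(cache=True)
def _reset_moments(mu, V, phases, variances, strengths, lam0):
    """Hazard and event-reset moments for one template at state (mu, V).

    Returns (Lam, mu_hat, V_hat): the total subjective hazard
    Lam = lam0 + sum_i Lam_i with Lam_i = lambda_i N(mu | phi_i, v_i + V),
    and the precision-weighted reset mean/variance, where the background
    term keeps the prior moments (mu, V).
    """
    n = phases.size
    Lam = lam0
    mu_hat = lam0 * mu
    # first pass: hazards and per-expectation conditional moments
    lam_i = np.empty(n)
    mu_i = np.empty(n)
    V_i = np.empty(n)
    for i in range(n):
        s = variances[i] + V
        d = mu - phases[i]
        lam_i[i] = strengths[i] * np.exp(-0.5 * d * d / s) / (_SQRT2PI * np.sqrt(s))
        prec = 1.0 / V + 1.0 / variances[i]
        mu_i[i] = (mu / V + phases[i] / variances[i]) / prec
        V_i[i] = 1.0 / prec
        Lam += lam_i[i]
        mu_hat += lam_i[i] * mu_i[i]
    mu_hat /= Lam
    V_hat = lam0 * (V + (mu - mu_hat) ** 2)
    for i in range(n):
        V_hat += lam_i[i] * (V_i[i] + (mu_i[i] - mu_hat) ** 2)
    V_hat /= Lam
    return Lam, mu_hat, V_hat


@njit(cache=True)
def pippet_kernel(n_steps, dt, mu0, V0, sigma, eta_mu, noise,
                  phases, variances, strengths, lam0, event_steps):
    """Single-template filter over ``n_steps`` Euler steps.

    Returns (mu, V, Lam, corrections, pre_event_V, floor_hits); trajectory
    arrays have length n_steps + 1.
    """
    mu = np.empty(n_steps + 1)
    V = np.empty(n_steps + 1)
    Lam_out = np.empty(n_steps + 1)
    n_ev = event_steps.size
    corrections = np.zeros(n_ev)
    pre_event_V = np.zeros(n_ev)
    mu[0] = mu0
    V[0] = V0
    sig2 = sigma * sigma
    ev_ptr = 0
    floor_hits = 0
    for k in range(n_steps):
        Lam, mu_hat, V_hat = _reset_moments(
            mu[k], V[k], phases, variances, strengths, lam0)
        Lam_out[k] = Lam
        dN = 0.0
        if ev_ptr < n_ev and event_steps[ev_ptr] == k:
            dN = 1.0
            corrections[ev_ptr] = mu_hat - mu[k]
            pre_event_V[ev_ptr] = V[k]
            ev_ptr += 1
        w = dN - Lam * dt
        mu[k + 1] = mu[k] + dt + (mu_hat - mu[k]) * w \
            + eta_mu * np.sqrt(dt) * noise[k]
        V_new = V[k] + sig2 * dt + (V_hat - V[k]) * w
        if V_new < V_FLOOR:
            V_new = V_FLOOR
            floor_hits += 1
        V[k + 1] = V_new
        if not (np.isfinite(mu[k + 1]) and np.isfinite(V[k + 1])):
            raise ValueError("filter state became non-finite (dt too large?)")
    Lam_out[n_steps], _, _ = _reset_moments(
        mu[n_steps], V[n_steps], phases, variances, strengths, lam0)
    return mu, V, Lam_out, corrections, pre_event_V, floor_hits


@njit(cache=True)
def ppippet_kernel(n_steps, dt, mu0, V0, sigma, eta_mu, noise,
                   phases, variances, strengths, indptr, lam0, p0,
                   event_steps):
    """Multiple-template filter with pattern inference.

    Template m owns the slice ``indptr[m]:indptr[m+1]`` of the flattened
    event arrays.  Per step: candidate (Lam^m, mu_hat^m, V_hat^m) are
    computed from the shared posterior, template probabilities are updated
    from the hazard ratios, the candidates are marginalized with the
    updated probabilities, and the shared posterior takes one Euler step.

    Returns (mu, V, Lam, probs, hazards, corrections, pre_event_V,
    floor_hits); ``probs`` and ``hazards`` are (n_steps + 1, M).
    """
    M = p0.size
    mu = np.empty(n_steps + 1)
    V = np.empty(n_steps + 1)
    Lam_out = np.empty(n_steps + 1)
    probs = np.empty((n_steps + 1, M))
    hazards = np.empty((n_steps + 1, M))
    n_ev = event_steps.size
    corrections = np.zeros(n_ev)
    pre_event_V = np.zeros(n_ev)
    mu[0] = mu0
    V[0] = V0
    probs[0] = p0
    sig2 = sigma * sigma
    ev_ptr = 0
    floor_hits = 0
    Lam_m = np.empty(M)
    mu_m = np.empty(M)
    V_m = np.empty(M)
    for k in range(n_steps):
        for m in range(M):
            Lam_m[m], mu_m[m], V_m[m] = _reset_moments(
                mu[k], V[k], phases[indptr[m]:indptr[m + 1]],
                variances[indptr[m]:indptr[m + 1]],
                strengths[indptr[m]:indptr[m + 1]], lam0)
            hazards[k, m] = Lam_m[m]
        Lam = 0.0
        for m in range(M):
            Lam += probs[k, m] * Lam_m[m]
        Lam_out[k] = Lam
        dN = 0.0
        is_event = ev_ptr < n_ev and event_steps[ev_ptr] == k
        if is_event:
            dN = 1.0
            pre_event_V[ev_ptr] = V[k]
        w = dN - Lam * dt
        # pattern inference (Euler step of the replicator-style update),
        # clipped at zero and renormalized
        total = 0.0
        for m in range(M):
            p_new = probs[k, m] + probs[k, m] * (Lam_m[m] / Lam - 1.0) * w
            if p_new < 0.0:
                p_new = 0.0
            probs[k + 1, m] = p_new
            total += p_new
        for m in range(M):
            probs[k + 1, m] /= total
        # marginalize the candidate posteriors with the updated weights
        mu_hat = 0.0
        for m in range(M):
            mu_hat += probs[k + 1, m] * mu_m[m]
        V_hat = 0.0
        for m in range(M):
            V_hat += probs[k + 1, m] * (V_m[m] + (mu_m[m] - mu_hat) ** 2)
        if is_event:
            corrections[ev_ptr] = mu_hat - mu[k]
            ev_ptr += 1
        mu[k + 1] = mu[k] + dt + (mu_hat - mu[k]) * w \
            + eta_mu * np.sqrt(dt) * noise[k]
        V_new = V[k] + sig2 * dt + (V_hat - V[k]) * w
        if V_new < V_FLOOR:
            V_new = V_FLOOR
            floor_hits += 1
        V[k + 1] = V_new
        if not (np.isfinite(mu[k + 1]) and np.isfinite(V[k + 1])):
            raise ValueError("filter state became non-finite (dt too large?)")
    Lam = 0.0
    for m in range(M):
        h, _, _ = _reset_moments(
            mu[n_steps], V[n_steps], phases[indptr[m]:indptr[m + 1]],
            variances[indptr[m]:indptr[m + 1]],
            strengths[indptr[m]:indptr[m + 1]], lam0)
        hazards[n_steps, m] = h
        Lam += probs[n_steps, m] * h
    Lam_out[n_steps] = Lam
    return (mu, V, Lam_out, probs, hazards, corrections, pre_event_V,
            floor_hits)
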