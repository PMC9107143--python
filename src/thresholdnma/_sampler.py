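"""Adaptive Metropolis-within-Gibbs sampler for the binomial-logit NMA model.

Model, for arm ``a`` of study ``i`` with treatment ``t``:

    r_ia ~ Binomial(n_ia, p_ia)          (continuous relaxation in r, n)
    logit(p_ia) = mu_i + delta_ia        (delta = 0 on the baseline arm)

Study effects ``delta_i`` follow the exchangeable random-effects prior with
mean ``d[t] - d[t_base]`` (consistency) and the standard multi-arm covariance
``tau^2 / 2 * (I + J)`` (variance tau^2, pairwise correlation 1/2).  In a
node-split fit, flagged (two-arm) studies take mean ``d_dir`` instead.

Priors: mu_i, d_k, d_dir ~ Normal(0, prior_sd^2); tau ~ Uniform(0, tau_upper).

The likelihood only ever enters Metropolis ratios, so the binomial
coefficient (a constant in the parameters, finite for real-valued counts via
log-gamma) cancels and is never evaluated.

Everything here is numba-compiled and operates on flat arrays; the public
wrapper lives in :mod:`thresholdnma.nma`.  One call runs one chain.
Component-wise Gaussian random walks adapt their scales toward a 0.44
acceptance rate during burn-in only (so the post-burn-in kernel is a fixed,
valid MCMC kernel).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _softplus(x: float) -> float:
    if x > 0.0:
        return x + np.log1p(np.exp(-x))
    return np.log1p(np.exp(x))


@njit(cache=True)
def _block_logp(i, study_start, arm_treat, delta, d, ddir, direct_flag, tau):
    """Log-density of study i's random-effect vector under the MVN prior.

    Uses the closed-form inverse/determinant of tau^2/2 (I + J):
    inv = (2/tau^2)(I - J/(m+1)), logdet = m log(tau^2/2) + log(m+1).
    """
    a0 = study_start[i]
    a1 = study_start[i + 1]
    m = a1 - a0 - 1
    tb = arm_treat[a0]
    t2 = tau * tau
    ssum = 0.0
    sq = 0.0
    for a in range(a0 + 1, a1):
        if direct_flag[i] == 1:
            mean = ddir
        else:
            mean = d[arm_treat[a]] - d[tb]
        z = delta[a] - mean
        ssum += z
        sq += z * z
    q = (2.0 / t2) * (sq - ssum * ssum / (m + 1.0))
    return -0.5 * (m * _LOG2PI + m * np.log(t2 / 2.0) + np.log(m + 1.0) + q)


@njit(cache=True)
def _total_block_logp(n_studies, study_start, arm_treat, delta, d, ddir, direct_flag, tau):
    tot = 0.0
    for i in range(n_studies):
        tot += _block_logp(i, study_start, arm_treat, delta, d, ddir, direct_flag, tau)
    return tot


@njit(cache=True)
def _study_involves(i, k, study_start, arm_treat):
    for a in range(study_start[i], study_start[i + 1]):
        if arm_treat[a] == k:
            return True
    return False


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burn_in,
    thin,
    arm_r,
    arm_n,
    arm_study,
    arm_treat,
    study_start,
    direct_flag,
    prior_sd,
    tau_upper,
    mu0,
    delta0,
    d0,
    tau0,
    ddir0,
):
    """Run one MCMC chain; returns (d, tau, mu, ddir) post-burn-in thinned draws."""
    np.random.seed(seed)
    n_arms = arm_r.shape[0]
    n_studies = study_start.shape[0] - 1
    K = d0.shape[0]

    mu = mu0.copy()
    delta = delta0.copy()
    d = d0.copy()
    tau = tau0
    ddir = ddir0
    has_direct = False
    for i in range(n_studies):
        if direct_flag[i] == 1:
            has_direct = True

    prior_var = prior_sd * prior_sd

    # proposal scales (log) and acceptance counters, adapted in batches of 50
    ls_mu = np.zeros(n_studies)
    ls_delta = np.zeros(n_arms)
    ls_d = np.full(K, -0.5)
    ls_td = np.full(K, -0.5)
    ls_tau = -1.0
    ls_tau_nc = -1.0
    ls_ddir = -0.5
    acc_mu = np.zeros(n_studies)
    acc_delta = np.zeros(n_arms)
    acc_d = np.zeros(K)
    acc_td = np.zeros(K)
    acc_tau = 0.0
    acc_tau_nc = 0.0
    acc_ddir = 0.0

    n_keep = (n_iter - burn_in) // thin
    out_d = np.empty((n_keep, K))
    out_tau = np.empty(n_keep)
    out_mu = np.empty((n_keep, n_studies))
    out_ddir = np.empty(n_keep)

    kept = 0
    batch = 0
    for it in range(n_iter):
        # --- study baselines mu_i
        for i in range(n_studies):
            prop = mu[i] + np.exp(ls_mu[i]) * np.random.normal()
            dlp = -0.5 * (prop * prop - mu[i] * mu[i]) / prior_var
            for a in range(study_start[i], study_start[i + 1]):
                eo = mu[i] + delta[a]
                en = prop + delta[a]
                dlp += arm_r[a] * (en - eo) - arm_n[a] * (_softplus(en) - _softplus(eo))
            if np.log(np.random.random()) < dlp:
                mu[i] = prop
                acc_mu[i] += 1.0

        # --- random effects delta_a (non-baseline arms)
        for i in range(n_studies):
            a0 = study_start[i]
            for a in range(a0 + 1, study_start[i + 1]):
                old = delta[a]
                lp_old = _block_logp(i, study_start, arm_treat, delta, d, ddir, direct_flag, tau)
                prop = old + np.exp(ls_delta[a]) * np.random.normal()
                eo = mu[i] + old
                en = mu[i] + prop
                dlp = arm_r[a] * (en - eo) - arm_n[a] * (_softplus(en) - _softplus(eo))
                delta[a] = prop
                lp_new = _block_logp(i, study_start, arm_treat, delta, d, ddir, direct_flag, tau)
                dlp += lp_new - lp_old
                if np.log(np.random.random()) < dlp:
                    acc_delta[a] += 1.0
                else:
                    delta[a] = old

        # --- basic parameters d_k, k = 2..K (index 1..K-1; d[0] pinned at 0)
        for k in range(1, K):
            old = d[k]
            prop = old + np.exp(ls_d[k]) * np.random.normal()
            dlp = -0.5 * (prop * prop - old * old) / prior_var
            for i in range(n_studies):
                if direct_flag[i] == 0 and _study_involves(i, k, study_start, arm_treat):
                    lp_old = _block_logp(
                        i, study_start, arm_treat, delta, d, ddir, direct_flag, tau
                    )
                    d[k] = prop
                    lp_new = _block_logp(
                        i, study_start, arm_treat, delta, d, ddir, direct_flag, tau
                    )
                    d[k] = old
                    dlp += lp_new - lp_old
            if np.log(np.random.random()) < dlp:
                d[k] = prop
                acc_d[k] += 1.0

        # --- translation moves: shift d_k together with the random effects of
        # the studies that involve k, leaving the exchangeable prior invariant.
        # This decouples the strong d-delta correlation of the hierarchy.
        for k in range(1, K):
            s = np.exp(ls_td[k]) * np.random.normal()
            prop_d = d[k] + s
            dlp = -0.5 * (prop_d * prop_d - d[k] * d[k]) / prior_var
            for i in range(n_studies):
                if direct_flag[i] == 1:
                    continue
                a0 = study_start[i]
                tb = arm_treat[a0]
                for a in range(a0 + 1, study_start[i + 1]):
                    shift = 0.0
                    if arm_treat[a] == k:
                        shift = s
                    elif tb == k:
                        shift = -s
                    if shift != 0.0:
                        eo = mu[i] + delta[a]
                        en = eo + shift
                        dlp += arm_r[a] * (en - eo) - arm_n[a] * (
                            _softplus(en) - _softplus(eo)
                        )
            if np.log(np.random.random()) < dlp:
                d[k] = prop_d
                for i in range(n_studies):
                    if direct_flag[i] == 1:
                        continue
                    a0 = study_start[i]
                    tb = arm_treat[a0]
                    for a in range(a0 + 1, study_start[i + 1]):
                        if arm_treat[a] == k:
                            delta[a] += s
                        elif tb == k:
                            delta[a] -= s
                acc_td[k] += 1.0

        # --- split-off direct effect
        if has_direct:
            old = ddir
            prop = old + np.exp(ls_ddir) * np.random.normal()
            dlp = -0.5 * (prop * prop - old * old) / prior_var
            for i in range(n_studies):
                if direct_flag[i] == 1:
                    lp_old = _block_logp(
                        i, study_start, arm_treat, delta, d, old, direct_flag, tau
                    )
                    lp_new = _block_logp(
                        i, study_start, arm_treat, delta, d, prop, direct_flag, tau
                    )
                    dlp += lp_new - lp_old
            if np.log(np.random.random()) < dlp:
                ddir = prop
                acc_ddir += 1.0

        # --- heterogeneity tau, Uniform(0, tau_upper) prior.
        # Conditional on the residuals z the precision 1/tau^2 is
        # Gamma((M-1)/2, W/2) (M = total random-effect dimensions,
        # W = sum of the studies' quadratic forms at tau = 1), truncated to
        # tau < tau_upper: draw it directly.  Falls back to a random walk
        # when M < 2, where that Gamma shape would be improper.
        M = n_arms - n_studies
        W = 0.0
        for i in range(n_studies):
            a0 = study_start[i]
            a1 = study_start[i + 1]
            tb = arm_treat[a0]
            m = a1 - a0 - 1
            ssum = 0.0
            sq = 0.0
            for a in range(a0 + 1, a1):
                if direct_flag[i] == 1:
                    mean = ddir
                else:
                    mean = d[arm_treat[a]] - d[tb]
                z = delta[a] - mean
                ssum += z
                sq += z * z
            W += 2.0 * (sq - ssum * ssum / (m + 1.0))
        if M >= 2 and W > 0.0:
            for _ in range(100):
                phi = np.random.gamma((M - 1) / 2.0, 2.0 / W)
                cand = 1.0 / np.sqrt(phi)
                if cand < tau_upper:
                    tau = cand
                    break
        else:
            prop = tau + np.exp(ls_tau) * np.random.normal()
            if 0.0 < prop < tau_upper:
                lp_old = _total_block_logp(
                    n_studies, study_start, arm_treat, delta, d, ddir, direct_flag, tau
                )
                lp_new = _total_block_logp(
                    n_studies, study_start, arm_treat, delta, d, ddir, direct_flag, prop
                )
                if np.log(np.random.random()) < lp_new - lp_old:
                    tau = prop
                    acc_tau += 1.0

        # --- non-centered tau moves (ancillarity-sufficiency interweaving):
        # hold the standardised residuals fixed and rescale delta with tau,
        # so the acceptance ratio is the likelihood ratio alone (uniform tau
        # prior; the residual prior does not depend on tau in this frame).
        # The posterior is ridge-shaped in (tau, shrinkage); several moves per
        # sweep, one of them long-range, keep the chain travelling along it.
        for nc_rep in range(4):
            width = np.exp(ls_tau_nc) * (8.0 if nc_rep == 3 else 1.0)
            prop = tau + width * np.random.normal()
            if not (0.0 < prop < tau_upper):
                continue
            scale = prop / tau
            dlp = 0.0
            for i in range(n_studies):
                a0 = study_start[i]
                tb = arm_treat[a0]
                for a in range(a0 + 1, study_start[i + 1]):
                    if direct_flag[i] == 1:
                        mean = ddir
                    else:
                        mean = d[arm_treat[a]] - d[tb]
                    eo = mu[i] + delta[a]
                    en = mu[i] + mean + (delta[a] - mean) * scale
                    dlp += arm_r[a] * (en - eo) - arm_n[a] * (_softplus(en) - _softplus(eo))
            if np.log(np.random.random()) < dlp:
                for i in range(n_studies):
                    a0 = study_start[i]
                    tb = arm_treat[a0]
                    for a in range(a0 + 1, study_start[i + 1]):
                        if direct_flag[i] == 1:
                            mean = ddir
                        else:
                            mean = d[arm_treat[a]] - d[tb]
                        delta[a] = mean + (delta[a] - mean) * scale
                tau = prop
                if nc_rep != 3:  # adapt on the small moves only
                    acc_tau_nc += 1.0 / 3.0

        # --- scale adaptation (burn-in only, diminishing)
        if it < burn_in and (it + 1) % 50 == 0:
            batch += 1
            step = min(0.1, 1.0 / np.sqrt(batch))
            for i in range(n_studies):
                ls_mu[i] += step if acc_mu[i] / 50.0 > 0.44 else -step
                acc_mu[i] = 0.0
            for a in range(n_arms):
                ls_delta[a] += step if acc_delta[a] / 50.0 > 0.44 else -step
                acc_delta[a] = 0.0
            for k in range(1, K):
                ls_d[k] += step if acc_d[k] / 50.0 > 0.44 else -step
                acc_d[k] = 0.0
                ls_td[k] += step if acc_td[k] / 50.0 > 0.44 else -step
                acc_td[k] = 0.0
            ls_tau += step if acc_tau / 50.0 > 0.44 else -step
            acc_tau = 0.0
            ls_tau_nc += step if acc_tau_nc / 50.0 > 0.44 else -step
            acc_tau_nc = 0.0
            if has_direct:
                ls_ddir += step if acc_ddir / 50.0 > 0.44 else -step
                acc_ddir = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            out_d[kept] = d
            out_tau[kept] = tau
            out_mu[kept] = mu
            out_ddir[kept] = ddir
            kept += 1

    return out_d, out_tau, out_mu, out_ddir
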