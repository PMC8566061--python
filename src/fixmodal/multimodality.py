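"""Bayesian multimodality assessment of fixation position distributions.

Each accepted fixation contributes a 500-sample horizontal or vertical
position distribution.  To decide whether such a distribution is unimodal,
a finite mixture of 1..kmax univariate normal components is fitted with a
reversible-jump MCMC sampler in the style of Richardson & Green: standard
Gibbs updates of the weights, means, variances and allocations within a
model, plus split/combine and birth/death moves that change the number of
components K.  The kept draws of K give a posterior over K, from which the
posterior odds of multimodality b = P(K>1 | data) / P(K=1 | data) and the
Bayes factor BF = b / a follow, with a the prior odds of K > 1.

Evidence categories on the natural-log Bayes factor:
log BF <= 1 unimodal; (1, 3] positive; (3, 5] strong; > 5 very strong.

The sampler uses data-adaptive hyperpriors (see :class:`MixturePrior`);
means are kept in ascending order (the identifiability constraint under
which the split/combine acceptance ratio is derived), which also fixes the
component labelling in reports.  Non-convergence of the single chain is
not detected; the chain length is a configuration choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "MixturePrior",
    "MixtureFit",
    "EVIDENCE_CATEGORIES",
    "DegenerateDataError",
    "fit_mixture_rjmcmc",
    "prior_odds_multimodal",
    "bayes_factor",
    "classify_evidence",
    "sanitize_bf_cohort",
    "component_count",
]

#: evidence categories in increasing order of support for multimodality
EVIDENCE_CATEGORIES = ("unimodal", "positive", "strong", "very_strong")

#: log-BF cap used by cohort sanitization when no finite value exists
LOGBF_FALLBACK_CAP = 2.0e4


class DegenerateDataError(ValueError):
    """Input has zero variance; a mixture of normals cannot be fitted."""


@dataclass
class MixturePrior:
    """Hyperprior configuration for the normal-mixture rjMCMC sampler.

    The location/scale hyperparameters adapt to the data: with R the data
    range and xi the midrange, component means are a priori
    N(xi, R^2 / kappa_scale) and component precisions Gamma(alpha, beta)
    with the rate beta itself Gamma(beta_shape, beta_rate_scale / R^2)
    (a weakly informative hierarchical variance prior).  Weights are
    symmetric Dirichlet(delta); K is a priori uniform on {1..kmax} unless
    ``k_weights`` is given.
    """

    kmax: int = 5
    k_weights: np.ndarray | None = None  # prior P(K = 1..kmax); None = uniform
    delta: float = 1.0
    kappa_scale: float = 1.0  # kappa = kappa_scale / R^2
    alpha: float = 2.0
    beta_shape: float = 0.2  # g
    beta_rate_scale: float = 10.0  # h = beta_rate_scale / R^2

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax must be at least 2")
        if self.k_weights is not None:
            kw = np.asarray(self.k_weights, dtype=float)
            if len(kw) != self.kmax:
                raise ValueError("k_weights must have length kmax")
            if (kw < 0).any() or not math.isclose(kw.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("k_weights must be a probability vector")
            self.k_weights = kw

    def log_pk(self) -> np.ndarray:
        """log prior over K = 1..kmax."""
        if self.k_weights is None:
            return np.full(self.kmax, -math.log(self.kmax))
        with np.errstate(divide="ignore"):
            return np.log(self.k_weights)


@dataclass
class MixtureFit:
    """Posterior summary of one fixation's mixture fit.

    ``posterior_k[j]`` is P(K = j+1 | data) estimated from the kept draws;
    ``components`` lists (mean, sd, weight) for the modal K, relabelled by
    ascending mean; ``bf``/``log_bf`` may be ``inf`` when no kept draw had
    K = 1 (cohort-level sanitization replaces these, see
    :func:`sanitize_bf_cohort`).
    """

    k_draws: np.ndarray
    posterior_k: np.ndarray
    modal_k: int
    components: list[tuple[float, float, float]]
    prior_odds: float
    posterior_odds: float
    bf: float
    log_bf: float
    category: str
    n_samples: int = 0
    axis: str = ""
    subject_id: str = ""
    session_id: str = ""
    trial_index: int = -1


def prior_odds_multimodal(
    prior: MixturePrior,
    n_sim: int | None = None,
    seed: int | None = None,
) -> float:
    """Prior odds a = P(K > 1) / P(K = 1).

    Computed in closed form from the prior over K; when ``n_sim`` is given,
    estimated instead by Monte-Carlo draws of K (a cross-check of the
    analytic route, and the general route for priors only available as a
    sampler).
    """
    pk = np.exp(prior.log_pk())
    if n_sim is None:
        p1 = pk[0]
        if p1 <= 0:
            raise ZeroDivisionError("prior puts no mass on K = 1; prior odds infinite")
        if p1 >= 1:
            raise ZeroDivisionError(
                "prior puts all mass on K = 1; prior odds zero and Bayes factors undefined"
            )
        return float((1.0 - p1) / p1)
    if n_sim < 10**5:
        raise ValueError("simulation estimate needs n_sim >= 1e5")
    rng = np.random.default_rng(seed)
    draws = rng.choice(np.arange(1, prior.kmax + 1), size=n_sim, p=pk)
    n1 = int(np.sum(draws == 1))
    if n1 == 0:
        raise ZeroDivisionError("no simulated draw had K = 1; prior odds infinite")
    return float((n_sim - n1) / n1)


def bayes_factor(fit: "MixtureFit | np.ndarray", a: float) -> tuple[float, float]:
    """Bayes factor BF = b / a from the kept K draws.

    b is the posterior odds P(K>1|data)/P(K=1|data).  When no kept draw has
    K = 1, BF is +inf (flagged for cohort sanitization); when no draw has
    K > 1, BF = 0 and log BF = -inf.
    """
    if a <= 0:
        raise ValueError("prior odds must be positive")
    post = fit.posterior_k if isinstance(fit, MixtureFit) else np.asarray(fit, float)
    p1 = float(post[0])
    pm = float(post[1:].sum())
    if p1 == 0.0:
        return math.inf, math.inf
    if pm == 0.0:
        return 0.0, -math.inf
    bf = (pm / p1) / a
    return bf, math.log(bf)


def classify_evidence(log_bf: float) -> str:
    """Map a log Bayes factor to its evidence category."""
    if log_bf <= 1.0:
        return "unimodal"
    if log_bf <= 3.0:
        return "positive"
    if log_bf <= 5.0:
        return "strong"
    return "very_strong"


def component_count(fit: MixtureFit) -> int:
    """Posterior-modal number of components (ties broken toward smaller K)."""
    return int(np.argmax(fit.posterior_k)) + 1


def sanitize_bf_cohort(fits: list[MixtureFit]) -> list[MixtureFit]:
    """Cohort-level cleanup of degenerate Bayes factors.

    BF = 0 is replaced by 0.003 before taking logs; infinite log BF is
    replaced by the maximum finite log BF in the cohort (or a documented
    cap when the whole cohort is infinite).  Categories are recomputed from
    the sanitized log BF.  Returns new fit objects; the inputs are left
    untouched so the raw values remain available.
    """
    finite = [f.log_bf for f in fits if math.isfinite(f.log_bf)]
    cap = max(finite) if finite else LOGBF_FALLBACK_CAP
    out = []
    for f in fits:
        bf, log_bf = f.bf, f.log_bf
        if bf == 0.0:
            bf = 0.003
            log_bf = math.log(bf)
        if math.isinf(log_bf) and log_bf > 0:
            log_bf = cap
            bf = math.exp(min(log_bf, 700.0))
        out.append(replace(f, bf=bf, log_bf=log_bf, category=classify_evidence(log_bf)))
    return out


# ---------------------------------------------------------------------------
# rjMCMC sampler internals
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


def _log_beta22(u: float) -> float:
    # Beta(2, 2) log density: 6 u (1 - u)
    return math.log(6.0) + math.log(u) + math.log1p(-u)


class _MixtureState:
    """Mutable sampler state: ordered means, variances, weights, allocations."""

    __slots__ = ("w", "mu", "var", "z", "beta")

    def __init__(self, w, mu, var, z, beta):
        self.w = np.asarray(w, float)
        self.mu = np.asarray(mu, float)
        self.var = np.asarray(var, float)
        self.z = np.asarray(z, np.int64)
        self.beta = float(beta)

    @property
    def k(self) -> int:
        return len(self.w)

    def counts(self) -> np.ndarray:
        return np.bincount(self.z, minlength=self.k)


def _gibbs_sweep(state, y, hp, rng):
    """Within-model updates: weights, means (order-constrained), variances,
    hyper rate beta, allocations."""
    k = state.k
    nj = state.counts()
    # weights | z
    state.w = rng.dirichlet(hp["delta"] + nj)
    # means | rest, with ordering constraint (Metropolis step with the
    # unconstrained full conditional as proposal: accept iff still ordered)
    sums = np.bincount(state.z, weights=y, minlength=k)
    for j in range(k):
        prec = nj[j] / state.var[j] + hp["kappa"]
        mean = (sums[j] / state.var[j] + hp["kappa"] * hp["xi"]) / prec
        prop = rng.normal(mean, 1.0 / math.sqrt(prec))
        lo = state.mu[j - 1] if j > 0 else -math.inf
        hi = state.mu[j + 1] if j < k - 1 else math.inf
        if lo < prop < hi:
            state.mu[j] = prop
    # variances | rest
    sse = np.bincount(state.z, weights=(y - state.mu[state.z]) ** 2, minlength=k)
    tau = rng.gamma(hp["alpha"] + 0.5 * nj, 1.0 / (state.beta + 0.5 * sse))
    state.var = 1.0 / tau
    # hyper rate beta | variances
    state.beta = rng.gamma(
        hp["g"] + k * hp["alpha"], 1.0 / (hp["h"] + np.sum(1.0 / state.var))
    )
    # allocations | rest
    logp = (
        np.log(state.w)[None, :]
        - 0.5 * np.log(state.var)[None, :]
        - 0.5 * (y[:, None] - state.mu[None, :]) ** 2 / state.var[None, :]
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(y))[:, None]
    state.z = (p.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)


def _norm_logpdf_sum(y, mu, var):
    if len(y) == 0:
        return 0.0
    return float(-0.5 * np.sum((y - mu) ** 2) / var - 0.5 * len(y) * (math.log(var) + _LOG_2PI))


def _split_log_accept(k_low, hp, w_star, mu_star, var_star,
                      w1, w2, mu1, mu2, var1, var2,
                      u1, u2, u3, l1, l2, dloglik, log_palloc, beta):
    """log acceptance ratio of a split from k_low to k_low + 1 components.

    The selection probabilities cancel: a split chooses among k_low
    components while the reverse combine chooses among the k_low adjacent
    pairs of the (k_low + 1)-component state.
    """
    delta, alpha = hp["delta"], hp["alpha"]
    log_pk = hp["log_pk"]
    la = dloglik
    la += log_pk[k_low] - log_pk[k_low - 1]  # p(k+1)/p(k), 1-based K
    la += math.log(k_low + 1)  # ordering factor (k+1)!/k!
    la += (
        (delta - 1.0 + l1) * math.log(w1)
        + (delta - 1.0 + l2) * math.log(w2)
        - (delta - 1.0 + l1 + l2) * math.log(w_star)
        - betaln(delta, k_low * delta)
    )
    la += 0.5 * math.log(hp["kappa"] / (2.0 * math.pi)) - 0.5 * hp["kappa"] * (
        (mu1 - hp["xi"]) ** 2 + (mu2 - hp["xi"]) ** 2 - (mu_star - hp["xi"]) ** 2
    )
    la += (
        alpha * math.log(beta)
        - gammaln(alpha)
        - (alpha + 1.0) * (math.log(var1) + math.log(var2) - math.log(var_star))
        - beta * (1.0 / var1 + 1.0 / var2 - 1.0 / var_star)
    )
    la += hp["log_d"][k_low + 1] - hp["log_b"][k_low] - log_palloc
    la -= _log_beta22(u1) + _log_beta22(u2)  # Beta(1,1) for u3 is flat
    la += (
        math.log(w_star)
        + math.log(mu2 - mu1)
        + math.log(var1)
        + math.log(var2)
        - math.log(var_star)
        - (math.log(u2) + math.log1p(-(u2**2)) + math.log(u3) + math.log1p(-u3))
    )
    return la


def _split_combine(state, y, hp, rng):
    k = state.k
    do_split = rng.random() < math.exp(hp["log_b"][k])
    if do_split:
        j = int(rng.integers(k))
        w_star, mu_star, var_star = state.w[j], state.mu[j], state.var[j]
        u1, u2 = rng.beta(2.0, 2.0), rng.beta(2.0, 2.0)
        u3 = rng.random()
        w1, w2 = w_star * u1, w_star * (1.0 - u1)
        sd_star = math.sqrt(var_star)
        mu1 = mu_star - u2 * sd_star * math.sqrt(w2 / w1)
        mu2 = mu_star + u2 * sd_star * math.sqrt(w1 / w2)
        var1 = u3 * (1.0 - u2**2) * var_star * w_star / w1
        var2 = (1.0 - u3) * (1.0 - u2**2) * var_star * w_star / w2
        lo = state.mu[j - 1] if j > 0 else -math.inf
        hi = state.mu[j + 1] if j < k - 1 else math.inf
        if not (lo < mu1 < mu2 < hi):
            return
        members = np.flatnonzero(state.z == j)
        ys = y[members]
        lp1 = math.log(w1) - 0.5 * (math.log(var1) + _LOG_2PI) - 0.5 * (ys - mu1) ** 2 / var1
        lp2 = math.log(w2) - 0.5 * (math.log(var2) + _LOG_2PI) - 0.5 * (ys - mu2) ** 2 / var2
        m = np.maximum(lp1, lp2)
        p1 = np.exp(lp1 - m) / (np.exp(lp1 - m) + np.exp(lp2 - m))
        pick1 = rng.random(len(members)) < p1
        log_palloc = float(
            np.sum(np.log(p1[pick1])) + np.sum(np.log1p(-p1[~pick1]))
        ) if len(members) else 0.0
        l1, l2 = int(pick1.sum()), int(len(members) - pick1.sum())
        dloglik = (
            _norm_logpdf_sum(ys[pick1], mu1, var1)
            + _norm_logpdf_sum(ys[~pick1], mu2, var2)
            - _norm_logpdf_sum(ys, mu_star, var_star)
        )
        la = _split_log_accept(
            k, hp, w_star, mu_star, var_star, w1, w2, mu1, mu2, var1, var2,
            u1, u2, u3, l1, l2, dloglik, log_palloc, state.beta,
        )
        if math.log(rng.random() + 1e-300) < la:
            state.w = np.insert(np.delete(state.w, j), j, [w1, w2])
            state.mu = np.insert(np.delete(state.mu, j), j, [mu1, mu2])
            state.var = np.insert(np.delete(state.var, j), j, [var1, var2])
            z = state.z.copy()
            z[z > j] += 1
            z[members[pick1]] = j
            z[members[~pick1]] = j + 1
            state.z = z
    else:
        if k < 2:
            return
        j = int(rng.integers(k - 1))  # adjacent pair (j, j+1) in mean order
        w1, w2 = state.w[j], state.w[j + 1]
        mu1, mu2 = state.mu[j], state.mu[j + 1]
        var1, var2 = state.var[j], state.var[j + 1]
        w_star = w1 + w2
        mu_star = (w1 * mu1 + w2 * mu2) / w_star
        var_star = (
            w1 * (mu1**2 + var1) + w2 * (mu2**2 + var2)
        ) / w_star - mu_star**2
        u1 = w1 / w_star
        u2 = (mu_star - mu1) / math.sqrt(var_star * w2 / w1)
        u3 = (w1 * var1) / (w1 * var1 + w2 * var2)
        members1 = np.flatnonzero(state.z == j)
        members2 = np.flatnonzero(state.z == j + 1)
        l1, l2 = len(members1), len(members2)
        ys1, ys2 = y[members1], y[members2]
        ys = np.concatenate((ys1, ys2))
        # allocation probability of the current assignment under the split

        def _logp(yv, w, mu, var):
            return math.log(w) - 0.5 * (math.log(var) + _LOG_2PI) - 0.5 * (yv - mu) ** 2 / var

        log_palloc = 0.0
        if l1 + l2:
            lpa1 = _logp(ys, w1, mu1, var1)
            lpa2 = _logp(ys, w2, mu2, var2)
            mx = np.maximum(lpa1, lpa2)
            pa1 = np.exp(lpa1 - mx) / (np.exp(lpa1 - mx) + np.exp(lpa2 - mx))
            with np.errstate(divide="ignore"):
                log_palloc = float(
                    np.sum(np.log(pa1[:l1])) + np.sum(np.log1p(-pa1[l1:]))
                )
        dloglik = (
            _norm_logpdf_sum(ys1, mu1, var1)
            + _norm_logpdf_sum(ys2, mu2, var2)
            - _norm_logpdf_sum(ys, mu_star, var_star)
        )
        la = -_split_log_accept(
            k - 1, hp, w_star, mu_star, var_star, w1, w2, mu1, mu2, var1, var2,
            u1, u2, u3, l1, l2, dloglik, log_palloc, state.beta,
        )
        if math.log(rng.random() + 1e-300) < la:
            state.w = np.insert(np.delete(state.w, [j, j + 1]), j, w_star)
            state.mu = np.insert(np.delete(state.mu, [j, j + 1]), j, mu_star)
            state.var = np.insert(np.delete(state.var, [j, j + 1]), j, var_star)
            z = state.z.copy()
            z[z == j + 1] = j
            z[z > j + 1] -= 1
            state.z = z


def _birth_log_accept(k_low, hp, w_star, n, k0_prev):
    """log acceptance of a birth from k_low to k_low + 1 components;
    ``k0_prev`` is the number of empty components before the birth."""
    delta = hp["delta"]
    log_pk = hp["log_pk"]
    la = log_pk[k_low] - log_pk[k_low - 1]
    la += math.log(k_low + 1) - math.log(k_low)  # ordering factor net of proposal
    la += -betaln(k_low * delta, delta) + (delta - 1.0) * math.log(w_star)
    la += (k_low * (delta - 1.0) + n) * math.log1p(-w_star)
    la += hp["log_d"][k_low + 1] - math.log(k0_prev + 1) - hp["log_b"][k_low]
    return la


def _birth_death(state, y, hp, rng):
    k = state.k
    nj = state.counts()
    k0 = int(np.sum(nj == 0))
    do_birth = rng.random() < math.exp(hp["log_b"][k])
    if do_birth:
        w_star = rng.beta(1.0, k)
        mu_star = rng.normal(hp["xi"], 1.0 / math.sqrt(hp["kappa"]))
        var_star = 1.0 / rng.gamma(hp["alpha"], 1.0 / state.beta)
        la = _birth_log_accept(k, hp, w_star, len(y), k0)
        if math.log(rng.random() + 1e-300) < la:
            pos = int(np.searchsorted(state.mu, mu_star))
            state.w = np.insert(state.w * (1.0 - w_star), pos, w_star)
            state.mu = np.insert(state.mu, pos, mu_star)
            state.var = np.insert(state.var, pos, var_star)
            z = state.z.copy()
            z[z >= pos] += 1
            state.z = z
    else:
        if k < 2 or k0 == 0:
            return
        empties = np.flatnonzero(nj == 0)
        j = int(rng.choice(empties))
        w_star = state.w[j]
        if w_star >= 1.0:
            return
        la = -_birth_log_accept(k - 1, hp, w_star, len(y), k0 - 1)
        if math.log(rng.random() + 1e-300) < la:
            state.w = np.delete(state.w, j) / (1.0 - w_star)
            state.mu = np.delete(state.mu, j)
            state.var = np.delete(state.var, j)
            z = state.z.copy()
            z[z > j] -= 1
            state.z = z


def fit_mixture_rjmcmc(
    values,
    prior: MixturePrior | None = None,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int | None = None,
    axis: str = "",
    subject_id: str = "",
    session_id: str = "",
    trial_index: int = -1,
) -> MixtureFit:
    """Fit a 1..kmax normal mixture by reversible-jump MCMC.

    Parameters
    ----------
    values : array-like
        Position samples (degrees); at least 10 finite values.
    prior : hyperprior configuration (default :class:`MixturePrior`).
    n_iter : kept iterations after burn-in (default 2000).
    burn_in : discarded initial sweeps (default 500).
    seed : RNG seed (required; pass an int for reproducibility).

    Each sweep performs the within-model Gibbs updates, one split/combine
    attempt and one birth/death attempt.  Returns a :class:`MixtureFit`
    whose Bayes factor is computed against the analytic prior odds.
    """
    y = np.asarray(getattr(values, "values", values), dtype=float).ravel()
    if len(y) < 10:
        raise ValueError(f"need at least 10 samples, got {len(y)}")
    if not np.isfinite(y).all():
        raise ValueError("values must be finite")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("zero-variance input")
    if seed is None:
        raise ValueError("seed is required for a reproducible chain")
    prior = prior or MixturePrior()
    rng = np.random.default_rng(seed)

    r = float(np.ptp(y))
    kmax = prior.kmax
    # move probabilities: b_k (split/birth) and d_k (combine/death), index by k
    log_b = np.full(kmax + 2, -math.inf)
    log_d = np.full(kmax + 2, -math.inf)
    for k in range(1, kmax + 1):
        if k == 1:
            log_b[k], log_d[k] = 0.0, -math.inf
        elif k == kmax:
            log_b[k], log_d[k] = -math.inf, 0.0
        else:
            log_b[k] = log_d[k] = math.log(0.5)
    hp = {
        "xi": float((y.min() + y.max()) / 2.0),
        "kappa": prior.kappa_scale / r**2,
        "alpha": prior.alpha,
        "g": prior.beta_shape,
        "h": prior.beta_rate_scale / r**2,
        "delta": prior.delta,
        "kmax": kmax,
        "log_pk": prior.log_pk(),
        "log_b": log_b,
        "log_d": log_d,
    }

    state = _MixtureState(
        w=[1.0],
        mu=[float(y.mean())],
        var=[float(y.var()) or r**2],
        z=np.zeros(len(y), np.int64),
        beta=hp["g"] / hp["h"],
    )

    k_draws = np.empty(n_iter, np.int64)
    snapshots: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for it in range(burn_in + n_iter):
        _gibbs_sweep(state, y, hp, rng)
        _split_combine(state, y, hp, rng)
        _birth_death(state, y, hp, rng)
        assert abs(state.w.sum() - 1.0) < 1e-9 and (state.var > 0).all()
        if it >= burn_in:
            k_draws[it - burn_in] = state.k
            snapshots.append((state.w.copy(), state.mu.copy(), state.var.copy()))

    counts = np.bincount(k_draws, minlength=kmax + 1)[1:]
    posterior_k = counts / counts.sum()
    modal_k = int(np.argmax(posterior_k)) + 1
    sel = [s for s, kk in zip(snapshots, k_draws) if kk == modal_k]
    w_mean = np.mean([s[0] for s in sel], axis=0)
    mu_mean = np.mean([s[1] for s in sel], axis=0)
    sd_mean = np.mean([np.sqrt(s[2]) for s in sel], axis=0)
    components = [
        (float(m), float(s), float(w)) for m, s, w in zip(mu_mean, sd_mean, w_mean)
    ]

    a = prior_odds_multimodal(prior)
    b_odds = (
        math.inf if posterior_k[0] == 0.0 else float(posterior_k[1:].sum() / posterior_k[0])
    )
    bf, log_bf = bayes_factor(posterior_k, a)
    return MixtureFit(
        k_draws=k_draws,
        posterior_k=posterior_k,
        modal_k=modal_k,
        components=components,
        prior_odds=a,
        posterior_odds=b_odds,
        bf=bf,
        log_bf=log_bf,
        category=classify_evidence(log_bf),
        n_samples=len(y),
        axis=axis,
        subject_id=subject_id,
        session_id=session_id,
        trial_index=trial_index,
    )
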