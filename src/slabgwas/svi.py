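"""Spike-and-slab Bayesian whole-genome regression by stochastic variational inference.

The model places an independent spike-and-slab prior on each standardized
variant effect,

    beta_j ~ (1 - pi) delta(0) + pi N(0, sigma^2),

with a Gaussian (quantitative) or Bernoulli-logit (binary) likelihood, and a
fully factorized spike-and-slab variational posterior

    q(beta_j) = (1 - psi_j) delta(0) + psi_j N(mu_j, sigma_j^2).

The ELBO is maximized by minibatch first-order updates on the unconstrained
parameters (logit psi_j, mu_j, log sigma_j^2) using Adam.  The per-sample
linear predictor is sampled from its implied Gaussian (the local
reparameterization trick) with antithetic +/-z pairs; for the linear model
an exact closed-form expectation of the quadratic data term is available
(``n_mc_samples=0``), the Rao–Blackwellised limit of the same estimator.

Multiple traits sharing one genotype matrix are fitted jointly: all
variational parameter arrays carry a trailing trait axis and every genotype
pass serves every trait.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriorSpec",
    "VariationalPosterior",
    "FitReport",
    "LocoResiduals",
    "OptimizerConfig",
    "kl_spike_slab",
    "elbo_linear",
    "elbo_logistic",
    "fit_svi",
    "loco_residuals",
    "heldout_residual_variance",
]

_PSI_EPS = 1e-6
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PriorSpec:
    """Spike-and-slab prior: slab probability, slab variance, noise variance.

    ``slab_prob`` is the prior probability that a variant is causal.  For a
    standardized trait and genotypes, consistency requires
    M * slab_prob * slab_var ~ h_g^2 and sigma_e2 ~ 1 - h_g^2; the
    ``from_h2`` constructor applies exactly that.  Fields may be scalars or
    per-trait arrays.
    """

    slab_prob: float | np.ndarray
    slab_var: float | np.ndarray
    sigma_e2: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        sp = np.asarray(self.slab_prob, dtype=float)
        if np.any((sp <= 0) | (sp >= 1)):
            raise ValueError("slab_prob must lie in (0, 1)")
        if np.any(np.asarray(self.slab_var, dtype=float) <= 0):
            raise ValueError("slab_var must be positive")

    @classmethod
    def from_h2(cls, h2, n_variants: int, slab_prob=0.01) -> "PriorSpec":
        h2 = np.clip(np.asarray(h2, dtype=float), 0.01, 0.95)
        sp = np.asarray(slab_prob, dtype=float)
        return cls(
            slab_prob=sp, slab_var=h2 / (n_variants * sp), sigma_e2=1.0 - h2
        )


@dataclass
class VariationalPosterior:
    """Factorized posterior: per-variant slab probability, mean and variance."""

    slab_prob: np.ndarray
    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.slab_prob = np.clip(
            np.asarray(self.slab_prob, float), _PSI_EPS, 1 - _PSI_EPS
        )
        self.mu = np.asarray(self.mu, float)
        self.var = np.asarray(self.var, float)
        if np.any(self.var <= 0):
            raise ValueError("posterior slab variances must be positive")

    @property
    def mean_effect(self) -> np.ndarray:
        """Posterior mean effect E[beta_j] = psi_j * mu_j."""
        return self.slab_prob * self.mu


@dataclass
class FitReport:
    elbo_trace: list = field(default_factory=list)
    epochs: int = 0
    converged: bool = False
    seed: int = 0
    wall_time: float = 0.0

    def smoothed_trace(self, window: int = 5) -> np.ndarray:
        t = np.asarray(self.elbo_trace, dtype=float)
        if t.size < window:
            return t
        kernel = np.ones(window) / window
        return np.convolve(t, kernel, mode="valid")


@dataclass
class LocoResiduals:
    """Per-chromosome leave-one-chromosome-out null-model outputs.

    Quantitative: ``residuals[c]`` = y_adj - X_{-c} E[beta_{-c}].
    Binary: ``phat[c]`` = sigmoid(covariate offset + X_{-c} E[beta_{-c}])
    and ``weights[c]`` = phat (1 - phat).
    """

    chromosomes: list
    model: str
    residuals: dict = field(default_factory=dict)
    phat: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    y_var: np.ndarray | None = None
    heldout_resid_var: np.ndarray | None = None

    @property
    def neff_gain(self) -> np.ndarray:
        """Effective-sample-size gain: var(y_adj) / held-out residual variance."""
        if self.heldout_resid_var is None or self.y_var is None:
            raise ValueError("held-out residual variance not estimated")
        return self.y_var / self.heldout_resid_var


@dataclass
class OptimizerConfig:
    """First-order (Adam) settings for the stochastic ELBO optimization."""

    learning_rate: float = 0.01
    batch_size: int = 128
    max_epochs: int = 100
    tol: float = 1e-4
    patience: int = 5
    n_mc_samples: int = 1  # antithetic pairs per batch; 0 = exact expectation
    antithetic: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8


# ---------------------------------------------------------------------------
# KL divergence and ELBO estimators
# ---------------------------------------------------------------------------


def kl_spike_slab(q: VariationalPosterior, prior: PriorSpec) -> np.ndarray:
    """Per-variant KL(q || prior) for spike-and-slab distributions.

    Bernoulli term on the slab indicator plus the slab-probability-weighted
    Gaussian KL; always non-negative.
    """
    psi = np.clip(q.slab_prob, _PSI_EPS, 1 - _PSI_EPS)
    pi = np.asarray(prior.slab_prob, float)
    sv = np.asarray(prior.slab_var, float)
    bern = psi * np.log(psi / pi) + (1 - psi) * np.log((1 - psi) / (1 - pi))
    gauss = 0.5 * (-1.0 + (q.mu**2 + q.var) / sv - np.log(q.var / sv))
    return bern + psi * gauss


def _predictor_moments(psi, mu, s2, X, X2, offset=None):
    """Mean and variance of the per-sample linear predictor under q."""
    w = psi * mu
    u = psi * (s2 + mu * mu) - w * w
    m = X @ w
    v = X2 @ u
    if offset is not None:
        m = m + (offset if m.ndim == 1 else np.asarray(offset).reshape(m.shape))
    return m, v


def _draw_etas(m, v, rng, n_pairs, antithetic, z=None):
    """Sampled linear predictors; antithetic pairs share one normal draw."""
    s = np.sqrt(np.maximum(v, 1e-30))
    if z is None:
        z = rng.standard_normal((n_pairs,) + m.shape)
    etas = [m + s * zk for zk in z]
    if antithetic:
        etas += [m - s * zk for zk in z]
    else:
        z2 = rng.standard_normal((n_pairs,) + m.shape)
        etas = [m + s * zk for zk in z] + [m + s * zk for zk in z2]
    return etas


def _gauss_loglik(y, eta, sigma_e2):
    return -0.5 * np.sum((y - eta) ** 2) / sigma_e2 - 0.5 * y.size * (
        _LOG2PI + np.log(sigma_e2)
    )


def _bernoulli_loglik(y, eta):
    # y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def elbo_linear(
    q: VariationalPosterior,
    prior: PriorSpec,
    X_batch: np.ndarray,
    y_batch: np.ndarray,
    n_mc_samples: int = 1,
    n_total: int | None = None,
    rng: np.random.Generator | None = None,
    antithetic: bool = True,
) -> float:
    """Stochastic (or exact, ``n_mc_samples=0``) batch ELBO, linear model.

    Returns the batch's contribution: expected Gaussian log-likelihood of
    the batch minus (batch/N) of the total KL; on the full batch this is an
    unbiased estimate of the full ELBO (exact when ``n_mc_samples=0``).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    nb = len(y_batch)
    n_total = n_total or nb
    X2 = X_batch * X_batch
    m, v = _predictor_moments(q.slab_prob, q.mu, q.var, X_batch, X2)
    se2 = float(np.asarray(prior.sigma_e2))
    if n_mc_samples == 0:
        data = -0.5 * (np.sum((y_batch - m) ** 2) + np.sum(v)) / se2
        data -= 0.5 * nb * (_LOG2PI + np.log(se2))
    else:
        etas = _draw_etas(m, v, rng, n_mc_samples, antithetic)
        data = float(np.mean([_gauss_loglik(y_batch, e, se2) for e in etas]))
    kl = float(np.sum(kl_spike_slab(q, prior)))
    elbo = data - (nb / n_total) * kl
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO estimate")
    return float(elbo)


def elbo_logistic(
    q: VariationalPosterior,
    prior: PriorSpec,
    X_batch: np.ndarray,
    y_batch: np.ndarray,
    n_mc_samples: int = 1,
    n_total: int | None = None,
    rng: np.random.Generator | None = None,
    antithetic: bool = True,
    offset: np.ndarray | None = None,
) -> float:
    """Stochastic batch ELBO for the Bernoulli-logit model."""
    if rng is None:
        rng = np.random.default_rng(0)
    nb = len(y_batch)
    n_total = n_total or nb
    X2 = X_batch * X_batch
    m, v = _predictor_moments(q.slab_prob, q.mu, q.var, X_batch, X2, offset)
    etas = _draw_etas(m, v, rng, max(n_mc_samples, 1), antithetic)
    data = float(np.mean([_bernoulli_loglik(y_batch, e) for e in etas]))
    kl = float(np.sum(kl_spike_slab(q, prior)))
    elbo = data - (nb / n_total) * kl
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO estimate")
    return float(elbo)


# ---------------------------------------------------------------------------
# Gradient engine
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def batch_loss_and_grads(
    a: np.ndarray,
    mu: np.ndarray,
    b: np.ndarray,
    X: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    model: str,
    frac: float,
    z: np.ndarray | None,
    sigma_e2,
    offset=None,
    antithetic: bool = True,
):
    """Negative batch ELBO and its gradients w.r.t. (logit psi, mu, log var).

    ``z`` holds the standard-normal draws for the local reparameterization,
    shape (n_pairs, batch, traits); ``z=None`` selects the exact expectation
    of the quadratic data term (linear model only).  ``frac`` = batch/N
    scales the KL contribution.
    """
    psi = np.clip(_sigmoid(a), _PSI_EPS, 1 - _PSI_EPS)
    s2 = np.exp(b)
    pi = np.asarray(prior.slab_prob, float)
    sv = np.asarray(prior.slab_var, float)

    # matmuls run in the genotype dtype (float32 at scale); scalar
    # reductions and KL bookkeeping stay in float64
    dt = X.dtype
    w = psi * mu
    u = psi * (s2 + mu * mu) - w * w
    m = X @ w.astype(dt, copy=False)
    v = X2 @ u.astype(dt, copy=False)
    if offset is not None:
        m = m + offset.astype(dt, copy=False)

    se2 = np.asarray(sigma_e2, float)
    nb = y.shape[0]
    if z is None:
        if model != "linear":
            raise ValueError("exact expectation requires the linear model")
        resid = m - y
        loss = float(
            np.sum((resid * resid + v) / (2.0 * se2))
            + 0.5 * nb * np.sum(np.atleast_1d(_LOG2PI + np.log(se2)))
        )
        dldm = resid / se2
        dldv = np.broadcast_to(0.5 / se2, v.shape)
    else:
        s = np.sqrt(np.maximum(v, 1e-30))
        losses = []
        dldm = np.zeros_like(m)
        dldv = np.zeros_like(v)
        signs = (1.0, -1.0) if antithetic else (1.0,)
        n_eval = z.shape[0] * len(signs)
        for zk in z:
            for sign in signs:
                eta = m + sign * s * zk
                if model == "linear":
                    dl = (eta - y) / se2
                    losses.append(
                        float(np.sum((y - eta) ** 2 / (2.0 * se2)))
                        + 0.5 * nb * np.sum(np.atleast_1d(_LOG2PI + np.log(se2)))
                    )
                else:
                    p = _sigmoid(eta)
                    dl = p - y
                    losses.append(-float(np.sum(y * eta - np.logaddexp(0.0, eta))))
                dldm += dl
                dldv += dl * (sign * zk) / (2.0 * s)
        dldm /= n_eval
        dldv /= n_eval
        loss = float(np.mean(losses))

    A = (X.T @ dldm.astype(dt, copy=False)).astype(np.float64)
    Bg = (X2.T @ dldv.astype(dt, copy=False)).astype(np.float64)

    gauss_kl = 0.5 * (-1.0 + (mu * mu + s2) / sv - np.log(s2 / sv))
    kl = psi * np.log(psi / pi) + (1 - psi) * np.log((1 - psi) / (1 - pi))
    kl = float(np.sum(kl + psi * gauss_kl))
    loss += frac * kl

    d_psi = A * mu + Bg * (s2 + mu * mu - 2.0 * psi * mu * mu)
    d_psi += frac * (np.log(psi / pi) - np.log((1 - psi) / (1 - pi)) + gauss_kl)
    d_mu = A * psi + Bg * 2.0 * mu * psi * (1 - psi)
    d_mu += frac * psi * mu / sv
    d_s2 = Bg * psi + frac * 0.5 * psi * (1.0 / sv - 1.0 / s2)

    g_a = d_psi * psi * (1 - psi)
    g_b = d_s2 * s2
    return loss, g_a, d_mu, g_b


def fit_svi(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    optimizer_cfg: OptimizerConfig | None = None,
    init: VariationalPosterior | None = None,
    exclude_chromosome=None,
    chromosomes: np.ndarray | None = None,
    model: str = "linear",
    offset: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[VariationalPosterior, FitReport]:
    """Fit the spike-and-slab posterior by minibatch Adam on the ELBO.

    ``X`` is standardized and covariate-adjusted (N x M); ``y`` is the
    adjusted trait (linear) or raw 0/1 status (logistic, with covariates
    entering through ``offset``); either may carry a trailing trait axis for
    joint multi-trait fits.  ``exclude_chromosome`` omits that chromosome's
    columns (labels in ``chromosomes``) and ``init`` — typically the
    whole-genome posterior — warm-starts all remaining parameters.  The
    returned posterior always spans all M columns, with excluded columns
    pinned at a zero-mean point mass.
    """
    cfg = optimizer_cfg or OptimizerConfig()
    start = time.time()
    rng = np.random.default_rng(seed)

    y = np.asarray(y, dtype=X.dtype)
    single_trait = y.ndim == 1
    Y = y[:, None] if single_trait else y
    n, m_all = X.shape
    t = Y.shape[1]

    if exclude_chromosome is not None:
        if chromosomes is None:
            raise ValueError("exclude_chromosome requires chromosome labels")
        used = np.flatnonzero(np.asarray(chromosomes) != exclude_chromosome)
    else:
        used = np.arange(m_all)
    # keep the working copy C-contiguous: minibatch row gathers and sgemm
    # are several-fold slower on the F-ordered view a column gather yields
    Xu = X if used.size == m_all else np.ascontiguousarray(X[:, used])
    X2u = Xu * Xu
    m = used.size

    pi = np.broadcast_to(np.asarray(prior.slab_prob, float), (t,)).astype(float)
    sv = np.broadcast_to(np.asarray(prior.slab_var, float), (t,)).astype(float)
    se2 = np.broadcast_to(np.asarray(prior.sigma_e2, float), (t,)).astype(float)

    if init is not None:
        psi0 = np.clip(init.slab_prob, _PSI_EPS, 1 - _PSI_EPS)
        mu0, s20 = init.mu, init.var
        if psi0.ndim == 1:
            psi0, mu0, s20 = psi0[:, None], mu0[:, None], s20[:, None]
        if psi0.shape[0] == m_all:
            psi0, mu0, s20 = psi0[used], mu0[used], s20[used]
        a = np.log(psi0 / (1 - psi0)).copy()
        mu = mu0.copy().astype(float)
        b = np.log(s20).copy()
    else:
        a = np.full((m, t), np.log(pi / (1 - pi)))
        mu = np.zeros((m, t))
        b = np.full((m, t), np.log(sv))

    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        if offset.ndim == 1:
            offset = offset[:, None]

    # Adam state
    ma = {k: np.zeros_like(v) for k, v in (("a", a), ("mu", mu), ("b", b))}
    va = {k: np.zeros_like(v) for k, v in (("a", a), ("mu", mu), ("b", b))}
    step = 0

    report = FitReport(seed=seed)
    diverged_once = False
    n_good = 0
    batch = min(cfg.batch_size, n)
    exact = cfg.n_mc_samples == 0 and model == "linear"

    full_batch = batch >= n
    for epoch in range(cfg.max_epochs):
        perm = None if full_batch else rng.permutation(n)
        epoch_elbo = 0.0
        for lo in range(0, n, batch):
            if full_batch:
                Xb, X2b, Yb = Xu, X2u, Y
                ob = offset
                idx = np.arange(n)
            else:
                idx = perm[lo : lo + batch]
                Xb, X2b, Yb = Xu[idx], X2u[idx], Y[idx]
                ob = offset[idx] if offset is not None else None
            z = (
                None
                if exact
                else rng.standard_normal(
                    (max(cfg.n_mc_samples, 1), len(idx), t)
                ).astype(X.dtype, copy=False)
            )
            loss, g_a, g_mu, g_b = batch_loss_and_grads(
                a, mu, b, Xb, X2b, Yb, prior, model,
                len(idx) / n, z, se2, ob, cfg.antithetic,
            )
            if not np.isfinite(loss):
                if diverged_once:
                    raise FloatingPointError(
                        f"ELBO diverged at epoch {epoch}; reduce the step size"
                    )
                diverged_once = True
                continue
            epoch_elbo -= loss
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(
                1 - cfg.beta2**step
            ) / (1 - cfg.beta1**step)
            for key, g in (("a", g_a), ("mu", g_mu), ("b", g_b)):
                ma[key] = cfg.beta1 * ma[key] + (1 - cfg.beta1) * g
                va[key] = cfg.beta2 * va[key] + (1 - cfg.beta2) * g * g
                upd = lr_t * ma[key] / (np.sqrt(va[key]) + cfg.adam_eps)
                if key == "a":
                    a -= upd
                elif key == "mu":
                    mu -= upd
                else:
                    b -= upd
            np.clip(a, -30.0, 30.0, out=a)
            np.clip(b, -40.0, 10.0, out=b)

        report.elbo_trace.append(epoch_elbo)
        report.epochs = epoch + 1
        sm = report.smoothed_trace()
        if len(sm) >= 2:
            rel = abs(sm[-1] - sm[-2]) / (abs(sm[-2]) + 1e-12)
            n_good = n_good + 1 if rel < cfg.tol else 0
            if n_good >= cfg.patience:
                report.converged = True
                break

    psi_full = np.full((m_all, t), _PSI_EPS)
    mu_full = np.zeros((m_all, t))
    var_full = np.broadcast_to(sv, (m_all, t)).copy()
    psi_full[used] = np.clip(_sigmoid(a), _PSI_EPS, 1 - _PSI_EPS)
    mu_full[used] = mu
    var_full[used] = np.exp(b)
    if single_trait:
        psi_full, mu_full, var_full = psi_full[:, 0], mu_full[:, 0], var_full[:, 0]

    report.wall_time = time.time() - start
    return VariationalPosterior(psi_full, mu_full, var_full), report


# ---------------------------------------------------------------------------
# LOCO residuals
# ---------------------------------------------------------------------------


def loco_residuals(
    X: np.ndarray,
    y: np.ndarray,
    posteriors: dict,
    model: str = "linear",
    chromosomes: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    heldout_resid_var: np.ndarray | None = None,
) -> LocoResiduals:
    """Build per-chromosome null-model residuals / predictions.

    ``posteriors[c]`` must be the fit excluding chromosome ``c`` (its
    columns carry zero posterior mean, so a full X product is exact).
    """
    if chromosomes is None:
        raise ValueError("chromosome labels are required")
    chroms = list(dict.fromkeys(np.asarray(chromosomes).tolist()))
    missing = [c for c in chroms if c not in posteriors]
    if missing:
        raise ValueError(f"missing LOCO posterior for chromosome(s) {missing}")

    y = np.asarray(y, dtype=float)
    Y = y[:, None] if y.ndim == 1 else y
    out = LocoResiduals(chromosomes=chroms, model=model)
    out.y_var = Y.var(axis=0)
    out.heldout_resid_var = heldout_resid_var

    for c in chroms:
        eb = posteriors[c].mean_effect
        EB = eb[:, None] if eb.ndim == 1 else eb
        pred = X @ EB.astype(X.dtype)
        if model == "linear":
            out.residuals[c] = np.asarray(Y - pred, dtype=float)
        else:
            if offset is None:
                raise ValueError("binary LOCO residuals require a covariate offset")
            off = np.asarray(offset, dtype=float)
            lin = np.asarray(pred, dtype=float) + (
                off[:, None] if off.ndim == 1 else off
            )
            p = np.clip(_sigmoid(np.asarray(lin, dtype=float)), 1e-8, 1 - 1e-8)
            out.phat[c] = p
            out.weights[c] = p * (1 - p)
    return out


def heldout_residual_variance(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    optimizer_cfg: OptimizerConfig | None = None,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> np.ndarray:
    """Held-out residual variance of the whole-genome predictor.

    Fits on a (1 - holdout_fraction) sample split and returns the residual
    variance of y on the held-out quarter — the quantity whose ratio to
    var(y) measures the effective-sample-size gain of the Bayesian
    regression used in test-statistic calibration.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_ho = max(int(round(holdout_fraction * n)), 1)
    ho, tr = perm[:n_ho], perm[n_ho:]
    q, _ = fit_svi(X[tr], y[tr], prior, optimizer_cfg, seed=seed + 1)
    eb = q.mean_effect
    EB = eb[:, None] if eb.ndim == 1 else eb
    Yho = y[ho][:, None] if y.ndim == 1 else y[ho]
    resid = Yho - X[ho] @ EB.astype(X.dtype)
    rv = np.asarray(resid, dtype=float).var(axis=0)
    return np.minimum(rv, Yho.var(axis=0))  # the predictor cannot lose information
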