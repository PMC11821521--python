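"""Variance-component estimation.

Quantitative traits use randomized Haseman–Elston regression: a single-GRM
method-of-moments solve whose quadratic trace tr(K^2), K = X X'/M, is
estimated with Hutchinson random vectors so the genotype matrix is only
touched through matrix-vector products.  Binary traits use a grid search
over candidate heritabilities, refitting the step-1 logistic regression at
each value and keeping the one with the highest converged ELBO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .svi import OptimizerConfig, PriorSpec, fit_svi

__all__ = ["VarianceComponents", "rhe_estimate", "grid_search_h2", "DEFAULT_H2_GRID"]

DEFAULT_H2_GRID = (0.01, 0.25, 0.5, 0.75)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    standard_error: float | None = None
    grid_elbos: dict | None = None

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or not 0 <= self.h2 <= 1:
            raise ValueError("variance components out of range after clamping")


def _solve_moments(tr_k2: float, tr_k: float, n: int, yky: float, yy: float):
    lhs = np.array([[tr_k2, tr_k], [tr_k, float(n)]])
    rhs = np.array([yky, yy])
    sg2, se2 = np.linalg.solve(lhs, rhs)
    return float(sg2), float(se2)


def rhe_estimate(
    X,
    y: np.ndarray,
    n_random_vectors: int = 50,
    seed: int = 0,
    exact_trace: bool = False,
):
    """Randomized Haseman–Elston variance components for one or more traits.

    ``X`` is a standardized, covariate-adjusted N x M matrix (an
    AdjustedMatrix's ``values`` is accepted directly); ``y`` the adjusted
    trait(s), shape (N,) or (N, T).  Solves the 2 x 2 moment system

        [tr(K^2)  tr(K)] [sigma_g2]   [y' K y]
        [tr(K)      N  ] [sigma_e2] = [y' y  ]

    with tr(K^2) estimated as mean_z ||X (X' z) / M||^2 over Rademacher
    vectors z (or computed exactly when ``exact_trace``).  Trace estimates
    are shared across traits, so the cost is one genotype pass per random
    vector.  Negative genetic variances are clamped to zero with a warning.

    Returns a single ``VarianceComponents`` for 1-D ``y``, else a list.
    """
    values = getattr(X, "values", X)
    values = np.asarray(values)
    n, m = values.shape
    if n_random_vectors < 10:
        raise ValueError("n_random_vectors must be at least 10")
    if n < n_random_vectors:
        warnings.warn("fewer samples than random vectors; estimates will be noisy")

    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[:, None] if single else y

    tr_k = float(np.sum(values.astype(np.float64) ** 2)) / m
    if exact_trace:
        if n <= m:
            K = (values @ values.T) / m
            tr_k2 = float(np.sum(K.astype(np.float64) ** 2))
        else:
            # tr((XX'/M)^2) = tr((X'X/M)^2), cheaper when M < N
            G = values.astype(np.float64).T @ values.astype(np.float64) / m
            tr_k2 = float(np.einsum("ij,ji->", G, G))
    else:
        rng = np.random.default_rng(seed)
        acc = 0.0
        for _ in range(n_random_vectors):
            z = rng.choice([-1.0, 1.0], size=n).astype(values.dtype)
            kz = values @ (values.T @ z) / m
            acc += float(np.sum(kz.astype(np.float64) ** 2))
        tr_k2 = acc / n_random_vectors

    xty = values.T @ Y.astype(values.dtype)
    yky = np.sum(xty.astype(np.float64) ** 2, axis=0) / m
    yy = np.sum(Y**2, axis=0)

    out = []
    for t in range(Y.shape[1]):
        sg2, se2 = _solve_moments(tr_k2, tr_k, n, float(yky[t]), float(yy[t]))
        if sg2 < 0:
            warnings.warn("negative genetic variance estimate clamped to 0")
            sg2 = 0.0
        se2 = max(se2, 1e-12)
        h2 = float(np.clip(sg2 / (sg2 + se2), 0.0, 1.0))
        out.append(VarianceComponents(sigma_g2=sg2, sigma_e2=se2, h2=h2))
    return out[0] if single else out


def grid_search_h2(
    X,
    y_binary: np.ndarray,
    offset: np.ndarray | None = None,
    grid=DEFAULT_H2_GRID,
    slab_prob: float = 0.01,
    optimizer_cfg: OptimizerConfig | None = None,
    chromosomes=None,
    seed: int = 0,
):
    """Heritability grid search for binary traits.

    Fits the step-1 spike-and-slab logistic regression at each grid value
    (prior slab variance h2 / (M * slab_prob)) and selects the value whose
    fit attains the highest final ELBO.  ``offset`` carries the fixed
    covariate effects on the logit scale.  Traits may be stacked along a
    trailing axis of ``y_binary``; selection is then per trait.

    Returns (VarianceComponents or list, dict h2 -> (posterior, report)).
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("empty heritability grid")
    values = getattr(X, "values", X)
    values = np.asarray(values)
    m = values.shape[1]
    y = np.asarray(y_binary)
    single = y.ndim == 1
    Y = y[:, None] if single else y
    t = Y.shape[1]

    fits = {}
    elbos = np.full((len(grid), t), -np.inf)
    for i, h2 in enumerate(grid):
        prior = PriorSpec.from_h2(h2, m, slab_prob)
        try:
            q, rep = fit_svi(
                values, Y, prior, optimizer_cfg, model="logistic",
                offset=offset, seed=seed + i,
            )
        except FloatingPointError:
            fits[h2] = None
            continue
        fits[h2] = (q, rep)
        # the joint trace is summed over traits; recompute per-trait final ELBO
        elbos[i] = _per_trait_elbo(q, prior, values, Y, offset, seed=seed + 100 + i)

    if all(v is None for v in fits.values()):
        raise RuntimeError(f"all grid fits diverged; grid={grid}")

    results = []
    for j in range(t):
        col = elbos[:, j]
        best = int(np.argmax(col))
        h2 = grid[best]
        if len(grid) == 1:
            h2 = grid[0]
        results.append(
            VarianceComponents(
                sigma_g2=h2,
                sigma_e2=1.0 - h2,
                h2=h2,
                grid_elbos={g: float(elbos[i, j]) for i, g in enumerate(grid)},
            )
        )
    return (results[0] if single else results), fits


def _per_trait_elbo(q, prior, X, Y, offset, seed, n_pairs: int = 8):
    """Low-noise per-trait ELBO of a fitted logistic posterior."""
    from .svi import _predictor_moments  # local import to keep surface tidy

    rng = np.random.default_rng(seed)
    X2 = X * X
    psi = q.slab_prob if q.slab_prob.ndim == 2 else q.slab_prob[:, None]
    mu = q.mu if q.mu.ndim == 2 else q.mu[:, None]
    var = q.var if q.var.ndim == 2 else q.var[:, None]
    m_lin, v_lin = _predictor_moments(psi, mu, var, X, X2)
    if offset is not None:
        off = np.asarray(offset, float)
        m_lin = m_lin + (off[:, None] if off.ndim == 1 else off)
    s = np.sqrt(np.maximum(np.asarray(v_lin, float), 1e-30))
    m_lin = np.asarray(m_lin, float)
    data = np.zeros(Y.shape[1])
    for _ in range(n_pairs):
        z = rng.standard_normal(m_lin.shape)
        for eta in (m_lin + s * z, m_lin - s * z):
            data += np.sum(Y * eta - np.logaddexp(0.0, eta), axis=0)
    data /= 2 * n_pairs

    from .svi import VariationalPosterior, kl_spike_slab

    kl = np.zeros(Y.shape[1])
    for j in range(Y.shape[1]):
        qj = VariationalPosterior(psi[:, j], mu[:, j], var[:, j])
        kl[j] = float(np.sum(kl_spike_slab(qj, prior)))
    return data - kl
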