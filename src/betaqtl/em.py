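"""Gaussian-mixture QTL model fitted by maximum beta-likelihood.

Each phenotype y_j is modelled as a mixture over latent QTL genotype classes,

    f(y_j | theta, X_j) = (1/sigma) sum_i p_ji phi((y_j - mu_ji) / sigma),

with class means mu_ji = X_j gamma + D_i E (D the genetic design matrix, E
the genetic effects, gamma covariate coefficients including the intercept)
and mixing proportions p_ji the conditional QTL-genotype probabilities given
flanking markers.  Estimation maximizes the beta-likelihood

    L_beta(theta) = (1/beta) [ (1/n) sum_j f(y_j)^beta / l_beta,j  -  1 ],
    l_beta = [ integral f(y)^(beta+1) dy ]^(beta/(beta+1)),

which reduces to the mean log-likelihood as beta -> 0 and, for beta > 0,
downweights observations of low model density by the factor f(y_j)^beta —
this is what makes the estimators robust to phenotypic outliers.  The
maximizer is an EM-type algorithm whose E-step computes beta-weighted
posteriors Pi_beta[j,i] = pi_ji f(y_j)^beta and whose M-step solves weighted
normal equations for E and gamma and a (1+beta)-scaled weighted residual
variance for sigma^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import logsumexp

from .genetics import DesignMatrix

LOG10E = float(np.log10(np.e))
_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateFitError(RuntimeError):
    """Raised when the weighted normal equations are singular."""


@dataclass
class Theta:
    """Full parameter set: genetic effects E, covariate coefficients gamma
    (intercept first), and shared residual variance sigma2 > 0."""

    E: np.ndarray
    gamma: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.E = np.atleast_1d(np.asarray(self.E, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")

    def copy(self) -> "Theta":
        return Theta(self.E.copy(), self.gamma.copy(), float(self.sigma2))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.E, self.gamma, [self.sigma2]])


@dataclass
class BetaPosterior:
    """Beta-weighted posterior class probabilities Pi_beta.

    Row j sums to f(y_j|theta)^beta; at beta = 0 rows are ordinary posterior
    probabilities and sum to 1.
    """

    Pi: np.ndarray
    beta: float


@dataclass
class FitResult:
    theta_hat: Theta
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    beta: float

    @property
    def objective(self) -> float:
        """Final beta-likelihood value (mean log-likelihood at beta = 0)."""
        return float(self.objective_trace[-1])


def component_means(theta: Theta, X: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Class means mu_ji = X_j gamma + D_i E as an (n, m) matrix."""
    base = X @ theta.gamma
    shift = D @ theta.E if D.shape[1] else np.zeros(D.shape[0])
    return base[:, None] + shift[None, :]


def _log_components(
    y: np.ndarray, means: np.ndarray, sigma2: float, probs: np.ndarray
) -> np.ndarray:
    """log[p_ji * N(y_j; mu_ji, sigma2)] with -inf where p_ji = 0."""
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    z2 = (y[:, None] - means) ** 2 / sigma2
    return logp - 0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * z2


def log_mixture_density(
    y: np.ndarray, means: np.ndarray, sigma2: float, probs: np.ndarray
) -> np.ndarray:
    """log f(y_j | theta, X_j) for every individual."""
    return logsumexp(_log_components(y, means, sigma2, probs), axis=1)


def mixture_density(y: float, theta: Theta, probs_row, means_row) -> float:
    """Mixture density of a single observation (convenience scalar form)."""
    probs_row = np.asarray(probs_row, dtype=float)
    means_row = np.asarray(means_row, dtype=float)
    return float(
        np.exp(
            log_mixture_density(
                np.array([y]), means_row[None, :], theta.sigma2, probs_row[None, :]
            )[0]
        )
    )


def _log_l_beta_gaussian(sigma2: float, beta: float) -> float:
    """log l_beta for a single Gaussian: closed form, independent of the mean.

    integral N^(beta+1) dy = (2 pi sigma2)^(-beta/2) (beta+1)^(-1/2).
    """
    if beta == 0.0:
        return 0.0
    logI = -0.5 * beta * (_LOG_2PI + np.log(sigma2)) - 0.5 * np.log1p(beta)
    return beta / (beta + 1.0) * logI


def _quadrature_nodes(lo: float, hi: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Panel-wise Gauss-Legendre nodes/weights resolving a Gaussian of scale sigma."""
    n_panels = int(np.clip(np.ceil((hi - lo) / sigma), 16, 256))
    x0, w0 = leggauss(10)
    edges = np.linspace(lo, hi, n_panels + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    nodes = (mid[:, None] + half[:, None] * x0[None, :]).ravel()
    weights = (half[:, None] * w0[None, :]).ravel()
    return nodes, weights


def log_l_beta(
    means: np.ndarray, sigma2: float, probs: np.ndarray, beta: float
) -> np.ndarray:
    """Per-observation log of the normalizer l_beta = [int f^(beta+1)]^(beta/(beta+1)).

    Uses the single-Gaussian closed form where the row's density is a single
    Gaussian (degenerate mixing probabilities, or all class means equal) and
    deterministic panel Gauss-Legendre quadrature over
    [min mu - 8 sigma, max mu + 8 sigma] otherwise.
    """
    n, m = means.shape
    out = np.empty(n)
    if beta == 0.0:
        out.fill(0.0)
        return out
    gauss_val = _log_l_beta_gaussian(sigma2, beta)
    degenerate = (probs >= 1.0 - 1e-12).any(axis=1)
    spread = means.max(axis=1) - means.min(axis=1)
    degenerate |= spread < 1e-12 * max(1.0, np.sqrt(sigma2))
    out[degenerate] = gauss_val
    rows = np.where(~degenerate)[0]
    if rows.size:
        sigma = np.sqrt(sigma2)
        lo = means[rows].min() - 8.0 * sigma
        hi = means[rows].max() + 8.0 * sigma
        t, w = _quadrature_nodes(lo, hi, sigma)
        # integrate f^(1+beta) in chunks to bound the (rows, m, nodes) tensor
        chunk = max(1, int(5e6 // (m * t.size)))
        for s in range(0, rows.size, chunk):
            sel = rows[s : s + chunk]
            logf_t = log_mixture_density_grid(t, means[sel], sigma2, probs[sel])
            I = np.exp(logsumexp((1.0 + beta) * logf_t, axis=1, b=w[None, :]))
            out[sel] = beta / (beta + 1.0) * np.log(I)
        if not np.isfinite(out[rows]).all():
            raise FloatingPointError(
                "l_beta quadrature produced non-finite values "
                f"(sigma2={sigma2}, beta={beta}, range=[{lo},{hi}])"
            )
    return out


def log_mixture_density_grid(
    t: np.ndarray, means: np.ndarray, sigma2: float, probs: np.ndarray
) -> np.ndarray:
    """log f_j(t) for a grid t: (n_rows, n_nodes) via (rows, classes, nodes)."""
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    z2 = (t[None, None, :] - means[:, :, None]) ** 2 / sigma2
    logc = logp[:, :, None] - 0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * z2
    return logsumexp(logc, axis=1)


def l_beta_normalizer(
    theta: Theta, probs: np.ndarray, X: np.ndarray, D: np.ndarray, beta: float
) -> np.ndarray:
    """Per-observation normalizer l_beta,j (equal to 1 everywhere at beta=0)."""
    means = component_means(theta, X, D)
    return np.exp(log_l_beta(means, theta.sigma2, probs, beta))


def beta_likelihood(
    Y: np.ndarray,
    X: np.ndarray,
    probs: np.ndarray,
    theta: Theta,
    D: np.ndarray,
    beta: float,
) -> float:
    """Per-observation-mean beta-likelihood (mean log-likelihood at beta=0)."""
    means = component_means(theta, X, D)
    logf = log_mixture_density(Y, means, theta.sigma2, probs)
    if not np.isfinite(logf).all():
        raise FloatingPointError("non-finite mixture density")
    if beta == 0.0:
        return float(np.mean(logf))
    logl = log_l_beta(means, theta.sigma2, probs, beta)
    # (f^beta / l - 1)/beta computed as expm1 for precision near beta = 0
    return float(np.mean(np.expm1(beta * logf - logl)) / beta)


def e_step(
    Y: np.ndarray,
    X: np.ndarray,
    probs: np.ndarray,
    theta: Theta,
    D: np.ndarray,
    beta: float,
) -> BetaPosterior:
    """Beta-weighted posteriors Pi_beta[j,i] = pi_ji f(y_j)^beta (log-space)."""
    means = component_means(theta, X, D)
    logc = _log_components(Y, means, theta.sigma2, probs)
    logf = logsumexp(logc, axis=1)
    Pi = np.exp(logc - logf[:, None] + beta * logf[:, None])
    return BetaPosterior(Pi=Pi, beta=beta)


def m_step(
    Pi: BetaPosterior,
    Y: np.ndarray,
    X: np.ndarray,
    D: np.ndarray,
    theta_prev: Theta,
    beta: float,
    e_update: str = "solve",
) -> Theta:
    """One M-step: genetic effects, covariate coefficients, residual variance.

    E solves the Pi_beta-weighted normal equations V E = b (``e_update="jacobi"``
    instead applies one sweep of the textbook recurrence E <- m - M E, which
    has the same fixed point); gamma is the f(y)^beta-weighted least-squares
    update; sigma2 is the (1+beta)-scaled Pi_beta-weighted mean squared
    residual over classes.
    """
    P = Pi.Pi
    w = P.sum(axis=1)  # per-observation robustness weight f(y_j)^beta
    r = Y - X @ theta_prev.gamma
    p = D.shape[1]
    if p:
        s = P.sum(axis=0)
        V = (D * s[:, None]).T @ D
        b = D.T @ (P.T @ r)
        if e_update == "jacobi":
            dv = np.diag(V)
            if np.any(dv <= 0):
                raise DegenerateFitError(f"zero class mass for effect column(s) {np.where(dv <= 0)[0].tolist()}")
            M = (V - np.diag(dv)) / dv[:, None]
            E_new = b / dv - M @ theta_prev.E
        else:
            try:
                E_new = np.linalg.solve(V, b)
            except np.linalg.LinAlgError:
                rank = np.linalg.matrix_rank(V)
                raise DegenerateFitError(
                    f"singular effect normal equations (rank {rank} of {p})"
                ) from None
    else:
        E_new = np.zeros(0)

    rhs = X.T @ (w * Y - P @ (D @ E_new))
    A = X.T @ (X * w[:, None])
    try:
        gamma_new = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(A)
        raise DegenerateFitError(
            f"singular covariate normal equations (rank {rank} of {X.shape[1]})"
        ) from None

    means = component_means(Theta(E_new, gamma_new, 1.0), X, D)
    sigma2_new = (1.0 + beta) * float(
        (P * (Y[:, None] - means) ** 2).sum() / P.sum()
    )
    if not sigma2_new > 0:
        raise DegenerateFitError("residual variance collapsed to zero")
    return Theta(E=E_new, gamma=gamma_new, sigma2=sigma2_new)


def _default_init(
    Y: np.ndarray, X: np.ndarray, probs: np.ndarray, D: np.ndarray
) -> Theta:
    """Deterministic start: OLS for gamma, OLS of residuals on expected
    genotype codes E[D|Q] for E, residual variance for sigma2."""
    gamma0, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ gamma0
    if D.shape[1]:
        Dexp = probs @ D
        E0, *_ = np.linalg.lstsq(Dexp - Dexp.mean(axis=0), resid, rcond=None)
        resid = resid - (Dexp - Dexp.mean(axis=0)) @ E0
    else:
        E0 = np.zeros(0)
    s2 = float(np.mean(resid**2))
    return Theta(E=E0, gamma=gamma0, sigma2=max(s2, 1e-12))


def fit(
    Y: np.ndarray,
    X: np.ndarray,
    probs,
    D,
    beta: float = 0.0,
    init: Theta | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    e_update: str = "solve",
) -> FitResult:
    """Maximize the beta-likelihood by alternating E- and M-steps.

    Convergence when the objective changes by less than tol*(1+|objective|);
    non-convergence is flagged on the result, not raised.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Q = probs.Q if hasattr(probs, "Q") else np.asarray(probs, dtype=float)
    Dm = D.D if isinstance(D, DesignMatrix) else np.asarray(D, dtype=float)
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    # Closed-form shortcut: with beta=0 and fully degenerate mixing rows the
    # latent class is observed, so the ML fit is exact OLS on [X | D codes]
    # (the same maximizer the EM iteration converges to).
    if beta == 0.0 and init is None and (Q.max(axis=1) >= 1.0 - 1e-12).all():
        codes = Dm[np.argmax(Q, axis=1)]  # (n, p) genetic codes per individual
        full = np.hstack([X, codes]) if Dm.shape[1] else X
        coef, _, rank, _ = np.linalg.lstsq(full, Y, rcond=None)
        if rank == full.shape[1]:
            resid = Y - full @ coef
            s2 = float(np.mean(resid**2))
            if s2 > 0:
                theta = Theta(E=coef[X.shape[1]:], gamma=coef[: X.shape[1]], sigma2=s2)
                obj = -0.5 * (_LOG_2PI + np.log(s2) + 1.0)
                return FitResult(
                    theta_hat=theta,
                    objective_trace=np.array([obj]),
                    converged=True,
                    n_iter=0,
                    beta=beta,
                )
    theta = init.copy() if init is not None else _default_init(Y, X, Q, Dm)
    trace = [beta_likelihood(Y, X, Q, theta, Dm, beta)]
    converged = False
    for _ in range(max_iter):
        Pi = e_step(Y, X, Q, theta, Dm, beta)
        theta = m_step(Pi, Y, X, Dm, theta, beta, e_update=e_update)
        obj = beta_likelihood(Y, X, Q, theta, Dm, beta)
        done = abs(obj - trace[-1]) <= tol * (1.0 + abs(obj))
        trace.append(obj)
        if done:
            converged = True
            break
    return FitResult(
        theta_hat=theta,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace) - 1,
        beta=beta,
    )


def fit_null(Y: np.ndarray, X: np.ndarray, beta: float = 0.0, **kwargs) -> FitResult:
    """Single-component (no-QTL) fit: at beta=0 this is OLS with MLE variance;
    at beta>0 it is an iteratively f(y)^beta-reweighted regression."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    probs = np.ones((n, 1))
    D = np.zeros((1, 0))
    return fit(Y, X, probs, D, beta=beta, **kwargs)


def lod_beta(fit_alt: FitResult, fit_null_: FitResult, n: int) -> float:
    """LOD_beta = log10(e) * n * (L_beta_alt - L_beta_null).

    At beta=0 this is the classical LOD score; negative values (possible for
    beta > 0 since beta-objectives are not nested-monotone) are reported as
    computed.
    """
    if fit_alt.beta != fit_null_.beta:
        raise ValueError(
            f"alternative (beta={fit_alt.beta}) and null (beta={fit_null_.beta}) "
            "fits use different beta"
        )
    return LOG10E * n * (fit_alt.objective - fit_null_.objective)


def estimating_function_bound_check(
    theta: Theta,
    probs_row,
    X_row,
    D,
    beta: float,
    y_grid: np.ndarray,
    rel_step: float = 1e-6,
) -> dict[str, tuple[float, float]]:
    """Supremum of each estimating-function component over a phenotype grid.

    The estimating function is the gradient of the per-observation objective
    (f(y)^beta / l_beta - 1)/beta (log f at beta = 0) with respect to
    (E..., gamma..., sigma2), evaluated by central finite differences.  For
    beta > 0 every component is bounded in y (the e^{-beta z^2} envelope);
    at beta = 0 components grow without bound as the grid extends — the
    numeric signature of B-robustness.  Returns
    {param_name: (sup |psi|, y at which it is attained)}.
    """
    y_grid = np.asarray(y_grid, dtype=float)
    probs_row = np.atleast_2d(np.asarray(probs_row, dtype=float))
    X_row = np.atleast_2d(np.asarray(X_row, dtype=float))
    Dm = D.D if isinstance(D, DesignMatrix) else np.asarray(D, dtype=float)

    def omega(th: Theta) -> np.ndarray:
        means = component_means(th, X_row, Dm)  # (1, m)
        logf = log_mixture_density_grid(y_grid, means, th.sigma2, probs_row)[0]
        if beta == 0.0:
            return logf
        logl = log_l_beta(means, th.sigma2, probs_row, beta)[0]
        return np.expm1(beta * logf - logl) / beta

    pack = theta.pack()
    names = (
        [f"E[{i}]" for i in range(theta.E.size)]
        + [f"gamma[{i}]" for i in range(theta.gamma.size)]
        + ["sigma2"]
    )
    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(names):
        h = rel_step * max(1.0, abs(pack[i]))
        up, dn = pack.copy(), pack.copy()
        up[i] += h
        dn[i] -= h
        nE = theta.E.size
        th_up = Theta(up[:nE], up[nE:-1], up[-1])
        th_dn = Theta(dn[:nE], dn[nE:-1], dn[-1])
        grad = (omega(th_up) - omega(th_dn)) / (2.0 * h)
        j = int(np.argmax(np.abs(grad)))
        out[name] = (float(np.abs(grad[j])), float(y_grid[j]))
    return out
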