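"""K-component Gaussian mixture over centered trajectories, fit by EM.

Model: conditional on visit ages t_i and baseline covariates z_i, a subject's
centered outcome vector y_i follows

    f(y_i | t_i, z_i) = sum_k pi_k(z_i) * N(y_i; X_i beta_k, Sigma_k(t_i)),

where X_i is a quadratic B-spline basis evaluated at the subject's ages,
beta_k the group-k mean-curve coefficients, Sigma_k an independence or
exponential-correlation working covariance with constant variance, and
pi_k(z) multinomial-logit membership probabilities with group K as the
reference.  Estimation is by EM with multiple starts; the number of groups
and the covariance structure are chosen by minimising BIC; subjects are
classified to their maximum-posterior group.

Unequal visit counts are handled by grouping subjects that share the same
visit-age pattern, so each E/M step is vectorised within patterns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .covariance import COV_KINDS, CovarianceModel, covariance_matrix
from .splines import SplineBasis, build_spline_basis
from .transform import CenteredPanel

__all__ = [
    "MixtureModel",
    "FitResult",
    "NonConvergenceError",
    "mixture_loglik",
    "e_step",
    "m_step_means",
    "m_step_covariance",
    "m_step_concomitant",
    "fit_em",
    "bic",
    "select_model",
    "classify",
]

VAR_FLOOR = 1e-8
ETA_CAP = 30.0
#: log-phi search range for the exponential correlation range (years)
PHI_BOUNDS = (math.log(0.01), math.log(100.0))
_PHI_GRID = np.exp(np.linspace(PHI_BOUNDS[0], PHI_BOUNDS[1], 61))
_PHI_GRID_SET = set(float(v) for v in _PHI_GRID)


class NonConvergenceError(RuntimeError):
    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces or []


# ---------------------------------------------------------------------------
# model containers


@dataclass(frozen=True)
class MixtureModel:
    """Parameters of the fitted mixture (see module docstring)."""

    K: int
    beta: np.ndarray  # (K, q) spline coefficients, centered-outcome units
    cov: tuple  # K CovarianceModel
    gamma: np.ndarray  # (K-1, 1+p) log-odds vs reference group K
    basis: SplineBasis
    covariate_names: tuple = ("intercept",)

    @property
    def n_params(self) -> int:
        q = self.basis.dimension
        d_cov = sum(c.n_params for c in self.cov)
        return self.K * q + d_cov + (self.K - 1) * len(self.covariate_names)

    def membership_probs(self, Z: np.ndarray) -> np.ndarray:
        """pi_k(z) for design rows Z (intercept first); rows sum to 1."""
        return np.exp(_log_membership(self.gamma, np.atleast_2d(Z)))

    def mean_curves(self, ages) -> np.ndarray:
        """(K, len(ages)) fitted group mean curves on the centered scale."""
        return self.basis.design(ages) @ self.beta.T


@dataclass
class FitResult:
    model: MixtureModel
    loglik: float
    bic: float
    n_subjects: int
    n_params: int
    posteriors: np.ndarray  # (n, K)
    subject_ids: list
    labels: np.ndarray  # (n,) groups 1..K
    converged: bool
    n_iter: int
    trace: np.ndarray
    var_floor_hit: bool = False
    data: CenteredPanel | None = None
    Z: np.ndarray | None = None

    @property
    def posterior_table(self) -> pd.DataFrame:
        cols = {f"prob_{k + 1}": self.posteriors[:, k] for k in range(self.model.K)}
        df = pd.DataFrame(cols, index=pd.Index(self.subject_ids, name="subject_id"))
        df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# prepared (pattern-grouped) data


@dataclass
class _Pattern:
    ages: np.ndarray  # (d,)
    X: np.ndarray  # (d, q)
    Y: np.ndarray  # (m, d)
    idx: np.ndarray  # (m,) positions in subject order
    pid: int = 0  # position in the pattern list


@dataclass
class _Prepared:
    subject_ids: list
    patterns: list
    Z: np.ndarray  # (n, 1+p)
    covariate_names: tuple
    basis: SplineBasis
    n: int
    n_records: int
    max_age: float
    _exp_cache: dict = field(default_factory=dict)

    def exp_factors(self, phi: float):
        """Per-pattern (cholesky L, logdet) of the unit-variance exponential
        correlation matrix.  Grid values are cached (patterns are fixed for
        a fit); off-grid values from local refinement are computed fresh."""
        key = float(phi)
        cached = self._exp_cache.get(key)
        if cached is not None:
            return cached
        out = []
        for p in self.patterns:
            gaps = np.abs(p.ages[:, None] - p.ages[None, :])
            L = cholesky(np.exp(-gaps / key), lower=True)
            out.append((L, 2.0 * float(np.sum(np.log(np.diag(L))))))
        if key in _PHI_GRID_SET:
            self._exp_cache[key] = out
        return out

    def exp_grid(self):
        """Per-pattern (Rinv over the whole phi grid, logdet over the grid),
        precomputed once: Rinv_all is (G, d, d), logdet_all is (G,)."""
        if "grid" not in self._exp_cache:
            out = []
            for p in self.patterns:
                gaps = np.abs(p.ages[:, None] - p.ages[None, :])
                Rinv_all = np.empty((_PHI_GRID.size, p.ages.size, p.ages.size))
                logdet_all = np.empty(_PHI_GRID.size)
                for g, phi in enumerate(_PHI_GRID):
                    R = np.exp(-gaps / phi)
                    sign, logdet_all[g] = np.linalg.slogdet(R)
                    Rinv_all[g] = np.linalg.inv(R)
                out.append((Rinv_all, logdet_all))
            self._exp_cache["grid"] = out
        return self._exp_cache["grid"]


def _prepare(
    data: CenteredPanel,
    basis: SplineBasis | None = None,
    Z: np.ndarray | None = None,
    covariate_names=None,
) -> _Prepared:
    subj = []
    groups: dict = {}
    all_ages = []
    for sid, ages, values in data.iter_subjects():
        i = len(subj)
        subj.append(sid)
        all_ages.append(ages)
        key = tuple(np.round(ages, 9))
        groups.setdefault(key, []).append((i, values))
    pooled = np.concatenate(all_ages)
    if basis is None:
        basis = build_spline_basis(pooled)
    patterns = []
    for pid, key in enumerate(sorted(groups)):
        entries = groups[key]
        ages = np.asarray(key, dtype=float)
        patterns.append(
            _Pattern(
                ages=ages,
                X=basis.design(ages),
                Y=np.vstack([v for _, v in entries]),
                idx=np.asarray([i for i, _ in entries], dtype=int),
                pid=pid,
            )
        )
    n = len(subj)
    if Z is None:
        Z = np.ones((n, 1))
        covariate_names = ("intercept",)
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] != n:
            raise ValueError(f"covariate rows ({Z.shape[0]}) != subjects ({n})")
        covariate_names = tuple(covariate_names or [f"z{j}" for j in range(Z.shape[1])])
    return _Prepared(
        subject_ids=subj,
        patterns=patterns,
        Z=Z,
        covariate_names=covariate_names,
        basis=basis,
        n=n,
        n_records=int(pooled.size),
        max_age=float(pooled.max()),
    )


def _covariates_to_design(data: CenteredPanel, covariates):
    """Accept None (intercept only) or a DataFrame of per-subject covariates."""
    if covariates is None:
        return None, None
    if isinstance(covariates, pd.DataFrame):
        missing = [s for s in data.subjects if s not in covariates.index]
        if missing:
            raise ValueError(f"covariate rows missing for subjects {missing[:5]}")
        M = covariates.loc[data.subjects]
        Z = np.column_stack([np.ones(len(M)), M.to_numpy(dtype=float)])
        return Z, ("intercept", *M.columns)
    raise TypeError("covariates must be None or a DataFrame indexed by subject_id")


# ---------------------------------------------------------------------------
# likelihood pieces


def _component_loglik(prep: _Prepared, beta: np.ndarray, cov) -> np.ndarray:
    """(n, K) log N(y_i; X_i beta_k, Sigma_k) for every subject and group."""
    K = beta.shape[0]
    ll = np.empty((prep.n, K))
    for k in range(K):
        ck = cov[k]
        for p in prep.patterns:
            d = p.ages.size
            R = p.Y - p.X @ beta[k]
            if ck.kind == "independence":
                qf = np.einsum("ij,ij->i", R, R) / ck.sigma2
                ld = d * math.log(ck.sigma2)
            else:
                L, logdet_corr = _pattern_exp_factor(prep, p, ck.phi)
                W = solve_triangular(L, R.T, lower=True)
                qf = np.einsum("ji,ji->i", W, W) / ck.sigma2
                ld = d * math.log(ck.sigma2) + logdet_corr
            ll[p.idx, k] = -0.5 * (d * math.log(2 * math.pi) + ld + qf)
    return ll


def _pattern_exp_factor(prep: _Prepared, pattern: _Pattern, phi: float):
    return prep.exp_factors(phi)[pattern.pid]


def _log_membership(gamma: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """(n, K) log pi_k(z); reference group K carries implicit zeros."""
    eta = Z @ gamma.T if gamma.size else np.zeros((Z.shape[0], 0))
    eta = np.hstack([eta, np.zeros((Z.shape[0], 1))])
    return eta - logsumexp(eta, axis=1, keepdims=True)


def _total_loglik(ll: np.ndarray, logpi: np.ndarray) -> tuple[float, np.ndarray]:
    joint = ll + logpi
    norm = logsumexp(joint, axis=1, keepdims=True)
    return float(norm.sum()), np.exp(joint - norm)


def mixture_loglik(model: MixtureModel, data: CenteredPanel, covariates=None) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k(z_i) N(y_i; ...)."""
    Z, names = _covariates_to_design(data, covariates)
    prep = _prepare(data, model.basis, Z, names)
    _check_dims(model, prep)
    ll = _component_loglik(prep, model.beta, model.cov)
    total, _ = _total_loglik(ll, _log_membership(model.gamma, prep.Z))
    return total


def _check_dims(model: MixtureModel, prep: _Prepared) -> None:
    if model.beta.shape != (model.K, model.basis.dimension):
        raise ValueError("beta shape inconsistent with K and basis dimension")
    if model.gamma.shape != (model.K - 1, prep.Z.shape[1]):
        raise ValueError(
            f"gamma shape {model.gamma.shape} inconsistent with K={model.K} "
            f"and {prep.Z.shape[1]} covariate columns"
        )


def e_step(model: MixtureModel, data: CenteredPanel, covariates=None) -> pd.DataFrame:
    """Posterior group probabilities; rows sum to 1 (log-sum-exp stable)."""
    Z, names = _covariates_to_design(data, covariates)
    prep = _prepare(data, model.basis, Z, names)
    _check_dims(model, prep)
    ll = _component_loglik(prep, model.beta, model.cov)
    _, W = _total_loglik(ll, _log_membership(model.gamma, prep.Z))
    return pd.DataFrame(
        W,
        index=pd.Index(prep.subject_ids, name="subject_id"),
        columns=[f"prob_{k + 1}" for k in range(model.K)],
    )


# ---------------------------------------------------------------------------
# M-steps


_rank_warned = False


def _m_means(prep: _Prepared, W: np.ndarray, cov) -> np.ndarray:
    """Posterior-weighted GLS for each group's spline coefficients.

    Solved by least squares on the normal equations; a rank-deficient
    pooled design (fewer distinct ages than basis functions) yields the
    minimum-norm solution — the likelihood depends only on X @ beta.
    """
    global _rank_warned
    K = W.shape[1]
    q = prep.basis.dimension
    beta = np.empty((K, q))
    for k in range(K):
        A = np.zeros((q, q))
        b = np.zeros(q)
        if cov[k].kind == "independence":
            for p in prep.patterns:
                w = W[p.idx, k]
                A += w.sum() * (p.X.T @ p.X)
                b += p.X.T @ (p.Y.T @ w)
        else:
            for p in prep.patterns:
                L, _ = _pattern_exp_factor(prep, p, cov[k].phi)
                Rinv = cho_solve((L, True), np.eye(p.ages.size))
                XtR = p.X.T @ Rinv
                w = W[p.idx, k]
                A += w.sum() * (XtR @ p.X)
                b += XtR @ (p.Y.T @ w)
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < q and not _rank_warned:
            warnings.warn(
                f"rank-deficient mean design for group {k + 1} "
                f"(rank {rank} < {q}); using minimum-norm solution",
                stacklevel=2,
            )
            _rank_warned = True
        beta[k] = sol
    return beta


def m_step_means(posteriors: np.ndarray, data: CenteredPanel, basis: SplineBasis, cov=None) -> np.ndarray:
    """Public wrapper for the mean-update M-step (independence by default)."""
    prep = _prepare(data, basis)
    W = np.asarray(posteriors, dtype=float)
    K = W.shape[1]
    if cov is None:
        cov = tuple(CovarianceModel("independence", 1.0) for _ in range(K))
    return _m_means(prep, W, cov)


def _exp_profile(prep: _Prepared, W_col: np.ndarray, resid: list, phi: float):
    """Profile quantities for one group at correlation range phi.

    resid[p] is the (m, d) residual matrix of pattern p at the current beta.
    Returns (profile loglik, sigma2_hat)."""
    qtot = 0.0
    ldtot = 0.0
    N = 0.0
    for p, R in zip(prep.patterns, resid):
        w = W_col[p.idx]
        L, logdet = _pattern_exp_factor(prep, p, phi)
        Wm = solve_triangular(L, R.T, lower=True)
        qtot += float(np.einsum("ji,ji->i", Wm, Wm) @ w)
        s = w.sum()
        ldtot += s * logdet
        N += s * p.ages.size
    sigma2 = max(qtot / N, VAR_FLOOR)
    obj = -0.5 * (N * math.log(sigma2) + ldtot + qtot / sigma2)
    return obj, sigma2


def _m_cov(prep: _Prepared, W: np.ndarray, beta: np.ndarray, kind: str, current=None):
    """Covariance M-step; returns (models, floor_hit flag)."""
    K = W.shape[1]
    out = []
    floor_hit = False
    for k in range(K):
        resid = [p.Y - p.X @ beta[k] for p in prep.patterns]
        wsum = sum(float(W[p.idx, k].sum()) for p in prep.patterns)
        if wsum <= 0:
            raise NonConvergenceError(f"group {k + 1} received zero posterior weight")
        if kind == "independence":
            num = sum(
                float(np.einsum("ij,ij->i", R, R) @ W[p.idx, k])
                for p, R in zip(prep.patterns, resid)
            )
            den = sum(float(W[p.idx, k].sum()) * p.ages.size for p in prep.patterns)
            sigma2 = num / den
            if sigma2 < VAR_FLOOR:
                sigma2 = VAR_FLOOR
                floor_hit = True
            out.append(CovarianceModel("independence", sigma2))
            continue
        # exponential: vectorised grid scan over log-phi, then a local
        # parabolic refinement step evaluated exactly
        col = W[:, k]
        G = _PHI_GRID.size
        qs = np.zeros(G)
        lds = np.zeros(G)
        N = 0.0
        grid = prep.exp_grid()
        for p, R in zip(prep.patterns, resid):
            w = col[p.idx]
            Rinv_all, logdet_all = grid[p.pid]
            q_gm = np.einsum("md,gde,me->gm", R, Rinv_all, R, optimize=True)
            s = w.sum()
            qs += q_gm @ w
            lds += s * logdet_all
            N += s * p.ages.size
        s2_grid = np.maximum(qs / N, VAR_FLOOR)
        objs = -0.5 * (N * np.log(s2_grid) + lds + qs / s2_grid)
        j = int(np.argmax(objs))
        candidates = [_PHI_GRID[j]]
        if 0 < j < G - 1:
            # parabolic step in log-phi through the three bracketing points
            lx = np.log(_PHI_GRID[j - 1 : j + 2])
            fy = objs[j - 1 : j + 2]
            num = (lx[1] - lx[0]) ** 2 * (fy[1] - fy[2]) - (lx[1] - lx[2]) ** 2 * (fy[1] - fy[0])
            den = (lx[1] - lx[0]) * (fy[1] - fy[2]) - (lx[1] - lx[2]) * (fy[1] - fy[0])
            if den != 0.0:
                lp = lx[1] - 0.5 * num / den
                if lx[0] < lp < lx[2]:
                    candidates.append(math.exp(lp))
        if current is not None and current[k].kind == "exponential":
            candidates.append(current[k].phi)
        best_phi, best_obj, best_s2 = None, -np.inf, None
        for phi in candidates:
            obj, s2 = _exp_profile(prep, col, resid, phi)
            if obj > best_obj:
                best_phi, best_obj, best_s2 = phi, obj, s2
        if best_s2 <= VAR_FLOOR:
            floor_hit = True
        out.append(CovarianceModel("exponential", max(best_s2, VAR_FLOOR), best_phi))
    return tuple(out), floor_hit


def m_step_covariance(
    posteriors: np.ndarray,
    data: CenteredPanel,
    basis: SplineBasis,
    beta: np.ndarray,
    kind: str = "independence",
):
    """Public wrapper: per-group covariance update at the current means."""
    if kind not in COV_KINDS:
        raise ValueError(f"unknown covariance kind {kind!r}")
    prep = _prepare(data, basis)
    models, floor_hit = _m_cov(prep, np.asarray(posteriors, float), beta, kind)
    if floor_hit:
        warnings.warn("variance hit the floor (1e-8); degenerate component", stacklevel=2)
    return models


def _weighted_multinomial_obj(gamma: np.ndarray, Z: np.ndarray, W: np.ndarray) -> float:
    return float(np.sum(W * _log_membership(gamma, Z)))


def m_step_concomitant(
    posteriors: np.ndarray,
    Z: np.ndarray,
    gamma_init: np.ndarray | None = None,
    max_newton: int = 100,
    gtol: float = 1e-9,
) -> np.ndarray:
    """Posterior-weighted multinomial-logit update of the membership model.

    Intercept-only designs have the closed form
    gamma_k0 = log(mean posterior_k / mean posterior_K); otherwise Newton
    iterations with step halving.  Quasi-separation is capped so that no
    subject's log-odds exceeds +/-30, with a warning.
    """
    W = np.asarray(posteriors, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, K = W.shape
    p1 = Z.shape[1]
    if K == 1:
        return np.zeros((0, p1))
    if p1 == 1 and np.allclose(Z, 1.0):
        means = W.mean(axis=0)
        ref = max(means[-1], 1e-300)
        g = np.log(np.maximum(means[:-1], 1e-300) / ref)
        return np.clip(g, -ETA_CAP, ETA_CAP).reshape(K - 1, 1)
    gamma = (
        np.zeros((K - 1, p1))
        if gamma_init is None
        else np.array(gamma_init, dtype=float, copy=True)
    )
    obj = _weighted_multinomial_obj(gamma, Z, W)
    for _ in range(max_newton):
        pi = np.exp(_log_membership(gamma, Z))
        G = Z.T @ (W[:, :-1] - pi[:, :-1])  # (p1, K-1)
        g = G.T.ravel()
        if np.max(np.abs(g)) < gtol:
            break
        dim = (K - 1) * p1
        H = np.empty((dim, dim))
        for a in range(K - 1):
            for b in range(K - 1):
                wts = pi[:, a] * ((1.0 if a == b else 0.0) - pi[:, b])
                H[a * p1 : (a + 1) * p1, b * p1 : (b + 1) * p1] = (Z * wts[:, None]).T @ Z
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, g).reshape(K - 1, p1)
        t = 1.0
        for _ in range(40):
            cand = gamma + t * step
            cand_obj = _weighted_multinomial_obj(cand, Z, W)
            if cand_obj >= obj:
                break
            t *= 0.5
        if cand_obj < obj:
            break
        gamma, obj = cand, cand_obj
    eta_max = float(np.max(np.abs(Z @ gamma.T))) if gamma.size else 0.0
    if eta_max > ETA_CAP:
        warnings.warn(
            "quasi-separation in the membership model; capping log-odds at "
            f"+/-{ETA_CAP:g}",
            stacklevel=2,
        )
        gamma = gamma * (ETA_CAP / eta_max)
    return gamma


# ---------------------------------------------------------------------------
# EM driver


def _init_kmeans(prep: _Prepared, K: int, seed: int) -> np.ndarray:
    """Hard partition of visit-aligned centered vectors (column-mean imputed)."""
    ages = sorted({round(float(a), 6) for p in prep.patterns for a in p.ages})
    col = {a: j for j, a in enumerate(ages)}
    M = np.full((prep.n, len(ages)), np.nan)
    for p in prep.patterns:
        cols = [col[round(float(a), 6)] for a in p.ages]
        M[np.ix_(p.idx, cols)] = p.Y
    mu = np.nanmean(M, axis=0)
    M = np.where(np.isnan(M), mu, M)
    labels = KMeans(n_clusters=K, n_init=4, random_state=seed % (2**31)).fit_predict(M)
    eps = 0.02
    W = np.full((prep.n, K), eps / max(K - 1, 1))
    W[np.arange(prep.n), labels] = 1.0 - eps
    return W / W.sum(axis=1, keepdims=True)


def _run_em(
    prep: _Prepared,
    K: int,
    cov_kind: str,
    init_W: np.ndarray | None,
    init_params=None,
    max_iter: int = 500,
    tol: float = 1e-8,
):
    """EM iterations from initial responsibilities or parameters.

    Returns dict with params, trace, posteriors, converged flag."""
    if init_params is not None:
        beta, cov, gamma = init_params
    else:
        W = init_W
        cov0 = tuple(CovarianceModel(cov_kind, 1.0, 1.0 if cov_kind == "exponential" else None) for _ in range(K))
        beta = _m_means(prep, W, cov0)
        cov, floor_hit = _m_cov(prep, W, beta, cov_kind)
        beta = _m_means(prep, W, cov)
        gamma = m_step_concomitant(W, prep.Z)
    trace = []
    converged = False
    floor_hit = False
    prev = -np.inf
    for _ in range(max_iter):
        ll = _component_loglik(prep, beta, cov)
        total, W = _total_loglik(ll, _log_membership(gamma, prep.Z))
        trace.append(total)
        if prev > -np.inf and abs(total - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = total
        beta = _m_means(prep, W, cov)
        cov, hit = _m_cov(prep, W, beta, cov_kind, current=cov)
        floor_hit = floor_hit or hit
        gamma = m_step_concomitant(W, prep.Z, gamma_init=gamma)
    return {
        "beta": beta,
        "cov": cov,
        "gamma": gamma,
        "trace": np.asarray(trace),
        "loglik": trace[-1],
        "posteriors": W,
        "converged": converged,
        "floor_hit": floor_hit,
    }


def _relabel(beta, cov, gamma, W, basis, max_age):
    """Order groups by fitted mean-curve value at the oldest observed age,
    descending — group 1 is the steepest riser, group K the flattest."""
    v = (basis.design([max_age]) @ beta.T).ravel()
    order = np.argsort(-v, kind="stable")
    K = beta.shape[0]
    G = np.vstack([gamma, np.zeros((1, gamma.shape[1]))]) if K > 1 else np.zeros((1, gamma.shape[1] if gamma.size else 1))
    Gp = G[order]
    new_gamma = (Gp[:-1] - Gp[-1]) if K > 1 else np.zeros((0, G.shape[1]))
    return beta[order], tuple(cov[i] for i in order), new_gamma, W[:, order]


def fit_em(
    data: CenteredPanel,
    covariates=None,
    K: int = 2,
    cov_kind: str = "independence",
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    basis: SplineBasis | None = None,
    init_posteriors: np.ndarray | None = None,
    screen_iter: int = 25,
    n_refine: int = 3,
) -> FitResult:
    """Multi-start EM fit of the K-group spline mixture.

    Starts: one k-means partition of visit-aligned centered vectors, the
    rest random responsibilities (plus ``init_posteriors`` as a warm start
    when given).  All starts run ``screen_iter`` iterations; the best
    ``n_refine`` continue to convergence and the best final log-likelihood
    wins.  Groups are relabelled by descending mean-curve value at the
    oldest observed age.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if cov_kind not in COV_KINDS:
        raise ValueError(f"unknown covariance kind {cov_kind!r}")
    Z, names = _covariates_to_design(data, covariates)
    prep = _prepare(data, basis, Z, names)
    if prep.n < K:
        raise ValueError(f"need at least K={K} subjects, have {prep.n}")

    rng = np.random.default_rng(seed)
    if K == 1:
        run = _run_em(prep, 1, cov_kind, np.ones((prep.n, 1)), max_iter=max_iter, tol=tol)
        runs = [run]
    else:
        starts = [_init_kmeans(prep, K, seed)]
        if init_posteriors is not None:
            W0 = np.asarray(init_posteriors, dtype=float)
            if W0.shape != (prep.n, K):
                raise ValueError("init_posteriors shape mismatch")
            starts.append(W0)
        while len(starts) < max(n_starts, 1):
            starts.append(rng.dirichlet(np.ones(K), size=prep.n))
        screened = [
            _run_em(prep, K, cov_kind, W0, max_iter=min(screen_iter, max_iter), tol=tol)
            for W0 in starts
        ]
        screened.sort(key=lambda r: -r["loglik"])
        runs = []
        for r in screened[: max(n_refine, 1)]:
            if r["converged"]:
                runs.append(r)
                continue
            cont = _run_em(
                prep,
                K,
                cov_kind,
                None,
                init_params=(r["beta"], r["cov"], r["gamma"]),
                max_iter=max_iter,
                tol=tol,
            )
            cont["trace"] = np.concatenate([r["trace"][:-1], cont["trace"]])
            cont["floor_hit"] = cont["floor_hit"] or r["floor_hit"]
            runs.append(cont)
    best = max(runs, key=lambda r: r["loglik"])
    if not best["converged"]:
        raise NonConvergenceError(
            f"no EM run converged within {max_iter} iterations (K={K}, {cov_kind})",
            traces=[r["trace"] for r in runs],
        )
    beta, cov, gamma, W = _relabel(
        best["beta"], best["cov"], best["gamma"], best["posteriors"], prep.basis, prep.max_age
    )
    model = MixtureModel(
        K=K,
        beta=beta,
        cov=cov,
        gamma=gamma,
        basis=prep.basis,
        covariate_names=prep.covariate_names,
    )
    labels = np.argmax(W, axis=1) + 1
    fit = FitResult(
        model=model,
        loglik=best["loglik"],
        bic=float("nan"),
        n_subjects=prep.n,
        n_params=model.n_params,
        posteriors=W,
        subject_ids=prep.subject_ids,
        labels=labels,
        converged=True,
        n_iter=len(best["trace"]),
        trace=best["trace"],
        var_floor_hit=best["floor_hit"],
        data=data,
        Z=prep.Z,
    )
    fit.bic = bic(fit)
    return fit


def bic(fit: FitResult) -> float:
    """BIC = -2 loglik + d log(n); n = number of subjects (the mixture's
    independent units), d = K q + covariance params + (K-1)(1+p)."""
    return -2.0 * fit.loglik + fit.n_params * math.log(fit.n_subjects)


def select_model(
    data: CenteredPanel,
    K_range=(2, 3, 4, 5),
    cov_kinds=("independence", "exponential"),
    seed: int = 0,
    **fit_kwargs,
):
    """Fit every (K, covariance kind) cell without covariates; minimise BIC.

    Returns ``(best_fit, table)`` where ``table`` has one row per cell with
    loglik, parameter count, BIC and convergence status.  Deterministic for
    a fixed seed.
    """
    cells = [(K, kind) for K in K_range for kind in cov_kinds]
    seeds = np.random.SeedSequence(seed).generate_state(len(cells)) & 0x7FFFFFFF
    rows = []
    fits = {}
    for (K, kind), s in zip(cells, seeds):
        try:
            fit = fit_em(data, K=K, cov_kind=kind, seed=int(s), **fit_kwargs)
            fits[(K, kind)] = fit
            rows.append(
                dict(K=K, cov_kind=kind, loglik=fit.loglik, n_params=fit.n_params,
                     bic=fit.bic, converged=True)
            )
        except NonConvergenceError as exc:
            warnings.warn(f"cell (K={K}, {kind}) did not converge: {exc}", stacklevel=2)
            rows.append(
                dict(K=K, cov_kind=kind, loglik=np.nan, n_params=np.nan,
                     bic=np.nan, converged=False)
            )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if len(ok) == 0:
        raise NonConvergenceError("no (K, covariance) cell converged")
    best_row = ok.loc[ok["bic"].idxmin()]
    best = fits[(int(best_row["K"]), best_row["cov_kind"])]
    return best, table


def classify(fit: FitResult):
    """Hard labels (max posterior, ties to the lowest group index) plus a
    per-group fraction of posterior probabilities in the uncertain band
    (0.1, 0.9) exclusive."""
    W = fit.posteriors
    labels = pd.Series(
        np.argmax(W, axis=1) + 1, index=pd.Index(fit.subject_ids, name="subject_id"),
        name="label",
    )
    frac = ((W > 0.1) & (W < 0.9)).mean(axis=0)
    uncertainty = pd.DataFrame(
        {"group": np.arange(1, fit.model.K + 1), "frac_uncertain": frac}
    )
    return labels, uncertainty


# ---------------------------------------------------------------------------
# parameter packing (used for observed-information standard errors)


def pack_params(model: MixtureModel) -> np.ndarray:
    parts = [model.beta.ravel()]
    for c in model.cov:
        parts.append([c.sigma2] if c.kind == "independence" else [c.sigma2, c.phi])
    parts.append(model.gamma.ravel())
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def unpack_params(theta: np.ndarray, template: MixtureModel) -> MixtureModel:
    K, q = template.beta.shape
    pos = K * q
    beta = np.asarray(theta[:pos], dtype=float).reshape(K, q)
    cov = []
    for c in template.cov:
        if c.kind == "independence":
            cov.append(CovarianceModel("independence", float(theta[pos])))
            pos += 1
        else:
            cov.append(CovarianceModel("exponential", float(theta[pos]), float(theta[pos + 1])))
            pos += 2
    gamma = np.asarray(theta[pos:], dtype=float).reshape(template.gamma.shape)
    return replace(template, beta=beta, cov=tuple(cov), gamma=gamma)


def gamma_param_indices(model: MixtureModel) -> np.ndarray:
    """Positions of the gamma entries inside the packed parameter vector,
    shaped (K-1, 1+p) to mirror ``model.gamma``."""
    K, q = model.beta.shape
    offset = K * q + sum(c.n_params for c in model.cov)
    return offset + np.arange(model.gamma.size).reshape(model.gamma.shape)
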