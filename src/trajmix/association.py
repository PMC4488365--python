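"""Exposure-membership association: relative risk ratios with Wald intervals.

After the number of groups and the covariance structure are fixed, baseline
risk factors enter the multinomial-logit membership model and the whole
mixture is re-estimated jointly.  For group j vs the reference group K, the
relative risk ratio per delta-unit covariate increase is

    RRR_j = [pi_j(z+delta)/pi_j(z)] / [pi_K(z+delta)/pi_K(z)]
          = exp(delta * gamma_j),

constant in z under the multinomial-logit model.  Standard errors come from
the observed information of the *full* mixture log-likelihood at the MLE
(numerical central differences), which propagates classification
uncertainty into the interval; a hard-label two-stage variant is available
for comparison.  Intervals are symmetric on the log scale:
exp(gamma +/- z_{a/2} SE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mixture import (
    FitResult,
    _component_loglik,
    _log_membership,
    _prepare,
    _total_loglik,
    fit_em,
    gamma_param_indices,
    pack_params,
    unpack_params,
)
from .panel import BaselineTable, ConfigError
from .transform import CenteredPanel

__all__ = [
    "ConcomitantDesign",
    "build_design",
    "refit_with_covariates",
    "rrr",
    "wald_ci",
    "adjusted_and_unadjusted",
    "interaction_scan",
]


@dataclass(frozen=True)
class ConcomitantDesign:
    """Per-subject numeric design for the membership model (intercept first)."""

    names: tuple  # ("intercept", covariate..., interaction...)
    matrix: np.ndarray  # (n, 1+p)
    subject_ids: tuple
    exposure_cols: tuple = ()
    confounder_cols: tuple = ()
    n_dropped: int = 0

    @property
    def frame(self) -> pd.DataFrame:
        """Covariate columns (no intercept) as a DataFrame for fit_em."""
        return pd.DataFrame(
            self.matrix[:, 1:],
            index=pd.Index(list(self.subject_ids), name="subject_id"),
            columns=list(self.names[1:]),
        )


def build_design(
    baseline: BaselineTable,
    subjects,
    exposures=(),
    confounders=(),
    interactions=(),
) -> ConcomitantDesign:
    """Assemble the concomitant design for the given subjects.

    Complete-case: subjects missing any requested covariate are dropped
    with a warning.  ``interactions`` is a list of (exposure, modifier)
    pairs adding product columns.  The design must have full column rank.
    """
    cols = [*exposures, *confounders]
    tab = baseline.table
    missing = [c for c in cols if c not in tab.columns]
    if missing:
        raise ConfigError(f"baseline column(s) not found: {missing}")
    absent = [s for s in subjects if s not in tab.index]
    if absent:
        raise ConfigError(f"subjects missing from baseline table: {absent[:5]}")
    df = tab.loc[list(subjects), cols].astype(float)
    for e, m in interactions:
        factors = []
        for c in (e, m):
            if c in df.columns:
                factors.append(df[c])
            elif c in tab.columns:
                factors.append(tab.loc[list(subjects), c].astype(float))
            else:
                raise ConfigError(f"interaction ({e}, {m}) references unknown columns")
        df[f"{e}:{m}"] = factors[0] * factors[1]
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        warnings.warn(
            f"complete-case analysis: dropped {n_dropped} subject(s) with "
            "missing covariates",
            stacklevel=2,
        )
    M = np.column_stack([np.ones(len(complete)), complete.to_numpy()])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(
            "concomitant design is rank-deficient (collinear or constant columns)"
        )
    return ConcomitantDesign(
        names=("intercept", *df.columns),
        matrix=M,
        subject_ids=tuple(complete.index),
        exposure_cols=tuple(exposures),
        confounder_cols=tuple(confounders),
        n_dropped=n_dropped,
    )


def refit_with_covariates(
    data: CenteredPanel,
    design: ConcomitantDesign,
    K: int,
    cov_kind: str,
    seed: int = 0,
    base_fit: FitResult | None = None,
    n_starts: int = 5,
    **fit_kwargs,
) -> FitResult:
    """Joint EM re-estimation (means, covariances and gamma) with covariates.

    Warm-started from the covariate-free fit's posteriors when given, plus
    random restarts to guard against the warm start being a poor basin.
    """
    sub = data.restrict(design.subject_ids)
    init = None
    if base_fit is not None:
        post = pd.DataFrame(
            base_fit.posteriors, index=pd.Index(base_fit.subject_ids)
        )
        init = post.loc[list(sub.subjects)].to_numpy()
    basis = base_fit.model.basis if base_fit is not None else None
    return fit_em(
        sub,
        covariates=design.frame,
        K=K,
        cov_kind=cov_kind,
        seed=seed,
        n_starts=n_starts,
        basis=basis,
        init_posteriors=init,
        **fit_kwargs,
    )


def _covariate_index(fit: FitResult, covariate: str) -> int:
    names = fit.model.covariate_names
    if covariate not in names:
        raise ConfigError(f"covariate {covariate!r} not in fitted design {names}")
    return names.index(covariate)


def rrr(fit: FitResult, covariate: str, delta: float = 1.0) -> pd.Series:
    """Point RRR_j = exp(delta * gamma_j,covariate) for groups 1..K-1 vs K."""
    j = _covariate_index(fit, covariate)
    vals = np.exp(delta * fit.model.gamma[:, j])
    return pd.Series(
        vals, index=pd.RangeIndex(1, fit.model.K, name="group"), name="rrr"
    )


def _full_loglik_fn(fit: FitResult):
    prep = _prepare(fit.data, fit.model.basis, fit.Z, fit.model.covariate_names)
    template = fit.model

    def f(theta):
        m = unpack_params(theta, template)
        ll = _component_loglik(prep, m.beta, m.cov)
        total, _ = _total_loglik(ll, _log_membership(m.gamma, prep.Z))
        return total

    return f


def _numeric_hessian(f, x, rel_step=1e-4, positive=None):
    """Central-difference Hessian; ``positive`` marks parameters that must
    stay > 0 (step shrunk to keep evaluations in-domain)."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    if positive is not None:
        h[positive] = np.minimum(h[positive], 0.45 * x[positive])
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _gamma_covariance(fit: FitResult, method: str = "full") -> np.ndarray:
    """Covariance of the packed gamma estimates.

    ``full``: inverse observed information of the complete mixture
    log-likelihood (propagates classification uncertainty).
    ``two_stage``: multinomial-only information with hard max-posterior
    labels, ignoring that the labels were estimated.
    """
    K = fit.model.K
    Z = fit.Z
    p1 = Z.shape[1]
    if method == "two_stage":
        W = np.zeros((len(fit.labels), K))
        W[np.arange(len(fit.labels)), fit.labels - 1] = 1.0
        pi = np.exp(_log_membership(fit.model.gamma, Z))
        dim = (K - 1) * p1
        info = np.empty((dim, dim))
        for a in range(K - 1):
            for b in range(K - 1):
                wts = pi[:, a] * ((1.0 if a == b else 0.0) - pi[:, b])
                info[a * p1 : (a + 1) * p1, b * p1 : (b + 1) * p1] = (
                    (Z * wts[:, None]).T @ Z
                )
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular multinomial information; separation or a degenerate fit"
            ) from exc
    theta = pack_params(fit.model)
    Kq = fit.model.K * fit.model.basis.dimension
    n_cov = sum(c.n_params for c in fit.model.cov)
    positive = np.zeros(theta.size, dtype=bool)
    positive[Kq : Kq + n_cov] = True
    H = _numeric_hessian(_full_loglik_fn(fit), theta, positive=positive)
    info = -H
    try:
        cov_all = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "observed information is singular; the fit may be on the boundary "
            "(degenerate variance, separation) — inspect var_floor_hit and gamma"
        ) from exc
    gi = gamma_param_indices(fit.model).ravel()
    return cov_all[np.ix_(gi, gi)]


def wald_ci(
    fit: FitResult,
    covariate: str,
    level: float = 0.95,
    delta: float = 1.0,
    method: str = "full",
) -> pd.DataFrame:
    """Per-group RRR with Wald CI symmetric on the log scale.

    Returns a DataFrame indexed by group 1..K-1 with columns gamma, se,
    rrr, ci_low, ci_high, p_value; negative estimated variances (a
    boundary/degenerate fit) raise.
    """
    j = _covariate_index(fit, covariate)
    K = fit.model.K
    p1 = len(fit.model.covariate_names)
    cov_g = _gamma_covariance(fit, method=method)
    idx = [k * p1 + j for k in range(K - 1)]
    var = np.diag(cov_g)[idx]
    if np.any(var < 0):
        raise np.linalg.LinAlgError(
            "negative variance estimate from the observed information; "
            "the fit looks degenerate or on the parameter-space boundary"
        )
    se = np.sqrt(var)
    g = fit.model.gamma[:, j]
    zq = norm.ppf(0.5 + level / 2.0)
    zstat = np.divide(g, se, out=np.full_like(g, np.inf), where=se > 0)
    return pd.DataFrame(
        {
            "gamma": delta * g,
            "se": delta * se,
            "rrr": np.exp(delta * g),
            "ci_low": np.exp(delta * (g - zq * se)),
            "ci_high": np.exp(delta * (g + zq * se)),
            "p_value": 2.0 * norm.sf(np.abs(zstat)),
        },
        index=pd.RangeIndex(1, K, name="group"),
    )


def adjusted_and_unadjusted(
    data: CenteredPanel,
    baseline: BaselineTable,
    exposures,
    confounders,
    K: int,
    cov_kind: str,
    seed: int = 0,
    base_fit: FitResult | None = None,
    stratum: str = "all",
    ci_method: str = "full",
    **fit_kwargs,
) -> pd.DataFrame:
    """One stratum's RRR table: per exposure, unadjusted (exposure only)
    and adjusted (exposure + confounders) models, each a full joint refit.

    Exposures enter one at a time — one model per compound per adjustment
    state — mirroring per-compound reporting.
    """
    if base_fit is None:
        base_fit = fit_em(data, K=K, cov_kind=cov_kind, seed=seed, **fit_kwargs)
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(list(exposures))) & 0x7FFFFFFF
    si = 0
    for exposure in exposures:
        for adjusted in (False, True):
            design = build_design(
                baseline,
                data.subjects,
                exposures=[exposure],
                confounders=list(confounders) if adjusted else [],
            )
            refit = refit_with_covariates(
                data, design, K, cov_kind, seed=int(seeds[si]), base_fit=base_fit,
                **fit_kwargs,
            )
            si += 1
            tab = wald_ci(refit, exposure, method=ci_method)
            for group, r in tab.iterrows():
                rows.append(
                    dict(
                        stratum=stratum,
                        exposure=exposure,
                        group=int(group),
                        rrr=r["rrr"],
                        ci_low=r["ci_low"],
                        ci_high=r["ci_high"],
                        p_value=r["p_value"],
                        adjusted=adjusted,
                    )
                )
    return pd.DataFrame(rows)


def interaction_scan(
    data: CenteredPanel,
    baseline: BaselineTable,
    exposure: str,
    modifiers,
    K: int,
    cov_kind: str,
    seed: int = 0,
    base_fit: FitResult | None = None,
    ci_method: str = "full",
    **fit_kwargs,
) -> pd.DataFrame:
    """Each modifier singly: refit with an exposure x modifier product term;
    report the interaction coefficients, Wald statistics, and BIC against
    the corresponding no-interaction model."""
    if base_fit is None:
        base_fit = fit_em(data, K=K, cov_kind=cov_kind, seed=seed, **fit_kwargs)
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(list(modifiers))) & 0x7FFFFFFF
    si = 0
    for modifier in modifiers:
        base_design = build_design(
            baseline, data.subjects, exposures=[exposure], confounders=[modifier]
        )
        fit0 = refit_with_covariates(
            data, base_design, K, cov_kind, seed=int(seeds[si]), base_fit=base_fit,
            **fit_kwargs,
        )
        int_design = build_design(
            baseline,
            data.subjects,
            exposures=[exposure],
            confounders=[modifier],
            interactions=[(exposure, modifier)],
        )
        fit1 = refit_with_covariates(
            data, int_design, K, cov_kind, seed=int(seeds[si + 1]), base_fit=base_fit,
            **fit_kwargs,
        )
        si += 2
        name = f"{exposure}:{modifier}"
        tab = wald_ci(fit1, name, method=ci_method)
        for group, r in tab.iterrows():
            rows.append(
                dict(
                    modifier=modifier,
                    group=int(group),
                    gamma_interaction=r["gamma"],
                    wald_z=r["gamma"] / r["se"] if r["se"] > 0 else np.inf,
                    p_value=r["p_value"],
                    bic_base=fit0.bic,
                    bic_interaction=fit1.bic,
                )
            )
    return pd.DataFrame(rows)
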