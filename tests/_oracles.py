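"""Independent oracles and helpers shared by the test suite.

Everything here deliberately avoids the package's EM path: the direct
maximizer drives scipy's quasi-Newton optimizer straight at the mixture
log-likelihood, and the label-matching helper scores agreement over all
group permutations.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from trajmix.covariance import CovarianceModel
from trajmix.mixture import (
    _component_loglik,
    _log_membership,
    _prepare,
    _total_loglik,
)
from trajmix.simulate import SimulationScenario, _shape_from_anchors

TINY_AGES = (2.0, 5.0, 9.0)


def match_accuracy(labels, truth) -> float:
    """Best label agreement over all permutations of group indices."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    groups = sorted(set(truth) | set(labels))
    best = 0.0
    for perm in itertools.permutations(groups):
        mapping = dict(zip(groups, perm))
        best = max(best, float(np.mean([mapping[t] == l for t, l in zip(truth, labels)])))
    return best


def tiny_two_group_scenario(seed: int, n_subjects: int = 30) -> SimulationScenario:
    """30 subjects, 3 complete visits, two well-separated shapes."""
    return SimulationScenario(
        n_subjects=n_subjects,
        group_curves=(
            _shape_from_anchors((18.0, 21.0, 25.0), TINY_AGES),
            _shape_from_anchors((16.5, 16.0, 16.2), TINY_AGES),
        ),
        group_levels=(21.3, 16.2),
        gamma_true=np.array([[0.4]]),
        visit_ages=TINY_AGES,
        p_visit_missing=0.0,
        min_visits=3,
        level_sd=1.5,
        noise=CovarianceModel("independence", 0.49),
        seed=seed,
    )


def direct_mixture_maximum(centered, seed: int, n_starts: int = 8) -> float:
    """Maximise the K=2 independence mixture log-likelihood directly with
    L-BFGS-B over (beta, log sigma2, intercept gamma); multi-start from a
    moment-based split plus random perturbations."""
    prep = _prepare(centered)
    q = prep.basis.dimension
    n = prep.n

    def negll(theta):
        beta = theta[: 2 * q].reshape(2, q)
        covs = tuple(
            CovarianceModel("independence", float(np.exp(t)))
            for t in theta[2 * q : 2 * q + 2]
        )
        gamma = theta[-1:].reshape(1, 1)
        ll = _component_loglik(prep, beta, covs)
        total, _ = _total_loglik(ll, _log_membership(gamma, prep.Z))
        return -total

    # moment start: split subjects at the median of their last observed value
    lastvals = np.empty(n)
    for p in prep.patterns:
        lastvals[p.idx] = p.Y[:, -1]
    lab = (lastvals < np.median(lastvals)).astype(int)
    base = np.zeros(2 * q + 3)
    for g in range(2):
        Ys, Xs = [], []
        for p in prep.patterns:
            for row, i in zip(p.Y, p.idx):
                if lab[i] == g:
                    Ys.append(row)
                    Xs.append(p.X)
        Yg = np.concatenate(Ys)
        Xg = np.vstack(Xs)
        b, *_ = np.linalg.lstsq(Xg, Yg, rcond=None)
        base[g * q : (g + 1) * q] = b
        base[2 * q + g] = math.log(max(float(np.mean((Yg - Xg @ b) ** 2)), 1e-4))
    base[-1] = math.log(max(np.mean(lab == 0), 0.05) / max(np.mean(lab == 1), 0.05))

    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(0, 0.3, size=base.size) for _ in range(n_starts - 1)]
    best = np.inf
    for s in starts:
        r = minimize(
            negll, s, method="L-BFGS-B",
            options=dict(maxiter=2000, ftol=1e-13, gtol=1e-9),
        )
        best = min(best, r.fun)
    return -best


def quantize_dyadic(x, bits: int = 20):
    """Round to the 2^-bits grid so float sums with grid offsets are exact."""
    scale = 2.0**bits
    return np.round(np.asarray(x, dtype=float) * scale) / scale
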