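"""Within-subject covariance structures for the mixture components.

Two working models, both with constant variance across visits:

* ``independence``: sigma^2 * I;
* ``exponential``:  sigma^2 * exp(-|t_s - t_u| / phi), continuous-time AR(1)
  correlation decaying with the age gap, range parameter ``phi`` in years.

Note the centered data these are fit to have a singular true covariance
(each subject's centered vector sums to zero); the nonsingular working
models are used deliberately — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CovarianceModel", "covariance_matrix"]

COV_KINDS = ("independence", "exponential")


@dataclass(frozen=True)
class CovarianceModel:
    kind: str
    sigma2: float
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in COV_KINDS:
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if self.kind == "exponential":
            if self.phi is None or not self.phi > 0:
                raise ValueError(f"exponential kind needs phi > 0, got {self.phi}")

    @property
    def n_params(self) -> int:
        return 1 if self.kind == "independence" else 2


def covariance_matrix(cov: CovarianceModel, ages) -> np.ndarray:
    """Covariance of one subject's observation vector at their visit ages."""
    t = np.asarray(ages, dtype=float)
    if t.ndim != 1 or not np.all(np.isfinite(t)):
        raise ValueError("ages must be a finite 1-d array")
    if np.unique(t).size != t.size:
        raise ValueError("ages must be distinct")
    if cov.kind == "independence":
        return cov.sigma2 * np.eye(t.size)
    gaps = np.abs(t[:, None] - t[None, :])
    return cov.sigma2 * np.exp(-gaps / cov.phi)
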