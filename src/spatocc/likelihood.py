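"""Likelihood kernels for single-season occupancy models.

Two site-likelihood kernels are provided.

Standard model (independent replicates)
    Pr(h) = psi * prod_k p_k^{y_k} (1-p_k)^{1-y_k} + (1-psi) * I[no detection]

Correlated-detection model
    Local presence z_k on segment k follows a first-order Markov chain:
    Pr(z_1=1) = pi, Pr(z_k=1 | z_{k-1}=0) = theta0,
    Pr(z_k=1 | z_{k-1}=1) = theta1.  Detection on a segment requires local
    presence there: Pr(y_k=1 | z_k=1) = p_k, Pr(y_k=1 | z_k=0) = 0.  The
    probability of a history given occupancy is computed by the two-state
    forward algorithm; missing segments contribute emission factor 1 while
    the chain still transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .data import CovariateTable, DetectionMatrix, ValidationError


def invlogit(x):
    """Numerically safe inverse logit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)


PI_MODES = ("estimated", "stationary", "fixed")
P_LEVELS = ("site", "segment")


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure for occupancy and detection, plus correlation switches.

    Parameters
    ----------
    psi_covariates, p_covariates : tuple of str
        Covariate names on logit psi and logit p; empty means intercept-only.
    correlated : bool
        Use the Markov availability chain (otherwise independent replicates).
    pi_mode : {"estimated", "stationary", "fixed"}
        How the first-segment local-presence probability pi is handled:
        a free logit-scale parameter (default), the chain's stationary value
        theta0 / (1 + theta0 - theta1), or a fixed constant.
    p_level : {"site", "segment"}
        Whether detection covariates enter at the grid level (default) or
        vary by segment (requires segment-level covariate arrays at fit time).
    """

    psi_covariates: tuple[str, ...] = ()
    p_covariates: tuple[str, ...] = ()
    correlated: bool = True
    pi_mode: str = "estimated"
    pi_value: float | None = None
    p_level: str = "site"

    def __post_init__(self):
        object.__setattr__(self, "psi_covariates", tuple(self.psi_covariates))
        object.__setattr__(self, "p_covariates", tuple(self.p_covariates))
        if self.pi_mode not in PI_MODES:
            raise ValidationError(f"pi_mode must be one of {PI_MODES}")
        if self.p_level not in P_LEVELS:
            raise ValidationError(f"p_level must be one of {P_LEVELS}")
        if self.pi_mode == "fixed":
            if self.pi_value is None or not 0 < self.pi_value < 1:
                raise ValidationError("pi_mode='fixed' requires pi_value in (0, 1)")

    @property
    def notation(self) -> str:
        """PRESENCE-style model string, e.g. ``psi(Term),th0(),th1(),p(Term+EVI+TRI),th0pi()``."""
        psi = "+".join(self.psi_covariates) or "."
        p = "+".join(self.p_covariates) or "."
        if self.correlated:
            pi = {"estimated": "", "stationary": "=stat", "fixed": f"={self.pi_value}"}[
                self.pi_mode
            ]
            return f"psi({psi}),th0(),th1(),p({p}),th0pi({pi})"
        return f"psi({psi}),p({p})"


@dataclass
class ParameterVector:
    """Free parameters on the link (logit) scale.

    Packing order: beta_psi (intercept first), alpha_p (intercept first),
    then, for the correlated model, logit theta0, logit theta1 and — when pi
    is estimated — logit pi.
    """

    beta_psi: np.ndarray
    alpha_p: np.ndarray
    logit_theta0: float | None = None
    logit_theta1: float | None = None
    logit_pi: float | None = None

    def pack(self) -> np.ndarray:
        parts = [np.asarray(self.beta_psi, float), np.asarray(self.alpha_p, float)]
        for v in (self.logit_theta0, self.logit_theta1, self.logit_pi):
            if v is not None:
                parts.append(np.array([v], float))
        x = np.concatenate(parts)
        if not np.all(np.isfinite(x)):
            raise ValidationError("non-finite parameter value")
        return x

    @classmethod
    def unpack(cls, x: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        x = np.asarray(x, float)
        n_psi = 1 + len(spec.psi_covariates)
        n_p = 1 + len(spec.p_covariates)
        n_extra = (2 + (spec.pi_mode == "estimated")) if spec.correlated else 0
        if x.size != n_psi + n_p + n_extra:
            raise ValidationError(
                f"parameter vector length {x.size} does not match spec "
                f"({n_psi + n_p + n_extra} expected)"
            )
        beta = x[:n_psi]
        alpha = x[n_psi : n_psi + n_p]
        pos = n_psi + n_p
        th0 = th1 = lpi = None
        if spec.correlated:
            th0 = float(x[pos])
            th1 = float(x[pos + 1])
            pos += 2
            if spec.pi_mode == "estimated":
                lpi = float(x[pos])
                pos += 1
        if pos != x.size:
            raise ValidationError(
                f"parameter vector length {x.size} does not match spec ({pos} expected)"
            )
        return cls(beta, alpha, th0, th1, lpi)


def build_linear_predictors(
    spec: ModelSpec,
    params: ParameterVector,
    covs: CovariateTable | None,
    n_segments: int = 1,
    segment_covariates: dict[str, np.ndarray] | None = None,
    n_sites: int | None = None,
):
    """Real-scale (psi_i, p_ik, theta0, theta1, pi) from link-scale parameters.

    ``p_ik`` has shape (n_sites, n_segments); it is constant over k when
    ``spec.p_level == "site"``.
    """
    needs_covs = spec.psi_covariates or (spec.p_covariates and spec.p_level == "site")
    if needs_covs and covs is None:
        raise ValidationError("spec uses covariates but no covariate table given")
    if covs is not None:
        n = len(covs.site_ids)
    elif segment_covariates:
        n = next(iter(segment_covariates.values())).shape[0]
    elif n_sites is not None:
        n = n_sites
    else:
        n = 1

    if spec.psi_covariates:
        X = covs.matrix(spec.psi_covariates)
        psi = invlogit(X @ np.asarray(params.beta_psi, float))
    else:
        psi = np.full(n, invlogit(float(params.beta_psi[0])))

    alpha = np.asarray(params.alpha_p, float)
    if spec.p_level == "segment" and spec.p_covariates:
        if segment_covariates is None:
            raise ValidationError("p_level='segment' requires segment_covariates")
        eta = np.full((n, n_segments), alpha[0])
        for j, name in enumerate(spec.p_covariates):
            if name not in segment_covariates:
                raise ValidationError(f"unknown segment covariate {name!r}")
            eta += alpha[1 + j] * np.asarray(segment_covariates[name], float)
        p = invlogit(eta)
    elif spec.p_covariates:
        Xp = covs.matrix(spec.p_covariates)
        p = np.repeat(invlogit(Xp @ alpha)[:, None], n_segments, axis=1)
    else:
        p = np.full((n, n_segments), invlogit(float(alpha[0])))

    th0 = th1 = pi = None
    if spec.correlated:
        th0 = invlogit(params.logit_theta0)
        th1 = invlogit(params.logit_theta1)
        if spec.pi_mode == "estimated":
            pi = invlogit(params.logit_pi)
        elif spec.pi_mode == "stationary":
            pi = th0 / (1.0 + th0 - th1)
        else:
            pi = float(spec.pi_value)
    return psi, p, th0, th1, pi


def _check_probs(*vals):
    for v in vals:
        a = np.asarray(v, float)
        if (a < 0).any() or (a > 1).any():
            raise ValidationError("probability outside [0, 1]")


def site_likelihood_standard(history, psi: float, p_k) -> float:
    """Pr(history) under the independent-replicate model (scalar reference)."""
    history = np.asarray(history)
    p_k = np.broadcast_to(np.asarray(p_k, float), history.shape)
    _check_probs([psi], p_k)
    if p_k.shape != history.shape:
        raise ValidationError("p_k length must equal number of segments")
    prod = 1.0
    nodet = True
    for yk, pk in zip(history, p_k):
        if yk == 1:
            nodet = False
            prod *= pk
        elif yk == 0:
            prod *= 1.0 - pk
    return psi * prod + (1.0 - psi) * (1.0 if nodet else 0.0)


def site_likelihood_correlated(history, psi, theta0, theta1, pi, p_k) -> float:
    """Pr(history) under the Markov-availability model via the forward recursion."""
    history = np.asarray(history)
    p_k = np.broadcast_to(np.asarray(p_k, float), history.shape)
    _check_probs([psi, theta0, theta1, pi], p_k)
    f = np.array([1.0 - pi, pi])
    T = np.array([[1.0 - theta0, theta0], [1.0 - theta1, theta1]])
    nodet = True
    for k, yk in enumerate(history):
        if k > 0:
            f = f @ T
        if yk == 1:
            nodet = False
            f = f * np.array([0.0, p_k[k]])
        elif yk == 0:
            f = f * np.array([1.0, 1.0 - p_k[k]])
    F = float(f.sum())
    return psi * F + (1.0 - psi) * (1.0 if nodet else 0.0)


def site_likelihood_bruteforce(history, psi, theta0, theta1, pi, p_k) -> float:
    """Oracle: explicit sum over all 2^K latent local-presence sequences."""
    history = np.asarray(history)
    K = history.size
    if K > 16:
        raise ValidationError("brute force limited to K <= 16")
    p_k = np.broadcast_to(np.asarray(p_k, float), history.shape)
    _check_probs([psi, theta0, theta1, pi], p_k)
    # enumerate latent sequences as bit patterns
    z = ((np.arange(2**K)[:, None] >> np.arange(K)[None, :]) & 1).astype(float)
    pz = np.where(z[:, 0] == 1, pi, 1.0 - pi)
    for k in range(1, K):
        trans = np.where(
            z[:, k - 1] == 1,
            np.where(z[:, k] == 1, theta1, 1.0 - theta1),
            np.where(z[:, k] == 1, theta0, 1.0 - theta0),
        )
        pz = pz * trans
    py = np.ones(2**K)
    nodet = True
    for k in range(K):
        yk = history[k]
        if yk == 1:
            nodet = False
            py = py * np.where(z[:, k] == 1, p_k[k], 0.0)
        elif yk == 0:
            py = py * np.where(z[:, k] == 1, 1.0 - p_k[k], 1.0)
    F = float((pz * py).sum())
    return psi * F + (1.0 - psi) * (1.0 if nodet else 0.0)


def site_loglikelihoods(
    y: np.ndarray, psi: np.ndarray, p: np.ndarray, theta0=None, theta1=None, pi=None
) -> np.ndarray:
    """Vectorised per-site log likelihood (compiled kernel)."""
    y = np.ascontiguousarray(y, dtype=np.int8)
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    p = np.ascontiguousarray(p, dtype=np.float64)
    if theta0 is None:
        return _kernels.loglik_standard(y, psi, p)
    return _kernels.loglik_correlated(y, psi, p, float(theta0), float(theta1), float(pi))


def total_neg_log_likelihood(
    params: ParameterVector | np.ndarray,
    y: DetectionMatrix | np.ndarray,
    covs: CovariateTable | None,
    spec: ModelSpec,
    segment_covariates: dict[str, np.ndarray] | None = None,
) -> float:
    """Negative log likelihood of the whole detection matrix.

    Finite for interior parameters; +inf only when some site has likelihood
    exactly zero (e.g. a detection where p = 0).
    """
    ymat = y.y if isinstance(y, DetectionMatrix) else np.asarray(y, dtype=np.int8)
    if isinstance(params, np.ndarray):
        params = ParameterVector.unpack(params, spec)
    psi, p, th0, th1, pi = build_linear_predictors(
        spec,
        params,
        covs,
        n_segments=ymat.shape[1],
        segment_covariates=segment_covariates,
        n_sites=ymat.shape[0],
    )
    ll = site_loglikelihoods(ymat, psi, p, th0, th1, pi)
    if np.isneginf(ll).any():
        return float("inf")
    return float(-ll.sum())
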