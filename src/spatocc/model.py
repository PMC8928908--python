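"""Maximum-likelihood fitting of occupancy models.

`OccupancyModel` holds the data and a `ModelSpec`; `fit()` maximises the
likelihood by multi-start quasi-Newton optimisation followed by a Newton
polish on finite-difference derivatives, and returns an `OccupancyResults`
carrying the MLE, its link-scale variance-covariance matrix, AIC and
diagnostics.  Real-scale estimates (psi-hat, p-hat, theta0, theta1, pi) with
delta-method standard errors hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import ConvergenceError, CovariateTable, DetectionMatrix, ValidationError
from .likelihood import (
    ModelSpec,
    ParameterVector,
    build_linear_predictors,
    invlogit,
    total_neg_log_likelihood,
)

GRAD_TOL = 1e-6
BOUNDARY_TOL = 1e-4


def count_parameters(spec: ModelSpec) -> int:
    """Number of free parameters: intercepts + coefficients for psi and p,
    plus (theta0, theta1) for the correlated model and pi when estimated."""
    k = 2 + len(spec.psi_covariates) + len(spec.p_covariates)
    if spec.correlated:
        k += 2
        if spec.pi_mode == "estimated":
            k += 1
    return k


def _param_names(spec: ModelSpec) -> list[str]:
    names = ["psi:(Intercept)"] + [f"psi:{c}" for c in spec.psi_covariates]
    names += ["p:(Intercept)"] + [f"p:{c}" for c in spec.p_covariates]
    if spec.correlated:
        names += ["th0:(Intercept)", "th1:(Intercept)"]
        if spec.pi_mode == "estimated":
            names += ["th0pi:(Intercept)"]
    return names


def _numeric_gradient(f, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _numeric_hessian(f, x, h=1e-5):
    """Central-difference Hessian of a scalar function."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


class OccupancyModel:
    """Single-season occupancy model bound to data.

    Parameters
    ----------
    detections : DetectionMatrix
    covariates : CovariateTable, optional
        Required when the spec names covariates; must be z-scaled.
    spec : ModelSpec
    segment_covariates : dict of str -> (n_sites, n_segments) arrays, optional
        Segment-level detection covariates (``spec.p_level == "segment"``).
    """

    def __init__(
        self,
        detections: DetectionMatrix,
        covariates: CovariateTable | None = None,
        spec: ModelSpec | None = None,
        segment_covariates: dict[str, np.ndarray] | None = None,
    ):
        self.detections = detections
        self.covariates = covariates
        self.spec = spec if spec is not None else ModelSpec()
        self.segment_covariates = segment_covariates
        used = set(self.spec.psi_covariates)
        if self.spec.p_level == "site":
            used |= set(self.spec.p_covariates)
        if used:
            if covariates is None:
                raise ValidationError("spec names covariates but none were supplied")
            if not covariates.scaled:
                raise ValidationError("covariates must be z-scaled before fitting")
            missing = used - set(covariates.columns)
            if missing:
                raise ValidationError(f"unknown covariates: {sorted(missing)}")
            if list(covariates.site_ids) != list(detections.site_ids):
                raise ValidationError("covariate site ids do not match detections")

    @classmethod
    def from_csv(cls, detections_path, covariates_path=None, spec=None):
        from .data import read_covariates, read_detection_matrix, zscore_scale

        dm = read_detection_matrix(detections_path)
        covs = None
        if covariates_path is not None:
            covs = zscore_scale(read_covariates(covariates_path))
        return cls(dm, covs, spec)

    @property
    def k_params(self) -> int:
        return count_parameters(self.spec)

    def nll(self, x: np.ndarray) -> float:
        return total_neg_log_likelihood(
            x, self.detections, self.covariates, self.spec, self.segment_covariates
        )

    def fit(
        self,
        n_starts: int = 10,
        seed: int = 0,
        x0: np.ndarray | None = None,
        compute_vcov: bool = True,
        polish: bool = True,
        maxiter: int = 500,
    ) -> "OccupancyResults":
        """Maximise the likelihood from ``n_starts`` jittered starting points.

        The first start is at zero on the link scale (probabilities 0.5), or
        at ``x0`` when given; subsequent starts add seeded N(0, 1) jitter.
        """
        if n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        k = self.k_params
        rng = np.random.default_rng(seed)
        base = np.zeros(k) if x0 is None else np.asarray(x0, float)
        best = None
        diagnostics = []
        for s in range(n_starts):
            start = base if s == 0 else base + rng.standard_normal(k)
            res = minimize(
                self.nll,
                start,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
            )
            diagnostics.append((s, res.fun, res.message))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError(f"all starts failed: {diagnostics}")

        x = best.x.copy()
        fval = float(best.fun)
        grad = _numeric_gradient(self.nll, x)
        hess = None
        if polish:
            x, fval, grad, hess = self._newton_polish(x, fval, grad)

        converged = bool(np.linalg.norm(grad) < GRAD_TOL)
        vcov = None
        if compute_vcov:
            if hess is None:
                hess = _numeric_hessian(self.nll, x)
            try:
                # positive definiteness via Cholesky
                np.linalg.cholesky(hess)
                vcov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                converged = False
        else:
            converged = bool(best.success)

        params = ParameterVector.unpack(x, self.spec)
        loglik = -fval
        return OccupancyResults(
            model=self,
            spec=self.spec,
            mle=params,
            x=x,
            loglik=loglik,
            K=k,
            aic=-2 * loglik + 2 * k,
            vcov=vcov,
            converged=converged,
            n_starts_used=n_starts,
            grad_norm=float(np.linalg.norm(grad)),
            boundary_flags=self._boundary_flags(params),
        )

    def _newton_polish(self, x, fval, grad, max_steps: int = 40):
        """Newton refinement on finite-difference derivatives.

        L-BFGS-B with numerical gradients stalls around ||grad|| ~ 1e-3; a
        few damped Newton steps bring the gradient norm below GRAD_TOL.
        """
        hess = None
        eye = np.eye(x.size)
        for _ in range(max_steps):
            gnorm = np.linalg.norm(grad)
            if gnorm < GRAD_TOL / 10:
                break
            hess = _numeric_hessian(self.nll, x)
            lam = 0.0
            accepted = False
            for _ in range(12):
                try:
                    step = np.linalg.solve(hess + lam * eye, grad)
                except np.linalg.LinAlgError:
                    lam = 10 * lam if lam else 1e-8
                    continue
                x_new = x - step
                f_new = self.nll(x_new)
                # near the optimum finite-difference noise dominates f; accept
                # on gradient-norm reduction as well as on descent
                if np.isfinite(f_new) and f_new <= fval + 1e-8:
                    g_new = _numeric_gradient(self.nll, x_new)
                    if np.linalg.norm(g_new) < 0.99 * gnorm or f_new < fval - 1e-10:
                        x, fval, grad = x_new, f_new, g_new
                        accepted = True
                        break
                lam = 10 * lam if lam else 1e-6
            if not accepted:
                break
        return x, fval, grad, hess

    def _boundary_flags(self, params: ParameterVector) -> list[str]:
        psi, p, th0, th1, pi = build_linear_predictors(
            self.spec,
            params,
            self.covariates,
            n_segments=self.detections.n_segments,
            segment_covariates=self.segment_covariates,
            n_sites=self.detections.n_sites,
        )
        flags = []
        reals = {"psi": np.asarray(psi), "p": np.asarray(p)}
        if self.spec.correlated:
            reals.update(theta0=np.asarray(th0), theta1=np.asarray(th1), pi=np.asarray(pi))
        for name, vals in reals.items():
            if (vals < BOUNDARY_TOL).any() or (vals > 1 - BOUNDARY_TOL).any():
                flags.append(name)
        return flags


@dataclass
class RealEstimate:
    """A probability-scale estimate with delta-method SE and 95% CI."""

    name: str
    value: float
    se: float
    lci: float
    uci: float


@dataclass
class OccupancyResults:
    """MLE fit of an occupancy model (the spec's FitResult)."""

    model: OccupancyModel
    spec: ModelSpec
    mle: ParameterVector
    x: np.ndarray
    loglik: float
    K: int
    aic: float
    vcov: np.ndarray | None
    converged: bool
    n_starts_used: int
    grad_norm: float
    boundary_flags: list[str] = field(default_factory=list)

    @property
    def notation(self) -> str:
        return self.spec.notation

    @property
    def data_shape(self) -> tuple[int, int]:
        return (self.model.detections.n_sites, self.model.detections.n_segments)

    # -- index helpers -----------------------------------------------------
    def _block(self, which: str) -> slice:
        n_psi = 1 + len(self.spec.psi_covariates)
        n_p = 1 + len(self.spec.p_covariates)
        if which == "psi":
            return slice(0, n_psi)
        if which == "p":
            return slice(n_psi, n_psi + n_p)
        extra = {"theta0": 0, "theta1": 1, "pi": 2}[which]
        if not self.spec.correlated:
            raise ValidationError(f"{which} is not a parameter of the standard model")
        if which == "pi" and self.spec.pi_mode != "estimated":
            raise ValidationError("pi is not a free parameter under this spec")
        i = n_psi + n_p + extra
        return slice(i, i + 1)

    def _require_vcov(self, force: bool):
        if self.vcov is None or (not self.converged and not force):
            raise ConvergenceError(
                "fit did not converge (or vcov unavailable); pass force=True to override"
            )

    # -- real-scale estimates ---------------------------------------------
    def real_estimates(self, at: dict[str, float] | None = None, force: bool = False):
        """Real-scale psi, p (and theta0/theta1/pi) with delta-method SEs.

        ``at`` gives scaled covariate values; the default (all zero) is the
        sample mean of every covariate.
        """
        self._require_vcov(force)
        out = [self._linked_estimate("psi", self.spec.psi_covariates, at)]
        out.append(self._linked_estimate("p", self.spec.p_covariates, at))
        if self.spec.correlated:
            out.append(self._scalar_estimate("theta0"))
            out.append(self._scalar_estimate("theta1"))
            if self.spec.pi_mode == "estimated":
                out.append(self._scalar_estimate("pi"))
        return out

    def _linked_estimate(self, which, cov_names, at):
        at = at or {}
        xvec = np.concatenate([[1.0], [at.get(c, 0.0) for c in cov_names]])
        sl = self._block(which)
        beta = self.x[sl]
        eta = float(xvec @ beta)
        value = invlogit(eta)
        gprime = value * (1 - value) * xvec
        var = float(gprime @ self.vcov[sl, sl] @ gprime)
        se = np.sqrt(max(var, 0.0))
        return RealEstimate(
            which,
            value,
            se,
            max(0.0, value - 1.96 * se),
            min(1.0, value + 1.96 * se),
        )

    def _scalar_estimate(self, which):
        sl = self._block(which)
        eta = float(self.x[sl][0])
        value = invlogit(eta)
        se_link = np.sqrt(max(float(self.vcov[sl, sl][0, 0]), 0.0))
        se = value * (1 - value) * se_link
        return RealEstimate(
            which,
            value,
            se,
            max(0.0, value - 1.96 * se),
            min(1.0, value + 1.96 * se),
        )

    def predict_psi(self, covariates: CovariateTable | None = None, force: bool = False):
        """Per-site occupancy probability with delta-method SEs.

        New sites must be scaled with the training scale parameters.
        """
        self._require_vcov(force)
        covs = covariates if covariates is not None else self.model.covariates
        if self.spec.psi_covariates:
            if covs is None or not covs.scaled:
                raise ValidationError("scaled covariates required for prediction")
            X = covs.matrix(self.spec.psi_covariates)
            site_ids = list(covs.site_ids)
        else:
            n = len(covs.site_ids) if covs is not None else self.model.detections.n_sites
            X = np.ones((n, 1))
            site_ids = (
                list(covs.site_ids) if covs is not None else list(self.model.detections.site_ids)
            )
        sl = self._block("psi")
        beta = self.x[sl]
        vc = self.vcov[sl, sl]
        eta = X @ beta
        psi = invlogit(eta)
        deriv = psi * (1 - psi)
        var = np.einsum("ij,jk,ik->i", X, vc, X)
        se = deriv * np.sqrt(np.maximum(var, 0.0))
        return [
            RealEstimate(
                f"psi[{sid}]", float(v), float(s), max(0.0, v - 1.96 * s), min(1.0, v + 1.96 * s)
            )
            for sid, v, s in zip(site_ids, psi, se)
        ]

    def mean_psi_estimate(self, force: bool = False) -> RealEstimate:
        """Mean of site-level psi-hat across the modelled sites, with a
        delta-method SE for the mean."""
        self._require_vcov(force)
        if self.spec.psi_covariates:
            X = self.model.covariates.matrix(self.spec.psi_covariates)
        else:
            X = np.ones((self.model.detections.n_sites, 1))
        sl = self._block("psi")
        psi = invlogit(X @ self.x[sl])
        g = (psi * (1 - psi))[:, None] * X  # gradient of each site psi wrt beta
        gmean = g.mean(axis=0)
        var = float(gmean @ self.vcov[sl, sl] @ gmean)
        value = float(psi.mean())
        se = np.sqrt(max(var, 0.0))
        return RealEstimate(
            "psi", value, se, max(0.0, value - 1.96 * se), min(1.0, value + 1.96 * se)
        )

    # -- tables ------------------------------------------------------------
    def coef_table(self) -> pd.DataFrame:
        """Link-scale coefficients with SEs and Wald 95% CIs."""
        names = _param_names(self.spec)
        se = (
            np.sqrt(np.maximum(np.diag(self.vcov), 0.0))
            if self.vcov is not None
            else np.full(self.K, np.nan)
        )
        return pd.DataFrame(
            {
                "beta": self.x,
                "se": se,
                "lci": self.x - 1.96 * se,
                "uci": self.x + 1.96 * se,
            },
            index=names,
        )

    def summary(self) -> str:
        lines = [
            "Occupancy model fit",
            f"  model:     {self.notation}",
            f"  sites:     {self.data_shape[0]}   segments: {self.data_shape[1]}",
            f"  logLik:    {self.loglik:.4f}   K: {self.K}   AIC: {self.aic:.2f}",
            f"  converged: {self.converged} (|grad| = {self.grad_norm:.2e}, "
            f"starts = {self.n_starts_used})",
        ]
        if self.boundary_flags:
            lines.append(f"  boundary:  {', '.join(self.boundary_flags)}")
        lines.append("")
        lines.append(self.coef_table().to_string(float_format=lambda v: f"{v:8.3f}"))
        if self.vcov is not None and self.converged:
            lines.append("")
            lines.append("Real-scale estimates (at covariate means):")
            for est in self.real_estimates():
                lines.append(
                    f"  {est.name:7s} {est.value:6.3f}  SE {est.se:6.3f}  "
                    f"95% CI [{est.lci:.3f}, {est.uci:.3f}]"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_model(
    y: DetectionMatrix,
    covs: CovariateTable | None,
    spec: ModelSpec,
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> OccupancyResults:
    """Fit ``spec`` to data; see :meth:`OccupancyModel.fit`."""
    return OccupancyModel(y, covs, spec).fit(n_starts=n_starts, seed=seed, **kwargs)


def derive_real_parameters(
    fit: OccupancyResults, at: dict[str, float] | None = None, force: bool = False
):
    """Real-scale parameter estimates with delta-method SEs and 95% CIs."""
    return fit.real_estimates(at=at, force=force)


def predict_psi(fit: OccupancyResults, covs: CovariateTable | None = None, force: bool = False):
    """Site-specific occupancy estimates for mapping or export."""
    return fit.predict_psi(covs, force=force)
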