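"""Parametric-bootstrap goodness-of-fit (MacKenzie-Bailey style).

The observed Pearson chi-square over detection histories is compared with
its distribution under the fitted model: datasets are simulated from the
MLE (holding covariates and the missingness pattern fixed), refitted, and
the statistic recomputed.  The overdispersion factor c-hat is the observed
statistic divided by the mean bootstrap statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .data import MISSING, ConvergenceError, DetectionMatrix, ValidationError
from .likelihood import build_linear_predictors, site_loglikelihoods
from .model import OccupancyModel, OccupancyResults
from .simulate import simulate_detections


@dataclass
class GofResult:
    observed_chisq: float
    bootstrap_chisq: np.ndarray
    p_value: float
    c_hat: float
    B: int
    n_refit_failures: int = 0

    def __repr__(self):
        return (
            f"Goodness of fit (parametric bootstrap, B = {self.B})\n"
            f"  X^2 observed: {self.observed_chisq:.2f}\n"
            f"  p-value:      {self.p_value:.4f}\n"
            f"  c-hat:        {self.c_hat:.3f}"
        )


def _real_params(fit: OccupancyResults, y: DetectionMatrix):
    return build_linear_predictors(
        fit.spec,
        fit.mle,
        fit.model.covariates,
        n_segments=y.n_segments,
        segment_covariates=fit.model.segment_covariates,
        n_sites=y.n_sites,
    )


def _chisq(y: np.ndarray, psi, p, th0, th1, pi) -> float:
    """Pearson X^2 over observed unique histories, by cohort.

    Sites sharing a missingness pattern and model-probability profile form a
    cohort; within each cohort the statistic sums (O-E)^2/E over the unique
    observed histories plus one pooled complement category holding the
    remaining probability mass.
    """
    n, K = y.shape
    psi = np.asarray(psi, float)
    p = np.asarray(p, float)
    # cohort key: missingness pattern + rounded parameter profile
    keys = {}
    for i in range(n):
        key = (
            tuple(np.flatnonzero(y[i] == MISSING)),
            round(float(psi[i]), 12),
            tuple(np.round(p[i], 12)),
        )
        keys.setdefault(key, []).append(i)
    total = 0.0
    for idx in keys.values():
        idx = np.array(idx)
        sub = y[idx]
        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        if th0 is None:
            ll = site_loglikelihoods(uniq, np.repeat(psi[idx[0]], len(uniq)),
                                     np.repeat(p[idx[:1]], len(uniq), axis=0))
        else:
            ll = site_loglikelihoods(
                uniq,
                np.repeat(psi[idx[0]], len(uniq)),
                np.repeat(p[idx[:1]], len(uniq), axis=0),
                th0,
                th1,
                pi,
            )
        probs = np.exp(ll)
        n_c = len(idx)
        E = n_c * probs
        if ((E == 0) & (counts > 0)).any():
            warnings.warn("observed history with zero expected frequency; X^2 = inf")
            return float("inf")
        total += float(((counts - E) ** 2 / E).sum())
        total += float(max(n_c - E.sum(), 0.0))  # complement: O=0, contribution E_c
    return total


def pearson_chisq_histories(y: DetectionMatrix, fit: OccupancyResults) -> float:
    """Observed Pearson chi-square over unique detection histories.

    With many segments almost every observed history is unique and its
    expected count minuscule, which makes this statistic extremely
    heavy-tailed; the detection-count statistic below is the stable default
    for the bootstrap.
    """
    if (y.n_sites, y.n_segments) != fit.data_shape:
        raise ValidationError("fit and data shapes differ")
    psi, p, th0, th1, pi = _real_params(fit, y)
    return _chisq(y.y, psi, p, th0, th1, pi)


def _count_chisq(y: np.ndarray, psi, p, th0, th1, pi, min_expected: float = 2.0) -> float:
    """Pearson X^2 comparing observed and expected site frequencies over the
    joint detection counts in the two transect halves.

    Expected frequencies come from a dynamic program over the availability
    chain; cross-classifying by half keeps degrees of freedom (and power for
    the Markov structure) that a single total-count margin would lose.
    Cells are pooled in ascending lexicographic order until each pooled cell
    has expectation >= ``min_expected``."""
    y = np.ascontiguousarray(y, dtype=np.int8)
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    p = np.ascontiguousarray(p, dtype=np.float64)
    if th0 is None:  # independent replicates: availability chain always "present"
        th0_, th1_, pi_ = 1.0, 1.0, 1.0
    else:
        th0_, th1_, pi_ = float(th0), float(th1), float(pi)
    K = y.shape[1]
    split = K // 2 if K > 1 else 1
    probs = _kernels.detection_count_pair_probs(y, psi, p, th0_, th1_, pi_, split)
    E_t = probs.sum(axis=0).ravel()
    t1 = (y[:, :split] == 1).sum(axis=1)
    t2 = (y[:, split:] == 1).sum(axis=1)
    codes = t1 * (K - split + 1) + t2
    O_t = np.bincount(codes, minlength=E_t.size).astype(float)
    # pool ascending so every cell has adequate expectation
    cells_O, cells_E = [], []
    accO = accE = 0.0
    for t in range(E_t.size):
        accO += O_t[t]
        accE += E_t[t]
        if accE >= min_expected:
            cells_O.append(accO)
            cells_E.append(accE)
            accO = accE = 0.0
    if accE > 0 or accO > 0:
        if cells_E:
            cells_O[-1] += accO
            cells_E[-1] += accE
        else:
            cells_O.append(accO)
            cells_E.append(accE)
    cells_O = np.array(cells_O)
    cells_E = np.array(cells_E)
    if (cells_E <= 0).any():
        warnings.warn("zero expected frequency in a pooled count cell")
        return float("inf")
    return float(((cells_O - cells_E) ** 2 / cells_E).sum())


def detection_count_chisq(
    y: DetectionMatrix, fit: OccupancyResults, min_expected: float = 2.0
) -> float:
    """Observed detection-count Pearson chi-square under ``fit``."""
    if (y.n_sites, y.n_segments) != fit.data_shape:
        raise ValidationError("fit and data shapes differ")
    psi, p, th0, th1, pi = _real_params(fit, y)
    return _count_chisq(y.y, psi, p, th0, th1, pi, min_expected)


def bootstrap_gof(
    y: DetectionMatrix,
    covs,
    fit: OccupancyResults,
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 1,
    statistic: str = "count",
) -> GofResult:
    """Parametric-bootstrap GoF for a fitted occupancy model.

    ``B`` datasets are simulated from the MLE with the original covariates
    and missingness pattern, refitted under the same spec (started at the
    parent MLE), and the statistic recomputed at each refit's own MLE.
    ``statistic`` is ``"count"`` (detection-count Pearson X^2, default) or
    ``"history"`` (unique-history X^2).  The p-value uses the
    (1 + count)/(B + 1) estimator.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not fit.converged:
        raise ConvergenceError("parent fit did not converge")
    if statistic not in ("count", "history"):
        raise ValidationError("statistic must be 'count' or 'history'")
    stat = _count_chisq if statistic == "count" else _chisq
    psi, p, th0, th1, pi = _real_params(fit, y)
    observed = stat(y.y, psi, p, th0, th1, pi)
    missing_mask = y.y == MISSING
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    failures = 0
    for b in range(B):
        if th0 is None:
            occ = (rng.random(y.n_sites) < psi).astype(np.int8)
            yb = ((rng.random(p.shape) < p) & (occ[:, None] == 1)).astype(np.int8)
            yb[missing_mask] = MISSING
        else:
            yb, _, _ = simulate_detections(rng, psi, p, th0, th1, pi, missing_mask)
        dm = DetectionMatrix(list(y.site_ids), yb)
        model = OccupancyModel(dm, covs, fit.spec, fit.model.segment_covariates)
        try:
            refit = model.fit(
                n_starts=n_starts, seed=b, x0=fit.x, compute_vcov=False, polish=False
            )
            psi_b, p_b, th0_b, th1_b, pi_b = build_linear_predictors(
                refit.spec, refit.mle, covs, n_segments=y.n_segments,
                segment_covariates=fit.model.segment_covariates, n_sites=y.n_sites,
            )
            boot[b] = stat(yb, psi_b, p_b, th0_b, th1_b, pi_b)
        except Exception:
            failures += 1
            boot[b] = np.nan
    ok = ~np.isnan(boot)
    if failures > 0.2 * B:
        raise ConvergenceError(
            f"{failures}/{B} bootstrap refits failed; increase n_starts"
        )
    boot_ok = boot[ok]
    B_eff = int(ok.sum())
    p_value = (1 + int((boot_ok >= observed).sum())) / (B_eff + 1)
    c_hat = observed / float(boot_ok.mean())
    return GofResult(observed, boot_ok, float(p_value), float(c_hat), B_eff, failures)
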