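"""AIC model selection, Akaike weights and model averaging.

Implements the two-step workflow used for sign-survey occupancy analyses:
first choose the detection (p) covariate structure under a global occupancy
structure, then model occupancy (psi) holding the best detection structure
fixed, building candidates by stepwise addition from univariate models.
Estimates are combined across the candidate set with Akaike weights and an
unconditional standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data import ConvergenceError, CovariateTable, DetectionMatrix, ValidationError
from .likelihood import ModelSpec
from .model import OccupancyModel, OccupancyResults


def aic_score(loglik: float, K: int) -> float:
    """Akaike information criterion, -2*logLik + 2*K."""
    if K < 0:
        raise ValidationError("K must be >= 0")
    return -2.0 * loglik + 2.0 * K


def akaike_weights(aic_values: Sequence[float]):
    """(delta, weight, model-likelihood) triples from a set of AIC scores.

    Invariant to adding a constant to every score, so plain delta-AIC values
    can be passed directly.
    """
    aic = np.asarray(aic_values, float)
    delta = aic - aic.min()
    ml = np.exp(-delta / 2.0)
    return delta, ml / ml.sum(), ml


@dataclass
class AICTable:
    """Ranked model set with delta-AIC, Akaike weights and model likelihoods."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if abs(t["deltaAIC"].iloc[0]) > 1e-9:
            raise ValidationError("first row must have deltaAIC = 0")
        if abs(t["w"].sum() - 1.0) > 1e-9:
            raise ValidationError("Akaike weights must sum to 1")

    def __len__(self):
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self):
        return self.table.to_string(
            index=False,
            formatters={
                "AIC": "{:.2f}".format,
                "deltaAIC": "{:.2f}".format,
                "w": "{:.2f}".format,
                "ML": "{:.2f}".format,
            },
        )


def rank_models(fits: Sequence[OccupancyResults]) -> AICTable:
    """Rank fitted models by AIC; ties broken by smaller K, then input order."""
    if not fits:
        raise ValidationError("no fits to rank")
    shapes = {f.data_shape for f in fits}
    if len(shapes) > 1:
        raise ValidationError(f"fits are on differing data shapes: {shapes}")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].K, i))
    aics = np.array([fits[i].aic for i in order])
    delta, w, ml = akaike_weights(aics)
    df = pd.DataFrame(
        {
            "model": [fits[i].notation for i in order],
            "AIC": aics,
            "deltaAIC": delta,
            "w": w,
            "ML": ml,
            "K": [fits[i].K for i in order],
        }
    )
    return AICTable(df)


def _fit_safe(y, covs, spec, seed, n_starts) -> OccupancyResults | None:
    try:
        fit = OccupancyModel(y, covs, spec).fit(n_starts=n_starts, seed=seed)
    except ConvergenceError as exc:
        warnings.warn(f"model {spec.notation} failed to fit: {exc}")
        return None
    if fit.vcov is None:
        warnings.warn(f"model {spec.notation} excluded: non-PD Hessian")
        return None
    return fit


def stepwise_additive(
    y: DetectionMatrix,
    covs: CovariateTable,
    fixed_p_structure: Sequence[str],
    psi_pool: Sequence[str],
    seed: int = 0,
    n_starts: int = 5,
    correlated: bool = True,
) -> list[OccupancyResults]:
    """Stepwise-additive occupancy covariate search under a fixed p structure.

    Fits the null and every univariate psi model, then greedily adds the
    covariate that most decreases AIC, stopping when no addition improves the
    score.  Returns every model fitted along the path, in fitting order.
    """
    if not psi_pool:
        raise ValidationError("psi_pool must be non-empty")

    def make(psi_covs):
        return ModelSpec(tuple(psi_covs), tuple(fixed_p_structure), correlated=correlated)

    fits: list[OccupancyResults] = []
    fitted: set[tuple[str, ...]] = set()

    def fit_structure(psi_covs):
        key = tuple(psi_covs)
        if key in fitted:
            return None
        fitted.add(key)
        f = _fit_safe(y, covs, make(psi_covs), seed, n_starts)
        if f is not None:
            fits.append(f)
        return f

    null = fit_structure(())
    uni = [fit_structure((c,)) for c in psi_pool]
    candidates = [f for f in ([null] + uni) if f is not None]
    if not candidates:
        raise ConvergenceError("no stepwise candidate converged")
    best = min(candidates, key=lambda f: f.aic)
    current = best.spec.psi_covariates
    best_aic = best.aic
    while True:
        remaining = [c for c in psi_pool if c not in current]
        if not remaining:
            break
        trial = [(c, fit_structure(tuple(current) + (c,))) for c in remaining]
        trial = [(c, f) for c, f in trial if f is not None]
        if not trial:
            break
        c_best, f_best = min(trial, key=lambda t: t[1].aic)
        if f_best.aic < best_aic:
            current = f_best.spec.psi_covariates
            best_aic = f_best.aic
        else:
            break
    return fits


class TwoStepResult(NamedTuple):
    detection_table: AICTable
    occupancy_table: AICTable
    detection_fits: list[OccupancyResults]
    occupancy_fits: list[OccupancyResults]


def two_step_selection(
    y: DetectionMatrix,
    covs: CovariateTable,
    psi_covariate_pool: Sequence[str],
    p_candidate_structures: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
    n_starts: int = 5,
    correlated: bool = True,
    include_second_best_p: bool = True,
) -> TwoStepResult:
    """Detection-first, occupancy-second AIC model selection.

    Step 1 fits psi(Global) — all covariates in ``psi_covariate_pool`` on
    occupancy — against each candidate p structure and ranks by AIC.  Step 2
    fixes the best p structure and searches psi structures stepwise from the
    null and univariate models; the null model under the second-best p
    structure is added to the candidate set when available.
    """
    if not psi_covariate_pool:
        raise ValidationError("psi covariate pool must be non-empty")
    if p_candidate_structures is None:
        p_candidate_structures = [()] + [(c,) for c in psi_covariate_pool]
    if not p_candidate_structures:
        raise ValidationError("p candidate pool must be non-empty")

    global_psi = tuple(psi_covariate_pool)
    det_fits = []
    for p_struct in p_candidate_structures:
        spec = ModelSpec(global_psi, tuple(p_struct), correlated=correlated)
        f = _fit_safe(y, covs, spec, seed, n_starts)
        if f is not None:
            det_fits.append(f)
    if not det_fits:
        raise ConvergenceError("no detection model converged in step 1")
    det_table = rank_models(det_fits)

    by_notation = {f.notation: f for f in det_fits}
    best_p = by_notation[det_table.table["model"].iloc[0]].spec.p_covariates
    occ_fits = stepwise_additive(
        y, covs, best_p, psi_covariate_pool, seed=seed, n_starts=n_starts, correlated=correlated
    )
    if include_second_best_p and len(det_table) > 1:
        second_p = by_notation[det_table.table["model"].iloc[1]].spec.p_covariates
        if tuple(second_p) != tuple(best_p):
            f = _fit_safe(
                y, covs, ModelSpec((), tuple(second_p), correlated=correlated), seed, n_starts
            )
            if f is not None:
                occ_fits.append(f)
    occ_table = rank_models(occ_fits)
    return TwoStepResult(det_table, occ_table, det_fits, occ_fits)


@dataclass
class AveragedEstimate:
    """AIC-weighted model-averaged estimate with unconditional SE."""

    value: float
    unconditional_se: float
    components: list[tuple[str, float, float, float]]  # (model, weight, estimate, se)


def model_average(
    fits: Sequence[OccupancyResults], table: AICTable, quantity: str = "psi"
) -> AveragedEstimate:
    """Average an estimate over the model set with Akaike weights.

    For ``quantity="psi"`` each model contributes the unweighted mean of its
    site-level psi-hat values; for ``"p"`` the detection probability at the
    covariate means.  The unconditional SE folds between-model spread into
    the within-model SEs:  sum_i w_i * sqrt(se_i^2 + (est_i - avg)^2).
    """
    if quantity not in ("psi", "p"):
        raise ValidationError("quantity must be 'psi' or 'p'")
    by_notation = {f.notation: f for f in fits}
    rows = table.table
    if abs(rows["w"].sum() - 1.0) > 1e-9:
        raise ValidationError("weights do not sum to 1")
    comps = []
    for _, row in rows.iterrows():
        fit = by_notation.get(row["model"])
        if fit is None:
            raise ValidationError(f"no fit supplied for model {row['model']!r}")
        if quantity == "psi":
            est = fit.mean_psi_estimate()
        else:
            est = next(e for e in fit.real_estimates() if e.name == "p")
        comps.append((row["model"], float(row["w"]), est.value, est.se))
    value = sum(w * est for _, w, est, _ in comps)
    use = sum(w * np.sqrt(se**2 + (est - value) ** 2) for _, w, est, se in comps)
    return AveragedEstimate(float(value), float(use), comps)
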