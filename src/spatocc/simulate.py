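"""Synthetic detection-history generation and parameter-recovery studies.

The generator mirrors the assumed data-generating process: site occupancy is
Bernoulli with a logit-linear covariate model; where a site is occupied,
local presence propagates along the transect segments as a first-order
Markov chain (pi, theta0, theta1); detection on a segment is Bernoulli given
local presence; segment-level covariate indicators are aggregated to
grid-level proportions before z-scaling; segments may be knocked out as
missing observations.

Defaults emulate a sign-survey design of 45 grids x 20 segments of 200 m
with an occupancy probability near 0.7, segment detection probability 0.25
and availability chain (theta0, theta1, pi) = (0.3, 0.7, 0.45).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    MISSING,
    CovariateTable,
    DetectionMatrix,
    SegmentRecordSet,
    ValidationError,
    zscore_scale,
)
from .likelihood import ModelSpec, invlogit
from .model import OccupancyModel


@dataclass
class SimulationConfig:
    """True parameters and design of a simulated sign survey.

    ``covariate_generators`` maps a covariate name to either
    ``("continuous",)`` — a standard-normal site score — or
    ``("segment", q)`` — per-segment presence indicators with probability
    ``q``, aggregated to a grid-level proportion.  ``beta_psi`` and
    ``alpha_p`` are link-scale coefficients (intercept first) over
    ``psi_covariates`` / ``p_covariates``.
    """

    n_sites: int = 45
    n_segments: int = 20
    beta_psi: tuple[float, ...] = (0.8473,)  # logit 0.7
    alpha_p: tuple[float, ...] = (-1.0986,)  # logit 0.25
    theta0: float = 0.3
    theta1: float = 0.7
    pi: float = 0.45
    psi_covariates: tuple[str, ...] = ()
    p_covariates: tuple[str, ...] = ()
    covariate_generators: dict = field(default_factory=dict)
    p_level: str = "site"  # "segment": alpha applies to raw per-segment indicators
    missing_rate: float = 0.0
    missing_mode: str = "uniform"  # or "block": contiguous trailing segments
    seed: int = 0

    def __post_init__(self):
        for name, v in (("theta0", self.theta0), ("theta1", self.theta1), ("pi", self.pi)):
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_sites < 1 or self.n_segments < 1:
            raise ValidationError("n_sites and n_segments must be >= 1")
        if len(self.beta_psi) != 1 + len(self.psi_covariates):
            raise ValidationError("beta_psi length must be 1 + #psi_covariates")
        if len(self.alpha_p) != 1 + len(self.p_covariates):
            raise ValidationError("alpha_p length must be 1 + #p_covariates")
        for c in set(self.psi_covariates) | set(self.p_covariates):
            if c not in self.covariate_generators:
                raise ValidationError(f"no generator for covariate {c!r}")
        if self.p_level == "segment":
            for c in self.p_covariates:
                if self.covariate_generators[c][0] != "segment":
                    raise ValidationError(
                        "segment-level detection coupling needs segment-indicator generators"
                    )

    def spec(self) -> ModelSpec:
        return ModelSpec(
            self.psi_covariates, self.p_covariates, correlated=True, p_level=self.p_level
        )


@dataclass
class SimulatedDataset:
    """A simulated survey with its latent truth retained for recovery tests."""

    y: DetectionMatrix
    covs: CovariateTable | None
    records: SegmentRecordSet
    occupancy: np.ndarray  # (n,) 0/1 truth
    z: np.ndarray  # (n, K) latent local presence (0 where unoccupied)
    psi_true: np.ndarray  # (n,) real-scale occupancy probabilities
    p_true: np.ndarray  # (n,) real-scale detection probabilities
    config: SimulationConfig


def simulate_z_chain(rng, n, K, pi, theta0, theta1) -> np.ndarray:
    """Latent local-presence chains for ``n`` occupied sites."""
    z = np.zeros((n, K), dtype=np.int8)
    z[:, 0] = rng.random(n) < pi
    for k in range(1, K):
        prob = np.where(z[:, k - 1] == 1, theta1, theta0)
        z[:, k] = rng.random(n) < prob
    return z


def simulate_detections(
    rng, psi, p, theta0, theta1, pi, missing_mask=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (y, occupancy, z) given real-scale parameters.

    ``p`` has shape (n, K); ``missing_mask`` marks segments to blank out.
    """
    psi = np.asarray(psi, float)
    p = np.asarray(p, float)
    n, K = p.shape
    occ = (rng.random(n) < psi).astype(np.int8)
    z = simulate_z_chain(rng, n, K, pi, theta0, theta1)
    z[occ == 0] = 0
    y = ((rng.random((n, K)) < p) & (z == 1)).astype(np.int8)
    if missing_mask is not None:
        y = y.copy()
        y[missing_mask] = MISSING
    return y, occ, z


def _missing_mask(rng, n, K, rate, mode) -> np.ndarray:
    if rate == 0:
        return np.zeros((n, K), dtype=bool)
    if mode == "uniform":
        mask = rng.random((n, K)) < rate
    elif mode == "block":
        # whole trailing blocks unsurveyed on a random subset of sites,
        # mimicking areas outside jurisdiction
        mask = np.zeros((n, K), dtype=bool)
        n_block = int(round(2 * rate * n))
        sites = rng.choice(n, size=min(n_block, n), replace=False)
        for i in sites:
            start = rng.integers(1, K)
            mask[i, start:] = True
    else:
        raise ValidationError("missing_mode must be 'uniform' or 'block'")
    # keep at least one observed segment per site
    all_gone = mask.all(axis=1)
    mask[all_gone, 0] = False
    return mask


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one synthetic survey; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_sites, config.n_segments

    missing = _missing_mask(rng, n, K, config.missing_rate, config.missing_mode)
    observed = ~missing

    raw_cols: dict[str, np.ndarray] = {}
    indicators: dict[str, np.ndarray] = {}
    for name, gen in config.covariate_generators.items():
        kind = gen[0]
        if kind == "continuous":
            raw_cols[name] = rng.standard_normal(n)
        elif kind == "segment":
            q = gen[1]
            seg = (rng.random((n, K)) < q).astype(np.int8)
            rec = seg.copy()
            rec[missing] = MISSING
            indicators[name] = rec
            raw_cols[name] = np.where(observed, seg, 0).sum(axis=1) / observed.sum(axis=1)
        else:
            raise ValidationError(f"unknown generator kind {kind!r}")

    covs = None
    if raw_cols:
        raw = CovariateTable([f"g{i + 1:03d}" for i in range(n)], pd.DataFrame(raw_cols))
        covs = zscore_scale(raw)

    def _linpred(coefs, names):
        eta = np.full(n, float(coefs[0]))
        for j, nm in enumerate(names):
            eta += coefs[1 + j] * covs.values[nm].to_numpy(float)
        return invlogit(eta)

    psi = _linpred(config.beta_psi, config.psi_covariates)
    if config.p_level == "segment" and config.p_covariates:
        # detection driven by the raw per-segment indicators (e.g. a termite
        # mound on the segment itself raising sign-detection odds there)
        eta = np.full((n, K), float(config.alpha_p[0]))
        for j, nm in enumerate(config.p_covariates):
            seg = np.where(indicators[nm] == MISSING, 0, indicators[nm]).astype(float)
            eta += config.alpha_p[1 + j] * seg
        p = invlogit(eta)
        p_site = p.mean(axis=1)
    else:
        p_site = _linpred(config.alpha_p, config.p_covariates)
        p = np.repeat(p_site[:, None], K, axis=1)

    y, occ, z = simulate_detections(
        rng, psi, p, config.theta0, config.theta1, config.pi, missing_mask=missing
    )
    site_ids = [f"g{i + 1:03d}" for i in range(n)]
    dm = DetectionMatrix(site_ids, y, segment_length_m=200.0)
    records = SegmentRecordSet(site_ids, indicators)
    return SimulatedDataset(dm, covs, records, occ, z, psi, p_site, config)


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    seed: int = 0,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Simulate -> fit -> summarise bias, RMSE and 95% CI coverage.

    Each replicate simulates a dataset from ``config`` (with a child seed),
    fits the matching correlated model and records real-scale estimates of
    psi, p, theta0, theta1 and pi.  Replicates whose fit fails are recorded
    and excluded from the summaries.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    truth = {
        "psi": float(np.mean(invlogit(config.beta_psi[0]))),
        "p": float(invlogit(config.alpha_p[0])),
        "theta0": config.theta0,
        "theta1": config.theta1,
        "pi": config.pi,
    }
    ss = np.random.SeedSequence([seed, config.seed])
    child_seeds = ss.generate_state(n_replicates)
    rows = {k: [] for k in truth}
    cover = {k: [] for k in truth}
    n_failed = 0
    spec = config.spec()
    for r in range(n_replicates):
        cfg = SimulationConfig(**{**config.__dict__, "seed": int(child_seeds[r] % 2**31)})
        ds = simulate_dataset(cfg)
        try:
            fit = OccupancyModel(ds.y, ds.covs, spec).fit(n_starts=n_starts, seed=r)
            ests = {e.name: e for e in fit.real_estimates(force=True)}
        except Exception:
            n_failed += 1
            continue
        for k, tv in truth.items():
            e = ests[k]
            rows[k].append(e.value)
            cover[k].append(e.lci <= tv <= e.uci)
    out = []
    for k, tv in truth.items():
        vals = np.array(rows[k])
        out.append(
            {
                "parameter": k,
                "true": tv,
                "mean_estimate": float(vals.mean()) if vals.size else np.nan,
                "median_bias": float(np.median(vals) - tv) if vals.size else np.nan,
                "bias": float(vals.mean() - tv) if vals.size else np.nan,
                "rmse": float(np.sqrt(np.mean((vals - tv) ** 2))) if vals.size else np.nan,
                "ci_coverage": float(np.mean(cover[k])) if cover[k] else np.nan,
                "n_ok": int(vals.size),
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(out)
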