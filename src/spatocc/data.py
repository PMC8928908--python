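"""Detection histories and site covariates.

Data model
----------
A survey consists of ``n_sites`` sampling units (grid cells), each visited
along a transect split into ``n_segments`` contiguous spatial replicates.
Each segment yields a detection (1), a non-detection (0), or a missing
observation (segment not surveyed).  Site covariates are either continuous
scores (remote-sensing indices) or proportions of segments in which a
feature (termite mounds, fruit trees, disturbance) was recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an unsurveyed segment in integer detection arrays.
MISSING: int = -1

DEFAULT_MISSING_TOKENS = frozenset({"NA", "-", ""})

PROPORTION_COLUMNS = ("Term", "Frut", "Dist")


class ValidationError(ValueError):
    """Raised when input data violate a structural contract."""


class ConvergenceError(RuntimeError):
    """Raised when an optimisation or resampling procedure fails."""


@dataclass
class DetectionMatrix:
    """Sites x segments detection/non-detection histories.

    Parameters
    ----------
    site_ids : list of str
        Unique site labels, one per row of ``y``.
    y : ndarray of int8, shape (n_sites, n_segments)
        Entries in {0, 1, MISSING}.
    segment_length_m : float, optional
        Length of one spatial replicate in metres (metadata only).
    """

    site_ids: list[str]
    y: np.ndarray
    segment_length_m: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 2 or self.y.shape[1] < 1:
            raise ValidationError("detection matrix must be 2-D with >= 1 segment")
        if len(self.site_ids) != self.y.shape[0]:
            raise ValidationError("site_ids length does not match matrix rows")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids")
        bad = ~np.isin(self.y, (0, 1, MISSING))
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid entry {self.y[i, k]} at site {self.site_ids[i]!r}, segment {k + 1}"
            )
        if self.segment_length_m is not None and self.segment_length_m <= 0:
            raise ValidationError("segment_length_m must be positive")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_segments(self) -> int:
        return self.y.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of surveyed segments."""
        return self.y != MISSING

    def to_frame(self) -> pd.DataFrame:
        cols = [f"seg{k + 1:02d}" for k in range(self.n_segments)]
        df = pd.DataFrame(self.y, index=pd.Index(self.site_ids, name="site"), columns=cols)
        return df


@dataclass
class CovariateTable:
    """Per-site named covariates, raw or z-scaled.

    ``scale_params`` maps each column to its (mean, sd) on the raw scale when
    ``scaled`` is True, so that new sites can be placed on the training scale
    and estimates back-transformed.
    """

    site_ids: list[str]
    values: pd.DataFrame
    scaled: bool = False
    scale_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.values.index = pd.Index(self.site_ids, name="site")
        if self.values.isna().any().any():
            raise ValidationError("covariate table contains missing values")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids in covariate table")
        if not self.scaled:
            for col in self.values.columns:
                if col in PROPORTION_COLUMNS:
                    v = self.values[col].to_numpy(float)
                    if (v < 0).any() or (v > 1).any():
                        raise ValidationError(f"proportion column {col!r} outside [0, 1]")

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        """Design matrix [1, x_1 .. x_q] for the named covariates."""
        for name in names:
            if name not in self.values.columns:
                raise ValidationError(f"unknown covariate {name!r}")
        n = len(self.site_ids)
        X = np.ones((n, 1 + len(names)))
        for j, name in enumerate(names):
            X[:, 1 + j] = self.values[name].to_numpy(float)
        return X

    def unscale(self) -> "CovariateTable":
        """Invert z-scaling using the stored per-column (mean, sd)."""
        if not self.scaled:
            return self
        raw = self.values.copy()
        for col, (m, s) in self.scale_params.items():
            raw[col] = raw[col] * s + m
        return CovariateTable(list(self.site_ids), raw, scaled=False)


@dataclass
class SegmentRecordSet:
    """Per-site, per-segment binary indicators of field-recorded features.

    ``indicators`` maps a feature name (e.g. ``"termite"``) to an int8 array
    of shape (n_sites, n_segments) with entries in {0, 1, MISSING}.
    """

    site_ids: list[str]
    indicators: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = set()
        for name, arr in self.indicators.items():
            arr = np.asarray(arr, dtype=np.int8)
            if not np.isin(arr, (0, 1, MISSING)).all():
                raise ValidationError(f"indicator {name!r} has entries outside 0/1/missing")
            self.indicators[name] = arr
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise ValidationError("indicator arrays have inconsistent shapes")
        if shapes:
            (shape,) = shapes
            if shape[0] != len(self.site_ids):
                raise ValidationError("indicator rows do not match site_ids")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_detection_matrix(
    path, missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS
) -> DetectionMatrix:
    """Read a detection-history CSV: header ``site,seg01..segK``.

    Tokens in ``missing_tokens`` (default ``{"NA", "-", ""}``) become MISSING.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValidationError(f"no sites in {path}")
    site_ids = df.iloc[:, 0].tolist()
    y = np.empty((df.shape[0], df.shape[1] - 1), dtype=np.int8)
    for j, col in enumerate(df.columns[1:]):
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok in missing_tokens:
                y[i, j] = MISSING
            elif tok in ("0", "1"):
                y[i, j] = int(tok)
            else:
                raise ValidationError(
                    f"non-binary token {tok!r} at row {site_ids[i]!r}, column {col!r}"
                )
    return DetectionMatrix(site_ids, y)


def write_detection_matrix(dm: DetectionMatrix, path) -> None:
    """Write a detection matrix as CSV; MISSING is written as ``NA``."""
    df = dm.to_frame().astype(object)
    df[dm.y == MISSING] = "NA"
    df.to_csv(path)


def read_covariates(path) -> CovariateTable:
    """Read a covariate CSV: header ``site,<name>...`` (raw scale)."""
    df = pd.read_csv(path, index_col=0)
    return CovariateTable(df.index.astype(str).tolist(), df)


def write_covariates(table: CovariateTable, path) -> None:
    table.values.to_csv(path)


# ---------------------------------------------------------------------------
# Covariate construction
# ---------------------------------------------------------------------------

def aggregate_segment_presence(records: SegmentRecordSet) -> CovariateTable:
    """Build grid-level Term/Frut/Dist proportions from segment indicators.

    Term and Frut are the proportion of *observed* segments in which the
    feature was present.  The disturbance score pools the three pressure
    indicators (human, livestock, fire) as their per-segment maximum, then
    averages over observed segments, keeping the score a proportion.

    Expected indicator names: ``termite``, ``fruit``, ``human``,
    ``livestock``, ``fire`` (any disturbance component may be absent).
    """
    ind = records.indicators

    def _prop(arr: np.ndarray) -> np.ndarray:
        obs = arr != MISSING
        n_obs = obs.sum(axis=1)
        if (n_obs == 0).any():
            bad = [records.site_ids[i] for i in np.flatnonzero(n_obs == 0)]
            raise ValidationError(f"sites with all segments missing: {bad}")
        return np.where(obs, arr, 0).sum(axis=1) / n_obs

    out = {}
    if "termite" in ind:
        out["Term"] = _prop(ind["termite"])
    if "fruit" in ind:
        out["Frut"] = _prop(ind["fruit"])
    dist_parts = [ind[k] for k in ("human", "livestock", "fire") if k in ind]
    if dist_parts:
        stack = np.stack(dist_parts)  # (3, n, K)
        obs = stack != MISSING
        pooled = np.where(obs, stack, 0).max(axis=0).astype(np.int8)
        # a segment is observed for Dist if any component was recorded there
        pooled[~obs.any(axis=0)] = MISSING
        out["Dist"] = _prop(pooled)
    if not out:
        raise ValidationError("no recognised indicators in SegmentRecordSet")
    return CovariateTable(list(records.site_ids), pd.DataFrame(out))


def zscore_scale(table: CovariateTable) -> CovariateTable:
    """Centre and scale every column to mean 0, sample sd 1 (n-1 denominator)."""
    if table.scaled:
        raise ValidationError("table is already scaled")
    scaled = table.values.copy().astype(float)
    params: dict[str, tuple[float, float]] = {}
    for col in scaled.columns:
        x = scaled[col].to_numpy(float)
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        if s == 0.0:
            raise ValidationError(f"constant column {col!r} (sd = 0)")
        scaled[col] = (x - m) / s
        params[col] = (m, s)
    return CovariateTable(list(table.site_ids), scaled, scaled=True, scale_params=params)


def collinearity_screen(
    table: CovariateTable, threshold: float = 0.5
) -> list[tuple[tuple[str, str], float, bool]]:
    """Pearson r for every unordered covariate pair; flag |r| >= threshold."""
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    if len(table.site_ids) < 3:
        raise ValidationError("need >= 3 sites for a correlation screen")
    cols = table.columns
    out = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = float(
                np.corrcoef(
                    table.values[cols[a]].to_numpy(float),
                    table.values[cols[b]].to_numpy(float),
                )[0, 1]
            )
            out.append(((cols[a], cols[b]), r, abs(r) >= threshold))
    return out


def naive_occupancy(dm: DetectionMatrix) -> float:
    """Fraction of sites with at least one detection among observed segments."""
    if dm.n_sites == 0:
        raise ValidationError("empty detection matrix")
    detected = (dm.y == 1).any(axis=1)
    return float(detected.sum() / dm.n_sites)
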