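"""Per-probe differential methylation statistics with empirical-Bayes moderation.

The site-level signal is the classic microarray linear-model workflow: fit an
ordinary least-squares model per probe with M-values as response and the
condition (plus covariates, and subject blocks for paired designs) as
predictors, then shrink the per-probe residual variances toward a common
prior by empirical Bayes before forming t-statistics.  The shrinkage borrows
strength across probes and adds prior degrees of freedom d0 to the residual
degrees of freedom, which is what makes the downstream chi-square
approximation of the smoothed statistic accurate even at small sample sizes.

The moderated t for probe j is

    t_j = effect_j / (s_post_j * u_j),   s_post_j^2 = (d0*s0^2 + d*s_j^2) / (d0 + d)

where s_j^2 is the residual variance with d residual df, u_j the unscaled
coefficient standard deviation from the design, and (d0, s0^2) are estimated
by moment matching on log-variances (trigamma inversion).  The squared
statistic y_j = t_j^2 feeds the kernel smoother.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .array_model import ConfigError, InputError

logger = logging.getLogger("nkdmr")

BETA_CLIP = 1e-3     # clip beta-values into [BETA_CLIP, 1-BETA_CLIP] before logit
D0_CAP = 1e9         # numerical stand-in for an infinite prior df


class ModelError(ValueError):
    """The design matrix cannot be fit (rank deficiency, too few samples)."""


class DegenerateDataError(ValueError):
    """The data admit no variance estimate (e.g. all residual variances zero)."""


def beta_to_m(beta, clip: float = BETA_CLIP):
    """Convert beta-values (proportion methylated) to M-values.

    M = log2(beta / (1 - beta)), after clipping beta into
    [clip, 1 - clip] so boundary values do not map to +/-infinity.
    Accepts scalars or arrays.
    """
    arr = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("beta values must be finite")
    if clip <= 0 or clip >= 0.5:
        raise ConfigError("clip must lie in (0, 0.5)")
    clipped = np.clip(arr, clip, 1.0 - clip)
    m = np.log2(clipped / (1.0 - clipped))
    if np.isscalar(beta):
        return float(m)
    return m


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values on the beta or M scale."""

    values: pd.DataFrame            # index: probe_id, columns: sample_id
    scale: str = "beta"             # "beta" | "mvalue"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "mvalue"):
            raise ConfigError(f"scale must be 'beta' or 'mvalue', got {self.scale!r}")
        if self.scale == "beta":
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise InputError("beta-scale values must lie in [0, 1]")
        if self.values.columns.duplicated().any():
            raise InputError("duplicated sample ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_mvalues(self, clip: float = BETA_CLIP) -> "MethylationMatrix":
        if self.scale == "mvalue":
            return self
        m = pd.DataFrame(beta_to_m(self.values.to_numpy(), clip=clip),
                         index=self.values.index, columns=self.values.columns)
        return MethylationMatrix(m, scale="mvalue")


def load_methylation_matrix(path, scale: str = "beta", sep: str | None = None) -> MethylationMatrix:
    """Read a probes x samples matrix (first column probe id, rest samples)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise InputError(f"{path}: need at least two sample columns")
    return MethylationMatrix(df, scale=scale)


@dataclass
class DesignInfo:
    """Sample-level design: condition labels, covariates, optional pairing.

    ``condition`` has exactly two levels; the contrast tested is
    (treatment level) - (reference level).  By default the reference is the
    alphabetically first level, so e.g. "control"/"treatment" and
    "normal"/"tumor" both get the conventional direction.  Paired designs
    are handled by subject-indicator blocking covariates.
    """

    condition: pd.Series                      # index: sample_id
    covariates: pd.DataFrame | None = None    # numeric or categorical
    pairing: pd.Series | None = None          # subject ids
    reference: str | None = None

    def __post_init__(self) -> None:
        levels = sorted(self.condition.unique())
        if len(levels) != 2:
            raise ModelError(f"condition must have exactly 2 levels, got {levels}")
        counts = self.condition.value_counts()
        if counts.min() < 2:
            raise ModelError("need >= 2 samples per condition")
        if self.reference is None:
            self.reference = levels[0]
        elif self.reference not in levels:
            raise ModelError(f"reference {self.reference!r} not a condition level")
        if self.pairing is not None and self.pairing.isna().any():
            raise ModelError("pairing ids, if given, must cover all samples")

    @property
    def treatment(self) -> str:
        levels = sorted(self.condition.unique())
        return next(l for l in levels if l != self.reference)


def load_sample_sheet(path, condition_col: str = "condition",
                      subject_col: str = "subject") -> DesignInfo:
    """Read a sample sheet TSV: ``sample_id,condition[,covariate...][,subject]``."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or condition_col not in df.columns:
        raise InputError(f"{path}: sample sheet needs 'sample_id' and '{condition_col}' columns")
    df = df.set_index("sample_id")
    condition = df[condition_col].astype(str)
    pairing = df[subject_col].astype(str) if subject_col in df.columns else None
    cov_cols = [c for c in df.columns if c not in (condition_col, subject_col)]
    covariates = df[cov_cols] if cov_cols else None
    return DesignInfo(condition=condition, covariates=covariates, pairing=pairing)


def build_design_matrix(design: DesignInfo, sample_ids) -> tuple[pd.DataFrame, int]:
    """Assemble the model matrix; returns (X, index of the condition column)."""
    sample_ids = pd.Index(sample_ids)
    missing = sample_ids.difference(design.condition.index)
    if len(missing):
        raise ModelError(f"samples missing from the sample sheet: {list(missing)}")
    cols: dict[str, np.ndarray] = {"(intercept)": np.ones(len(sample_ids))}
    cond = design.condition.loc[sample_ids]
    cols[f"condition[{design.treatment}]"] = (cond == design.treatment).to_numpy(float)
    contrast_idx = 1
    if design.covariates is not None:
        cov = design.covariates.loc[sample_ids]
        for name in cov.columns:
            col = cov[name]
            if pd.api.types.is_numeric_dtype(col):
                cols[name] = col.to_numpy(float)
            else:
                for level in sorted(col.astype(str).unique())[1:]:  # drop first level
                    cols[f"{name}[{level}]"] = (col.astype(str) == level).to_numpy(float)
    if design.pairing is not None:
        subj = design.pairing.loc[sample_ids].astype(str)
        for level in sorted(subj.unique())[1:]:
            cols[f"subject[{level}]"] = (subj == level).to_numpy(float)
    X = pd.DataFrame(cols, index=sample_ids)
    _check_full_rank(X)
    if X.shape[0] - X.shape[1] < 1:
        raise ModelError("residual degrees of freedom < 1")
    return X, contrast_idx


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank == X.shape[1]:
        return
    # identify offending columns via pivoted QR diagonal
    from scipy.linalg import qr
    _, r, piv = qr(mat, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps
    bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    raise ModelError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_site_models(matrix: MethylationMatrix, design: DesignInfo) -> pd.DataFrame:
    """Per-probe OLS fits of M-values against the design.

    Probes with any missing value are dropped (logged).  Returns a frame
    indexed by probe_id with columns ``effect`` (condition contrast,
    treatment minus reference, in M-value units), ``sigma2`` (residual
    variance), ``residual_df`` and ``stdev_unscaled`` (the coefficient sd
    factor sqrt((X'X)^-1_kk), identical across probes).
    """
    if matrix.scale != "mvalue":
        raise InputError("fit_site_models expects an M-value matrix; call to_mvalues() first")
    X, k = build_design_matrix(design, matrix.sample_ids)
    Y = matrix.values.to_numpy(float)
    complete = np.isfinite(Y).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d probes with missing values", n_dropped)
    Y = Y[complete]
    probe_ids = matrix.probe_ids[complete]
    if Y.shape[0] == 0:
        raise InputError("no complete probes to fit")

    Xm = X.to_numpy(float)
    n, p = Xm.shape
    q, r = np.linalg.qr(Xm)
    coefs = np.linalg.solve(r, q.T @ Y.T)          # p x probes
    fitted = Xm @ coefs
    resid = Y.T - fitted
    residual_df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / residual_df
    xtx_inv = np.linalg.inv(r.T @ r)
    stdev_unscaled = float(np.sqrt(xtx_inv[k, k]))

    return pd.DataFrame({
        "effect": coefs[k],
        "sigma2": sigma2,
        "residual_df": float(residual_df),
        "stdev_unscaled": stdev_unscaled,
    }, index=probe_ids)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


@dataclass
class SqueezeResult:
    d0: float                      # prior degrees of freedom (capped at D0_CAP)
    s0_sq: float                   # prior variance
    posterior_var: np.ndarray = field(repr=False)


def squeeze_variances(sigma2, residual_df: float) -> SqueezeResult:
    """Shrink per-probe variances toward a common prior (empirical Bayes).

    Assumes sigma2_j ~ s0^2 * chi^2_d / d under the prior; the
    hyperparameters (d0, s0^2) are estimated by matching the mean and
    variance of log(sigma2_j) using digamma/trigamma identities, and each
    posterior variance is the df-weighted average

        s_post_j^2 = (d0*s0^2 + d*sigma2_j) / (d0 + d).

    When the observed log-variance dispersion is no larger than expected
    from chi-square sampling noise alone, d0 is effectively infinite (capped
    numerically) and every posterior variance equals s0^2.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if s2.size < 2:
        raise DegenerateDataError("need >= 2 probes to estimate the variance prior")
    if not np.all(np.isfinite(s2)) or (s2 < 0).any():
        raise ValueError("variances must be finite and non-negative")
    if np.all(s2 == 0):
        raise DegenerateDataError("all residual variances are zero")
    if (s2 == 0).any():
        floor = s2[s2 > 0].min() * 1e-8
        logger.warning("flooring %d zero variances at %g", int((s2 == 0).sum()), floor)
        s2 = np.where(s2 == 0, floor, s2)
    d = float(residual_df)
    if d <= 0:
        raise ValueError("residual_df must be > 0")

    z = np.log(s2)
    e = z - float(digamma(d / 2.0)) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = min(2.0 * trigamma_inverse(evar), D0_CAP)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s0_sq = float(np.exp(emean))
    if d0 >= D0_CAP:
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + d * s2) / (d0 + d)
    return SqueezeResult(d0=d0, s0_sq=s0_sq, posterior_var=post)


def moderated_t(fits: pd.DataFrame, squeeze: SqueezeResult) -> pd.DataFrame:
    """Moderated t-statistics and their squares from per-probe fits.

    Returns a frame with columns ``effect, sigma2, residual_df,
    moderated_t, nu, y`` where nu = residual_df + d0 (total df after
    moderation) and y = t^2.  Probes with zero posterior variance get an
    infinite t, are flagged, and should be excluded downstream.
    """
    post = squeeze.posterior_var
    se = np.sqrt(post) * fits["stdev_unscaled"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits["effect"].to_numpy() / se
    infinite = ~np.isfinite(t)
    if infinite.any():
        logger.warning("%d probes have zero posterior variance (infinite t)", int(infinite.sum()))
    nu = fits["residual_df"].to_numpy() + min(squeeze.d0, D0_CAP)
    out = pd.DataFrame({
        "effect": fits["effect"],
        "sigma2": fits["sigma2"],
        "residual_df": fits["residual_df"],
        "posterior_var": post,
        "moderated_t": t,
        "nu": nu,
        "y": t ** 2,
        "infinite_t": infinite,
    }, index=fits.index)
    return out


def site_statistics(matrix: MethylationMatrix, design: DesignInfo,
                    clip: float = BETA_CLIP) -> pd.DataFrame:
    """End-to-end site-level testing: M-values -> OLS -> shrinkage -> t, y."""
    m = matrix.to_mvalues(clip=clip)
    fits = fit_site_models(m, design)
    squeeze = squeeze_variances(fits["sigma2"].to_numpy(), fits["residual_df"].iloc[0])
    return moderated_t(fits, squeeze)
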