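"""Satterthwaite scaled-chi-square p-values and FDR control for smoothed sites.

Under the null each squared moderated t is approximately chi^2_1 (the total
degrees of freedom after empirical-Bayes moderation are large even for small
samples), so S(x_i) = y_i + sum_j w_j y_j is a positive linear combination
of chi^2_1 variables with mean 1 + sum_j w_j and variance 2(1 + sum_j w_j^2).
Matching those two moments to a scaled chi-square p * chi^2_q gives

    p_xi = (1 + sum_w2) / (1 + sum_w),
    q_xi = (1 + sum_w)^2 / (1 + sum_w2),

and S(x_i)/p_xi is referred to the chi^2 distribution with q_xi degrees of
freedom.  With normalized weights (sum_w = 1) the scale-df product p*q is
exactly 2 and q ranges over [2, 4): q = 2 with a single neighbor, rising
toward 4 as weight spreads over many neighbors.  Raw p-values are corrected
genome-wide by Benjamini-Hochberg and sites are retained when the adjusted
p-value is strictly below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SatterthwaiteParams:
    p_xi: float   # scale of the approximating chi-square
    q_xi: float   # degrees of freedom


def satterthwaite_params(sum_w, sum_w2):
    """Moment-matched scale and df from the weight sums.

    Accepts scalars or aligned arrays; (0, 0) — an isolated site — yields
    (1, 1), i.e. S ~ chi^2_1 unchanged.
    """
    sw = np.asarray(sum_w, dtype=float)
    sw2 = np.asarray(sum_w2, dtype=float)
    if (sw < 0).any() or (sw2 < 0).any():
        raise ValueError("weight sums must be non-negative")
    p = (1.0 + sw2) / (1.0 + sw)
    q = (1.0 + sw) ** 2 / (1.0 + sw2)
    if p.ndim == 0:
        return SatterthwaiteParams(float(p), float(q))
    return p, q


def site_pvalue(S, p_xi, q_xi):
    """Upper-tail chi-square probability of S/p_xi at q_xi degrees of freedom."""
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("S must be non-negative")
    out = chi2.sf(S / np.asarray(p_xi, float), df=np.asarray(q_xi, float))
    return float(out) if out.ndim == 0 else out


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def infer_sites(smoothed: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Attach Satterthwaite params, raw/BH p-values and significance flags.

    ``smoothed`` is the genome-ordered frame from the smoothing stage (one
    row per site, columns S, sum_w, sum_w2).  BH is applied in a single
    family across all chromosomes.  Sites are significant when
    p_adj < alpha (ties at exactly alpha are removed, the conservative
    reading of the retention rule).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p_xi, q_xi = satterthwaite_params(smoothed["sum_w"].to_numpy(),
                                      smoothed["sum_w2"].to_numpy())
    p_raw = site_pvalue(smoothed["S"].to_numpy(), p_xi, q_xi)
    p_adj = bh_adjust(p_raw)
    out = smoothed.copy()
    out["p_xi"] = p_xi
    out["q_xi"] = q_xi
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["significant"] = p_adj < alpha
    return out


def filter_significant(sites: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Retain sites with p_adj strictly below alpha, preserving genomic order."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return sites.loc[sites["p_adj"] < alpha].copy()
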