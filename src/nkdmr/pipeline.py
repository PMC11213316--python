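"""End-to-end DMR detection: the faDMR / aaDMR pipeline.

Stages, in order: convert beta-values to M-values if needed; per-probe
linear-model fits with empirical-Bayes variance moderation; square the
moderated t-statistics; smooth them per chromosome with normalized Gaussian
kernel weights (bandwidth fixed at 500 bp for faDMR, per-chromosome median
probe spacing for aaDMR); Satterthwaite scaled-chi-square p-values;
genome-wide Benjamini-Hochberg correction; retain sites with adjusted
p < alpha; agglomerate retained sites within g bp into ranked regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import inference, regions, sitestats, smoothing
from .array_model import ArrayLayout, ConfigError, make_bandwidth_policy

logger = logging.getLogger("nkdmr")

MODES = {"faDMR": "fixed", "aaDMR": "adaptive"}


@dataclass
class RunConfig:
    """Tunables of one detection run (defaults follow the published method)."""

    mode: str = "aaDMR"            # "faDMR" (h = fixed 500 bp) | "aaDMR" (median gap)
    fixed_h: float = 500.0         # bp; bandwidth in faDMR mode and adaptive fallback
    g: float = 1000.0              # bp; agglomeration distance
    alpha: float = 0.05            # BH-adjusted significance level
    min_probes: int = 2            # minimum sites per reported region
    window_factor: float = smoothing.WINDOW_FACTOR
    beta_clip: float = sitestats.BETA_CLIP

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {sorted(MODES)}, got {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.g <= 0 or self.fixed_h <= 0:
            raise ConfigError("g and fixed_h must be > 0")


def detect_dmrs(matrix: sitestats.MethylationMatrix, layout: ArrayLayout,
                design: sitestats.DesignInfo,
                config: RunConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline; returns (site table, DMR table).

    The site table has one row per probe shared between the matrix and the
    layout, in genomic order, with columns
    ``probe_id, chrom, pos, y, S, sum_w, sum_w2, n_neighbors, h, p_xi,
    q_xi, p_raw, p_adj, significant``.  The DMR table has
    ``chrom, start, end, n_probes, p_rep, p_rep_adj, rank``.
    """
    config = config or RunConfig()
    stats = sitestats.site_statistics(matrix, design, clip=config.beta_clip)
    n_inf = int(stats["infinite_t"].sum())
    if n_inf:
        logger.warning("excluding %d probes with infinite t from smoothing", n_inf)
        stats = stats.loc[~stats["infinite_t"]]

    policy = make_bandwidth_policy(layout, MODES[config.mode], fixed_h=config.fixed_h)
    smoothed = smoothing.smooth_layout(stats, layout, policy,
                                       window_factor=config.window_factor)
    sites = inference.infer_sites(smoothed, alpha=config.alpha)
    sig = inference.filter_significant(sites, alpha=config.alpha)
    dmrs = regions.agglomerate(sig, g=config.g, min_probes=config.min_probes)
    logger.info("%s: %d/%d significant sites -> %d regions",
                config.mode, len(sig), len(sites), len(dmrs))
    return sites, dmrs
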