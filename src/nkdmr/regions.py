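"""Agglomeration of significant CpG sites into differentially methylated regions.

Significant sites on the same chromosome are chained into one region
whenever consecutive sites are within g base pairs of each other (g = 1000
bp by default, the agglomeration distance shared by the mainstream region
callers).  Region boundaries are the first and last member probe positions
(no padding), the representative p-value of a region is the minimum over
its member sites, and regions are ranked by that representative p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .array_model import InputError

logger = logging.getLogger("nkdmr")

DEFAULT_G = 1000       # bp; maximum gap between chained significant sites
DEFAULT_MIN_PROBES = 2  # a single significant CpG is a DMP, not a region

DMR_COLUMNS = ["chrom", "start", "end", "n_probes", "p_rep", "p_rep_adj", "rank"]


def representative_p(p_values, p_adjusted) -> tuple[float, float]:
    """Minimum raw and adjusted p-value over a region's member sites."""
    p = np.asarray(p_values, dtype=float)
    pa = np.asarray(p_adjusted, dtype=float)
    if p.size == 0:
        raise ValueError("a region must have at least one member site")
    return float(p.min()), float(pa.min())


def agglomerate(significant_sites: pd.DataFrame, g: float = DEFAULT_G,
                min_probes: int = DEFAULT_MIN_PROBES) -> pd.DataFrame:
    """Chain significant sites within g bp into regions.

    ``significant_sites`` must be sorted by (chrom, pos) and carry
    ``chrom, pos, p_raw, p_adj`` columns.  Consecutive same-chromosome
    sites with gap <= g join one region; regions never span chromosomes;
    regions with fewer than ``min_probes`` members are dropped (logged).
    Output is sorted by (chrom, start) with a stable rank by p_rep.
    """
    if g <= 0:
        raise ValueError("g must be > 0")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    df = significant_sites
    if len(df) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    order_ok = all(
        (np.diff(pos[chrom == c]) >= 0).all() for c in pd.unique(chrom)
    ) and (pd.Index(chrom).is_monotonic_increasing or _grouped(chrom))
    if not order_ok:
        raise InputError("significant sites must be sorted by (chrom, pos)")

    new_chrom = np.empty(len(df), dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    gap_break = np.empty(len(df), dtype=bool)
    gap_break[0] = True
    gap_break[1:] = (pos[1:] - pos[:-1]) > g
    region_id = np.cumsum(new_chrom | gap_break)

    records = []
    for rid in np.unique(region_id):
        mask = region_id == rid
        members = df.loc[mask]
        if mask.sum() < min_probes:
            continue
        p_rep, p_rep_adj = representative_p(members["p_raw"], members["p_adj"])
        records.append({
            "chrom": members["chrom"].iloc[0],
            "start": int(members["pos"].iloc[0]),
            "end": int(members["pos"].iloc[-1]),
            "n_probes": int(mask.sum()),
            "p_rep": p_rep,
            "p_rep_adj": p_rep_adj,
        })
    n_dropped = len(np.unique(region_id)) - len(records)
    if n_dropped:
        logger.info("dropped %d candidate regions with < %d probes", n_dropped, min_probes)
    out = pd.DataFrame(records, columns=DMR_COLUMNS[:-1])
    if len(out):
        out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        out["rank"] = out["p_rep"].rank(method="first").astype(int)
    else:
        out["rank"] = pd.Series(dtype=int)
    return out


def _grouped(chrom: np.ndarray) -> bool:
    """True when each chromosome occupies one contiguous block."""
    seen: set = set()
    prev = None
    for c in chrom:
        if c != prev:
            if c in seen:
                return False
            seen.add(c)
            prev = c
    return True


def to_bed6(dmrs: pd.DataFrame) -> str:
    """BED6 export (0-based half-open, score = min(1000, -10*log10 p_rep))."""
    lines = []
    for i, row in dmrs.reset_index(drop=True).iterrows():
        p = max(row["p_rep"], 1e-300)
        score = int(min(1000, round(-10.0 * np.log10(p))))
        lines.append(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}"
                     f"\tDMR_{i + 1}\t{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")
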