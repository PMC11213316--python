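"""Probe genomic layout: coordinates, gap statistics, bandwidth selection.

Methylation arrays interrogate CpG sites at fixed genomic coordinates that
are highly irregularly spaced: probes pile up in CpG islands and promoters
(gaps of tens of bp) and thin out in open sea (gaps of kilobases).  The gap
distribution on a chromosome is what drives the choice of kernel bandwidth
for smoothing site-level statistics, so this module owns both the layout
container and the bandwidth policy, plus an emulator that produces
realistic synthetic layouts with annotated promoter-like clusters.

Coordinates are 1-based internally (Illumina manifest convention); BED
input/output converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("nkdmr")

DEFAULT_FIXED_H = 500.0  # bp; fixed-bandwidth (faDMR) default

LAYOUT_COLUMNS = ["probe_id", "chrom", "pos"]
REGION_COLUMNS = ["region_id", "chrom", "start", "end", "n_probes", "feature_class"]


class FormatError(ValueError):
    """An input file does not have the expected columns/shape."""


class InputError(ValueError):
    """Input values violate a precondition (empty layout, unsorted sites...)."""


class ConfigError(ValueError):
    """A configuration value is out of range or inconsistent."""


@dataclass(frozen=True)
class ProbeLocus:
    """A single array probe at a genomic coordinate (1-based)."""

    probe_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError(f"position must be >= 1, got {self.position}")


class ArrayLayout:
    """Probe coordinates grouped by chromosome, sorted by position.

    Wraps a DataFrame with columns ``probe_id, chrom, pos`` (plus an
    optional ``region_id`` column when the layout carries promoter-like
    region annotation, as the emulator's output does).
    """

    def __init__(self, table: pd.DataFrame, regions: pd.DataFrame | None = None):
        missing = [c for c in LAYOUT_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"layout table missing columns: {missing}")
        if len(table) == 0:
            raise InputError("empty probe layout")
        if table["probe_id"].duplicated().any():
            dups = table.loc[table["probe_id"].duplicated(), "probe_id"].unique()
            raise InputError(f"duplicated probe ids: {list(dups[:5])}...")
        if (table["pos"] < 1).any():
            raise InputError("positions must be 1-based (>= 1)")
        table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.table = table
        self.regions = regions

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.table["chrom"].unique())

    @property
    def n_probes(self) -> int:
        return len(self.table)

    def positions(self, chromosome: str) -> np.ndarray:
        sub = self.table.loc[self.table["chrom"] == chromosome, "pos"]
        return sub.to_numpy(dtype=np.int64)

    def probe_ids(self, chromosome: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chromosome, "probe_id"].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover
        return f"ArrayLayout({self.n_probes} probes, {len(self.chromosomes)} chromosomes)"


def load_probe_annotation(path, dialect: str = "manifest_csv") -> ArrayLayout:
    """Read a probe annotation table into an :class:`ArrayLayout`.

    ``manifest_csv`` expects a header with ``probe_id,chrom,pos`` (1-based
    position, Illumina manifest convention).  ``bed3plus`` expects BED
    columns ``chrom,start,end,probe_id`` with 0-based starts, converted to
    1-based positions (start + 1).
    """
    if dialect == "manifest_csv":
        df = pd.read_csv(path)
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        df = df[LAYOUT_COLUMNS].copy()
    elif dialect == "bed3plus":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "probe_id"],
                         usecols=[0, 1, 2, 3])
        df["pos"] = df["start"].astype("Int64") + 1  # 0-based BED start -> 1-based
        df = df[LAYOUT_COLUMNS].copy()
    else:
        raise ConfigError(f"unknown annotation dialect: {dialect!r}")

    n_before = len(df)
    df = df.dropna(subset=["chrom", "pos"])
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d probes with missing coordinates", dropped)
    if len(df) == 0:
        raise InputError(f"{path}: no probes with coordinates")
    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    return ArrayLayout(df)


def chromosome_gaps(layout: ArrayLayout, chromosome: str) -> np.ndarray:
    """Successive probe spacings (bp) on one chromosome; empty if < 2 probes."""
    pos = layout.positions(chromosome)
    if len(pos) < 2:
        return np.array([], dtype=np.int64)
    return np.diff(pos)


def median_gap(layout: ArrayLayout, chromosome: str,
               fallback: float | None = None) -> float:
    """Median probe spacing on a chromosome (even counts: mean of central pair).

    Chromosomes with fewer than two probes have no gaps; if ``fallback`` is
    given it is returned with a warning, otherwise this is an error.
    """
    gaps = chromosome_gaps(layout, chromosome)
    if len(gaps) == 0:
        if fallback is not None:
            logger.warning("chromosome %s has < 2 probes; falling back to h = %g bp",
                           chromosome, fallback)
            return float(fallback)
        raise InputError(f"chromosome {chromosome} has < 2 probes and no fallback bandwidth")
    return float(np.median(gaps))


@dataclass
class BandwidthPolicy:
    """Kernel bandwidth h per chromosome.

    ``fixed`` mode (faDMR): one h everywhere, 500 bp by default.
    ``adaptive`` mode (aaDMR): h equals the median probe spacing of each
    chromosome, so the kernel scale tracks the array's local density.
    """

    mode: str
    fixed_h: float = DEFAULT_FIXED_H
    per_chromosome_h: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ConfigError(f"bandwidth mode must be 'fixed' or 'adaptive', got {self.mode!r}")
        if self.fixed_h <= 0:
            raise ConfigError("fixed_h must be > 0")
        if any(h <= 0 for h in self.per_chromosome_h.values()):
            raise ConfigError("all bandwidths must be > 0")

    def bandwidth(self, chromosome: str) -> float:
        if self.mode == "fixed":
            return self.fixed_h
        try:
            return self.per_chromosome_h[chromosome]
        except KeyError:
            raise ConfigError(f"no bandwidth for chromosome {chromosome!r}") from None


def make_bandwidth_policy(layout: ArrayLayout, mode: str,
                          fixed_h: float = DEFAULT_FIXED_H) -> BandwidthPolicy:
    """Build the bandwidth policy for a layout.

    Fixed mode maps every chromosome to ``fixed_h``; adaptive mode maps each
    chromosome to its median probe gap, falling back to ``fixed_h`` (with a
    warning) on chromosomes with fewer than two probes.
    """
    if fixed_h <= 0:
        raise ConfigError("fixed_h must be > 0")
    if mode == "fixed":
        per = {c: float(fixed_h) for c in layout.chromosomes}
        return BandwidthPolicy("fixed", fixed_h=float(fixed_h), per_chromosome_h=per)
    if mode == "adaptive":
        per = {c: median_gap(layout, c, fallback=fixed_h) for c in layout.chromosomes}
        per = {c: (h if h > 0 else float(fixed_h)) for c, h in per.items()}
        return BandwidthPolicy("adaptive", fixed_h=float(fixed_h), per_chromosome_h=per)
    raise ConfigError(f"unknown bandwidth mode: {mode!r}")


# ---------------------------------------------------------------------------
# Synthetic layout emulation
# ---------------------------------------------------------------------------

@dataclass
class LayoutConfig:
    """Parameters of the synthetic probe-layout emulator.

    The emulator reproduces the qualitative shape of array probe-spacing
    distributions: a sharp mode well below 200 bp (CpG-island / promoter
    probes) and a heavy right tail (open sea).  Gaps are drawn from a
    two-component log-normal mixture; ``island_weight`` is the fraction of
    probes placed inside promoter-like clusters (within-cluster gaps come
    from the island component), the remainder being scattered open-sea
    singletons.  Clusters of >= 2 probes are annotated as candidate regions
    (TSS200-like if their span is <= 200 bp, TSS1500-like otherwise).
    """

    probes_per_chromosome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2000, "chr2": 1500})
    island_gap_median: float = 80.0     # bp, median of within-cluster gaps
    island_gap_sigma: float = 0.7       # log-scale sd
    opensea_gap_median: float = 3000.0  # bp, median of between-unit gaps
    opensea_gap_sigma: float = 1.0
    island_weight: float = 0.7          # fraction of probes in clusters
    cluster_size_range: tuple[int, int] = (4, 10)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.probes_per_chromosome.values()):
            raise ConfigError("probe counts must be positive")
        if not (0.0 <= self.island_weight <= 1.0):
            raise ConfigError("island_weight must lie in [0, 1]")
        lo, hi = self.cluster_size_range
        if lo < 2 or hi < lo:
            raise ConfigError("cluster_size_range must satisfy 2 <= lo <= hi")
        if min(self.island_gap_median, self.opensea_gap_median) <= 0:
            raise ConfigError("gap medians must be > 0")


def _lognormal_gaps(rng: np.random.Generator, median: float, sigma: float,
                    size: int) -> np.ndarray:
    # parameterized so exp(mu) = median; rounded to >= 1 bp
    draws = rng.lognormal(mean=np.log(median), sigma=sigma, size=size)
    return np.maximum(np.rint(draws).astype(np.int64), 1)


def emulate_layout(config: LayoutConfig, seed: int) -> ArrayLayout:
    """Generate a synthetic :class:`ArrayLayout` with annotated clusters.

    Reproducible given ``seed``.  The returned layout's ``table`` carries a
    ``region_id`` column (empty string for singleton background probes) and
    ``regions`` holds the cluster annotation usable as candidate regions
    for simulation and benchmarking.
    """
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    region_rows: list[dict] = []
    probe_counter = 0
    region_counter = 0

    for chrom in sorted(config.probes_per_chromosome):
        n = config.probes_per_chromosome[chrom]
        n_clustered = int(round(config.island_weight * n))
        lo, hi = config.cluster_size_range

        # carve the clustered probes into clusters of random size
        cluster_sizes: list[int] = []
        remaining = n_clustered
        while remaining >= 2:
            k = int(rng.integers(lo, hi + 1))
            k = min(k, remaining)
            cluster_sizes.append(k)
            remaining -= k
        n_singletons = n - sum(cluster_sizes)

        # interleave clusters and singleton probes in random order
        units = [("cluster", k) for k in cluster_sizes] + [("single", 1)] * n_singletons
        order = rng.permutation(len(units))
        units = [units[i] for i in order]

        pos = int(_lognormal_gaps(rng, config.opensea_gap_median,
                                  config.opensea_gap_sigma, 1)[0])
        chrom_pos: list[int] = []
        chrom_region: list[str] = []
        for kind, k in units:
            if kind == "cluster" and k >= 2:
                region_counter += 1
                rid = f"region_{region_counter:06d}"
                gaps = _lognormal_gaps(rng, config.island_gap_median,
                                       config.island_gap_sigma, k - 1)
                positions = pos + np.concatenate([[0], np.cumsum(gaps)])
                chrom_pos.extend(int(p) for p in positions)
                chrom_region.extend([rid] * k)
                span = int(positions[-1] - positions[0])
                region_rows.append({
                    "region_id": rid, "chrom": chrom,
                    "start": int(positions[0]), "end": int(positions[-1]),
                    "n_probes": k,
                    "feature_class": "TSS200-like" if span <= 200 else "TSS1500-like",
                })
                pos = int(positions[-1])
            else:
                chrom_pos.append(pos)
                chrom_region.append("")
            pos += int(_lognormal_gaps(rng, config.opensea_gap_median,
                                       config.opensea_gap_sigma, 1)[0])

        ids = [f"cg{probe_counter + i:08d}" for i in range(len(chrom_pos))]
        probe_counter += len(chrom_pos)
        rows.append(pd.DataFrame({"probe_id": ids, "chrom": chrom,
                                  "pos": np.asarray(chrom_pos, dtype=np.int64),
                                  "region_id": chrom_region}))

    table = pd.concat(rows, ignore_index=True)
    regions = pd.DataFrame(region_rows, columns=REGION_COLUMNS)
    return ArrayLayout(table, regions=regions)


def gap_histogram(layout: ArrayLayout, bin_width: int = 50,
                  truncate_at: int | None = 1000) -> pd.DataFrame:
    """Genome-wide gap histogram as a ``gap_bp,count`` table (for QC export)."""
    gaps = np.concatenate([chromosome_gaps(layout, c) for c in layout.chromosomes]
                          or [np.array([], dtype=np.int64)])
    if truncate_at is not None:
        gaps = gaps[gaps <= truncate_at]
    if len(gaps) == 0:
        return pd.DataFrame({"gap_bp": [], "count": []})
    edges = np.arange(0, gaps.max() + bin_width + 1, bin_width)
    counts, _ = np.histogram(gaps, bins=edges)
    return pd.DataFrame({"gap_bp": edges[:-1], "count": counts})
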