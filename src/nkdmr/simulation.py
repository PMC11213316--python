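"""Synthetic methylation-array datasets with known true DMRs.

The generator reproduces the benchmark design for array DMR callers: a set
of promoter-like candidate regions on an emulated probe layout, a random
subset of which are designated true DMRs (half hypermethylated, half
hypomethylated); beta-values drawn per probe and sample from a beta
distribution parameterized by its mode; and a group mean shift of
delta_beta inside true DMRs between control and treatment samples.  The
study conditions default to 10 control vs 10 treatment samples and effect
sizes delta_beta = 0.2 (large) or 0.09 (small).

Outside true DMRs each probe is assigned a methylation status (methylated,
mode 0.9, or unmethylated, mode 0.1, equiprobably) and both groups draw
from the same status distribution.  Inside a hypermethylated true DMR the
control group sits at the unmethylated mode and the treatment group at
mode + delta_beta; hypomethylated DMRs mirror this from the methylated
mode downward.  A beta distribution with mode m and concentration c
(= a + b, c > 2) has shape parameters a = m(c-2)+1, b = (1-m)(c-2)+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation, pipeline, sitestats
from .array_model import ArrayLayout, ConfigError, LayoutConfig, emulate_layout

TRUTH_COLUMNS = ["region_id", "chrom", "start", "end", "label"]


@dataclass
class SimConfig:
    """Parameters of one simulated dataset (defaults = the study conditions)."""

    n_control: int = 10
    n_treatment: int = 10
    n_true: int | None = None        # None -> 10% of candidate regions
    delta_beta: float = 0.2          # group difference in beta inside true DMRs
    hyper_fraction: float = 0.5
    mode_methylated: float = 0.9
    mode_unmethylated: float = 0.1
    concentration: float = 10.0      # a + b of every beta draw
    status_by_region: bool = False   # null-probe status constant within a region

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treatment < 2:
            raise ConfigError("need >= 2 samples per group")
        if not 0 < self.delta_beta < 1:
            raise ConfigError("delta_beta must lie in (0, 1)")
        if not 0 <= self.hyper_fraction <= 1:
            raise ConfigError("hyper_fraction must lie in [0, 1]")
        for m in (self.mode_methylated, self.mode_unmethylated):
            if not 0 < m < 1:
                raise ConfigError("beta modes must lie in (0, 1)")
        if self.concentration <= 2:
            raise ConfigError("concentration must exceed 2 (mode undefined otherwise)")


@dataclass
class SimulatedDataset:
    """A simulated beta matrix plus its ground truth."""

    matrix: sitestats.MethylationMatrix
    design: sitestats.DesignInfo
    truth: pd.DataFrame               # region_id, chrom, start, end, label
    probe_status: pd.Series = field(repr=False)  # per-probe status / direction


def beta_from_mode(mode: float, concentration: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the beta distribution with a given mode.

    a = mode*(c-2)+1, b = (1-mode)*(c-2)+1, so the density argmax
    (a-1)/(a+b-2) equals ``mode`` and a + b = c.
    """
    if concentration <= 2:
        raise ConfigError("concentration must exceed 2")
    if not 0 < mode < 1:
        raise ConfigError("mode must lie in (0, 1)")
    a = mode * (concentration - 2.0) + 1.0
    b = (1.0 - mode) * (concentration - 2.0) + 1.0
    return a, b


def assign_truth(regions: pd.DataFrame, n_true: int,
                 hyper_fraction: float = 0.5,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Label a random subset of candidate regions as true DMRs.

    Uniform selection without replacement; floor(n_true * hyper_fraction)
    of the selected regions are hypermethylated, the rest hypomethylated.
    Returns the region table with a ``label`` column in
    {"hyper", "hypo", "null"}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_true > len(regions):
        raise ConfigError(f"n_true = {n_true} exceeds the {len(regions)} candidate regions")
    chosen = rng.choice(len(regions), size=n_true, replace=False)
    n_hyper = int(np.floor(n_true * hyper_fraction))
    labels = np.full(len(regions), "null", dtype=object)
    labels[chosen[:n_hyper]] = "hyper"
    labels[chosen[n_hyper:]] = "hypo"
    out = regions.copy()
    out["label"] = labels
    return out


def simulate_dataset(layout: ArrayLayout, truth: pd.DataFrame, config: SimConfig,
                     seed: int | np.random.Generator = 0) -> SimulatedDataset:
    """Draw a beta matrix over the layout given region truth labels.

    All draws are independent across probes and samples.  Probes outside
    true DMRs draw both groups from the beta at that probe's methylation
    status mode; probes inside a true DMR draw the control group at the
    baseline mode (unmethylated for hyper regions, methylated for hypo)
    and the treatment group at baseline +/- delta_beta.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = config.concentration
    hyper_treat = config.mode_unmethylated + config.delta_beta
    hypo_treat = config.mode_methylated - config.delta_beta
    for name, m in (("hyper treatment", hyper_treat), ("hypo treatment", hypo_treat)):
        if not 0 < m < 1:
            raise ConfigError(
                f"{name} mode {m:.3f} falls outside (0,1); "
                "reduce delta_beta or move the baseline modes inward")

    table = layout.table
    if "region_id" not in table.columns:
        raise ConfigError("layout carries no region annotation; use emulate_layout")
    region_label = truth.set_index("region_id")["label"]
    probe_label = table["region_id"].map(region_label).fillna("null").to_numpy()

    # per-probe methylation status for null probes
    if config.status_by_region:
        region_ids = table["region_id"].to_numpy()
        unique_regions = pd.unique(region_ids)
        status_map = {r: s for r, s in zip(
            unique_regions, rng.random(len(unique_regions)) < 0.5)}
        methylated = np.array([status_map[r] for r in region_ids])
        scattered = region_ids == ""
        methylated[scattered] = rng.random(int(scattered.sum())) < 0.5
    else:
        methylated = rng.random(len(table)) < 0.5

    # control and treatment beta modes per probe
    mode_ctrl = np.where(methylated, config.mode_methylated, config.mode_unmethylated)
    mode_trt = mode_ctrl.copy()
    is_hyper = probe_label == "hyper"
    is_hypo = probe_label == "hypo"
    mode_ctrl[is_hyper] = config.mode_unmethylated
    mode_trt[is_hyper] = hyper_treat
    mode_ctrl[is_hypo] = config.mode_methylated
    mode_trt[is_hypo] = hypo_treat

    n_probes = len(table)
    k = c - 2.0

    def draw(modes: np.ndarray, n_samples: int) -> np.ndarray:
        a = modes * k + 1.0
        b = (1.0 - modes) * k + 1.0
        g1 = rng.gamma(np.broadcast_to(a[:, None], (n_probes, n_samples)))
        g2 = rng.gamma(np.broadcast_to(b[:, None], (n_probes, n_samples)))
        return g1 / (g1 + g2)

    ctrl = draw(mode_ctrl, config.n_control)
    trt = draw(mode_trt, config.n_treatment)
    beta = np.clip(np.hstack([ctrl, trt]), 1e-12, 1 - 1e-12)

    sample_ids = ([f"ctrl_{i + 1:02d}" for i in range(config.n_control)]
                  + [f"trt_{i + 1:02d}" for i in range(config.n_treatment)])
    values = pd.DataFrame(beta, index=table["probe_id"].to_numpy(), columns=sample_ids)
    matrix = sitestats.MethylationMatrix(values, scale="beta")
    condition = pd.Series(["control"] * config.n_control
                          + ["treatment"] * config.n_treatment,
                          index=sample_ids, name="condition")
    design = sitestats.DesignInfo(condition=condition)

    status = pd.Series(np.where(probe_label != "null", probe_label,
                                np.where(methylated, "methylated", "unmethylated")),
                       index=table["probe_id"].to_numpy(), name="status")
    return SimulatedDataset(matrix=matrix, design=design,
                            truth=truth[TRUTH_COLUMNS].copy(), probe_status=status)


def run_replicates(layout_config: LayoutConfig, sim_config: SimConfig,
                   n_reps: int, master_seed: int = 0,
                   modes: tuple[str, ...] = ("faDMR", "aaDMR"),
                   criteria: tuple[str, ...] = ("EO", "AO"),
                   run_config: pipeline.RunConfig | None = None) -> pd.DataFrame:
    """Simulate, detect and score ``n_reps`` replicate datasets.

    The probe layout is generated once from the master seed (the array is
    fixed across replicates, as on a real chip); truth assignment and beta
    draws use per-replicate seeds derived from the master seed.  Returns a
    long-format frame with one row per (replicate, detection mode,
    criterion): confusion counts and precision/recall/F1/type-I metrics.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    layout_seed, data_seed = ss.spawn(2)
    layout = emulate_layout(layout_config,
                            seed=int(layout_seed.generate_state(1)[0] % (2 ** 31)))
    regions = layout.regions
    n_true = sim_config.n_true
    if n_true is None:
        n_true = max(1, int(round(0.1 * len(regions))))

    rows = []
    for rep, child in enumerate(data_seed.spawn(n_reps)):
        rng = np.random.default_rng(child)
        truth = assign_truth(regions, n_true, sim_config.hyper_fraction, seed=rng)
        data = simulate_dataset(layout, truth, sim_config, seed=rng)
        for mode in modes:
            cfg = replace(run_config or pipeline.RunConfig(), mode=mode)
            _, dmrs = pipeline.detect_dmrs(data.matrix, layout, data.design, cfg)
            for criterion in criteria:
                conf = evaluation.classify_calls(dmrs, truth, criterion)
                metrics = evaluation.compute_metrics(conf)
                rows.append({"rep": rep, "mode": mode, "criterion": criterion,
                             "n_calls": len(dmrs),
                             "TP": conf.TP, "FP": conf.FP,
                             "FN": conf.FN, "TN": conf.TN,
                             "n_true": conf.n_true, "n_null": conf.n_null,
                             "precision": metrics.precision,
                             "recall": metrics.recall,
                             "f1": metrics.f1,
                             "type1": metrics.type1})
    return pd.DataFrame(rows)
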