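"""Quantitative readouts: modulation latency, gap effect, model reaction
times, and the regression statistics used to compare models.

Latency is defined operationally as the first timestep at which an
activity trace reaches 90 % of its maximum; the same operator serves unit
activity and output-layer Q traces.  Reaction-time regressions use
ordinary least squares after the reciprocal-RT outlier filter, and R²
values of competing models are compared through their standard errors
(Cohen's formula) and a two-sided Z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from growthnet.decision import qmap_from_activity
from growthnet.dynamics import RecurrentWeights, run_to_fixed_point
from growthnet.gates import gate_stack_for
from growthnet.stimuli import BottleneckSpec, Stimulus, generate_bottleneck_pair


# ---------------------------------------------------------------- latencies

def modulation_latency(series: Sequence[float]) -> Optional[int]:
    """First index at which the series reaches 90 % of its maximum.

    Returns None (flagged) when the series never rises above zero.
    Invariant under positive rescaling of the series.
    """
    a = np.asarray(series, dtype=float)
    if a.size == 0:
        raise ValueError("empty activity series")
    peak = a.max()
    if peak <= 0:
        return None
    return int(np.argmax(a >= 0.9 * peak))


def unit_trace(state, layer: int, cell, channel: int = 0) -> np.ndarray:
    """Activity time series of one pyramidal unit from a recorded run."""
    if state.history is None:
        raise ValueError("state was run without history recording")
    r, c = cell
    return np.array([h[layer][channel, r, c] for h in state.history])


@dataclass
class LatencyProfile:
    condition: str           # e.g. "narrow/near"
    cell: tuple
    latency: Optional[int]


def gap_effect(w: RecurrentWeights, gates, gap_narrow: int = 1,
               gap_wide: int = 3, seeds: Sequence[int] = (0, 1, 2),
               t_max: int = 60, grid_size: int = 36,
               length: int = 24) -> dict:
    """Latency table (near/far × narrow/wide) on bottleneck stimuli.

    For each seed a matched pair of bottleneck stimuli is generated
    (identical geometry except the gap) and the layer-1 modulation latency
    is measured at probe cells on the target curve before (near) and
    behind (far) the bottleneck.
    """
    table = {"narrow": {"near": [], "far": []}, "wide": {"near": [], "far": []}}
    for s in seeds:
        for name, gap in (("narrow", gap_narrow), ("wide", gap_wide)):
            stim, spec = generate_bottleneck_pair(gap, s, grid_size=grid_size,
                                                  length=length)
            stack = gate_stack_for(stim, gates)
            state = run_to_fixed_point(stim, stack, w, t_max=t_max,
                                       record_history=True)
            for probe, cell in (("near", spec.probe_cells_near),
                                ("far", spec.probe_cells_far)):
                if cell not in stim.target_cells():
                    raise ValueError(f"probe {cell} is not on the target curve")
                lat = modulation_latency(unit_trace(state, 1, cell))
                table[name][probe].append(lat)
    return table


def model_rt(w: RecurrentWeights, gates, stim: Stimulus,
             t_max: int = 60) -> Optional[int]:
    """Model reaction time on an object (or curve) stimulus: the timestep
    at which the output-layer unit on the blue target pixel enhances its
    response by 90 %.  None when the marker is never reached (censored).
    """
    stack = gate_stack_for(stim, gates)
    state = run_to_fixed_point(stim, stack, w, t_max=t_max, record_history=True)
    tr, tc = stim.target_cell
    px = stim.cell_px
    pixel = (tr * px + px // 2, tc * px + px // 2)
    qs = [qmap_from_activity(ys, w)[pixel] for ys in state.history]
    return modulation_latency(qs)


# --------------------------------------------------------------- statistics

@dataclass
class RTFit:
    n: int
    k: int
    r2: float
    se_r2: float
    noise_ceiling: Optional[float] = None


def r2_standard_error(r2: float, n: int, k: int) -> float:
    """Standard error of a coefficient of determination (Cohen 2003):

        SE = sqrt( 4 R² (1−R²)² (n−k−1)² / ((n²−1)(n+3)) )
    """
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    return float(np.sqrt(4.0 * r2 * (1.0 - r2) ** 2 * (n - k - 1) ** 2
                         / ((n * n - 1.0) * (n + 3.0))))


def r2_difference_test(fit_a: RTFit, fit_b: RTFit) -> tuple:
    """Z test on the difference of two R² values fitted to the same
    observations: Z = (R²_a − R²_b) / sqrt(SE_a² + SE_b²), two-sided p.
    """
    se_diff = float(np.hypot(fit_a.se_r2, fit_b.se_r2))
    if se_diff == 0.0:
        if fit_a.r2 == fit_b.r2:
            return 0.0, 1.0
        raise ZeroDivisionError("zero standard error of the difference")
    z = (fit_a.r2 - fit_b.r2) / se_diff
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def filter_outliers_inverse_rt(rts: np.ndarray, sd_limit: float = 2.5) -> np.ndarray:
    """Boolean mask keeping RTs whose reciprocal lies within ``sd_limit``
    standard deviations of the mean of the 1/RT distribution."""
    inv = 1.0 / np.asarray(rts, dtype=float)
    mu, sd = inv.mean(), inv.std(ddof=1)
    if sd == 0:
        return np.ones(inv.shape, dtype=bool)
    return np.abs(inv - mu) <= sd_limit * sd


def rt_regression(model_rts: Sequence[float], human_rts: Sequence[float],
                  filter_outliers: bool = True) -> RTFit:
    """OLS of (human) RT on model RT (one predictor plus intercept)."""
    import statsmodels.api as sm

    x = np.asarray(model_rts, dtype=float)
    y = np.asarray(human_rts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired observations required")
    if filter_outliers:
        keep = filter_outliers_inverse_rt(y)
        x, y = x[keep], y[keep]
    if x.size <= 2:
        raise ValueError("too few observations after filtering")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(res.rsquared)
    return RTFit(n=int(x.size), k=1, r2=r2,
                 se_r2=r2_standard_error(r2, int(x.size), 1))


def synthetic_human_rts(model_rts: Sequence[float], target_r2: float,
                        seed: int, intercept: float = 250.0,
                        slope: float = 40.0) -> np.ndarray:
    """Simulated observer RTs: an affine transform of the model RTs plus
    Gaussian noise calibrated so the population R² equals ``target_r2``.

    Synthetic stand-in for external psychophysics tables, allowing every
    regression statistic to be exercised offline.
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError("target_r2 must lie in (0, 1]")
    x = np.asarray(model_rts, dtype=float)
    rng = np.random.default_rng(seed)
    signal = slope * x
    var_s = signal.var()
    var_n = var_s * (1.0 - target_r2) / target_r2
    return intercept + signal + rng.normal(0.0, np.sqrt(var_n), x.shape)


def plot_gap_effect(table: dict, path) -> None:
    """Bar plot of the latency table (near/far × narrow/wide)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    conds = [("near", "wide"), ("near", "narrow"),
             ("far", "wide"), ("far", "narrow")]
    means, errs, labels = [], [], []
    for probe, gap in conds:
        vals = [v for v in table[gap][probe] if v is not None]
        means.append(np.mean(vals) if vals else np.nan)
        errs.append(np.std(vals) if len(vals) > 1 else 0.0)
        labels.append(f"{probe}\n{gap}")
    ax.bar(range(4), means, yerr=errs, color=["C0", "C1", "C0", "C1"])
    ax.set_xticks(range(4), labels)
    ax.set_ylabel("modulation latency (steps)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_scale_fits(fits: dict, path, noise_ceiling: Optional[float] = None) -> None:
    """Explained variance per scale-count variant, with standard errors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ks = sorted(fits)
    ax.bar(range(len(ks)), [fits[k].r2 for k in ks],
           yerr=[fits[k].se_r2 for k in ks], color="C0")
    if noise_ceiling is not None:
        ax.axhline(noise_ceiling, color="red", lw=1)
    ax.set_xticks(range(len(ks)), [f"{k} scales" for k in ks])
    ax.set_ylabel("explained variance (R²)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def object_geodesic_distance(stim: Stimulus) -> int:
    """Breadth-first within-object cell distance from cue to target marker
    (oracle for RT monotonicity checks)."""
    from collections import deque

    mask = np.asarray(stim.target)
    start, goal = tuple(stim.fixation_cell), tuple(stim.target_cell)
    seen = {start}
    dq = deque([(start, 0)])
    while dq:
        (r, c), d = dq.popleft()
        if (r, c) == goal:
            return d
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nxt = (r + dr, c + dc)
            if (0 <= nxt[0] < mask.shape[0] and 0 <= nxt[1] < mask.shape[1]
                    and mask[nxt] and nxt not in seen):
                seen.add(nxt)
                dq.append((nxt, d + 1))
    raise ValueError("cue and marker are not connected within the object")
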