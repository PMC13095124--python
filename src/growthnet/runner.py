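"""Experiment orchestration: configs, end-to-end runs, scale ablation.

An experiment = train gates → train the recurrent network with the
reinforcement curriculum → evaluate (frozen tests, generalization,
transfer) → analysis readouts.  Every artifact in a run directory is
regenerable from the resolved config and seed, which are stored verbatim.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from growthnet import analysis
from growthnet.dynamics import RecurrentWeights
from growthnet.gates import OracleGates, train_gates_for_task
from growthnet.relearnn import (
    TrainerConfig, evaluate, retrain_object_task, train_curve_task,
)
from growthnet.stimuli import generate_curve_pair, generate_object_pair


@dataclass
class ExperimentConfig:
    """Resolved configuration of one end-to-end experiment."""

    task: str = "curve"
    grid_size: int = 36
    object_grid_size: int = 72
    n_scales: int = 4
    seed: int = 0
    # gate training
    gate_stimuli: int = 1200
    gate_epochs: int = 10
    gate_grid_size: int = 27
    oracle_gates: bool = False
    # reinforcement learning
    rl: TrainerConfig = field(default_factory=TrainerConfig)
    # evaluation
    final_test_trials: int = 100
    generalization_lengths: Sequence[int] = (30,)
    generalization_trials: int = 15
    run_gap_analysis: bool = True
    object_transfer_trials: int = 100

    def __post_init__(self):
        if self.n_scales not in (1, 2, 3, 4):
            raise ValueError("n_scales must be 1..4")
        if isinstance(self.rl, dict):
            self.rl = TrainerConfig(**self.rl)
        self.rl.n_scales = self.n_scales
        self.rl.grid_size = self.grid_size
        self.rl.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generalization_lengths"] = list(self.generalization_lengths)
        return d


def _gate_provider(cfg: ExperimentConfig, task: str):
    if cfg.oracle_gates:
        return OracleGates(task, n_scales=cfg.n_scales), {"oracle": True}
    w, report = train_gates_for_task(
        task, n_stimuli=cfg.gate_stimuli, epochs=cfg.gate_epochs,
        seed=cfg.seed, n_scales=cfg.n_scales,
        holdout_grid=cfg.gate_grid_size)
    return w, {"oracle": False,
               "holdout_accuracy": report["holdout"]["accuracy"].tolist()}


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) a
    metrics dictionary."""
    out = {"config": cfg.to_dict()}
    gates, gate_info = _gate_provider(cfg, "curve")
    out["gates"] = gate_info

    w, log = train_curve_task(cfg.rl, gates)
    out["curriculum_log"] = log
    out["training_trials"] = log[-1]["trial"] if log else 0

    battery = [generate_curve_pair(cfg.grid_size, cfg.rl.end_length, 5_000_000 + i)
               for i in range(cfg.final_test_trials)]
    out["curve_accuracy"] = evaluate(w, gates, battery, cfg.rl)

    gen = {}
    for ln in cfg.generalization_lengths:
        batt = [generate_curve_pair(cfg.grid_size, ln, 6_000_000 + i)
                for i in range(cfg.generalization_trials)]
        gen[int(ln)] = evaluate(w, gates, batt, cfg.rl)
    out["generalization_accuracy"] = gen

    if cfg.run_gap_analysis:
        out["gap_effect"] = analysis.gap_effect(w, gates)

    obj_gates, obj_info = _gate_provider(cfg, "object")
    out["object_gates"] = obj_info
    w, obj_log = retrain_object_task(w, obj_gates, cfg.rl,
                                     max_trials=cfg.object_transfer_trials,
                                     grid_size=cfg.object_grid_size)
    obj_battery = [generate_object_pair(cfg.object_grid_size, 7_000_000 + i)
                   for i in range(cfg.final_test_trials)]
    out["object_accuracy"] = evaluate(w, obj_gates, obj_battery, cfg.rl)
    out["object_log"] = obj_log
    out["curve_accuracy_after_transfer"] = evaluate(w, gates, battery, cfg.rl)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(out, fh, indent=2, default=_json_default)
        save_weights(w, out_dir / "weights.h5")
    out["weights"] = w
    return out


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)


# ------------------------------------------------------------ scale ablation

def truncate_scales(w: RecurrentWeights, n_scales: int) -> RecurrentWeights:
    """Build a 2- or 3-scale variant by dropping the top layers; the
    remaining readout skips are unchanged (they already span layers
    0..n_scales)."""
    if n_scales > w.n_scales:
        raise ValueError("cannot extend a network by truncation")
    out = RecurrentWeights(
        n_scales,
        [k.copy() for k in w.ff2[:n_scales]],
        [k.copy() for k in w.fb[:n_scales]],
        [k.copy() for k in w.hor[:n_scales]],
        w.li0.copy(),
        [k.copy() for k in w.wskip[:n_scales + 1]])
    out.fb[n_scales - 1] = np.zeros_like(out.fb[n_scales - 1])
    return out


def scale_ablation(w: RecurrentWeights, gates_by_scale: dict,
                   stimuli: Sequence, human_rts: Optional[Sequence] = None,
                   scales: Sequence[int] = (2, 3, 4), t_max: int = 60) -> dict:
    """Model RTs of truncated-scale variants on a common stimulus battery,
    with R² fits against (human or synthetic) RTs when provided.

    ``gates_by_scale`` maps a scale count to the gate provider used by the
    variant (gates are convolutional, so the same provider restricted to
    fewer scales is the natural choice).
    """
    out = {"scales": {}, "fits": {}}
    for n in scales:
        wn = truncate_scales(w, n) if n < w.n_scales else w
        gates = gates_by_scale[n]
        rts = [analysis.model_rt(wn, gates, s, t_max=t_max) for s in stimuli]
        out["scales"][n] = rts
    if human_rts is not None:
        fits = {}
        y = np.asarray(human_rts, dtype=float)
        for n, rts in out["scales"].items():
            keep = np.array([r is not None for r in rts])
            x = np.array([r if r is not None else np.nan for r in rts])
            fits[n] = analysis.rt_regression(x[keep], y[keep])
        out["fits"] = fits
        pairs = {}
        top = max(scales)
        for n in scales:
            if n != top:
                pairs[f"{top}v{n}"] = analysis.r2_difference_test(
                    fits[top], fits[n])
        out["difference_tests"] = pairs
    return out


def append_trial_log(records: Sequence[dict], path) -> None:
    """Append per-trial records (action, r, delta, qa, T) to a CSV file."""
    import csv

    path = Path(path)
    fields = ["action_row", "action_col", "r", "delta", "qa", "T", "correct"]
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        wr = csv.writer(fh)
        if new:
            wr.writerow(fields)
        for rec in records:
            wr.writerow([rec["action"][0], rec["action"][1], rec["r"],
                         rec["delta"], rec["qa"], rec["T"], int(rec["correct"])])


# -------------------------------------------------------------- persistence

def save_weights(w: RecurrentWeights, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["n_scales"] = w.n_scales
        for name, arr in w.kernel_families().items():
            fh.create_dataset(name, data=arr)


def load_weights(path) -> RecurrentWeights:
    import h5py

    with h5py.File(path, "r") as fh:
        n = int(fh.attrs["n_scales"])
        w = RecurrentWeights.initialize(n, seed=0)
        for name in w.kernel_families():
            arr = np.asarray(fh[name])
            fam = w.kernel_families()[name]
            fam[...] = arr
    return w
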