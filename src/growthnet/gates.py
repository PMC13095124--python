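"""Feedforward scale-selection pathway ("gates").

A shared 1×1 projection maps the RGB image to a single feature map X0.
Each scale ``l`` has an independent two-layer detector: a stride-1
convolution with 20 feature maps and kernel side ``3^l`` produces an
intermediate map, and a stride-``3^l`` output convolution followed by a
logistic squashed through a 0.7 threshold yields the gate map at the
resolution of hidden layer ``l``:

    X0        = ReLU(FF0 ⊗ X)
    Xint_l    = ReLU(FFint_l ⊗ X0)            (stride 1, same padding)
    Xgate_l   = ReLU(σ(FFout_l ⊗ Xint_l) − 0.7)   (stride 3^l)

Gates are trained supervised (per-scale cross-entropy against the
geometric "unambiguous RF" labels, class-rebalanced, Adam) and frozen
before reinforcement learning.  The cross-entropy acts on σ(pre-output);
the −0.7 shift plus rectification is the behavioural decision threshold
passed to the recurrent dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import expit

from growthnet import convops as co
from growthnet.stimuli import (
    GateLabelSet, Stimulus, gate_labels_curve, gate_labels_object,
    generate_curve_pair, generate_object_pair, pyramid_resolutions,
)

GATE_THRESHOLD = 0.7
N_FEATURES = 20


@dataclass
class GateWeights:
    """Kernels and biases of the scale-selection pathway."""

    n_scales: int
    w0: np.ndarray                 # (1, 3) shared 1x1 projection
    b0: np.ndarray                 # (1,)
    k_int: List[np.ndarray]        # per scale: (20, K, K), K = 3^l
    b_int: List[np.ndarray]        # per scale: (20,)
    k_out: List[np.ndarray]        # per scale: (1, 20, K, K)
    b_out: List[np.ndarray]        # per scale: (1,)
    frozen: bool = False

    @classmethod
    def initialize(cls, n_scales: int = 4, seed: int = 0) -> "GateWeights":
        rng = np.random.default_rng(seed)
        w0 = rng.normal(0.0, 0.5, (1, 3))
        b0 = np.zeros(1)
        k_int, b_int, k_out, b_out = [], [], [], []
        for l in range(1, n_scales + 1):
            k = 3 ** l
            k_int.append(rng.normal(0.0, np.sqrt(2.0 / (k * k)), (N_FEATURES, k, k)))
            b_int.append(np.zeros(N_FEATURES))
            k_out.append(rng.normal(0.0, np.sqrt(2.0 / (N_FEATURES * k * k)),
                                    (1, N_FEATURES, k, k)))
            b_out.append(np.zeros(1))
        return cls(n_scales, w0, b0, k_int, b_int, k_out, b_out)

    def params(self) -> dict:
        p = {"w0": self.w0, "b0": self.b0}
        for l in range(self.n_scales):
            p[f"k_int{l}"] = self.k_int[l]
            p[f"b_int{l}"] = self.b_int[l]
            p[f"k_out{l}"] = self.k_out[l]
            p[f"b_out{l}"] = self.b_out[l]
        return p

    def fingerprint(self) -> float:
        """Cheap bit-level digest used to assert the freezing contract."""
        return float(sum(np.abs(v).sum() for v in self.params().values()))


@dataclass
class GateStack:
    """Forward activity of the gate pathway for one image."""

    x0: np.ndarray                     # (1, H, W)
    xint: List[np.ndarray]             # per scale: (20, H, W)
    sigma: List[np.ndarray]            # per scale: σ(pre-output), (1, H_l, W_l)
    xgate: List[np.ndarray]            # per scale: ReLU(σ − 0.7)

    def __post_init__(self):
        for g in self.xgate:
            assert g.min() >= 0.0


def _as_chw(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3:
        raise ValueError("expected an H×W×3 or 3×H×W image")
    if image.shape[-1] == 3 and image.shape[0] != 3:
        return np.ascontiguousarray(image.transpose(2, 0, 1))
    if image.shape[0] == 3:
        return image
    raise ValueError("image must carry 3 color channels")


def gate_forward(image: np.ndarray, w: GateWeights,
                 keep_intermediates: bool = True) -> GateStack:
    """Run the scale-selection pathway on one image."""
    x = _as_chw(np.asarray(image, dtype=float))
    x0 = np.maximum(co.conv1x1(x, w.w0) + w.b0[:, None, None], 0.0)
    xint, sig, xgate = [], [], []
    for l in range(w.n_scales):
        xi = np.maximum(
            co.corr2_same(x0[0], w.k_int[l]) + w.b_int[l][:, None, None], 0.0)
        z = co.block_conv(xi, w.k_out[l]) + w.b_out[l][:, None, None]
        s = expit(z)
        xint.append(xi if keep_intermediates else None)
        sig.append(s)
        xgate.append(np.maximum(s - GATE_THRESHOLD, 0.0))
    return GateStack(x0=x0, xint=xint, sigma=sig, xgate=xgate)


def gate_stack_from_labels(labels: GateLabelSet, h: int,
                           gate_value: float = 0.25) -> GateStack:
    """Build an idealized GateStack from geometric labels (oracle gates).

    Used by tests and by the analytically constructed reference network;
    positive RFs receive the constant ``gate_value`` (max attainable is
    1 − 0.7 = 0.3).
    """
    n = len(labels)
    xgate = [labels[l].astype(float)[None] * gate_value for l in range(1, n + 1)]
    sigma = [g + GATE_THRESHOLD * (g > 0) for g in xgate]
    return GateStack(x0=np.zeros((1, h, h)), xint=[None] * n,
                     sigma=sigma, xgate=xgate)


class OracleGates:
    """Idealized gates computed from stimulus geometry instead of learned
    kernels.  Useful for fast, deterministic experiments isolating the
    recurrent pathway from gate-training error; interchangeable with
    :class:`GateWeights` wherever a gate provider is expected.
    """

    frozen = True

    def __init__(self, task: str, gate_value: float = 0.25, n_scales: int = 4):
        if task not in ("curve", "object"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.gate_value = gate_value
        self.n_scales = n_scales

    def __call__(self, stim: Stimulus) -> GateStack:
        lab = (gate_labels_curve(stim, self.n_scales) if self.task == "curve"
               else gate_labels_object(stim, self.n_scales))
        return gate_stack_from_labels(lab, stim.image.shape[0], self.gate_value)

    def fingerprint(self) -> float:
        return 0.0


def gate_stack_for(stim: Stimulus, gates) -> GateStack:
    """Dispatch: a GateWeights instance runs the conv pathway, a callable
    (e.g. OracleGates) is invoked directly."""
    if isinstance(gates, GateWeights):
        return gate_forward(stim.image_chw, gates, keep_intermediates=False)
    if callable(gates):
        return gates(stim)
    raise TypeError("gates must be GateWeights or a callable")


# ------------------------------------------------------------------ training

def make_gate_dataset(task: str, n_stimuli: int, seed: int,
                      grid_size: int = 27, lengths: Sequence[int] = tuple(range(3, 17)),
                      n_scales: int = 4) -> list:
    """Generate (stimulus, labels) pairs for gate training.

    Defaults use a 27×27-cell (81×81 px) canvas: the kernels are shared
    across space, so gates trained on the small canvas apply unchanged to
    the larger task images.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_stimuli):
        s = int(rng.integers(0, 2**31 - 1))
        if task == "curve":
            ln = int(lengths[rng.integers(len(lengths))])
            stim = generate_curve_pair(grid_size, ln, s)
            out.append((stim, gate_labels_curve(stim, n_scales)))
        elif task == "object":
            stim = generate_object_pair(grid_size, s)
            out.append((stim, gate_labels_object(stim, n_scales)))
        else:
            raise ValueError(f"unknown task {task!r}")
    return out


def _batch_forward(xb: np.ndarray, w: GateWeights):
    """Batched forward pass keeping every intermediate for backprop.

    xb: (B, 3, H, W) → per-scale logits (B, 1, H_l, W_l).
    """
    x0 = np.einsum("oc,bchw->bohw", w.w0, xb) + w.b0[None, :, None, None]
    m0 = x0 > 0
    x0 = x0 * m0
    per_scale = []
    for l in range(w.n_scales):
        xi = co.corr2_same(x0[:, 0], w.k_int[l])
        xi += w.b_int[l][None, :, None, None]
        mi = xi > 0
        xi = xi * mi
        k = w.k_out[l].shape[-1]
        b, f, h, wd = xi.shape
        ho, wo = co.out_res(h, k), co.out_res(wd, k)
        xip = co.pad_to(xi, ho * k, wo * k).reshape(b, f, ho, k, wo, k)
        z = np.einsum("bfiajc,ofac->boij", xip, w.k_out[l])
        z += w.b_out[l][None, :, None, None]
        per_scale.append({"xi": xi, "mi": mi, "xip_shape": (b, f, h, wd),
                          "z": z, "k": k})
    return x0, m0, per_scale


def _bce_grad(z: np.ndarray, y: np.ndarray, wpos: float):
    """Weighted binary cross-entropy on σ(z); returns (loss, dL/dz)."""
    p = expit(z)
    eps = 1e-12
    wmap = np.where(y > 0.5, wpos, 1.0)
    loss = -(wmap * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).mean()
    gz = wmap * (p - y) / z.size
    return loss, gz


def train_gates(dataset: Sequence, task: Optional[str] = None,
                epochs: int = 20, lr: float = 1e-3, batch_size: int = 16,
                seed: int = 0, weights: Optional[GateWeights] = None,
                n_scales: int = 4, class_weight_cap: float = 100.0,
                verbose: bool = False):
    """Train the gates against geometric labels; returns (weights, log).

    The loss is the sum over scales of class-rebalanced cross-entropy; the
    scale-specific kernels receive gradients only from their own scale's
    loss while the shared FF0 projection accumulates all of them.
    """
    from scipy.signal import fftconvolve

    rng = np.random.default_rng(seed)
    w = weights if weights is not None else GateWeights.initialize(n_scales, seed)
    if w.frozen:
        raise RuntimeError("gate weights are frozen")
    _cast_params(w, np.float32)   # single precision is ample for training

    images = np.stack([s.image_chw for s, _ in dataset]).astype(np.float32)
    labels = [np.stack([lab[l] for _, lab in dataset]).astype(np.float32)[:, None]
              for l in range(1, n_scales + 1)]
    wpos = []
    for lab in labels:
        pos = lab.sum()
        neg = lab.size - pos
        wpos.append(float(np.clip(neg / max(pos, 1.0), 1.0, class_weight_cap)))

    params = w.params()
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    tstep = 0
    log = []
    n = len(dataset)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = images[idx]
            x0, m0, per_scale = _batch_forward(xb, w)
            grads = {k: np.zeros_like(val) for k, val in params.items()}
            gx0 = np.zeros_like(x0)
            total = 0.0
            for l in range(n_scales):
                ps = per_scale[l]
                y = labels[l][idx]
                loss, gz = _bce_grad(ps["z"], y, wpos[l])
                total += loss
                b, f, h, wd = ps["xip_shape"]
                k = ps["k"]
                ho, wo = gz.shape[-2:]
                grads[f"b_out{l}"] += gz.sum(axis=(0, 2, 3))
                xip = co.pad_to(ps["xi"], ho * k, wo * k).reshape(b, f, ho, k, wo, k)
                grads[f"k_out{l}"] += np.einsum("boij,bfiajc->ofac", gz, xip)
                gxi = np.einsum("boij,ofac->bfiajc", gz, w.k_out[l]).reshape(
                    b, f, ho * k, wo * k)[:, :, :h, :wd]
                gxi = gxi * ps["mi"]
                grads[f"b_int{l}"] += gxi.sum(axis=(0, 2, 3))
                grads[f"k_int{l}"] += co.corr2_same_vjp_k(gxi, x0[:, 0], k)
                gx0 += co.corr2_same_vjp_x(gxi, w.k_int[l])[:, None]
            gx0 = gx0 * m0
            grads["b0"] += gx0.sum(axis=(0, 2, 3))
            grads["w0"] += np.einsum("bohw,bchw->oc", gx0, xb)
            ep_loss += total
            tstep += 1
            for key, val in params.items():
                g = grads[key]
                m[key] = 0.9 * m[key] + 0.1 * g
                v[key] = 0.999 * v[key] + 0.001 * g * g
                mh = m[key] / (1 - 0.9 ** tstep)
                vh = v[key] / (1 - 0.999 ** tstep)
                val -= lr * mh / (np.sqrt(vh) + 1e-8)
        log.append({"epoch": epoch, "loss": ep_loss / max(1, n // batch_size)})
        if verbose:
            print(f"epoch {epoch}: loss {log[-1]['loss']:.4f}")
    _cast_params(w, np.float64)
    return w, log


def _cast_params(w: GateWeights, dtype) -> None:
    w.w0 = w.w0.astype(dtype)
    w.b0 = w.b0.astype(dtype)
    for l in range(w.n_scales):
        w.k_int[l] = w.k_int[l].astype(dtype)
        w.b_int[l] = w.b_int[l].astype(dtype)
        w.k_out[l] = w.k_out[l].astype(dtype)
        w.b_out[l] = w.b_out[l].astype(dtype)


def gate_accuracy(w: GateWeights, dataset: Sequence,
                  threshold: float = GATE_THRESHOLD) -> dict:
    """Per-scale accuracy of the behavioural gate (σ > 0.7) vs labels."""
    correct = np.zeros(w.n_scales)
    count = np.zeros(w.n_scales)
    fp = np.zeros(w.n_scales)
    fn = np.zeros(w.n_scales)
    for stim, lab in dataset:
        stack = gate_forward(stim.image_chw, w, keep_intermediates=False)
        for l in range(w.n_scales):
            pred = stack.sigma[l][0] > threshold
            truth = lab[l + 1]
            correct[l] += (pred == truth).sum()
            count[l] += truth.size
            fp[l] += (pred & ~truth).sum()
            fn[l] += (~pred & truth).sum()
    return {"accuracy": correct / count,
            "false_positives": fp, "false_negatives": fn, "n": count}


# canvas (grid cells) and curve lengths used to train each scale; kernels
# are shared across space, so each detector can be trained on a canvas
# matched to its receptive field and applied to any image size
_SCALE_CANVAS = {1: (9, range(2, 7)), 2: (9, range(2, 7)),
                 3: (18, range(3, 13)), 4: (27, range(3, 17))}


def _scale_batch_forward(x0, w, l):
    """Forward for a single scale given a precomputed (B,1,H,W) x0."""
    xi = co.corr2_same(x0[:, 0], w.k_int[l]) + w.b_int[l][None, :, None, None]
    mi = xi > 0
    xi = xi * mi
    k = w.k_out[l].shape[-1]
    b, f, h, wd = xi.shape
    ho, wo = co.out_res(h, k), co.out_res(wd, k)
    xip = co.pad_to(xi, ho * k, wo * k).reshape(b, f, ho, k, wo, k)
    z = np.einsum("bfiajc,ofac->boij", xip, w.k_out[l])
    z += w.b_out[l][None, :, None, None]
    return xi, mi, z, k


def train_gates_multiscale(task: str, n_stimuli: int = 600, epochs: int = 10,
                           lr: float = 2e-3, batch_size: int = 16,
                           seed: int = 0, n_scales: int = 4,
                           class_weight_cap: float = 100.0,
                           verbose: bool = False):
    """Train each scale's detector on its own canvas (sizes matched to the
    receptive field), sharing the FF0 projection across scales.

    Much faster than single-canvas training because the wide-kernel FFTs
    run only on the small canvases that need them.
    """
    rng = np.random.default_rng(seed)
    w = GateWeights.initialize(n_scales, seed + 1)
    _cast_params(w, np.float32)

    images, labels, wpos = {}, {}, {}
    for l in range(1, n_scales + 1):
        grid, lengths = _SCALE_CANVAS[l]
        ds = make_gate_dataset(task, n_stimuli, seed + 31 * l, grid_size=grid,
                               lengths=tuple(lengths), n_scales=l)
        images[l] = np.stack([s.image_chw for s, _ in ds]).astype(np.float32)
        labels[l] = np.stack([lab[l] for _, lab in ds]).astype(np.float32)[:, None]
        pos = labels[l].sum()
        wpos[l] = float(np.clip((labels[l].size - pos) / max(pos, 1.0),
                                1.0, class_weight_cap))

    params = w.params()
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    tstep = 0
    log = []
    n_batches = max(1, n_stimuli // batch_size)
    for epoch in range(epochs):
        orders = {l: rng.permutation(n_stimuli) for l in images}
        ep_loss = 0.0
        for bi in range(n_batches):
            grads = {k: np.zeros_like(val) for k, val in params.items()}
            total = 0.0
            for l1 in range(1, n_scales + 1):
                l = l1 - 1
                idx = orders[l1][bi * batch_size:(bi + 1) * batch_size]
                xb = images[l1][idx]
                x0 = np.einsum("oc,bchw->bohw", w.w0, xb) + w.b0[None, :, None, None]
                m0 = x0 > 0
                x0 = x0 * m0
                xi, mi, z, k = _scale_batch_forward(x0, w, l)
                loss, gz = _bce_grad(z, labels[l1][idx], wpos[l1])
                total += loss
                b, f, h, wd = xi.shape
                ho, wo = gz.shape[-2:]
                grads[f"b_out{l}"] += gz.sum(axis=(0, 2, 3))
                xip = co.pad_to(xi, ho * k, wo * k).reshape(b, f, ho, k, wo, k)
                grads[f"k_out{l}"] += np.einsum("boij,bfiajc->ofac", gz, xip)
                gxi = np.einsum("boij,ofac->bfiajc", gz, w.k_out[l]).reshape(
                    b, f, ho * k, wo * k)[:, :, :h, :wd]
                gxi = gxi * mi
                grads[f"b_int{l}"] += gxi.sum(axis=(0, 2, 3))
                grads[f"k_int{l}"] += co.corr2_same_vjp_k(gxi, x0[:, 0], k)
                gx0 = co.corr2_same_vjp_x(gxi, w.k_int[l])[:, None] * m0
                grads["b0"] += gx0.sum(axis=(0, 2, 3))
                grads["w0"] += np.einsum("bohw,bchw->oc", gx0, xb)
            ep_loss += total
            tstep += 1
            for key, val in params.items():
                g = grads[key]
                m[key] = 0.9 * m[key] + 0.1 * g
                v[key] = 0.999 * v[key] + 0.001 * g * g
                val -= lr * (m[key] / (1 - 0.9 ** tstep)) / (
                    np.sqrt(v[key] / (1 - 0.999 ** tstep)) + 1e-8)
        log.append({"epoch": epoch, "loss": ep_loss / n_batches})
        if verbose:
            print(f"epoch {epoch}: loss {log[-1]['loss']:.4f}", flush=True)
    _cast_params(w, np.float64)
    return w, log


def train_gates_for_task(task: str, n_stimuli: int = 600, epochs: int = 10,
                         seed: int = 0, n_scales: int = 4,
                         holdout_grid: int = 27, **kw):
    """Convenience wrapper: train per-scale canvases, freeze, report."""
    w, log = train_gates_multiscale(task, n_stimuli=n_stimuli, epochs=epochs,
                                    seed=seed, n_scales=n_scales, **kw)
    holdout = make_gate_dataset(task, 100, seed + 10_000, grid_size=holdout_grid,
                                n_scales=n_scales)
    acc = gate_accuracy(w, holdout)
    w.frozen = True
    return w, {"train_log": log, "holdout": acc}


# ------------------------------------------------------------- scale usage

def scale_usage_map(gates: GateStack, trace, stim: Stimulus) -> dict:
    """For each target cell: the coarsest scale whose gate is active over
    that cell, and the timestep its layer-1 enhancement reached 90 % of
    maximum (None when the cell is never enhanced).
    """
    out = {}
    n_scales = len(gates.xgate)
    for (r, c) in stim.target_cells():
        scale = 1
        for l in range(n_scales, 0, -1):
            side = 3 ** (l - 1)
            if gates.xgate[l - 1][0, r // side, c // side] > 0:
                scale = l
                break
        series = np.array([h[1][0, r, c] for h in trace.history])
        peak = series.max()
        if peak <= 0:
            out[(r, c)] = (scale, None)
        else:
            lat = int(np.argmax(series >= 0.9 * peak))
            out[(r, c)] = (scale, lat)
    return out
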