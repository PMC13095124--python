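"""Recurrent disinhibitory dynamics: pyramidal / VIP / SOM populations.

The network has an input layer (l=0, one pyramidal channel per color) and
``n_scales`` hidden layers at resolutions shrinking by a factor 3 per
level.  Horizontal and feedback connections drive VIP interneurons, which
inhibit tonically active SOM interneurons, which inhibit pyramidal cells:
activity can only be *released* up to the feedforward drive, never added,
so the dynamics are bounded for any weight setting.

Per synchronous timestep (interneurons read the previous state, pyramidal
layers then sweep bottom-up within the step, so stimulus onset produces a
feedforward sweep at t=1):

    VIP_0(t) = Θ(FB_0 ⊛ Y_1(t-1))
    VIP_l(t) = Θ(Hor_l ⊗ Y_l(t-1) + FB_l ⊛ Y_{l+1}(t-1)),  1 <= l < n
    VIP_n(t) = Θ(Hor_n ⊗ Y_n(t-1))
    SOM_l(t) = ReLU(1 - VIP_l(t))
    Y_0(t)   = ReLU(φ(X) ⊙ (-LI_0 ⊗ SOM_0(t)))
    Y_l(t)   = ReLU(φ(X^gate_l) ⊙ (FF2_l ⊗ Y_{l-1}(t) - SOM_l(t)))

Θ clips to [0, 1]; φ is a steep saturating gate; ⊛ is the RF-aligned
transposed convolution.  ``step_vjp`` implements the exact vector-Jacobian
product of one step at a fixed point — the accessory (credit-assignment)
network of the learning rule is the iteration of this adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from growthnet import convops as co
from growthnet.stimuli import Stimulus, pyramid_resolutions

DEFAULT_TOL = 1e-6
DEFAULT_T_MAX = 30


class DivergenceError(RuntimeError):
    """Non-finite activity: impossible under the bounded dynamics, so a bug."""


def theta(x: np.ndarray) -> np.ndarray:
    """Clipped linear function: clamp to [0, 1]."""
    return np.clip(x, 0.0, 1.0)


def phi(x: np.ndarray, variant: str = "saturating") -> np.ndarray:
    """Steep gate: ~0 at 0 and ~1 for any appreciable input.

    ``saturating`` (default): 100|x| / sqrt(1 + (100 x)^2), monotone in |x|.
    ``bump``: 100|x| / (1 + (100 x)^2), the non-monotone alternative reading,
    kept for comparison.
    """
    z = 100.0 * np.abs(x)
    if variant == "saturating":
        return z / np.sqrt(1.0 + z * z)
    if variant == "bump":
        return z / (1.0 + z * z)
    raise ValueError(f"unknown phi variant: {variant}")


@dataclass
class ChannelSpec:
    """Channel counts per layer: RGB input, 1 at the first scale, 6 above."""

    n_scales: int = 4

    @property
    def channels(self) -> list:
        return ([3] + [1] + [6] * (self.n_scales - 1))[: self.n_scales + 1]


@dataclass
class RecurrentWeights:
    """All learnable kernels of the recurrent pathway plus the Q readout.

    ``hor`` kernels are stored as per-direction channel mixes (4, C, C) so
    the von-Neumann restriction is structural; ``li0`` stores the center
    entries of the input layer's self-connection kernel (all off-center
    entries are structurally zero).
    """

    n_scales: int
    ff2: List[np.ndarray]    # index l-1: (C_l, C_{l-1}, 3, 3)
    fb: List[np.ndarray]     # index l:   (C_l, C_{l+1}, 3, 3), l = 0..n-1
    hor: List[np.ndarray]    # index l-1: (4, C_l, C_l)
    li0: np.ndarray          # (C0, C0)
    wskip: List[np.ndarray]  # l=0: (1, C0); l>=1: (1, C_l, 3^l, 3^l)

    @classmethod
    def initialize(cls, n_scales: int = 4, seed: int = 0,
                   kernel_scale: float = 0.5, skip_scale: float = 0.1,
                   li0_base: float = 1.0, ff1_drive: float = 2.0,
                   ff2_scale: float = 1.0, hor_scale: float = 0.15,
                   fb_scale: float = 0.15) -> "RecurrentWeights":
        """Random init.

        ``li0`` starts near minus the identity so the input layer initially
        relays the stimulus veridically (Y_0 ≈ φ(X) under baseline SOM
        inhibition).  The layer-1 feedforward kernel is excitatory
        (positive uniform) and scaled so the expected drive of a figure
        cell is ``ff1_drive``, just above the tonic SOM threshold: figure
        units then start in the linear regime and the accessory network
        can assign credit to every kernel family from the first trials.
        The remaining kernels are zero-mean uniform.
        """
        rng = np.random.default_rng(seed)
        ch = ChannelSpec(n_scales).channels
        u = lambda *shape: rng.uniform(-kernel_scale, kernel_scale, shape)
        # a figure cell renders as 9 pixels of one color at Y0 ≈ 1.05;
        # uniform(0, hi) entries give E[cell drive] = 1.05 * 9 * hi / 2
        hi = 2.0 * ff1_drive / (9.0 * 1.05)
        ff2 = [rng.uniform(0.0, hi, (ch[1], ch[0], 3, 3))]
        # scale-2 feedforward likewise positive, scaled so a parent whose
        # children carry weak activity sits near the SOM threshold — this
        # keeps the coarse-scale grouping route trainable from the start
        if n_scales >= 2:
            ff2.append(rng.uniform(0.0, ff2_scale, (ch[2], ch[1], 3, 3)))
        ff2 += [rng.uniform(0.0, 0.5, (ch[l], ch[l - 1], 3, 3))
                for l in range(3, n_scales + 1)]
        # horizontal and feedback links start weakly excitatory and
        # sub-critical: the disinhibitory loop then operates in its linear
        # range, where a slightly elevated cue produces a graded activity
        # halo along the connected figure and every link carries credit
        fb = [rng.uniform(0.0, fb_scale, (ch[l], ch[l + 1], 3, 3))
              for l in range(n_scales)]
        hor = [rng.uniform(0.0, hor_scale, (4, ch[l], ch[l]))
               for l in range(1, n_scales + 1)]
        li0 = -(np.eye(ch[0]) + rng.uniform(0.0, 0.1, (ch[0], ch[0])))
        # positive input-layer readout: the output layer starts weakly
        # excited by any stimulus-driven input, so greedy choices fall on
        # colored pixels and colors that never earn reward are pruned by
        # negative prediction errors (cold-start exploration).
        wskip = [rng.uniform(0.0, skip_scale, (1, ch[0]))]
        # hidden-layer skips start at zero: the Q map then begins small
        # (bounded prediction errors, no early punishment avalanche) and
        # the readout of each hidden layer grows from rewarded credit
        # before recurrent credit flows back through it
        for l in range(1, n_scales + 1):
            s = 3 ** l
            wskip.append(np.zeros((1, ch[l], s, s)))
        return cls(n_scales, ff2, fb, hor, li0, wskip)

    @property
    def channels(self) -> list:
        return ChannelSpec(self.n_scales).channels

    def copy(self) -> "RecurrentWeights":
        return RecurrentWeights(
            self.n_scales,
            [k.copy() for k in self.ff2], [k.copy() for k in self.fb],
            [k.copy() for k in self.hor], self.li0.copy(),
            [k.copy() for k in self.wskip])

    def hor_full(self, l: int) -> np.ndarray:
        """Materialize Hor_l as a (C, C, 3, 3) kernel (mask made explicit)."""
        c = self.hor[l - 1].shape[1]
        k = np.zeros((c, c, 3, 3))
        for d, (di, dj) in enumerate(co.HOR_OFFSETS):
            k[:, :, 1 + di, 1 + dj] = self.hor[l - 1][d]
        return k

    def li0_full(self) -> np.ndarray:
        """Materialize LI_0 as a (C0, C0, 3, 3) kernel with center-only support."""
        c = self.li0.shape[0]
        k = np.zeros((c, c, 3, 3))
        k[:, :, 1, 1] = self.li0
        return k

    def kernel_families(self) -> dict:
        fams = {"li0": self.li0, "wskip0": self.wskip[0]}
        for l in range(1, self.n_scales + 1):
            fams[f"ff2_{l}"] = self.ff2[l - 1]
            fams[f"hor_{l}"] = self.hor[l - 1]
            fams[f"wskip_{l}"] = self.wskip[l]
        for l in range(self.n_scales):
            fams[f"fb_{l}"] = self.fb[l]
        return fams


@dataclass
class NetworkState:
    """Time-indexed population activity; ``history`` holds Y per timestep."""

    t: int
    Y: List[np.ndarray]
    VIP: List[np.ndarray]
    SOM: List[np.ndarray]
    converged: bool = False
    T: int = 0
    history: Optional[list] = None
    cache: Optional[dict] = field(default=None, repr=False)
    ctx: Optional["RunContext"] = field(default=None, repr=False)


@dataclass
class RunContext:
    """Per-stimulus constants of a run: φ(X), φ(gates) and resolutions."""

    phiX: np.ndarray          # (C0, H, W)
    phiG: List[np.ndarray]    # (1, H_l, W_l) per hidden layer
    res: List[int]
    w: RecurrentWeights

    @classmethod
    def build(cls, stim: Stimulus, gates, w: RecurrentWeights,
              phi_variant: str = "saturating") -> "RunContext":
        x = stim.image_chw
        h = x.shape[-1]
        res = pyramid_resolutions(h, w.n_scales)
        phiG = [phi(gates.xgate[l - 1], phi_variant)
                for l in range(1, w.n_scales + 1)]
        return cls(phi(x, phi_variant), phiG, res, w)


def zero_state(ctx: RunContext) -> List[np.ndarray]:
    ch = ctx.w.channels
    ys = [np.zeros((ch[0], ctx.res[0], ctx.res[0]))]
    for l in range(1, ctx.w.n_scales + 1):
        ys.append(np.zeros((ch[l], ctx.res[l], ctx.res[l])))
    return ys


def step_core(yprev: List[np.ndarray], ctx: RunContext):
    """One synchronous update; returns (Y_new, cache of intermediates)."""
    w = ctx.w
    n = w.n_scales
    # interneurons read the previous state
    pre_v = [co.block_upconv(yprev[1], w.fb[0], yprev[0].shape)]
    for l in range(1, n + 1):
        p = co.hor_conv(yprev[l], w.hor[l - 1])
        if l < n:
            p += co.block_upconv(yprev[l + 1], w.fb[l], yprev[l].shape)
        pre_v.append(p)
    vip = [theta(p) for p in pre_v]
    som = [np.maximum(1.0 - v, 0.0) for v in vip]
    # pyramidal sweep, bottom-up within the step
    a0 = co.conv1x1(som[0], -w.li0)
    pre_y = [ctx.phiX * a0]
    ynew = [np.maximum(pre_y[0], 0.0)]
    drive = [a0]
    for l in range(1, n + 1):
        d = co.block_conv(ynew[l - 1], w.ff2[l - 1])
        pre = ctx.phiG[l - 1] * (d - som[l])
        pre_y.append(pre)
        ynew.append(np.maximum(pre, 0.0))
        drive.append(d)
    cache = {"pre_v": pre_v, "vip": vip, "som": som,
             "pre_y": pre_y, "drive": drive, "ynew": ynew, "yprev": yprev}
    return ynew, cache


def step(state: NetworkState, stim: Stimulus, gates, w: RecurrentWeights,
         phi_variant: str = "saturating") -> NetworkState:
    """Public single-step API over :func:`step_core`."""
    ctx = state.ctx or RunContext.build(stim, gates, w, phi_variant)
    ynew, cache = step_core(state.Y, ctx)
    return NetworkState(t=state.t + 1, Y=ynew, VIP=cache["vip"],
                        SOM=cache["som"], cache=cache, ctx=ctx)


def run_to_fixed_point(stim: Stimulus, gates, w: RecurrentWeights,
                       t_max: int = DEFAULT_T_MAX, tol: float = DEFAULT_TOL,
                       record_history: bool = True,
                       phi_variant: str = "saturating",
                       ctx: Optional[RunContext] = None) -> NetworkState:
    """Iterate the dynamics from the all-zero state until the activity of
    every population changes by at most ``tol`` between consecutive steps,
    or ``t_max`` steps elapse.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if ctx is None:
        ctx = RunContext.build(stim, gates, w, phi_variant)
    y = zero_state(ctx)
    history = [[a.copy() for a in y]] if record_history else None
    prev_cache = None
    converged, t = False, 0
    cache = None
    for t in range(1, t_max + 1):
        ynew, cache = step_core(y, ctx)
        if not all(np.isfinite(a).all() for a in ynew):
            raise DivergenceError(f"non-finite activity at t={t}")
        delta = max(np.max(np.abs(a - b)) for a, b in zip(ynew, y))
        if prev_cache is not None:
            for key in ("vip", "som"):
                delta = max(delta, max(
                    np.max(np.abs(a - b))
                    for a, b in zip(cache[key], prev_cache[key])))
        y = ynew
        if record_history:
            history.append([a.copy() for a in y])
        if delta <= tol:
            converged = True
            break
        prev_cache = cache
    return NetworkState(t=t, Y=y, VIP=cache["vip"], SOM=cache["som"],
                        converged=converged, T=t, history=history,
                        cache=cache, ctx=ctx)


# ------------------------------------------------------------------ adjoint

def step_vjp(lam: List[np.ndarray], cache: dict, ctx: RunContext,
             with_grads: bool = False):
    """Vector-Jacobian product of one step at the cached operating point.

    Maps an adjoint on Y(t) to the adjoint on Y(t-1); with ``with_grads``
    also returns the kernel gradients (credit × presynaptic activity summed
    over tied positions) and the per-population credit maps.
    """
    w = ctx.w
    n = w.n_scales
    yprev = cache["yprev"]
    ynew = cache["ynew"]
    acc = [g.copy() for g in lam]
    grads = {} if with_grads else None
    credits = {"Y": acc, "preY": [], "VIP": [], "SOM": []} if with_grads else None
    g_som = [None] * (n + 1)

    g_pre_y = [None] * (n + 1)
    for l in range(n, 0, -1):
        gpre = acc[l] * (cache["pre_y"][l] > 0)
        g_pre_y[l] = gpre
        gd = gpre * ctx.phiG[l - 1]
        g_som[l] = -gd
        acc[l - 1] = acc[l - 1] + co.block_conv_vjp_x(
            gd, w.ff2[l - 1], ynew[l - 1].shape)
        if with_grads:
            grads[f"ff2_{l}"] = co.block_conv_vjp_k(
                gd, ynew[l - 1], w.ff2[l - 1].shape)
    gpre0 = acc[0] * (cache["pre_y"][0] > 0)
    g_pre_y[0] = gpre0
    ga0 = gpre0 * ctx.phiX
    g_som[0] = co.conv1x1_vjp_x(ga0, -w.li0)
    if with_grads:
        grads["li0"] = -co.conv1x1_vjp_k(ga0, cache["som"][0])

    lam_prev = [np.zeros_like(y) for y in yprev]
    for l in range(n + 1):
        gvip = -g_som[l] * (1.0 - cache["vip"][l] > 0)
        p = cache["pre_v"][l]
        gpre_v = gvip * ((p > 0) & (p < 1))
        if with_grads:
            credits["VIP"].append(gvip)
            credits["SOM"].append(g_som[l])
        if l == 0:
            lam_prev[1] += co.block_upconv_vjp_x(gpre_v, w.fb[0], yprev[1].shape)
            if with_grads:
                grads["fb_0"] = co.block_upconv_vjp_k(gpre_v, yprev[1], w.fb[0].shape)
        else:
            lam_prev[l] += co.hor_conv_vjp_x(gpre_v, w.hor[l - 1], yprev[l].shape)
            if with_grads:
                grads[f"hor_{l}"] = co.hor_conv_vjp_k(gpre_v, yprev[l])
            if l < n:
                lam_prev[l + 1] += co.block_upconv_vjp_x(
                    gpre_v, w.fb[l], yprev[l + 1].shape)
                if with_grads:
                    grads[f"fb_{l}"] = co.block_upconv_vjp_k(
                        gpre_v, yprev[l + 1], w.fb[l].shape)
    if with_grads:
        credits["preY"] = g_pre_y
    return lam_prev, grads, credits
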