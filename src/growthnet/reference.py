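"""An analytically constructed tracer network.

The recurrent architecture admits a closed-form solution of the tracing
task, wired by hand rather than learned.  It operates in the seeded-wave
regime:

* the input layer relays the stimulus veridically (LI0 = −I);
* layer-1 drive from a red (cue) cell exceeds the tonic SOM inhibition,
  so the cue ignites; green/blue cells sit below threshold and stay
  silent until disinhibited;
* horizontal weights are strong enough that a single enhanced neighbour
  saturates VIP (full disinhibition) — the enhancement advances one cell
  per step without attenuation, and cannot ignite spontaneously because
  the sub-threshold baseline is exactly zero;
* a hidden unit at scale ``l ≥ 2`` fires as soon as any child is
  enhanced, and its feedback then disinhibits its whole 3×3 child block
  in the next step, so spread is faster wherever coarser gates are open;
* the readout scores blue pixels, adds the layer-1 enhancement and
  suppresses the red cue, so the maximum-Q pixel is the blue marker on
  the cued figure once the wave has reached it.

The reference network is used as a fast, deterministic stand-in for a
trained network in analysis tests (latency, gap effect, model RT) and as
evidence that the gated dynamics support scale-dependent tracing.  It is
paired with idealized gates built from the geometric labels
(:func:`growthnet.gates.gate_stack_from_labels`).
"""

from __future__ import annotations

import numpy as np

from growthnet.dynamics import ChannelSpec, RecurrentWeights

# channel indices of the rendered stimulus
RED, GREEN, BLUE = 0, 1, 2


def make_reference_tracer(n_scales: int = 4, cue_drive: float = 2.0,
                          figure_drive: float = 0.55, hor_gain: float = 2.0,
                          parent_gain: float = 20.0, fb_gain: float = 2.0,
                          blue_bonus: float = 0.2, red_penalty: float = 2.0,
                          ) -> RecurrentWeights:
    """Hand-set weights implementing curve tracing and region filling.

    ``cue_drive`` > 1 ignites the cue cell against tonic SOM inhibition;
    ``figure_drive`` < 1 keeps uncued figure cells silent until
    disinhibited; ``hor_gain * figure_drive >= 1`` makes the wave advance
    without attenuation.
    """
    ch = ChannelSpec(n_scales).channels
    w = RecurrentWeights.initialize(n_scales, seed=0, kernel_scale=0.0,
                                    skip_scale=0.0)
    w.li0 = -np.eye(ch[0])
    # layer 1 drive: per-pixel weights over the 3×3 cell block
    ff2_1 = np.zeros((ch[1], ch[0], 3, 3))
    ff2_1[0, RED] = cue_drive / 9.0
    ff2_1[0, GREEN] = figure_drive / 9.0
    ff2_1[0, BLUE] = figure_drive / 9.0
    w.ff2[0] = ff2_1
    # cell-to-cell horizontal spread at scale 1
    w.hor[0] = np.zeros((4, ch[1], ch[1]))
    w.hor[0][:, 0, 0] = hor_gain
    # coarser layers: fire on any enhanced child, fill the block via feedback
    for l in range(2, n_scales + 1):
        k = np.zeros((ch[l], ch[l - 1], 3, 3))
        k[0, 0] = parent_gain
        w.ff2[l - 1] = k
    for l in range(1, n_scales):
        k = np.zeros((ch[l], ch[l + 1], 3, 3))
        k[0, 0] = fb_gain
        w.fb[l] = k
    w.fb[0] = np.zeros_like(w.fb[0])
    # readout: blue bonus, red suppression, layer-1 enhancement
    w.wskip[0] = np.zeros((1, ch[0]))
    w.wskip[0][0, BLUE] = blue_bonus
    w.wskip[0][0, RED] = -red_penalty
    sk1 = np.zeros((1, ch[1], 3, 3))
    sk1[0, 0] = 1.0
    w.wskip[1] = sk1
    for l in range(2, n_scales + 1):
        w.wskip[l] = np.zeros_like(w.wskip[l])
    return w
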