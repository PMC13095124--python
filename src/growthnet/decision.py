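"""Q-value readout, action selection and reward.

The output layer is retinotopic: every pixel carries the expected reward
(Q-value) of an eye movement to it.  It integrates all scales through skip
connections — a 1×1 convolution from the input layer and, from each hidden
layer ``l``, a transposed kernel whose unit projects only to the
``3^l × 3^l`` pixels of its own receptive field:

    Q = Σ_{l=0..n} Wskip_l ⊛ Y_l(T)

Actions are greedy with probability 1−ε and otherwise sampled from the
Boltzmann distribution over Q (temperature 1).  A correct saccade — any
pixel of the blue target cell's 3×3 block — earns reward 1; the
reward-prediction error δ = r − Q_a drives learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from growthnet import convops as co
from growthnet.dynamics import NetworkState, RecurrentWeights
from growthnet.stimuli import Stimulus


@dataclass
class QMap:
    q: np.ndarray                      # (H, W)
    action: Optional[Tuple[int, int]] = None
    qa: Optional[float] = None
    converged: bool = True


@dataclass
class RewardSignal:
    r: float
    delta: float


def compute_qmap(state: NetworkState, w: RecurrentWeights) -> QMap:
    """Read the Q map off the (converged) state at time T."""
    return QMap(q=qmap_from_activity(state.Y, w), converged=state.converged)


def qmap_from_activity(ys, w: RecurrentWeights) -> np.ndarray:
    h, wd = ys[0].shape[-2:]
    q = co.conv1x1(ys[0], w.wskip[0])[0]
    for l in range(1, w.n_scales + 1):
        q = q + co.block_upconv(ys[l], w.wskip[l], (h, wd))[0]
    return q


def boltzmann_probabilities(q: np.ndarray) -> np.ndarray:
    """Softmax over all pixels with max-subtraction for stability."""
    z = q - q.max()
    p = np.exp(z)
    return p / p.sum()


def select_action(q: QMap, epsilon: float, rng_seed) -> Tuple[int, int]:
    """Greedy with prob 1−ε (ties → lowest row-major index), else a
    Boltzmann sample.  ``rng_seed`` may be an int or a Generator."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    qv = q.q
    if epsilon > 0 and rng.random() < epsilon:
        p = boltzmann_probabilities(qv).ravel()
        flat = rng.choice(p.size, p=p)
    else:
        flat = int(np.argmax(qv))
    action = np.unravel_index(flat, qv.shape)
    q.action = (int(action[0]), int(action[1]))
    q.qa = float(qv[q.action])
    return q.action


def is_correct(action: Tuple[int, int], stim: Stimulus) -> bool:
    r, c = action
    tr, tc = stim.target_cell
    px = stim.cell_px
    return (tr * px <= r < (tr + 1) * px) and (tc * px <= c < (tc + 1) * px)


def reward(action: Tuple[int, int], stim: Stimulus, qa: float) -> RewardSignal:
    """Reward 1 for a saccade to the blue cell on the cued figure, else 0;
    δ = r − Q_a."""
    h, wd = stim.image.shape[:2]
    if not (0 <= action[0] < h and 0 <= action[1] < wd):
        raise ValueError("action outside image bounds")
    r = 1.0 if is_correct(action, stim) else 0.0
    return RewardSignal(r=r, delta=r - qa)
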