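"""Numba-compiled per-trial choice-probability kernels.

These duplicate the semantics of :mod:`odorchoice.models`'s pure-Python
``trial_step`` path for the hot loops of MLE and MCMC fitting; unit tests
pin the two paths together to 1e-12.

Encoding: odor 0=left_forced, 1=right_forced, 2=free; choice 0=left,
1=right; ``new_sess[t]`` flags the first trial of each session (values and
the perseveration memory reset there).  Four-state state indices: 0 Left,
1 Right, 2 Left-NoRwd, 3 Right-NoRwd.  Six-state index = 2*odor + choice.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _p_left(dv_l, dv_r, beta, lapse):
    x = beta * (dv_l - dv_r)
    if x >= 0.0:
        core = 1.0 / (1.0 + np.exp(-x))
    else:
        e = np.exp(x)
        core = e / (1.0 + e)
    return (1.0 - lapse) * core + 0.5 * lapse


@njit(cache=True)
def _s4(odor, action):
    # valid (free, or forced side matches) -> Left/Right; else NoRwd of side
    if odor == 2 or odor == action:
        return action
    return 2 + action


@njit(cache=True)
def hybrid_value_p_left(
    odor, choice, valid, r, d, new_sess, eta, gamma, beta, b, p, w4, lapse
):
    """P(left) per trial for the hybrid-value model (w4=1: four-state,
    w4=0: six-state); both value tables updated in parallel each trial."""
    n = odor.shape[0]
    out = np.empty(n)
    v4 = np.zeros(4)
    v6 = np.zeros(6)
    prev = -1
    for t in range(n):
        if new_sess[t]:
            for i in range(4):
                v4[i] = 0.0
            for i in range(6):
                v6[i] = 0.0
            prev = -1
        o = odor[t]
        dv_l = w4 * v4[_s4(o, 0)] + (1.0 - w4) * v6[2 * o + 0]
        dv_r = w4 * v4[_s4(o, 1)] + (1.0 - w4) * v6[2 * o + 1] + b
        if prev == 0:
            dv_l += p
        elif prev == 1:
            dv_r += p
        out[t] = _p_left(dv_l, dv_r, beta, lapse)
        c = choice[t]
        target = (gamma ** d[t]) * r[t] if r[t] > 0.0 else 0.0
        i4 = c if valid[t] else 2 + c
        v4[i4] += eta * (target - v4[i4])
        i6 = 2 * o + c
        v6[i6] += eta * (target - v6[i6])
        prev = c
    return out


@njit(cache=True)
def hybrid_learning_p_left(
    odor, choice, valid, r, d, new_sess, eta, gamma, beta, b, p, eta_g, lapse
):
    """P(left) per trial for the hybrid-learning model (eta_g=0: six-state).

    Valid outcomes update the experienced six-state entry at rate eta and
    the paired same-side state (forced <-> free) at rate eta_g, both toward
    gamma**d * r relative to their own values."""
    n = odor.shape[0]
    out = np.empty(n)
    v6 = np.zeros(6)
    prev = -1
    for t in range(n):
        if new_sess[t]:
            for i in range(6):
                v6[i] = 0.0
            prev = -1
        o = odor[t]
        dv_l = v6[2 * o + 0]
        dv_r = v6[2 * o + 1] + b
        if prev == 0:
            dv_l += p
        elif prev == 1:
            dv_r += p
        out[t] = _p_left(dv_l, dv_r, beta, lapse)
        c = choice[t]
        target = (gamma ** d[t]) * r[t] if r[t] > 0.0 else 0.0
        i6 = 2 * o + c
        v6[i6] += eta * (target - v6[i6])
        if valid[t] and eta_g > 0.0:
            # pair of (free, c) is (c_forced, c); pair of a valid forced
            # trial (o == c) is (free, c)
            pair = 3 * c if o == 2 else 4 + c
            v6[pair] += eta_g * (target - v6[pair])
        prev = c
    return out
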