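"""Brute-force Brownian-dynamics oracle for pair first-passage times.

Simulates the relative motion of an isolated reactive pair as a 3-D random
walk with absorbing contact sphere, including the Brownian-bridge correction
for undetected crossings between steps.  Independent of the IRT sampler it
validates; test-scale only.
"""

from __future__ import annotations

import numpy as np


def bd_pair_survival(
    r0: float,
    big_r: float,
    d_mutual: float,
    t_grid,
    *,
    n_walkers: int = 20000,
    dt: float | None = None,
    rng=None,
) -> np.ndarray:
    """Fraction of pairs NOT yet reacted at each time in ``t_grid``.

    The pair separation starts at ``r0`` and diffuses with mutual diffusion
    coefficient ``d_mutual``; contact at ``big_r`` absorbs.  Between steps a
    Brownian-bridge crossing probability ``exp(-(d1*d2)/(D*dt))`` (d1, d2 =
    distances above contact before/after the step) catches unseen crossings.
    """
    rng = np.random.default_rng(rng)
    t_grid = np.asarray(t_grid, dtype=float)
    if dt is None:
        dt = (big_r / 10.0) ** 2 / (2.0 * d_mutual)
    pos = np.zeros((n_walkers, 3))
    pos[:, 0] = r0
    alive = np.ones(n_walkers, bool)
    t_react = np.full(n_walkers, np.inf)
    t = 0.0
    sigma = np.sqrt(2.0 * d_mutual * dt)
    t_end = t_grid.max()
    while t < t_end and alive.any():
        idx = np.flatnonzero(alive)
        d_before = np.linalg.norm(pos[idx], axis=1) - big_r
        pos[idx] += rng.normal(size=(len(idx), 3)) * sigma
        d_after = np.linalg.norm(pos[idx], axis=1) - big_r
        hit = d_after <= 0
        # Brownian-bridge correction for excursions below contact
        both_out = ~hit
        p_cross = np.exp(
            -np.maximum(d_before[both_out], 0.0)
            * np.maximum(d_after[both_out], 0.0)
            / (d_mutual * dt)
        )
        cross = np.zeros(len(idx), bool)
        cross[both_out] = rng.random(int(both_out.sum())) < p_cross
        reacted = hit | cross
        t += dt
        t_react[idx[reacted]] = t
        alive[idx[reacted]] = False
    return np.array([(t_react > tt).mean() for tt in t_grid])
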