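"""Static linear measurement fixtures: y = Mx + e without network dynamics.

Used by the decoder's unit and oracle tests, and handy for quick sanity
checks of solver behaviour at known sparsity and noise levels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_linear_fixture"]


def make_linear_fixture(
    n: int,
    n_trials: int,
    sparsity: float,
    noise_sd: float,
    rng: np.random.Generator,
    fraction_stim: float = 0.3,
    signed: bool = True,
):
    """Draw (M, x_true, y) with Bernoulli M and a k-sparse signed x.

    k = round(sparsity * n) entries of x are nonzero, with magnitudes
    Uniform(0.5, 1.5) and random signs (when ``signed``); e is Gaussian with
    s.d. ``noise_sd``.  Returns (M, x_true, y).
    """
    if n < 1 or n_trials < 1:
        raise ValueError("n and n_trials must be at least 1")
    M = (rng.random((n_trials, n)) < fraction_stim).astype(float)
    x = np.zeros(n)
    k = int(round(sparsity * n))
    if k > 0:
        support = rng.choice(n, size=k, replace=False)
        mags = rng.uniform(0.5, 1.5, size=k)
        signs = rng.choice([-1.0, 1.0], size=k) if signed else np.ones(k)
        x[support] = mags * signs
    e = noise_sd * rng.standard_normal(n_trials) if noise_sd > 0 else np.zeros(n_trials)
    y = M @ x + e
    return M, x, y
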