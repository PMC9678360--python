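"""Independent brute-force oracles used only by the tests."""

import numpy as np


def lerp_scalar(xs, ys, x):
    """Plain scalar linear interpolation with manual bracket search."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            return (1 - w) * ys[i] + w * ys[i + 1]
    raise AssertionError("bracket not found")


def bilinear_track_oracle(profiles, T, L):
    """Two-pass linear interpolation of a track, one grid point at a time.

    ``profiles`` is a list of 1-D arrays (frame order). Position is first
    resampled within each frame, then time across frames — the same
    composition the kymograph gridding claims, computed scalar-by-scalar.
    """
    F = len(profiles)
    out = np.empty((T, L))
    for ti in range(T):
        tau = ti / (T - 1)
        for li in range(L):
            xi = li / (L - 1)
            per_frame = []
            for p in profiles:
                xs = [j / (len(p) - 1) for j in range(len(p))]
                per_frame.append(lerp_scalar(xs, list(p), xi))
            ts = [f / (F - 1) for f in range(F)]
            out[ti, li] = lerp_scalar(ts, per_frame, tau)
    return out


def rm_anova_permutation_p(values, n_perm, seed):
    """Within-block permutation null for the repeated-measures F statistic."""
    values = np.asarray(values, dtype=float)
    k, n = values.shape

    def f_stat(v):
        grand = v.mean()
        ss_total = ((v - grand) ** 2).sum()
        ss_strain = n * ((v.mean(axis=1) - grand) ** 2).sum()
        ss_block = k * ((v.mean(axis=0) - grand) ** 2).sum()
        ss_error = ss_total - ss_strain - ss_block
        if ss_error <= 0:
            return np.inf
        return (ss_strain / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))

    obs = f_stat(values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = values.copy()
        for j in range(n):
            rng.shuffle(perm[:, j])
        if f_stat(perm) >= obs:
            count += 1
    return count / n_perm
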