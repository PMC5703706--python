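"""Shared test utilities: independent oracles kept deliberately naive."""

from __future__ import annotations

import numpy as np


def naive_lag_oracle(data, reference, dt, max_lag=7.0, step=0.5):
    """Per-voxel double-loop Pearson cross-correlation lag estimator.

    Independent of the vectorized implementation: explicit loops over
    voxels and shifts, correlation via np.corrcoef on the overlap, and the
    documented tie rule (smallest |tau|, then negative) applied by
    explicit comparison.  Returns (lag, peak_r, valid) arrays.
    """
    data = np.atleast_2d(np.asarray(data, float))
    reference = np.asarray(reference, float)
    spr = int(round(step / dt))
    k_max = int(round(max_lag / step))
    n = data.shape[1]
    taus = np.arange(-k_max, k_max + 1) * step
    # tie-preference order: |tau| ascending, negative before positive
    pref = sorted(range(len(taus)), key=lambda i: (abs(taus[i]), taus[i]))

    lags = np.empty(data.shape[0])
    peaks = np.empty(data.shape[0])
    valid = np.empty(data.shape[0], dtype=bool)
    for v in range(data.shape[0]):
        corrs = np.empty(len(taus))
        for i, tau in enumerate(taus):
            k = int(round(tau / dt))
            if k >= 0:
                x = data[v, : n - k] if k else data[v]
                y = reference[k:]
            else:
                x = data[v, -k:]
                y = reference[: n + k]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                corrs[i] = 0.0
            else:
                corrs[i] = np.corrcoef(x, y)[0, 1]
        best = pref[0]
        for i in pref[1:]:
            if corrs[i] > corrs[best]:
                best = i
        tau_sel, r_sel = taus[best], corrs[best]
        bad = abs(tau_sel) >= max_lag - 1e-12 or r_sel < 0
        lags[v] = -max_lag if bad else tau_sel
        peaks[v] = r_sel
        valid[v] = not bad
    return lags, peaks, valid


def shifted_copies(reference, shifts_samples):
    """Rows = reference advanced by k samples (row leads ref by k)."""
    n = len(reference)
    out = []
    for k in shifts_samples:
        out.append(np.roll(reference, -k))
    return np.array(out), n
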