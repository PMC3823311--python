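"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's vectorised/streaming code paths:
the detector oracle materializes every flag's validity interval and
intersects them; the energy oracle recomputes each sliding sum from
scratch; the mean oracle is a literal arithmetic mean.
"""

import numpy as np

from impactsense.signal import dc_suppress, n_window, window_energy


def naive_window_energy(abs_ac: np.ndarray, n_w: int) -> np.ndarray:
    """Recompute e_ac[t] = sum of the last n_w |a_AC| values, per index."""
    n, k = abs_ac.shape
    out = np.zeros((n, k))
    for t in range(n):
        lo = max(0, t - n_w + 1)
        out[t] = abs_ac[lo : t + 1].sum(axis=0)
    return out


def oracle_detect_indices(
    series,
    mode,
    amplitude_threshold,
    energy_threshold,
    hold_ms,
    tau_ms,
    amplitude_on="ac",
):
    """Rising-edge sample indices of the detector output, computed by
    materializing all flag intervals and intersecting them."""
    ac = dc_suppress(series)
    energy = window_energy(ac, tau_ms)
    n = series.n_samples
    n_h = int(round(hold_ms / series.t_s))

    def union_of_intervals(cross):
        active = np.zeros(n, dtype=bool)
        for ax in range(cross.shape[1]):
            for idx in np.flatnonzero(cross[:, ax]):
                active[idx : min(idx + n_h, n - 1) + 1] = True
        return active

    e = np.asarray(energy_threshold, dtype=float)
    if e.ndim == 0:
        e = np.full(series.n_axes, float(e))
    ef = union_of_intervals(energy.e_avg > e[None, :])
    if mode == "isotropic_full":
        amp = np.abs(ac.data if amplitude_on == "ac" else series.data)
        af = union_of_intervals(amp > float(amplitude_threshold))
        h = af & ef
    else:
        h = ef
    prev = np.concatenate(([False], h[:-1]))
    return np.flatnonzero(h & ~prev)


def random_trace(rng, n_axes=3, min_len=60, max_len=240, t_s=27.5):
    """A trace with quiet noise plus a few random spikes and bursts, so
    thresholds land on interesting values."""
    from impactsense.signal import AccelSeries

    n = int(rng.integers(min_len, max_len))
    data = rng.normal(0, 0.01, size=(n, n_axes))
    for _ in range(int(rng.integers(0, 4))):  # spikes
        data[rng.integers(0, n), rng.integers(0, n_axes)] += rng.uniform(-2, 2)
    for _ in range(int(rng.integers(0, 3))):  # bursts
        i0 = int(rng.integers(0, max(1, n - 30)))
        ln = int(rng.integers(5, 30))
        ax = int(rng.integers(0, n_axes))
        amp = rng.uniform(0.05, 0.8)
        data[i0 : i0 + ln, ax] += amp * ((-1.0) ** np.arange(len(data[i0 : i0 + ln])))
    return AccelSeries(data, axes=("x1", "y1", "y2", "x2")[:n_axes], t_s=t_s)


def random_config(rng, n_axes=3):
    mode = ("isotropic_full", "isotropic_energy", "anisotropic")[
        int(rng.integers(0, 3))
    ]
    if mode == "anisotropic":
        e = rng.uniform(0.0, 0.2, size=n_axes)
    else:
        e = float(rng.uniform(0.0, 0.2))
    return dict(
        mode=mode,
        amplitude_threshold=float(rng.uniform(0.0, 1.5)),
        energy_threshold=e,
        hold_ms=float(rng.choice([0.0, 110.0, 550.0, 1760.0])),
        tau_ms=float(rng.choice([330.0, 660.0])),
    )
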