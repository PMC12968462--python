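"""Sliding-window segmentation and windowed connectivity.

Edge weights are absolute Fisher r-to-z transformed Pearson correlations,
computed within each fixed-length window.  The absolute value makes weights
nonnegative so they can serve directly as connection strengths for the
community-detection stage; the atanh transform is variance-stabilizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netreconf.io import ParcellatedSeries

#: Correlations are clipped to ±(1 − 1e−7) before atanh so Fisher z stays finite.
DEFAULT_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds.

    Defaults (60 s window, 10 s step) segment a 300-sample series at
    TR = 1 s into exactly 25 windows.
    """

    window_seconds: float = 60.0
    step_seconds: float = 10.0

    def length_samples(self, tr_seconds: float) -> int:
        L = int(round(self.window_seconds / tr_seconds))
        if L < 2:
            raise ValueError(f"window of {self.window_seconds}s is {L} samples at "
                             f"TR={tr_seconds}s; need >= 2")
        return L

    def step_samples(self, tr_seconds: float) -> int:
        S = int(round(self.step_seconds / tr_seconds))
        if S < 1:
            raise ValueError(f"step of {self.step_seconds}s is {S} samples at "
                             f"TR={tr_seconds}s; need >= 1")
        return S


@dataclass
class WindowedConnectivity:
    """Per-window region × region nonnegative weight matrices."""

    weights: np.ndarray  # (n_windows, n_regions, n_regions)
    window_bounds: list  # half-open [start, end) sample intervals
    region_ids: list

    @property
    def n_windows(self) -> int:
        return self.weights.shape[0]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[1]

    def export_tsv(self, directory) -> list:
        """Write one region × region TSV per window; returns the paths."""
        import os

        import pandas as pd

        from netreconf.io import write_table

        os.makedirs(directory, exist_ok=True)
        paths = []
        for w, (start, end) in enumerate(self.window_bounds):
            df = pd.DataFrame(self.weights[w], index=self.region_ids,
                              columns=self.region_ids)
            p = os.path.join(directory, f"window_{w:03d}.tsv")
            write_table(df, p, window=w, start=start, end=end)
            paths.append(p)
        return paths

    def validate(self) -> None:
        w = self.weights
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValueError("weights must be finite and nonnegative")
        if not np.allclose(w, np.swapaxes(w, 1, 2)):
            raise ValueError("each window's weight matrix must be symmetric")
        if np.abs(np.diagonal(w, axis1=1, axis2=2)).max(initial=0.0) != 0.0:
            raise ValueError("diagonals must be zero")


def make_windows(n_timepoints: int, tr_seconds: float, spec: WindowSpec) -> list:
    """Half-open [start, end) sample intervals for the sliding windows.

    Starts are 0, S, 2S, …; the count is floor((N − L)/S) + 1.  Trailing
    samples not covered by a full window are dropped, never padded.
    """
    L = spec.length_samples(tr_seconds)
    S = spec.step_samples(tr_seconds)
    if L > n_timepoints:
        raise ValueError(f"window of {L} samples exceeds the series length {n_timepoints}")
    n_windows = (n_timepoints - L) // S + 1
    return [(w * S, w * S + L) for w in range(n_windows)]


def windowed_correlation(series: ParcellatedSeries, spec: WindowSpec = WindowSpec(),
                         clip: float = DEFAULT_CLIP) -> WindowedConnectivity:
    """Absolute Fisher-z Pearson connectivity for every window.

    For window w and region pair (i, j) the weight is ``|atanh(r_ij)|`` with
    r clipped to [−clip, clip]; the diagonal is forced to zero.  A region
    with zero variance inside any window is a hard error naming the region
    and the window, because Pearson correlation is undefined there.
    """
    bounds = make_windows(series.n_timepoints, series.tr_seconds, spec)
    n = series.n_regions
    out = np.empty((len(bounds), n, n), dtype=float)
    for w, (start, end) in enumerate(bounds):
        seg = series.signals[:, start:end]
        sd = seg.std(axis=1)
        if (sd == 0).any():
            bad = [series.region_ids[i] for i in np.where(sd == 0)[0]]
            raise ValueError(
                f"zero-variance signal for region(s) {bad[:5]} in window {w} "
                f"[{start}, {end})")
        r = np.corrcoef(seg)
        np.clip(r, -clip, clip, out=r)
        z = np.abs(np.arctanh(r))
        np.fill_diagonal(z, 0.0)
        # enforce exact symmetry against floating-point asymmetries
        out[w] = (z + z.T) / 2.0
    wc = WindowedConnectivity(out, bounds, list(series.region_ids))
    wc.validate()
    return wc
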