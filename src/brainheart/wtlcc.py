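"""Windowed time-lagged cross-correlation (WTLCC) matrices.

A WTLCC matrix summarises the fine-grained, possibly delayed coupling
between two aligned 1-min index series over an N-minute analysis window.
The window is split into K contiguous, non-overlapping sub-windows of
length w = N/K minutes (rows); for each of J lag columns the entry (k, j)
is the Pearson correlation between series I1 restricted to sub-window k and
series I2 shifted by ``lag = j - J/2`` minutes. Sliding the N-minute window
with stride S over a 72-h panel yields floor((T-N)/S)+1 overlapping
matrices per patient, which downstream models treat as images.

Lag sign convention: positive lag means I1 leads I2 (I2's samples are taken
``lag`` minutes later). Lagged samples are drawn from the full panel beyond
the analysis window when available; otherwise the pair is missing (no
zero-padding), guarded by a minimum valid-pair fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import h5py
import numpy as np

from .types import MinutePanel, MinuteSeries

__all__ = [
    "WTLCCParams",
    "WTLCCMatrix",
    "column_lag",
    "build_matrix",
    "extract_matrices",
    "save_matrices_h5",
    "load_matrices_h5",
]

logger = logging.getLogger(__name__)

#: Published hyperparameter grids ("paper mode").
PAPER_N_SET = (360, 720, 1080)
PAPER_S_SET = (15, 30, 60, 90)
PAPER_K_SET = (15, 30, 60)
PAPER_J = 240


@dataclass(frozen=True)
class WTLCCParams:
    """Geometry of a WTLCC matrix: span N, stride S, rows K, lag columns J."""

    N: int = 1080
    S: int = 90
    K: int = 60
    J: int = PAPER_J
    min_valid_frac: float = 0.8
    paper_mode: bool = False

    def __post_init__(self) -> None:
        if not (self.N >= self.K >= 1):
            raise ValueError("need N >= K >= 1")
        if self.J % 2 != 0:
            raise ValueError("J must be even")
        if self.S < 1:
            raise ValueError("stride S must be >= 1")
        if self.N % self.K != 0:
            raise ValueError("N must be divisible by K (contiguous sub-windows)")
        if self.subwindow < 3:
            raise ValueError("sub-window length N/K must be >= 3 min")
        if self.paper_mode and (
            self.N not in PAPER_N_SET or self.S not in PAPER_S_SET
            or self.K not in PAPER_K_SET or self.J != PAPER_J
        ):
            raise ValueError(
                f"paper mode restricts N to {PAPER_N_SET}, S to {PAPER_S_SET}, "
                f"K to {PAPER_K_SET}, J = {PAPER_J}"
            )

    @property
    def subwindow(self) -> int:
        """Sub-window (row) length in minutes: w = N/K."""
        return self.N // self.K

    def lags(self) -> np.ndarray:
        """Lag (min) of every column, j - J/2."""
        return np.arange(self.J) - self.J // 2


@dataclass
class WTLCCMatrix:
    """K x J lagged-correlation matrix with provenance; NaN marks missing."""

    values: np.ndarray
    patient_id: str
    window_start: int
    params: WTLCCParams
    pair: Tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.params.K, self.params.J):
            raise ValueError("matrix shape must be (K, J)")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def missing_frac(self) -> float:
        return float(np.mean(~np.isfinite(self.values)))


def column_lag(j: int, J: int) -> int:
    """Lag in minutes of column ``j``: j - J/2 (J=240 spans -120..+119)."""
    if not 0 <= j < J:
        raise ValueError(f"column index {j} out of range [0, {J})")
    return j - J // 2


def build_matrix(
    I1: MinuteSeries,
    I2: MinuteSeries,
    start: int,
    params: WTLCCParams,
    patient_id: str = "",
    pair: Tuple[str, str] = ("I1", "I2"),
) -> WTLCCMatrix:
    """Compute one K x J WTLCC matrix for the window starting at ``start`` min.

    Entry (k, j) is the Pearson correlation over valid pairs between
    I1 on sub-window k and I2 shifted by ``column_lag(j, J)`` minutes.
    Entries with fewer than ``min_valid_frac * w`` valid pairs (or < 3), or
    with zero variance in either slice, are NaN.
    """
    if len(I1) != len(I2):
        raise ValueError("series must share length")
    T = len(I1)
    w = params.subwindow
    half = params.J // 2
    if start < 0 or start + params.N > T:
        raise ValueError("analysis window exceeds the panel")

    x_all = I1.masked()
    # pad I2 with NaN so lagged windows index safely: index i+lag -> pad[i+lag+half]
    y_pad = np.full(T + 2 * half, np.nan)
    y_pad[half:half + T] = I2.masked()

    min_pairs = max(3, int(np.ceil(params.min_valid_frac * w)))
    out = np.full((params.K, params.J), np.nan)
    from numpy.lib.stride_tricks import sliding_window_view

    for k in range(params.K):
        lo = start + k * w
        x = x_all[lo:lo + w]
        # windows for all J lags at once: segment [lo-half, lo+half+w) of y_pad
        seg = y_pad[lo:lo + w + 2 * half]          # offset: seg[i] = I2[lo - half + i]
        Y = sliding_window_view(seg, w)[: params.J]  # row j <-> lag j - half
        V = np.isfinite(x)[None, :] & np.isfinite(Y)
        n = V.sum(axis=1)
        ok = n >= min_pairs
        if not ok.any():
            continue
        xs = np.where(V, x[None, :], 0.0)
        ys = np.where(V, Y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(n > 0, n, 1)
            mx = xs.sum(axis=1) / nn
            my = ys.sum(axis=1) / nn
            cov = (xs * ys).sum(axis=1) / nn - mx * my
            vx = (xs * xs).sum(axis=1) / nn - mx * mx
            vy = (ys * ys).sum(axis=1) / nn - my * my
            r = cov / np.sqrt(vx * vy)
        ok &= (vx > 1e-14) & (vy > 1e-14)
        row = np.where(ok, np.clip(r, -1.0, 1.0), np.nan)
        out[k] = row
    return WTLCCMatrix(out, patient_id=patient_id, window_start=start,
                       params=params, pair=pair)


def extract_matrices(
    panel: MinutePanel,
    pair: Tuple[str, str],
    params: WTLCCParams,
    max_missing_frac: float = 0.5,
) -> List[WTLCCMatrix]:
    """All WTLCC matrices of a patient: window starts 0, S, 2S, ...

    For a gap-free panel of length T this yields floor((T - N)/S) + 1
    matrices. Matrices whose fraction of missing entries exceeds
    ``max_missing_frac`` are dropped with a logged reason; a panel shorter
    than N yields an empty list with a warning (cohort attrition).
    """
    T = panel.length
    if T < params.N:
        logger.warning(
            "panel %s shorter than N (%d < %d): no matrices",
            panel.patient_id, T, params.N,
        )
        return []
    I1, I2 = panel[pair[0]], panel[pair[1]]
    out = []
    for start in range(0, T - params.N + 1, params.S):
        m = build_matrix(I1, I2, start, params,
                         patient_id=panel.patient_id, pair=pair)
        if m.missing_frac > max_missing_frac:
            logger.info(
                "dropping matrix %s@%d: %.0f%% entries missing",
                panel.patient_id, start, 100 * m.missing_frac,
            )
            continue
        out.append(m)
    return out


# ----------------------------------------------------------------------------
# storage and rendering
# ----------------------------------------------------------------------------

def save_matrices_h5(path, matrices: List[WTLCCMatrix]) -> None:
    """Matrices as an HDF5 stack with per-matrix provenance attributes."""
    with h5py.File(path, "w") as f:
        g = f.create_group("matrices")
        for i, m in enumerate(matrices):
            d = g.create_dataset(str(i), data=m.values)
            d.attrs["patient_id"] = m.patient_id
            d.attrs["window_start"] = m.window_start
            d.attrs["pair"] = list(m.pair)
            for name in ("N", "S", "K", "J", "min_valid_frac"):
                d.attrs[name] = getattr(m.params, name)


def load_matrices_h5(path) -> List[WTLCCMatrix]:
    out = []
    with h5py.File(path, "r") as f:
        g = f["matrices"]
        for key in sorted(g, key=int):
            d = g[key]
            params = WTLCCParams(
                N=int(d.attrs["N"]), S=int(d.attrs["S"]), K=int(d.attrs["K"]),
                J=int(d.attrs["J"]), min_valid_frac=float(d.attrs["min_valid_frac"]),
            )
            pair = tuple(
                p.decode() if isinstance(p, bytes) else str(p) for p in d.attrs["pair"]
            )
            out.append(WTLCCMatrix(
                d[()], patient_id=str(d.attrs["patient_id"]),
                window_start=int(d.attrs["window_start"]), params=params, pair=pair,
            ))
    return out


def render_heatmap(matrix: WTLCCMatrix, path) -> None:
    """Render one matrix as a heatmap PNG (lag on x, sub-window on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    lags = matrix.params.lags()
    im = ax.imshow(
        matrix.values, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1,
        extent=[lags[0], lags[-1] + 1, matrix.params.K, 0],
    )
    ax.set_xlabel("lag [min]")
    ax.set_ylabel("sub-window")
    ax.set_title(f"{matrix.pair[0]} vs {matrix.pair[1]} @ {matrix.window_start} min")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
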