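"""Per-window features, electrode-grid mapping, and normalization.

The core feature is differential entropy (DE).  For a Gaussian variable the
differential entropy has the closed form

    h = 1/2 * ln(2 * pi * e * sigma^2)        [nats]

and a band-limited EEG window is well approximated as Gaussian, so the DE of
a 1-s band-filtered window is computed from its sample variance alone.  Two
alternate features are provided: the raw periodogram PSD (averaged over the
window) and the maximum Lyapunov exponent (Rosenstein-style estimate), the
latter mostly as a point of comparison — it is orders of magnitude slower.

Per-channel feature vectors are placed onto a 9x9 scalp grid (62 named cells,
19 structural zeros) so a 2-D convolutional classifier can exploit electrode
adjacency, and finally standardized over time per grid position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DEValue",
    "differential_entropy",
    "de_values",
    "psd_periodogram",
    "psd_feature",
    "EmbeddingSpec",
    "LyapunovResult",
    "max_lyapunov",
    "ElectrodeMap",
    "map_to_grid",
    "grid_to_vector",
    "compute_feature_tensor",
    "normalize_features",
    "VAR_FLOOR",
]

#: variance floor applied before the log; guards silent/constant channels
VAR_FLOOR = 1e-12

GRID_SIZE = 9


# ---------------------------------------------------------------------------
# differential entropy


@dataclass(frozen=True)
class DEValue:
    """Differential entropy of one window plus the moments it came from."""

    h: float
    sigma2: float
    mu: float
    floored: bool = False


def differential_entropy(window: np.ndarray, var_floor: float = VAR_FLOOR) -> DEValue:
    """Gaussian closed-form DE of a 1-D window, natural log (nats).

    The sample variance (maximum-likelihood, ddof=0) is floored at
    ``var_floor`` before the log; a floored value is flagged.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    mu = float(window.mean())
    sigma2 = float(window.var())
    floored = sigma2 < var_floor
    h = 0.5 * np.log(2 * np.pi * np.e * max(sigma2, var_floor))
    return DEValue(h=float(h), sigma2=sigma2, mu=mu, floored=floored)


def de_values(x: np.ndarray, axis: int = -1,
              var_floor: float = VAR_FLOOR) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized closed-form DE along ``axis``; returns (h, floored_mask)."""
    sigma2 = np.var(np.asarray(x, dtype=np.float64), axis=axis)
    floored = sigma2 < var_floor
    h = 0.5 * np.log(2 * np.pi * np.e * np.maximum(sigma2, var_floor))
    return h, floored


# ---------------------------------------------------------------------------
# periodogram PSD


def psd_periodogram(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided periodogram:  psd[f] = |DFT(x)[f]|^2 / (L * F).

    Returns (freqs, psd) over the full DFT frequency set, so that
    ``sum(psd) * fs`` equals the window's energy exactly (Parseval).
    """
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("window must be 1-D and non-empty")
    L = x.size
    X = np.fft.fft(x)
    psd = (X.real**2 + X.imag**2) / (L * fs)
    freqs = np.fft.fftfreq(L, d=1.0 / fs)
    return freqs, psd


def psd_feature(x: np.ndarray, fs: float, axis: int = -1) -> np.ndarray:
    """Window-average periodogram power along ``axis`` (the PSD analogue of
    the per-window DE scalar)."""
    x = np.asarray(x, dtype=np.float64)
    L = x.shape[axis]
    if L == 0:
        raise ValueError("empty window")
    X = np.fft.fft(x, axis=axis)
    return np.mean(np.abs(X) ** 2, axis=axis) / (L * fs)


# ---------------------------------------------------------------------------
# maximum Lyapunov exponent (Rosenstein-style)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters for the Lyapunov estimator.

    ``horizon`` is the number of steps the neighbour divergence is followed;
    ``theiler`` (None -> D * tau) excludes temporally close false neighbours.
    """

    D: int = 10
    tau: int = 4
    horizon: int = 10
    theiler: int | None = None

    def __post_init__(self) -> None:
        if self.D < 2 or self.tau < 1 or self.horizon < 1:
            raise ValueError("need D >= 2, tau >= 1, horizon >= 1")


@dataclass(frozen=True)
class LyapunovResult:
    lam: float            # divergence rate per step (least-squares slope)
    delta0: float         # mean initial neighbour separation
    delta_h: float        # mean separation at the horizon
    n_steps: int
    curve: np.ndarray     # mean log-divergence vs step


def max_lyapunov(series: np.ndarray, spec: EmbeddingSpec = EmbeddingSpec()) -> LyapunovResult:
    """Largest Lyapunov exponent from the mean log-divergence of nearest
    phase-space neighbours, followed for ``spec.horizon`` steps and fitted by
    least squares.  Positive for chaotic series, ~0 for periodic ones.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    theiler = spec.theiler if spec.theiler is not None else spec.D * spec.tau
    m = x.size - (spec.D - 1) * spec.tau  # embedded points
    if m - spec.horizon < theiler + 2:
        raise ValueError(
            f"series of length {x.size} too short for D={spec.D}, tau={spec.tau}, "
            f"horizon={spec.horizon}"
        )
    if x.std() == 0:
        raise ValueError("constant series has no phase-space neighbours")

    idx = np.arange(m)[:, None] + np.arange(spec.D)[None, :] * spec.tau
    emb = x[idx]  # (m, D)
    usable = m - spec.horizon  # trajectories must be followable to the horizon
    tree = cKDTree(emb[:usable])
    # enough candidates to step past the Theiler window
    k = min(usable, 2 * theiler + 4)
    dist, nbr = tree.query(emb[:usable], k=k)
    lag = np.abs(nbr - np.arange(usable)[:, None])
    dist = np.where(lag > theiler, dist, np.inf)
    pick = np.argmin(dist, axis=1)
    rows = np.arange(usable)
    nn = nbr[rows, pick]
    ok = np.isfinite(dist[rows, pick])
    if not np.any(ok):
        raise ValueError("no valid neighbours outside the Theiler window")
    rows, nn = rows[ok], nn[ok]

    steps = np.arange(spec.horizon + 1)
    # ||emb[j+k] - emb[nn+k]|| for every followed pair, all k at once
    diffs = emb[rows[:, None] + steps[None, :]] - emb[nn[:, None] + steps[None, :]]
    d = np.linalg.norm(diffs, axis=-1)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.maximum(d, 1e-300)), np.nan)
    curve = np.nanmean(logd, axis=0)
    valid = np.isfinite(curve)
    if valid.sum() < 2:
        raise ValueError("degenerate divergence curve (identical trajectories)")
    slope = np.polyfit(steps[valid], curve[valid], 1)[0]
    return LyapunovResult(
        lam=float(slope),
        delta0=float(np.exp(curve[0])) if np.isfinite(curve[0]) else 0.0,
        delta_h=float(np.exp(curve[-1])) if np.isfinite(curve[-1]) else 0.0,
        n_steps=spec.horizon,
        curve=curve,
    )


# ---------------------------------------------------------------------------
# electrode grid


class ElectrodeMap:
    """Placement of recording channels on a 9x9 scalp grid.

    The grid is data, not code: any placement of the recording's channels
    into the 81 cells is accepted, as long as names are unique.  Cells with
    no electrode stay exactly zero in mapped feature maps.
    """

    def __init__(self, grid: list[list[str | None]]):
        if len(grid) != GRID_SIZE or any(len(r) != GRID_SIZE for r in grid):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}")
        self.grid = [list(row) for row in grid]
        self.positions: dict[str, tuple[int, int]] = {}
        for r, row in enumerate(self.grid):
            for c, name in enumerate(row):
                if name is not None:
                    if name in self.positions:
                        raise ValueError(f"duplicate channel {name!r} in grid")
                    self.positions[name] = (r, c)
        #: canonical channel order = row-major traversal of the grid
        self.channel_names = [n for row in self.grid for n in row if n is not None]
        rc = np.array([self.positions[n] for n in self.channel_names])
        self._rows, self._cols = rc[:, 0], rc[:, 1]

    @property
    def n_named(self) -> int:
        return len(self.channel_names)

    @property
    def n_empty(self) -> int:
        return GRID_SIZE * GRID_SIZE - self.n_named

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeMap":
        payload = json.loads(Path(path).read_text())
        return cls(payload["grid"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"grid": self.grid}, indent=1))

    _default: "ElectrodeMap | None" = None

    @classmethod
    def default(cls) -> "ElectrodeMap":
        """The packaged 62-channel 10-20 extended layout."""
        if cls._default is None:
            ref = resources.files("eegid.data") / "electrode_map_9x9.json"
            cls._default = cls(json.loads(ref.read_text())["grid"])
        return cls._default


def map_to_grid(values: np.ndarray, emap: ElectrodeMap) -> np.ndarray:
    """Scatter per-channel values (..., n_named) onto the grid (..., 9, 9).

    Channel order follows ``emap.channel_names``; empty cells are exactly 0.
    """
    values = np.asarray(values)
    if values.shape[-1] != emap.n_named:
        raise ValueError(
            f"got {values.shape[-1]} channel values for a map with "
            f"{emap.n_named} named cells"
        )
    out = np.zeros(values.shape[:-1] + (GRID_SIZE, GRID_SIZE), dtype=values.dtype)
    out[..., emap._rows, emap._cols] = values
    return out


def grid_to_vector(grid_values: np.ndarray, emap: ElectrodeMap) -> np.ndarray:
    """Inverse of :func:`map_to_grid` on the named cells."""
    grid_values = np.asarray(grid_values)
    if grid_values.shape[-2:] != (GRID_SIZE, GRID_SIZE):
        raise ValueError("expected trailing 9x9 grid axes")
    return grid_values[..., emap._rows, emap._cols]


# ---------------------------------------------------------------------------
# feature tensors


def compute_feature_tensor(banded: np.ndarray, emap: ElectrodeMap,
                           feature: str = "de", fs: float = 200.0,
                           var_floor: float = VAR_FLOOR) -> np.ndarray:
    """(n_sub, n_bands, n_ch, window) -> (n_sub, n_bands, 9, 9) feature tensor.

    ``feature`` is "de" (differential entropy, nats) or "psd" (window-average
    periodogram power).
    """
    banded = np.asarray(banded)
    if banded.ndim != 4:
        raise ValueError("banded clip must be 4-D (sub-windows, bands, channels, samples)")
    if banded.shape[2] != emap.n_named:
        raise ValueError(
            f"clip has {banded.shape[2]} channels but map names {emap.n_named}"
        )
    if feature == "de":
        vals, _ = de_values(banded, axis=-1, var_floor=var_floor)
    elif feature == "psd":
        vals = psd_feature(banded, fs, axis=-1)
    else:
        raise ValueError(f"unknown feature {feature!r} (choose 'de' or 'psd')")
    return map_to_grid(vals, emap)


def normalize_features(tensors: np.ndarray, mode: str = "time",
                       emap: ElectrodeMap | None = None,
                       eps: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Standardize a clip sequence of feature tensors.

    ``tensors`` is (n_clips, n_sub, n_bands, 9, 9).  In the default "time"
    mode every (sub-window, band, grid-cell) position is standardized to mean
    0 / sd 1 across the clip axis; positions with zero spread (including the
    structural empty cells) are set to 0 and flagged.  The alternative
    "channel" mode standardizes across the named grid cells within each
    (clip, sub-window, band) slice instead and needs the electrode map.

    Returns (normalized, flagged) where ``flagged`` marks zero-spread
    positions.  Standardizing an already standardized sequence is a no-op.
    """
    x = np.asarray(tensors, dtype=np.float64)
    if x.ndim != 5:
        raise ValueError("expected (n_clips, n_sub, n_bands, 9, 9)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 clips to estimate spread")

    if mode == "time":
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        flagged = (sd <= eps)[0]
        out = np.where(sd > eps, (x - mu) / np.where(sd > eps, sd, 1.0), 0.0)
        return out, flagged
    if mode == "channel":
        if emap is None:
            raise ValueError("channel mode needs the electrode map")
        vec = grid_to_vector(x, emap)  # (n, sub, band, 62)
        mu = vec.mean(axis=-1, keepdims=True)
        sd = vec.std(axis=-1, keepdims=True)
        flat = (vec - mu) / np.where(sd > eps, sd, 1.0)
        flat = np.where(np.broadcast_to(sd > eps, flat.shape), flat, 0.0)
        flagged = np.broadcast_to((sd <= eps), flat.shape).copy()
        return map_to_grid(flat, emap), map_to_grid(flagged, emap).astype(bool)
    raise ValueError(f"unknown normalization mode {mode!r}")
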