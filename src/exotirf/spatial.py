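"""Spatial statistics of exocytic events.

Implements the random-placement Monte Carlo null model for consecutive
events: N events are placed i.i.d. uniform on the foreground of a
thresholded neuron image, given a random time order, and a fixed fraction
marked persistent; a replicate scores a success when some persistent event
has a strictly later event inside a small colocalization window (a
2x2-pixel block realizing "within 1 um^2").  For small foreground/event
counts the estimate can be checked against exhaustive enumeration, and for
small windows against the closed-form approximation
1 - (1 - w/M) ** n_pairs.

Also provides pairing of observed consecutive events and dual-channel
Pearson colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import colocalization_halfwidth_px

__all__ = [
    "ThresholdMask",
    "NullModelConfig",
    "NullModelResult",
    "threshold_image",
    "run_null_replicate",
    "estimate_probability",
    "observed_consecutive_fraction",
    "pearson_colocalization",
]


@dataclass
class ThresholdMask:
    """Binary image It(i,j) = 1 iff I(i,j) >= T."""

    it: np.ndarray
    T: float
    provenance: str = "unknown"

    @property
    def M(self) -> int:
        return int(self.it.sum())


@dataclass
class NullModelConfig:
    N: int = 40
    persistent_fraction: float = 0.10
    window_px: int = 2            # side of the colocalization block (2x2 = 4 px)
    replicates: int = 100_000
    exact_persistent_count: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.window_px < 1:
            raise ValueError("window must cover at least one pixel")


@dataclass
class NullModelResult:
    p_hat: float
    mc_se: float
    replicates: int
    config: NullModelConfig
    curve: pd.DataFrame | None = None   # p_hat as a function of N


def threshold_image(image: np.ndarray, T: float, provenance: str = "unknown") -> ThresholdMask:
    """Threshold rule It(i,j) = 1 iff I(i,j) >= T."""
    img = np.asarray(image)
    if not np.issubdtype(img.dtype, np.number) and img.dtype != bool:
        raise TypeError("image must be numeric")
    return ThresholdMask((img >= T), float(T), provenance)


def _window_hit(dx: np.ndarray, dy: np.ndarray, window_px: int) -> np.ndarray:
    """Membership of an offset in the s x s window anchored on the event.

    For side s the window covers offsets -floor(s/2) .. ceil(s/2)-1 in each
    axis, so s=1 is the same pixel and s=2 the 4-pixel block used as the
    1 um^2 realization.
    """
    lo = -(window_px // 2)
    hi = lo + window_px - 1
    return (dx >= lo) & (dx <= hi) & (dy >= lo) & (dy <= hi)


def _foreground_coords(mask) -> tuple[np.ndarray, np.ndarray]:
    it = mask.it if isinstance(mask, ThresholdMask) else np.asarray(mask, bool)
    ys, xs = np.nonzero(it)
    if xs.size == 0:
        raise ValueError("mask has no foreground pixels")
    return xs.astype(np.int64), ys.astype(np.int64)


def _n_persistent(cfg: NullModelConfig, rng: np.random.Generator) -> int:
    if cfg.exact_persistent_count:
        return int(round(cfg.persistent_fraction * cfg.N))
    return int(rng.binomial(cfg.N, cfg.persistent_fraction))


def run_null_replicate(
    mask: ThresholdMask | np.ndarray,
    config: NullModelConfig,
    rng: np.random.Generator,
) -> bool:
    """One replicate of the null model; reference scalar implementation.

    Events receive positions i.i.d. uniform on the foreground; the index
    order is the (uniformly random) time order; ``round(fraction * N)``
    events at uniformly random ranks are persistent.  Returns True iff a
    persistent event is followed (strictly later) by an event inside the
    window centered on it.
    """
    xs, ys = _foreground_coords(mask)
    N = config.N
    if N == 0:
        return False
    idx = rng.integers(0, xs.size, N)
    ex, ey = xs[idx], ys[idx]
    k = _n_persistent(config, rng)
    ranks = rng.choice(N, size=min(k, N), replace=False)
    for r in ranks:
        later = np.arange(r + 1, N)
        if later.size and _window_hit(
            ex[later] - ex[r], ey[later] - ey[r], config.window_px
        ).any():
            return True
    return False


def _batch_probability(
    xs: np.ndarray, ys: np.ndarray, cfg: NullModelConfig,
    replicates: int, rng: np.random.Generator,
) -> int:
    """Vectorized success count over a batch of replicates."""
    N = cfg.N
    if N == 0:
        return 0
    R = replicates
    idx = rng.integers(0, xs.size, (R, N))
    ex, ey = xs[idx], ys[idx]
    if cfg.exact_persistent_count:
        k = int(round(cfg.persistent_fraction * N))
        if k == 0:
            return 0
        ranks = np.argsort(rng.random((R, N)), axis=1)[:, :k]
    else:
        # Bernoulli labels: emulate via per-replicate counts on random ranks
        counts = rng.binomial(N, cfg.persistent_fraction, R)
        k = int(counts.max(initial=0))
        if k == 0:
            return 0
        ranks = np.argsort(rng.random((R, N)), axis=1)[:, :k]
        ranks = np.where(np.arange(k)[None, :] < counts[:, None], ranks, N)  # N = inactive
    rows = np.arange(R)
    success = np.zeros(R, dtype=bool)
    order = np.arange(N)
    for c in range(ranks.shape[1]):
        r = ranks[:, c]
        active = r < N
        rr = np.where(active, r, 0)
        px = ex[rows, rr][:, None]
        py = ey[rows, rr][:, None]
        later = order[None, :] > rr[:, None]
        hit = _window_hit(ex - px, ey - py, cfg.window_px) & later
        success |= active & hit.any(axis=1)
    return int(success.sum())


def estimate_probability(
    mask: ThresholdMask | np.ndarray,
    config: NullModelConfig,
    curve_n: list[int] | None = None,
    batch: int = 20_000,
) -> NullModelResult:
    """Monte Carlo estimate of the consecutive-event probability.

    ``curve_n`` optionally requests the probability-vs-N curve (each N
    evaluated with the same replicate count).
    """
    xs, ys = _foreground_coords(mask)
    rng = np.random.default_rng(config.seed)

    def run_for(n: int) -> float:
        cfg = NullModelConfig(
            N=n, persistent_fraction=config.persistent_fraction,
            window_px=config.window_px, replicates=config.replicates,
            exact_persistent_count=config.exact_persistent_count,
        )
        hits = 0
        done = 0
        while done < config.replicates:
            b = min(batch, config.replicates - done)
            hits += _batch_probability(xs, ys, cfg, b, rng)
            done += b
        return hits / config.replicates

    p_hat = run_for(config.N)
    mc_se = float(np.sqrt(p_hat * (1.0 - p_hat) / config.replicates))
    curve = None
    if curve_n is not None:
        curve = pd.DataFrame(
            {"N": list(curve_n), "p_hat": [run_for(n) for n in curve_n]}
        )
    return NullModelResult(float(p_hat), mc_se, config.replicates, config, curve)


def expected_pairs(N: int, persistent_fraction: float, exact: bool = True) -> float:
    """Expected number of (persistent, later event) pairs per replicate."""
    k = round(persistent_fraction * N) if exact else persistent_fraction * N
    return k * (N - 1) / 2.0


def analytic_approximation(M: int, N: int, persistent_fraction: float, window_px: int) -> float:
    """Closed-form approximation 1 - (1 - w/M)^n_pairs for small w/M."""
    w = window_px**2
    n_pairs = expected_pairs(N, persistent_fraction)
    return float(1.0 - (1.0 - w / M) ** n_pairs)


def observed_consecutive_fraction(
    events: pd.DataFrame,
    pixel_pitch_um: float,
    window_um2: float = 1.0,
    max_gap_s: float | None = None,
    persistent_labels: tuple[str, ...] = (
        "persistent", "biphasic_persistent", "kiss_and_run_pair_first",
    ),
    label_column: str | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of persistent events followed by a later event at the same site.

    ``events`` needs columns x_px, y_px, t_on_s and a class column (either
    ``label`` from the classifier or ``mech_class`` from the simulator).
    A pair requires the later event to start within ``max_gap_s`` (default:
    the rest of the movie) and within a square window of ``window_um2``
    centered on the persistent event.
    """
    col = label_column or ("label" if "label" in events.columns else "mech_class")
    x = events["x_px"].to_numpy(float)
    y = events["y_px"].to_numpy(float)
    t = events["t_on_s"].to_numpy(float)
    lab = events[col].astype(str).to_numpy()
    persistent_idx = np.nonzero(np.isin(lab, persistent_labels))[0]
    if persistent_idx.size == 0:
        return float("nan"), pd.DataFrame(columns=["first_index", "second_index", "gap_s"])

    halfwidth = colocalization_halfwidth_px(window_um2, pixel_pitch_um)
    pairs = []
    for i in persistent_idx:
        later = (t > t[i]) if max_gap_s is None else ((t > t[i]) & (t <= t[i] + max_gap_s))
        close = (np.abs(x - x[i]) <= halfwidth) & (np.abs(y - y[i]) <= halfwidth)
        cand = np.nonzero(later & close)[0]
        if cand.size:
            j = cand[np.argmin(t[cand])]
            pairs.append({"first_index": int(i), "second_index": int(j),
                          "gap_s": float(t[j] - t[i])})
    frac = len(pairs) / persistent_idx.size
    return float(frac), pd.DataFrame(pairs)


def pearson_colocalization(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation over foreground pixels of max-intensity projections.

    3-D inputs (T, H, W) are reduced by maximum projection over time.
    Raises on zero variance in either channel.
    """
    a = np.asarray(channel_a, dtype=np.float64)
    b = np.asarray(channel_b, dtype=np.float64)
    if a.ndim == 3:
        a = a.max(axis=0)
    if b.ndim == 3:
        b = b.max(axis=0)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 foreground pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance channel; Pearson undefined")
    return float(np.corrcoef(a, b)[0, 1])
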