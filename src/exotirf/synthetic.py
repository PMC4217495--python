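"""Mechanistic simulator of receptor-exocytosis TIRF movies.

The generator produces seeded dual-channel (SEP / mCherry, optional
clathrin) movies together with a ground-truth event table, so that event
detection, kinetic classification and the spatial statistics can all be
validated without any external data.

The vesicle state machine distinguishes three mechanistic classes:

``transient``
    Fusion pore opens and the whole cargo is released in one step; the
    fluorescent spot decays with the released-pool half-life (~2 s) as
    receptors diffuse away.

``persistent``
    The pore opens briefly and closes again with the cargo retained.
    Under control conditions the lumen reacidifies and the pH-sensitive
    SEP signal decays slowly (~17 s half-life).  Under bafilomycin the
    lumen stays neutral, producing a plateau that ends with a fast decay
    when the retained cargo is finally released.

``kiss_and_run_pair_first`` / ``..._second``
    A persistent event that releases a fraction of its cargo at the first
    opening and the remainder at a later reopening of the same pore — a
    consecutive event at the same site.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .config import CONDITION_MULTIPLIERS, SimulationConfig, VesicleKinetics

__all__ = [
    "GroundTruthEvent",
    "Movie",
    "generate_mask",
    "sample_events",
    "render_event_traces",
    "render_movie",
    "simulate_movie",
    "events_to_frame",
    "events_from_frame",
    "PERSISTENT_CLASSES",
]

PERSISTENT_CLASSES = frozenset({"persistent", "kiss_and_run_pair_first"})


@dataclass
class GroundTruthEvent:
    """One exocytic fusion event as generated by the simulator.

    Coordinates are 0-based with x rightward (column) and y downward
    (row); times are seconds from movie start.  ``t_release_s`` is the
    time of the final full release (None when the cargo is never released
    within the movie, as for control persistent events).
    """

    event_id: int
    x_px: int
    y_px: int
    t_on_s: float
    mech_class: str
    cargo_units: float
    pair_id: int | None = None
    t_release_s: float | None = None


@dataclass
class Movie:
    """Multi-channel fluorescence image time series.

    ``pixels`` has axis order (frame, row, column, channel).
    """

    pixels: np.ndarray
    frame_rate_hz: float
    pixel_pitch_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pixels.ndim == 3:
            self.pixels = self.pixels[..., None]
        if self.pixels.shape[-1] != len(self.channel_names):
            raise ValueError("channel_names does not match pixel array")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def channel(self, name: str = "SEP") -> np.ndarray:
        """Frames of one channel as a (T, H, W) view."""
        return self.pixels[..., self.channel_names.index(name)]


# ---------------------------------------------------------------------------
# Neuron mask
# ---------------------------------------------------------------------------

def _neuron_potential(
    width: int, height: int, rng: np.random.Generator, n_processes: int | None = None
) -> np.ndarray:
    """Scalar field whose level sets look like a soma with tapering processes."""
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    cx = width * rng.uniform(0.42, 0.58)
    cy = height * rng.uniform(0.42, 0.58)
    sigma_soma = 0.16 * min(width, height)
    pot = 1.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_soma**2))

    if n_processes is None:
        n_processes = int(rng.integers(2, 5))
    reach = 0.46 * min(width, height)
    for k in range(n_processes):
        theta = 2 * np.pi * (k + rng.uniform(-0.2, 0.2)) / n_processes
        x, y = cx, cy
        step = 2.0
        n_steps = int(reach / step)
        for i in range(n_steps):
            theta += rng.normal(0.0, 0.12)
            x += step * np.cos(theta)
            y += step * np.sin(theta)
            if not (0 <= x < width and 0 <= y < height):
                break
            frac = i / max(1, n_steps - 1)
            w = 5.0 * (1.0 - 0.8 * frac) + 0.8   # tapering ridge width (px)
            amp = 0.65 * (1.0 - 0.55 * frac)
            r2 = (xx - x) ** 2 + (yy - y) ** 2
            pot = np.maximum(pot, amp * np.exp(-r2 / (2 * w**2)))
    # deterministic tie-breaking noise
    pot *= 1.0 + 0.01 * rng.random(pot.shape)
    return pot


def _grow_region(
    potential: np.ndarray, target_px: int | None, level: float
) -> np.ndarray:
    """Greedy region growing from the potential maximum.

    Pixels are added in decreasing order of potential, restricted to the
    8-connected frontier of the current region, which guarantees a
    connected mask with an exact foreground count when ``target_px`` is
    given.
    """
    h, w = potential.shape
    mask = np.zeros((h, w), dtype=bool)
    start = np.unravel_index(int(np.argmax(potential)), potential.shape)
    heap: list[tuple[float, int, int]] = [(-potential[start], start[0], start[1])]
    queued = np.zeros_like(mask)
    queued[start] = True
    count = 0
    limit = target_px if target_px is not None else potential.size
    while heap and count < limit:
        negp, i, j = heapq.heappop(heap)
        if target_px is None and -negp < level:
            break
        mask[i, j] = True
        count += 1
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < h and 0 <= jj < w and not queued[ii, jj]:
                    queued[ii, jj] = True
                    heapq.heappush(heap, (-potential[ii, jj], ii, jj))
    if target_px is not None and count < target_px:
        raise ValueError(
            f"mask request of {target_px} px exceeds the available area"
        )
    return mask


def generate_mask(
    mask_spec: Any,
    width_px: int,
    height_px: int,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Binary neuron footprint used as the support of event placement.

    ``mask_spec`` may be ``"full"`` (whole frame), ``"neuron"`` (soma blob
    plus 2–4 tapering processes), a dict like
    ``{"kind": "neuron", "target_px": 15318, "n_processes": 3}`` requesting
    an exact foreground pixel count, a path to an image file, or a boolean
    array.  The neuron mask keeps an 8-px margin from the frame border so
    analysis ROIs around events rarely clip.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("mask dimensions must be positive")
    if isinstance(mask_spec, np.ndarray):
        if mask_spec.shape != (height_px, width_px):
            raise ValueError("mask array shape mismatch")
        mask = mask_spec.astype(bool)
        if not mask.any():
            raise ValueError("zero-area mask")
        return mask
    if isinstance(mask_spec, (str, Path)) and str(mask_spec) not in ("full", "neuron"):
        import tifffile

        arr = tifffile.imread(str(mask_spec))
        return generate_mask(np.asarray(arr) > 0, width_px, height_px, seed)

    spec: dict[str, Any]
    if isinstance(mask_spec, dict):
        spec = dict(mask_spec)
    else:
        spec = {"kind": str(mask_spec)}
    kind = spec.get("kind", "neuron")
    if kind == "full":
        return np.ones((height_px, width_px), dtype=bool)
    if kind != "neuron":
        raise ValueError(f"unknown mask_spec kind {kind!r}")

    target = spec.get("target_px")
    margin = int(spec.get("margin_px", 8))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pot = _neuron_potential(width_px, height_px, rng, spec.get("n_processes"))
    if margin > 0:
        pot[:margin, :] = 0.0
        pot[-margin:, :] = 0.0
        pot[:, :margin] = 0.0
        pot[:, -margin:] = 0.0
    if target is not None and target <= 0:
        raise ValueError("zero-area mask requested")
    mask = _grow_region(pot, target, level=float(spec.get("level", 0.12)))
    if not mask.any():
        raise ValueError("zero-area mask")
    return mask


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------

def _sample_dwell(rng: np.random.Generator, mean_s: float) -> float:
    """Clustered dwell / pore-reopen gap: > 4 s with exponential tail."""
    return 4.0 + rng.exponential(max(0.5, mean_s - 4.0))


def sample_events(
    config: SimulationConfig,
    mask: np.ndarray,
    seed: int | np.random.Generator | None = None,
    kinetics: VesicleKinetics | None = None,
) -> list[GroundTruthEvent]:
    """Draw ground-truth events for one movie.

    Event count is Poisson(``n_events``) unless ``n_events_exact``;
    positions are i.i.d. uniform on the mask foreground; each event is
    persistent with the condition-adjusted persistent fraction, and each
    persistent event spawns a consecutive partner at the same site with
    probability ``consecutive_fraction`` provided the reopening fits in
    the movie.
    """
    if not mask.any():
        raise ValueError("mask has no foreground")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    kin = (kinetics or VesicleKinetics()).for_condition(config.condition)

    lam = config.n_events_effective
    n = int(round(lam)) if config.n_events_exact else int(rng.poisson(lam))
    p_persistent = config.persistent_fraction_effective
    warn_no_pairs = (
        p_persistent * lam < 1.0 and config.consecutive_fraction > 0 and lam > 0
    )
    if warn_no_pairs:
        warnings.warn(
            "expected persistent count < 1; consecutive pairs disabled",
            stacklevel=2,
        )

    fg_y, fg_x = np.nonzero(mask)
    duration = config.duration_s
    t_min, t_max = 0.5, max(1.0, duration - 1.0)

    events: list[GroundTruthEvent] = []
    eid = 0
    pair_id = 0
    for _ in range(n):
        k = int(rng.integers(0, fg_x.size))
        x, y = int(fg_x[k]), int(fg_y[k])
        cargo = float(np.clip(rng.normal(config.cargo_mean, config.cargo_sd), 200.0, 900.0))
        persistent = rng.random() < p_persistent
        if not persistent:
            t_on = float(rng.uniform(t_min, t_max))
            events.append(
                GroundTruthEvent(eid, x, y, t_on, "transient", cargo, t_release_s=t_on)
            )
            eid += 1
            continue

        make_pair = (not warn_no_pairs) and rng.random() < config.consecutive_fraction
        if make_pair:
            delay = _sample_dwell(rng, kin.pore_reopen_delay_s)
            latest = duration - delay - 3.0
            if latest <= t_min:
                make_pair = False
        if make_pair:
            t_on = float(rng.uniform(t_min, latest))
            t2 = t_on + delay
            events.append(
                GroundTruthEvent(
                    eid, x, y, t_on, "kiss_and_run_pair_first", cargo,
                    pair_id=pair_id, t_release_s=t2,
                )
            )
            events.append(
                GroundTruthEvent(
                    eid + 1, x, y, t2, "kiss_and_run_pair_second", cargo,
                    pair_id=pair_id, t_release_s=t2,
                )
            )
            eid += 2
            pair_id += 1
        else:
            t_on = float(rng.uniform(t_min, t_max))
            t_rel = None
            if not kin.reacidification:
                # bafilomycin: the retained cargo is eventually fully released
                t_rel = t_on + _sample_dwell(rng, kin.persistence_dwell_s)
                if t_rel >= duration - 0.5:
                    t_rel = None  # release falls outside the movie
            events.append(
                GroundTruthEvent(eid, x, y, t_on, "persistent", cargo, t_release_s=t_rel)
            )
            eid += 1
    events.sort(key=lambda e: e.t_on_s)
    return events


def events_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    """Ground-truth table with the canonical CSV column order."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "pair_id": [e.pair_id for e in events],
            "x_px": [e.x_px for e in events],
            "y_px": [e.y_px for e in events],
            "t_on_s": [e.t_on_s for e in events],
            "mech_class": [e.mech_class for e in events],
            "cargo_units": [e.cargo_units for e in events],
            "t_release_s": [e.t_release_s for e in events],
        }
    )


def events_from_frame(df: pd.DataFrame) -> list[GroundTruthEvent]:
    out = []
    for row in df.itertuples(index=False):
        pid = row.pair_id
        pid = None if pid is None or (isinstance(pid, float) and np.isnan(pid)) else int(pid)
        trel = getattr(row, "t_release_s", None)
        if trel is not None and isinstance(trel, float) and np.isnan(trel):
            trel = None
        out.append(
            GroundTruthEvent(
                int(row.event_id), int(row.x_px), int(row.y_px), float(row.t_on_s),
                str(row.mech_class), float(row.cargo_units), pid, trel,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-event ideal traces
# ---------------------------------------------------------------------------

def _phi(ph: float, pka: float) -> float:
    """SEP fluorescence factor: Hill sigmoid of pH with unit slope."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def render_event_traces(
    event: GroundTruthEvent,
    kinetics: VesicleKinetics,
    frame_rate_hz: float,
    n_frames: int,
    channels: Sequence[str] = ("SEP", "mCherry"),
) -> dict[str, dict[str, np.ndarray]]:
    """Ideal (noise-free) spot and surround amplitude traces for one event.

    Returns ``{channel: {"spot": a, "surround": a}}`` plus bookkeeping
    arrays ``{"_vesicle": cargo in the vesicle, "_released_cum":
    cumulative released cargo}``.  The mCherry spot amplitude equals the
    vesicle content (pH independent, steps down only at release instants);
    the SEP spot amplitude is the vesicle content scaled by the pH sigmoid
    of the state machine plus the released pool decaying exponentially at
    the spot with the transient-release half-life.
    """
    t = np.arange(n_frames) / frame_rate_hz
    if not (0.0 <= event.t_on_s <= t[-1]):
        raise ValueError("event time outside the movie")
    kin = kinetics
    ln2 = np.log(2.0)
    phi_open = _phi(kin.ph_open, kin.sep_pka)
    phi_closed = _phi(kin.ph_closed, kin.sep_pka)
    cargo = event.cargo_units

    t_app = max(0.0, event.t_on_s - kin.appear_lead_s)
    t_on = event.t_on_s
    t_close = t_on + kin.pore_open_s

    vesicle = np.zeros(n_frames)
    phi_t = np.full(n_frames, phi_closed)
    released_cum = np.zeros(n_frames)
    pools: list[tuple[float, float]] = []  # (release time, amount)

    in_field = t >= t_app
    vesicle[in_field] = cargo

    def pore_open(lo: float, hi: float) -> None:
        phi_t[(t >= lo) & (t < hi)] = phi_open

    cls = event.mech_class
    if cls == "kiss_and_run_pair_second":
        # the full pair trace is rendered on the first event of the pair
        zero = np.zeros(n_frames)
        out: dict[str, Any] = {c: {"spot": zero.copy(), "surround": zero.copy()} for c in channels}
        out["_vesicle"] = zero.copy()
        out["_released_cum"] = zero.copy()
        return out

    if cls == "transient":
        pore_open(t_on, t_close)
        vesicle[t >= t_on] = 0.0
        released_cum[t >= t_on] = cargo
        pools.append((t_on, cargo))
    elif cls in ("persistent", "kiss_and_run_pair_first"):
        frac = kin.partial_release_fraction if cls == "kiss_and_run_pair_first" else 0.0
        t_reopen = event.t_release_s
        pore_open(t_on, t_close)
        if frac > 0:
            vesicle[t >= t_close] = cargo * (1.0 - frac)
            released_cum[t >= t_close] = cargo * frac
            pools.append((t_close, cargo * frac))
        retained = cargo * (1.0 - frac)
        if t_reopen is not None and t_reopen < t[-1]:
            t_reclose = t_reopen + kin.pore_open_s
            pore_open(t_reopen, t_reclose)
            vesicle[t >= t_reclose] = 0.0
            released_cum[t >= t_reclose] = cargo
            pools.append((t_reclose, retained))
            closed_hi = t_reopen
        else:
            closed_hi = np.inf
        closed = (t >= t_close) & (t < closed_hi)
        if kin.reacidification:
            decay = np.exp(-ln2 * (t[closed] - t_close) / kin.persistent_decay_halflife_s)
            phi_t[closed] = phi_closed + (phi_open - phi_closed) * decay
        else:
            phi_t[closed] = phi_open
        if np.isfinite(closed_hi):
            post = t >= t_reclose
            phi_t[post] = phi_closed  # empty vesicle; factor irrelevant
    else:
        raise ValueError(f"unknown mech_class {cls!r}")

    fast = kin.bafilomycin_fast_halflife_s if not kin.reacidification else kin.transient_release_halflife_s
    pool_spot = np.zeros(n_frames)
    for t0, amount in pools:
        sel = t >= t0
        pool_spot[sel] += amount * np.exp(-ln2 * (t[sel] - t0) / fast)

    sep_spot = vesicle * phi_t + pool_spot * phi_open
    mch_spot = vesicle.copy()
    # sustained surround offset from released receptors, slowly dispersing
    # over the rest of the cell
    surround = np.zeros(n_frames)
    for t0, amount in pools:
        sel = t >= t0
        surround[sel] += (
            kin.surround_gain * amount
            * np.exp(-ln2 * (t[sel] - t0) / kin.released_offset_halflife_s)
        )

    out = {}
    for c in channels:
        if c == "SEP":
            out[c] = {"spot": sep_spot, "surround": surround * phi_open}
        elif c == "mCherry":
            out[c] = {"spot": mch_spot, "surround": surround}
        else:
            out[c] = {"spot": np.zeros(n_frames), "surround": np.zeros(n_frames)}
    out["_vesicle"] = vesicle
    out["_released_cum"] = released_cum
    return out


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def _gaussian_patch(sigma: float, radius: int) -> tuple[np.ndarray, int]:
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    return g, radius


def _stamp(frames: np.ndarray, amp: np.ndarray, x: int, y: int, patch: np.ndarray, r: int) -> None:
    """Add ``amp[t] * patch`` centered at (x, y), clipping at frame borders."""
    h, w = frames.shape[1:]
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    sub = patch[y0 - (y - r): y1 - (y - r), x0 - (x - r): x1 - (x - r)]
    nz = np.nonzero(amp)[0]
    if nz.size == 0:
        return
    lo = nz[0]
    frames[lo:, y0:y1, x0:x1] += amp[lo:, None, None] * sub[None, :, :]


def render_movie(
    config: SimulationConfig,
    kinetics: VesicleKinetics | None,
    events: Sequence[GroundTruthEvent],
    seed: int | np.random.Generator | None = None,
    mask: np.ndarray | None = None,
) -> tuple[Movie, pd.DataFrame]:
    """Compose events into a noisy movie.

    Each event's spot trace is rendered as a Gaussian of ``psf_sigma_px``;
    the sustained released-pool offset as a 3x wider Gaussian.  A global
    multiplicative bleaching ramp removes ``bleach_fraction`` of all
    intensity (background included) by the last frame, then Poisson shot
    noise with gain ``poisson_gain`` and Gaussian read noise are applied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    kin = (kinetics or VesicleKinetics()).for_condition(config.condition)
    if mask is None:
        mask = generate_mask(config.mask_spec, config.width_px, config.height_px,
                             rng.integers(2**31))
    for e in events:
        if not mask[e.y_px, e.x_px]:
            raise ValueError(f"event {e.event_id} lies outside the mask")

    T = config.n_frames
    H, W = config.height_px, config.width_px
    chans = config.channels
    ideal = np.zeros((T, H, W, len(chans)), dtype=np.float64)
    ideal += config.background_level

    spot_patch, r_s = _gaussian_patch(config.psf_sigma_px, int(np.ceil(4 * config.psf_sigma_px)))
    wide_sigma = 3.0 * config.psf_sigma_px
    wide_patch, r_w = _gaussian_patch(wide_sigma, int(np.ceil(3 * wide_sigma)))

    pair_second = {e.pair_id: e for e in events if e.mech_class == "kiss_and_run_pair_second"}
    for e in events:
        if e.mech_class == "kiss_and_run_pair_second":
            continue
        traces = render_event_traces(e, kin, config.frame_rate_hz, T, channels=chans)
        for ci, c in enumerate(chans):
            if c == "CLC":
                continue
            _stamp(ideal[..., ci], traces[c]["spot"], e.x_px, e.y_px, spot_patch, r_s)
            _stamp(ideal[..., ci], traces[c]["surround"], e.x_px, e.y_px, wide_patch, r_w)

    if "CLC" in chans:
        _render_clathrin(ideal[..., chans.index("CLC")], mask, config, rng)

    if config.bleach_fraction > 0:
        ramp = (1.0 - config.bleach_fraction) ** (np.arange(T) / max(1, T - 1))
        ideal *= ramp[:, None, None, None]

    gain = config.poisson_gain
    noisy = gain * rng.poisson(ideal / gain).astype(np.float64)
    if config.read_noise_sd > 0:
        noisy += rng.normal(0.0, config.read_noise_sd, noisy.shape)
    np.clip(noisy, 0.0, None, out=noisy)

    movie = Movie(noisy.astype(np.float32), config.frame_rate_hz,
                  config.pixel_pitch_um, chans)
    return movie, events_to_frame(events)


def _render_clathrin(
    frames: np.ndarray, mask: np.ndarray, config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Transient 2x2-pixel endocytic puncta, spatially independent of events."""
    fg_y, fg_x = np.nonzero(mask)
    T = frames.shape[0]
    for _ in range(config.n_clathrin_puncta):
        k = int(rng.integers(0, fg_x.size))
        x, y = int(fg_x[k]), int(fg_y[k])
        t0 = int(rng.integers(0, max(1, T - 1)))
        dur = int(rng.integers(5, 20))  # 0.5-2 s at 10 Hz
        amp = 0.4 * config.cargo_mean * rng.uniform(0.5, 1.5)
        y1, x1 = min(y + 2, frames.shape[1]), min(x + 2, frames.shape[2])
        frames[t0: t0 + dur, y:y1, x:x1] += amp


def simulate_movie(
    config: SimulationConfig,
    kinetics: VesicleKinetics | None = None,
    seed: int | None = None,
) -> tuple[Movie, pd.DataFrame, np.ndarray]:
    """Convenience wrapper: mask -> events -> movie, all from one seed."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    mask_rng, ev_rng, noise_rng = root.spawn(3)
    mask = generate_mask(config.mask_spec, config.width_px, config.height_px, mask_rng)
    events = sample_events(config, mask, ev_rng, kinetics)
    movie, truth = render_movie(config, kinetics, events, noise_rng, mask=mask)
    return movie, truth, mask
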