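"""Synthetic colony-array experiments with known ground truth.

Each colony grows along a logistic trajectory in *effective time*:

    I(t) = K / (1 + exp(-r (tau(t) - t_mid))),   tau(t) = integral of m(s) ds

where the rate multiplier m(s) encodes the programmed phenotype: 1 during
normal growth, ``post_stall_rate_fraction`` after ``stall_time`` (stall
classes), and 0 during a treatment-induced pause (treated plates only).
This keeps every class curve analytic, so pipeline outputs can be checked
against closed-form expectations at zero noise.

Phenotype classes
-----------------
reference            population-typical growth; unaffected by treatment.
lag                  halved maximal rate, later midpoint: slow throughout.
stall                rate collapses to a fraction after ``stall_time``:
                     tracks the population early, then falls behind.
uvr_sensitive        reference growth, but treatment inserts a long pause.
uvr_resistant_stall  stall strain whose post-stall rate fraction RISES
                     under treatment (the stall weakens — the
                     mitochondrial-deficient behavior).

Replicates are modeled as whole-plate repeats: every strain occupies a
fixed grid position on each of ``n_replicates`` plates per condition.
Noise is multiplicative lognormal per timepoint plus a smooth low-order
polynomial multiplicative bias field per plate.  All randomness derives
from one seed; per-colony substreams are keyed by (condition, plate
replicate, row, col), so layouts can change without reshuffling everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .curves import FRAME_INTERVAL_MIN

__all__ = [
    "PhenotypeSpec",
    "SimConfig",
    "SimulatedExperiment",
    "DEFAULT_CLASSES",
    "simulate_curves",
    "class_curve",
    "render_plate_images",
    "ground_truth_eval",
    "LayoutError",
]

RESPONDER_CLASSES = frozenset({"uvr_sensitive", "uvr_resistant_stall"})


class LayoutError(ValueError):
    """Plate layout does not fit the image or colonies would overlap."""


@dataclass(frozen=True)
class PhenotypeSpec:
    """Growth parameters for one phenotype class.

    carrying_capacity is in summed-pixel-intensity units; max_rate in 1/min;
    times in minutes.  ``stall_time``/``post_stall_rate_fraction`` apply only
    to two-phase (stall) classes; ``pause_duration`` is the growth pause
    inserted after the treatment frame on treated plates;
    ``treated_post_stall_rate_fraction`` overrides the post-stall fraction
    under treatment (resistant-stall behavior).

    The stall fraction must be small enough that a stalled colony is close
    to its own plateau at the end of the time course: its endpoint-
    normalized curve then lies above the plate reference (positive
    lagVstall), the diauxic-arrest behavior the class emulates.
    """

    class_label: str
    carrying_capacity: float = 2.0e5
    max_rate: float = 0.006
    midpoint_time: float = 1500.0
    stall_time: float | None = None
    post_stall_rate_fraction: float = 1.0
    pause_duration: float = 0.0
    treated_post_stall_rate_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.max_rate <= 0 or self.carrying_capacity <= 0:
            raise ValueError("rates and carrying capacity must be positive")
        if not 0.0 <= self.post_stall_rate_fraction <= 1.0:
            raise ValueError("post_stall_rate_fraction must lie in [0, 1]")


DEFAULT_CLASSES: dict[str, PhenotypeSpec] = {
    "reference": PhenotypeSpec("reference"),
    "lag": PhenotypeSpec("lag", max_rate=0.003, midpoint_time=2000.0),
    "stall": PhenotypeSpec("stall", stall_time=1500.0, post_stall_rate_fraction=0.05),
    "uvr_sensitive": PhenotypeSpec("uvr_sensitive", pause_duration=600.0),
    "uvr_resistant_stall": PhenotypeSpec(
        "uvr_resistant_stall", stall_time=1500.0, post_stall_rate_fraction=0.05,
        treated_post_stall_rate_fraction=0.15,
    ),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults mirror the screening design the pipeline targets: 5-minute
    frames for 48 hr, treatment administered after frame 48 (4 hr),
    11 replicate plates per condition, and 5% of strains programmed as
    treatment responders.
    """

    n_strains: int = 1000
    n_replicates: int = 11
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "reference": 0.90,
        "lag": 0.025,
        "stall": 0.025,
        "uvr_sensitive": 0.025,
        "uvr_resistant_stall": 0.025,
    })
    n_rows: int = 32
    n_cols: int = 48
    frame_interval_min: float = FRAME_INTERVAL_MIN
    total_hours: float = 48.0
    treatment_frame: int = 48          # treatment right after this frame (1-based)
    gradient_amplitude: float = 0.10   # peak multiplicative spatial bias
    noise_sigma: float = 0.05          # lognormal per-timepoint sigma
    seed: int = 0
    classes: dict[str, PhenotypeSpec] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    fill_extra_positions: bool = True  # cycle strains into unused wells (extra replicates)

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        unknown = set(self.class_proportions) - set(self.classes)
        if unknown:
            raise ValueError(f"proportions name unknown classes: {sorted(unknown)}")
        if self.n_strains > self.n_rows * self.n_cols:
            raise ValueError("more strains than plate positions")

    @property
    def times(self) -> np.ndarray:
        n_frames = int(round(self.total_hours * 60.0 / self.frame_interval_min)) + 1
        return np.arange(n_frames) * self.frame_interval_min

    @property
    def treatment_time(self) -> float:
        return self.treatment_frame * self.frame_interval_min


@dataclass
class SimulatedExperiment:
    """Labeled output: per-colony metadata, noisy and true intensity series."""

    config: SimConfig
    meta: pd.DataFrame           # strain_id, plate_id, condition, replicate, row, col, class_label
    values: np.ndarray           # (n_colonies, n_times) noisy intensities
    times: np.ndarray
    truth: np.ndarray | None     # noiseless, bias-free intensities (same shape) if kept
    labels: pd.DataFrame         # strain_id, class_label, is_responder

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV layout (one row per colony per timepoint)."""
        n_c, n_t = self.values.shape
        rep = self.meta.loc[self.meta.index.repeat(n_t),
                            ["strain_id", "plate_id", "condition", "replicate"]]
        rep = rep.reset_index(drop=True)
        rep["time_min"] = np.tile(self.times, n_c)
        rep["intensity"] = self.values.ravel()
        return rep


def _effective_time(times: np.ndarray, *, stall_time: float | None, frac: float,
                    pause_start: float | None, pause_duration: float) -> np.ndarray:
    """tau(t) = integral of the rate multiplier m(s), computed analytically.

    m(s) is 1 during normal growth, ``frac`` after ``stall_time`` and 0
    inside the treatment pause window.
    """
    t = np.asarray(times, dtype=float)
    tau = np.zeros_like(t)
    # Breakpoints where the multiplier changes.
    events: list[tuple[float, float]] = []  # (start, multiplier from start)
    events.append((0.0, 1.0))
    if stall_time is not None:
        events.append((stall_time, frac))
    if pause_start is not None and pause_duration > 0:
        post = frac if (stall_time is not None and pause_start + pause_duration > stall_time) else 1.0
        events.append((pause_start, 0.0))
        events.append((pause_start + pause_duration, post))
        # A stall beginning inside the pause is overridden by the pause,
        # then resumes at the post-pause multiplier above.
        events = [e for e in events
                  if not (stall_time is not None
                          and pause_start <= e[0] < pause_start + pause_duration
                          and e[1] == frac)]
    events.sort(key=lambda e: e[0])
    # Piecewise-linear tau.
    starts = np.array([e[0] for e in events])
    mults = np.array([e[1] for e in events])
    tau_at = np.concatenate([[0.0], np.cumsum(mults[:-1] * np.diff(starts))])
    seg = np.searchsorted(starts, t, side="right") - 1
    tau = tau_at[seg] + mults[seg] * (t - starts[seg])
    return tau


def class_curve(spec: PhenotypeSpec, times: np.ndarray, *, treated: bool,
                treatment_time: float | None) -> np.ndarray:
    """Noiseless intensity trajectory of one phenotype class."""
    frac = spec.post_stall_rate_fraction
    if treated and spec.treated_post_stall_rate_fraction is not None:
        frac = spec.treated_post_stall_rate_fraction
    pause_start = treatment_time if (treated and spec.pause_duration > 0) else None
    tau = _effective_time(np.asarray(times, float), stall_time=spec.stall_time,
                          frac=frac, pause_start=pause_start,
                          pause_duration=spec.pause_duration)
    r, tm, cap = spec.max_rate, spec.midpoint_time, spec.carrying_capacity
    return cap / (1.0 + np.exp(-r * (tau - tm)))


def _assign_classes(config: SimConfig) -> list[str]:
    """Deterministic class labels: proportions realized by largest remainder."""
    items = sorted(config.class_proportions.items())
    counts = {k: int(math.floor(v * config.n_strains)) for k, v in items}
    short = config.n_strains - sum(counts.values())
    remainders = sorted(items, key=lambda kv: (-(kv[1] * config.n_strains % 1), kv[0]))
    for k, _ in remainders[:short]:
        counts[k] += 1
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(99,)))
    labels = [k for k, c in counts.items() for _ in range(c)]
    return list(rng.permutation(labels))


def _bias_field(config: SimConfig, cond_idx: int, rep: int) -> np.ndarray:
    """Smooth multiplicative plate bias: low-order polynomial in (row, col)."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1, cond_idx, rep)))
    r = (np.arange(config.n_rows) / max(config.n_rows - 1, 1) - 0.5)[:, None]
    c = (np.arange(config.n_cols) / max(config.n_cols - 1, 1) - 0.5)[None, :]
    a = rng.uniform(-1, 1, size=5)
    surf = a[0] * r + a[1] * c + a[2] * r * c + a[3] * (r ** 2 - 1 / 12) + a[4] * (c ** 2 - 1 / 12)
    peak = np.max(np.abs(surf))
    if peak > 0:
        surf = surf / peak * config.gradient_amplitude
    return 1.0 + surf


def simulate_curves(config: SimConfig, keep_truth: bool = False) -> SimulatedExperiment:
    """Generate the full labeled experiment (both conditions, all plates)."""
    times = config.times
    labels = _assign_classes(config)
    strains = [f"strain_{i:05d}" for i in range(config.n_strains)]

    # Fixed layout: strain i at position (i // n_cols, i % n_cols); spare
    # positions optionally cycle through strains again (extra replicates).
    n_positions = config.n_rows * config.n_cols
    occupancy = list(range(config.n_strains))
    if config.fill_extra_positions:
        occupancy += [i % config.n_strains for i in range(n_positions - config.n_strains)]
    positions = [(p // config.n_cols, p % config.n_cols) for p in range(len(occupancy))]

    # Noiseless class curves are shared; compute once per (class, condition).
    curve_cache: dict[tuple[str, bool], np.ndarray] = {}
    for label, spec in config.classes.items():
        for treated in (False, True):
            curve_cache[(label, treated)] = class_curve(
                spec, times, treated=treated, treatment_time=config.treatment_time)

    meta_rows = []
    chunks = []
    truth_chunks = [] if keep_truth else None
    for cond_idx, condition in enumerate(("untreated", "treated")):
        treated = condition == "treated"
        for rep in range(config.n_replicates):
            plate_id = f"{condition}_plate{rep:02d}"
            bias = _bias_field(config, cond_idx, rep)
            base = np.empty((len(occupancy), times.size))
            for k, strain_idx in enumerate(occupancy):
                base[k] = curve_cache[(labels[strain_idx], treated)]
            row_idx = np.array([p[0] for p in positions])
            col_idx = np.array([p[1] for p in positions])
            biased = base * bias[row_idx, col_idx][:, None]
            if config.noise_sigma > 0:
                noise = np.empty_like(biased)
                for k, (r_, c_) in enumerate(positions):
                    rng = np.random.default_rng(np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(2, cond_idx, rep, r_, c_)))
                    noise[k] = rng.standard_normal(times.size)
                noisy = biased * np.exp(config.noise_sigma * noise)
            else:
                noisy = biased
            chunks.append(noisy)
            if truth_chunks is not None:
                truth_chunks.append(base)
            for k, strain_idx in enumerate(occupancy):
                meta_rows.append((strains[strain_idx], plate_id, condition, rep,
                                  positions[k][0], positions[k][1], labels[strain_idx]))

    meta = pd.DataFrame(meta_rows, columns=["strain_id", "plate_id", "condition",
                                            "replicate", "row", "col", "class_label"])
    label_df = pd.DataFrame({
        "strain_id": strains,
        "class_label": labels,
        "is_responder": [l in RESPONDER_CLASSES for l in labels],
    })
    return SimulatedExperiment(
        config=config, meta=meta, values=np.vstack(chunks), times=times,
        truth=np.vstack(truth_chunks) if truth_chunks is not None else None,
        labels=label_df,
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_plate_images(
    intensities: np.ndarray,
    n_rows: int,
    n_cols: int,
    *,
    pitch_px: int = 12,
    margin_px: int = 12,
    blob_sigma: float = 2.5,
    blob_exponent: float = 8.0,
    background: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render per-frame plate images from programmed colony intensities.

    ``intensities`` is (n_colonies, n_frames) with colonies in row-major
    grid order.  Each colony is a radially symmetric blob with profile
    exp(-(r/blob_sigma)^blob_exponent), normalized so its summed pixel
    intensity equals the programmed intensity exactly (before background
    and noise).  The default high exponent gives the near-sharp edge of a
    real colony, so thresholding at half-max captures almost all of the
    blob's intensity.  Blob support is limited to the colony's own pitch
    cell; a ``blob_sigma`` too large for the pitch raises
    :class:`LayoutError`.
    """
    intensities = np.asarray(intensities, dtype=float)
    n_colonies, n_frames = intensities.shape
    if n_colonies != n_rows * n_cols:
        raise LayoutError(f"{n_colonies} colonies do not fill a {n_rows}x{n_cols} grid")
    radius = pitch_px // 2 - 1
    if radius < 1 or blob_sigma > radius / 2.0:
        raise LayoutError(
            f"blob_sigma {blob_sigma} overlaps neighbors at pitch {pitch_px}px")
    h = 2 * margin_px + (n_rows - 1) * pitch_px + 1
    w = 2 * margin_px + (n_cols - 1) * pitch_px + 1
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    rr = np.sqrt(yy ** 2 + xx ** 2)
    kernel = np.exp(-((rr / blob_sigma) ** blob_exponent))
    kernel /= kernel.sum()  # truncated and renormalized: blob sum is exact
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    frames = np.full((n_frames, h, w), float(background))
    for k in range(n_colonies):
        r, c = divmod(k, n_cols)
        cy = margin_px + r * pitch_px
        cx = margin_px + c * pitch_px
        sl = (slice(cy - radius, cy + radius + 1), slice(cx - radius, cx + radius + 1))
        frames[:, sl[0], sl[1]] += intensities[k][:, None, None] * kernel[None, :, :]
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    return np.clip(frames, 0.0, None)


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------

def ground_truth_eval(
    labels: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    nominated: Iterable[str] | None = None,
) -> dict[str, float]:
    """Score pipeline output against programmed phenotypes.

    With ``metrics`` (per-colony lag_v_stall values): sign accuracy of the
    per-strain median untreated lagVstall against lag (negative) / stall
    (positive) labels.  With ``nominated``: recall and empirical FDR of
    nomination against programmed responders.
    """
    out: dict[str, float] = {}
    lab = labels.set_index("strain_id")
    if metrics is not None:
        ut = metrics[(metrics["condition"] == "untreated") & metrics["lag_v_stall"].notna()]
        med = ut.groupby("strain_id")["lag_v_stall"].median()
        correct = total = 0
        for strain, value in med.items():
            cls = lab.loc[strain, "class_label"]
            expected = {"lag": -1, "stall": 1}.get(cls)
            if expected is None:
                continue
            total += 1
            correct += int(np.sign(value) == expected)
        out["sign_accuracy"] = correct / total if total else float("nan")
        out["n_lag_stall_strains"] = float(total)
    if nominated is not None:
        nominated = set(nominated)
        responders = set(lab.index[lab["is_responder"]])
        tp = len(nominated & responders)
        out["recall"] = tp / len(responders) if responders else float("nan")
        out["fdr"] = (len(nominated) - tp) / len(nominated) if nominated else 0.0
        out["n_nominated"] = float(len(nominated))
    return out
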