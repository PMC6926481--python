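"""Lighting paradigm generators.

Every paradigm used to probe circadian color responses is expressed as a
:class:`LightTimeline`: a uniform time grid (1-min default) of per-receptor
log10 photon fluxes plus a cone-opponent color coordinate and a block label
per sample. Paradigms include square light:dark cycles, constant light,
jet-lag shifts, chromatic and melanopsin/rod-modulation cycles, and
naturalistic days where intensity and color follow solar elevation through
twilight with stochastic cloud attenuation superimposed on intensity only.

Darkness is encoded with an explicit finite floor
(:data:`DARKNESS_LOG10_FLUX`) rather than -inf, so downstream log arithmetic
never silently produces invalid values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DARKNESS_LOG10_FLUX",
    "LightState",
    "LightTimeline",
    "TwilightModel",
    "CloudModel",
    "solar_elevation",
    "twilight_state",
    "cloud_attenuation",
    "make_ld_cycle",
    "make_constant",
    "make_jetlag",
    "make_color_cycle",
    "make_melrod_cycle",
    "make_colmel_cycle",
    "make_natural_block",
    "make_intensity_only_block",
    "make_constant_dim_epoch",
    "assemble_paradigm",
    "make_natural_paradigm",
    "default_blue_yellow_states",
    "default_melrod_states",
]

#: Sentinel log10 photon flux used for darkness. Chosen far below any
#: behaviorally relevant intensity; the simulator treats fluxes at or below
#: this floor as zero circadian drive.
DARKNESS_LOG10_FLUX = 5.0

RECEPTORS = ("S", "L", "mel", "rod")
STEP_MIN_DEFAULT = 1.0


@dataclass(frozen=True)
class LightState:
    """A single static light condition: per-receptor log10 flux + color."""

    log_S: float
    log_L: float
    log_mel: float
    log_rod: float
    color: float

    @classmethod
    def darkness(cls) -> "LightState":
        f = DARKNESS_LOG10_FLUX
        return cls(f, f, f, f, 0.0)

    @classmethod
    def from_design(cls, design) -> "LightState":
        """Build a state from a photometry StimulusDesign audit."""
        lg = design.fluxes.log10
        return cls(lg["S"], lg["L"], lg["mel"], lg["rod"], design.color)

    def shifted(self, dlog: float) -> "LightState":
        """Uniform intensity shift (log units); color unchanged."""
        return LightState(self.log_S + dlog, self.log_L + dlog,
                          self.log_mel + dlog, self.log_rod + dlog, self.color)

    def as_dict(self) -> dict[str, float]:
        return {"S": self.log_S, "L": self.log_L,
                "mel": self.log_mel, "rod": self.log_rod}


@dataclass
class LightTimeline:
    """Uniformly sampled light schedule.

    Attributes
    ----------
    time_min : ndarray
        Minutes since schedule start, uniform step.
    log_S, log_L, log_mel, log_rod : ndarray
        Per-receptor log10 photon flux series.
    color : ndarray
        Cone-opponent color coordinate series.
    labels : ndarray of str
        Block label per sample; labels partition the timeline.
    """

    time_min: np.ndarray
    log_S: np.ndarray
    log_L: np.ndarray
    log_mel: np.ndarray
    log_rod: np.ndarray
    color: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        n = len(self.time_min)
        for name in ("log_S", "log_L", "log_mel", "log_rod", "color", "labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        steps = np.diff(self.time_min)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time grid must be uniform and increasing")

    @property
    def step_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])

    @property
    def duration_min(self) -> float:
        return float(len(self.time_min) * self.step_min)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, f"log_{name}")

    def melrod_mean(self) -> np.ndarray:
        """Mean of melanopsin and rod log flux — the intensity channel."""
        return 0.5 * (self.log_mel + self.log_rod)


def _constant_block(n: int, step: float, state: LightState, label: str,
                    t0: float = 0.0) -> LightTimeline:
    ones = np.ones(n)
    return LightTimeline(
        time_min=t0 + step * np.arange(n),
        log_S=state.log_S * ones,
        log_L=state.log_L * ones,
        log_mel=state.log_mel * ones,
        log_rod=state.log_rod * ones,
        color=state.color * ones,
        labels=np.full(n, label, dtype=object),
    )


def _from_state_sequence(states, step: float, label: str) -> LightTimeline:
    """Timeline from an (n,) sequence of LightState-like channel arrays."""
    arrs = {k: np.asarray(v, dtype=float) for k, v in states.items()}
    n = len(arrs["log_mel"])
    return LightTimeline(
        time_min=step * np.arange(n),
        log_S=arrs["log_S"], log_L=arrs["log_L"],
        log_mel=arrs["log_mel"], log_rod=arrs["log_rod"],
        color=arrs["color"],
        labels=np.full(n, label, dtype=object),
    )


# ---------------------------------------------------------------------------
# Default stimulus states
# ---------------------------------------------------------------------------


def default_blue_yellow_states(
    melrod: float = 12.7, contrast: float = 1.2, mu: float = 13.0
) -> tuple[LightState, LightState]:
    """Equi-luminant blue/yellow pair as plain light states.

    Both states share melanopsin and rod log flux (``melrod``) and mean cone
    log-illuminance ``mu``; they differ only in the L:S ratio (total color
    separation ``2*contrast``). Use photometry.design_metamer_pair to obtain
    such states from actual primaries.
    """
    blue = LightState(mu + contrast / 2, mu - contrast / 2, melrod, melrod, -contrast)
    yellow = LightState(mu - contrast / 2, mu + contrast / 2, melrod, melrod, +contrast)
    return blue, yellow


def default_melrod_states(
    melrod_lo: float = 12.0, amplitude: float = 0.75, mu: float = 13.0,
    color: float = 0.0,
) -> tuple[LightState, LightState]:
    """Hi/lo states modulating melanopsin+rod only (cones and color fixed).

    The daily peak-trough excursion in melanopsin and rod log flux equals
    ``amplitude`` (0.75 log units by default) while cone illuminance and
    color are identical between phases — the "mel/rod" paradigm.
    """
    lo = LightState(mu - color / 2, mu + color / 2, melrod_lo, melrod_lo, color)
    hi = LightState(mu - color / 2, mu + color / 2,
                    melrod_lo + amplitude, melrod_lo + amplitude, color)
    return hi, lo


# ---------------------------------------------------------------------------
# Square-cycle paradigms
# ---------------------------------------------------------------------------


def _square_days(
    days: float,
    phase1: LightState,
    phase2: LightState,
    phase1_hours: float,
    step_min: float,
    label: str,
    onset_hour: float = 0.0,
) -> LightTimeline:
    """Repeating two-phase day: phase1 from onset_hour for phase1_hours."""
    n = int(round(days * 24 * 60 / step_min))
    t_h = (np.arange(n) * step_min / 60.0) % 24.0
    in1 = ((t_h - onset_hour) % 24.0) < phase1_hours
    chans = {}
    for name in ("log_S", "log_L", "log_mel", "log_rod", "color"):
        a, b = getattr(phase1, name), getattr(phase2, name)
        chans[name] = np.where(in1, a, b)
    return _from_state_sequence(chans, step_min, label)


def make_ld_cycle(
    days: float,
    day_state: LightState,
    night_state: LightState | None = None,
    photoperiod_h: float = 12.0,
    step_min: float = STEP_MIN_DEFAULT,
    lights_on_hour: float = 0.0,
    label: str = "LD",
) -> LightTimeline:
    """Square light:dark cycle; lights on at ``lights_on_hour`` each day."""
    night = night_state or LightState.darkness()
    return _square_days(days, day_state, night, photoperiod_h, step_min,
                        label, onset_hour=lights_on_hour)


def make_constant(
    days: float, state: LightState, step_min: float = STEP_MIN_DEFAULT,
    label: str = "LL",
) -> LightTimeline:
    """Constant illumination (or darkness) for ``days`` days."""
    n = int(round(days * 24 * 60 / step_min))
    return _constant_block(n, step_min, state, label)


def make_jetlag(
    pre_days: int,
    post_days: int,
    shift_hours: float,
    day_state: LightState,
    night_state: LightState | None = None,
    photoperiod_h: float = 12.0,
    step_min: float = STEP_MIN_DEFAULT,
) -> LightTimeline:
    """LD cycle with a single abrupt phase shift of the light onset.

    ``shift_hours`` > 0 delays lights-on (e.g. +6 for a 6-h delay),
    < 0 advances it. The shift is implemented as a one-off change in the
    lights-on hour at the start of ``post_days``, so the timeline contains
    exactly one discontinuity in light-onset phase.
    """
    if not (0 < abs(shift_hours) < 24):
        raise ValueError("shift must be a non-zero fraction of a day")
    pre = make_ld_cycle(pre_days, day_state, night_state, photoperiod_h,
                        step_min, lights_on_hour=0.0, label="LD_pre")
    post = make_ld_cycle(post_days, day_state, night_state, photoperiod_h,
                         step_min, lights_on_hour=shift_hours % 24.0,
                         label="LD_shifted")
    return assemble_paradigm([pre, post])


def _check_silencing(a: LightState, b: LightState, receptors, tol: float,
                     paradigm: str):
    for r in receptors:
        if r == "mu":
            va = 0.5 * (a.log_L + a.log_S)
            vb = 0.5 * (b.log_L + b.log_S)
        else:
            va, vb = a.as_dict()[r], b.as_dict()[r]
        if abs(va - vb) > tol:
            raise ValueError(
                f"{paradigm}: phases differ by {abs(va - vb):.3g} log units "
                f"on constrained channel {r!r} (tolerance {tol})"
            )


def make_color_cycle(
    days: float,
    blue: LightState,
    yellow: LightState,
    blue_first: bool = False,
    step_min: float = STEP_MIN_DEFAULT,
    silencing_tol: float = 0.01,
) -> LightTimeline:
    """12h:12h chromatic cycle with constant melanopsin, rod and mu(L,S).

    Raises ``ValueError`` naming the offending receptor if the supplied pair
    is not metameric for melanopsin/rods (or differs in cone illuminance)
    within ``silencing_tol`` log units.
    """
    _check_silencing(blue, yellow, ("mel", "rod", "mu"), silencing_tol,
                     "color cycle")
    first, second = (blue, yellow) if blue_first else (yellow, blue)
    lbl = "blue:yellow" if blue_first else "yellow:blue"
    return _square_days(days, first, second, 12.0, step_min, lbl)


def make_melrod_cycle(
    days: float,
    hi: LightState,
    lo: LightState,
    amplitude: float = 0.75,
    step_min: float = STEP_MIN_DEFAULT,
) -> LightTimeline:
    """12h:12h melanopsin/rod-only modulation; color and cones constant.

    The peak-trough excursion of both melanopsin and rod log flux must equal
    ``amplitude`` (default 0.75 log units) to 1e-6, and color and mu(L,S)
    must be identical between phases.
    """
    for r in ("mel", "rod"):
        exc = hi.as_dict()[r] - lo.as_dict()[r]
        if abs(exc - amplitude) > 1e-6:
            raise ValueError(
                f"mel/rod cycle: {r} excursion {exc:.6f} != {amplitude} log units"
            )
    _check_silencing(hi, lo, ("mu",), 1e-9, "mel/rod cycle")
    if abs(hi.color - lo.color) > 1e-9:
        raise ValueError("mel/rod cycle: color differs between phases")
    return _square_days(days, hi, lo, 12.0, step_min, "melrod")


def make_colmel_cycle(
    days: float,
    bright_yellow: LightState,
    dim_blue: LightState,
    amplitude: float = 0.75,
    step_min: float = STEP_MIN_DEFAULT,
) -> LightTimeline:
    """12h:12h cycle coupling a 0.75-log mel/rod modulation with color.

    The blue color is aligned with the dim phase, as in natural twilight.
    """
    for r in ("mel", "rod"):
        exc = bright_yellow.as_dict()[r] - dim_blue.as_dict()[r]
        if abs(exc - amplitude) > 1e-6:
            raise ValueError(
                f"col+mel cycle: {r} excursion {exc:.6f} != {amplitude} log units"
            )
    if bright_yellow.color <= dim_blue.color:
        raise ValueError("col+mel cycle: dim phase must be the bluer phase")
    return _square_days(days, bright_yellow, dim_blue, 12.0, step_min, "colmel")


# ---------------------------------------------------------------------------
# Twilight, clouds, naturalistic days
# ---------------------------------------------------------------------------


def solar_elevation(
    time_of_day_h: float | np.ndarray,
    photoperiod_h: float = 16.0,
    twilight_duration_min: float = 60.0,
    noon_hour: float = 12.0,
) -> float | np.ndarray:
    """Smooth daily solar-elevation proxy, degrees.

    A sinusoid in hour angle calibrated so that elevation crosses +6 deg at
    ``noon_hour +/- photoperiod/2`` and -4 deg ``twilight_duration`` later
    (civil-twilight-like descent). Symmetric about solar noon and periodic
    over 24 h; it crosses each of +6 and -4 deg exactly twice per day.
    """
    if not (0.0 < photoperiod_h < 24.0):
        raise ValueError("photoperiod must lie strictly between 0 and 24 h")
    dt = twilight_duration_min / 60.0
    if photoperiod_h + 2 * dt >= 24.0:
        raise ValueError("photoperiod plus twilights exceeds the day")
    # elevation = a + b cos(omega (t - noon)); two calibration conditions.
    w = 2.0 * np.pi / 24.0
    c1 = np.cos(w * photoperiod_h / 2.0)
    c2 = np.cos(w * (photoperiod_h / 2.0 + dt))
    b = (6.0 - (-4.0)) / (c1 - c2)
    a = 6.0 - b * c1
    t = np.asarray(time_of_day_h, dtype=float)
    out = a + b * np.cos(w * (t - noon_hour))
    return float(out) if np.isscalar(time_of_day_h) else out


@dataclass(frozen=True)
class TwilightModel:
    """Maps solar elevation to (log10 intensity, color coordinate).

    Between -4 and +6 degrees both maps are linear ramps; above +6 deg they
    clamp to the day plateau and below -4 deg to the night floor. Intensity
    is the melanopsin/rod channel; cone channels are placed symmetrically
    about the intensity trace at ``+/- color/2``.

    Parameters
    ----------
    day_log_intensity : float
        Plateau melanopsin/rod log10 flux during full day.
    intensity_slope : float
        Log units of intensity lost per degree of solar descent through
        twilight (default 0.25 log/deg -> 2.5 log units across the window).
    day_color, color_ramp : float
        Color coordinate at the day plateau and the total blue shift across
        the twilight window (color decreases — gets bluer — as the sun
        descends).
    """

    day_log_intensity: float = 13.5
    intensity_slope: float = 0.25
    day_color: float = 0.6
    color_ramp: float = 0.6
    elevation_hi: float = 6.0
    elevation_lo: float = -4.0

    @property
    def night_log_intensity(self) -> float:
        span = self.elevation_hi - self.elevation_lo
        return self.day_log_intensity - self.intensity_slope * span

    @property
    def night_color(self) -> float:
        return self.day_color - self.color_ramp


def twilight_state(
    elevation_deg: float | np.ndarray, model: TwilightModel
) -> tuple[np.ndarray, np.ndarray]:
    """Clear-sky (log10 intensity, color) at the given solar elevation."""
    e = np.clip(np.asarray(elevation_deg, dtype=float),
                model.elevation_lo, model.elevation_hi)
    drop = model.elevation_hi - e
    intensity = model.day_log_intensity - model.intensity_slope * drop
    span = model.elevation_hi - model.elevation_lo
    color = model.day_color - model.color_ramp * (drop / span)
    return intensity, color


@dataclass(frozen=True)
class CloudModel:
    """First-order autoregressive cloud attenuation on the log-flux scale.

    The latent process is a stationary AR(1) with mean ``mean`` and standard
    deviation ``scale`` whose autocorrelation decays as
    exp(-lag/correlation_time); attenuation is the latent reflected at zero
    and capped, so it is non-negative, bounded by ``cap``, and positively
    autocorrelated. Defaults give frequent >1 log-unit (>10-fold) dimming
    episodes over a few simulated days.
    """

    correlation_time_min: float = 30.0
    mean: float = 0.45
    scale: float = 0.28
    cap: float = 1.2

    def __post_init__(self):
        if self.correlation_time_min <= 0:
            raise ValueError("correlation time must be positive")
        if self.cap <= 0 or self.scale <= 0:
            raise ValueError("cap and scale must be positive")


def cloud_attenuation(
    duration_min: float,
    model: CloudModel,
    seed: int,
    step_min: float = STEP_MIN_DEFAULT,
) -> np.ndarray:
    """Simulate a log-attenuation series (log10 units, >= 0, <= cap).

    The same seed reproduces the same series; distinct day-seeds give
    distinct series, so no two simulated days share a cloud pattern.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_min / step_min))
    rho = float(np.exp(-step_min / model.correlation_time_min))
    x = np.empty(n)
    x[0] = model.mean + model.scale * rng.standard_normal()
    innov = model.scale * np.sqrt(1.0 - rho**2) * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = model.mean + rho * (x[i - 1] - model.mean) + innov[i - 1]
    return np.minimum(np.abs(x), model.cap)


def make_natural_block(
    days: int = 3,
    twilight: TwilightModel | None = None,
    clouds: CloudModel | None = None,
    seed: int = 0,
    photoperiod_h: float = 16.0,
    twilight_duration_min: float = 60.0,
    step_min: float = STEP_MIN_DEFAULT,
    label: str = "natural",
) -> LightTimeline:
    """Naturalistic days: twilight intensity+color cycle with clouds.

    Cloud attenuation is drawn independently per day (seed + day index) and
    subtracted from the intensity channels only — the twilight blue shift is
    retained whatever the cloud cover, as in the real sky.
    """
    twilight = twilight or TwilightModel()
    clouds = clouds or CloudModel()
    n_day = int(round(24 * 60 / step_min))
    t_h = (np.arange(n_day) * step_min) / 60.0
    elev = solar_elevation(t_h, photoperiod_h, twilight_duration_min)
    clear_I, color = twilight_state(elev, twilight)
    chans = {k: [] for k in ("log_S", "log_L", "log_mel", "log_rod", "color")}
    for d in range(days):
        att = cloud_attenuation(24 * 60, clouds, seed=seed + d, step_min=step_min)
        I = clear_I - att
        chans["log_mel"].append(I)
        chans["log_rod"].append(I)
        chans["log_L"].append(I + color / 2.0)
        chans["log_S"].append(I - color / 2.0)
        chans["color"].append(color)
    chans = {k: np.concatenate(v) for k, v in chans.items()}
    return _from_state_sequence(chans, step_min, label)


def make_intensity_only_block(
    natural: LightTimeline, day_color: float | None = None,
    label: str = "intensity_only",
) -> LightTimeline:
    """Control block: identical intensity trace, color pinned to day.

    The melanopsin, rod and mean-cone intensity series are copied bin-for-bin
    from the natural block; the color coordinate is held constant at
    ``day_color`` (default: the natural block's maximum, i.e. full day).
    """
    if day_color is None:
        day_color = float(natural.color.max())
    base = 0.5 * (natural.log_L + natural.log_S)
    return LightTimeline(
        time_min=natural.time_min.copy(),
        log_S=base - day_color / 2.0,
        log_L=base + day_color / 2.0,
        log_mel=natural.log_mel.copy(),
        log_rod=natural.log_rod.copy(),
        color=np.full(len(base), day_color),
        labels=np.full(len(base), label, dtype=object),
    )


def make_constant_dim_epoch(
    duration_h: float = 24.0,
    state: LightState | None = None,
    twilight: TwilightModel | None = None,
    step_min: float = STEP_MIN_DEFAULT,
    label: str = "dim",
) -> LightTimeline:
    """Constant dim illumination of intermediate color.

    The default state sits at the twilight model's night floor intensity
    with color midway between day and deep-twilight values.
    """
    if state is None:
        tw = twilight or TwilightModel()
        mid_color = tw.day_color - tw.color_ramp / 2.0
        I = tw.night_log_intensity
        state = LightState(I - mid_color / 2.0, I + mid_color / 2.0, I, I, mid_color)
    n = int(round(duration_h * 60 / step_min))
    return _constant_block(n, step_min, state, label)


def assemble_paradigm(blocks: list[LightTimeline]) -> LightTimeline:
    """Concatenate blocks onto one contiguous time grid, keeping labels."""
    if not blocks:
        raise ValueError("no blocks to assemble")
    step = blocks[0].step_min
    for b in blocks[1:]:
        if not np.isclose(b.step_min, step):
            raise ValueError(
                f"grid mismatch: {b.step_min} min vs {step} min step"
            )
    t0 = 0.0
    times, parts = [], {k: [] for k in
                        ("log_S", "log_L", "log_mel", "log_rod", "color", "labels")}
    for b in blocks:
        times.append(t0 + b.time_min - b.time_min[0])
        t0 = times[-1][-1] + step
        for k in parts:
            parts[k].append(getattr(b, k))
    return LightTimeline(
        time_min=np.concatenate(times),
        **{k: np.concatenate(v) for k, v in parts.items()},
    )


def make_natural_paradigm(
    seed: int = 0,
    epochs: int = 5,
    block_days: int = 3,
    baseline_days: int = 7,
    twilight: TwilightModel | None = None,
    clouds: CloudModel | None = None,
    photoperiod_h: float = 16.0,
    step_min: float = STEP_MIN_DEFAULT,
) -> LightTimeline:
    """Full natural-entrainment paradigm.

    A ``baseline_days`` clear-sky twilight cycle (16:8 by default, labelled
    ``baseline`` and excluded from analysis) entrains the animal first, then
    ``epochs`` interleaved repetitions of (3-day natural block, 24-h
    constant dim, matched 3-day intensity-only block, 24-h constant dim).
    Each intensity-only block copies its partner natural block's intensity
    trace bin-for-bin with color fixed at the day value, so the two
    conditions see exactly the same cloud realisations; interleaving keeps
    the paired comparison free of slow order effects across the recording.
    """
    twilight = twilight or TwilightModel()
    clouds = clouds or CloudModel()
    blocks: list[LightTimeline] = []
    if baseline_days:
        clear = CloudModel(correlation_time_min=clouds.correlation_time_min,
                           mean=0.0, scale=1e-12, cap=clouds.cap)
        blocks.append(make_natural_block(baseline_days, twilight, clear,
                                         seed=seed,
                                         photoperiod_h=photoperiod_h,
                                         step_min=step_min, label="baseline"))
    for e in range(epochs):
        nat = make_natural_block(block_days, twilight, clouds,
                                 seed=seed + 1000 * e,
                                 photoperiod_h=photoperiod_h,
                                 step_min=step_min, label=f"natural_{e}")
        blocks.append(nat)
        blocks.append(make_constant_dim_epoch(24.0, twilight=twilight,
                                              step_min=step_min,
                                              label=f"dim_natural_{e}"))
        blocks.append(make_intensity_only_block(nat,
                                                label=f"intensity_only_{e}"))
        blocks.append(make_constant_dim_epoch(24.0, twilight=twilight,
                                              step_min=step_min,
                                              label=f"dim_intensity_only_{e}"))
    return assemble_paradigm(blocks)
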