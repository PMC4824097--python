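"""Stochastic simulation of gated-scanner translocation and its ensemble assays.

A molecule enters the substrate at position 0 and translocates toward the far
end at ``v_pre``.  At each Chi position encountered in the scanning state it
forms a stalled encounter complex with probability ``p_pause``; the stall lasts
a gamma-distributed dwell (``pause_shape`` sequential steps of mean
``pause_scale``) and ends either in commitment to the Chi-modified state
(probability ``p_commit``; translocation resumes at ``v_post`` and further Chi
sequences are ignored) or in release back into the scanning state.
Independently, the scanner may isomerize spontaneously into the Chi-modified
state at hazard ``k_iso`` per second of pre-Chi translocation, and may detach
at hazard ``k_detach`` per second of translocation.

The same stochastic paths drive three ensemble observables: rendered
magnetic-tweezers traces, exonuclease-chase survival series, and stopped-flow
triplex-displacement transients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import EnzymeParams, SubstrateSpec


@dataclass(frozen=True)
class TraceConfig:
    """Acquisition settings for rendering a path into a bead trace.

    Defaults mirror the magnetic-tweezers instrument: 60 Hz camera sampling,
    3 Hz analysis bandwidth, 3 pN applied force.  ``noise_sd_bp`` is the
    Gaussian positional noise per raw sample; ``rise_per_bp_nm`` is metadata
    for converting bp to nm of bead height at the applied force.
    """

    sample_rate_hz: float = 60.0
    filter_rate_hz: float = 3.0
    noise_sd_bp: float = 30.0
    rise_per_bp_nm: float = 0.33
    force_pn: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > self.filter_rate_hz > 0:
            raise ValueError("require sample_rate_hz > filter_rate_hz > 0")
        if self.noise_sd_bp < 0:
            raise ValueError("noise_sd_bp must be >= 0")


@dataclass
class Path:
    """Noiseless piecewise-linear position-vs-time path of one molecule.

    ``times``/``positions`` are the vertices; pauses appear as horizontal
    segments.  ``events`` is the ground-truth log: pause records
    (start, duration, position, committed), the state switch (time, position,
    cause 'chi' or 'spontaneous'), and detachment, if any.
    """

    times: np.ndarray
    positions: np.ndarray
    events: dict

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def position_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.positions)

    def arrival_time_at(self, position_bp: float) -> float | None:
        """First time the path reaches ``position_bp``; None if never reached."""
        pos = self.positions
        idx = np.searchsorted(pos, position_bp, side="left")
        if idx >= len(pos):
            return None
        if idx == 0:
            return float(self.times[0])
        t0, t1 = self.times[idx - 1], self.times[idx]
        x0, x1 = pos[idx - 1], pos[idx]
        if x1 == x0:
            return float(t0)
        return float(t0 + (position_bp - x0) / (x1 - x0) * (t1 - t0))


@dataclass
class Trace:
    """Sampled position-vs-time record of one translocating molecule.

    ``events`` carries the generator's ground-truth log as hidden metadata so
    detector output can be validated against truth in tests; real traces read
    from disk may have an empty log.
    """

    time_s: np.ndarray
    position_bp: np.ndarray
    events: dict = field(default_factory=dict)
    variant: str = ""
    seed: int | None = None

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class ChaseSeries:
    """Chi-fragment survival time course under an exonuclease chase.

    ``fragment_fraction`` is the surviving Chi-fragment signal normalized to
    the pre-chase amount; its expectation is exp(-k_off_chi * t).
    """

    time_min: np.ndarray
    fragment_fraction: np.ndarray
    n_molecules: int
    dissociation_times_min: np.ndarray | None = None


@dataclass
class TriplexCurve:
    """Endpoint-normalized triplex-displacement fluorescence transient."""

    time_s: np.ndarray
    signal: np.ndarray
    n_chi: int
    triplex_distance_bp: float
    n_molecules: int = 0
    n_reported: int = 0
    n_committed: int = 0


def _rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def draw_pause_duration(params: EnzymeParams, rng_seed) -> float:
    """One stalled-encounter-complex dwell: gamma(pause_shape, pause_scale) s."""
    rng = _rng(rng_seed)
    return float(rng.gamma(params.pause_shape, params.pause_scale))


def simulate_path(
    params: EnzymeParams, substrate: SubstrateSpec, rng_seed
) -> Path:
    """Simulate one molecule's noiseless path from entry to exit.

    The path ends at detachment or at the far end of the substrate.  Events
    compete as exponential clocks in translocation time; pauses are inserted
    at Chi positions reached in the scanning state.
    """
    rng = _rng(rng_seed)
    times = [0.0]
    positions = [0.0]
    pauses: list[dict] = []
    switch: dict | None = None
    detach: dict | None = None

    t = 0.0
    x = 0.0
    v = params.v_pre
    state_pre = True
    rem_iso = rng.exponential(1.0 / params.k_iso) if params.k_iso > 0 else math.inf
    rem_det = rng.exponential(1.0 / params.k_detach) if params.k_detach > 0 else math.inf

    # Targets: Chi positions while scanning, then the substrate end.
    targets = list(substrate.chi_positions) + [substrate.length_bp]
    i = 0
    while i < len(targets):
        target = targets[i]
        if not state_pre:
            target = substrate.length_bp  # Chi list no longer consulted
        if target <= x:
            i += 1
            continue
        dt_move = (target - x) / v
        dt_iso = rem_iso if state_pre else math.inf
        step = min(dt_move, dt_iso, rem_det)

        if rem_det <= min(dt_move, dt_iso):
            t += rem_det
            x += v * rem_det
            times.append(t)
            positions.append(x)
            detach = {"time_s": t, "position_bp": x}
            break
        if state_pre and dt_iso < dt_move:
            t += dt_iso
            x += v * dt_iso
            rem_det -= dt_iso
            times.append(t)
            positions.append(x)
            state_pre = False
            v = params.v_post
            switch = {"time_s": t, "position_bp": x, "cause": "spontaneous"}
            continue

        # reached the target position
        t += dt_move
        x = target
        rem_det -= dt_move
        if state_pre:
            rem_iso -= dt_move
        times.append(t)
        positions.append(x)
        if x >= substrate.length_bp:
            break
        i += 1
        if state_pre and rng.random() < params.p_pause:
            dwell = float(rng.gamma(params.pause_shape, params.pause_scale))
            committed = rng.random() < params.p_commit
            pauses.append(
                {
                    "start_s": t,
                    "duration_s": dwell,
                    "position_bp": x,
                    "committed": committed,
                }
            )
            t += dwell
            times.append(t)
            positions.append(x)
            if committed:
                state_pre = False
                v = params.v_post
                switch = {"time_s": t, "position_bp": x, "cause": "chi"}

    events = {
        "pauses": pauses,
        "switch": switch,
        "detach": detach,
        "end_time_s": t,
        "end_position_bp": x,
        "variant": params.name,
    }
    return Path(np.asarray(times), np.asarray(positions), events)


def render_trace(path: Path, cfg: TraceConfig, variant: str = "") -> Trace:
    """Discretize a path at the camera rate and add Gaussian positional noise,
    emulating the optically detected bead height."""
    if len(path.times) < 2 or path.duration <= 0:
        raise ValueError("cannot render an empty path")
    n = math.ceil(path.duration * cfg.sample_rate_hz)
    t = np.arange(n) / cfg.sample_rate_hz
    pos = path.position_at(t)
    if cfg.noise_sd_bp > 0:
        rng = np.random.default_rng(cfg.seed)
        pos = pos + rng.normal(0.0, cfg.noise_sd_bp, size=n)
    return Trace(
        time_s=t,
        position_bp=pos,
        events=dict(path.events),
        variant=variant or path.events.get("variant", ""),
        seed=cfg.seed,
    )


def simulate_trace(
    params: EnzymeParams,
    substrate: SubstrateSpec,
    cfg: TraceConfig,
    rng_seed,
) -> Trace:
    """Convenience: simulate_path then render_trace with a derived noise seed."""
    rng = _rng(rng_seed)
    path_seed, noise_seed = rng.integers(0, 2**31 - 1, size=2)
    path = simulate_path(params, substrate, int(path_seed))
    cfg_seeded = TraceConfig(
        sample_rate_hz=cfg.sample_rate_hz,
        filter_rate_hz=cfg.filter_rate_hz,
        noise_sd_bp=cfg.noise_sd_bp,
        rise_per_bp_nm=cfg.rise_per_bp_nm,
        force_pn=cfg.force_pn,
        seed=int(noise_seed),
    )
    return render_trace(path, cfg_seeded, variant=params.name)


def simulate_trace_ensemble(
    params: EnzymeParams,
    substrate: SubstrateSpec,
    cfg: TraceConfig,
    n_traces: int,
    rng_seed,
    require_reach_bp: float | None = None,
    max_attempts_factor: int = 20,
) -> list[Trace]:
    """Simulate an ensemble of traces, optionally keeping only molecules that
    translocate past ``require_reach_bp``.

    Mirrors experimental practice: translocation traces used for at-Chi pause
    analysis are those that pass through the Chi locus; molecules detaching
    earlier are not scored.
    """
    rng = _rng(rng_seed)
    traces: list[Trace] = []
    attempts = 0
    limit = max_attempts_factor * n_traces
    while len(traces) < n_traces:
        if attempts >= limit:
            raise RuntimeError(
                "too few molecules reach the required position; "
                "check k_detach / require_reach_bp"
            )
        attempts += 1
        trace = simulate_trace(params, substrate, cfg, rng)
        if (
            require_reach_bp is not None
            and trace.events["end_position_bp"] < require_reach_bp
        ):
            continue
        traces.append(trace)
    return traces


def simulate_chase(
    params: EnzymeParams,
    timepoints_min,
    n_molecules: int,
    noise_cv: float = 0.0,
    rng_seed=0,
) -> ChaseSeries:
    """Simulate Chi-fragment survival under an exonuclease chase.

    Enzyme:Chi complexes dissociate after exponential waiting times with rate
    ``k_off_chi`` (per min).  Each timepoint is an independent quenched
    aliquot of ``n_molecules`` complexes (as in the gel assay, where every
    lane is a separate sample of the reaction), so its fragment fraction is
    the surviving share of its own molecules - binomial over ``n_molecules``
    - optionally scaled by multiplicative lognormal measurement noise of
    coefficient ``noise_cv`` (densitometry error).

    ``dissociation_times_min`` carries the first aliquot's per-molecule
    waiting times for single-molecule-level consumers.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    t = np.asarray(timepoints_min, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be non-negative and increasing")
    rng = _rng(rng_seed)
    if params.k_off_chi > 0:
        diss = rng.exponential(1.0 / params.k_off_chi, size=(len(t), n_molecules))
    else:
        diss = np.full((len(t), n_molecules), np.inf)
    frac = (diss > t[:, None]).mean(axis=1)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        frac = frac * rng.lognormal(-0.5 * sigma**2, sigma, size=len(t))
    frac = np.clip(frac, 0.0, 1.0)
    return ChaseSeries(
        time_min=t,
        fragment_fraction=frac,
        n_molecules=n_molecules,
        dissociation_times_min=diss[0],
    )


def simulate_triplex_curve(
    params: EnzymeParams,
    substrate: SubstrateSpec,
    n_molecules: int,
    displacement_rate: float,
    rng_seed=0,
    time_grid=None,
    n_points: int = 600,
) -> TriplexCurve:
    """Simulate an endpoint-normalized triplex-displacement transient.

    Each molecule's arrival time at the triplex is drawn via
    :func:`simulate_path`; displacement of the reporter then takes an
    additional exponential step of rate ``displacement_rate`` (per s).  The
    signal at time t is the fraction of displacement events completed by t,
    normalized over molecules that reach the triplex (molecules that detach
    earlier never contribute, mirroring endpoint normalization).
    """
    if substrate.triplex_pos is None:
        raise ValueError("substrate has no triplex position")
    if displacement_rate <= 0:
        raise ValueError("displacement_rate must be > 0")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = _rng(rng_seed)
    event_times = []
    n_committed = 0
    for _ in range(n_molecules):
        path = simulate_path(params, substrate, rng)
        arrival = path.arrival_time_at(substrate.triplex_pos)
        if arrival is None:
            continue
        if path.events["switch"] is not None:
            n_committed += 1
        event_times.append(arrival + rng.exponential(1.0 / displacement_rate))
    if not event_times:
        raise ValueError("no molecule reached the triplex")
    event_times = np.sort(np.asarray(event_times))
    if time_grid is None:
        t_max = 1.1 * event_times[-1]
        time_grid = np.linspace(0.0, t_max, n_points)
    else:
        time_grid = np.asarray(time_grid, dtype=float)
    signal = np.searchsorted(event_times, time_grid, side="right") / len(event_times)
    chi_before = [c for c in substrate.chi_positions if c < substrate.triplex_pos]
    return TriplexCurve(
        time_s=time_grid,
        signal=signal,
        n_chi=len(chi_before),
        triplex_distance_bp=float(substrate.triplex_pos),
        n_molecules=n_molecules,
        n_reported=len(event_times),
        n_committed=n_committed,
    )


def simulate_chi_yield(
    params: EnzymeParams, substrate: SubstrateSpec, n_molecules: int, rng_seed=0
) -> float:
    """Fraction of molecules that commit to the Chi-modified state at a Chi
    position on this substrate (the per-molecule Chi-fragment yield)."""
    if not substrate.chi_positions:
        raise ValueError("substrate has no Chi positions")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = _rng(rng_seed)
    n_commit = 0
    for _ in range(n_molecules):
        path = simulate_path(params, substrate, rng)
        switch = path.events["switch"]
        if switch is not None and switch["cause"] == "chi":
            n_commit += 1
    return n_commit / n_molecules
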