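"""Rate statistics over elongation traces.

The first ``burn_in`` elongation events of a run reflect the unrelaxed
initial random molecule placement and are discarded (1000 events by
default).  The specific elongation rate is the ordinary-least-squares
slope of cumulative step count over event time within the retained
window, normalised by the total ribosome count in the volume.
Replicate errors come from independent runs with derived seeds; slope
differences between two traces are compared with the classical z-score
for regression coefficients (two-sided Student-t p with
df = n1 + n2 - 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ScenarioConfig
from .sequences import CodonSequence
from .ssa import ElongationTrace, run_simulation

__all__ = [
    "RateEstimate",
    "EncounterStats",
    "encounter_stats",
    "elongation_rate",
    "replicate_rate",
    "compare_slopes",
    "spawn_seeds",
]


@dataclass(frozen=True)
class RateEstimate:
    """Ribosome-specific elongation rate in aa per ribosome per second."""

    rate: float
    se: float | None
    n_seeds: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rate < 0 or (self.se is not None and self.se < 0):
            raise ValueError("rate and se must be non-negative")


@dataclass(frozen=True)
class EncounterStats:
    """Moments of the encounter-time distribution t_enc (seconds)."""

    mean: float
    median: float
    sd: float
    n: int


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-run seeds derived from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _window(trace: ElongationTrace, burn_in: int) -> np.ndarray:
    if len(trace.times) <= burn_in + 1:
        raise ValueError(
            f"trace has {len(trace.times)} events; needs > {burn_in + 1} for burn-in {burn_in}"
        )
    return trace.times[burn_in:]


def encounter_stats(trace: ElongationTrace, burn_in: int = 1000) -> EncounterStats:
    """Mean/median/sd of successive event-time differences after burn-in."""
    dt = np.diff(_window(trace, burn_in))
    return EncounterStats(
        mean=float(dt.mean()), median=float(np.median(dt)), sd=float(dt.std(ddof=1)), n=len(dt)
    )


def elongation_rate(trace: ElongationTrace, burn_in: int = 1000) -> RateEstimate:
    """OLS slope of cumulative step count vs time, per ribosome (one seed)."""
    t = _window(trace, burn_in)
    counts = np.arange(burn_in + 1, burn_in + 1 + len(t), dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate trace: all events at a single time")
    slope = np.polyfit(t, counts, 1)[0]
    return RateEstimate(
        rate=float(slope / trace.n_ribosomes),
        se=None,
        n_seeds=1,
        window=(burn_in + 1, burn_in + len(t)),
    )


def rate_in_time_window(trace: ElongationTrace, t_start: float, t_end: float) -> RateEstimate:
    """OLS rate over an absolute simulated-time window (per ribosome).

    Event-count windows cover 8x less simulated time in an 8x larger
    volume; comparisons across volumes (intensivity checks) therefore
    use a fixed time window so both traces are equally relaxed.
    """
    sel = (trace.times >= t_start) & (trace.times <= t_end)
    idx = np.flatnonzero(sel)
    if len(idx) < 10:
        raise ValueError(f"only {len(idx)} events in time window [{t_start}, {t_end}]")
    t = trace.times[idx]
    counts = idx.astype(float) + 1.0
    slope = np.polyfit(t, counts, 1)[0]
    return RateEstimate(
        rate=float(slope / trace.n_ribosomes),
        se=None,
        n_seeds=1,
        window=(int(idx[0] + 1), int(idx[-1] + 1)),
    )


def timed_rate(
    config: ScenarioConfig,
    sequence: CodonSequence,
    seed: int,
    t_start: float,
    t_end: float,
) -> RateEstimate:
    """Single-seed specific rate over a fixed simulated-time window.

    The run is terminated at ``t_end``; the event buffer is bounded by
    the 24 aa/rib/s catalytic cap, so no stop-step choice is needed.
    """
    cap = int(np.ceil(24.0 * config.machines.ribosomes * t_end)) + 1000
    trace = run_simulation(config, sequence, seed=seed, stop_steps=cap, t_end=t_end)
    return rate_in_time_window(trace, t_start, t_end)


def replicate_timed_rate(
    config: ScenarioConfig,
    sequence: CodonSequence,
    t_start: float,
    t_end: float,
    n_seeds: int = 3,
    master_seed: int = 0,
) -> RateEstimate:
    """Mean/SE of time-windowed rates over replicates (SE None if 1 seed)."""
    rates = [
        timed_rate(config, sequence, s, t_start, t_end).rate
        for s in spawn_seeds(master_seed, n_seeds)
    ]
    arr = np.asarray(rates)
    return RateEstimate(
        rate=float(arr.mean()),
        se=float(arr.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else None,
        n_seeds=n_seeds,
        window=(0, 0),
    )


def replicate_rate(
    config: ScenarioConfig,
    sequence: CodonSequence,
    n_seeds: int = 10,
    master_seed: int = 0,
    burn_in: int | None = None,
    stop_steps: int | None = None,
) -> RateEstimate:
    """Mean and standard error of the specific rate over replicate runs."""
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2 for a replicate error")
    burn = config.kinetics.burn_in_steps if burn_in is None else burn_in
    rates = []
    for s in spawn_seeds(master_seed, n_seeds):
        try:
            trace = run_simulation(config, sequence, seed=s, stop_steps=stop_steps)
        except Exception as e:
            raise RuntimeError(f"replicate with seed {s} failed: {e}") from e
        est = elongation_rate(trace, burn_in=burn)
        rates.append(est.rate)
        window = est.window
    rates = np.asarray(rates)
    return RateEstimate(
        rate=float(rates.mean()),
        se=float(rates.std(ddof=1) / np.sqrt(n_seeds)),
        n_seeds=n_seeds,
        window=window,
    )


def compare_slopes(
    trace_a: ElongationTrace,
    trace_b: ElongationTrace,
    burn_in: int = 1000,
    window_end: int = 3000,
) -> tuple[float, int, float]:
    """z-score comparison of two overall elongation-time slopes.

    Fits count-vs-time OLS on events ``burn_in+1 .. window_end`` of each
    trace and returns ``z = (b1 - b2) / sqrt(SE1^2 + SE2^2)``, the
    degrees of freedom ``n1 + n2 - 4`` and the two-sided Student-t p.
    With the default window (events 1001-3000 of each trace) df = 3996.
    """
    out = []
    for tr in (trace_a, trace_b):
        if len(tr.times) < window_end:
            raise ValueError(f"trace has {len(tr.times)} events; window ends at {window_end}")
        t = tr.times[burn_in:window_end]
        y = np.arange(burn_in + 1, window_end + 1, dtype=float)
        res = stats.linregress(t, y)
        out.append((res.slope, res.stderr, len(t)))
    (b1, se1, n1), (b2, se2, n2) = out
    denom = np.hypot(se1, se2)
    z = 0.0 if b1 == b2 else float((b1 - b2) / denom)
    df = n1 + n2 - 4
    p = float(2.0 * stats.t.sf(abs(z), df))
    return z, df, p
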