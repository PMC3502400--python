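"""Trajectory observables: spikes, pauses, bursts, firing regimes.

The loop's behavioural classes over (stimulation current, initial ATP) are
``continuous`` firing, ``pause_then_fire`` (firing after an initial pause),
``bursting``, a mixed ``transition`` band, and ``resting`` (return to rest
after a pulse).  Classification is rule-based on the detected spike train;
the sustained-firing predicate behind the threshold-current search is
"spiking persists through the final 20% of the run".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import ScenarioConfig, TimeSeries, run_simulation
from .params import ModelParams

__all__ = [
    "SpikeTrain", "detect_spikes", "measure_initial_pause", "Burst",
    "detect_bursts", "classify_regime", "find_threshold_current",
    "regime_scan", "sustained_firing", "REGIME_LABELS",
]

REGIME_LABELS = ("continuous", "pause_then_fire", "bursting",
                 "transition", "resting")

#: default classifier constants
PAUSE_CUTOFF = 0.3       # s, first-spike delay separating continuous from pause
BURST_GAP = 0.25         # s, inter-spike gap that splits bursts
REFRACTORY = 0.002       # s, spike-detector refractory guard
#: detection threshold (mV); late-run action potentials ride a depolarized
#: baseline with reduced overshoot, so the threshold sits below 0 mV while
#: still clearing subthreshold oscillations by tens of mV
SPIKE_THRESHOLD = -15.0


@dataclass
class SpikeTrain:
    """Ordered spike times in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def rate(self, t0: float, t1: float) -> float:
        """Mean firing rate (Hz) in the window [t0, t1)."""
        n = int(np.count_nonzero((self.times >= t0) & (self.times < t1)))
        return n / (t1 - t0)


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY) -> SpikeTrain:
    """Upward threshold crossings of the membrane potential.

    A crossing is counted where v moves from below to at-or-above
    ``threshold`` (mV); crossings closer than ``refractory`` seconds to
    the previous one are ignored.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times = []
    last = -np.inf
    for i in up:
        # linear interpolation of the crossing instant
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(np.array(times))


def measure_initial_pause(spikes: SpikeTrain, stim_onset: float) -> float:
    """First spike time minus stimulus onset; ``inf`` for an empty train."""
    after = spikes.times[spikes.times >= stim_onset]
    if after.size == 0:
        return np.inf
    return float(after[0] - stim_onset)


@dataclass
class Burst:
    start: float
    end: float
    n_spikes: int

    @property
    def rate(self) -> float:
        """Intra-burst firing rate (Hz); single-spike bursts report 0."""
        if self.n_spikes < 2:
            return 0.0
        return (self.n_spikes - 1) / (self.end - self.start)


def detect_bursts(spikes: SpikeTrain, isi_gap: float = BURST_GAP
                  ) -> list[Burst]:
    """Partition a spike train into bursts separated by gaps > isi_gap."""
    if isi_gap <= REFRACTORY:
        raise ValueError("isi_gap must exceed the refractory period")
    if len(spikes) == 0:
        return []
    times = spikes.times
    breaks = np.flatnonzero(np.diff(times) > isi_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [times.size - 1]))
    return [Burst(start=times[a], end=times[b], n_spikes=b - a + 1)
            for a, b in zip(starts, ends)]


def sustained_firing(series: TimeSeries, tail_fraction: float = 0.2,
                     max_gap: float = 1.35) -> bool:
    """Does spiking persist *through* the final ``tail_fraction`` of the run?

    The tail window must be covered by spiking: no silent gap longer than
    ``max_gap`` seconds between consecutive spikes, the window start, and
    the window end.
    """
    spikes = detect_spikes(series.t, series.column("V_m"))
    t_tail = (1.0 - tail_fraction) * series.config.duration
    tail = spikes.times[spikes.times >= t_tail]
    if tail.size == 0:
        return False
    edges = np.concatenate(([t_tail], tail, [series.config.duration]))
    return bool(np.max(np.diff(edges)) <= max_gap)


def classify_regime(series: TimeSeries,
                    config: ScenarioConfig | None = None,
                    pause_cutoff: float = PAUSE_CUTOFF,
                    isi_gap: float = BURST_GAP) -> str:
    """Rule-based firing-regime label for a completed run.

    resting          no spikes, or (pulse stimulus) none after the pulse
    bursting         >= 2 brief spike volleys (median cluster shorter than
                     ``burst_max_len``) separated by quiescent gaps
    pause_then_fire  first spike delayed beyond ``pause_cutoff`` after
                     stimulus onset, then prolonged firing
    continuous       prompt firing in long clusters
    transition       anything mixed
    """
    config = config or series.config
    spikes = detect_spikes(series.t, series.column("V_m"))
    if len(spikes) == 0:
        return "resting"
    if config.stim_type == "pulse" and \
            not np.any(spikes.times > config.stim_end + 0.05):
        return "resting"

    burst_max_len = 2.0
    bursts = detect_bursts(spikes, isi_gap=isi_gap)
    pause = measure_initial_pause(spikes, config.onset)
    durations = np.array([b.end - b.start for b in bursts])
    if len(bursts) >= 2:
        span = bursts[-1].end - bursts[0].start
        active = float(durations.sum())
        quiescent = (span - active) / span if span > 0 else 0.0
        if np.median(durations) < burst_max_len and quiescent > 0.3:
            return "bursting"
        if pause > pause_cutoff:
            return "pause_then_fire"
        return "transition"
    return "pause_then_fire" if pause > pause_cutoff else "continuous"


def find_threshold_current(atp0: float = 20.0,
                           interval: tuple[float, float] = (0.03, 0.12),
                           tolerance: float = 0.0025,
                           duration: float = 30.0,
                           params: ModelParams | None = None,
                           seed: int = 0) -> float:
    """Smallest continuous stimulation current (mA/cm^2) that sustains
    firing over the full run, by bisection on the sustained-firing
    predicate.

    Raises ``ValueError`` if the interval does not bracket the
    transition.
    """
    lo, hi = interval

    def fires(amp: float) -> bool:
        cfg = ScenarioConfig(name="threshold-probe", stim_type="constant",
                             amplitude=amp, atp0=atp0, duration=duration,
                             seed=seed)
        return sustained_firing(run_simulation(cfg, params))

    f_lo, f_hi = fires(lo), fires(hi)
    if f_lo or not f_hi:
        raise ValueError(
            f"interval [{lo}, {hi}] mA/cm^2 does not bracket the "
            f"sustained-firing transition (fires: {f_lo}, {f_hi})")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class RegimeScan:
    """Tidy result of a (stimulation current x initial ATP) regime scan."""

    i_s: np.ndarray
    atp0: np.ndarray
    labels: np.ndarray            # (len(i_s), len(atp0)) object array
    failures: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"I_s": i, "ATP0": a, "label": self.labels[ii, aa]}
            for ii, i in enumerate(self.i_s)
            for aa, a in enumerate(self.atp0)
        ]
        return pd.DataFrame(rows)


def regime_scan(i_s_grid, atp0_grid, duration: float = 30.0,
                params: ModelParams | None = None, seed: int = 0
                ) -> RegimeScan:
    """Label every (I_s, ATP0) grid cell with its firing regime.

    Per-cell solver failures are recorded in ``failures`` and labelled
    ``"failed"`` rather than aborting the scan.
    """
    i_s_grid = np.asarray(i_s_grid, dtype=float)
    atp0_grid = np.asarray(atp0_grid, dtype=float)
    labels = np.empty((i_s_grid.size, atp0_grid.size), dtype=object)
    failures = []
    for ii, amp in enumerate(i_s_grid):
        for aa, atp0 in enumerate(atp0_grid):
            cfg = ScenarioConfig(name=f"scan-{amp:g}-{atp0:g}",
                                 stim_type="constant", amplitude=float(amp),
                                 atp0=float(atp0), duration=duration,
                                 seed=seed)
            try:
                labels[ii, aa] = classify_regime(run_simulation(cfg, params))
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                labels[ii, aa] = "failed"
                failures.append((float(amp), float(atp0), repr(exc)))
    return RegimeScan(i_s=i_s_grid, atp0=atp0_grid, labels=labels,
                      failures=failures)
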