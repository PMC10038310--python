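"""Synthetic recordings and survival cohorts with known ground truth.

No raw recordings ship with the package, so every stage is exercised on
generated data that reproduces the *statistical* structure of microchamber
recordings of arrested L1 larvae: alternating wake/sleep states, movement
speed that collapses during sleep, RIS calcium transients riding on a
constant baseline and coupled to quiescence onsets (or, for the constantly
depolarized strains, an elevated baseline with no transients), a wake-active
RIM channel with state-dependent peak rates, and binomially sampled
starvation-survival cohorts drawn from logistic survival curves.  The
generator is a pure function of (parameters, seed); ground truth is
returned alongside every trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SurvivalTable, Trace

__all__ = [
    "StrainPhenotype", "GroundTruth", "simulate_recording", "strain_panel",
    "simulate_survival_cohort", "simulate_image_stack",
]

#: arbitrary-unit fluorescence scale of the wild-type RIS baseline
BASELINE_AU = 100.0
#: mKate2 reference intensity (constant apart from noise and bleaching)
MKATE2_AU = 100.0
#: linear mKate2 bleach per 12 h of recording
BLEACH_PER_12H = 0.05
#: microchamber side length for the position random walk (micrometers)
CHAMBER_UM = 110.0


@dataclass(frozen=True)
class StrainPhenotype:
    """Generator parameters for one strain's behavior/calcium profile.

    Rates are events per hour; durations in seconds; speeds in um/s.
    ``coupled=True`` places one RIS transient at each sleep-bout onset
    (the wild-type regime where transients and quiescence coincide);
    ``coupled=False`` draws transients as an independent Poisson stream
    (rate ``transient_rate``), which with rate 0 yields the
    constant-baseline, transient-free profile of the strong-activation
    strain.
    """

    name: str
    ris_baseline_scale: float = 1.0
    transient_rate: float = 0.0
    transient_amplitude: float = 1.0
    sleep_bout_rate: float = 1.2
    mean_bout_duration: float = 1000.0
    wake_speed_mean: float = 2.0
    wake_speed_sd: float = 0.3
    sleep_speed_scale: float = 0.1
    rim_peak_rate_wake: float = 25.0
    rim_peak_rate_sleep: float = 2.0
    coupled: bool = True

    def validate(self) -> None:
        for name in ("transient_rate", "sleep_bout_rate", "rim_peak_rate_wake",
                     "rim_peak_rate_sleep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.sleep_speed_scale < 1.0:
            raise ValueError("sleep_speed_scale must lie in [0, 1)")
        if self.mean_bout_duration <= 0 or self.wake_speed_mean < 0 or self.wake_speed_sd < 0:
            raise ValueError("invalid phenotype magnitudes")
        if self.ris_baseline_scale <= 0 or self.transient_amplitude < 0:
            raise ValueError("baseline scale must be positive, amplitude >= 0")

    @property
    def stationary_sleep_fraction(self) -> float:
        """Long-run sleep occupancy of the alternating renewal process:
        rho / (1 + rho) with rho = bout rate x mean bout duration."""
        rho = (self.sleep_bout_rate / 3600.0) * self.mean_bout_duration
        return rho / (1.0 + rho)


@dataclass
class GroundTruth:
    """What the generator actually planted in one recording."""

    sleep_bouts: list[tuple[int, int]]
    transient_times: np.ndarray
    rim_peak_times: np.ndarray
    seed: int
    phenotype: StrainPhenotype

    @property
    def n_sleep_bouts(self) -> int:
        return len(self.sleep_bouts)

    def sleep_fraction(self, n_frames: int) -> float:
        return sum(e - s for s, e in self.sleep_bouts) / n_frames


def strain_panel() -> dict[str, StrainPhenotype]:
    """Six phenotype presets spanning the RIS activity dose-response.

    The strong-activation baseline fold-change (1.55 x wild type) is the one
    anchored magnitude; all other values are generator conventions chosen to
    reproduce the qualitative ordering of baseline activity, transients and
    sleep amount across the inactivation -> wild type -> activation series.
    """
    return {
        # strong inactivation: low baseline, no transients, near-zero sleep
        "twk18gf": StrainPhenotype(
            name="twk18gf", ris_baseline_scale=0.6, transient_amplitude=0.0,
            sleep_bout_rate=0.0, coupled=True, rim_peak_rate_wake=30.0),
        "egl23_strong": StrainPhenotype(
            name="egl23_strong", ris_baseline_scale=0.5, transient_amplitude=0.0,
            sleep_bout_rate=0.0, coupled=True, rim_peak_rate_wake=30.0),
        # weak inactivation: reduced transients and sleep
        "egl23_weak": StrainPhenotype(
            name="egl23_weak", ris_baseline_scale=0.8, transient_amplitude=0.7,
            sleep_bout_rate=0.5, mean_bout_duration=600.0),
        "wildtype": StrainPhenotype(name="wildtype"),
        # weak activation: elevated baseline, more transients / sleep
        "unc58_weak": StrainPhenotype(
            name="unc58_weak", ris_baseline_scale=1.2, transient_amplitude=1.2,
            sleep_bout_rate=2.0, mean_bout_duration=1200.0),
        # strong activation: 1.55x baseline, no transients, near-zero sleep,
        # elevated wake-circuit activity
        "unc58_strong": StrainPhenotype(
            name="unc58_strong", ris_baseline_scale=1.55, transient_amplitude=0.0,
            sleep_bout_rate=0.0, coupled=False, transient_rate=0.0,
            rim_peak_rate_wake=35.0),
    }


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def _simulate_states(rng: np.random.Generator, phen: StrainPhenotype,
                     duration: float) -> list[tuple[float, float]]:
    """Continuous-time sleep intervals of the alternating renewal process.

    Exponential dwells are memoryless, so drawing the initial state from the
    stationary occupancy and then alternating full exponential dwells yields
    an exactly stationary process (no start-of-recording bias).
    """
    if phen.sleep_bout_rate <= 0:
        return []
    wake_mean = 3600.0 / phen.sleep_bout_rate
    asleep = bool(rng.random() < phen.stationary_sleep_fraction)
    t = 0.0
    intervals = []
    while t < duration:
        dwell = rng.exponential(phen.mean_bout_duration if asleep else wake_mean)
        if asleep:
            intervals.append((t, min(t + dwell, duration)))
        t += dwell
        asleep = not asleep
    return intervals


def _transient_kernel(t_rel: np.ndarray, amplitude_au: float,
                      rise: float = 30.0, tau: float = 60.0) -> np.ndarray:
    """RIS activation transient: linear rise over ``rise`` s, then
    exponential decay with time constant ``tau``."""
    out = np.zeros_like(t_rel)
    up = (t_rel >= 0) & (t_rel < rise)
    out[up] = amplitude_au * t_rel[up] / rise
    down = t_rel >= rise
    out[down] = amplitude_au * np.exp(-(t_rel[down] - rise) / tau)
    return out


def simulate_recording(phenotype: StrainPhenotype, duration: float = 12 * 3600.0,
                       dt: float = 10.0, noise_sd: float = 0.05,
                       seed: int | None = None, animal_id: str = "sim0",
                       ) -> tuple[Trace, GroundTruth]:
    """Simulate one animal's recording plus its ground truth.

    ``noise_sd`` is the Gaussian measurement noise added to every channel,
    expressed as a fraction of that channel's characteristic scale (wake
    speed for the speed channel, the strain baseline for the fluorescence
    channels).  The per-channel random streams are split from the seed, so
    perturbing one channel's noise cannot shift another channel's draws.
    """
    phenotype.validate()
    if duration < 600.0:
        raise ValueError("duration must be at least 10 minutes")
    if seed is None:
        raise ValueError("seed is mandatory")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_state, rng_speed, rng_gcamp, rng_mkate2, rng_rim, rng_pos = \
        (np.random.default_rng(s) for s in streams)

    # --- wake/sleep states ---
    sleep_iv = _simulate_states(rng_state, phenotype, duration)
    asleep = np.zeros(n, dtype=bool)
    for t0, t1 in sleep_iv:
        asleep[int(np.ceil(t0 / dt)): int(np.ceil(t1 / dt))] = True
    sleep_bouts = [(s, e) for s, e in _bool_runs(asleep)]

    # --- speed ---
    base_speed = np.abs(rng_speed.normal(phenotype.wake_speed_mean,
                                         phenotype.wake_speed_sd, size=n))
    speed = np.where(asleep, phenotype.sleep_speed_scale * base_speed, base_speed)
    speed = np.abs(speed + rng_speed.normal(0.0, noise_sd * phenotype.wake_speed_mean, size=n))

    # --- RIS calcium ---
    base_au = BASELINE_AU * phenotype.ris_baseline_scale
    gcamp = np.full(n, base_au)
    if phenotype.coupled:
        onset_times = np.array([s * dt for s, _ in sleep_bouts])
    else:
        n_ev = rng_gcamp.poisson(phenotype.transient_rate * duration / 3600.0)
        onset_times = np.sort(rng_gcamp.uniform(0.0, duration, size=n_ev))
    if phenotype.transient_amplitude > 0:
        for t0 in onset_times:
            gcamp += _transient_kernel(t - t0, phenotype.transient_amplitude * base_au)
    gcamp = np.maximum(gcamp + rng_gcamp.normal(0.0, noise_sd * base_au, size=n), 0.0)

    # --- mKate2: constant, multiplicative noise, slow linear bleach ---
    bleach = 1.0 - BLEACH_PER_12H * t / (12 * 3600.0)
    mkate2 = MKATE2_AU * bleach * (1.0 + rng_mkate2.normal(0.0, 0.02, size=n))
    mkate2 = np.maximum(mkate2 + rng_mkate2.normal(0.0, noise_sd * MKATE2_AU, size=n), 1e-6)

    # --- RIM: baseline + peaks at Poisson times with state-dependent rate ---
    rate = np.where(asleep, phenotype.rim_peak_rate_sleep,
                    phenotype.rim_peak_rate_wake) / 3600.0  # events per second
    peak_mask = rng_rim.random(n) < rate * dt
    rim_peak_times = t[peak_mask]
    rim = np.ones(n)
    amps = rng_rim.uniform(0.4, 1.0, size=int(peak_mask.sum()))
    for t0, amp in zip(rim_peak_times, amps):
        rim += _rim_kernel(t - t0, amp, dt)
    rim += rng_rim.normal(0.0, noise_sd, size=n)

    # --- positions: random walk with speed-proportional steps, reflected ---
    theta = rng_pos.uniform(0.0, 2 * np.pi, size=n)
    steps = speed * dt
    x = _reflect(np.cumsum(steps * np.cos(theta)) + CHAMBER_UM / 2, 0.0, CHAMBER_UM)
    y = _reflect(np.cumsum(steps * np.sin(theta)) + CHAMBER_UM / 2, 0.0, CHAMBER_UM)

    trace = Trace(animal_id=animal_id, strain=phenotype.name, dt=dt, t=t,
                  x=x, y=y, gcamp=gcamp, mkate2=mkate2, speed=speed, rim=rim,
                  motion=None, valid=np.ones(n, dtype=bool))
    truth = GroundTruth(sleep_bouts=sleep_bouts, transient_times=onset_times,
                        rim_peak_times=rim_peak_times, seed=seed,
                        phenotype=phenotype)
    return trace, truth


def _rim_kernel(t_rel: np.ndarray, amplitude: float, dt: float) -> np.ndarray:
    """Short triangular calcium event (~3 frames wide) for the RIM channel."""
    width = 1.5 * dt
    out = np.maximum(0.0, 1.0 - np.abs(t_rel) / width)
    return amplitude * out


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    folded = np.mod(pos - lo, 2 * span)
    return lo + np.where(folded <= span, folded, 2 * span - folded)


def _bool_runs(mask: np.ndarray):
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    yield from zip(starts, ends)


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

def simulate_survival_cohort(A: float, t50: float, k: float, days,
                             n_per_day: int, seed: int | None = None,
                             strain: str = "sim", endpoint: str = "survival",
                             ) -> SurvivalTable:
    """Binomial sampling from a logistic survival curve.

    For each day, n_alive ~ Binomial(n_per_day, S(day)) with
    S(t) = A / (1 + exp(k (t - t50))).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    days = np.asarray(days, dtype=float)
    s = A / (1.0 + np.exp(k * (days - t50)))
    if np.any((s < 0) | (s > 1)):
        raise ValueError("survival probabilities fall outside [0, 1]")
    rng = np.random.default_rng(seed)
    alive = rng.binomial(n_per_day, s)
    return SurvivalTable(pd.DataFrame({
        "strain": strain, "day": days.astype(int), "n_alive": alive,
        "n_scored": n_per_day, "endpoint": endpoint,
    }))


# ---------------------------------------------------------------------------
# Image stacks (fixture generator for signal extraction)
# ---------------------------------------------------------------------------

def simulate_image_stack(n_frames: int, blob_trajectory: np.ndarray,
                         blob_intensity: float = 200.0, background: float = 10.0,
                         noise_sd: float = 1.0, seed: int | None = None,
                         shape: tuple[int, int] = (64, 64),
                         blob_sigma: float = 1.5,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Render a Gaussian blob moving along a trajectory over flat background.

    Returns ``(stack, true_centroids)`` where ``true_centroids`` is the
    (n_frames, 2) array of (x, y) positions actually rendered, usable as the
    oracle for ROI extraction and speed computation.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    traj = np.asarray(blob_trajectory, dtype=float)
    if traj.shape != (n_frames, 2):
        raise ValueError("blob_trajectory must be (n_frames, 2) of (x, y)")
    h, w = shape
    if np.any(traj[:, 0] < 0) or np.any(traj[:, 0] > w - 1) or \
       np.any(traj[:, 1] < 0) or np.any(traj[:, 1] > h - 1):
        raise ValueError("blob trajectory leaves the frame bounds")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.empty((n_frames, h, w))
    for i, (cx, cy) in enumerate(traj):
        blob = blob_intensity * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                       / (2 * blob_sigma ** 2))
        stack[i] = background + blob + rng.normal(0.0, noise_sd, size=(h, w))
    return stack, traj.copy()
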