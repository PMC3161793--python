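"""Seeded simulator of the audiovisual localization experiment.

Emulates a two-session protocol (acoustic and visual localization of a
primary stimulus, with an optional secondary stimulus in the other
modality): per subject and task, 450 trials = 75 unimodal + 75 spatially
coincident + 300 non-coincident bimodal, primary positions on a 5-deg grid
in [-10, 10] deg, secondary offsets in {0, +/-5, +/-10} deg.  Responses are
given with a rotating pointer starting from a 40-deg neutral stop.

The percept generator implements visual capture: in the acoustic task the
localization mean is shifted toward the secondary (visual) stimulus by a
subject-specific fusion weight ``w``; in the visual task the secondary
(acoustic) stimulus leaves the percept untouched (segregation).  Decision
times are log-normal with medians depending on task and mode of
presentation, plus an eccentricity penalty for the most eccentric
(+/-20 deg) secondary positions in the acoustic task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SENTINEL",
    "TASK_ACOUSTIC",
    "TASK_VISUAL",
    "PRIMARY_POSITIONS",
    "OFFSETS",
    "NEUTRAL_POSITION",
    "POINTER_RANGE",
    "SubjectProfile",
    "SimParams",
    "Trajectory",
    "build_design",
    "draw_subject_profile",
    "simulate_percept",
    "simulate_decision_time",
    "simulate_trajectory",
    "simulate_dataset",
    "write_trials",
    "read_trials",
]

#: Secondary-stimulus value encoding "no secondary stimulus" (unimodal trial).
SENTINEL: float = float("nan")

TASK_ACOUSTIC = 0
TASK_VISUAL = 1

PRIMARY_POSITIONS = (-10.0, -5.0, 0.0, 5.0, 10.0)
#: Secondary-stimulus offsets relative to the primary; 0 = coincident.
OFFSETS = (-10.0, -5.0, 0.0, 5.0, 10.0)
NON_COINCIDENT_OFFSETS = (-10.0, -5.0, 5.0, 10.0)

NEUTRAL_POSITION = 40.0  # deg, right stop of the pointer
POINTER_RANGE = (-40.0, 40.0)  # deg, physical limits of the pointer

#: Trial-table serialization token for the unimodal secondary stimulus.
NA_TOKEN = "NA_UNIMODAL"


def is_unimodal(xs) -> np.ndarray | bool:
    """True where the secondary stimulus is the unimodal sentinel."""
    return np.isnan(xs)


@dataclass
class SubjectProfile:
    """Latent per-subject parameters of the response generator.

    All position quantities are in degrees, time quantities on the
    log-seconds scale.  ``mu_logT[s][m]`` indexes task (0 acoustic,
    1 visual) then mode (0 unisensory, 1 bisensory).
    """

    bias: float
    sigma_a_uni: float
    sigma_a_bi: float
    sigma_v_uni: float
    sigma_v_bi: float
    w: float
    mu_logT: tuple  # ((a_uni, a_bi), (v_uni, v_bi)) in log-seconds
    delta_ecc: float
    sigma_logT: float
    subject_T_offset: float

    def __post_init__(self):
        for name in ("sigma_a_uni", "sigma_a_bi", "sigma_v_uni", "sigma_v_bi",
                     "sigma_logT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("fusion weight w must lie in [0, 1]")

    def percept_sigma(self, s: int, bimodal) -> np.ndarray:
        """Localization noise SD for task ``s`` and mode."""
        if s == TASK_ACOUSTIC:
            return np.where(bimodal, self.sigma_a_bi, self.sigma_a_uni)
        return np.where(bimodal, self.sigma_v_bi, self.sigma_v_uni)


# Default calibration.  The dispersion parameters reproduce the observed
# per-condition SDs of the emulated study (7.5 / 2.8 deg unisensory
# acoustic/visual, 5.8 deg acoustic coincident); the fusion weight solves
# w^2 * 62.5 + sigma_a_bi^2 = 9.5^2, with 62.5 the variance of the
# equiprobable non-coincident offsets, so that pooled non-coincident
# acoustic responses have a 9.5 deg SD.  Decision-time dispersions
# (sigma_logT, subject_T_offset_sd) are fixed by the cross-validated-R^2
# expectation oracle in :mod:`avpercept.evaluate`; see docs/methods.md.
_W_DEFAULT = float(np.sqrt((9.5**2 - 5.8**2) / 62.5))  # ~0.9517


@dataclass
class SimParams:
    """Population calibration and bookkeeping for a simulated dataset."""

    n_subjects: int = 10
    n_reps: int = 15
    seed: int = 0

    bias_sd: float = 3.0  # deg, between-subject sensorimotor offset SD

    sigma_a_uni: float = 7.5
    sigma_a_bi: float = 5.8
    sigma_v_uni: float = 2.8
    sigma_v_bi: float = 3.1
    sigma_jitter_sd: float = 0.3  # deg, between-subject jitter on each SD

    w: float = _W_DEFAULT
    w_sd: float = 0.02

    # log-seconds; orderings: acoustic > visual, unisensory > bisensory
    mu_logT_a_uni: float = float(np.log(0.95))
    mu_logT_a_bi: float = float(np.log(0.80))
    mu_logT_v_uni: float = float(np.log(0.75))
    mu_logT_v_bi: float = float(np.log(0.62))
    delta_ecc: float = 0.25       # log-s bump for |Xs| = 20 in the acoustic task
    delta_ecc_sd: float = 0.02
    sigma_logT: float = 0.417     # within-subject log-time SD (oracle-calibrated)
    sigma_logT_jitter_sd: float = 0.02
    subject_T_offset_sd: float = 0.01  # between-subject log-time offset SD

    # pointer kinematics (movement duration independent of condition)
    movement_duration_mean: float = 1.1   # s
    movement_duration_sd: float = 0.15    # s, lognormal on this scale
    sample_rate: float = 100.0            # Hz
    stimulus_time: float = 0.0            # s, stimulus onset in trajectory time

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for name in ("sigma_a_uni", "sigma_a_bi", "sigma_v_uni", "sigma_v_bi",
                     "sigma_logT", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Uniformly sampled pointer trajectory (times in s, positions in deg)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")


def build_design(n_subjects: int, n_reps: int) -> pd.DataFrame:
    """Enumerate the full-factorial trial design.

    Per subject and task: ``5 * n_reps`` unimodal trials, ``5 * n_reps``
    coincident and ``20 * n_reps`` non-coincident bimodal trials (offsets
    +/-5, +/-10 around each primary position).  Deterministic ordering;
    shuffling happens downstream with the dataset seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    rows = []
    for subject in range(n_subjects):
        for task in (TASK_ACOUSTIC, TASK_VISUAL):
            for xp in PRIMARY_POSITIONS:
                for rep in range(n_reps):
                    rows.append((subject, task, 0, xp, SENTINEL, rep))
                for off in OFFSETS:
                    for rep in range(n_reps):
                        rows.append((subject, task, 1, xp, xp + off, rep))
    return pd.DataFrame(
        rows, columns=["subject", "task", "mode", "xp", "xs", "rep"]
    )


def draw_subject_profile(params: SimParams, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's latent parameters around the population values."""
    params.validate()

    def jitter(mean, sd, positive=False):
        v = mean + rng.normal(0.0, sd)
        if positive:  # keep scale parameters away from zero
            v = max(v, 0.05 * mean)
        return float(v)

    return SubjectProfile(
        bias=float(rng.normal(0.0, params.bias_sd)),
        sigma_a_uni=jitter(params.sigma_a_uni, params.sigma_jitter_sd, True),
        sigma_a_bi=jitter(params.sigma_a_bi, params.sigma_jitter_sd, True),
        sigma_v_uni=jitter(params.sigma_v_uni, params.sigma_jitter_sd / 2, True),
        sigma_v_bi=jitter(params.sigma_v_bi, params.sigma_jitter_sd / 2, True),
        w=float(np.clip(params.w + rng.normal(0.0, params.w_sd), 0.0, 1.0)),
        mu_logT=(
            (params.mu_logT_a_uni, params.mu_logT_a_bi),
            (params.mu_logT_v_uni, params.mu_logT_v_bi),
        ),
        delta_ecc=jitter(params.delta_ecc, params.delta_ecc_sd),
        sigma_logT=jitter(params.sigma_logT, params.sigma_logT_jitter_sd, True),
        subject_T_offset=float(rng.normal(0.0, params.subject_T_offset_sd)),
    )


def _check_on_grid(xp, xs):
    xp = np.atleast_1d(np.asarray(xp, dtype=float))
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if not np.isin(xp, PRIMARY_POSITIONS).all():
        raise ValueError("primary position off the design grid")
    bi = ~np.isnan(xs)
    if bi.any():
        off = xs[bi] - xp[bi]
        if not np.isin(off, OFFSETS).all():
            raise ValueError("secondary position off the design grid")
    return xp, xs


def simulate_percept(profile: SubjectProfile, s: int, xp, xs,
                     rng: np.random.Generator):
    """Raw pointer localization (deg) for one or more trials.

    Mean is ``xp + bias`` for unimodal trials and in the visual task
    (segregation), ``xp + w * (xs - xp) + bias`` for bimodal acoustic
    trials (visual capture).  Gaussian noise with the (task, mode) SD,
    clipped to the physical pointer range.
    """
    xp, xs = _check_on_grid(xp, xs)
    bimodal = ~np.isnan(xs)
    mean = xp + profile.bias
    if s == TASK_ACOUSTIC:
        mean = np.where(bimodal, xp + profile.w * (np.where(bimodal, xs, 0.0) - xp)
                        + profile.bias, mean)
    sigma = profile.percept_sigma(s, bimodal)
    out = rng.normal(mean, sigma)
    out = np.clip(out, *POINTER_RANGE)
    return out if out.size > 1 else float(out[0])


def simulate_decision_time(profile: SubjectProfile, s: int, m, xs,
                           rng: np.random.Generator):
    """Decision time (s): log-normal in task x mode, eccentricity penalty.

    ``log T ~ N(mu_logT[s][m] + subject_T_offset + delta_ecc * 1[s=0, |xs|=20],
    sigma_logT)``.  Requires ``m = 0`` exactly on unimodal (sentinel) trials.
    """
    m = np.atleast_1d(np.asarray(m, dtype=int))
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if ((m == 0) != np.isnan(xs)).any():
        raise ValueError("inconsistent mode/secondary: m=0 iff xs is sentinel")
    mu = np.array([profile.mu_logT[s][mi] for mi in m])
    mu = mu + profile.subject_T_offset
    if s == TASK_ACOUSTIC:
        ecc = np.abs(np.nan_to_num(xs, nan=0.0)) == 20.0
        mu = mu + profile.delta_ecc * ecc
    t = np.exp(rng.normal(mu, profile.sigma_logT))
    return t if t.size > 1 else float(t[0])


def minimum_jerk(t: np.ndarray, start: float, end: float, duration: float) -> np.ndarray:
    """Minimum-jerk position profile on normalized time ``t / duration``."""
    tau = np.clip(t / duration, 0.0, 1.0)
    return start + (end - start) * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def simulate_trajectory(endpoint: float, decision_time: float,
                        movement_duration: float, sample_rate: float,
                        hold_duration: float = 1.0) -> Trajectory:
    """Pointer trajectory: hold at 40 deg, minimum-jerk reach, hold at endpoint."""
    if movement_duration <= 0 or sample_rate <= 0:
        raise ValueError("movement_duration and sample_rate must be positive")
    if not POINTER_RANGE[0] <= endpoint <= POINTER_RANGE[1]:
        raise ValueError("endpoint outside the pointer range")
    total = decision_time + movement_duration + hold_duration
    n = int(np.floor(total * sample_rate)) + 1
    times = np.arange(n) / sample_rate
    positions = np.full(n, NEUTRAL_POSITION)
    moving = times >= decision_time
    positions[moving] = minimum_jerk(
        times[moving] - decision_time, NEUTRAL_POSITION, endpoint, movement_duration
    )
    return Trajectory(times, positions)


def simulate_dataset(params: SimParams | None = None) -> pd.DataFrame:
    """Simulate the full trial table (one row per design trial).

    Columns: subject, task, mode, xp, xs, response_raw, decision_time,
    movement_time.  Trial order is shuffled within subject x task.
    Fully reproducible from ``params.seed``.
    """
    params = params or SimParams()
    params.validate()
    root = np.random.default_rng(params.seed)
    # independent substreams: profiles, responses, shuffling
    seeds = root.integers(0, 2**31 - 1, size=3)
    rng_prof = np.random.default_rng(seeds[0])
    rng_resp = np.random.default_rng(seeds[1])
    rng_shuf = np.random.default_rng(seeds[2])

    design = build_design(params.n_subjects, params.n_reps)
    profiles = [draw_subject_profile(params, rng_prof)
                for _ in range(params.n_subjects)]

    parts = []
    for subject in range(params.n_subjects):
        prof = profiles[subject]
        for task in (TASK_ACOUSTIC, TASK_VISUAL):
            block = design[(design.subject == subject)
                           & (design.task == task)].copy()
            block = block.sample(frac=1.0, random_state=np.random.RandomState(
                rng_shuf.integers(0, 2**31 - 1))).reset_index(drop=True)
            resp = simulate_percept(prof, task, block["xp"].to_numpy(),
                                    block["xs"].to_numpy(), rng_resp)
            dt = simulate_decision_time(prof, task, block["mode"].to_numpy(),
                                        block["xs"].to_numpy(), rng_resp)
            mt = np.exp(rng_resp.normal(
                np.log(params.movement_duration_mean),
                params.movement_duration_sd / params.movement_duration_mean,
                size=len(block)))
            block["response_raw"] = np.atleast_1d(resp)
            block["decision_time"] = np.atleast_1d(dt)
            block["movement_time"] = mt
            parts.append(block)
    table = pd.concat(parts, ignore_index=True).drop(columns="rep")
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as comma-delimited text (sentinel -> NA_UNIMODAL)."""
    out = table.copy()
    out["xs"] = out["xs"].map(
        lambda v: NA_TOKEN if np.isnan(v) else format(float(v), "g"))
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    table = pd.read_csv(path, dtype={"xs": str})
    table["xs"] = table["xs"].map(
        lambda v: SENTINEL if str(v).strip() == NA_TOKEN else float(v))
    return table
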