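"""Synthetic dual-wrist accelerometry and EMA prompt logs with ground truth.

The generator emulates a 5-day ambulatory monitoring study in chronic
stroke survivors: two wrist accelerometers sampled at 30 Hz and a
smartphone EMA protocol of 6 scheduled prompts per day (>= 2 h apart,
5-min reminder signals, optional self-triggered prompts).  Everything is
seeded and carries exact ground truth, so the downstream pipeline can be
validated without any real recordings.

Three tiers of fidelity are provided, consistent with each other by
construction:

* **Signal tier** — :func:`generate_wrist_signals` renders scripted
  movement bouts (rest / unimanual / bimanual / non-wear) as band-limited
  sinusoids plus noise and gravity at 30 Hz.  Bout durations are whole
  epochs, so the true per-epoch classification is exact.
* **Log tier** — :func:`generate_prompt_log` draws a full prompt log
  (delivery failures, reminders, completion times, duplicates,
  self-triggers) from a configurable behaviour model.
* **Summary tier** — :func:`simulate_daily_dataset` and
  :func:`simulate_window_dataset` draw the daily and 10-min-window time
  metrics directly from the participant-level distributions implied by
  the activity model, for Monte-Carlo studies of the validity statistics
  where rendering raw signals would be pointlessly slow.

Injectable effects: a response bias (answer probability raised after
recent paretic-arm movement), an immediate reactivity (paretic activity
multiplied in the 10 min after a completed prompt) and an accumulative
reactivity (paretic activity share growing by a fixed fraction per day).
With all three at their neutral values the generator is an exact null for
the validity tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from armuse import accelerometry as acc
from armuse.accelerometry import Category, EPOCH_LENGTH_S, RawRecording

__all__ = [
    "Bout",
    "MOVEMENT_MODES",
    "GroundTruth",
    "BehaviorModel",
    "ActivityTemplate",
    "SyntheticStudy",
    "generate_wrist_signals",
    "generate_prompt_log",
    "generate_day_script",
    "generate_study",
    "script_metrics",
    "simulate_daily_dataset",
    "simulate_window_dataset",
    "expected_bias_difference",
]

MOVEMENT_MODES = ("uni_right", "uni_left", "bimanual")
NONWEAR_MODES = ("nonwear_right", "nonwear_left", "nonwear_both")
ALL_MODES = ("rest",) + MOVEMENT_MODES + NONWEAR_MODES

#: Combined two-wrist classification implied by each bout mode.
_MODE_TO_CATEGORY = {
    "rest": Category.NO_MOVEMENT,
    "uni_right": Category.UNI_RIGHT,
    "uni_left": Category.UNI_LEFT,
    "bimanual": Category.BIMANUAL,
    "nonwear_right": Category.INVALID,
    "nonwear_left": Category.INVALID,
    "nonwear_both": Category.INVALID,
}

ITEM_COLUMNS = [f"item_{i}" for i in range(1, 18)]
#: Items 1-16 are close-ended (arm/hand use, self-efficacy, mood, context);
#: item 17 is a free-text comment field.  Configurable wherever it matters.
DEFAULT_CLOSE_ENDED = tuple(range(1, 17))


class Bout(NamedTuple):
    """One scripted behaviour bout.

    ``duration_s`` must be a positive multiple of the 2-s epoch so that
    ground-truth epoch labels are exact.  ``frequency_hz`` must lie inside
    the 0.25-2.5 Hz pass band, otherwise the band-pass filter would
    attenuate the bout and break the ground truth.
    """

    duration_s: float
    mode: str
    intensity_g: float = 0.2
    frequency_hz: float = 1.0


def _validate_script(script: Sequence[Bout]) -> None:
    if len(script) == 0:
        raise ValueError("bout script is empty")
    for i, bout in enumerate(script):
        if bout.mode not in ALL_MODES:
            raise ValueError(f"bout {i}: unknown mode {bout.mode!r}")
        if bout.duration_s <= 0:
            raise ValueError(f"bout {i}: duration must be positive")
        if abs(bout.duration_s / EPOCH_LENGTH_S - round(bout.duration_s / EPOCH_LENGTH_S)) > 1e-9:
            raise ValueError(
                f"bout {i}: duration {bout.duration_s} s is not a whole number of "
                f"{EPOCH_LENGTH_S:g}-s epochs"
            )
        if bout.mode in MOVEMENT_MODES:
            if not (0.25 <= bout.frequency_hz <= 2.5):
                raise ValueError(
                    f"bout {i}: frequency {bout.frequency_hz} Hz outside the "
                    "0.25-2.5 Hz pass band"
                )
            if bout.intensity_g <= 0:
                raise ValueError(f"bout {i}: intensity must be positive")


@dataclass
class GroundTruth:
    """Exact per-epoch truth for one scripted recording.

    ``categories`` holds the true combined classification
    (:class:`~armuse.accelerometry.Category` codes); ``wear_right`` /
    ``wear_left`` the true wear state per wrist.
    """

    categories: np.ndarray
    wear_right: np.ndarray
    wear_left: np.ndarray
    mode_right: np.ndarray  # per-epoch wrist state: "move" / "rest" / "nonwear"
    mode_left: np.ndarray

    def true_metrics(self) -> acc.TimeMetrics:
        return acc.time_metrics(self.categories)


def _script_epoch_truth(script: Sequence[Bout]) -> GroundTruth:
    cats, wr, wl, mr, ml = [], [], [], [], []
    for bout in script:
        n = int(round(bout.duration_s / EPOCH_LENGTH_S))
        cats += [_MODE_TO_CATEGORY[bout.mode]] * n
        r_worn = bout.mode not in ("nonwear_right", "nonwear_both")
        l_worn = bout.mode not in ("nonwear_left", "nonwear_both")
        wr += [r_worn] * n
        wl += [l_worn] * n
        r_move = bout.mode in ("uni_right", "bimanual")
        l_move = bout.mode in ("uni_left", "bimanual")
        mr += [("move" if r_move else "rest") if r_worn else "nonwear"] * n
        ml += [("move" if l_move else "rest") if l_worn else "nonwear"] * n
    return GroundTruth(
        categories=np.array(cats, dtype=np.int8),
        wear_right=np.array(wr, dtype=bool),
        wear_left=np.array(wl, dtype=bool),
        mode_right=np.array(mr),
        mode_left=np.array(ml),
    )


def script_metrics(script: Sequence[Bout]) -> acc.TimeMetrics:
    """Daily TimeR/TimeL/TimeB and wearing time implied by a bout script."""
    _validate_script(script)
    return _script_epoch_truth(script).true_metrics()


# ---------------------------------------------------------------------------
# signal tier

DEFAULT_START = pd.Timestamp("2024-03-04 07:00:00-08:00")
#: Taper length (s) smoothing bout onsets/offsets; keeps spectral leakage
#: into neighbouring epochs below the count deadband.
_EDGE_TAPER_S = 0.5


def generate_wrist_signals(
    script: Sequence[Bout],
    noise_sd: float = 0.02,
    seed: int = 0,
    start_time: pd.Timestamp = DEFAULT_START,
    sample_rate: float = 30.0,
) -> tuple[RawRecording, RawRecording, GroundTruth]:
    """Render a bout script into two 30 Hz tri-axial wrist streams.

    The worn, moving wrist carries a sinusoid at the bout frequency on the
    x axis (randomised phase, half-cosine edge tapers), both worn wrists
    carry white noise of ``noise_sd`` g on every axis, gravity (1 g) sits
    on the z axis throughout, and an off-wrist device records gravity only
    — an exactly constant signal.  ``noise_sd`` must stay below the count
    deadband (~0.05 g) for rest epochs to remain sub-threshold.
    """
    _validate_script(script)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = int(round(sum(b.duration_s for b in script) * sample_rate))
    sig = {w: np.zeros((n_total, 3)) for w in ("right", "left")}
    for w in sig:
        sig[w][:, 2] = 1.0  # gravity

    pos = 0
    for bout in script:
        n = int(round(bout.duration_s * sample_rate))
        sl = slice(pos, pos + n)
        t = np.arange(n) / sample_rate
        r_worn = bout.mode not in ("nonwear_right", "nonwear_both")
        l_worn = bout.mode not in ("nonwear_left", "nonwear_both")
        for wrist, worn in (("right", r_worn), ("left", l_worn)):
            if worn and noise_sd > 0:
                sig[wrist][sl] += rng.normal(0.0, noise_sd, size=(n, 3))
            moving = (
                (wrist == "right" and bout.mode in ("uni_right", "bimanual"))
                or (wrist == "left" and bout.mode in ("uni_left", "bimanual"))
            )
            if moving:
                phase = rng.uniform(0, 2 * np.pi)
                wave = bout.intensity_g * np.sin(
                    2 * np.pi * bout.frequency_hz * t + phase
                )
                sig[wrist][sl, 0] += wave * _edge_taper(n, sample_rate)
        pos += n

    truth = _script_epoch_truth(script)
    right = RawRecording("right", start_time, sig["right"], sample_rate)
    left = RawRecording("left", start_time, sig["left"], sample_rate)
    return right, left, truth


def _edge_taper(n: int, sample_rate: float) -> np.ndarray:
    """Half-cosine ramps at both ends of a bout."""
    taper = np.ones(n)
    k = min(int(_EDGE_TAPER_S * sample_rate), n // 2)
    if k > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        taper[:k] = ramp
        taper[-k:] = ramp[::-1]
    return taper


# ---------------------------------------------------------------------------
# behaviour model / log tier


@dataclass
class BehaviorModel:
    """EMA prompting and answering behaviour for one participant.

    Defaults mirror the study protocol: 6 scheduled prompts/day spaced at
    least 2 h apart within a 07:00-24:00 waking day, two 5-min reminder
    signals, and a small probability that a scheduled prompt is never
    delivered (phone off / technical failure) — such prompts do not
    appear in the log at all.

    Injection knobs (all neutral by default):

    * ``answer_prob_given_recent_movement`` — response bias: answer
      probability used when the paretic arm moved in the 10 min before
      the prompt (None = no dependence).
    * ``post_prompt_boost`` — immediate reactivity: multiplier on paretic
      activity in the 10 min after a completed prompt.
    * ``reactivity_daily_increment`` — accumulative reactivity:
      fractional increase in the paretic-use activity share per day
      (0.08 = +8 %/day).
    """

    n_days: int = 5
    prompts_per_day: int = 6
    min_spacing_min: float = 120.0
    reminder_interval_min: float = 5.0
    n_reminders: int = 2
    answer_prob: float = 0.85
    answer_prob_given_recent_movement: float | None = None
    self_trigger_rate: float = 0.45
    selftrigger_compensation: float = 0.6
    duplicate_prob: float = 0.02
    undelivered_prob: float = 10.0 / 900.0
    reactivity_daily_increment: float = 0.0
    post_prompt_boost: float = 1.0
    completion_mean_min: float = 4.0
    completion_sd_min: float = 1.7
    waking_start: str = "07:00"
    waking_hours: float = 17.0

    def __post_init__(self) -> None:
        for name in ("answer_prob", "duplicate_prob", "undelivered_prob",
                     "selftrigger_compensation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        p = self.answer_prob_given_recent_movement
        if p is not None and not (0.0 <= p <= 1.0):
            raise ValueError("answer_prob_given_recent_movement must be in [0, 1]")
        if self.n_days < 1 or self.prompts_per_day < 1:
            raise ValueError("n_days and prompts_per_day must be >= 1")
        if self.self_trigger_rate < 0:
            raise ValueError("self_trigger_rate must be non-negative")
        if self.post_prompt_boost <= 0:
            raise ValueError("post_prompt_boost must be positive")
        span = self.min_spacing_min * (self.prompts_per_day - 1)
        if span > self.waking_hours * 60.0:
            raise ValueError(
                f"infeasible schedule: {self.prompts_per_day} prompts at "
                f">= {self.min_spacing_min:g} min spacing do not fit in a "
                f"{self.waking_hours:g}-h waking day"
            )


def _schedule_day(
    model: BehaviorModel, day_start: pd.Timestamp, rng: np.random.Generator
) -> list[pd.Timestamp]:
    """Scheduled prompt times for one day: sorted uniforms with a minimum
    gap, drawn exactly via the spacing-subtraction transform."""
    k = model.prompts_per_day
    slack = model.waking_hours * 60.0 - model.min_spacing_min * (k - 1)
    u = np.sort(rng.uniform(0.0, slack, size=k))
    offsets_min = u + model.min_spacing_min * np.arange(k)
    return [day_start + pd.Timedelta(minutes=float(m)) for m in offsets_min]


def _draw_responses(rng: np.random.Generator) -> dict[str, object]:
    """Placeholder item responses: 1-6 arm/hand use, 7-9 self-efficacy,
    10-13 mood, 14-16 context (close-ended), 17 free text."""
    resp: dict[str, object] = {}
    for i in range(1, 7):
        resp[f"item_{i}"] = int(rng.integers(0, 6))
    for i in range(7, 10):
        resp[f"item_{i}"] = int(rng.integers(1, 8))
    for i in range(10, 14):
        resp[f"item_{i}"] = int(rng.integers(1, 6))
    for i in range(14, 17):
        resp[f"item_{i}"] = int(rng.integers(0, 4))
    resp["item_17"] = ""
    return resp


def generate_prompt_log(
    model: BehaviorModel,
    day_start: pd.Timestamp | str = DEFAULT_START.normalize(),
    seed: int = 0,
    participant_id: str = "P01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a full multi-day prompt log for one participant.

    Returns ``(log, truth)``.  ``log`` follows the prompt-log CSV dialect
    (one row per logged prompt, columns ``participant_id, prompt_id, type,
    notify_time, start_time, completion_time, item_1..item_17``).
    Undelivered scheduled prompts are absent from the log (the phone never
    fired) but present in ``truth`` with ``delivered == False``.  ``truth``
    additionally marks which rows are duplicates (``duplicate_of``).
    """
    rng = np.random.default_rng(seed)
    day0 = pd.Timestamp(day_start)
    if day0.tzinfo is None:
        day0 = day0.tz_localize(DEFAULT_START.tz)
    wake_h, wake_m = (int(x) for x in model.waking_start.split(":"))

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for day in range(1, model.n_days + 1):
        start = (day0 + pd.Timedelta(days=day - 1)).replace(
            hour=wake_h, minute=wake_m, second=0
        )
        notify_times = _schedule_day(model, start, rng)
        n_missed = 0
        for i, notify in enumerate(notify_times, start=1):
            pid = f"{participant_id}-d{day}-s{i}"
            delivered = rng.random() >= model.undelivered_prob
            answered = bool(delivered and rng.random() < model.answer_prob)
            truth_rows.append(
                {"prompt_id": pid, "type": "scheduled", "day": day,
                 "delivered": delivered, "answered": answered,
                 "duplicate_of": None}
            )
            if not delivered:
                continue
            row = {
                "participant_id": participant_id, "prompt_id": pid,
                "type": "scheduled", "notify_time": notify,
                "start_time": pd.NaT, "completion_time": pd.NaT,
                **{c: "" for c in ITEM_COLUMNS},
            }
            if answered:
                # respond after the first, second or third signal
                signal = rng.choice(model.n_reminders + 1, p=_signal_probs(model))
                latency = signal * model.reminder_interval_min + rng.uniform(
                    0.0, model.reminder_interval_min
                )
                start_t = notify + pd.Timedelta(minutes=float(latency))
                dur = max(0.5, rng.normal(model.completion_mean_min,
                                          model.completion_sd_min))
                row["start_time"] = start_t
                row["completion_time"] = start_t + pd.Timedelta(minutes=float(dur))
                row.update(_draw_responses(rng))
            else:
                n_missed += 1
            rows.append(row)
            if answered and rng.random() < model.duplicate_prob:
                dup = dict(row)
                dup_id = pid + "-dup"
                dup["prompt_id"] = dup_id
                gap = rng.uniform(5.0, 55.0)
                dup["start_time"] = row["start_time"] + pd.Timedelta(seconds=gap)
                dup["completion_time"] = dup["start_time"] + pd.Timedelta(
                    seconds=float(rng.uniform(10.0, 60.0))
                )
                dup["item_17"] = ""  # open-ended may differ; close-ended identical
                rows.append(dup)
                truth_rows.append(
                    {"prompt_id": dup_id, "type": "scheduled", "day": day,
                     "delivered": True, "answered": True, "duplicate_of": pid}
                )
        # self-triggers: a spontaneous rate plus compensation for misses
        n_self = int(rng.poisson(model.self_trigger_rate))
        n_self += int(rng.binomial(n_missed, model.selftrigger_compensation))
        self_times = _self_trigger_times(model, start, notify_times, n_self, rng)
        for j, t in enumerate(sorted(self_times), start=1):
            pid = f"{participant_id}-d{day}-t{j}"
            dur = max(0.5, rng.normal(model.completion_mean_min,
                                      model.completion_sd_min))
            rows.append({
                "participant_id": participant_id, "prompt_id": pid,
                "type": "self_triggered", "notify_time": pd.NaT,
                "start_time": t,
                "completion_time": t + pd.Timedelta(minutes=float(dur)),
                **_draw_responses(rng),
            })
            truth_rows.append(
                {"prompt_id": pid, "type": "self_triggered", "day": day,
                 "delivered": True, "answered": True, "duplicate_of": None}
            )

    log = pd.DataFrame(rows, columns=["participant_id", "prompt_id", "type",
                                      "notify_time", "start_time",
                                      "completion_time"] + ITEM_COLUMNS)
    tz = day0.tz
    for col in ("notify_time", "start_time", "completion_time"):
        log[col] = pd.to_datetime(log[col])
        if log[col].dt.tz is None:  # all-NaT column parses as naive
            log[col] = log[col].dt.tz_localize(tz)
    order = log["start_time"].fillna(log["notify_time"])
    log = log.assign(_k=order).sort_values("_k").drop(columns="_k")
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "participant_id", participant_id)
    return log.reset_index(drop=True), truth


def _signal_probs(model: BehaviorModel) -> np.ndarray:
    """Probability of responding after the initial signal vs each reminder."""
    w = 0.6 ** np.arange(model.n_reminders + 1)
    return w / w.sum()


def _self_trigger_times(
    model: BehaviorModel,
    day_start: pd.Timestamp,
    scheduled: list[pd.Timestamp],
    n: int,
    rng: np.random.Generator,
) -> list[pd.Timestamp]:
    """Uniform over waking hours, excluding 1 min around scheduled prompts."""
    times: list[pd.Timestamp] = []
    guard = pd.Timedelta(minutes=1)
    while len(times) < n:
        t = day_start + pd.Timedelta(minutes=float(rng.uniform(0, model.waking_hours * 60)))
        if all(abs(t - s) > guard for s in scheduled):
            times.append(t)
    return times


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass
class ActivityTemplate:
    """Distribution of daily arm-use behaviour across participants.

    Shares are fractions of *worn* time; defaults roughly match a chronic
    stroke cohort with the right (dominant) side paretic — little
    unimanual paretic use, substantial non-paretic and bimanual use.  Each
    day contains one off-wrist block (both devices removed together, e.g.
    bathing) long enough to be detectable (>= 3 h).
    """

    uni_right_share: float = 0.058
    uni_left_share: float = 0.225
    bimanual_share: float = 0.29
    share_participant_log_sd: float = 0.35  # heterogeneity of the paretic share
    nonwear_hours_mean: float = 3.3
    nonwear_hours_sd: float = 0.4
    nonwear_hours_min: float = 3.05
    bout_min_s: float = 10.0
    bout_max_s: float = 60.0
    intensity_mean_g: float = 0.2
    intensity_sd_g: float = 0.05
    intensity_min_g: float = 0.1
    freq_range_hz: tuple[float, float] = (0.5, 2.0)
    noise_sd_g: float = 0.02


def generate_day_script(
    template: ActivityTemplate,
    rng: np.random.Generator,
    waking_hours: float = 17.0,
    uni_right_multiplier: float = 1.0,
) -> list[Bout]:
    """One day's bout script: random bouts filling the waking day, with a
    single detectable non-wear block inserted at a random position."""
    nw_hours = min(
        max(rng.normal(template.nonwear_hours_mean, template.nonwear_hours_sd),
            template.nonwear_hours_min),
        waking_hours - 1.0,
    )
    nw_s = round(nw_hours * 3600.0 / EPOCH_LENGTH_S) * EPOCH_LENGTH_S
    worn_s = waking_hours * 3600.0 - nw_s

    p_r = min(template.uni_right_share * uni_right_multiplier, 0.5)
    shares = np.array([p_r, template.uni_left_share, template.bimanual_share])
    p_rest = max(1.0 - shares.sum(), 0.0)
    probs = np.concatenate((shares, [p_rest]))
    probs = probs / probs.sum()
    modes = ("uni_right", "uni_left", "bimanual", "rest")

    bouts: list[Bout] = []
    # devices are handled when doffed/donned: bracket the off-wrist block
    # with short bimanual bouts, which also pins down the non-wear run
    doff = Bout(10.0, "bimanual", template.intensity_mean_g, 1.0)
    remaining = worn_s - 2 * doff.duration_s
    lo = int(template.bout_min_s / EPOCH_LENGTH_S)
    hi = int(template.bout_max_s / EPOCH_LENGTH_S)
    while remaining > 0:
        dur = min(int(rng.integers(lo, hi + 1)) * EPOCH_LENGTH_S, remaining)
        mode = modes[int(rng.choice(4, p=probs))]
        intensity = max(rng.normal(template.intensity_mean_g, template.intensity_sd_g),
                        template.intensity_min_g)
        freq = rng.uniform(*template.freq_range_hz)
        bouts.append(Bout(dur, mode, round(intensity, 4), round(freq, 3)))
        remaining -= dur
    insert_at = int(rng.integers(0, len(bouts) + 1))
    bouts[insert_at:insert_at] = [doff, Bout(nw_s, "nonwear_both"), doff]
    return bouts


def _logit_normal_centre(mean_p: float, sd: float) -> float:
    """Logit-scale centre of a logistic-normal with the given marginal mean.

    Solved by Gauss-Hermite quadrature and bisection so that
    ``E[sigmoid(centre + sd * Z)] == mean_p``.
    """
    if sd == 0.0 or mean_p in (0.0, 1.0):
        return float(np.log(mean_p / (1 - mean_p))) if 0 < mean_p < 1 else np.inf
    from scipy.optimize import brentq

    nodes, weights = np.polynomial.hermite.hermgauss(41)
    weights = weights / np.sqrt(np.pi)

    def marginal(mu: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(mu + sd * np.sqrt(2) * nodes)))))

    return float(brentq(lambda m: marginal(m) - mean_p, -40.0, 40.0))


@dataclass
class SyntheticStudy:
    """Handle onto a generated study directory."""

    root: Path
    participant_ids: list[str]
    manifest: dict

    def participant_dir(self, pid: str) -> Path:
        return self.root / "participants" / pid

    def prompts_path(self, pid: str) -> Path:
        return self.participant_dir(pid) / "prompts.csv"

    def raw_path(self, pid: str, wrist: str, day: int) -> Path:
        return self.participant_dir(pid) / f"raw_{wrist}_day{day}.csv"

    def ground_truth(self, pid: str) -> dict:
        with open(self.participant_dir(pid) / "ground_truth.json") as fh:
            return json.load(fh)


def generate_study(
    n_participants: int,
    out_dir: str | Path,
    model: BehaviorModel | None = None,
    template: ActivityTemplate | None = None,
    seed: int = 0,
    start_date: str | pd.Timestamp = "2024-03-04",
    answer_prob_logit_sd: float = 1.0,
    write_signals: bool = True,
) -> SyntheticStudy:
    """Generate a full multi-participant study on disk.

    Per-participant seeds are spawned deterministically from the master
    seed, so the same seed reproduces the study byte for byte.  Each
    participant directory holds a prompt-log CSV, per-day raw
    accelerometry CSVs for both wrists (unless ``write_signals`` is
    False), and a ``ground_truth.json`` sidecar with the bout scripts,
    true daily metrics, prompt truth and drawn participant parameters.

    ``answer_prob_logit_sd`` spreads the answer probability across
    participants on the logit scale (between-person heterogeneity), and
    the paretic activity share gets a lognormal participant multiplier —
    both make the two-level model structure of the validity tests
    non-degenerate.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    model = model or BehaviorModel()
    template = template or ActivityTemplate()
    out_dir = Path(out_dir)
    (out_dir / "participants").mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(seed).spawn(n_participants)
    day0 = pd.Timestamp(start_date)
    pids = [f"P{i + 1:02d}" for i in range(n_participants)]

    for pid, seq in zip(pids, seeds):
        rng = np.random.default_rng(seq)
        pdir = out_dir / "participants" / pid
        pdir.mkdir(exist_ok=True)

        # participant-level heterogeneity on the logit scale; the centre is
        # chosen so the marginal mean answer probability stays at the
        # configured value
        centre = _logit_normal_centre(model.answer_prob, answer_prob_logit_sd)
        p_answer = 1.0 / (1.0 + np.exp(-(centre + rng.normal(0, answer_prob_logit_sd))))
        share_mult = float(np.exp(rng.normal(0, template.share_participant_log_sd)))
        p_model = replace(model, answer_prob=float(p_answer))

        log_seed = int(rng.integers(0, 2**31))
        log, prompt_truth = generate_prompt_log(
            p_model, day_start=day0, seed=log_seed, participant_id=pid
        )
        log.to_csv(pdir / "prompts.csv", index=False)

        scripts, daily_truth = [], []
        for day in range(1, model.n_days + 1):
            mult = share_mult * (1.0 + model.reactivity_daily_increment) ** (day - 1)
            script = generate_day_script(
                template, rng, waking_hours=model.waking_hours,
                uni_right_multiplier=mult,
            )
            scripts.append(script)
            m = script_metrics(script)
            daily_truth.append(
                {"day": day, "time_r_s": m.time_r, "time_l_s": m.time_l,
                 "time_b_s": m.time_b, "wearing_time_s": m.wearing_time_s}
            )
            if write_signals:
                wake_h, wake_m = (int(x) for x in model.waking_start.split(":"))
                t0 = (day0 + pd.Timedelta(days=day - 1)).tz_localize(
                    DEFAULT_START.tz
                ).replace(hour=wake_h, minute=wake_m)
                sig_seed = int(rng.integers(0, 2**31))
                right, left, _ = generate_wrist_signals(
                    script, noise_sd=template.noise_sd_g, seed=sig_seed,
                    start_time=t0,
                )
                acc.write_raw_csv(right, pdir / f"raw_right_day{day}.csv")
                acc.write_raw_csv(left, pdir / f"raw_left_day{day}.csv")

        truth = {
            "participant_id": pid,
            "answer_prob": float(p_answer),
            "uni_right_share_multiplier": share_mult,
            "true_daily_metrics": daily_truth,
            "prompt_truth": prompt_truth.to_dict(orient="records"),
            "bout_scripts": [[list(b) for b in script] for script in scripts],
        }
        with open(pdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)

    manifest = {
        "seed": int(seed),
        "n_participants": int(n_participants),
        "start_date": str(pd.Timestamp(start_date).date()),
        "behavior_model": {k: v for k, v in asdict(model).items()},
        "activity_template": {k: list(v) if isinstance(v, tuple) else v
                              for k, v in asdict(template).items()},
        "answer_prob_logit_sd": answer_prob_logit_sd,
        "write_signals": bool(write_signals),
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return SyntheticStudy(root=out_dir, participant_ids=pids, manifest=manifest)


# ---------------------------------------------------------------------------
# summary tier: direct simulation of the analysis datasets


def simulate_daily_dataset(
    n_participants: int = 30,
    n_days: int = 5,
    reactivity_daily_increment: float = 0.0,
    seed: int = 0,
    base_pct: tuple[float, float, float] = (5.0, 22.5, 29.0),
    participant_log_sd: tuple[float, float, float] = (0.65, 0.40, 0.45),
    day_log_sd: float = 0.15,
    wearing_mean_h: float = 13.7,
    wearing_participant_sd_h: float = 2.8,
    wearing_day_sd_h: float = 0.8,
) -> pd.DataFrame:
    """Participant-day TimeR/TimeL/TimeB percents and wearing hours.

    Percents are lognormal with a multiplicative participant intercept and
    day-to-day noise, matching the positive skew of real daily arm-use
    shares.  ``reactivity_daily_increment`` multiplies the paretic (TimeR)
    percent by ``(1 + increment)`` per additional day — the accumulative
    reactivity injection; TimeL and TimeB carry no day effect ever.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        b = rng.normal(0.0, participant_log_sd, size=3)
        wear_i = rng.normal(wearing_mean_h, wearing_participant_sd_h)
        for day in range(1, n_days + 1):
            eps = rng.normal(0.0, day_log_sd, size=3)
            drift = (1.0 + reactivity_daily_increment) ** (day - 1)
            pct = [
                base_pct[0] * drift * np.exp(b[0] + eps[0]),
                base_pct[1] * np.exp(b[1] + eps[1]),
                base_pct[2] * np.exp(b[2] + eps[2]),
            ]
            wearing = float(np.clip(wear_i + rng.normal(0, wearing_day_sd_h),
                                    4.0, 17.0))
            rows.append({
                "participant_id": pid, "day": day, "wearing_hours": wearing,
                "time_r_pct": pct[0], "time_l_pct": pct[1],
                "time_b_pct": pct[2],
            })
    return pd.DataFrame(rows)


def simulate_window_dataset(
    n_participants: int = 30,
    n_days: int = 5,
    prompts_per_day: int = 6,
    answer_prob: float = 0.85,
    answer_prob_given_recent_movement: float | None = None,
    post_prompt_boost: float = 1.0,
    movement_factor: float = 2.0,
    self_trigger_rate: float = 1.0,
    seed: int = 0,
    median_s: tuple[float, float, float] = (30.0, 130.0, 170.0),
    participant_log_sd: tuple[float, float, float] = (0.55, 0.40, 0.40),
    residual_log_sd: tuple[float, float, float] = (0.50, 0.35, 0.35),
    window_s: float = 600.0,
) -> pd.DataFrame:
    """Per-prompt pre/post 10-min-window time metrics (seconds).

    Each prompt carries a latent recent-movement state (fair coin, drawn
    independently for the pre and post windows) that multiplies the
    paretic TimeR by ``movement_factor``; metrics are lognormal around
    participant-level medians and capped at the window length.

    Injections:

    * response bias — when ``answer_prob_given_recent_movement`` is set,
      the answer probability follows the *pre-window* movement state, so
      answered prompts over-sample high-TimeR windows;
    * immediate reactivity — ``post_prompt_boost`` multiplies TimeR in
      the post window of answered prompts.

    With both neutral, pre/post and answered/unanswered TimeR are
    identically distributed: an exact null for the validity tests.
    Self-triggered prompts share the null distribution and are always
    answered.
    """
    rng = np.random.default_rng(seed)
    log_med = np.log(np.array(median_s))
    rows = []

    def _metrics(b: np.ndarray, m_state: int, boost: float) -> dict[str, float]:
        eps = rng.normal(0.0, residual_log_sd)
        vals = np.exp(log_med + b + eps)
        vals[0] *= (movement_factor ** m_state) * boost
        vals = np.minimum(vals, window_s)
        return {"time_r_s": float(vals[0]), "time_l_s": float(vals[1]),
                "time_b_s": float(vals[2])}

    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        b = rng.normal(0.0, participant_log_sd, size=3)
        n_sched = n_days * prompts_per_day
        for j in range(1, n_sched + 1):
            m_pre = int(rng.random() < 0.5)
            if answer_prob_given_recent_movement is not None and m_pre:
                p = answer_prob_given_recent_movement
            else:
                p = answer_prob
            answered = bool(rng.random() < p)
            base = {"participant_id": pid, "prompt_id": f"{pid}-s{j}",
                    "prompt_type": "scheduled", "answered": answered}
            rows.append({**base, "phase": "pre", **_metrics(b, m_pre, 1.0)})
            if answered:
                m_post = int(rng.random() < 0.5)
                rows.append({**base, "phase": "post",
                             **_metrics(b, m_post, post_prompt_boost)})
        n_self = int(rng.poisson(self_trigger_rate * n_days))
        for j in range(1, n_self + 1):
            base = {"participant_id": pid, "prompt_id": f"{pid}-t{j}",
                    "prompt_type": "self_triggered", "answered": True}
            rows.append({**base, "phase": "pre",
                         **_metrics(b, int(rng.random() < 0.5), 1.0)})
            rows.append({**base, "phase": "post",
                         **_metrics(b, int(rng.random() < 0.5), post_prompt_boost)})
    return pd.DataFrame(rows)


def expected_bias_difference(
    answer_prob: float,
    answer_prob_given_recent_movement: float,
    movement_factor: float = 2.0,
) -> float:
    """Expected answered-minus-unanswered difference in log pre-window TimeR.

    With movement state M ~ Bernoulli(1/2) multiplying TimeR by
    ``movement_factor`` and answer probabilities p0 (M=0) / p1 (M=1), the
    induced log-scale contrast is ``log(factor) * (P(M|answered) -
    P(M|unanswered))``.
    """
    p0, p1 = answer_prob, answer_prob_given_recent_movement
    p_ans = 0.5 * (p0 + p1)
    p_m_ans = 0.5 * p1 / p_ans
    p_m_un = 0.5 * (1 - p1) / (1 - p_ans)
    return float(np.log(movement_factor) * (p_m_ans - p_m_un))
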