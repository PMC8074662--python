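"""Synthetic fTCD data: LI tables from a latent two-factor model and raw
bilateral CBFV recordings with a known, injected laterality.

Two generators cover the two entry points of the pipeline:

* :func:`generate_li_table` draws participants x (task x session) laterality
  indices directly from the orthogonal two-factor measurement model used
  downstream (marker task D fixed at loadings 1 and 0, factor-2 variance
  fixed at 1, factor means 0, session-tied loadings/means/residuals), so the
  CFA engine can be tested against known truth.

* :func:`generate_recording` synthesizes a raw recording — an asymmetric
  cardiac pulse train modulated by a task-locked trapezoidal hemodynamic
  response whose left-minus-right amplitude equals the requested LI — so
  the whole preprocessing chain can be exercised round-trip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import INDICATORS, MARKER_TASK, TASKS, CBFVRecording, LITable

_MARKER_IDX = TASKS.index(MARKER_TASK)


# ======================================================================
# Latent-model LI tables
# ======================================================================
@dataclass
class GroupLatentConfig:
    """Latent two-factor model parameters for one handedness group.

    Vectors are ordered by task A..F. The sentence-generation (task D)
    loadings are the identification markers and must be 1 on factor 1 and 0
    on factor 2; factor-2 variance is fixed at 1 and factor means at 0, so
    they are not configurable.
    """

    label: str
    n: int
    task_means: Sequence[float]
    loadings_f1: Sequence[float]
    loadings_f2: Sequence[float]
    factor1_var: float
    residual_vars: Sequence[float]
    site: str = "sim"

    def __post_init__(self) -> None:
        self.task_means = np.asarray(self.task_means, float)
        self.loadings_f1 = np.asarray(self.loadings_f1, float)
        self.loadings_f2 = np.asarray(self.loadings_f2, float)
        self.residual_vars = np.asarray(self.residual_vars, float)
        for name in ("task_means", "loadings_f1", "loadings_f2", "residual_vars"):
            if len(getattr(self, name)) != 6:
                raise ValueError(f"{name} must have 6 entries (tasks A-F)")
        if self.loadings_f1[_MARKER_IDX] != 1.0 or self.loadings_f2[_MARKER_IDX] != 0.0:
            raise ValueError("marker task D loadings must be fixed at (1, 0)")
        if np.any(self.residual_vars < 0):
            raise ValueError("residual variances must be non-negative")
        if self.factor1_var < 0:
            raise ValueError("factor-1 variance must be non-negative")
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass
class LatentModelConfig:
    """Full configuration for drawing an LI table from the latent model."""

    groups: list[GroupLatentConfig]
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not (0.0 <= self.missing_prob <= 0.2):
            raise ValueError("missing probability must lie in [0, 0.2]")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "seed": int(self.seed),
            "missing_prob": float(self.missing_prob),
            "groups": [
                {
                    "label": g.label,
                    "n": int(g.n),
                    "site": g.site,
                    "task_means": [float(x) for x in g.task_means],
                    "loadings_f1": [float(x) for x in g.loadings_f1],
                    "loadings_f2": [float(x) for x in g.loadings_f2],
                    "factor1_var": float(g.factor1_var),
                    "residual_vars": [float(x) for x in g.residual_vars],
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "LatentModelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("config file must state a seed")
        groups = [GroupLatentConfig(**g) for g in doc["groups"]]
        return cls(groups=groups, missing_prob=doc.get("missing_prob", 0.0), seed=doc["seed"])


def implied_moments(group: GroupLatentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied 12-vector mean and 12x12 covariance for one group.

    Sigma = Lambda diag(psi1, 1) Lambda' + Theta with session-tied loadings,
    means and residual variances; the indicator order is A1..F1, A2..F2.
    """
    lam = np.zeros((12, 2))
    lam[:6, 0] = lam[6:, 0] = group.loadings_f1
    lam[:6, 1] = lam[6:, 1] = group.loadings_f2
    phi = np.diag([group.factor1_var, 1.0])
    theta = np.diag(np.tile(group.residual_vars, 2))
    mu = np.tile(group.task_means, 2)
    return mu, lam @ phi @ lam.T + theta


def generate_li_table(config: LatentModelConfig, return_latents: bool = False):
    """Draw an LI table from the latent model.

    Each participant gets one latent draw (f1, f2) shared by both sessions;
    session cells add independent residual noise. Missing cells are inserted
    completely at random at ``config.missing_prob`` (a participant is never
    left with zero observed cells). With ``return_latents=True`` also
    returns the per-participant factor draws (for validity checks).
    """
    rng = np.random.default_rng(config.seed)
    rows, counts_rows, index, latents = [], [], [], []
    for g in config.groups:
        sd_res = np.sqrt(g.residual_vars)
        for i in range(g.n):
            f1 = rng.normal(0.0, np.sqrt(g.factor1_var))
            f2 = rng.normal(0.0, 1.0)
            latents.append({"f1": f1, "f2": f2})
            cells = {}
            for s in (1, 2):
                eps = rng.normal(0.0, 1.0, 6) * sd_res
                vals = g.task_means + g.loadings_f1 * f1 + g.loadings_f2 * f2 + eps
                for t, v in zip(TASKS, vals):
                    cells[f"{t}{s}"] = v
            if config.missing_prob > 0:
                miss = rng.random(12) < config.missing_prob
                if miss.all():
                    miss[rng.integers(12)] = False
                for ind, m in zip(INDICATORS, miss):
                    if m:
                        cells[ind] = np.nan
            subj = f"{g.label[0].upper()}{i + 1:03d}"
            index.append(subj)
            rows.append({"group": g.label, "site": g.site, **cells})
            counts_rows.append({ind: (0 if np.isnan(cells[ind]) else 15) for ind in INDICATORS})
    data = pd.DataFrame(rows, index=index)
    counts = pd.DataFrame(counts_rows, index=index)
    reasons = {
        (s, ind): "simulated-missing"
        for s, row in data.iterrows()
        for ind in INDICATORS
        if pd.isna(row[ind])
    }
    table = LITable(data, counts=counts, reasons=reasons)
    if return_latents:
        return table, pd.DataFrame(latents, index=index)
    return table


def default_study_config(seed: int = 0, n_left: int = 31, n_right: int = 43) -> LatentModelConfig:
    """Study-scale default: a left-handed and a right-handed group.

    Parameter values emulate the qualitative pattern reported for the six
    language tasks: sentence generation (D) lateralizes most strongly in both
    groups; left-handers have weaker means, larger between-subject variance
    and substantial factor-2 loadings on the receptive tasks; list generation
    (A) has poor test-retest reliability (small loading, large residual).
    """
    left = GroupLatentConfig(
        label="left",
        n=n_left,
        task_means=[1.7, 0.6, 0.0, 2.4, 0.2, -0.2],
        loadings_f1=[0.4, 0.9, 1.0, 1.0, 0.8, 0.1],
        loadings_f2=[0.0, 0.6, 0.7, 0.0, 0.8, 0.9],
        factor1_var=6.0,
        residual_vars=[3.5, 1.3, 1.0, 1.2, 1.1, 1.6],
    )
    right = GroupLatentConfig(
        label="right",
        n=n_right,
        task_means=[2.2, 2.4, 2.4, 4.2, 2.4, 0.3],
        loadings_f1=[0.35, 0.8, 0.9, 1.0, 0.9, 0.7],
        loadings_f2=[0.0, 0.0, 0.0, 0.0, 0.0, 0.4],
        factor1_var=4.0,
        residual_vars=[3.0, 1.2, 1.0, 1.0, 1.0, 1.5],
    )
    return LatentModelConfig(groups=[left, right], missing_prob=0.01, seed=seed)


def strong_two_factor_group(label: str = "left", n: int = 150) -> GroupLatentConfig:
    """A group with clearly separated factors (for power simulations)."""
    return GroupLatentConfig(
        label=label,
        n=n,
        task_means=[1.5, 1.0, 1.0, 3.0, 1.0, 0.5],
        loadings_f1=[0.5, 0.9, 1.0, 1.0, 0.1, 0.1],
        loadings_f2=[0.0, 0.0, 0.0, 0.0, 1.0, 1.1],
        factor1_var=4.0,
        residual_vars=[2.0, 1.0, 1.0, 1.0, 1.0, 1.2],
    )


def one_factor_group(label: str = "right", n: int = 150) -> GroupLatentConfig:
    """A purely one-factor group (factor-2 loadings all zero; null model)."""
    return GroupLatentConfig(
        label=label,
        n=n,
        task_means=[2.0, 2.0, 2.2, 4.0, 2.2, 0.5],
        loadings_f1=[0.4, 0.8, 0.9, 1.0, 0.9, 0.7],
        loadings_f2=[0.0] * 6,
        factor1_var=4.0,
        residual_vars=[3.0, 1.2, 1.0, 1.0, 1.0, 1.5],
    )


# ======================================================================
# Raw recordings
# ======================================================================
@dataclass
class ArtifactSpec:
    """Artifacts to plant in a recording.

    ``spikes``: (time_s, amplitude_in_channel_SDs, duration_s, channel) with
    channel one of 'left'|'right'|'both'. ``dropouts``: (start_s, end_s)
    intervals where both channels collapse toward zero.
    """

    spikes: list[tuple] = field(default_factory=list)
    dropouts: list[tuple] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.spikes and not self.dropouts


@dataclass
class RecordingConfig:
    """Parameters of the synthetic bilateral CBFV recording.

    The trial structure mirrors the acquisition protocol: a 3 s prompt, a
    20 s task period and 10 s rest, 15 trials per task-session at a 33 s
    inter-stimulus interval. ``response_amplitude`` is the bilateral task
    response in percent signal change; the injected LI splits it
    left/right as amplitude +/- LI/2.
    """

    fs: float = 100.0
    heart_rate_bpm: float = 70.0
    heart_rate_jitter: float = 0.05
    n_trials: int = 15
    isi: float = 33.0
    prompt_dur: float = 3.0
    task_dur: float = 20.0
    rest_dur: float = 10.0
    response_amplitude: float = 3.0
    response_rise: float = 3.0
    response_fall: float = 5.0
    noise_sd: float = 0.0
    pulsatility: float = 0.5
    baseline_level: float = 50.0
    pre_time: float = 10.0
    post_time: float = 10.0
    artifacts: Optional[ArtifactSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.fs < 50:
            raise ValueError("sampling rate must be >= 50 Hz before down-sampling")
        if self.fs % 25 != 0:
            raise ValueError("sampling rate must be divisible by 25 for exact decimation")
        if self.n_trials < 1:
            raise ValueError("trial count must be >= 1")

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc.pop("artifacts")
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "RecordingConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("config file must state a seed")
        return cls(**doc)


def _cardiac_pulse(phase: np.ndarray, rise: float = 0.06, decay: float = 0.25) -> np.ndarray:
    """Asymmetric pulse: fast systolic rise, exponential diastolic decay."""
    return (1.0 - np.exp(-phase / rise)) * np.exp(-phase / decay)


def _trapezoid(t: np.ndarray, onset: float, rise: float, plateau_end: float, fall: float) -> np.ndarray:
    """Hemodynamic envelope: ramps 0->1 over ``rise`` after ``onset``, holds
    until ``plateau_end``, returns to 0 over ``fall``."""
    y = np.zeros_like(t)
    up = (t >= onset) & (t < onset + rise)
    y[up] = (t[up] - onset) / rise
    hold = (t >= onset + rise) & (t < plateau_end)
    y[hold] = 1.0
    down = (t >= plateau_end) & (t < plateau_end + fall)
    y[down] = 1.0 - (t[down] - plateau_end) / fall
    return y


def generate_recording(
    target_li,
    config: RecordingConfig,
    subject: str = "S001",
    task: str = "D",
    session: int = 1,
) -> CBFVRecording:
    """Synthesize a bilateral CBFV recording with a known injected LI.

    ``target_li`` is a scalar or per-trial array in percent-signal units;
    during each trial's task window the left-channel response exceeds the
    right by the target. Requires |target| <= 2 * response_amplitude so
    neither channel's response goes negative.
    """
    cfg = config
    li = np.broadcast_to(np.asarray(target_li, float), (cfg.n_trials,)).copy()
    if np.any(np.abs(li) > 2 * cfg.response_amplitude):
        raise ValueError("injected LI exceeds the response-amplitude ceiling (2*amplitude)")
    rng = np.random.default_rng(cfg.seed)

    duration = cfg.pre_time + cfg.n_trials * cfg.isi + cfg.post_time
    n = int(round(duration * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    # jittered beat train
    mean_ibi = 60.0 / cfg.heart_rate_bpm
    beats = [0.0]
    while beats[-1] < duration:
        beats.append(beats[-1] + mean_ibi * (1.0 + cfg.heart_rate_jitter * rng.uniform(-1, 1)))
    beats = np.asarray(beats)
    prev = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, len(beats) - 1)
    pulse = _cardiac_pulse(t - beats[prev])

    onsets = cfg.pre_time + np.arange(cfg.n_trials) * cfg.isi
    resp_left = np.zeros(n)
    resp_right = np.zeros(n)
    for k, t0 in enumerate(onsets):
        env = _trapezoid(
            t,
            onset=t0 + cfg.prompt_dur,
            rise=cfg.response_rise,
            plateau_end=t0 + cfg.prompt_dur + cfg.task_dur,
            fall=cfg.response_fall,
        )
        resp_left += (cfg.response_amplitude + li[k] / 2.0) * env
        resp_right += (cfg.response_amplitude - li[k] / 2.0) * env

    base = cfg.baseline_level * (1.0 + cfg.pulsatility * pulse)
    left = base * (1.0 + resp_left / 100.0)
    right = base * (1.0 + resp_right / 100.0)
    if cfg.noise_sd > 0:
        left = left + rng.normal(0.0, cfg.noise_sd, n)
        right = right + rng.normal(0.0, cfg.noise_sd, n)

    rec = CBFVRecording(
        fs=cfg.fs,
        time=t,
        left=left,
        right=right,
        marker_times=onsets,
        subject=subject,
        task=task,
        session=session,
    )
    if cfg.artifacts is not None and not cfg.artifacts.is_empty():
        rec, _ = inject_artifacts(rec, cfg.artifacts)
    return rec


def inject_artifacts(
    recording: CBFVRecording,
    spec: ArtifactSpec,
    epoch_window: tuple[float, float] = (-7.0, 27.0),
) -> tuple[CBFVRecording, dict]:
    """Plant spikes/dropouts into a copy of ``recording``.

    Returns the modified copy and an artifact log mapping each artifact to
    the trials whose peri-stimulus epoch it overlaps. Spike amplitudes are
    multiples of the affected channel's SD; dropout intervals collapse both
    channels toward zero.
    """
    rec = recording.copy()
    if spec.is_empty():
        return rec, {"spikes": [], "dropouts": []}
    t = rec.time
    t_end = t[-1]
    log = {"spikes": [], "dropouts": []}

    def trials_hit(start: float, stop: float) -> list[int]:
        out = []
        for k, on in enumerate(rec.marker_times):
            if start <= on + epoch_window[1] and stop >= on + epoch_window[0]:
                out.append(k)
        return out

    for time_s, amp_sd, dur_s, channel in spec.spikes:
        if not (t[0] <= time_s <= t_end):
            raise ValueError(f"spike at {time_s}s outside recording")
        i0 = int(np.searchsorted(t, time_s))
        i1 = min(i0 + max(1, int(round(dur_s * rec.fs))), len(t))
        for ch in (("left", "right") if channel == "both" else (channel,)):
            arr = getattr(rec, ch)
            arr[i0:i1] += amp_sd * np.std(arr)
        log["spikes"].append(
            {"time_s": time_s, "channel": channel, "trials": trials_hit(time_s, time_s + dur_s)}
        )
    for start, stop in spec.dropouts:
        if start >= stop or start < t[0] or stop > t_end:
            raise ValueError(f"dropout interval ({start}, {stop}) outside recording")
        sel = (t >= start) & (t <= stop)
        rec.left[sel] = 0.01 * np.mean(rec.left)
        rec.right[sel] = 0.01 * np.mean(rec.right)
        log["dropouts"].append({"start_s": start, "end_s": stop, "trials": trials_hit(start, stop)})
    return rec, log
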