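"""Synthetic photoplethysmography (PPG) cohorts with controllable apnea episodes.

A PPG waveform is modelled as a train of beats, each beat a sum of Gaussian
bumps (systolic peak plus dicrotic hump) placed at fixed fractions of the beat
period, amplitude-modulated by respiration, riding on low-frequency baseline
wander, with additive white sensor noise.  Sleep-apnea (SAS) recordings are the
same waveforms interrupted by apnea episodes: the pulse-wave amplitude is
attenuated during each episode and the instantaneous heart rate dips during the
event and rebounds afterwards — the classic cyclic bradycardia/tachycardia
pattern of obstructive apnea.  SAS subjects additionally carry elevated
beat-to-beat heart-rate variability, another well-described apnea signature,
so that the subject-level class label is expressed throughout the recording
and not only inside episodes.

All generation is a pure function of (configuration, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "SynthConfig",
    "ApneaEventSpec",
    "EventModel",
    "PPGRecord",
    "generate_baseline_ppg",
    "inject_apnea_events",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

#: default beat morphology: (amplitude, center / period, width / period)
#: systolic peak followed by a diastolic (dicrotic) hump
DEFAULT_MORPHOLOGY = ((1.0, 0.28, 0.10), (0.45, 0.62, 0.16))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one subject's baseline (apnea-free) PPG waveform."""

    sampling_rate_hz: float = 100.0
    duration_s: float = 600.0
    mean_heart_rate_bpm: float = 70.0
    hrv_sd_bpm: float = 2.0
    beat_morphology: tuple = DEFAULT_MORPHOLOGY
    respiratory_modulation_depth: float = 0.15
    respiratory_rate_bpm: float = 15.0
    baseline_wander_amplitude: float = 0.3
    sensor_noise_sd: float = 0.02
    beat_amplitude_jitter_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not self.mean_heart_rate_bpm > 0:
            raise ValueError(f"mean_heart_rate_bpm must be positive, got {self.mean_heart_rate_bpm}")
        if self.hrv_sd_bpm < 0:
            raise ValueError(f"hrv_sd_bpm must be non-negative, got {self.hrv_sd_bpm}")
        if not 0 <= self.respiratory_modulation_depth < 1:
            raise ValueError(
                "respiratory_modulation_depth must lie in [0, 1), got "
                f"{self.respiratory_modulation_depth}"
            )
        if not self.respiratory_rate_bpm > 0:
            raise ValueError(f"respiratory_rate_bpm must be positive, got {self.respiratory_rate_bpm}")
        if self.baseline_wander_amplitude < 0:
            raise ValueError(
                f"baseline_wander_amplitude must be non-negative, got {self.baseline_wander_amplitude}"
            )
        if self.sensor_noise_sd < 0:
            raise ValueError(f"sensor_noise_sd must be non-negative, got {self.sensor_noise_sd}")
        if self.beat_amplitude_jitter_sd < 0:
            raise ValueError(
                f"beat_amplitude_jitter_sd must be non-negative, got {self.beat_amplitude_jitter_sd}")
        if not self.beat_morphology:
            raise ValueError("beat_morphology must contain at least one Gaussian component")
        for amp, center, width in self.beat_morphology:
            if not width > 0:
                raise ValueError(f"beat_morphology widths must be positive, got {width}")


@dataclass(frozen=True)
class ApneaEventSpec:
    """One apnea episode: when it happens and how it deforms the waveform.

    ``amplitude_attenuation`` is the fractional pulse-wave-amplitude drop inside
    the episode (1.0 = pulse fully suppressed).  ``hr_dip_bpm`` is the
    bradycardic heart-rate shift during the event; ``hr_rebound_bpm`` the
    tachycardic overshoot decaying over ``rebound_duration_s`` afterwards.
    """

    onset_s: float
    duration_s: float
    amplitude_attenuation: float = 0.8
    hr_dip_bpm: float = 5.0
    hr_rebound_bpm: float = 10.0
    rebound_duration_s: float = 10.0

    def validate(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be non-negative, got {self.onset_s}")
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not 0 <= self.amplitude_attenuation <= 1:
            raise ValueError(
                f"amplitude_attenuation must lie in [0, 1], got {self.amplitude_attenuation}"
            )
        if self.hr_rebound_bpm < 0:
            raise ValueError(f"hr_rebound_bpm must be non-negative, got {self.hr_rebound_bpm}")
        if self.rebound_duration_s < 0:
            raise ValueError(f"rebound_duration_s must be non-negative, got {self.rebound_duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class PPGRecord:
    """One subject's waveform with metadata and (synthetic) ground-truth events."""

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str
    label: str  # "healthy" | "sas"
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("healthy", "sas"):
            raise ValueError(f"label must be 'healthy' or 'sas', got {self.label!r}")
        if self.label == "healthy" and self.events:
            raise ValueError("a healthy record cannot carry apnea events")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


def _render_beats(onsets: np.ndarray, periods: np.ndarray, amp_factors: np.ndarray,
                  morphology, fs: float, n_samples: int) -> np.ndarray:
    """Sum per-beat Gaussian bumps onto the sample grid.

    Each component is rendered over +/- 4 sigma around its center; windows are
    computed in integer samples relative to the beat onset so that identical
    periods give bit-identical beat shapes (exact periodicity when HRV = 0).
    """
    pulse = np.zeros(n_samples)
    for onset, period, beat_amp in zip(onsets, periods, amp_factors):
        onset_idx = int(round(onset * fs))
        for amp, center, width in morphology:
            sigma = width * period * fs  # samples
            c = center * period * fs     # samples, relative to onset
            half = int(np.ceil(4 * sigma))
            lo = int(np.floor(c)) - half
            hi = int(np.ceil(c)) + half + 1
            idx0 = max(onset_idx + lo, 0)
            idx1 = min(onset_idx + hi, n_samples)
            if idx0 >= idx1:
                continue
            rel = np.arange(idx0 - onset_idx, idx1 - onset_idx)
            pulse[idx0:idx1] += beat_amp * amp * np.exp(-0.5 * ((rel - c) / sigma) ** 2)
    return pulse


def generate_baseline_ppg(config: SynthConfig, rng: np.random.Generator | None = None,
                          subject_id: str = "subject-0") -> PPGRecord:
    """Generate one healthy (apnea-free) PPG record.

    Beat periods are drawn from Normal(60 / mean_heart_rate, sd) truncated to
    positive values, where the period sd is the heart-rate sd propagated
    through T = 60/HR.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    mean_period = 60.0 / config.mean_heart_rate_bpm
    period_sd = 60.0 * config.hrv_sd_bpm / config.mean_heart_rate_bpm ** 2

    # draw enough beats to cover the recording, then trim
    n_beats = int(np.ceil(config.duration_s / mean_period)) + 8
    if period_sd > 0:
        periods = rng.normal(mean_period, period_sd, size=n_beats)
        periods = np.clip(periods, 0.25, None)  # truncate to positive (>= 250 ms)
    else:
        periods = np.full(n_beats, mean_period)
    onsets = np.concatenate([[0.0], np.cumsum(periods[:-1])])
    keep = onsets < config.duration_s + mean_period
    onsets, periods = onsets[keep], periods[keep]

    # beat-to-beat pulse-wave-amplitude variability (sympathetic modulation)
    if config.beat_amplitude_jitter_sd > 0:
        amp_factors = np.clip(
            rng.normal(1.0, config.beat_amplitude_jitter_sd, size=len(onsets)), 0.3, None)
    else:
        amp_factors = np.ones(len(onsets))

    pulse = _render_beats(onsets, periods, amp_factors, config.beat_morphology, fs, n)

    resp_phase = rng.uniform(0, 2 * np.pi)
    resp = 1.0 + config.respiratory_modulation_depth * np.sin(
        2 * np.pi * config.respiratory_rate_bpm / 60.0 * t + resp_phase
    )
    wander_phase = rng.uniform(0, 2 * np.pi)
    wander = config.baseline_wander_amplitude * np.sin(2 * np.pi * 0.08 * t + wander_phase)
    noise = rng.normal(0.0, config.sensor_noise_sd, size=n) if config.sensor_noise_sd > 0 else 0.0

    samples = pulse * resp + wander + noise
    return PPGRecord(samples=samples, sampling_rate_hz=fs, subject_id=subject_id,
                     label="healthy", events=[])


def _estimate_heart_rate(x: np.ndarray, fs: float) -> float:
    """Median beat rate (bpm) from systolic peaks; falls back to 70 bpm."""
    if len(x) < fs:
        return 70.0
    height = np.min(x) + 0.5 * (np.max(x) - np.min(x))
    peaks, _ = find_peaks(x, height=height, distance=int(0.3 * fs))
    if len(peaks) < 3:
        return 70.0
    return float(60.0 * fs / np.median(np.diff(peaks)))


def _event_footprint(ev: ApneaEventSpec, ramp_s: float) -> tuple[float, float]:
    return (ev.onset_s - ramp_s, ev.end_s + max(ev.rebound_duration_s, ramp_s))


def inject_apnea_events(record: PPGRecord, events: list, ramp_s: float = 1.2) -> PPGRecord:
    """Return a new SAS-labelled record with apnea episodes stamped in.

    Within each event the oscillatory (pulse) component is scaled by
    ``1 - amplitude_attenuation`` with raised-cosine on/off ramps of ``ramp_s``
    seconds immediately before the onset and after the end; the local baseline
    is preserved.  The instantaneous heart rate is lowered by ``hr_dip_bpm``
    during the event and raised by ``hr_rebound_bpm`` (decaying over
    ``rebound_duration_s``) afterwards, realised as a locality-preserving time
    warp of the affected samples.  Samples outside events, ramps and rebounds
    are bit-identical to the input.
    """
    fs = record.sampling_rate_hz
    n = len(record.samples)
    duration = n / fs
    events = sorted(events, key=lambda e: e.onset_s)
    for ev in events:
        ev.validate()
        if ev.end_s > duration + 1e-9:
            raise ValueError(
                f"event ending at {ev.end_s:.2f}s exceeds record duration {duration:.2f}s"
            )
    for a, b in zip(events, events[1:]):
        if _event_footprint(a, ramp_s)[1] > _event_footprint(b, ramp_s)[0]:
            raise ValueError(
                f"events at {a.onset_s:.2f}s and {b.onset_s:.2f}s overlap (including ramps)"
            )

    x = record.samples.copy()
    for ev in events:
        i0 = int(round(ev.onset_s * fs))
        i1 = min(int(round(ev.end_s * fs)), n)
        r = int(round(ramp_s * fs))

        # --- heart-rate perturbation: time warp over event + rebound -------
        if ev.hr_dip_bpm != 0.0 or ev.hr_rebound_bpm != 0.0:
            i_reb = min(i1 + int(round(ev.rebound_duration_s * fs)), n)
            hr0 = _estimate_heart_rate(x[max(i0 - int(5 * fs), 0):i1], fs)
            m = i_reb - i0
            if m > 4:
                speed = np.ones(m)
                speed[: i1 - i0] = max(1.0 - ev.hr_dip_bpm / hr0, 0.3)
                n_reb = m - (i1 - i0)
                if n_reb > 0 and ev.hr_rebound_bpm > 0:
                    decay = np.exp(-3.0 * np.arange(n_reb) / max(n_reb, 1))
                    speed[i1 - i0:] = 1.0 + (ev.hr_rebound_bpm / hr0) * decay
                u = np.concatenate([[0.0], np.cumsum(speed[:-1])])
                u *= (m - 1) / u[-1]  # pin both endpoints: warp is local
                x[i0:i_reb] = np.interp(u, np.arange(m), x[i0:i_reb])

        # --- amplitude attenuation with raised-cosine ramps ----------------
        j0, j1 = max(i0 - r, 0), min(i1 + r, n)
        env = np.ones(j1 - j0)
        att = ev.amplitude_attenuation
        core0, core1 = i0 - j0, i1 - j0
        env[core0:core1] = 1.0 - att
        ramp_in = i0 - j0
        if ramp_in > 0:
            s = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_in) / ramp_in))
            env[:ramp_in] = 1.0 - att * s
        ramp_out = j1 - i1
        if ramp_out > 0:
            s = 0.5 * (1 + np.cos(np.pi * np.arange(ramp_out) / ramp_out))
            env[core1:] = 1.0 - att * s

        # local baseline over ~one beat so only the oscillatory part attenuates
        hr_loc = _estimate_heart_rate(x[max(j0 - int(5 * fs), 0):max(j0, int(5 * fs))], fs)
        win = max(int(round(fs * 60.0 / hr_loc)), 3)
        pad = win  # baseline filter reads beyond the window but writes inside it
        k0, k1 = max(j0 - pad, 0), min(j1 + pad, n)
        base = uniform_filter1d(x[k0:k1], size=win, mode="nearest")[j0 - k0:j1 - k0]
        x[j0:j1] = base + (x[j0:j1] - base) * env

    return PPGRecord(samples=x, sampling_rate_hz=fs, subject_id=record.subject_id,
                     label="sas", events=list(events))


@dataclass(frozen=True)
class EventModel:
    """Distributions from which a SAS subject's apnea episodes are drawn.

    Defaults describe a severe-range cohort (~45 events/h, episodes of
    10-60 s), typical of a sleep-center referral population.
    """

    rate_per_hour: float = 60.0
    duration_mean_s: float = 25.0
    duration_sd_s: float = 7.0
    duration_min_s: float = 15.0
    duration_max_s: float = 45.0
    attenuation_range: tuple = (0.7, 0.98)
    hr_dip_range: tuple = (10.0, 25.0)
    hr_rebound_range: tuple = (10.0, 20.0)
    rebound_duration_range: tuple = (8.0, 15.0)
    ramp_s: float = 1.2

    def sample_events(self, duration_s: float, rng: np.random.Generator) -> list:
        """Draw a non-overlapping event list; SAS records carry >= 1 event.

        The event count is Poisson(rate x duration), so the expected count
        matches the nominal rate whenever the recording can hold it.  Events
        are placed by distributing the free time (duration minus the summed
        footprints of event + ramps + rebound) over the inter-event gaps with
        a uniform stick-breaking draw, which always yields disjoint
        footprints; events are shed only when they physically cannot fit.
        """
        expected = self.rate_per_hour * duration_s / 3600.0
        n = max(int(rng.poisson(expected)), 1)
        while n >= 1:
            durs = np.clip(rng.normal(self.duration_mean_s, self.duration_sd_s, n),
                           self.duration_min_s, self.duration_max_s)
            rebs = rng.uniform(*self.rebound_duration_range, size=n)
            foot = durs + np.maximum(rebs, self.ramp_s) + self.ramp_s
            free = duration_s - self.ramp_s - foot.sum()
            if free <= 0:
                n -= 1  # recording too short/busy for n events; shed one
                continue
            gaps = rng.dirichlet(np.ones(n + 1)) * free
            onsets = self.ramp_s + np.cumsum(gaps[:-1]) + np.concatenate(
                [[0.0], np.cumsum(foot[:-1])])
            return [
                ApneaEventSpec(
                    onset_s=float(onsets[i]),
                    duration_s=float(durs[i]),
                    amplitude_attenuation=float(rng.uniform(*self.attenuation_range)),
                    hr_dip_bpm=float(rng.uniform(*self.hr_dip_range)),
                    hr_rebound_bpm=float(rng.uniform(*self.hr_rebound_range)),
                    rebound_duration_s=float(rebs[i]),
                )
                for i in range(n)
            ]
        return []


def _jitter_config(config: SynthConfig, rng: np.random.Generator, sas: bool) -> SynthConfig:
    """Per-subject physiological variability.

    SAS subjects draw an elevated beat-to-beat HR variability — the cyclic
    bradycardia/tachycardia signature of apnea — so their class is expressed
    throughout the night, not only inside annotated episodes.
    """
    morph = tuple(
        (a * rng.uniform(0.85, 1.15), c * rng.uniform(0.97, 1.03), w * rng.uniform(0.9, 1.1))
        for a, c, w in config.beat_morphology
    )
    hrv = rng.uniform(4.0, 8.0) if sas else rng.uniform(1.0, 2.5)
    amp_jitter = rng.uniform(0.25, 0.45) if sas else rng.uniform(0.02, 0.08)
    return replace(
        config,
        beat_amplitude_jitter_sd=float(amp_jitter),
        mean_heart_rate_bpm=float(np.clip(rng.normal(70.0, 6.0), 50.0, 95.0)),
        hrv_sd_bpm=float(hrv),
        beat_morphology=morph,
        respiratory_modulation_depth=float(rng.uniform(0.10, 0.25)),
        respiratory_rate_bpm=float(rng.uniform(12.0, 18.0)),
        baseline_wander_amplitude=float(rng.uniform(0.2, 0.4)),
    )


def generate_cohort(n_healthy: int, n_sas: int, config: SynthConfig | None = None,
                    event_model: EventModel | None = None, seed: int = 0) -> list:
    """Generate a labelled cohort of ``n_healthy`` + ``n_sas`` subjects.

    Deterministic in (arguments, seed): each subject consumes an independent
    child stream of the seed sequence.
    """
    if n_healthy < 0 or n_sas < 0:
        raise ValueError("subject counts must be non-negative")
    if n_healthy + n_sas < 1:
        raise ValueError("cohort must contain at least one subject")
    config = config or SynthConfig()
    config.validate()
    event_model = event_model or EventModel()

    streams = np.random.SeedSequence(seed).spawn(n_healthy + n_sas)
    records = []
    for i in range(n_healthy):
        rng = np.random.default_rng(streams[i])
        cfg = _jitter_config(config, rng, sas=False)
        records.append(generate_baseline_ppg(cfg, rng, subject_id=f"H{i:03d}"))
    for j in range(n_sas):
        rng = np.random.default_rng(streams[n_healthy + j])
        cfg = _jitter_config(config, rng, sas=True)
        rec = generate_baseline_ppg(cfg, rng, subject_id=f"S{j:03d}")
        events = event_model.sample_events(cfg.duration_s, rng)
        records.append(inject_apnea_events(rec, events, ramp_s=event_model.ramp_s))
    return records


def save_cohort(records: list, out_dir: str | Path) -> None:
    """Serialise a cohort: one ``<subject_id>.npy`` per subject + CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label", "sampling_rate_hz", "duration_s", "n_events"])
        for rec in records:
            np.save(out_dir / f"{rec.subject_id}.npy", rec.samples)
            w.writerow([rec.subject_id, rec.label, rec.sampling_rate_hz,
                        f"{rec.duration_s:.3f}", len(rec.events)])
    with open(out_dir / "events.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "onset_s", "duration_s", "amplitude_attenuation",
                    "hr_dip_bpm", "hr_rebound_bpm", "rebound_duration_s"])
        for rec in records:
            for ev in rec.events:
                w.writerow([rec.subject_id, ev.onset_s, ev.duration_s,
                            ev.amplitude_attenuation, ev.hr_dip_bpm,
                            ev.hr_rebound_bpm, ev.rebound_duration_s])


def load_cohort(in_dir: str | Path) -> list:
    in_dir = Path(in_dir)
    events_by_subject: dict[str, list] = {}
    ev_path = in_dir / "events.csv"
    if ev_path.exists():
        with open(ev_path, newline="") as fh:
            for row in csv.DictReader(fh):
                events_by_subject.setdefault(row["subject_id"], []).append(
                    ApneaEventSpec(
                        onset_s=float(row["onset_s"]),
                        duration_s=float(row["duration_s"]),
                        amplitude_attenuation=float(row["amplitude_attenuation"]),
                        hr_dip_bpm=float(row["hr_dip_bpm"]),
                        hr_rebound_bpm=float(row["hr_rebound_bpm"]),
                        rebound_duration_s=float(row["rebound_duration_s"]),
                    )
                )
    records = []
    with open(in_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(PPGRecord(
                samples=np.load(in_dir / f"{row['subject_id']}.npy"),
                sampling_rate_hz=float(row["sampling_rate_hz"]),
                subject_id=row["subject_id"],
                label=row["label"],
                events=events_by_subject.get(row["subject_id"], []),
            ))
    return records
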