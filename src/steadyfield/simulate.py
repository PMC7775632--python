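"""Synthetic source-space cohort generator.

Emulates the statistical structure of epoched auditory MEG responses to 40 Hz
click trains in a two-group (neurotypical vs ASD) pediatric cohort, directly in
source space: every vertex carries a fixed MNI coordinate and a trials x time
current waveform composed of

* child-like transient deflections (P50m ~40 ms, P100m ~82 ms, both positive),
* a 40 Hz auditory steady-state response (ASSR) whose trial-to-trial phase is
  von Mises distributed (concentration ``assr_phase_kappa`` controls ITPC),
* a negative-polarity sustained field (SF): logistic rise from a configurable
  onset latency, plateau until stimulus offset (500 ms), exponential decay,
* 1/f ("pink") trial noise.

Group / condition structure: contralateral responses exceed ipsilateral ones
(``contra_gain``), right-hemisphere responses exceed left (``right_gain``);
the ASD condition attenuates the SF bilaterally (``asd_sf_amplitude_scale``),
delays its onset in the left hemisphere only (``asd_left_onset_delay``), and
shifts the left SF spatial cluster medially (``asd_left_sf_shift_mm``).
A minority of vertices (``flip_fraction``) carries an inverted source polarity,
as happens on opposite sulcal walls; the true labels are stored so that
polarity-alignment operations can be validated against ground truth.

All randomness flows from a single integer seed; identical parameters and seed
give bit-identical cohorts.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ClickTrainStimulus",
    "SimulationParams",
    "EpochedSourceData",
    "generate_click_train",
    "make_transient_kernel",
    "simulate_subject_epochs",
    "simulate_cohort",
    "iter_cohort_epochs",
    "simulate_psychometrics",
    "null_params",
    "CLUSTER_CENTERS",
]


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClickTrainStimulus:
    """A periodic click-train waveform and its spectral attributes.

    ``f0`` is the repetition rate (1000/soa Hz); ``f_sp`` is the greatest
    common divisor of the represented harmonics — for a plain periodic train
    it coincides with ``f0`` and is kept as a descriptive attribute only.
    """

    sampling_rate: float          # Hz
    train_duration: float         # ms
    click_duration: float         # ms
    soa: float                    # ms, stimulus onset asynchrony
    waveform: np.ndarray          # unit-amplitude samples
    f0: float                     # Hz
    n_clicks: int
    f_sp: float

    @property
    def time(self) -> np.ndarray:
        """Time axis of the waveform in ms."""
        return np.arange(self.waveform.size) * 1000.0 / self.sampling_rate


def generate_click_train(
    sampling_rate: float = 1000.0,
    train_duration: float = 500.0,
    click_duration: float = 2.0,
    soa: float = 25.0,
) -> ClickTrainStimulus:
    """Build a train of rectangular unit clicks.

    Clicks of ``click_duration`` ms are placed at onsets 0, soa, 2*soa, ...;
    one click per full SOA period fits in the train, so
    ``n_clicks = floor(train_duration / soa)`` (20 with the defaults).
    """
    if train_duration <= 0 or click_duration <= 0 or soa <= 0:
        raise ValueError("durations and SOA must be positive")
    if soa < click_duration:
        raise ValueError(
            f"clicks would overlap: soa={soa} ms < click_duration={click_duration} ms"
        )
    if sampling_rate * click_duration / 1000.0 < 1.0:
        raise ValueError("sampling_rate does not resolve click_duration")

    n_samples = int(round(train_duration * sampling_rate / 1000.0))
    waveform = np.zeros(n_samples)
    n_clicks = int(math.floor(train_duration / soa))
    for k in range(n_clicks):
        a = int(round(k * soa * sampling_rate / 1000.0))
        b = int(round((k * soa + click_duration) * sampling_rate / 1000.0))
        waveform[a : max(b, a + 1)] = 1.0

    f0 = 1000.0 / soa
    return ClickTrainStimulus(
        sampling_rate=sampling_rate,
        train_duration=train_duration,
        click_duration=click_duration,
        soa=soa,
        waveform=waveform,
        f0=f0,
        n_clicks=n_clicks,
        f_sp=f0,
    )


def make_transient_kernel(
    latency: float,
    width: float,
    polarity: int,
    amplitude: float,
    time_axis: np.ndarray,
) -> np.ndarray:
    """Gaussian-shaped deflection peaking at ``latency`` ms.

    ``width`` is the Gaussian sigma in ms; the peak sample equals
    ``polarity * amplitude``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    t0, t1 = float(time_axis[0]), float(time_axis[-1])
    if not (t0 <= latency <= t1):
        raise ValueError(f"latency {latency} ms outside epoch [{t0}, {t1}] ms")
    return polarity * amplitude * np.exp(-0.5 * ((time_axis - latency) / width) ** 2)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: Cluster centres in MNI mm (negative X = left). The SF cluster sits
#: anterolateral (and slightly inferior) to the ASSR cluster in each
#: hemisphere, matching the relative geometry of the two responses.
CLUSTER_CENTERS = {
    ("left", "assr"): (-45.5, -28.5, 11.0),
    ("right", "assr"): (50.2, -25.3, 11.1),
    ("left", "sf"): (-51.9, -20.5, 6.6),
    ("right", "sf"): (53.7, -17.2, 7.4),
}


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of the simulated study.

    Amplitudes are in arbitrary but consistent source-current units; latencies
    and durations in ms; ``assr_phase_kappa`` is the von Mises concentration
    of the trial phase at 40 Hz (``math.inf`` = perfectly phase locked).
    """

    n_per_group: int = 35
    sampling_rate: float = 1000.0
    epoch_start: float = -500.0
    epoch_end: float = 1000.0
    n_trials: int = 80
    n_vertices: int = 100

    # ASSR
    assr_amplitude: float = 2.0
    assr_phase_kappa: float = 2.0
    assr_freq: float = 40.0
    assr_ramp: float = 20.0            # raised-cosine on/off ramp, ms

    # SF (negative-polarity sustained current)
    sf_amplitude: float = -10.0
    sf_onset_latency: float = 150.0
    sf_rise_time: float = 100.0        # 10-90% logistic rise, ms
    sf_decay_tau: float = 100.0        # exponential decay after offset, ms
    stim_duration: float = 500.0

    # transients: (latency ms, sigma ms, polarity, amplitude)
    transient_kernels: tuple = ((40.0, 12.0, 1, 3.0), (82.0, 16.0, 1, 4.0))

    # condition gains
    contra_gain: float = 1.5
    right_gain: float = 1.2

    # ASD effects
    asd_sf_amplitude_scale: float = 0.85
    asd_left_onset_delay: float = 25.0
    asd_left_sf_shift_mm: float = 5.0

    # spatial structure
    assr_cluster_frac: float = 0.4
    sf_cluster_frac: float = 0.4
    cluster_sd_mm: float = 6.0
    background_gain: float = 0.2
    flip_fraction: float = 0.15

    # noise and between-subject variability
    noise_exponent: float = 1.0
    noise_sd: float = 5.0
    subject_sf_amp_cv: float = 0.3
    subject_onset_jitter_sd: float = 20.0
    subject_assr_amp_cv: float = 0.3
    trial_sf_amp_cv: float = 0.1       # trial-to-trial SF variability (free parameter)

    age_range: tuple = (7.0, 12.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contra_gain <= 0 or self.right_gain <= 0:
            raise ValueError("gains must be positive")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")
        if self.assr_phase_kappa < 0:
            raise ValueError("assr_phase_kappa must be >= 0")
        if self.asd_sf_amplitude_scale <= 0:
            raise ValueError("asd_sf_amplitude_scale must be positive")
        if self.n_trials < 1 or self.n_vertices < 1:
            raise ValueError("n_trials and n_vertices must be >= 1")
        if self.epoch_end <= self.epoch_start:
            raise ValueError("epoch_end must exceed epoch_start")

    def time_axis(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        n = int(round((self.epoch_end - self.epoch_start) / step))
        return self.epoch_start + step * np.arange(n)


def null_params(params: SimulationParams) -> SimulationParams:
    """Neutralize every ASD effect (null simulation: groups exchangeable)."""
    return replace(
        params,
        asd_sf_amplitude_scale=1.0,
        asd_left_onset_delay=0.0,
        asd_left_sf_shift_mm=0.0,
    )


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EpochedSourceData:
    """Per-subject, per-condition trials x vertices x time source array."""

    subject_id: str
    group: str                      # "NT" | "ASD"
    hemisphere: str                 # "left" | "right"
    stimulated_ear: str             # "left" | "right"
    data: np.ndarray                # (n_trials, n_vertices, n_times)
    time_axis: np.ndarray           # ms
    vertex_coords: np.ndarray       # (n_vertices, 3) MNI mm
    vertex_polarity_truth: np.ndarray | None = None   # hidden +-1 labels

    def __post_init__(self) -> None:
        steps = np.diff(self.time_axis)
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time_axis must be strictly increasing and uniform")
        if self.data.shape[-1] != self.time_axis.size:
            raise ValueError("data / time_axis length mismatch")
        if self.data.shape[1] != self.vertex_coords.shape[0]:
            raise ValueError("data / vertex_coords vertex-count mismatch")

    @property
    def laterality(self) -> str:
        return "contralateral" if self.hemisphere != self.stimulated_ear else "ipsilateral"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Internal building blocks
# ---------------------------------------------------------------------------

def _one_over_f_noise(
    rng: np.random.Generator,
    n_series: int,
    n_times: int,
    exponent: float,
    sd: float,
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent, unit-free.

    Scaled analytically so each series has per-sample standard deviation
    ``sd`` in expectation (no data-dependent normalization, which would break
    independence across series).
    """
    n_freq = n_times // 2 + 1
    weights = np.zeros(n_freq)
    k = np.arange(1, n_freq)
    weights[1:] = k ** (-exponent / 2.0)          # amplitude ~ f^(-exp/2)
    # complex spectrum with unit-variance real/imag parts
    spec = rng.standard_normal((n_series, n_freq)) + 1j * rng.standard_normal(
        (n_series, n_freq)
    )
    spec *= weights
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    # Var(x_t) = (2*sum w_k^2 over interior bins + edge terms) / n^2, with
    # Re/Im each unit variance.  DC weight is zero.
    w2 = weights**2
    var = 2.0 * w2[1:].sum() / n_times**2
    if n_times % 2 == 0:
        var -= w2[-1] / n_times**2               # Nyquist bin enters once
    x *= sd / math.sqrt(var)
    return x


def _assr_envelope(t: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Unit envelope: raised-cosine ramps into a plateau over 0..stim_duration."""
    env = np.zeros_like(t)
    ramp = params.assr_ramp
    dur = params.stim_duration
    on = (t >= 0) & (t <= dur)
    env[on] = 1.0
    rise = (t >= 0) & (t < ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / ramp))
    fall = (t > dur - ramp) & (t <= dur)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (dur - t[fall]) / ramp))
    return env


def _sf_shape(t: np.ndarray, onset_latency: float, params: SimulationParams) -> np.ndarray:
    """Unit-plateau SF waveform: logistic rise, plateau, exponential decay."""
    tau = params.sf_rise_time / (2.0 * math.log(9.0))   # 10-90% = rise_time
    t_half = onset_latency + params.sf_rise_time / 2.0
    shape = 1.0 / (1.0 + np.exp(-(t - t_half) / tau))
    dur = params.stim_duration
    after = t > dur
    level = 1.0 / (1.0 + math.exp(-(dur - t_half) / tau))
    shape[after] = level * np.exp(-(t[after] - dur) / params.sf_decay_tau)
    return shape


@dataclass
class _SubjectProfile:
    """Latent per-subject draws shared across ears and hemispheres."""

    sf_amp_factor: float
    assr_amp_factor: float
    onset_jitter: float
    coords: dict            # hemisphere -> (n_vertices, 3)
    assr_gain: dict         # hemisphere -> (n_vertices,)
    sf_gain: dict
    polarity: dict          # hemisphere -> (n_vertices,) of +-1


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Positive multiplicative factor with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _subject_rng(params: SimulationParams, subject_id: str, stream: int) -> np.random.Generator:
    key = zlib.crc32(subject_id.encode())
    return np.random.default_rng(np.random.SeedSequence([params.seed, key, stream]))


def _make_profile(params: SimulationParams, subject_id: str, group: str) -> _SubjectProfile:
    rng = _subject_rng(params, subject_id, 0)
    n = params.n_vertices
    n_assr = int(round(params.assr_cluster_frac * n))
    n_sf = int(round(params.sf_cluster_frac * n))
    n_bg = n - n_assr - n_sf
    coords, assr_gain, sf_gain, polarity = {}, {}, {}, {}
    for hemi in ("left", "right"):
        c_assr = np.array(CLUSTER_CENTERS[(hemi, "assr")])
        c_sf = np.array(CLUSTER_CENTERS[(hemi, "sf")])
        if group == "ASD" and hemi == "left":
            # medial displacement of the left SF cluster (toward x = 0)
            c_sf = c_sf + np.array([params.asd_left_sf_shift_mm, 0.0, 0.0])
        sd = params.cluster_sd_mm
        xyz = np.vstack(
            [
                rng.normal(c_assr, sd, size=(n_assr, 3)),
                rng.normal(c_sf, sd, size=(n_sf, 3)),
                rng.normal((c_assr + c_sf) / 2.0, 3.0 * sd, size=(n_bg, 3)),
            ]
        )
        g_assr = np.full(n, params.background_gain)
        g_sf = np.full(n, params.background_gain)
        g_assr[:n_assr] = 1.0
        g_sf[n_assr : n_assr + n_sf] = 1.0
        pol = np.ones(n)
        n_flip = int(round(params.flip_fraction * n))
        if n_flip:
            pol[rng.choice(n, size=n_flip, replace=False)] = -1.0
        coords[hemi] = xyz
        assr_gain[hemi] = g_assr
        sf_gain[hemi] = g_sf
        polarity[hemi] = pol
    return _SubjectProfile(
        sf_amp_factor=_lognormal_factor(rng, params.subject_sf_amp_cv),
        assr_amp_factor=_lognormal_factor(rng, params.subject_assr_amp_cv),
        onset_jitter=float(rng.normal(0.0, params.subject_onset_jitter_sd))
        if params.subject_onset_jitter_sd > 0
        else 0.0,
        coords=coords,
        assr_gain=assr_gain,
        sf_gain=sf_gain,
        polarity=polarity,
    )


# ---------------------------------------------------------------------------
# Subject- and cohort-level simulation
# ---------------------------------------------------------------------------

def simulate_subject_epochs(
    params: SimulationParams,
    subject_id: str,
    group: str,
    ear: str,
) -> dict[str, EpochedSourceData]:
    """Simulate one stimulation condition (ear) for one subject.

    Returns ``{"left": EpochedSourceData, "right": EpochedSourceData}``.
    Subject-level latent draws (anatomy, amplitude factors, onset jitter) are
    derived from the seed and subject id only, so both ear conditions of a
    subject share them.
    """
    if group not in ("NT", "ASD"):
        raise ValueError(f"unknown group {group!r}")
    if ear not in ("left", "right"):
        raise ValueError(f"unknown ear {ear!r}")

    profile = _make_profile(params, subject_id, group)
    t = params.time_axis()
    env = _assr_envelope(t, params)
    transients = np.zeros_like(t)
    for latency, width, pol, amp in params.transient_kernels:
        transients += make_transient_kernel(latency, width, pol, amp, t)

    out: dict[str, EpochedSourceData] = {}
    ear_code = 1 if ear == "left" else 2
    for hemi in ("left", "right"):
        rng = _subject_rng(params, subject_id, 10 * ear_code + (0 if hemi == "left" else 1))
        gain = (params.contra_gain if hemi != ear else 1.0) * (
            params.right_gain if hemi == "right" else 1.0
        )

        # per-trial ASSR phase
        if math.isinf(params.assr_phase_kappa):
            phases = np.zeros(params.n_trials)
        elif params.assr_phase_kappa == 0:
            phases = rng.uniform(-np.pi, np.pi, params.n_trials)
        else:
            phases = rng.vonmises(0.0, params.assr_phase_kappa, params.n_trials)
        omega = 2.0 * np.pi * params.assr_freq / 1000.0      # rad per ms
        assr = (
            params.assr_amplitude
            * profile.assr_amp_factor
            * env[None, :]
            * np.sin(omega * t[None, :] + phases[:, None])
        )

        onset = params.sf_onset_latency + profile.onset_jitter
        sf_amp = params.sf_amplitude * profile.sf_amp_factor
        if group == "ASD":
            sf_amp *= params.asd_sf_amplitude_scale
            if hemi == "left":
                onset += params.asd_left_onset_delay
        sf_unit = _sf_shape(t, onset, params)
        if params.trial_sf_amp_cv > 0:
            trial_fac = np.maximum(
                rng.normal(1.0, params.trial_sf_amp_cv, params.n_trials), 0.0
            )
        else:
            trial_fac = np.ones(params.n_trials)
        sf = sf_amp * trial_fac[:, None] * sf_unit[None, :]

        g_a = profile.assr_gain[hemi]
        g_s = profile.sf_gain[hemi]
        g_t = 0.5 * (g_a + g_s)
        signal = (
            g_a[None, :, None] * assr[:, None, :]
            + g_s[None, :, None] * sf[:, None, :]
            + g_t[None, :, None] * transients[None, None, :]
        )
        signal *= gain * profile.polarity[hemi][None, :, None]

        if params.noise_sd > 0:
            noise = _one_over_f_noise(
                rng,
                params.n_trials * params.n_vertices,
                t.size,
                params.noise_exponent,
                params.noise_sd,
            ).reshape(params.n_trials, params.n_vertices, t.size)
            signal += noise

        out[hemi] = EpochedSourceData(
            subject_id=subject_id,
            group=group,
            hemisphere=hemi,
            stimulated_ear=ear,
            data=signal,
            time_axis=t,
            vertex_coords=profile.coords[hemi],
            vertex_polarity_truth=profile.polarity[hemi].copy(),
        )
    return out


def _subject_table(params: SimulationParams) -> list[tuple[str, str]]:
    return [(f"NT{i + 1:02d}", "NT") for i in range(params.n_per_group)] + [
        (f"ASD{i + 1:02d}", "ASD") for i in range(params.n_per_group)
    ]


def iter_cohort_epochs(
    params: SimulationParams,
) -> Iterator[tuple[str, str, str, dict[str, EpochedSourceData]]]:
    """Yield ``(subject_id, group, ear, {hemisphere: epochs})`` lazily.

    Preferred over :func:`simulate_cohort` for realistic sizes, where holding
    every epoch array in memory at once is wasteful.
    """
    for subject_id, group in _subject_table(params):
        for ear in ("left", "right"):
            yield subject_id, group, ear, simulate_subject_epochs(
                params, subject_id, group, ear
            )


def simulate_cohort(
    params: SimulationParams,
) -> tuple[list[EpochedSourceData], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Returns every :class:`EpochedSourceData` (4 per subject: 2 ears x 2
    hemispheres) plus the cohort metadata table.  Deterministic under
    ``params.seed``.
    """
    if params.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    epochs = [
        e
        for _, _, _, per_hemi in iter_cohort_epochs(params)
        for e in per_hemi.values()
    ]
    cohort = simulate_psychometrics(
        params.n_per_group, seed=params.seed, age_range=params.age_range
    )
    return epochs, cohort


# ---------------------------------------------------------------------------
# Psychometrics
# ---------------------------------------------------------------------------

#: Per-group scale means and SDs (NT, ASD) for the default pediatric cohort.
PSYCHOMETRIC_DEFAULTS = {
    "age": {"ASD": (9.69, 1.5), "NT": (10.08, 1.5)},
    "sequential_iq": {"ASD": (78.9, 19.1), "NT": (106.8, 13.7)},
    "simultaneous_iq": {"ASD": (89.2, 22.0), "NT": (123.3, 15.3)},
    "mpi": {"ASD": (84.3, 22.0), "NT": (121.2, 12.6)},
    "srs": {"ASD": (104.8, 23.9), "NT": (45.2, 22.6)},
    "scq": {"ASD": (24.7, 5.4), "NT": (6.6, 4.2)},
    "aq": {"ASD": (90.3, 12.2), "NT": (53.7, 13.0)},
}

_SCALES = ["sequential_iq", "simultaneous_iq", "mpi", "srs", "scq", "aq"]


def _default_correlation() -> np.ndarray:
    """Within-group correlations: IQ block ~0.7, autism block ~0.55, cross ~-0.2."""
    corr = np.eye(6)
    iq = slice(0, 3)
    autism = slice(3, 6)
    corr[iq, iq.start : iq.stop] = np.where(np.eye(3), 1.0, 0.7)
    corr[autism, autism.start : autism.stop] = np.where(np.eye(3), 1.0, 0.55)
    corr[iq, autism.start : autism.stop] = -0.2
    corr[autism, iq.start : iq.stop] = -0.2
    return corr


def simulate_psychometrics(
    n_per_group: int,
    group_means: dict | None = None,
    group_sds: dict | None = None,
    correlation_structure: np.ndarray | None = None,
    missing_rate: float = 0.06,
    seed: int = 0,
    age_range: tuple = (7.0, 12.9),
) -> pd.DataFrame:
    """Draw correlated psychometric scale scores for a two-group cohort.

    Missing entries (at ``missing_rate``) are introduced only in the three
    parent-questionnaire autism scales (srs, scq, aq), as happens with
    questionnaire data in practice.
    """
    means = {k: dict(v) for k, v in PSYCHOMETRIC_DEFAULTS.items()}
    if group_means:
        for scale, per_group in group_means.items():
            means[scale].update(
                {g: (m, means[scale][g][1]) for g, m in per_group.items()}
            )
    if group_sds:
        for scale, per_group in group_sds.items():
            means[scale].update(
                {g: (means[scale][g][0], s) for g, s in per_group.items()}
            )
    corr = _default_correlation() if correlation_structure is None else np.asarray(
        correlation_structure, dtype=float
    )
    if corr.shape != (6, 6) or not np.allclose(corr, corr.T):
        raise ValueError("correlation_structure must be a symmetric 6x6 matrix")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation_structure is not positive semidefinite")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(6))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))
    rows = []
    for group in ("NT", "ASD"):
        z = rng.standard_normal((n_per_group, 6)) @ chol.T
        lo, hi = age_range
        mu_a, sd_a = means["age"][group]
        age = np.clip(rng.normal(mu_a, sd_a, n_per_group), lo, hi)
        for i in range(n_per_group):
            row = {"subject_id": f"{group}{i + 1:02d}", "group": group, "age": age[i]}
            for j, scale in enumerate(_SCALES):
                mu, sd = means[scale][group]
                row[scale] = mu + sd * z[i, j]
            rows.append(row)
    table = pd.DataFrame(rows)
    if missing_rate > 0:
        for scale in ("srs", "scq", "aq"):
            mask = rng.random(len(table)) < missing_rate
            table.loc[mask, scale] = np.nan
    return table
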