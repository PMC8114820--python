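"""Synthetic hybrid EEG + fNIRS recording generator.

Emulates the geometry of a two-class hybrid BCI study: 29 subjects x 3
sessions x 20 trials (1740 observations), 36 fNIRS source-detector pairs
(two wavelengths each, so 72 optical-density channels), 32 EEG channels,
fNIRS acquired at 12.5 Hz, EEG at 1000 Hz, 10 s task epochs preceded by a
2 s instruction baseline and followed by 15-17 s rest.

Class structure:

* hemodynamics - a subset of "active" fNIRS pairs carries a task-locked
  response (canonical double-gamma HRF convolved with the 10 s task
  boxcar); for class 2 its amplitude is multiplied by ``hemo_effect_size``.
  dHbR is a scaled negative copy of dHbO.  Ground-truth concentrations are
  converted to optical density through the exact forward Beer-Lambert map,
  then 1/f + white noise is added.
* EEG - pink background noise plus an 8-13 Hz oscillation during the task;
  on a subset of channels the oscillation amplitude is multiplied by
  ``erd_effect_size`` for class 2 only, mimicking event-related
  desynchronization.

Labels never influence random-draw order, so with both effect sizes at 1
the two classes are statistically (and, per draw, bitwise) identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .nirs import MBLLParams, mbll_forward

__all__ = [
    "SimConfig",
    "ChannelInfo",
    "Marker",
    "RawRecording",
    "make_hrf",
    "simulate_trial_od",
    "simulate_trial_eeg",
    "iter_recordings",
    "generate_dataset",
]

# Fixed physiological scales (see docs/methods.md for rationale).
HBO_PEAK_MM = 0.01          # peak dHbO on active channels, mM
HBR_RATIO = -0.4            # dHbR = HBR_RATIO * dHbO
ALPHA_AMP_UV = 5.0          # task-window alpha oscillation amplitude, uV
EEG_NOISE_GAIN = 2000.0     # EEG noise amplitude = noise_sd * gain, uV
PINK_FRACTION = 0.7         # share of OD/EEG noise that is 1/f
LEAD_IN_S = 5.0             # rest before the first instruction, s
HRF_TAIL_S = 15.0           # hemodynamic response tail beyond task end, s


@dataclass(frozen=True)
class SimConfig:
    """Study-geometry and signal parameters of the synthetic dataset.

    Defaults reproduce the reference geometry: 29 x 3 x 20 = 1740 trials.
    ``hemo_effect_size`` and ``erd_effect_size`` are the class-separability
    dials (1.0 = no class difference); ``noise_sd`` is in optical-density
    units and also scales EEG noise via ``EEG_NOISE_GAIN``.
    """

    n_subjects: int = 29
    n_sessions: int = 3
    trials_per_session: int = 20
    n_nirs_channels: int = 36
    n_eeg_channels: int = 32
    fs_nirs_raw: float = 12.5
    fs_eeg_raw: float = 1000.0
    task_duration: float = 10.0
    baseline_duration: float = 2.0
    inter_trial_rest: tuple[float, float] = (15.0, 17.0)
    hemo_effect_size: float = 1.3
    erd_effect_size: float = 0.7
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_subjects, self.n_sessions, self.trials_per_session,
            self.n_nirs_channels, self.n_eeg_channels,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise InvalidParameterError(f"all counts must be integers >= 1: {counts}")
        durations = (self.task_duration, self.baseline_duration)
        if any(d <= 0 for d in durations):
            raise InvalidParameterError(f"durations must be > 0: {durations}")
        if self.fs_nirs_raw <= 0 or self.fs_eeg_raw <= 0:
            raise InvalidParameterError("sampling rates must be > 0")
        lo, hi = self.inter_trial_rest
        if not 0 < lo <= hi:
            raise InvalidParameterError(f"invalid rest range {self.inter_trial_rest}")
        if self.hemo_effect_size < 0 or self.erd_effect_size < 0 or self.noise_sd < 0:
            raise InvalidParameterError("effect sizes and noise_sd must be >= 0")

    @property
    def n_trials_total(self) -> int:
        return self.n_subjects * self.n_sessions * self.trials_per_session

    @property
    def active_nirs(self) -> np.ndarray:
        """Indices of fNIRS pairs carrying the class-dependent response."""
        return np.arange(max(1, self.n_nirs_channels // 3))

    @property
    def active_eeg(self) -> np.ndarray:
        """Indices of EEG channels with class-dependent alpha attenuation."""
        return np.arange(max(1, self.n_eeg_channels // 4))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ChannelInfo:
    id: str
    modality: str                    # "eeg" or "od"
    wavelength: float | None = None  # nm, od only
    pair_id: int | None = None       # links the two wavelengths of a pair
    rho: float | None = None         # cm, od only


@dataclass(frozen=True)
class Marker:
    onset: int   # sample index of task onset
    label: int   # class, 1 or 2


@dataclass
class RawRecording:
    """One continuous multichannel recording (EEG in uV or OD units)."""

    data: np.ndarray              # channels x samples
    fs: float
    channels: list[ChannelInfo]
    markers: list[Marker]
    subject: int = 0
    session: int = 0
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise InvalidParameterError(
                f"data must be channels x samples with {len(self.channels)} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def replace(self, **kw) -> "RawRecording":
        return dataclasses.replace(self, **kw)


def make_hrf(fs: float, duration: float) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, normalized to peak 1.

    Peak near 6 s, undershoot near 16 s with 1/6 relative amplitude; the
    curve starts at exactly 0.  Returns ``round(duration * fs)`` samples.
    """
    if fs <= 0 or duration <= 0:
        raise InvalidParameterError("fs and duration must be > 0")
    n = round(duration * fs)
    t = np.arange(n) / fs
    from scipy.stats import gamma

    h = gamma.pdf(t, a=7.0, scale=1.0) - gamma.pdf(t, a=17.0, scale=1.0) / 6.0
    peak = np.max(np.abs(h))
    if peak == 0:  # duration too short to reach the rise
        raise InvalidParameterError("duration too short for an HRF")
    h = h / np.max(h)
    h[0] = 0.0
    return h


def _task_response_shape(fs: float, task_duration: float, tail: float = HRF_TAIL_S):
    """Unit-peak response of the vasculature to a task boxcar.

    Convolution of a ``task_duration`` boxcar with the canonical HRF,
    truncated to task + tail seconds after onset.
    """
    kernel = make_hrf(fs, min(30.0, task_duration + tail))
    box = np.ones(round(task_duration * fs))
    r = np.convolve(box, kernel)[: round((task_duration + tail) * fs)]
    return r / np.max(r)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f-amplitude-spectrum noise per channel.

    Shaping is done at the next fast FFT length and truncated, which keeps
    the transform cost low for arbitrary recording lengths.
    """
    from scipy.fft import irfft, next_fast_len

    n = shape[-1]
    nfft = next_fast_len(n)
    nf = nfft // 2 + 1
    spec_shape = shape[:-1] + (nf,)
    spec = rng.standard_normal(spec_shape) + 1j * rng.standard_normal(spec_shape)
    f = np.fft.rfftfreq(nfft)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = irfft(spec * scale, n=nfft, axis=-1)[..., :n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _noise(rng, shape, sd):
    if sd == 0:
        return np.zeros(shape)
    return sd * (
        PINK_FRACTION * _pink_noise(rng, shape)
        + (1.0 - PINK_FRACTION) * rng.standard_normal(shape)
    )


def _channel_gains(rng, n):
    return rng.uniform(0.8, 1.2, size=n)


def _class_scale(cfg: SimConfig, label: int, active: np.ndarray, n: int,
                 effect: float) -> np.ndarray:
    if label not in (1, 2):
        raise InvalidParameterError(f"label must be 1 or 2, got {label}")
    scale = np.ones(n)
    if label == 2:
        scale[active] = effect
    return scale


def simulate_trial_od(cfg: SimConfig, label: int, rng: np.random.Generator,
                      params: MBLLParams = MBLLParams()):
    """One trial's two-wavelength OD segment plus ground-truth concentrations.

    The segment spans the instruction baseline and the task,
    ``baseline_duration + task_duration`` seconds at ``fs_nirs_raw``.
    Returns ``(od, hbo, hbr)`` with ``od`` of shape
    ``(2 * n_nirs_channels, n)`` (wavelength-1 row directly above its
    wavelength-2 partner) and noiseless ground truth ``hbo``/``hbr`` of
    shape ``(n_nirs_channels, n)``.  Class membership only rescales active
    channels and never alters random-draw order.
    """
    fs = cfg.fs_nirs_raw
    n = round((cfg.baseline_duration + cfg.task_duration) * fs)
    onset = round(cfg.baseline_duration * fs)
    nch = cfg.n_nirs_channels

    shape = _task_response_shape(fs, cfg.task_duration)[: n - onset]
    gains = _channel_gains(rng, nch)
    amp = HBO_PEAK_MM * gains
    amp_active = np.zeros(nch)
    amp_active[cfg.active_nirs] = amp[cfg.active_nirs]
    amp_active *= _class_scale(cfg, label, cfg.active_nirs, nch,
                               cfg.hemo_effect_size)

    hbo = np.zeros((nch, n))
    hbo[:, onset:] = amp_active[:, None] * shape[None, :]
    hbr = HBR_RATIO * hbo

    od = np.empty((2 * nch, n))
    od1, od2 = mbll_forward(hbo, hbr, params)
    od[0::2] = od1
    od[1::2] = od2
    od += _noise(rng, od.shape, cfg.noise_sd)
    return od, hbo, hbr


def simulate_trial_eeg(cfg: SimConfig, label: int, rng: np.random.Generator):
    """One trial's EEG segment (baseline + task) at ``fs_eeg_raw``.

    Pink background noise plus an 8-13 Hz oscillation confined to the task
    window; on active channels the oscillation amplitude is multiplied by
    ``erd_effect_size`` for class 2.  Shape: ``(n_eeg_channels, n)``.
    """
    fs = cfg.fs_eeg_raw
    n = round((cfg.baseline_duration + cfg.task_duration) * fs)
    onset = round(cfg.baseline_duration * fs)
    nch = cfg.n_eeg_channels

    freqs = rng.uniform(8.0, 13.0, size=nch)
    phases = rng.uniform(0.0, 2 * np.pi, size=nch)
    gains = _channel_gains(rng, nch)
    amp = ALPHA_AMP_UV * gains * _class_scale(cfg, label, cfg.active_eeg, nch,
                                              cfg.erd_effect_size)

    eeg = _noise(rng, (nch, n), cfg.noise_sd * EEG_NOISE_GAIN)
    t = np.arange(n - onset) / fs
    osc = amp[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                                + phases[:, None])
    eeg[:, onset:] += osc
    return eeg


def _session_labels(cfg: SimConfig, rng: np.random.Generator,
                    session_parity: int) -> np.ndarray:
    """Balanced, randomly ordered labels for one session.

    For an odd trial count the extra label alternates between sessions so
    the full dataset stays as balanced as possible.
    """
    t = cfg.trials_per_session
    labels = [1] * (t // 2) + [2] * (t // 2)
    if t % 2:
        labels.append(1 if session_parity % 2 == 0 else 2)
    return rng.permutation(np.array(labels, dtype=int))


def _nirs_channel_info(cfg: SimConfig, params: MBLLParams) -> list[ChannelInfo]:
    chans = []
    for p in range(cfg.n_nirs_channels):
        for w, wl in enumerate(params.wavelengths):
            chans.append(ChannelInfo(
                id=f"NIRS{p + 1:02d}_{int(wl)}", modality="od",
                wavelength=float(wl), pair_id=p + 1, rho=params.rho,
            ))
    return chans


def _eeg_channel_info(cfg: SimConfig) -> list[ChannelInfo]:
    return [ChannelInfo(id=f"EEG{c + 1:02d}", modality="eeg")
            for c in range(cfg.n_eeg_channels)]


def _session_recordings(cfg: SimConfig, subject: int, session: int,
                        params: MBLLParams):
    """Build the paired (eeg, od) continuous recordings for one session."""
    rng = np.random.default_rng([cfg.seed, subject, session])
    t_trials = cfg.trials_per_session
    labels = _session_labels(cfg, rng, (subject * cfg.n_sessions + session))
    rests = rng.uniform(*cfg.inter_trial_rest, size=t_trials)

    # onsets of the task phase, in seconds
    onsets_s = np.empty(t_trials)
    t_cursor = LEAD_IN_S
    for i in range(t_trials):
        t_cursor += cfg.baseline_duration          # instruction phase
        onsets_s[i] = t_cursor
        t_cursor += cfg.task_duration + rests[i]   # task + rest
    total_s = t_cursor + 1.0

    # --- fNIRS: continuous ground-truth concentrations -> OD + noise
    fsn = cfg.fs_nirs_raw
    n_nirs = round(total_s * fsn)
    nch = cfg.n_nirs_channels
    shape = _task_response_shape(fsn, cfg.task_duration)
    hbo = np.zeros((nch, n_nirs))
    nirs_markers = []
    for i in range(t_trials):
        gains = _channel_gains(rng, nch)
        amp = np.zeros(nch)
        amp[cfg.active_nirs] = HBO_PEAK_MM * gains[cfg.active_nirs]
        amp *= _class_scale(cfg, int(labels[i]), cfg.active_nirs, nch,
                            cfg.hemo_effect_size)
        o = round(onsets_s[i] * fsn)
        seg = min(len(shape), n_nirs - o)
        hbo[:, o:o + seg] += amp[:, None] * shape[None, :seg]
        nirs_markers.append(Marker(onset=o, label=int(labels[i])))
    hbr = HBR_RATIO * hbo
    od = np.empty((2 * nch, n_nirs))
    od1, od2 = mbll_forward(hbo, hbr, params)
    od[0::2] = od1
    od[1::2] = od2
    od += _noise(rng, od.shape, cfg.noise_sd)
    od_rec = RawRecording(
        data=od, fs=fsn, channels=_nirs_channel_info(cfg, params),
        markers=nirs_markers, subject=subject, session=session,
        truth={"hbo": hbo, "hbr": hbr},
    )

    # --- EEG: pink background + task-locked alpha with class attenuation
    fse = cfg.fs_eeg_raw
    n_eeg = round(total_s * fse)
    ne = cfg.n_eeg_channels
    eeg = _noise(rng, (ne, n_eeg), cfg.noise_sd * EEG_NOISE_GAIN)
    eeg_markers = []
    n_task = round(cfg.task_duration * fse)
    t_task = np.arange(n_task) / fse
    for i in range(t_trials):
        freqs = rng.uniform(8.0, 13.0, size=ne)
        phases = rng.uniform(0.0, 2 * np.pi, size=ne)
        gains = _channel_gains(rng, ne)
        amp = ALPHA_AMP_UV * gains * _class_scale(
            cfg, int(labels[i]), cfg.active_eeg, ne, cfg.erd_effect_size)
        o = round(onsets_s[i] * fse)
        eeg[:, o:o + n_task] += amp[:, None] * np.sin(
            2 * np.pi * freqs[:, None] * t_task[None, :] + phases[:, None])
        eeg_markers.append(Marker(onset=o, label=int(labels[i])))
    eeg_rec = RawRecording(
        data=eeg, fs=fse, channels=_eeg_channel_info(cfg),
        markers=eeg_markers, subject=subject, session=session,
    )
    return eeg_rec, od_rec


def iter_recordings(cfg: SimConfig, params: MBLLParams = MBLLParams()):
    """Yield ``(eeg_recording, od_recording)`` pairs, one per subject x session.

    Streaming counterpart of :func:`generate_dataset`; at the default
    geometry the full dataset is large, so downstream pipelines should
    consume this iterator and discard each recording after processing.
    """
    for subject in range(1, cfg.n_subjects + 1):
        for session in range(1, cfg.n_sessions + 1):
            yield _session_recordings(cfg, subject, session, params)


def generate_dataset(cfg: SimConfig, params: MBLLParams = MBLLParams()):
    """All recordings as a list of ``(eeg, od)`` pairs.

    Deterministic given ``cfg`` (including its seed); total markers equal
    ``n_subjects * n_sessions * trials_per_session`` with balanced classes.
    Prefer :func:`iter_recordings` at the default geometry (memory).
    """
    return list(iter_recordings(cfg, params))
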