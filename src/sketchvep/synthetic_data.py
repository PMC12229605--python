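"""Synthetic inputs for the full pipeline.

Three generators with the statistical structure the analysis assumes:

* surrogate natural-image corpora (1/f-amplitude noise whose binarized
  patch statistics are heavy-tailed, dominated by the uniform patches);
* synthetic 30-channel, 500 Hz EEG sessions with a planted C1 component
  whose latency depends on stimulus SNR (group means 74/71/70/69 ms for
  SNR 0/30/60/100%), a polarity reversal between upper- and lower-field
  stimulation, an SNR-independent C2, and pink/line/drift noise;
* 2AFC choices from a logistic preference model in Delta-SNR.

Everything is reproducible from (seed, parameters).  Sessions serialize
to 16-bit EDF plus an events TSV; reading goes through MNE.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus_builder import SNR_LEVELS, TrialSchedule

#: The 30-channel montage of the recording system (10/20 layout).
CHANNELS = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "C3", "Cz", "C4",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
)

SFREQ = 500.0

#: Posterior electrode cluster used for VEP averaging.
CLUSTER = ("POz", "PO3", "PO4", "Pz")


def make_image_corpus(
    n: int,
    size_px: int = 256,
    rng: np.random.Generator | None = None,
    exponent: float = 1.0,
) -> list[np.ndarray]:
    """Generate grayscale 1/f-amplitude-spectrum noise images.

    Gaussian white noise is shaped in the Fourier domain by an amplitude
    envelope ``f ** -exponent`` (default 1, the classic natural-image
    amplitude falloff).  After median binarization the tiled 3x3 patch
    distribution is heavy-tailed with most mass on the all-black and
    all-white patches, mimicking natural images; a ``exponent = 0``
    control gives white noise with a near-uniform patch distribution.
    """
    if n < 1:
        raise ValueError("need at least one image")
    rng = np.random.default_rng() if rng is None else rng
    fy = np.fft.fftfreq(size_px)[:, None]
    fx = np.fft.rfftfreq(size_px)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    amplitude = f**-exponent
    images = []
    for _ in range(n):
        white = rng.standard_normal((size_px, size_px))
        img = np.fft.irfft2(np.fft.rfft2(white) * amplitude, s=(size_px, size_px))
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# ERP forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatencyModel:
    """Planted C1 latency structure.

    ``condition_means_ms`` are the group-mean C1 peak latencies per SNR
    level; ``subject_sd_ms`` spreads a per-participant offset common to
    all conditions (latency effects are within-subject);
    ``trial_jitter_sd_ms`` is the within-participant trial-to-trial
    spread.
    """

    condition_means_ms: dict[int, float] = field(
        default_factory=lambda: {0: 74.0, 30: 71.0, 60: 70.0, 100: 69.0}
    )
    subject_sd_ms: float = 3.0
    trial_jitter_sd_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.subject_sd_ms < 0 or self.trial_jitter_sd_ms < 0:
            raise ValueError("spreads must be non-negative")
        for snr, m in self.condition_means_ms.items():
            if not 40.0 <= m <= 100.0:
                raise ValueError(
                    f"C1 mean for SNR {snr} ({m} ms) outside the 40-100 ms "
                    "detection window"
                )


def _default_topography() -> dict[str, float]:
    topo = {ch: 0.0 for ch in CHANNELS}
    for ch in CLUSTER:
        topo[ch] = 1.0
    for ch in ("PO7", "PO8", "O1", "O2", "P3", "P4"):
        topo[ch] = 0.5
    return topo


@dataclass(frozen=True)
class ERPTemplateParams:
    """Gaussian-bump templates for the planted C1 and C2 components.

    C1 polarity follows the retinotopy of V1: negative for upper-field,
    positive for lower-field stimulation; C2 has the opposite sign per
    field.  ``topography`` weights (in [0, 1]) scale the bump per
    channel, peaked over the parieto-occipital cluster.
    """

    c1_amplitude_uv: float = 2.0
    c1_sd_ms: float = 10.0
    c2_amplitude_uv: float = 1.5
    c2_latency_ms: float = 130.0  # independent of SNR by construction
    c2_sd_ms: float = 15.0
    topography: dict[str, float] = field(default_factory=_default_topography)

    def __post_init__(self) -> None:
        for ch, w in self.topography.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"topography weight for {ch} outside [0, 1]")

    def topography_vector(self) -> np.ndarray:
        return np.array([self.topography.get(ch, 0.0) for ch in CHANNELS])


@dataclass(frozen=True)
class NoiseParams:
    """Additive background activity per channel."""

    pink_rms_uv: float = 10.0
    line_amplitude_uv: float = 5.0
    line_freq_hz: float = 50.0
    drift_amplitude_uv: float = 20.0
    drift_corner_hz: float = 0.05

    def __post_init__(self) -> None:
        vals = (self.pink_rms_uv, self.line_amplitude_uv,
                self.drift_amplitude_uv, self.drift_corner_hz)
        if any(v < 0 for v in vals):
            raise ValueError("noise parameters must be non-negative")


@dataclass
class EEGSession:
    """One (synthetic) participant's continuous recording.

    ``data`` is channels x samples in microvolts; ``events`` holds one
    row per trial with its onset sample and the schedule fields.
    """

    sfreq: float
    ch_names: tuple[str, ...]
    data: np.ndarray
    events: pd.DataFrame
    participant: str = "sim"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows must match channel count")
        s = self.events["sample"].to_numpy()
        if (np.diff(s) <= 0).any():
            raise ValueError("event samples must be strictly increasing")
        if s.min() < 0 or s.max() >= self.data.shape[1]:
            raise ValueError("event samples outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, sfreq: float
) -> np.ndarray:
    """Unit-RMS pink (1/f power) noise, independent per channel.

    Shaped in the Fourier domain at a padded fast FFT length, then
    truncated, so arbitrary recording lengths stay cheap.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_fft))
    spec = rfft(white, axis=1)
    f = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    f[0] = f[1]
    spec *= f**-0.5
    x = irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    return x / x.std(axis=1, keepdims=True)


def _add_bump(
    data: np.ndarray,
    weights: np.ndarray,
    chan_idx: np.ndarray,
    sfreq: float,
    peak_s: float,
    sd_s: float,
    amplitude: float,
) -> None:
    """Add a Gaussian bump scaled per channel; peak time is continuous."""
    half = 4.5 * sd_s
    s0 = max(0, int(np.floor((peak_s - half) * sfreq)))
    s1 = min(data.shape[1], int(np.ceil((peak_s + half) * sfreq)) + 1)
    if s1 <= s0:
        return
    t = np.arange(s0, s1) / sfreq
    bump = amplitude * np.exp(-0.5 * ((t - peak_s) / sd_s) ** 2)
    data[np.ix_(chan_idx, np.arange(s0, s1))] += weights[chan_idx, None] * bump


def simulate_session(
    schedule: TrialSchedule,
    lat: LatencyModel = LatencyModel(),
    erp: ERPTemplateParams = ERPTemplateParams(),
    noise: NoiseParams = NoiseParams(),
    participant: str = "sim01",
    rng: np.random.Generator | int | None = None,
    pad_s: float = 1.0,
) -> EEGSession:
    """Forward-simulate a continuous EEG recording for one participant.

    Each single trial contributes a C1 bump at the condition mean plus a
    subject offset plus trial jitter, and a C2 bump at a fixed latency,
    both scaled by the topography and signed by the stimulated field
    (C1: negative upper / positive lower; C2 opposite).  2AFC trials
    place compounds in both fields (each field's C1 latency follows that
    field's SNR) and are flagged for exclusion from the EEG averages.
    Pink, line and drift noise are added per channel.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    trials = schedule.trials
    fs = SFREQ
    # onsets from cumulative duration + isi
    gaps_s = (trials["duration_ms"].to_numpy() + trials["isi_ms"].to_numpy()) / 1000.0
    onsets_s = pad_s + np.concatenate([[0.0], np.cumsum(gaps_s[:-1])])
    onset_samples = np.round(onsets_s * fs).astype(int)
    n_samples = int(np.ceil((onsets_s[-1] + gaps_s[-1] + pad_s) * fs))

    n_ch = len(CHANNELS)
    data = np.zeros((n_ch, n_samples))
    t = np.arange(n_samples) / fs
    if noise.pink_rms_uv > 0:
        data += noise.pink_rms_uv * _pink_noise(rng, n_ch, n_samples, fs)
    for ch in range(n_ch):
        if noise.line_amplitude_uv > 0:
            data[ch] += noise.line_amplitude_uv * np.sin(
                2 * np.pi * noise.line_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.drift_amplitude_uv > 0:
            f_drift = rng.uniform(noise.drift_corner_hz / 10, noise.drift_corner_hz)
            data[ch] += noise.drift_amplitude_uv * np.sin(
                2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi)
            )

    weights = erp.topography_vector()
    chan_idx = np.flatnonzero(weights)
    subject_offset_ms = rng.normal(0.0, lat.subject_sd_ms)
    c1_sign = {"upper": -1.0, "lower": +1.0}

    def plant(onset_s: float, field_name: str, snr: int) -> None:
        c1_lat_ms = (
            lat.condition_means_ms[snr]
            + subject_offset_ms
            + rng.normal(0.0, lat.trial_jitter_sd_ms)
        )
        _add_bump(data, weights, chan_idx, fs, onset_s + c1_lat_ms / 1000.0,
                  erp.c1_sd_ms / 1000.0, c1_sign[field_name] * erp.c1_amplitude_uv)
        c2_lat_ms = erp.c2_latency_ms + rng.normal(0.0, lat.trial_jitter_sd_ms)
        _add_bump(data, weights, chan_idx, fs, onset_s + c2_lat_ms / 1000.0,
                  erp.c2_sd_ms / 1000.0, -c1_sign[field_name] * erp.c2_amplitude_uv)

    for i, row in enumerate(trials.itertuples(index=False)):
        if row.kind == "single":
            plant(onsets_s[i], row.field, int(row.snr))
        else:  # afc: compounds in both fields
            high_field = row.afc_high_field
            low_field = "lower" if high_field == "upper" else "upper"
            plant(onsets_s[i], high_field, int(row.afc_high_snr))
            plant(onsets_s[i], low_field, 0)

    events = trials.copy()
    events.insert(0, "sample", onset_samples)
    return EEGSession(
        sfreq=fs, ch_names=CHANNELS, data=data, events=events,
        participant=participant, seed=None,
    )


def simulate_behavior(
    schedule: TrialSchedule,
    slope: float = 0.03,
    lapse: float = 0.1,
    rng: np.random.Generator | int | None = None,
    participant: str = "sim01",
) -> pd.DataFrame:
    """Simulate 2AFC choices with a logistic preference in Delta-SNR.

    The probability of choosing the higher-SNR compound is
    ``lapse/2 + (1 - lapse) * sigmoid(slope * dSNR)``; at the default
    slope 0.03 and lapse 0.1 this gives preferences of about 0.69, 0.82
    and 0.91 for dSNR 30, 60 and 100.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    afc = schedule.trials[schedule.trials["kind"] == "afc"]
    if afc.empty:
        raise ValueError("schedule contains no 2AFC trials")
    d_snr = afc["afc_high_snr"].to_numpy(dtype=float)  # low member is SNR 0
    p_high = lapse / 2 + (1 - lapse) / (1 + np.exp(-slope * d_snr))
    chose_higher = rng.random(len(afc)) < p_high
    high_field = afc["afc_high_field"].to_numpy()
    up_when_high = np.where(high_field == "upper", "up", "down")
    down_when_high = np.where(high_field == "upper", "down", "up")
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": afc["index"].to_numpy(),
            "afc_high_snr": afc["afc_high_snr"].to_numpy(),
            "afc_high_field": high_field,
            "choice": np.where(chose_higher, up_when_high, down_when_high),
            "chose_higher": chose_higher,
        }
    )


# ---------------------------------------------------------------------------
# EDF serialization
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = value[:width]
    return s.encode("ascii") + b" " * (width - len(s))


def _edf_number(value: float, width: int = 8) -> str:
    """Shortest decimal representation of value that fits the field."""
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {value} in {width} chars")


def write_session(session: EEGSession, base_path: str | Path) -> tuple[Path, Path]:
    """Serialize a session to ``<base>.edf`` + ``<base>.events.tsv``.

    Plain 16-bit EDF with 1-second data records; each channel is scaled
    to its own symmetric physical range, so the quantization step is
    ``2 * phys_max / 65534`` microvolts.  The final partial record is
    zero-padded; the true sample count is stored in the events file
    header line and in the recording-id field.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    edf_path = base.with_suffix(".edf")
    ev_path = base.with_suffix(".events.tsv")

    fs = int(round(session.sfreq))
    n_ch, n_samples = session.data.shape
    n_records = int(np.ceil(n_samples / fs))
    phys_max = np.maximum(np.abs(session.data).max(axis=1), 1e-3) * 1.0001
    phys_strs = [_edf_number(pm, 7) for pm in phys_max]  # leave room for '-'

    with open(edf_path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"X X X {session.participant}", 80))
        fh.write(_edf_field(f"Startdate X nsamples={n_samples}", 80))
        fh.write(_edf_field("01.01.24", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 * (n_ch + 1)), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))
        fh.write(_edf_field(str(n_ch), 4))
        for ch in session.ch_names:
            fh.write(_edf_field(ch, 16))
        for _ in session.ch_names:
            fh.write(_edf_field("", 80))  # transducer
        for _ in session.ch_names:
            fh.write(_edf_field("uV", 8))
        for s in phys_strs:
            fh.write(_edf_field(f"-{s}", 8))
        for s in phys_strs:
            fh.write(_edf_field(s, 8))
        for _ in session.ch_names:
            fh.write(_edf_field("-32767", 8))
        for _ in session.ch_names:
            fh.write(_edf_field("32767", 8))
        for _ in session.ch_names:
            fh.write(_edf_field("", 80))  # prefiltering
        for _ in session.ch_names:
            fh.write(_edf_field(str(fs), 8))
        for _ in session.ch_names:
            fh.write(_edf_field("", 32))
        padded = np.zeros((n_ch, n_records * fs))
        padded[:, :n_samples] = session.data
        # physical range [-pm, pm] maps to digital [-32767, 32767];
        # use the values as printed so the reader recovers the same scale
        scale = 32767.0 / np.array(phys_strs, dtype=float)
        digital = np.clip(
            np.round(padded * scale[:, None]), -32767, 32767
        ).astype("<i2")
        for rec in range(n_records):
            fh.write(digital[:, rec * fs : (rec + 1) * fs].tobytes())

    with open(ev_path, "w") as fh:
        fh.write(f"# participant={session.participant} sfreq={session.sfreq} "
                 f"n_samples={n_samples}\n")
        session.events.to_csv(fh, sep="\t", index=False)
    return edf_path, ev_path


def read_session(base_path: str | Path) -> EEGSession:
    """Load a session written by :func:`write_session` via MNE's EDF reader."""
    import mne

    base = Path(base_path)
    raw = mne.io.read_raw_edf(base.with_suffix(".edf"), preload=True,
                              verbose="error")
    ev_path = base.with_suffix(".events.tsv")
    header = ev_path.read_text().splitlines()[0]
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split()
                if "=" in kv)
    n_samples = int(meta["n_samples"])
    events = pd.read_csv(ev_path, sep="\t", comment="#")
    events["afc_high_snr"] = events["afc_high_snr"].astype("Int64")
    events["snr"] = events["snr"].astype("Int64")
    return EEGSession(
        sfreq=float(meta["sfreq"]),
        ch_names=tuple(raw.ch_names),
        data=raw.get_data()[:, :n_samples] * 1e6,  # V -> uV
        events=events,
        participant=meta.get("participant", "unknown"),
    )
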