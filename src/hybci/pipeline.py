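"""End-to-end orchestration: recordings -> epochs -> the six feature tables.

Processing order for fNIRS: MBLL conversion at the native rate, 3rd-order
0.01-0.09 Hz zero-phase Butterworth band-pass, polyphase downsampling to
10 Hz, stimulus-locked segmentation with the -2..0 s instruction baseline,
baseline correction.  EEG is downsampled to 200 Hz and then epoched the
same way (no band-pass).  After preprocessing each trial is 100 samples
per fNIRS channel and 2000 per EEG channel.

The pipeline streams: each recording pair is reduced to its per-trial
feature rows and discarded, so the default 29 x 3 geometry fits in modest
memory.
"""

from __future__ import annotations

import numpy as np

from .epochs import baseline_correct, segment
from .errors import ShapeError
from .features import FeatureTable, build_table, combine_tables
from .nirs import HemoRecording, MBLLParams, bandpass, mbll_inverse, resample
from .synth import Marker, RawRecording, SimConfig, iter_recordings

__all__ = [
    "mbll_recording",
    "preprocess_nirs",
    "preprocess_eeg",
    "recording_tables",
    "run_synthetic_pipeline",
    "FEATURE_SETS",
]

FEATURE_SETS = ("hbo", "hbr", "eeg", "hbo+hbr", "eeg+hbo", "eeg+hbr")


def _rescale_markers(markers, fs_in: float, fs_out: float):
    return [Marker(onset=round(m.onset * fs_out / fs_in), label=m.label)
            for m in markers]


def mbll_recording(od_rec: RawRecording,
                   params: MBLLParams = MBLLParams()) -> HemoRecording:
    """Convert a paired-wavelength OD recording to hemoglobin series.

    Channels are matched by ``pair_id``; each pair must contain exactly the
    two wavelengths.
    """
    pairs: dict[int, dict[float, int]] = {}
    for idx, ch in enumerate(od_rec.channels):
        if ch.modality != "od":
            raise ShapeError(f"channel {ch.id} is not an OD channel")
        pairs.setdefault(ch.pair_id, {})[ch.wavelength] = idx
    wl1, wl2 = params.wavelengths
    pair_ids = sorted(pairs)
    rows1, rows2 = [], []
    for p in pair_ids:
        by_wl = pairs[p]
        if set(by_wl) != {wl1, wl2}:
            raise ShapeError(
                f"pair {p} must have exactly wavelengths {wl1} and {wl2} nm"
            )
        rows1.append(by_wl[wl1])
        rows2.append(by_wl[wl2])
    hbo, hbr = mbll_inverse(od_rec.data[rows1], od_rec.data[rows2], params)
    return HemoRecording(hbo=hbo, hbr=hbr, fs=od_rec.fs, pair_ids=pair_ids,
                         markers=list(od_rec.markers),
                         subject=od_rec.subject, session=od_rec.session)


def preprocess_nirs(od_rec: RawRecording, params: MBLLParams = MBLLParams(),
                    low: float = 0.01, high: float = 0.09, order: int = 3,
                    fs_out: float = 10.0) -> HemoRecording:
    """MBLL -> band-pass -> downsample, with markers carried along."""
    hemo = mbll_recording(od_rec, params)
    hbo = bandpass(hemo.hbo, hemo.fs, low=low, high=high, order=order)
    hbr = bandpass(hemo.hbr, hemo.fs, low=low, high=high, order=order)
    hbo = resample(hbo, hemo.fs, fs_out)
    hbr = resample(hbr, hemo.fs, fs_out)
    return hemo.replace(
        hbo=hbo, hbr=hbr, fs=fs_out,
        markers=_rescale_markers(hemo.markers, hemo.fs, fs_out),
    )


def preprocess_eeg(eeg_rec: RawRecording, fs_out: float = 200.0) -> RawRecording:
    """Downsample an EEG recording, with markers carried along."""
    data = resample(eeg_rec.data, eeg_rec.fs, fs_out)
    return eeg_rec.replace(
        data=data, fs=fs_out,
        markers=_rescale_markers(eeg_rec.markers, eeg_rec.fs, fs_out),
    )


def recording_tables(eeg_rec: RawRecording, od_rec: RawRecording,
                     params: MBLLParams = MBLLParams(),
                     window=(0.0, 10.0), baseline=(-2.0, 0.0)):
    """Per-recording singular feature tables {"hbo", "hbr", "eeg"}."""
    context = (baseline[0], window[1])
    hemo = preprocess_nirs(od_rec, params)
    hbo_ep, hbr_ep = segment(hemo, window=window, context=context)
    hbo_ep = baseline_correct(hbo_ep, baseline=baseline)
    hbr_ep = baseline_correct(hbr_ep, baseline=baseline)

    eeg = preprocess_eeg(eeg_rec)
    eeg_ep = segment(eeg, window=window, context=context)
    eeg_ep = baseline_correct(eeg_ep, baseline=baseline)
    return {
        "hbo": build_table(hbo_ep, name="hbo"),
        "hbr": build_table(hbr_ep, name="hbr"),
        "eeg": build_table(eeg_ep, name="eeg"),
    }


def run_synthetic_pipeline(cfg: SimConfig,
                           params: MBLLParams = MBLLParams(),
                           window=(0.0, 10.0), baseline=(-2.0, 0.0)):
    """Generate, preprocess, and featurize the full synthetic dataset.

    Returns the six feature tables keyed ``hbo``, ``hbr``, ``eeg``,
    ``hbo+hbr``, ``eeg+hbo``, ``eeg+hbr``, each with one row per trial
    (1740 at the default geometry) and a shared label vector.
    """
    parts = {"hbo": [], "hbr": [], "eeg": []}
    for eeg_rec, od_rec in iter_recordings(cfg, params):
        tabs = recording_tables(eeg_rec, od_rec, params, window, baseline)
        for k in parts:
            parts[k].append(tabs[k])
    singles = {k: FeatureTable.vstack(v) for k, v in parts.items()}
    return {
        "hbo": singles["hbo"],
        "hbr": singles["hbr"],
        "eeg": singles["eeg"],
        "hbo+hbr": combine_tables(singles["hbo"], singles["hbr"]),
        "eeg+hbo": combine_tables(singles["eeg"], singles["hbo"]),
        "eeg+hbr": combine_tables(singles["eeg"], singles["hbr"]),
    }
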