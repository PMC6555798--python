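"""File I/O for the standard artefact formats: WAV waveforms, HDF5
spectrograms/recordings/filters, and TSV schedules, alignments and
tables."""

from __future__ import annotations

import numpy as np

from .spectrogram import Spectrogram

__all__ = [
    "read_wav",
    "write_wav",
    "save_spectrogram",
    "load_spectrogram",
    "read_phoneme_tsv",
]


def read_wav(path):
    """Mono waveform as float64 in [-1, 1]-ish units; returns (wave, fs)."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)


def write_wav(path, wave, fs):
    from scipy.io import wavfile

    wavfile.write(path, int(fs), np.asarray(wave, dtype=np.float32))


def save_spectrogram(spec: Spectrogram, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=spec.values)
        f.create_dataset("frame_rate", data=float(spec.frame_rate))
        f.create_dataset("center_freqs", data=spec.center_freqs)


def load_spectrogram(path) -> Spectrogram:
    import h5py

    with h5py.File(path, "r") as f:
        return Spectrogram(f["values"][()], float(f["frame_rate"][()]), f["center_freqs"][()])


def read_phoneme_tsv(path):
    """(onset_s, offset_s, label) triples from a 3-column TSV with header."""
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            t0, t1, lab = line.rstrip("\n").split("\t")
            out.append((float(t0), float(t1), lab))
    return out
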