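"""File formats: recording TSV/EDF, hypnogram TSV, mask rasters, tables.

TSV is the primary interchange format (self-describing header comments).
EDF support: reading goes through MNE; writing uses a minimal built-in
single-channel EDF encoder (16-bit, physical dimension µV) sufficient for
round-tripping synthetic recordings.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CODE_STATES, Hypnogram, ParameterError, RawRecording, STATE_CODES

__all__ = ["write_recording_tsv", "read_recording_tsv", "write_edf", "read_edf",
           "write_hypnogram_tsv", "read_hypnogram_tsv", "write_mask", "read_mask",
           "write_json", "read_json"]


def write_recording_tsv(rec: RawRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs}\n")
        fh.write(f"# input_range_mv={rec.input_range_mv}\n")
        fh.write(f"# zt0_offset_h={rec.zt0_offset_h}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write("sample_index\tvalue_uV\n")
        np.savetxt(fh, np.column_stack([np.arange(rec.n_samples), rec.samples]),
                   fmt=("%d", "%.6f"), delimiter="\t")


def read_recording_tsv(path) -> RawRecording:
    meta = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    if "fs_hz" not in meta:
        raise ParameterError(f"{path}: missing '# fs_hz=' header")
    return RawRecording(df["value_uV"].to_numpy(float), fs=float(meta["fs_hz"]),
                        input_range_mv=float(meta.get("input_range_mv", 200.0)),
                        zt0_offset_h=float(meta.get("zt0_offset_h", 0.0)),
                        subject_id=meta.get("subject_id", ""))


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path) -> None:
    """Write a single-channel EDF file (16-bit, µV).

    The data-record duration is chosen so the per-record sample count is
    integral for the recording's rate; a trailing partial record is
    dropped (EDF stores whole records only).
    """
    for dur in range(1, 61):
        ns = rec.fs * dur
        if abs(ns - round(ns)) < 1e-6:
            record_dur, ns = dur, int(round(ns))
            break
    else:
        raise ParameterError(f"rate {rec.fs} Hz has no integral record length <= 60 s")
    n_rec = rec.n_samples // ns
    phys = rec.rail_uv
    x = np.clip(rec.samples[:n_rec * ns], -phys, phys)
    dig = np.round(x / phys * 32767).astype("<i2")
    hdr = b""
    hdr += _edf_field("0", 8)                       # version
    hdr += _edf_field(rec.subject_id or "X", 80)    # patient id
    hdr += _edf_field("synthetic", 80)              # recording id
    hdr += _edf_field("01.01.00", 8)                # start date
    hdr += _edf_field("00.00.00", 8)                # start time
    hdr += _edf_field(256 + 256, 8)                 # header bytes
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(record_dur, 8)
    hdr += _edf_field(1, 4)                         # one signal
    hdr += _edf_field("EEG", 16)                    # label
    hdr += _edf_field("", 80)                       # transducer
    hdr += _edf_field("uV", 8)                      # physical dimension
    hdr += _edf_field(f"{-phys:.1f}", 8)
    hdr += _edf_field(f"{phys:.1f}", 8)
    hdr += _edf_field(-32768, 8)
    hdr += _edf_field(32767, 8)
    hdr += _edf_field("", 80)                       # prefiltering
    hdr += _edf_field(ns, 8)
    hdr += _edf_field("", 32)
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())


def read_edf(path, input_range_mv: float = 200.0,
             zt0_offset_h: float = 0.0) -> RawRecording:
    """Read a single-channel EDF recording via MNE; samples returned in µV."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()[0] * 1e6  # MNE loads EEG in volts
    return RawRecording(data, fs=float(raw.info["sfreq"]),
                        input_range_mv=input_range_mv, zt0_offset_h=zt0_offset_h,
                        subject_id=str(Path(path).stem))


def write_hypnogram_tsv(hyp: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epoch_len_s={hyp.epoch_len_s}\n")
        fh.write(f"# zt0_offset_h={hyp.zt0_offset_h}\n")
        fh.write("epoch_index\tlabel\n")
        for i, lab in enumerate(hyp.labels):
            fh.write(f"{i}\t{STATE_CODES[str(lab)]}\n")


def read_hypnogram_tsv(path) -> Hypnogram:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif not line.startswith("epoch_index"):
                _, _, code = line.partition("\t")
                code = code.strip().lower()
                if code not in CODE_STATES:
                    raise ParameterError(f"unknown hypnogram code {code!r}")
                rows.append(CODE_STATES[code])
    return Hypnogram(np.array(rows, dtype="U8"),
                     epoch_len_s=float(meta.get("epoch_len_s", 4.0)),
                     zt0_offset_h=float(meta.get("zt0_offset_h", 0.0)))


def write_mask(mask: np.ndarray, um_per_pixel: float, path) -> None:
    """Write a binary mask as 8-bit PNG plus a sidecar scale file."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    with open(path.with_suffix(path.suffix + ".scale.txt"), "w") as fh:
        fh.write(f"um_per_pixel={um_per_pixel}\n")


def read_mask(path) -> tuple[np.ndarray, float]:
    import imageio.v3 as iio

    path = Path(path)
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    scale_path = path.with_suffix(path.suffix + ".scale.txt")
    um_per_pixel = 1.0
    if scale_path.exists():
        for line in open(scale_path):
            if line.startswith("um_per_pixel="):
                um_per_pixel = float(line.split("=", 1)[1])
    return img > 127, um_per_pixel


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
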