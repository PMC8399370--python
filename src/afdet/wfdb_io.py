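"""Minimal WFDB subset I/O: format-16 signals and MIT rhythm annotations.

Supports exactly what AF-database replication needs: reading and writing
single- or two-channel records stored as little-endian 16-bit samples
(.hea header + .dat signal) and MIT-format annotation files (.atr)
carrying rhythm-change events ("+" annotations whose aux string names
the rhythm, e.g. "(AFIB" or "(N").

This is a deliberate subset — no format 212/80, no multi-segment
records, no calibrated checksums beyond what the header requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# MIT annotation type codes
_CODE_RHYTHM = 40  # '+' rhythm change
_CODE_SKIP = 59  # long interval escape
_CODE_NUM = 60
_CODE_SUB = 61
_CODE_CHN = 62
_CODE_AUX = 63


@dataclass(frozen=True)
class Annotation:
    """One annotation event: absolute sample index, type code, aux string."""

    sample: int
    code: int
    aux: str = ""


def write_record(
    directory: str | Path,
    record: str,
    signals: np.ndarray,
    fs: float,
    gain: float = 200.0,
    units: str = "mV",
) -> None:
    """Write ``signals`` (n_samples, n_channels) as a format-16 record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:  # accept (channels, samples) too
        signals = signals.T
    n, nch = signals.shape
    digital = np.clip(np.rint(signals * gain), -32768, 32767).astype("<i2")
    lines = [f"{record} {nch} {fs:g} {n}"]
    for ch in range(nch):
        first = int(digital[0, ch])
        lines.append(
            f"{record}.dat 16 {gain:g}({0})/{units} 16 0 {first} 0 0 ch{ch}"
        )
    (directory / f"{record}.hea").write_text("\n".join(lines) + "\n")
    digital.reshape(-1, order="C").tofile(directory / f"{record}.dat")


def read_record(directory: str | Path, record: str) -> tuple[np.ndarray, float]:
    """Read a format-16 record; returns (signals (n, nch) in physical units, fs)."""
    directory = Path(directory)
    hea = directory / f"{record}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"missing header {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    nch, fs, n = int(head[1]), float(head[2]), int(head[3])
    gains = []
    for ln in lines[1 : 1 + nch]:
        fields = ln.split()
        if fields[1] != "16":
            raise ValueError(f"unsupported signal format {fields[1]} (only 16)")
        gain_field = fields[2].split("(")[0].split("/")[0]
        gains.append(float(gain_field) if float(gain_field) != 0 else 200.0)
    dat = directory / f"{record}.dat"
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    raw = raw[: n * nch].reshape(n, nch)
    physical = raw.astype(float) / np.asarray(gains)[None, :]
    return physical, fs


def write_annotations(
    directory: str | Path, record: str, annotations: list[Annotation], ext: str = "atr"
) -> None:
    """Write MIT-format annotations (absolute samples -> stored deltas)."""
    out = bytearray()
    prev = 0
    for ann in sorted(annotations, key=lambda a: a.sample):
        delta = ann.sample - prev
        prev = ann.sample
        if delta > 1023:  # SKIP escape for long intervals
            out += _pack(_CODE_SKIP, 0)
            out += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        out += _pack(ann.code, delta)
        if ann.aux:
            aux_bytes = ann.aux.encode()
            out += _pack(_CODE_AUX, len(aux_bytes))
            out += aux_bytes
            if len(aux_bytes) % 2:
                out += b"\x00"
    out += b"\x00\x00"  # end of file
    Path(directory, f"{record}.{ext}").write_bytes(bytes(out))


def read_annotations(
    directory: str | Path, record: str, ext: str = "atr"
) -> list[Annotation]:
    """Read MIT-format annotations back to absolute sample positions."""
    path = Path(directory, f"{record}.{ext}")
    if not path.exists():
        raise FileNotFoundError(f"missing annotation file {path}")
    data = path.read_bytes()
    anns: list[Annotation] = []
    pos = 0
    sample = 0
    pending_skip = 0
    while pos + 1 < len(data):
        word = int.from_bytes(data[pos : pos + 2], "little")
        pos += 2
        code = word >> 10
        payload = word & 0x3FF
        if code == 0 and payload == 0:
            break
        if code == _CODE_SKIP:
            high = int.from_bytes(data[pos : pos + 2], "little")
            low = int.from_bytes(data[pos + 2 : pos + 4], "little")
            pending_skip = (high << 16) | low
            pos += 4
        elif code == _CODE_AUX:
            aux = data[pos : pos + payload].decode(errors="replace")
            pos += payload + (payload % 2)
            if anns:
                anns[-1] = Annotation(anns[-1].sample, anns[-1].code, aux)
        elif code in (_CODE_NUM, _CODE_SUB, _CODE_CHN):
            continue
        else:
            sample += payload + pending_skip
            pending_skip = 0
            anns.append(Annotation(sample=sample, code=code))
    return anns


def _pack(code: int, payload: int) -> bytes:
    return int((code << 10) | (payload & 0x3FF)).to_bytes(2, "little")
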