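"""Dataset assembly and experiment harness.

Turns annotated ECG records (real WFDB records or synthetic ones) into
balanced, labeled, fixed-length segment sets, and runs scripted
experiment grids (segment duration x pooling window x classifier) that
mirror the evaluation protocol: denoise -> segment -> featurize ->
stratified 9:1 split -> train -> Acc/Se/Sp.

Rhythm handling: only AFIB intervals (label AF) and N intervals (label
non-AF) are used; AFL and J intervals are skipped. Segments are tiled
non-overlapping from the start of each interval and windows crossing an
interval boundary are discarded, so no segment ever mixes rhythms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from afdet import wfdb_io
from afdet.classify import (
    AF,
    NON_AF,
    EvalReport,
    GksvmParams,
    LabeledDataset,
    evaluate,
    stratified_split,
    train_model,
)
from afdet.features import PoolingWindow, featurize
from afdet.fswt import FswtConfig
from afdet.preprocess import denoise
from afdet.signal import EcgSignal
from afdet.synthetic_ecg import AF_SPEC, NSR_SPEC, add_noise, generate_segment

#: Records excluded from the AF database (rhythm annotations only, no signals).
EXCLUDED_RECORDS = ("00735", "03665")

RHYTHMS = ("AFIB", "AFL", "J", "N")

#: Default contamination applied to synthetic study segments: slow baseline
#: drift, mains interference, and broadband (EMG-like) noise.
DEFAULT_NOISE = dict(
    baseline_amp=0.2,
    baseline_freq=0.3,
    powerline_amp=0.05,
    powerline_freq=50.0,
    white_sd=0.05,
)


@dataclass(frozen=True)
class RhythmInterval:
    """Half-open annotated rhythm stretch [start, end) in sample indices."""

    start: int
    end: int
    rhythm: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must precede end")
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}")


@dataclass
class SegmentSet:
    """Fixed-length labeled segments, all with duration*fs samples."""

    segments: list[EcgSignal]
    duration: float
    fs: float

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.segments])


def load_wfdb_record(
    directory: str | Path, record: str, channel: int = 0
) -> tuple[EcgSignal, list[RhythmInterval]]:
    """Load one locally present AF-database record plus its rhythm intervals.

    Records 00735 and 03665 are rejected: they carry rhythm annotations
    but no usable signal files. Downloading is out of band; missing
    files raise with the path that was expected.
    """
    if record in EXCLUDED_RECORDS:
        raise ValueError(
            f"record {record} is excluded (annotation-only record without signals)"
        )
    signals, fs = wfdb_io.read_record(directory, record)
    anns = wfdb_io.read_annotations(directory, record)
    n = signals.shape[0]
    events = [
        (a.sample, a.aux.lstrip("(").strip("\x00 "))
        for a in anns
        if a.code == wfdb_io._CODE_RHYTHM and a.aux
    ]
    intervals: list[RhythmInterval] = []
    for i, (start, rhythm) in enumerate(events):
        end = events[i + 1][0] if i + 1 < len(events) else n
        if rhythm in RHYTHMS and start < end:
            intervals.append(RhythmInterval(start=start, end=min(end, n), rhythm=rhythm))
    sig = EcgSignal(samples=signals[:, channel], fs=fs)
    return sig, intervals


def segment_by_rhythm(
    signal: EcgSignal, intervals: list[RhythmInterval], duration: float
) -> SegmentSet:
    """Tile non-overlapping fixed-length windows within AFIB and N intervals.

    AFIB windows are labeled AF, N windows non-AF; AFL and J intervals
    contribute nothing; partial trailing windows are dropped.
    """
    seg_len = duration * signal.fs
    if abs(seg_len - round(seg_len)) > 1e-9:
        raise ValueError("duration * fs must be an integral sample count")
    seg_len = int(round(seg_len))
    segments: list[EcgSignal] = []
    for iv in intervals:
        if iv.rhythm not in ("AFIB", "N"):
            continue
        label = AF if iv.rhythm == "AFIB" else NON_AF
        start = iv.start
        while start + seg_len <= min(iv.end, signal.n):
            chunk = signal.samples[start : start + seg_len]
            segments.append(EcgSignal(samples=chunk, fs=signal.fs, label=label))
            start += seg_len
    return SegmentSet(segments=segments, duration=duration, fs=signal.fs)


def balance_classes(segments: SegmentSet, seed: int = 0) -> SegmentSet:
    """Randomly subsample the majority class down to the minority count."""
    labels = segments.labels
    af_idx = np.flatnonzero(labels == AF)
    non_idx = np.flatnonzero(labels == NON_AF)
    if af_idx.size == 0 or non_idx.size == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    m = min(af_idx.size, non_idx.size)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(af_idx, size=m, replace=False),
                rng.choice(non_idx, size=m, replace=False),
            ]
        )
    )
    return SegmentSet(
        segments=[segments.segments[i] for i in keep],
        duration=segments.duration,
        fs=segments.fs,
    )


def build_synthetic_dataset(
    n_per_class: int = 100,
    duration: float = 5.0,
    fs: float = 250.0,
    seed: int = 0,
    noise: dict | None = None,
    apply_denoise: bool = True,
    fswt_config: FswtConfig = FswtConfig(),
    window: PoolingWindow = PoolingWindow(),
) -> LabeledDataset:
    """Generate a balanced synthetic NSR/AF feature dataset.

    Each segment gets an independent seed derived from ``seed``; the
    default contamination (:data:`DEFAULT_NOISE`) is applied before the
    denoising chain, exercising the full pipeline end to end.
    """
    noise = DEFAULT_NOISE if noise is None else noise
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class + 1) % (2**31)
    feats, labels = [], []
    for i in range(2 * n_per_class):
        spec = NSR_SPEC if i % 2 == 0 else AF_SPEC
        s = int(seeds[i])
        seg = generate_segment(spec, duration, fs, seed=s)
        seg = add_noise(seg, seed=s + 1, **noise)
        if apply_denoise:
            seg = denoise(seg)
        fv = featurize(seg, fswt_config, window, segment_id=f"syn-{i}")
        feats.append(fv.values)
        labels.append(seg.label)
    return LabeledDataset(np.vstack(feats), np.asarray(labels))


def run_experiment(config: dict | str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run a (duration x pooling window x model) grid and tabulate Acc/Se/Sp.

    ``config`` is a dict or a path to a JSON file with keys:
    source ("synthetic"), n_per_class, fs, durations, windows (list of
    "MxN" strings or [m, n] pairs), models, seed, test_fraction, noise.
    Unknown keys raise a config error. Results (and a log of every
    resolved parameter) are written to ``out_dir`` when given.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    defaults = dict(
        source="synthetic",
        n_per_class=100,
        fs=250.0,
        durations=[5.0],
        windows=["10x5"],
        models=["gksvm"],
        seed=0,
        test_fraction=0.1,
        noise=None,
        fswt=dict(f_min=0.0, f_max=80.0, k=3.0, slice="gaussian"),
    )
    unknown = set(config) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**defaults, **config}
    if cfg["source"] != "synthetic":
        raise ValueError("only the synthetic source is supported by run_experiment")
    fswt_config = FswtConfig(**cfg["fswt"])

    rows = []
    for duration in cfg["durations"]:
        for win in cfg["windows"]:
            window = _parse_window(win)
            data = build_synthetic_dataset(
                n_per_class=cfg["n_per_class"],
                duration=float(duration),
                fs=float(cfg["fs"]),
                seed=int(cfg["seed"]),
                noise=cfg["noise"],
                fswt_config=fswt_config,
                window=window,
            )
            split = stratified_split(data, cfg["test_fraction"], seed=int(cfg["seed"]))
            for kind in cfg["models"]:
                model = train_model(kind, split.train, seed=int(cfg["seed"]))
                report = evaluate(model, split.test)
                train_report = evaluate(model, split.train)
                rows.append(
                    dict(
                        duration_s=float(duration),
                        window=f"{window.m}x{window.n}",
                        model=kind,
                        feature_len=data.features.shape[1],
                        n_segments=data.n,
                        test_accuracy=report.accuracy,
                        test_sensitivity=report.sensitivity,
                        test_specificity=report.specificity,
                        train_accuracy=train_report.accuracy,
                    )
                )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "results.csv", index=False)
        (out_dir / "resolved_config.json").write_text(json.dumps(cfg, indent=2))
    return table


def _parse_window(win) -> PoolingWindow:
    if isinstance(win, str):
        m, n = win.lower().split("x")
        return PoolingWindow(m=int(m), n=int(n))
    return PoolingWindow(m=int(win[0]), n=int(win[1]))


def write_wfdb_fixture(
    directory: str | Path,
    record: str,
    signal: EcgSignal,
    intervals: list[RhythmInterval],
) -> None:
    """Write a synthetic record + rhythm annotations as WFDB files.

    Round-trip companion to :func:`load_wfdb_record`, used to exercise
    the loader without any real database download.
    """
    wfdb_io.write_record(directory, record, signal.samples[:, None], signal.fs)
    anns = [
        wfdb_io.Annotation(sample=iv.start, code=wfdb_io._CODE_RHYTHM, aux=f"({iv.rhythm}")
        for iv in intervals
    ]
    wfdb_io.write_annotations(directory, record, anns)
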