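"""End-to-end recognition: scan a record frame by frame and emit a traceable
annotation track.

A record is tiled with 3 s frames overlapping by 1 s; each frame runs the
featuring chain (low-pass filter, EMD, Hilbert spectral analysis, marginal
spectra of the first three modes, centroid extraction) and is labelled
independently by a trained model.  An optional majority-vote smoother over
neighbouring frames is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .hht import (
    FilterSpec,
    emd,
    hilbert_analysis,
    lowpass_filter,
    marginal_spectrum,
    mhs_centroid,
)
from .models import PatternModel, predict
from .records import (
    AnnotationTrack,
    ECGRecord,
    FeatureRecord,
    Frame,
    sliding_frames,
)


@dataclass
class ScanResult:
    """Per-frame labels and scores for one scanned record."""

    record_id: str
    track: AnnotationTrack
    frame_scores: list[dict[int, float]]
    model_name: str
    config: dict = field(default_factory=dict)


def extract_features_frame(frame: Frame, cfg: PipelineConfig | None = None) -> FeatureRecord:
    """Centroid feature vector of one frame: (freq, power) of IMF1..IMF3.

    A frame that decomposes into fewer than three modes (e.g. a flat line)
    gets the missing centroids as (0, 0) and a ``"padded_imfs"`` flag.
    """
    cfg = cfg or PipelineConfig()
    filtered = lowpass_filter(
        frame, FilterSpec(order=cfg.filter_order, cutoff_hz=cfg.filter_cutoff_hz)
    )
    imfset = emd(
        filtered,
        stop_sd=cfg.emd_stop_sd,
        max_imfs=cfg.emd_max_imfs,
        max_sifts=cfg.emd_max_sifts,
    )
    flags: tuple[str, ...] = ()
    values = np.zeros(6)
    if len(imfset) == 0:
        return FeatureRecord(values, label=frame.label, flags=("padded_imfs",))
    hs = hilbert_analysis(imfset)
    for j in range(3):
        if j >= len(imfset):
            flags = ("padded_imfs",)
            break
        mhs = marginal_spectrum(
            hs, j, bin_hz=cfg.mhs_bin_hz, fmax_hz=cfg.mhs_fmax_hz, energy=cfg.mhs_energy
        )
        c = mhs_centroid(mhs)
        values[2 * j] = c.freq_hz
        values[2 * j + 1] = c.power
    return FeatureRecord(values, label=frame.label, flags=flags)


def extract_features_record(
    rec: ECGRecord,
    cfg: PipelineConfig | None = None,
    duration_s: float = 3.0,
    mode: str = "annotations",
    overlap_s: float = 1.0,
) -> list[FeatureRecord]:
    """Feature records from annotation-centered frames or a sliding window."""
    from .records import frame_at_annotation

    if mode == "annotations":
        frames = [frame_at_annotation(rec, t, duration_s) for t, _ in rec.annotations]
    elif mode == "sliding":
        frames = sliding_frames(rec, duration_s=duration_s, overlap_s=overlap_s)
    else:
        raise ValueError("mode must be 'annotations' or 'sliding'")
    return [extract_features_frame(f, cfg) for f in frames]


def scan_record(
    rec: ECGRecord,
    model: PatternModel,
    cfg: PipelineConfig | None = None,
    duration_s: float = 3.0,
    overlap_s: float = 1.0,
    smooth: bool = False,
) -> ScanResult:
    """Label every sliding frame of a record with the given model.

    With ``smooth=True`` each frame's label is replaced by the majority label
    of itself and its two neighbours (ties keep the frame's own label).
    """
    cfg = cfg or PipelineConfig()
    frames = sliding_frames(rec, duration_s=duration_s, overlap_s=overlap_s)
    feats = [extract_features_frame(f, cfg) for f in frames]
    preds = predict(model, feats)
    labels = [p.label for p in preds]
    if smooth and len(labels) > 2:
        labels = _majority_smooth(labels)
    entries = [
        (f.start_s, f.end_s, lab, model.config.method)
        for f, lab in zip(frames, labels)
    ]
    return ScanResult(
        record_id=rec.record_id,
        track=AnnotationTrack(entries=entries),
        frame_scores=[p.scores for p in preds],
        model_name=model.config.method,
        config=cfg.to_dict(),
    )


def _majority_smooth(labels: list[int]) -> list[int]:
    out = list(labels)
    for i in range(len(labels)):
        window = labels[max(0, i - 1):i + 2]
        counts: dict[int, int] = {}
        for lab in window:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out[i] = labels[i] if labels[i] in winners else winners[0]
    return out


def export_trace(
    result: ScanResult,
    path: str | Path,
    rec: ECGRecord | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write the annotation track as CSV (and optionally a trace plot).

    The CSV has columns ``start_s,end_s,label,model`` and round-trips through
    :func:`read_trace`.  With ``plot=True`` and the record given, a PNG with
    the signal and per-frame colored label bands is written next to the CSV.
    """
    if not result.track.entries:
        raise ValueError("scan result has no frames to export")
    path = Path(path)
    df = pd.DataFrame(
        result.track.entries, columns=["start_s", "end_s", "label", "model"]
    )
    df.to_csv(path, index=False)
    written = [path]
    if plot:
        if rec is None:
            raise ValueError("plotting requires the scanned record")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .records import SYMPTOM_NAMES

        colors = {1: "#4daf4a", 2: "#ff7f00", 3: "#e41a1c", 4: "#984ea3", 5: "#a65628"}
        t = np.arange(rec.samples.size) / rec.fs
        fig, ax = plt.subplots(figsize=(12, 3.5))
        ax.plot(t, rec.samples, lw=0.6, color="k")
        seen = set()
        for start, end, label, _model in result.track.entries:
            ax.axvspan(
                start, end, color=colors[label], alpha=0.18,
                label=SYMPTOM_NAMES[label] if label not in seen else None,
            )
            seen.add(label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mV")
        ax.set_title(f"{result.record_id} — {result.model_name}")
        ax.legend(loc="upper right", fontsize=8)
        png = path.with_suffix(".png")
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(png)
    return written


def read_trace(path: str | Path) -> AnnotationTrack:
    df = pd.read_csv(path)
    entries = [
        (float(r.start_s), float(r.end_s), int(r.label), str(r.model))
        for r in df.itertuples()
    ]
    return AnnotationTrack(entries=entries)
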