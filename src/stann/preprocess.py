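"""ECG cleaning and per-beat delineation.

Pipeline order: segment the record into 5-minute pieces, remove baseline
wander with a two-pass median filter, soft-threshold wavelet denoising,
signal-quality gating, wavelet/derivative-based beat delineation, and
R-amplitude normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .wavelets import denoise_soft

MISSING = -1  # sentinel for absent fiducials in integer annotation columns

ANNOTATION_COLUMNS = ["beat_index", "p_idx", "qrs_on_idx", "r_idx", "s_idx", "t_idx"]


class QualityError(ValueError):
    """Raised when a segment fails an amplitude/quality precondition."""


@dataclass
class EcgSignal:
    """Continuous single-lead voltage trace in millivolts."""

    samples: np.ndarray
    fs: float
    patient_id: str = "anonymous"
    lead: str = "II"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class BeatAnnotations:
    """Per-beat fiducial sample indices; missing labels are MISSING (-1), never guessed."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True).astype(int)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def empty(cls) -> "BeatAnnotations":
        return cls(pd.DataFrame({c: pd.Series(dtype=int) for c in ANNOTATION_COLUMNS}))

    def validate_against(self, n_samples: int) -> None:
        """Check bounds and within-beat ordering of the fiducials that are present."""
        for _, row in self.frame.iterrows():
            present = [row[c] for c in ANNOTATION_COLUMNS[1:] if row[c] != MISSING]
            if any(i < 0 or i >= n_samples for i in present):
                raise ValueError(f"beat {row['beat_index']}: fiducial out of signal bounds")
            if any(b <= a for a, b in zip(present, present[1:])):
                raise ValueError(f"beat {row['beat_index']}: fiducials not strictly increasing")


@dataclass
class SegmentQuality:
    start: int
    end: int
    score: float
    keep: bool
    partial: bool = False


def segment_signal(sig: EcgSignal, seg_len_s: float = 300.0) -> list[tuple[int, int, bool]]:
    """Tile the record into contiguous (start, end, is_partial) index ranges."""
    if seg_len_s <= 0:
        raise ValueError("segment length must be positive")
    n = len(sig.samples)
    if n == 0:
        return []
    step = int(round(seg_len_s * sig.fs))
    ranges = []
    for start in range(0, n, step):
        end = min(start + step, n)
        ranges.append((start, end, end - start < step))
    return ranges


def _median_baseline(x: np.ndarray, fs: float) -> np.ndarray:
    # standard two-pass recipe: ~200 ms pass flattens QRS, ~600 ms pass tracks wander
    k1 = max(3, int(round(0.2 * fs)) | 1)
    k2 = max(3, int(round(0.6 * fs)) | 1)
    est = ndimage.median_filter(x, size=k1, mode="nearest")
    return ndimage.median_filter(est, size=k2, mode="nearest")


def remove_baseline(segment: np.ndarray, fs: float) -> np.ndarray:
    """Subtract a two-pass median-filter baseline estimate."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) == 0:
        raise ValueError("empty segment")
    return segment - _median_baseline(segment, fs)


def denoise_wavelet(segment: np.ndarray) -> np.ndarray:
    """Soft-threshold wavelet shrinkage of high-frequency noise (db4, 4 levels)."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) == 0:
        raise ValueError("empty segment")
    return denoise_soft(segment, levels=4)


def normalize_amplitude(segment: np.ndarray, ann: BeatAnnotations) -> np.ndarray:
    """Divide the segment by its mean R-peak amplitude."""
    segment = np.asarray(segment, dtype=float)
    r_idx = ann.frame["r_idx"].to_numpy()
    r_idx = r_idx[r_idx != MISSING]
    if len(r_idx) == 0:
        raise QualityError("no annotated R peaks in segment")
    mean_r = float(np.mean(segment[r_idx]))
    if mean_r <= 0:
        raise QualityError(f"non-positive mean R amplitude ({mean_r:.4g} mV)")
    return segment / mean_r


def _detect_r_amplitude(x: np.ndarray, fs: float) -> np.ndarray:
    amp = np.max(x) if len(x) else 0.0
    if amp <= 1e-9:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(x, height=0.55 * amp, distance=max(1, int(0.25 * fs)))
    return peaks


def _detect_r_energy(x: np.ndarray, fs: float) -> np.ndarray:
    if len(x) < 3:
        return np.array([], dtype=int)
    d = np.diff(x)
    energy = ndimage.uniform_filter1d(d * d, size=max(1, int(0.06 * fs)))
    if np.max(energy) <= 1e-12:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(
        energy, height=0.25 * np.max(energy), distance=max(1, int(0.25 * fs))
    )
    return peaks


def _agreement_score(a: np.ndarray, b: np.ndarray, tol: int) -> float:
    if len(a) + len(b) == 0:
        return 0.0
    matches = 0
    j = 0
    for pa in a:
        while j < len(b) and b[j] < pa - tol:
            j += 1
        if j < len(b) and abs(int(b[j]) - int(pa)) <= tol:
            matches += 1
            j += 1
    return 2.0 * matches / (len(a) + len(b))


def quality_filter(
    segments: list[np.ndarray], fs: float, threshold: float = 0.8
) -> list[SegmentQuality]:
    """Agreement-style SQI: concordance of two independent R detectors within 150 ms."""
    if not segments:
        raise ValueError("no segments provided")
    tol = max(1, int(0.15 * fs))
    out = []
    cursor = 0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        pa = _detect_r_amplitude(seg, fs)
        pb = _detect_r_energy(seg, fs)
        score = _agreement_score(pa, pb, tol) if min(len(pa), len(pb)) >= 1 else 0.0
        out.append(
            SegmentQuality(
                start=cursor, end=cursor + len(seg), score=score, keep=score >= threshold
            )
        )
        cursor += len(seg)
    return out


def delineate_beats(segment: np.ndarray, fs: float) -> BeatAnnotations:
    """Locate P, QRS-onset, R, S and T fiducials per beat.

    A simplified derivative/threshold delineator standing in for a full
    wavelet-transform delineator: R from peak detection, QRS onset by
    backward slope search, S as the post-R trough, T as the point where
    the signal leaves the ST plateau, P as the pre-QRS local maximum.
    Labels that cannot be located are flagged MISSING rather than guessed.
    """
    x = np.asarray(segment, dtype=float)
    r_peaks = _detect_r_amplitude(x, fs)
    if len(r_peaks) == 0:
        return BeatAnnotations.empty()

    rows = []
    for b, r in enumerate(r_peaks):
        r_amp = x[r]
        # QRS onset: walk back until the signal drops below 5% of the R amplitude
        qrs_on = MISSING
        lo = max(0, r - int(0.10 * fs))
        for j in range(r - 1, lo - 1, -1):
            if x[j] < 0.05 * r_amp:
                qrs_on = j
                break
        # S: trough shortly after R
        s_idx = MISSING
        s_hi = min(len(x) - 1, r + int(0.06 * fs))
        if s_hi > r + 1:
            s_idx = int(r + 1 + np.argmin(x[r + 1 : s_hi + 1]))
        # P: local max in the window before QRS onset
        p_idx = MISSING
        if qrs_on != MISSING:
            p_lo = max(0, qrs_on - int(0.15 * fs))
            p_hi = max(0, qrs_on - int(0.02 * fs))
            if p_hi - p_lo >= 3:
                cand = int(p_lo + np.argmax(x[p_lo:p_hi]))
                if x[cand] > 0.05 * r_amp:
                    p_idx = cand
        # T label: last sample on the ST plateau before the T upstroke
        t_idx = MISSING
        if s_idx != MISSING:
            ref_lo, ref_hi = s_idx + 2, min(len(x), s_idx + 2 + int(0.08 * fs))
            next_r = r_peaks[b + 1] if b + 1 < len(r_peaks) else len(x)
            search_hi = min(int(s_idx + 0.35 * fs), next_r - 1, len(x) - 1)
            if ref_hi - ref_lo >= 3 and search_hi > ref_hi:
                plateau = float(np.median(x[ref_lo:ref_hi]))
                rise = plateau + 0.04 * max(r_amp, 1e-9)
                for j in range(ref_hi, search_hi + 1):
                    if x[j] > rise:
                        t_idx = j - 1
                        break
        # enforce strict ordering among present labels; drop violators to MISSING
        fiducials = {"p_idx": p_idx, "qrs_on_idx": qrs_on, "r_idx": int(r), "s_idx": s_idx, "t_idx": t_idx}
        prev = -1
        for name in ["p_idx", "qrs_on_idx", "r_idx", "s_idx", "t_idx"]:
            v = fiducials[name]
            if v == MISSING:
                continue
            if v <= prev:
                fiducials[name] = MISSING
            else:
                prev = v
        rows.append({"beat_index": b, **fiducials})
    return BeatAnnotations(pd.DataFrame(rows))


@dataclass
class CleanRecord:
    """Output of the full preprocessing chain for one record."""

    signal: EcgSignal
    annotations: BeatAnnotations
    segment_quality: list[SegmentQuality]
    kept_fraction: float


def preprocess_record(
    sig: EcgSignal, seg_len_s: float = 300.0, sqi_threshold: float = 0.8
) -> CleanRecord:
    """Run segmentation, baseline removal, denoising, SQI gating and delineation.

    Beats from rejected segments are dropped; the cleaned segments are
    R-normalized independently and re-concatenated (rejected stretches are
    zeroed so downstream indexing stays aligned with the raw record).
    """
    ranges = segment_signal(sig, seg_len_s)
    cleaned = np.zeros_like(sig.samples)
    segs = []
    for start, end, _ in ranges:
        piece = denoise_wavelet(remove_baseline(sig.samples[start:end], sig.fs))
        cleaned[start:end] = piece
        segs.append(piece)
    quality = quality_filter(segs, sig.fs, threshold=sqi_threshold)
    for (start, end, partial), q in zip(ranges, quality):
        q.partial = partial

    all_rows = []
    beat_counter = 0
    for (start, end, _), q in zip(ranges, quality):
        if not q.keep:
            cleaned[start:end] = 0.0
            continue
        ann = delineate_beats(cleaned[start:end], sig.fs)
        if len(ann) == 0:
            continue
        try:
            cleaned[start:end] = normalize_amplitude(cleaned[start:end], ann)
        except QualityError:
            q.keep = False
            cleaned[start:end] = 0.0
            continue
        frame = ann.frame.copy()
        for col in ANNOTATION_COLUMNS[1:]:
            frame[col] = np.where(frame[col] == MISSING, MISSING, frame[col] + start)
        frame["beat_index"] = np.arange(beat_counter, beat_counter + len(frame))
        beat_counter += len(frame)
        all_rows.append(frame)

    if all_rows:
        merged = BeatAnnotations(pd.concat(all_rows, ignore_index=True))
    else:
        merged = BeatAnnotations.empty()
    kept = sum(q.keep for q in quality) / len(quality)
    clean_sig = EcgSignal(cleaned, sig.fs, sig.patient_id, sig.lead)
    return CleanRecord(clean_sig, merged, quality, kept)
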