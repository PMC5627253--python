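"""ST-segment isolation and orthonormal-polynomial morphology coefficients.

Each retained beat contributes a 16-sample ST window centered on the
midpoint between its S-wave and T-wave labels. The window is projected
onto an orthonormal polynomial basis built by Gram-Schmidt on monomials
over 16 equispaced points: coefficient 1 measures the ST level (exactly
4x the window mean), coefficient 2 the slope, higher orders the
curvature/noise. Per-component series are normalized by their
full-record standard deviations; models consume the first two components
over the first 50 retained beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MISSING, BeatAnnotations, EcgSignal

ST_WIDTH = 16
MIN_SPAN = 16
MAX_SPAN = 32
DEFAULT_WINDOW_BEATS = 50
DISCARD_REASONS = ("missing_label", "too_short", "too_long", "out_of_bounds")


class InsufficientBeats(ValueError):
    """Exclusion signal: the patient has fewer clean beats than the window needs."""

    def __init__(self, n_available: int, n_required: int, patient_id: str = ""):
        self.n_available = n_available
        self.n_required = n_required
        self.patient_id = patient_id
        super().__init__(
            f"patient {patient_id or '<unknown>'}: {n_available} clean beats "
            f"< required window of {n_required}"
        )


@dataclass
class StSegmentMatrix:
    matrix: np.ndarray  # (n_retained, 16)
    beat_indices: np.ndarray  # provenance into the annotation table
    discards: dict[str, int]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size and self.matrix.shape[1] != ST_WIDTH:
            raise ValueError(f"ST matrix must have width {ST_WIDTH}")

    @property
    def n_retained(self) -> int:
        return 0 if self.matrix.size == 0 else self.matrix.shape[0]

    @property
    def n_input(self) -> int:
        return self.n_retained + sum(self.discards.values())


@dataclass
class OrthonormalBasis:
    matrix: np.ndarray  # (n, n); column k spans polynomials of degree <= k

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CoefficientSeries:
    """Per-beat projection coefficients, optionally SD-normalized."""

    coeffs: np.ndarray  # (n_beats, n_components) intermediate coefficients
    sds: np.ndarray | None = None  # per-component normalization SDs
    normalized: np.ndarray | None = None  # (n_beats, k_retained)
    k_retained: int = 2
    zero_sd_flagged: bool = False

    def __len__(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class StFeatureVector:
    mean_c1: float
    sd_c1: float
    mean_c2: float
    sd_c2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_c1, self.sd_c1, self.mean_c2, self.sd_c2])


def extract_st_segments(sig_clean: EcgSignal | np.ndarray, ann: BeatAnnotations) -> StSegmentMatrix:
    """Cut the 16-sample ST window out of every beat with usable S/T labels.

    Beats missing either label, or whose inclusive S..T span falls outside
    [16, 32] samples, are discarded and counted by reason.
    """
    x = sig_clean.samples if isinstance(sig_clean, EcgSignal) else np.asarray(sig_clean, float)
    rows, kept_idx = [], []
    discards = {reason: 0 for reason in DISCARD_REASONS}
    for _, row in ann.frame.iterrows():
        s, t = int(row["s_idx"]), int(row["t_idx"])
        if s == MISSING or t == MISSING:
            discards["missing_label"] += 1
            continue
        if s < 0 or t >= len(x):
            raise ValueError(f"beat {row['beat_index']}: annotation index out of signal bounds")
        span = t - s + 1
        if span < MIN_SPAN:
            discards["too_short"] += 1
            continue
        if span > MAX_SPAN:
            discards["too_long"] += 1
            continue
        mid = (s + t) // 2
        lo, hi = mid - ST_WIDTH // 2, mid + ST_WIDTH // 2
        if lo < 0 or hi > len(x):
            discards["out_of_bounds"] += 1
            continue
        rows.append(x[lo:hi])
        kept_idx.append(int(row["beat_index"]))
    matrix = np.array(rows) if rows else np.empty((0, ST_WIDTH))
    return StSegmentMatrix(matrix, np.asarray(kept_idx, dtype=int), discards)


def build_orthonormal_basis(n_samples: int = ST_WIDTH) -> OrthonormalBasis:
    """Gram-Schmidt orthonormalization of monomials on n equispaced points.

    Monomials are evaluated on a centered/scaled grid for conditioning (the
    spanned spaces are identical); modified Gram-Schmidt with one
    re-orthogonalization pass keeps B'B = I to well below 1e-10. Signs are
    fixed so each column's leading-degree coefficient is positive (column 0
    positive constant, column 1 increasing).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 sample points")
    n = n_samples
    x = (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0)
    basis = np.empty((n, n))
    for k in range(n):
        v = x**k
        for _ in range(2):  # MGS with re-orthogonalization
            for j in range(k):
                v = v - np.dot(basis[:, j], v) * basis[:, j]
        norm = np.linalg.norm(v)
        if norm <= 0:
            raise ValueError("degenerate monomial set")
        v = v / norm
        # sign: positive projection onto x**k (leading coefficient positive)
        if np.dot(v, x**k) < 0:
            v = -v
        basis[:, k] = v
    return OrthonormalBasis(basis)


def project_coefficients(st: StSegmentMatrix, basis: OrthonormalBasis) -> CoefficientSeries:
    """Coefficient vector = basis' . segment for each retained beat."""
    if st.matrix.shape[1] != basis.n and st.n_retained > 0:
        raise ValueError(
            f"segment width {st.matrix.shape[1]} != basis dimension {basis.n}"
        )
    coeffs = st.matrix @ basis.matrix
    return CoefficientSeries(coeffs=coeffs)


def normalize_by_sd(series: CoefficientSeries, k_retained: int = 2) -> CoefficientSeries:
    """Divide each component by its SD over the full series (sample SD, ddof=1).

    A component with zero SD keeps its raw values (divisor 1) and the
    series is flagged rather than the patient being dropped.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 beats to compute normalization SDs")
    sds = np.std(series.coeffs, axis=0, ddof=1)
    flagged = bool(np.any(sds[:k_retained] <= 0.0))
    divisors = np.where(sds > 0.0, sds, 1.0)
    normalized = series.coeffs[:, :k_retained] / divisors[:k_retained]
    return CoefficientSeries(
        coeffs=series.coeffs,
        sds=sds,
        normalized=normalized,
        k_retained=k_retained,
        zero_sd_flagged=flagged,
    )


def first_window(series: CoefficientSeries, n_beats: int = DEFAULT_WINDOW_BEATS,
                 patient_id: str = "") -> np.ndarray:
    """First n_beats rows of the normalized series; short series raise InsufficientBeats."""
    values = series.normalized if series.normalized is not None else series.coeffs
    if values.shape[0] < n_beats:
        raise InsufficientBeats(values.shape[0], n_beats, patient_id)
    return values[:n_beats]


def summarize(window: np.ndarray) -> StFeatureVector:
    """Mean and sample SD of the first two coefficient series over the window."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] < 1 or window.shape[1] < 2:
        raise ValueError("window must contain >=1 beat with components c1, c2")
    ddof = 1 if window.shape[0] > 1 else 0
    return StFeatureVector(
        mean_c1=float(np.mean(window[:, 0])),
        sd_c1=float(np.std(window[:, 0], ddof=ddof)),
        mean_c2=float(np.mean(window[:, 1])),
        sd_c2=float(np.std(window[:, 1], ddof=ddof)),
    )


def cohort_windows(
    series_by_patient: dict[str, np.ndarray], n_beats: int = DEFAULT_WINDOW_BEATS
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Normalize, window and summarize raw per-patient coefficient series.

    Returns (included ids, (n, n_beats, 2) window stack, (n, 4) summary
    features, excluded ids). Exclusion follows the fewer-than-window rule.
    """
    ids, windows, feats, excluded = [], [], [], []
    for pid, raw in series_by_patient.items():
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        try:
            norm = normalize_by_sd(CoefficientSeries(coeffs=raw))
            win = first_window(norm, n_beats, patient_id=pid)
        except (InsufficientBeats, ValueError):
            excluded.append(pid)
            continue
        ids.append(pid)
        windows.append(win)
        feats.append(summarize(win).as_array())
    if not ids:
        return [], np.empty((0, n_beats, 2)), np.empty((0, 4)), excluded
    return ids, np.stack(windows), np.stack(feats), excluded


def record_to_features(
    sig_clean: EcgSignal,
    ann: BeatAnnotations,
    n_beats: int = DEFAULT_WINDOW_BEATS,
    patient_id: str = "",
) -> tuple[np.ndarray, StFeatureVector, CoefficientSeries]:
    """Full per-record feature chain: extract, project, normalize, window, summarize."""
    st = extract_st_segments(sig_clean, ann)
    basis = build_orthonormal_basis(ST_WIDTH)
    series = normalize_by_sd(project_coefficients(st, basis))
    window = first_window(series, n_beats, patient_id=patient_id)
    return window, summarize(window), series
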