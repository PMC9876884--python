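"""Fluorescence histogram I/O, G0/G1 peak detection and CV-based QC.

Peak detection is a one-dimensional Gaussian-mixture deconvolution: peak
candidates are seeded from a smoothed histogram (optionally augmented with
expected positions, e.g. the internal standard's calibrated channel), then
refined by EM with an optional exponential debris component, with the
number of Gaussian components chosen by BIC.  Mixture deconvolution rather
than plain mode-finding matters because real calibration layouts can put a
sample peak within ~2 standard deviations of the standard peak (e.g. a
1.90 pg tetraploid against the 2.00 pg tomato standard).

Event-to-peak assignment is deterministic: each event belongs to the
nearest fitted peak mean provided it lies within 3 fitted SD of it, ties
going to the lower peak; events assigned to no peak count as debris and
are excluded from event-fraction denominators.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .synthetic import CHANNELS, FlowSample

__all__ = [
    "PeakEstimate",
    "PeakDetection",
    "FlowFormatError",
    "read_flow_table",
    "write_flow_table",
    "detect_peaks",
    "assign_events",
    "qc_cv",
    "mark_standard",
    "bin_events",
    "expand_binned",
]

#: Acceptance rule for G0/G1 peaks: CV strictly below 5%.
DEFAULT_CV_THRESHOLD = 5.0

FLOW_COLUMNS = ("sample_id", "channel", "intensity")


class FlowFormatError(ValueError):
    """Raised for malformed flow event tables."""


@dataclass(frozen=True)
class PeakEstimate:
    """A detected G0/G1 peak.

    ``cv`` is 100 * sd / mean over the events assigned to the peak;
    ``event_fraction`` is the peak's share of all non-debris (assigned)
    events.  ``qc_pass`` is ``None`` until :func:`qc_cv` has been applied.
    """

    mean_channel: float
    sd: float
    cv: float
    event_count: int
    event_fraction: float
    is_standard: bool = False
    qc_pass: bool | None = None
    qc_reason: str = ""


class PeakDetection(Sequence):
    """Sequence of :class:`PeakEstimate` plus detection-level QC flags."""

    def __init__(self, peaks: list[PeakEstimate], flags: list[str] | None = None):
        self.peaks = list(peaks)
        self.flags = list(flags or [])

    def __getitem__(self, i):
        return self.peaks[i]

    def __len__(self) -> int:
        return len(self.peaks)

    def __repr__(self) -> str:
        return f"PeakDetection(peaks={self.peaks!r}, flags={self.flags!r})"


# ---------------------------------------------------------------------------
# I/O

def read_flow_table(path: str | Path, dialect: str = ",") -> list[FlowSample]:
    """Read tidy events (columns sample_id, channel, intensity).

    Returns one :class:`FlowSample` per (sample_id, channel), intensities
    preserved exactly, in first-appearance order.
    """
    df = pd.read_csv(path, sep=dialect, float_precision="round_trip")
    for col in FLOW_COLUMNS:
        if col not in df.columns:
            raise FlowFormatError(
                f"missing required column {col!r} (found {list(df.columns)})"
            )
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise FlowFormatError(
            f"unknown channel label(s) {sorted(bad)}; allowed: {list(CHANNELS)}"
        )
    samples = []
    for (sid, channel), grp in df.groupby(["sample_id", "channel"], sort=False):
        samples.append(
            FlowSample(str(sid), str(channel), grp["intensity"].to_numpy(float))
        )
    return samples


def write_flow_table(
    samples: Sequence[FlowSample], path: str | Path, dialect: str = ","
) -> None:
    """Write samples as tidy delimited text; round-trips exactly."""
    frames = [
        pd.DataFrame(
            {"sample_id": s.sample_id, "channel": s.channel, "intensity": s.events}
        )
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=dialect, index=False, float_format="%.17g"
    )


def bin_events(
    events: np.ndarray, n_channels: int = 1024, max_intensity: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bin continuous intensities into instrument-like channels.

    Returns ``(midpoints, counts)``.
    """
    events = np.asarray(events, float)
    upper = max_intensity if max_intensity is not None else events.max() * (1 + 1e-9)
    edges = np.linspace(0.0, upper, n_channels + 1)
    counts, _ = np.histogram(events, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return mids, counts


def expand_binned(midpoints: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Expand a binned histogram back to pseudo-events at bin midpoints.

    An approximation: within-bin spread is lost, so CVs computed from the
    expansion are floor-biased by up to half a bin width.
    """
    return np.repeat(np.asarray(midpoints, float), np.asarray(counts, int))


# ---------------------------------------------------------------------------
# Peak detection

def _histogram_candidates(
    x: np.ndarray, bins: int, max_candidates: int
) -> list[tuple[float, float]]:
    """(position, prominence) seeds from a smoothed histogram."""
    counts, edges = np.histogram(x, bins=bins)
    smooth = gaussian_filter1d(counts.astype(float), sigma=2.0)
    floor = max(3.0, 0.01 * smooth.max())
    idx, props = find_peaks(smooth, prominence=floor)
    mids = 0.5 * (edges[:-1] + edges[1:])
    cand = sorted(
        zip(mids[idx], props["prominences"]), key=lambda t: -t[1]
    )[:max_candidates]
    return cand


def _em_fit(
    x: np.ndarray,
    mu0: np.ndarray,
    model_debris: bool,
    max_iter: int = 300,
    tol: float = 1e-8,
):
    """EM for k Gaussians (+ optional exponential debris) in one dimension.

    Returns (weights, means, sds, debris_weight, debris_scale, loglik, n_params).
    """
    n = x.size
    k = mu0.size
    mu = mu0.astype(float).copy()
    sd = np.maximum(0.03 * mu, 1e-9 * max(1.0, float(np.ptp(x))) + 1e-300)
    if model_debris:
        w_debris = 0.05
        lam = max(float(np.mean(x[x < 0.5 * mu.min()])) if (x < 0.5 * mu.min()).any() else 0.3 * mu.min(), 1e-12)
    else:
        w_debris = 0.0
        lam = 1.0
    w = np.full(k, (1.0 - w_debris) / k)

    prev_ll = -np.inf
    for _ in range(max_iter):
        comp = w * np.exp(-0.5 * ((x[:, None] - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        if model_debris:
            dens_d = w_debris * np.exp(-x / lam) / lam
            total = comp.sum(axis=1) + dens_d
        else:
            total = comp.sum(axis=1)
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        resp = comp / total[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, (1e-6 * np.maximum(mu, 1e-12)) ** 2))
        w = nk / n
        if model_debris:
            resp_d = dens_d / total
            nd = max(resp_d.sum(), 1e-12)
            lam = max(float((resp_d * x).sum() / nd), 1e-12)
            w_debris = nd / n
            norm = w.sum() + w_debris
            w, w_debris = w / norm, w_debris / norm
        else:
            w = w / w.sum()
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    n_params = (k - 1) + 2 * k + (2 if model_debris else 0)
    return w, mu, sd, w_debris, lam, prev_ll, n_params


def assign_events(
    x: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Deterministic event-to-peak assignment.

    Each event goes to the nearest peak mean if within 3 SD of that peak;
    otherwise it is unassigned (-1, debris).  Ties break toward the lower
    peak (means are sorted ascending, argmin takes the first).
    """
    order = np.argsort(means)
    means = means[order]
    sds = sds[order]
    dist = np.abs(x[:, None] - means)
    nearest = np.argmin(dist, axis=1)
    within = dist[np.arange(x.size), nearest] <= 3.0 * sds[nearest]
    out = np.where(within, nearest, -1)
    return out


def detect_peaks(
    sample: FlowSample,
    max_peaks: int = 5,
    min_fraction: float = 0.05,
    expected_means: Sequence[float] = (),
    model_debris: bool = True,
    bins: int = 512,
) -> PeakDetection:
    """Detect G0/G1 peaks in one channel's events.

    ``expected_means`` are prior peak positions (e.g. the internal
    standard's calibrated channel) that are always kept as mixture seeds;
    they let the deconvolution separate peaks too close for the histogram
    scan alone.  Peaks below ``min_fraction`` of non-debris events are
    dropped; if nothing survives, an empty detection is returned with a
    ``"no_peak_above_min_fraction"`` flag rather than raising.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    x = np.asarray(sample.events, float)
    if x.size == 0:
        raise ValueError("sample has no events")
    flags: list[str] = []
    if np.ptp(x) == 0:  # degenerate: all events identical
        peak = PeakEstimate(float(x[0]), 0.0, 0.0, int(x.size), 1.0)
        return PeakDetection([peak], flags)

    cand = _histogram_candidates(x, bins=bins, max_candidates=max_peaks + 2)
    seeds = [(float(m), np.inf) for m in expected_means]
    for pos, prom in cand:
        # keep near-duplicates apart only when truly coincident (<0.5%):
        # a bump slightly off an expected position is often a merged pair
        # that the mixture should be allowed to split
        if all(abs(pos - s) / max(s, 1e-12) > 0.005 for s, _ in seeds):
            seeds.append((pos, float(prom)))
    if not seeds:
        flags.append("no_peak_above_min_fraction")
        return PeakDetection([], flags)
    seeds.sort(key=lambda t: -t[1])

    best = None
    for k in range(1, min(max_peaks, len(seeds)) + 1):
        mu0 = np.sort(np.array([s for s, _ in seeds[:k]]))
        w, mu, sd, wd, lam, ll, p = _em_fit(x, mu0, model_debris)
        bic = -2.0 * ll + p * np.log(x.size)
        if best is None or bic < best[0]:
            best = (bic, w, mu, sd)
    _, w, mu, sd = best

    keep = w > 1e-4  # drop numerically dead components before assignment
    mu, sd = mu[keep], sd[keep]
    order = np.argsort(mu)
    mu, sd = mu[order], sd[order]

    for _ in range(2):  # drop sub-threshold peaks, re-assign, re-check
        assign = assign_events(x, mu, sd)
        counts = np.array([(assign == j).sum() for j in range(mu.size)])
        total = counts.sum()
        if total == 0:
            flags.append("no_peak_above_min_fraction")
            return PeakDetection([], flags)
        frac = counts / total
        ok = frac >= min_fraction
        if ok.all():
            break
        mu, sd = mu[ok], sd[ok]
        if mu.size == 0:
            flags.append("no_peak_above_min_fraction")
            return PeakDetection([], flags)

    peaks = []
    for j in range(mu.size):
        ev = x[assign == j]
        m = float(ev.mean())
        s = float(ev.std(ddof=0))
        peaks.append(
            PeakEstimate(
                mean_channel=m,
                sd=s,
                cv=100.0 * s / m if m > 0 else 0.0,
                event_count=int(ev.size),
                event_fraction=float(ev.size / total),
            )
        )
    peaks.sort(key=lambda p: p.mean_channel)
    return PeakDetection(peaks, flags)


def qc_cv(
    peaks: Sequence[PeakEstimate], threshold: float = DEFAULT_CV_THRESHOLD
) -> list[PeakEstimate]:
    """Apply the CV acceptance rule: a peak passes iff cv < threshold.

    The inequality is strict (a peak at exactly the threshold fails).
    Failing peaks are retained but flagged; downstream estimation refuses
    them.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    for p in peaks:
        passed = p.cv < threshold
        reason = "" if passed else f"cv {p.cv:.2f}% >= {threshold:g}%"
        out.append(replace(p, qc_pass=passed, qc_reason=reason))
    return out


def mark_standard(
    peaks: Sequence[PeakEstimate], expected_mean: float, rel_tol: float = 0.10
) -> list[PeakEstimate]:
    """Flag the peak nearest ``expected_mean`` (within ``rel_tol``) as the
    internal standard.

    The standard cannot be told apart from sample peaks by shape alone, so
    its expected position (from gain calibration or user annotation) is a
    required input.  Raises if no peak falls within tolerance.
    """
    if not peaks:
        raise ValueError("no peaks to mark")
    dists = [abs(p.mean_channel - expected_mean) for p in peaks]
    i = int(np.argmin(dists))
    if dists[i] > rel_tol * expected_mean:
        raise ValueError(
            f"no peak within {rel_tol:.0%} of expected standard position "
            f"{expected_mean:g} (nearest at {peaks[i].mean_channel:g})"
        )
    return [replace(p, is_standard=(j == i)) for j, p in enumerate(peaks)]
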