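"""Interaction calling from binary fragend coverage.

The caller slides a window of k consecutive usable fragends (step one
fragend) along the viewpoint chromosome and asks whether the number of
covered fragends in the window exceeds what a uniform background coverage
would produce, using the upper tail of the binomial distribution. Windows
below the significance threshold (default p < 1e-8) are merged into
interaction segments.

The window size k is calibrated per viewpoint so that a window holds on
average 20 covered fragends in the viewpoint-proximal region (+/- 100 kbp),
where coverage is densest; the background rate p0 is the covered fraction
of the rest of the chromosome. The binary covered/uncovered reduction makes
the statistic robust to PCR-efficiency differences between fragends.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .fragends import CoverageProfile, ViewpointSpec

__all__ = [
    "ViewpointQCError",
    "WindowScan",
    "InteractionSegment",
    "compute_window_size",
    "background_rate",
    "binomial_pvalue",
    "scan_windows",
    "scan_and_call",
    "write_segments_bed",
    "read_segments_bed",
]


class ViewpointQCError(ValueError):
    """Raised when a viewpoint has too little proximal signal to calibrate."""


@dataclass
class WindowScan:
    """Per-window covered counts and binomial upper-tail p-values."""

    k: int
    p0: float
    x: np.ndarray          # covered fragends per window
    pvalues: np.ndarray
    starts: np.ndarray     # genomic start of each window (first fragend start)
    ends: np.ndarray       # genomic end (last fragend end)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class InteractionSegment:
    """A merged run of significant windows."""

    chrom: str
    start: int
    end: int
    min_p: float
    n_windows: int
    distance_bp: int
    snp_id: str = ""

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_window_size(
    profile: CoverageProfile,
    viewpoint: ViewpointSpec | None = None,
    flank: int = 100_000,
    target_covered: int = 20,
) -> int:
    """Adaptive window size: k fragends containing on average
    ``target_covered`` covered fragends in the viewpoint +/- ``flank`` zone.

    k = round(target_covered / r) with r the covered fraction near the
    viewpoint (rounding half away from zero), floored at ``target_covered``.
    E.g. 100 covered of 150 fragends with target 20 gives k = 30.
    """
    vp = viewpoint or profile.viewpoint
    mid = profile.midpoints
    sel = np.abs(mid - vp.position) <= flank
    total = int(sel.sum())
    covered = int(profile.status[sel].sum())
    if total == 0 or covered == 0:
        raise ViewpointQCError(
            f"viewpoint {vp.snp_id} failed QC: no covered fragends within "
            f"+/-{flank} bp; cannot calibrate window size"
        )
    r = covered / total
    return max(_round_half_away(target_covered / r), target_covered)


def background_rate(
    profile: CoverageProfile,
    viewpoint: ViewpointSpec | None = None,
    exclusion: int = 100_000,
) -> float:
    """Chromosome-wide covered fraction outside the viewpoint-proximal zone.

    The +/- ``exclusion`` bp around the viewpoint is dominated by the
    contact-frequency decay and would inflate the background; it is left
    out. The estimate is clamped into the open interval via
    [1/(n+2), (n+1)/(n+2)] so the binomial tail is always defined.
    """
    vp = viewpoint or profile.viewpoint
    mid = profile.midpoints
    sel = np.abs(mid - vp.position) > exclusion
    n = int(sel.sum())
    if n == 0:
        raise ViewpointQCError(
            f"viewpoint {vp.snp_id}: all fragends inside the +/-{exclusion} bp "
            "exclusion zone; no background estimate"
        )
    if n < 1000:
        warnings.warn(
            f"viewpoint {vp.snp_id}: only {n} fragends outside the exclusion "
            "zone; background rate is noisy"
        )
    covered = int(profile.status[sel].sum())
    p0 = covered / n
    return float(min(max(p0, 1.0 / (n + 2)), (n + 1.0) / (n + 2)))


def binomial_pvalue(x: int, k: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= x), X ~ Binomial(k, p0).

    The tail includes x itself, so binomial_pvalue(0, k, p0) == 1 for any
    k and p0 (equivalent to R's pbinom(x-1, k, p0, lower.tail=FALSE)).
    """
    if not (0 <= x <= k):
        raise ValueError(f"need 0 <= x <= k, got x={x}, k={k}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"need 0 < p0 < 1, got p0={p0}")
    if x == 0:
        return 1.0
    return float(binom.sf(x - 1, k, p0))


def scan_windows(profile: CoverageProfile, k: int, p0: float) -> WindowScan:
    """Count covered fragends in every window of k consecutive fragends
    (step one fragend) and attach the binomial upper-tail p-value."""
    status = profile.status.astype(np.int64)
    n = len(status)
    if n < k:
        warnings.warn(
            f"{profile.viewpoint.snp_id}/{profile.cell_type}: chromosome has "
            f"{n} fragends < window size {k}; no windows"
        )
        empty = np.empty(0, dtype=np.int64)
        return WindowScan(k, p0, empty, empty.astype(float), empty, empty)
    csum = np.concatenate([[0], np.cumsum(status)])
    x = csum[k:] - csum[:-k]
    pvals = binom.sf(x - 1, k, p0)
    starts = profile.starts[: n - k + 1]
    ends = profile.ends[k - 1:]
    return WindowScan(k, float(p0), x, pvals, starts, ends)


def scan_and_call(
    profile: CoverageProfile,
    viewpoint: ViewpointSpec | None = None,
    threshold: float = 1e-8,
    k: int | None = None,
    p0: float | None = None,
    flank: int = 100_000,
    target_covered: int = 20,
    exclusion: int = 100_000,
    self_circle_radius: int = 2,
    exclude_self_circle: bool = True,
) -> list[InteractionSegment]:
    """Call interaction segments on the viewpoint chromosome.

    Windows with p < ``threshold`` are significant; overlapping or adjacent
    significant windows (window-start indices at most k fragends apart) are
    merged into segments. Each segment carries the minimum member-window
    p-value and its genomic span, the union of the member windows' fragend
    spans. Windows lying wholly inside the viewpoint self-circle zone
    (viewpoint fragend +/- ``self_circle_radius`` fragends) are excluded
    from calling, to suppress trivially significant self-ligation signal.
    """
    vp = viewpoint or profile.viewpoint
    if k is None:
        k = compute_window_size(profile, vp, flank=flank, target_covered=target_covered)
    if p0 is None:
        p0 = background_rate(profile, vp, exclusion=exclusion)
    scan = scan_windows(profile, k, p0)
    if len(scan) == 0:
        return []
    sig = scan.pvalues < threshold
    if exclude_self_circle and sig.any():
        vi = int(np.argmin(np.abs(profile.midpoints - vp.position)))
        w_idx = np.arange(len(scan))
        inside = (w_idx >= vi - self_circle_radius) & (
            w_idx + k - 1 <= vi + self_circle_radius
        )
        sig &= ~inside
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    segments: list[InteractionSegment] = []
    run_start = 0
    breaks = np.flatnonzero(np.diff(idx) > k)
    bounds = np.concatenate([[0], breaks + 1, [idx.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        run = idx[a:b]
        first, last = int(run[0]), int(run[-1])
        gstart = int(profile.starts[first])
        gend = int(profile.ends[last + k - 1])
        min_p = float(scan.pvalues[run].min())
        dist = 0
        if vp.position < gstart:
            dist = gstart - vp.position
        elif vp.position >= gend:
            dist = vp.position - gend + 1
        segments.append(
            InteractionSegment(
                chrom=profile.chrom,
                start=gstart,
                end=gend,
                min_p=min_p,
                n_windows=len(run),
                distance_bp=dist,
                snp_id=vp.snp_id,
            )
        )
    return segments


def write_segments_bed(segments: list[InteractionSegment], path) -> None:
    """BED export of called segments: name = SNP id, score = -log10(min p),
    capped at 1000 (p-values can underflow to 0)."""
    with open(path, "w") as fh:
        fh.write("# 4C interaction segments\n")
        for seg in segments:
            score = 1000.0 if seg.min_p <= 0 else min(1000.0, -math.log10(seg.min_p))
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.snp_id}\t{score:.4f}\n"
            )


def read_segments_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score"],
        dtype={"chrom": str},
    )
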