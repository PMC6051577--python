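"""Quality screening of directional Sanger reads.

Three steps, applied in order:

1. windowed base calling -- a base is kept only if it sits inside at least
   one sliding window (default 18 bp) whose mean Phred score reaches the
   cutoff (default 20, i.e. >99% per-base accuracy); bases failing every
   window are masked to N;
2. whole-read flagging -- a read whose mean Phred score over the original
   qualities falls below 20 is flagged low quality (it is carried through
   the pipeline but barred from novel-barcode publication);
3. terminal-N trimming -- leading/trailing positions are removed until a
   12-bp window holds at most one N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

DEFAULT_WINDOW = 18
DEFAULT_CUTOFF = 20.0
DEFAULT_TRIM_WINDOW = 12
DEFAULT_MAX_N = 1
LOW_QUALITY_MEAN = 20.0


@dataclass(frozen=True)
class SangerRead:
    """One directional read: called bases plus per-base Phred scores."""

    sample_id: str
    direction: Literal["forward", "reverse"]
    bases: str
    quals: tuple[int, ...]
    marker: str = "COI"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.sample_id}/{self.direction}: bases and qualities differ "
                f"in length ({len(self.bases)} vs {len(self.quals)})"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError("Phred scores must lie in 0..60")
        if set(self.bases) - set("ACGTN"):
            raise ValueError("read bases must be over A,C,G,T,N")
        object.__setattr__(self, "quals", tuple(int(q) for q in self.quals))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrimReport:
    """Outcome of QC for one read: kept interval and quality flags."""

    kept_interval: tuple[int, int]  # 0-based half-open on the masked read
    mean_phred: float
    low_quality: bool
    n_masked: int


def phred_accuracy(q: float) -> float:
    """Probability that a base call with Phred score ``q`` is correct."""
    if q < 0:
        raise ValueError("Phred scores are non-negative")
    return 1.0 - 10.0 ** (-q / 10.0)


def window_quality_mask(
    read: SangerRead, window: int = DEFAULT_WINDOW, cutoff: float = DEFAULT_CUTOFF
) -> SangerRead:
    """Mask bases not covered by any window of mean Phred >= cutoff.

    A position is *called* iff at least one length-``window`` contiguous
    window containing it has mean Phred >= ``cutoff``; reads shorter than
    the window use the whole read as the only window.  Uncalled bases are
    replaced by N; the quality string is left untouched.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n == 0:
        raise ValueError("cannot mask an empty read")
    quals = np.asarray(read.quals, dtype=float)
    w = min(window, n)
    # means of all windows [s, s+w)
    csum = np.concatenate([[0.0], np.cumsum(quals)])
    means = (csum[w:] - csum[:-w]) / w
    passing = means >= cutoff
    called = np.zeros(n, dtype=bool)
    # union of passing windows via a difference array
    diff = np.zeros(n + 1, dtype=int)
    for s in np.flatnonzero(passing):
        diff[s] += 1
        diff[s + w] -= 1
    called = np.cumsum(diff[:-1]) > 0
    bases = "".join(b if keep else "N" for b, keep in zip(read.bases, called))
    return replace(read, bases=bases)


def flag_low_quality(read: SangerRead) -> bool:
    """True iff the read's mean Phred score is strictly below 20."""
    if len(read) == 0:
        raise ValueError("cannot flag an empty read")
    return float(np.mean(read.quals)) < LOW_QUALITY_MEAN


def trim_terminal_ns(
    bases: str, window: int = DEFAULT_TRIM_WINDOW, max_n: int = DEFAULT_MAX_N
) -> tuple[int, int]:
    """Kept interval after trimming N-rich ends.

    ``start`` is the smallest s whose window ``bases[s:s+window]`` holds at
    most ``max_n`` Ns; ``end`` is the largest e whose window
    ``bases[e-window:e]`` does.  Sequences shorter than the window are
    judged as a single whole-sequence window.  Returns ``(0, 0)`` when no
    window qualifies.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if max_n < 0:
        raise ValueError("max_n must be >= 0")
    n = len(bases)
    if n == 0:
        return (0, 0)
    w = min(window, n)
    is_n = np.fromiter((b == "N" for b in bases), dtype=int, count=n)
    csum = np.concatenate([[0], np.cumsum(is_n)])
    counts = csum[w:] - csum[:-w]  # Ns in window starting at s
    ok = np.flatnonzero(counts <= max_n)
    if ok.size == 0:
        return (0, 0)
    start = int(ok[0])
    end = int(ok[-1]) + w
    return (start, end)


def qc_read(
    read: SangerRead,
    window: int = DEFAULT_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    trim_window: int = DEFAULT_TRIM_WINDOW,
    max_n: int = DEFAULT_MAX_N,
) -> tuple[SangerRead, TrimReport]:
    """Run the full QC chain: window mask -> low-quality flag -> N trim.

    Returns the masked-and-trimmed read plus a report.  The low-quality
    flag is computed on the original qualities of the whole read; the trim
    interval refers to positions of the masked read.
    """
    masked = window_quality_mask(read, window=window, cutoff=cutoff)
    low = flag_low_quality(read)
    start, end = trim_terminal_ns(masked.bases, window=trim_window, max_n=max_n)
    trimmed = replace(
        masked, bases=masked.bases[start:end], quals=masked.quals[start:end]
    )
    report = TrimReport(
        kept_interval=(start, end),
        mean_phred=float(np.mean(read.quals)),
        low_quality=low,
        n_masked=sum(
            1 for b, m in zip(read.bases, masked.bases) if m == "N" and b != "N"
        ),
    )
    return trimmed, report
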