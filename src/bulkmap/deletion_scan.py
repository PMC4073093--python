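"""Stage 2: read-depth screening of capture targets for putative deletions.

Radiation mutagenesis commonly induces large deletions, so a homozygous
deletion in the mutant bulk shows up as a capture target covered in the
wildtype pool but (almost) devoid of reads in the mutant pool.  "Almost"
because a single mis-phenotyped heterozygote in the mutant bulk leaves a
thin residue of coverage -- the reason for the relaxed second condition.

The scan computes maximal contiguously covered intervals on the wildtype
track (so a fully deleted mutant region still yields an interval), clips
them to capture targets, attaches per-pool mean depths, and flags:

* condition 1 -- length >= 150 bp, wildtype mean >= 5x, mutant mean = 0;
* condition 2 -- length >= 150 bp, mutant mean <= 2x, wildtype mean >= 5x
  and at least 4-fold higher than the mutant mean.

Condition 1 takes precedence where both hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from bulkmap.io_formats import CaptureTarget, DepthTrack

__all__ = [
    "CoverageInterval",
    "DeletionCall",
    "covered_intervals",
    "call_deletions",
    "calls_to_frame",
]

DEFAULT_MIN_LENGTH = 150
DEFAULT_WT_MIN = 5.0
DEFAULT_MUT_MAX = 2.0
DEFAULT_RATIO_MIN = 4.0


@dataclass(frozen=True)
class CoverageInterval:
    """A contiguously covered stretch of a capture target (1-based incl.)."""

    contig_id: str
    start: int
    end: int
    mean_depth_mut: float
    mean_depth_wt: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DeletionCall:
    """A coverage interval flagged as putatively deleted in the mutant."""

    interval: CoverageInterval
    condition: int  # 1 or 2

    @property
    def length(self) -> int:
        return self.interval.length


def _runs_of_positive(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as (start, end) offsets."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def covered_intervals(
    depth_mut: DepthTrack,
    depth_wt: DepthTrack,
    targets: Sequence[CaptureTarget],
) -> list[CoverageInterval]:
    """Contiguously covered intervals over capture targets.

    Runs are maximal stretches of consecutive positions with wildtype
    depth > 0; each run is clipped to every capture target it overlaps by
    at least 1 bp (so a run straddling two nearby targets yields two
    intervals).  Per-pool mean depths are computed over every base of the
    clipped interval, counting uncovered bases as 0.
    """
    targets_by_contig: dict[str, list[CaptureTarget]] = {}
    for t in targets:
        targets_by_contig.setdefault(t.contig_id, []).append(t)

    out: list[CoverageInterval] = []
    for contig, ctargets in targets_by_contig.items():
        pos = depth_wt._positions.get(contig)
        if pos is None or pos.size == 0:
            continue
        lo = min(int(pos[0]), min(t.start for t in ctargets))
        hi = max(int(pos[-1]), max(t.end for t in ctargets))
        wt = depth_wt.depth_array(contig, lo, hi)
        mut = depth_mut.depth_array(contig, lo, hi)
        runs = _runs_of_positive(wt > 0)
        for t in sorted(ctargets, key=lambda t: (t.start, t.end)):
            for r_lo, r_hi in runs:
                start = max(lo + r_lo, t.start)
                end = min(lo + r_hi, t.end)
                if start > end:
                    continue
                sl = slice(start - lo, end - lo + 1)
                out.append(
                    CoverageInterval(
                        contig_id=contig,
                        start=start,
                        end=end,
                        mean_depth_mut=float(mut[sl].mean()),
                        mean_depth_wt=float(wt[sl].mean()),
                    )
                )
    out.sort(key=lambda iv: (iv.contig_id, iv.start, iv.end))
    return out


def call_deletions(
    intervals: Sequence[CoverageInterval],
    min_length: int = DEFAULT_MIN_LENGTH,
    wt_min: float = DEFAULT_WT_MIN,
    mut_max: float = DEFAULT_MUT_MAX,
    ratio_min: float = DEFAULT_RATIO_MIN,
) -> list[DeletionCall]:
    """Flag putatively deleted intervals by the two-condition rule.

    The ratio rule is expressed multiplicatively (``mean_wt >=
    ratio_min * mean_mut``) so it stays well-defined when the mutant mean
    is exactly 0; calls use full precision even though reports round
    means to one decimal.
    """
    calls: list[DeletionCall] = []
    for iv in intervals:
        if iv.length < min_length:
            continue
        if iv.mean_depth_wt >= wt_min and iv.mean_depth_mut == 0.0:
            calls.append(DeletionCall(iv, condition=1))
        elif (
            iv.mean_depth_mut <= mut_max
            and iv.mean_depth_wt >= wt_min
            and iv.mean_depth_wt >= ratio_min * iv.mean_depth_mut
        ):
            calls.append(DeletionCall(iv, condition=2))
    return calls


def calls_to_frame(calls: Sequence[DeletionCall]) -> pd.DataFrame:
    """Tabulate calls; mean depths are rounded to one decimal for report."""
    return pd.DataFrame(
        [
            (
                c.interval.contig_id,
                c.interval.start,
                c.interval.end,
                c.length,
                round(c.interval.mean_depth_mut, 1),
                round(c.interval.mean_depth_wt, 1),
                c.condition,
            )
            for c in calls
        ],
        columns=["contig", "start", "end", "length", "cov_mut", "cov_wt", "condition"],
    )
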