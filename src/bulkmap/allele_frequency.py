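"""Stage 1: pooled allele-frequency mapping along the genetic framework.

Per-site pool frequencies are computed from allelic depths, filtered
(coverage, uninformative high-in-both sites), averaged in 1-cM bins using
each contig's genetic anchor, and scanned for the bin with the largest
mutant-minus-wildtype frequency difference -- the causal-locus signature
of a recessive bulk experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from bulkmap.io_formats import ContigAnchor, PoolSiteCounts

__all__ = [
    "BinnedFrequency",
    "PeakCall",
    "FilterStats",
    "site_frequency",
    "filter_sites",
    "bin_frequencies",
    "bins_to_frame",
    "detect_peak",
]

logger = logging.getLogger(__name__)

#: Default thresholds of the published procedure: >= 30x coverage in both
#: pools; sites >= 80% in both pools discarded; 1-cM bins with >= 30 SNPs.
DEFAULT_MIN_DEPTH = 30
DEFAULT_BOTH_HIGH = 0.80
DEFAULT_BIN_CM = 1.0
DEFAULT_MIN_SNPS = 30
DEFAULT_WARN_THRESHOLD = 0.2


@dataclass(frozen=True)
class BinnedFrequency:
    """Unweighted mean pool frequencies of the SNPs in one genetic bin."""

    chromosome: str
    bin_start: float
    n_snps: int
    mean_freq_mut: float
    mean_freq_wt: float

    @property
    def score(self) -> float:
        return self.mean_freq_mut - self.mean_freq_wt


@dataclass(frozen=True)
class PeakCall:
    """The bin maximizing the mutant-wildtype frequency difference."""

    chromosome: str
    bin_start: float
    bin_width: float
    mean_freq_mut: float
    mean_freq_wt: float
    score: float
    runners_up: tuple[BinnedFrequency, ...] = field(default=())

    @property
    def bin_midpoint_cm(self) -> float:
        return self.bin_start + self.bin_width / 2.0


@dataclass
class FilterStats:
    """Counts at each filter boundary, for reproducible reporting."""

    n_input: int = 0
    n_low_depth: int = 0
    n_both_high: int = 0
    n_retained: int = 0
    n_unanchored: int = 0


def site_frequency(counts: PoolSiteCounts, pool: str) -> float:
    """Alternate-allele frequency in one pool: alt / (ref + alt).

    The alternate allele is the mutant-linked allele when reads were
    aligned to the wildtype-parent reference.  Zero total depth is an
    error here; such sites are removed upstream by the coverage filter.
    """
    if pool == "mutant":
        ref, alt = counts.ref_depth_mut, counts.alt_depth_mut
    elif pool == "wildtype":
        ref, alt = counts.ref_depth_wt, counts.alt_depth_wt
    else:
        raise ValueError(f"pool must be 'mutant' or 'wildtype', got {pool!r}")
    total = ref + alt
    if total == 0:
        raise ZeroDivisionError(
            f"undefined frequency: zero {pool} depth at "
            f"{counts.contig_id}:{counts.position}"
        )
    return alt / total


def filter_sites(
    sites: Sequence[PoolSiteCounts],
    min_depth: int = DEFAULT_MIN_DEPTH,
    both_high: float = DEFAULT_BOTH_HIGH,
    stats: FilterStats | None = None,
) -> list[PoolSiteCounts]:
    """Apply the coverage and high-in-both-pools site filters.

    A site is retained iff its total depth is >= ``min_depth`` in *both*
    pools and its frequency is **not** >= ``both_high`` in both pools.
    The second rule removes sites where the mutant parent simply differs
    from the reference genome-wide; the causal-locus signature (high in
    the mutant pool only) passes it.  The depth filter is applied first.
    """
    out: list[PoolSiteCounts] = []
    s = stats if stats is not None else FilterStats()
    for site in sites:
        s.n_input += 1
        if site.total_mut < min_depth or site.total_wt < min_depth:
            s.n_low_depth += 1
            continue
        f_mut = site.alt_depth_mut / site.total_mut
        f_wt = site.alt_depth_wt / site.total_wt
        if f_mut >= both_high and f_wt >= both_high:
            s.n_both_high += 1
            continue
        s.n_retained += 1
        out.append(site)
    logger.info(
        "filter_sites: %d input, %d below %dx, %d >= %.0f%% in both pools, %d retained",
        s.n_input, s.n_low_depth, min_depth, s.n_both_high, 100 * both_high,
        s.n_retained,
    )
    return out


def bin_frequencies(
    sites: Sequence[PoolSiteCounts],
    anchors: Sequence[ContigAnchor],
    bin_width: float = DEFAULT_BIN_CM,
    min_snps: int = DEFAULT_MIN_SNPS,
    stats: FilterStats | None = None,
) -> list[BinnedFrequency]:
    """Average per-site pool frequencies in genetic bins.

    Each site inherits its contig's (chromosome, cM) anchor; bins are
    half-open ``[k*w, (k+1)*w)`` cM, so a contig's single cM value places
    all its sites in one bin.  Sites on unanchored contigs are excluded
    (counted in ``stats``); bins with fewer than ``min_snps`` sites are
    dropped.  Means are unweighted over sites.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    anchor_map = {a.contig_id: a for a in anchors}
    s = stats if stats is not None else FilterStats()
    rows = []
    for site in sites:
        anchor = anchor_map.get(site.contig_id)
        if anchor is None:
            s.n_unanchored += 1
            continue
        rows.append(
            (
                anchor.chromosome,
                np.floor(anchor.cm_position / bin_width) * bin_width,
                site.alt_depth_mut / site.total_mut,
                site.alt_depth_wt / site.total_wt,
            )
        )
    if s.n_unanchored:
        logger.info("bin_frequencies: %d sites on unanchored contigs", s.n_unanchored)
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["chromosome", "bin_start", "f_mut", "f_wt"])
    grouped = (
        df.groupby(["chromosome", "bin_start"], sort=True)
        .agg(n_snps=("f_mut", "size"), mean_freq_mut=("f_mut", "mean"),
             mean_freq_wt=("f_wt", "mean"))
        .reset_index()
    )
    grouped = grouped[grouped["n_snps"] >= min_snps]
    return [
        BinnedFrequency(
            chromosome=str(r.chromosome),
            bin_start=float(r.bin_start),
            n_snps=int(r.n_snps),
            mean_freq_mut=float(r.mean_freq_mut),
            mean_freq_wt=float(r.mean_freq_wt),
        )
        for r in grouped.itertuples(index=False)
    ]


def bins_to_frame(bins: Sequence[BinnedFrequency]) -> pd.DataFrame:
    """Tabulate bins with the stable column order of the freqmap report."""
    return pd.DataFrame(
        [
            (b.chromosome, b.bin_start, b.n_snps, b.mean_freq_mut,
             b.mean_freq_wt, b.score)
            for b in bins
        ],
        columns=["chromosome", "bin_start", "n_snps", "f_mut", "f_wt", "score"],
    )


def detect_peak(
    bins: Sequence[BinnedFrequency],
    bin_width: float = DEFAULT_BIN_CM,
    n_best: int = 5,
    warn_threshold: float = DEFAULT_WARN_THRESHOLD,
) -> PeakCall:
    """Return the bin maximizing score = mean_freq_mut - mean_freq_wt.

    Ties are broken deterministically by (chromosome order, lower
    bin_start).  Up to ``n_best`` runner-up bins are attached for
    diagnostics.  When the best score is below ``warn_threshold`` the
    genome looks flat (no linked locus) and a warning is logged.
    """
    if not bins:
        raise ValueError("no bins survived filtering; cannot detect a peak")
    ordered = sorted(bins, key=lambda b: (-b.score, b.chromosome, b.bin_start))
    best = ordered[0]
    if best.score < warn_threshold:
        logger.warning(
            "detect_peak: maximal score %.3f is below %.2f; "
            "no clear causal-locus signal", best.score, warn_threshold,
        )
    return PeakCall(
        chromosome=best.chromosome,
        bin_start=best.bin_start,
        bin_width=bin_width,
        mean_freq_mut=best.mean_freq_mut,
        mean_freq_wt=best.mean_freq_wt,
        score=best.score,
        runners_up=tuple(ordered[1 : n_best + 1]),
    )
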