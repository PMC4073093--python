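"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions
----------------------
Internally everything is **1-based inclusive**: a feature spanning
positions 2107..2455 has length 349.  BED input/output (0-based
half-open) is converted at the boundary, so the BED line
``ctg<TAB>2106<TAB>2455`` becomes start=2107, end=2455.

Formats
-------
* Depth track: tab-separated ``contig<TAB>pos<TAB>depth_mut<TAB>depth_wt``
  (the ``samtools depth`` dialect, one depth column per sample; positions
  1-based, strictly increasing per contig; absent positions mean depth 0).
* Variants: VCF 4.x with two samples (mutant pool, wildtype pool) and a
  per-sample allelic-depth (AD) field.
* Capture targets: BED.  Genes: 6-column TSV.  Anchors: 3-column TSV
  (contig, chromosome, cM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ConfigurationError",
    "DepthRecord",
    "DepthTrack",
    "CaptureTarget",
    "GeneModel",
    "ContigAnchor",
    "PoolSiteCounts",
    "read_depth_track",
    "write_depth_tracks",
    "read_pool_vcf",
    "write_pool_vcf",
    "read_targets_bed",
    "write_targets_bed",
    "read_anchor_table",
    "write_anchor_table",
    "read_gene_table",
    "write_gene_table",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigurationError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class DepthRecord:
    """Per-base read depth at one position of one contig (1-based)."""

    contig_id: str
    position: int
    depth: int


@dataclass(frozen=True)
class CaptureTarget:
    """An exome-capture target interval, 1-based inclusive."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"need 1 <= start <= end, got {self.start}..{self.end} on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene on an assembly contig, 1-based inclusive."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    confidence: str  # "high" or "low"
    annotation: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.confidence not in ("high", "low"):
            raise ValueError(
                f"gene {self.gene_id}: confidence must be 'high' or 'low', "
                f"got {self.confidence!r}"
            )


@dataclass(frozen=True)
class ContigAnchor:
    """Placement of an assembly contig on the genetic framework."""

    contig_id: str
    chromosome: str
    cm_position: float

    def __post_init__(self) -> None:
        if self.cm_position < 0:
            raise ValueError(
                f"anchor for {self.contig_id}: cM position must be >= 0"
            )


@dataclass(frozen=True)
class PoolSiteCounts:
    """Allelic read depths of one biallelic SNP in the two pools.

    The alternate allele is defined relative to the wildtype-parent
    reference, so ``alt`` is the mutant-linked allele.
    """

    contig_id: str
    position: int
    ref_depth_mut: int
    alt_depth_mut: int
    ref_depth_wt: int
    alt_depth_wt: int

    @property
    def total_mut(self) -> int:
        return self.ref_depth_mut + self.alt_depth_mut

    @property
    def total_wt(self) -> int:
        return self.ref_depth_wt + self.alt_depth_wt


class DepthTrack:
    """Sparse per-base depth of one sample over one contig universe.

    Positions absent from the track have depth 0 by convention, matching
    the output of ``samtools depth`` on a BAM without zero-depth rows.
    """

    def __init__(self) -> None:
        self._positions: dict[str, np.ndarray] = {}
        self._depths: dict[str, np.ndarray] = {}

    @property
    def contigs(self) -> list[str]:
        return list(self._positions)

    def set_contig(
        self, contig_id: str, positions: np.ndarray, depths: np.ndarray
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        depths = np.asarray(depths, dtype=np.int64)
        if positions.shape != depths.shape:
            raise ValueError("positions and depths must have equal length")
        if positions.size and positions[0] < 1:
            raise FormatError(f"{contig_id}: positions must be 1-based (>= 1)")
        if positions.size > 1 and np.any(np.diff(positions) <= 0):
            raise FormatError(
                f"{contig_id}: positions must be strictly increasing"
            )
        if np.any(depths < 0):
            raise FormatError(f"{contig_id}: negative depth")
        self._positions[contig_id] = positions
        self._depths[contig_id] = depths

    def records(self, contig_id: str) -> list[DepthRecord]:
        pos = self._positions.get(contig_id, np.empty(0, dtype=np.int64))
        dep = self._depths.get(contig_id, np.empty(0, dtype=np.int64))
        return [
            DepthRecord(contig_id, int(p), int(d)) for p, d in zip(pos, dep)
        ]

    def depth_array(self, contig_id: str, start: int, end: int) -> np.ndarray:
        """Dense depth over ``start..end`` (1-based inclusive); absent = 0."""
        if start < 1 or end < start:
            raise ValueError(f"invalid range {start}..{end}")
        out = np.zeros(end - start + 1, dtype=np.int64)
        pos = self._positions.get(contig_id)
        if pos is None or pos.size == 0:
            return out
        dep = self._depths[contig_id]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        out[pos[lo:hi] - start] = dep[lo:hi]
        return out

    def depth_at(self, contig_id: str, position: int) -> int:
        return int(self.depth_array(contig_id, position, position)[0])


def read_depth_track(path: str | Path, sample_count: int = 2) -> list[DepthTrack]:
    """Read a multi-sample ``samtools depth``-style track.

    Each row is ``contig<TAB>pos<TAB>depth_1[<TAB>depth_2...]`` with one
    depth column per sample.  Rows with fewer columns than declared
    samples are a hard error, never a silent zero-fill.

    Returns one :class:`DepthTrack` per sample.  An empty file yields
    ``sample_count`` empty tracks.
    """
    if sample_count < 1:
        raise ValueError("sample_count must be >= 1")
    tracks = [DepthTrack() for _ in range(sample_count)]
    cur_contig: str | None = None
    positions: list[int] = []
    depths: list[list[int]] = [[] for _ in range(sample_count)]

    def flush() -> None:
        if cur_contig is None:
            return
        pos_arr = np.array(positions, dtype=np.int64)
        for s in range(sample_count):
            tracks[s].set_contig(
                cur_contig, pos_arr, np.array(depths[s], dtype=np.int64)
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 + sample_count:
                raise FormatError(
                    f"{path}:{lineno}: expected {2 + sample_count} columns "
                    f"(contig, pos, {sample_count} depths), got {len(fields)}"
                )
            contig = fields[0]
            try:
                pos = int(fields[1])
                row_depths = [int(f) for f in fields[2:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if contig != cur_contig:
                if contig in tracks[0]._positions:
                    raise FormatError(
                        f"{path}:{lineno}: contig {contig} appears in two blocks"
                    )
                flush()
                cur_contig = contig
                positions = []
                depths = [[] for _ in range(sample_count)]
            if positions and pos <= positions[-1]:
                raise FormatError(
                    f"{path}:{lineno}: non-monotone position {pos} on {contig}"
                )
            positions.append(pos)
            for s in range(sample_count):
                depths[s].append(row_depths[s])
    flush()
    return tracks


def write_depth_tracks(tracks: Sequence[DepthTrack], path: str | Path) -> None:
    """Write tracks as one multi-sample depth file (union of positions).

    A position present in any track is written with the per-sample depths
    (0 where absent), preserving the absent-means-zero convention.
    """
    contigs: list[str] = []
    for t in tracks:
        for c in t.contigs:
            if c not in contigs:
                contigs.append(c)
    with open(path, "w") as fh:
        for contig in contigs:
            all_pos = np.unique(
                np.concatenate(
                    [
                        t._positions.get(contig, np.empty(0, dtype=np.int64))
                        for t in tracks
                    ]
                )
            )
            if all_pos.size == 0:
                continue
            lo, hi = int(all_pos[0]), int(all_pos[-1])
            dense = [t.depth_array(contig, lo, hi) for t in tracks]
            for p in all_pos:
                row = "\t".join(str(int(d[p - lo])) for d in dense)
                fh.write(f"{contig}\t{int(p)}\t{row}\n")


def read_pool_vcf(
    path: str | Path, mutant_sample: str, wildtype_sample: str
) -> list[PoolSiteCounts]:
    """Read per-site pooled allelic depths from a two-sample VCF.

    Only biallelic SNP records are kept; multiallelic records and indels
    are skipped and the skip count logged.  Allelic depths come from the
    per-sample AD field; the site total is ref+alt, not the site DP.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (mutant_sample, wildtype_sample):
        if name not in samples:
            raise ConfigurationError(
                f"sample {name!r} not in VCF {path} (has {samples})"
            )
    i_mut = samples.index(mutant_sample)
    i_wt = samples.index(wildtype_sample)
    out: list[PoolSiteCounts] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {var.CHROM}:{var.POS} lacks the AD field"
            )
        ad = np.asarray(ad)
        out.append(
            PoolSiteCounts(
                contig_id=var.CHROM,
                position=int(var.POS),
                ref_depth_mut=int(ad[i_mut, 0]),
                alt_depth_mut=int(ad[i_mut, 1]),
                ref_depth_wt=int(ad[i_wt, 0]),
                alt_depth_wt=int(ad[i_wt, 1]),
            )
        )
    if n_skipped:
        logger.info("read_pool_vcf: skipped %d non-biallelic/indel records", n_skipped)
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bulkmap
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
"""


def write_pool_vcf(
    sites: Iterable[PoolSiteCounts],
    path: str | Path,
    mutant_sample: str = "mutant_pool",
    wildtype_sample: str = "wildtype_pool",
) -> None:
    """Write pooled allelic depths as a minimal two-sample VCF 4.2 file."""
    sites = list(sites)
    contigs: list[str] = []
    for s in sites:
        if s.contig_id not in contigs:
            contigs.append(s.contig_id)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            f"\t{mutant_sample}\t{wildtype_sample}\n"
        )
        for s in sites:
            fh.write(
                f"{s.contig_id}\t{s.position}\t.\tA\tG\t.\tPASS\t.\tAD"
                f"\t{s.ref_depth_mut},{s.alt_depth_mut}"
                f"\t{s.ref_depth_wt},{s.alt_depth_wt}\n"
            )


def read_targets_bed(path: str | Path) -> list[CaptureTarget]:
    """Read capture targets from BED, converting to 1-based inclusive."""
    out: list[CaptureTarget] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start0 < 0 or end0 <= start0:
                raise FormatError(
                    f"{path}:{lineno}: invalid BED interval {start0}..{end0}"
                )
            out.append(CaptureTarget(fields[0], start0 + 1, end0))
    return out


def write_targets_bed(targets: Iterable[CaptureTarget], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.contig_id}\t{t.start - 1}\t{t.end}\n")


def read_anchor_table(path: str | Path) -> list[ContigAnchor]:
    """Read the contig -> (chromosome, cM) anchoring table (3-column TSV).

    Duplicate contig ids are an error: a contig has at most one anchor.
    Contigs absent from the table are treated as unanchored downstream.
    """
    out: list[ContigAnchor] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (contig, chromosome, cM)"
                )
            contig, chrom, cm_text = fields
            try:
                cm = float(cm_text)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: cM position {cm_text!r} is not a number"
                ) from None
            if cm < 0:
                raise FormatError(f"{path}:{lineno}: negative cM position {cm}")
            if contig in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate anchor for contig {contig}"
                )
            seen.add(contig)
            out.append(ContigAnchor(contig, chrom, cm))
    return out


def write_anchor_table(anchors: Iterable[ContigAnchor], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(f"{a.contig_id}\t{a.chromosome}\t{a.cm_position:g}\n")


_GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "confidence", "annotation"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the 6-column gene table (TSV with header, 1-based inclusive)."""
    out: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise FormatError(
                f"{path}: expected header {_GENE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                gene = GeneModel(
                    gene_id=fields[0],
                    contig_id=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    confidence=fields[4],
                    annotation=fields[5],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            out.append(gene)
    return out


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.contig_id}\t{g.start}\t{g.end}"
                f"\t{g.confidence}\t{g.annotation}\n"
            )
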