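"""A worked example: deleted capture targets at the barley *mnd* locus.

The eight putatively deleted exome-capture intervals found on barley
chromosome 5H between 80 and 110 cM in the published *many-noded dwarf*
mapping experiment, with their per-pool mean read depths, the
high-confidence gene on each contig and the contig's POPSEQ anchor.
Feeding them through :func:`bulkmap.deletion_scan.call_deletions` and
:func:`bulkmap.candidate_ranking.rank_candidates` against the 97-cM
allele-frequency peak reproduces the candidate shortlist, headed by the
cytochrome P450 gene MLOC_64838.2 whose two exons are deleted in the
mutant.
"""

from __future__ import annotations

from bulkmap.deletion_scan import CoverageInterval
from bulkmap.io_formats import ContigAnchor, GeneModel

__all__ = [
    "mnd_intervals",
    "mnd_genes",
    "mnd_anchors",
    "MND_PEAK_CM",
    "MND_INTERVAL_CM",
]

#: cM position of the mutant-bulk allele-frequency peak on 5H.
MND_PEAK_CM = 97.0
#: The broadly defined mapping interval on 5H.
MND_INTERVAL_CM = (80.0, 110.0)

# (contig, start, end, mean depth mutant pool, mean depth wildtype pool,
#  gene id, functional annotation, anchor cM on 5H); 1-based inclusive.
_ROWS = [
    ("contig_49382", 2107, 2455, 0.4, 24.4, "MLOC_64838.2", "Cytochrome P450", 96.6),
    ("contig_49382", 3871, 4101, 1.1, 8.8, "MLOC_64838.2", "Cytochrome P450", 96.6),
    ("contig_159829", 785, 996, 0.9, 8.2, "MLOC_21734.1", "CC-NBS-LRR", 99.9),
    ("contig_159829", 4501, 4709, 0.4, 12.4, "MLOC_21734.1", "CC-NBS-LRR", 99.9),
    ("contig_1558349", 1236, 1477, 1.5, 11.5, "MLOC_10070.1", "MATE efflux family", 99.9),
    ("contig_45126", 14800, 14961, 0.8, 7.3, "AK365660", "Tumor susceptibility 101 protein", 107.1),
    ("contig_2547452", 4712, 4913, 0.1, 10.5, "AK357178", "3'-5' exoribonuclease CSL4", 108.1),
    ("contig_58347", 7926, 8186, 1.0, 14.5, "MLOC_70680.1", "DNA repair protein-like", 109.4),
]


def mnd_intervals() -> list[CoverageInterval]:
    """The eight deleted intervals as coverage intervals with pool means."""
    return [
        CoverageInterval(
            contig_id=contig, start=start, end=end,
            mean_depth_mut=mut, mean_depth_wt=wt,
        )
        for contig, start, end, mut, wt, *_ in _ROWS
    ]


def mnd_genes() -> list[GeneModel]:
    """One high-confidence gene per contig, spanning that contig's
    deleted intervals (the published table gives no gene coordinates, so
    the span of the deleted intervals stands in for the gene span)."""
    by_gene: dict[str, list[tuple]] = {}
    for row in _ROWS:
        by_gene.setdefault(row[5], []).append(row)
    genes = []
    for gene_id, rows in by_gene.items():
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=rows[0][0],
                start=min(r[1] for r in rows),
                end=max(r[2] for r in rows),
                confidence="high",
                annotation=rows[0][6],
            )
        )
    return genes


def mnd_anchors() -> list[ContigAnchor]:
    """POPSEQ anchors of the six contigs, all on chromosome 5H."""
    seen: dict[str, float] = {}
    for row in _ROWS:
        seen.setdefault(row[0], row[7])
    return [ContigAnchor(contig, "5H", cm) for contig, cm in seen.items()]
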