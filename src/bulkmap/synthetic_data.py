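"""Ground-truth simulator for a bulked-segregant exome-capture experiment.

The generator reproduces the study design end to end:

1. **F2 genotypes** -- a homozygous recessive mutant is outcrossed to a
   wildtype cultivar; the F1 is selfed.  Each F2 individual receives two
   independent gametes; gametes are built marker-to-marker with
   recombination probabilities from the Haldane map function (Poisson
   crossovers, no interference).  Markers are parent-diagnostic SNPs, so
   a gamete's allele at a marker records which parental chromosome the
   segment came from.
2. **Phenotypic bulks** -- a mutant bulk (default 18 plants, one of them
   a mis-phenotyped heterozygote) and a wildtype bulk (default 30 plants
   drawn at random from the phenotypic wildtypes).
3. **Pooled sequencing** -- per-site read depths from a negative-binomial
   (or Poisson) model and alternate-read counts from a binomial around
   the bulk's true allele frequency, plus per-base depth tracks over
   capture targets with a homozygous deletion spanning the causal gene's
   exons (the causal mutation is simultaneously a SNP marker and a
   deletion, mirroring a radiation-induced allele).

All randomness flows from explicit seeds; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bulkmap.genetics import BulkComposition, haldane_cm_to_r
from bulkmap.io_formats import (
    CaptureTarget,
    ConfigurationError,
    ContigAnchor,
    DepthTrack,
    GeneModel,
    PoolSiteCounts,
    write_anchor_table,
    write_depth_tracks,
    write_gene_table,
    write_pool_vcf,
    write_targets_bed,
)

__all__ = [
    "GeneticMapConfig",
    "DepthModel",
    "MarkerMap",
    "F2Individual",
    "F2Population",
    "BulkSpec",
    "DeletionSpec",
    "build_marker_map",
    "simulate_f2",
    "compose_bulks",
    "simulate_pool_counts",
    "simulate_depth_tracks",
    "default_scenario_config",
    "write_scenario",
]

#: Capture-target template repeated on every simulated contig
#: (1-based inclusive).  On the causal contig the same two intervals are
#: the deleted exons of the causal gene.
_TARGET_TEMPLATE = ((1201, 1549), (2401, 2631))
_GENE_SPAN = (1201, 2631)

_ANNOTATIONS = (
    "protein kinase family protein",
    "MYB transcription factor",
    "pentatricopeptide repeat protein",
    "ABC transporter family protein",
    "glycosyl hydrolase",
    "zinc finger protein",
    "heat shock protein 70",
    "ribosomal protein L10",
)


@dataclass(frozen=True)
class GeneticMapConfig:
    """Layout of the simulated genetic framework.

    Contigs are evenly spaced along each chromosome and each carries
    ``markers_per_cm * length / contigs_per_chromosome`` diagnostic SNPs,
    all at the contig's anchor position (a short contig recombines
    negligibly within itself).  A random ``unanchored_fraction`` of
    contigs is omitted from the anchor table, emulating the unplaced part
    of a draft assembly; the causal contig is always anchored.
    """

    chromosomes: tuple[tuple[str, float], ...] = (("1H", 150.0), ("2H", 150.0))
    markers_per_cm: float = 35.0
    contigs_per_chromosome: int = 150
    unanchored_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.markers_per_cm <= 0:
            raise ValueError("markers_per_cm must be positive")
        if self.contigs_per_chromosome < 1:
            raise ValueError("contigs_per_chromosome must be >= 1")
        if not 0.0 <= self.unanchored_fraction < 1.0:
            raise ValueError("unanchored_fraction must be in [0, 1)")


@dataclass(frozen=True)
class DepthModel:
    """Per-site sequencing depth model for a pooled sample.

    ``dispersion`` is the negative-binomial shape parameter (variance =
    mean + mean^2/dispersion); ``math.inf`` gives Poisson depths.
    ``error_rate`` is the per-read probability of reporting the wrong
    allele.
    """

    mean_depth: float = 60.0
    dispersion: float = 20.0
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (use inf for Poisson)")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must be in [0, 0.01]")

    def draw_depths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if np.isinf(self.dispersion):
            return rng.poisson(self.mean_depth, size=n)
        p = self.dispersion / (self.dispersion + self.mean_depth)
        return rng.negative_binomial(self.dispersion, p, size=n)


@dataclass(frozen=True)
class MarkerMap:
    """Positions and contig assignment of every simulated locus.

    One row per locus; the causal locus is an ordinary row flagged by
    ``causal_index``.  ``cm`` is sorted within each chromosome.
    """

    table: pd.DataFrame  # columns: chromosome, cm, contig_id, position
    causal_index: int
    anchors: tuple[ContigAnchor, ...]

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def causal_contig(self) -> str:
        return str(self.table["contig_id"].iloc[self.causal_index])


@dataclass(frozen=True)
class F2Individual:
    """One simulated F2 plant: per-marker mutant-allele dosage + phenotype."""

    dosages: np.ndarray  # int8, one entry per locus of the MarkerMap
    phenotype: str  # "mutant" or "wildtype"


class F2Population:
    """A simulated F2 population (sequence of :class:`F2Individual`).

    Dosages are stored as a dense (n_individuals x n_loci) int8 matrix of
    mutant-allele counts in {0, 1, 2}; the phenotype is recessive on the
    causal-locus dosage.
    """

    def __init__(self, dosages: np.ndarray, marker_map: MarkerMap) -> None:
        self.dosages = dosages
        self.marker_map = marker_map
        self.phenotypes = np.where(
            dosages[:, marker_map.causal_index] == 2, "mutant", "wildtype"
        )

    def __len__(self) -> int:
        return self.dosages.shape[0]

    def __getitem__(self, i: int) -> F2Individual:
        return F2Individual(self.dosages[i], str(self.phenotypes[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))


@dataclass(frozen=True)
class BulkSpec:
    """Composition of one sequenced pool."""

    name: str
    member_indices: tuple[int, ...]
    composition: BulkComposition  # genotype counts at the causal locus

    @property
    def n_plants(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class DeletionSpec:
    """The causal deletion: exon intervals on the causal contig.

    Zygosity per individual is derived from the causal-locus dosage --
    the deletion *is* the causal mutation, so it co-segregates perfectly.
    """

    contig_id: str
    exons: tuple[tuple[int, int], ...]


def build_marker_map(
    config: GeneticMapConfig, causal: tuple[str, float]
) -> MarkerMap:
    """Lay out contigs, markers, anchors and the causal locus.

    The causal locus is inserted at its exact cM position on the contig
    whose anchor is nearest; that contig is always anchored.
    """
    causal_chrom, causal_cm = causal
    chrom_names = [name for name, _ in config.chromosomes]
    if causal_chrom not in chrom_names:
        raise ConfigurationError(
            f"causal chromosome {causal_chrom!r} is not on the map {chrom_names}"
        )
    length = dict(config.chromosomes)[causal_chrom]
    if not 0.0 <= causal_cm <= length:
        raise ConfigurationError(
            f"causal position {causal_cm} cM is off chromosome "
            f"{causal_chrom} (length {length} cM)"
        )

    rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, float, str, int]] = []
    anchors: list[ContigAnchor] = []
    causal_index = -1
    for chrom, chrom_len in config.chromosomes:
        n_contigs = config.contigs_per_chromosome
        contig_cms = (np.arange(n_contigs) + 0.5) * chrom_len / n_contigs
        per_contig = max(
            1, int(round(config.markers_per_cm * chrom_len / n_contigs))
        )
        causal_contig_i = (
            int(np.argmin(np.abs(contig_cms - causal_cm)))
            if chrom == causal_chrom
            else -1
        )
        unanchored = rng.random(n_contigs) < config.unanchored_fraction
        for i in range(n_contigs):
            contig = f"sim_contig_{chrom}_{i:04d}"
            cm = float(contig_cms[i])
            if not unanchored[i] or i == causal_contig_i:
                anchors.append(ContigAnchor(contig, chrom, round(cm, 4)))
            for j in range(per_contig):
                rows.append((chrom, cm, contig, 3000 + 211 * j))
            if i == causal_contig_i:
                causal_index = len(rows)
                # the causal SNP sits at the start of the first deleted exon
                rows.append((chrom, causal_cm, contig, _TARGET_TEMPLATE[0][0]))

    table = pd.DataFrame(
        rows, columns=["chromosome", "cm", "contig_id", "position"]
    )
    order = np.argsort(
        table["chromosome"].map({c: k for k, c in enumerate(chrom_names)})
        * 1e9
        + table["cm"].to_numpy(),
        kind="stable",
    )
    causal_index = int(np.flatnonzero(order == causal_index)[0])
    table = table.iloc[order].reset_index(drop=True)
    return MarkerMap(table=table, causal_index=causal_index, anchors=tuple(anchors))


def _simulate_gametes(
    marker_map: MarkerMap, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_gametes x n_loci) matrix: 1 = mutant-parent allele.

    Within each chromosome, the parental origin switches between
    consecutive loci with probability given by Haldane on the inter-locus
    distance (0 for co-located loci).
    """
    table = marker_map.table
    out = np.empty((n_gametes, len(table)), dtype=np.int8)
    for chrom in table["chromosome"].unique():
        idx = np.flatnonzero((table["chromosome"] == chrom).to_numpy())
        cms = table["cm"].to_numpy()[idx]
        r = 0.5 * (1.0 - np.exp(-2.0 * np.diff(cms) / 100.0))  # Haldane, vectorized
        start = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
        if idx.size > 1:
            switches = rng.random((n_gametes, idx.size - 1)) < r
            states = np.cumsum(switches, axis=1, dtype=np.int64) & 1
            alleles = np.concatenate(
                [start[:, None], start[:, None] ^ states.astype(np.int8)], axis=1
            )
        else:
            alleles = start[:, None]
        out[:, idx] = alleles
    return out


def simulate_f2(
    config: GeneticMapConfig,
    n_individuals: int = 100,
    causal: tuple[str, float] = ("1H", 97.0),
    seed: int | None = None,
) -> F2Population:
    """Simulate an F2 population of a mutant x wildtype cross.

    Each individual is the union of two independent gametes of the
    selfed F1; the phenotype is recessive on the causal dosage.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    marker_map = build_marker_map(config, causal)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gametes = _simulate_gametes(marker_map, 2 * n_individuals, rng)
    dosages = gametes[0::2] + gametes[1::2]
    return F2Population(dosages, marker_map)


def compose_bulks(
    pop: F2Population,
    mutant_bulk_size: int = 18,
    wildtype_bulk_size: int = 30,
    n_misphenotyped_het: int = 1,
    seed: int = 0,
) -> tuple[BulkSpec, BulkSpec]:
    """Draw the two sequenced bulks from the population.

    The mutant bulk holds ``mutant_bulk_size - n_misphenotyped_het``
    phenotypic mutants plus ``n_misphenotyped_het`` heterozygotes (the
    phenotyping error of the study design); the wildtype bulk is drawn
    uniformly without replacement from the remaining phenotypic
    wildtypes.
    """
    if n_misphenotyped_het > mutant_bulk_size:
        raise ValueError("more mis-phenotyped plants than mutant bulk slots")
    rng = np.random.default_rng(seed)
    causal_dos = pop.dosages[:, pop.marker_map.causal_index]
    mutants = np.flatnonzero(causal_dos == 2)
    hets = np.flatnonzero(causal_dos == 1)
    n_true_mut = mutant_bulk_size - n_misphenotyped_het
    if mutants.size < n_true_mut:
        raise ValueError(
            f"population has {mutants.size} phenotypic mutants, "
            f"need {n_true_mut}"
        )
    if hets.size < n_misphenotyped_het:
        raise ValueError(
            f"population has {hets.size} heterozygotes, "
            f"need {n_misphenotyped_het}"
        )
    mut_members = np.concatenate(
        [
            rng.choice(mutants, size=n_true_mut, replace=False),
            rng.choice(hets, size=n_misphenotyped_het, replace=False),
        ]
    )
    wildtypes = np.flatnonzero(pop.phenotypes == "wildtype")
    wildtypes = np.setdiff1d(wildtypes, mut_members)
    if wildtypes.size < wildtype_bulk_size:
        raise ValueError(
            f"population has {wildtypes.size} available phenotypic "
            f"wildtypes, need {wildtype_bulk_size}"
        )
    wt_members = rng.choice(wildtypes, size=wildtype_bulk_size, replace=False)

    def make_bulk(name: str, members: np.ndarray) -> BulkSpec:
        dos = causal_dos[members]
        comp = BulkComposition(
            n_hom_mutant=int(np.sum(dos == 2)),
            n_het=int(np.sum(dos == 1)),
            n_hom_wildtype=int(np.sum(dos == 0)),
        )
        return BulkSpec(name, tuple(int(m) for m in np.sort(members)), comp)

    return make_bulk("mutant", mut_members), make_bulk("wildtype", wt_members)


def _true_bulk_freqs(pop: F2Population, bulk: BulkSpec) -> np.ndarray:
    idx = np.array(bulk.member_indices, dtype=np.int64)
    return pop.dosages[idx].sum(axis=0) / (2.0 * idx.size)


def simulate_pool_counts(
    pop: F2Population,
    mutant_bulk: BulkSpec,
    wildtype_bulk: BulkSpec,
    depth_model: DepthModel = DepthModel(),
    seed: int = 0,
) -> list[PoolSiteCounts]:
    """Draw pooled allelic depths at every marker.

    Site depth comes from the depth model; the alternate-read count is
    binomial around the bulk's true allele frequency blurred by the
    per-read error rate.  Sites where both pools drew depth 0 are
    dropped (they would not appear in a VCF).
    """
    rng = np.random.default_rng(seed)
    table = pop.marker_map.table
    n = len(table)
    e = depth_model.error_rate
    out_cols = {}
    for bulk in (mutant_bulk, wildtype_bulk):
        f_true = _true_bulk_freqs(pop, bulk)
        f_obs = f_true * (1.0 - e) + (1.0 - f_true) * e
        depth = depth_model.draw_depths(n, rng)
        alt = rng.binomial(depth, f_obs)
        out_cols[bulk.name] = (depth - alt, alt)
    sites: list[PoolSiteCounts] = []
    ref_m, alt_m = out_cols["mutant"]
    ref_w, alt_w = out_cols["wildtype"]
    contigs = table["contig_id"].to_numpy()
    positions = table["position"].to_numpy()
    for i in range(n):
        if ref_m[i] + alt_m[i] + ref_w[i] + alt_w[i] == 0:
            continue
        sites.append(
            PoolSiteCounts(
                contig_id=str(contigs[i]),
                position=int(positions[i]),
                ref_depth_mut=int(ref_m[i]),
                alt_depth_mut=int(alt_m[i]),
                ref_depth_wt=int(ref_w[i]),
                alt_depth_wt=int(alt_w[i]),
            )
        )
    return sites


def simulate_depth_tracks(
    pop: F2Population,
    mutant_bulk: BulkSpec,
    wildtype_bulk: BulkSpec,
    targets: Sequence[CaptureTarget],
    deletion: DeletionSpec,
    depth_model: DepthModel = DepthModel(),
    seed: int = 0,
    target_lognorm_sigma: float = 0.5,
) -> tuple[DepthTrack, DepthTrack]:
    """Per-base depth of both pools over the capture targets.

    Off-target positions carry no reads.  Each target gets a
    multiplicative lognormal capture-efficiency factor (sigma =
    ``target_lognorm_sigma``) shared by both pools; per-base depths are
    Poisson around ``mean_depth * factor``, scaled on deleted exons by
    the fraction of non-deleted chromosomes in the bulk (a mutant bulk of
    17 homozygous-deleted plants plus 1 heterozygote retains 1/36 of its
    chromosomes there).
    """
    for ex_start, ex_end in deletion.exons:
        if not any(
            t.contig_id == deletion.contig_id
            and t.start <= ex_start
            and ex_end <= t.end
            for t in targets
        ):
            raise ConfigurationError(
                f"deletion exon {deletion.contig_id}:{ex_start}-{ex_end} "
                "lies within no capture target"
            )
    rng = np.random.default_rng(seed)
    causal_dos = pop.dosages[:, pop.marker_map.causal_index]

    def intact_fraction(bulk: BulkSpec) -> float:
        idx = np.array(bulk.member_indices, dtype=np.int64)
        deleted = int(causal_dos[idx].sum())  # deleted chromosomes in pool
        return 1.0 - deleted / (2.0 * idx.size)

    intact = {"mutant": intact_fraction(mutant_bulk), "wildtype": intact_fraction(wildtype_bulk)}
    tracks = {"mutant": DepthTrack(), "wildtype": DepthTrack()}
    per_contig: dict[str, dict[str, list[np.ndarray]]] = {}
    pos_per_contig: dict[str, list[np.ndarray]] = {}
    for t in sorted(targets, key=lambda t: (t.contig_id, t.start)):
        factor = float(rng.lognormal(mean=0.0, sigma=target_lognorm_sigma))
        positions = np.arange(t.start, t.end + 1, dtype=np.int64)
        deleted_mask = np.zeros(positions.size, dtype=bool)
        if t.contig_id == deletion.contig_id:
            for ex_start, ex_end in deletion.exons:
                deleted_mask |= (positions >= ex_start) & (positions <= ex_end)
        for pool in ("mutant", "wildtype"):
            lam = np.full(positions.size, depth_model.mean_depth * factor)
            lam[deleted_mask] *= intact[pool]
            depths = rng.poisson(lam)
            per_contig.setdefault(t.contig_id, {"mutant": [], "wildtype": []})[
                pool
            ].append(depths)
        pos_per_contig.setdefault(t.contig_id, []).append(positions)
    for contig, pos_chunks in pos_per_contig.items():
        positions = np.concatenate(pos_chunks)
        for pool in ("mutant", "wildtype"):
            depths = np.concatenate(per_contig[contig][pool])
            tracks[pool].set_contig(contig, positions, depths)
    return tracks["mutant"], tracks["wildtype"]


# ---------------------------------------------------------------------------
# Default scenario: the study design at test-bench scale.


@dataclass(frozen=True)
class ScenarioConfig:
    """The complete default scenario (the study design, desk-scale)."""

    map: GeneticMapConfig = field(default_factory=GeneticMapConfig)
    n_individuals: int = 100
    causal: tuple[str, float] = ("1H", 97.0)
    mutant_bulk_size: int = 18
    wildtype_bulk_size: int = 30
    n_misphenotyped_het: int = 1
    depth: DepthModel = field(default_factory=DepthModel)
    #: capture-target per-base depth is shallower than the SNP sites that
    #: survive the 30x filter (published per-target pool means sit in the
    #: 7-25x range)
    target_depth: DepthModel = field(
        default_factory=lambda: DepthModel(mean_depth=25.0)
    )


def default_scenario_config(seed: int = 0) -> ScenarioConfig:
    """The default scenario: 2 x 150 cM chromosomes, 35 markers/cM, a
    100-plant F2, bulks of 18 (one heterozygote) and 30, causal locus at
    (1H, 97 cM)."""
    return ScenarioConfig(map=GeneticMapConfig(seed=seed))


@dataclass(frozen=True)
class Scenario:
    """In-memory result of one simulated experiment."""

    config: ScenarioConfig
    population: F2Population
    mutant_bulk: BulkSpec
    wildtype_bulk: BulkSpec
    sites: list[PoolSiteCounts]
    targets: list[CaptureTarget]
    genes: list[GeneModel]
    deletion: DeletionSpec
    depth_mut: DepthTrack
    depth_wt: DepthTrack

    @property
    def causal_gene_id(self) -> str:
        return f"GENE_{self.deletion.contig_id}"


def _scenario_genes_targets(
    marker_map: MarkerMap, rng: np.random.Generator
) -> tuple[list[CaptureTarget], list[GeneModel], DeletionSpec]:
    causal_contig = marker_map.causal_contig
    contigs = list(dict.fromkeys(marker_map.table["contig_id"]))
    targets: list[CaptureTarget] = []
    genes: list[GeneModel] = []
    for k, contig in enumerate(contigs):
        for start, end in _TARGET_TEMPLATE:
            targets.append(CaptureTarget(contig, start, end))
        confidence = "high" if (contig == causal_contig or rng.random() < 0.8) else "low"
        annotation = (
            "cytochrome P450 family protein"
            if contig == causal_contig
            else _ANNOTATIONS[k % len(_ANNOTATIONS)]
        )
        genes.append(
            GeneModel(
                gene_id=f"GENE_{contig}",
                contig_id=contig,
                start=_GENE_SPAN[0],
                end=_GENE_SPAN[1],
                confidence=confidence,
                annotation=annotation,
            )
        )
    deletion = DeletionSpec(contig_id=causal_contig, exons=_TARGET_TEMPLATE)
    return targets, genes, deletion


def simulate_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 0,
    with_depth_tracks: bool = True,
) -> Scenario:
    """Run the full generator: genotypes -> bulks -> counts (-> tracks).

    One seed drives everything: the map layout, meioses, bulk draws and
    sequencing noise each consume an independent stream spawned from it.
    """
    if config is None:
        config = default_scenario_config(seed)
    else:
        config = replace(config, map=replace(config.map, seed=seed))
    streams = np.random.SeedSequence(seed).spawn(4)
    # An F2 of 100 occasionally segregates too few mutants to fill the
    # bulk (as an experimenter would, we only run the experiment on a
    # population with enough phenotypic mutants): re-draw the meioses
    # with a derived sub-seed until the bulks can be composed.
    for attempt in range(100):
        pop = simulate_f2(
            config.map,
            n_individuals=config.n_individuals,
            causal=config.causal,
            seed=int(streams[0].generate_state(attempt + 1)[-1] % (2**31)),
        )
        try:
            mut_bulk, wt_bulk = compose_bulks(
                pop,
                mutant_bulk_size=config.mutant_bulk_size,
                wildtype_bulk_size=config.wildtype_bulk_size,
                n_misphenotyped_het=config.n_misphenotyped_het,
                seed=int(streams[1].generate_state(1)[0] % (2**31)),
            )
        except ValueError:
            continue
        break
    else:
        raise ConfigurationError(
            "could not compose bulks in 100 population draws; "
            "bulk sizes are implausible for this population size"
        )
    sites = simulate_pool_counts(
        pop, mut_bulk, wt_bulk, config.depth,
        seed=int(streams[2].generate_state(1)[0] % (2**31)),
    )
    gene_rng = np.random.default_rng(config.map.seed)
    targets, genes, deletion = _scenario_genes_targets(pop.marker_map, gene_rng)
    if with_depth_tracks:
        depth_mut, depth_wt = simulate_depth_tracks(
            pop, mut_bulk, wt_bulk, targets, deletion, config.target_depth,
            seed=int(streams[3].generate_state(1)[0] % (2**31)),
        )
    else:
        depth_mut, depth_wt = DepthTrack(), DepthTrack()
    return Scenario(
        config=config,
        population=pop,
        mutant_bulk=mut_bulk,
        wildtype_bulk=wt_bulk,
        sites=sites,
        targets=targets,
        genes=genes,
        deletion=deletion,
        depth_mut=depth_mut,
        depth_wt=depth_wt,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus a ground-truth JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "pools.vcf",
        "depth": outdir / "depth.tsv",
        "targets": outdir / "targets.bed",
        "anchors": outdir / "anchors.tsv",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.json",
    }
    write_pool_vcf(scenario.sites, paths["vcf"])
    write_depth_tracks([scenario.depth_mut, scenario.depth_wt], paths["depth"])
    write_targets_bed(scenario.targets, paths["targets"])
    write_anchor_table(scenario.population.marker_map.anchors, paths["anchors"])
    write_gene_table(scenario.genes, paths["genes"])
    mm = scenario.population.marker_map
    truth = {
        "causal_chromosome": scenario.config.causal[0],
        "causal_cm": scenario.config.causal[1],
        "causal_contig": scenario.deletion.contig_id,
        "causal_gene": scenario.causal_gene_id,
        "deletion_exons": [list(e) for e in scenario.deletion.exons],
        "mutant_bulk": {
            "members": list(scenario.mutant_bulk.member_indices),
            "n_hom_mutant": scenario.mutant_bulk.composition.n_hom_mutant,
            "n_het": scenario.mutant_bulk.composition.n_het,
            "n_hom_wildtype": scenario.mutant_bulk.composition.n_hom_wildtype,
        },
        "wildtype_bulk": {
            "members": list(scenario.wildtype_bulk.member_indices),
            "n_hom_mutant": scenario.wildtype_bulk.composition.n_hom_mutant,
            "n_het": scenario.wildtype_bulk.composition.n_het,
            "n_hom_wildtype": scenario.wildtype_bulk.composition.n_hom_wildtype,
        },
        "n_markers": mm.n_loci,
        "seed": scenario.config.map.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
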