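"""Closed-form pool genetics shared by the simulator and the analysis.

Covers map functions (Haldane, Kosambi), the expected frequency of the
mutant-linked allele in a sequenced bulk of known genotypic composition,
Mendelian F2 genotype probabilities, and the Pearson goodness-of-fit test
for a segregation ratio.

Conventions
-----------
Genetic distances are in centimorgan (cM).  A recombination fraction ``r``
is the per-gamete probability that a marker and the causal locus are
inherited from different parental chromosomes; ``r`` lies in ``[0, 0.5]``
with 0.5 meaning free recombination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "BulkComposition",
    "SegregationResult",
    "haldane_cm_to_r",
    "kosambi_cm_to_r",
    "map_cm_to_r",
    "expected_bulk_freq",
    "f2_genotype_probs",
    "wildtype_het_hom_ratio",
    "segregation_chi2",
]


@dataclass(frozen=True)
class BulkComposition:
    """Genotypic composition of a sequenced bulk at the causal locus.

    Attributes
    ----------
    n_hom_mutant : int
        Plants homozygous for the mutant allele.
    n_het : int
        Heterozygous plants (e.g. a mis-phenotyped plant included in the
        mutant bulk).
    n_hom_wildtype : int
        Plants homozygous for the wildtype allele.
    """

    n_hom_mutant: int
    n_het: int
    n_hom_wildtype: int

    def __post_init__(self) -> None:
        counts = (self.n_hom_mutant, self.n_het, self.n_hom_wildtype)
        if any(c < 0 for c in counts):
            raise ValueError(f"bulk counts must be non-negative, got {counts}")
        if sum(counts) == 0:
            raise ValueError("bulk must contain at least one plant")

    @property
    def n_plants(self) -> int:
        return self.n_hom_mutant + self.n_het + self.n_hom_wildtype

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_plants

    @property
    def causal_mutant_freq(self) -> float:
        """Frequency of the mutant allele at the causal locus itself."""
        return (2 * self.n_hom_mutant + self.n_het) / self.n_chromosomes


@dataclass(frozen=True)
class SegregationResult:
    """Pearson goodness-of-fit result for a two-class segregation ratio."""

    chi2: float
    p_value: float
    df: int


def haldane_cm_to_r(distance_cm: float) -> float:
    """Haldane map function: crossovers are Poisson, no interference.

    r = (1 - exp(-2d)) / 2 with d in Morgan.
    """
    if distance_cm < 0:
        raise ValueError(f"genetic distance must be >= 0, got {distance_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cm / 100.0))


def kosambi_cm_to_r(distance_cm: float) -> float:
    """Kosambi map function: r = tanh(2d) / 2 with d in Morgan.

    Allows for positive crossover interference; the convention linkage
    mapping software typically reports distances in.
    """
    if distance_cm < 0:
        raise ValueError(f"genetic distance must be >= 0, got {distance_cm}")
    return 0.5 * math.tanh(2.0 * distance_cm / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane_cm_to_r, "kosambi": kosambi_cm_to_r}


def map_cm_to_r(distance_cm: float, method: str = "haldane") -> float:
    """Convert a genetic distance in cM to a recombination fraction.

    Parameters
    ----------
    distance_cm : float
        Genetic distance, >= 0.
    method : {"haldane", "kosambi"}
        Map function.  Haldane (no interference) is the process model used
        by the simulator; Kosambi is offered for distance reporting.
    """
    try:
        fn = _MAP_FUNCTIONS[method]
    except KeyError:
        raise ValueError(
            f"unknown map function {method!r}; choose from {sorted(_MAP_FUNCTIONS)}"
        ) from None
    return fn(distance_cm)


def expected_bulk_freq(
    r: float, composition: BulkComposition, bulk: str = "mutant"
) -> float:
    """Expected frequency of the mutant-linked marker allele in a bulk.

    Each of the bulk's ``2N`` chromosomes either carries the causal mutant
    allele or not; a chromosome that does carries the linked marker allele
    with probability ``1 - r``, and one that does not with probability
    ``r``.  The expectation is therefore affine in ``r``::

        f(r) = f0 * (1 - r) + (1 - f0) * r

    where ``f0`` is the mutant-allele frequency at the causal locus given
    the composition.  At ``r = 0`` this is ``f0`` itself (e.g. 35/36 for a
    mutant bulk of 17 homozygotes plus 1 mis-phenotyped heterozygote); at
    ``r = 0.5`` it is 0.5 for every composition.

    The ``bulk`` label is informational (the composition carries all the
    information); it is validated only.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    if bulk not in ("mutant", "wildtype"):
        raise ValueError(f"bulk must be 'mutant' or 'wildtype', got {bulk!r}")
    f0 = composition.causal_mutant_freq
    return f0 * (1.0 - r) + (1.0 - f0) * r


def f2_genotype_probs() -> dict[str, float]:
    """Mendelian genotype probabilities in a selfed-F1 (F2) population."""
    return {"hom_mutant": 0.25, "het": 0.5, "hom_wildtype": 0.25}


def wildtype_het_hom_ratio() -> float:
    """Expected het : hom-wildtype ratio among phenotypically wildtype F2.

    A recessive mutation leaves heterozygotes phenotypically wildtype, so
    the wildtype class contains hets and homozygous wildtypes at 1/2 : 1/4,
    i.e. exactly 2:1 -- the reason a wildtype bulk sits near allele
    frequency 1/3 at the causal locus rather than 0.
    """
    p = f2_genotype_probs()
    return p["het"] / p["hom_wildtype"]


def segregation_chi2(
    n_mutant: int, n_wildtype: int, expected_mutant_fraction: float = 0.25
) -> SegregationResult:
    """Pearson goodness-of-fit test of a two-class segregation ratio.

    No continuity correction is applied; the p-value is the upper tail of
    the chi-square distribution with 1 degree of freedom.  For a recessive
    monogenic trait the expected mutant fraction is 1/4; e.g. 19 mutants
    vs. 81 wildtypes gives chi2 = 1.92, p = 0.166 -- consistent with 3:1
    segregation.

    Parameters
    ----------
    n_mutant, n_wildtype : int
        Observed class counts.
    expected_mutant_fraction : float
        Expected proportion of mutants, strictly between 0 and 1.
    """
    if n_mutant < 0 or n_wildtype < 0:
        raise ValueError("class counts must be non-negative")
    total = n_mutant + n_wildtype
    if total == 0:
        raise ValueError("total count must be positive")
    if not 0.0 < expected_mutant_fraction < 1.0:
        raise ValueError(
            f"expected_mutant_fraction must be in (0, 1), got {expected_mutant_fraction}"
        )
    exp_mut = total * expected_mutant_fraction
    exp_wt = total - exp_mut
    stat = (n_mutant - exp_mut) ** 2 / exp_mut + (n_wildtype - exp_wt) ** 2 / exp_wt
    p = float(_chi2_dist.sf(stat, df=1))
    return SegregationResult(chi2=float(stat), p_value=p, df=1)
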