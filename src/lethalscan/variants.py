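"""Candidate causative-mutation filtering.

Given a detected haplotype region, sequence variants from heterozygous carrier
bulls and non-carrier controls are filtered in three steps:

1. positional — the search region is the haplotype interval extended by a
   flank (default 6 Mb) on each side, because incomplete linkage
   disequilibrium can place the causative mutation well outside the detected
   window;
2. genotype pattern — a recessive lethal carried by every live carrier bull
   must be heterozygous in all carriers and absent (homozygous reference) in
   all controls;
3. consequence — protein-truncating classes (stop gain, frameshift, essential
   splice) are kept unconditionally; missense variants only when flagged
   damaging by both external predictors (the predictor calls are consumed as
   an annotation table, not computed).

A final haplotype-association check on a key-ancestor panel distinguishes
variants exclusively associated with the detected haplotype from those riding
on several haplotypes, eliminates variants observed homozygous in a live
animal, and flags haplotype homozygotes that lack the variant (an ancestral
version of the haplotype without the mutation still segregating).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import VariantTable

logger = logging.getLogger(__name__)

PROTEIN_TRUNCATING = {"stop_gained", "frameshift", "splice"}


@dataclass
class SearchRegion:
    """Half-open genomic interval [start_bp, end_bp) searched for candidates."""

    chromosome: int
    start_bp: int
    end_bp: int
    flank_bp: int

    def contains(self, positions) -> np.ndarray:
        pos = np.asarray(positions)
        return (pos >= self.start_bp) & (pos < self.end_bp)


def define_search_region(chromosome: int, start_bp: int, end_bp: int,
                         flank_mb: float = 6.0) -> SearchRegion:
    """Extend a haplotype interval by ``flank_mb`` on each side, clamped at the
    chromosome start. The output always contains the input interval."""
    if flank_mb < 0:
        raise ValueError("flank must be nonnegative")
    if start_bp >= end_bp:
        raise ValueError("region start must precede end")
    flank = int(round(flank_mb * 1e6))
    return SearchRegion(
        chromosome=chromosome,
        start_bp=max(1, start_bp - flank),
        end_bp=end_bp + flank,
        flank_bp=flank,
    )


def filter_genotype_pattern(
    vt: VariantTable,
    carriers,
    controls,
    region: SearchRegion | None = None,
    lenient: bool = False,
) -> VariantTable:
    """Retain variants heterozygous in every carrier and homozygous reference
    in every control.

    In strict mode (default) a missing genotype fails the condition; with
    ``lenient`` missing genotypes are skipped. An empty control set leaves the
    control condition vacuous (logged). Unknown animal ids raise KeyError
    naming the id.
    """
    carriers = list(carriers)
    controls = list(controls)
    if not carriers:
        raise ValueError("carrier set must be non-empty")
    if set(carriers) & set(controls):
        raise ValueError("carrier and control sets must be disjoint")
    if not controls:
        logger.warning("empty control set: control condition is vacuous")
    car_cols = [vt.sample_column(a) for a in carriers]
    con_cols = [vt.sample_column(a) for a in controls]

    keep = np.ones(vt.n_variants, dtype=bool)
    if region is not None:
        keep &= (vt.sites["chromosome"].to_numpy() == region.chromosome) & region.contains(
            vt.sites["position"].to_numpy()
        )
    g_car = vt.genotypes[:, car_cols]
    if lenient:
        keep &= ((g_car == 1) | (g_car == -1)).all(axis=1) & (g_car == 1).any(axis=1)
    else:
        keep &= (g_car == 1).all(axis=1)
    if con_cols:
        g_con = vt.genotypes[:, con_cols]
        if lenient:
            keep &= ((g_con == 0) | (g_con == -1)).all(axis=1)
        else:
            keep &= (g_con == 0).all(axis=1)
    logger.info("genotype-pattern filter kept %d of %d variants", int(keep.sum()), vt.n_variants)
    return vt.subset(keep)


def filter_consequence(candidates: VariantTable, annotation: pd.DataFrame) -> pd.DataFrame:
    """Restrict candidates to protein-affecting variants.

    The annotation joins on (chromosome, position, alt) and must carry columns
    ``gene, consequence, sift_damaging, polyphen_damaging``. Stop gains,
    frameshifts and splice variants pass unconditionally; missense only when
    damaging by both predictors; anything else is dropped. Candidates missing
    from the annotation are retained with class ``"unknown"`` and a warning,
    never silently discarded.
    """
    sites = candidates.sites[["chromosome", "position", "ref", "alt"]].copy()
    ann = annotation.drop_duplicates(subset=["chromosome", "position", "alt"])
    merged = sites.merge(ann, on=["chromosome", "position", "alt"], how="left")
    unannotated = merged["consequence"].isna()
    if unannotated.any():
        logger.warning("%d candidate variants lack annotation; kept as 'unknown'",
                       int(unannotated.sum()))
        merged.loc[unannotated, "consequence"] = "unknown"
        merged.loc[unannotated, "gene"] = ""
    cons = merged["consequence"].astype(str)
    truncating = cons.isin(PROTEIN_TRUNCATING)
    sift = merged["sift_damaging"].astype(object).apply(lambda v: bool(v) if pd.notna(v) else False)
    poly = merged["polyphen_damaging"].astype(object).apply(lambda v: bool(v) if pd.notna(v) else False)
    damaging_missense = (cons == "missense") & sift & poly
    keep = truncating | damaging_missense | (cons == "unknown")
    out = merged.loc[keep].reset_index(drop=True)
    logger.info("consequence filter kept %d of %d candidates", len(out), len(merged))
    return out


@dataclass
class AssociationReport:
    """Haplotype association of one candidate variant on a key-ancestor panel."""

    variant: str
    associated_haplotypes: list = field(default_factory=list)
    multiple_association: bool = False
    eliminated: bool = False                # a live animal is homozygous alt
    hom_alt_animals: list = field(default_factory=list)
    ancestral_segregating: list = field(default_factory=list)  # hap-homozygote yet variant-het
    carriers_lacking_variant: list = field(default_factory=list)

    @property
    def exclusive(self) -> bool:
        return len(self.associated_haplotypes) == 1 and not self.eliminated


def haplotype_association_check(
    variant_genotypes: pd.Series,
    target_haplotype: str,
    diplotypes: pd.DataFrame,
    variant_name: str = "variant",
) -> AssociationReport:
    """Check which haplotypes the alt allele rides on in a key-ancestor panel.

    ``variant_genotypes``: per-animal codes {0,1,2,-1} indexed by animal id.
    ``diplotypes``: DataFrame indexed by animal id with columns ``hap1, hap2``
    (window haplotype names, e.g. allele strings). The associated haplotypes
    are found by greedy cover: the haplotype carried by the most unexplained
    alt-carrying animals is added until every alt carrier is explained; ties
    break by name for determinism. A variant whose alt allele is seen
    homozygous in a live genotyped animal is eliminated as a lethal candidate.
    """
    common = diplotypes.index.intersection(variant_genotypes.index)
    if len(common) == 0:
        raise ValueError("variant panel and diplotype panel share no animals")
    gt = variant_genotypes.loc[common]
    dip = diplotypes.loc[common]

    alt_animals = list(gt.index[gt >= 1])
    hom_alt = list(gt.index[gt == 2])

    # greedy cover of alt carriers by haplotypes
    unexplained = set(alt_animals)
    associated: list = []
    while unexplained:
        tallies: dict = {}
        for a in unexplained:
            for h in (dip.at[a, "hap1"], dip.at[a, "hap2"]):
                tallies[h] = tallies.get(h, 0) + 1
        best = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        associated.append(best)
        unexplained = {
            a for a in unexplained if best not in (dip.at[a, "hap1"], dip.at[a, "hap2"])
        }

    carries_target = (dip["hap1"] == target_haplotype) | (dip["hap2"] == target_haplotype)
    lacking = list(dip.index[carries_target & (gt == 0)])
    hap_hom = (dip["hap1"] == target_haplotype) & (dip["hap2"] == target_haplotype)
    ancestral = list(dip.index[hap_hom & (gt == 1)])

    return AssociationReport(
        variant=variant_name,
        associated_haplotypes=associated,
        multiple_association=len(associated) > 1,
        eliminated=len(hom_alt) > 0,
        hom_alt_animals=hom_alt,
        ancestral_segregating=ancestral,
        carriers_lacking_variant=lacking,
    )
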