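"""Synthetic AI-cattle population generator.

Emulates the data structure the deficit-of-homozygotes scan assumes: a
multi-breed-style artificial-insemination population with a small number of
influential sires and maternal grandsires (MGS) drawn from a limited founder
haplotype pool, ungenotyped dams that are daughters of genotyped MGS,
genotyped progeny produced by gene drop with recombination, one or more
embedded recessive lethal haplotypes that kill homozygous conceptuses before
genotyping, per-insemination conception outcomes whose mean rate µ is reduced
by lethal homozygosity, and whole-genome-sequencing-style variants in the
region of a lethal haplotype.

The generator is a founder-pool gene drop, not a coalescent simulator: the
scan only needs haplotype identity-by-state over short marker windows, which
the founder structure provides directly. Linkage-disequilibrium decay,
selection across generations and genotyping error are deliberately not
modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_qc import MAP_COLUMNS, MISSING_PARENT, PhasedGenotypes, VariantTable

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass
class LethalSpec:
    """One embedded recessive lethal haplotype.

    The lethal is realized as one specific founder allele string over a marker
    window; ``target_frequency`` is the per-chromosome-copy sampling frequency
    of that founder haplotype, and ``penetrance`` the probability that a
    homozygous conceptus dies before genotyping. With ``fertility_effect`` the
    death happens at conception and zeroes the insemination outcome; without
    it, homozygotes are merely missing from the genotyped cohort (the
    live-but-never-genotyped case, as for a visible non-lethal defect).
    """

    chromosome: int = 1
    window_start_marker: int = 0
    window_n_markers: int = 20
    target_frequency: float = 0.05
    penetrance: float = 1.0
    fertility_effect: bool = True

    def validate(self) -> None:
        if not 0 < self.target_frequency < 0.5:
            raise ConfigError("target_frequency must be in (0, 0.5)")
        if not 0 <= self.penetrance <= 1:
            raise ConfigError("penetrance must be in [0, 1]")
        if self.window_n_markers < 1 or self.window_start_marker < 0:
            raise ConfigError("lethal window indices invalid")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic population.

    Defaults emulate a single breed at roughly half the size of the mid-sized
    cohort the scan is designed for (~8,000 genotyped animals): 80 widely used
    sires and 80 MGS, ~2,000 dams each producing a Poisson(4) family, founder
    haplotypes drawn from a pool of 30, and mean conception rates of 55%
    (heifers) and 42% (lactating cows) — within the 40-55% range typical of
    dairy AI records. Marker spacing (250 markers over 15 Mb, ~60 kb) matches
    50k-chip density so a 20-marker window spans ~1.2 Mb, short enough that
    recombination within a window is negligible over one meiosis.

    ``sire_usage_concentration``: by default (None) dams are assigned to sires
    and to their own sires (the MGS) in balanced round-robin, the planned-AI
    limit; a positive float instead draws Dirichlet(alpha) usage weights,
    concentrating matings on few bulls as alpha shrinks.
    """

    n_sires: int = 80
    n_mgs: int = 80
    n_dams: int = 2000
    progeny_per_mating_mean: float = 4.0
    n_founder_haplotypes: int = 30
    n_chromosomes: int = 2
    markers_per_chromosome: int = 250
    chromosome_length_bp: int = 15_000_000
    lethal_specs: list = field(default_factory=list)
    mean_conception_heifer: float = 0.55
    mean_conception_cow: float = 0.42
    recombination_rate_per_bp: float = 1e-8
    inseminations_per_dam_mean: float = 3.0
    heifer_fraction: float = 0.35
    emit_dam_genotypes: bool = False
    sire_usage_concentration: float | None = None  # None = balanced round-robin
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_sires": self.n_sires, "n_mgs": self.n_mgs, "n_dams": self.n_dams,
            "n_founder_haplotypes": self.n_founder_haplotypes,
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.chromosome_length_bp < self.markers_per_chromosome:
            raise ConfigError("chromosome_length_bp too small for marker count")
        for mu in (self.mean_conception_heifer, self.mean_conception_cow):
            if not 0 <= mu <= 1:
                raise ConfigError("mean conception rates must be in [0, 1]")
        if not 0 <= self.heifer_fraction <= 1:
            raise ConfigError("heifer_fraction must be in [0, 1]")
        if self.recombination_rate_per_bp < 0:
            raise ConfigError("recombination rate must be nonnegative")
        if self.progeny_per_mating_mean <= 0 or self.inseminations_per_dam_mean <= 0:
            raise ConfigError("family-size means must be positive")
        total_f = 0.0
        for spec in self.lethal_specs:
            spec.validate()
            if spec.chromosome < 1 or spec.chromosome > self.n_chromosomes:
                raise ConfigError("lethal chromosome outside simulated genome")
            if spec.window_start_marker + spec.window_n_markers > self.markers_per_chromosome:
                raise ConfigError("lethal window exceeds chromosome marker count")
            total_f += spec.target_frequency
        if self.lethal_specs:
            if self.n_founder_haplotypes < 1 + len(self.lethal_specs):
                raise ConfigError(
                    "founder pool too small to realize the lethal haplotypes at "
                    "the requested frequencies"
                )
            if total_f >= 1:
                raise ConfigError("lethal target frequencies must sum below 1")


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

def simulate_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Uniform-randomly spaced markers with strictly increasing 1-based
    positions on autosomes 1..n_chromosomes; ids unique genome-wide."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    rows = []
    m = config.markers_per_chromosome
    for chrom in range(1, config.n_chromosomes + 1):
        pos = np.unique(rng.integers(1, config.chromosome_length_bp + 1, size=2 * m + 16))
        while len(pos) < m:  # collisions are vanishingly rare at 50k-chip density
            pos = np.unique(
                np.append(pos, rng.integers(1, config.chromosome_length_bp + 1, size=m))
            )
        pos = np.sort(rng.choice(pos, size=m, replace=False))
        for i, p in enumerate(pos):
            rows.append((f"chr{chrom}_m{i:05d}", chrom, int(p), "1", "2"))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


# ---------------------------------------------------------------------------
# Population gene drop
# ---------------------------------------------------------------------------

def _founder_pool(marker_map: pd.DataFrame, config: SimulationConfig, rng) -> np.ndarray:
    """Founder haplotype pool, shape (K, m_total), allele codes 1/2.

    Founder haplotype 1 + i is reserved as the carrier string of lethal spec i
    (index 0 stays a plain background haplotype); within each lethal window the
    reserved string is forced to be unique in the pool.
    """
    k = config.n_founder_haplotypes
    m = len(marker_map)
    base_freq = rng.uniform(0.15, 0.85, size=m)
    pool = (rng.random((k, m)) < base_freq).astype(np.uint8) + 1
    chrom = marker_map["chromosome"].to_numpy()
    for li, spec in enumerate(config.lethal_specs):
        cols = np.flatnonzero(chrom == spec.chromosome)[
            spec.window_start_marker : spec.window_start_marker + spec.window_n_markers
        ]
        carrier = 1 + li
        lethal_str = pool[carrier, cols]
        for other in range(k):
            if other == carrier:
                continue
            if np.array_equal(pool[other, cols], lethal_str):
                flip = cols[rng.integers(len(cols))]
                pool[other, flip] = 3 - pool[other, flip]
    return pool


def _background_indices(config: SimulationConfig) -> np.ndarray:
    """Founder-pool indices not reserved for a lethal haplotype."""
    reserved = set(range(1, 1 + len(config.lethal_specs)))
    return np.array([i for i in range(config.n_founder_haplotypes) if i not in reserved])


def _allocate_lethal_copies(haps: np.ndarray, pool: np.ndarray, specs: list, rng) -> None:
    """Place each lethal founder haplotype at exactly round(f * n) copies per
    chromosome-slot compartment (paternal, maternal), on distinct animals.

    Balanced allocation realizes the target frequency exactly in every founder
    cohort instead of binomially, which is the variance-reduced design the
    frequency targets describe; no founder animal ends up a lethal homozygote.
    """
    n = haps.shape[0]
    free = np.ones(n, dtype=bool)
    for li, spec in enumerate(specs):
        n_pat = int(round(spec.target_frequency * n))
        n_mat = int(round(spec.target_frequency * n))
        avail = np.flatnonzero(free)
        if len(avail) < n_pat + n_mat:
            raise ConfigError("too few founder animals to place the lethal copies")
        chosen = rng.permutation(avail)[: n_pat + n_mat]
        haps[chosen[:n_pat], 0] = pool[1 + li]
        haps[chosen[n_pat:], 1] = pool[1 + li]
        free[chosen] = False


def _lethal_columns(marker_map: pd.DataFrame, spec: LethalSpec) -> np.ndarray:
    chrom = marker_map["chromosome"].to_numpy()
    return np.flatnonzero(chrom == spec.chromosome)[
        spec.window_start_marker : spec.window_start_marker + spec.window_n_markers
    ]


def _gametes(parent_haps: np.ndarray, marker_map: pd.DataFrame, rate: float, rng) -> np.ndarray:
    """One gamete per parent row by Mendelian sampling with recombination.

    ``parent_haps``: (n, 2, m). Crossovers occur independently between adjacent
    markers with probability rate * gap_bp (capped at 0.5); the starting copy
    is chosen at random per chromosome.
    """
    n, _, m = parent_haps.shape
    source = np.empty((n, m), dtype=np.intp)
    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        gaps = np.diff(pos[cols]).astype(float)
        r = np.minimum(rate * gaps, 0.5)
        start = rng.integers(0, 2, size=n)
        if len(cols) > 1 and rate > 0:
            switches = rng.random((n, len(cols) - 1)) < r
            cum = np.concatenate([start[:, None], switches], axis=1).cumsum(axis=1) % 2
        else:
            cum = np.repeat(start[:, None], len(cols), axis=1)
        source[:, cols] = cum
    rows = np.arange(n)[:, None]
    return parent_haps[rows, source, np.arange(m)[None, :]]


def _copies(haps: np.ndarray, cols: np.ndarray, lethal_str: np.ndarray) -> np.ndarray:
    """Number of chromosome copies (per animal) matching the lethal string."""
    return (haps[:, :, cols] == lethal_str).all(axis=2).sum(axis=1)


def _assign_partners(n_dams: int, n_partners: int, concentration, rng) -> np.ndarray:
    """Assign each dam a partner index: balanced round-robin (shuffled) when
    ``concentration`` is None, else Dirichlet-weighted sampling."""
    if concentration is None:
        return rng.permutation(np.arange(n_dams) % n_partners)
    w = rng.dirichlet(np.full(n_partners, float(concentration)))
    return rng.choice(n_partners, size=n_dams, p=w)


def simulate_population(marker_map: pd.DataFrame, config: SimulationConfig):
    """Gene-drop a population and return ``(pedigree, phased, carrier_truth)``.

    Pedigree and phased genotypes contain only live animals; dams are listed in
    the pedigree but their genotypes are withheld unless
    ``config.emit_dam_genotypes`` is set. ``carrier_truth`` records every
    simulated animal's copy number at each lethal window, including dams and
    conceptuses removed by lethality (``genotyped`` is False for those).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    specs = list(config.lethal_specs)
    pool = _founder_pool(marker_map, config, rng)
    bg_idx = _background_indices(config)
    lethal_cols = [_lethal_columns(marker_map, s) for s in specs]
    lethal_strs = [pool[1 + li, cols] for li, cols in enumerate(lethal_cols)]
    rate = config.recombination_rate_per_bp

    sire_ids = np.array([f"S{i:04d}" for i in range(config.n_sires)], dtype=object)
    mgs_ids = np.array([f"G{i:04d}" for i in range(config.n_mgs)], dtype=object)
    dam_ids = np.array([f"D{i:05d}" for i in range(config.n_dams)], dtype=object)

    def draw_bg(shape):
        return pool[rng.choice(bg_idx, size=shape)]

    sire_haps = draw_bg((config.n_sires, 2)).copy()
    mgs_haps = draw_bg((config.n_mgs, 2)).copy()
    _allocate_lethal_copies(sire_haps, pool, specs, rng)
    _allocate_lethal_copies(mgs_haps, pool, specs, rng)

    # dams: paternal copy = MGS gamete, maternal copy from the founder pool
    # with the lethal copies placed by balanced allocation
    alpha = config.sire_usage_concentration
    dam_mgs = _assign_partners(config.n_dams, config.n_mgs, alpha, rng)
    dam_pat = _gametes(mgs_haps[dam_mgs], marker_map, rate, rng)
    dam_mat = draw_bg(config.n_dams).copy()
    free = np.ones(config.n_dams, dtype=bool)
    for li, spec in enumerate(specs):
        n_mat = int(round(spec.target_frequency * config.n_dams))
        chosen = rng.permutation(np.flatnonzero(free))[:n_mat]
        dam_mat[chosen] = pool[1 + li]
        free[chosen] = False
    dam_haps = np.stack([dam_pat, dam_mat], axis=1)
    # dam viability: a homozygous-lethal dam would not be alive to be mated;
    # replace with a fresh paternal gamete and a background maternal copy
    for li, (spec, cols) in enumerate(zip(specs, lethal_cols)):
        for _ in range(100):
            hom = _copies(dam_haps, cols, lethal_strs[li]) == 2
            dead = hom & (rng.random(config.n_dams) < spec.penetrance)
            if not dead.any():
                break
            idx = np.flatnonzero(dead)
            dam_haps[idx, 0] = _gametes(mgs_haps[dam_mgs[idx]], marker_map, rate, rng)
            dam_haps[idx, 1] = draw_bg(len(idx))

    # matings and progeny
    dam_sire = _assign_partners(config.n_dams, config.n_sires, alpha, rng)
    n_prog = rng.poisson(config.progeny_per_mating_mean, size=config.n_dams)
    prog_dam = np.repeat(np.arange(config.n_dams), n_prog)
    total = len(prog_dam)
    prog_sire = dam_sire[prog_dam]
    prog_pat = _gametes(sire_haps[prog_sire], marker_map, rate, rng)
    prog_mat = _gametes(dam_haps[prog_dam], marker_map, rate, rng)
    prog_haps = np.stack([prog_pat, prog_mat], axis=1)
    prog_ids = np.array([f"P{i:06d}" for i in range(total)], dtype=object)

    alive = np.ones(total, dtype=bool)
    for li, (spec, cols) in enumerate(zip(specs, lethal_cols)):
        hom = _copies(prog_haps, cols, lethal_strs[li]) == 2
        dies = hom & (rng.random(total) < spec.penetrance)
        alive &= ~dies
    logger.info("gene drop: %d conceptuses, %d survive to genotyping", total, int(alive.sum()))

    # pedigree (live animals only)
    def founder_rows(ids, sex):
        return pd.DataFrame(
            {
                "animal_id": ids, "sire_id": MISSING_PARENT, "mgs_id": MISSING_PARENT,
                "dam_id": MISSING_PARENT, "sex": sex, "parity_class": "na",
            }
        )

    dam_rows = pd.DataFrame(
        {
            "animal_id": dam_ids,
            "sire_id": mgs_ids[dam_mgs],
            "mgs_id": MISSING_PARENT,
            "dam_id": MISSING_PARENT,
            "sex": "F",
            "parity_class": "na",
        }
    )
    live = np.flatnonzero(alive)
    prog_rows = pd.DataFrame(
        {
            "animal_id": prog_ids[live],
            "sire_id": sire_ids[prog_sire[live]],
            "mgs_id": mgs_ids[dam_mgs[prog_dam[live]]],
            "dam_id": dam_ids[prog_dam[live]],
            "sex": rng.choice(np.array(["M", "F"], dtype=object), size=len(live)),
            "parity_class": "na",
        }
    )
    pedigree = pd.concat(
        [founder_rows(sire_ids, "M"), founder_rows(mgs_ids, "M"), dam_rows, prog_rows],
        ignore_index=True,
    )

    geno_ids = [sire_ids, mgs_ids]
    geno_haps = [sire_haps, mgs_haps]
    if config.emit_dam_genotypes:
        geno_ids.append(dam_ids)
        geno_haps.append(dam_haps)
    geno_ids.append(prog_ids[live])
    geno_haps.append(prog_haps[live])
    phased = PhasedGenotypes(np.concatenate(geno_ids), np.concatenate(geno_haps))

    # truth table over every simulated animal
    truth_rows = []
    roles = [
        (sire_ids, sire_haps, "sire", np.ones(config.n_sires, bool)),
        (mgs_ids, mgs_haps, "mgs", np.ones(config.n_mgs, bool)),
        (dam_ids, dam_haps, "dam", np.full(config.n_dams, config.emit_dam_genotypes)),
        (prog_ids, prog_haps, "progeny", alive),
    ]
    for li, (spec, cols) in enumerate(zip(specs, lethal_cols)):
        for ids, haps, role, genotyped in roles:
            copies = _copies(haps, cols, lethal_strs[li])
            truth_rows.append(
                pd.DataFrame(
                    {
                        "animal_id": ids, "role": role, "lethal": li,
                        "n_copies": copies, "genotyped": genotyped,
                    }
                )
            )
    if specs:
        carrier_truth = pd.concat(truth_rows, ignore_index=True)
    else:
        carrier_truth = pd.DataFrame(
            columns=["animal_id", "role", "lethal", "n_copies", "genotyped"]
        )
    return pedigree, phased, carrier_truth


def lethal_haplotype_string(marker_map: pd.DataFrame, config: SimulationConfig,
                            lethal_index: int = 0) -> str:
    """The exact allele string of an embedded lethal over its window (what the
    scan should flag). Recomputed from the same seeded pool construction."""
    rng = np.random.default_rng([config.seed, 23])
    pool = _founder_pool(marker_map, config, rng)
    spec = config.lethal_specs[lethal_index]
    cols = _lethal_columns(marker_map, spec)
    return "".join(map(str, pool[1 + lethal_index, cols]))


# ---------------------------------------------------------------------------
# Inseminations
# ---------------------------------------------------------------------------

def simulate_inseminations(
    pedigree: pd.DataFrame,
    carrier_truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-insemination conception outcomes.

    Each dam receives a Poisson number of inseminations (>=1) by bulls drawn
    from the sire panel; the outcome is 1 with probability
    µ_parity * (1 - P(conceptus homozygous lethal) * penetrance) where the
    homozygosity probability is the product of the true parental transmission
    probabilities at each lethal with a fertility effect.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 37])
    dams = pedigree[pedigree["animal_id"].str.startswith("D")]
    sires = pedigree[pedigree["animal_id"].str.startswith("S")]["animal_id"].to_numpy()
    if len(dams) == 0 or len(sires) == 0:
        raise ConfigError("population must be simulated before inseminations")

    n_ins = np.maximum(rng.poisson(config.inseminations_per_dam_mean, size=len(dams)), 1)
    rep = np.repeat(np.arange(len(dams)), n_ins)
    total = len(rep)
    cow = dams["animal_id"].to_numpy()[rep]
    cow_sire = dams["sire_id"].to_numpy()[rep]
    bull = sires[rng.integers(0, len(sires), size=total)]
    parity = np.where(
        rng.random(total) < config.heifer_fraction, "heifer", "cow"
    )
    mu = np.where(parity == "heifer", config.mean_conception_heifer, config.mean_conception_cow)

    surv = np.ones(total)
    for li, spec in enumerate(config.lethal_specs):
        if not spec.fertility_effect:
            continue
        tr = carrier_truth[carrier_truth["lethal"] == li].set_index("animal_id")["n_copies"]
        bull_t = tr.reindex(bull).to_numpy(dtype=float) / 2.0
        dam_t = tr.reindex(cow).to_numpy(dtype=float) / 2.0
        surv *= 1.0 - bull_t * dam_t * spec.penetrance
    outcome = (rng.random(total) < mu * surv).astype(int)
    return pd.DataFrame(
        {
            "cow_id": cow, "bull_id": bull, "cow_sire_id": cow_sire,
            "parity_class": parity, "outcome": outcome,
        }
    )


# ---------------------------------------------------------------------------
# Sequence variants
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"), dtype=object)

CONSEQUENCE_CLASSES = (
    "synonymous", "missense", "intron", "intergenic", "stop_gained",
    "frameshift", "splice",
)


@dataclass
class CausativeSpec:
    """The embedded causative variant: het in all carriers, absent in controls."""

    position: int | None = None        # random inside the region when None
    ref: str = "C"
    alt: str = "T"
    gene: str = "GENE1"
    consequence: str = "stop_gained"
    sift_damaging: bool = True
    polyphen_damaging: bool = True


def simulate_vcf(
    region: tuple,
    carrier_ids,
    control_ids,
    causative_spec: CausativeSpec | None = None,
    n_background: int = 50,
    seed: int = 0,
):
    """Sequence variants over ``region = (chromosome, start_bp, end_bp)``.

    Background variant genotypes are sampled in Hardy-Weinberg proportions
    independently of carrier status; the causative variant (if any) is
    heterozygous in every carrier and homozygous reference in every control.
    Returns ``(VariantTable, annotation DataFrame)``; see :func:`write_vcf`
    and :func:`write_annotation` for the file forms.
    """
    carriers = list(carrier_ids)
    controls = list(control_ids)
    if not carriers:
        raise ConfigError("carrier set must be non-empty")
    if set(carriers) & set(controls):
        raise ConfigError("carrier and control sets must be disjoint")
    chrom, start, end = region
    if end - start < n_background + 1:
        raise ConfigError("region too small for the requested variant count")
    rng = np.random.default_rng([int(seed), 53])
    samples = carriers + controls
    n_s = len(samples)

    draw = rng.integers(start + 1, end + 1, size=4 * n_background + 16)
    bg_pos = np.unique(draw)
    rng.shuffle(bg_pos)
    bg_pos = bg_pos[:n_background]
    caus_pos = None
    if causative_spec is not None:
        if causative_spec.position is not None:
            caus_pos = int(causative_spec.position)
            if not start < caus_pos <= end:
                raise ConfigError("causative position outside the region")
        else:
            caus_pos = int(rng.integers(start + 1, end + 1))
        bg_pos = bg_pos[bg_pos != caus_pos][:n_background]
        positions = np.sort(np.append(bg_pos, caus_pos))
        caus_idx = int(np.searchsorted(positions, caus_pos))
    else:
        positions = np.sort(bg_pos)
        caus_idx = None

    rows = []
    gts = np.empty((len(positions), n_s), dtype=np.int8)
    for vi, pos in enumerate(positions):
        if caus_idx is not None and vi == caus_idx:
            cs = causative_spec
            gts[vi, : len(carriers)] = 1
            gts[vi, len(carriers):] = 0
            rows.append((chrom, int(pos), cs.ref, cs.alt, cs.gene, cs.consequence,
                         cs.sift_damaging, cs.polyphen_damaging, True))
            continue
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        af = rng.uniform(0.05, 0.5)
        g = (rng.random((n_s, 2)) < af).sum(axis=1)
        gts[vi] = g
        cons = str(rng.choice(CONSEQUENCE_CLASSES[:4]))  # background: non-truncating
        sift = bool(rng.random() < 0.2) if cons == "missense" else False
        poly = bool(rng.random() < 0.2) if cons == "missense" else False
        rows.append((chrom, int(pos), str(ref), str(alt), f"BG{vi:03d}", cons, sift, poly, False))

    sites = pd.DataFrame(
        rows,
        columns=["chromosome", "position", "ref", "alt", "gene", "consequence",
                 "sift_damaging", "polyphen_damaging", "causative"],
    )
    sites["damaging"] = sites["sift_damaging"] & sites["polyphen_damaging"]
    vt = VariantTable(sites, gts, samples)
    annotation = sites[
        ["chromosome", "position", "alt", "gene", "consequence",
         "sift_damaging", "polyphen_damaging"]
    ].copy()
    return vt, annotation


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(vt: VariantTable, path, contig_length: int = 200_000_000) -> None:
    """Serialize a :class:`VariantTable` as VCF 4.2 (deterministic bytes)."""
    contigs = pd.unique(vt.sites["chromosome"]) if len(vt.sites) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lethalscan-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={contig_length}>\n")
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##INFO=<ID=DEL,Number=0,Type=Flag,Description="Damaging by both predictors">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
        for vi in range(vt.n_variants):
            s = vt.sites.iloc[vi]
            info = f"CSQ={s['consequence']}"
            if bool(s.get("damaging", False)):
                info += ";DEL"
            gt_field = "\t".join(_GT_STR[int(g)] for g in vt.genotypes[vi])
            fh.write(
                f"{s['chromosome']}\t{int(s['position'])}\t.\t{s['ref']}\t{s['alt']}"
                f"\t.\tPASS\t{info}\tGT\t{gt_field}\n"
            )


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the config with a different seed (replicate helper)."""
    return replace(config, seed=seed)
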