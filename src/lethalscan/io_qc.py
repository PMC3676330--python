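"""Readers, writers and marker quality control for 50k-style SNP array data.

The in-memory containers are deliberately thin: a marker map is a pandas
DataFrame (columns ``marker_id, chromosome, position_bp, allele_a, allele_b``,
sorted by chromosome then position), a pedigree is a DataFrame
(``animal_id, sire_id, mgs_id, dam_id, sex, parity_class`` with ``"0"`` for
unknown parents), and phased genotypes live in :class:`PhasedGenotypes`, a
numpy-backed structure holding two labelled chromosome copies per animal.

Alleles are coded ``1``/``2`` (array A/B convention). Haplotype identity
throughout the package is exact allele-string identity over a marker window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
PEDIGREE_COLUMNS = ["animal_id", "sire_id", "mgs_id", "dam_id", "sex", "parity_class"]
MISSING_PARENT = "0"


class FormatError(ValueError):
    """A file violated the expected dialect; the message names the line."""


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise FormatError(f"marker map lacks columns: {missing}")
    for _, sub in marker_map.groupby("chromosome", sort=False):
        pos = sub["position_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise FormatError("marker positions must be strictly increasing per chromosome")
    if marker_map["marker_id"].duplicated().any():
        raise FormatError("duplicate marker ids in map")


@dataclass
class PhasedGenotypes:
    """Phased diplotypes over a marker map.

    ``haplotypes`` has shape ``(n_animals, 2, n_markers)`` with axis 1 indexing
    the paternal (0) and maternal (1) chromosome copy; values are the allele
    codes 1 and 2.
    """

    animal_ids: np.ndarray
    haplotypes: np.ndarray
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_animals, 2, n_markers)")
        if len(self.animal_ids) != self.haplotypes.shape[0]:
            raise ValueError("animal_ids length does not match haplotypes")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise FormatError("duplicate animal id in phased genotypes")
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def row(self, animal_id: str) -> int:
        return self._index[animal_id]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def subset_markers(self, keep: np.ndarray) -> "PhasedGenotypes":
        """Restrict to a boolean marker mask or integer index array."""
        return PhasedGenotypes(self.animal_ids.copy(), self.haplotypes[:, :, keep])

    def subset_animals(self, ids) -> "PhasedGenotypes":
        rows = [self._index[a] for a in ids]
        return PhasedGenotypes(np.asarray(list(ids), dtype=object), self.haplotypes[rows])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PhasedGenotypes)
            and np.array_equal(self.animal_ids, other.animal_ids)
            and np.array_equal(self.haplotypes, other.haplotypes)
        )


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def allele_b_frequency(phased: PhasedGenotypes) -> np.ndarray:
    """Per-marker frequency of allele 2 over all chromosome copies."""
    return (phased.haplotypes == 2).mean(axis=(0, 1))


def filter_maf(
    phased: PhasedGenotypes,
    marker_map: pd.DataFrame,
    threshold: float = 0.03,
    breed_labels=None,
) -> pd.DataFrame:
    """Drop markers whose minor allele frequency is strictly below ``threshold``.

    The frequency is pooled over all animals regardless of breed;
    ``breed_labels`` is accepted for reporting symmetry but does not alter the
    computation. Monomorphic markers have MAF 0 and are removed.
    """
    if phased.n_animals < 1:
        raise ValueError("MAF filter requires at least one animal")
    if phased.n_markers != len(marker_map):
        raise ValueError("genotypes are not aligned with the marker map")
    f = allele_b_frequency(phased)
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF filter removed %d of %d markers", dropped, len(keep))
    return marker_map.loc[keep].reset_index(drop=True)


def hwe_test(n_aa: np.ndarray, n_ab: np.ndarray, n_bb: np.ndarray):
    """One-degree-of-freedom chi-square goodness of fit to Hardy-Weinberg.

    Expected genotype counts come from the observed allele frequencies; the
    statistic is the plain ``sum((O-E)^2/E)`` over the three genotype classes
    without continuity correction. Monomorphic markers get chi2=0, p=1.
    Returns ``(chi2, p)`` arrays.
    """
    n_aa = np.asarray(n_aa, dtype=float)
    n_ab = np.asarray(n_ab, dtype=float)
    n_bb = np.asarray(n_bb, dtype=float)
    n = n_aa + n_ab + n_bb
    p_a = np.where(n > 0, (2 * n_aa + n_ab) / np.maximum(2 * n, 1), 0.5)
    exp = np.stack([n * p_a**2, 2 * n * p_a * (1 - p_a), n * (1 - p_a) ** 2])
    obs = np.stack([n_aa, n_ab, n_bb])
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
    chi2 = cells.sum(axis=0)
    return chi2, stats.chi2.sf(chi2, df=1)


def filter_hwe(
    phased: PhasedGenotypes,
    marker_map: pd.DataFrame,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Drop markers deviating from Hardy-Weinberg equilibrium (p strictly below
    ``p_threshold``). Diploid genotypes are collapsed from the phased copies."""
    if phased.n_markers != len(marker_map):
        raise ValueError("genotypes are not aligned with the marker map")
    if phased.n_animals < 2:
        logger.warning("HWE filter skipped: fewer than 2 animals")
        return marker_map.reset_index(drop=True)
    n_b = (phased.haplotypes == 2).sum(axis=1)  # (animals, markers) in {0,1,2}
    n_aa = (n_b == 0).sum(axis=0)
    n_ab = (n_b == 1).sum(axis=0)
    n_bb = (n_b == 2).sum(axis=0)
    _, p = hwe_test(n_aa, n_ab, n_bb)
    keep = p >= p_threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("HWE filter removed %d of %d markers", dropped, len(keep))
    return marker_map.loc[keep].reset_index(drop=True)


def apply_marker_qc(
    phased: PhasedGenotypes,
    marker_map: pd.DataFrame,
    maf_threshold: float = 0.03,
    hwe_p_threshold: float = 1e-4,
):
    """Run both per-marker filters and subset the genotypes to the survivors.

    The two filters are per-marker predicates, so their order is immaterial.
    Returns ``(phased_qc, map_qc)``.
    """
    f = allele_b_frequency(phased)
    maf_keep = np.minimum(f, 1 - f) >= maf_threshold
    n_b = (phased.haplotypes == 2).sum(axis=1)
    _, p = hwe_test((n_b == 0).sum(axis=0), (n_b == 1).sum(axis=0), (n_b == 2).sum(axis=0))
    hwe_keep = p >= hwe_p_threshold if phased.n_animals >= 2 else np.ones_like(maf_keep)
    keep = maf_keep & hwe_keep
    logger.info("marker QC kept %d of %d markers", int(keep.sum()), len(keep))
    return phased.subset_markers(keep), marker_map.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Flat-file dialects
# ---------------------------------------------------------------------------

def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "allele_a": str, "allele_b": str})
    validate_marker_map(mm)
    return mm


def write_phased(phased: PhasedGenotypes, path) -> None:
    """Phased TSV dialect: header, then two rows per animal —
    ``animal_id<TAB>P|M<TAB>allele string`` (paternal row first)."""
    with open(path, "w") as fh:
        fh.write("animal_id\tcopy\thaplotype\n")
        for i, aid in enumerate(phased.animal_ids):
            for j, label in enumerate(("P", "M")):
                hap = "".join(map(str, phased.haplotypes[i, j]))
                fh.write(f"{aid}\t{label}\t{hap}\n")


def read_phased(path, marker_map: pd.DataFrame | None = None) -> PhasedGenotypes:
    n_markers = None if marker_map is None else len(marker_map)
    ids: list = []
    rows: list = []
    pending: dict = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("animal_id"):
            raise FormatError("line 1: missing phased TSV header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            aid, label, hap = parts
            if label not in ("P", "M"):
                raise FormatError(f"line {lineno}: copy label must be P or M")
            if n_markers is not None and len(hap) != n_markers:
                raise FormatError(
                    f"line {lineno}: haplotype length {len(hap)} != map size {n_markers}"
                )
            try:
                arr = np.frombuffer(hap.encode(), dtype=np.uint8) - ord("0")
            except ValueError as exc:  # pragma: no cover - frombuffer cannot fail here
                raise FormatError(f"line {lineno}: {exc}") from exc
            if not np.all((arr == 1) | (arr == 2)):
                raise FormatError(f"line {lineno}: unknown allele code in haplotype")
            key = (aid, label)
            if key in pending or (label == "P" and aid in ids):
                raise FormatError(f"line {lineno}: duplicate animal id {aid!r}")
            pending[key] = arr
            if label == "M":
                if (aid, "P") not in pending:
                    raise FormatError(f"line {lineno}: maternal row before paternal for {aid!r}")
                ids.append(aid)
                rows.append(np.stack([pending.pop((aid, "P")), pending.pop((aid, "M"))]))
    if pending:
        raise FormatError(f"unpaired paternal rows for: {sorted(k[0] for k in pending)}")
    if not rows:
        m = n_markers or 0
        return PhasedGenotypes(np.array([], dtype=object), np.empty((0, 2, m), dtype=np.uint8))
    return PhasedGenotypes(np.array(ids, dtype=object), np.stack(rows))


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING_PARENT)
    missing = [c for c in ("animal_id", "sire_id", "mgs_id") if c not in ped.columns]
    if missing:
        raise FormatError(f"pedigree lacks columns: {missing}")
    dup = ped["animal_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(f"line {line}: duplicate animal id {ped['animal_id'][dup].iloc[0]!r}")
    return ped


def read_inseminations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cow_id": str, "bull_id": str, "cow_sire_id": str})
    need = {"cow_id", "bull_id", "cow_sire_id", "parity_class", "outcome"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"insemination table lacks columns: {sorted(missing)}")
    if not df["outcome"].isin((0, 1)).all():
        raise FormatError("insemination outcome must be 0/1")
    return df


def write_inseminations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Sequence variants with per-animal genotype codes.

    ``genotypes`` has shape ``(n_variants, n_samples)`` with codes
    0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing. ``sites`` carries
    chromosome, position (1-based), ref, alt and any INFO annotation columns.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list

    @property
    def n_variants(self) -> int:
        return len(self.sites)

    def sample_column(self, animal_id: str) -> int:
        try:
            return self.samples.index(animal_id)
        except ValueError:
            raise KeyError(f"animal {animal_id!r} not present in VCF samples") from None

    def subset(self, mask) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            list(self.samples),
        )


def write_phased_vcf(phased: PhasedGenotypes, marker_map: pd.DataFrame, path) -> None:
    """Export phased genotypes as VCF 4.2 with phased GT fields.

    Allele 1 maps to REF, allele 2 to ALT; the left GT allele is the paternal
    copy by convention (``1|0`` means paternal = ALT).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lethalscan-phased-export\n")
        for c in pd.unique(marker_map["chromosome"]):
            length = int(marker_map.loc[marker_map["chromosome"] == c, "position_bp"].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, phased.animal_ids)) + "\n")
        pat = phased.haplotypes[:, 0, :] - 1
        mat = phased.haplotypes[:, 1, :] - 1
        for m in range(len(marker_map)):
            row = marker_map.iloc[m]
            gts = "\t".join(f"{pat[i, m]}|{mat[i, m]}" for i in range(phased.n_animals))
            fh.write(f"{row['chromosome']}\t{row['position_bp']}\t{row['marker_id']}"
                     f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path) -> PhasedGenotypes:
    """Read a phased VCF back into :class:`PhasedGenotypes` (paternal = left
    GT allele). Sites must be phased biallelic SNPs in map order."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pat_rows, mat_rows = [], []
    for rec in vcf:
        g = np.array([gt[:2] for gt in rec.genotypes], dtype=np.int8)
        phased_flags = [gt[2] for gt in rec.genotypes]
        if not all(phased_flags):
            raise FormatError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        pat_rows.append(g[:, 0])
        mat_rows.append(g[:, 1])
    vcf.close()
    pat = np.stack(pat_rows, axis=1) + 1  # (animals, markers)
    mat = np.stack(mat_rows, axis=1) + 1
    return PhasedGenotypes(
        np.array(samples, dtype=object),
        np.stack([pat, mat], axis=1).astype(np.uint8),
    )


def read_vcf_genotypes(path) -> VariantTable:
    """Parse a VCF 4.2 file into a :class:`VariantTable` via cyvcf2.

    Phased genotypes ``a|b`` follow the convention paternal = ``a``. INFO keys
    ``CSQ`` (consequence class) and ``DEL`` (damaging flag) are lifted into
    site columns when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    gts = []
    for rec in vcf:
        rows.append(
            {
                "chromosome": rec.CHROM,
                "position": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "consequence": rec.INFO.get("CSQ", None),
                "damaging": bool(rec.INFO.get("DEL", False)),
            }
        )
        types = rec.gt_types  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        code = np.where(types == 3, 2, np.where(types == 2, -1, types))
        gts.append(code.astype(np.int8))
    vcf.close()
    if not rows:
        return VariantTable(
            pd.DataFrame(columns=["chromosome", "position", "ref", "alt", "consequence", "damaging"]),
            np.empty((0, len(samples)), dtype=np.int8),
            samples,
        )
    return VariantTable(pd.DataFrame(rows), np.stack(gts), samples)
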