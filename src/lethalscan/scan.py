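"""Deficit-of-homozygotes haplotype scan.

The scan slides a fixed-size marker window (default 20 SNPs, step 1) along
each autosome of a phased, pedigree-structured population. Within a window,
each chromosome copy is reduced to its exact allele string (the haplotype
key). For every haplotype k frequent enough in the population the scan
contrasts the observed count of homozygous progeny O(k) with its Mendelian
expectation E(k) computed from the genotypes of the sire and the maternal
grandsire (MGS) and the population frequency f_k:

    E(k) = sum_ij  n_ij * p_ik * (q_jk + f_k) / 2

where n_ij is the number of progeny of sire i out of daughters of MGS j,
p_ik in {0.5, 1} is sire i's transmission probability (only sires carrying k
enter the sum), and q_jk in {0, 0.5, 1} is the MGS transmission probability
to his daughter; the dam carries k on her paternal copy with probability
q_jk and on her maternal copy with probability f_k, and transmits either with
probability 1/2. When dams are genotyped their transmission probability r_jk
replaces (q_jk + f_k)/2 and the expectation no longer depends on f_k.

A recessive lethal acting before genotyping produces O(k) far below E(k);
significance is assessed with the one-cell chi-square (O-E)^2/E on 1 df
(upper tail). Only the deficit direction (O < E) is biologically meaningful
and only deficit windows are reported as candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import PhasedGenotypes, MISSING_PARENT

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "chromosome", "window", "start_marker", "end_marker", "start_bp", "end_bp",
    "haplotype", "freq", "expected", "observed", "chi2", "p", "deficit",
]


@dataclass
class ScanConfig:
    """Tunables of the window scan."""

    window_size: int = 20
    slide_step: int = 1
    min_haplotype_freq: float = 0.01   # strict: haplotypes with f <= this are dropped
    p_threshold: float = 1e-4          # strict: windows with p < this are significant

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 0 < self.min_haplotype_freq < 1:
            raise ValueError("min_haplotype_freq must be in (0, 1)")
        if self.slide_step < 1:
            raise ValueError("slide_step must be >= 1")


@dataclass
class MatingGroup:
    """One (sire, MGS) cell of the expectation sum for a fixed haplotype k."""

    sire_id: str
    mgs_id: str
    n: int          # progeny with this sire and this maternal grandsire
    p: float        # sire transmission probability of k: 0.5 or 1
    q: float        # MGS transmission probability of k to his daughter: 0, 0.5 or 1
    r: float | None = None  # dam transmission probability, when dams are genotyped


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def enumerate_window_haplotypes(
    phased: PhasedGenotypes,
    marker_map: pd.DataFrame,
    chromosome: int,
    start_marker: int,
    window_size: int,
) -> np.ndarray:
    """Haplotype key (exact allele string) for both chromosome copies of every
    animal over one window. ``start_marker`` indexes markers within the
    chromosome (0-based). Returns an object array of shape ``(n_animals, 2)``.
    """
    on_chrom = np.flatnonzero((marker_map["chromosome"] == chromosome).to_numpy())
    if start_marker < 0 or start_marker + window_size > len(on_chrom):
        raise ValueError("window does not fit inside the chromosome")
    cols = on_chrom[start_marker : start_marker + window_size]
    sub = phased.haplotypes[:, :, cols]
    flat = sub.reshape(-1, window_size) + ord("0")
    keys = np.array([row.tobytes().decode() for row in flat], dtype=object)
    return keys.reshape(phased.n_animals, 2)


def animals_with_progeny(pedigree: pd.DataFrame) -> set:
    """Ids appearing as sire, dam, or maternal grandsire of some animal."""
    parents = set()
    for col in ("sire_id", "dam_id", "mgs_id"):
        if col in pedigree.columns:
            parents.update(pedigree[col].astype(str))
    parents.discard(MISSING_PARENT)
    return parents


def estimate_frequencies(
    keys: np.ndarray,
    animal_ids: np.ndarray,
    pedigree: pd.DataFrame,
) -> pd.Series:
    """Haplotype frequencies counted on the maternal chromosomes of genotyped
    animals that have at least one progeny. Sums to 1 over all haplotypes.
    """
    parents = animals_with_progeny(pedigree)
    eligible = np.array([a in parents for a in animal_ids])
    if not eligible.any():
        logger.warning("no genotyped animal has progeny; empty frequency estimate")
        return pd.Series(dtype=float)
    maternal = keys[eligible, 1]
    counts = pd.Series(maternal).value_counts()
    return counts / counts.sum()


def expected_homozygotes(groups, f_k: float, use_dam: bool = False) -> float:
    """Evaluate E(k) over mating groups.

    ``groups`` is an iterable of :class:`MatingGroup` or a DataFrame/dict of
    arrays with columns ``n, p, q`` (and ``r`` when ``use_dam``). Every group
    must have sire transmission probability p > 0: the counting is restricted
    to sires carrying the haplotype.
    """
    if isinstance(groups, pd.DataFrame):
        n = groups["n"].to_numpy(dtype=float)
        p = groups["p"].to_numpy(dtype=float)
        q = groups["q"].to_numpy(dtype=float)
        r = groups["r"].to_numpy(dtype=float) if "r" in groups.columns else None
    elif isinstance(groups, dict):
        n = np.asarray(groups["n"], dtype=float)
        p = np.asarray(groups["p"], dtype=float)
        q = np.asarray(groups["q"], dtype=float)
        r = np.asarray(groups["r"], dtype=float) if "r" in groups else None
    else:
        gl = list(groups)
        n = np.array([g.n for g in gl], dtype=float)
        p = np.array([g.p for g in gl], dtype=float)
        q = np.array([g.q for g in gl], dtype=float)
        r = np.array([np.nan if g.r is None else g.r for g in gl], dtype=float)
    if np.any(p <= 0):
        raise ValueError("groups must be restricted to sires carrying the haplotype (p > 0)")
    if use_dam:
        if r is None or np.any(np.isnan(r)):
            raise ValueError("use_dam requires dam transmission probabilities r")
        return float(np.sum(n * p * r))
    return float(np.sum(n * p * (q + f_k) / 2.0))


def observed_homozygotes(progeny_keys: np.ndarray, k: str, mask=None) -> int:
    """Count progeny whose two window keys both equal ``k``.

    ``mask`` restricts to the progeny of the sire set used for E(k)."""
    keys = np.asarray(progeny_keys)
    hom = (keys[:, 0] == k) & (keys[:, 1] == k)
    if mask is not None:
        hom = hom & np.asarray(mask)
    return int(hom.sum())


def deficit_test(observed: float, expected: float):
    """One-cell chi-square of observed vs expected homozygote counts.

    chi2 = (O - E)^2 / E, p = upper tail of chi-square with 1 df. The test is
    two-sided in the statistic; callers flag a deficit only when O < E.
    Raises for E <= 0 (the test is undefined there).
    """
    if expected <= 0:
        raise ValueError("deficit test undefined for expected <= 0")
    chi2 = (observed - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def carrier_concordance(status_a, status_b) -> dict:
    """Overlap of two carrier sets over the same animal panel.

    Returns the percentage of a-carriers that are also b-carriers (rounded to
    the nearest integer for reporting) together with the raw counts, including
    b-carriers outside a.
    """
    a, b = set(status_a), set(status_b)
    if not a:
        raise ValueError("carrier concordance undefined for an empty reference set")
    overlap = len(a & b)
    return {
        "percent": int(round(100.0 * overlap / len(a))),
        "n_a": len(a),
        "n_overlap": overlap,
        "n_b_only": len(b - a),
    }


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def _pack_window(hap_slice: np.ndarray) -> np.ndarray:
    """Encode a (n, 2, w) allele slice (codes 1/2) into integer keys."""
    bits = (hap_slice.astype(np.int64) - 1)
    weights = 1 << np.arange(hap_slice.shape[2], dtype=np.int64)
    return bits @ weights


def _key_string(code: int, window_size: int) -> str:
    return "".join("2" if (code >> i) & 1 else "1" for i in range(window_size))


def scan_genome(
    phased: PhasedGenotypes,
    pedigree: pd.DataFrame,
    marker_map: pd.DataFrame,
    config: ScanConfig | None = None,
    use_dam: bool = False,
) -> pd.DataFrame:
    """Run the sliding-window deficit scan over all chromosomes.

    Progeny are the genotyped animals whose sire and maternal grandsire are
    both genotyped (the AI design); animals failing that requirement are
    excluded with a logged count. Returns one row per (window, haplotype)
    tested, sorted by (chromosome, window, p).
    """
    config = config or ScanConfig()
    if phased.n_animals == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    ped = pedigree.set_index("animal_id", drop=False)
    genotyped = set(phased.animal_ids)

    is_prog = (
        pedigree["animal_id"].isin(genotyped)
        & pedigree["sire_id"].isin(genotyped)
        & pedigree["mgs_id"].isin(genotyped)
    )
    n_candidates = int((pedigree["sire_id"] != MISSING_PARENT).sum())
    progeny = pedigree.loc[is_prog]
    excluded = n_candidates - len(progeny)
    if excluded > 0:
        logger.info("excluded %d animals lacking a genotyped sire or MGS", excluded)
    if use_dam:
        has_dam = progeny["dam_id"].isin(genotyped)
        progeny = progeny.loc[has_dam]

    prog_rows = np.array([phased.row(a) for a in progeny["animal_id"]], dtype=np.intp)
    sire_rows = np.array([phased.row(a) for a in progeny["sire_id"]], dtype=np.intp)
    mgs_rows = np.array([phased.row(a) for a in progeny["mgs_id"]], dtype=np.intp)
    dam_rows = (
        np.array([phased.row(a) for a in progeny["dam_id"]], dtype=np.intp)
        if use_dam else None
    )

    # maternal-chromosome frequency panel: genotyped animals with >=1 progeny
    parents = animals_with_progeny(pedigree)
    elig_rows = np.array(
        [i for i, a in enumerate(phased.animal_ids) if a in parents], dtype=np.intp
    )
    if elig_rows.size == 0:
        logger.warning("no genotyped animal has progeny; scan returns empty result")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    chrom_arr = marker_map["chromosome"].to_numpy()
    pos_arr = marker_map["position_bp"].to_numpy()
    records: list = []
    w = config.window_size

    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        if len(cols) < w:
            logger.info("chromosome %s shorter than one window; skipped", chrom)
            continue
        haps = phased.haplotypes[:, :, cols]
        for start in range(0, len(cols) - w + 1, config.slide_step):
            codes = _pack_window(haps[:, :, start : start + w])
            mat_codes = codes[elig_rows, 1]
            uniq, counts = np.unique(mat_codes, return_counts=True)
            freqs = counts / counts.sum()
            keep = freqs > config.min_haplotype_freq
            if not keep.any():
                continue
            sire_c = codes[sire_rows]
            mgs_c = codes[mgs_rows]
            prog_c = codes[prog_rows]
            dam_c = codes[dam_rows] if use_dam else None
            prog_hom = prog_c[:, 0] == prog_c[:, 1]
            for k_code, f_k in zip(uniq[keep], freqs[keep]):
                p_vec = ((sire_c[:, 0] == k_code).astype(np.float64)
                         + (sire_c[:, 1] == k_code)) / 2.0
                sel = p_vec > 0
                if not sel.any():
                    continue
                if use_dam:
                    r_vec = ((dam_c[:, 0] == k_code).astype(np.float64)
                             + (dam_c[:, 1] == k_code)) / 2.0
                    e_k = float(np.sum(p_vec[sel] * r_vec[sel]))
                else:
                    q_vec = ((mgs_c[:, 0] == k_code).astype(np.float64)
                             + (mgs_c[:, 1] == k_code)) / 2.0
                    e_k = float(np.sum(p_vec[sel] * (q_vec[sel] + f_k) / 2.0))
                if e_k <= 0:
                    continue
                o_k = int(np.sum(prog_hom & sel & (prog_c[:, 0] == k_code)))
                chi2, p = deficit_test(o_k, e_k)
                records.append(
                    (
                        int(chrom), start, start, start + w - 1,
                        int(pos_arr[cols[start]]), int(pos_arr[cols[start + w - 1]]),
                        _key_string(int(k_code), w), float(f_k), e_k, o_k,
                        chi2, p, o_k < e_k,
                    )
                )
    result = pd.DataFrame(records, columns=RESULT_COLUMNS)
    return result.sort_values(["chromosome", "window", "p"], kind="mergesort").reset_index(drop=True)


def merge_windows(
    results: pd.DataFrame,
    marker_map: pd.DataFrame,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Collapse significant deficit windows into candidate regions.

    Significant windows (p < threshold, O < E) are grouped into maximal runs of
    consecutive windows per chromosome. Within a run, the windows sharing the
    run's minimum observed-homozygote count are merged: the region spans from
    the first marker of the left-most such window to the last marker of the
    right-most one, and carries the E, O, f and p of the most significant
    window among them.
    """
    config = config or ScanConfig()
    cols = ["chromosome", "start_bp", "end_bp", "start_mb", "end_mb",
            "expected", "observed", "freq_pct", "p"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    sig = results[(results["p"] < config.p_threshold) & results["deficit"]]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    regions = []
    for chrom, sub in sig.groupby("chromosome"):
        # a window may contribute several haplotypes; reduce to best per window
        best = sub.sort_values("p", kind="mergesort").drop_duplicates("window")
        best = best.sort_values("window")
        windows = best["window"].to_numpy()
        breaks = np.flatnonzero(np.diff(windows) > config.slide_step)
        run_bounds = np.split(np.arange(len(windows)), breaks + 1)
        for idx in run_bounds:
            run = best.iloc[idx]
            min_o = run["observed"].min()
            at_min = run[run["observed"] == min_o]
            left = at_min.iloc[0]
            right = at_min.iloc[-1]
            top = at_min.loc[at_min["p"].idxmin()]
            regions.append(
                {
                    "chromosome": int(chrom),
                    "start_bp": int(left["start_bp"]),
                    "end_bp": int(right["end_bp"]),
                    "start_mb": round(left["start_bp"] / 1e6, 1),
                    "end_mb": round(right["end_bp"] / 1e6, 1),
                    "expected": float(top["expected"]),
                    "observed": int(min_o),
                    "freq_pct": round(100 * float(top["freq"]), 1),
                    "p": float(top["p"]),
                }
            )
    out = pd.DataFrame(regions, columns=cols)
    return out.sort_values(["chromosome", "start_bp"]).reset_index(drop=True)
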