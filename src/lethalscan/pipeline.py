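"""End-to-end orchestration: simulate -> QC -> scan -> fertility -> variants.

The demo pipeline runs entirely on synthetic data under a single seed and
writes a reproducible report bundle: the window-scan region table, the
per-region fertility contrast, the candidate-variant table, and a manifest
echoing the seed and parameters. Each stage failure aborts with an error
naming the stage.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fertility import classify_matings, fertility_report
from .io_qc import apply_marker_qc
from .scan import ScanConfig, carrier_concordance, deficit_test, merge_windows, scan_genome
from .simulate import (
    CausativeSpec,
    LethalSpec,
    SimulationConfig,
    simulate_inseminations,
    simulate_marker_map,
    simulate_population,
    simulate_vcf,
    write_annotation,
    write_vcf,
)
from .variants import define_search_region, filter_consequence, filter_genotype_pattern

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def format_p(p: float) -> str:
    """Scientific notation with 2 significant figures (half-to-even), the
    report style used throughout: e.g. 2.6E-12."""
    return f"{p:.1E}"


@dataclass
class PipelineConfig:
    seed: int = 0
    scan: ScanConfig = field(default_factory=ScanConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    flank_mb: float = 6.0
    n_background_variants: int = 50
    out_dir: str = "lethalscan_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        lethals = [LethalSpec(**d) for d in sim_raw.pop("lethal_specs", [])]
        scan_raw = raw.pop("scan", {})
        return cls(
            scan=ScanConfig(**scan_raw),
            simulation=SimulationConfig(lethal_specs=lethals, **sim_raw),
            **raw,
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Demo-mode pipeline on synthetic data. Returns a dict of output paths and
    in-memory results; writes TSV reports plus a manifest under out_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if not sim.lethal_specs:
        sim.lethal_specs = [LethalSpec()]
    sim = SimulationConfig(**{**asdict(sim), "seed": config.seed,
                              "lethal_specs": sim.lethal_specs})

    marker_map = _stage("simulate")(simulate_marker_map)(sim)
    pedigree, phased, truth = _stage("simulate")(simulate_population)(marker_map, sim)
    insems = _stage("simulate")(simulate_inseminations)(pedigree, truth, sim)

    phased_qc, map_qc = _stage("qc")(apply_marker_qc)(phased, marker_map)

    results = _stage("scan")(scan_genome)(phased_qc, pedigree, map_qc, config.scan)
    regions = _stage("scan")(merge_windows)(results, map_qc, config.scan)
    regions.to_csv(out / "scan_regions.tsv", sep="\t", index=False)
    results.to_csv(out / "scan_windows.tsv", sep="\t", index=False)

    bundle = {
        "out_dir": str(out),
        "regions": regions,
        "scan_results": results,
        "n_regions": len(regions),
    }
    if regions.empty:
        logger.warning("scan found no candidate region; fertility and variant "
                       "filter stages skipped")
        (out / "fertility.tsv").write_text("")
        (out / "candidates.tsv").write_text("")
        bundle["fertility"] = pd.DataFrame()
        bundle["candidates"] = pd.DataFrame()
    else:
        top = regions.loc[regions["p"].idxmin()]
        # carrier status of the bulls for the top region's haplotype
        sig = results[(results["chromosome"] == top["chromosome"])
                      & (results["start_bp"] == top["start_bp"])]
        hap = sig.loc[sig["p"].idxmin()]
        bulls = pedigree.loc[
            pedigree["animal_id"].isin(phased_qc.animal_ids)
            & (pedigree["sex"] == "M"), "animal_id"
        ]
        status = _stage("fertility")(predict_carrier_status)(
            phased_qc, map_qc, int(hap["chromosome"]), int(hap["window"]),
            config.scan.window_size, hap["haplotype"], bulls
        )
        classified = _stage("fertility")(classify_matings)(insems, status)
        fert = _stage("fertility")(fertility_report)(classified, haplotype_name="region1")
        fert.to_csv(out / "fertility.tsv", sep="\t", index=False)
        bundle["fertility"] = fert

        carriers = [a for a, s in status.items() if s][:4]
        controls = [a for a, s in status.items() if not s][:10]
        region = define_search_region(
            int(top["chromosome"]), int(top["start_bp"]), int(top["end_bp"]),
            config.flank_mb,
        )
        vt, annotation = _stage("filter")(simulate_vcf)(
            (region.chromosome, region.start_bp, region.end_bp),
            carriers, controls, CausativeSpec(), config.n_background_variants,
            seed=config.seed,
        )
        write_vcf(vt, out / "variants.vcf")
        write_annotation(annotation, out / "annotation.tsv")
        kept = _stage("filter")(filter_genotype_pattern)(vt, carriers, controls, region)
        candidates = _stage("filter")(filter_consequence)(kept, annotation)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        bundle["candidates"] = candidates

    manifest = {
        "seed": config.seed,
        "lethalscan_version": __version__,
        "scan": asdict(config.scan),
        "simulation": asdict(sim),
        "n_regions": int(len(regions)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def predict_carrier_status(phased, marker_map, chromosome, window_start, window_size,
                           haplotype, animal_ids) -> dict:
    """Carrier status (>=1 copy of ``haplotype`` over the window) per animal."""
    from .scan import enumerate_window_haplotypes

    keys = enumerate_window_haplotypes(phased, marker_map, chromosome,
                                       window_start, window_size)
    status = {}
    for a in animal_ids:
        i = phased.row(a)
        status[a] = haplotype in (keys[i, 0], keys[i, 1])
    return status


# ---------------------------------------------------------------------------
# Published-region regression harness
# ---------------------------------------------------------------------------

def load_reference_regions() -> pd.DataFrame:
    """Bundled table of published deficit-of-homozygotes regions from three
    French dairy breeds (expected/observed homozygote counts, haplotype
    frequency and reported p-value per region)."""
    ref = importlib.resources.files("lethalscan.data") / "deficit_regions.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"p": str})


def recompute_table1(pairs=None) -> pd.DataFrame:
    """Re-derive the chi-square p-value for (expected, observed) homozygote
    pairs and format it in the report style.

    With no argument, runs over the bundled published regions and adds the
    recomputed columns next to the reported ones.
    """
    if pairs is None:
        df = load_reference_regions()
    else:
        df = pd.DataFrame(pairs, columns=["expected", "observed"])
    chi2s, ps = [], []
    for e, o in zip(df["expected"], df["observed"]):
        chi2, p = deficit_test(float(o), float(e))
        chi2s.append(chi2)
        ps.append(p)
    df = df.copy()
    df["chi2_recomputed"] = chi2s
    df["p_recomputed"] = [format_p(p) for p in ps]
    return df


__all__ = [
    "PipelineConfig", "run_pipeline", "recompute_table1", "load_reference_regions",
    "format_p", "StageError", "predict_carrier_status", "carrier_concordance",
]
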