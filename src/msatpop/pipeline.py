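"""Pipeline driver: simulate -> call -> stats -> dapc -> migrate.

Each stage writes its tables under the configured output directory and
records counts and seeds in a JSON run manifest.  Genotypes can enter the
pipeline three ways: simulated (with truth kept for comparison), called
from a FASTQ directory, or loaded directly from a genotype CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calling import call_all
from .clustering import (
    dapc,
    encode_alleles,
    find_clusters,
    gene_pool_frequencies,
    mixed_genotypes,
)
from .io import export_genepop, read_genotype_csv, write_genotype_csv
from .loci import read_regions, synthetic_panel, write_regions
from .matrix import GenotypeMatrix
from .migration import bootstrap_support, directional_migration, write_dot, write_edge_list
from .popgen import allele_freqs, diversity, hwe_all, null_allele_table, pairwise_theta, private_alleles
from .simulate import ReadNoise, diverged_populations, random_ancestral_freqs, sample_genotypes, write_fastq_dir

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the protocol's standard thresholds."""

    out_dir: str = "msatpop_out"
    # inputs (exactly one route: simulate, fastq_dir, or genotype_csv)
    simulate: bool = False
    fastq_dir: str | None = None
    regions_file: str | None = None
    reference_fasta: str | None = None
    genotype_csv: str | None = None
    # read QC and calling thresholds
    min_phred: float = 30.0
    min_len: int = 75
    min_depth: int = 10
    major_threshold: float = 0.80
    minor_threshold: float = 0.20
    flank_k: int = 8
    # analysis settings
    group_by: str = "region"
    site_to_region: dict[str, str] = field(default_factory=dict)
    n_perm: int = 999
    k_max: int = 10
    dapc_threshold: float = 0.5
    migration_filter: float = 0.35
    migration_indices: tuple[str, ...] = ("G", "D", "Nm")
    n_boot: int = 100
    # simulation settings (used when simulate=True)
    sim_n_pops: int = 4
    sim_n_individuals: int = 50
    sim_fst: float = 0.15
    sim_fis: float = 0.25
    sim_depth_mean: float = 40.0
    sim_stutter_rate: float = 0.05
    sim_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "major_threshold",
            "minor_threshold",
            "dapc_threshold",
            "migration_filter",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "migration_indices" in data:
            data["migration_indices"] = tuple(data["migration_indices"])
        return cls(**data)


def _load_loci(config: PipelineConfig):
    if config.regions_file and config.reference_fasta:
        return read_regions(config.regions_file, config.reference_fasta)
    if config.regions_file or config.reference_fasta:
        raise FileNotFoundError(
            "regions_file and reference_fasta must be given together"
        )
    return synthetic_panel()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON).

    Idempotent under a fixed seed: rerunning with the same configuration
    reproduces every output byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_phred": config.min_phred,
            "min_len": config.min_len,
            "min_depth": config.min_depth,
            "major_threshold": config.major_threshold,
            "minor_threshold": config.minor_threshold,
            "dapc_threshold": config.dapc_threshold,
            "migration_filter": config.migration_filter,
        },
        "stages": [],
    }

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise exc

    loci = _load_loci(config)

    # -- acquire genotypes ---------------------------------------------
    gm: GenotypeMatrix
    try:
        if config.simulate:
            ancestral = random_ancestral_freqs(loci, seed=config.seed)
            pops = diverged_populations(
                ancestral,
                names=[f"P{i + 1}" for i in range(config.sim_n_pops)],
                fst=config.sim_fst,
                n_individuals=config.sim_n_individuals,
                fis=config.sim_fis,
                seed=config.seed + 1,
            )
            truth = sample_genotypes(
                pops, loci, seed=config.seed + 2, site_to_region=config.site_to_region
            )
            noise = ReadNoise(
                depth_mean=config.sim_depth_mean,
                stutter_rate=config.sim_stutter_rate,
                error_rate=config.sim_error_rate,
            )
            fastq_dir = out / "fastq"
            write_fastq_dir(truth, loci, noise, fastq_dir, seed=config.seed + 3)
            write_genotype_csv(truth.genotypes, out / "truth_genotypes.csv")
            write_regions(loci, out / "regions.tsv", out / "reference.fasta")
            manifest["stages"].append(
                {
                    "stage": "simulate",
                    "n_individuals": len(truth.genotypes),
                    "n_loci": len(loci),
                }
            )
            source_fastq = fastq_dir
        elif config.fastq_dir:
            source_fastq = Path(config.fastq_dir)
            if not source_fastq.exists():
                raise FileNotFoundError(f"fastq dir not found: {source_fastq}")
        else:
            source_fastq = None
    except Exception as exc:  # noqa: BLE001 - manifest records the failure point
        _fail("simulate", exc)

    try:
        if source_fastq is not None:
            gm, audit = call_all(
                source_fastq,
                loci,
                min_phred=config.min_phred,
                min_len=config.min_len,
                min_depth=config.min_depth,
                major_threshold=config.major_threshold,
                minor_threshold=config.minor_threshold,
                flank_k=config.flank_k,
                site_to_region=config.site_to_region,
            )
            audit.to_csv(out / "call_audit.csv", index=False)
            n_na = int((audit["status"] == "NA").sum())
            manifest["stages"].append(
                {
                    "stage": "call",
                    "n_calls": len(audit) - n_na,
                    "n_na": n_na,
                    "n_reads_discarded": int(audit["n_discarded"].sum()),
                    "n_reads_counted": int(audit["depth"].sum()),
                }
            )
        elif config.genotype_csv:
            path = Path(config.genotype_csv)
            if not path.exists():
                raise FileNotFoundError(f"genotype CSV not found: {path}")
            gm = read_genotype_csv(path)
            manifest["stages"].append({"stage": "load", "n_individuals": len(gm)})
        else:
            raise ValueError(
                "no input: set simulate=true, fastq_dir, or genotype_csv"
            )
        write_genotype_csv(gm, out / "genotypes.csv")
        export_genepop(gm, out / "genotypes.genepop", group_by=config.group_by)
    except Exception as exc:  # noqa: BLE001
        _fail("call", exc)

    # -- stats ----------------------------------------------------------
    try:
        means, per_locus = diversity(gm, config.group_by)
        means.to_csv(out / "diversity_means.csv", index=False)
        per_locus.to_csv(out / "diversity_per_locus.csv", index=False)
        tables = allele_freqs(gm, config.group_by)
        priv = private_alleles(tables) if len(tables) > 1 else []
        with open(out / "private_alleles.csv", "w") as fh:
            fh.write("population,locus,allele,frequency\n")
            for pop, locus, allele, freq in priv:
                fh.write(f"{pop},{locus},{allele},{freq:.6f}\n")
        hwe = hwe_all(gm, config.group_by)
        hwe.to_csv(out / "hwe.csv", index=False)
        nulls = null_allele_table(gm, config.group_by)
        nulls.to_csv(out / "null_alleles.csv", index=False)
        theta, pvals = pairwise_theta(
            gm, config.group_by, n_perm=config.n_perm, seed=config.seed + 10
        )
        theta.to_csv(out / "theta_matrix.csv")
        pvals.to_csv(out / "theta_pvalues.csv")
        manifest["stages"].append(
            {
                "stage": "stats",
                "n_populations": len(gm.populations(config.group_by)),
                "n_private_alleles": len(priv),
                "n_perm": config.n_perm,
            }
        )
    except Exception as exc:  # noqa: BLE001
        _fail("stats", exc)

    # -- dapc -----------------------------------------------------------
    try:
        dosage = encode_alleles(gm)
        if gm.missing_fraction() > 0.10:
            logger.warning(
                "missingness %.1f%% > 10%%: mean-imputation may blur structure",
                100 * gm.missing_fraction(),
            )
        fc = find_clusters(dosage, k_max=config.k_max, seed=config.seed + 20)
        with open(out / "bic_curve.csv", "w") as fh:
            fh.write("k,bic\n")
            for k, v in fc.bic.items():
                fh.write(f"{k},{v:.6f}\n")
        sites = gm.labels("site").loc[dosage.individuals]
        if fc.k_best >= 2:
            fit = dapc(dosage, fc.assignments)
            flags, n_mixed = mixed_genotypes(
                fit.memberships, sites, threshold=config.dapc_threshold
            )
            comp = gene_pool_frequencies(fc.assignments, sites)
            comp.to_csv(out / "gene_pool_frequencies.csv")
            mem = fit.memberships.copy()
            mem.insert(0, "site", sites)
            mem.insert(1, "region", gm.labels("region").loc[dosage.individuals])
            mem["assigned"] = fit.memberships.idxmax(axis=1)
            mem["mixed"] = flags
            mem.index.name = "individual"
            mem.to_csv(out / "memberships.csv")
        else:
            n_mixed = 0
        manifest["stages"].append(
            {"stage": "dapc", "k_best": fc.k_best, "n_mixed": n_mixed}
        )
    except Exception as exc:  # noqa: BLE001
        _fail("dapc", exc)

    # -- migration -------------------------------------------------------
    try:
        tables = allele_freqs(gm, config.group_by)
        mig_summary = {}
        for index in config.migration_indices:
            if config.n_boot > 0:
                net = bootstrap_support(
                    gm,
                    index=index,
                    group_by=config.group_by,
                    n_boot=config.n_boot,
                    filter_threshold=config.migration_filter,
                    seed=config.seed + 30,
                )
                net.boot_support.to_csv(out / f"migration_{index}_support.csv")
                net.asymmetry.to_csv(out / f"migration_{index}_asymmetry.csv", index=False)
            else:
                net = directional_migration(tables, index, config.migration_filter)
            net.raw.to_csv(out / f"migration_{index}_raw.csv")
            net.relative.to_csv(out / f"migration_{index}_relative.csv")
            write_dot(net, out / f"migration_{index}.dot")
            write_edge_list(net, out / f"migration_{index}_edges.tsv")
            mig_summary[index] = len(net.edges)
        manifest["stages"].append(
            {"stage": "migrate", "edges_passing_filter": mig_summary}
        )
    except Exception as exc:  # noqa: BLE001
        _fail("migrate", exc)

    manifest["failed_stage"] = None
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
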