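"""Synthetic multi-population microsatellite genotypes and amplicon reads.

The generator exists so that every downstream stage of the pipeline can be
exercised against a known truth.  It produces

* diploid genotypes drawn from per-population allele-frequency
  distributions with an inbreeding coefficient ``fis`` modelled as an
  identity-by-descent mixture (with probability ``fis`` one allele draw is
  used twice, so E[Ho] = (1 - fis) * (1 - sum p^2));
* amplicon reads per individual x locus with negative-binomial depth,
  polymerase stutter of +/- one repeat unit, per-base substitution error,
  and Gaussian Phred scores — the noise modes the read-QC and calling rules
  defend against.

Helpers at the bottom construct population systems with a chosen degree of
differentiation (Dirichlet divergence from an ancestral pool) and forward
drift/migration simulations used to plant directional gene flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .loci import LocusDef
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

_FREQ_TOL = 1e-9
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PopModel:
    """One population: per-locus allele frequencies, inbreeding, sample size.

    ``allele_freqs[locus]`` maps tract length (bp) to relative frequency;
    frequencies at each locus must sum to 1.  ``fis`` is the inbreeding
    coefficient in [0, 1] (probability that an individual's two alleles are
    identical by descent).
    """

    name: str
    allele_freqs: dict[str, dict[int, float]]
    fis: float = 0.0
    n_individuals: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fis <= 1.0:
            raise ValueError(f"population {self.name}: fis must be in [0,1]")
        if self.n_individuals < 0:
            raise ValueError(f"population {self.name}: n_individuals must be >= 0")
        for locus, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > _FREQ_TOL:
                raise ValueError(
                    f"population {self.name}, locus {locus}: frequencies sum "
                    f"to {total!r}, not 1"
                )
            if any(length <= 0 for length in freqs):
                raise ValueError(
                    f"population {self.name}, locus {locus}: tract lengths must "
                    "be positive"
                )


@dataclass
class ReadNoise:
    """Sequencing-noise parameters for read simulation.

    depth_mean
        Expected reads per individual x locus.
    depth_dispersion
        Negative-binomial size parameter r (variance = m + m^2/r); smaller
        values give more overdispersed depth.  ``math.inf`` degenerates to
        a constant depth of round(depth_mean).
    stutter_rate
        Probability that a read's tract is off by one repeat unit.
    error_rate
        Per-base substitution probability.
    qual_mean, qual_sd
        Phred score distribution; scores are truncated to [2, 40].
    """

    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    stutter_rate: float = 0.05
    error_rate: float = 0.005
    qual_mean: float = 35.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("stutter_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")


@dataclass
class SimTruth:
    """Ground truth of a simulation: genotypes plus the parameters used."""

    genotypes: GenotypeMatrix
    pops: list[PopModel]
    noise: ReadNoise | None
    seed: int
    site_to_region: dict[str, str] = field(default_factory=dict)


def sample_genotypes(
    pops: list[PopModel],
    loci: list[LocusDef],
    seed: int,
    site_to_region: dict[str, str] | None = None,
) -> SimTruth:
    """Draw diploid genotypes for every population.

    With probability ``fis`` the two alleles of an individual are identical
    by descent (a single frequency draw used twice); otherwise they are two
    independent draws.  Individuals are labelled ``<pop>_<serial>``; the
    site label is the population name and the region label defaults to the
    site unless ``site_to_region`` maps it elsewhere.
    """
    for pop in pops:
        for loc in loci:
            if loc.name not in pop.allele_freqs:
                raise KeyError(
                    f"population {pop.name} supplies no frequencies for locus "
                    f"{loc.name}"
                )
        for loc in loci:
            freqs = pop.allele_freqs[loc.name]
            unit = len(loc.motif)
            bad = [length for length in freqs if length % unit]
            if bad:
                raise ValueError(
                    f"population {pop.name}, locus {loc.name}: tract lengths "
                    f"{bad} are not multiples of the {unit}-bp motif"
                )

    rng = np.random.default_rng(seed)
    calls: dict[str, dict[str, tuple[int, int]]] = {}
    site: dict[str, str] = {}
    for pop in pops:
        indiv_ids = [f"{pop.name}_{i:04d}" for i in range(pop.n_individuals)]
        per_locus: dict[str, np.ndarray] = {}
        for loc in loci:
            freqs = pop.allele_freqs[loc.name]
            lengths = np.fromiter(freqs.keys(), dtype=np.int64)
            probs = np.fromiter(freqs.values(), dtype=float)
            probs = probs / probs.sum()  # normalize away rounding slack
            n = pop.n_individuals
            first = rng.choice(lengths, size=n, p=probs)
            second = rng.choice(lengths, size=n, p=probs)
            ibd = rng.random(n) < pop.fis
            second = np.where(ibd, first, second)
            per_locus[loc.name] = np.stack([first, second], axis=1)
        for k, indiv in enumerate(indiv_ids):
            calls[indiv] = {
                loc.name: tuple(sorted(per_locus[loc.name][k].tolist()))
                for loc in loci
            }
            site[indiv] = pop.name
    region = None
    if site_to_region:
        region = {i: site_to_region.get(s, s) for i, s in site.items()}
    gm = GenotypeMatrix.from_calls(
        calls, site=site, region=region, loci=[loc.name for loc in loci]
    )
    return SimTruth(
        genotypes=gm,
        pops=pops,
        noise=None,
        seed=seed,
        site_to_region=dict(site_to_region or {}),
    )


# -- read simulation ----------------------------------------------------


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _qual_string(rng: np.random.Generator, length: int, noise: ReadNoise) -> str:
    q = np.rint(rng.normal(noise.qual_mean, noise.qual_sd, size=length))
    q = np.clip(q, 2, 40).astype(np.int64)
    return "".join(chr(33 + int(v)) for v in q)


def simulate_reads(
    truth: SimTruth,
    loci: list[LocusDef],
    noise: ReadNoise,
    seed: int,
):
    """Yield simulated reads as ``(read_id, sequence, quality)`` triples.

    Depth per individual x locus is negative-binomial; each read copies one
    of the two true alleles with probability 1/2; with probability
    ``stutter_rate`` the tract shifts by one repeat unit (sign
    equiprobable, clamped at one unit); substitutions are applied at
    ``error_rate``; qualities are Gaussian Phred scores truncated to
    [2, 40].  Read IDs encode ``<individual>|<locus>|<serial>``.

    Deterministic: identical truth, loci, noise and seed give an identical
    read stream.
    """
    rng = np.random.default_rng(seed)
    locus_defs = {loc.name: loc for loc in loci}
    gm = truth.genotypes
    constant_depth = not np.isfinite(noise.depth_dispersion)
    if not constant_depth:
        p_nb = noise.depth_dispersion / (noise.depth_dispersion + noise.depth_mean)
    for indiv in gm.individuals:
        for locus in gm.loci:
            loc = locus_defs[locus]
            call = gm.df.at[indiv, locus]
            if call is None:
                continue
            if noise.depth_mean == 0:
                continue
            if constant_depth:
                depth = int(round(noise.depth_mean))
            else:
                depth = int(rng.negative_binomial(noise.depth_dispersion, p_nb))
            unit = len(loc.motif)
            for serial in range(depth):
                allele = call[int(rng.integers(2))]
                tract = allele
                if noise.stutter_rate > 0 and rng.random() < noise.stutter_rate:
                    shift = unit if rng.random() < 0.5 else -unit
                    tract = allele + shift
                    if tract < unit:
                        logger.debug(
                            "%s %s: stutter below one unit clamped", indiv, locus
                        )
                        tract = unit
                seq = _mutate(rng, loc.amplicon(tract), noise.error_rate)
                qual = _qual_string(rng, len(seq), noise)
                yield f"{indiv}|{locus}|{serial}", seq, qual


def write_fastq_dir(
    truth: SimTruth,
    loci: list[LocusDef],
    noise: ReadNoise,
    out_dir: str | Path,
    seed: int,
) -> list[Path]:
    """Write one 4-line FASTQ file per individual; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, list[str]] = {i: [] for i in truth.genotypes.individuals}
    for read_id, seq, qual in simulate_reads(truth, loci, noise, seed):
        indiv = read_id.split("|", 1)[0]
        handles[indiv].append(f"@{read_id}\n{seq}\n+\n{qual}\n")
    paths = []
    for indiv, chunks in handles.items():
        path = out_dir / f"{indiv}.fastq"
        path.write_text("".join(chunks))
        paths.append(path)
    return paths


# -- population-system builders -----------------------------------------


def random_ancestral_freqs(
    loci: list[LocusDef],
    n_alleles: int = 6,
    seed: int = 0,
    concentration: float = 2.0,
) -> dict[str, dict[int, float]]:
    """Draw an ancestral allele-frequency distribution per locus.

    Allele tract lengths are consecutive repeat counts around the reference
    tract; frequencies are a flat-Dirichlet draw.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[int, float]] = {}
    for loc in loci:
        unit = len(loc.motif)
        base = max(loc.n_repeats - n_alleles // 2, 1)
        lengths = [(base + j) * unit for j in range(n_alleles)]
        probs = rng.dirichlet(np.full(n_alleles, concentration))
        out[loc.name] = {length: float(p) for length, p in zip(lengths, probs)}
    return out


def diverged_populations(
    ancestral: dict[str, dict[int, float]],
    names: list[str],
    fst: float,
    n_individuals: int | list[int],
    fis: float | list[float] = 0.0,
    seed: int = 0,
) -> list[PopModel]:
    """Populations diverged from an ancestral pool to a target F_ST.

    Per-population, per-locus frequencies are Dirichlet draws with
    concentration ``p * (1 - fst) / fst``, the standard F-model under which
    the expected among-population differentiation equals ``fst``.
    ``fst = 0`` returns identical copies of the ancestral frequencies.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_individuals, int):
        n_individuals = [n_individuals] * len(names)
    if isinstance(fis, float):
        fis = [fis] * len(names)
    pops = []
    for name, n, f in zip(names, n_individuals, fis):
        freqs: dict[str, dict[int, float]] = {}
        for locus, anc in ancestral.items():
            lengths = list(anc)
            p = np.fromiter(anc.values(), dtype=float)
            if fst <= 0:
                drawn = p
            else:
                alpha = np.maximum(p * (1.0 - fst) / fst, 1e-6)
                drawn = rng.dirichlet(alpha)
            drawn = drawn / drawn.sum()
            freqs[locus] = {length: float(v) for length, v in zip(lengths, drawn)}
        pops.append(PopModel(name=name, allele_freqs=freqs, fis=f, n_individuals=n))
    return pops


def drift_migration_freqs(
    ancestral: dict[str, dict[int, float]],
    migration: np.ndarray,
    n_pops: int,
    generations: int = 200,
    ne: int = 200,
    seed: int = 0,
) -> list[dict[str, dict[int, float]]]:
    """Forward-simulate allele frequencies under drift plus migration.

    ``migration[i, j]`` is the fraction of population i's gene pool
    replaced each generation by migrants from population j (rows must sum
    to <= 1; the diagonal is filled with the remainder).  Each generation
    applies deterministic migration then binomial drift with 2*Ne gametes.
    Returns per-population frequency dictionaries in the ancestral's locus
    and allele order.
    """
    rng = np.random.default_rng(seed)
    m = np.asarray(migration, dtype=float).copy()
    if m.shape != (n_pops, n_pops):
        raise ValueError("migration matrix shape mismatch")
    np.fill_diagonal(m, 0.0)
    off = m.sum(axis=1)
    if np.any(off > 1.0):
        raise ValueError("migration rows must sum to <= 1")
    np.fill_diagonal(m, 1.0 - off)

    out: list[dict[str, dict[int, float]]] = [dict() for _ in range(n_pops)]
    for locus, anc in ancestral.items():
        lengths = list(anc)
        p = np.tile(np.fromiter(anc.values(), dtype=float), (n_pops, 1))
        for _ in range(generations):
            p = m @ p
            for i in range(n_pops):
                counts = rng.multinomial(2 * ne, p[i] / p[i].sum())
                p[i] = counts / (2.0 * ne)
        for i in range(n_pops):
            pi = p[i] / p[i].sum()
            out[i][locus] = {length: float(v) for length, v in zip(lengths, pi)}
    return out
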