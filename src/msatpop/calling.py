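"""Read quality filtering and the read-fraction microsatellite calling rule.

The calling rule operates on per-allele read tallies at one individual x
locus: with fewer than 10 reads no call is made (NA); if the most-supported
allele holds more than 80% of the reads the individual is homozygous for
it; otherwise, if the second allele holds at least 20% of the reads the
individual is heterozygous for the top two; anything else is NA.  At the
minimum depth of 10 the 20% floor means at least two reads must confirm
the minor allele, which is what keeps single stutter or error reads from
creating false heterozygotes.

Reads are assigned to a locus and measured by exact flank anchoring: the
last ``flank_k`` bases of the left flank and the first ``flank_k`` bases of
the right flank must occur in order in the read (or its reverse
complement), and the enclosed segment must be a whole-number repetition of
the locus motif.  Reads failing quality, anchoring, or motif purity are
tallied as discarded, never guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .loci import LocusDef, reverse_complement
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_PHRED = 30.0
DEFAULT_MIN_LEN = 75
DEFAULT_MIN_DEPTH = 10
DEFAULT_MAJOR_THRESHOLD = 0.80
DEFAULT_MINOR_THRESHOLD = 0.20


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTQ file (Phred+33), rejecting malformed records."""
    try:
        return list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def filter_reads(
    reads: Iterable[SeqRecord],
    min_phred: float = DEFAULT_MIN_PHRED,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[SeqRecord]:
    """Keep reads with length >= ``min_len`` and mean Phred >= ``min_phred``.

    Order is preserved.  The quality condition uses the mean Phred score of
    the read (whole-read filtering, no per-base trimming).
    """
    kept = []
    for rec in reads:
        if len(rec) < min_len:
            continue
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise ValueError(f"read {rec.id} has no quality scores")
        if float(np.mean(quals)) < min_phred:
            continue
        kept.append(rec)
    return kept


def measure_tract(read: str, locus: LocusDef, flank_k: int = 8) -> int | None:
    """Measure the repeat-tract length (bp) of a read at one locus.

    Anchors the last ``flank_k`` bases of the left flank and the first
    ``flank_k`` bases of the right flank as exact substrings of the read or
    its reverse complement; if both are found in order and the enclosed
    segment is a non-empty whole-number repetition of the motif, returns
    its length.  Returns ``None`` otherwise (caller tallies as discarded).
    """
    if flank_k > len(locus.left_flank) or flank_k > len(locus.right_flank):
        raise ValueError(
            f"flank_k={flank_k} exceeds flank length at locus {locus.name}"
        )
    left_anchor = locus.left_flank[-flank_k:]
    right_anchor = locus.right_flank[:flank_k]
    motif = locus.motif
    for seq in (read, reverse_complement(read)):
        i = seq.find(left_anchor)
        while i != -1:
            j = seq.find(right_anchor, i + flank_k)
            if j != -1:
                tract = seq[i + flank_k : j]
                k, rem = divmod(len(tract), len(motif))
                if k >= 1 and rem == 0 and tract == motif * k:
                    return len(tract)
            i = seq.find(left_anchor, i + 1)
    return None


@dataclass
class AlleleCount:
    """Per-allele read tallies at one individual x locus."""

    individual: str
    locus: str
    counts: dict[int, int] = field(default_factory=dict)
    n_discarded: int = 0

    def add(self, tract_bp: int | None) -> None:
        if tract_bp is None:
            self.n_discarded += 1
        else:
            self.counts[tract_bp] = self.counts.get(tract_bp, 0) + 1

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenotypeCall:
    """A called genotype (two bp-length alleles) or a missing (NA) call."""

    individual: str
    locus: str
    allele1: int | None
    allele2: int | None
    depth: int
    major_frac: float
    minor_frac: float
    status: str  # "called" | "NA"

    @property
    def call(self) -> tuple[int, int] | None:
        if self.status != "called":
            return None
        return (self.allele1, self.allele2)


def call_genotype(
    count: AlleleCount,
    min_depth: int = DEFAULT_MIN_DEPTH,
    major_threshold: float = DEFAULT_MAJOR_THRESHOLD,
    minor_threshold: float = DEFAULT_MINOR_THRESHOLD,
) -> GenotypeCall:
    """Apply the depth / >80% / >=20% rule to one allele tally.

    * depth < ``min_depth`` -> NA;
    * top allele fraction > ``major_threshold`` -> homozygote top/top;
    * else second allele fraction >= ``minor_threshold`` -> heterozygote;
    * else NA.

    Alleles are ranked by read count; ties rank the shorter tract first.
    """
    depth = count.depth
    na = GenotypeCall(
        individual=count.individual,
        locus=count.locus,
        allele1=None,
        allele2=None,
        depth=depth,
        major_frac=0.0,
        minor_frac=0.0,
        status="NA",
    )
    if depth < min_depth or not count.counts:
        return na
    ranked = sorted(count.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_len, top_n = ranked[0]
    top_frac = top_n / depth
    if top_frac > major_threshold:
        return GenotypeCall(
            individual=count.individual,
            locus=count.locus,
            allele1=top_len,
            allele2=top_len,
            depth=depth,
            major_frac=top_frac,
            minor_frac=top_frac,
            status="called",
        )
    if len(ranked) >= 2:
        second_len, second_n = ranked[1]
        second_frac = second_n / depth
        if second_frac >= minor_threshold:
            a1, a2 = sorted((top_len, second_len))
            return GenotypeCall(
                individual=count.individual,
                locus=count.locus,
                allele1=a1,
                allele2=a2,
                depth=depth,
                major_frac=top_frac,
                minor_frac=second_frac,
                status="called",
            )
    return na


def _default_site_of(individual: str) -> str:
    """Site label from the individual ID, by convention ``<site>_<serial>``."""
    return individual.rsplit("_", 1)[0] if "_" in individual else "unknown"


def tally_reads(
    fastq_paths: Iterable[str | Path],
    loci: list[LocusDef],
    min_phred: float = DEFAULT_MIN_PHRED,
    min_len: int = DEFAULT_MIN_LEN,
    flank_k: int = 8,
) -> Iterator[AlleleCount]:
    """Filter, assign and measure all reads; yield one tally per indiv x locus.

    Read IDs must encode ``<individual>|<locus>|<serial>``.  Reads naming a
    locus absent from ``loci`` raise a KeyError naming it.  QC-failed reads
    are counted as discarded for their individual x locus.
    """
    locus_defs = {loc.name: loc for loc in loci}
    tallies: dict[tuple[str, str], AlleleCount] = {}
    for path in fastq_paths:
        records = read_fastq(path)
        passed_ids = {id(rec) for rec in filter_reads(records, min_phred, min_len)}
        for rec in records:
            try:
                indiv, locus, _serial = rec.id.split("|")
            except ValueError as exc:
                raise ValueError(
                    f"{path}: read ID {rec.id!r} is not <individual>|<locus>|<serial>"
                ) from exc
            if locus not in locus_defs:
                raise KeyError(
                    f"{path}: read {rec.id!r} names unknown locus {locus!r}"
                )
            key = (indiv, locus)
            if key not in tallies:
                tallies[key] = AlleleCount(individual=indiv, locus=locus)
            if id(rec) not in passed_ids:
                tallies[key].n_discarded += 1
                continue
            tallies[key].add(measure_tract(str(rec.seq), locus_defs[locus], flank_k))
    yield from tallies.values()


def call_all(
    fastq_dir: str | Path,
    loci: list[LocusDef],
    min_phred: float = DEFAULT_MIN_PHRED,
    min_len: int = DEFAULT_MIN_LEN,
    min_depth: int = DEFAULT_MIN_DEPTH,
    major_threshold: float = DEFAULT_MAJOR_THRESHOLD,
    minor_threshold: float = DEFAULT_MINOR_THRESHOLD,
    flank_k: int = 8,
    site_of=None,
    site_to_region: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Call genotypes for every individual x locus found under ``fastq_dir``.

    Returns the genotype matrix (NA where no call could be made, including
    individual x locus pairs with zero reads) and a per-call audit table
    with depth, allele fractions and discarded-read counts.
    """
    fastq_dir = Path(fastq_dir)
    paths = sorted(fastq_dir.glob("*.fastq")) + sorted(fastq_dir.glob("*.fq"))
    if not paths:
        raise FileNotFoundError(f"no FASTQ files under {fastq_dir}")
    if site_of is None:
        site_of = _default_site_of

    tallies = list(
        tally_reads(paths, loci, min_phred=min_phred, min_len=min_len, flank_k=flank_k)
    )
    individuals = sorted({t.individual for t in tallies})
    by_key = {(t.individual, t.locus): t for t in tallies}

    calls: dict[str, dict[str, tuple[int, int] | None]] = {}
    audit_rows = []
    for indiv in individuals:
        calls[indiv] = {}
        for loc in loci:
            tally = by_key.get((indiv, loc.name), AlleleCount(indiv, loc.name))
            gt = call_genotype(
                tally,
                min_depth=min_depth,
                major_threshold=major_threshold,
                minor_threshold=minor_threshold,
            )
            calls[indiv][loc.name] = gt.call
            audit_rows.append(
                {
                    "individual": indiv,
                    "locus": loc.name,
                    "status": gt.status,
                    "allele1": gt.allele1,
                    "allele2": gt.allele2,
                    "depth": gt.depth,
                    "major_frac": gt.major_frac,
                    "minor_frac": gt.minor_frac,
                    "n_discarded": tally.n_discarded,
                }
            )

    site = {i: site_of(i) for i in individuals}
    region = None
    if site_to_region:
        region = {i: site_to_region.get(s, s) for i, s in site.items()}
    gm = GenotypeMatrix.from_calls(
        calls, site=site, region=region, loci=[loc.name for loc in loci]
    )
    audit = pd.DataFrame(audit_rows)
    n_na = int((audit["status"] == "NA").sum())
    logger.info(
        "called %d individuals x %d loci; %d NA calls (%.1f%%)",
        len(individuals),
        len(loci),
        n_na,
        100.0 * n_na / max(len(audit), 1),
    )
    return gm, audit
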