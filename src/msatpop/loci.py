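"""Microsatellite locus definitions and the on-disk regions format.

A locus is described by a reference amplicon sequence, the coordinates of
its repeat tract within that sequence, and the repeat motif.  Alleles are
identified by tract length in base pairs (e.g. a 7x ATT tract is allele 21),
which is the convention used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: Minimum flank length (bp) required on each side of the repeat tract so
#: that exact k-mer anchoring has something to hold on to.
MIN_FLANK = 8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus.

    Parameters
    ----------
    name:
        Locus label (e.g. ``"ProC10"``).
    reference:
        Full reference amplicon sequence, flanks included.
    repeat_start, repeat_end:
        0-based half-open coordinates of the repeat tract within
        ``reference``.  The on-disk regions file uses 1-based inclusive
        coordinates; :func:`read_regions` converts.
    motif:
        Repeat unit, 3 or 4 bases (tri- or tetra-nucleotide repeats).
    """

    name: str
    reference: str
    repeat_start: int
    repeat_end: int
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) not in (3, 4):
            raise ValueError(
                f"locus {self.name}: motif {self.motif!r} must be 3 or 4 bases"
            )
        if not (0 <= self.repeat_start < self.repeat_end <= len(self.reference)):
            raise ValueError(f"locus {self.name}: repeat coordinates out of range")
        tract = self.reference[self.repeat_start : self.repeat_end]
        k, rem = divmod(len(tract), len(self.motif))
        if rem or tract != self.motif * k:
            raise ValueError(
                f"locus {self.name}: reference tract is not a whole-number "
                f"repetition of motif {self.motif!r}"
            )
        if len(self.left_flank) < MIN_FLANK or len(self.right_flank) < MIN_FLANK:
            raise ValueError(
                f"locus {self.name}: flanks must be >= {MIN_FLANK} bases each"
            )

    @property
    def left_flank(self) -> str:
        return self.reference[: self.repeat_start]

    @property
    def right_flank(self) -> str:
        return self.reference[self.repeat_end :]

    @property
    def tract_length(self) -> int:
        """Reference tract length in bp."""
        return self.repeat_end - self.repeat_start

    @property
    def n_repeats(self) -> int:
        return self.tract_length // len(self.motif)

    def amplicon(self, tract_bp: int) -> str:
        """Full amplicon sequence for the allele with a ``tract_bp`` tract."""
        k, rem = divmod(tract_bp, len(self.motif))
        if rem or k < 1:
            raise ValueError(
                f"locus {self.name}: {tract_bp} bp is not a positive whole "
                f"number of {self.motif!r} units"
            )
        return self.left_flank + self.motif * k + self.right_flank

    def valid_allele(self, tract_bp: int) -> bool:
        return tract_bp > 0 and tract_bp % len(self.motif) == 0


def read_regions(regions_path: str | Path, fasta_path: str | Path) -> list[LocusDef]:
    """Load locus definitions from a regions TSV plus a reference FASTA.

    The regions file is tab-separated with columns
    ``locus  start  end  motif`` where start/end are 1-based inclusive
    coordinates of the repeat tract in the locus reference sequence.
    FASTA record IDs must match locus names.
    """
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci: list[LocusDef] = []
    with open(regions_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{regions_path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, start, end, motif = fields
            if name not in refs:
                raise KeyError(
                    f"{regions_path}:{lineno}: locus {name!r} has no reference "
                    f"sequence in {fasta_path}"
                )
            loci.append(
                LocusDef(
                    name=name,
                    reference=refs[name],
                    repeat_start=int(start) - 1,
                    repeat_end=int(end),
                    motif=motif.upper(),
                )
            )
    return loci


def write_regions(loci: list[LocusDef], regions_path: str | Path, fasta_path: str | Path) -> None:
    """Write the regions TSV (1-based inclusive) and companion FASTA."""
    with open(regions_path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.name}\t{loc.repeat_start + 1}\t{loc.repeat_end}\t{loc.motif}\n")
    with open(fasta_path, "w") as fh:
        for loc in loci:
            fh.write(f">{loc.name}\n{loc.reference}\n")


def _random_flank(rng: np.random.Generator, length: int, motif: str) -> str:
    """Random flank that neither ends nor starts with the motif.

    Keeps the repeat tract unambiguous: the simulated tract is exactly the
    run of motif copies between the flanks.
    """
    bases = np.array(list("ACGT"))
    while True:
        flank = "".join(rng.choice(bases, size=length))
        if not flank.endswith(motif) and not flank.startswith(motif) and motif not in flank:
            return flank


def synthetic_panel(seed: int = 20200916) -> list[LocusDef]:
    """An eight-locus tri/tetra-nucleotide panel with synthetic references.

    Locus names follow the ProC microsatellite panel of *Prochilodus
    costatus*; the reference sequences themselves are synthetic stand-ins
    generated deterministically from ``seed`` (real flanking sequences are
    not bundled).  Flank length 40 bp on each side — long enough that any
    plausible allele's amplicon clears the 75 bp read-length filter —
    with a 7-unit reference tract.
    """
    motifs = {
        "ProC10": "ATT",
        "ProC18": "ATCT",
        "ProC22": "AAT",
        "ProC36": "AGAT",
        "ProC37": "ATC",
        "ProC44": "ACT",
        "ProC48": "AAAT",
        "ProC49": "ATG",
    }
    rng = np.random.default_rng(seed)
    panel = []
    for name, motif in motifs.items():
        left = _random_flank(rng, 40, motif)
        right = _random_flank(rng, 40, motif)
        tract = motif * 7
        panel.append(
            LocusDef(
                name=name,
                reference=left + tract + right,
                repeat_start=len(left),
                repeat_end=len(left) + len(tract),
                motif=motif,
            )
        )
    return panel


def pcos10_example_locus(seed: int = 10) -> LocusDef:
    """The worked-example locus: Pcos10, motif ATT, 7-unit reference tract.

    Flanks are synthetic stand-ins (deterministic from ``seed``); the locus
    name, motif and tract follow the assay's reference example, in which
    every read carrying a 5'-ATTATTATTATTATTATTATT-3' tract is genotyped
    21/21.
    """
    rng = np.random.default_rng(seed)
    left = _random_flank(rng, 30, "ATT")
    right = _random_flank(rng, 30, "ATT")
    return LocusDef(
        name="Pcos10",
        reference=left + "ATT" * 7 + right,
        repeat_start=30,
        repeat_end=30 + 21,
        motif="ATT",
    )
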