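"""The genotype matrix: individuals x loci allele-pair table.

This is the central exchange object of the pipeline: the caller produces
one, the simulator's truth is one, and every downstream statistic consumes
one.  Each cell holds a sorted pair of tract lengths in bp, or ``None`` for
a missing (NA) call.  Each individual carries a sampling-site label and a
region label (sites are grouped into regions for the regional analyses).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

META_COLUMNS = ("site", "region")

Call = tuple[int, int] | None


def _normalize_call(call) -> Call:
    if call is None:
        return None
    a, b = call
    a, b = int(a), int(b)
    if a <= 0 or b <= 0:
        raise ValueError(f"alleles must be positive bp lengths, got {call!r}")
    return (a, b) if a <= b else (b, a)


class GenotypeMatrix:
    """Individuals x loci table of allele pairs with site/region labels.

    Backed by a :class:`pandas.DataFrame` indexed by individual ID with
    columns ``site``, ``region`` and one object column per locus holding
    ``(a1, a2)`` tuples (``a1 <= a2``, bp lengths) or ``None``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"genotype matrix lacks columns {missing}")
        dupes = df.index[df.index.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate individual IDs: {dupes}")
        loci = [c for c in df.columns if c not in META_COLUMNS]
        df = df[[*META_COLUMNS, *loci]].copy()
        for locus in loci:
            df[locus] = df[locus].map(_normalize_call)
        self.df = df

    # -- construction ---------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        calls: Mapping[str, Mapping[str, Call]],
        site: Mapping[str, str],
        region: Mapping[str, str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Build from ``calls[individual][locus] -> (a1, a2) | None``."""
        individuals = list(calls)
        if loci is None:
            seen: dict[str, None] = {}
            for row in calls.values():
                for locus in row:
                    seen.setdefault(locus)
            loci = list(seen)
        loci = list(loci)
        data = {
            "site": [site[i] for i in individuals],
            "region": [
                (region[i] if region is not None else site[i]) for i in individuals
            ],
        }
        for locus in loci:
            data[locus] = [calls[i].get(locus) for i in individuals]
        return cls(pd.DataFrame(data, index=pd.Index(individuals, name="individual")))

    # -- basic accessors ------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.df.index)

    @property
    def loci(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    def labels(self, group_by: str = "region") -> pd.Series:
        if group_by not in META_COLUMNS:
            raise ValueError(f"group_by must be one of {META_COLUMNS}, got {group_by!r}")
        return self.df[group_by]

    def populations(self, group_by: str = "region") -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.labels(group_by)))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.df.equals(other.df)

    # -- subsetting ------------------------------------------------------

    def subset(self, individuals: Iterable[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.df.loc[list(individuals)])

    def subset_pops(self, pops: Iterable[str], group_by: str = "region") -> "GenotypeMatrix":
        pops = set(pops)
        mask = self.labels(group_by).isin(pops)
        return GenotypeMatrix(self.df.loc[mask])

    # -- genotype access -------------------------------------------------

    def calls(self, locus: str) -> pd.Series:
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        return self.df[locus]

    def pop_calls(self, pop: str, locus: str, group_by: str = "region") -> list[tuple[int, int]]:
        """Non-missing allele pairs for one population at one locus."""
        mask = self.labels(group_by) == pop
        return [c for c in self.df.loc[mask, locus] if c is not None]

    def allele_array(self, locus: str) -> np.ndarray:
        """Integer array of shape (n_individuals, 2); missing rows are -1."""
        out = np.full((len(self.df), 2), -1, dtype=np.int64)
        for i, call in enumerate(self.df[locus]):
            if call is not None:
                out[i] = call
        return out

    def missing_fraction(self) -> float:
        loci = self.loci
        total = len(self.df) * len(loci)
        if total == 0:
            return 0.0
        n_missing = sum(self.df[locus].isna().sum() for locus in loci)
        return float(n_missing) / total
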