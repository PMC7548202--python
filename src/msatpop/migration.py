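"""Directional relative migration networks from allele frequencies.

For every ordered pair of populations (a, b) a hypothetical pool is formed
whose per-locus allele frequencies are the mean of a's and b's.  The
migration from a into b is estimated from the genetic differentiation
between the *recipient* b and the pool: one-way gene flow a -> b drags b
toward the joint pool, so a small recipient-vs-pool distance signals high
incoming migration.  Differentiation is measured with Nei's G_ST ("G"),
Jost's D ("D", the Crawford-cited estimator), or converted to Wright's
island-model migrant number ("Nm"); G and D are turned into migration via
m = (1 - d) / (2 d).  The full directed matrix is normalized by its
maximum, giving relative migration in [0, 1]; edges below a filter
threshold (default 0.35) are pruned from the network.  Bootstrap
resampling of individuals within populations yields per-edge support and a
percentile test for directional asymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .popgen import FreqTable, allele_freqs

logger = logging.getLogger(__name__)

INDICES = ("G", "D", "Nm")
DEFAULT_FILTER = 0.35
_EPS = 1e-12


def _freq_vector(
    table: FreqTable, alleles: list[int]
) -> np.ndarray:
    return np.array([table.freqs.get(a, 0.0) for a in alleles])


def _pair_differentiation(
    fa: dict[str, FreqTable],
    fb: dict[str, FreqTable],
    index: str,
) -> float:
    """Differentiation between two frequency profiles across shared loci.

    G: Nei's G_ST from across-locus mean Hs and Ht.  D: Jost's D, the
    arithmetic mean of per-locus values with the n/(n-1) two-deme
    correction.  Both compare exactly two frequency profiles, equally
    weighted.
    """
    hs_list, ht_list, d_list = [], [], []
    for locus in fa:
        ta, tb = fa[locus], fb.get(locus)
        if tb is None or (not ta.freqs and not tb.freqs):
            continue
        alleles = sorted(set(ta.freqs) | set(tb.freqs))
        pa = _freq_vector(ta, alleles)
        pb = _freq_vector(tb, alleles)
        pbar = (pa + pb) / 2
        hs = 1.0 - ((pa**2).sum() + (pb**2).sum()) / 2
        ht = 1.0 - (pbar**2).sum()
        hs_list.append(hs)
        ht_list.append(ht)
        if 1.0 - hs > _EPS:
            d_list.append((ht - hs) / (1.0 - hs) * 2.0)  # n/(n-1), n = 2
    if not ht_list:
        return np.nan
    if index in ("G", "Nm"):
        hs_bar = float(np.mean(hs_list))
        ht_bar = float(np.mean(ht_list))
        if ht_bar <= _EPS:
            return 0.0
        return (ht_bar - hs_bar) / ht_bar
    if index == "D":
        return float(np.mean(d_list)) if d_list else 0.0
    raise ValueError(f"unknown index {index!r}; expected one of {INDICES}")


def _to_migration(d: float, index: str) -> float:
    """Island-model transform from differentiation to a migration estimate."""
    if np.isnan(d):
        return np.nan
    if d <= _EPS:
        return np.inf  # capped at the matrix max downstream
    if index == "Nm":
        return (1.0 - d) / (4.0 * d)  # Wright: F = 1 / (4 Nm + 1)
    return (1.0 - d) / (2.0 * d)


@dataclass
class MigrationNetwork:
    """Directed relative-migration matrix for one genetic index."""

    populations: list[str]
    index: str
    raw: pd.DataFrame
    relative: pd.DataFrame
    filter_threshold: float = DEFAULT_FILTER
    boot_support: pd.DataFrame | None = None
    asymmetry: pd.DataFrame | None = None
    n_boot_skipped: int = 0

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return filter_network(self, self.filter_threshold)

    def to_networkx(self, threshold: float | None = None) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.populations)
        thr = self.filter_threshold if threshold is None else threshold
        for src, dst, w in filter_network(self, thr):
            g.add_edge(src, dst, weight=w)
        return g


def directional_migration(
    freq_tables: dict[str, dict[str, FreqTable]],
    index: str = "G",
    filter_threshold: float = DEFAULT_FILTER,
) -> MigrationNetwork:
    """Directed relative migration between every ordered population pair.

    ``raw[a, b]`` estimates migration from a into b (recipient-vs-pool
    differentiation, island-model transform); ``relative`` is raw divided
    by its maximum, so the strongest flow is exactly 1.  Pairs whose
    recipient is indistinguishable from the pool (zero differentiation)
    are capped at the matrix maximum before normalization.
    """
    if index not in INDICES:
        raise ValueError(f"unknown index {index!r}; expected one of {INDICES}")
    pops = list(freq_tables)
    if len(pops) < 2:
        raise ValueError("directional migration needs at least two populations")
    raw = pd.DataFrame(np.nan, index=pops, columns=pops)
    for a in pops:
        for b in pops:
            if a == b:
                continue
            pool = _mean_pool(freq_tables[a], freq_tables[b])
            d_recipient = _pair_differentiation(freq_tables[b], pool, index)
            raw.loc[a, b] = _to_migration(d_recipient, index)
    vals = raw.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    cap = finite.max() if finite.size and finite.max() > 0 else 1.0
    if np.isinf(vals).any():
        logger.info(
            "%s: %d zero-differentiation pairs capped at matrix max",
            index,
            int(np.isinf(vals).sum()),
        )
    vals[np.isinf(vals)] = cap
    raw.loc[:, :] = vals
    mx = np.nanmax(vals)
    relative = raw / mx if mx > 0 else raw.copy()
    return MigrationNetwork(
        populations=pops,
        index=index,
        raw=raw,
        relative=relative,
        filter_threshold=filter_threshold,
    )


def _mean_pool(
    fa: dict[str, FreqTable], fb: dict[str, FreqTable]
) -> dict[str, FreqTable]:
    pool: dict[str, FreqTable] = {}
    for locus in fa:
        if locus not in fb:
            continue
        alleles = sorted(set(fa[locus].freqs) | set(fb[locus].freqs))
        freqs = {
            a: (fa[locus].freqs.get(a, 0.0) + fb[locus].freqs.get(a, 0.0)) / 2
            for a in alleles
        }
        pool[locus] = FreqTable(
            population="pool",
            locus=locus,
            freqs=freqs,
            n_typed=fa[locus].n_typed + fb[locus].n_typed,
        )
    return pool


def filter_network(
    net: MigrationNetwork, threshold: float = DEFAULT_FILTER
) -> list[tuple[str, str, float]]:
    """Directed edges whose relative migration is >= ``threshold``."""
    edges = []
    for a in net.populations:
        for b in net.populations:
            if a == b:
                continue
            w = net.relative.loc[a, b]
            if not np.isnan(w) and w >= threshold:
                edges.append((a, b, float(w)))
    return edges


def bootstrap_support(
    gm: GenotypeMatrix,
    index: str = "G",
    group_by: str = "region",
    n_boot: int = 100,
    filter_threshold: float = DEFAULT_FILTER,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MigrationNetwork:
    """Bootstrap the migration network by resampling individuals.

    Individuals are resampled with replacement within populations;
    ``boot_support[a, b]`` is the fraction of replicates in which the edge
    a -> b passes the filter.  Asymmetry of an ordered pair is tested
    two-sided at level ``alpha``: it is significant when the
    (alpha/2, 1 - alpha/2) percentile interval of ``m_ab - m_ba`` over
    replicates excludes 0.  Replicates that are monomorphic everywhere
    (no differentiation signal at any locus) are skipped and counted in
    ``n_boot_skipped``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    tables = allele_freqs(gm, group_by)
    net = directional_migration(tables, index, filter_threshold)
    pops = net.populations
    labels = gm.labels(group_by)
    pop_indices = {
        pop: np.flatnonzero((labels == pop).to_numpy()) for pop in pops
    }
    all_ids = np.array(gm.individuals)

    reps: list[np.ndarray] = []
    skipped = 0
    for _ in range(n_boot):
        chosen: list[str] = []
        for pop in pops:
            idx = pop_indices[pop]
            chosen.extend(all_ids[rng.choice(idx, size=len(idx), replace=True)])
        boot_df = gm.df.loc[chosen].copy()
        boot_df.index = pd.Index(
            [f"b{i}" for i in range(len(chosen))], name="individual"
        )
        boot_gm = GenotypeMatrix(boot_df)
        boot_tables = allele_freqs(boot_gm, group_by)
        rep = directional_migration(boot_tables, index, filter_threshold)
        vals = rep.relative.to_numpy(dtype=float)
        if np.isnan(vals[~np.eye(len(pops), dtype=bool)]).all():
            skipped += 1
            continue
        reps.append(vals)
    if not reps:
        raise RuntimeError("all bootstrap replicates were degenerate")
    stack = np.stack(reps)  # (n_reps, n_pops, n_pops)

    support = pd.DataFrame(np.nan, index=pops, columns=pops)
    asym_rows = []
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i == j:
                continue
            support.loc[a, b] = float(
                np.mean(stack[:, i, j] >= filter_threshold)
            )
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if j <= i:
                continue
            diffs = stack[:, i, j] - stack[:, j, i]
            lo, hi = np.quantile(diffs, [alpha / 2, 1.0 - alpha / 2])
            significant = bool(lo > 0 or hi < 0)
            asym_rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "mean_diff": float(diffs.mean()),
                    "lo": float(lo),
                    "hi": float(hi),
                    "significant": significant,
                    "direction": a + "->" + b if diffs.mean() > 0 else b + "->" + a,
                }
            )
    net.boot_support = support
    net.asymmetry = pd.DataFrame(asym_rows)
    net.n_boot_skipped = skipped
    return net


def write_dot(net: MigrationNetwork, path: str | Path, threshold: float | None = None) -> None:
    """Write the filtered network as a GraphViz DOT file."""
    thr = net.filter_threshold if threshold is None else threshold
    lines = [f"digraph migration_{net.index} {{"]
    for pop in net.populations:
        lines.append(f'  "{pop}";')
    for a, b, w in filter_network(net, thr):
        lines.append(f'  "{a}" -> "{b}" [label="{w:.2f}", penwidth={1 + 4 * w:.2f}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(net: MigrationNetwork, path: str | Path, threshold: float | None = None) -> None:
    thr = net.filter_threshold if threshold is None else threshold
    with open(path, "w") as fh:
        fh.write("source\ttarget\trelative_migration\n")
        for a, b, w in filter_network(net, thr):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")
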