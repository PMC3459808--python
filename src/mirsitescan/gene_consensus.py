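"""Target-database consensus and disease-gene enrichment.

Links a candidate miRNA to a disease in two steps.  First, k-of-n voting
over n in-silico target databases (default 4 of 6) keeps genes predicted by
at least k lists; an experimentally validated list (Tarbase role) bypasses
the vote and is always included.  When only a single database covers the
miRNA, voting is bypassed and that list passes through whole.  Second, the
consensus target set is tested for association with a curated disease-gene
catalogue by a two-sided Fisher exact test over a stated gene universe.

The two-sided p-value follows the point-probability summation convention of
R's ``fisher.test`` default: the sum of hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's (within 1e-7 relative slack).  The sample odds ratio
(a*d)/(b*c) is always reported; the conditional MLE odds ratio is optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

__all__ = [
    "TargetDatabaseSet",
    "ContingencyTable",
    "EnrichmentResult",
    "knofn_consensus",
    "build_contingency",
    "fisher_two_sided",
    "enrich",
    "venn_counts",
    "load_database_tsv",
    "load_disease_tsv",
]

_REL_SLACK = 1e-7


@dataclass
class TargetDatabaseSet:
    """Named per-database gene lists plus an optional validated list."""

    databases: dict                 # name -> set of gene ids
    validated: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.databases = {k: set(v) for k, v in self.databases.items()}
        self.validated = set(self.validated)

    @property
    def n(self) -> int:
        return len(self.databases)

    @property
    def universe(self) -> set:
        u = set().union(*self.databases.values()) if self.databases else set()
        return u | self.validated


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts over a gene universe of size a+b+c+d."""

    a: int  # target & disease
    b: int  # target only
    c: int  # disease only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    pvalue: float
    odds_ratio: float                   # sample (a*d)/(b*c); inf if b*c == 0
    odds_ratio_cmle: float | None = None
    overlap: tuple = ()
    single_database: bool = False       # k-of-n bypassed (one covering list)


def knofn_consensus(dbset: TargetDatabaseSet, k: int, n: int | None = None) -> set:
    """Genes in >= k of the n prediction lists, plus every validated gene.

    With a single covering database the vote is bypassed (k-of-n is not
    meaningful) and that list is returned whole.
    """
    n = dbset.n if n is None else n
    if n != dbset.n:
        raise ValueError(f"n={n} does not match the {dbset.n} databases given")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if n == 1:
        (only,) = dbset.databases.values()
        return set(only) | dbset.validated
    counts: dict = {}
    for genes in dbset.databases.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= k} | dbset.validated


def build_contingency(
    universe_size: int, target_size: int, disease_size: int, overlap: int
) -> ContingencyTable:
    """2x2 table from the four set sizes; validates consistency."""
    if overlap > min(target_size, disease_size):
        raise ValueError("overlap exceeds a margin")
    if target_size + disease_size - overlap > universe_size:
        raise ValueError("sets do not fit in the universe")
    return ContingencyTable(
        a=overlap,
        b=target_size - overlap,
        c=disease_size - overlap,
        d=universe_size - target_size - disease_size + overlap,
    )


def fisher_two_sided(table: ContingencyTable) -> EnrichmentResult:
    """Two-sided Fisher exact test by hypergeometric summation.

    Conditional on the margins, the overlap count follows a hypergeometric
    law; the p-value sums the probabilities of every achievable table at
    most as probable as the observed one (R default convention).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.n
    K = a + c          # disease genes in the universe
    n_draw = a + b     # target-set size
    lo = max(0, n_draw + K - N)
    hi = min(n_draw, K)
    support = np.arange(lo, hi + 1)
    if len(support) == 1 or N == 0:
        p = 1.0
    else:
        pmf = hypergeom.pmf(support, N, K, n_draw)
        p_obs = hypergeom.pmf(a, N, K, n_draw)
        p = float(pmf[pmf <= p_obs * (1 + _REL_SLACK)].sum())
        p = min(1.0, p)
    orr = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(table=table, pvalue=p, odds_ratio=orr)


def enrich(
    targets: set,
    disease: set,
    universe: set,
    conditional_or: bool = False,
) -> EnrichmentResult:
    """Fisher enrichment of *targets* against *disease* within *universe*.

    Genes outside the universe are ignored; the overlap gene list is
    attached to the result.
    """
    targets = set(targets) & set(universe)
    disease = set(disease) & set(universe)
    overlap = targets & disease
    table = build_contingency(len(universe), len(targets), len(disease), len(overlap))
    res = fisher_two_sided(table)
    res.overlap = tuple(sorted(overlap))
    if conditional_or:
        res.odds_ratio_cmle = float(
            _cmle_odds_ratio(table.as_array(), kind="conditional").statistic
        )
    return res


def venn_counts(named_sets: dict) -> dict:
    """Sizes of every non-empty intersection of the named sets.

    Keys are '&'-joined sorted name tuples, e.g. ``"A&B"``; singletons give
    set sizes.  Mirrors a Venn-diagram summary (pairwise and higher-order
    overlaps).
    """
    from itertools import combinations

    names = sorted(named_sets)
    out = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(set(named_sets[n]) for n in combo))
            out["&".join(combo)] = len(inter)
    return out


def load_database_tsv(path: str | Path) -> dict:
    """Read a per-database target table (columns: mirna, database, geneid).

    Returns ``{mirna: {database: set(geneid)}}``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("mirna", "database", "geneid"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["mirna"], {}).setdefault(row["database"], set()).add(
            row["geneid"]
        )
    return out


def load_disease_tsv(path: str | Path) -> set:
    """Read a disease catalogue (column: geneid; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "geneid" not in df.columns:
        raise ValueError(f"{path}: missing column 'geneid'")
    return set(df["geneid"])
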