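"""Constraint-based seed-site finder.

Reports a binding site wherever the UTR carries a (near-)exact complement of
the miRNA seed and the full heteroduplex around it satisfies hard
constraints: a minimum number of paired-up bases and a maximum folding
energy.  Defaults mirror a stringent published configuration: seed extent 6
(anchored at miRNA position 2), zero unpaired bases within the seed extent,
at least 14 paired bases, folding energy at most -25 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

from .duplex import (
    PAIR_SYMBOL,
    WOBBLE_SYMBOL,
    DuplexSite,
    EnergyParameters,
    _rna,
    can_pair,
    default_energy_parameters,
    duplex_mfe,
)
from .seqio import GenomicInterval, UTRRecord, local_to_genomic

__all__ = ["SeedSiteConstraints", "find_seed_sites"]


@dataclass(frozen=True)
class SeedSiteConstraints:
    seed_extent: int = 6
    seed_anchor: int = 2          # first seed position, 1-based from miRNA 5'
    max_seed_unpaired: int = 0
    min_paired: int = 14
    max_energy: float = -25.0     # kcal/mol
    window_pad: int = 10          # fold window extends the seed match by
                                  # miRNA length + this many nt

    def __post_init__(self) -> None:
        if self.seed_extent < 1 or self.seed_anchor < 1:
            raise ValueError("seed extent and anchor must be >= 1")
        if self.max_seed_unpaired < 0 or self.min_paired < 1:
            raise ValueError("invalid pairing constraints")
        if self.max_energy > 0:
            raise ValueError("max folding energy must be <= 0")


def find_seed_sites(
    mirna_id: str,
    mirna,
    utr: UTRRecord,
    constraints: SeedSiteConstraints = SeedSiteConstraints(),
    params: EnergyParameters | None = None,
    program: str = "seedsite",
) -> list[DuplexSite]:
    """Sites passing the seed-complementarity and heteroduplex constraints.

    Every UTR window complementary to the seed with at most
    ``max_seed_unpaired`` unpaired seed bases is folded in full; it is
    reported iff paired bases >= ``min_paired`` and energy <= ``max_energy``.
    Overlapping windows collapse to the lowest-energy site.
    """
    params = params or default_energy_parameters()
    m = _rna(str(mirna.as_rna() if hasattr(mirna, "as_rna") else mirna))
    t = utr.seq.as_rna()
    c = constraints
    s0 = c.seed_anchor - 1
    if s0 + c.seed_extent > len(m):
        raise ValueError("seed extent exceeds miRNA length")
    seed_rev = m[s0:s0 + c.seed_extent][::-1]  # antiparallel match
    L = c.seed_extent
    sites: list[DuplexSite] = []
    for p in range(len(t) - L + 1):
        mismatches = sum(
            0 if can_pair(seed_rev[q], t[p + q], allow_gu=False) else 1
            for q in range(L)
        )
        if mismatches > c.max_seed_unpaired:
            continue
        up = len(m) - (s0 + L)
        w_lo = max(0, p - up - c.window_pad)
        w_hi = min(len(t), p + L + s0 + c.window_pad)
        res = duplex_mfe(m, t[w_lo:w_hi], params)
        if not res.pairs:
            continue
        paired = res.pairing.count(PAIR_SYMBOL) + res.pairing.count(WOBBLE_SYMBOL)
        if paired < c.min_paired or res.energy > c.max_energy:
            continue
        lo = w_lo + res.target_span[0] + 1
        hi = w_lo + res.target_span[1] + 1
        genomic = None
        if utr.interval is not None:
            g = sorted((local_to_genomic(lo, utr), local_to_genomic(hi, utr)))
            genomic = GenomicInterval(utr.interval.chrom, g[0], g[1],
                                      utr.interval.strand)
        sites.append(
            DuplexSite(
                program=program, mirna_id=mirna_id, utr_id=utr.id,
                local_start=lo, local_end=hi, pairing=res.pairing,
                energy=res.energy, paired=paired, genomic=genomic,
            )
        )
    sites.sort(key=lambda s: (s.energy, s.local_start))
    kept: list[DuplexSite] = []
    for s in sites:
        if not any(s.overlaps(k) for k in kept):
            kept.append(s)
    kept.sort(key=lambda s: s.local_start)
    return kept
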