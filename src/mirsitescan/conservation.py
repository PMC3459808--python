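"""Cross-species conservation of UTR regions and binding sites.

Works on a gapped multiple alignment of orthologous 3'UTRs with a designated
reference species (here: human).  A *conserved region* is a maximal run of
reference positions whose column is shared -- the reference's nucleotide
present, ungapped, in at least ``min_species`` members including the
reference -- for at least ``min_run`` consecutive reference positions.
Site conservation to a single species is percent identity over the site's
reference columns, a species gap counting as a mismatch, rounded half-up to
an integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import AlignmentSet

__all__ = [
    "ConservationPolicy",
    "ConservationProfile",
    "conserved_regions",
    "site_identity",
    "is_site_conserved",
    "round_half_up_percent",
]


@dataclass(frozen=True)
class ConservationPolicy:
    min_species: int = 7   # including the reference
    min_run: int = 10      # consecutive conserved reference positions

    def __post_init__(self) -> None:
        if self.min_species < 2:
            raise ValueError("min_species must be >= 2")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class ConservationProfile:
    site: tuple[int, int]                  # reference interval, 1-based
    identity: dict[str, int]               # species -> percent
    conserved: bool


def round_half_up_percent(matches: int, length: int) -> int:
    """Percent identity rounded half-up (93.75 -> 94, 87.5 -> 88)."""
    if length < 1 or matches < 0 or matches > length:
        raise ValueError("invalid match count")
    return int(math.floor(matches / length * 100 + 0.5))


def _reference_columns(msa: AlignmentSet) -> list[int]:
    """Alignment column index of each ungapped reference position."""
    ref = msa.sequences[msa.reference]
    return [i for i, c in enumerate(ref) if c != "-"]


def conserved_regions(
    msa: AlignmentSet, policy: ConservationPolicy = ConservationPolicy()
) -> list[tuple[int, int]]:
    """Maximal conserved runs, as 1-based inclusive reference intervals.

    A column counts as conserved when at least ``policy.min_species``
    members (reference included) carry the reference's nucleotide.
    """
    if policy.min_species > len(msa.sequences):
        raise ValueError(
            f"min_species {policy.min_species} exceeds alignment size "
            f"{len(msa.sequences)}"
        )
    ref = msa.sequences[msa.reference]
    cols = _reference_columns(msa)
    rows = list(msa.sequences.values())
    conserved = []
    for col in cols:
        base = ref[col]
        n = sum(1 for row in rows if row[col] == base)
        conserved.append(n >= policy.min_species)
    regions = []
    start = None
    for pos, ok in enumerate(conserved, start=1):
        if ok and start is None:
            start = pos
        elif not ok and start is not None:
            if pos - start >= policy.min_run:
                regions.append((start, pos - 1))
            start = None
    if start is not None and len(conserved) - start + 1 >= policy.min_run:
        regions.append((start, len(conserved)))
    return regions


def site_identity(msa: AlignmentSet, site: tuple[int, int], species: str) -> int:
    """Percent identity of *species* to the reference over *site*.

    *site* is a 1-based inclusive interval on the ungapped reference
    sequence; species gaps count as mismatches.
    """
    if species not in msa.sequences:
        raise KeyError(f"species {species!r} not in alignment")
    lo, hi = site
    cols = _reference_columns(msa)
    if lo < 1 or hi > len(cols) or lo > hi:
        raise ValueError(f"site {site} outside reference length {len(cols)}")
    ref = msa.sequences[msa.reference]
    other = msa.sequences[species]
    matches = sum(
        1 for pos in range(lo, hi + 1)
        if other[cols[pos - 1]] == ref[cols[pos - 1]]
    )
    return round_half_up_percent(matches, hi - lo + 1)


def is_site_conserved(
    site: tuple[int, int],
    regions: list[tuple[int, int]],
    msa: AlignmentSet | None = None,
) -> ConservationProfile | bool:
    """True iff *site* lies entirely inside one conserved region.

    With *msa* given, returns a :class:`ConservationProfile` carrying the
    per-species identity percentages as well.
    """
    lo, hi = site
    flag = any(r_lo <= lo and hi <= r_hi for r_lo, r_hi in regions)
    if msa is None:
        return flag
    identity = {sp: site_identity(msa, site, sp) for sp in msa.species}
    return ConservationProfile(site=site, identity=identity, conserved=flag)
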