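"""Complementarity local alignment of a miRNA against a 3'UTR.

This engine aligns the miRNA read 3'->5' against the UTR read 5'->3' with a
Smith-Waterman-style dynamic program whose substitution scores reward
complementarity (A=U, G=C Watson-Crick; G:U wobble scored weakly) rather than
identity.  Gaps are affine.  Columns that fall on miRNA 5'-region positions
(default 2-8) have their substitution scores multiplied by a scaling factor
after alignment, reflecting the dominant contribution of seed pairing; the
score threshold applies to the scaled score.

A seed-quality rule mirrors the engine this emulates: at most one G:U wobble
is tolerated in the seed, and only when compensated by consecutive
Watson-Crick pairs in the miRNA 3' region.  Surviving sites are annotated
with (and filtered on) their duplex minimum free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .duplex import (
    GAP_MIRNA,
    GAP_TARGET,
    PAIR_SYMBOL,
    WOBBLE_SYMBOL,
    DuplexSite,
    EnergyParameters,
    _WC,
    _WOBBLE,
    _rna,
    default_energy_parameters,
    duplex_mfe,
)
from .seqio import GenomicInterval, UTRRecord, local_to_genomic

__all__ = [
    "ComplementarityScoring",
    "AlignedSite",
    "align_complementarity",
    "enforce_seed_wobble_rule",
    "filter_by_energy",
    "run_complement_engine",
]

MISMATCH_SYMBOL = "x"


@dataclass(frozen=True)
class ComplementarityScoring:
    """Scores, thresholds and the 5'-region scaling rule."""

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    score_threshold: float = 50.0
    energy_threshold: float = -20.0
    scale_factor: float = 4.0
    scaled_region: tuple[int, int] = (2, 8)     # miRNA positions, 1-based 5'
    comp_window: tuple[int, int] = (13, 16)     # 3' compensation window
    comp_min_consecutive: int = 4

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.scale_factor < 1:
            raise ValueError("scale factor must be >= 1")
        if self.energy_threshold > 0:
            raise ValueError("energy threshold must be <= 0")


@dataclass
class AlignedSite:
    """One local complementarity alignment between a miRNA and a UTR window.

    ``columns`` holds (mirna_pos, target_pos, symbol) per alignment column;
    positions are 1-based (miRNA from its 5' end) or None inside gaps.
    """

    mirna_id: str
    utr_id: str
    local_start: int
    local_end: int
    mirna_start: int   # 5'-most aligned miRNA position
    mirna_end: int
    columns: list
    raw_score: float
    score: float       # after 5'-region scaling

    @property
    def pairing(self) -> str:
        return "".join(sym for _, _, sym in self.columns)

    @property
    def paired(self) -> int:
        return sum(1 for _, _, s in self.columns if s in (PAIR_SYMBOL, WOBBLE_SYMBOL))


def _col_score(a: str, b: str, sc: ComplementarityScoring) -> tuple[float, str]:
    p = (a, b)
    if p in _WC:
        return sc.match, PAIR_SYMBOL
    if p in _WOBBLE:
        return sc.wobble, WOBBLE_SYMBOL
    return sc.mismatch, MISMATCH_SYMBOL


def _scaled_score(columns, sc: ComplementarityScoring) -> float:
    """Re-score columns, scaling substitution columns in the 5' region."""
    lo, hi = sc.scaled_region
    total = 0.0
    for mpos, tpos, sym in columns:
        if sym == GAP_TARGET or sym == GAP_MIRNA:
            continue  # gap run costs added separately
        s, _ = (sc.match, None) if sym == PAIR_SYMBOL else \
               (sc.wobble, None) if sym == WOBBLE_SYMBOL else (sc.mismatch, None)
        if mpos is not None and lo <= mpos <= hi:
            s *= sc.scale_factor
        total += s
    # affine gap costs, unscaled
    prev = None
    for _, _, sym in columns:
        if sym in (GAP_TARGET, GAP_MIRNA):
            total += sc.gap_extend if sym == prev else sc.gap_open
            prev = sym
        else:
            prev = None
    return total


def _best_local_alignment(mr: str, t: str, j_lo: int, j_hi: int,
                          sc: ComplementarityScoring):
    """Gotoh local alignment of reversed miRNA *mr* vs t[j_lo:j_hi].

    Returns (raw_score, columns, t_start, t_end) with target positions
    0-based absolute, or None if no positive-scoring alignment exists.
    """
    seg = t[j_lo:j_hi]
    M, N = len(mr), len(seg)
    if N == 0:
        return None
    NEG = float("-inf")
    H = [[0.0] * (N + 1) for _ in range(M + 1)]
    E = [[NEG] * (N + 1) for _ in range(M + 1)]   # gap in miRNA (target unpaired)
    F = [[NEG] * (N + 1) for _ in range(M + 1)]   # gap in target (miRNA unpaired)
    bt = [[None] * (N + 1) for _ in range(M + 1)]
    best, bi, bj = 0.0, None, None
    for i in range(1, M + 1):
        for j in range(1, N + 1):
            E[i][j] = max(H[i][j - 1] + sc.gap_open, E[i][j - 1] + sc.gap_extend)
            F[i][j] = max(H[i - 1][j] + sc.gap_open, F[i - 1][j] + sc.gap_extend)
            s, _ = _col_score(mr[i - 1], seg[j - 1], sc)
            diag = H[i - 1][j - 1] + s
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0:
                bt[i][j] = None
            elif h == diag:
                bt[i][j] = "d"
            elif h == E[i][j]:
                bt[i][j] = "e"
            else:
                bt[i][j] = "f"
            if h > best:
                best, bi, bj = h, i, j
    if bi is None:
        return None
    # traceback
    cols = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0 and bt[i][j] is not None:
        move = bt[i][j]
        if move == "d":
            _, sym = _col_score(mr[i - 1], seg[j - 1], sc)
            cols.append((i, j, sym))
            i, j = i - 1, j - 1
        elif move == "e":
            # consume target bases until the gap opened
            while True:
                cols.append((None, j, GAP_TARGET))
                if E[i][j] == H[i][j - 1] + sc.gap_open or j == 1:
                    j -= 1
                    break
                j -= 1
        else:
            while True:
                cols.append((i, None, GAP_MIRNA))
                if F[i][j] == H[i - 1][j] + sc.gap_open or i == 1:
                    i -= 1
                    break
                i -= 1
    cols.reverse()
    t_start = j_lo + min(c[1] for c in cols if c[1] is not None) - 1
    t_end = j_lo + max(c[1] for c in cols if c[1] is not None) - 1
    return best, cols, t_start, t_end


def align_complementarity(
    mirna_id: str,
    mirna,
    utr: UTRRecord,
    scoring: ComplementarityScoring = ComplementarityScoring(),
) -> list[AlignedSite]:
    """All maximal non-overlapping local complementarity optima >= threshold.

    The best alignment is extracted, the target is split around its
    footprint, and the flanks are searched recursively; scaled scores below
    the threshold are discarded at the end.
    """
    m = _rna(str(mirna.as_rna() if hasattr(mirna, "as_rna") else mirna))
    t = utr.seq.as_rna()
    mr = m[::-1]  # miRNA 3'->5' against target 5'->3'
    L = len(m)
    # raw-score floor: scaling multiplies a subset of columns by scale_factor,
    # so scaled <= raw * scale_factor; anything below this cannot pass
    floor = scoring.score_threshold / scoring.scale_factor
    found = []

    def search(j_lo: int, j_hi: int) -> None:
        res = _best_local_alignment(mr, t, j_lo, j_hi, scoring)
        if res is None or res[0] < floor:
            return
        raw, cols, t_start, t_end = res
        # reversed-miRNA index i -> original 5'-based position L - i + 1
        cols = [
            (L - c[0] + 1 if c[0] is not None else None,
             c[1] + j_lo if c[1] is not None else None,
             c[2])
            for c in cols
        ]
        mpos = [c[0] for c in cols if c[0] is not None]
        site = AlignedSite(
            mirna_id=mirna_id, utr_id=utr.id,
            local_start=t_start + 1, local_end=t_end + 1,
            mirna_start=min(mpos), mirna_end=max(mpos),
            columns=cols, raw_score=raw,
            score=_scaled_score(cols, scoring),
        )
        found.append(site)
        search(j_lo, t_start)
        search(t_end + 1, j_hi)

    search(0, len(t))
    kept = [s for s in found if s.score >= scoring.score_threshold]
    kept.sort(key=lambda s: (-s.score, s.local_start))
    return kept


def enforce_seed_wobble_rule(
    site: AlignedSite, scoring: ComplementarityScoring = ComplementarityScoring()
) -> tuple[bool, str]:
    """Accept/reject a site on seed pairing quality.

    The seed region (``scoring.scaled_region``) must be fully paired with no
    mismatch or gap; one G:U wobble is tolerated if compensated by at least
    ``comp_min_consecutive`` consecutive Watson-Crick pairs inside
    ``comp_window`` on the miRNA 3' side.
    """
    lo, hi = scoring.scaled_region
    by_pos = {c[0]: c[2] for c in site.columns if c[0] is not None}
    gap_positions = {c[0] for c in site.columns if c[0] is not None and c[2] == GAP_MIRNA}
    wobbles = 0
    for pos in range(lo, hi + 1):
        sym = by_pos.get(pos)
        if sym is None:
            return False, "seed incomplete"
        if sym == MISMATCH_SYMBOL or pos in gap_positions or sym == GAP_MIRNA:
            return False, "seed mismatch/gap"
        if sym == WOBBLE_SYMBOL:
            wobbles += 1
    # target-side gaps between seed columns also break the seed helix
    seed_cols = [c for c in site.columns
                 if (c[0] is not None and lo <= c[0] <= hi) or c[2] == GAP_TARGET]
    in_seed = False
    for c in site.columns:
        if c[0] is not None and lo <= c[0] <= hi:
            in_seed = True
        elif c[0] is not None:
            in_seed = False
        elif in_seed and c[2] == GAP_TARGET:
            return False, "seed mismatch/gap"
    del seed_cols
    if wobbles > 1:
        return False, "seed wobble count"
    if wobbles == 1:
        wlo, whi = scoring.comp_window
        run = best_run = 0
        for pos in range(wlo, whi + 1):
            if by_pos.get(pos) == PAIR_SYMBOL:
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        if best_run < scoring.comp_min_consecutive:
            return False, "uncompensated seed wobble"
    return True, "ok"


def filter_by_energy(
    sites: list[AlignedSite],
    mirna,
    utr: UTRRecord,
    params: EnergyParameters | None = None,
    threshold: float = -20.0,
    pad: int = 5,
    program: str = "complement",
) -> list[DuplexSite]:
    """Annotate sites with duplex MFE and keep those at or below *threshold*."""
    if threshold > 0:
        raise ValueError("energy threshold must be <= 0")
    params = params or default_energy_parameters()
    t = utr.seq.as_rna()
    out = []
    for s in sites:
        w_lo = max(0, s.local_start - 1 - pad)
        w_hi = min(len(t), s.local_end + pad)
        res = duplex_mfe(mirna, t[w_lo:w_hi], params)
        if not res.pairs or res.energy > threshold:
            continue
        genomic = None
        if utr.interval is not None:
            g = sorted((local_to_genomic(s.local_start, utr),
                        local_to_genomic(s.local_end, utr)))
            genomic = GenomicInterval(utr.interval.chrom, g[0], g[1],
                                      utr.interval.strand)
        out.append(
            DuplexSite(
                program=program, mirna_id=s.mirna_id, utr_id=s.utr_id,
                local_start=s.local_start, local_end=s.local_end,
                pairing=s.pairing, energy=res.energy, paired=s.paired,
                genomic=genomic, score=s.score,
            )
        )
    return out


def run_complement_engine(
    mirna_id: str,
    mirna,
    utr: UTRRecord,
    scoring: ComplementarityScoring = ComplementarityScoring(),
    params: EnergyParameters | None = None,
) -> list[DuplexSite]:
    """Full engine: align, apply the seed-wobble rule, filter on energy."""
    sites = align_complementarity(mirna_id, mirna, utr, scoring)
    sites = [s for s in sites if enforce_seed_wobble_rule(s, scoring)[0]]
    return filter_by_energy(sites, mirna, utr, params, scoring.energy_threshold)
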