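"""Intermolecular miRNA:target duplex energy minimization and site statistics.

The hybridization model forbids intramolecular pairs and branching: a duplex
is a set of miRNA:target base pairs that is monotone on both strands
(antiparallel, no pseudoknots).  Its free energy is the sum of published
nearest-neighbor stacking increments for adjacent pairs, a single affine
penalty (``loop_init + loop_per_nt * u``) for every bulge/internal loop with
``u`` total unpaired bases, a duplex initiation penalty, and a terminal
penalty for helix ends closed by A:U or G:U pairs.  Energies are handled
internally in integer units of 0.01 kcal/mol, so equal-energy structures tie
exactly and the documented tie-break (more paired bases, then 5'-most target
position) is deterministic.

A hybridization scan uses the seed-match speed-up: the full duplex is only
computed around windows where the complement of the miRNA seed occurs in the
target.  Site significance follows extreme-value statistics of
length-normalized minimum free energies, with a Poisson approximation for
multiple binding sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import yaml
from scipy.stats import poisson

from .seqio import GenomicInterval, NucleotideSequence, UTRRecord, local_to_genomic

__all__ = [
    "EnergyParameters",
    "SeedPolicy",
    "EvdParameters",
    "DuplexSite",
    "DuplexResult",
    "duplex_mfe",
    "scan_hybridization",
    "evd_pvalue",
    "poisson_multisite",
    "find_seed_matches",
]

PAIR_SYMBOL = "|"      # Watson-Crick pair
WOBBLE_SYMBOL = ":"    # G:U pair
GAP_TARGET = "."       # unpaired target base inside the duplex
GAP_MIRNA = "-"        # unpaired miRNA base inside the duplex

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}
_CANONICAL = _WC | _WOBBLE

_INF = 1 << 30


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    """True if bases *a* and *b* (either alphabet) can form a pair."""
    p = (_rna(a), _rna(b))
    return p in _CANONICAL if allow_gu else p in _WC


@dataclass(frozen=True)
class EnergyParameters:
    """Nearest-neighbor stacking table plus affine loop and end terms.

    ``stack[(P1, P2)]`` is the increment (kcal/mol) of the step whose left
    pair, written miRNA-base/target-base, is ``P1`` and right pair ``P2``.
    """

    stack: dict
    loop_init: float
    loop_per_nt: float
    duplex_init: float
    terminal_au: float
    version: str = "unversioned"
    # integer tables in centi-kcal, derived once
    _istack: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for (p1, p2), e in self.stack.items():
            if p1 in ("AU", "UA", "CG", "GC") and p2 in ("AU", "UA", "CG", "GC"):
                if e >= 0:
                    raise ValueError(f"Watson-Crick stack {p1}/{p2} must be negative")
        if self.loop_init < 0 or self.loop_per_nt < 0:
            raise ValueError("loop penalties must be non-negative")
        object.__setattr__(
            self,
            "_istack",
            {k: round(v * 100) for k, v in self.stack.items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "EnergyParameters":
        """Load parameters; with no path, the packaged Turner-2004 table."""
        if path is None:
            text = (
                resources.files("mirsitescan.data")
                .joinpath("energy_params.yaml")
                .read_text()
            )
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        stack = {
            (p1, p2): float(e)
            for p1, row in raw["stack"].items()
            for p2, e in row.items()
        }
        return cls(
            stack=stack,
            loop_init=float(raw["loop_init"]),
            loop_per_nt=float(raw["loop_per_nt"]),
            duplex_init=float(raw["duplex_init"]),
            terminal_au=float(raw["terminal_au"]),
            version=str(raw.get("version", "unversioned")),
        )


_DEFAULT_PARAMS: EnergyParameters | None = None


def default_energy_parameters() -> EnergyParameters:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = EnergyParameters.from_yaml()
    return _DEFAULT_PARAMS


@dataclass(frozen=True)
class SeedPolicy:
    """Which miRNA positions nucleate a site and whether G:U may seed-match.

    ``start`` counts from the miRNA 5' end, 1-based; the canonical seed is
    positions 2-8, and the default window here is positions 2-7.
    """

    start: int = 2
    length: int = 6
    allow_gu: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.length < 1:
            raise ValueError("seed start and length must be >= 1")


@dataclass(frozen=True)
class EvdParameters:
    """Gumbel location/shape for length-normalized energy statistics."""

    location: float = 1.9
    shape: float = 0.28

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("EVD shape must be > 0")


@dataclass
class DuplexSite:
    """One predicted miRNA:UTR heteroduplex site."""

    program: str
    mirna_id: str
    utr_id: str
    local_start: int          # 1-based inclusive on the UTR
    local_end: int
    pairing: str
    energy: float             # kcal/mol
    paired: int
    genomic: GenomicInterval | None = None
    score: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.energy > 0:
            raise ValueError("reported sites must have energy <= 0")
        n_sym = self.pairing.count(PAIR_SYMBOL) + self.pairing.count(WOBBLE_SYMBOL)
        if n_sym != self.paired:
            raise ValueError("paired count inconsistent with pairing string")

    @property
    def local_interval(self) -> tuple[int, int]:
        return (self.local_start, self.local_end)

    def overlaps(self, other: "DuplexSite") -> bool:
        return (
            self.utr_id == other.utr_id
            and self.local_start <= other.local_end
            and other.local_start <= self.local_end
        )


class DuplexResult(NamedTuple):
    """MFE duplex of one miRNA against one target window."""

    energy: float
    pairing: str
    pairs: tuple        # ((mirna_idx, target_idx), ...) 0-based, target 5'->3'
    target_span: tuple  # (start, end) 0-based inclusive on the window, or None
    mirna_span: tuple


_EMPTY = DuplexResult(0.0, "", (), None, None)


def _seq_str(seq) -> str:
    if isinstance(seq, NucleotideSequence):
        return seq.as_rna()
    return _rna(str(seq))


def duplex_mfe(mirna, target, params: EnergyParameters | None = None) -> DuplexResult:
    """Minimum-free-energy intermolecular duplex of *mirna* vs *target*.

    Returns a :class:`DuplexResult`; ``energy`` is 0.0 with an empty pairing
    string when no structure achieves negative free energy.  Ties are broken
    toward more paired bases, then toward the 5'-most target position.
    """
    params = params or default_energy_parameters()
    m = _seq_str(mirna)
    t = _seq_str(target)
    if not m or not t:
        raise ValueError("sequences must be non-empty")
    for s in (m, t):
        bad = set(s) - set("ACGUN")
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}")

    r = t[::-1]  # walk the target 3'->5' so both strand indices increase
    M, N = len(m), len(r)
    istack = params._istack
    init = round(params.duplex_init * 100)
    loop_init = round(params.loop_init * 100)
    per_nt = round(params.loop_per_nt * 100)
    term = round(params.terminal_au * 100)

    def pair_key(i: int, k: int) -> str | None:
        p = m[i] + r[k]
        return p if (m[i], r[k]) in _CANONICAL else None

    def end_pen(key: str) -> int:
        return term if key in ("AU", "UA", "GU", "UG") else 0

    # DP over (energy_centikcal, -paired) tuples.
    # P[i][k]: best structure whose last pair is (i,k); includes initiation and
    # the left-terminal penalty, not the right one.  Q[i][k]: best
    # P[i'][k'] + loop_init + per_nt*((i-i')+(k-k')) over pairs (i',k') <= (i,k).
    NONE = (_INF, 0)
    P = [[NONE] * N for _ in range(M)]
    Q = [[NONE] * N for _ in range(M)]
    bp_P = [[None] * N for _ in range(M)]   # "new" | "stack" | "loop"
    bp_Q = [[None] * N for _ in range(M)]   # "pair" | "up" | "left"

    for i in range(M):
        for k in range(N):
            key = pair_key(i, k)
            if key is not None:
                best = (init + end_pen(key), -1)
                choice = "new"
                if i > 0 and k > 0:
                    prev = P[i - 1][k - 1]
                    pkey = pair_key(i - 1, k - 1)
                    if prev is not NONE and pkey is not None:
                        cand = (prev[0] + istack[(pkey, key)], prev[1] - 1)
                        if cand < best:
                            best, choice = cand, "stack"
                    qprev = Q[i - 1][k - 1]
                    if qprev[0] < _INF:
                        cand = (qprev[0], qprev[1] - 1)
                        if cand < best:
                            best, choice = cand, "loop"
                P[i][k] = best
                bp_P[i][k] = choice
            # Q recurrence
            qbest, qchoice = NONE, None
            if P[i][k][0] < _INF:
                qbest, qchoice = (P[i][k][0] + loop_init, P[i][k][1]), "pair"
            if i > 0 and Q[i - 1][k][0] < _INF:
                cand = (Q[i - 1][k][0] + per_nt, Q[i - 1][k][1])
                if cand < qbest:
                    qbest, qchoice = cand, "up"
            if k > 0 and Q[i][k - 1][0] < _INF:
                cand = (Q[i][k - 1][0] + per_nt, Q[i][k - 1][1])
                if cand < qbest:
                    qbest, qchoice = cand, "left"
            Q[i][k] = qbest
            bp_Q[i][k] = qchoice

    # Closing: add the right-terminal penalty; among ties prefer more pairs,
    # then the 5'-most target position (largest k of the final pair).
    best = (NONE, None)
    for i in range(M):
        for k in range(N):
            if P[i][k][0] >= _INF:
                continue
            key = pair_key(i, k)
            val = (P[i][k][0] + end_pen(key), P[i][k][1])
            if val < best[0] or (val == best[0] and best[1] is not None
                                 and k > best[1][1]):
                best = (val, (i, k))
    if best[1] is None or best[0][0] >= 0:
        return _EMPTY

    # traceback
    pairs_rev = []
    i, k = best[1]
    state = "P"
    while True:
        if state == "P":
            pairs_rev.append((i, k))
            move = bp_P[i][k]
            if move == "new":
                break
            i, k = i - 1, k - 1
            state = "P" if move == "stack" else "Q"
        else:
            move = bp_Q[i][k]
            if move == "pair":
                state = "P"
            elif move == "up":
                i -= 1
            else:
                k -= 1
    pairs = pairs_rev[::-1]

    # pairing string: one column per position between the first and last pair
    cols = []
    for idx, (pi, pk) in enumerate(pairs):
        if idx:
            qi, qk = pairs[idx - 1]
            cols.extend(GAP_MIRNA * (pi - qi - 1))
            cols.extend(GAP_TARGET * (pk - qk - 1))
        sym = PAIR_SYMBOL if (m[pi], r[pk]) in _WC else WOBBLE_SYMBOL
        cols.append(sym)
    # convert reversed-target indices back to 5'->3' target coordinates
    tpairs = tuple((pi, N - 1 - pk) for pi, pk in pairs)
    t_lo = min(j for _, j in tpairs)
    t_hi = max(j for _, j in tpairs)
    m_lo = min(i for i, _ in tpairs)
    m_hi = max(i for i, _ in tpairs)
    return DuplexResult(
        energy=best[0][0] / 100.0,
        pairing="".join(cols),
        pairs=tpairs,
        target_span=(t_lo, t_hi),
        mirna_span=(m_lo, m_hi),
    )


def find_seed_matches(mirna, target, seed: SeedPolicy) -> list[int]:
    """0-based target start positions whose window complements the seed.

    The seed (miRNA positions ``start..start+length-1`` from the 5' end)
    pairs antiparallel, so the target window is compared against the seed
    read 3'->5'.  G:U counts as a match only under ``seed.allow_gu``.
    """
    m = _seq_str(mirna)
    t = _seq_str(target)
    s0 = seed.start - 1
    if s0 + seed.length > len(m):
        raise ValueError("seed window exceeds miRNA length")
    seed_rev = m[s0:s0 + seed.length][::-1]
    L = seed.length
    hits = []
    for p in range(len(t) - L + 1):
        if all(can_pair(seed_rev[q], t[p + q], seed.allow_gu) for q in range(L)):
            hits.append(p)
    return hits


def scan_hybridization(
    mirna_id: str,
    mirna,
    utr: UTRRecord,
    params: EnergyParameters | None = None,
    seed: SeedPolicy = SeedPolicy(),
    energy_cutoff: float = -20.0,
    evd: EvdParameters | None = None,
    window_pad: int = 10,
    max_window: int = 60,
    program: str = "hybrid",
) -> list[DuplexSite]:
    """Seed-anchored energy scan of one miRNA against one UTR.

    Full duplex folding runs only around seed matches; a site is reported
    when its window MFE is at or below *energy_cutoff*.  Overlapping sites
    keep the lower energy (ties: 5'-most).  Sites are sorted by energy
    ascending; with *evd* given, each carries a Gumbel p-value.
    """
    if energy_cutoff > 0:
        raise ValueError("energy cutoff must be <= 0")
    params = params or default_energy_parameters()
    m = _seq_str(mirna)
    t = utr.seq.as_rna()
    sites: list[DuplexSite] = []
    s0 = seed.start - 1
    for p in find_seed_matches(m, t, seed):
        # miRNA 3' tail pairs upstream of the seed match, 5' head downstream
        up = len(m) - (s0 + seed.length)
        w_lo = max(0, p - up - window_pad)
        w_hi = min(len(t), p + seed.length + s0 + window_pad)
        if w_hi - w_lo > max_window:
            w_lo = max(0, w_hi - max_window)
        res = duplex_mfe(m, t[w_lo:w_hi], params)
        if not res.pairs or res.energy > energy_cutoff:
            continue
        lo = w_lo + res.target_span[0] + 1
        hi = w_lo + res.target_span[1] + 1
        genomic = None
        if utr.interval is not None:
            g = sorted((local_to_genomic(lo, utr), local_to_genomic(hi, utr)))
            genomic = GenomicInterval(utr.interval.chrom, g[0], g[1],
                                      utr.interval.strand)
        pval = None
        if evd is not None:
            pval = evd_pvalue(res.energy, len(m), len(utr), evd)
        sites.append(
            DuplexSite(
                program=program, mirna_id=mirna_id, utr_id=utr.id,
                local_start=lo, local_end=hi, pairing=res.pairing,
                energy=res.energy,
                paired=res.pairing.count(PAIR_SYMBOL)
                + res.pairing.count(WOBBLE_SYMBOL),
                genomic=genomic, pvalue=pval,
            )
        )
    # resolve overlaps: lower energy wins, ties 5'-most
    sites.sort(key=lambda s: (s.energy, s.local_start))
    kept: list[DuplexSite] = []
    for s in sites:
        if not any(s.overlaps(k) for k in kept):
            kept.append(s)
    return kept


def evd_pvalue(energy: float, mirna_len: int, utr_len: int,
               evd: EvdParameters = EvdParameters()) -> float:
    """Gumbel p-value of a length-normalized duplex energy.

    The statistic is ``s = -energy / ln(mirna_len * utr_len)`` and
    ``p = 1 - exp(-exp(-(s - location)/shape))``: the survival function of
    the extreme-value distribution of minimum free energies.
    """
    if energy > 0:
        raise ValueError("energy must be <= 0")
    if mirna_len < 1 or utr_len < 1 or mirna_len * utr_len <= 1:
        raise ValueError("sequence lengths must satisfy m*n > 1")
    s = -energy / math.log(mirna_len * utr_len)
    return float(1.0 - math.exp(-math.exp(-(s - evd.location) / evd.shape)))


def poisson_multisite(p_single: float, k: int) -> float:
    """Combined p-value for observing >= k sites, Poisson approximation.

    With ``lambda = -ln(1 - p_single)`` the single-site p-value is recovered
    exactly at k = 1.
    """
    if not 0 <= p_single < 1:
        raise ValueError("p_single must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    lam = -math.log1p(-p_single)
    return float(poisson.sf(k - 1, lam))
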