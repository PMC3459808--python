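"""Merge per-engine sites into per-miRNA candidates and rank them.

Candidates are miRNAs supported by a minimum number of prediction engines
(default 2 of 3).  Each carries its per-engine best binding energies, their
arithmetic mean (rounded half-up to 2 decimals), the number of distinct
binding loci, external evidence flags (AD-differential tissues, brain
expression, literature, mouse-UTR support, database support) and a
conserved-site flag.  Ranking is a stable lexicographic sort: engine count,
then count of positive evidence flags, then zebrafish conservation, then
mean energy, then miRNA id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .duplex import DuplexSite

__all__ = [
    "CriteriaAnnotation",
    "CandidateSummary",
    "merge_predictions",
    "mean_energy",
    "rank_candidates",
    "annotations_from_tables",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class CriteriaAnnotation:
    """External selection-criteria evidence for one miRNA.

    Flags are tri-state: True/False/None (unknown).
    """

    ad_tissues: tuple = ()
    brain_expression: bool | None = None
    literature_ad: bool | None = None
    mouse_support: bool | None = None
    targetscan: bool | None = None
    microrna_db: bool | None = None
    zebrafish: bool | None = None

    @property
    def evidence_count(self) -> int:
        flags = (
            bool(self.ad_tissues),
            self.brain_expression is True,
            self.literature_ad is True,
            self.mouse_support is True,
            self.targetscan is True,
            self.microrna_db is True,
        )
        return sum(flags)


@dataclass
class CandidateSummary:
    mirna_id: str
    programs: tuple                      # supporting engine tags, sorted
    energies: dict                       # engine -> best (lowest) energy
    mean_energy: float                   # 2-decimal half-up mean
    site_count: int                      # distinct binding loci
    annotation: CriteriaAnnotation = field(default_factory=CriteriaAnnotation)
    conserved: bool | None = None
    rank: int | None = None

    @property
    def program_count(self) -> int:
        return len(self.programs)

    @property
    def multiple_sites(self) -> bool:
        return self.site_count >= 2


def mean_energy(energies) -> float:
    """Arithmetic mean in kcal/mol, rounded half-up to 2 decimals."""
    vals = list(energies)
    if not vals:
        raise ValueError("no energies to average")
    mean = sum(Decimal(str(v)) for v in vals) / len(vals)
    return float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _cluster_loci(sites: list[DuplexSite]) -> list[list[DuplexSite]]:
    """Group sites of one miRNA/UTR into loci by interval overlap."""
    loci: list[list[DuplexSite]] = []
    for s in sorted(sites, key=lambda x: (x.local_start, x.local_end)):
        if loci and any(s.overlaps(o) for o in loci[-1]):
            loci[-1].append(s)
        else:
            loci.append([s])
    return loci


def merge_predictions(
    sites_by_program: dict,
    min_programs: int = 2,
    policy: str = "per-mirna",
) -> list[CandidateSummary]:
    """One candidate per miRNA supported by >= *min_programs* engines.

    ``policy="per-mirna"`` counts every engine that reports any site for the
    miRNA; ``policy="per-locus"`` requires the engines to agree on an
    overlapping locus and counts the best-supported locus.
    """
    if policy not in ("per-mirna", "per-locus"):
        raise ValueError(f"unknown support policy {policy!r}")
    by_mirna: dict[str, list[DuplexSite]] = {}
    for program, sites in sites_by_program.items():
        for s in sites:
            if s.program != program:
                s = replace(s) if False else s  # tags are advisory
            by_mirna.setdefault(s.mirna_id, []).append(s)
    out = []
    for mirna_id in sorted(by_mirna):
        sites = by_mirna[mirna_id]
        loci = _cluster_loci(sites)
        if policy == "per-mirna":
            programs = sorted({s.program for s in sites})
        else:
            best_locus = max(loci, key=lambda l: len({s.program for s in l}))
            programs = sorted({s.program for s in best_locus})
        if len(programs) < min_programs:
            continue
        energies = {}
        for s in sites:
            if s.program in programs:
                e = energies.get(s.program)
                energies[s.program] = s.energy if e is None else min(e, s.energy)
        out.append(
            CandidateSummary(
                mirna_id=mirna_id,
                programs=tuple(programs),
                energies=energies,
                mean_energy=mean_energy(energies.values()),
                site_count=len(loci),
            )
        )
    return out


def rank_candidates(candidates: list[CandidateSummary]) -> list[CandidateSummary]:
    """Stable total-order ranking; ties broken finally by miRNA id."""
    ranked = sorted(
        candidates,
        key=lambda c: (
            -c.program_count,
            -c.annotation.evidence_count,
            -(1 if (c.annotation.zebrafish or False) else 0),
            c.mean_energy,
            c.mirna_id,
        ),
    )
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def annotations_from_tables(
    mirna_ids,
    tissues_tsv: str | Path | None = None,
    brain_tsv: str | Path | None = None,
    literature_tsv: str | Path | None = None,
    mouse_supported=(),
    targetscan=(),
    microrna_db=(),
    zebrafish=(),
) -> dict[str, CriteriaAnnotation]:
    """Build per-miRNA annotations from plain TSV evidence tables.

    ``tissues_tsv`` needs columns ``mirna``/``tissue`` (one row per pair);
    ``brain_tsv`` and ``literature_tsv`` need ``mirna``/``flag`` (0/1).
    The remaining arguments are id collections.
    """
    tissues: dict[str, list[str]] = {}
    if tissues_tsv is not None:
        df = pd.read_csv(tissues_tsv, sep="\t", comment="#")
        for _, row in df.iterrows():
            tissues.setdefault(str(row["mirna"]), []).append(str(row["tissue"]))

    def flag_table(path):
        if path is None:
            return {}
        df = pd.read_csv(path, sep="\t", comment="#")
        return {str(r["mirna"]): bool(r["flag"]) for _, r in df.iterrows()}

    brain = flag_table(brain_tsv)
    lit = flag_table(literature_tsv)
    mouse_supported = set(mouse_supported)
    targetscan = set(targetscan)
    microrna_db = set(microrna_db)
    zebrafish = set(zebrafish)
    out = {}
    for mid in mirna_ids:
        out[mid] = CriteriaAnnotation(
            ad_tissues=tuple(tissues.get(mid, ())),
            brain_expression=brain.get(mid),
            literature_ad=lit.get(mid),
            mouse_support=(mid in mouse_supported) or None,
            targetscan=(mid in targetscan) or None,
            microrna_db=(mid in microrna_db) or None,
            zebrafish=(mid in zebrafish) or None,
        )
    return out


def candidates_to_frame(candidates: list[CandidateSummary]) -> pd.DataFrame:
    """Ranked-candidate table, column-compatible with a printed summary."""
    rows = []
    for c in candidates:
        conf = []
        if c.program_count == 3:
            conf.append("predicted by 3 programs")
        if c.annotation.targetscan:
            conf.append("predicted by TargetScan")
        if c.annotation.microrna_db:
            conf.append("predicted by microRNA")
        if c.annotation.literature_ad:
            conf.append("literature for AD")
        if c.annotation.mouse_support:
            conf.append("mouse UTR")
        rows.append(
            {
                "mirna": c.mirna_id,
                "mean_kcal_mol": c.mean_energy,
                "programs": c.program_count,
                "sites": c.site_count,
                "confirmations": ", ".join(conf),
                "ad_tissues": ", ".join(c.annotation.ad_tissues),
                "zebrafish": "+" if c.annotation.zebrafish else "",
                "conserved": "" if c.conserved is None else ("+" if c.conserved else "-"),
                "rank": c.rank,
            }
        )
    return pd.DataFrame(rows)
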