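"""Synthetic inputs with controlled ground truth.

Every input class of the pipeline can be generated here: miRNAs with defined
seeds, UTRs with planted binding sites of known position and pairing extent,
ortholog alignments with per-species divergence (optionally protecting the
planted site, which is what real purifying selection does to functional
sites), and gene universes with planted target/disease overlap.  Generators
write the exact external formats the pipeline reads (FASTA, aligned FASTA,
TSV), are deterministic under a fixed seed, and return machine-readable
truth alongside the data.

Substitutions draw uniformly from the three alternative nucleotides, so a
species with substitution rate r has expected site identity (1 - r) * 100.
No indels are simulated; ortholog alignments are gapless by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    AlignmentSet,
    GenomicInterval,
    NucleotideSequence,
    UTRRecord,
    write_fasta,
)

__all__ = [
    "SimulationConfig",
    "simulate_mirna_and_utr",
    "simulate_orthologs",
    "simulate_gene_universe",
    "write_simulation",
]

_BASES = np.array(list("ACGT"))
_MAX_RETRIES = 1000

# per-species substitution probabilities, loosely ordered by divergence from
# a primate reference: close primates low, birds/fish high
DEFAULT_SPECIES_RATES = {
    "chimp": 0.01,
    "rhesus": 0.03,
    "mouse": 0.10,
    "dog": 0.10,
    "horse": 0.10,
    "opossum": 0.20,
    "chicken": 0.28,
    "zebrafinch": 0.30,
    "zebrafish": 0.35,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    mirna_len: tuple[int, int] = (21, 23)
    utr_len: int = 1236
    n_sites: int = 1
    seed_start: int = 2              # miRNA seed anchor used for planting
    seed_extent: int = 6
    site_mode: str = "perfect"       # "perfect" | "seed-only"
    species_rates: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_RATES))
    site_protection: float = 1.0     # multiplies the rate inside planted sites
    reference: str = "human"
    # gene-universe block
    universe_size: int = 18915
    n_databases: int = 6
    consensus_k: int = 4
    target_size: int = 156
    disease_size: int = 636
    overlap: int | None = None       # None -> disease drawn independently (null)
    n_validated: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.site_protection:
            raise ValueError("site_protection must be >= 0")
        for sp, r in self.species_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"substitution rate for {sp} outside [0,1]")
        if self.utr_len <= 0 or self.universe_size <= 0:
            raise ValueError("sizes must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _revcomp_dna(rna: str) -> str:
    return rna.upper().replace("U", "T").translate(
        str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_mirna_and_utr(config: SimulationConfig, rng=None):
    """A miRNA, a UTR with planted complements, and the planted-site truth.

    The UTR contains the planted (reverse-complement) sites at recorded
    1-based positions and -- by rejection sampling of the flanks -- no
    additional occurrence of the seed complement.  Raises RuntimeError if a
    conflict-free UTR is not found within the retry budget.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m_len = int(rng.integers(config.mirna_len[0], config.mirna_len[1] + 1))
    mirna = NucleotideSequence(_random_seq(rng, m_len).replace("T", "U"), "RNA")
    site_dna = _revcomp_dna(mirna.residues)
    if config.site_mode == "seed-only":
        # keep only the seed-complement tail; scramble the rest of the site
        s0 = config.seed_start - 1
        keep = len(site_dna) - s0 - config.seed_extent  # offset of seed in site
        scrambled = _random_seq(rng, keep)
        site_dna = scrambled + site_dna[keep:]
    L = len(site_dna)
    s0 = config.seed_start - 1
    seed_rna = mirna.residues[s0:s0 + config.seed_extent]
    seed_dna = _revcomp_dna(seed_rna)

    if config.n_sites * (L + 2) > config.utr_len:
        raise ValueError("UTR too short for the requested planted sites")
    # evenly spaced planting positions (0-based)
    gap = (config.utr_len - config.n_sites * L) // (config.n_sites + 1)
    starts = [gap * (i + 1) + L * i for i in range(config.n_sites)]

    planted = [(p, p + L - 1) for p in starts]
    for _ in range(_MAX_RETRIES):
        utr = list(_random_seq(rng, config.utr_len))
        for p in starts:
            utr[p:p + L] = site_dna
        seq = "".join(utr)
        stray = [
            i for i in range(len(seq) - len(seed_dna) + 1)
            if seq[i:i + len(seed_dna)] == seed_dna
            and not any(lo <= i and i + len(seed_dna) - 1 <= hi for lo, hi in planted)
        ]
        if not stray:
            break
    else:
        raise RuntimeError("rejection sampling failed to avoid stray seed matches")

    g_start = 1_000_001
    record = UTRRecord(
        "synthetic_utr",
        NucleotideSequence(seq, "DNA"),
        GenomicInterval("chrS", g_start, g_start + config.utr_len - 1, "+"),
    )
    truth = [
        {"local_start": lo + 1, "local_end": hi + 1, "mode": config.site_mode}
        for lo, hi in planted
    ]
    return mirna, record, truth


def simulate_orthologs(utr: UTRRecord, config: SimulationConfig, rng=None,
                       site_intervals=()):
    """Gapless ortholog alignment by per-column substitution.

    Columns inside *site_intervals* (1-based inclusive) mutate at
    ``rate * site_protection``; protection 0 freezes the site, emulating a
    functional element under purifying selection.  Returns the alignment and
    the realized per-species site identities.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ref = utr.seq.as_dna()
    n = len(ref)
    in_site = np.zeros(n, dtype=bool)
    for lo, hi in site_intervals:
        in_site[lo - 1:hi] = True
    rows = {config.reference: ref}
    realized = {}
    for sp, rate in config.species_rates.items():
        probs = np.where(in_site, rate * config.site_protection, rate)
        mutate = rng.random(n) < probs
        seq = list(ref)
        for i in np.flatnonzero(mutate):
            alternatives = [b for b in "ACGT" if b != ref[i]]
            seq[i] = alternatives[int(rng.integers(3))]
        rows[sp] = "".join(seq)
        if site_intervals:
            lo, hi = site_intervals[0]
            site_len = hi - lo + 1
            matches = sum(
                1 for i in range(lo - 1, hi) if rows[sp][i] == ref[i]
            )
            realized[sp] = matches / site_len
    return AlignmentSet(rows, config.reference), realized


def simulate_gene_universe(config: SimulationConfig, rng=None):
    """Database lists whose k-of-n consensus equals a known truth set.

    Truth genes appear in at least k prediction lists, decoys in at most
    k-1.  The disease catalogue is drawn with the configured overlap with
    the truth set, or independently (hypergeometric null) when
    ``config.overlap`` is None.  Returns (TargetDatabaseSet, disease set,
    truth dict).
    """
    from .gene_consensus import TargetDatabaseSet

    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    N, k, n = config.universe_size, config.consensus_k, config.n_databases
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if config.target_size + config.n_validated > N:
        raise ValueError("target set does not fit in the universe")
    genes = np.array([f"g{i}" for i in range(1, N + 1)])
    perm = rng.permutation(N)
    truth = set(genes[perm[:config.target_size]])
    validated = set(genes[perm[config.target_size:
                               config.target_size + config.n_validated]])
    db_names = [f"db{i}" for i in range(1, n + 1)]
    dbs: dict[str, set] = {d: set() for d in db_names}
    for g in genes[perm[:config.target_size]]:
        votes = int(rng.integers(k, n + 1))
        for d in rng.choice(db_names, size=votes, replace=False):
            dbs[d].add(g)
    for g in genes[perm[config.target_size + config.n_validated:]]:
        votes = int(rng.integers(0, k))  # 0..k-1: never reaches consensus
        if votes:
            for d in rng.choice(db_names, size=votes, replace=False):
                dbs[d].add(g)

    if config.overlap is None:
        disease = set(rng.choice(genes, size=config.disease_size, replace=False))
    else:
        a = config.overlap
        if a > min(config.target_size, config.disease_size):
            raise ValueError("planted overlap exceeds a set size")
        truth_arr = np.array(sorted(truth))
        rest = np.array(sorted(set(genes) - truth))
        disease = set(rng.choice(truth_arr, size=a, replace=False)) | set(
            rng.choice(rest, size=config.disease_size - a, replace=False)
        )
    dbset = TargetDatabaseSet(databases=dbs, validated=validated)
    truth_info = {
        "consensus": sorted(truth | validated),
        "target_size": config.target_size,
        "overlap": (None if config.overlap is None
                    else len(truth & disease)),
    }
    return dbset, disease, truth_info


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict:
    """Emit a self-contained input directory plus truth.json.

    Files: mirna.fasta, utr.fasta, orthologs.afa (aligned FASTA),
    databases.tsv (mirna/database/geneid), disease.tsv (geneid), truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    mirna, utr, site_truth = simulate_mirna_and_utr(config, rng)
    intervals = [(s["local_start"], s["local_end"]) for s in site_truth]
    msa, realized = simulate_orthologs(utr, config, rng, intervals)
    dbset, disease, gene_truth = simulate_gene_universe(config, rng)

    with open(outdir / "mirna.fasta", "w") as fh:
        fh.write(f">synthetic_mir\n{mirna.residues}\n")
    write_fasta(outdir / "utr.fasta", [utr])
    with open(outdir / "orthologs.afa", "w") as fh:
        for sp, seq in msa.sequences.items():
            fh.write(f">{sp}\n{seq}\n")
    with open(outdir / "databases.tsv", "w") as fh:
        fh.write("mirna\tdatabase\tgeneid\n")
        for db, gset in dbset.databases.items():
            for g in sorted(gset):
                fh.write(f"synthetic_mir\t{db}\t{g}\n")
        for g in sorted(dbset.validated):
            fh.write(f"synthetic_mir\tvalidated\t{g}\n")
    with open(outdir / "disease.tsv", "w") as fh:
        fh.write("geneid\n")
        for g in sorted(disease):
            fh.write(f"{g}\n")
    truth = {
        "sites": site_truth,
        "mirna": mirna.residues,
        "site_identity": realized,
        "genes": gene_truth,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if not isinstance(v, dict)
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
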