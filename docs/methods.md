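# Methods

This note documents the models implemented in `mirsitescan`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data can and cannot tell you about real inputs.

## Coordinate conventions

All intervals are 1-based and inclusive on both ends (`length = end − start
+ 1`), matching transcript annotations such as the human ADAM10 3'UTR
(NM_001110, chr15:58888510–58889745, 1236 nt) and its miR-1306 site
(chr15:58889309–58889324, local positions 800–815). BED exports alone are
0-based half-open. Local positions count 5'→3' along the given UTR
sequence; on the minus strand the genomic mapping reverses, and the
round-trip `genomic_to_local(local_to_genomic(x)) = x` holds exactly on
every position of every record. miRNAs are stored as RNA (U), UTRs as DNA
(T); all pairing logic treats U ≡ T.

## Duplex energy model

A heteroduplex is a set of miRNA:target pairs, monotone on both strands
(antiparallel, no pseudoknots); intramolecular pairing and branching are
forbidden. Its free energy is

```
ΔG = ΔG_init + Σ_stacks ΔG_stack(P1,P2) + Σ_loops (α + β·u) + Σ_ends ΔG_AU
```

- **Stacking.** The 6×6 table (Watson–Crick + G:U) ships in
  `src/mirsitescan/data/energy_params.yaml`, transcribed from the published
  Turner 2004 nearest-neighbor free energies at 0.1 kcal/mol precision,
  with `ΔG_init = +4.09` and a terminal A:U/G:U penalty of +0.45 per helix
  end from the same parameter set.
- **Loops.** Any interruption between consecutive pairs costs a single
  affine term `α + β·u` with `α = 3.6`, `β = 0.4` kcal/mol and `u` the
  total unpaired bases on both strands. This deliberately collapses the
  separate bulge/internal-loop tables of full secondary-structure models
  into one affine law; it keeps the dynamic program exactly decomposable
  (Gotoh-style loop states) while penalizing interruptions on the right
  scale (a 1-nt bulge ≈ +4, as in full models). The values are package
  defaults, versioned in the config file.
- **Arithmetic.** Energies are integers in centi-kcal internally, so equal
  energies tie exactly and the tie-break — more paired bases, then the
  5'-most target position — is deterministic. The dynamic program is
  checked against exhaustive enumeration of all monotone pairings for
  sequences ≤ 8 nt in the test suite.

Scanning uses the seed-match speed-up: full folding runs only in windows
around occurrences of the seed complement (seed = miRNA positions 2–7 by
default; G:U in the seed match is off by default for this engine). The fold
window extends the seed match by the miRNA length plus 10 nt, capped at
60 nt. Overlapping sites keep the lower energy.

## Site statistics

The normalized statistic of a site energy `E` against a miRNA of length m
and a UTR of length n is `s = −E / ln(m·n)` (natural log; the base is a
package decision recorded here and in the config). Its p-value is the
Gumbel survival function `p = 1 − exp(−exp(−(s − μ)/β))` with defaults
`μ = 1.9, β = 0.28` (the published mouse-scan pair; the human pair is not
printed anywhere and therefore defaults to the same values, overridable in
config). Multiple binding sites combine via a Poisson approximation:
`λ = −ln(1 − p)` and `P(X ≥ k)`; at `k = 1` this returns `p` exactly.

## Complementarity alignment

The aligner is Smith–Waterman with complementarity scores instead of
identity: Watson–Crick +5, G:U +1, mismatch −3, affine gaps (open −8,
extend −2). The per-column base scores are package defaults (they are not
part of any published parameter print-out); the gap penalties, score
threshold 50, energy threshold −20 kcal/mol and scaling factor 4 are the
published defaults of the engine this emulates. Score scaling ×4 applies to
substitution columns on miRNA positions 2–8, after alignment and before
thresholding (whether the original engine thresholds before or after
scaling is not documented; "after" is this package's recorded choice). Gap
penalties are not scaled. Non-overlapping optima are extracted by
find-best-then-split-target recursion; a raw-score floor of
`threshold / scale_factor` bounds the recursion, since scaling can inflate
a raw score at most by the scale factor.

The seed-quality rule: no mismatch or gap on miRNA positions 2–8, at most
one G:U wobble, and a single wobble must be compensated by at least 4
consecutive Watson–Crick pairs within miRNA positions 13–16. The "3'
compensation" window numbers operationalize a qualitative published rule and
are configurable. Surviving sites are annotated with the duplex MFE of
their window and kept at or below −20 kcal/mol.

## Constraint-based seed-site finder

The third engine reduces a pattern-discovery method to its printed
constraint set (the pattern-discovery stage itself is out of scope): seed
extent 6 with zero unpaired seed bases (anchored at miRNA position 2 —
the extent is published, the anchor is this package's choice consistent
with the positions-2–8 seed convention), at least 14 paired bases in the
full heteroduplex, and folding energy ≤ −25 kcal/mol. The fold window
around a seed match is the miRNA length + 10 nt (unpublished; package
default). Every reported site satisfies all three constraints by
construction, and loosening any constraint can only grow the site set.

## Conservation

"Conserved region" has no published operational definition; the rule here
is: an alignment column is conserved when ≥ `min_species` members
(including the reference, default 7 of 10) carry the reference's non-gap
nucleotide, and a region is a maximal run of ≥ `min_run` (default 10)
consecutive conserved reference positions. Reference-gap columns are
skipped so site coordinates are ungapped reference positions. Per-species
site identity is matches / site length × 100 with species gaps counting as
mismatches, rounded half-up to an integer (93.75 → 94, 87.5 → 88 — the
rounding rule consistent with all eight published site percentages). A
site is conserved iff it lies entirely inside one region.

## Merging and ranking

A candidate is a miRNA supported by ≥ 2 engines; support is counted
per-miRNA by default (any site anywhere in the UTR), with a stricter
per-locus policy (engines must overlap on a shared position) available —
the published workflow does not disambiguate the two, so both are
implemented and tested. Per-engine best (lowest) energies are averaged
arithmetically and rounded half-up to 2 decimals; distinct loci are merged
overlap clusters, with ≥ 2 loci setting the multiple-binding-site flag.
Ranking is a stable lexicographic sort — engine count desc, positive
evidence flags desc, zebrafish conservation desc, mean energy asc, miRNA id
asc. The published ranked table states no sort key; this rule is the
package's choice and reproduces the published top-of-table ordering.

## Database consensus and enrichment

k-of-n voting (default 4 of 6) over per-database gene-identifier lists,
with validated (Tarbase-role) genes always included; when a single database
covers the miRNA the vote is bypassed and flagged. Gene identity is by
stable numeric identifier (Entrez-style). Enrichment builds the 2×2 table
(target∩disease, target-only, disease-only, neither) over a stated
universe and computes the two-sided Fisher exact p-value by hypergeometric
point-probability summation — all tables with the observed margins whose
probability is ≤ the observed one within 1e−7 relative slack, the default
convention of the standard R implementation. That convention is load-
bearing: the published p-values (0.0065 / 0.0009 / 0.1904) are only
reproducible under it. The implementation is verified in the tests against
an exact rational-arithmetic oracle (`math.comb` fractions) and
cross-checked against `scipy.stats.fisher_exact`, which is never the
implementation. The sample odds ratio a·d/(b·c) is always reported, the
conditional-MLE odds ratio on request.

## Synthetic data

Generators are deterministic under a fixed seed and emit the exact external
formats the pipeline reads (FASTA, aligned FASTA, TSV), so tests exercise
the real readers. Defaults emulate the study conditions: miRNAs 21–23 nt,
UTR 1236 nt, one planted site, ten-species ortholog sets, a gene universe
of 18915 with 636 disease genes and 156 targets.

- **Sites** are planted as exact reverse complements (or seed-only
  variants); flanks are rejection-sampled (cap 1000 retries) to contain no
  stray seed complement, so absence of extra sites is guaranteed, not just
  likely.
- **Orthologs** mutate each column independently per species (rates from
  0.01 for chimp to 0.35 for zebrafish, chosen once as divergence-ordered
  plausible values); substitutions draw uniformly from the three
  alternative bases, so expected identity is exactly (1 − rate)·100.
  `site_protection` multiplies the rate inside planted sites (0 freezes
  them), emulating purifying selection on functional elements. No indels
  are simulated — alignments are gapless by construction — and there is no
  phylogenetic correlation between species.
- **Gene universes** assign truth genes to ≥ k databases and decoys to
  ≤ k−1, so the k-of-n consensus equals the truth set exactly; disease
  sets are drawn with a planted overlap, or independently for a
  hypergeometric null.

Passing tests on these inputs show the machinery is correct under its own
model; they do not show that real 3'UTRs have rejection-sampled flanks,
independent-site evolution, or gapless orthology, and recovery rates on
synthetic data say nothing about sensitivity on real transcripts.

## Calibration and problem sizes

The type-I-error check of the enrichment stage draws disease sets
independently of a fixed target set at the published single-database
margins (universe 16819, targets 890, disease 591) and requires the
rejection fraction at α = 0.05 over 1000 replicates to sit inside the 95%
binomial CI around 0.05. Those margins were chosen analytically: the exact
discrete level of the Fisher test there is 0.0492, the closest to nominal
among the published configurations (the 18915/636/156 margins have exact
level 0.0429 — Fisher is conservative under discreteness, which is a
property of the test, not a defect of the implementation). Brute-force
oracle comparisons run on sequences ≤ 8 nt (duplex) and ≤ 10 nt
(alignment), the sizes at which exhaustive enumeration stays comfortable;
end-to-end recovery uses a 600-nt UTR, a size at which all three engines
complete in seconds while exercising every code path.

## Known limitations

- The duplex model has no target-site accessibility, no intramolecular
  structure, no ensemble partition function; energies are comparable
  within this package but not to other tools' printed energies, which
  encode their own internals.
- The published funnel counts (236 → 122 → 52 → 11 candidate miRNAs) and
  database-derived counts (156/157/890/130) depend on 2008–2011 database
  snapshots and era-specific program internals; they are reproducible from
  fixtures that encode their margins but are not recomputed from live
  sources.
- Conservation is consensus-counting, not phylogeny-aware; a clade of
  close species counts the same as distant independent lineages.
- Alignment computation itself (ClustalW in the original workflow) is an
  input, not a feature.
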