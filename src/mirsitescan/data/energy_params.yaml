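# Nearest-neighbor RNA/RNA duplex free-energy parameters (37 C, kcal/mol).
#
# Stacking free energies are the published Turner 2004 values for the six
# canonical pairs (Watson-Crick plus G:U wobble), tabulated at 0.1 kcal/mol
# precision.  Key convention: a pair "XY" is written with the miRNA (top,
# 5'->3') base first and the target (bottom, 3'->5') base second; the entry
# stack[P1][P2] is the free-energy increment of the dinucleotide step
#
#       5' W X 3'   (miRNA)        P1 = "WZ", P2 = "XY"
#       3' Z Y 5'   (target)
#
# Loop model: any interruption between two consecutive pairs (bulge or
# internal loop) costs  loop_init + loop_per_nt * u  where u is the total
# number of unpaired bases on both strands.  A single affine term is used for
# both loop kinds.
#
# duplex_init is the Turner 2004 intermolecular initiation penalty;
# terminal_au is the per-helix-end penalty applied when a terminal pair is
# A:U, U:A, G:U or U:G.
version: turner2004-stack-affine-loops-v1
stack:
  CG: {CG: -3.30, GC: -2.40, GU: -1.40, UG: -2.10, AU: -2.10, UA: -2.10}
  GC: {CG: -3.40, GC: -3.30, GU: -1.50, UG: -2.50, AU: -2.40, UA: -2.20}
  GU: {CG: -2.50, GC: -2.10, GU: -0.50, UG: 1.30, AU: -1.30, UA: -1.40}
  UG: {CG: -1.50, GC: -1.40, GU: 0.30, UG: -0.50, AU: -1.00, UA: -0.60}
  AU: {CG: -2.20, GC: -2.10, GU: -0.60, UG: -1.40, AU: -0.90, UA: -1.10}
  UA: {CG: -2.40, GC: -2.10, GU: -1.00, UG: -1.30, AU: -1.30, UA: -0.90}
loop_init: 3.60
loop_per_nt: 0.40
duplex_init: 4.09
terminal_au: 0.45
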