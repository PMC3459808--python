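"""Fold a miRNA against a UTR window and scan a full UTR for sites.

Builds a synthetic UTR with one planted perfect complement, runs the
energy-based hybridization scan and prints the site with its minimum free
energy, Gumbel p-value and the Poisson-combined p-value for two such sites.
"""

from mirsitescan import (EvdParameters, SimulationConfig, duplex_mfe,
                         poisson_multisite, scan_hybridization)
from mirsitescan.synthdata import simulate_mirna_and_utr

cfg = SimulationConfig(seed=7, utr_len=500)
mirna, utr, truth = simulate_mirna_and_utr(cfg)
print(f"miRNA ({len(mirna)} nt): {mirna.residues}")
print(f"planted site: local {truth[0]['local_start']}-{truth[0]['local_end']}")

res = duplex_mfe(mirna, mirna.reverse_complement())
print(f"perfect duplex: {res.energy:.2f} kcal/mol, pairing {res.pairing}")

sites = scan_hybridization("mir", mirna, utr, evd=EvdParameters(1.9, 0.28))
for s in sites:
    print(f"site {s.local_start}-{s.local_end} ({s.genomic}): "
          f"{s.energy:.2f} kcal/mol, p = {s.pvalue:.3g}")
    print(f"  two-site Poisson p = {poisson_multisite(s.pvalue, 2):.3g}")
# The site energy is far below the -20 kcal/mol cutoff and its Gumbel
# p-value is small: a length-normalized energy this low is unlikely for a
# random miRNA/UTR pair of these lengths.
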