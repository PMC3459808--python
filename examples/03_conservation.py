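"""Conserved regions and per-species site identity.

Simulates a ten-species ortholog set in which the planted site is frozen
(purifying selection) while flanks diverge, then recovers the site as a
conserved region and prints the identity ladder.
"""

from mirsitescan import SimulationConfig, conserved_regions, is_site_conserved
from mirsitescan.synthdata import simulate_mirna_and_utr, simulate_orthologs

cfg = SimulationConfig(seed=3, utr_len=400, site_protection=0.0)
mirna, utr, truth = simulate_mirna_and_utr(cfg)
site = (truth[0]["local_start"], truth[0]["local_end"])
msa, _ = simulate_orthologs(utr, cfg, site_intervals=[site])

regions = conserved_regions(msa)  # >= 7 of 10 species, runs >= 10 nt
print(f"conserved regions (reference coordinates): {regions}")
profile = is_site_conserved(site, regions, msa)
print(f"site {site} conserved: {profile.conserved}")
for sp, pct in sorted(profile.identity.items(), key=lambda kv: -kv[1]):
    print(f"  {sp:11s} {pct:3d}%")
# The frozen site is 100% identical in every species, so it always lies
# inside a conserved region; flank identity decays with each species' rate.
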