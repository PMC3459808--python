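import filecmp
import json

import numpy as np
import pytest

from mirsitescan import (
    SimulationConfig,
    conserved_regions,
    knofn_consensus,
    read_fasta,
    read_msa,
    site_identity,
    write_simulation,
)
from mirsitescan.duplex import SeedPolicy, find_seed_matches, scan_hybridization
from mirsitescan.gene_consensus import load_database_tsv, load_disease_tsv
from mirsitescan.seedsite import find_seed_sites
from mirsitescan.synthdata import (
    simulate_gene_universe,
    simulate_mirna_and_utr,
    simulate_orthologs,
)


class TestMirnaAndUtr:
    def test_planted_site_is_exact_complement_at_truth(self):
        cfg = SimulationConfig(seed=5)
        mirna, utr, truth = simulate_mirna_and_utr(cfg)
        (site,) = truth
        lo, hi = site["local_start"], site["local_end"]
        assert hi - lo + 1 == len(mirna)
        planted = utr.seq.as_rna()[lo - 1:hi]
        rc = mirna.reverse_complement().as_rna()
        assert planted == rc

    def test_no_stray_seed_matches_outside_planted_sites(self):
        cfg = SimulationConfig(seed=5, n_sites=2)
        mirna, utr, truth = simulate_mirna_and_utr(cfg)
        hits = find_seed_matches(mirna, utr.seq.as_rna(), SeedPolicy())
        spans = [(s["local_start"] - 1, s["local_end"] - 1) for s in truth]
        for h in hits:
            assert any(lo <= h <= hi for lo, hi in spans)

    def test_zero_sites_means_engines_report_nothing(self, params):
        cfg = SimulationConfig(seed=6, n_sites=0, utr_len=400)
        mirna, utr, truth = simulate_mirna_and_utr(cfg)
        assert truth == []
        assert scan_hybridization("m", mirna, utr, params) == []
        assert find_seed_sites("m", mirna, utr, params=params) == []

    def test_infeasible_request_raises(self):
        with pytest.raises(ValueError):
            simulate_mirna_and_utr(SimulationConfig(seed=0, utr_len=30, n_sites=3))


class TestOrthologs:
    def test_rate_zero_gives_full_identity(self):
        cfg = SimulationConfig(seed=7, utr_len=300,
                               species_rates={"sp1": 0.0, "sp2": 0.0})
        mirna, utr, truth = simulate_mirna_and_utr(cfg)
        site = (truth[0]["local_start"], truth[0]["local_end"])
        msa, _ = simulate_orthologs(utr, cfg, site_intervals=[site])
        assert site_identity(msa, site, "sp1") == 100
        assert site_identity(msa, site, "sp2") == 100

    def test_identity_matches_binomial_expectation(self):
        # each substitution event always changes the base, so expected
        # identity is (1 - rate); check a 0.2-rate species over many columns
        rate = 0.2
        cfg = SimulationConfig(seed=8, utr_len=2000, n_sites=0,
                               species_rates={"sp": rate})
        mirna, utr, _ = simulate_mirna_and_utr(cfg)
        msa, _ = simulate_orthologs(utr, cfg)
        ref = msa.sequences["human"]
        other = msa.sequences["sp"]
        mismatches = sum(1 for a, b in zip(ref, other) if a != b)
        n = len(ref)
        ci = 4 * np.sqrt(rate * (1 - rate) / n)  # ~99.99% binomial band
        assert abs(mismatches / n - rate) < ci

    def test_frozen_site_recovered_as_conserved_region(self):
        rates = {f"sp{i}": 0.5 for i in range(9)}  # heavy flank divergence
        cfg = SimulationConfig(seed=9, utr_len=400, species_rates=rates,
                               site_protection=0.0)
        mirna, utr, truth = simulate_mirna_and_utr(cfg)
        site = (truth[0]["local_start"], truth[0]["local_end"])
        msa, realized = simulate_orthologs(utr, cfg, site_intervals=[site])
        assert all(v == 1.0 for v in realized.values())
        regions = conserved_regions(msa)
        assert any(lo <= site[0] and site[1] <= hi for lo, hi in regions)


class TestGeneUniverse:
    def test_consensus_recovers_truth_exactly(self):
        cfg = SimulationConfig(seed=10, universe_size=2000, target_size=50,
                               disease_size=100, n_validated=5)
        dbset, disease, truth = simulate_gene_universe(cfg)
        got = knofn_consensus(dbset, cfg.consensus_k)
        assert sorted(got) == truth["consensus"]
        assert len(truth["consensus"]) == 55

    def test_planted_overlap_realized(self):
        cfg = SimulationConfig(seed=11, universe_size=2000, target_size=50,
                               disease_size=100, overlap=12)
        dbset, disease, truth = simulate_gene_universe(cfg)
        consensus = knofn_consensus(dbset, cfg.consensus_k)
        assert len(consensus & disease) == 12
        assert truth["overlap"] == 12

    def test_infeasible_overlap_rejected(self):
        cfg = SimulationConfig(seed=0, universe_size=500, target_size=10,
                               disease_size=20, overlap=15)
        with pytest.raises(ValueError):
            simulate_gene_universe(cfg)


class TestFileEmission:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=3, utr_len=300, universe_size=500,
                               target_size=20, disease_size=30)
        write_simulation(cfg, tmp_path / "a")
        write_simulation(cfg, tmp_path / "b")
        for name in ("mirna.fasta", "utr.fasta", "orthologs.afa",
                     "databases.tsv", "disease.tsv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_emitted_files_readable_by_pipeline_readers(self, tmp_path):
        cfg = SimulationConfig(seed=4, utr_len=300, universe_size=500,
                               target_size=20, disease_size=30)
        truth = write_simulation(cfg, tmp_path)
        (utr,) = read_fasta(tmp_path / "utr.fasta")
        assert len(utr) == 300 and utr.interval is not None
        msa = read_msa(tmp_path / "orthologs.afa", "human")
        assert set(msa.species) == {"human", *cfg.species_rates}
        tables = load_database_tsv(tmp_path / "databases.tsv")
        assert set(tables["synthetic_mir"]) <= {f"db{i}" for i in range(1, 7)}
        disease = load_disease_tsv(tmp_path / "disease.tsv")
        assert len(disease) == 30
        saved = json.loads((tmp_path / "truth.json").read_text())
        assert saved["sites"] == truth["sites"]
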