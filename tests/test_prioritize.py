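import random

import pytest

from mirsitescan import CriteriaAnnotation, mean_energy, merge_predictions, rank_candidates
from mirsitescan.duplex import DuplexSite
from mirsitescan.prioritize import annotations_from_tables, candidates_to_frame


def site(program, mirna, lo, hi, energy):
    return DuplexSite(program=program, mirna_id=mirna, utr_id="utr",
                      local_start=lo, local_end=hi,
                      pairing="|" * 10, energy=energy, paired=10)


class TestMeanEnergy:
    @pytest.mark.parametrize("energies,expected", [
        ((-32.29, -25.7, -22.55), -26.85),
        ((-27.9, -23.66), -25.78),
        ((-26.2, -22.28), -24.24),
        ((-31.2, -25.6, -21.84), -26.21),
    ])
    def test_printed_per_program_energies_average(self, energies, expected):
        assert mean_energy(energies) == expected

    def test_single_value_is_itself(self):
        assert mean_energy([-19.5]) == -19.5

    def test_half_up_rounding_at_two_decimals(self):
        assert mean_energy([-26.845]) == -26.85
        assert mean_energy([-26.844]) == -26.84

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_energy([])


class TestMergePredictions:
    def test_three_programs_one_locus(self):
        sites = {
            "hybrid": [site("hybrid", "mir-a", 100, 121, -25.7)],
            "complement": [site("complement", "mir-a", 102, 120, -22.55)],
            "seedsite": [site("seedsite", "mir-a", 99, 122, -32.29)],
        }
        (cand,) = merge_predictions(sites, min_programs=2)
        assert cand.program_count == 3
        assert cand.site_count == 1
        assert cand.mean_energy == -26.85

    def test_single_program_excluded_at_min_two(self):
        sites = {"hybrid": [site("hybrid", "mir-b", 10, 30, -25.0)],
                 "complement": [], "seedsite": []}
        assert merge_predictions(sites, min_programs=2) == []

    def test_disjoint_loci_policies_differ(self):
        sites = {
            "hybrid": [site("hybrid", "mir-c", 10, 30, -25.0)],
            "complement": [site("complement", "mir-c", 200, 220, -21.0)],
            "seedsite": [],
        }
        per_mirna = merge_predictions(sites, 2, policy="per-mirna")
        assert len(per_mirna) == 1 and per_mirna[0].site_count == 2
        per_locus = merge_predictions(sites, 2, policy="per-locus")
        assert per_locus == []

    def test_min_programs_filters_are_nested(self):
        r = random.Random(0)
        sites = {"hybrid": [], "complement": [], "seedsite": []}
        for i in range(12):
            for prog in random.Random(i).sample(list(sites), r.randint(1, 3)):
                lo = r.randint(1, 500)
                sites[prog].append(site(prog, f"mir-{i}", lo, lo + 20, -25.0))
        ids = [
            {c.mirna_id for c in merge_predictions(sites, k)} for k in (1, 2, 3)
        ]
        assert ids[2] <= ids[1] <= ids[0]

    def test_best_energy_per_program_kept(self):
        sites = {
            "hybrid": [site("hybrid", "mir-d", 10, 30, -18.0),
                       site("hybrid", "mir-d", 100, 120, -27.0)],
            "complement": [site("complement", "mir-d", 12, 28, -21.0)],
            "seedsite": [],
        }
        (cand,) = merge_predictions(sites, 2)
        assert cand.energies["hybrid"] == -27.0
        assert cand.site_count == 2 and cand.multiple_sites


def _candidate(mirna, programs, energy, zebrafish=False, evidence=0):
    sites = {p: [site(p, mirna, 10, 30, energy)] for p in programs}
    for p in ("hybrid", "complement", "seedsite"):
        sites.setdefault(p, [])
    (cand,) = merge_predictions(sites, min_programs=1)
    flags = {}
    if evidence >= 1:
        flags["targetscan"] = True
    if evidence >= 2:
        flags["literature_ad"] = True
    cand.annotation = CriteriaAnnotation(zebrafish=zebrafish, **flags)
    return cand


class TestRanking:
    def test_three_program_zebrafish_candidate_ranks_first(self):
        mir1306 = _candidate("mir-1306", ["hybrid", "complement", "seedsite"],
                             -26.85, zebrafish=True)
        mir107 = _candidate("mir-107", ["hybrid", "complement"], -24.24,
                            evidence=2)
        ranked = rank_candidates([mir107, mir1306])
        assert [c.mirna_id for c in ranked] == ["mir-1306", "mir-107"]
        assert [c.rank for c in ranked] == [1, 2]

    def test_tie_broken_by_mean_energy(self):
        a = _candidate("mir-x", ["hybrid", "complement"], -20.0)
        b = _candidate("mir-y", ["hybrid", "complement"], -25.0)
        assert [c.mirna_id for c in rank_candidates([a, b])] == ["mir-y", "mir-x"]

    def test_empty_input(self):
        assert rank_candidates([]) == []

    def test_order_invariant_under_input_permutation(self):
        cands = [
            _candidate(f"mir-{i}", ["hybrid", "complement"], -20.0 - i % 3,
                       zebrafish=bool(i % 2), evidence=i % 3)
            for i in range(8)
        ]
        ref = [c.mirna_id for c in rank_candidates(list(cands))]
        for seed in range(3):
            shuffled = list(cands)
            random.Random(seed).shuffle(shuffled)
            assert [c.mirna_id for c in rank_candidates(shuffled)] == ref


class TestAnnotationTables:
    def test_tsv_round_trip(self, tmp_path):
        (tmp_path / "tissues.tsv").write_text(
            "mirna\ttissue\nmir-103\thippocampus\nmir-103\tcerebellum\n")
        (tmp_path / "brain.tsv").write_text("mirna\tflag\nmir-103\t1\nmir-9\t0\n")
        ann = annotations_from_tables(
            ["mir-103", "mir-9"],
            tissues_tsv=tmp_path / "tissues.tsv",
            brain_tsv=tmp_path / "brain.tsv",
            targetscan=["mir-103"],
        )
        assert ann["mir-103"].ad_tissues == ("hippocampus", "cerebellum")
        assert ann["mir-103"].evidence_count == 3
        assert ann["mir-9"].brain_expression is False
        assert ann["mir-9"].evidence_count == 0

    def test_candidate_frame_columns(self):
        cand = _candidate("mir-1306", ["hybrid", "complement", "seedsite"],
                          -26.85, zebrafish=True)
        df = candidates_to_frame(rank_candidates([cand]))
        row = df.iloc[0]
        assert row["mirna"] == "mir-1306"
        assert row["mean_kcal_mol"] == -26.85
        assert "predicted by 3 programs" in row["confirmations"]
        assert row["zebrafish"] == "+"
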