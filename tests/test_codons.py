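import numpy as np
import pytest

from introscan.codons import (
    CodonTableError,
    Gene,
    classify_codon_switches,
    default_preferred_table,
    degeneration_sign_tests,
    excess_and_frequency,
    extract_coding_alignment,
    load_preferred_table,
    load_reference_switch_counts,
    round_half_up,
    write_preferred_table,
)
from introscan.simulate import (
    SimulationConfig,
    SwitchRates,
    count_codon_patterns,
    simulate_codon_alignment,
)
from .conftest import make_alignment

TABLE = default_preferred_table()


def codon_array(*codons: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate("ACGT")}
    return np.array([[lut[b] for b in c] for c in codons], dtype=np.uint8)


class TestPreferredTable:
    def test_default_table_is_valid_and_loads(self, tmp_path):
        write_preferred_table(TABLE, tmp_path / "t.tsv")
        back = load_preferred_table(tmp_path / "t.tsv")
        assert back.status == TABLE.status
        assert len(back.status) == 61

    def test_missing_codon_is_named(self, tmp_path):
        write_preferred_table(TABLE, tmp_path / "t.tsv")
        text = (tmp_path / "t.tsv").read_text()
        text = "\n".join(l for l in text.splitlines() if not l.startswith("GCC"))
        (tmp_path / "bad.tsv").write_text(text)
        with pytest.raises(CodonTableError, match="GCC"):
            load_preferred_table(tmp_path / "bad.tsv")

    def test_genetic_code_consistency(self, tmp_path):
        write_preferred_table(TABLE, tmp_path / "t.tsv")
        text = (tmp_path / "t.tsv").read_text().replace("GCC\tA\t", "GCC\tG\t")
        (tmp_path / "bad.tsv").write_text(text)
        with pytest.raises(CodonTableError, match="GCC"):
            load_preferred_table(tmp_path / "bad.tsv")

    def test_family_without_preferred_codon_rejected(self):
        status = dict(TABLE.status)
        for codon in TABLE.synonyms("GCC", "PR"):
            status[codon] = "NPR"
        with pytest.raises(CodonTableError, match="no preferred"):
            from introscan.codons import PreferredCodonTable

            PreferredCodonTable(status, dict(TABLE.amino_acid))


class TestExtractCodingAlignment:
    def test_single_forward_gene(self):
        aln = make_alignment({"a": "TTATGGCCTT", "b": "TTATGGCGTT"})
        genes = [Gene("chr1", 2, 8, "g1", "+")]
        coding = extract_coding_alignment(aln, genes, ("chr1", 0, 10))
        assert coding.n_codons == 2
        np.testing.assert_array_equal(coding.codons["a"], codon_array("ATG", "GCC"))

    def test_gene_with_missing_data_excluded(self):
        aln = make_alignment({"a": "ATGGCC", "b": "ATGNCC"})
        coding = extract_coding_alignment(
            aln, [Gene("chr1", 0, 6, "g1")], ("chr1", 0, 6)
        )
        assert coding.n_codons == 0
        assert coding.n_excluded_incomplete == 1

    def test_gene_outside_region_excluded(self):
        aln = make_alignment({"a": "ATGGCCATGGCC"})
        genes = [Gene("chr1", 0, 6, "in"), Gene("chr1", 6, 12, "out")]
        coding = extract_coding_alignment(aln, genes, ("chr1", 0, 6))
        assert coding.gene_names == ["in"]
        assert coding.n_excluded_outside == 1

    def test_frame_violation_excluded(self):
        aln = make_alignment({"a": "ATGGCCA"})
        coding = extract_coding_alignment(
            aln, [Gene("chr1", 0, 7, "bad")], ("chr1", 0, 7)
        )
        assert coding.n_excluded_frame == 1 and coding.n_codons == 0

    def test_reverse_strand_gene_reverse_complemented(self):
        # reverse complement of 'GGCCAT' is 'ATGGCC'
        aln = make_alignment({"a": "GGCCAT"})
        coding = extract_coding_alignment(
            aln, [Gene("chr1", 0, 6, "g1", "-")], ("chr1", 0, 6)
        )
        np.testing.assert_array_equal(coding.codons["a"], codon_array("ATG", "GCC"))

    def test_simulator_codon_count_matches_truth(self, small_dataset, small_trimmed):
        trimmed, _ = small_trimmed
        cfg = small_dataset.config
        coding = extract_coding_alignment(
            trimmed, small_dataset.genes, ("LGI", *cfg.central_region)
        )
        assert coding.n_codons == cfg.n_genes * cfg.gene_length_codons


class TestClassifySwitches:
    def test_pattern_pr_npr_pr_is_mat_a_switch(self):
        # GCC is the preferred Ala codon in the default table, GCT non-preferred
        tbl = classify_codon_switches(
            codon_array("GCC"), codon_array("GCT"), codon_array("GCC"), TABLE
        )
        assert tbl.n_pr_to_npr == {"mat_a": 1, "mat_A": 0}

    def test_nonsynonymous_codon_excluded(self):
        tbl = classify_codon_switches(
            codon_array("GCC"), codon_array("ACC"), codon_array("GCC"), TABLE
        )
        assert tbl.n_excluded_nonsyn == 1
        assert sum(tbl.n_pr_to_npr.values()) + sum(tbl.n_npr_to_pr.values()) == 0

    def test_identical_codons_uninformative(self):
        tbl = classify_codon_switches(
            codon_array("GCC"), codon_array("GCC"), codon_array("GCC"), TABLE
        )
        assert tbl.n_uninformative == 1

    def test_both_derived_state_uninformative(self):
        # both alleles switched to NPR: no allele-specific polarity
        tbl = classify_codon_switches(
            codon_array("GCC"), codon_array("GCT"), codon_array("GCT"), TABLE
        )
        assert tbl.n_uninformative == 1
        assert sum(tbl.n_pr_to_npr.values()) == 0

    def test_swapping_alleles_swaps_counts(self):
        codons, _ = simulate_codon_alignment(
            SimulationConfig(seed=21, n_genes=5, gene_length_codons=200)
        )
        a = classify_codon_switches(codons["NC"], codons["mat_a"], codons["mat_A"], TABLE)
        b = classify_codon_switches(codons["NC"], codons["mat_A"], codons["mat_a"], TABLE)
        assert a.n_pr_to_npr["mat_a"] == b.n_pr_to_npr["mat_A"]
        assert a.n_npr_to_pr["mat_A"] == b.n_npr_to_pr["mat_a"]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            classify_codon_switches(
                codon_array("GCC"), codon_array("GCC", "GCC"), codon_array("GCC"), TABLE
            )

    def test_exact_recovery_of_simulator_truth(self, small_dataset, small_trimmed):
        """Classified switch counts equal the generator's per-pattern truth
        exactly, and the accounting closes."""
        trimmed, _ = small_trimmed
        cfg = small_dataset.config
        coding = extract_coding_alignment(
            trimmed, small_dataset.genes, ("LGI", *cfg.central_region)
        )
        for lineage in ("L1", "L4", "L9"):
            truth = small_dataset.truth.codon_switch_counts[lineage]
            tbl = classify_codon_switches(
                coding.codons["NC"],
                coding.codons[f"{lineage}a"],
                coding.codons[f"{lineage}A"],
                small_dataset.codon_table,
            )
            assert tbl.n_pr_to_npr["mat_a"] == truth["mat_a"]["pr_to_npr"]
            assert tbl.n_npr_to_pr["mat_a"] == truth["mat_a"]["npr_to_pr"]
            assert tbl.n_pr_to_npr["mat_A"] == truth["mat_A"]["pr_to_npr"]
            assert tbl.n_npr_to_pr["mat_A"] == truth["mat_A"]["npr_to_pr"]
            assert tbl.n_excluded_nonsyn == truth["n_excluded_nonsyn"]
            assert tbl.n_excluded_missing == truth["n_excluded_missing"]
            # accounting closure
            assert (
                tbl.n_analyzed + tbl.n_excluded_missing + tbl.n_excluded_nonsyn
                == tbl.total_codons
            )


class TestCodonSimulation:
    def test_zero_rates_give_zero_switches(self):
        cfg = SimulationConfig(
            seed=4, n_genes=5, gene_length_codons=100,
            switch_rates=SwitchRates(0, 0, 0, 0), nonsyn_rate=0.0,
        )
        _, truth = simulate_codon_alignment(cfg)
        assert truth["mat_a"] == {"pr_to_npr": 0, "npr_to_pr": 0}
        assert truth["mat_A"] == {"pr_to_npr": 0, "npr_to_pr": 0}
        assert truth["n_excluded_nonsyn"] == 0

    def test_forced_nonsynonymous_excludes_everything(self):
        cfg = SimulationConfig(
            seed=4, n_genes=2, gene_length_codons=100, nonsyn_rate=1.0
        )
        codons, truth = simulate_codon_alignment(cfg)
        assert truth["n_excluded_nonsyn"] == 200
        tbl = classify_codon_switches(
            codons["NC"], codons["mat_a"], codons["mat_A"], TABLE
        )
        assert sum(tbl.n_pr_to_npr.values()) + sum(tbl.n_npr_to_pr.values()) == 0

    def test_switch_count_calibrated_and_recountable(self):
        """10,000 codons at mat-a PR->NPR rate 0.01: the truth count falls
        within 3 SE of its expectation and an independent recount of the
        emitted alignment reproduces it exactly."""
        cfg = SimulationConfig(
            seed=17, n_genes=20, gene_length_codons=500,
            switch_rates=SwitchRates(0, 0, 0.01, 0), nonsyn_rate=0.0,
        )
        codons, truth = simulate_codon_alignment(cfg)
        # eligible codons: preferred codons of degenerate families
        n = 20 * 500
        p_eligible = (18 / 20) * cfg.preferred_fraction
        expected = n * p_eligible * 0.01
        se = np.sqrt(n * p_eligible * 0.01 * (1 - p_eligible * 0.01))
        assert abs(truth["mat_a"]["pr_to_npr"] - expected) < 3 * se
        # independent recount oracle over the emitted codon strings
        idx_to_b = "ACGT"
        count = 0
        for i in range(n):
            c_nc = "".join(idx_to_b[b] for b in codons["NC"][i])
            c_a = "".join(idx_to_b[b] for b in codons["mat_a"][i])
            c_A = "".join(idx_to_b[b] for b in codons["mat_A"][i])
            if (
                TABLE.status.get(c_nc) == "PR"
                and TABLE.status.get(c_a) == "NPR"
                and TABLE.status.get(c_A) == "PR"
            ):
                count += 1
        assert count == truth["mat_a"]["pr_to_npr"]

    def test_truth_counts_sum_to_total(self):
        cfg = SimulationConfig(seed=9, n_genes=10, gene_length_codons=100)
        _, truth = simulate_codon_alignment(cfg)
        assert sum(truth["patterns"].values()) == 1000


class TestExcessAndFrequency:
    def test_recomputes_published_rows(self):
        """E and F recomputed from the published switch-count pairs and codon
        totals match the published values exactly at 2-decimal rounding."""
        expected = {
            ("L1", "mat_a"): (510, 1.80),
            ("L1", "mat_A"): (736, 2.60),
            ("L4", "mat_a"): (765, 2.70),
            ("L4", "mat_A"): (875, 3.09),
            ("L9", "mat_a"): (812, 2.87),
            ("L9", "mat_A"): (751, 2.66),
        }
        df = load_reference_switch_counts()
        for _, row in df.iterrows():
            e = int(row.n_pr_to_npr - row.n_npr_to_pr)
            f = round_half_up(e / row.total_codons * 1000, 2)
            assert (e, f) == expected[(row.lineage, row.allele)]

    def test_equal_counts_give_zero(self):
        from introscan.codons import CodonSwitchTable

        tbl = CodonSwitchTable(
            {"mat_a": 7, "mat_A": 7}, {"mat_a": 7, "mat_A": 7}, 100, 0, 0, 86
        )
        excess_and_frequency(tbl)
        assert tbl.excess == {"mat_a": 0, "mat_A": 0}
        assert tbl.frequency == {"mat_a": 0.0, "mat_A": 0.0}


class TestDegenerationSignTests:
    def _table(self, a_counts, A_counts, T=283_392):
        from introscan.codons import CodonSwitchTable

        return CodonSwitchTable(
            {"mat_a": a_counts[0], "mat_A": A_counts[0]},
            {"mat_a": a_counts[1], "mat_A": A_counts[1]},
            T, 0, 0, 0,
        )

    def test_published_counts_reject_net_accumulation(self):
        tests = degeneration_sign_tests(self._table((1308, 798), (1531, 795)))
        assert tests["net_mat_a"].p_value < 1e-10
        assert tests["net_mat_A"].p_value < 1e-10

    def test_balanced_counts_do_not_reject(self):
        tests = degeneration_sign_tests(self._table((100, 100), (100, 100)))
        assert tests["net_mat_a"].p_value == pytest.approx(1.0, abs=0.1)

    def test_between_allele_test_equals_enumeration(self):
        from .test_shared_sites import exact_two_sided_p

        tests = degeneration_sign_tests(self._table((20, 10), (25, 10)))
        # net test for mat_a: k=20, n=30
        assert tests["net_mat_a"].p_value == pytest.approx(
            exact_two_sided_p(20, 30), abs=1e-12
        )
        # between alleles: k = E(mat_A) = 15 of E sum 25
        assert tests["between_alleles"].p_value == pytest.approx(
            exact_two_sided_p(15, 25), abs=1e-12
        )

    def test_negative_excess_disables_between_test(self):
        tests = degeneration_sign_tests(self._table((5, 10), (20, 10)))
        assert not tests["between_alleles"].defined
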