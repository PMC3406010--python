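import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from introscan.alignment import remove_gap_columns
from introscan.simulate import (
    Centromere,
    ConfigError,
    LineageTree,
    SimulationConfig,
    SwitchRates,
    compose_divergence,
    replicate_config,
    simulate_dataset,
    split_branch,
    write_dataset,
)


def tiny_config(**overrides) -> SimulationConfig:
    base = dict(
        seed=2,
        chromosome_lengths={"LGI": 400_000, "LGII": 150_000},
        central_region=(100_000, 320_000),
        tract=(120_000, 300_000),
        centromere=Centromere(340_000, 370_000),
        n_genes=5,
        n_autosome_genes=3,
        gene_length_codons=60,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def dir_digest(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()


class TestConfigValidation:
    def test_tract_must_nest_in_central(self):
        with pytest.raises(ConfigError, match="nest"):
            tiny_config(tract=(50_000, 300_000)).validate()

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            tiny_config(chromosome_lengths={"LGI": 0}).validate()

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            tiny_config(nonsyn_rate=1.5).validate()

    def test_branch_composition_round_trip(self):
        for d in (0.0045, 0.024, 0.05):
            half = split_branch(d)
            assert compose_divergence(half, half) == pytest.approx(d, abs=1e-12)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = tiny_config()
        write_dataset(simulate_dataset(cfg), tmp_path / "run1")
        write_dataset(simulate_dataset(cfg), tmp_path / "run2")
        assert dir_digest(tmp_path / "run1") == dir_digest(tmp_path / "run2")

    def test_different_seed_differs(self, tmp_path):
        write_dataset(simulate_dataset(tiny_config(seed=2)), tmp_path / "a")
        write_dataset(simulate_dataset(tiny_config(seed=3)), tmp_path / "b")
        assert dir_digest(tmp_path / "a") != dir_digest(tmp_path / "b")


class TestNoMutationLimit:
    def test_all_zero_rates_give_identical_genomes(self):
        cfg = tiny_config(
            lineage_tree=LineageTree(0.0, 0.0, {"L1": 0.0, "L4": 0.0, "L9": 0.0}),
            intra_lineage_autosome_divergence=0.0,
            central_divergence=0.0,
            central_reference_divergence=0.0,
            donor_branch_length=0.0,
            switch_rates=SwitchRates(0, 0, 0, 0),
            nonsyn_rate=0.0,
            centromere=Centromere(340_000, 370_000, missing_fraction=0.0),
            gap_fraction=0.0,
        )
        ds = simulate_dataset(cfg)
        for chrom, arr in ds.core_alignment.chromosomes.items():
            for row in arr[1:]:
                np.testing.assert_array_equal(row, arr[0])
        for chrom, divs in ds.truth.realized_divergences.items():
            assert all(v == 0.0 for v in divs.values())


@pytest.fixture(scope="module")
def calib():
    """Gene-free dataset: calibration targets the pure substitution process."""
    return simulate_dataset(
        SimulationConfig(
            seed=13,
            chromosome_lengths={"LGI": 2_000_000, "LGII": 1_000_000},
            central_region=(400_000, 1_600_000),
            tract=(500_000, 1_500_000),
            centromere=Centromere(1_700_000, 1_800_000),
            n_genes=0,
            n_autosome_genes=0,
        )
    )


class TestCalibration:

    @staticmethod
    def naive_divergence(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
        """Site-by-site loop oracle over ASCII arrays."""
        n_comp = n_diff = 0
        bx, by = x.tobytes(), y.tobytes()
        for a, b in zip(bx, by):
            if chr(a) in "ACGT" and chr(b) in "ACGT":
                n_comp += 1
                n_diff += a != b
        return n_comp, n_diff

    def test_autosome_divergence_within_3_se(self, calib):
        core = calib.core_alignment
        d = calib.config.intra_lineage_autosome_divergence
        x = core.sequence("LGII", "L1A")
        y = core.sequence("LGII", "L1a")
        n_comp, n_diff = self.naive_divergence(x, y)
        se = np.sqrt(d * (1 - d) / n_comp)
        assert abs(n_diff / n_comp - d) < 3 * se

    def test_tract_divergences_within_3_se(self, calib):
        core = calib.core_alignment
        t0, t1 = calib.config.tract
        for pair, expected in [
            (("L9a", "NC"), calib.config.donor_branch_length),
            (("L9A", "NC"), calib.config.central_reference_divergence),
        ]:
            x = core.sequence("LGI", pair[0])[t0:t1]
            y = core.sequence("LGI", pair[1])[t0:t1]
            valid = (x != ord("N")) & (y != ord("N"))
            n_comp = int(valid.sum())
            n_diff = int((valid & (x != y)).sum())
            se = np.sqrt(expected * (1 - expected) / n_comp)
            assert abs(n_diff / n_comp - expected) < 3 * se

    def test_centromere_gc_within_3_se(self, calib):
        cen = calib.config.centromere
        seq = calib.core_alignment.sequence("LGI", "NC")[cen.start:cen.end]
        gc = 0
        counted = 0
        for b in seq.tobytes():
            if chr(b) in "ACGT":
                counted += 1
                gc += chr(b) in "GC"
        se = np.sqrt(cen.gc_level * (1 - cen.gc_level) / counted)
        assert abs(gc / counted - cen.gc_level) < 3 * se

    def test_centromere_missing_fraction(self, calib):
        cen = calib.config.centromere
        seq = calib.core_alignment.sequence("LGI", "L1A")[cen.start:cen.end]
        frac = float((seq == ord("N")).mean())
        se = np.sqrt(cen.missing_fraction * (1 - cen.missing_fraction) / seq.size)
        assert abs(frac - cen.missing_fraction) < 3 * se


class TestTruthAndStructure:
    def test_truth_intervals_equal_config(self, small_dataset):
        cfg = small_dataset.config
        truth = small_dataset.truth.regions
        assert truth["central"] == cfg.central_region
        assert truth["tract"] == cfg.tract
        assert truth["PA1"] == (0, cfg.central_region[0])
        assert truth["PA2"] == (
            cfg.central_region[1], cfg.chromosome_lengths["LGI"]
        )

    def test_gap_planting_and_trimming_are_inverse(self, small_dataset):
        cfg = small_dataset.config
        f = cfg.gap_fraction
        for chrom, core_len in cfg.chromosome_lengths.items():
            orig_len = small_dataset.alignment.length(chrom)
            assert orig_len == core_len + int(round(core_len * f / (1 - f)))
        trimmed, _ = remove_gap_columns(small_dataset.alignment)
        for chrom in cfg.chromosome_lengths:
            np.testing.assert_array_equal(
                trimmed.chromosomes[chrom],
                small_dataset.core_alignment.chromosomes[chrom],
            )

    def test_truth_json_round_trip(self, small_dataset, tmp_path):
        from introscan.simulate import TruthSet

        small_dataset.truth.to_json(tmp_path / "t.json")
        back = TruthSet.from_json(tmp_path / "t.json")
        assert back.regions == small_dataset.truth.regions
        assert back.codon_switch_counts == small_dataset.truth.codon_switch_counts

    def test_replicate_config_jitters_on_fine_grid(self):
        base = SimulationConfig()
        for seed in range(5):
            cfg = replicate_config(seed)
            c0, c1 = cfg.central_region
            t0, t1 = cfg.tract
            assert c0 % 10_000 == 0 and c1 % 10_000 == 0
            assert 0 <= c0 - base.central_region[0] <= 40_000
            assert 0 <= base.central_region[1] - c1 <= 40_000
            assert c0 <= t0 <= t1 <= c1
            cfg.validate()
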