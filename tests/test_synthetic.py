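"""Determinism and statistical structure of the synthetic-data generator."""

import numpy as np
import pytest

from ntacet import quant
from ntacet.io import read_quant_table, write_quant_table
from ntacet.nterm import natb_consensus
from ntacet.quant import LabelOrientation, compute_ratios, pair_replicates
from ntacet.synthetic import (
    SimulationConfig,
    generate_ortholog_groups,
    generate_phospho_table,
    generate_proteome,
    generate_quant_tables,
    write_run_directory,
)


SMALL = dict(n_proteins=300, n_natb_substrates=15, n_phospho_sites=300)


class TestProteome:
    def test_consensus_fraction_matches_config(self):
        config = SimulationConfig(seed=5)  # 4000 proteins, fraction 0.16
        proteome, _ = generate_proteome(config)
        frac = np.mean([natb_consensus(p.sequence[:2]) for p in proteome])
        assert frac == pytest.approx(0.16, abs=0.02)

    def test_zero_fraction_no_consensus_starts(self):
        config = SimulationConfig(
            seed=5, n_proteins=200, fraction_natb_consensus=0.0, n_natb_substrates=0
        )
        proteome, _ = generate_proteome(config)
        assert not any(natb_consensus(p.sequence[:2]) for p in proteome)

    def test_same_seed_identical_output(self):
        config = SimulationConfig(seed=9, **SMALL)
        a, _ = generate_proteome(config)
        b, _ = generate_proteome(config)
        assert a == b

    def test_substrates_are_consensus_proteins(self):
        config = SimulationConfig(seed=3, **SMALL)
        proteome, truth = generate_proteome(config)
        by_acc = {p.accession: p for p in proteome}
        assert len(truth.natb_substrates) == 15
        for acc in truth.natb_substrates:
            assert natb_consensus(by_acc[acc].sequence[:2])

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_proteome(SimulationConfig(seed=1, n_proteins=0))
        with pytest.raises(ValueError):
            generate_proteome(
                SimulationConfig(seed=1, n_proteins=20, n_natb_substrates=19,
                                 fraction_natb_consensus=0.1)
            )


@pytest.fixture(scope="module")
def world():
    config = SimulationConfig(seed=21, **SMALL)
    proteome, truth = generate_proteome(config)
    rep1, rep2 = generate_quant_tables(proteome, truth, config)
    return config, proteome, truth, rep1, rep2


class TestQuantTables:
    def test_tables_pass_io_schema_round_trip(self, world, tmp_path):
        _, _, _, rep1, _ = world
        path = tmp_path / "rep1.tsv"
        write_quant_table(rep1, path)
        assert read_quant_table(path, replicate_id=1) == rep1

    def test_planted_substrate_effect_recovered(self, world):
        config, _, truth, rep1, rep2 = world
        pairs = pair_replicates(compute_ratios(rep1), compute_ratios(rep2))
        acetyl = {
            p.accession: p.mean_ratio
            for p in pairs
            if p.modification == "ac" and p.accession in truth.natb_substrates
        }
        assert acetyl  # substrates are represented
        for ratio in acetyl.values():
            assert ratio == pytest.approx(config.natb_effect_log2, abs=1.0)
        assert np.mean(list(acetyl.values())) == pytest.approx(
            config.natb_effect_log2, abs=0.5
        )

    def test_null_proteins_within_noise_bound(self, world):
        config, _, truth, rep1, rep2 = world
        pairs = pair_replicates(compute_ratios(rep1), compute_ratios(rep2))
        bound = 3 * config.noise_sd / np.sqrt(2)
        null_ratios = [
            p.mean_ratio - truth.protein_effects[p.accession]
            for p in pairs
            if p.modification == "unmod" and p.n_replicates == 2
        ]
        inside = np.mean([abs(r) <= bound for r in null_ratios])
        assert inside > 0.98  # 3-sigma bound on centred ratios

    def test_unswapped_orientation_negates_rep2(self, world):
        _, _, _, rep1, rep2 = world
        swapped = compute_ratios(rep2)  # correct orientation (KO on 15N)
        unswapped = compute_ratios(
            rep2, LabelOrientation(ko_channel={2: "14N"})
        )
        for key, value in swapped.items():
            assert unswapped[key] == pytest.approx(-value)

    def test_singleton_replicate_rows_occur(self, world):
        _, _, _, rep1, rep2 = world
        pairs = pair_replicates(compute_ratios(rep1), compute_ratios(rep2))
        assert any(p.n_replicates == 1 for p in pairs)

    def test_determinism(self, world):
        config, proteome, truth, rep1, rep2 = world
        again1, again2 = generate_quant_tables(proteome, truth, config)
        assert again1 == rep1 and again2 == rep2


class TestPhospho:
    def test_up_fraction_recovered_through_quant(self):
        config = SimulationConfig(seed=13, n_proteins=300, n_natb_substrates=10,
                                  n_phospho_sites=2000)
        proteome, truth = generate_proteome(config)
        rep1, rep2, _, _, _ = generate_phospho_table(proteome, config, truth)
        pairs = pair_replicates(compute_ratios(rep1), compute_ratios(rep2))
        labels = [quant.classify_fold_change(p) for p in pairs]
        frac_up = labels.count("up") / len(labels)
        assert 0.18 <= frac_up <= 0.28

    def test_zero_sites_empty_outputs(self):
        config = SimulationConfig(seed=1, n_proteins=50, n_natb_substrates=2,
                                  n_phospho_sites=0)
        proteome, truth = generate_proteome(config)
        rep1, rep2, kin, loc, table = generate_phospho_table(proteome, config, truth)
        assert rep1 == [] and rep2 == [] and kin == {} and len(table) == 0

    def test_annotations_cover_every_site(self):
        config = SimulationConfig(seed=2, n_proteins=100, n_natb_substrates=5,
                                  n_phospho_sites=200)
        proteome, truth = generate_proteome(config)
        _, _, site_kinase, protein_loc, table = generate_phospho_table(
            proteome, config, truth
        )
        assert set(table["site_id"]) == set(site_kinase)
        assert set(table["accession"]) <= set(protein_loc)


class TestOrthologs:
    def test_full_conservation_probability(self):
        from ntacet.conservation import species_conservation

        config = SimulationConfig(seed=4, n_ortholog_groups=10, n_species=8,
                                  n_top_conserved=0, baseline_conservation=1.0)
        groups, _ = generate_ortholog_groups(config)
        for pct in species_conservation(groups).values():
            assert pct == pytest.approx(100.0)

    def test_determinism(self):
        config = SimulationConfig(seed=6, n_ortholog_groups=12, n_species=10)
        a, ta = generate_ortholog_groups(config)
        b, tb = generate_ortholog_groups(config)
        assert a == b and ta.conserved_top == tb.conserved_top


def test_run_directory_same_seed_identical_bytes(tmp_path):
    config = SimulationConfig(
        seed=17, n_proteins=60, n_natb_substrates=4, n_phospho_sites=40,
        n_ortholog_groups=6, n_species=5, n_top_conserved=2,
    )
    paths_a = write_run_directory(config, tmp_path / "a")
    paths_b = write_run_directory(config, tmp_path / "b")
    assert set(paths_a) == set(paths_b)
    for key in paths_a:
        assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key
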