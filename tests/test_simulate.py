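"""Ground-truth generation, forward simulation, and dataset persistence."""

import numpy as np
import pandas as pd
import pytest

from proturn import isotopologue as iso
from proturn import simulate


class TestGroundTruth:
    def test_empty_study_rejected(self):
        with pytest.raises(ValueError, match="n_proteins"):
            simulate.simulate_ground_truth(0)

    def test_deterministic_for_fixed_seed(self):
        a = simulate.simulate_ground_truth(20, seed=5)
        b = simulate.simulate_ground_truth(20, seed=5)
        assert a == b

    def test_point_mass_half_life_law(self):
        prots = simulate.simulate_ground_truth(
            10, half_life_law={"dist": "point", "value": 25.0}
        )
        assert all(p.true_half_life == 25.0 for p in prots)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.simulate_ground_truth(
                5, compartment_props={"mito": 0.5, "cyto": 0.2, "other": 0.2}
            )

    def test_compartment_specific_law(self):
        prots = simulate.simulate_ground_truth(
            200,
            half_life_law={"dist": "point", "value": 18.0},
            half_life_law_by_compartment={"mito": {"dist": "point", "value": 40.0}},
            seed=2,
        )
        mito = [p.true_half_life for p in prots if p.compartment == "mito"]
        rest = [p.true_half_life for p in prots if p.compartment != "mito"]
        assert set(mito) == {40.0} and set(rest) == {18.0}


class TestGeneratePeptides:
    def test_point_mass_count(self):
        prots = simulate.simulate_ground_truth(1, seed=0)
        peps = simulate.generate_peptides(
            prots, peptides_per_protein_law={"dist": "point", "value": 3}
        )
        assert len(peps) == 3
        assert {p.protein_id for p in peps} == {prots[0].protein_id}

    def test_zero_leucine_edge_case(self):
        prots = simulate.simulate_ground_truth(2, seed=0)
        peps = simulate.generate_peptides(
            prots, leu_count_law={"dist": "point", "value": 0}
        )
        assert all(p.n_leu == 0 for p in peps)

    def test_deterministic(self):
        prots = simulate.simulate_ground_truth(5, seed=1)
        assert simulate.generate_peptides(prots, seed=3) == simulate.generate_peptides(
            prots, seed=3
        )

    def test_unique_mapping(self):
        prots = simulate.simulate_ground_truth(10, seed=4)
        peps = simulate.generate_peptides(prots, seed=4)
        ids = [p.peptide_id for p in peps]
        assert len(ids) == len(set(ids))


class TestSimulateTimecourse:
    def test_one_half_life_elapsed_gives_half_new(self):
        # noiseless protein with t_half = 20 observed at t = 20: f = 0.5
        design = simulate.StudyDesign(
            time_points=(20.0,), groups=("young_EDL",), n_animals_per_group=1,
            noise_cv=0.0, missing_rate=0.0, enrichment_max=0.5,
        )
        prots = simulate.simulate_ground_truth(
            1, half_life_law={"dist": "point", "value": 20.0}
        )
        peps = simulate.generate_peptides(
            prots,
            peptides_per_protein_law={"dist": "point", "value": 1},
            leu_count_law={"dist": "point", "value": 2},
        )
        env = simulate.simulate_timecourse(prots, peps, design)
        inten = env.sort_values("channel")["intensity"].to_numpy()
        f = iso.deconvolve_fraction_new(inten, 0.5).f_hat
        assert f == pytest.approx(0.5, abs=1e-12)

    def test_fraction_new_monotone_in_time_and_half_life(self):
        design = simulate.StudyDesign(
            groups=("young_EDL",), n_animals_per_group=1, noise_cv=0.0,
            missing_rate=0.0,
        )
        prots = [
            simulate.GroundTruthProtein("Pfast", "other", 10.0, 1e6),
            simulate.GroundTruthProtein("Pslow", "other", 40.0, 1e6),
        ]
        peps = [
            simulate.GroundTruthPeptide(f"{p.protein_id}_pep1", p.protein_id, 2, 50.0, 1.0)
            for p in prots
        ]
        env = simulate.simulate_timecourse(prots, peps, design)
        fr, _ = iso.deconvolve_table(env, p=0.5)
        for pid in ("Pfast_pep1", "Pslow_pep1"):
            series = fr[fr["peptide_id"] == pid].sort_values("time_days")["percent_new"]
            assert series.is_monotonic_increasing
        merged = fr.pivot_table(index="time_days", columns="peptide_id", values="percent_new")
        assert (merged["Pfast_pep1"] > merged["Pslow_pep1"]).all()

    def test_channels_per_peptide(self, noiseless_design):
        prots = simulate.simulate_ground_truth(3, seed=1)
        peps = simulate.generate_peptides(prots, seed=1)
        env = simulate.simulate_timecourse(prots, peps, noiseless_design)
        counts = env.groupby(["peptide_id", "sample_id"]).size()
        n_leu = {p.peptide_id: p.n_leu for p in peps}
        for (pep, _), c in counts.items():
            assert c == n_leu[pep] + 1


class TestSimulateAbundances:
    def _study(self, effect, noise_cv, n_proteins=5, seed=0):
        design = simulate.StudyDesign(
            groups=("young_EDL", "old_EDL"), n_animals_per_group=2,
            noise_cv=noise_cv, missing_rate=0.0, seed=seed,
        )
        prots = [
            simulate.GroundTruthProtein(
                f"P{i}", "other", 20.0, 1e6, group_log2_effect=effect
            )
            for i in range(n_proteins)
        ]
        peps = simulate.generate_peptides(prots, seed=seed)
        return prots, peps, simulate.simulate_abundances(prots, peps, design)

    def test_noiseless_effect_doubles_auc(self):
        _, _, auc = self._study(effect=1.0, noise_cv=0.0)
        wide = auc.pivot_table(index="peptide_id", columns="group", values="auc")
        np.testing.assert_allclose(wide["old_EDL"] / wide["young_EDL"], 2.0)

    def test_null_effect_centered_at_unit_ratio(self):
        from proturn.abundance import abundance_table

        _, _, auc = self._study(effect=0.0, noise_cv=0.2, n_proteins=60, seed=9)
        res = abundance_table(auc, "young_EDL", "old_EDL")
        # 60 null proteins: mean log2 fold change ~ N(0, ~0.02)
        assert abs(res["log2_fc_old_over_young"].mean()) < 0.06

    def test_deterministic(self):
        _, _, a = self._study(effect=0.3, noise_cv=0.1, seed=11)
        _, _, b = self._study(effect=0.3, noise_cv=0.1, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestWriteDataset:
    def test_roundtrip(self, tmp_path, small_design):
        study = simulate.simulate_study(5, small_design)
        paths = simulate.write_dataset(
            {k: study[k] for k in ("envelope", "abundance", "ground_truth")}, tmp_path
        )
        back = pd.read_csv(paths["envelope"], sep="\t")
        pd.testing.assert_frame_equal(back, study["envelope"], check_dtype=False)

    def test_empty_table_writes_header_only(self, tmp_path):
        from proturn import io

        empty = pd.DataFrame(columns=io.ENVELOPE_COLUMNS)
        paths = simulate.write_dataset({"envelope": empty}, tmp_path)
        text = paths["envelope"].read_text().strip().splitlines()
        assert len(text) == 1 and text[0].split("\t") == io.ENVELOPE_COLUMNS

    def test_ground_truth_one_row_per_protein(self, tmp_path):
        prots = simulate.simulate_ground_truth(7, seed=2)
        gt = simulate.ground_truth_frame(prots)
        assert len(gt) == 7 and gt["protein_id"].is_unique

    def test_identical_seeds_byte_identical_files(self, tmp_path, small_design):
        for sub in ("a", "b"):
            study = simulate.simulate_study(4, small_design)
            simulate.write_dataset({"envelope": study["envelope"]}, tmp_path / sub)
        assert (tmp_path / "a/envelope.tsv").read_bytes() == (
            tmp_path / "b/envelope.tsv"
        ).read_bytes()
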