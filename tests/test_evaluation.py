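"""Metrics, ranking, similarity computations and generalization filtering."""

from __future__ import annotations

import math
import stat

import numpy as np
import pandas as pd
import pytest

from affinity_attn.evaluation import (
    AlignerNotFoundError,
    SimilarityRecord,
    average_rank,
    generalization_filter,
    ligand_fingerprint,
    ligand_tanimoto,
    max_similarity_to_training,
    protein_similarity,
    regression_metrics,
)
from affinity_attn.synthetic import generate_complex, make_two_contact_fixture


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        y = np.array([2.0, 4.0, 6.0, 8.0])
        m = regression_metrics(y, y)
        assert (m.mae, m.rmse, m.sd) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
        assert m.pcc == pytest.approx(1.0)
        assert m.scc == pytest.approx(1.0)

    def test_perfect_linear_scaling_has_zero_sd_but_nonzero_mae(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, 2 * y)
        assert m.pcc == pytest.approx(1.0)
        assert m.scc == pytest.approx(1.0)
        assert m.sd == pytest.approx(0.0, abs=1e-9)
        assert m.mae > 0

    def test_five_point_hand_worked_values(self):
        y_true = [2.0, 4.0, 6.0, 8.0, 10.0]
        y_pred = [2.5, 3.5, 6.5, 7.0, 10.5]
        m = regression_metrics(y_true, y_pred)
        # independent closed-form computation (sums by hand)
        yt, yp = np.asarray(y_true), np.asarray(y_pred)
        pcc = np.sum((yt - yt.mean()) * (yp - yp.mean())) / math.sqrt(
            np.sum((yt - yt.mean()) ** 2) * np.sum((yp - yp.mean()) ** 2)
        )
        assert m.mae == pytest.approx(0.6)
        assert m.rmse == pytest.approx(0.6324555)
        assert m.pcc == pytest.approx(pcc)
        assert m.scc == pytest.approx(1.0)  # order preserved
        assert m.sd == pytest.approx(0.7026735)

    def test_affine_transform_of_predictions_preserves_correlations_and_sd(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5, 2, 30)
        p = y + rng.normal(0, 1, 30)
        base = regression_metrics(y, p)
        shifted = regression_metrics(y, 3.5 * p - 2.0)
        assert shifted.pcc == pytest.approx(base.pcc)
        assert shifted.scc == pytest.approx(base.scc)
        assert shifted.sd == pytest.approx(base.sd)

    def test_rmse_dominates_mae_and_sd(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        p = y + rng.normal(0, 0.5, 50)
        m = regression_metrics(y, p)
        assert m.rmse >= m.mae
        assert m.sd <= m.rmse

    def test_input_validation(self):
        with pytest.raises(ValueError):
            regression_metrics([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            regression_metrics([1.0, 1.0, 1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            regression_metrics([1, 2], [1, 2])


class TestAverageRank:
    def test_strict_winner_ranks_first_everywhere(self):
        table = pd.DataFrame(
            {"ds1": [0.9, 0.5, 0.3], "ds2": [0.8, 0.6, 0.2]},
            index=["best", "mid", "worst"],
        )
        ranks = average_rank(table, higher_is_better=True)
        assert ranks["best"] == 1.0
        assert ranks["worst"] == 3.0

    def test_ties_share_the_average_rank(self):
        table = pd.DataFrame({"ds": [0.7, 0.7, 0.1]}, index=["a", "b", "c"])
        ranks = average_rank(table, higher_is_better=True)
        assert ranks["a"] == ranks["b"] == 1.5

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        got = average_rank(table, higher_is_better=False)
        expected = np.zeros(5)
        for col in table.columns:
            values = table[col].to_numpy()
            for i, v in enumerate(values):
                less = np.sum(values < v)
                equal = np.sum(values == v)
                expected[i] += less + (equal + 1) / 2
        expected /= len(table.columns)
        assert got.to_numpy() == pytest.approx(expected)

    def test_per_dataset_ranks_sum_correctly(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.normal(size=(6, 3)))
        ranks = table.rank(axis=0, method="average")
        assert np.allclose(ranks.sum(axis=0), 6 * 7 / 2)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"ds": [1.0, np.nan]})
        with pytest.raises(ValueError):
            average_rank(table, higher_is_better=True)


class TestLigandTanimoto:
    def test_identical_ligands_score_one(self):
        s = generate_complex(4, n_ligand=8, n_pocket=5, contact_density=0.5)
        assert ligand_tanimoto(s, s) == 1.0

    def test_disjoint_fingerprints_score_zero(self):
        a = generate_complex(11, n_ligand=1, n_pocket=2, contact_density=0.0)
        b = generate_complex(12, n_ligand=1, n_pocket=2, contact_density=0.0)
        fa, fb = ligand_fingerprint(a), ligand_fingerprint(b)
        if fa & fb:
            pytest.skip("single-atom fingerprints unexpectedly collide")
        assert ligand_tanimoto(a, b) == 0.0 or a.ligand_atoms()[0].element == b.ligand_atoms()[0].element

    @pytest.mark.parametrize("seeds", [(1, 2), (3, 8)])
    def test_matches_bit_set_arithmetic(self, seeds):
        a = generate_complex(seeds[0], n_ligand=9, n_pocket=4, contact_density=0.3)
        b = generate_complex(seeds[1], n_ligand=7, n_pocket=4, contact_density=0.3)
        fa, fb = ligand_fingerprint(a), ligand_fingerprint(b)
        expected = len(fa & fb) / len(fa | fb)
        assert ligand_tanimoto(a, b) == pytest.approx(expected)


TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  ALA B   1       0.000   5.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA B   2       3.800   5.000   0.000  1.00  0.00           C
TER
END
"""


def _stub_score(name_a: str, name_b: str) -> float:
    return 0.30 + ((len(name_a) * 7 + len(name_b) * 13 + ord(name_a[-5]) + ord(name_b[-5])) % 40) / 100


@pytest.fixture
def tmalign_stub(tmp_path):
    """Synthetic stand-in for the TM-align executable (deterministic scores)."""
    calls = tmp_path / "calls.txt"
    script = tmp_path / "TMalign"
    script.write_text(
        "#!/usr/bin/env python\n"
        "import sys, os\n"
        f"open({str(calls)!r}, 'a').write(' '.join(sys.argv[1:]) + '\\n')\n"
        "a, b = [os.path.basename(p) for p in sys.argv[1:3]]\n"
        "score = 0.30 + ((len(a)*7 + len(b)*13 + ord(a[-5]) + ord(b[-5])) % 40) / 100\n"
        "print('Length of Chain_1: 100 residues')\n"
        "print('Length of Chain_2: 120 residues')\n"
        "print(f'TM-score= {score:.5f} (if normalized by length of Chain_1)')\n"
        "print(f'TM-score= {score*0.9:.5f} (if normalized by length of Chain_2)')\n"
    )
    script.chmod(script.stat().st_mode | stat.S_IEXEC)
    return script, calls


class TestProteinSimilarity:
    def test_missing_aligner_raises_with_install_hint(self, tmp_path):
        (tmp_path / "a.pdb").write_text(TWO_CHAIN_PDB)
        with pytest.raises(AlignerNotFoundError, match="TM-align"):
            protein_similarity(tmp_path / "a.pdb", tmp_path / "a.pdb", executable="definitely-not-a-tool")

    def test_chain_pairs_enumerated_and_min_max_parsed(self, tmp_path, tmalign_stub):
        script, calls = tmalign_stub
        (tmp_path / "qa.pdb").write_text(TWO_CHAIN_PDB)
        (tmp_path / "qb.pdb").write_text(TWO_CHAIN_PDB)
        lowest = protein_similarity(tmp_path / "qa.pdb", tmp_path / "qb.pdb", "lowest", str(script))
        highest = protein_similarity(tmp_path / "qa.pdb", tmp_path / "qb.pdb", "highest", str(script))
        invocations = calls.read_text().strip().splitlines()
        assert len(invocations) == 8  # 2x2 chain pairs for each of the two calls
        expected = [
            _stub_score(f"qa_{ca}.pdb", f"qb_{cb}.pdb") for ca in "AB" for cb in "AB"
        ]
        assert lowest == pytest.approx(min(expected))
        assert highest == pytest.approx(max(expected))
        assert lowest <= highest

    def test_bad_mode_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            protein_similarity(tmp_path / "x.pdb", tmp_path / "y.pdb", mode="median")


class TestMaxSimilarityToTraining:
    def test_ligand_present_in_training_scores_one(self):
        test = generate_complex(21, n_ligand=8, n_pocket=5, contact_density=0.4)
        training = [generate_complex(s, n_ligand=6, n_pocket=5, contact_density=0.4) for s in (22, 23)]
        assert max_similarity_to_training(test, training + [test], kind="ligand") == 1.0

    def test_singleton_training_equals_pairwise_value(self):
        a = generate_complex(24, n_ligand=8, n_pocket=5, contact_density=0.4)
        b = generate_complex(25, n_ligand=8, n_pocket=5, contact_density=0.4)
        assert max_similarity_to_training(a, [b], kind="ligand") == pytest.approx(ligand_tanimoto(a, b))

    def test_matches_brute_force_max_over_training(self):
        test = generate_complex(26, n_ligand=8, n_pocket=5, contact_density=0.4)
        training = [generate_complex(s, n_ligand=7, n_pocket=5, contact_density=0.4) for s in range(30, 35)]
        expected = max(ligand_tanimoto(test, t) for t in training)
        assert max_similarity_to_training(test, training, kind="ligand") == pytest.approx(expected)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            max_similarity_to_training(make_two_contact_fixture(), [], kind="ligand")


class TestGeneralizationFilter:
    records = [
        SimilarityRecord(f"c{i}", protein_sim=p, ligand_sim=l)
        for i, (p, l) in enumerate([(0.2, 0.9), (0.8, 0.1), (0.45, 0.55), (0.99, 0.98)])
    ]

    def test_threshold_above_one_keeps_everything(self):
        assert generalization_filter(self.records, protein_threshold=1.01) == self.records

    def test_threshold_zero_removes_everything(self):
        assert generalization_filter(self.records, ligand_threshold=0.0) == []

    @pytest.mark.parametrize("threshold", [0.3, 0.5, 0.9])
    def test_matches_list_comprehension_oracle(self, threshold):
        got = generalization_filter(self.records, protein_threshold=threshold)
        assert got == [r for r in self.records if r.protein_sim < threshold]
        got = generalization_filter(self.records, ligand_threshold=threshold)
        assert got == [r for r in self.records if r.ligand_sim < threshold]

    def test_some_threshold_is_mandatory(self):
        with pytest.raises(ValueError):
            generalization_filter(self.records)
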