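import io

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from idrscape.evolution import (
    AA_MODEL_ORDER,
    Alignment,
    center_star_msa,
    load_model,
    mean_region_distance,
    nj_tree,
    pair_distance,
    pairwise_align,
    region_subalignment,
)
from idrscape.synthetic import FamilyConfig, simulate_family

from _oracles import dp_align_score, grid_ml_distance


class TestModels:
    @pytest.mark.parametrize("name", ["dayhoff", "jtt"])
    def test_generator_properties(self, name):
        m = load_model(name)
        Q = m.rate_matrix
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert m.pi.sum() == pytest.approx(1.0)
        # detailed balance and unit expected rate
        flux = m.pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-14)
        assert -np.sum(m.pi * np.diag(Q)) == pytest.approx(1.0)

    @pytest.mark.parametrize("name", ["dayhoff", "jtt"])
    def test_transition_matrix_is_stochastic(self, name):
        m = load_model(name)
        for t in (0.01, 0.5, 5.0):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12
        assert np.allclose(m.transition_matrix(0.0), np.eye(20), atol=1e-10)


class TestPairwiseAlign:
    def test_identity(self):
        aln = pairwise_align(("a", "ACD"), ("b", "ACD"))
        assert aln.records == [("a", "ACD"), ("b", "ACD")]

    def test_single_gap(self):
        aln = pairwise_align(("a", "ACD"), ("b", "AD"))
        assert aln.row("a") == "ACD"
        assert aln.row("b").count("-") == 1
        assert aln.row("b").replace("-", "") == "AD"

    def test_scores_match_dp_oracle(self, rng, random_peptide):
        blosum = substitution_matrices.load("BLOSUM62")
        for _ in range(15):
            a, b = random_peptide(12), random_peptide(12)
            aln = pairwise_align(("a", a), ("b", b))
            assert aln.score == pytest.approx(dp_align_score(a, b, blosum, -11.0, -1.0))


class TestCenterStar:
    def test_identical_sequences_gap_free(self):
        aln = center_star_msa([("a", "ACDEF"), ("b", "ACDEF"), ("c", "ACDEF")])
        assert all("-" not in s for _, s in aln.records)

    def test_two_sequences_reduce_to_pairwise(self):
        msa = center_star_msa([("a", "ACDKF"), ("b", "ACF")])
        pw = pairwise_align(("a", "ACDKF"), ("b", "ACF"))
        assert {r for r in msa.records} == {r for r in pw.records}

    def test_ungapping_recovers_inputs(self):
        seqs = [("a", "MKTAYIAK"), ("b", "MKTAIAK"), ("c", "MKTAYIAKQR")]
        aln = center_star_msa(seqs)
        for rid, seq in seqs:
            assert aln.ungapped(rid) == seq


class TestRegionSubalignment:
    MSA = Alignment(records=[("ref", "A-CD"), ("hom", "AQCD")])

    def test_whole_region(self):
        sub = region_subalignment(self.MSA, "ref", 1, 3)
        assert sub.records == self.MSA.records

    def test_gapped_columns(self):
        # reference residues 2..3 (C, D) sit in columns 3-4
        sub = region_subalignment(self.MSA, "ref", 2, 3)
        assert sub.records == [("ref", "CD"), ("hom", "CD")]

    def test_single_residue_region(self):
        sub = region_subalignment(self.MSA, "ref", 2, 2)
        assert sub.records == [("ref", "C"), ("hom", "C")]

    def test_interior_gap_columns_are_kept(self):
        msa = Alignment(records=[("ref", "AC--DE"), ("hom", "ACQWDE")])
        sub = region_subalignment(msa, "ref", 2, 3)
        assert sub.row("ref") == "C--D"
        assert sub.row("hom") == "CQWD"

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            region_subalignment(self.MSA, "ref", 2, 9)


class TestPairDistance:
    @pytest.mark.parametrize("model", ["p_distance", "dayhoff", "jtt"])
    def test_identical_rows_are_zero(self, model):
        assert pair_distance("ACDEF", "ACDEF", model).distance == 0.0

    def test_p_distance_count(self):
        result = pair_distance("AAAA", "AAAT", "p_distance")
        assert result.distance == pytest.approx(0.25)
        assert result.sites == 4

    def test_gap_sites_excluded_pairwise(self):
        result = pair_distance("AC-E", "A-DE", "p_distance")
        assert result.sites == 2

    def test_all_gaps_undefined(self):
        result = pair_distance("A--", "-CC", "p_distance")
        assert not result.defined

    def test_correction_rarely_and_barely_shortens(self, rng):
        # The multiple-hit correction lengthens distances in the typical
        # regime. It is not a pointwise theorem: when the few observed
        # differences concentrate on high-exchangeability pairs (e.g. I-V)
        # the ML distance can dip slightly below the p-distance, a
        # behaviour shared by reference ML-distance implementations. Assert
        # the statistical form: violations are rare and small.
        aas = list(AA_MODEL_ORDER)
        checked = violations = 0
        for _ in range(1000):
            a = "".join(rng.choice(aas, size=60))
            b = list(a)
            for pos in rng.choice(60, size=rng.integers(1, 25), replace=False):
                b[pos] = aas[int(rng.integers(20))]
            b = "".join(b)
            p = pair_distance(a, b, "p_distance").distance
            for model in ("dayhoff", "jtt"):
                ml = pair_distance(a, b, model)
                if ml.capped:
                    continue
                checked += 1
                if ml.distance < p - 1e-9:
                    violations += 1
                    assert ml.distance >= 0.5 * p  # never a gross shortening
        assert violations <= 0.02 * checked

    def test_ml_matches_grid_oracle(self):
        fam = simulate_family(
            FamilyConfig(root_length=200, n_leaves=2, branch_length=0.25, seed=42,
                         multipliers={"ordered": 1.0, "disordered": 1.0})
        )
        (_, a), (_, b) = fam.alignment.records
        for model in ("dayhoff", "jtt"):
            mine = pair_distance(a, b, model).distance
            assert mine == pytest.approx(grid_ml_distance(a, b, model), abs=1e-3)

    def test_simulation_recovery_at_known_distance(self):
        # two leaves at branch length 0.25 are separated by t = 0.5
        estimates = []
        for seed in range(50):
            fam = simulate_family(
                FamilyConfig(root_length=200, n_leaves=2, branch_length=0.25,
                             seed=seed, multipliers={"ordered": 1.0, "disordered": 1.0})
            )
            (_, a), (_, b) = fam.alignment.records
            estimates.append(pair_distance(a, b, "jtt").distance)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)


class TestMeanRegionDistance:
    def test_identical_alignment(self):
        aln = Alignment(records=[("a", "ACDE"), ("b", "ACDE"), ("c", "ACDE")])
        assert mean_region_distance(aln, "p_distance").mean == 0.0

    def test_two_rows_reduce_to_pair(self):
        aln = Alignment(records=[("a", "AAAA"), ("b", "AAAT")])
        assert mean_region_distance(aln, "p_distance").mean == pytest.approx(0.25)

    def test_mean_is_average_of_upper_triangle(self):
        # 4 rows of length 10 with hand-built pairwise p-distances
        aln = Alignment(
            records=[
                ("a", "AAAAAAAAAA"),
                ("b", "CAAAAAAAAA"),
                ("c", "CCAAAAAAAA"),
                ("d", "CCCAAAAAAA"),
            ]
        )
        est = mean_region_distance(aln, "p_distance")
        # pairs: ab .1, ac .2, ad .3, bc .1, bd .2, cd .1
        assert est.mean == pytest.approx((0.1 + 0.2 + 0.3 + 0.1 + 0.2 + 0.1) / 6)

    def test_concatenation_mean_between_region_means(self):
        fam = simulate_family(FamilyConfig(root_length=200, n_leaves=4, seed=9))
        aln = fam.alignment
        left = Alignment(records=[(i, s[:100]) for i, s in aln.records])
        right = Alignment(records=[(i, s[100:]) for i, s in aln.records])
        m_left = mean_region_distance(left, "p_distance").mean
        m_right = mean_region_distance(right, "p_distance").mean
        m_all = mean_region_distance(aln, "p_distance").mean
        assert min(m_left, m_right) <= m_all <= max(m_left, m_right)
        assert m_all == pytest.approx((m_left + m_right) / 2, abs=1e-12)

    def test_complete_deletion_drops_gapped_columns(self):
        aln = Alignment(records=[("a", "AC-E"), ("b", "ACDE"), ("c", "ACTE")])
        est = mean_region_distance(aln, "p_distance", complete_deletion=True)
        assert est.sites.iloc[0, 1] == 3


class TestNJTree:
    def test_three_taxa(self):
        aln = Alignment(records=[("a", "AAAA"), ("b", "AAAC"), ("c", "AACC")])
        newick = nj_tree(mean_region_distance(aln, "p_distance"))
        assert newick.count(",") == 2 and newick.endswith(";")

    def test_additive_matrix_reproduced_exactly(self):
        import pandas as pd
        from skbio import TreeNode

        from idrscape.evolution import DistanceEstimate

        ids = ["A", "B", "C", "D"]
        # tree ((A:1,B:2):1,(C:3,D:4))
        mat = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=ids, columns=ids, dtype=float,
        )
        est = DistanceEstimate("p_distance", mat, mat * 0, [], [])
        tree = TreeNode.read(io.StringIO(nj_tree(est)))
        dm = tree.tip_tip_distances(ids)
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                assert dm[x, y] == pytest.approx(mat.iloc[i, j], abs=1e-9)

    def test_known_topology_recovered(self):
        import pandas as pd
        from skbio import TreeNode

        from idrscape.evolution import DistanceEstimate

        ids = ["A", "B", "C", "D", "E"]
        # ultrametric caterpillar: ((((A,B),C),D),E)
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        heights = {("A", "B"): 2, ("A", "C"): 4, ("B", "C"): 4,
                   ("A", "D"): 6, ("B", "D"): 6, ("C", "D"): 6,
                   ("A", "E"): 8, ("B", "E"): 8, ("C", "E"): 8, ("D", "E"): 8}
        for (x, y), h in heights.items():
            mat.loc[x, y] = mat.loc[y, x] = float(h)
        est = DistanceEstimate("p_distance", mat, mat * 0, [], [])
        tree = TreeNode.read(io.StringIO(nj_tree(est)))
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_flagged_entries_rejected(self):
        import pandas as pd

        from idrscape.evolution import DistanceEstimate

        ids = ["a", "b", "c"]
        mat = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=ids, columns=ids)
        est = DistanceEstimate("jtt", mat, mat * 0, [("a", "b")], [])
        with pytest.raises(ValueError, match="capped"):
            nj_tree(est)
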