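import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

import forestbeta as fb
from forestbeta.beta_diversity import (
    bst_pair,
    chao_jaccard_dissimilarity,
    enumerate_pairs,
    mean_pairwise_between,
    mean_pairwise_within,
    pairwise_stats,
)
from forestbeta.data_io import ValidationError
from forestbeta.trait_space import DistanceMatrix
from _oracles import bst_oracle, chao_jaccard_oracle, mean_pairwise_oracle, random_instance


def dmat(vals):
    vals = np.asarray(vals, float)
    return DistanceMatrix([f"s{i}" for i in range(len(vals))], vals)


class TestChaoJaccard:
    def test_identical_communities(self):
        assert chao_jaccard_dissimilarity([5, 3], [5, 3]) == pytest.approx(0.0)

    def test_disjoint_communities(self):
        assert chao_jaccard_dissimilarity([5, 0], [0, 7]) == 1.0

    def test_single_shared_species_frozen_value(self):
        # straight-from-formula oracle value, independently confirmed by
        # vegan's chao index: U = 10/11, V = 8/10 -> 1 - UV/(U+V-UV)
        got = chao_jaccard_dissimilarity([10, 1, 0], [8, 0, 2])
        assert got == pytest.approx(0.25925925925, abs=1e-9)
        assert got == pytest.approx(chao_jaccard_oracle([10, 1, 0], [8, 0, 2]))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            chao_jaccard_dissimilarity([0, 0], [1, 2])

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            x, y, _ = random_instance(rng)
            assert chao_jaccard_dissimilarity(x, y) == pytest.approx(
                chao_jaccard_oracle(x, y), abs=1e-12
            )

    def test_matches_vegan_reference(self, tmp_path):
        """Independent cross-check against the vegan implementation."""
        rng = np.random.default_rng(7)
        mats = []
        for _ in range(5):
            x, y, _ = random_instance(rng, max_species=6)
            mats.append((x, y))
        width = max(len(x) for x, _ in mats)
        lines = []
        for x, y in mats:  # zero-pad so all rows share one width
            lines.append("\t".join(map(str, list(x) + [0] * (width - len(x)))))
            lines.append("\t".join(map(str, list(y) + [0] * (width - len(y)))))
        (tmp_path / "counts.tsv").write_text("\n".join(lines) + "\n")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            m <- as.matrix(read.table("counts.tsv", sep="\\t"))
            out <- c()
            for (i in seq(1, nrow(m), by=2)) {
              out <- c(out, as.numeric(vegdist(m[i:(i+1),], method="chao")))
            }
            cat(sprintf("%.12f", out), sep="\\n")
            """
        )
        (tmp_path / "chao.R").write_text(script)
        res = subprocess.run(
            ["Rscript", "chao.R"], cwd=tmp_path, capture_output=True, text=True, timeout=120
        )
        assert res.returncode == 0, res.stderr
        ref = [float(v) for v in res.stdout.split()]
        ours = [chao_jaccard_dissimilarity(x, y) for x, y in mats]
        assert np.allclose(ours, ref, atol=1e-9)


class TestMeanPairwise:
    def test_disjoint_monocultures(self):
        D = dmat([[0, 2], [2, 0]])
        val, deg = mean_pairwise_between([1, 0], [0, 1], D)
        assert val == pytest.approx(2.0) and not deg

    def test_even_two_species_worked_case(self):
        D = dmat([[0, 2], [2, 0]])
        val, _ = mean_pairwise_between([0.5, 0.5], [0.5, 0.5], D)
        assert val == pytest.approx(2.0)
        within, _ = mean_pairwise_within([0.5, 0.5], D)
        assert within == pytest.approx(2.0)

    def test_identical_monocultures_degenerate(self):
        D = dmat([[0, 2], [2, 0]])
        val, deg = mean_pairwise_between([1, 0], [1, 0], D)
        assert val == 0.0 and deg

    def test_constant_distance_identity(self):
        d = 3.3
        D = dmat(d * (1 - np.eye(3)))
        val, _ = mean_pairwise_within([1 / 3, 1 / 3, 1 / 3], D)
        assert val == pytest.approx(d)

    def test_label_mismatch_rejected(self):
        D = dmat([[0, 2], [2, 0]])
        f = pd.Series([0.5, 0.5], index=["x", "y"])
        with pytest.raises(ValidationError, match="labels"):
            mean_pairwise_between(f, f, D)


class TestBst:
    def test_identical_communities_zero_turnover(self):
        D = dmat([[0, 1, 4], [1, 0, 2], [4, 2, 0]])
        f = [0.2, 0.5, 0.3]
        assert bst_pair(f, f, D) == pytest.approx(0.0)

    def test_complete_turnover_between_monocultures(self):
        D = dmat([[0, 2], [2, 0]])
        assert bst_pair([1, 0], [0, 1], D) == pytest.approx(1.0)

    def test_three_species_worked_pair_against_oracle(self):
        # distances from the 1-D UPGMA example (cophenetic 1 / 4.5 / 4.5)
        D = np.array([[0, 1, 4.5], [1, 0, 4.5], [4.5, 4.5, 0]])
        fk, fl = [0.5, 0.5, 0.0], [0.0, 0.5, 0.5]
        got = bst_pair(fk, fl, dmat(D))
        assert got == pytest.approx(bst_oracle(fk, fl, D), abs=1e-12)

    def test_undefined_for_identical_monocultures(self):
        D = dmat([[0, 2], [2, 0]])
        assert np.isnan(bst_pair([1, 0], [1, 0], D))

    def test_symmetry_and_scale_invariance(self, rng):
        for _ in range(20):
            x, y, D = random_instance(rng)
            fk = x / x.sum()
            fl = y / y.sum()
            dm = dmat(D)
            b1 = bst_pair(fk, fl, dm)
            b2 = bst_pair(fl, fk, dm)
            b3 = bst_pair(fk, fl, dmat(7.5 * D))
            if np.isnan(b1):
                assert np.isnan(b2) and np.isnan(b3)
            else:
                assert b2 == pytest.approx(b1, abs=1e-12)
                assert b3 == pytest.approx(b1, abs=1e-10)

    def test_vectorized_matches_scalar_path(self, rng):
        for _ in range(20):
            x, y, D = random_instance(rng)
            F = np.vstack([x / x.sum(), y / y.sum()])
            stats = pairwise_stats(F, D, np.array([0]), np.array([1]))
            expect = bst_pair(F[0], F[1], dmat(D))
            if np.isnan(expect):
                assert np.isnan(stats["bst"][0])
            else:
                assert stats["bst"][0] == pytest.approx(expect, abs=1e-12)

    def test_raw_variant_is_unnormalized_mean(self, rng):
        x, y, D = random_instance(rng)
        fk, fl = x / x.sum(), y / y.sum()
        val, _ = mean_pairwise_between(fk, fl, dmat(D), variant="raw")
        expect, _ = mean_pairwise_oracle(fk, fl, D, species_centered=False)
        assert val == pytest.approx(expect, abs=1e-12)


class TestPairEnumeration:
    @staticmethod
    def _meta(n_plots, subplots_per_plot, regimes):
        rows = []
        for p in range(n_plots):
            for s in range(subplots_per_plot):
                rows.append({"plot_id": p + 1, "regime": regimes[p]})
        return pd.DataFrame(rows)

    def test_within_plot_pair_count_grain20(self):
        meta = self._meta(1, 25, [1])
        ki, li = enumerate_pairs(meta, "within")
        assert len(ki) == 300  # C(25, 2)

    def test_between_plot_pair_count_one_regime(self):
        meta = self._meta(3, 25, [1, 1, 1])
        ki, li = enumerate_pairs(meta, "between")
        assert len(ki) == 3 * 625

    def test_within_pairs_grain10_nine_plots(self):
        meta = self._meta(9, 100, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        ki, li = enumerate_pairs(meta, "within")
        assert len(ki) == 9 * (100 * 99 // 2)

    def test_between_pairs_respect_regime(self):
        meta = self._meta(4, 2, [1, 1, 2, 2])
        ki, li = enumerate_pairs(meta, "between")
        plots = meta["plot_id"].to_numpy()
        regs = meta["regime"].to_numpy()
        assert (regs[ki] == regs[li]).all()
        assert (plots[ki] != plots[li]).all()


class TestPairTable:
    def test_columns_and_level_semantics(self, reduced_neutral):
        cm = fb.grid_stems(reduced_neutral.stems, 25)
        Dphy = fb.phylo_cophenetic_distance(reduced_neutral.phylogeny)
        pairs = fb.pair_table(
            cm, Dphy, habitat=reduced_neutral.habitat, plots=reduced_neutral.plots,
            level="within",
        )
        assert (pairs["plot_k"] == pairs["plot_l"]).all()
        assert (pairs["spatial_distance"] > 0).all()
        assert (pairs["habitat_distance"] >= 0).all()
        assert pairs["bst"].abs().max() <= 1.0 + 1e-9

    def test_between_level_spans_plots(self, reduced_neutral):
        cm = fb.grid_stems(reduced_neutral.stems, 25)
        Dphy = fb.phylo_cophenetic_distance(reduced_neutral.phylogeny)
        pairs = fb.pair_table(cm, Dphy, plots=reduced_neutral.plots, level="between")
        assert (pairs["plot_k"] != pairs["plot_l"]).all()
        assert (pairs["group"].str.contains(r"\|")).all()
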