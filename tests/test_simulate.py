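"""Tests for the synthetic data generators: determinism, truth, and geometry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gilakit import simulate, phylo
from gilakit.simulate import SimConfig, MorphoSimConfig
from gilakit._util import stage_rng
from gilakit.rad_filtering import MISSING_GT


# ---------------------------------------------------------------------------
# RNG plumbing


def test_stage_rng_reproducible_and_stage_separated():
    a1 = stage_rng(7, "alpha").random(5)
    a2 = stage_rng(7, "alpha").random(5)
    b = stage_rng(7, "beta").random(5)
    np.testing.assert_array_equal(a1, a2)
    assert not np.array_equal(a1, b)


# ---------------------------------------------------------------------------
# Jukes-Cantor engine


def test_jc_evolve_zero_time_is_identity(rng):
    parent = rng.integers(0, 4, 1000, dtype=np.int8)
    child = simulate._jc_evolve(parent, 0.0, rng)
    np.testing.assert_array_equal(parent, child)


def test_jc_evolve_expected_divergence(rng):
    # expected differing fraction = 3/4 * (1 - exp(-4t/3))
    t = 0.05
    parent = rng.integers(0, 4, 200_000, dtype=np.int8)
    child = simulate._jc_evolve(parent, t, rng)
    observed = float(np.mean(parent != child))
    expected = 0.75 * (1 - np.exp(-4 * t / 3))
    assert observed == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# quartet simulator


def test_quartet_determinism_and_truth():
    cfg = SimConfig(n_loci=50, locus_length=100,
                    admixture_pulses=[("P3", "P2", 0.4)], seed=42)
    d1 = simulate.simulate_quartet_loci(cfg)
    d2 = simulate.simulate_quartet_loci(cfg)
    pd.testing.assert_frame_equal(d1.truth, d2.truth)
    s1, _ = d1.concatenated()
    s2, _ = d2.concatenated()
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])


def test_quartet_gamma_extremes():
    none = simulate.simulate_quartet_loci(
        SimConfig(n_loci=40, locus_length=50, seed=1)
    )
    assert not none.truth["introgressed"].any()
    full = simulate.simulate_quartet_loci(
        SimConfig(n_loci=40, locus_length=50,
                  admixture_pulses=[("P3", "P2", 1.0)], seed=1)
    )
    assert full.truth["introgressed"].all()


def test_quartet_invalid_gamma_rejected():
    with pytest.raises(ValueError, match="admixture fraction"):
        SimConfig(admixture_pulses=[("P3", "P2", 1.5)])


def test_quartet_concatenated_shape():
    cfg = SimConfig(n_loci=10, locus_length=30, seed=0)
    data = simulate.simulate_quartet_loci(cfg)
    seqs, locus_ids = data.concatenated()
    assert set(seqs) == {"P1", "P2", "P3", "O"}
    assert all(v.size == 300 for v in seqs.values())
    assert locus_ids.size == 300 and len(np.unique(locus_ids)) == 10


# ---------------------------------------------------------------------------
# RADseq simulator


def test_radseq_missing_iff_zero_depth():
    cfg = SimConfig(
        population_tree="((p1:0.004,p2:0.004):0.01,out:0.014);",
        n_loci=40, locus_length=120, n_individuals_per_pop=3,
        dropout=0.3, seed=5,
    )
    data = simulate.simulate_complex_radseq(cfg)
    contigs = list(data.depth.index)
    for rec in data.records:
        li = contigs.index(rec.contig)
        for ii, ind in enumerate(data.individuals):
            missing = rec.genotypes[ii] == MISSING_GT
            assert missing == (data.depth.iloc[li, ii] == 0)
            assert rec.depths[ii] == data.depth.iloc[li, ii]


def test_radseq_ref_is_majority_allele():
    cfg = SimConfig(
        population_tree="((p1:0.004,p2:0.004):0.01,out:0.014);",
        n_loci=30, locus_length=100, n_individuals_per_pop=3,
        dropout=0.0, seed=8,
    )
    data = simulate.simulate_complex_radseq(cfg)
    for rec in data.records[:50]:
        counts = {0: 0}
        for gt in rec.genotypes:
            for a in gt.split("/"):
                counts[int(a)] = counts.get(int(a), 0) + 1
        assert counts[0] == max(counts.values())


def test_read_observations_consistent_with_depth():
    cfg = SimConfig(
        population_tree="((p1:0.004,p2:0.004):0.01,out:0.014);",
        n_loci=15, locus_length=100, n_individuals_per_pop=2,
        dropout=0.2, seed=3,
    )
    data = simulate.simulate_complex_radseq(cfg)
    obs = simulate.simulate_read_observations(data, error_rate=0.0, seed=3)
    per = obs.groupby(["contig", "individual"])["count"].sum()
    for (contig, ind), total in per.items():
        assert total == int(data.depth.loc[contig, ind])
    # without sequencing error, every combination matches a true haplotype
    for row in obs.itertuples(index=False):
        sites = sorted(r.pos - 1 for r in data.records if r.contig == row.contig)
        h1, h2 = data.haplotypes[row.contig][row.individual]
        true_combos = {
            simulate.decode_sequence(h[np.array(sites)]) for h in (h1, h2)
        }
        assert row.combination in true_combos


# ---------------------------------------------------------------------------
# clock trees and mtDNA alignments


def test_sample_clock_tree_is_ultrametric_with_separated_nodes():
    rng = np.random.default_rng(0)
    tree = simulate.sample_clock_tree(8, depth=0.5, rng=rng, min_separation=0.05)
    depths = simulate._tip_depths(tree)
    assert len(depths) == 8
    np.testing.assert_allclose(list(depths.values()), 0.5, rtol=1e-9)
    heights = sorted(
        {round(0.5 - d, 12) for d in _node_depths(tree)}
    )
    gaps = np.diff([0.0] + heights)
    assert (gaps >= 0.05 * 0.5 - 1e-9).all()


def _node_depths(tree):
    out = []
    for node in tree.non_tips(include_self=True):
        d, cur = 0.0, node
        while cur.parent is not None:
            d += cur.length or 0.0
            cur = cur.parent
        out.append(d)
    return out


def test_sample_clock_tree_two_taxa_and_validation():
    rng = np.random.default_rng(1)
    tree = simulate.sample_clock_tree(2, depth=1.0, rng=rng)
    assert {t.name for t in tree.tips()} == {"t0", "t1"}
    with pytest.raises(ValueError):
        simulate.sample_clock_tree(1, depth=1.0, rng=rng)
    with pytest.raises(ValueError, match="min_separation"):
        simulate.sample_clock_tree(30, depth=1.0, rng=rng, min_separation=0.05)


def test_true_tmrca_matrix_matches_tree():
    tree = phylo.read_newick("((a:0.1,b:0.1):0.3,c:0.4);")
    tm = simulate.true_tmrca_matrix(tree)
    assert tm.loc["a", "b"] == pytest.approx(0.1)
    assert tm.loc["a", "c"] == pytest.approx(0.4)
    assert tm.loc["a", "a"] == 0.0


def test_mtdna_alignment_rate_and_shape():
    tree = phylo.read_newick("(a:1.0,b:1.0);")  # depths in Myr
    data = simulate.simulate_mtdna_alignment(tree, rate=0.02, length=50_000, seed=0)
    assert set(data.sequences) == {"a", "b"}
    d = phylo.p_distance_matrix(data.sequences)["a", "b"]
    # pairwise rate 2%/Myr at TMRCA 1 Myr -> d ~ 0.02 (JC correction negligible)
    assert d == pytest.approx(0.02, rel=0.15)


def test_mtdna_alignment_rejects_non_ultrametric():
    tree = phylo.read_newick("(a:1.0,b:2.0);")
    with pytest.raises(ValueError, match="ultrametric"):
        simulate.simulate_mtdna_alignment(tree, rate=0.02, length=100, seed=0)


# ---------------------------------------------------------------------------
# morphometric simulator


def test_morpho_shapes_and_type_series():
    cfg = MorphoSimConfig(n_per_group=6, type_series_size=2, seed=2)
    data = simulate.simulate_morphometrics(cfg)
    n_groups = cfg.group_means.shape[1]
    n_chars = cfg.group_means.shape[0]
    assert len(data.standardized) == 6 * n_groups
    assert len(data.type_ranges) == n_groups * n_chars
    assert (data.type_ranges["min"] <= data.type_ranges["max"]).all()
    # meristics are integer-valued and pass through standardization unchanged
    for c in cfg.meristic_characters:
        vals = data.standardized[c]
        assert (vals == vals.round()).all()
        assert (data.specimens[c] == vals).all()


def test_morpho_determinism():
    cfg = MorphoSimConfig(n_per_group=5, type_series_size=2, seed=9)
    a = simulate.simulate_morphometrics(cfg)
    b = simulate.simulate_morphometrics(cfg)
    pd.testing.assert_frame_equal(a.standardized, b.standardized)
    pd.testing.assert_frame_equal(a.specimens, b.specimens)


def test_morpho_config_validation():
    with pytest.raises(ValueError, match="type_series_size"):
        MorphoSimConfig(n_per_group=3, type_series_size=4)
    with pytest.raises(ValueError, match="within_sd"):
        MorphoSimConfig(within_sd=-0.1)


# ---------------------------------------------------------------------------
# fixture bundles


def test_fixture_bundle_round_trip(tmp_path):
    qcfg = SimConfig(n_loci=8, locus_length=40,
                     admixture_pulses=[("P3", "P2", 0.5)], seed=4)
    quartet = simulate.simulate_quartet_loci(qcfg)
    manifest = simulate.write_fixture_bundle({"quartet": quartet}, tmp_path)
    assert (tmp_path / "manifest.json").exists()
    assert manifest["files"]
    back = simulate.read_quartet_bundle(tmp_path, "quartet")
    s1, ids1 = quartet.concatenated()
    s2, ids2 = back.concatenated()
    np.testing.assert_array_equal(ids1, ids2)
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])
    pd.testing.assert_frame_equal(quartet.truth, back.truth)
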