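"""The generator's planted structure must be exactly what downstream tests assume."""

import numpy as np
import pytest

import embryosex as ex


def test_reproducible_given_seed(small_config):
    a = ex.simulate_counts(small_config)
    b = ex.simulate_counts(small_config)
    assert (a[0].values != b[0].values).nnz == 0
    assert a[1].equals(b[1])
    assert a[3].planted_sexdegs == b[3].planted_sexdegs


def test_no_planted_sexdegs_when_zero(small_config):
    cfg = ex.SimConfig(n_genes=200, n_sexdeg_per_stage=0, seed=3)
    _, _, _, truth = ex.simulate_counts(cfg)
    assert all(len(v) == 0 for v in truth.planted_sexdegs.values())


def test_y_genes_silent_in_females(small_dataset):
    counts, metadata, annotation, truth = small_dataset
    y_genes = annotation.loc[annotation["chromosome_class"] == "Y", "gene_id"]
    females = truth.true_sex[truth.true_sex == "female"].index
    sub = counts.subset_genes(np.asarray(y_genes)).subset_cells(
        np.asarray(females, dtype=object))
    assert sub.values.sum() == 0


def test_marker_structure(small_dataset, small_config):
    counts, _, _, truth = small_dataset
    xist = counts.gene_row(small_config.marker_ids[0])
    eif = counts.gene_row(small_config.marker_ids[1])
    female = (truth.true_sex == "female").to_numpy()
    assert eif[female].sum() == 0          # Y marker structurally absent
    assert (eif[~female] > 0).mean() > 0.95
    assert xist[female].mean() > 10 * max(xist[~female].mean(), 0.01)


def test_planted_sexdegs_disjoint_from_markers_and_stages(small_dataset, small_config):
    _, _, _, truth = small_dataset
    seen = set()
    for stage, degs in truth.planted_sexdegs.items():
        assert not set(degs) & set(small_config.marker_ids)
        assert not set(degs) & seen
        seen |= set(degs)


def test_nb_moments_match_closed_form():
    """Monte-Carlo mean/variance of the NB sampler vs closed-form moments."""
    from embryosex.simulate import _nb_sample
    rng = np.random.default_rng(5)
    mu, a0, a1 = 5.0, 0.2, 0.0
    n = 2000
    draws = _nb_sample(rng, np.full(n, mu), a0, a1)
    var = mu + a0 * mu ** 2  # NB2 variance
    se_mean = np.sqrt(var / n)
    assert abs(draws.mean() - mu) < 3 * se_mean
    # variance within Monte-Carlo error (normal-approx se of the variance)
    se_var = var * np.sqrt(2.0 / (n - 1)) * 2.5
    assert abs(draws.var(ddof=1) - var) < 4 * se_var


def test_dispersion_trend_recovered_at_scale():
    """Method-of-moments dispersion follows a0 + a1/mu at 2000 cells."""
    from embryosex.simulate import _nb_sample
    rng = np.random.default_rng(6)
    a0, a1 = 0.1, 1.0
    for mu in (2.0, 10.0, 40.0):
        draws = _nb_sample(rng, np.full(2000, mu), a0, a1).astype(float)
        alpha_hat = (draws.var(ddof=1) - draws.mean()) / draws.mean() ** 2
        assert alpha_hat == pytest.approx(a0 + a1 / mu, abs=0.08)


def test_unsatisfiable_config_rejected():
    with pytest.raises(ValueError):
        ex.simulate_counts(ex.SimConfig(n_genes=50, n_sexdeg_per_stage=40,
                                        n_stages=4, seed=0))
    with pytest.raises(ValueError):
        ex.SimConfig(frac_x_linked=0.7, frac_y_linked=0.5)
    with pytest.raises(ValueError):
        ex.SimConfig(dispersion_a0=0.0)


def test_genesets_counts_and_coverage(small_dataset):
    _, _, _, truth = small_dataset
    sets = ex.simulate_genesets(truth, n_decoy_sets=2, seed=1)
    n_meta = max(truth.metagene_membership.values()) + 1
    assert len(sets) == n_meta + 2
    for m in range(n_meta):
        members = {g for g, mm in truth.metagene_membership.items() if mm == m}
        planted = set(sets[f"metagene_{m}"])
        assert set(list(members)[:500]) <= planted or len(members) > 500
        assert 15 <= len(planted) <= 500


def test_decoy_overlap_matches_hypergeometric(small_dataset):
    """Decoy-set overlap with a metagene behaves like a random draw."""
    _, _, _, truth = small_dataset
    members = {g for g, m in truth.metagene_membership.items() if m == 0}
    n_genes = len(truth.gene_annotation)
    overlaps, sizes = [], []
    for seed in range(30):
        sets = ex.simulate_genesets(truth, n_decoy_sets=1, seed=seed)
        decoy = set(sets["decoy_0"])
        overlaps.append(len(decoy & members))
        sizes.append(len(decoy))
    expected = np.mean([s * len(members) / n_genes for s in sizes])
    # hypergeometric mean with Monte-Carlo slack
    assert np.mean(overlaps) == pytest.approx(expected, rel=0.25)


def test_ppi_extremes(small_dataset):
    _, _, _, truth = small_dataset
    assert ex.simulate_ppi(truth, 0.0, 0.0, seed=0) == []
    # complete graph within a single 4-gene module
    sub_truth = ex.SimTruth(
        gene_annotation=truth.gene_annotation.iloc[:4],
        true_sex=truth.true_sex,
        planted_sexdegs={},
        metagene_membership={g: 0 for g in truth.gene_annotation["gene_id"][:4]},
    )
    edges = ex.simulate_ppi(sub_truth, 1.0, 0.0, seed=0)
    assert len(edges) == 6
    assert all(a < b for a, b in edges)


def test_ppi_densities_match_probabilities(small_dataset):
    _, _, _, truth = small_dataset
    p_within, p_between = 0.3, 0.05
    edges = set(ex.simulate_ppi(truth, p_within, p_between, seed=2))
    genes = list(truth.gene_annotation["gene_id"])
    mod = truth.metagene_membership
    n_within = n_between = e_within = e_between = 0
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pair = tuple(sorted((genes[i], genes[j])))
            same = genes[i] in mod and genes[j] in mod and mod[genes[i]] == mod[genes[j]]
            if same:
                n_within += 1
                e_within += pair in edges
            else:
                n_between += 1
                e_between += pair in edges
    for emp, p, n in ((e_within / n_within, p_within, n_within),
                      (e_between / n_between, p_between, n_between)):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(emp - p) < 4 * se


def test_metagene_matrix_shapes_and_nonnegativity():
    V, gb, sb = ex.simulate_metagene_matrix(n_genes=30, n_samples=12,
                                            n_metagenes=3, seed=0)
    assert V.shape == (30, 12)
    assert (V >= 0).all()
    assert set(gb) == {0, 1, 2} and set(sb) == {0, 1, 2}
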