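"""Generalized stage groups, profile-correlation conservation, expression masks."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import embryosex as ex


def _md(stages, prefix="c"):
    return pd.DataFrame({"cell_id": [f"{prefix}{j}" for j in range(len(stages))],
                         "stage": stages, "species": "m", "sex": "female"})


def test_assign_generalized_stages():
    md = _md(["a", "a", "b", "c"])
    out = ex.assign_generalized_stages(md, {"a": "S1", "b": "S1", "c": "S2"})
    assert (out.loc[out["stage"].isin(["a", "b"]), "group"] == "S1").all()
    assert (out["group"] == "S1").sum() == 3
    with pytest.raises(ValueError, match="c"):
        ex.assign_generalized_stages(md, {"a": "S1", "b": "S1"})


def _setup_profiles(profA, profB):
    """Two one-gene species tables whose group means equal the given profiles."""
    groups = [f"S{i+1}" for i in range(len(profA))]
    mdA = _md(groups, "a")
    mdB = _md(groups, "b")
    mdA["group"] = groups
    mdB["group"] = groups
    normA = pd.DataFrame([profA], index=["gA"], columns=mdA["cell_id"])
    normB = pd.DataFrame([profB], index=["gB"], columns=mdB["cell_id"])
    return normA, normB, mdA, mdB


def test_identical_and_reversed_profiles():
    prof = [1.0, 2.0, 3.0, 4.0]
    normA, normB, mdA, mdB = _setup_profiles(prof, prof)
    res = ex.conservation_scores(normA, normB, mdA, mdB, [("gA", "gB")],
                                 n_perm=19, seed=0)
    assert res["score"].iloc[0] == pytest.approx(1.0)
    normA, normB, mdA, mdB = _setup_profiles(prof, prof[::-1])
    res = ex.conservation_scores(normA, normB, mdA, mdB, [("gA", "gB")],
                                 n_perm=19, seed=0)
    assert res["score"].iloc[0] == pytest.approx(-1.0)


def test_constant_profile_reported_missing():
    normA, normB, mdA, mdB = _setup_profiles([2.0, 2.0, 2.0, 2.0],
                                             [1.0, 2.0, 3.0, 4.0])
    res = ex.conservation_scores(normA, normB, mdA, mdB, [("gA", "gB")],
                                 n_perm=19, seed=0)
    assert np.isnan(res["score"].iloc[0])


def test_species_symmetry():
    rng = np.random.default_rng(0)
    groups = ["S1", "S2", "S3", "S4"]
    mdA = _md(groups, "a"); mdA["group"] = groups
    mdB = _md(groups, "b"); mdB["group"] = groups
    normA = pd.DataFrame(rng.normal(size=(5, 4)),
                         index=[f"gA{i}" for i in range(5)], columns=mdA["cell_id"])
    normB = pd.DataFrame(rng.normal(size=(5, 4)),
                         index=[f"gB{i}" for i in range(5)], columns=mdB["cell_id"])
    pairs = [(f"gA{i}", f"gB{i}") for i in range(5)]
    fwd = ex.conservation_scores(normA, normB, mdA, mdB, pairs, n_perm=99, seed=1)
    rev = ex.conservation_scores(normB, normA, mdB, mdA,
                                 [(b, a) for a, b in pairs], n_perm=99, seed=1)
    f = fwd.set_index("gene_a")["score"]
    r = rev.set_index("gene_b")["score"]
    assert np.allclose(f.sort_index(), r.sort_index(), atol=1e-12)


def test_permutation_p_small_pairing_oracle():
    """With 5 pairs the permutation p approximates the exhaustive pairing null."""
    rng = np.random.default_rng(2)
    groups = ["S1", "S2", "S3", "S4"]
    mdA = _md(groups, "a"); mdA["group"] = groups
    mdB = _md(groups, "b"); mdB["group"] = groups
    A = rng.normal(size=(5, 4))
    B = A + rng.normal(0, 0.2, size=(5, 4))  # true pairs strongly correlated
    normA = pd.DataFrame(A, index=[f"gA{i}" for i in range(5)], columns=mdA["cell_id"])
    normB = pd.DataFrame(B, index=[f"gB{i}" for i in range(5)], columns=mdB["cell_id"])
    pairs = [(f"gA{i}", f"gB{i}") for i in range(5)]
    res = ex.conservation_scores(normA, normB, mdA, mdB, pairs,
                                 n_perm=2000, seed=3).set_index("gene_a")

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    Az = np.array([z(r) for r in A])
    Bz = np.array([z(r) for r in B])
    obs = (Az * Bz).sum(axis=1) / 4
    for i in range(5):
        null_ge = [((Az[i] * Bz[list(p)[i]]).sum() / 4) >= obs[i]
                   for p in permutations(range(5))]
        exact = np.mean(null_ge)
        mc = res.loc[f"gA{i}", "pvalue"]
        assert mc == pytest.approx(exact, abs=0.06)


def test_true_pairs_beat_shuffled_pairs_on_synthetic_programs():
    """Shared planted stage programs give true orthologs higher mean scores."""
    rng = np.random.default_rng(4)
    n_pairs, k = 200, 4
    programs = rng.normal(size=(n_pairs, k))
    A = programs + rng.normal(0, 0.5, size=(n_pairs, k))
    B = programs + rng.normal(0, 0.5, size=(n_pairs, k))
    groups = [f"S{i+1}" for i in range(k)]
    mdA = _md(groups, "a"); mdA["group"] = groups
    mdB = _md(groups, "b"); mdB["group"] = groups
    normA = pd.DataFrame(A, index=[f"gA{i}" for i in range(n_pairs)],
                         columns=mdA["cell_id"])
    normB = pd.DataFrame(B, index=[f"gB{i}" for i in range(n_pairs)],
                         columns=mdB["cell_id"])
    true_pairs = [(f"gA{i}", f"gB{i}") for i in range(n_pairs)]
    perm = rng.permutation(n_pairs)
    shuf_pairs = [(f"gA{i}", f"gB{perm[i]}") for i in range(n_pairs)]
    t = ex.conservation_scores(normA, normB, mdA, mdB, true_pairs, n_perm=9, seed=5)
    s = ex.conservation_scores(normA, normB, mdA, mdB, shuf_pairs, n_perm=9, seed=5)
    assert t["score"].mean() > s["score"].mean() + 0.3


def test_top_expression_mask():
    gene = pd.DataFrame([np.arange(10, dtype=float)], index=["g"],
                        columns=[f"c{j}" for j in range(10)])
    mask = ex.top_expression_mask(gene, q=0.9)
    assert mask.to_numpy().sum() == 1 and mask.iloc[0, 9]
    const = pd.DataFrame([[5.0] * 6], index=["g"],
                         columns=[f"c{j}" for j in range(6)])
    assert not ex.top_expression_mask(const, q=0.9).to_numpy().any()
    low_q = ex.top_expression_mask(gene, q=1e-9)
    assert low_q.to_numpy().sum() == 9  # everything strictly above the minimum
    with pytest.raises(ValueError):
        ex.top_expression_mask(gene, q=1.5)
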