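"""Synthetic two-sex embryo single-cell data with known planted structure.

The generator emulates the shape of pre-implantation single-cell count
datasets: stage-labelled cells of both sexes, negative-binomial counts whose
excess zeros arise from low means, X/Y/autosomal gene classes, an X-linked
female marker (Xist-like) and a Y-linked male marker (Eif2s3y-like), planted
per-stage sex effects, and non-negative stage programs ("metagenes") that a
matrix factorization can recover.  Every downstream module is testable
against the returned :class:`SimTruth`.

Counts for gene g in cell c at stage s are NB draws with mean

    mu_gc = baseline_g * program_m(g)(s) * 2^(+-log2fc if planted at s)

and dispersion alpha(mu) = a0 + a1/mu; Y-linked genes are structurally zero
in female cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, validate_annotation


@dataclass
class SimConfig:
    """Parameters of the synthetic embryo dataset.

    Defaults describe a small two-species-style design: 4 stages, 30 cells
    per stage per sex, 2000 genes with 5% X-linked and 2% Y-linked, 20
    planted sex-differential genes per stage at |log2FC| = 2, and 3
    stage-program metagenes.
    """

    n_genes: int = 2000
    n_stages: int = 4
    cells_per_stage_per_sex: int = 30
    frac_x_linked: float = 0.05
    frac_y_linked: float = 0.02
    frac_tf: float = 0.08
    frac_ee: float = 0.04
    n_sexdeg_per_stage: int = 20
    sexdeg_log2fc: float = 2.0
    n_metagenes: int = 3
    baseline_logmean_mu: float = 1.0
    baseline_logmean_sd: float = 1.2
    dispersion_a0: float = 0.1
    dispersion_a1: float = 1.0
    frac_metagene_genes: float = 0.6
    marker_ids: tuple = ("XistL", "Eif2s3yL")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_x_linked", "frac_y_linked", "frac_tf", "frac_ee",
                     "frac_metagene_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_x_linked + self.frac_y_linked > 1.0:
            raise ValueError("frac_x_linked + frac_y_linked exceeds 1")
        for name in ("n_genes", "n_stages", "cells_per_stage_per_sex", "n_metagenes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_sexdeg_per_stage < 0:
            raise ValueError("n_sexdeg_per_stage must be >= 0")
        if not np.isfinite(self.sexdeg_log2fc):
            raise ValueError("sexdeg_log2fc must be finite")
        if self.dispersion_a0 <= 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion trend must be positive for all means")
        if len(self.marker_ids) != 2:
            raise ValueError("marker_ids must name the X-linked and Y-linked markers")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    gene_annotation: pd.DataFrame
    true_sex: pd.Series
    planted_sexdegs: dict  # stage -> {gene_id: "female"|"male"}
    metagene_membership: dict  # gene_id -> metagene index
    module_edges: list = field(default_factory=list)

    def planted_set(self, stage: str) -> set:
        return set(self.planted_sexdegs.get(stage, {}))


# Expression levels of the two sexing markers (mean counts).  The female
# marker is constitutively high in females and near-silent in males; the male
# marker is Y-linked hence structurally absent in females.
_MARKER_FEMALE_X_MEAN = 50.0
_MARKER_MALE_X_MEAN = 0.2
_MARKER_MALE_Y_MEAN = 30.0


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """NB draws with mean mu and dispersion alpha(mu) = a0 + a1/mu."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        m = mu[pos]
        alpha = a0 + a1 / m
        lam = rng.gamma(shape=1.0 / alpha, scale=m * alpha)
        out[pos] = rng.poisson(lam)
    return out


def simulate_counts(config: SimConfig):
    """Generate a synthetic dataset.

    Returns
    -------
    (CountMatrix, SampleMetadata, GeneAnnotation, SimTruth)
        Counts are genes x cells; metadata carries stage/sex labels; the
        annotation marks chromosome class and TF/EE/protein-coding flags.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    marker_x, marker_y = cfg.marker_ids
    if n < 2 + cfg.n_metagenes:
        raise ValueError("n_genes too small for markers plus metagenes")

    gene_ids = np.array([f"g{i:05d}" for i in range(n - 2)] + [marker_x, marker_y],
                        dtype=object)

    # chromosome classes; the two markers are forced to X and Y
    n_x = int(round(cfg.frac_x_linked * n))
    n_y = int(round(cfg.frac_y_linked * n))
    chrom = np.array(["autosome"] * n, dtype=object)
    nonmarker = np.arange(n - 2)
    perm = rng.permutation(nonmarker)
    chrom[perm[:max(n_x - 1, 0)]] = "X"
    chrom[perm[max(n_x - 1, 0):max(n_x - 1, 0) + max(n_y - 1, 0)]] = "Y"
    chrom[n - 2] = "X"
    chrom[n - 1] = "Y"

    is_tf = np.zeros(n, dtype=bool)
    is_ee = np.zeros(n, dtype=bool)
    flag_perm = rng.permutation(nonmarker)
    n_tf = int(round(cfg.frac_tf * n))
    n_ee = int(round(cfg.frac_ee * n))
    is_tf[flag_perm[:n_tf]] = True
    is_ee[flag_perm[n_tf:n_tf + n_ee]] = True
    is_pc = rng.random(n) < 0.85

    annotation = pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": gene_ids,
        "chromosome_class": chrom,
        "is_protein_coding": is_pc,
        "is_tf": is_tf,
        "is_ee": is_ee,
    })
    validate_annotation(annotation)

    stages = [f"S{i + 1}" for i in range(cfg.n_stages)]
    cells, cell_stage, cell_sex = [], [], []
    for s in stages:
        for sex in ("female", "male"):
            for j in range(cfg.cells_per_stage_per_sex):
                cells.append(f"{s}_{sex[0]}{j:03d}")
                cell_stage.append(s)
                cell_sex.append(sex)
    cell_ids = np.array(cells, dtype=object)
    cell_stage = np.array(cell_stage, dtype=object)
    cell_sex = np.array(cell_sex, dtype=object)
    n_cells = len(cell_ids)

    baseline = np.exp(rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sd, size=n))

    # metagene membership: a subset of non-marker genes, split evenly
    n_member = int(round(cfg.frac_metagene_genes * (n - 2)))
    member_idx = rng.permutation(nonmarker)[:n_member]
    membership = {}
    for j, gi in enumerate(member_idx):
        membership[gene_ids[gi]] = j % cfg.n_metagenes

    # stage programs: each metagene peaks at a distinct (cycled) stage
    prog = np.ones((cfg.n_metagenes, cfg.n_stages))
    for m in range(cfg.n_metagenes):
        peak = m % cfg.n_stages
        for s in range(cfg.n_stages):
            prog[m, s] = 0.5 + 3.0 * np.exp(-0.5 * (s - peak) ** 2)

    # planted sex effects: disjoint across stages, never on markers or Y genes
    eligible = [gi for gi in nonmarker if chrom[gi] != "Y"]
    need = cfg.n_sexdeg_per_stage * cfg.n_stages
    if need > len(eligible):
        raise ValueError(
            f"cannot plant {need} sexDEGs among {len(eligible)} eligible genes")
    planted_order = rng.permutation(np.array(eligible))[:need]
    planted = {}
    gene_stage_dir = {}
    for si, s in enumerate(stages):
        block = planted_order[si * cfg.n_sexdeg_per_stage:(si + 1) * cfg.n_sexdeg_per_stage]
        planted[s] = {}
        for gi in block:
            direction = "female" if rng.random() < 0.5 else "male"
            planted[s][gene_ids[gi]] = direction
            gene_stage_dir[(gi, s)] = direction
            # keep planted genes comfortably detectable
            baseline[gi] = max(baseline[gi], 5.0)

    # mean matrix per (gene, cell)
    stage_index = {s: i for i, s in enumerate(stages)}
    mu = np.empty((n, n_cells))
    prog_per_gene = np.ones((n, cfg.n_stages))
    for gid, m in membership.items():
        prog_per_gene[np.flatnonzero(gene_ids == gid)[0]] = prog[m]
    col_stage = np.array([stage_index[s] for s in cell_stage])
    mu[:] = baseline[:, None] * prog_per_gene[:, col_stage]

    female_cols = cell_sex == "female"
    for (gi, s), direction in gene_stage_dir.items():
        cols = (cell_stage == s)
        shift = 2.0 ** cfg.sexdeg_log2fc
        if direction == "female":
            mu[gi, cols & female_cols] *= shift
        else:
            mu[gi, cols & ~female_cols] *= shift

    # sex-chromosome structure
    y_rows = np.flatnonzero(chrom == "Y")
    mu[np.ix_(y_rows, np.flatnonzero(female_cols))] = 0.0
    xi = n - 2
    yi = n - 1
    mu[xi, female_cols] = _MARKER_FEMALE_X_MEAN
    mu[xi, ~female_cols] = _MARKER_MALE_X_MEAN
    mu[yi, ~female_cols] = _MARKER_MALE_Y_MEAN
    mu[yi, female_cols] = 0.0

    counts = _nb_sample(rng, mu, cfg.dispersion_a0, cfg.dispersion_a1)
    cm = CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids)

    metadata = pd.DataFrame({
        "cell_id": cell_ids,
        "stage": pd.Categorical(cell_stage, categories=stages, ordered=True),
        "species": "simulated",
        "sex": pd.NA,
    })
    truth = SimTruth(
        gene_annotation=annotation,
        true_sex=pd.Series(cell_sex, index=cell_ids, name="true_sex"),
        planted_sexdegs=planted,
        metagene_membership=membership,
    )
    return cm, metadata, annotation, truth


def simulate_metagene_matrix(n_genes: int = 150, n_samples: int = 60,
                             n_metagenes: int = 3, seed: int = 0,
                             mixing: float = 0.35):
    """Non-negative matrix with a planted, recoverable factorization.

    Genes split into ``n_metagenes`` blocks with high loadings on their own
    metagene; sample mixture columns are Dirichlet draws sharpened toward
    the sample's block, so samples overlap the way adjacent embryonic
    stages do (boundary samples are genuinely ambiguous, which is what
    makes under-ranked factorizations unstable).  Counts are Poisson.

    Returns ``(V, gene_membership, sample_groups)``.
    """
    if n_metagenes < 1 or n_genes < n_metagenes or n_samples < n_metagenes:
        raise ValueError("need at least one gene and sample per metagene")
    rng = np.random.default_rng(seed)
    gene_block = np.arange(n_genes) % n_metagenes
    samp_block = np.sort(np.arange(n_samples) % n_metagenes)
    W0 = np.full((n_genes, n_metagenes), 0.3)
    W0[np.arange(n_genes), gene_block] = rng.uniform(2.0, 4.0, n_genes)
    H0 = rng.dirichlet(np.full(n_metagenes, mixing), size=n_samples).T * 0.9
    H0[samp_block, np.arange(n_samples)] += 1.2
    V = rng.poisson(W0 @ H0).astype(float)
    return V, gene_block, samp_block


def simulate_genesets(truth: SimTruth, n_decoy_sets: int, seed: int,
                      min_size: int = 15, max_size: int = 500) -> dict:
    """One gene set per planted metagene plus random decoy sets.

    Planted sets contain each metagene's member genes (truncated at
    ``max_size``), padded with random non-member genes up to ``min_size`` if
    a metagene is small.  Decoys are uniform random draws from all genes.
    """
    if not truth.metagene_membership:
        raise ValueError("truth has no metagene membership")
    rng = np.random.default_rng(seed)
    all_genes = np.asarray(truth.gene_annotation["gene_id"], dtype=object)
    n_meta = max(truth.metagene_membership.values()) + 1
    sets = {}
    for m in range(n_meta):
        members = sorted(g for g, mm in truth.metagene_membership.items() if mm == m)
        members = members[:max_size]
        if len(members) < min_size:
            pool = [g for g in all_genes if g not in set(members)]
            extra = rng.choice(pool, size=min_size - len(members), replace=False)
            members = members + sorted(extra)
        sets[f"metagene_{m}"] = list(members)
    for d in range(n_decoy_sets):
        size = int(rng.integers(min_size, min(max_size, len(all_genes)) + 1))
        sets[f"decoy_{d}"] = list(rng.choice(all_genes, size=size, replace=False))
    return sets


def simulate_ppi(truth: SimTruth, p_within: float, p_between: float, seed: int) -> list:
    """Stochastic-block-model PPI edges over the metagene modules.

    Edge probability is ``p_within`` for gene pairs sharing a metagene and
    ``p_between`` otherwise.  Returns a deduplicated, self-loop-free list of
    canonically ordered undirected edges; the edges are also recorded on
    ``truth.module_edges``.
    """
    if not 0 <= p_between <= p_within <= 1:
        raise ValueError("require 0 <= p_between <= p_within <= 1")
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.gene_annotation["gene_id"], dtype=object)
    module = np.array([truth.metagene_membership.get(g, -1) for g in genes])
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    same = (module[iu] >= 0) & (module[iu] == module[ju])
    p = np.where(same, p_within, p_between)
    keep = rng.random(len(iu)) < p
    edges = [(genes[i], genes[j]) if genes[i] <= genes[j] else (genes[j], genes[i])
             for i, j in zip(iu[keep], ju[keep])]
    edges = sorted(set(edges))
    truth.module_edges = edges
    return edges
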