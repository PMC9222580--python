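"""Benchmark protocols on synthetic stand-ins.

Each function runs one of the package's evaluation experiments end to end on
seeded synthetic data and returns per-replicate summaries:

- ``link_prediction_benchmark``: the three graph-model variants (1-layer BCE,
  2-layer BCE, 2-layer BCE+contrastive, all with 3-column embeddings) trained
  on sparse distance-decay contact maps with planted TADs; reports blind-test
  AP/AUC per variant.
- ``structure_recovery_benchmark``: binary contact maps thresholded from
  random-walk polymer structures, recovered with the 2-layer
  BCE+contrastive model; reports test AP/AUC and the correlation between
  recovered contact probabilities and reconstructed-structure distances.
- ``naive_tad_recovery``: block-diagonal naive-TAD matrices at several
  within-TAD retention levels, TADs called by the full embed-and-cluster
  pipeline; reports boundary overlap coefficients and TAD counts.

All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .gae import ModelConfig, build_graph, train
from .structure import distance_matrix, embedding_to_structure, structure_vs_contacts_correlation
from .synthetic import NaiveTadSpec, PolymerSpec, ScHicSpec, make_naive_tads, make_polymer, make_schic_cell
from .tads import call_tads, overlap_coefficient

__all__ = [
    "MODEL_VARIANTS",
    "random_tad_lengths",
    "make_tad_map",
    "link_prediction_benchmark",
    "structure_recovery_benchmark",
    "naive_tad_recovery",
]

#: The three graph models benchmarked for 3D reconstruction: all embed into
#: 3 dimensions; the 2-layer variants go through a 128-wide ReLU layer.
#: 1-layer 3D models are hard to train, so every variant gets a few restarts.
MODEL_VARIANTS: dict[str, dict] = {
    "1layer_bce": {"layers": 1, "loss": "bce"},
    "2layer_bce": {"layers": 2, "loss": "bce"},
    "2layer_bce_contrastive": {"layers": 2, "loss": "bce_plus_contrastive"},
}


def random_tad_lengths(n_bins: int, rng: np.random.Generator,
                       lo: int = 8, hi: int = 30) -> list[int]:
    """Contiguous TAD lengths covering ``n_bins``, uniform in [lo, hi]."""
    lengths: list[int] = []
    left = n_bins
    while left > 0:
        l = min(int(rng.integers(lo, hi + 1)), left)
        lengths.append(l)
        left -= l
    return lengths


def make_tad_map(seed: int, n_bins: int = 500, total_contacts: int = 10_000,
                 enrichment: float = 4.0):
    """Sparse distance-decay contact map with planted TAD enrichment.

    The |i-j|^-1 decay alone carries no pair-specific signal beyond genomic
    distance; the planted domains (lengths 8-30 bins, 4x interior
    enrichment) supply the block structure that real single-cell maps have
    and that link prediction exploits.
    """
    rng = np.random.default_rng(seed)
    lengths = random_tad_lengths(n_bins, rng)
    return make_schic_cell(ScHicSpec(
        n_bins=n_bins,
        total_contacts=total_contacts,
        decay_exponent=1.0,
        tad_lengths=lengths,
        enrichment=enrichment,
        seed=int(rng.integers(2**31 - 1)),
    ))


def link_prediction_benchmark(
    seed: int = 0,
    n_replicates: int = 10,
    n_bins: int = 500,
    contacts_range: tuple[int, int] = (5_000, 20_000),
    epochs: int = 200,
    restarts: int = 3,
) -> dict[str, dict[str, list[float]]]:
    """Blind-test AP/AUC of the three model variants over replicate maps.

    Returns ``{variant: {"ap": [...], "auc": [...]}}`` with one entry per
    replicate; contact totals are spread evenly across ``contacts_range``.
    """
    rng = np.random.default_rng(seed)
    totals = np.linspace(contacts_range[0], contacts_range[1], n_replicates).astype(int)
    out = {name: {"ap": [], "auc": []} for name in MODEL_VARIANTS}
    for rep in range(n_replicates):
        map_seed = int(rng.integers(2**31 - 1))
        m = make_tad_map(map_seed, n_bins=n_bins, total_contacts=int(totals[rep]))
        g = build_graph(m)
        for name, kw in MODEL_VARIANTS.items():
            cfg = ModelConfig(out_dim=3, epochs=epochs, restarts=restarts,
                              seed=map_seed % (2**31 - 1), **kw)
            res = train(g, cfg)
            out[name]["ap"].append(res.test_ap)
            out[name]["auc"].append(res.test_auc)
    return out


def structure_recovery_benchmark(
    seed: int = 0,
    n_replicates: int = 20,
    beads_range: tuple[int, int] = (100, 300),
    contact_density: float = 0.10,
    epochs: int = 200,
    restarts: int = 3,
) -> dict[str, list[float]]:
    """Recover polymer-walk contact maps with the 2-layer 3D model.

    Each replicate generates a random-walk structure, thresholds its
    distance matrix at the ``contact_density`` quantile (within the 5-15%
    density band), trains the 2-layer BCE+contrastive model, and records
    test AP/AUC plus the Pearson/Spearman correlation between the decoded
    probability matrix and the distance matrix of the learned 3D structure.
    """
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(seed)
    sizes = np.linspace(beads_range[0], beads_range[1], n_replicates).astype(int)
    out = {"ap": [], "auc": [], "pearson": [], "spearman": []}
    for rep in range(n_replicates):
        sub = int(rng.integers(2**31 - 1))
        struct, adj = make_polymer(PolymerSpec(n_beads=int(sizes[rep]), seed=sub))
        g = build_graph(adj)
        cfg = ModelConfig(layers=2, out_dim=3, loss="bce_plus_contrastive",
                          epochs=epochs, restarts=restarts, seed=sub)
        res = train(g, cfg)
        recon = embedding_to_structure(res.best_embedding)
        d = distance_matrix(recon)
        pear, spear = structure_vs_contacts_correlation(res.reconstructed, d)
        out["ap"].append(res.test_ap)
        out["auc"].append(res.test_auc)
        out["pearson"].append(pear)
        out["spearman"].append(spear)
    return out


def naive_tad_recovery(
    seed: int = 0,
    n_chromosomes: int = 20,
    bins_range: tuple[int, int] = (300, 600),
    tad_length_range: tuple[int, int] = (4, 40),
    retentions: tuple[float, ...] = (1.0, 0.9, 0.8),
    epochs: int = 50,
) -> dict[float, dict[str, list[float]]]:
    """Boundary recovery on block-diagonal naive-TAD matrices.

    For each synthetic chromosome and retention level the full pipeline
    (1-layer 128-dim embedding, constrained clustering, S_Dbw cut) is run
    and the overlap coefficient between called and true boundaries (+/- 1
    bin) plus called/true TAD counts are recorded.  Returns
    ``{retention: {"overlap": [...], "n_called": [...], "n_true": [...]}}``.
    """
    rng = np.random.default_rng(seed)
    layouts = []
    for _ in range(n_chromosomes):
        n_bins = int(rng.integers(bins_range[0], bins_range[1] + 1))
        lengths = random_tad_lengths(n_bins, rng, *tad_length_range)
        layouts.append((n_bins, lengths, int(rng.integers(2**31 - 1))))
    out = {r: {"overlap": [], "n_called": [], "n_true": []} for r in retentions}
    for n_bins, lengths, sub in layouts:
        for retention in retentions:
            m, truth = make_naive_tads(NaiveTadSpec(
                n_bins=n_bins, tad_lengths=lengths,
                retention=retention, seed=sub))
            cfg = ModelConfig(layers=1, out_dim=128, loss="bce",
                              epochs=epochs, seed=sub)
            part, _ = call_tads(m, model_config=cfg)
            ov = overlap_coefficient(truth.boundaries, part.boundaries, tol_bins=1)
            out[retention]["overlap"].append(ov)
            out[retention]["n_called"].append(len(part.clusters))
            out[retention]["n_true"].append(len(truth.clusters))
    return out
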