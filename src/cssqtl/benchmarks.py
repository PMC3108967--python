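"""Calibration and recovery experiments on simulated crosses.

Each function runs the pipeline (or one stage) on freshly simulated data and
returns a scalar summary: type-I error of the permutation threshold, QTL
peak/interval recovery, planted-module recovery, and end-to-end candidate
ranking.  These back the validation suite and the reproducibility script.
"""

from __future__ import annotations

import numpy as np

from .data import MarkerMap
from .network import adjacency, cluster_and_cut, topological_overlap
from .pipeline import run_pipeline
from .qtl import (
    _ScanKernel,
    genotype_probabilities,
    impute_genotypes,
    permutation_threshold,
    scan_trait,
)
from .sim import TruthSpec, default_truth, simulate_dataset, simulate_f2_genotypes, simulate_traits


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (comb-based closed form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def type_i_error_rate(
    n_datasets: int = 500,
    n_individuals: int = 100,
    n_markers: int = 15,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null traits whose max LOD exceeds the permutation threshold."""
    markers = MarkerMap.evenly_spaced(n_markers=n_markers, spacing_cm=2.0,
                                      spacing_bp=3_000_000)
    hits = 0
    for k in range(n_datasets):
        s = seed * 100_003 + k
        geno = simulate_f2_genotypes(markers, n_individuals, seed=s, missing_rate=0.0)
        y = np.random.default_rng(2_000_000 + s).standard_normal(n_individuals)
        probs = genotype_probabilities(geno, step_cm=1000.0, error_rate=0.0)
        imp = impute_genotypes(probs, 1, seed=s)
        kernel = _ScanKernel(imp)
        thr = permutation_threshold(y, imp, n_perm=n_perm, alpha=alpha, seed=s,
                                    kernel=kernel)
        hits += kernel.lod(y)[:, 0].max() > thr
    return hits / n_datasets


def qtl_recovery(
    n_sims: int = 100,
    n_individuals: int = 60,
    additive_effect: float = 1.0,
    peak_tolerance_cm: float = 10.0,
    seed: int = 0,
) -> dict[str, float]:
    """Peak localization and -LOD1 coverage for a single planted additive QTL."""
    markers = MarkerMap.evenly_spaced()
    qtl_cm = float(np.mean(markers.span_cm))
    truth_bp = markers.cm_to_bp(qtl_cm)
    peak_ok = cover_ok = 0
    for k in range(n_sims):
        s = seed * 100_003 + k
        truth = TruthSpec(qtl_position_cm=qtl_cm, additive_effect=additive_effect,
                          dominance_effect=0.0, noise_sd=1.0)
        geno = simulate_f2_genotypes(markers, n_individuals, seed=s)
        y = simulate_traits(geno, truth, seed=s)["DM1"]
        probs = genotype_probabilities(geno, step_cm=2.0)
        imp = impute_genotypes(probs, 8, seed=s)
        scan = scan_trait(y.to_numpy(), imp)
        if abs(scan.peak_position_cm - qtl_cm) <= peak_tolerance_cm:
            peak_ok += 1
        lo, hi = scan.support_interval
        if lo <= truth_bp <= hi:
            cover_ok += 1
    return {"peak_within_tolerance": peak_ok / n_sims,
            "interval_covers_truth": cover_ok / n_sims}


def module_recovery(
    n_seeds: int = 50,
    n_samples: int = 60,
    n_modules: int = 5,
    module_size: int = 40,
    loading: float = 0.7,
    ari_threshold: float = 0.8,
    seed: int = 0,
) -> dict[str, float]:
    """Planted-block recovery of the clustering stage."""
    import pandas as pd

    hits = 0
    aris = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 100_003 + k)
        F = rng.standard_normal((n_modules, n_samples))
        rows, truth_labels = [], []
        for m in range(n_modules):
            for _ in range(module_size):
                rows.append(loading * F[m]
                            + np.sqrt(1 - loading**2) * rng.standard_normal(n_samples))
                truth_labels.append(m)
        frame = pd.DataFrame(rows, index=[f"g{i:04d}" for i in range(len(rows))])
        net = topological_overlap(adjacency(frame, beta=7))
        modules = cluster_and_cut(net, min_module_size=25, cut_height=0.99)
        ari = adjusted_rand_index(truth_labels, modules.labels.to_numpy())
        aris.append(ari)
        hits += ari >= ari_threshold
    return {"fraction_recovered": hits / n_seeds, "mean_ari": float(np.mean(aris))}


def _one_candidate_run(s: int, n_probes: int, n_perm: int):
    ds = simulate_dataset(seed=s, n_probes=n_probes)
    res = run_pipeline(ds.genotypes, ds.traits, ds.expression,
                       n_draws=4, step_cm=2.0, n_perm=n_perm, seed=s)
    table = res.report.table
    if len(table) == 0:
        return None, res
    row = table[table["probe"] == ds.candidate_probe]
    rank = int(row["rank"].iloc[0]) if len(row) else None
    return rank, res


def candidate_recovery(
    n_seeds: int = 100,
    n_probes: int = 2000,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Full-pipeline rank of the planted fully supported candidate gene."""
    rank1 = 0
    for k in range(n_seeds):
        rank, _ = _one_candidate_run(seed * 100_003 + k, n_probes, n_perm)
        rank1 += rank == 1
    return {"rank1_fraction": rank1 / n_seeds}


def null_full_evidence(
    n_seeds: int = 50,
    n_probes: int = 500,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Average count of full-evidence genes when nothing is planted."""
    markers = MarkerMap.evenly_spaced()
    counts = []
    for k in range(n_seeds):
        s = seed * 100_003 + k
        truth = default_truth(
            markers, n_probes=n_probes,
            trait_couplings=(0.0,) * 5, module_qtl_loadings=(0.0,) * 5,
            additive_effect=0.0, cis_effect_range=(0.0, 0.0),
            candidate_cis_effect=0.0, trans_effect=0.0,
            snp_probe_magnitude=0.0, seed=s,
        )
        ds = simulate_dataset(truth=truth, seed=s)
        res = run_pipeline(ds.genotypes, ds.traits, ds.expression,
                           n_draws=4, step_cm=2.0, n_perm=n_perm, seed=s)
        counts.append(res.report.counts["full_evidence_genes"])
    return {"mean_full_evidence_genes": float(np.mean(counts))}
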