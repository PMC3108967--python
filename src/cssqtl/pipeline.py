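"""One-call end-to-end analysis: preprocess -> scans -> network -> candidates.

Mirrors the CLI stages but operates in memory, which is what the worked
example, the recovery simulations and the acceptance script use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import ExpressionMatrix, GenotypeMatrix
from .integrate import (
    CandidateReport,
    PrioritizeConfig,
    gene_trait_correlation,
    prioritize_candidates,
)
from .network import CoexpressionNetwork, ModuleResults
from .preprocess import preprocess
from .qtl import EqtlScanResults, F2IntervalMapper, QtlScanResults


@dataclass
class PipelineResults:
    """Everything the full analysis produced, stage by stage."""

    expression: ExpressionMatrix
    mapper: F2IntervalMapper
    behavioral: dict[str, QtlScanResults]
    eqtl: EqtlScanResults
    modules: ModuleResults
    gene_trait: pd.DataFrame
    report: CandidateReport


def run_pipeline(
    geno: GenotypeMatrix,
    traits: pd.DataFrame,
    expression: ExpressionMatrix,
    detection_alpha: float = 0.01,
    min_detected_samples: int = 1,
    step_cm: float = 1.0,
    error_rate: float = 0.002,
    n_draws: int = 16,
    behavioral_lod_threshold: float = 1.5,
    n_perm: int = 1000,
    fdr_target: float = 0.01,
    beta: int = 7,
    top_n: int | None = 4000,
    min_module_size: int = 25,
    cut_height: float = 0.99,
    config: PrioritizeConfig | None = None,
    seed: int = 0,
) -> PipelineResults:
    """Run the complete candidate-narrowing analysis on one dataset."""
    expr = expression
    if expr.stage == "raw":
        expr = preprocess(expr, alpha=detection_alpha,
                          min_detected_samples=min_detected_samples)
    mapper = F2IntervalMapper(geno, step_cm=step_cm, error_rate=error_rate,
                              n_draws=n_draws, seed=seed)
    behavioral = {
        name: mapper.fit(traits[name], threshold=behavioral_lod_threshold)
        for name in traits.columns
    }
    # expression may cover only a dissected subset of the mapped individuals
    if set(expr.samples) != set(geno.individuals):
        sub = geno.subset([i for i in geno.individuals if i in set(expr.samples)])
        expr_mapper = F2IntervalMapper(sub, step_cm=step_cm, error_rate=error_rate,
                                       n_draws=n_draws, seed=seed)
    else:
        expr_mapper = mapper
    eqtl = expr_mapper.fit_expression(expr, n_perm=n_perm, fdr_target=fdr_target, seed=seed)
    netmodel = CoexpressionNetwork(
        expr, beta=beta, top_n=None if top_n is None else min(top_n, expr.n_probes)
    )
    modules = netmodel.fit(min_module_size=min_module_size, cut_height=cut_height)
    gene_trait = gene_trait_correlation(expr, traits)
    report = prioritize_candidates(
        eqtl.records,
        modules,
        {name: res.scan for name, res in behavioral.items()},
        gene_trait,
        traits,
        focal_chromosome=geno.markers.chromosome,
        annotation=expr.annotation,
        config=config,
    )
    return PipelineResults(expr, mapper, behavioral, eqtl, modules, gene_trait, report)
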