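"""Combine eQTL, network and behavioral-QTL evidence into a candidate ranking.

A candidate gene accumulates one evidence point for each satisfied line of
support: a significant cis eQTL, an eQTL support interval overlapping every
behavioral -LOD1 interval, a gene position inside every behavioral interval,
membership in a module whose eigengene is significantly correlated (same
sign) with all behavioral traits, and a significant per-gene trait
correlation.  Probes flagged as SNP-in-probe artifacts are excluded from the
evidence (they mimic strong cis-eQTLs through genotype-dependent
hybridization) but retained in an audit list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .network import UNASSIGNED, ModuleResults
from .qtl import QtlScan, QtlScanResults
from .stats import pearson_test

ALL_CRITERIA = (
    "cis_eqtl",
    "interval_overlap",
    "gene_in_qtl",
    "module_trait",
    "gene_trait",
)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on one chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("inverted interval: start_bp > end_bp")


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the closed intervals share at least one bp (same chromosome)."""
    if str(a.chromosome) != str(b.chromosome):
        return False
    return max(a.start_bp, b.start_bp) <= min(a.end_bp, b.end_bp)


def point_in_interval(pos: int, a: GenomicInterval, chromosome: str | None = None) -> bool:
    if chromosome is not None and str(chromosome) != str(a.chromosome):
        return False
    return a.start_bp <= pos <= a.end_bp


def classify_cis_trans(eqtls: pd.DataFrame, focal_chromosome: str) -> pd.DataFrame:
    """Label each eQTL cis/trans by whether its gene is on the focal chromosome.

    In a chromosome-substitution cross only the focal chromosome varies, so
    any eQTL maps there; "cis" means the regulated gene itself resides on the
    varying chromosome.  Counts are stored in ``result.attrs['counts']``.
    """
    out = eqtls.copy()
    chrom = out.get("gene_chromosome")
    if chrom is None:
        raise ValueError("eQTL table lacks a gene_chromosome column")
    labels = []
    for c in chrom:
        if pd.isna(c) or str(c) == "":
            warnings.warn("record with missing gene chromosome labeled 'unknown'")
            labels.append("unknown")
        else:
            labels.append("cis" if str(c) == str(focal_chromosome) else "trans")
    out["regulation"] = labels
    out.attrs["counts"] = {
        "cis": int(sum(x == "cis" for x in labels)),
        "trans": int(sum(x == "trans" for x in labels)),
        "unknown": int(sum(x == "unknown" for x in labels)),
    }
    return out


def flag_snp_probes(
    eqtls: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the eQTL table into (retained, artifact audit list).

    Probes whose sequence overlaps a strain-polymorphic SNP hybridize
    genotype-dependently and are removed from further analyses.
    """
    if "snp_in_probe" not in annotation.columns:
        raise ValueError("annotation lacks snp_in_probe")
    missing = set(eqtls["probe"]) - set(annotation.index.astype(str))
    if missing:
        raise ValueError(f"annotation missing for probe(s): {sorted(missing)[:5]}")
    flags = annotation.loc[eqtls["probe"], "snp_in_probe"].to_numpy().astype(bool)
    retained = eqtls[~flags].reset_index(drop=True)
    audit = eqtls[flags].reset_index(drop=True)
    audit = audit.assign(artifact=True)
    return retained, audit


def gene_trait_correlation(x, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r/p per probe x trait; constant probes are skipped with a warning.

    ``x`` may be an ExpressionMatrix or a probes x samples DataFrame aligned
    with ``traits`` (samples x traits).
    """
    frame = x.intensities if isinstance(x, ExpressionMatrix) else x
    common = frame.columns.intersection(traits.index)
    if len(common) < 4:
        raise ValueError("need at least 4 aligned samples")
    E = frame[common]
    T = traits.loc[common]
    rows = []
    for probe in E.index:
        e = E.loc[probe].to_numpy(dtype=float)
        if e.std() == 0:
            warnings.warn(f"probe {probe!r} is constant; skipped")
            continue
        row: dict = {"probe": probe}
        for trait in T.columns:
            r, p, _ = pearson_test(e, T[trait].to_numpy(dtype=float))
            row[f"r_{trait}"] = r
            row[f"p_{trait}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("probe") if rows else pd.DataFrame()


@dataclass
class PrioritizeConfig:
    """Knobs for candidate ranking."""

    module_p: float = 0.05
    gene_p: float = 0.05
    criteria: tuple[str, ...] = ALL_CRITERIA
    #: score interval criteria once per behavioral trait (graded evidence, the
    #: way published overlap tables record "both traits" vs "one trait")
    #: rather than all-traits-or-nothing
    per_trait_intervals: bool = True
    include_unassigned_module: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.criteria) - set(ALL_CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")


@dataclass
class CandidateReport:
    """Ranked per-gene evidence table plus run counts."""

    table: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def top(self) -> pd.Series | None:
        return self.table.iloc[0] if len(self.table) else None

    def summary(self) -> str:
        lines = ["Candidate prioritization"]
        for key, val in self.counts.items():
            lines.append(f"  {key:<24} {val}")
        if len(self.table):
            t = self.top
            lines.append(
                f"  top candidate          {t['gene_symbol']} "
                f"(evidence {int(t['evidence_count'])}/{self.counts.get('criteria', '?')})"
            )
        return "\n".join(lines)


def _behavioral_intervals(
    behavioral_scans: dict[str, QtlScan | QtlScanResults], chromosome: str
) -> dict[str, GenomicInterval]:
    out = {}
    for trait, scan in behavioral_scans.items():
        lo, hi = scan.support_interval
        out[trait] = GenomicInterval(chromosome, lo, hi)
    return out


def prioritize_candidates(
    eqtls: pd.DataFrame,
    modules: ModuleResults,
    behavioral_scans: dict[str, QtlScan | QtlScanResults],
    gene_trait: pd.DataFrame,
    traits: pd.DataFrame,
    focal_chromosome: str,
    annotation: pd.DataFrame,
    config: PrioritizeConfig | None = None,
) -> CandidateReport:
    """Rank significant eQTL genes by accumulated evidence.

    The report covers significant, non-artifact eQTL records.  Ranking is a
    deterministic total order: evidence count (desc), max |gene-trait r|
    (desc), gene symbol (asc).
    """
    if not behavioral_scans:
        raise ValueError("behavioral scans are required")
    config = config or PrioritizeConfig()
    sig = eqtls[eqtls["significant"]].copy() if "significant" in eqtls.columns else eqtls.copy()
    sig = classify_cis_trans(sig, focal_chromosome)
    kept, audit = flag_snp_probes(sig, annotation)
    intervals = _behavioral_intervals(behavioral_scans, focal_chromosome)
    trait_names = list(traits.columns)

    module_sig = modules.significance(
        traits, include_unassigned=config.include_unassigned_module
    )
    good_modules: set[str] = set()
    for module in module_sig.index:
        signs = [np.sign(module_sig.loc[module, (t, "r")]) for t in trait_names]
        ps = [module_sig.loc[module, (t, "p")] for t in trait_names]
        if all(p < config.module_p for p in ps) and len(set(signs)) == 1 and signs[0] != 0:
            good_modules.add(module)

    rows = []
    for _, rec in kept.iterrows():
        probe = rec["probe"]
        eqtl_iv = GenomicInterval(focal_chromosome, int(rec["ci_low_bp"]), int(rec["ci_high_bp"]))
        module = modules.modules.labels.get(probe, UNASSIGNED)
        flags = {
            "cis_eqtl": rec["regulation"] == "cis",
            "interval_overlap": all(
                interval_overlap(eqtl_iv, iv) for iv in intervals.values()
            ),
            "gene_in_qtl": rec["regulation"] == "cis"
            and all(
                point_in_interval(int(rec["gene_bp"]), iv, chromosome=rec["gene_chromosome"])
                for iv in intervals.values()
            ),
            "module_trait": module in good_modules
            and (module != UNASSIGNED or config.include_unassigned_module),
        }
        rvals = []
        ok_gene_trait = probe in gene_trait.index
        for t in trait_names:
            if ok_gene_trait:
                rvals.append(float(gene_trait.loc[probe, f"r_{t}"]))
        flags["gene_trait"] = ok_gene_trait and all(
            gene_trait.loc[probe, f"p_{t}"] < config.gene_p for t in trait_names
        )
        if config.per_trait_intervals:
            evidence = sum(
                flags[c] for c in config.criteria
                if c not in ("interval_overlap", "gene_in_qtl")
            )
            if "interval_overlap" in config.criteria:
                evidence += sum(
                    interval_overlap(eqtl_iv, intervals[t]) for t in trait_names
                )
            if "gene_in_qtl" in config.criteria:
                evidence += sum(
                    rec["regulation"] == "cis"
                    and point_in_interval(int(rec["gene_bp"]), intervals[t],
                                          chromosome=rec["gene_chromosome"])
                    for t in trait_names
                )
        else:
            evidence = sum(flags[c] for c in config.criteria)
        row = {
            "probe": probe,
            "gene_symbol": rec["gene_symbol"],
            "gene_chromosome": rec["gene_chromosome"],
            "gene_bp": int(rec["gene_bp"]),
            "max_lod": float(rec["max_lod"]),
            "regulation": rec["regulation"],
            "module": module,
            "max_abs_r": max((abs(r) for r in rvals), default=0.0),
            "evidence_count": int(evidence),
            "snp_in_probe": 0,
        }
        for t in trait_names:
            row[f"eqtl_overlaps_{t}"] = bool(interval_overlap(eqtl_iv, intervals[t]))
            row[f"gene_in_{t}"] = bool(
                point_in_interval(int(rec["gene_bp"]), intervals[t],
                                  chromosome=rec["gene_chromosome"])
            )
            if ok_gene_trait:
                row[f"r_{t}"] = float(gene_trait.loc[probe, f"r_{t}"])
                row[f"p_{t}"] = float(gene_trait.loc[probe, f"p_{t}"])
        for c in ALL_CRITERIA:
            row[c] = bool(flags[c])
        rows.append(row)

    for _, rec in audit.iterrows():
        # artifact probes stay visible but carry no evidence
        rows.append(
            {
                "probe": rec["probe"],
                "gene_symbol": rec["gene_symbol"],
                "gene_chromosome": rec["gene_chromosome"],
                "gene_bp": int(rec["gene_bp"]),
                "max_lod": float(rec["max_lod"]),
                "regulation": rec["regulation"],
                "module": modules.modules.labels.get(rec["probe"], UNASSIGNED),
                "max_abs_r": 0.0,
                "evidence_count": 0,
                "snp_in_probe": 1,
                **{c: False for c in ALL_CRITERIA},
            }
        )

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            by=["evidence_count", "max_abs_r", "gene_symbol"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    n_criteria = len(config.criteria)
    if config.per_trait_intervals:
        n_criteria += sum(
            (len(trait_names) - 1)
            for c in ("interval_overlap", "gene_in_qtl") if c in config.criteria
        )
    counts = {
        "significant_eqtls": int(len(sig)),
        "artifacts_removed": int(len(audit)),
        "cis": int(sum(kept["regulation"] == "cis")) if len(kept) else 0,
        "trans": int(sum(kept["regulation"] == "trans")) if len(kept) else 0,
        "modules_trait_significant": len(good_modules),
        "criteria": n_criteria,
        "full_evidence_genes": int((table["evidence_count"] == n_criteria).sum())
        if len(table)
        else 0,
    }
    return CandidateReport(table, counts)
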