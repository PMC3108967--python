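"""Synthetic chromosome-substitution-strain F2 crosses with planted effects.

A CSS F2 population segregates on a single donor chromosome; everything else
is isogenic.  The generator emulates that design end to end: F2 genotypes by
standard meiosis under the Haldane (no-interference) map function, two
correlated behavioral traits with a planted QTL, and an expression matrix
containing cis-eQTLs, trans-regulated targets, block-structured co-expression
modules (optionally coupled to the traits through a shared latent factor),
SNP-in-probe artifact probes, and detection p-values.  Every planted effect
is recorded in a :class:`TruthSpec` so downstream recovery can be scored.

Trait and expression simulation share the module latent factors whenever they
are called with the same seed, which is what couples modules to behavior.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AB, MISSING, ExpressionMatrix, GenotypeMatrix, MarkerMap

# spawn keys for the per-purpose random streams derived from one user seed
_KEY_GAMETES = 0
_KEY_DROPOUT = 1
_KEY_FACTORS = 2
_KEY_TRAIT_NOISE = 3
_KEY_EXPR = 4
_KEY_DETECTION = 5
_KEY_ANNOTATION = 6


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(key)]))


def haldane_recombination_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Members load on one latent factor F with loading ``loading`` (lambda);
    a nonzero ``trait_coupling`` (gamma) adds ``gamma * F`` to every trait,
    which makes the module's eigengene trait-correlated.  A nonzero
    ``qtl_loading`` (delta) mixes the standardized QTL genotype into the
    factor, F = delta * x_add/sd + sqrt(1 - delta^2) * eta: the module is then
    itself under (trans) genetic control, the mechanism by which a
    cis-regulated hub gene can drive both a pathway and a behavior.
    """

    name: str
    probes: tuple[str, ...]
    loading: float
    trait_coupling: float = 0.0
    qtl_loading: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError(f"module {self.name}: loading must be in [0, 1]")
        if not 0.0 <= self.qtl_loading <= 1.0:
            raise ValueError(f"module {self.name}: qtl_loading must be in [0, 1]")
        if len(set(self.probes)) != len(self.probes):
            raise ValueError(f"module {self.name}: duplicate probes")


@dataclass
class TruthSpec:
    """Ground truth for one simulated dataset.

    Effect sizes are in trait-SD units (traits) or log2-intensity units
    (expression); ``noise_sd`` is the residual SD sigma shared by traits and
    expression.
    """

    qtl_position_cm: float
    additive_effect: float = 0.5
    dominance_effect: float = 0.0
    trait_names: tuple[str, ...] = ("DM1", "FVSOP1")
    modules: list[ModuleSpec] = field(default_factory=list)
    cis_effects: dict[str, float] = field(default_factory=dict)
    trans_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    snp_probes: dict[str, float] = field(default_factory=dict)
    absent_probes: tuple[str, ...] = ()
    annotation: pd.DataFrame | None = None
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            overlap = seen & set(mod.probes)
            if overlap:
                raise ValueError(f"probe(s) {sorted(overlap)} assigned to multiple modules")
            seen |= set(mod.probes)

    @property
    def module_of(self) -> dict[str, str]:
        return {p: m.name for m in self.modules for p in m.probes}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["modules"] = [dataclasses.asdict(m) for m in self.modules]
        ann = d.pop("annotation")
        if ann is not None:
            d["annotation"] = self.annotation.reset_index().to_dict(orient="list")
        return json.dumps(d, sort_keys=True, default=list)


def simulate_gametes(markers: MarkerMap, n_gametes: int, seed: int) -> np.ndarray:
    """Simulate F1 gametes along the marker map.

    Returns an ``(n_gametes, n_markers)`` 0/1 array (1 = donor allele).  The
    F1 is fully heterozygous, so each gamete is a two-state Markov chain with
    switch probability equal to the Haldane recombination fraction of each
    marker interval.
    """
    if n_gametes < 1:
        raise ValueError("n_gametes must be >= 1")
    rng = _rng(seed, _KEY_GAMETES)
    r = haldane_recombination_fraction(np.diff(markers.cm))
    g = np.empty((n_gametes, markers.n_markers), dtype=np.int8)
    g[:, 0] = rng.random(n_gametes) < 0.5
    for j, rj in enumerate(r, start=1):
        switch = rng.random(n_gametes) < rj
        g[:, j] = np.where(switch, 1 - g[:, j - 1], g[:, j - 1])
    return g


def simulate_f2_genotypes(
    markers: MarkerMap,
    n: int,
    seed: int,
    missing_rate: float = 0.05,
) -> GenotypeMatrix:
    """Simulate ``n`` F2 individuals as unions of two independent F1 gametes.

    Genotype calls are dropped to missing independently at ``missing_rate``;
    the complete pre-dropout calls are kept on the returned matrix
    (``true_calls``) for ground-truth use.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    gametes = simulate_gametes(markers, 2 * n, seed)
    donor_dosage = gametes[0::2] + gametes[1::2]  # 0, 1 or 2 donor alleles
    true_calls = (2 - donor_dosage).astype(np.int8)  # AA=0 donor hom ... BB=2 host hom
    calls = true_calls.copy()
    if missing_rate > 0:
        drop = _rng(seed, _KEY_DROPOUT).random(calls.shape) < missing_rate
        calls[drop] = MISSING
    individuals = [f"F2_{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(individuals, markers, calls, true_calls=true_calls)


def _effect_codes(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive (-1/0/+1 for AA/AB/BB) and dominance (1 for AB) codings.

    Missing calls contribute their F2 expectations (0 and 0.5), which only
    matters if a caller passes observed rather than true genotypes.
    """
    x_add = np.where(calls == MISSING, 0.0, calls - 1.0)
    x_dom = np.where(calls == MISSING, 0.5, (calls == AB).astype(float))
    return x_add, x_dom


def _true_calls(geno: GenotypeMatrix) -> np.ndarray:
    return geno.true_calls if geno.true_calls is not None else geno.calls


def _module_factors(
    truth: TruthSpec, geno: GenotypeMatrix, seed: int
) -> dict[str, np.ndarray]:
    rng = _rng(seed, _KEY_FACTORS)
    # one stream, modules in declaration order -> identical across trait/expression calls
    qtl_idx = geno.markers.nearest_marker_index(truth.qtl_position_cm)
    x_add, _ = _effect_codes(_true_calls(geno)[:, qtl_idx])
    x_std = x_add / np.sqrt(0.5)  # F2 additive code has population variance 1/2
    out = {}
    for m in truth.modules:
        eta = rng.standard_normal(geno.n_individuals)
        d = m.qtl_loading
        out[m.name] = d * x_std + np.sqrt(1.0 - d * d) * eta
    return out


def simulate_traits(geno: GenotypeMatrix, truth: TruthSpec, seed: int) -> pd.DataFrame:
    """Simulate behavioral traits sharing the planted QTL and module factors.

    Each trait is ``y = a*x_add + d*x_dom + sum_m gamma_m * F_m + sigma * eps``
    with the QTL effect applied at the marker nearest ``qtl_position_cm``.
    Returns a samples x traits DataFrame.
    """
    lo, hi = geno.markers.span_cm
    if not lo <= truth.qtl_position_cm <= hi:
        raise ValueError("QTL position outside map span")
    couplings = [m.trait_coupling for m in truth.modules]
    if (
        truth.additive_effect == 0
        and truth.dominance_effect == 0
        and not any(couplings)
        and truth.noise_sd == 0
    ):
        raise ValueError("degenerate constant trait")
    qtl_idx = geno.markers.nearest_marker_index(truth.qtl_position_cm)
    x_add, x_dom = _effect_codes(_true_calls(geno)[:, qtl_idx])
    factors = _module_factors(truth, geno, seed)
    genetic = truth.additive_effect * x_add + truth.dominance_effect * x_dom
    shared = genetic + sum(
        m.trait_coupling * factors[m.name] for m in truth.modules
    )
    out = {}
    for t, name in enumerate(truth.trait_names):
        eps = _rng(seed, _KEY_TRAIT_NOISE).spawn(len(truth.trait_names))[t].standard_normal(
            geno.n_individuals
        )
        out[name] = shared + truth.noise_sd * eps
    return pd.DataFrame(out, index=geno.individuals)


def simulate_expression(geno: GenotypeMatrix, truth: TruthSpec, seed: int) -> ExpressionMatrix:
    """Simulate a raw expression matrix with planted regulatory structure.

    cis genes get an additive shift proportional to genotype at the marker
    nearest their own position; trans targets respond to a regulator locus;
    module members share a latent factor (loading lambda, residual scaled by
    sqrt(1 - lambda^2)); SNP-in-probe probes get a genotype-dependent
    intensity drop on the donor allele.  Intensities are 2**(log2 signal);
    detection p-values are Beta(0.1, 10) for expressed probes and
    Uniform(0, 1) for "absent" probes.
    """
    if truth.annotation is None:
        raise ValueError("truth.annotation is required to simulate expression")
    ann = truth.annotation
    planted = (
        set(truth.cis_effects)
        | set(truth.trans_effects)
        | set(truth.snp_probes)
        | set(truth.module_of)
    )
    for probe in sorted(planted):
        if probe not in ann.index:
            raise ValueError(f"probe {probe!r} has no annotation")

    probes = list(ann.index.astype(str))
    n = geno.n_individuals
    markers = geno.markers
    true_calls = _true_calls(geno)
    rng = _rng(seed, _KEY_EXPR)
    module_of = truth.module_of
    factors = _module_factors(truth, geno, seed)
    loadings = {m.name: m.loading for m in truth.modules}
    absent = set(truth.absent_probes)
    focal = markers.chromosome

    baseline = np.where(
        np.isin(probes, sorted(absent)),
        rng.normal(4.5, 0.3, len(probes)),
        rng.normal(8.5, 1.0, len(probes)),
    )
    log2 = np.tile(baseline[:, None], (1, n))
    noise = rng.standard_normal((len(probes), n)) * truth.noise_sd

    bp_to_cm = lambda bp: float(np.interp(bp, markers.bp, markers.cm))  # noqa: E731
    for i, probe in enumerate(probes):
        if probe in module_of:
            lam = loadings[module_of[probe]]
            log2[i] += lam * factors[module_of[probe]]
            noise[i] *= np.sqrt(max(0.0, 1.0 - lam**2))
        if probe in truth.cis_effects:
            if str(ann.loc[probe, "chromosome"]) != focal:
                raise ValueError(f"cis probe {probe!r} not on focal chromosome")
            idx = markers.nearest_marker_index(bp_to_cm(int(ann.loc[probe, "start_bp"])))
            x_add, _ = _effect_codes(true_calls[:, idx])
            log2[i] += truth.cis_effects[probe] * x_add
        if probe in truth.trans_effects:
            reg_cm, effect = truth.trans_effects[probe]
            idx = markers.nearest_marker_index(reg_cm)
            x_add, _ = _effect_codes(true_calls[:, idx])
            log2[i] += effect * x_add
        if probe in truth.snp_probes:
            # artifact: hybridization loss proportional to donor-allele dosage
            mag = truth.snp_probes[probe]
            idx = markers.nearest_marker_index(bp_to_cm(int(ann.loc[probe, "start_bp"])))
            dosage = np.where(true_calls[:, idx] == MISSING, 1.0, 2.0 - true_calls[:, idx])
            log2[i] -= mag * dosage / 2.0
    log2 += noise

    det_rng = _rng(seed, _KEY_DETECTION)
    detection = np.empty((len(probes), n))
    for i, probe in enumerate(probes):
        if probe in absent:
            detection[i] = det_rng.random(n)
        else:
            detection[i] = det_rng.beta(0.1, 10.0, n)

    samples = list(geno.individuals)
    intensities = pd.DataFrame(np.exp2(log2), index=probes, columns=samples)
    detection_p = pd.DataFrame(detection, index=probes, columns=samples)
    return ExpressionMatrix(
        intensities=intensities,
        detection_p=detection_p,
        annotation=ann.copy(),
        stage="raw",
        metadata={"seed": int(seed), "simulated": True},
    )


def default_truth(
    markers: MarkerMap,
    n_probes: int = 2000,
    n_modules: int = 5,
    module_size: int = 40,
    module_loading: float = 0.75,
    trait_couplings: tuple[float, ...] = (1.3, -0.8, 0.0, 0.0, 0.0),
    module_qtl_loadings: tuple[float, ...] = (0.5, 0.0, 0.0, 0.0, 0.0),
    qtl_position_cm: float | None = None,
    additive_effect: float = 0.5,
    dominance_effect: float = 0.0,
    n_cis: int = 12,
    cis_effect_range: tuple[float, float] = (0.9, 1.5),
    candidate_cis_effect: float = 1.5,
    n_trans: int = 15,
    trans_effect: float = 0.8,
    n_snp_probes: int = 6,
    snp_probe_magnitude: float = 3.0,
    absent_fraction: float = 0.45,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TruthSpec:
    """Build the default planted truth for one focal-chromosome dataset.

    Probe 1 is the fully supported candidate: a cis-regulated member of the
    first (trait-coupled) module, located on the focal chromosome near the
    QTL.  Remaining planted roles (other cis genes, trans targets, SNP-probe
    artifacts, neutral modules) are laid out deterministically from ``seed``.
    """
    if n_probes < n_modules * module_size + n_cis + n_trans + n_snp_probes + 10:
        raise ValueError("n_probes too small for the requested planted structure")
    rng = _rng(seed, _KEY_ANNOTATION)
    probes = [f"P{i + 1:05d}" for i in range(n_probes)]
    genes = [f"Gene{i + 1:05d}" for i in range(n_probes)]
    lo_cm, hi_cm = markers.span_cm
    qtl_cm = 0.5 * (lo_cm + hi_cm) if qtl_position_cm is None else qtl_position_cm

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = probes[cursor : cursor + k]
        cursor += k
        return out

    candidate = take(1)[0]
    module_probes = [take(module_size) for _ in range(n_modules)]
    module_probes[0] = [candidate] + module_probes[0][:-1]
    couplings = tuple(trait_couplings) + (0.0,) * max(0, n_modules - len(trait_couplings))
    qtl_loadings = tuple(module_qtl_loadings) + (0.0,) * max(
        0, n_modules - len(module_qtl_loadings)
    )
    modules = [
        ModuleSpec(
            name=f"M{m + 1}",
            probes=tuple(module_probes[m]),
            loading=module_loading,
            trait_coupling=couplings[m],
            qtl_loading=qtl_loadings[m],
        )
        for m in range(n_modules)
    ]
    cis_probes = [candidate] + take(n_cis - 1)
    trans_probes = take(n_trans)
    snp_probe_ids = take(n_snp_probes)

    focal = markers.chromosome
    chrom = np.array([str(c) for c in rng.integers(1, 20, n_probes)], dtype=object)
    start = rng.integers(3_000_000, 190_000_000, n_probes).astype(np.int64)
    ann = pd.DataFrame(
        {
            "gene_symbol": genes,
            "chromosome": chrom,
            "start_bp": start,
            "snp_in_probe": 0,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    span_bp = markers.bp[-1] - markers.bp[0]
    # focal-chromosome placements: cis genes and artifact probes live on the
    # varying chromosome, inside the marker span
    for p in cis_probes + snp_probe_ids:
        ann.loc[p, "chromosome"] = focal
        ann.loc[p, "start_bp"] = int(markers.bp[0] + rng.integers(0, span_bp))
    ann.loc[candidate, "start_bp"] = markers.cm_to_bp(qtl_cm)
    ann.loc[snp_probe_ids, "snp_in_probe"] = 1

    # heterogeneous cis strengths: most eQTL panels show a few strong and a
    # tail of marginal cis effects
    lo_e, hi_e = cis_effect_range
    grades = np.linspace(hi_e, lo_e, max(1, n_cis - 1))
    cis_effects = {p: float(grades[i]) for i, p in enumerate(cis_probes[1:])}
    cis_effects[candidate] = float(candidate_cis_effect)
    reg_choices = np.linspace(lo_cm, hi_cm, 5)
    trans_effects = {
        p: (float(reg_choices[i % len(reg_choices)]), float(trans_effect))
        for i, p in enumerate(trans_probes)
    }
    snp_probes = {p: float(snp_probe_magnitude) for p in snp_probe_ids}

    unplanted = probes[cursor:]
    n_absent = int(round(absent_fraction * n_probes))
    absent = tuple(unplanted[: min(n_absent, len(unplanted))])

    return TruthSpec(
        qtl_position_cm=float(qtl_cm),
        additive_effect=float(additive_effect),
        dominance_effect=float(dominance_effect),
        modules=modules,
        cis_effects=cis_effects,
        trans_effects=trans_effects,
        snp_probes=snp_probes,
        absent_probes=absent,
        annotation=ann,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    traits: pd.DataFrame
    expression: ExpressionMatrix
    truth: TruthSpec

    @property
    def candidate_probe(self) -> str:
        """The planted fully supported candidate (first cis probe in a coupled module)."""
        coupled = {p for m in self.truth.modules if m.trait_coupling != 0 for p in m.probes}
        hits = sorted(set(self.truth.cis_effects) & coupled)
        if not hits:
            raise ValueError("no cis probe inside a trait-coupled module")
        return hits[0]


def simulate_dataset(
    markers: MarkerMap | None = None,
    n_individuals: int = 57,
    n_expression_samples: int | None = 37,
    truth: TruthSpec | None = None,
    seed: int = 0,
    missing_rate: float = 0.05,
    **truth_kwargs,
) -> SimulatedDataset:
    """One-call generation of genotypes, traits and expression.

    By default 57 individuals are phenotyped and genotyped while expression
    is measured on the first 37 — the behavioral cohort is typically larger
    than the dissected one.  Pass ``n_expression_samples=None`` to profile
    everyone.
    """
    markers = markers if markers is not None else MarkerMap.evenly_spaced()
    truth = truth if truth is not None else default_truth(markers, seed=seed, **truth_kwargs)
    geno = simulate_f2_genotypes(markers, n_individuals, seed, missing_rate=missing_rate)
    traits = simulate_traits(geno, truth, seed)
    expr = simulate_expression(geno, truth, seed)
    if n_expression_samples is not None and n_expression_samples < n_individuals:
        cols = geno.individuals[:n_expression_samples]
        expr = ExpressionMatrix(
            intensities=expr.intensities[cols],
            detection_p=expr.detection_p[cols],
            annotation=expr.annotation,
            stage=expr.stage,
            metadata=expr.metadata,
        )
    return SimulatedDataset(geno, traits, expr, truth)
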