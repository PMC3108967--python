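"""Single-chromosome interval mapping by multiple imputation.

Genotype probabilities at markers and pseudomarkers come from a three-state
(AA/AB/BB) hidden Markov chain with Haldane transition probabilities; full
genotype vectors are sampled jointly from the chain (forward filtering,
backward sampling).  At every evaluation position the trait is regressed on
additive + dominance genotype codes, which for a fully observed three-class
genotype is the one-way group-means model, so

    LOD = (n / 2) * log10(RSS0 / RSS1)

is computed from group sums.  Per-draw LOD curves are combined on the
likelihood scale, ``LOD = log10(mean_d 10**LOD_d)``.  Significance comes from
either the fixed single-chromosome rule (LOD >= 1.5 with a -LOD1 support
interval, used for the behavioral traits) or a permutation null (quantile
threshold for one trait; an expected-exceedance FDR threshold for the
transcriptome-wide scan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import F2_PRIOR, MISSING, ExpressionMatrix, GenotypeMatrix, MarkerMap
from .sim import haldane_recombination_fraction

LOD_CAP = 50.0
_PERFECT_FIT = 1e-12


# ---------------------------------------------------------------------------
# evaluation grid and HMM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalGrid:
    """Markers plus pseudomarkers, spaced at most ``step_cm`` apart."""

    labels: list[str]
    positions_cm: np.ndarray
    positions_bp: np.ndarray
    marker_col: np.ndarray  # index into genotype columns, -1 for pseudomarkers

    @property
    def n_positions(self) -> int:
        return len(self.labels)


def build_grid(markers: MarkerMap, step_cm: float) -> EvalGrid:
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    cm = markers.cm
    bp = markers.bp
    ids = markers.marker_ids
    chrom = markers.chromosome
    labels: list[str] = []
    pos_cm: list[float] = []
    pos_bp: list[int] = []
    col: list[int] = []
    for j in range(markers.n_markers):
        labels.append(ids[j])
        pos_cm.append(float(cm[j]))
        pos_bp.append(int(bp[j]))
        col.append(j)
        if j + 1 < markers.n_markers:
            gap = cm[j + 1] - cm[j]
            k = int(np.ceil(gap / step_cm)) - 1
            for s in range(1, k + 1):
                c = cm[j] + gap * s / (k + 1)
                labels.append(f"c{chrom}.loc{c:g}")
                pos_cm.append(float(c))
                pos_bp.append(int(round(np.interp(c, cm, bp))))
                col.append(-1)
    return EvalGrid(labels, np.array(pos_cm), np.array(pos_bp, dtype=np.int64),
                    np.array(col, dtype=np.int64))


def _transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transitions for adjacent loci (two independent gametes)."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on the evaluation grid.

    ``probs`` has shape (n_individuals, n_positions, 3) over (AA, AB, BB);
    each triple conditions on all observed markers of that individual.
    Forward filtered distributions and transitions are retained so joint
    imputation can sample from the same chain.
    """

    individuals: list[str]
    grid: EvalGrid
    probs: np.ndarray
    error_rate: float
    _filtered: np.ndarray = field(repr=False)
    _transitions: np.ndarray = field(repr=False)


def _emissions(geno: GenotypeMatrix, grid: EvalGrid, error_rate: float) -> np.ndarray:
    """(n, P, 3) emission likelihoods; ones at pseudomarkers and missing calls."""
    n = geno.n_individuals
    e = np.ones((n, grid.n_positions, 3))
    for p, col in enumerate(grid.marker_col):
        if col < 0:
            continue
        obs = geno.calls[:, col]
        typed = obs != MISSING
        if not typed.any():
            continue
        probs = np.full((typed.sum(), 3), error_rate / 2.0)
        probs[np.arange(typed.sum()), obs[typed]] = 1.0 - error_rate
        e[typed, p, :] = probs
    return e


def genotype_probabilities(
    geno: GenotypeMatrix,
    step_cm: float = 1.0,
    error_rate: float = 0.002,
) -> GenotypeProbabilities:
    """Forward–backward smoothing of F2 genotypes along one chromosome.

    An individual with no typed markers gets the F2 prior (1/4, 1/2, 1/4)
    everywhere.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    grid = build_grid(geno.markers, step_cm)
    P = grid.n_positions
    n = geno.n_individuals
    r = haldane_recombination_fraction(np.diff(grid.positions_cm))
    trans = np.stack([_transition_matrix(float(ri)) for ri in r])  # (P-1, 3, 3)
    emit = _emissions(geno, grid, error_rate)

    fwd = np.empty((n, P, 3))
    f = F2_PRIOR[None, :] * emit[:, 0, :]
    f /= f.sum(axis=1, keepdims=True)
    fwd[:, 0, :] = f
    for p in range(1, P):
        f = (f @ trans[p - 1]) * emit[:, p, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, p, :] = f

    post = np.empty((n, P, 3))
    b = np.ones((n, 3))
    post[:, P - 1, :] = fwd[:, P - 1, :]
    for p in range(P - 2, -1, -1):
        b = (emit[:, p + 1, :] * b) @ trans[p].T
        b /= b.sum(axis=1, keepdims=True)
        u = fwd[:, p, :] * b
        post[:, p, :] = u / u.sum(axis=1, keepdims=True)

    return GenotypeProbabilities(
        list(geno.individuals), grid, post, error_rate, fwd, trans
    )


@dataclass
class ImputationSet:
    """Joint genotype draws from the conditional chain.

    ``draws`` has shape (n_draws, n_individuals, n_positions) with values in
    {0, 1, 2}.
    """

    individuals: list[str]
    grid: EvalGrid
    draws: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def impute_genotypes(probs: GenotypeProbabilities, n_draws: int, seed: int) -> ImputationSet:
    """Sample full genotype vectors by forward filtering / backward sampling."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    fwd = probs._filtered
    trans = probs._transitions
    n, P, _ = fwd.shape
    draws = np.empty((n_draws, n, P), dtype=np.int8)
    for d in range(n_draws):
        u = rng.random((n, P))
        z = np.empty((n, P), dtype=np.int8)
        cdf = np.cumsum(fwd[:, P - 1, :], axis=1)
        z[:, P - 1] = (u[:, P - 1, None] > cdf[:, :2]).sum(axis=1)
        for p in range(P - 2, -1, -1):
            # p(z_p | z_{p+1}, obs) ∝ filtered_p(z) * T[z, z_{p+1}]
            w = fwd[:, p, :] * trans[p][:, z[:, p + 1]].T
            cdf = np.cumsum(w, axis=1)
            cdf /= cdf[:, -1:]
            z[:, p] = (u[:, p, None] > cdf[:, :2]).sum(axis=1)
        draws[d] = z
    return ImputationSet(list(probs.individuals), probs.grid, draws, int(seed))


# ---------------------------------------------------------------------------
# LOD scans
# ---------------------------------------------------------------------------

class _ScanKernel:
    """Vectorized group-sum LOD evaluation over all positions and draws.

    Stacks one-hot genotype indicators into a single (P*D*3, n) matrix so a
    scan over any trait matrix is one matmul.
    """

    def __init__(self, imputations: ImputationSet):
        draws = imputations.draws  # (D, n, P)
        D, n, P = draws.shape
        onehot = np.zeros((P, D, 3, n))
        pos_idx = np.arange(P)[:, None]
        for d in range(D):
            g = draws[d].T  # (P, n)
            onehot[pos_idx, d, g, np.arange(n)[None, :]] = 1.0
        self.counts = onehot.sum(axis=3)  # (P, D, 3)
        self.A = onehot.reshape(P * D * 3, n)
        self.D, self.n, self.P = D, n, P

    def lod(self, y: np.ndarray) -> np.ndarray:
        """LOD curves for a (n,) or (n, T) trait matrix -> (P, T)."""
        Y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, T)
        if Y.shape[0] != self.n:
            raise ValueError("trait length does not match individuals")
        Yc = Y - Y.mean(axis=0, keepdims=True)
        rss0 = (Yc**2).sum(axis=0)  # (T,)
        if np.any(rss0 == 0):
            raise ValueError("zero-variance trait")
        S = (self.A @ Yc).reshape(self.P, self.D, 3, -1)
        counts = self.counts[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            between = np.where(counts > 0, S**2 / counts, 0.0).sum(axis=2)  # (P, D, T)
        rss1 = np.clip(rss0[None, None, :] - between, 0.0, None)
        with np.errstate(divide="ignore"):
            lod_d = 0.5 * self.n * np.log10(rss0[None, None, :] / rss1)
        lod_d = np.where(rss1 < _PERFECT_FIT * rss0[None, None, :], LOD_CAP, lod_d)
        # combine draws on the likelihood scale: log10(mean_d 10**lod_d)
        m = lod_d.max(axis=1, keepdims=True)
        combined = m[:, 0, :] + np.log10(
            np.mean(np.power(10.0, lod_d - m), axis=1)
        )
        return np.minimum(combined, LOD_CAP)


@dataclass
class QtlScan:
    """A per-position LOD curve with peak and -LOD1 support interval."""

    trait: str
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    lod: np.ndarray
    threshold: float | None = None
    drop: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.lod)):
            raise ValueError("non-finite LOD values")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.lod))  # argmax is leftmost on ties

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])

    @property
    def peak_position_bp(self) -> int:
        return int(self.positions_bp[self.peak_index])

    @property
    def peak_position_cm(self) -> float:
        return float(self.positions_cm[self.peak_index])

    @property
    def support_interval(self) -> tuple[int, int]:
        return lod_support_interval(self, self.drop)

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.peak_lod >= self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_bp": self.positions_bp,
                "position_cm": self.positions_cm,
                "lod": self.lod,
            }
        )


def lod_support_interval(scan: QtlScan, drop: float = 1.0) -> tuple[int, int]:
    """-LOD``drop`` support interval as [bp of first, bp of last] position.

    The interval is the contiguous run of evaluation positions around the
    (leftmost) peak whose LOD stays within ``drop`` of the maximum.
    """
    lod = scan.lod
    if len(lod) == 0:
        raise ValueError("empty scan")
    peak = int(np.argmax(lod))
    cut = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    return int(scan.positions_bp[lo]), int(scan.positions_bp[hi])


def scan_trait(
    trait: np.ndarray | pd.Series,
    imputations: ImputationSet,
    kernel: _ScanKernel | None = None,
    trait_name: str = "trait",
    threshold: float | None = None,
) -> QtlScan:
    """Interval-mapping LOD curve for one trait (additive + dominance model)."""
    if isinstance(trait, pd.Series):
        trait_name = str(trait.name) if trait.name is not None else trait_name
        trait = trait.to_numpy(dtype=float)
    kernel = kernel or _ScanKernel(imputations)
    lod = kernel.lod(trait)[:, 0]
    return QtlScan(
        trait=trait_name,
        positions_bp=imputations.grid.positions_bp,
        positions_cm=imputations.grid.positions_cm,
        lod=lod,
        threshold=threshold,
    )


def permutation_threshold(
    trait: np.ndarray | pd.Series,
    imputations: ImputationSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    kernel: _ScanKernel | None = None,
    return_maxima: bool = False,
):
    """(1 - alpha) quantile of the permutation distribution of max LOD."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    y = trait.to_numpy(dtype=float) if isinstance(trait, pd.Series) else np.asarray(trait, float)
    kernel = kernel or _ScanKernel(imputations)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 8]))
    perms = np.stack([rng.permutation(len(y)) for _ in range(n_perm)], axis=1)
    maxima = kernel.lod(y[perms]).max(axis=0)  # (n_perm,)
    thr = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    if return_maxima:
        return thr, maxima
    return thr


# ---------------------------------------------------------------------------
# transcriptome-wide eQTL scan with permutation FDR threshold
# ---------------------------------------------------------------------------

def _fdr_threshold(
    observed_max: np.ndarray,
    perm_max: np.ndarray,
    fdr_target: float,
    grid_step: float = 0.01,
) -> tuple[float, pd.DataFrame]:
    """Smallest LOD t on a 0.01 grid with estimated FDR(t) <= target.

    FDR(t) = (mean permutation count of probes with max LOD >= t) /
             (observed count >= t), capped at 1.
    """
    n_perm = perm_max.shape[0]
    obs_sorted = np.sort(observed_max)
    perm_sorted = np.sort(perm_max.ravel())
    t0 = np.floor(observed_max.min() / grid_step) * grid_step
    t1 = np.ceil(observed_max.max() / grid_step) * grid_step
    ts = np.round(np.arange(t0, t1 + grid_step / 2, grid_step), 10)
    obs_count = len(obs_sorted) - np.searchsorted(obs_sorted, ts, side="left")
    perm_count = (len(perm_sorted) - np.searchsorted(perm_sorted, ts, side="left")) / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_count > 0, np.minimum(perm_count / obs_count, 1.0), np.nan)
    table = pd.DataFrame({"lod": ts, "n_observed": obs_count,
                          "mean_permuted": perm_count, "fdr": fdr})
    ok = np.where((obs_count > 0) & (fdr <= fdr_target))[0]
    if len(ok) == 0:
        warnings.warn("no LOD threshold achieves the requested FDR; returning +inf")
        return float("inf"), table
    return float(ts[ok[0]]), table


def eqtl_scan_all(
    expr: ExpressionMatrix,
    imputations: ImputationSet,
    n_perm: int = 1000,
    fdr_target: float = 0.01,
    seed: int = 0,
    drop: float = 1.0,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Scan every probe; returns (records, lod_threshold, fdr_table).

    Permutations shuffle sample rows jointly across all probes, preserving
    inter-gene correlation in the null.  Records carry per-probe peak, max
    LOD, -LOD1 support interval and a significance flag.
    """
    samples = list(expr.samples)
    if set(samples) != set(imputations.individuals):
        raise ValueError("expression samples do not match genotyped individuals")
    order = [samples.index(i) for i in imputations.individuals]
    Y = expr.intensities.to_numpy(dtype=float).T[order]  # (n, P_probes)
    if np.any(Y.std(axis=0) == 0):
        bad = [p for p, s in zip(expr.probes, Y.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance probe(s): {bad[:5]}")
    kernel = _ScanKernel(imputations)
    lod = kernel.lod(Y)  # (P_pos, P_probes)
    observed_max = lod.max(axis=0)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9]))
    n = Y.shape[0]
    perm_max = np.empty((n_perm, Y.shape[1]))
    for k in range(n_perm):
        perm_max[k] = kernel.lod(Y[rng.permutation(n)]).max(axis=0)
    threshold, fdr_table = _fdr_threshold(observed_max, perm_max, fdr_target)

    grid = imputations.grid
    peaks = lod.argmax(axis=0)
    rows = []
    ann = expr.annotation
    for j, probe in enumerate(expr.probes):
        scan = QtlScan(
            trait=probe,
            positions_bp=grid.positions_bp,
            positions_cm=grid.positions_cm,
            lod=lod[:, j],
            drop=drop,
        )
        lo, hi = scan.support_interval
        rows.append(
            {
                "probe": probe,
                "gene_symbol": ann.loc[probe, "gene_symbol"],
                "gene_chromosome": str(ann.loc[probe, "chromosome"]),
                "gene_bp": int(ann.loc[probe, "start_bp"]),
                "max_lod": float(observed_max[j]),
                "peak_bp": int(grid.positions_bp[peaks[j]]),
                "peak_cm": float(grid.positions_cm[peaks[j]]),
                "ci_low_bp": lo,
                "ci_high_bp": hi,
                "significant": bool(observed_max[j] >= threshold),
            }
        )
    records = pd.DataFrame(rows)
    return records, threshold, fdr_table


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class F2IntervalMapper:
    """Interval-mapping model for one CSS F2 chromosome.

    Builds genotype probabilities and joint imputations once; ``fit`` scans a
    trait, ``fit_expression`` scans a whole expression matrix.

    Parameters
    ----------
    geno : GenotypeMatrix
    step_cm : pseudomarker spacing (cM).
    error_rate : HMM genotyping-error rate.
    n_draws : number of imputation draws combined per scan.
    seed : seed for the imputation draws.
    """

    def __init__(
        self,
        geno: GenotypeMatrix,
        step_cm: float = 1.0,
        error_rate: float = 0.002,
        n_draws: int = 128,
        seed: int = 0,
    ):
        self.geno = geno
        self.step_cm = step_cm
        self.error_rate = error_rate
        self.probabilities = genotype_probabilities(geno, step_cm, error_rate)
        self.imputations = impute_genotypes(self.probabilities, n_draws, seed)
        self._kernel = _ScanKernel(self.imputations)

    def _align(self, trait: pd.Series | np.ndarray) -> np.ndarray:
        if isinstance(trait, pd.Series):
            return trait.loc[self.geno.individuals].to_numpy(dtype=float)
        return np.asarray(trait, dtype=float)

    def fit(
        self,
        trait: pd.Series | np.ndarray,
        trait_name: str = "trait",
        threshold: float | None = 1.5,
        drop: float = 1.0,
    ) -> "QtlScanResults":
        """Scan one trait.  Default threshold is the fixed single-chromosome
        LOD >= 1.5 rule; pass ``threshold=None`` and use
        :meth:`permutation_threshold` for a permutation-based cutoff."""
        if isinstance(trait, pd.Series) and trait.name is not None:
            trait_name = str(trait.name)
        y = self._align(trait)
        scan = scan_trait(y, self.imputations, kernel=self._kernel,
                          trait_name=trait_name, threshold=threshold)
        scan.drop = drop
        return QtlScanResults(self, scan)

    def permutation_threshold(self, trait, n_perm: int = 1000, alpha: float = 0.05,
                              seed: int = 0, **kw):
        return permutation_threshold(self._align(trait), self.imputations, n_perm,
                                     alpha, seed, kernel=self._kernel, **kw)

    def fit_expression(self, expr: ExpressionMatrix, n_perm: int = 1000,
                       fdr_target: float = 0.01, seed: int = 0) -> "EqtlScanResults":
        records, threshold, fdr_table = eqtl_scan_all(
            expr, self.imputations, n_perm=n_perm, fdr_target=fdr_target, seed=seed
        )
        return EqtlScanResults(self, records, threshold, fdr_table,
                               n_perm=n_perm, fdr_target=fdr_target, seed=seed)


@dataclass
class QtlScanResults:
    """Results of one trait scan; wraps the LOD curve with its summary."""

    model: F2IntervalMapper
    scan: QtlScan

    def __getattr__(self, name):
        return getattr(self.scan, name)

    def summary(self) -> str:
        s = self.scan
        lo, hi = s.support_interval
        lines = [
            f"Interval mapping: trait {s.trait!r}",
            f"  n individuals        {self.model.geno.n_individuals}",
            f"  evaluation positions {len(s.lod)} (step {self.model.step_cm} cM)",
            f"  imputation draws     {self.model.imputations.n_draws}",
            f"  peak LOD             {s.peak_lod:.3f} at {s.peak_position_bp:,} bp"
            f" ({s.peak_position_cm:g} cM)",
            f"  -LOD{s.drop:g} interval      [{lo:,}, {hi:,}] bp",
        ]
        if s.threshold is not None:
            verdict = "significant" if s.significant else "not significant"
            lines.append(f"  threshold            LOD >= {s.threshold:g} -> {verdict}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.scan
        ax.plot(s.positions_bp / 1e6, s.lod)
        lo, hi = s.support_interval
        ax.axvspan(lo / 1e6, hi / 1e6, alpha=0.15)
        if s.threshold is not None:
            ax.axhline(s.threshold, ls="--", color="grey")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("LOD")
        ax.set_title(s.trait)
        return ax


@dataclass
class EqtlScanResults:
    """Transcriptome-wide scan: per-probe records plus the FDR threshold."""

    model: F2IntervalMapper
    records: pd.DataFrame
    threshold: float
    fdr_table: pd.DataFrame
    n_perm: int
    fdr_target: float
    seed: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.records[self.records["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        n_sig = int(self.records["significant"].sum())
        focal = self.model.geno.markers.chromosome
        on_focal = int(
            (self.records["significant"]
             & (self.records["gene_chromosome"] == focal)).sum()
        )
        return "\n".join(
            [
                "Expression QTL scan",
                f"  probes scanned   {len(self.records)}",
                f"  permutations     {self.n_perm}",
                f"  LOD threshold    {self.threshold:g} (FDR <= {self.fdr_target:g})",
                f"  significant      {n_sig} ({on_focal} with genes on chr {focal})",
            ]
        )
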