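"""Core data containers shared across the pipeline.

The experimental design is an F2 intercross derived from a chromosome
substitution strain: every animal is genetically identical except on one
donor chromosome, so genotypes are recorded for markers on that single
chromosome only.  Genotype calls use three states — donor-strain homozygote
(``AA``), heterozygote (``AB``) and host-strain homozygote (``BB``) — plus a
missing code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# integer genotype codes used throughout; -1 marks a missing call
AA, AB, BB, MISSING = 0, 1, 2, -1

GENOTYPE_LETTERS = {AA: "A", AB: "H", BB: "B", MISSING: "-"}
LETTER_CODES = {v: k for k, v in GENOTYPE_LETTERS.items()}

#: expected F2 segregation frequencies for (AA, AB, BB)
F2_PRIOR = np.array([0.25, 0.5, 0.25])


class StageError(ValueError):
    """Raised when an operation is applied at the wrong pipeline stage."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered genetic/physical map of markers on one chromosome.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker_id``, ``chromosome``, ``position_bp`` (1-based) and
        ``position_cm``.  Markers must be sorted, with strictly increasing bp
        and non-decreasing cM.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position_bp", "position_cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if len(self.table) < 2:
            raise ValueError("map has fewer than 2 markers")
        chroms = self.table["chromosome"].astype(str).unique()
        if len(chroms) != 1:
            raise ValueError("marker map must cover exactly one chromosome")
        bp = self.table["position_bp"].to_numpy()
        cm = self.table["position_cm"].to_numpy(dtype=float)
        if np.any(np.diff(bp) <= 0):
            raise ValueError("bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM positions must be non-decreasing")
        if np.any(cm < 0):
            raise ValueError("cM positions must be non-negative")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].astype(str).tolist()

    @property
    def chromosome(self) -> str:
        return str(self.table["chromosome"].iloc[0])

    @property
    def cm(self) -> np.ndarray:
        return self.table["position_cm"].to_numpy(dtype=float)

    @property
    def bp(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy(dtype=np.int64)

    @property
    def span_cm(self) -> tuple[float, float]:
        cm = self.cm
        return float(cm[0]), float(cm[-1])

    def nearest_marker_index(self, position_cm: float) -> int:
        """Index of the marker closest in cM (leftmost on ties)."""
        d = np.abs(self.cm - position_cm)
        return int(np.argmin(d))

    def cm_to_bp(self, position_cm: float) -> int:
        """Physical position by linear interpolation along the map."""
        return int(round(float(np.interp(position_cm, self.cm, self.bp))))

    @classmethod
    def evenly_spaced(
        cls,
        chromosome: str = "15",
        n_markers: int = 33,
        start_bp: int = 3_000_000,
        spacing_bp: int = 3_000_000,
        spacing_cm: float = 2.0,
        start_cm: float = 0.0,
        prefix: str = "m",
    ) -> "MarkerMap":
        """Regular marker panel: by default 33 markers spanning a whole
        chromosome (~3 Mb / 2 cM spacing, ~100 Mb / 64 cM total), so planted
        genes can fall inside or outside a QTL support interval."""
        idx = np.arange(n_markers)
        return cls(
            pd.DataFrame(
                {
                    "marker_id": [f"{prefix}{i + 1:02d}" for i in idx],
                    "chromosome": chromosome,
                    "position_bp": start_bp + idx * spacing_bp,
                    "position_cm": start_cm + idx * spacing_cm,
                }
            )
        )


@dataclass
class GenotypeMatrix:
    """Genotype calls for F2 individuals at the mapped markers.

    ``calls`` is an ``(n_individuals, n_markers)`` int8 array over
    ``{AA, AB, BB, MISSING}``.  When produced by the simulator, the
    pre-dropout calls are retained in ``true_calls`` so planted effects can
    be defined on the underlying genotypes.
    """

    individuals: list[str]
    markers: MarkerMap
    calls: np.ndarray
    true_calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), self.markers.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {self.markers.n_markers} markers"
            )
        valid = np.isin(self.calls, [AA, AB, BB, MISSING])
        if not valid.all():
            raise ValueError("genotype calls must be in {AA, AB, BB, missing}")
        if self.true_calls is not None:
            self.true_calls = np.asarray(self.true_calls, dtype=np.int8)
            if self.true_calls.shape != self.calls.shape:
                raise ValueError("true_calls shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset(self, individuals: list[str]) -> "GenotypeMatrix":
        """Restrict to a subset of individuals (order as given)."""
        idx = [self.individuals.index(i) for i in individuals]
        return GenotypeMatrix(
            list(individuals),
            self.markers,
            self.calls[idx],
            true_calls=None if self.true_calls is None else self.true_calls[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Letter-coded calls (A/H/B/-), individuals x markers."""
        letters = np.vectorize(GENOTYPE_LETTERS.get)(self.calls)
        return pd.DataFrame(letters, index=self.individuals, columns=self.markers.marker_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, markers: MarkerMap) -> "GenotypeMatrix":
        if list(frame.columns) != markers.marker_ids:
            raise ValueError("genotype columns do not match marker map")
        calls = frame.apply(lambda col: col.map(LETTER_CODES)).to_numpy(dtype=np.int8)
        return cls(list(frame.index.astype(str)), markers, calls)


STAGES = ("raw", "transformed", "normalized")


@dataclass
class ExpressionMatrix:
    """Microarray expression with per-cell detection p-values and annotation.

    intensities, detection_p : probes x samples DataFrames (shared index and
    columns).  annotation is indexed by probe id with columns
    ``gene_symbol``, ``chromosome``, ``start_bp`` and ``snp_in_probe``.
    The ``stage`` tag tracks the raw -> transformed -> normalized pipeline.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    annotation: pd.DataFrame
    stage: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.intensities.shape != self.detection_p.shape:
            raise ValueError("intensity and detection matrices must share shape")
        if not self.intensities.index.equals(self.detection_p.index) or not (
            self.intensities.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("intensity/detection index or columns differ")
        missing = self.intensities.index.difference(self.annotation.index)
        if len(missing) > 0:
            raise ValueError(f"annotation missing for probe(s): {list(missing[:5])}")
        for col in ("gene_symbol", "chromosome", "start_bp", "snp_in_probe"):
            if col not in self.annotation.columns:
                raise ValueError(f"annotation missing column {col!r}")
        dp = self.detection_p.to_numpy()
        if dp.size and (np.nanmin(dp) < 0 or np.nanmax(dp) > 1):
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probes(self) -> list[str]:
        return list(self.intensities.index.astype(str))

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns.astype(str))

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def _require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, matrix is {self.stage!r}"
            )

    def subset_probes(self, probes: Sequence[str], stage: str | None = None,
                      **meta) -> "ExpressionMatrix":
        """New matrix restricted to ``probes`` (order preserved as given)."""
        probes = list(probes)
        return ExpressionMatrix(
            intensities=self.intensities.loc[probes].copy(),
            detection_p=self.detection_p.loc[probes].copy(),
            annotation=self.annotation.loc[probes].copy(),
            stage=stage or self.stage,
            metadata={**self.metadata, **meta},
        )

    def replace_values(self, values: pd.DataFrame, stage: str, **meta) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=values,
            detection_p=self.detection_p.copy(),
            annotation=self.annotation.copy(),
            stage=stage,
            metadata={**self.metadata, **meta},
        )
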