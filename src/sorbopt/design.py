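"""Box-Behnken designs and the coded/actual variable transform.

A three-factor Box-Behnken design (BBD) places runs at the twelve edge
midpoints of the ``[-1, 1]^3`` cube — every pair of factors crossed at
``+/-1`` with the third held at its centre — plus replicated centre
points.  Each factor therefore takes exactly three levels (coded -1, 0,
+1), the coded columns are mean-zero and pairwise orthogonal, and the
centre replicates supply the pure-error degrees of freedom used by the
lack-of-fit test.

Coded and actual units are related by the affine map

    coded = (actual - center) / half_range,

with ``center`` the midpoint of the factor's range and ``half_range``
half the distance between its low and high levels.  All model fitting in
this package happens in coded units; actual units are carried alongside
for readability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UnsupportedDesignError, ValidationError

__all__ = [
    "FactorSpec",
    "DesignTable",
    "build_bbd",
    "to_actual",
    "to_coded",
    "read_design",
    "write_design",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor: name, low/high levels and centre.

    The centre must be the midpoint of ``(low, high)`` — the coding
    transform divides by half the range about the mean, which is only an
    involution-friendly affine map when the three levels are equispaced.
    """

    name: str
    low: float
    high: float
    center: float = None  # type: ignore[assignment]  # default: midpoint

    def __post_init__(self) -> None:
        if self.center is None:
            object.__setattr__(self, "center", 0.5 * (self.low + self.high))
        if not self.low < self.high:
            raise ValidationError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )
        mid = 0.5 * (self.low + self.high)
        if abs(self.center - mid) > 1e-9 * (self.high - self.low):
            raise ValidationError(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"{mid} of (low, high); three-level coding requires equispaced levels"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def to_actual(self, coded):
        return self.center + np.asarray(coded, dtype=float) * self.half_range

    def to_coded(self, actual):
        return (np.asarray(actual, dtype=float) - self.center) / self.half_range


def to_actual(spec: FactorSpec, coded):
    """Decode a coded value (coded 0 -> centre, +/-1 -> high/low).

    Values outside ``[-1, 1]`` are legal and mean extrapolation beyond
    the design region.
    """
    return spec.to_actual(coded)


def to_coded(spec: FactorSpec, actual):
    """Code an actual value; exact inverse of :func:`to_actual`."""
    return spec.to_coded(actual)


@dataclass
class DesignTable:
    """A coded design with optional measured responses.

    ``coded`` is an ``(n_runs, n_factors)`` array; ``responses`` (percent
    removal, or any response in consistent units) aligns with the rows.
    """

    factors: tuple[FactorSpec, ...]
    coded: np.ndarray
    run_ids: np.ndarray = None  # type: ignore[assignment]
    responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        if self.coded.shape[1] != len(self.factors):
            raise ValidationError(
                f"coded matrix has {self.coded.shape[1]} columns for "
                f"{len(self.factors)} factors"
            )
        if self.run_ids is None:
            self.run_ids = np.arange(1, self.n_runs + 1)
        self.run_ids = np.asarray(self.run_ids)
        if self.run_ids.shape != (self.n_runs,):
            raise ValidationError("run_ids length must match the number of runs")
        if self.responses is not None:
            self.responses = np.asarray(self.responses, dtype=float)
            if self.responses.shape != (self.n_runs,):
                raise ValidationError("responses length must match the number of runs")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def actual(self) -> np.ndarray:
        """Actual-unit design matrix, column-wise decoded."""
        cols = [f.to_actual(self.coded[:, i]) for i, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def with_responses(self, responses) -> "DesignTable":
        return replace(self, responses=np.asarray(responses, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run, coded columns, actual columns, response."""
        data: dict[str, np.ndarray] = {"run": self.run_ids}
        for i, f in enumerate(self.factors):
            data[f"{f.name}_coded"] = self.coded[:, i]
        act = self.actual
        for i, f in enumerate(self.factors):
            data[f"{f.name}_actual"] = act[:, i]
        if self.responses is not None:
            data["response"] = self.responses
        return pd.DataFrame(data)


# Edge-point block order for the 3-factor BBD: factor pairs (0,1), (0,2),
# (1,2), each crossed (-1,-1), (-1,+1), (+1,-1), (+1,+1), third factor 0.
_BBD3_PAIRS = ((0, 1), (0, 2), (1, 2))
_BBD3_SIGNS = ((-1, -1), (-1, 1), (1, -1), (1, 1))


def build_bbd(factors: Sequence[FactorSpec], n_center: int = 3) -> DesignTable:
    """Three-factor Box-Behnken design: 12 edge midpoints + centre replicates.

    Edge points are emitted in a fixed lexicographic block order (pairs
    (1,2), (1,3), (2,3); signs --, -+, +-, ++) followed by ``n_center``
    copies of the centre point; run ids are 1..12+n_center.  Model fits
    are invariant to run order.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only the 3-factor Box-Behnken design is supported, got {len(factors)} factors"
        )
    if n_center < 1:
        raise ValidationError("n_center must be >= 1 (pure error needs replicates)")
    rows = []
    for i, j in _BBD3_PAIRS:
        for si, sj in _BBD3_SIGNS:
            point = [0.0, 0.0, 0.0]
            point[i], point[j] = float(si), float(sj)
            rows.append(point)
    rows.extend([[0.0, 0.0, 0.0]] * n_center)
    return DesignTable(factors=factors, coded=np.asarray(rows))


def write_design(table: DesignTable, path, comments: Sequence[str] = ()) -> None:
    """Write a design/response table as CSV; optional '#' header comments."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        table.to_frame().to_csv(fh, index=False)


def _infer_factors(frame: pd.DataFrame, names: Sequence[str]) -> tuple[FactorSpec, ...]:
    """Recover FactorSpecs from paired coded/actual columns (affine fit)."""
    specs = []
    for name in names:
        coded = frame[f"{name}_coded"].to_numpy(dtype=float)
        actual = frame[f"{name}_actual"].to_numpy(dtype=float)
        # actual = center + coded * half_range: solve from two distinct levels
        order = np.argsort(coded)
        c0, c1 = coded[order[0]], coded[order[-1]]
        if c1 - c0 < 1e-12:
            raise ValidationError(f"factor {name!r}: cannot infer levels, coded column constant")
        a0, a1 = actual[order[0]], actual[order[-1]]
        half = (a1 - a0) / (c1 - c0)
        center = a0 - c0 * half
        specs.append(FactorSpec(name, center - half, center + half))
    return tuple(specs)


def read_design(path, factors: Sequence[FactorSpec] | None = None) -> DesignTable:
    """Read a design/response CSV written by :func:`write_design`.

    Factor specs are taken from ``factors`` when given, otherwise
    reconstructed from the paired ``<name>_coded`` / ``<name>_actual``
    columns.
    """
    frame = pd.read_csv(path, comment="#")
    if factors is None:
        names = [c[: -len("_coded")] for c in frame.columns if c.endswith("_coded")]
        factors = _infer_factors(frame, names)
    factors = tuple(factors)
    coded = np.column_stack(
        [frame[f"{f.name}_coded"].to_numpy(dtype=float) for f in factors]
    )
    responses = (
        frame["response"].to_numpy(dtype=float) if "response" in frame.columns else None
    )
    run_ids = (
        frame["run"].to_numpy() if "run" in frame.columns else None
    )
    return DesignTable(factors=factors, coded=coded, run_ids=run_ids, responses=responses)
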