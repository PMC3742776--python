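"""Exhaustive miRNA-subset search with AIC selection.

Every non-empty combination of panel markers is added to the clinical base
model; each candidate is scored by the global Wald chi-square p-value, its
AIC, and a likelihood-ratio test against the base model.  The final model is
the AIC minimiser, the base ("no miRNA") model being a candidate itself.
Ties break towards parsimony, then enumeration order (sizes ascending, input
order within a size) — the layout of the published added-value tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, MODEL1_BASE_VARS, design_matrix
from .errors import FitError, InputError, SelectionError
from .regression import Logistic, RegressionResults, Tobit, lrt


def enumerate_subsets(marker_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty marker subsets: sizes ascending, input order within size."""
    names = list(marker_names)
    if len(set(names)) != len(names):
        raise InputError(f"duplicate marker names: {names}")
    if not names:
        raise InputError("need at least one marker")
    out: list[tuple[str, ...]] = []
    for r in range(1, len(names) + 1):
        out.extend(combinations(names, r))
    return out


@dataclass
class SubsetResult:
    """One row of the added-value table (empty subset = base model)."""

    subset: tuple[str, ...]
    wald_p: float | None = None
    aic: float | None = None
    lrt_p: float | None = None
    fit: RegressionResults | None = None
    failed: bool = False
    reason: str | None = None

    @property
    def label(self) -> str:
        return "+".join(self.subset) if self.subset else "None"


@dataclass
class SelectionTable:
    """Base row plus all 2^m - 1 subset rows, with the AIC-best subset."""

    family: str
    base_vars: tuple[str, ...]
    rows: list[SubsetResult]
    metadata: dict = field(default_factory=dict)

    @property
    def best_subset(self) -> tuple[str, ...]:
        return select_best(self)

    @property
    def base_row(self) -> SubsetResult:
        return self.rows[0]

    def row(self, subset: Sequence[str]) -> SubsetResult:
        key = tuple(subset)
        for r in self.rows:
            if r.subset == key:
                return r
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "subset": r.label,
                    "wald_chi_square_p": r.wald_p,
                    "aic": r.aic,
                    "lrt_p": r.lrt_p,
                    "failed": r.failed,
                }
            )
        return pd.DataFrame(recs)


def select_best(table: SelectionTable) -> tuple[str, ...]:
    """Argmin-AIC subset; ties break to the smaller subset, then table order."""
    ok = [r for r in table.rows if not r.failed]
    if not ok:
        raise SelectionError("every candidate fit failed")
    best = min(ok, key=lambda r: (r.aic, len(r.subset)))
    return best.subset


class SelectionEngine:
    """Precomputed design columns for repeated (bootstrap) subset searches.

    Builds the full base+panel design once; each call fits all subsets on a
    row-subsample by column slicing, avoiding per-replicate cohort plumbing.
    """

    def __init__(
        self,
        cohort: Cohort,
        base_vars: Sequence[str] = MODEL1_BASE_VARS,
        marker_names: Sequence[str] | None = None,
        family: str = "logistic",
        censor_floor: float = 1.0,
    ):
        if family not in ("logistic", "tobit"):
            raise InputError(f"unknown family {family!r}")
        self.family = family
        self.base_vars = tuple(base_vars)
        self.marker_names = tuple(marker_names if marker_names is not None else cohort.marker_names)
        self.censor_floor = float(censor_floor)
        X, wmis, impaired = design_matrix(cohort, self.base_vars, self.marker_names)
        self.col_names = list(X.columns)
        self.X = X.to_numpy(dtype=float)
        self.n_base = 1 + len(self.base_vars)
        self.wmis = wmis
        self.impaired = impaired.astype(float)
        self.y = wmis if family == "tobit" else self.impaired
        self.subsets = enumerate_subsets(self.marker_names)
        self._marker_col = {m: self.n_base + j for j, m in enumerate(self.marker_names)}

    def _fit(self, cols: list[int], idx: np.ndarray | None):
        X = self.X[:, cols] if idx is None else self.X[np.ix_(idx, cols)]
        y = self.y if idx is None else self.y[idx]
        names = [self.col_names[j] for j in cols]
        if self.family == "logistic":
            return Logistic(pd.DataFrame(X, columns=names), y).fit()
        return Tobit(pd.DataFrame(X, columns=names), y, censor_floor=self.censor_floor).fit()

    def table(self, idx: np.ndarray | None = None) -> SelectionTable:
        """Added-value table on the full sample or on a row-index resample."""
        base_cols = list(range(self.n_base))
        rows: list[SubsetResult] = []
        base_fit = self._fit(base_cols, idx)  # base failure propagates
        rows.append(
            SubsetResult((), base_fit.wald_global().p_value, base_fit.aic, None, base_fit)
        )
        for sub in self.subsets:
            cols = base_cols + [self._marker_col[m] for m in sub]
            try:
                f = self._fit(cols, idx)
                rows.append(
                    SubsetResult(sub, f.wald_global().p_value, f.aic, lrt(base_fit, f).p_value, f)
                )
            except FitError as exc:
                rows.append(SubsetResult(sub, failed=True, reason=str(exc)))
        return SelectionTable(self.family, self.base_vars, rows,
                              {"wald_scope": "all non-intercept terms"})


def added_value_table(
    cohort: Cohort,
    base_vars: Sequence[str] = MODEL1_BASE_VARS,
    marker_names: Sequence[str] | None = None,
    family: str = "logistic",
    censor_floor: float = 1.0,
) -> SelectionTable:
    """Fit the base model plus every marker combination and tabulate the scores."""
    return SelectionEngine(cohort, base_vars, marker_names, family, censor_floor).table()
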