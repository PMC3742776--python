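"""Internal validation: bootstrap optimism correction and borderline LOOCV.

The bootstrap wraps the *entire* subset-selection process: each replicate
resamples patients with replacement, reruns the exhaustive AIC search, fits
the selected model on the resample, and evaluates the reclassification
measure both on the resample (training value) and — with the resample-fitted
coefficients — on the original sample (test value).  The mean train-minus-test
difference over B replicates is the optimism, subtracted from the apparent
full-sample value.  Selection frequencies over replicates quantify the
stability of the chosen panel.

Borderline patients (WMIS strictly between 1.0 and 1.4, i.e. near the 1.2
decision threshold) are evaluated by leave-one-out cross-validation: each is
omitted in turn from the logistic fit, predicted, and classified at
probability 0.5; sensitivity/specificity/PPV/NPV are computed over the
borderline patients only, for the clinical base model and for base+panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import norm

from .cohort import Cohort, MODEL1_BASE_VARS, design_matrix
from .errors import FitError, InputError, MirapanelError
from .reclassification import idi_value, nri_value
from .regression import Logistic
from .selection import SelectionEngine, select_best

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    """Apparent / optimism / corrected measure plus per-subset selection rates."""

    measure: str
    apparent: float
    optimism: float
    corrected: float
    B: int
    seed: int
    selection_freq: dict[str, float]
    failures: int
    apparent_subset: str = "None"
    train_values: list[float] = field(default_factory=list)
    test_values: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "apparent": self.apparent,
            "optimism": self.optimism,
            "corrected": self.corrected,
            "B": self.B,
            "seed": self.seed,
            "apparent_subset": self.apparent_subset,
            "failures": self.failures,
            "selection_freq": self.selection_freq,
        }


def _resolve_measures(measure) -> dict[str, Callable]:
    if callable(measure):
        return {"custom": measure}
    names = [measure] if isinstance(measure, str) else list(measure)
    fns = {}
    for m in names:
        if m == "nri":
            fns[m] = nri_value
        elif m == "idi":
            fns[m] = idi_value
        else:
            raise InputError(f"unknown measure {m!r} (expected 'nri', 'idi' or a callable)")
    return fns


class _RiskModel:
    """Coefficient vectors of a fitted base / selected model, applied anywhere."""

    def __init__(self, engine: SelectionEngine, table, subset, threshold: float):
        self.family = engine.family
        self.threshold = threshold
        base = table.base_row.fit
        self.base_cols = list(range(engine.n_base))
        self.base_beta = base._beta
        self.base_scale = base.scale
        if subset:
            sel = table.row(subset).fit
            self.sel_cols = self.base_cols + [engine._marker_col[m] for m in subset]
            self.sel_beta = sel._beta
            self.sel_scale = sel.scale
        else:
            self.sel_cols, self.sel_beta, self.sel_scale = (
                self.base_cols, self.base_beta, self.base_scale,
            )

    def _risk(self, X, cols, beta, scale):
        eta = X[:, cols] @ beta
        if self.family == "logistic":
            return special.expit(eta)
        return norm.sf((self.threshold - eta) / scale)

    def risks(self, X) -> tuple[np.ndarray, np.ndarray]:
        return (
            self._risk(X, self.base_cols, self.base_beta, self.base_scale),
            self._risk(X, self.sel_cols, self.sel_beta, self.sel_scale),
        )


def bootstrap_validate(
    cohort: Cohort,
    base_vars: Sequence[str] = MODEL1_BASE_VARS,
    marker_names: Sequence[str] | None = None,
    family: str = "logistic",
    measure="nri",
    B: int = 150,
    seed: int = 0,
    threshold: float = 1.2,
    censor_floor: float = 1.0,
    stratified: bool = False,
    _resample_hook: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> ValidationResult | dict[str, ValidationResult]:
    """Optimism-corrected reclassification measure with nested re-selection.

    ``measure`` may be ``"nri"``, ``"idi"``, a sequence of both (one bootstrap
    pass, a dict of results), or a callable ``f(p_old, p_new, y) -> float``.
    ``_resample_hook`` is a testing hook replacing the resampling draw.
    Deterministic given ``seed``.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    single = isinstance(measure, str) or callable(measure)
    fns = _resolve_measures(measure)
    engine = SelectionEngine(cohort, base_vars, marker_names, family, censor_floor)
    n = engine.X.shape[0]
    ybin = engine.impaired

    # apparent value: full-sample selection + full-sample fits
    full_table = engine.table()
    best = select_best(full_table)
    best_label = "+".join(best) if best else "None"
    full_model = _RiskModel(engine, full_table, best, threshold)
    p_old_full, p_new_full = full_model.risks(engine.X)
    apparent = {
        m: (fn(p_old_full, p_new_full, ybin) if best else 0.0) for m, fn in fns.items()
    }

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    ev_idx = np.nonzero(ybin == 1)[0]
    ne_idx = np.nonzero(ybin == 0)[0]

    def draw() -> np.ndarray:
        if _resample_hook is not None:
            return np.asarray(_resample_hook(rng, n))
        if stratified:
            return np.concatenate([
                rng.choice(ev_idx, size=len(ev_idx), replace=True),
                rng.choice(ne_idx, size=len(ne_idx), replace=True),
            ])
        return rng.integers(0, n, size=n)

    train: dict[str, list[float]] = {m: [] for m in fns}
    test: dict[str, list[float]] = {m: [] for m in fns}
    selections: list[str] = []
    failures = 0
    attempts = 0
    done = 0
    while done < B:
        if attempts >= 10 * B:
            raise MirapanelError(
                f"bootstrap exhausted {attempts} attempts for {B} replicates "
                f"({failures} failures)"
            )
        attempts += 1
        idx = draw()
        yb = ybin[idx]
        try:
            if yb.min() == yb.max():
                raise FitError("single-class resample")
            table = engine.table(idx)
            sub = select_best(table)
        except (FitError, MirapanelError) as exc:
            failures += 1
            logger.debug("replicate redrawn: %s", exc)
            continue
        selections.append("+".join(sub) if sub else "None")
        if sub:
            model = _RiskModel(engine, table, sub, threshold)
            po_b, pn_b = model.risks(engine.X[idx])
            po_o, pn_o = model.risks(engine.X)
            for m, fn in fns.items():
                train[m].append(fn(po_b, pn_b, yb))
                test[m].append(fn(po_o, pn_o, ybin))
        else:
            for m in fns:
                train[m].append(0.0)
                test[m].append(0.0)
        done += 1

    freq: dict[str, float] = {}
    for lab in selections:
        freq[lab] = freq.get(lab, 0.0) + 1.0 / B

    results = {}
    for m in fns:
        tr, te = np.asarray(train[m]), np.asarray(test[m])
        optimism = float(np.mean(tr - te))
        results[m] = ValidationResult(
            measure=m,
            apparent=float(apparent[m]),
            optimism=optimism,
            corrected=float(apparent[m]) - optimism,
            B=B,
            seed=int(seed),
            selection_freq=dict(freq),
            failures=failures,
            apparent_subset=best_label,
            train_values=tr.tolist(),
            test_values=te.tolist(),
        )
    if single:
        return next(iter(results.values()))
    return results


def selection_frequencies(result: ValidationResult) -> pd.DataFrame:
    """Percentage of replicates selecting each subset, descending; sums to 100."""
    items = sorted(result.selection_freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"subset": k, "percentage": 100.0 * v} for k, v in items]
    )


# ---------------------------------------------------------------------------
# borderline patients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BorderlineMetrics:
    """Confusion-matrix summary over the borderline patients for one model."""

    model_tag: str
    n_borderline: int
    confusion: tuple[int, int, int, int]  # (tp, fp, fn, tn)

    @property
    def sensitivity(self) -> float:
        tp, fp, fn, tn = self.confusion
        return tp / (tp + fn) if (tp + fn) else float("nan")

    @property
    def specificity(self) -> float:
        tp, fp, fn, tn = self.confusion
        return tn / (tn + fp) if (tn + fp) else float("nan")

    @property
    def ppv(self) -> float:
        tp, fp, fn, tn = self.confusion
        return tp / (tp + fp) if (tp + fp) else float("nan")

    @property
    def npv(self) -> float:
        tp, fp, fn, tn = self.confusion
        return tn / (tn + fn) if (tn + fn) else float("nan")

    def to_dict(self) -> dict:
        tp, fp, fn, tn = self.confusion
        return {
            "model": self.model_tag, "n_borderline": self.n_borderline,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
        }


@dataclass
class BorderlineEvaluation:
    """LOOCV metrics for the base model and base+panel, with per-patient log."""

    base: BorderlineMetrics
    panel: BorderlineMetrics
    records: list[dict]
    skipped: int

    def __iter__(self):
        return iter((self.base, self.panel))


def borderline_eval(
    cohort: Cohort,
    base_vars: Sequence[str] = MODEL1_BASE_VARS,
    subset: Sequence[str] = (),
    low: float = 1.0,
    high: float = 1.4,
    threshold: float = 1.2,
) -> BorderlineEvaluation:
    """Leave-one-out classification of patients with ``low < WMIS < high``.

    Each borderline patient is omitted in turn (all other patients, borderline
    or not, stay in the training set), both logistic models are refitted, and
    the held-out patient is classified at probability >= 0.5 against the truth
    ``wmis_followup > threshold``.
    """
    Xb_df, wmis, _ = design_matrix(cohort, base_vars, ())
    Xf_df, _, _ = design_matrix(cohort, base_vars, subset)
    Xb, Xf = Xb_df.to_numpy(dtype=float), Xf_df.to_numpy(dtype=float)
    y = (wmis > threshold).astype(float)
    border = np.nonzero((wmis > low) & (wmis < high))[0]
    if len(border) < 2:
        raise InputError(f"need at least 2 borderline patients, found {len(border)}")

    conf = {"base": [0, 0, 0, 0], "panel": [0, 0, 0, 0]}  # tp, fp, fn, tn
    records: list[dict] = []
    skipped = 0
    for i in border:
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        try:
            fb = Logistic(Xb[mask], y[mask]).fit()
            ff = Logistic(Xf[mask], y[mask]).fit()
        except FitError as exc:
            warnings.warn(f"borderline fold for patient index {i} skipped: {exc}",
                          stacklevel=2)
            skipped += 1
            continue
        pb = float(special.expit(Xb[i] @ fb._beta))
        pf = float(special.expit(Xf[i] @ ff._beta))
        truth = int(y[i])
        for tag, prob in (("base", pb), ("panel", pf)):
            pred = int(prob >= 0.5)
            c = conf[tag]
            if pred and truth:
                c[0] += 1
            elif pred and not truth:
                c[1] += 1
            elif not pred and truth:
                c[2] += 1
            else:
                c[3] += 1
        records.append({"index": int(i), "truth": truth, "p_base": pb, "p_panel": pf})

    n_eval = len(records)
    return BorderlineEvaluation(
        base=BorderlineMetrics("base", n_eval, tuple(conf["base"])),
        panel=BorderlineMetrics("base+panel", n_eval, tuple(conf["panel"])),
        records=records,
        skipped=skipped,
    )
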