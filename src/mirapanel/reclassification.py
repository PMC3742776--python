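"""Continuous (category-free) NRI and IDI between two risk models.

For each patient the new model either raises ("up") or lowers ("down") the
predicted risk relative to the old model.  The continuous net reclassification
improvement is

    NRI = P(up|event) - P(down|event) + P(down|nonevent) - P(up|nonevent)

(range [-2, 2]); exact ties count in neither direction while keeping the full
group denominators.  The integrated discrimination improvement is the change
in discrimination slope (mean risk in events minus mean risk in nonevents)
between the models.  Both come with large-sample standard errors, z tests of
nullity and 95% Wald intervals; these are apparent (in-sample) quantities —
honest versions come from the bootstrap validation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cohort import Cohort, MODEL1_BASE_VARS, design_matrix
from .errors import DegenerateOutcomeError, InputError
from .regression import Logistic, Tobit, Z_95


@dataclass(frozen=True)
class ReclassResult:
    """NRI and IDI point estimates with SEs, z statistics, p-values, CIs."""

    nri: float
    nri_se: float
    nri_z: float
    nri_p: float
    nri_ci: tuple[float, float]
    idi: float
    idi_se: float
    idi_z: float
    idi_p: float
    idi_ci: tuple[float, float]
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "nri": self.nri, "nri_se": self.nri_se, "nri_z": self.nri_z, "nri_p": self.nri_p,
            "nri_ci_low": self.nri_ci[0], "nri_ci_high": self.nri_ci[1],
            "idi": self.idi, "idi_se": self.idi_se, "idi_z": self.idi_z, "idi_p": self.idi_p,
            "idi_ci_low": self.idi_ci[0], "idi_ci_high": self.idi_ci[1],
            **self.counts,
        }


def _validate(p_old, p_new, y):
    p_old = np.asarray(p_old, dtype=float).ravel()
    p_new = np.asarray(p_new, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (len(p_old) == len(p_new) == len(y)):
        raise InputError("p_old, p_new and y must have equal length")
    if y.min() == y.max():
        raise DegenerateOutcomeError("both outcome classes are required")
    return p_old, p_new, y == 1


def nri_value(p_old, p_new, y, tie_eps: float = 0.0) -> float:
    """Point estimate of the continuous NRI (fast path for the bootstrap)."""
    p_old, p_new, ev = _validate(p_old, p_new, y)
    d = p_new - p_old
    up, down = d > tie_eps, d < -tie_eps
    ne, nn = int(ev.sum()), int((~ev).sum())
    return float(
        (up[ev].sum() - down[ev].sum()) / ne + (down[~ev].sum() - up[~ev].sum()) / nn
    )


def idi_value(p_old, p_new, y) -> float:
    """Point estimate of the IDI (difference in discrimination slopes)."""
    p_old, p_new, ev = _validate(p_old, p_new, y)
    d = p_new - p_old
    return float(d[ev].mean() - d[~ev].mean())


def _nri_stats(p_old, p_new, y, tie_eps):
    p_old, p_new, ev = _validate(p_old, p_new, y)
    d = p_new - p_old
    up, down = d > tie_eps, d < -tie_eps
    ne, nn = int(ev.sum()), int((~ev).sum())
    up_e, down_e = int(up[ev].sum()), int(down[ev].sum())
    up_ne, down_ne = int(up[~ev].sum()), int(down[~ev].sum())
    nri = (up_e - down_e) / ne + (down_ne - up_ne) / nn
    # multinomial large-sample variance per group
    pe_u, pe_d = up_e / ne, down_e / ne
    pn_u, pn_d = up_ne / nn, down_ne / nn
    var = (pe_u + pe_d - (pe_u - pe_d) ** 2) / ne + (pn_u + pn_d - (pn_d - pn_u) ** 2) / nn
    se = float(np.sqrt(var))
    counts = {
        "n_event": ne, "n_nonevent": nn,
        "up_e": up_e, "down_e": down_e, "tie_e": ne - up_e - down_e,
        "up_ne": up_ne, "down_ne": down_ne, "tie_ne": nn - up_ne - down_ne,
    }
    return float(nri), se, counts


def _idi_stats(p_old, p_new, y):
    p_old, p_new, ev = _validate(p_old, p_new, y)
    d = p_new - p_old
    de, dn = d[ev], d[~ev]
    idi = float(de.mean() - dn.mean())
    se = float(np.sqrt(de.var(ddof=1) / len(de) + dn.var(ddof=1) / len(dn)))
    return idi, se


def _ztest(est: float, se: float):
    if se > 0:
        z = est / se
        p = float(2 * norm.sf(abs(z)))
    else:
        z, p = (np.inf if est > 0 else (-np.inf if est < 0 else 0.0)), (0.0 if est else 1.0)
    return float(z), p, (est - Z_95 * se, est + Z_95 * se)


def _assemble(p_old, p_new, y, tie_eps) -> ReclassResult:
    nri, nri_se, counts = _nri_stats(p_old, p_new, y, tie_eps)
    idi, idi_se = _idi_stats(p_old, p_new, y)
    nz, np_, nci = _ztest(nri, nri_se)
    iz, ip_, ici = _ztest(idi, idi_se)
    return ReclassResult(nri, nri_se, nz, np_, nci, idi, idi_se, iz, ip_, ici, counts)


def nri_continuous(p_old, p_new, y, tie_eps: float = 0.0) -> ReclassResult:
    """Continuous NRI with SE, z, p and CI (IDI fields filled alongside)."""
    return _assemble(p_old, p_new, y, tie_eps)


def idi(p_old, p_new, y) -> ReclassResult:
    """IDI with SE, z, p and CI (NRI fields filled alongside)."""
    return _assemble(p_old, p_new, y, 0.0)


def compare_models(
    cohort: Cohort,
    base_vars: Sequence[str] = MODEL1_BASE_VARS,
    subset: Sequence[str] = (),
    family: str = "logistic",
    tie_eps: float = 0.0,
    censor_floor: float = 1.0,
    threshold: float = 1.2,
) -> ReclassResult:
    """Reclassification of the base model by base+subset on in-sample risks.

    For the logistic family risks are fitted probabilities; for tobit they are
    the model-implied exceedance probabilities P(latent > threshold | x).
    """
    Xb, wmis, imp = design_matrix(cohort, base_vars, ())
    Xf, _, _ = design_matrix(cohort, base_vars, subset)
    if family == "logistic":
        p_old = Logistic(Xb, imp).fit().predictions
        p_new = Logistic(Xf, imp).fit().predictions
    elif family == "tobit":
        fb = Tobit(Xb, wmis, censor_floor=censor_floor).fit()
        ff = Tobit(Xf, wmis, censor_floor=censor_floor).fit()
        p_old = fb.exceedance_prob(Xb, threshold)
        p_new = ff.exceedance_prob(Xf, threshold)
    else:
        raise InputError(f"unknown family {family!r}")
    return _assemble(p_old, p_new, imp, tie_eps)


def reclassification_table(
    cohort: Cohort,
    base_vars: Sequence[str] = MODEL1_BASE_VARS,
    marker_names: Sequence[str] | None = None,
    family: str = "logistic",
    tie_eps: float = 0.0,
):
    """NRI/IDI of every non-empty marker combination added to the base model."""
    import pandas as pd

    from .selection import enumerate_subsets

    markers = list(marker_names if marker_names is not None else cohort.marker_names)
    rows = []
    for sub in enumerate_subsets(markers):
        r = compare_models(cohort, base_vars, sub, family=family, tie_eps=tie_eps)
        rows.append({
            "subset": "+".join(sub),
            "nri": r.nri, "nri_ci_low": r.nri_ci[0], "nri_ci_high": r.nri_ci[1],
            "nri_p": r.nri_p,
            "idi": r.idi, "idi_ci_low": r.idi_ci[0], "idi_ci_high": r.idi_ci[1],
            "idi_p": r.idi_p,
        })
    return pd.DataFrame(rows)
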