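"""Association tests relating compliance deviation to device and demographics.

Correlations are two-sided with p-values from the exact t reference
distribution on n-2 degrees of freedom.  The stage-level mixed model uses a
patient-level random intercept fitted by REML (statsmodels ``MixedLM``);
categorical terms use treatment coding with the reference level stated in the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from patsy import dmatrix

from .timeline import PatientMeta, STAGE_NAMES
from .criteria import CRITERION_IDS


class ZeroVarianceError(ValueError):
    """A correlation input has no variance, so the coefficient is undefined."""


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("correlation undefined: an input has zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    return r, _t_pvalue(r, n)


def point_biserial(binary: Sequence[int], x: Sequence[float]) -> tuple[float, float]:
    """Correlation between a 0/1 variable and a continuous one.

    Computed from the closed-form group-mean expression
    ``r = (m1 - m0) / s_n * sqrt(n1 * n0 / n^2)`` (population SD ``s_n``),
    which is algebraically identical to the Pearson correlation of the 0/1
    coding with ``x``.
    """
    b = np.asarray(binary, dtype=float)
    x = np.asarray(x, dtype=float)
    if b.shape != x.shape or b.ndim != 1:
        raise ValueError("binary and x must be 1-D vectors of equal length")
    if not set(np.unique(b)) <= {0.0, 1.0}:
        raise ValueError("binary vector must contain only 0 and 1")
    n = len(b)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    n1 = int(b.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ZeroVarianceError("both groups must be nonempty")
    s_n = float(np.std(x))  # population (ddof=0) SD pairs with the n^2 factor
    if s_n == 0:
        raise ZeroVarianceError("x has zero variance")
    m1 = float(x[b == 1].mean())
    m0 = float(x[b == 0].mean())
    r = (m1 - m0) / s_n * np.sqrt(n1 * n0 / n**2)
    r = max(-1.0, min(1.0, r))
    return float(r), _t_pvalue(r, n)


def build_stage_table(
    stage_table: pd.DataFrame, metas: Mapping[str, PatientMeta]
) -> pd.DataFrame:
    """Join stage compliance values with patient covariates for modelling.

    One row per (patient, criterion, stage) in deterministic order; raises if
    any patient is missing a stage value.
    """
    expected = len(CRITERION_IDS) * len(STAGE_NAMES)
    rows = []
    for pid in sorted(metas):
        meta = metas[pid]
        sub = stage_table[stage_table["patient_id"] == pid]
        if len(sub) != expected:
            raise ValueError(
                f"patient {pid!r} has {len(sub)} stage values, expected {expected}"
            )
        lookup = {(r.criterion, r.stage): r.value for r in sub.itertuples(index=False)}
        for criterion in CRITERION_IDS:
            for stage in STAGE_NAMES:
                rows.append(
                    (
                        pid,
                        criterion,
                        stage,
                        lookup[(criterion, stage)],
                        meta.device,
                        meta.age,
                        meta.gender,
                        meta.bmi,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "criterion", "stage", "compliance",
            "device", "age", "gender", "bmi",
        ],
    )


@dataclass
class FitReport:
    """Fixed-effect estimates and omnibus term tests from a mixed model."""

    effects: pd.DataFrame  # term, estimate, se, statistic, p
    omnibus: pd.DataFrame  # term, statistic, df, p
    group_var: float
    method: str
    formula: str
    converged: bool
    coding: str = "treatment (first level alphabetically is the reference)"

    def effect(self, term_substring: str) -> pd.Series:
        """First fixed-effect row whose term contains ``term_substring``."""
        hit = self.effects[self.effects["term"].str.contains(term_substring, regex=False)]
        if hit.empty:
            raise KeyError(f"no fixed-effect term matching {term_substring!r}")
        return hit.iloc[0]


def _check_rank(formula_rhs: str, table: pd.DataFrame) -> None:
    X = np.asarray(dmatrix(formula_rhs, table, return_type="dataframe"))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = dmatrix(formula_rhs, table, return_type="dataframe").columns
        # identify columns whose removal does not lower the rank (aliased)
        aliased = []
        for j in range(X.shape[1]):
            keep = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(keep) == rank:
                aliased.append(str(names[j]))
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def stage_effect_model(
    table: pd.DataFrame,
    response: str = "compliance",
    fixed: Sequence[str] = ("C(criterion)", "C(stage)", "age", "bmi", "C(gender)", "C(device)"),
    reml: bool = True,
) -> FitReport:
    """Fit a linear model with fixed terms and a patient random intercept.

    Returns per-coefficient estimates with standard errors and Wald z
    p-values, plus an omnibus Wald chi-square test per model term.
    Interactions may be included in ``fixed`` using patsy syntax
    (e.g. ``"C(device):C(stage)"``).
    """
    if response not in table.columns:
        raise KeyError(f"response column {response!r} not in table")
    rhs = " + ".join(fixed)
    if float(np.var(table[response])) == 0.0:
        # degenerate response: all effects zero, no subject variance
        names = dmatrix(rhs, table, return_type="dataframe").columns
        effects = pd.DataFrame(
            {
                "term": [str(n) for n in names],
                "estimate": [float(table[response].iloc[0]) if n == "Intercept" else 0.0
                             for n in names],
                "se": 0.0,
                "statistic": np.nan,
                "p": np.nan,
            }
        )
        omnibus = pd.DataFrame(columns=["term", "statistic", "df", "p"])
        return FitReport(
            effects=effects, omnibus=omnibus, group_var=0.0,
            method="degenerate", formula=f"{response} ~ {rhs}", converged=True,
        )
    _check_rank(rhs, table)
    formula = f"{response} ~ {rhs}"
    model = smf.mixedlm(formula, table, groups=table["patient_id"])
    fit = model.fit(reml=reml)

    fe = fit.fe_params
    effects = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.values,
            "se": fit.bse_fe.values,
            "statistic": fit.tvalues[fe.index].values,
            "p": fit.pvalues[fe.index].values,
        }
    ).reset_index(drop=True)

    omni_rows = []
    for term in fixed:
        cols = [c for c in fe.index if c != "Intercept" and _belongs(c, term)]
        if not cols:
            continue
        contrast = np.zeros((len(cols), len(fit.params)))
        for i, c in enumerate(cols):
            contrast[i, list(fit.params.index).index(c)] = 1.0
        wald = fit.wald_test(contrast, scalar=True)
        omni_rows.append(
            (term, float(wald.statistic), int(len(cols)), float(wald.pvalue))
        )
    omnibus = pd.DataFrame(omni_rows, columns=["term", "statistic", "df", "p"])

    return FitReport(
        effects=effects,
        omnibus=omnibus,
        group_var=float(fit.cov_re.iloc[0, 0]),
        method="REML" if reml else "ML",
        formula=formula,
        converged=bool(fit.converged),
    )


def _belongs(coef_name: str, term: str) -> bool:
    """Match a patsy coefficient name to the model term that generated it."""
    if ":" in term:
        parts = term.split(":")
        return ":" in coef_name and all(p.strip() in coef_name for p in parts)
    if ":" in coef_name:
        return False
    return coef_name.startswith(term.strip().replace(" ", ""))
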