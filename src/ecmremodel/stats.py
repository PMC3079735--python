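"""Statistical comparison of remodeling scores across inhibitor conditions.

Replicate scores (one per field) are grouped by (condition, layer).
Because group variances scale with group means, scores are converted to
natural-log scale before testing.  Each inhibitor condition is compared
against the untreated control per layer with a one-way ANOVA; the family of
(condition x layer) raw p-values is adjusted with the Benjamini–Hochberg
step-up procedure at a false-discovery rate of 0.05, and comparisons with
raw p <= 0.01 are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateVarianceError,
    MissingControlError,
    ParameterError,
    TransformError,
)

ALPHA_SIGNIFICANT = 0.01
ALPHA_FDR = 0.05


@dataclass(frozen=True)
class ConditionGroup:
    """Replicate scores of one (condition, layer) cell of the design."""

    condition: str
    layer: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ParameterError(
                f"group ({self.condition}, {self.layer}) needs n >= 2"
            )


@dataclass
class TestResult:
    """One condition-vs-control comparison within a layer."""

    condition: str
    layer: str
    f_statistic: float
    p_value: float
    p_adjusted: float
    significant: bool  # raw p <= 0.01
    fdr_pass: bool  # BH-adjusted p <= 0.05
    n_condition: int
    n_control: int
    mean: float
    se: float


def log_transform(groups: list[ConditionGroup]) -> list[ConditionGroup]:
    """Natural-log transform every group's values (variance stabilization)."""
    out = []
    for g in groups:
        vals = np.asarray(g.values, dtype=float)
        if np.any(vals <= 0):
            raise TransformError(
                f"group ({g.condition}, {g.layer}) has non-positive values; "
                "log transform undefined"
            )
        out.append(replace(g, values=tuple(np.log(vals))))
    return out


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups of observations.

    Returns ``(F, p)`` with ``F = (SSB/(k-1)) / (SSW/(N-k))`` and the
    p-value from the F(k-1, N-k) distribution.  Zero within-group variance
    is an error (the statistic is undefined), never a silent p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ParameterError("every group needs n >= 2")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw <= 0:
        raise DegenerateVarianceError("zero within-group variance")
    f, p = sps.f_oneway(*arrays)
    if not np.isfinite(f):  # identical group means with scipy edge handling
        f, p = 0.0, 1.0
    return float(f), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``adjusted_(i) = min_{j >= i} (m * p_(j) / j)`` over the ascending
    order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def compare_conditions(
    groups: list[ConditionGroup],
    control: str = "untreated",
    alpha_sig: float = ALPHA_SIGNIFICANT,
    alpha_fdr: float = ALPHA_FDR,
    log: bool = True,
) -> list[TestResult]:
    """Test every inhibitor condition against the untreated control per layer.

    The BH family is all (condition x layer) comparisons passed in one call.
    Reported means/SEs are on the original (percent) scale; the tests run on
    log scale when ``log=True``.
    """
    layers = sorted({g.layer for g in groups}, key=_layer_order)
    by_key = {(g.condition, g.layer): g for g in groups}
    tested = log_transform(groups) if log else groups
    tested_by_key = {(g.condition, g.layer): g for g in tested}

    comparisons = []
    for layer in layers:
        if (control, layer) not in by_key:
            raise MissingControlError(
                f"no {control!r} control group for layer {layer!r}"
            )
        for g in groups:
            if g.layer == layer and g.condition != control:
                comparisons.append((g.condition, layer))
    if not comparisons:
        raise ParameterError("no non-control condition to compare")

    raw_p, fs = [], []
    for cond, layer in comparisons:
        f, p = one_way_anova(
            [tested_by_key[(cond, layer)].values,
             tested_by_key[(control, layer)].values]
        )
        fs.append(f)
        raw_p.append(p)
    adj = benjamini_hochberg(raw_p)

    results = []
    for (cond, layer), f, p, pa in zip(comparisons, fs, raw_p, adj):
        vals = np.asarray(by_key[(cond, layer)].values)
        results.append(
            TestResult(
                condition=cond,
                layer=layer,
                f_statistic=f,
                p_value=p,
                p_adjusted=float(pa),
                significant=p <= alpha_sig,
                fdr_pass=pa <= alpha_fdr,
                n_condition=len(vals),
                n_control=len(by_key[(control, layer)].values),
                mean=float(vals.mean()),
                se=float(vals.std(ddof=1) / np.sqrt(len(vals))),
            )
        )
    return results


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Tidy condition x layer table of the comparison results.

    One row per condition and layer with mean ± SE, F, raw and adjusted p,
    and the two flags — the layout of a per-layer inhibitor summary table.
    """
    return pd.DataFrame(
        {
            "condition": [r.condition for r in results],
            "layer": [r.layer for r in results],
            "n": [r.n_condition for r in results],
            "mean": [r.mean for r in results],
            "se": [r.se for r in results],
            "F": [r.f_statistic for r in results],
            "p": [r.p_value for r in results],
            "p_adj": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
            "fdr_pass": [r.fdr_pass for r in results],
        }
    )


def _layer_order(layer: str) -> int:
    return {"top": 0, "middle": 1, "bottom": 2}.get(layer, 99)
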