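"""ΔΔCt relative expression, significance testing, stress-response calls.

Relative expression of a target gene is computed by the efficiency-free
delta-delta-Ct method: technical replicates of the quantification cycle (Cq)
are averaged, ΔCt = Cq(target) - Cq(reference) per (condition, biological
replicate), ΔΔCt(b) = ΔCt(treated, b) - mean ΔCt(control), and
fold(b) = 2^(-ΔΔCt(b)), so control expression is 1 by construction.

Significance is a two-sided pooled-variance Student t-test on the ΔCt values
across biological replicates (ΔCt is the approximately normal scale; the
fold scale is log-normal). Welch's correction is available by flag. Stars:
"*" for P < 0.05, "**" for P < 0.01. No multiple-testing correction is
applied by default (per-gene stars); Benjamini-Hochberg is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CqTable, ValidationError

logger = logging.getLogger(__name__)


def stars_for(p_value: float) -> str:
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass
class DeltaDeltaCt:
    """Per-biological-replicate ΔΔCt outcome for one gene."""

    gene: str
    control_dcts: np.ndarray        # ΔCt per control bio rep
    treated_dcts: np.ndarray        # ΔCt per treated bio rep
    ddct: np.ndarray                # ΔΔCt per treated bio rep
    folds: np.ndarray               # 2^(-ΔΔCt) per treated bio rep

    @property
    def mean_fold(self) -> float:
        """Point estimate: 2^(-mean ΔΔCt) (geometric mean of replicate folds)."""
        return float(2.0 ** (-self.ddct.mean()))

    @property
    def log2_fold(self) -> float:
        return float(-self.ddct.mean())


def delta_delta_ct(cq: CqTable, gene: str,
                   control_condition: str = "control") -> DeltaDeltaCt:
    """ΔΔCt fold changes for one gene against the table's reference gene."""
    df = cq.data
    conditions = set(df["condition"].unique())
    if control_condition not in conditions:
        raise ValidationError(f"no condition {control_condition!r} in table")
    treated_conditions = conditions - {control_condition}
    if len(treated_conditions) != 1:
        raise ValidationError(
            f"expected exactly one treated condition, found {sorted(treated_conditions)}")
    treated_condition = treated_conditions.pop()
    if gene not in set(df["gene"]):
        raise ValidationError(f"gene {gene!r} not in table")

    # average technical replicates, then ΔCt per (condition, bio_rep)
    mean_cq = (df.groupby(["gene", "condition", "bio_rep"], sort=True)["cq"]
                 .mean().unstack("gene"))
    if mean_cq[gene].isna().any() or mean_cq[cq.reference_gene].isna().any():
        raise ValidationError(
            f"gene {gene!r} or reference missing from some (condition, bio_rep)")
    dct = mean_cq[gene] - mean_cq[cq.reference_gene]
    control_dcts = dct.loc[control_condition].sort_index().to_numpy()
    treated_dcts = dct.loc[treated_condition].sort_index().to_numpy()
    ddct = treated_dcts - control_dcts.mean()
    if min(len(control_dcts), len(treated_dcts)) < 2:
        logger.warning("gene %s: fewer than 2 biological replicates; "
                       "significance testing disabled", gene)
    return DeltaDeltaCt(gene, control_dcts, treated_dcts, ddct, 2.0 ** (-ddct))


def test_differential(control_dcts: Sequence[float], treated_dcts: Sequence[float],
                      equal_var: bool = True) -> tuple[float, str]:
    """Two-sided Student t-test on ΔCt values (pooled variance by default).

    Degenerate zero-variance groups: equal means give p = 1; unequal means
    give p = 0 with a logged warning (no dispersion to test against).
    """
    a = np.asarray(control_dcts, dtype=float)
    b = np.asarray(treated_dcts, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValidationError("t-test needs >= 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 1.0, ""
        logger.warning("degenerate t-test: zero variance with unequal means")
        return 0.0, "**"
    p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return p, stars_for(p)


@dataclass
class ExpressionResult:
    """Fold change, significance and stress call for one gene."""

    gene: str
    fold: float
    log2_fold: float
    p_value: float
    stars: str
    call: str            # up / down / none
    n_bio: int
    fold_sd: float = float("nan")   # sd of per-bio-replicate folds


def analyze_expression(cq: CqTable, genes: Optional[Sequence[str]] = None,
                       control_condition: str = "control",
                       equal_var: bool = True) -> list[ExpressionResult]:
    """ΔΔCt + t-test for each target gene (reference gene excluded)."""
    targets = [g for g in (genes or cq.genes) if g != cq.reference_gene]
    results = []
    for gene in targets:
        dd = delta_delta_ct(cq, gene, control_condition)
        if min(len(dd.control_dcts), len(dd.treated_dcts)) >= 2:
            p, st = test_differential(dd.control_dcts, dd.treated_dcts, equal_var)
        else:
            p, st = float("nan"), ""
        results.append(ExpressionResult(
            gene=gene, fold=dd.mean_fold, log2_fold=dd.log2_fold,
            p_value=p, stars=st, call="none", n_bio=len(dd.treated_dcts),
            fold_sd=float(dd.folds.std(ddof=1)) if len(dd.folds) > 1 else float("nan")))
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    return stats.false_discovery_control(np.asarray(p_values), method="bh")


def call_stress_response(results: Iterable[ExpressionResult],
                         up_fold: float = 2.0,
                         strong_down_fold: float = 3.0,
                         require_significance: bool = True,
                         alpha: float = 0.05,
                         class_of: Optional[Mapping[str, str]] = None,
                         ) -> tuple[list[ExpressionResult], pd.DataFrame]:
    """Call induced / strongly suppressed genes with inclusive thresholds.

    "up" requires fold >= up_fold ("at least two-fold" is inclusive);
    "down" (strong suppression) requires fold <= 1/strong_down_fold. When
    ``require_significance``, calls additionally need p < alpha. Returns the
    updated results and a per-class summary of call counts (classes taken
    from ``class_of`` when given, else a single "all" bucket).
    """
    results = list(results)
    for r in results:
        significant = (not require_significance) or (
            not math.isnan(r.p_value) and r.p_value < alpha)
        if r.fold >= up_fold and significant:
            r.call = "up"
        elif r.fold <= 1.0 / strong_down_fold and significant:
            r.call = "down"
        else:
            r.call = "none"
    rows = []
    for r in results:
        rows.append({"class": (class_of or {}).get(r.gene, "all"), "call": r.call})
    summary = (pd.DataFrame(rows).groupby(["class", "call"]).size()
               .unstack(fill_value=0).reindex(columns=["up", "down", "none"],
                                              fill_value=0).reset_index())
    return results, summary


def results_frame(results: Iterable[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "fold": r.fold, "log2_fold": r.log2_fold,
        "fold_sd": r.fold_sd, "p_value": r.p_value, "stars": r.stars,
        "call": r.call, "n_bio": r.n_bio} for r in results])
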