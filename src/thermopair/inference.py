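"""Comparative statistics for paired invasive/non-invasive trait data.

Three complementary analyses of a trait (LDT or SET) against invasive
status, mirroring the standard toolkit for matched comparative designs:

1. t-tests — a pooled two-sample t ignoring the pairing, and a
   paired-difference t on per-pair differences (df = n_pairs - 1);
2. a linear mixed model with a random intercept per pair (the model-based
   analogue of the paired t), whose variance components give the intraclass
   correlation ICC = s2_pair / (s2_pair + s2_res) between pair members;
3. mixed models on the nested taxonomic hierarchy (none / order /
   family-within-order) with likelihood-ratio tests between successive
   random-effect structures.

Fixed-effect t-tests in the mixed models use Satterthwaite denominator
degrees of freedom.  A Pearson correlation of the per-pair LDT and SET
differences quantifies whether pairs trade a higher threshold for a lower
thermal sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import RandomInterceptModel, REMLFit
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    statistic_t: float
    df: float
    p_value: float
    mean_difference: float
    variant: str  # "pooled_two_sample" | "paired_differences"


@dataclass
class MixedModelFit:
    """Fixed status effect with Satterthwaite df, variance components and ICC."""

    fixed_effect_status: float
    se_fixed: float
    statistic_t: float
    satterthwaite_df: float
    p_value: float
    var_between: float
    var_residual: float
    icc: float
    log_likelihood: float
    grouping: str  # "pair" | "order" | "family_in_order" | "none"
    var_components: dict = field(default_factory=dict)
    _model: RandomInterceptModel | None = field(default=None, repr=False)
    _fit: REMLFit | None = field(default=None, repr=False)


@dataclass(frozen=True)
class LRTestResult:
    statistic_L: float
    df: int
    p_value: float
    model_null: str
    model_alt: str


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    concordance_fraction: float


@dataclass(frozen=True)
class NormalityReport:
    skewness: float
    kurtosis: float  # excess (normal = 0)
    shapiro_w: float
    shapiro_p: float


# --------------------------------------------------------------------- #
# t-tests


def status_t_test(
    values: np.ndarray,
    status: np.ndarray,
    pairing: np.ndarray | None = None,
    variant: str = "pooled_two_sample",
) -> TTestResult:
    """Compare a trait between invasive (status 1) and non-invasive (status 0).

    ``pooled_two_sample`` is the classical equal-variance two-sample t that
    ignores the pairing; ``paired_differences`` forms per-pair differences
    (invasive minus non-invasive, via ``pairing`` labels) and tests their
    mean against zero with df = n_pairs - 1.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status)
    inv, noninv = values[status == 1], values[status == 0]

    if variant == "pooled_two_sample":
        if inv.size < 2 or noninv.size < 2:
            raise ValidationError("need at least two values per status group")
        mean_diff = float(inv.mean() - noninv.mean())
        if np.ptp(inv) == 0 and np.ptp(noninv) == 0:
            if mean_diff == 0:
                return TTestResult(0.0, inv.size + noninv.size - 2, 1.0, 0.0, variant)
            raise ValidationError("zero variance with nonzero group difference")
        t, p = stats.ttest_ind(inv, noninv, equal_var=True)
        return TTestResult(
            float(t), float(inv.size + noninv.size - 2), float(p), mean_diff, variant
        )

    if variant == "paired_differences":
        if pairing is None:
            raise ValidationError("paired_differences requires pairing labels")
        frame = pd.DataFrame({"v": values, "s": status, "p": np.asarray(pairing)})
        wide = frame.pivot_table(index="p", columns="s", values="v")
        if wide.isna().any().any() or wide.shape[1] != 2:
            raise ValidationError("each pair needs exactly one value per status")
        diffs = (wide[1] - wide[0]).to_numpy()
        if diffs.size < 2:
            raise ValidationError("need at least two pairs")
        mean_diff = float(diffs.mean())
        if np.ptp(diffs) == 0:
            if mean_diff == 0:
                return TTestResult(0.0, diffs.size - 1, 1.0, 0.0, variant)
            raise ValidationError("zero variance with nonzero mean difference")
        t, p = stats.ttest_1samp(diffs, 0.0)
        return TTestResult(float(t), float(diffs.size - 1), float(p), mean_diff, variant)

    raise ValidationError(f"unknown variant {variant!r}")


# --------------------------------------------------------------------- #
# mixed models


def _mixed_fit(
    values: np.ndarray,
    status: np.ndarray,
    factors: list[np.ndarray],
    factor_names: list[str],
    grouping: str,
) -> MixedModelFit:
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(status, dtype=float)])
    model = RandomInterceptModel(y, X, factors, factor_names)
    fit = model.fit()
    beta = float(fit.beta[1])
    se = float(np.sqrt(fit.cov_beta[1, 1]))
    df = model.satterthwaite_df(fit, 1)
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df))
    var_between = float(fit.variances.sum()) if fit.variances.size else 0.0
    var_res = float(fit.sigma2)
    icc = var_between / (var_between + var_res) if var_between + var_res > 0 else 0.0
    if fit.variances.size and var_between == 0.0:
        logger.info("boundary fit for grouping=%s: between-group variance is 0", grouping)
    return MixedModelFit(
        fixed_effect_status=beta,
        se_fixed=se,
        statistic_t=t,
        satterthwaite_df=float(df),
        p_value=p,
        var_between=var_between,
        var_residual=var_res,
        icc=float(icc),
        log_likelihood=float(fit.loglik),
        grouping=grouping,
        var_components=dict(zip(factor_names, map(float, fit.variances))),
        _model=model,
        _fit=fit,
    )


def paired_lmm(
    long_table: pd.DataFrame,
    value_col: str = "value",
    status_col: str = "status",
    pair_col: str = "pair_id",
) -> MixedModelFit:
    """Mixed model trait ~ status with a random intercept per pair (REML).

    The model-based analogue of a paired t-test; its variance decomposition
    separates between-pair from within-pair variation and yields the
    intraclass correlation of trait values within pairs.
    """
    counts = long_table.groupby(pair_col).size()
    if (counts != 2).any():
        raise ValidationError("long table must hold exactly two rows per pair")
    if counts.size < 3:
        raise ValidationError("need at least three pairs")
    return _mixed_fit(
        long_table[value_col].to_numpy(),
        long_table[status_col].to_numpy(),
        [long_table[pair_col].to_numpy()],
        ["pair"],
        grouping="pair",
    )


def nested_taxonomy_lmm(
    species_table: pd.DataFrame,
    hierarchy: str = "family_in_order",
    value_col: str = "value",
    status_col: str = "status",
) -> MixedModelFit:
    """Mixed model trait ~ status with taxonomic random intercepts (REML).

    ``hierarchy``: "none" (plain linear model; equivalent to the pooled
    two-sample t), "order" (random intercept per order) or
    "family_in_order" (random intercepts per order and per family nested
    within order).  A hierarchy level with a single group falls back to the
    next simpler structure with a warning.
    """
    if hierarchy not in ("none", "order", "family_in_order"):
        raise ValidationError(f"unknown hierarchy {hierarchy!r}")
    df = species_table
    if hierarchy != "none" and df["order"].nunique() < 2:
        logger.warning("single order in data; falling back to hierarchy='none'")
        hierarchy = "none"
    if hierarchy == "family_in_order" and df["family"].nunique() < 2:
        logger.warning("single family in data; falling back to hierarchy='order'")
        hierarchy = "order"

    factors: list[np.ndarray] = []
    names: list[str] = []
    if hierarchy in ("order", "family_in_order"):
        factors.append(df["order"].to_numpy())
        names.append("order")
    if hierarchy == "family_in_order":
        fam = (df["order"].astype(str) + "//" + df["family"].astype(str)).to_numpy()
        factors.append(fam)
        names.append("family_in_order")
    return _mixed_fit(
        df[value_col].to_numpy(), df[status_col].to_numpy(), factors, names, hierarchy
    )


def lr_test_sequence(
    species_table: pd.DataFrame,
    value_col: str = "value",
    status_col: str = "status",
) -> list[LRTestResult]:
    """Likelihood-ratio tests across the nested random-effect structures.

    Fits (i) no random effect, (ii) random order intercepts, (iii) random
    order and family-within-order intercepts on identical data with
    identical fixed effects (REML), and returns L = 2 (l_alt - l_null) for
    (ii) vs (i) and (iii) vs (ii), each on 1 df.  Negative statistics
    (numerically possible at boundary optima) are clipped to zero and
    logged.
    """
    fits = {
        h: nested_taxonomy_lmm(species_table, h, value_col, status_col)
        for h in ("none", "order", "family_in_order")
    }
    out = []
    for null, alt in (("none", "order"), ("order", "family_in_order")):
        L = 2.0 * (fits[alt].log_likelihood - fits[null].log_likelihood)
        if L < 0:
            logger.info("negative LR statistic %.3g for %s vs %s clipped to 0", L, alt, null)
            L = 0.0
        out.append(
            LRTestResult(
                statistic_L=float(L),
                df=1,
                p_value=float(stats.chi2.sf(L, 1)),
                model_null=null,
                model_alt=alt,
            )
        )
    return out


# --------------------------------------------------------------------- #
# correlation and diagnostics


def difference_correlation(differences: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of per-pair LDT and SET differences.

    Pairs with a missing SET difference are dropped.  The concordance
    fraction is the share of pairs whose differences have strictly opposite
    signs (higher threshold with lower thermal sum, or vice versa); zero
    differences count as non-concordant.
    """
    frame = differences[["d_ldt", "d_set"]].dropna()
    if len(frame) < 3:
        raise ValidationError("need at least three complete pairs")
    x = frame["d_ldt"].to_numpy(dtype=float)
    y = frame["d_set"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in a difference vector")
    r, p = stats.pearsonr(x, y)
    opposite = np.sign(x) * np.sign(y) < 0
    n_zero = int(np.sum((x == 0) | (y == 0)))
    if n_zero:
        logger.info("%d pair(s) with a zero difference counted as non-concordant", n_zero)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        n=int(len(frame)),
        concordance_fraction=float(opposite.mean()),
    )


def normality_diagnostics(values: np.ndarray) -> NormalityReport:
    """Sample skewness, excess kurtosis and the Shapiro–Wilk test."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValidationError("need at least four finite values")
    if np.ptp(v) == 0:
        raise ValidationError("constant vector")
    w, p = stats.shapiro(v)
    return NormalityReport(
        skewness=float(stats.skew(v)),
        kurtosis=float(stats.kurtosis(v)),  # excess, normal = 0
        shapiro_w=float(w),
        shapiro_p=float(p),
    )


def residual_diagnostics(fit: MixedModelFit) -> tuple[pd.DataFrame, list[dict]]:
    """Per-observation fitted values/residuals plus per-group random intercepts.

    Fitted values are conditional (fixed effects plus predicted random
    intercepts); the second element holds one {level: BLUP} dict per random
    factor, shrunk toward zero relative to raw group means.
    """
    if fit._model is None or fit._fit is None:
        raise ValidationError("fit does not carry its model data")
    model, rfit = fit._model, fit._fit
    fitted = model.fitted(rfit, conditional=True)
    y = np.empty(model.n)
    y[model.order] = model.y
    table = pd.DataFrame({"fitted": fitted, "residual": y - fitted})
    blups = model.blups(rfit) if model.k else []
    return table, blups


def plot_residuals(fit: MixedModelFit, path: str) -> None:
    """Residual-vs-fitted panel(s), including random-effect residuals."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table, blups = residual_diagnostics(fit)
    n_panels = 1 + len(blups)
    fig, axes = plt.subplots(1, n_panels, figsize=(4.5 * n_panels, 3.5), squeeze=False)
    ax = axes[0][0]
    ax.scatter(table["fitted"], table["residual"], s=12, alpha=0.7)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("fitted value")
    ax.set_ylabel("residual")
    ax.set_title(f"grouping: {fit.grouping}")
    for i, b in enumerate(blups, start=1):
        ax = axes[0][i]
        vals = np.fromiter(b.values(), dtype=float)
        ax.scatter(np.arange(vals.size), np.sort(vals), s=12)
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xlabel("group (sorted)")
        ax.set_ylabel("predicted random intercept")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
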