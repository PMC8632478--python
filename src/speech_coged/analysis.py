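"""Statistics for the effort-discounting paradigm.

The pipeline summarizes each six-trial block by the lowest monetary amount
chosen, averages those per hard SNR into per-subject discounting curves,
normalizes the curve sum into an area-under-the-curve (AUC) statistic in
[0, 1] (1 = no discounting), and then runs the inferential battery: group
discounting curves with t-based confidence intervals, Wilcoxon rank-sum
group contrasts, a Bonferroni-corrected Pearson correlation battery, and a
linear mixed-effects model of block-level lowest selections with subject
random intercepts compared through likelihood-ratio tests.

Likelihood-ratio machinery: for a random-intercept model the maximum
likelihood can be profiled analytically over the fixed effects and the
residual variance, leaving a one-dimensional optimization over the
variance ratio.  ``random_intercept_ml`` implements that profile exactly
(general-purpose numerical optimizers can stall short of the optimum,
which deflates likelihood-ratio statistics); statsmodels' ``MixedLM``
provides the REML coefficient table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm, pearsonr, rankdata, t as t_dist
from scipy.special import comb
import statsmodels.formula.api as smf

__all__ = [
    "FAMILYWISE_ALPHA",
    "N_PLANNED_CORRELATIONS",
    "bonferroni_threshold",
    "PTAResult",
    "compute_pta",
    "lowest_selection",
    "block_summary",
    "condition_means",
    "compute_auc",
    "discounting_summary",
    "group_curves",
    "ContrastResult",
    "group_contrast",
    "correlation_battery",
    "intelligibility_by_condition",
    "prepare_model_frame",
    "MLFit",
    "random_intercept_ml",
    "LRTResult",
    "likelihood_ratio_test",
    "fit_discounting_model",
    "model_comparison",
    "DiscountingModel",
]

FAMILYWISE_ALPHA = 0.05
N_PLANNED_CORRELATIONS = 5
PTA_FREQUENCIES = (500, 1000, 2000)
HARD_REWARD = 2.0


def bonferroni_threshold(
    alpha: float = FAMILYWISE_ALPHA, n_tests: int = N_PLANNED_CORRELATIONS
) -> float:
    """Per-test significance threshold for the planned correlation battery."""
    return alpha / n_tests


# ---------------------------------------------------------------------------
# audiometry


@dataclass(frozen=True)
class PTAResult:
    """Pure-tone averages (mean threshold at 500/1000/2000 Hz) per ear."""

    left_pta: float
    right_pta: float
    subject_id: Optional[str] = None

    @property
    def better_ear_pta(self) -> float:
        return min(self.left_pta, self.right_pta)


def compute_pta(thresholds: Mapping[str, Mapping[int, float]], subject_id: str | None = None) -> PTAResult:
    """Average 500/1000/2000 Hz thresholds per ear; analyses use the better ear."""
    ptas = {}
    for ear in ("left", "right"):
        if ear not in thresholds:
            raise ValueError(f"missing thresholds for {ear} ear")
        missing = [f for f in PTA_FREQUENCIES if f not in thresholds[ear]]
        if missing:
            raise ValueError(f"{ear} ear missing frequencies {missing}")
        ptas[ear] = float(np.mean([thresholds[ear][f] for f in PTA_FREQUENCIES]))
    return PTAResult(left_pta=ptas["left"], right_pta=ptas["right"], subject_id=subject_id)


# ---------------------------------------------------------------------------
# block summaries, curves, AUC


def lowest_selection(chosen_amounts: Sequence[float]) -> float:
    """Lowest monetary amount chosen across a six-trial block."""
    amounts = list(chosen_amounts)
    if len(amounts) != 6:
        raise ValueError(f"a block has exactly 6 trials, got {len(amounts)}")
    return float(min(amounts))


def block_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Per-block lowest selections from a trial-level choice log."""
    grouped = log.groupby(["subject_id", "block"], sort=True)
    rows = []
    for (sid, block), g in grouped:
        snrs = g["snr_db"].unique()
        if len(snrs) != 1:
            raise ValueError(f"block {block} of {sid} mixes SNRs {sorted(snrs)}")
        rows.append((sid, block, float(snrs[0]), lowest_selection(g["chosen_amount"])))
    return pd.DataFrame(rows, columns=["subject_id", "block", "snr_db", "lowest"])


def condition_means(blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean lowest selection at each hard SNR (long format)."""
    out = (
        blocks.groupby(["subject_id", "snr_db"], sort=True)["lowest"]
        .mean()
        .reset_index()
        .rename(columns={"lowest": "mean_lowest"})
    )
    return out


def compute_auc(
    means: Mapping[float, float] | Sequence[float],
    hard_reward: float = HARD_REWARD,
    n_conditions: int = 5,
) -> float:
    """Normalized discounting AUC: sum of per-SNR means over the maximum
    attainable (five conditions × the $2 hard reward = $10)."""
    values = list(means.values()) if isinstance(means, Mapping) else list(means)
    if len(values) != n_conditions:
        raise ValueError(f"expected {n_conditions} condition means, got {len(values)}")
    total = float(np.sum(values))
    auc = total / (n_conditions * hard_reward)
    if not -1e-12 <= auc <= 1 + 1e-12:
        raise ValueError(f"AUC {auc} outside [0, 1]; check the input means")
    return float(min(max(auc, 0.0), 1.0))


def discounting_summary(blocks: pd.DataFrame, hard_reward: float = HARD_REWARD) -> pd.DataFrame:
    """Wide per-subject summary: mean lowest selection per SNR plus AUC."""
    cm = condition_means(blocks)
    wide = cm.pivot(index="subject_id", columns="snr_db", values="mean_lowest")
    wide = wide[sorted(wide.columns, reverse=True)]
    n_cond = wide.shape[1]
    wide["auc"] = wide.iloc[:, :n_cond].sum(axis=1) / (n_cond * hard_reward)
    return wide.reset_index()


def group_curves(
    cond_means: pd.DataFrame,
    groups: pd.DataFrame,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Group discounting curves: mean and t-based CI of subject-level means.

    ``cond_means`` is the long per-subject table from :func:`condition_means`;
    ``groups`` maps ``subject_id`` to ``age_group``.  Groups with a single
    subject get NaN interval bounds (flagged by ``ci_defined``).
    """
    merged = cond_means.merge(groups[["subject_id", "age_group"]], on="subject_id")
    rows = []
    for (grp, snr), g in merged.groupby(["age_group", "snr_db"], sort=True):
        vals = g["mean_lowest"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            half = float(t_dist.ppf(0.5 + confidence / 2, n - 1) * vals.std(ddof=1) / math.sqrt(n))
            lo, hi, ok = mean - half, mean + half, True
        else:
            warnings.warn(f"group {grp!r} has a single subject; CI undefined")
            lo = hi = float("nan")
            ok = False
        rows.append((grp, snr, mean, lo, hi, n, ok))
    return pd.DataFrame(
        rows, columns=["age_group", "snr_db", "mean", "ci_low", "ci_high", "n", "ci_defined"]
    )


# ---------------------------------------------------------------------------
# group contrast (Wilcoxon rank-sum)


@dataclass(frozen=True)
class ContrastResult:
    statistic: float  # rank sum of the first sample
    pvalue: float
    method: str
    alternative: str


_EXACT_LIMIT = 50_000  # max number of label assignments to enumerate


def group_contrast(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> ContrastResult:
    """Wilcoxon rank-sum test comparing two groups of subject-level values.

    Small samples are tested against the exact permutation null of the rank
    sum (ties handled by mid-ranks, so the reference distribution is exact
    even with ties); larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = float(ranks[:n1].sum())

    if comb(n1 + n2, n1, exact=True) <= _EXACT_LIMIT:
        sums = np.fromiter(
            (ranks[list(idx)].sum() for idx in itertools.combinations(range(n1 + n2), n1)),
            dtype=float,
        )
        eps = 1e-9
        p_greater = float(np.mean(sums >= w_obs - eps))
        p_less = float(np.mean(sums <= w_obs + eps))
        method = "exact permutation"
    else:
        mean_w = n1 * (n1 + n2 + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:
            p_greater = p_less = 1.0
        else:
            sd = math.sqrt(var_w)
            # continuity correction toward the mean
            p_greater = float(norm.sf((w_obs - mean_w - 0.5) / sd))
            p_less = float(norm.cdf((w_obs - mean_w + 0.5) / sd))
        method = "normal approximation"

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return ContrastResult(statistic=w_obs, pvalue=p, method=method, alternative=alternative)


# ---------------------------------------------------------------------------
# correlation battery


def correlation_battery(
    summary: pd.DataFrame,
    profiles: pd.DataFrame,
    alpha: float = FAMILYWISE_ALPHA,
    n_tests: int = N_PLANNED_CORRELATIONS,
) -> pd.DataFrame:
    """Planned Pearson correlations of AUC with the individual-difference
    covariates: working memory and better-ear PTA in both groups, hearing
    handicap in the older group only, at the Bonferroni-corrected threshold.
    """
    merged = summary[["subject_id", "auc"]].merge(profiles, on="subject_id")
    threshold = alpha / n_tests
    plan = [
        ("young", "wm_score"),
        ("older", "wm_score"),
        ("young", "better_ear_pta"),
        ("older", "better_ear_pta"),
        ("older", "hhie_score"),
    ]
    rows = []
    for group, covariate in plan:
        g = merged[merged["age_group"] == group]
        pair = g[["auc", covariate]].dropna()
        n = len(pair)
        if n < 3:
            warnings.warn(f"skipping {group}/{covariate}: n={n} < 3")
            continue
        cov_vals = pair[covariate].to_numpy(dtype=float)
        if np.ptp(cov_vals) == 0 or np.ptp(pair["auc"].to_numpy()) == 0:
            warnings.warn(f"{group}/{covariate}: zero variance, correlation undefined")
            rows.append((group, covariate, n, float("nan"), float("nan"), False))
            continue
        r, p = pearsonr(pair["auc"], cov_vals)
        rows.append((group, covariate, n, float(r), float(p), bool(p < threshold)))
    out = pd.DataFrame(
        rows, columns=["age_group", "covariate", "n", "r", "p", "significant"]
    )
    out.attrs["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# mixed-effects model


def intelligibility_by_condition(familiarization: pd.DataFrame, n_keywords: int = 4) -> pd.DataFrame:
    """Per-subject, per-SNR proportion of keywords correct on target trials."""
    targets = familiarization[~familiarization["is_filler"].astype(bool)]
    out = (
        targets.groupby(["subject_id", "snr_db"], sort=True)["keywords_correct"]
        .mean()
        .div(n_keywords)
        .reset_index()
        .rename(columns={"keywords_correct": "intelligibility"})
    )
    return out


def prepare_model_frame(
    blocks: pd.DataFrame,
    profiles: pd.DataFrame,
    intelligibility: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge block-level lowest selections with covariates for modeling.

    Intelligibility (per subject × SNR) is z-standardized across the merged
    rows into ``intelligibility_z``.
    """
    frame = blocks.merge(
        profiles[[c for c in ("subject_id", "age_group", "wm_score", "better_ear_pta") if c in profiles]],
        on="subject_id",
        how="left",
    )
    if intelligibility is not None:
        frame = frame.merge(intelligibility, on=["subject_id", "snr_db"], how="left")
        vals = frame["intelligibility"].to_numpy(dtype=float)
        sd = np.nanstd(vals, ddof=1)
        if sd == 0:
            frame["intelligibility_z"] = 0.0
        else:
            frame["intelligibility_z"] = (vals - np.nanmean(vals)) / sd
    return frame


@dataclass(frozen=True)
class MLFit:
    """Exact maximum-likelihood fit of a Gaussian random-intercept model."""

    loglik: float
    beta: np.ndarray
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    nobs: int
    k_fixed: int


def random_intercept_ml(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> MLFit:
    """Maximum likelihood for ``y = X b + u[group] + e`` by exact profiling.

    The fixed effects and residual variance are profiled out in closed form
    for any value of the variance ratio ``tau2/sigma2`` (Woodbury identity
    per group), leaving a one-dimensional concave search over the log ratio.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    _, idx = np.unique(np.asarray(groups), return_inverse=True)
    sizes = np.bincount(idx)
    n_groups = len(sizes)

    def profile(loglam: float):
        lam = math.exp(loglam)
        w = lam / (1.0 + lam * sizes)
        Xg = np.zeros((n_groups, k))
        yg = np.zeros(n_groups)
        np.add.at(Xg, idx, X)
        np.add.at(yg, idx, y)
        XtX = X.T @ X - (Xg * w[:, None]).T @ Xg
        Xty = X.T @ y - (Xg * w[:, None]).T @ yg
        yty = float(y @ y - w @ (yg**2))
        beta = np.linalg.solve(XtX, Xty)
        rss = max(yty - float(beta @ Xty), 1e-300)
        sigma2 = rss / n
        logdet = float(np.sum(np.log1p(lam * sizes)))
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, lam

    res = minimize_scalar(
        lambda t: -profile(t)[0], bounds=(-20.0, 20.0), method="bounded",
        options={"xatol": 1e-12},
    )
    ll, beta, sigma2, lam = profile(float(res.x))
    # variance ratio pinned to the lower boundary means tau2 ~ 0
    if lam < 1e-8:
        lam = 0.0
    return MLFit(loglik=ll, beta=beta, sigma2=sigma2, tau2=lam * sigma2, nobs=n, k_fixed=k)


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    pvalue: float
    loglik_null: float
    loglik_full: float


def likelihood_ratio_test(
    data: pd.DataFrame,
    formula_null: str,
    formula_full: str,
    groups: str = "subject_id",
) -> LRTResult:
    """Likelihood-ratio test between nested random-intercept models (ML fits)."""
    y0, X0 = patsy.dmatrices(formula_null, data, return_type="dataframe")
    y1, X1 = patsy.dmatrices(formula_full, data, return_type="dataframe")
    if X1.shape[1] <= X0.shape[1]:
        raise ValueError("full model must add parameters over the null model")
    g = data.loc[X1.index, groups].to_numpy()
    fit0 = random_intercept_ml(y0.to_numpy().ravel(), X0.to_numpy(), data.loc[X0.index, groups].to_numpy())
    fit1 = random_intercept_ml(y1.to_numpy().ravel(), X1.to_numpy(), g)
    stat = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    df = X1.shape[1] - X0.shape[1]
    return LRTResult(
        chi2=stat,
        df=df,
        pvalue=float(chi2.sf(stat, df)),
        loglik_null=fit0.loglik,
        loglik_full=fit1.loglik,
    )


_SNR_TERM = "C(snr_db, Treatment(4.0))"
_AGE_TERM = "C(age_group, Treatment('young'))"

#: canonical stepwise model sequence: each term is tested by a likelihood-ratio
#: test against the model containing all preceding terms.
MODEL_STEPS: tuple[tuple[str, str], ...] = (
    ("snr", _SNR_TERM),
    ("age_group", _AGE_TERM),
    ("snr:age_group", f"{_SNR_TERM}:{_AGE_TERM}"),
    ("intelligibility", "intelligibility_z"),
    ("snr:intelligibility", f"{_SNR_TERM}:intelligibility_z"),
    ("age_group:intelligibility", f"{_AGE_TERM}:intelligibility_z"),
    ("wm", "wm_score"),
    ("pta", "better_ear_pta"),
)


@dataclass
class DiscountingModel:
    """REML coefficient table plus the stepwise likelihood-ratio comparison."""

    result: object  # statsmodels MixedLMResults
    comparison: pd.DataFrame
    formula: str

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.result.pvalues


def _check_rank(formula: str, data: pd.DataFrame) -> None:
    _, X = patsy.dmatrices(formula, data, return_type="dataframe")
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(mat, mode="economic", pivoting=True)
        aliased = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def fit_discounting_model(
    frame: pd.DataFrame,
    formula: str | None = None,
    groups: str = "subject_id",
    steps: Sequence[tuple[str, str]] | None = None,
    reml: bool = True,
) -> DiscountingModel:
    """Fit the block-level discounting model with subject random intercepts.

    The default fixed-effect structure is categorical SNR (treatment-coded
    against the +4 dB reference) crossed with age group and standardized
    intelligibility, the age × intelligibility interaction, and working
    memory and better-ear PTA as subject-level covariates.  Coefficients and
    SEs come from a REML fit (``statsmodels MixedLM``); the stepwise term
    comparison uses exact-ML likelihood-ratio tests.
    """
    steps = tuple(steps) if steps is not None else MODEL_STEPS
    available = [
        (name, term)
        for name, term in steps
        if all(
            col in frame.columns
            for col in _columns_in_term(term)
        )
    ]
    if formula is None:
        formula = "lowest ~ " + " + ".join(term for _, term in available)
    _check_rank(formula, frame)
    comparison = _stepwise_comparison(frame, available, groups)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, frame, groups=frame[groups])
        result = model.fit(reml=reml, method="powell")
    return DiscountingModel(result=result, comparison=comparison, formula=formula)


def _columns_in_term(term: str) -> list[str]:
    cols = []
    for piece in term.split(":"):
        piece = piece.strip()
        if piece.startswith("C("):
            cols.append(piece[2:].split(",")[0].strip())
        else:
            cols.append(piece)
    return cols


def _stepwise_comparison(
    frame: pd.DataFrame, steps: Sequence[tuple[str, str]], groups: str
) -> pd.DataFrame:
    rows = []
    prev = "lowest ~ 1"
    for name, term in steps:
        full = f"lowest ~ {term}" if prev == "lowest ~ 1" else prev + " + " + term
        res = likelihood_ratio_test(frame, prev, full, groups=groups)
        rows.append((name, res.df, res.chi2, res.pvalue))
        prev = full
    return pd.DataFrame(rows, columns=["term", "df", "chi2", "p"])


def model_comparison(
    frame: pd.DataFrame, groups: str = "subject_id", steps: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Stepwise likelihood-ratio table without fitting the REML model."""
    steps = tuple(steps) if steps is not None else MODEL_STEPS
    available = [
        (name, term)
        for name, term in steps
        if all(col in frame.columns for col in _columns_in_term(term))
    ]
    return _stepwise_comparison(frame, available, groups)
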