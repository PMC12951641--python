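"""Behavioral indicators and the nested one- vs two-factor comparison.

Indicator construction follows the study design: per participant and task,
trials are divided into equal partitions by trial order and the median
response time of each partition is one observed indicator (a complex-span
task is instead partitioned by memory set size). Participants are screened
by an accuracy floor (applied only when they fail it in *both* working-memory
tasks) and a group-level mean-RT outlier rule.

The confirmatory factor model is fit by maximum likelihood directly on the
sample covariance matrix S, minimizing the discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over loadings Lambda, unique variances Psi (diagonal), and the inter-factor
correlation Phi (factor variances fixed at 1 for identification — with 8
indicators this gives df = 19 for the two-factor and df = 20 for the
one-factor model). chi^2 = (n - 1) F_min; nested models are compared with
the chi-square difference test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("wmcoupling")

WM_TASKS = ("maintenance", "manipulation")


# ---------------------------------------------------------------------------
# Indicator construction and screening
# ---------------------------------------------------------------------------

def make_indicators(
    table: pd.DataFrame,
    partitions: int = 4,
    set_size_tasks: tuple[str, ...] = ("ospan",),
) -> pd.DataFrame:
    """Participants x indicators matrix of median RTs.

    For ordinary tasks, each participant's trials are sorted by trial index
    and divided into ``partitions`` equal groups; the indicator
    ``{task}_p{k}`` is the median RT of partition k. Tasks listed in
    ``set_size_tasks`` are instead partitioned by their ``set_size`` column
    (indicator ``{task}_s{size}``). Participants missing any partition of a
    task they performed are dropped from that task's indicators; rows with
    any missing cell are excluded from the returned table (logged).
    """
    pieces = []
    ordinary = table[~table["task"].isin(set_size_tasks)]
    if len(ordinary):
        df = ordinary.sort_values(["participant_id", "task", "trial"], kind="stable").copy()
        grp = df.groupby(["participant_id", "task"], sort=True)
        pos = grp.cumcount().to_numpy()
        size = grp["trial"].transform("size").to_numpy()
        short = df.loc[size < partitions, ["participant_id", "task"]].drop_duplicates()
        for pid, task in short.itertuples(index=False):
            logger.warning("participant %s task %s: missing a partition", pid, task)
        df = df[size >= partitions].copy()
        pos, size = pos[size >= partitions], size[size >= partitions]
        df["indicator"] = (
            df["task"] + "_p" + ((pos * partitions) // size + 1).astype(str)
        )
        pieces.append(df)
    by_size = table[table["task"].isin(set_size_tasks)]
    if len(by_size):
        if "set_size" not in by_size.columns:
            raise ValueError("set-size tasks require a set_size column")
        df = by_size.copy()
        df["indicator"] = df["task"] + "_s" + df["set_size"].astype(int).astype(str)
        pieces.append(df)
    if not pieces:
        raise ValueError("empty behavioral table")
    stacked = pd.concat(pieces, ignore_index=True)
    ind = (
        stacked.groupby(["participant_id", "indicator"])["rt_s"]
        .median()
        .unstack()
        .sort_index()
    )
    ind.columns.name = None
    ind.index.name = None
    complete = ind.dropna()
    n_dropped = len(ind) - len(complete)
    if n_dropped:
        logger.info("make_indicators: dropped %d participants with missing cells", n_dropped)
    return complete


def exclusion_filter(
    table: pd.DataFrame,
    accuracy_floor: float = 0.8,
    sd_k: float = 4.0,
    wm_tasks: tuple[str, str] = WM_TASKS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen participants by accuracy and group-level RT deviation.

    A participant is removed if their accuracy is below ``accuracy_floor``
    in *both* working-memory tasks (failing only one is retained), and then
    if their mean RT lies more than ``sd_k`` standard deviations from the
    group mean. Returns (filtered table, report of removals with reasons).
    """
    removals: list[tuple[str, str]] = []
    acc = (
        table[table["task"].isin(wm_tasks)]
        .groupby(["participant_id", "task"])["correct"]
        .mean()
        .unstack()
    )
    for pid, row in acc.iterrows():
        if all(row.get(t, 1.0) < accuracy_floor for t in wm_tasks):
            removals.append((pid, "accuracy below floor in both WM tasks"))
    removed = {pid for pid, _ in removals}
    kept = table[~table["participant_id"].isin(removed)]
    mean_rt = kept.groupby("participant_id")["rt_s"].mean()
    mu, sd = mean_rt.mean(), mean_rt.std(ddof=1)
    if sd > 0:
        for pid, v in mean_rt.items():
            if abs(v - mu) > sd_k * sd:
                removals.append((pid, f"mean RT beyond {sd_k} SD of the group mean"))
                removed.add(pid)
    filtered = table[~table["participant_id"].isin(removed)].reset_index(drop=True)
    report = pd.DataFrame(removals, columns=["participant_id", "reason"])
    for pid, reason in removals:
        logger.info("excluded %s: %s", pid, reason)
    return filtered, report


@dataclass
class ContrastResult:
    t: float
    p: float
    df: int
    cohens_d: float
    pearson_r: float
    mean_diff: float


def describe_contrast(
    table: pd.DataFrame, task1: str = WM_TASKS[0], task2: str = WM_TASKS[1]
) -> ContrastResult:
    """Paired t-test, paired Cohen's d and Pearson r of participant-mean RTs.

    d = mean(diff) / SD(diff) on the per-participant task2 - task1
    differences; r correlates the two tasks' participant means.
    """
    means = (
        table[table["task"].isin((task1, task2))]
        .groupby(["participant_id", "task"])["rt_s"]
        .mean()
        .unstack()
        .dropna()
    )
    x, y = means[task1].to_numpy(), means[task2].to_numpy()
    diff = y - x
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else 0.0
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else np.nan
    else:
        r = float(stats.pearsonr(x, y).statistic)
    if sd > 0:
        t, p = stats.ttest_rel(y, x)
    else:
        t, p = (np.inf if diff.mean() != 0 else 0.0), (0.0 if diff.mean() != 0 else 1.0)
    return ContrastResult(
        t=float(t), p=float(p), df=len(diff) - 1, cohens_d=d,
        pearson_r=r, mean_diff=float(diff.mean()),
    )


# ---------------------------------------------------------------------------
# Confirmatory factor model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorModelSpec:
    """Indicator-to-factor map with unit-variance factors.

    ``factors`` maps each factor name to the tuple of indicator names
    loading on it (simple structure, no cross-loadings). Inter-factor
    correlations are free parameters; uniquenesses are one per indicator.
    """

    name: str
    factors: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(ind for _, inds in self.factors for ind in inds)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def n_free_parameters(self) -> int:
        p = len(self.indicator_names)
        m = self.n_factors
        return p + p + m * (m - 1) // 2  # loadings + uniquenesses + factor corrs


def two_factor_spec(
    indicators1: tuple[str, ...], indicators2: tuple[str, ...],
    names: tuple[str, str] = WM_TASKS,
) -> FactorModelSpec:
    return FactorModelSpec(
        "two_factor", ((names[0], tuple(indicators1)), (names[1], tuple(indicators2)))
    )


def one_factor_spec(indicators: tuple[str, ...]) -> FactorModelSpec:
    return FactorModelSpec("one_factor", (("general", tuple(indicators)),))


@dataclass
class FactorModelFit:
    spec: FactorModelSpec
    chi_square: float
    df: int
    p_value: float
    discrepancy: float
    loadings: pd.Series
    uniquenesses: pd.Series
    factor_corr: np.ndarray
    n: int
    converged: bool
    heywood: bool


def _sigma(lam: np.ndarray, phi: np.ndarray, psi: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    lam_mat = pattern * lam[:, None]
    return lam_mat @ phi @ lam_mat.T + np.diag(psi)


def _discrepancy(S: np.ndarray, sigma: np.ndarray, log_det_s: float) -> float:
    sign, log_det = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    try:
        tr = float(np.trace(np.linalg.solve(sigma, S)))
    except np.linalg.LinAlgError:
        return 1e10
    return log_det + tr - log_det_s - S.shape[0]


def fit_factor_model(
    indicators: pd.DataFrame | tuple[np.ndarray, int],
    spec: FactorModelSpec,
    n_starts: int = 3,
    seed: int = 0,
) -> FactorModelFit:
    """Maximum-likelihood confirmatory fit on the sample covariance matrix.

    ``indicators`` is either a participants x indicators DataFrame (the
    covariance is computed with ddof = 1) or a pre-computed ``(S, n)`` pair.
    The ML discrepancy is minimized by L-BFGS-B from ``n_starts`` starting
    points (one analytic, the rest jittered); uniquenesses are bounded below
    at zero (a fit pinned there is flagged as a Heywood case) and factor
    correlations inside (-1, 1). A non-converged fit is returned flagged,
    with NaN chi-square.
    """
    if isinstance(indicators, pd.DataFrame):
        cols = list(spec.indicator_names)
        missing = [c for c in cols if c not in indicators.columns]
        if missing:
            raise KeyError(f"indicators missing columns: {missing}")
        data = indicators[cols].to_numpy(dtype=float)
        S = np.cov(data, rowvar=False, ddof=1)
        n = data.shape[0]
    else:
        S, n = indicators
        S = np.asarray(S, dtype=float)
    p = len(spec.indicator_names)
    if S.shape != (p, p):
        raise ValueError("covariance shape does not match the indicator list")
    eigvals = np.linalg.eigvalsh(S)
    if eigvals.min() <= 0:
        raise ValueError("sample covariance must be positive definite")
    m = spec.n_factors
    pattern = np.zeros((p, m))
    col = 0
    idx = {name: k for k, name in enumerate(spec.indicator_names)}
    for f, (fname, inds) in enumerate(spec.factors):
        for ind in inds:
            pattern[idx[ind], f] = 1.0
    n_corr = m * (m - 1) // 2
    n_free = spec.n_free_parameters()
    df = p * (p + 1) // 2 - n_free
    assert df == p * (p + 1) // 2 - (2 * p + n_corr)

    diag_s = np.diag(S)
    log_det_s = float(np.linalg.slogdet(S)[1])
    tri = np.tril_indices(m, -1)

    def unpack(theta: np.ndarray):
        lam = theta[:p]
        psi = theta[p : 2 * p]
        phi = np.eye(m)
        if n_corr:
            phi[tri] = theta[2 * p :]
            phi.T[tri] = theta[2 * p :]
        return lam, phi, psi

    def objective(theta: np.ndarray) -> float:
        lam, phi, psi = unpack(theta)
        return _discrepancy(S, _sigma(lam, phi, psi, pattern), log_det_s)

    # factor correlations may reach +/-1 exactly: the one-factor model is the
    # phi = 1 boundary of the two-factor space, and clipping inside (-1, 1)
    # would break the nesting the chi-square difference test relies on
    bounds = [(None, None)] * p + [(1e-10, None)] * p + [(-1.0, 1.0)] * n_corr
    base = np.concatenate(
        [np.sqrt(0.5 * diag_s), 0.5 * diag_s, np.full(n_corr, 0.3)]
    )
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        start = base if s == 0 else base * rng.uniform(0.6, 1.4, size=base.size)
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or (res.success and res.fun < best.fun) or (
            not best.success and res.success
        ):
            best = res
    lam, phi, psi = unpack(best.x)
    heywood = bool(np.any(psi <= 1e-8 * np.maximum(diag_s, 1e-12)))
    if heywood:
        warnings.warn(f"{spec.name}: Heywood case, uniqueness bounded at 0")
    converged = bool(best.success) and best.fun < 1e9
    f_min = float(best.fun)
    chi2 = (n - 1) * f_min if converged else np.nan
    p_value = float(stats.chi2.sf(chi2, df)) if converged and df > 0 else np.nan
    factor_of = {ind: fname for fname, inds in spec.factors for ind in inds}
    index = pd.Index(spec.indicator_names)
    return FactorModelFit(
        spec=spec,
        chi_square=float(chi2),
        df=df,
        p_value=p_value,
        discrepancy=f_min,
        loadings=pd.Series(lam, index=index, name="loading"),
        uniquenesses=pd.Series(psi, index=index, name="uniqueness"),
        factor_corr=phi,
        n=n,
        converged=converged,
        heywood=heywood,
    )


@dataclass
class ChiSqDifference:
    delta_chi2: float
    delta_df: int
    p: float


def chisq_difference(fit_restricted: FactorModelFit, fit_full: FactorModelFit) -> ChiSqDifference:
    """Chi-square difference test between nested covariance-structure fits.

    The restricted model (fewer free parameters, larger df) is tested
    against the full model; a negative difference — possible only through
    optimizer noise — is floored at zero with a warning.
    """
    if fit_restricted.df <= fit_full.df:
        raise ValueError("restricted model must have larger df than the full model")
    if not (fit_restricted.converged and fit_full.converged):
        raise ValueError("both fits must have converged")
    delta = fit_restricted.chi_square - fit_full.chi_square
    if delta < 0:
        if delta < -1e-6 * max(1.0, fit_full.chi_square):
            warnings.warn(f"negative chi-square difference ({delta:.3g}) floored at 0")
        delta = 0.0
    ddf = fit_restricted.df - fit_full.df
    return ChiSqDifference(
        delta_chi2=float(delta), delta_df=ddf, p=float(stats.chi2.sf(delta, ddf))
    )


def compare_one_vs_two_factor(
    indicators: pd.DataFrame,
    indicators_factor1: tuple[str, ...],
    indicators_factor2: tuple[str, ...],
    seed: int = 0,
) -> tuple[FactorModelFit, FactorModelFit, ChiSqDifference]:
    """Fit both models on the same indicator table and test their difference.

    Returns (one-factor fit, two-factor fit, difference test); a small
    difference-test p-value prefers the two-factor model.
    """
    all_inds = tuple(indicators_factor1) + tuple(indicators_factor2)
    fit1 = fit_factor_model(indicators, one_factor_spec(all_inds), seed=seed)
    fit2 = fit_factor_model(
        indicators, two_factor_spec(indicators_factor1, indicators_factor2), seed=seed
    )
    return fit1, fit2, chisq_difference(fit1, fit2)


# ---------------------------------------------------------------------------
# Split-half consistency
# ---------------------------------------------------------------------------

def split_by_median(table: pd.DataFrame, value_col: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-participant median split of trials on a value column.

    Returns (low subset, high subset); ties at the median go to the low
    half, keeping the split deterministic.
    """
    low_parts, high_parts = [], []
    for _, grp in table.groupby("participant_id"):
        med = grp[value_col].median()
        low_parts.append(grp[grp[value_col] <= med])
        high_parts.append(grp[grp[value_col] > med])
    return (
        pd.concat(low_parts).reset_index(drop=True),
        pd.concat(high_parts).reset_index(drop=True),
    )


def split_half_consistency(
    indicators: pd.DataFrame,
    indicators_factor1: tuple[str, ...],
    indicators_factor2: tuple[str, ...],
    split_rule: str = "odd_even",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Run the one- vs two-factor comparison in each participant half.

    ``split_rule``: "odd_even" alternates participants by sorted position;
    "first_second" takes the first and second halves in sorted order. Both
    are deterministic. Raises if a half would have fewer participants than
    indicators (covariance not positive definite). Returns per-half fits and
    tests plus a ``consistent`` flag (same preferred model in both halves).
    """
    ind = indicators.sort_index()
    n = len(ind)
    p = len(indicators_factor1) + len(indicators_factor2)
    if n < 2 * (p + 1):
        raise ValueError(f"too few participants ({n}) to split against {p} indicators")
    pos = np.arange(n)
    if split_rule == "odd_even":
        halves = {"half1": ind.iloc[pos % 2 == 0], "half2": ind.iloc[pos % 2 == 1]}
    elif split_rule == "first_second":
        halves = {"half1": ind.iloc[: n // 2], "half2": ind.iloc[n // 2 :]}
    else:
        raise ValueError(f"unknown split rule {split_rule!r}")
    out: dict = {}
    preferred = []
    for name, half in halves.items():
        fit1, fit2, diff = compare_one_vs_two_factor(
            half, indicators_factor1, indicators_factor2, seed=seed
        )
        pref = "two_factor" if diff.p < alpha else "one_factor"
        preferred.append(pref)
        out[name] = {
            "one_factor": fit1, "two_factor": fit2,
            "difference": diff, "preferred": pref,
        }
    out["consistent"] = preferred[0] == preferred[1]
    return out
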