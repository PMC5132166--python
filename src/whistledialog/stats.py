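"""Statistical analyses for whistle-dialog contests.

Five reusable pieces:

* :func:`paired_signed_rank` — Wilcoxon signed-rank with a centered S
  statistic, exact tie-aware null distribution for small samples.
* :func:`binomial_z_test` — proportion vs. a null, normal approximation
  without continuity correction (exact tail reported alongside).
* :func:`winner_model` / :func:`agreement_model` — binary logistic mixed
  models with a pair-level random intercept, fitted by Gauss–Hermite
  quadrature maximum likelihood; interaction screening and Wald F-type
  term tests with between–within denominator degrees of freedom.
* :func:`within_subject_change` — paired signed-rank on per-unit
  condition means.
* :func:`listener_concordance` — intercept-only binary mixed model with
  crossed random intercepts (listener, dialog).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy import stats as sps

from .core import Channel, Condition, score_round
from .features import FEATURE_NAMES, compute_features

__all__ = [
    "TestResult",
    "PairedModelFit",
    "paired_signed_rank",
    "binomial_z_test",
    "fit_logistic_mixed",
    "winner_model",
    "agreement_model",
    "within_subject_change",
    "listener_concordance",
    "round_records",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    statistic_name: str
    p_value: float
    n: int
    side: str = "two_sided"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p_value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _exact_signed_rank_p(
    ranks: np.ndarray, w_plus: float, side: str
) -> float:
    """Exact null distribution of the positive-rank sum by dynamic
    programming over sign assignments; handles midranks (ties)."""
    r2 = np.round(ranks * 2).astype(int)  # midranks *2 are integers
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    mu2 = total / 2.0
    values = np.arange(total + 1)
    if side == "greater":
        return float(counts[values >= w2 - 1e-9].sum())
    if side == "less":
        return float(counts[values <= w2 + 1e-9].sum())
    dev = abs(w2 - mu2)
    return float(counts[np.abs(values - mu2) >= dev - 1e-9].sum())


def paired_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    side: str = "two_sided",
    exact_max_n: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank test on pairwise differences x − y.

    The statistic is the centered positive-rank sum
    ``S = W+ − m(m+1)/4`` over the m nonzero differences (so S > 0 means
    x tends to exceed y).  Zero differences are dropped, ties midranked.
    p is exact (sign-flip distribution) for m <= ``exact_max_n``, normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    n_pairs = int(keep.sum())
    d = d[d != 0]
    m = d.size
    if m == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, "S", 1.0, n_pairs, side,
            notes={"m_nonzero": 0, "mode": "degenerate"},
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    s = w_plus - m * (m + 1) / 4.0
    alt = {"two_sided": "two_sided", "greater": "greater", "less": "less"}[side]
    if m <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus, alt)
        mode = "exact"
    else:
        sigma = math.sqrt(float(np.sum(ranks**2)) / 4.0)
        z = s / sigma
        if alt == "greater":
            p = float(sps.norm.sf(z))
        elif alt == "less":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2 * sps.norm.sf(abs(z)))
        mode = "normal_approx"
    return TestResult(
        "wilcoxon_signed_rank", float(s), "S", min(p, 1.0), n_pairs, side,
        notes={"m_nonzero": m, "mode": mode, "w_plus": w_plus},
    )


# ---------------------------------------------------------------------------
# Binomial proportion test


def binomial_z_test(
    k: int, n: int, p0: float = 0.5, side: str = "one_sided"
) -> TestResult:
    """Normal-approximation test of k/n against p0, no continuity correction.

    ``one_sided`` tests the upper tail (proportion > p0).  The exact
    binomial tail probability is reported in ``notes``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    phat = k / n
    z = (phat - p0) / math.sqrt(p0 * (1 - p0) / n)
    if side == "one_sided":
        p = float(sps.norm.sf(z))
        exact = sps.binomtest(k, n, p0, alternative="greater").pvalue
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        exact = sps.binomtest(k, n, p0, alternative="two-sided").pvalue
    return TestResult(
        "binomial_z", float(z), "Z", p, n, side,
        notes={"k": k, "p0": p0, "proportion": phat, "exact_p": float(exact)},
    )


# ---------------------------------------------------------------------------
# Logistic mixed model (single random intercept, Gauss-Hermite ML)


@dataclass
class MixedFit:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    separation: bool
    penalized: bool
    n_obs: int
    n_groups: int
    cov: np.ndarray


@dataclass
class PairedModelFit:
    coefficients: dict  # name -> (estimate, se)
    random_effect_variance: float
    term_tests: list
    converged: bool
    separation: bool
    penalized: bool
    n_obs: int
    n_groups: int
    dropped_interactions: list = field(default_factory=list)
    max_abs_predictor_corr: float = math.nan
    notes: dict = field(default_factory=dict)


def _mixed_loglik(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
    ridge: float,
) -> tuple[float, np.ndarray]:
    """Negative marginal loglik and its gradient (beta, log sigma)."""
    from scipy.special import expit, logsumexp

    beta = theta[:-1]
    sigma = math.exp(min(theta[-1], 10.0))  # line searches can probe huge steps
    eta = X @ beta
    # (n_obs, K) linear predictor at each quadrature node
    E = eta[:, None] + math.sqrt(2.0) * sigma * nodes[None, :]
    ll_obs = y[:, None] * E - np.logaddexp(0.0, E)
    group_ll = np.zeros((n_groups, nodes.size))
    np.add.at(group_ll, group_idx, ll_obs)
    group_ll += log_weights[None, :]
    norm = logsumexp(group_ll, axis=1)
    ll = float(norm.sum())
    # posterior node weights per group
    a = np.exp(group_ll - norm[:, None])
    resid = y[:, None] - expit(E)  # (n_obs, K)
    weighted = a[group_idx] * resid
    grad_beta = X.T @ weighted.sum(axis=1)
    grad_logsig = float(
        (weighted * (math.sqrt(2.0) * sigma * nodes)[None, :]).sum()
    )
    grad = np.append(grad_beta, grad_logsig)
    if ridge > 0:
        ll -= ridge * float(beta @ beta)
        grad[:-1] -= 2.0 * ridge * beta
    return -ll, -grad


def fit_logistic_mixed(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    n_quad: int = 21,
    ridge: float = 0.0,
    max_abs_beta: float = 15.0,
) -> MixedFit:
    """ML fit of logit P(y=1) = X beta + b_g, b_g ~ N(0, sigma^2).

    The group integral is evaluated with ``n_quad``-node Gauss–Hermite
    quadrature.  Apparent separation (runaway coefficients) triggers one
    refit with a weak ridge penalty, flagged on the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_obs, p) matching y")
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    z, w = hermgauss(n_quad)
    log_w = np.log(w) - 0.5 * math.log(math.pi)
    p = X.shape[1]

    def objective(theta, pen):
        return _mixed_loglik(theta, X, y, codes, n_groups, z, log_w, pen)

    theta0 = np.zeros(p + 1)
    theta0[-1] = math.log(0.5)
    res = optimize.minimize(
        objective, theta0, args=(ridge,), method="BFGS", jac=True
    )
    separation = bool(np.max(np.abs(res.x[:-1])) > max_abs_beta)
    penalized = ridge > 0
    if (separation or not res.success) and ridge == 0.0:
        res2 = optimize.minimize(
            objective, theta0, args=(0.5,), method="BFGS", jac=True
        )
        if np.max(np.abs(res2.x[:-1])) <= max_abs_beta and res2.success:
            res = res2
            penalized = True

    from statsmodels.tools.numdiff import approx_hess

    pen = 0.5 if penalized and ridge == 0.0 else ridge
    hess = approx_hess(res.x, lambda th: objective(th, pen)[0])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        ok = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    except np.linalg.LinAlgError:
        cov = np.full((p + 1, p + 1), np.nan)
        se = np.full(p, np.nan)
        ok = False
    return MixedFit(
        beta=res.x[:p],
        beta_se=se,
        sigma=math.exp(res.x[-1]),
        loglik=-float(res.fun),
        converged=bool(res.success and ok),
        separation=separation,
        penalized=penalized,
        n_obs=int(y.size),
        n_groups=n_groups,
        cov=cov[: p + 1, : p + 1],
    )


def _wald_term_tests(
    names: Sequence[str],
    fit: MixedFit,
    skip: Sequence[str] = ("intercept",),
) -> list:
    """Wald F-type test per fixed effect, denominator df by a between-within
    convention: ddf = n_obs − n_groups − (number of non-intercept terms)."""
    ddf = max(1, fit.n_obs - fit.n_groups - (len(names) - 1))
    tests = []
    for j, name in enumerate(names):
        if name in skip:
            continue
        est, se = fit.beta[j], fit.beta_se[j]
        if not np.isfinite(se) or se <= 0:
            tests.append(
                TestResult(
                    f"wald_F[{name}]", math.nan, "F", math.nan, fit.n_obs,
                    notes={"estimate": float(est), "df": (1, ddf),
                           "inestimable": True},
                )
            )
            continue
        f_stat = (est / se) ** 2
        p = float(sps.f.sf(f_stat, 1, ddf))
        tests.append(
            TestResult(
                f"wald_F[{name}]", float(f_stat), "F", p, fit.n_obs,
                notes={"estimate": float(est), "se": float(se),
                       "df": (1, ddf)},
            )
        )
    return tests


def _max_pairwise_corr(X: np.ndarray, names: Sequence[str]) -> float:
    cols = [j for j, nm in enumerate(names) if nm != "intercept"]
    if len(cols) < 2:
        return math.nan
    sub = X[:, cols]
    keep = [j for j in range(sub.shape[1]) if np.std(sub[:, j]) > 0]
    if len(keep) < 2:
        return math.nan
    corr = np.corrcoef(sub[:, keep], rowvar=False)
    mask = ~np.eye(corr.shape[0], dtype=bool)
    return float(np.max(np.abs(corr[mask])))


def _fit_paired_model(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    response: str,
    include_round: bool,
    test_interactions: bool,
    alpha: float = 0.05,
) -> PairedModelFit:
    frame = frame.dropna(subset=list(predictors) + [response]).reset_index(drop=True)
    if not len(frame):
        raise ValueError("no complete rows to fit")
    y = frame[response].astype(float).to_numpy()
    groups = frame["pair_id"].to_numpy()

    def design(with_interactions: bool):
        names = ["intercept"]
        cols = [np.ones(len(frame))]
        usable = [p for p in predictors if np.std(frame[p].to_numpy()) > 0]
        for p_name in usable:
            names.append(p_name)
            cols.append(frame[p_name].to_numpy(dtype=float))
        round_c = None
        if include_round and frame["round_index"].nunique() > 1:
            round_c = frame["round_index"].to_numpy(dtype=float)
            round_c = round_c - round_c.mean()
            names.append("round")
            cols.append(round_c)
        if with_interactions and round_c is not None:
            for p_name in usable:
                names.append(f"{p_name}:round")
                cols.append(frame[p_name].to_numpy(dtype=float) * round_c)
        return np.column_stack(cols), names, usable

    dropped = []
    if test_interactions:
        X_full, names_full, usable = design(True)
        has_inter = any(":" in nm for nm in names_full)
        if has_inter:
            fit_full = fit_logistic_mixed(X_full, y, groups)
            inter_tests = [
                t for t in _wald_term_tests(names_full, fit_full)
                if ":" in t.method
            ]
            significant = [
                t for t in inter_tests
                if np.isfinite(t.p_value) and t.p_value < alpha
            ]
            if not significant:
                dropped = [t.method[7:-1] for t in inter_tests]
            else:
                X, names = X_full, names_full
                fit = fit_full
                tests = _wald_term_tests(names, fit)
                return PairedModelFit(
                    coefficients={
                        nm: (float(b), float(s))
                        for nm, b, s in zip(names, fit.beta, fit.beta_se)
                    },
                    random_effect_variance=fit.sigma**2,
                    term_tests=tests,
                    converged=fit.converged,
                    separation=fit.separation,
                    penalized=fit.penalized,
                    n_obs=fit.n_obs,
                    n_groups=fit.n_groups,
                    dropped_interactions=[],
                    max_abs_predictor_corr=_max_pairwise_corr(X, names),
                    notes={"interactions_retained": True},
                )
    X, names, usable = design(False)
    fit = fit_logistic_mixed(X, y, groups)
    tests = _wald_term_tests(names, fit)
    excluded = [p for p in predictors if p not in usable]
    return PairedModelFit(
        coefficients={
            nm: (float(b), float(s))
            for nm, b, s in zip(names, fit.beta, fit.beta_se)
        },
        random_effect_variance=fit.sigma**2,
        term_tests=tests,
        converged=fit.converged,
        separation=fit.separation,
        penalized=fit.penalized,
        n_obs=fit.n_obs,
        n_groups=fit.n_groups,
        dropped_interactions=dropped,
        max_abs_predictor_corr=_max_pairwise_corr(X, names),
        notes={"constant_predictors_excluded": excluded} if excluded else {},
    )


# ---------------------------------------------------------------------------
# Round-record construction and the two contest models


def round_records(dialogs) -> pd.DataFrame:
    """Per pair-round records for the contest models.

    Columns: identifiers, outcome (winner channel, agreement flag), the
    signed channel differences ``d_<feature>`` (A − B) and absolute
    differences ``abs_d_<feature>`` for each acoustic feature.
    """
    rows = []
    for d in dialogs:
        if d.condition != Condition.COMPETITIVE:
            continue
        outcome = score_round(d)
        fvs = compute_features(d)
        rec = {
            "pair_id": d.pair_id,
            "round_index": d.round_index,
            "resolved": outcome.resolved,
            "winner": outcome.winner.value if outcome.winner else None,
            "agreement": outcome.agreement,
            "agreement_known": outcome.agreement_known,
        }
        for name in FEATURE_NAMES:
            a = getattr(fvs[Channel.A], name)
            b = getattr(fvs[Channel.B], name)
            diff = float(a) - float(b)
            rec[f"d_{name}"] = diff
            rec[f"abs_d_{name}"] = abs(diff)
        rows.append(rec)
    return pd.DataFrame(rows)


def winner_model(
    records: pd.DataFrame,
    predictors: Optional[Sequence[str]] = None,
    seed: int = 0,
    include_round: bool = True,
    test_interactions: bool = True,
) -> PairedModelFit:
    """Which acoustic differences predict who wins a resolved round.

    For each pair one focal individual is chosen by a seeded draw; the
    response is whether the focal won, the predictors are the focal-signed
    channel differences.  Unresolved rounds are excluded (no winner).
    """
    if predictors is None:
        predictors = [f"d_{name}" for name in FEATURE_NAMES]
    sub = records[records["resolved"].astype(bool)].copy()
    if not len(sub):
        raise ValueError("no resolved rounds")
    rng = np.random.default_rng(seed)
    focal = {
        pid: rng.choice([Channel.A.value, Channel.B.value])
        for pid in sorted(sub["pair_id"].unique())
    }
    sign = sub["pair_id"].map(
        lambda pid: 1.0 if focal[pid] == Channel.A.value else -1.0
    )
    sub["won"] = (
        sub["winner"] == sub["pair_id"].map(focal)
    ).astype(float)
    for p in predictors:
        sub[p] = sub[p] * sign
    fit = _fit_paired_model(
        sub, predictors, "won", include_round, test_interactions
    )
    fit.notes["focal"] = focal
    return fit


def agreement_model(
    records: pd.DataFrame,
    predictors: Optional[Sequence[str]] = None,
    include_round: bool = True,
    test_interactions: bool = True,
) -> PairedModelFit:
    """Which absolute acoustic differences predict reaching an agreement."""
    if predictors is None:
        predictors = [f"abs_d_{name}" for name in FEATURE_NAMES]
    sub = records[records["agreement_known"].astype(bool)].copy()
    if not len(sub):
        raise ValueError("no rounds with a defined agreement flag")
    sub["agree"] = sub["agreement"].astype(float)
    return _fit_paired_model(
        sub, predictors, "agree", include_round, test_interactions
    )


def within_subject_change(
    values_a: Sequence[float], values_b: Sequence[float], side: str = "two_sided"
) -> TestResult:
    """Paired signed-rank on per-unit condition means; units missing either
    condition are dropped (count in notes)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    result = paired_signed_rank(a[keep], b[keep], side=side)
    result.notes["n_excluded"] = int((~keep).sum())
    return result


# ---------------------------------------------------------------------------
# Listener concordance (crossed random intercepts)


def listener_concordance(responses) -> tuple[TestResult, pd.DataFrame]:
    """Were listeners' winner designations better than the 50% coin flip?

    Fits an intercept-only binary mixed model with crossed random
    intercepts for listener and playback dialog (variational Bayes), and
    reports the intercept test against logit(0.5) = 0 plus the pooled
    proportion with its simple binomial z cross-check.  Returns the test
    and a per-dialog proportion table.
    """
    frame = pd.DataFrame(
        [
            {
                "listener_id": r.listener_id,
                "dialog_id": r.dialog_id,
                "correct": int(r.correct),
            }
            for r in responses
        ]
    )
    if frame["listener_id"].nunique() < 2:
        raise ValueError("need at least two listeners")
    per_dialog = (
        frame.groupby("dialog_id")["correct"].agg(["mean", "count"]).reset_index()
    )
    k = int(frame["correct"].sum())
    n = int(len(frame))
    pooled = k / n
    cross_check = binomial_z_test(k, n, 0.5, side="two_sided")

    notes = {
        "pooled_proportion": pooled,
        "binomial_z": cross_check.statistic,
        "binomial_z_p": cross_check.p_value,
        "n_listeners": int(frame["listener_id"].nunique()),
        "n_dialogs": int(frame["dialog_id"].nunique()),
    }
    if pooled in (0.0, 1.0):
        notes["separation"] = True
        return (
            TestResult(
                "mixed_intercept", math.inf if pooled == 1.0 else -math.inf,
                "t", 0.0, n, "two_sided", notes,
            ),
            per_dialog,
        )

    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    endog = frame["correct"].to_numpy(dtype=float)
    exog = np.ones((n, 1))
    vc_parts = [pd.get_dummies(frame["listener_id"]).to_numpy(dtype=float)]
    vc_names = ["listener"]
    if frame["dialog_id"].nunique() > 1:
        vc_parts.append(pd.get_dummies(frame["dialog_id"]).to_numpy(dtype=float))
        vc_names.append("dialog")
    else:
        notes["dialog_variance_dropped"] = True
    exog_vc = np.column_stack(vc_parts)
    ident = np.concatenate(
        [np.full(part.shape[1], i) for i, part in enumerate(vc_parts)]
    )
    model = BinomialBayesMixedGLM(
        endog, exog, exog_vc, ident, vcp_p=2.0, fe_p=2.0
    )
    fit = model.fit_vb()
    est = float(fit.fe_mean[0])
    se = float(fit.fe_sd[0])
    t_stat = est / se
    # normal reference for the intercept test
    p = float(2 * sps.norm.sf(abs(t_stat)))
    notes["intercept_logit"] = est
    notes["intercept_se"] = se
    notes["vc_names"] = vc_names
    return (
        TestResult("mixed_intercept", t_stat, "t", p, n, "two_sided", notes),
        per_dialog,
    )
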