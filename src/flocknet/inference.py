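"""Dyadic matrix regressions with restricted permutation inference.

Dyadic observations (one row per female–male pair) are not independent, so
coefficients are estimated by ordinary maximum likelihood / least squares
on the vectorized dyad table, while *inference* comes entirely from
refitting the model on permuted datasets — the MRQAP family of network
regressions.  Three null models are provided:

* :func:`permute_strength_within_order` — shuffle the winter association
  strength among dyads of the same neighbourhood order (social pairs are
  pooled with order-1 dyads), preserving the spatial breeding structure.
* :func:`permute_nodes_by_last_feeder` — a spatially restricted node
  permutation: whole network positions are swapped among individuals whose
  last winter feeder was the same, separating social preference from
  shared space use.
* :func:`category_mean_test` — label shuffles over pooled strengths for
  comparing category means (social pair / extra-pair partner / order-1 /
  order-2, or the five neighbourhood orders).

Two-sided empirical p-values use the (1 + #{|b*| >= |b|}) / (n_perm + 1)
convention and are reported alongside the outside-95%-null-range
significance flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "scale_2sd",
    "LogisticFit",
    "fit_logistic",
    "fit_linear",
    "score_statistics",
    "permute_strength_within_order",
    "permute_nodes_by_last_feeder",
    "permutation_test",
    "category_mean_test",
]


def scale_2sd(values: np.ndarray, name: str = "covariate") -> tuple[np.ndarray, float]:
    """Divide a covariate by twice its standard deviation (ddof=1).

    Puts binary and continuous predictors on a comparable effect-size
    scale; the resulting sd is 0.5.  Returns scaled values and divisor.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"cannot 2-SD scale {name}: standard deviation is zero")
    return values / (2.0 * sd), 2.0 * sd


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit on a dyad table."""

    coef: np.ndarray          # includes leading intercept
    converged: bool
    separated: bool
    loglik: float
    n_iter: int
    names: list[str] = field(default_factory=list)

    @property
    def exp_coef(self) -> np.ndarray:
        return np.exp(self.coef)


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    names: list[str] | None = None,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    ``X`` excludes the intercept (added internally).  Convergence is
    declared when the log-likelihood improves by less than ``tol``.
    Complete or quasi-complete separation is flagged (diverging
    coefficients); the point estimates are then unreliable, but
    permutation inference can fall back to score statistics.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response has no variation (all 0 or all 1)")
    from scipy.special import expit

    Xd = _add_intercept(np.asarray(X, dtype=float))
    n, p = Xd.shape

    def loglik(b):
        eta = Xd @ b
        # log(1 + e^eta) computed stably for large |eta|
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    ll_old = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        WX = Xd * w[:, None]
        try:
            proposal = np.linalg.solve(Xd.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        # step-halving: plain IRLS can overshoot on near-separated data
        step = proposal - beta
        ll = loglik(proposal)
        halvings = 0
        while ll < ll_old and halvings < 30:
            step /= 2.0
            proposal = beta + step
            ll = loglik(proposal)
            halvings += 1
        beta = proposal
        if abs(ll - ll_old) < tol:
            ll_old = ll
            converged = True
            break
        ll_old = ll
    eta_final = Xd @ beta
    perfectly_classified = bool(np.all((2 * y - 1) * eta_final >= 0))
    separated = (
        not converged
        or np.abs(beta).max() > 30
        or (perfectly_classified and np.abs(beta).max() > 10)
    )
    if separated:
        logger.warning("separation detected: max |coef| = %.1f", np.abs(beta).max())
    return LogisticFit(
        coef=beta,
        converged=converged,
        separated=separated,
        loglik=ll_old,
        n_iter=it,
        names=["intercept"] + (names or [f"x{i}" for i in range(p - 1)]),
    )


def fit_linear(
    X: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Ordinary least squares on a dyad table (intercept added internally).

    Raises on rank deficiency, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("response needs at least two distinct values")
    Xd = _add_intercept(np.asarray(X, dtype=float))
    names = ["intercept"] + (names or [f"x{i}" for i in range(Xd.shape[1] - 1)])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # identify columns involved in the deficiency via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(Xd, pivoting=True)
        bad = [names[i] for i in sorted(piv[rank:])]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return beta, names


def score_statistics(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized score statistics at the null (intercept-only) model.

    Finite even under separation, which makes them a safe permutation
    statistic when maximum-likelihood estimates diverge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p0 = y.mean()
    resid = y - p0
    Xc = X - X.mean(axis=0)
    u = Xc.T @ resid
    denom = np.sqrt(p0 * (1 - p0) * (Xc**2).sum(axis=0))
    denom = np.where(denom > 0, denom, 1.0)
    return u / denom


# ---------------------------------------------------------------------------
# Null models


def permute_strength_within_order(
    table: pd.DataFrame,
    rng: np.random.Generator,
    strength_col: str = "strength",
    order_col: str = "order",
    social_pair_col: str | None = "social_pair",
) -> pd.DataFrame:
    """Shuffle association strengths among dyads of equal neighbourhood order.

    Social-pair dyads (if the column is present) are pooled with order-1
    dyads into one stratum, mirroring the idea that the social pair sits
    inside the first-order neighbourhood.  Dyads with missing order form
    their own stratum.  All other columns are untouched; strata of size 1
    stay fixed.
    """
    out = table.copy()
    order = out[order_col].to_numpy(dtype=float)
    strata = np.where(np.isnan(order), -1.0, order)
    if social_pair_col is not None and social_pair_col in out.columns:
        strata = np.where(out[social_pair_col].to_numpy(dtype=bool), 1.0, strata)
    strata = np.where(strata == 0.0, 1.0, strata)  # order-0 coding also pools
    values = out[strength_col].to_numpy(dtype=float).copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < 2:
            continue
        values[idx] = values[rng.permutation(idx)]
    out[strength_col] = values
    return out


def permute_nodes_by_last_feeder(
    ids: list[str],
    matrix: np.ndarray,
    last_feeder_map: dict,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially restricted node permutation of a dyadic matrix.

    Network positions (rows/columns of ``matrix``) are permuted among
    individuals sharing the same last-feeder label; everything attached to
    the identity (sex, age, nest) stays put because only the matrix moves.
    Individuals alone at their feeder keep their position.
    """
    missing = [t for t in ids if t not in last_feeder_map]
    if missing:
        raise ValueError(f"individuals without a last-feeder label: {missing}")
    perm = np.arange(len(ids))
    groups: dict = {}
    for i, tag in enumerate(ids):
        groups.setdefault(last_feeder_map[tag], []).append(i)
    for members in groups.values():
        if len(members) < 2:
            continue
        members = np.array(members)
        perm[members] = members[rng.permutation(len(members))]
    return matrix[np.ix_(perm, perm)]


# ---------------------------------------------------------------------------
# Permutation tests


def _null_band(null: np.ndarray) -> tuple[float, float]:
    return float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975))


def permutation_test(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    null_draw,
    n_perm: int = 1000,
    seed: int = 0,
    family: str = "logistic",
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Generic dyadic permutation test.

    ``null_draw(rng)`` must return a permuted design matrix X* (same
    shape); the model is refit on (X*, y) for each of ``n_perm`` draws.
    Reports, per coefficient: the observed estimate, exp(estimate),
    two-sided empirical p with the +1 convention, the central 95% range of
    the null distribution, and the outside-range significance flag.

    Replicates whose refit fails are dropped and counted; more than
    ``max_failure_rate`` failures aborts.  If the observed logistic fit is
    separated, the test statistic switches to the score statistic for the
    observed data and every replicate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    use_score = False
    exp_obs = None

    if family == "logistic":
        fit = fit_logistic(X, y, names=names)
        if fit.separated:
            use_score = True
            obs = score_statistics(X, y)
            stat_names = list(names)
        else:
            obs = fit.coef
            exp_obs = fit.exp_coef
            stat_names = fit.names
    elif family == "linear":
        obs, stat_names = fit_linear(X, y, names=names)
    else:
        raise ValueError(f"unknown family {family!r}")

    def statistic(Xp: np.ndarray) -> np.ndarray | None:
        try:
            if use_score:
                return score_statistics(Xp, y)
            if family == "logistic":
                f = fit_logistic(Xp, y)
                return None if f.separated else f.coef
            beta, _ = fit_linear(Xp, y)
            return beta
        except (ValueError, np.linalg.LinAlgError):
            return None

    null = []
    failures = 0
    for _ in range(n_perm):
        stat = statistic(null_draw(rng))
        if stat is None:
            failures += 1
        else:
            null.append(stat)
    if failures > max_failure_rate * n_perm:
        raise RuntimeError(f"{failures}/{n_perm} null refits failed")
    null = np.asarray(null)

    rows = []
    for k, name in enumerate(stat_names):
        dist = null[:, k]
        p = (1.0 + np.sum(np.abs(dist) >= np.abs(obs[k]))) / (len(dist) + 1.0)
        lo, hi = _null_band(dist)
        rows.append(
            {
                "term": name,
                "estimate": float(obs[k]),
                "exp_estimate": float(exp_obs[k]) if exp_obs is not None else np.nan,
                "p_empirical": float(p),
                "null_low95": lo,
                "null_high95": hi,
                "significant": bool(obs[k] < lo or obs[k] > hi),
                "n_null": int(len(dist)),
                "n_failed": failures,
                "statistic": "score" if use_score else "coef",
            }
        )
    return pd.DataFrame(rows)


def category_mean_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise mean differences between categories with label-shuffle nulls.

    The observed difference in mean value is computed for every unordered
    category pair; the null pools all values and reshuffles the labels.
    Categories with fewer than 2 members are flagged (difference still
    reported).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cats = [c for c in pd.unique(labels)]
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    rng = np.random.default_rng(seed)

    def mean_diffs(labs: np.ndarray) -> dict:
        means = {c: values[labs == c].mean() for c in cats}
        return {(a, b): means[a] - means[b] for a, b in itertools.combinations(cats, 2)}

    obs = mean_diffs(labels)
    null: dict = {k: [] for k in obs}
    for _ in range(n_perm):
        shuffled = labels[rng.permutation(len(labels))]
        for k, v in mean_diffs(shuffled).items():
            null[k].append(v)

    rows = []
    for (a, b), d_obs in obs.items():
        dist = np.asarray(null[(a, b)])
        p = (1.0 + np.sum(np.abs(dist) >= np.abs(d_obs))) / (len(dist) + 1.0)
        lo, hi = _null_band(dist)
        rows.append(
            {
                "category_a": a,
                "category_b": b,
                "mean_a": float(values[labels == a].mean()),
                "mean_b": float(values[labels == b].mean()),
                "diff": float(d_obs),
                "p_empirical": float(p),
                "null_low95": lo,
                "null_high95": hi,
                "significant": bool(d_obs < lo or d_obs > hi),
                "small_category": bool(
                    (labels == a).sum() < 2 or (labels == b).sum() < 2
                ),
            }
        )
    return pd.DataFrame(rows)
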