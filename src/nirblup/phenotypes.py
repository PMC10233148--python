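"""Trial-adjusted phenotypes: outlier editing, per-line BLUEs, and
broad-sense heritability from a trial-plus-line mixed model.

Field records from unbalanced multi-year trials are adjusted with the
linear model

    value = mean + trial + line + error

where *trial* is the concatenation of year, location and nursery fitted
as a fixed group effect. Fitting *line* as fixed gives best linear
unbiased estimates (BLUEs) used as the working phenotype downstream;
fitting *line* as random gives the line variance component used in the
line-mean repeatability

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / (T * R))

with T and R the mean numbers of trials and replications per line.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ComputationError, ConvergenceError, DataError

__all__ = [
    "trial_key",
    "edit_outliers",
    "fit_blues",
    "estimate_line_variance",
    "LineVarianceEstimate",
    "broad_h2",
]


def trial_key(table: pd.DataFrame) -> pd.Series:
    """Concatenated year_location_nursery group label per record."""
    return table["year"] + "_" + table["location"] + "_" + table["nursery"]


def edit_outliers(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records beyond mean +/- 4 SD, per trait, in a single pass.

    Moments are computed once per trait on all of its records (sample SD,
    ddof=1); there is no iteration, so one gross outlier can inflate the SD
    enough to save itself — that is the documented behaviour of a
    non-iterative edit. Returns the cleaned table and the removed records.
    """
    removed_idx = []
    for trait, grp in table.groupby("trait"):
        if len(grp) < 2:
            raise DataError(f"trait {trait!r} has fewer than 2 records")
        mu = grp["value"].mean()
        sd = grp["value"].std(ddof=1)
        if sd == 0:
            continue
        bad = grp.index[(grp["value"] - mu).abs() > 4.0 * sd]
        removed_idx.extend(bad)
    removed = table.loc[removed_idx]
    kept = table.drop(index=removed_idx).reset_index(drop=True)
    return kept, removed


def _design(table: pd.DataFrame):
    """Corner-point design matrix for value = mean + trial + line.

    Columns: intercept, trial dummies (first trial reference), line dummies
    (first line reference). Returns (X, lines, trials, y).
    """
    trials = sorted(trial_key(table).unique())
    lines = sorted(table["line_id"].unique())
    t_pos = {t: i for i, t in enumerate(trials)}
    l_pos = {l: i for i, l in enumerate(lines)}
    nrec = len(table)
    X = np.zeros((nrec, 1 + len(trials) - 1 + len(lines) - 1))
    X[:, 0] = 1.0
    tk = trial_key(table).to_numpy()
    li = table["line_id"].to_numpy()
    for r in range(nrec):
        ti = t_pos[tk[r]]
        if ti > 0:
            X[r, ti] = 1.0
        lj = l_pos[li[r]]
        if lj > 0:
            X[r, len(trials) - 1 + lj] = 1.0
    return X, lines, trials, table["value"].to_numpy(dtype=float)


def _check_connected(table: pd.DataFrame) -> None:
    g = nx.Graph()
    tk = trial_key(table)
    for line, t in zip(table["line_id"], tk):
        g.add_edge(("line", line), ("trial", t))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        desc = [
            sorted(n for kind, n in comp if kind == "line")[:5] for comp in comps
        ]
        raise DataError(
            f"line-by-trial design is disconnected ({len(comps)} components; "
            f"example lines per component: {desc})"
        )


def fit_blues(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-line BLUEs for one trait by OLS with corner-point constraints.

    The reported BLUE is ``intercept + line effect`` (the reference line's
    BLUE equals the estimated intercept), so BLUE differences between lines
    are free of trial effects. Lines whose effect is not estimable (aliased
    with a trial) are reported with infinite standard error.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise DataError(f"no records for trait {trait!r}")
    _check_connected(sub)
    X, lines, _, y = _design(sub)
    XtX = X.T @ X
    Xty = X.T @ y
    XtX_pinv = np.linalg.pinv(XtX)
    beta = XtX_pinv @ Xty
    resid = y - X @ beta
    dof = len(y) - np.linalg.matrix_rank(XtX)
    s2 = float(resid @ resid / dof) if dof > 0 else 0.0

    n_lines = len(lines)
    offset = X.shape[1] - (n_lines - 1)
    counts = sub.groupby("line_id").size()
    out = []
    for j, line in enumerate(lines):
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        if j > 0:
            c[offset + j - 1] = 1.0
        blue = float(c @ beta)
        # estimability: c must lie in the row space of X
        c_proj = XtX @ XtX_pinv @ c
        if np.allclose(c_proj, c, atol=1e-8):
            se = float(np.sqrt(max(c @ XtX_pinv @ c, 0.0) * s2))
        else:
            se = np.inf
        out.append((line, trait, blue, se, int(counts[line])))
    return pd.DataFrame(out, columns=["line_id", "trait", "blue", "se", "n_records"])


@dataclass
class LineVarianceEstimate:
    sigma2_g: float
    sigma2_e: float
    T: float
    R: float
    H2: float
    loglik: float
    trace: list


def _reml_one_ratio(y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    """Profiled REML for y = Xb + Zu + e with u ~ N(0, s2g I).

    Maximizes the restricted likelihood over the single ratio
    lam = s2g/s2e; s2e then has a closed form. Returns (s2g, s2e, loglik,
    trace of (lam, loglik) evaluations).
    """
    n = len(y)
    p = np.linalg.matrix_rank(X)
    ZZt = Z @ Z.T
    trace: list[tuple[float, float]] = []

    def neg_restricted(log_lam: float) -> float:
        lam = np.exp(log_lam)
        V = np.eye(n) + lam * ZZt
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e30
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, y)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            # rank-deficient fixed design: use pseudo-determinant
            w = np.linalg.eigvalsh(XtViX)
            logdetX = np.log(w[w > 1e-10]).sum()
        b = np.linalg.lstsq(XtViX, X.T @ Vi_y, rcond=None)[0]
        yPy = float(y @ Vi_y - (X.T @ Vi_y) @ b)
        if yPy <= 0:
            return 1e30
        # profiled restricted loglik up to an additive constant
        ll = -0.5 * (logdetV + logdetX + (n - p) * np.log(yPy))
        trace.append((lam, ll))
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise ConvergenceError("one-ratio REML failed to converge", trace)
    lam = float(np.exp(res.x))
    # boundary handling: treat tiny ratios as zero line variance
    V = np.eye(n) + lam * ZZt
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    b = np.linalg.lstsq(XtViX, X.T @ Vi_y, rcond=None)[0]
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ b)
    s2e = yPy / (n - p)
    s2g = lam * s2e
    if lam <= np.exp(-11.5):
        s2g = 0.0
    return s2g, s2e, float(-res.fun), trace


def estimate_line_variance(table: pd.DataFrame, trait: str) -> LineVarianceEstimate:
    """Line and residual variances with trial fixed and line random."""
    sub = table[table["trait"] == trait]
    lines = sorted(sub["line_id"].unique())
    if len(lines) < 2:
        raise DataError("need at least 2 lines to estimate a line variance")
    tk = trial_key(sub)
    trials = sorted(tk.unique())
    t_pos = {t: i for i, t in enumerate(trials)}
    l_pos = {l: i for i, l in enumerate(lines)}
    n = len(sub)
    X = np.zeros((n, len(trials)))  # full trial dummies (intercept absorbed)
    Z = np.zeros((n, len(lines)))
    for r, (line, t) in enumerate(zip(sub["line_id"], tk)):
        X[r, t_pos[t]] = 1.0
        Z[r, l_pos[line]] = 1.0
    y = sub["value"].to_numpy(dtype=float)
    s2g, s2e, ll, trace = _reml_one_ratio(y, X, Z)

    per_line_trials = sub.assign(trial=tk.to_numpy()).groupby("line_id")["trial"].nunique()
    T = float(per_line_trials.mean())
    reps = sub.assign(trial=tk.to_numpy()).groupby(["line_id", "trial"]).size()
    R = float(reps.mean())
    return LineVarianceEstimate(
        sigma2_g=s2g,
        sigma2_e=s2e,
        T=T,
        R=R,
        H2=broad_h2(s2g, s2e, T, R),
        loglik=ll,
        trace=trace,
    )


def broad_h2(sigma2_g: float, sigma2_e: float, T: float, R: float = 1.0) -> float:
    """Line-mean broad-sense heritability sigma_g^2/(sigma_g^2 + sigma_e^2/(T R))."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ComputationError("variances must be non-negative")
    if T * R <= 0:
        raise ComputationError("T * R must be positive")
    denom = sigma2_g + sigma2_e / (T * R)
    if denom == 0:
        raise ComputationError("both variance components are zero; H2 undefined")
    return sigma2_g / denom
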