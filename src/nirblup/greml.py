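"""Genomic REML (GREML) variance components and GBLUP breeding values.

The single-trait model is ``y = 1 mu + Z u + e`` with
``u ~ N(0, G sigma_g^2)`` for a genomic relationship matrix G and
``e ~ N(0, I sigma_e^2)``. The bivariate end-product/NIR model stacks the
two trait vectors, gives each trait its own intercept, structures the
genetic covariance as ``G0 (x) G`` (a 2x2 between-trait covariance
Kronecker the GRM) and the residuals as an unstructured 2x2 ``R0``
applied per line: the cross-trait residual covariance binds only the
lines observed for both traits, and records missing for a trait are
simply absent rows of the likelihood — never imputed.

Estimation maximizes the restricted log-likelihood

    l(theta) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

(constant terms ``-(n - p)/2 log(2 pi)`` are dropped throughout, so
likelihoods are comparable across parameter values but not across
datasets) by average-information updates with step halving, falling back
to a scaled gradient step whenever an AI step fails to improve the
likelihood. Covariance matrices are kept in the positive-semidefinite
cone by eigenvalue clipping after every update.

GEBVs for every line in the GRM (phenotyped or not) come from the BLUP
conditional mean ``u_hat = Cov(u, y) V^-1 (y - X b_hat)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import ComputationError, ConvergenceError, DataError
from .grm import GRM

__all__ = [
    "FitOptions",
    "SingleTraitFit",
    "BivariateFit",
    "reml_loglik",
    "fit_single_trait",
    "fit_bivariate",
    "predict_gebv",
]


@dataclass
class FitOptions:
    max_iter: int = 100
    tol: float = 1e-6  # on the change in restricted loglik
    param_tol: float = 1e-6  # on the relative change in parameters
    #: freeze the genetic covariance at zero (nested model for LR comparisons)
    fix_genetic_cov: bool = False
    #: "pearson" correlates the two BLUE vectors; "components" uses (G0+R0)
    phenotypic_corr: str = "pearson"


@dataclass
class SingleTraitFit:
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool
    n_iter: int
    gebv: pd.Series
    se: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)


@dataclass
class BivariateFit:
    G0: np.ndarray
    R0: np.ndarray
    r_g: float
    r_p: float
    loglik: float
    converged: bool
    n_iter: int
    gebv_ep: pd.Series
    gebv_nir: pd.Series
    h2: tuple[float, float] = (np.nan, np.nan)
    se: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)


def _tri_to_mat(theta: np.ndarray, k: int) -> np.ndarray:
    M = np.zeros((k, k))
    iu = np.triu_indices(k)
    M[iu] = theta
    M.T[iu] = theta
    return M


def _mat_to_tri(M: np.ndarray) -> np.ndarray:
    return M[np.triu_indices(M.shape[0])]


class _Model:
    """Dense REML machinery for a k-trait GBLUP with per-trait missingness.

    Records are internally ordered by trait so each trait occupies one
    contiguous slice of y and of V.
    """

    def __init__(self, y_by_trait: list[pd.Series], grm: GRM):
        self.grm = grm
        self.k = len(y_by_trait)
        ys, self.line_idx, self.slices = [], [], []
        start = 0
        for t, s in enumerate(y_by_trait):
            if s.index.duplicated().any():
                raise DataError(f"duplicate line ids in trait {t} phenotypes")
            idx = grm.index_of(s.index)
            order = np.argsort(idx)
            self.line_idx.append(idx[order])
            ys.append(s.to_numpy(dtype=float)[order])
            self.slices.append(slice(start, start + len(s)))
            start += len(s)
        self.y = np.concatenate(ys) if ys else np.empty(0)
        self.n = len(self.y)
        # one intercept per trait that actually has records
        active = [t for t in range(self.k) if self.slices[t].stop > self.slices[t].start]
        self.X = np.zeros((self.n, len(active)))
        for col, t in enumerate(active):
            self.X[self.slices[t], col] = 1.0
        # GRM blocks per trait pair
        G = grm.values
        self.Gsub = [
            [G[np.ix_(self.line_idx[t], self.line_idx[s])] for s in range(self.k)]
            for t in range(self.k)
        ]
        # records of the same line across trait pairs (for cross residuals)
        self.match = {}
        for t in range(self.k):
            for s in range(t + 1, self.k):
                pos_s = {l: j for j, l in enumerate(self.line_idx[s])}
                mi, mj = [], []
                for i, l in enumerate(self.line_idx[t]):
                    if l in pos_s:
                        mi.append(self.slices[t].start + i)
                        mj.append(self.slices[s].start + pos_s[l])
                self.match[(t, s)] = (np.array(mi, dtype=int), np.array(mj, dtype=int))
        # parameter bookkeeping: genetic upper triangle then residual
        self.pairs = [(t, s) for t in range(self.k) for s in range(t, self.k)]
        self.n_par = 2 * len(self.pairs)

    # -- parameter vector <-> (G0, R0) ------------------------------------
    def split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = len(self.pairs)
        return _tri_to_mat(theta[:h], self.k), _tri_to_mat(theta[h:], self.k)

    def join(self, G0: np.ndarray, R0: np.ndarray) -> np.ndarray:
        return np.concatenate([_mat_to_tri(G0), _mat_to_tri(R0)])

    # -- covariance assembly ----------------------------------------------
    def build_V(self, theta: np.ndarray) -> np.ndarray:
        G0, R0 = self.split(theta)
        V = np.zeros((self.n, self.n))
        for t in range(self.k):
            st = self.slices[t]
            V[st, st] += G0[t, t] * self.Gsub[t][t]
            V[st, st] += R0[t, t] * np.eye(st.stop - st.start)
            for s in range(t + 1, self.k):
                ss = self.slices[s]
                V[st, ss] += G0[t, s] * self.Gsub[t][s]
                V[ss, st] += G0[t, s] * self.Gsub[t][s].T
                mi, mj = self.match[(t, s)]
                V[mi, mj] += R0[t, s]
                V[mj, mi] += R0[t, s]
        return V

    def mul_component(self, which: str, t: int, s: int, M: np.ndarray) -> np.ndarray:
        """Multiply the derivative matrix dV/dtheta_(which,t,s) by M."""
        out = np.zeros_like(M)
        st, ss = self.slices[t], self.slices[s]
        if which == "g":
            if t == s:
                out[st] += self.Gsub[t][t] @ M[st]
            else:
                out[st] += self.Gsub[t][s] @ M[ss]
                out[ss] += self.Gsub[t][s].T @ M[st]
        else:
            if t == s:
                out[st] += M[st]
            else:
                mi, mj = self.match[(t, s)]
                out[mi] += M[mj]
                out[mj] += M[mi]
        return out

    def trace_with(self, which: str, t: int, s: int, Vinv: np.ndarray) -> float:
        st, ss = self.slices[t], self.slices[s]
        if which == "g":
            if t == s:
                return float(np.sum(Vinv[st, st] * self.Gsub[t][t]))
            return 2.0 * float(np.sum(Vinv[st, ss] * self.Gsub[t][s]))
        if t == s:
            return float(np.trace(Vinv[st, st]))
        mi, mj = self.match[(t, s)]
        return 2.0 * float(Vinv[mi, mj].sum())

    def component_list(self) -> list[tuple[str, int, int]]:
        return [("g", t, s) for t, s in self.pairs] + [("r", t, s) for t, s in self.pairs]

    # -- likelihood ---------------------------------------------------------
    def loglik_terms(self, theta: np.ndarray):
        """Return (loglik, cho, Viy, ViX, XtViX_inv, w=Py) or None if V fails."""
        V = self.build_V(theta)
        try:
            c = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.log(np.diag(c[0])).sum()
        ViX = cho_solve(c, self.X, check_finite=False)
        Viy = cho_solve(c, self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        K = np.linalg.inv(XtViX)
        b = K @ (self.X.T @ Viy)
        w = Viy - ViX @ b
        yPy = float(self.y @ w)
        ll = -0.5 * (logdetV + logdetX + yPy)
        return ll, c, ViX, K, w, b

    def loglik(self, theta: np.ndarray) -> float | None:
        out = self.loglik_terms(theta)
        return None if out is None else out[0]

    def gebv(self, theta: np.ndarray, w: np.ndarray) -> np.ndarray:
        """BLUP for every GRM line, all traits: (n_lines, k)."""
        G0, _ = self.split(theta)
        G = self.grm.values
        out = np.zeros((self.grm.n_lines, self.k))
        for t in range(self.k):
            for s in range(self.k):
                if G0[t, s] != 0.0 and self.line_idx[s].size:
                    out[:, t] += G0[t, s] * (G[:, self.line_idx[s]] @ w[self.slices[s]])
        return out


def _project_psd(M: np.ndarray, floor_eig: float, floor_diag: float) -> np.ndarray:
    w, v = np.linalg.eigh(M)
    M2 = v @ np.diag(np.clip(w, floor_eig, None)) @ v.T
    M2 = (M2 + M2.T) / 2.0
    for i in range(M.shape[0]):
        if M2[i, i] < floor_diag:
            M2[i, i] = floor_diag
    return M2


def _fit(model: _Model, options: FitOptions, frozen: np.ndarray):
    """AI-REML driver. ``frozen`` marks parameters held at their start value."""
    k = model.k
    var_y = np.array(
        [np.var(model.y[model.slices[t]], ddof=1) if model.slices[t].stop > model.slices[t].start + 1 else 1.0 for t in range(k)]
    )
    scale = float(np.mean(var_y))
    floor_diag = 1e-8 * scale
    floor_eig = 1e-8 * scale

    G0 = np.diag(0.5 * var_y)
    R0 = np.diag(0.5 * var_y)
    theta = model.join(G0, R0)
    comps = model.component_list()
    free = ~frozen
    # indices of variance (diagonal) parameters, eligible for boundary pinning
    diag_idx = np.array(
        [i for i, (_, t, s) in enumerate(model.component_list()) if t == s]
    )

    def project(th: np.ndarray) -> np.ndarray:
        g, r = model.split(th)
        g = _project_psd(g, floor_eig, floor_diag)
        r = _project_psd(r, floor_eig, floor_diag)
        out = model.join(g, r)
        out[frozen] = theta0[frozen]
        return out

    theta0 = theta.copy()
    terms = model.loglik_terms(theta)
    if terms is None:
        raise ComputationError("starting values yield an indefinite covariance")
    ll = terms[0]
    trace = [(0, ll, theta.copy())]
    converged = False
    n_iter = 0
    flat_count = 0
    ai_free = None

    for it in range(1, options.max_iter + 1):
        n_iter = it
        _, c, ViX, K, w, _ = terms
        Vinv = cho_solve(c, np.eye(model.n), check_finite=False)

        score = np.zeros(model.n_par)
        q = np.zeros((model.n_par, model.n))
        for i, (which, t, s) in enumerate(comps):
            qi = model.mul_component(which, t, s, w)
            q[i] = qi
            tr_vi = model.trace_with(which, t, s, Vinv)
            Ui = model.mul_component(which, t, s, ViX)
            tr_p = tr_vi - float(np.trace(K @ (ViX.T @ Ui)))
            score[i] = -0.5 * (tr_p - float(w @ qi))
        Pq = np.zeros_like(q)
        for i in range(model.n_par):
            vq = Vinv @ q[i]
            Pq[i] = vq - ViX @ (K @ (ViX.T @ q[i]))
        AI = 0.5 * (q @ Pq.T)
        AI = (AI + AI.T) / 2.0

        # variances stuck at the floor with a negative score stay there this
        # iteration; updating them only stalls the rest of the system
        pinned = np.zeros(model.n_par, dtype=bool)
        pinned[diag_idx] = (theta[diag_idx] <= 1.001 * floor_diag) & (
            score[diag_idx] < 0
        )
        idx = np.flatnonzero(free & ~pinned)
        if idx.size == 0:
            converged = True
            break
        ai_free = AI[np.ix_(idx, idx)]
        ai_idx = idx
        sc_free = score[idx]
        try:
            delta_free = np.linalg.solve(ai_free + 1e-10 * scale * np.eye(len(idx)), sc_free)
        except np.linalg.LinAlgError:
            delta_free = sc_free * scale
        delta = np.zeros(model.n_par)
        delta[idx] = delta_free

        def try_step(direction: np.ndarray):
            alpha = 1.0
            for _ in range(14):
                cand = project(theta + alpha * direction)
                t2 = model.loglik_terms(cand)
                if t2 is not None and t2[0] > ll - 1e-13:
                    return cand, t2
                alpha *= 0.5
            return None, None

        cand, t2 = try_step(delta)
        if cand is None:
            # gradient fallback, scaled to parameter magnitude (EM-flavoured)
            grad_dir = np.zeros(model.n_par)
            grad_dir[idx] = sc_free * (scale / max(model.n, 1))
            cand, t2 = try_step(grad_dir)
        if cand is None:
            # no ascent found along the AI or gradient directions after full
            # step halving: a (possibly boundary-constrained) maximum up to
            # line-search resolution
            converged = True
            break

        dll = t2[0] - ll
        dpar = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-3 * scale))
        theta, terms, ll = cand, t2, t2[0]
        trace.append((it, ll, theta.copy()))
        if abs(dll) < options.tol:
            if dpar < max(options.param_tol, 1e-6):
                converged = True
                break
            # weakly identified directions can creep while the likelihood is
            # flat; three consecutive negligible improvements end the search
            flat_count += 1
            if flat_count >= 3:
                converged = True
                break
        else:
            flat_count = 0
        # diminishing returns: accepted steps are monotone in loglik, so a
        # window gaining less than w*tol total means the optimum is reached
        # (covers zigzag along the PSD boundary of G0/R0)
        w = 5
        if len(trace) > w and trace[-1][1] - trace[-1 - w][1] < w * options.tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {options.max_iter} iterations", trace
        )

    # observed-information SEs from the AI matrix at the optimum
    se = np.full(model.n_par, np.nan)
    if ai_free is not None:
        try:
            cov = np.linalg.inv(ai_free)
            se[ai_idx] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    return theta, terms, ll, converged, n_iter, se, trace


def reml_loglik(y, lines, traits, grm: GRM, g_cov, r_cov) -> float:
    """Restricted log-likelihood of one parameter point.

    Parameters
    ----------
    y, lines, traits : record vectors (value, line id, trait index 0..k-1).
    grm : conditioned genomic relationship matrix.
    g_cov, r_cov : k x k genetic and residual covariance matrices (scalars
        accepted for k = 1).

    Returns ``-1/2 [log|V| + log|X' V^-1 X| + y' P y]`` with per-trait
    intercepts as the only fixed effects; the additive constant
    ``-(n-p)/2 log(2 pi)`` is omitted.
    """
    g_cov = np.atleast_2d(np.asarray(g_cov, dtype=float))
    r_cov = np.atleast_2d(np.asarray(r_cov, dtype=float))
    k = g_cov.shape[0]
    traits = np.asarray(traits, dtype=int)
    y = np.asarray(y, dtype=float)
    lines = np.asarray(lines)
    series = [
        pd.Series(y[traits == t], index=lines[traits == t]) for t in range(k)
    ]
    model = _Model(series, grm)
    theta = model.join(g_cov, r_cov)
    ll = model.loglik(theta)
    if ll is None:
        raise ComputationError(
            f"covariance parameters G0={g_cov.tolist()}, R0={r_cov.tolist()} "
            "yield an indefinite phenotypic covariance"
        )
    return float(ll)


def _as_series(blues) -> pd.Series:
    if isinstance(blues, pd.Series):
        s = blues.copy()
        s.index = s.index.astype(str)
        return s
    if isinstance(blues, pd.DataFrame):
        if blues["trait"].nunique() > 1:
            raise DataError("BLUE table holds several traits; pass one")
        return pd.Series(
            blues["blue"].to_numpy(), index=blues["line_id"].astype(str)
        )
    raise DataError("phenotypes must be a Series or a BLUE table")


def fit_single_trait(blues, grm: GRM, options: FitOptions | None = None) -> SingleTraitFit:
    """Single-trait GREML fit with GEBVs for every GRM line."""
    options = options or FitOptions()
    y = _as_series(blues)
    keep = y.index.isin(grm.line_ids)
    if keep.sum() < 2:
        raise DataError("fewer than 2 phenotyped lines overlap the GRM")
    y = y[keep]
    model = _Model([y], grm)
    theta, terms, ll, converged, n_iter, se, trace = _fit(
        model, options, frozen=np.zeros(2, dtype=bool)
    )
    G0, R0 = model.split(theta)
    s2g, s2e = float(G0[0, 0]), float(R0[0, 0])
    w = terms[4]
    gebv = pd.Series(model.gebv(theta, w)[:, 0], index=grm.line_ids, name="gebv")
    return SingleTraitFit(
        sigma2_g=s2g,
        sigma2_e=s2e,
        h2=s2g / (s2g + s2e),
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        gebv=gebv,
        se={"sigma2_g": se[0], "sigma2_e": se[1]},
        trace=[(it, l) for it, l, _ in trace],
    )


def fit_bivariate(
    blues_ep, blues_nir, grm: GRM, options: FitOptions | None = None
) -> BivariateFit:
    """Bivariate EP/NIR GREML fit with per-trait record missingness.

    Lines observed for only one trait contribute that trait's row alone;
    the cross-trait residual covariance is estimable only from lines with
    both traits (frozen at zero, with a warning, when fewer than two such
    lines exist). If one trait has no records at all the model degenerates
    to the single-trait fit of the other, with all cross parameters frozen.
    """
    options = options or FitOptions()
    y_ep = _as_series(blues_ep)
    y_nir = _as_series(blues_nir)
    y_ep = y_ep[y_ep.index.isin(grm.line_ids)]
    y_nir = y_nir[y_nir.index.isin(grm.line_ids)]
    if len(y_ep) == 0 and len(y_nir) == 0:
        raise DataError("no phenotyped lines overlap the GRM")

    model = _Model([y_ep, y_nir], grm)
    # theta layout: g11 g12 g22 r11 r12 r22
    frozen = np.zeros(6, dtype=bool)
    n_both = len(model.match[(0, 1)][0])
    if n_both < 2:
        warnings.warn(
            "fewer than 2 lines observed for both traits; residual covariance "
            "fixed at 0",
            stacklevel=2,
        )
        frozen[4] = True
    if options.fix_genetic_cov:
        frozen[1] = True
    if len(y_ep) == 0:
        frozen[[0, 1, 3, 4]] = True
    if len(y_nir) == 0:
        frozen[[1, 2, 4, 5]] = True

    theta, terms, ll, converged, n_iter, se, trace = _fit(model, options, frozen)
    G0, R0 = model.split(theta)
    w = terms[4]
    u = model.gebv(theta, w)
    denom = np.sqrt(G0[0, 0] * G0[1, 1])
    r_g = float(G0[0, 1] / denom) if denom > 0 else np.nan

    if options.phenotypic_corr == "components":
        P0 = G0 + R0
        r_p = float(P0[0, 1] / np.sqrt(P0[0, 0] * P0[1, 1]))
    else:
        both = y_ep.index.intersection(y_nir.index)
        r_p = (
            float(np.corrcoef(y_ep[both], y_nir[both])[0, 1]) if len(both) > 2 else np.nan
        )

    # delta-method SE for r_g from the AI covariance of (g11, g12, g22)
    r_g_se = np.nan
    if denom > 0 and np.isfinite(se[:3]).all():
        g11, g12, g22 = G0[0, 0], G0[0, 1], G0[1, 1]
        grad = np.array(
            [-0.5 * g12 / (denom * g11), 1.0 / denom, -0.5 * g12 / (denom * g22)]
        )
        r_g_se = float(np.sqrt(np.sum((grad * se[:3]) ** 2)))

    names = ["g_ep", "g_ep_nir", "g_nir", "e_ep", "e_ep_nir", "e_nir"]
    return BivariateFit(
        G0=G0,
        R0=R0,
        r_g=r_g,
        r_p=r_p,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        gebv_ep=pd.Series(u[:, 0], index=grm.line_ids, name="gebv_ep"),
        gebv_nir=pd.Series(u[:, 1], index=grm.line_ids, name="gebv_nir"),
        h2=(
            float(G0[0, 0] / (G0[0, 0] + R0[0, 0])),
            float(G0[1, 1] / (G0[1, 1] + R0[1, 1])),
        ),
        se=dict(zip(names, se)) | {"r_g": r_g_se},
        trace=[(it, l) for it, l, _ in trace],
    )


def predict_gebv(fit: SingleTraitFit | BivariateFit, target_lines) -> pd.DataFrame:
    """BLUP values for the requested lines (which must be in the GRM)."""
    target_lines = [str(l) for l in target_lines]
    if isinstance(fit, SingleTraitFit):
        missing = [l for l in target_lines if l not in fit.gebv.index]
        if missing:
            raise DataError(f"unknown line ids: {missing}")
        return pd.DataFrame({"line_id": target_lines, "gebv": fit.gebv[target_lines].to_numpy()})
    missing = [l for l in target_lines if l not in fit.gebv_ep.index]
    if missing:
        raise DataError(f"unknown line ids: {missing}")
    return pd.DataFrame(
        {
            "line_id": target_lines,
            "gebv_ep": fit.gebv_ep[target_lines].to_numpy(),
            "gebv_nir": fit.gebv_nir[target_lines].to_numpy(),
        }
    )
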