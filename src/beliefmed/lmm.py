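"""Two-level linear mixed models with participants as clusters.

The model is ``y = X beta + Z_j u_j + eps`` within each cluster *j*,
with mutually uncorrelated random effects ``u_j ~ N(0, diag(tau^2))``
(diagonal covariance only) and ``eps ~ N(0, sigma^2 I)``.  Estimation
profiles the fixed effects and the residual variance out of the REML
(or ML) criterion and optimises the variance *ratios* ``lambda_k =
tau_k^2 / sigma^2`` on the log scale with a bounded quasi-Newton
method, so fits are deterministic.  Wald t tests use Satterthwaite
approximate degrees of freedom.

Random-effect structures that cannot be supported by the data (variance
at the boundary, a ridge-flat likelihood, or a collapsing residual
variance) are reported through ``LmmFit.diagnostics`` and consumed by
:func:`prune_random_effects`, which removes one random term per round
until the fit is clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import TrialTable
from .exceptions import RankDeficiencyError

INTERCEPT = "intercept"

#: bounds for the variance ratio lambda = tau^2 / sigma^2 (log scale)
_LOG_LB = np.log(1e-10)
_LOG_UB = np.log(1e10)
#: a variance ratio at or below this value counts as "at the boundary"
BOUNDARY_TOL = 1e-8
#: a variance ratio this large means the residual has collapsed into
#: a random term (perfect confounding)
_RUNAWAY = 1e9


@dataclass(frozen=True)
class LmmSpec:
    """Declarative description of a two-level mixed model.

    ``fixed_terms`` are predictor column names (a fixed intercept is
    implicit unless ``suppress_fixed_intercept``); ``random_terms`` may
    contain ``"intercept"`` and any of the fixed terms.  Only the
    diagonal random-effects covariance is supported.
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = ()
    method: str = "reml"
    suppress_fixed_intercept: bool = False
    covariance: str = "diagonal"

    def __post_init__(self):
        if self.method not in ("reml", "ml"):
            raise ValueError(f"method must be 'reml' or 'ml', got {self.method!r}")
        if self.covariance != "diagonal":
            raise ValueError("only the diagonal covariance structure is supported")
        allowed = set(self.fixed_terms) | {INTERCEPT}
        bad = [t for t in self.random_terms if t not in allowed]
        if bad:
            raise ValueError(f"random terms {bad} are not in fixed_terms or 'intercept'")

    def without(self, term: str) -> "LmmSpec":
        return replace(self, random_terms=tuple(t for t in self.random_terms if t != term))


@dataclass
class LmmFit:
    """Result of a two-level mixed-model fit."""

    params: pd.DataFrame          # Estimate, SE, df, t, p, CI Lower, CI Upper per term
    variance_components: dict[str, float]
    residual_variance: float
    loglik: float
    method: str
    n_obs: int
    n_clusters: int
    converged: bool
    spec: LmmSpec
    blups: pd.DataFrame | None = None
    pruned: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        """Fixed effects + variance components (incl. residual)."""
        return len(self.params) + len(self.spec.random_terms) + 1

    def __getitem__(self, term: str) -> pd.Series:
        return self.params.loc[term]

    def to_dict(self) -> dict:
        return {
            "params": {t: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                       for t, row in self.params.iterrows()},
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "residual_variance": float(self.residual_variance),
            "loglik": float(self.loglik),
            "method": self.method,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "pruned": self.pruned,
        }

    def summary(self) -> str:
        lines = [
            f"Two-level LMM ({self.method.upper()}), outcome: {self.spec.outcome}",
            f"n_obs = {self.n_obs}, clusters = {self.n_clusters}, "
            f"loglik = {self.loglik:.4f}, converged = {self.converged}",
            "",
            self.params.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "Random effects (variances):",
        ]
        for term, v in self.variance_components.items():
            lines.append(f"  {term:<12s} {v:.6f}")
        lines.append(f"  {'residual':<12s} {self.residual_variance:.6f}")
        for entry in self.pruned:
            lines.append(f"Pruned random term {entry['term']!r}: {entry['reason']}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# assembly


def _design(spec: LmmSpec, data, groups: str = "participant"):
    """Extract y, X, Z and the cluster index from a table."""
    if isinstance(data, TrialTable):
        df = data.included_df
    else:
        df = data
    cols = [spec.outcome, *spec.fixed_terms]
    cols += [t for t in spec.random_terms if t != INTERCEPT]
    cols = list(dict.fromkeys(cols))
    sub = df[[groups, *cols]].dropna()
    # sort by cluster for contiguous blocks; estimates are order-invariant
    sub = sub.sort_values(groups, kind="stable")

    y = sub[spec.outcome].to_numpy(float)
    names = [] if spec.suppress_fixed_intercept else ["Intercept"]
    blocks = [] if spec.suppress_fixed_intercept else [np.ones(len(sub))]
    for t in spec.fixed_terms:
        names.append(t)
        blocks.append(sub[t].to_numpy(float))
    X = np.column_stack(blocks) if blocks else np.empty((len(sub), 0))

    rank = np.linalg.matrix_rank(X) if X.size else 0
    if X.size and rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise RankDeficiencyError(
            f"fixed-effects design is rank deficient; collinear terms: {bad}", terms=bad
        )

    znames = list(spec.random_terms)
    zblocks = [np.ones(len(sub)) if t == INTERCEPT else sub[t].to_numpy(float) for t in znames]
    Z = np.column_stack(zblocks) if zblocks else np.empty((len(sub), 0))

    codes, uniques = pd.factorize(sub[groups], sort=False)
    return y, X, names, Z, znames, codes, list(uniques)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r <= np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j])
    return bad


def _cluster_stats(y, X, Z, codes):
    """Per-cluster cross-products needed by the Woodbury likelihood."""
    J = codes.max() + 1
    q, p = Z.shape[1], X.shape[1]
    A = np.zeros((J, q, q))
    B = np.zeros((J, q, p))
    c = np.zeros((J, q))
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(J + 1))
    for j in range(J):
        idx = order[bounds[j]:bounds[j + 1]]
        Zj = Z[idx]
        A[j] = Zj.T @ Zj
        B[j] = Zj.T @ X[idx]
        c[j] = Zj.T @ y[idx]
    return A, B, c


class _Engine:
    """Numerical core shared by the profiled and full likelihoods."""

    def __init__(self, y, X, Z, codes, method):
        self.y, self.X, self.Z, self.codes = y, X, Z, codes
        self.method = method
        self.n, self.p = len(y), X.shape[1]
        self.q = Z.shape[1]
        self.J = int(codes.max()) + 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        if self.q:
            self.A, self.B, self.c = _cluster_stats(y, X, Z, codes)

    def _whitened(self, lam: np.ndarray):
        """XtVX, XtVy, ytVy and sum log|Vbar_j| for Vbar = I + Z diag(lam) Z'."""
        if self.q == 0 or not len(lam):
            return self.XtX, self.Xty, self.yty, 0.0
        s = np.sqrt(lam)
        M = np.eye(self.q) + self.A * np.outer(s, s)
        sign, logdet = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("indefinite capacitance matrix")
        DB = s[:, None] * self.B          # (J, q, p)
        Dc = self.c * s                   # (J, q)
        solB = np.linalg.solve(M, DB)
        solc = np.linalg.solve(M, Dc[..., None])[..., 0]
        XtVX = self.XtX - np.einsum("jqp,jqr->pr", DB, solB)
        XtVy = self.Xty - np.einsum("jqp,jq->p", DB, solc)
        ytVy = self.yty - np.einsum("jq,jq->", Dc, solc)
        return XtVX, XtVy, ytVy, float(logdet.sum())

    def profile(self, lam: np.ndarray):
        """Profiled loglik; beta and sigma^2 at the optimum for given lam."""
        XtVX, XtVy, ytVy, ldV = self._whitened(lam)
        beta = np.linalg.solve(XtVX, XtVy) if self.p else np.zeros(0)
        quad = ytVy - (beta @ XtVy if self.p else 0.0)
        quad = max(quad, 1e-300)
        n, p = self.n, self.p
        if self.method == "reml":
            sigma2 = quad / (n - p)
            _, ldX = np.linalg.slogdet(XtVX)
            ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + ldV + ldX)
        else:
            sigma2 = quad / n
            ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + ldV)
        return ll, beta, sigma2, XtVX

    def profile_grad(self, lam: np.ndarray):
        """Profiled loglik and its analytic gradient w.r.t. lambda.

        Uses the envelope theorem over beta-hat and sigma2-hat; all
        pieces come from the same Woodbury quantities as the likelihood.
        """
        q = self.q
        s = np.sqrt(lam)
        M = np.eye(q) + self.A * np.outer(s, s)
        sign, logdet = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("indefinite capacitance matrix")
        DB = s[:, None] * self.B
        Dc = self.c * s
        solB = np.linalg.solve(M, DB)
        solc = np.linalg.solve(M, Dc[..., None])[..., 0]
        XtVX = self.XtX - np.einsum("jqp,jqr->pr", DB, solB)
        XtVy = self.Xty - np.einsum("jqp,jq->p", DB, solc)
        ytVy = self.yty - np.einsum("jq,jq->", Dc, solc)
        beta = np.linalg.solve(XtVX, XtVy) if self.p else np.zeros(0)
        quad = max(ytVy - (beta @ XtVy if self.p else 0.0), 1e-300)

        # Z' Vbar^-1 Z, Z' Vbar^-1 r and X' Vbar^-1 Z per cluster
        SA = s[:, None] * np.linalg.solve(M, s[:, None] * self.A)   # S A, (J,q,q)
        W = self.A - np.einsum("jqk,jkr->jqr", self.A, SA)          # (J,q,q)
        t = self.c - np.einsum("jqp,p->jq", self.B, beta)
        ztvr = t - np.einsum("jqk,jk->jq", self.A,
                             s * np.linalg.solve(M, (t * s)[..., None])[..., 0])
        G = np.transpose(self.B, (0, 2, 1)) - np.einsum(
            "jpq,jqr->jpr", np.transpose(self.B, (0, 2, 1)), SA)     # X'V^-1 Z, (J,p,q)

        trV = np.einsum("jkk->k", W)                                 # sum_j z_k' V^-1 z_k
        dquad = -np.einsum("jk,jk->k", ztvr, ztvr)
        n, p = self.n, self.p
        if self.method == "reml":
            Cmat = np.linalg.inv(XtVX)
            trX = np.einsum("jpk,pr,jrk->k", G, Cmat, G)
            grad = -0.5 * (trV - trX + (n - p) * dquad / quad)
            sigma2 = quad / (n - p)
            _, ldX = np.linalg.slogdet(XtVX)
            ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                         + float(logdet.sum()) + ldX)
        else:
            grad = -0.5 * (trV + n * dquad / quad)
            sigma2 = quad / n
            ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + float(logdet.sum()))
        return ll, grad

    def loglik_theta(self, tau2: np.ndarray, sigma2: float) -> float:
        """Unprofiled restricted/full loglik at variances (tau^2, sigma^2)."""
        lam = np.asarray(tau2, float) / sigma2
        XtVX, XtVy, ytVy, ldV = self._whitened(lam)
        beta = np.linalg.solve(XtVX, XtVy) if self.p else np.zeros(0)
        quad = ytVy - (beta @ XtVy if self.p else 0.0)
        n, p = self.n, self.p
        if self.method == "reml":
            _, ldX = np.linalg.slogdet(XtVX)
            return -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(sigma2)
                           + ldV + ldX + quad / sigma2)
        return -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + ldV + quad / sigma2)


# ---------------------------------------------------------------------------
# fitting


def fit_lmm(spec: LmmSpec, data, groups: str = "participant",
            alpha: float = 0.05) -> LmmFit:
    """Fit a two-level LMM by profiled REML/ML.  Deterministic.

    With no random terms the model collapses to OLS (fixed effects by
    least squares, residual df for the t tests).
    """
    y, X, names, Z, znames, codes, uniques = _design(spec, data, groups)
    n, p = len(y), X.shape[1]
    q = Z.shape[1]
    eng = _Engine(y, X, Z, codes, spec.method)
    diagnostics: dict = {"boundary_terms": [], "runaway_terms": [],
                         "flat_terms": [], "degenerate_terms": [],
                         "residual_collapse": False}

    # structural check: a random slope on a column with no within-cluster
    # variation anywhere is confounded with cluster-level structure
    for k, t in enumerate(znames):
        if t == INTERCEPT:
            continue
        col = Z[:, k]
        wvar = pd.Series(col).groupby(codes).var(ddof=0)
        if np.all(wvar.fillna(0.0) < 1e-12):
            diagnostics["degenerate_terms"].append(t)

    if q == 0:
        ll, beta, sigma2, XtVX = eng.profile(np.empty(0))
        cov = sigma2 * np.linalg.inv(XtVX)
        dfs = np.full(p, float(n - p))
        converged = True
        lam_hat = np.empty(0)
    else:
        def objective(x):
            lam = np.exp(x)
            try:
                ll, grad = eng.profile_grad(lam)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros(q)
            if not np.isfinite(ll):
                return 1e12, np.zeros(q)
            return -ll, -grad * lam  # chain rule onto the log scale

        x0 = np.zeros(q)
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                bounds=[(_LOG_LB, _LOG_UB)] * q,
                                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 1000})
        # Newton polish on the analytic score: quasi-Newton termination
        # leaves O(1e-6) error in the variance ratios, which is visible
        # in the mediation vs moderation equivalence check
        res.x = _newton_polish(objective, np.clip(res.x, _LOG_LB, _LOG_UB))
        # near-flat ridges (a variance heading to zero) can defeat both
        # the quasi-Newton run and the Newton polish; coordinate-wise
        # bounded Brent sweeps are slow but unconditionally robust
        for _ in range(4):
            f0, g0 = objective(res.x)
            interior = [k for k in range(q) if _LOG_LB + 1.0 < res.x[k] < _LOG_UB - 1.0]
            if not interior or np.abs(g0[interior]).max() < 1e-9:
                break
            for k in interior:
                def slice_f(t, k=k):
                    xt = res.x.copy()
                    xt[k] = t
                    return objective(xt)[0]
                br = optimize.minimize_scalar(slice_f, bounds=(_LOG_LB, _LOG_UB),
                                              method="bounded",
                                              options={"xatol": 1e-10})
                if br.fun < f0:
                    res.x[k] = br.x
                    f0 = br.fun
            res.x = _newton_polish(objective, res.x)
        lam_hat = np.exp(res.x)
        ll, beta, sigma2, XtVX = eng.profile(lam_hat)
        # judge convergence by the final score, not the optimizer's own
        # flag: the polish steps can reach the optimum after an
        # "abnormal" quasi-Newton line search
        _, g_final = objective(res.x)
        interior = [k for k in range(q) if _LOG_LB + 1.0 < res.x[k] < _LOG_UB - 1.0]
        grad_ok = (not interior
                   or np.abs(np.asarray(g_final)[interior]).max() < 1e-6)
        converged = bool(res.success or grad_ok)
        diagnostics["optimizer_message"] = str(res.message)

        yvar = float(np.var(y)) or 1.0
        if sigma2 < 1e-10 * yvar:
            diagnostics["residual_collapse"] = True
            converged = False
        diagnostics["boundary_terms"] = [znames[k] for k in range(q)
                                         if lam_hat[k] <= BOUNDARY_TOL]
        diagnostics["runaway_terms"] = [znames[k] for k in range(q)
                                        if lam_hat[k] >= _RUNAWAY]
        if diagnostics["runaway_terms"]:
            converged = False
        if converged:
            diagnostics["flat_terms"] = _flat_terms(eng, res.x, lam_hat, znames)

        cov = sigma2 * np.linalg.inv(XtVX)
        if converged:
            dfs = _satterthwaite(eng, lam_hat, sigma2, cov, znames)
            dfs = np.clip(dfs, 1.0, float(n - p))
        else:
            dfs = np.full(p, np.nan)

    se = np.sqrt(np.diag(cov)) if p else np.empty(0)
    tvals = beta / se if p else np.empty(0)
    if converged:
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, dfs)
        lo, hi = beta - tcrit * se, beta + tcrit * se
    else:
        pvals = np.full(p, np.nan)
        lo = hi = np.full(p, np.nan)

    params = pd.DataFrame(
        {"Estimate": beta, "SE": se, "df": dfs, "t": tvals, "p": pvals,
         "CI Lower": lo, "CI Upper": hi},
        index=pd.Index(names, name="term"),
    )
    vc = {znames[k]: float(lam_hat[k] * sigma2) for k in range(q)}
    blups = _blups(eng, lam_hat, beta, znames, names, uniques, params) if (q and converged) else None

    return LmmFit(
        params=params, variance_components=vc, residual_variance=float(sigma2),
        loglik=float(ll), method=spec.method, n_obs=n, n_clusters=len(uniques),
        converged=converged, spec=spec, blups=blups, diagnostics=diagnostics,
    )


def _newton_polish(objective, x, max_steps: int = 12) -> np.ndarray:
    """Safeguarded Newton refinement on interior coordinates.

    ``objective`` returns (f, grad).  Coordinates at or past the box
    bounds are left untouched; interior ones are polished with Newton
    steps (Hessian from finite differences of the analytic gradient)
    until the score is ~0 or the step stalls.
    """
    interior = [k for k in range(len(x)) if _LOG_LB + 1.0 < x[k] < _LOG_UB - 1.0]
    if not interior:
        return x
    h = 1e-6
    f0, g0 = objective(x)
    for _ in range(max_steps):
        gi = g0[interior]
        if np.abs(gi).max() < 1e-11:
            break
        m = len(interior)
        H = np.zeros((m, m))
        for a in range(m):
            xp = x.copy(); xp[interior[a]] += h
            _, gp = objective(xp)
            H[:, a] = (gp[interior] - gi) / h
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, gi)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        norm = np.abs(step).max()
        if norm > 1.0:
            step = step / norm  # trust region: log-scale steps <= 1
        trial = x.copy()
        trial[interior] -= step
        trial = np.clip(trial, _LOG_LB, _LOG_UB)
        f1, g1 = objective(trial)
        if f1 <= f0 + 1e-9:
            x, f0, g0 = trial, f1, g1
        else:
            break
    return x


def _flat_terms(eng: _Engine, xopt, lam_hat, znames) -> list[str]:
    """Random terms lying on a flat ridge of the profiled likelihood.

    A near-zero curvature direction of the profiled loglik (in log-
    variance coordinates, away from the boundary) means the variances
    are not separately identified — e.g. two random-slope columns that
    are proportional within every cluster.
    """
    active = [k for k in range(len(xopt))
              if BOUNDARY_TOL < lam_hat[k] < _RUNAWAY]
    if not active:
        return []
    h = 1e-4
    m = len(active)
    H = np.zeros((m, m))

    def score(x):
        try:
            ll, g = eng.profile_grad(np.exp(x))
        except np.linalg.LinAlgError:
            return np.full(len(x), np.nan)
        return g * np.exp(x)  # d loglik / d log lambda

    g0 = score(xopt)
    for a in range(m):
        xp = xopt.copy(); xp[active[a]] += h
        H[:, a] = (score(xp)[active] - g0[active]) / h
    H = 0.5 * (H + H.T)
    curv = -H
    if not np.all(np.isfinite(curv)):
        return []
    evals, evecs = np.linalg.eigh(curv)
    flat = []
    for i, ev in enumerate(evals):
        if ev < max(1e-6 * abs(evals).max(), 1e-5):
            k = active[int(np.argmax(np.abs(evecs[:, i])))]
            flat.append(znames[k])
    return flat


def _satterthwaite(eng: _Engine, lam_hat, sigma2, cov, znames) -> np.ndarray:
    """Satterthwaite dfs: 2 * C_ii^2 / Var(C_ii), with the delta method
    over the (non-boundary) variance components and the inverse observed
    REML/ML information for Var(theta_hat)."""
    active = [k for k in range(len(lam_hat)) if lam_hat[k] > BOUNDARY_TOL]
    theta = np.array([lam_hat[k] * sigma2 for k in active] + [sigma2])
    m = len(theta)
    p = eng.p

    def covdiag(th):
        lam = np.zeros(len(lam_hat))
        for i, k in enumerate(active):
            lam[k] = th[i] / th[-1]
        XtVX, *_ = eng._whitened(lam)
        return th[-1] * np.diag(np.linalg.inv(XtVX))

    def ll(th):
        if np.any(th[:-1] < 0) or th[-1] <= 0:
            return -1e12
        tau2 = np.zeros(len(lam_hat))
        for i, k in enumerate(active):
            tau2[k] = th[i]
        try:
            return eng.loglik_theta(tau2, th[-1])
        except np.linalg.LinAlgError:
            return -1e12

    steps = np.maximum(1e-5 * np.abs(theta), 1e-10)
    grad = np.zeros((m, p))
    for i in range(m):
        tp = theta.copy(); tp[i] += steps[i]
        tm = theta.copy(); tm[i] = max(tm[i] - steps[i], 1e-12)
        grad[i] = (covdiag(tp) - covdiag(tm)) / (tp[i] - tm[i])

    H = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            ha, hb = steps[a], steps[b]
            tpp = theta.copy(); tpp[a] += ha; tpp[b] += hb
            tpm = theta.copy(); tpm[a] += ha; tpm[b] -= hb
            tmp = theta.copy(); tmp[a] -= ha; tmp[b] += hb
            tmm = theta.copy(); tmm[a] -= ha; tmm[b] -= hb
            H[a, b] = H[b, a] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * ha * hb)
    try:
        vtheta = np.linalg.inv(-H)
        if np.any(np.diag(vtheta) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # information matrix not usable; fall back to residual-style df
        return np.full(p, float(eng.n - eng.p))

    cdiag = np.diag(cov)
    dfs = np.empty(p)
    for i in range(p):
        g = grad[:, i]
        denom = float(g @ vtheta @ g)
        dfs[i] = 2.0 * cdiag[i] ** 2 / denom if denom > 0 else eng.n - eng.p
    return dfs


def _blups(eng: _Engine, lam_hat, beta, znames, fixed_names, uniques, params) -> pd.DataFrame:
    """Per-cluster realized coefficients: fixed estimate + BLUP."""
    s = np.sqrt(lam_hat)
    M = np.eye(eng.q) + eng.A * np.outer(s, s)
    t = eng.c - np.einsum("jqp,p->jq", eng.B, beta)          # Z' r per cluster
    inner = np.linalg.solve(M, (t * s)[..., None])[..., 0] * s
    ztvr = t - np.einsum("jqk,jk->jq", eng.A, inner)
    u = lam_hat * ztvr                                        # (J, q)
    base = np.array([
        params.loc["Intercept", "Estimate"] if (t_ == INTERCEPT and "Intercept" in params.index)
        else (params.loc[t_, "Estimate"] if t_ in params.index else 0.0)
        for t_ in znames
    ])
    return pd.DataFrame(u + base, index=pd.Index(uniques, name="participant"),
                        columns=znames)


# ---------------------------------------------------------------------------
# pruning and model comparison


def prune_random_effects(spec: LmmSpec, data, groups: str = "participant"):
    """Iteratively remove unsupported random terms, one per round.

    Removal order within a round: the term implicated by the failure
    (a runaway/degenerate term confounded with the residual, a flat
    ridge direction, a boundary variance), else the smallest-variance
    term.  Terminates with a converging spec; every removal is logged.

    Returns ``(final_spec, log, final_fit)``.
    """
    log: list[dict] = []
    current = spec
    for _ in range(len(spec.random_terms) + 1):
        fit = fit_lmm(current, data, groups=groups)
        d = fit.diagnostics
        term, reason = None, None
        if d.get("degenerate_terms"):
            term, reason = d["degenerate_terms"][0], "no within-cluster variation (confounded with cluster structure)"
        elif d.get("runaway_terms"):
            term, reason = d["runaway_terms"][0], "estimation failure: variance ratio diverged (confounded with residual)"
        elif d.get("residual_collapse"):
            lams = {t: fit.variance_components.get(t, 0.0) for t in current.random_terms}
            term = max(lams, key=lams.get)
            reason = "estimation failure: residual variance collapsed"
        elif d.get("flat_terms"):
            term, reason = d["flat_terms"][0], "estimation failure: variance not identified (flat likelihood ridge)"
        elif d.get("boundary_terms"):
            bterms = d["boundary_terms"]
            term = min(bterms, key=lambda t: fit.variance_components.get(t, 0.0))
            reason = f"variance estimate at boundary (ratio <= {BOUNDARY_TOL:g})"
        elif not fit.converged:
            if current.random_terms:
                term = min(current.random_terms,
                           key=lambda t: fit.variance_components.get(t, np.inf))
                reason = "optimizer failed to converge"
        if term is None:
            fit.pruned = log
            return current, log, fit
        log.append({"term": term, "reason": reason})
        current = current.without(term)
    fit = fit_lmm(current, data, groups=groups)
    fit.pruned = log
    return current, log, fit


def information_criteria(spec: LmmSpec, data, groups: str = "participant",
                         label: str | None = None) -> dict:
    """One model-comparison entry: ML loglik, parameter count and BIC.

    Always refits under ML (BIC under REML is not comparable across
    fixed structures); BIC = -2*loglik_ML + n_params * ln(n_obs) with
    n_params = fixed effects + variance components incl. residual.
    """
    ml_spec = replace(spec, method="ml")
    try:
        fit = fit_lmm(ml_spec, data, groups=groups)
        usable = fit.converged
    except Exception:  # estimation blew up entirely
        return {"model": label or _spec_label(spec), "usable": False,
                "loglik_ml": None, "n_params": None, "bic": None}
    k = fit.n_params
    bic = -2.0 * fit.loglik + k * np.log(fit.n_obs)
    return {"model": label or _spec_label(spec), "usable": usable,
            "loglik_ml": float(fit.loglik), "n_params": int(k), "bic": float(bic)}


def _spec_label(spec: LmmSpec) -> str:
    r = "+".join(spec.random_terms) or "none"
    return f"{spec.outcome}~{'+'.join(spec.fixed_terms)} (random: {r})"


@dataclass
class ModelComparison:
    """BIC comparison of two nested specifications (ML-based)."""

    entries: list[dict]

    @property
    def usable(self) -> bool:
        return all(e["usable"] for e in self.entries)

    @property
    def delta_bic(self) -> float | None:
        """Worse minus better BIC (positive by construction)."""
        if not self.usable:
            return None
        bics = [e["bic"] for e in self.entries]
        return float(max(bics) - min(bics))

    @property
    def preferred(self) -> str | None:
        if not self.usable:
            return None
        return min(self.entries, key=lambda e: e["bic"])["model"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_dict(self) -> dict:
        return {"entries": self.entries, "delta_bic": self.delta_bic,
                "preferred": self.preferred, "usable": self.usable}
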