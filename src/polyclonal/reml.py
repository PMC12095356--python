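"""Univariate linear mixed models for clone-evaluation trials, fitted by REML.

Model
-----
For one trait, the plot-level multi-year averages ``y`` follow

    y = X b + Z u + e,      u ~ N(0, G),  e ~ N(0, s2_e I),

with fixed effects ``b`` (overall mean and resolvable-replicate effects) and
independent random factors stacked in ``u``: clone (genotypic) effects,
rows within replicates and columns within replicates, each with covariance
``s2_i I``.  Variance components are estimated by restricted maximum
likelihood; clone effects are predicted by their empirical BLUPs, whose
prediction error variances (PEV) yield a generalized broad-sense
heritability

    H2 = sum_j (1 - PEV_j / s2_g) / t,   t = rank(I - C_gg / s2_g),

where ``C_gg`` is the prediction-error covariance matrix of the genotypic
effects.  All computations go through Henderson's mixed-model equations with
cross-products assembled once per data set, so each likelihood evaluation
costs one Cholesky factorization of a (p+q) x (p+q) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trial import TrialTable

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "CloneMixedModel",
    "MixedModelResults",
    "HeritabilityReport",
    "remlrt_sigma_g",
    "eblup_direct_dense",
]

_RANDOM_FACTORS = ("genotype", "row", "col")


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_components=None):
        super().__init__(message)
        self.last_components = last_components


class DegenerateModelError(ValueError):
    """The model has no variance to work with (e.g. constant data)."""


class UndefinedHeritabilityError(ValueError):
    """H2 is undefined because the genotypic variance is zero."""


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the mixed model for one trait.

    The genotype term is always first among the random factors.  Row/column
    terms (and the replicate fixed effect) can be dropped for small test
    models or for reduced fits in likelihood-ratio tests.
    """

    trait: str
    include_replicate: bool = True
    include_genotype: bool = True
    include_row: bool = True
    include_col: bool = True

    @property
    def random_factors(self) -> tuple[str, ...]:
        out = []
        if self.include_genotype:
            out.append("genotype")
        if self.include_row:
            out.append("row")
        if self.include_col:
            out.append("col")
        return tuple(out)

    def drop_genotype(self) -> "ModelSpec":
        return ModelSpec(self.trait, self.include_replicate, False,
                         self.include_row, self.include_col)


@dataclass
class VarianceComponents:
    """REML variance-component estimates (trait units squared)."""

    sigma2_g: float = 0.0
    sigma2_row: float = 0.0
    sigma2_col: float = 0.0
    sigma2_e: float = 0.0
    standard_errors: dict[str, float] = field(default_factory=dict)
    at_boundary: set[str] = field(default_factory=set)

    def __getitem__(self, factor: str) -> float:
        return {"genotype": self.sigma2_g, "row": self.sigma2_row,
                "col": self.sigma2_col, "residual": self.sigma2_e}[factor]

    def as_dict(self) -> dict[str, float]:
        return {"genotype": self.sigma2_g, "row": self.sigma2_row,
                "col": self.sigma2_col, "residual": self.sigma2_e}


class CloneMixedModel:
    """Mixed model for one trait of an aggregated trial table.

    Parameters
    ----------
    table : TrialTable
        Aggregated table (one record per experimental unit).  Units with a
        missing value for `spec.trait` are dropped for this trait only.
    spec : ModelSpec or str
        Model specification, or just the trait name for the default model
        (replicate fixed; genotype, row and column random).

    Examples
    --------
    >>> res = CloneMixedModel(table, "YD").fit()
    >>> res.components.sigma2_g, res.h2, res.cv_g   # doctest: +SKIP
    """

    def __init__(self, table: TrialTable, spec: ModelSpec | str):
        if isinstance(spec, str):
            spec = ModelSpec(trait=spec)
        if spec.trait not in table.traits:
            raise ValueError(f"trait {spec.trait!r} not in table traits {table.traits}")
        self.spec = spec
        df = table.data.loc[table.data[spec.trait].notna()].reset_index(drop=True)
        if len(df) < 2:
            raise DegenerateModelError("need at least 2 observations with data")
        if spec.include_genotype and df["clone"].nunique() < 2:
            raise DegenerateModelError("need at least 2 clones with data")
        self.data = df
        self.endog = df[spec.trait].to_numpy(float)
        self.nobs = len(df)
        self.overall_mean = float(self.endog.mean())
        self._build_design()
        self._precompute()

    # -- design matrices ----------------------------------------------------
    def _build_design(self) -> None:
        df, spec = self.data, self.spec
        n = self.nobs
        Xcols = [np.ones(n)]
        self.exog_names = ["intercept"]
        reps = sorted(df["rep"].unique())
        if spec.include_replicate and len(reps) > 1:
            for r in reps[1:]:
                Xcols.append((df["rep"] == r).to_numpy(float))
                self.exog_names.append(f"rep[{r}]")
        X = np.column_stack(Xcols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient fixed-effects design")
        self.exog = X

        self.random_levels: dict[str, list] = {}
        Zblocks = []
        for name in spec.random_factors:
            if name == "genotype":
                labels = df["clone"]
            elif name == "row":
                labels = df["rep"].astype(str) + ":" + df["row"].astype(str)
            else:
                labels = df["rep"].astype(str) + ":" + df["col"].astype(str)
            levels = sorted(labels.unique())
            idx = pd.Categorical(labels, categories=levels).codes
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), idx] = 1.0
            self.random_levels[name] = levels
            Zblocks.append(Z)
        self.Zblocks = Zblocks
        self.clone_labels = self.random_levels.get("genotype", [])

    def _precompute(self) -> None:
        W = np.column_stack([self.exog] + self.Zblocks) if self.Zblocks else self.exog
        self.W = W
        self.WtW = W.T @ W
        self.Wty = W.T @ self.endog
        self.yty = float(self.endog @ self.endog)
        self.p = self.exog.shape[1]
        self.q_sizes = [Z.shape[1] for Z in self.Zblocks]
        self.q = int(sum(self.q_sizes))
        # index slices of each random block inside the MME system
        self.slices = []
        start = self.p
        for q_i in self.q_sizes:
            self.slices.append(slice(start, start + q_i))
            start += q_i

    # -- restricted likelihood machinery ------------------------------------
    def _mme_matrix(self, gammas: np.ndarray) -> np.ndarray:
        M = self.WtW.copy()
        for sl, g in zip(self.slices, gammas):
            M[sl, sl] += np.eye(sl.stop - sl.start) / g
        return M

    def _profiled_m2ll(self, log_gammas: np.ndarray, grad: bool = False):
        """-2 * restricted log-likelihood, profiled over s2_e, plus gradient.

        With variance ratios g_i = s2_i / s2_e and M the MME coefficient
        matrix times s2_e,

            -2 l_R = (n-p) log(2 pi) + (n-p)(1 + log(S/(n-p)))
                     + sum_i q_i log g_i + log|M|,

        where S = y'y - b'M^{-1}b with b = W'y.
        """
        gammas = np.exp(log_gammas)
        M = self._mme_matrix(gammas)
        try:
            cf = linalg.cho_factor(M, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return (np.inf, np.zeros_like(log_gammas)) if grad else np.inf
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        sol = linalg.cho_solve(cf, self.Wty, check_finite=False)
        S = self.yty - float(self.Wty @ sol)
        nmp = self.nobs - self.p
        if S <= 0:
            S = max(S, 1e-300)
        f = (nmp * (np.log(2 * np.pi) + 1.0 + np.log(S / nmp))
             + float(np.dot(self.q_sizes, log_gammas)) + logdet)
        if not grad:
            return f
        Minv = linalg.cho_solve(cf, np.eye(M.shape[0]), check_finite=False)
        g = np.empty_like(log_gammas)
        for j, (sl, q_i, gam) in enumerate(zip(self.slices, self.q_sizes, gammas)):
            tr = float(np.trace(Minv[sl, sl]))
            u2 = float(sol[sl] @ sol[sl])
            g[j] = q_i - tr / gam - nmp * u2 / (gam * S)
        return f, g

    def _m2ll_variances(self, sig2: np.ndarray) -> float:
        """-2 restricted log-likelihood at explicit variance components.

        ``sig2`` holds (s2 per random factor ..., s2_e), unprofiled; used for
        numeric standard errors of the REML estimates.
        """
        s2e = sig2[-1]
        if s2e <= 0 or np.any(sig2[:-1] <= 0):
            return np.inf
        gammas = sig2[:-1] / s2e
        M = self._mme_matrix(gammas)
        try:
            cf = linalg.cho_factor(M, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        sol = linalg.cho_solve(cf, self.Wty, check_finite=False)
        S = self.yty - float(self.Wty @ sol)
        nmp = self.nobs - self.p
        return (nmp * np.log(2 * np.pi) + nmp * np.log(s2e)
                + float(np.dot(self.q_sizes, np.log(gammas))) + logdet + S / s2e)

    # -- fitting -------------------------------------------------------------
    def fit(self, maxiter: int = 500, compute_se: bool = True) -> "MixedModelResults":
        """Estimate variance components by REML and solve the MME.

        Deterministic given the data and spec.  Components whose estimate
        lands on the lower boundary (below ``1e-10`` times the phenotypic
        variance) are reported as 0 with a boundary flag.
        """
        var_y = float(np.var(self.endog, ddof=1)) if self.nobs > 1 else 0.0
        if var_y <= 0:
            # constant data: all variance components 0, intercept = the value
            comps = VarianceComponents(sigma2_e=0.0,
                                       at_boundary=set(self.spec.random_factors) | {"residual"})
            return self._degenerate_results(comps)
        if not self.Zblocks:
            return self._fixed_only_results()

        k = len(self.Zblocks)
        best = None
        for start in ([0.0] * k, [np.log(0.1)] * k):
            res = optimize.minimize(
                self._profiled_m2ll, np.asarray(start), jac=True, args=(True,),
                method="L-BFGS-B", bounds=[(-30.0, 30.0)] * k,
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        # simplex polish guards against premature L-BFGS-B termination
        polish = optimize.minimize(
            self._profiled_m2ll, best.x, args=(False,), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if polish.fun < best.fun:
            best = polish
        # Newton polish on the analytic gradient: the profiled likelihood is
        # too flat near the optimum for function-value-based line searches
        x = self._newton_polish(best.x)
        if not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed", None)

        gammas = np.exp(np.clip(x, -30.0, 30.0))
        M = self._mme_matrix(gammas)
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        sol = linalg.cho_solve(cf, self.Wty, check_finite=False)
        S = self.yty - float(self.Wty @ sol)
        s2e = S / (self.nobs - self.p)
        sig2 = {name: float(g * s2e) for name, g in zip(self.spec.random_factors, gammas)}

        floor = 1e-10 * var_y
        boundary = {name for name, v in sig2.items() if v < floor}
        comps = VarianceComponents(
            sigma2_g=0.0 if "genotype" in boundary else sig2.get("genotype", 0.0),
            sigma2_row=0.0 if "row" in boundary else sig2.get("row", 0.0),
            sigma2_col=0.0 if "col" in boundary else sig2.get("col", 0.0),
            sigma2_e=float(s2e),
            at_boundary=boundary,
        )
        log_reml = -0.5 * self._profiled_m2ll(np.log(np.maximum(gammas, 1e-300)))
        if compute_se:
            comps.standard_errors = self._component_ses(comps)
        return self.solve(comps, log_reml=float(log_reml))

    def _newton_polish(self, x: np.ndarray, max_steps: int = 8) -> np.ndarray:
        """Drive the analytic gradient of the profiled -2 log-lik to zero.

        Interior optima only: components near the log-ratio bounds are left
        where the bounded optimizer put them.
        """
        if np.any(np.abs(x) > 25.0):
            return x
        k = len(x)
        _, g = self._profiled_m2ll(x, grad=True)
        best_x, best_norm = x.copy(), np.linalg.norm(g)
        h = 1e-5
        for _ in range(max_steps):
            if best_norm < 1e-10:
                break
            J = np.empty((k, k))
            for i in range(k):
                e = np.zeros(k)
                e[i] = h
                _, gp = self._profiled_m2ll(best_x + e, grad=True)
                _, gm = self._profiled_m2ll(best_x - e, grad=True)
                J[:, i] = (gp - gm) / (2 * h)
            try:
                step = np.linalg.solve(J, -np.asarray(
                    self._profiled_m2ll(best_x, grad=True)[1]))
            except np.linalg.LinAlgError:
                break
            cand = best_x + np.clip(step, -1.0, 1.0)
            if np.any(np.abs(cand) > 29.0):
                break
            _, g_new = self._profiled_m2ll(cand, grad=True)
            norm = np.linalg.norm(g_new)
            if not np.isfinite(norm) or norm >= best_norm:
                break
            best_x, best_norm = cand, norm
        return best_x

    def _component_ses(self, comps: VarianceComponents) -> dict[str, float]:
        """Asymptotic SEs from the numerically differentiated information matrix.

        Components on the zero boundary are held out (structurally zero); the
        observed information is built over the interior components only, so
        boundary components get no SE (NaN).
        """
        sig2 = comps.as_dict()
        active = [f for f in self.spec.random_factors if f not in comps.at_boundary]
        sub = self._submodel(active)
        theta = np.array([sig2[f] for f in active] + [comps.sigma2_e])
        names = active + ["residual"]
        k = len(theta)
        H = np.empty((k, k))
        h = np.maximum(1e-4 * np.abs(theta), 1e-12)
        f0 = sub._m2ll_variances(theta)

        def f(v):
            return sub._m2ll_variances(v)

        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            for j in range(i):
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = 2.0 * np.linalg.inv(H)
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            ses = np.full(k, np.nan)
        out = {name: np.nan for name in self.spec.random_factors}
        out.update(dict(zip(names, ses)))
        return out

    def _submodel(self, active: list[str]) -> "CloneMixedModel":
        """Shallow copy restricted to the given random factors."""
        sub = CloneMixedModel.__new__(CloneMixedModel)
        sub.__dict__.update(self.__dict__)
        keep = [i for i, f in enumerate(self.spec.random_factors) if f in active]
        sub.Zblocks = [self.Zblocks[i] for i in keep]
        sub._precompute()
        return sub

    # -- solving at fixed components -----------------------------------------
    def solve(self, components: VarianceComponents,
              log_reml: float | None = None) -> "MixedModelResults":
        """Solve Henderson's mixed-model equations at fixed variance components.

        Returns EBLUEs of the fixed effects, EBLUPs of every random factor and
        the genotype prediction-error-variance matrix ``C_gg``.  Random
        factors with a zero variance component get zero EBLUPs and zero PEV
        (complete shrinkage).
        """
        s2e = components.sigma2_e
        sig2 = components.as_dict()
        if s2e <= 0 and all(sig2[f] <= 0 for f in self.spec.random_factors):
            raise DegenerateModelError("zero total variance")
        if s2e <= 0:
            raise DegenerateModelError("zero residual variance is not supported")

        active = [f for f in self.spec.random_factors if sig2[f] > 0]
        # assemble the MME over fixed effects + active random blocks
        cols = [self.exog]
        act_slices, act_sizes = [], []
        start = self.exog.shape[1]
        for name, Z in zip(self.spec.random_factors, self.Zblocks):
            if name in active:
                cols.append(Z)
                act_slices.append(slice(start, start + Z.shape[1]))
                act_sizes.append(Z.shape[1])
                start += Z.shape[1]
        W = np.column_stack(cols)
        M = W.T @ W
        for name, sl in zip(active, act_slices):
            M[sl, sl] += np.eye(sl.stop - sl.start) * (s2e / sig2[name])
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        sol = linalg.cho_solve(cf, W.T @ self.endog, check_finite=False)

        eblue = pd.Series(sol[: self.p], index=self.exog_names)
        eblups: dict[str, pd.Series] = {}
        for name in self.spec.random_factors:
            levels = self.random_levels[name]
            if name in active:
                sl = act_slices[active.index(name)]
                eblups[name] = pd.Series(sol[sl], index=levels)
            else:
                eblups[name] = pd.Series(np.zeros(len(levels)), index=levels)

        pev_matrix = None
        genotype_pev = None
        if "genotype" in self.spec.random_factors:
            q1 = len(self.clone_labels)
            if "genotype" in active:
                sl = act_slices[active.index("genotype")]
                Minv_block = linalg.cho_solve(
                    cf, np.eye(M.shape[0])[:, sl], check_finite=False)[sl, :]
                pev_matrix = s2e * Minv_block
            else:
                pev_matrix = np.zeros((q1, q1))
            genotype_pev = pd.Series(np.diag(pev_matrix).copy(), index=self.clone_labels)

        if log_reml is None:
            log_reml = self._log_reml_at(components, active)
        return MixedModelResults(
            model=self, components=components, eblue=eblue, eblups=eblups,
            genotype_pev=genotype_pev, pev_matrix=pev_matrix,
            log_reml=float(log_reml),
        )

    def _log_reml_at(self, components: VarianceComponents, active: list[str]) -> float:
        sig2 = components.as_dict()
        if not active:
            return self._fixed_only_loglik(components.sigma2_e)
        # evaluate on the active blocks only (zero components drop out of V)
        sub = self._submodel(active)
        return -0.5 * sub._m2ll_variances(
            np.array([sig2[f] for f in active] + [components.sigma2_e]))

    def _fixed_only_loglik(self, s2e: float) -> float:
        X = self.exog
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ self.endog)
        resid = self.endog - X @ beta
        nmp = self.nobs - self.p
        return -0.5 * (nmp * np.log(2 * np.pi) + nmp * np.log(s2e)
                       + np.linalg.slogdet(XtX)[1] + float(resid @ resid) / s2e)

    def _fixed_only_results(self) -> "MixedModelResults":
        X = self.exog
        beta = np.linalg.solve(X.T @ X, X.T @ self.endog)
        resid = self.endog - X @ beta
        nmp = self.nobs - self.p
        s2e = float(resid @ resid) / nmp
        comps = VarianceComponents(sigma2_e=s2e)
        return MixedModelResults(
            model=self, components=comps,
            eblue=pd.Series(beta, index=self.exog_names), eblups={},
            genotype_pev=None, pev_matrix=None,
            log_reml=self._fixed_only_loglik(s2e),
        )

    def _degenerate_results(self, comps: VarianceComponents) -> "MixedModelResults":
        eblups = {name: pd.Series(np.zeros(len(levels)), index=levels)
                  for name, levels in self.random_levels.items()}
        q1 = len(self.clone_labels)
        pev_matrix = np.zeros((q1, q1)) if "genotype" in self.random_levels else None
        genotype_pev = (pd.Series(np.zeros(q1), index=self.clone_labels)
                        if pev_matrix is not None else None)
        eblue = pd.Series(np.zeros(self.p), index=self.exog_names)
        eblue.iloc[0] = self.overall_mean
        return MixedModelResults(model=self, components=comps, eblue=eblue,
                                 eblups=eblups, genotype_pev=genotype_pev,
                                 pev_matrix=pev_matrix, log_reml=np.nan)


@dataclass
class HeritabilityReport:
    """Generalized heritability and related variability measures for one trait."""

    h2: float
    t_rank: int
    cv_g: float
    remlrt_stat: float | None = None
    remlrt_p: float | None = None


@dataclass
class MixedModelResults:
    """REML fit of a `CloneMixedModel`: components, EBLUEs, EBLUPs, PEVs."""

    model: CloneMixedModel
    components: VarianceComponents
    eblue: pd.Series
    eblups: dict[str, pd.Series]
    genotype_pev: pd.Series | None
    pev_matrix: np.ndarray | None
    log_reml: float

    # -- convenience accessors ----------------------------------------------
    @property
    def trait(self) -> str:
        return self.model.spec.trait

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def overall_mean(self) -> float:
        return self.model.overall_mean

    @property
    def genotype_eblups(self) -> pd.Series:
        if "genotype" not in self.eblups:
            raise ValueError("model has no genotype term")
        return self.eblups["genotype"]

    # -- heritability and variability ----------------------------------------
    @property
    def t_rank(self) -> int:
        """Numerical rank of I - C_gg / s2_g (effective dimension of contrasts)."""
        s2g = self.components.sigma2_g
        if s2g <= 0:
            raise UndefinedHeritabilityError("s2_g = 0: heritability undefined")
        A = np.eye(self.pev_matrix.shape[0]) - self.pev_matrix / s2g
        sv = np.linalg.svd(A, compute_uv=False)
        return int((sv > 1e-8 * sv[0]).sum()) if sv[0] > 0 else 0

    @property
    def h2(self) -> float:
        """Generalized broad-sense heritability, mean of 1 - PEV_j/s2_g over rank t."""
        s2g = self.components.sigma2_g
        if s2g <= 0:
            raise UndefinedHeritabilityError("s2_g = 0: heritability undefined")
        num = float((1.0 - self.genotype_pev.to_numpy() / s2g).sum())
        t = self.t_rank
        if t == 0:  # PEV = s2_g for every clone: no information at all
            return 0.0
        return num / t

    @property
    def cv_g(self) -> float:
        """Coefficient of genotypic variation, 100 * s_g / overall mean (%)."""
        return 100.0 * np.sqrt(max(self.components.sigma2_g, 0.0)) / self.overall_mean

    def heritability(self) -> HeritabilityReport:
        return HeritabilityReport(h2=self.h2, t_rank=self.t_rank, cv_g=self.cv_g)

    def test_genotypic_variance(self) -> HeritabilityReport:
        """Likelihood-ratio test of H0: s2_g = 0 against the fitted model.

        Refits the model without the genotype term on the same observations
        and refers twice the restricted log-likelihood difference to a
        chi-square with one degree of freedom (conservative convention for a
        boundary hypothesis).
        """
        reduced = CloneMixedModel(
            TrialTable(self.model.data, traits=[self.trait]),
            self.model.spec.drop_genotype(),
        ).fit(compute_se=False)
        stat, p = remlrt_sigma_g(self, reduced)
        try:
            rep = self.heritability()
        except UndefinedHeritabilityError:
            rep = HeritabilityReport(h2=np.nan, t_rank=0, cv_g=self.cv_g)
        rep.remlrt_stat, rep.remlrt_p = stat, p
        return rep

    # -- reporting ------------------------------------------------------------
    def eblup_frame(self) -> pd.DataFrame:
        """Clone EBLUPs with PEV and EBLUP as % of the overall mean."""
        e = self.genotype_eblups
        return pd.DataFrame({
            "clone": e.index,
            "eblup": e.to_numpy(),
            "pev": self.genotype_pev.to_numpy(),
            "eblup_pct_of_mean": 100.0 * e.to_numpy() / self.overall_mean,
        })

    def summary(self) -> str:
        c = self.components
        se = c.standard_errors
        lines = [
            f"Mixed model REML fit - trait {self.trait}",
            "=" * 44,
            f"observations          {self.nobs}",
            f"clones                {len(self.model.clone_labels)}",
            f"overall mean          {self.overall_mean:.4f}",
            f"log restricted lik.   {self.log_reml:.4f}",
            "",
            "variance components (SE):",
        ]
        for name, val in c.as_dict().items():
            if name != "residual" and name not in self.model.spec.random_factors:
                continue
            s = se.get(name, np.nan)
            flag = "  [boundary]" if name in c.at_boundary else ""
            lines.append(f"  {name:<10} {val:12.6g}  ({s:.3g}){flag}")
        if c.sigma2_g > 0:
            lines += [
                "",
                f"CV_G                  {self.cv_g:.2f} %",
                f"H2 (generalized)      {self.h2:.3f}",
            ]
        return "\n".join(lines)


def remlrt_sigma_g(fit_full: MixedModelResults,
                   fit_reduced: MixedModelResults) -> tuple[float, float]:
    """REML likelihood-ratio test of a genotypic variance component.

    ``fit_reduced`` must be the same model without the genotype term on the
    identical observations.  The statistic ``2 (lR_full - lR_reduced)`` is
    clamped at 0 and referred to a chi-square with 1 degree of freedom.
    """
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("fits use different observation sets")
    yf = np.sort(fit_full.model.endog)
    yr = np.sort(fit_reduced.model.endog)
    if not np.allclose(yf, yr, rtol=0, atol=1e-12):
        raise ValueError("fits use different observation sets")
    stat = max(0.0, 2.0 * (fit_full.log_reml - fit_reduced.log_reml))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


def eblup_direct_dense(model: CloneMixedModel,
                       components: VarianceComponents) -> dict[str, pd.Series]:
    """Reference EBLUPs through the direct dense-V formula.

    Computes ``u = G Z' V^{-1} (y - X b)`` with ``b`` the generalized
    least-squares EBLUE, building the full n x n marginal covariance
    ``V = Z G Z' + s2_e I``.  O(n^3); used to cross-check the Henderson-route
    solution.
    """
    s2e = components.sigma2_e
    sig2 = components.as_dict()
    n = model.nobs
    V = s2e * np.eye(n)
    for name, Z in zip(model.spec.random_factors, model.Zblocks):
        V += sig2[name] * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    X, y = model.exog, model.endog
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = y - X @ beta
    out = {}
    for name, Z in zip(model.spec.random_factors, model.Zblocks):
        u = sig2[name] * (Z.T @ (Vinv @ resid))
        out[name] = pd.Series(u, index=model.random_levels[name])
    return out
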