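"""Binomial presence model: cyclic diel smoother, tide/season factors,
per-individual intercepts.

The response is hourly presence/absence of a behaviour (headshaking, the
foraging proxy) on the logit scale:

.. math::

    \\mathrm{logit}\\,P(\\text{present}_{it}) = \\beta_0 + f(\\text{hour}_t)
        + \\beta_{\\text{tide}(t)} + \\beta_{\\text{season}(t)} + b_i

where :math:`f` is a cyclic cubic spline with period 24 h (so
:math:`f(0) = f(24)`), tide phase (reference Ebb) and season (reference
wet) are dummy-coded factors, and :math:`b_i` is a per-individual
intercept.  The individual intercepts are realised as a ridge-penalised
block — the standard mixed-model representation of a Gaussian random
intercept — so the fit is a penalised IRLS with block penalty

.. math:: S = \\lambda_s S_{\\text{spline}} \\oplus \\lambda_b I_{\\text{id}},

with both smoothing parameters chosen by a Laplace-approximate restricted
marginal likelihood over a log-spaced grid.  Pointwise 95% bands come from
the Bayesian posterior covariance :math:`(X'WX + S)^{-1}`.

Model comparison follows the field convention for this analysis: candidate
covariate sets are ranked by log-likelihood (closest to zero best).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.gam.smooth_basis import CyclicCubicSplines

TIDE_LEVELS = ("Ebb", "Flood", "High", "Low")
SEASON_LEVELS = ("wet", "dry")

#: the standard candidate covariate sets for model selection
DEFAULT_CANDIDATES = (
    ("hour", "tide", "season"),
    ("hour", "season"),
    ("hour", "tide"),
    ("hour",),
    ("tide", "season"),
    ("tide",),
    ("season",),
)


def _sigmoid(eta):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class PresenceModelResult:
    """Fit results: coefficients, smoother curve, diagnostics.

    Attributes
    ----------
    params, bse, zvalues : pandas.Series
        Parametric coefficients (intercept and factor levels) with
        standard errors and Wald z statistics.
    smoother : pandas.DataFrame or None
        Fitted diel curve on a fine hour grid (columns ``hour, fit, lo,
        hi``; logit scale, centred).  ``fit`` at hour 0 equals hour 24.
    edf_smoother : float
        Effective degrees of freedom of the hour smoother.
    random_intercept_var : float
        Empirical variance of the estimated per-individual intercepts.
    llf : float
        Binomial log-likelihood at the fit (non-positive).
    """

    model: "PresenceModel"
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    smoother: pd.DataFrame | None
    edf_smoother: float
    edf_total: float
    random_intercepts: pd.Series
    random_intercept_var: float
    llf: float
    marginal_llf: float
    deviance: float
    null_deviance: float
    rsquared_adj: float
    lambdas: dict = field(default_factory=dict)
    _beta: np.ndarray = None
    _cov: np.ndarray = None

    @property
    def formula(self) -> tuple[str, ...]:
        return self.model.formula

    def smoother_at(self, hours) -> np.ndarray:
        """Centred smoother value (logit scale) at hour-of-day, period 24."""
        if self.model._spline_slice is None:
            raise ValueError("model has no hour smoother")
        hours = np.mod(np.asarray(hours, dtype=float), 24.0)
        B = self.model._spline.transform(hours[:, None])
        return B @ self._beta[self.model._spline_slice]

    def peak_hour(self, resolution: float = 0.1) -> float:
        """Hour of day at which the fitted diel curve peaks."""
        if self.smoother is None:
            raise ValueError("model has no hour smoother")
        grid = np.arange(0.0, 24.0, resolution)
        return float(grid[np.argmax(self.smoother_at(grid))])

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Fitted presence probability for new hourly records."""
        X = self.model._design_for(records)
        return _sigmoid(X @ self._beta)

    def summary(self) -> str:
        lines = [
            "Binomial presence model (logit link)",
            f"  terms: {' + '.join(self.formula)}"
            + (" + individual intercepts" if self.model.random_intercept else ""),
            f"  observations: {self.model.nobs}, individuals: {self.model.n_individuals}",
            f"  log-likelihood (marginal): {self.marginal_llf:.3f}   "
            f"conditional: {self.llf:.3f}   deviance: {self.deviance:.3f}",
            f"  adj. R-squared: {self.rsquared_adj:.4f}",
            "",
            "Parametric coefficients:",
        ]
        tab = pd.DataFrame(
            {"coef": self.params, "SE": self.bse, "z": self.zvalues}
        ).round(3)
        lines.append(tab.to_string())
        if self.smoother is not None:
            lines += [
                "",
                f"Smoother s(hour): edf {self.edf_smoother:.2f}, "
                f"peak at {self.peak_hour():.1f} h",
            ]
        if self.model.random_intercept:
            lines.append(
                f"Individual intercept variance: {self.random_intercept_var:.4f}"
            )
        return "\n".join(lines)

    def plot_smoother(self, ax=None):
        """Plot the fitted diel curve with its 95% band (logit scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.smoother
        ax.plot(s["hour"], s["fit"], color="k")
        ax.fill_between(s["hour"], s["lo"], s["hi"], alpha=0.3, color="grey")
        ax.set_xlabel("hour of day")
        ax.set_ylabel("effect on logit presence")
        return ax


class PresenceModel:
    """Penalised binomial GAMM for hourly behaviour presence.

    Parameters
    ----------
    records : pandas.DataFrame
        Hourly records with columns ``present`` (bool/0-1) and, as needed
        by the formula, ``hour_of_day`` (0–23), ``tide_phase``
        (Ebb/Low/Flood/High), ``season`` (wet/dry) and ``shark_id``.
    formula : sequence of {"hour", "tide", "season"}
        Covariates to include; ``hour`` enters as a cyclic smoother.
    df_hour : int
        Basis dimension of the cyclic cubic spline (default 8).
    random_intercept : bool
        Include ridge-penalised per-individual intercepts (default True).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        formula=("hour", "tide", "season"),
        df_hour: int = 8,
        random_intercept: bool = True,
    ) -> None:
        self.records = records.reset_index(drop=True)
        self.formula = tuple(formula)
        unknown = set(self.formula) - {"hour", "tide", "season"}
        if unknown:
            raise ValueError(f"unknown model terms {sorted(unknown)}")
        self.df_hour = df_hour
        self.random_intercept = bool(random_intercept)
        self.y = self.records["present"].to_numpy(dtype=float)
        if self.y.min() == self.y.max():
            raise ValueError("presence outcome has a single level; nothing to model")
        self.nobs = len(self.y)
        if self.random_intercept:
            self.individuals = tuple(pd.unique(self.records["shark_id"]))
            if len(self.individuals) < 2:
                raise ValueError("random intercepts need at least two individuals")
        else:
            self.individuals = ()
        self.n_individuals = len(self.individuals)
        self._build_design()

    # -- design ------------------------------------------------------------
    def _build_design(self) -> None:
        rec = self.records
        cols = [np.ones((self.nobs, 1))]
        names = ["Intercept"]
        self._spline = None
        self._spline_slice = None
        if "hour" in self.formula:
            hours = rec["hour_of_day"].to_numpy(dtype=float)
            # augment the fitting domain with 0 and 24 so the cyclic
            # constraint enforces f(0) == f(24) (period 24 h)
            aug = np.r_[hours, 0.0, 24.0]
            self._spline = CyclicCubicSplines(aug[:, None], df=[self.df_hour],
                                              constraints="center")
            basis = self._spline.transform(hours[:, None])
            start = sum(c.shape[1] for c in cols)
            self._spline_slice = slice(start, start + basis.shape[1])
            cols.append(basis)
            names += [f"s(hour).{k}" for k in range(basis.shape[1])]
        self._factor_names = []
        if "tide" in self.formula:
            tide = pd.Categorical(rec["tide_phase"], categories=TIDE_LEVELS)
            if tide.isna().any():
                raise ValueError("tide_phase outside Ebb/Flood/High/Low")
            d = pd.get_dummies(tide, drop_first=True).to_numpy(dtype=float)
            cols.append(d)
            self._factor_names += [f"tide[{c}]" for c in TIDE_LEVELS[1:]]
        if "season" in self.formula:
            season = pd.Categorical(rec["season"], categories=SEASON_LEVELS)
            if season.isna().any():
                raise ValueError("season outside wet/dry")
            d = pd.get_dummies(season, drop_first=True).to_numpy(dtype=float)
            cols.append(d)
            self._factor_names += ["season[dry]"]
        names += self._factor_names
        self._id_slice = None
        if self.random_intercept:
            ids = pd.Categorical(rec["shark_id"], categories=self.individuals)
            d = pd.get_dummies(ids).to_numpy(dtype=float)
            start = sum(c.shape[1] for c in cols)
            self._id_slice = slice(start, start + d.shape[1])
            cols.append(d)
            names += [f"id[{i}]" for i in self.individuals]
        self.exog = np.hstack(cols)
        self.exog_names = names

    def _design_for(self, records: pd.DataFrame) -> np.ndarray:
        """Design matrix for new records (unknown individuals get b = 0)."""
        rec = records
        cols = [np.ones((len(rec), 1))]
        if "hour" in self.formula:
            hours = np.mod(rec["hour_of_day"].to_numpy(dtype=float), 24.0)
            cols.append(self._spline.transform(hours[:, None]))
        if "tide" in self.formula:
            tide = pd.Categorical(rec["tide_phase"], categories=TIDE_LEVELS)
            cols.append(pd.get_dummies(tide, drop_first=True).to_numpy(dtype=float))
        if "season" in self.formula:
            season = pd.Categorical(rec["season"], categories=SEASON_LEVELS)
            cols.append(pd.get_dummies(season, drop_first=True).to_numpy(dtype=float))
        if self.random_intercept:
            ids = pd.Categorical(rec["shark_id"], categories=self.individuals)
            d = pd.get_dummies(ids).to_numpy(dtype=float)
            cols.append(d)
        return np.hstack(cols)

    def _penalty(self, lam_s: float, lam_b: float) -> np.ndarray:
        p = self.exog.shape[1]
        S = np.zeros((p, p))
        if self._spline_slice is not None:
            S[self._spline_slice, self._spline_slice] = (
                lam_s * self._spline.penalty_matrices[0]
            )
        if self._id_slice is not None:
            idx = np.arange(self._id_slice.start, self._id_slice.stop)
            S[idx, idx] = lam_b
        return S

    # -- fitting -----------------------------------------------------------
    def _pirls(self, S: np.ndarray, max_iter: int = 100, tol: float = 1e-9):
        X, y = self.exog, self.y
        mu = (y + 0.5) / 2.0
        eta = np.log(mu / (1 - mu))
        beta = np.zeros(X.shape[1])
        for _ in range(max_iter):
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            XtW = X.T * w
            H = XtW @ X + S
            new_beta = np.linalg.solve(H, XtW @ z)
            if np.max(np.abs(new_beta - beta)) < tol:
                beta = new_beta
                eta = X @ beta
                break
            beta = new_beta
            eta = X @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X.T * w) @ X + S
        return beta, eta, mu, H, (X.T * w) @ X

    def _loglik(self, mu: np.ndarray) -> float:
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(self.y * np.log(mu) + (1 - self.y) * np.log(1 - mu)))

    def _reml(self, lam_s: float, lam_b: float) -> float:
        """Laplace-approximate restricted marginal likelihood (to maximise)."""
        S = self._penalty(lam_s, lam_b)
        beta, _, mu, H, _ = self._pirls(S)
        ll = self._loglik(mu)
        pen = 0.5 * beta @ S @ beta
        _, logdet_h = np.linalg.slogdet(H)
        logdet_s = 0.0
        if self._spline_slice is not None:
            eig = np.linalg.eigvalsh(self._spline.penalty_matrices[0])
            pos = eig[eig > 1e-10 * eig.max()]
            logdet_s += pos.size * np.log(lam_s) + np.sum(np.log(pos))
        if self._id_slice is not None:
            nb = self._id_slice.stop - self._id_slice.start
            logdet_s += nb * np.log(lam_b)
        return ll - pen + 0.5 * logdet_s - 0.5 * logdet_h

    def fit(
        self,
        lambda_smooth: float | None = None,
        lambda_id: float | None = None,
        smooth_grid: np.ndarray | None = None,
        id_grid: np.ndarray | None = None,
    ) -> PresenceModelResult:
        """Fit the model, selecting penalties by the marginal-likelihood grid.

        Either penalty can be pinned by passing ``lambda_smooth`` /
        ``lambda_id`` explicitly.
        """
        need_s = self._spline_slice is not None and lambda_smooth is None
        need_b = self._id_slice is not None and lambda_id is None
        s_grid = (
            np.geomspace(1e-2, 1e4, 10) if smooth_grid is None else np.asarray(smooth_grid)
        ) if need_s else np.array([lambda_smooth if lambda_smooth is not None else 0.0])
        b_grid = (
            np.geomspace(1e-2, 1e2, 7) if id_grid is None else np.asarray(id_grid)
        ) if need_b else np.array([lambda_id if lambda_id is not None else 0.0])
        best, best_score = (s_grid[0], b_grid[0]), -np.inf
        if need_s or need_b:
            for ls in s_grid:
                for lb in b_grid:
                    score = self._reml(max(ls, 1e-12), max(lb, 1e-12))
                    if score > best_score:
                        best_score, best = score, (ls, lb)
        lam_s, lam_b = best
        S = self._penalty(lam_s if self._spline_slice is not None else 0.0,
                          lam_b if self._id_slice is not None else 0.0)
        beta, eta, mu, H, XtWX = self._pirls(S)

        factor_idx = [self.exog_names.index(n) for n in ["Intercept"] + self._factor_names]
        if np.max(np.abs(beta[factor_idx])) > 10:
            warnings.warn(
                "quasi-separation detected in parametric terms; refitting with a "
                "small ridge penalty on the parametric block",
                stacklevel=2,
            )
            S = S.copy()
            S[factor_idx, factor_idx] += 1e-2
            beta, eta, mu, H, XtWX = self._pirls(S)

        Hinv = np.linalg.inv(H)
        cov = Hinv  # Bayesian posterior covariance
        edf_mat = Hinv @ XtWX
        edf_total = float(np.trace(edf_mat))
        edf_smoother = (
            float(np.trace(edf_mat[self._spline_slice, self._spline_slice]))
            if self._spline_slice is not None
            else 0.0
        )
        params = pd.Series(beta[factor_idx], index=["Intercept"] + self._factor_names)
        bse = pd.Series(np.sqrt(np.diag(cov))[factor_idx], index=params.index)
        zvals = params / bse

        smoother = None
        if self._spline_slice is not None:
            grid = np.linspace(0.0, 24.0, 241)
            B = self._spline.transform(np.mod(grid, 24.0)[:, None])
            fit_vals = B @ beta[self._spline_slice]
            cov_s = cov[self._spline_slice, self._spline_slice]
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov_s, B), 0.0))
            smoother = pd.DataFrame(
                {"hour": grid, "fit": fit_vals, "lo": fit_vals - 1.96 * se,
                 "hi": fit_vals + 1.96 * se}
            )

        if self._id_slice is not None:
            rint = pd.Series(beta[self._id_slice], index=[str(i) for i in self.individuals])
        else:
            rint = pd.Series(dtype=float)
        llf = self._loglik(mu)
        # Laplace-approximate marginal log-likelihood (random effects and
        # smoother integrated out) — the likelihood mixed-model software
        # reports, and the one on which candidate models are compared
        marginal_llf = self._reml(
            max(lam_s, 1e-12) if self._spline_slice is not None else 1e-12,
            max(lam_b, 1e-12) if self._id_slice is not None else 1e-12,
        )
        dev = -2.0 * llf
        p0 = self.y.mean()
        null_dev = -2.0 * float(
            np.sum(self.y * np.log(p0) + (1 - self.y) * np.log(1 - p0))
        )
        explained = 1.0 - dev / null_dev
        n = self.nobs
        rsq_adj = 1.0 - (1.0 - explained) * (n - 1) / max(n - edf_total - 1, 1)
        return PresenceModelResult(
            model=self,
            params=params,
            bse=bse,
            zvalues=zvals,
            smoother=smoother,
            edf_smoother=edf_smoother,
            edf_total=edf_total,
            random_intercepts=rint,
            random_intercept_var=float(rint.var(ddof=0)) if len(rint) else 0.0,
            llf=llf,
            marginal_llf=float(marginal_llf),
            deviance=dev,
            null_deviance=null_dev,
            rsquared_adj=rsq_adj,
            lambdas={"smooth": float(lam_s), "id": float(lam_b)},
            _beta=beta,
            _cov=cov,
        )


def fit_presence_model(
    records: pd.DataFrame,
    formula=("hour", "tide", "season"),
    **kwargs,
) -> PresenceModelResult:
    """Convenience wrapper: build and fit a :class:`PresenceModel`."""
    return PresenceModel(records, formula=formula, **kwargs).fit()


def select_model(
    candidates=DEFAULT_CANDIDATES,
    records: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit candidate covariate sets and rank them by log-likelihood.

    Ranking uses the marginal log-likelihood (closest to zero best), the
    likelihood a mixed-model fit reports; the conditional value is also
    tabulated.  Returns ``(table, results)``: a DataFrame sorted
    best-first with columns ``formula, llf, conditional_llf, edf, rank``,
    and a dict mapping formula strings to their
    :class:`PresenceModelResult`.  Candidates whose fit fails are excluded
    with a warning.
    """
    if records is None:
        raise ValueError("records are required")
    if len(candidates) < 1:
        raise ValueError("at least one candidate formula is required")
    rows, results = [], {}
    for formula in candidates:
        key = " + ".join(formula)
        try:
            res = PresenceModel(records, formula=formula, **kwargs).fit()
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            warnings.warn(f"candidate {key!r} failed to fit: {exc}", stacklevel=2)
            continue
        rows.append({"formula": key, "llf": res.marginal_llf,
                     "conditional_llf": res.llf, "edf": res.edf_total})
        results[key] = res
    out = pd.DataFrame(rows).sort_values("llf", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out, results
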