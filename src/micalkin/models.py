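"""Model objects for apparent Michaelis-Menten and global activator fits.

The interface follows the convention of statistical modelling packages: a
model object is constructed from data, ``fit()`` returns a results object
carrying estimates, standard errors, residual diagnostics and a ``summary()``
table, and nested fits are compared with an extra-sum-of-squares F-test via
``results.compare_f_test(restricted)``.

Two models are provided:

* :class:`MichaelisMentenModel` — velocities at a single activator level,
  fitted to v = E * k_cat_app * S / (K_M_app + S);
* :class:`NonEssentialActivatorModel` — the full condition grid fitted
  simultaneously to the five-parameter rapid-equilibrium rate law, optionally
  with the coupling factor alpha fixed (e.g. alpha = 1, the no-coupling
  hypothesis that the F-test interrogates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assay import AssayDataset
from .kinetics import _rate

__all__ = [
    "MichaelisMentenModel",
    "NonEssentialActivatorModel",
    "KineticFitResults",
    "FTestResult",
    "extra_ss_f_test",
    "apparent_constants_table",
]

_LSQ_OPTS = dict(method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)

ALPHA_BOUNDS = (1e-3, 1e3)
BETA_BOUNDS = (0.0, 1e3)
POS_BOUNDS = (1e-9, 1e9)


@dataclass(frozen=True)
class FTestResult:
    """Extra-sum-of-squares F-test between nested least-squares fits."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float

    def __str__(self) -> str:
        return (
            f"F({self.df_num}, {self.df_den}) = {self.f_statistic:.4g}, "
            f"p = {self.p_value:.4g}"
        )


class KineticFitResults:
    """Least-squares estimates with Gauss-Newton standard errors.

    Attributes
    ----------
    params : pandas.Series
        Point estimates, indexed by parameter name (fixed parameters are
        included with their fixed value).
    bse : pandas.Series
        Standard errors from (JᵀJ)⁻¹ · rss/dof at the optimum; NaN for fixed
        parameters.
    rss, dof, nobs : float, int, int
        Residual sum of squares, residual degrees of freedom, data points.
    converged : bool
    model_tag : str
        One of ``MM_apparent``, ``global_alpha_free``, ``global_alpha_fixed``.
    """

    def __init__(self, model, params, bse, rss, dof, nobs, converged, model_tag,
                 fixed=(), fingerprint=None):
        self.model = model
        self.params = pd.Series(params)
        self.bse = pd.Series(bse)
        self.rss = float(rss)
        self.dof = int(dof)
        self.nobs = int(nobs)
        self.converged = bool(converged)
        self.model_tag = str(model_tag)
        self.fixed = tuple(fixed)
        self._fingerprint = fingerprint

    @property
    def n_free(self) -> int:
        return len(self.params) - len(self.fixed)

    @property
    def s2(self) -> float:
        """Residual variance estimate rss/dof."""
        return self.rss / self.dof

    def conf_int(self, nsig: float = 2.0) -> pd.DataFrame:
        lo = self.params - nsig * self.bse
        hi = self.params + nsig * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def compare_f_test(self, restricted: "KineticFitResults") -> FTestResult:
        """Extra-sum-of-squares F-test with ``self`` as the full model."""
        return extra_ss_f_test(restricted, self)

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "estimates": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: (None if np.isnan(v) else float(v))
                                for k, v in self.bse.items()},
            "rss": self.rss,
            "dof": self.dof,
            "nobs": self.nobs,
            "converged": self.converged,
            "fixed": list(self.fixed),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [
            f"Model: {self.model_tag}",
            f"N obs: {self.nobs}   RSS: {self.rss:.6g}   dof: {self.dof}   "
            f"converged: {self.converged}",
            f"{'parameter':<10} {'estimate':>12} {'std err':>12}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            tag = " (fixed)" if name in self.fixed else ""
            se_s = f"{se:12.5g}" if np.isfinite(se) else "           -"
            lines.append(f"{name:<10} {self.params[name]:12.5g} {se_s}{tag}")
        return "\n".join(lines)


def extra_ss_f_test(restricted: KineticFitResults, full: KineticFitResults,
                    rtol: float = 1e-8) -> FTestResult:
    """Compare nested least-squares fits on the same data.

    F = ((RSS_r - RSS_f)/(dof_r - dof_f)) / (RSS_f/dof_f) referred to the
    F(dof_r - dof_f, dof_f) distribution.  The restricted model must have
    strictly fewer free parameters and be fitted to the same dataset.
    """
    if restricted.nobs != full.nobs:
        raise ValueError("fits have different numbers of observations; not the same dataset")
    if (restricted._fingerprint is not None and full._fingerprint is not None
            and restricted._fingerprint != full._fingerprint):
        raise ValueError("fits were made on different datasets")
    if restricted.dof <= full.dof:
        raise ValueError("restricted model must have more residual dof than the full model")
    tol = rtol * max(1.0, full.rss)
    if full.rss > restricted.rss + tol:
        raise ValueError(
            "full-model RSS exceeds restricted-model RSS; models are not nested "
            "or a fit failed"
        )
    df_num = restricted.dof - full.dof
    df_den = full.dof
    num = max(restricted.rss - full.rss, 0.0) / df_num
    den = full.rss / df_den
    f = num / den
    p = float(stats.f.sf(f, df_num, df_den))
    return FTestResult(f_statistic=float(f), df_num=df_num, df_den=df_den, p_value=p)


def _prepare(data, enzyme_conc):
    df = data.data if isinstance(data, AssayDataset) else pd.DataFrame(data)
    S = df["substrate_uM"].to_numpy(dtype=float)
    v = df["velocity_uM_per_s"].to_numpy(dtype=float)
    if "enzyme_uM" in df.columns:
        E = df["enzyme_uM"].to_numpy(dtype=float)
    elif enzyme_conc is not None:
        E = np.full_like(S, float(enzyme_conc))
    else:
        raise ValueError("enzyme concentration required (column enzyme_uM or enzyme_conc=)")
    A = df["activator_uM"].to_numpy(dtype=float) if "activator_uM" in df.columns else np.zeros_like(S)
    return df, S, A, E, v


def _fingerprint(S, A, E, v):
    h = np.round(np.concatenate([S, A, E, v]), 12)
    return hash((len(S), h.tobytes()))


def _gauss_newton_se(jac, rss, dof):
    """SEs from the Gauss-Newton covariance (JᵀJ)⁻¹ · rss/dof (pinv if singular)."""
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    cov = cov * rss / dof
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


class MichaelisMentenModel:
    """Apparent Michaelis-Menten fit at a single activator level.

    Parameters
    ----------
    data : AssayDataset or DataFrame
        Must carry ``substrate_uM`` and ``velocity_uM_per_s``; the enzyme
        concentration comes from an ``enzyme_uM`` column or ``enzyme_conc``.
    """

    param_names = ("k_cat_app", "K_M_app")

    def __init__(self, data, enzyme_conc: float | None = None):
        self.df, self.S, self.A, self.E, self.v = _prepare(data, enzyme_conc)
        if len(np.unique(self.S)) < 3:
            raise ValueError("need >= 3 distinct substrate levels")
        a_levels = np.unique(self.A)
        if len(a_levels) > 1:
            raise ValueError(
                "data span multiple activator levels; slice one level first "
                "(AssayDataset.slice_activator)"
            )
        self.activator_conc = float(a_levels[0])

    @classmethod
    def from_dataset(cls, dataset: AssayDataset, activator_conc: float):
        return cls(dataset.slice_activator(activator_conc))

    def predict(self, params, S=None):
        kc, km = params
        S = self.S if S is None else np.asarray(S, dtype=float)
        return self.E * kc * S / (km + S)

    def fit(self) -> KineticFitResults:
        """Least-squares fit of (k_cat_app, K_M_app), seeded from the data.

        Initial k_cat is max(v)/E; initial K_M is the substrate level whose
        velocity is nearest half the maximum.  Non-convergence (including a
        K_M running into its bound, as happens when velocities carry no
        substrate dependence) is reported through ``converged``, never as an
        exception.
        """
        vmax = self.v.max()
        kc0 = max(vmax / self.E.mean(), 1e-9)
        km0 = self.S[np.argmin(np.abs(self.v - vmax / 2.0))]
        km0 = max(km0, 1e-3)

        def resid(x):
            return self.predict(x) - self.v

        best = None
        for scale in (1.0, 0.3, 3.0):
            x0 = np.array([kc0, km0 * scale])
            try:
                res = optimize.least_squares(
                    resid, x0, bounds=([POS_BOUNDS[0]] * 2, [POS_BOUNDS[1]] * 2),
                    **_LSQ_OPTS)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        nobs = len(self.v)
        dof = nobs - 2
        if dof <= 0:
            raise ValueError("fewer data points than parameters")
        if best is None:
            nan = {n: np.nan for n in self.param_names}
            return KineticFitResults(self, nan, nan, np.nan, dof, nobs, False, "MM_apparent")
        rss = 2.0 * best.cost
        # a K_M far outside the substrate range means the hyperbola is
        # indistinguishable from a constant (K_M -> 0) or a line (K_M -> inf)
        km = best.x[1]
        identified = (self.S.min() * 1e-3) < km < (self.S.max() * 1e3)
        converged = bool(best.success) and identified
        se = _gauss_newton_se(best.jac, rss, dof) if dof > 0 else np.full(2, np.nan)
        return KineticFitResults(
            self,
            dict(zip(self.param_names, best.x)),
            dict(zip(self.param_names, se)),
            rss, dof, nobs, converged, "MM_apparent",
            fingerprint=_fingerprint(self.S, self.A, self.E, self.v),
        )


class NonEssentialActivatorModel:
    """Global fit of the five-parameter rapid-equilibrium activator model.

    Fits (k_cat, K_M, K_act, alpha, beta) simultaneously to velocities over
    the full substrate x activator grid.  ``fit(fix_alpha=1.0)`` yields the
    restricted no-coupling model; comparing it with the free fit by
    :func:`extra_ss_f_test` reproduces the published nested-model inference.

    Parameters
    ----------
    data : AssayDataset or DataFrame
        Tidy replicate table (``substrate_uM, activator_uM, enzyme_uM,
        velocity_uM_per_s``).
    weights : None, 'relative', 'sem' or array
        None (default) fits unweighted.  'relative' weights each point by the
        inverse squared condition-mean velocity — the variance-matched choice
        when velocity errors have constant coefficient of variation, and the
        weighting under which the nested F-test is calibrated for such noise.
        'sem' weights by the inverse squared SEM of the condition (noisy with
        few replicates).  An array gives per-point weights w_i multiplying
        squared residuals.
    """

    param_names = ("k_cat", "K_M", "K_act", "alpha", "beta")

    def __init__(self, data, enzyme_conc: float | None = None, weights=None):
        self.df, self.S, self.A, self.E, self.v = _prepare(data, enzyme_conc)
        a_levels = np.unique(self.A)
        if len(a_levels) < 2 or a_levels.min() > 0:
            raise ValueError("need >= 2 activator levels including 0 "
                             "(beta is unidentifiable otherwise)")
        if len(self.v) <= 5:
            raise ValueError("need more data points than the 5 free parameters")
        self.sqrt_w = self._build_weights(weights)
        self._fp = _fingerprint(self.S, self.A, self.E, self.v)

    @classmethod
    def from_dataset(cls, dataset: AssayDataset, weights=None):
        return cls(dataset, weights=weights)

    def _build_weights(self, weights):
        if weights is None:
            return np.ones_like(self.v)
        if isinstance(weights, str) and weights == "relative":
            df = self.df
            vbar = df.groupby(["substrate_uM", "activator_uM"])["velocity_uM_per_s"].transform("mean")
            vbar = vbar.to_numpy(dtype=float)
            floor = vbar[vbar > 0].min() if (vbar > 0).any() else 1.0
            return 1.0 / np.maximum(vbar, floor)
        if isinstance(weights, str) and weights == "sem":
            df = self.df.copy()
            sem = df.groupby(["substrate_uM", "activator_uM"])["velocity_uM_per_s"].transform("sem")
            if sem.isna().any() or (sem <= 0).any():
                raise ValueError("SEM weighting needs >= 2 replicates with scatter per condition")
            return 1.0 / sem.to_numpy(dtype=float)
        w = np.asarray(weights, dtype=float)
        if w.shape != self.v.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per data point")
        return np.sqrt(w)

    def predict(self, params, S=None, A=None, E=None):
        S = self.S if S is None else np.asarray(S, dtype=float)
        A = self.A if A is None else np.asarray(A, dtype=float)
        E = self.E if E is None else np.asarray(E, dtype=float)
        return _rate(S, A, E, *params)

    def _mm_seed(self) -> np.ndarray:
        """Data-driven starting point from per-level apparent constants."""
        a_levels = np.sort(np.unique(self.A))
        kc0 = km0 = None
        try:
            r0 = MichaelisMentenModel(self.df[np.isclose(self.A, a_levels[0])]).fit()
            if r0.converged:
                kc0, km0 = r0.params["k_cat_app"], r0.params["K_M_app"]
        except ValueError:
            pass
        if kc0 is None or not np.isfinite(kc0) or not np.isfinite(km0):
            kc0 = max(self.v.max() / self.E.mean(), 1e-6)
            km0 = np.median(self.S)
        nz = a_levels[a_levels > 0]
        kact0 = np.median(nz) if len(nz) else 1.0
        # beta seed from the velocity gain at the top activator level
        top = np.isclose(self.A, a_levels[-1])
        base = np.isclose(self.A, a_levels[0])
        gain = self.v[top].mean() / max(self.v[base].mean(), 1e-12)
        beta0 = float(np.clip(2.0 * gain, 1.0, 500.0))
        return np.array([kc0, km0, kact0, 1.0, beta0])

    def fit(self, fix_alpha: float | None = None, n_starts: int = 8,
            seed: int = 0) -> KineticFitResults:
        """Multi-start bounded least squares over the condition grid.

        ``fix_alpha`` pins the coupling factor (alpha = 1 gives the pure
        non-essential-activation null).  ``n_starts`` log-uniform
        perturbations of the data-derived seed guard against local minima;
        1 start with the Michaelis-Menten seed is usually sufficient and much
        faster for simulation studies.
        """
        fixed = ()
        names = list(self.param_names)
        if fix_alpha is not None:
            if not (ALPHA_BOUNDS[0] <= fix_alpha <= ALPHA_BOUNDS[1]):
                raise ValueError(f"fix_alpha outside bounds {ALPHA_BOUNDS}")
            fixed = ("alpha",)
        free_idx = [i for i, n in enumerate(names) if n not in fixed]
        lo_full = np.array([POS_BOUNDS[0], POS_BOUNDS[0], POS_BOUNDS[0],
                            ALPHA_BOUNDS[0], BETA_BOUNDS[0]])
        hi_full = np.array([POS_BOUNDS[1], POS_BOUNDS[1], POS_BOUNDS[1],
                            ALPHA_BOUNDS[1], BETA_BOUNDS[1]])

        def expand(x_free):
            full = np.empty(5)
            full[free_idx] = x_free
            if fix_alpha is not None:
                full[3] = fix_alpha
            return full

        def resid(x_free):
            return self.sqrt_w * (self.predict(expand(x_free)) - self.v)

        base = self._mm_seed()
        if fix_alpha is not None:
            base[3] = fix_alpha
        rng = np.random.default_rng(seed)
        starts = [base[free_idx]]
        for _ in range(max(n_starts - 1, 0)):
            # log-uniform perturbation in [1/3, 3] of each positive seed entry
            fac = np.exp(rng.uniform(np.log(1 / 3), np.log(3), size=5))
            pert = np.clip(base * fac, lo_full + 1e-12, hi_full - 1e-12)
            pert[4] = max(pert[4], 1e-3)
            starts.append(pert[free_idx])

        best = None
        for x0 in starts:
            x0c = np.clip(x0, lo_full[free_idx] + 1e-12, hi_full[free_idx])
            try:
                res = optimize.least_squares(
                    resid, x0c, bounds=(lo_full[free_idx], hi_full[free_idx]),
                    x_scale="jac", **_LSQ_OPTS)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost - 1e-14):
                best = res
        nobs = len(self.v)
        dof = nobs - len(free_idx)
        if dof <= 0:
            raise ValueError("fewer data points than free parameters")
        tag = "global_alpha_free" if fix_alpha is None else "global_alpha_fixed"
        if best is None:
            nan = {n: np.nan for n in names}
            return KineticFitResults(self, nan, nan, np.nan, dof, nobs, False, tag,
                                     fixed=fixed, fingerprint=self._fp)
        rss = 2.0 * best.cost
        se_free = _gauss_newton_se(best.jac, rss, dof)
        full_x = expand(best.x)
        se = np.full(5, np.nan)
        se[free_idx] = se_free
        return KineticFitResults(
            self,
            dict(zip(names, full_x)),
            dict(zip(names, se)),
            rss, dof, nobs, True, tag,
            fixed=fixed, fingerprint=self._fp,
        )


def apparent_constants_table(dataset: AssayDataset) -> pd.DataFrame:
    """Per-activator-level apparent constants and catalytic power.

    Fits the apparent Michaelis-Menten model at each F-actin level of the
    dataset and assembles the report-style table (catalytic power in
    s⁻¹ mM⁻¹).  Failed fits yield NaN rows rather than aborting.
    """
    from .kinetics import catalytic_power

    rows = []
    for a in dataset.activator_levels:
        try:
            r = MichaelisMentenModel.from_dataset(dataset, a).fit()
            kc, km = r.params["k_cat_app"], r.params["K_M_app"]
            kc_se, km_se = r.bse["k_cat_app"], r.bse["K_M_app"]
            power = catalytic_power(kc, km) if r.converged else np.nan
            ok = r.converged
        except ValueError:
            kc = km = kc_se = km_se = power = np.nan
            ok = False
        rows.append({
            "activator_uM": a, "k_cat_app": kc, "k_cat_app_se": kc_se,
            "K_M_app": km, "K_M_app_se": km_se,
            "catalytic_power": power, "converged": ok,
        })
    return pd.DataFrame(rows)
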