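"""Gaussian linear mixed models with posterior-simulation inference.

All space-use analyses share one inferential recipe: fit a Gaussian linear
mixed model by REML, then draw fixed-effect vectors from the flat-prior
approximate joint posterior — a multivariate normal centered at the REML
estimates whose covariance is rescaled by a scaled-inverse-chi-square draw
of the residual variance — and report each coefficient's posterior mean and
2.5%/97.5% quantiles.  A coefficient (or a difference of group-specific
means) is called "significant" when its 95% credible interval excludes
zero.

The model layer is statsmodels ``MixedLM``; what this module adds is the
posterior simulation, credible-interval significance, and group-mean
contrasts built from the fitted design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.formula.api as smf

DEFAULT_N_DRAWS = 5000


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    Parameters
    ----------
    response : response column name.
    transform : "log" (natural log, applied before fitting) or "identity".
    fixed : patsy right-hand-side string for the fixed effects.
    random : grouping-factor column names for independent random
        intercepts.  One factor maps onto a plain grouped fit; two factors
        use a nested parameterization when the second is nested in the
        first, and a crossed (single-group variance-component) fit
        otherwise.
    """

    response: str
    transform: str = "identity"
    fixed: str = "1"
    random: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ValueError("transform must be 'identity' or 'log'")


class MixedPosteriorModel:
    """LMM + posterior simulation, statsmodels-style Model object."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        data = data.copy()
        y = data[spec.response].astype(float)
        if spec.transform == "log":
            if (y <= 0).any():
                bad = int((y <= 0).sum())
                raise ValueError(
                    f"log transform of '{spec.response}': {bad} non-positive values")
            data["_y"] = np.log(y)
        else:
            data["_y"] = y
        if not np.isfinite(data["_y"]).all():
            raise ValueError("non-finite response after transform")
        self.data = data
        self.formula = f"_y ~ {spec.fixed}"
        self._check_design()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     random: list[str] | None = None) -> "MixedPosteriorModel":
        resp, fixed = (s.strip() for s in formula.split("~", 1))
        return cls(data, ModelSpec(response=resp, fixed=fixed, random=random or []))

    def _check_design(self) -> None:
        X = patsy.dmatrix(self.spec.fixed, self.data, return_type="dataframe")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name one aliased column via the smallest R diagonal of a QR
            r = np.linalg.qr(X.to_numpy(), mode="r")
            diag = np.abs(np.diag(r))
            aliased = X.columns[int(np.argmin(diag))]
            raise ValueError(f"singular fixed-effect design; aliased term near '{aliased}'")
        for g in self.spec.random:
            if self.data[g].nunique() < 2:
                raise ValueError(f"random factor '{g}' has fewer than 2 levels")

    def _build(self):
        random = self.spec.random
        if len(random) == 0:
            # no grouping: fall back to a single all-encompassing group with
            # a pinned-to-zero variance is not supported by MixedLM; use OLS
            return smf.ols(self.formula, data=self.data)
        if len(random) == 1:
            return smf.mixedlm(self.formula, data=self.data,
                               groups=self.data[random[0]])
        if len(random) == 2:
            outer, inner = random
            nested = (self.data.groupby(inner)[outer].nunique() <= 1).all()
            if nested:
                vc = {inner: f"0 + C({inner})"}
                return smf.mixedlm(self.formula, data=self.data,
                                   groups=self.data[outer], re_formula="1",
                                   vc_formula=vc)
            ones = pd.Series(np.ones(len(self.data)), index=self.data.index)
            vc = {g: f"0 + C({g})" for g in random}
            return smf.mixedlm(self.formula, data=self.data, groups=ones,
                               vc_formula=vc)
        raise ValueError("at most two random grouping factors supported")

    def fit(self, reml: bool = True) -> "MixedPosteriorResults":
        model = self._build()
        def _cov_ok(f) -> bool:
            c = np.asarray(f.cov_params())[: len(f.model.exog_names),
                                           : len(f.model.exog_names)]
            if not np.isfinite(c).all():
                return False
            eig = np.linalg.eigvalsh((c + c.T) / 2)
            return eig.min() >= -1e-6 * max(np.abs(eig).max(), 1e-300)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if model.__class__.__name__ == "MixedLM":
                fitted = None
                # optimizers occasionally stop at points with an indefinite
                # Hessian; walk the chain until the covariance is usable
                for method in (None, "powell", "cg"):
                    try:
                        cand = (model.fit(reml=reml) if method is None
                                else model.fit(reml=reml, method=method))
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                    fitted = cand
                    if _cov_ok(cand):
                        break
                if fitted is None:
                    raise ValueError("mixed-model fit failed for every optimizer")
            else:
                fitted = model.fit()
        names = list(fitted.model.exog_names)
        if fitted.model.__class__.__name__ == "MixedLM":
            params = pd.Series(np.asarray(fitted.fe_params), index=names)
            cov = pd.DataFrame(
                np.asarray(fitted.cov_params())[: len(names), : len(names)],
                index=names, columns=names)
            scale = float(fitted.scale)
            vcomp = {}
            if fitted.model.k_re > 0 and fitted.model.exog_re is not None:
                try:
                    vcomp[self.spec.random[0]] = float(np.asarray(fitted.cov_re)[0, 0])
                except Exception:
                    pass
            if getattr(fitted, "vcomp", None) is not None and len(fitted.vcomp):
                for nm, v in zip(fitted.model.exog_vc.names, np.asarray(fitted.vcomp)):
                    vcomp[nm] = float(v)
            # at the boundary (all RE variances ~ 0) MixedLM's profiled fixed
            # effects are unreliable; the model degenerates to OLS exactly
            if vcomp and all(v <= max(1e-10 * max(scale, 1e-30), 1e-30)
                             for v in vcomp.values()):
                ols = smf.ols(self.formula, data=self.data).fit()
                params = pd.Series(np.asarray(ols.params), index=names)
                cov = pd.DataFrame(np.asarray(ols.cov_params()), index=names,
                                   columns=names)
                scale = float(ols.scale)
        else:  # OLS
            params = pd.Series(np.asarray(fitted.params), index=names)
            cov = pd.DataFrame(np.asarray(fitted.cov_params()), index=names,
                               columns=names)
            scale = float(fitted.scale)
            vcomp = {}
        df_resid = max(int(len(self.data) - len(names)), 1)
        design_info = fitted.model.data.design_info
        return MixedPosteriorResults(
            model=self, names=names, params=params, cov=cov, scale=scale,
            vcomp=vcomp, df_resid=df_resid, design_info=design_info,
            converged=bool(getattr(fitted, "converged", True)))


@dataclass
class MixedPosteriorResults:
    """REML estimates plus (after simulate_posterior) credible intervals."""

    model: MixedPosteriorModel
    names: list[str]
    params: pd.Series
    cov: pd.DataFrame
    scale: float
    vcomp: dict
    df_resid: int
    design_info: object
    converged: bool = True
    draws: np.ndarray | None = None
    table: pd.DataFrame | None = None

    def simulate_posterior(self, n_draws: int = DEFAULT_N_DRAWS,
                           seed: int | None = None) -> "MixedPosteriorResults":
        """Draw fixed-effect vectors from the approximate flat-prior posterior.

        Per draw: sigma2 ~ scale * df / chisq(df), then
        beta ~ N(beta_hat, cov_hat * sigma2 / scale).  Fills the per-
        coefficient posterior mean, 2.5%/97.5% quantiles and the CI-excludes-
        zero significance flag.
        """
        if n_draws < 1:
            raise ValueError("n_draws must be positive")
        rng = np.random.default_rng(seed)
        covm = self.cov.to_numpy().copy()
        if not np.isfinite(covm).all():
            if self.scale <= 0:  # degenerate fit: no residual variance
                covm = np.zeros_like(covm)
            else:
                raise ValueError("fixed-effect covariance contains non-finite values")
        covm = (covm + covm.T) / 2
        vals, vecs = np.linalg.eigh(covm)
        if vals.min() < -1e-6 * max(np.abs(vals).max(), 1e-300):
            raise ValueError("fixed-effect covariance is not positive semidefinite")
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))  # cov = root @ root.T
        df = self.df_resid
        if self.scale > 0:
            ratio = df / rng.chisquare(df, size=n_draws)
        else:  # zero residual variance: posterior degenerate at the estimate
            ratio = np.ones(n_draws)
        z = rng.standard_normal((n_draws, len(self.names)))
        beta = self.params.to_numpy()[None, :] + np.sqrt(ratio)[:, None] * (z @ root.T)
        self.draws = beta
        lo = np.quantile(beta, 0.025, axis=0)
        hi = np.quantile(beta, 0.975, axis=0)
        mean = beta.mean(axis=0)
        self.table = pd.DataFrame({
            "term": self.names,
            "estimate": self.params.to_numpy(),
            "mean": mean,
            "q2.5": lo,
            "q97.5": hi,
            "significant": (lo > 0) | (hi < 0),
        })
        return self

    def summary(self) -> pd.DataFrame:
        """Coefficient table (posterior mean, 95% CI, significance)."""
        if self.table is None:
            self.simulate_posterior()
        return self.table.copy()

    def cell_design_row(self, cell: dict, covariates: dict | None = None) -> np.ndarray:
        """Design row for one factor cell (continuous covariates at given or
        mean values)."""
        row = {}
        data = self.model.data
        for col in data.columns:
            if col in ("_y",):
                continue
            if cell and col in cell:
                row[col] = cell[col]
            elif covariates and col in covariates:
                row[col] = covariates[col]
            elif pd.api.types.is_numeric_dtype(data[col]):
                row[col] = data[col].mean()
            else:
                row[col] = data[col].iloc[0]
        try:
            (X,) = patsy.build_design_matrices([self.design_info], pd.DataFrame([row]))
        except Exception as exc:
            raise ValueError(f"cell {cell!r} not expressible in the fitted design: {exc}")
        return np.asarray(X)[0]


@dataclass
class GroupContrast:
    cell_a: dict
    cell_b: dict
    mean: float
    q2_5: float
    q97_5: float
    different: bool
    draws: np.ndarray = field(repr=False, default=None)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> MixedPosteriorResults:
    """REML point fit of the Gaussian LMM described by ``spec``."""
    return MixedPosteriorModel(data, spec).fit()


def simulate_posterior(fit: MixedPosteriorResults, n_draws: int = DEFAULT_N_DRAWS,
                       seed: int | None = None) -> MixedPosteriorResults:
    return fit.simulate_posterior(n_draws=n_draws, seed=seed)


def group_contrasts(fit: MixedPosteriorResults, cells: list[tuple[dict, dict]],
                    covariates: dict | None = None) -> list[GroupContrast]:
    """Posterior contrasts of group-specific means.

    Each element of ``cells`` is a pair of factor-cell dicts (A, B); the
    difference of cell means is computed per posterior draw and the pair is
    flagged "different" when the 95% CI of the difference excludes zero.
    """
    if fit.draws is None:
        fit.simulate_posterior()
    out = []
    for cell_a, cell_b in cells:
        la = fit.cell_design_row(cell_a, covariates)
        lb = fit.cell_design_row(cell_b, covariates)
        diff = fit.draws @ (la - lb)
        lo, hi = np.quantile(diff, [0.025, 0.975])
        out.append(GroupContrast(
            cell_a=cell_a, cell_b=cell_b, mean=float(diff.mean()),
            q2_5=float(lo), q97_5=float(hi),
            different=bool(lo > 0 or hi < 0), draws=diff))
    return out


def _drop_constant_terms(terms: list[str], data: pd.DataFrame,
                         cols: list[str]) -> list[str]:
    """Remove formula terms whose underlying column has a single level."""
    keep = []
    for term, col in zip(terms, cols):
        if col is None or data[col].nunique() > 1:
            keep.append(term)
    return keep


def space_use_model_suite(
    seasonal: pd.DataFrame,
    shifts: pd.DataFrame,
    windows: pd.DataFrame,
    steps: pd.DataFrame,
    pressure: pd.DataFrame | None = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | None = None,
    log_pressure_offset: float = 1e-3,
) -> dict[str, MixedPosteriorResults]:
    """Fit and posterior-simulate the full set of space-use models.

    Seven models: the hunting-pressure risk model (when ``pressure`` given);
    per-sex seasonal log home-range size (risk x season BACI); per-sex log
    center shift (risk x 2-level season); moving-window log size and log
    step distance on log pressure, sex, median date and window length.
    Study site and individual enter as random intercepts; a year term is
    included only when more than one year is present.  Models whose data are
    empty after filtering are skipped with a logged reason.
    """
    import logging
    logger = logging.getLogger(__name__)
    results: dict[str, MixedPosteriorResults] = {}
    rng = np.random.default_rng(seed)

    def _seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def _fit(name: str, data: pd.DataFrame, spec: ModelSpec) -> None:
        if len(data) == 0:
            logger.warning("model %s skipped: no data after filters", name)
            return
        try:
            res = MixedPosteriorModel(data, spec).fit()
            res.simulate_posterior(n_draws=n_draws, seed=_seed())
            results[name] = res
        except ValueError as exc:
            logger.warning("model %s skipped: %s", name, exc)

    if pressure is not None:
        from .risk import fit_risk_model
        try:
            results["risk"] = fit_risk_model(pressure, n_draws=n_draws, seed=_seed())
        except ValueError as exc:
            logger.warning("risk model skipped: %s", exc)

    def _year_term(df: pd.DataFrame) -> str:
        return " + C(year)" if "year" in df.columns and df["year"].nunique() > 1 else ""

    if len(seasonal) == 0 or "sex" not in seasonal.columns:
        seasonal = pd.DataFrame(columns=["sex"])
    if len(shifts) == 0 or "sex" not in shifts.columns:
        shifts = pd.DataFrame(columns=["sex", "distance_m"])
    if len(windows) == 0 or "pressure" not in getattr(windows, "columns", []):
        windows = pd.DataFrame(columns=["pressure", "area95_ha"])
    if len(steps) == 0 or "previous_pressure" not in getattr(steps, "columns", []):
        steps = pd.DataFrame(columns=["previous_pressure", "distance_m"])

    for sex in ("F", "M"):
        dat = seasonal[seasonal["sex"] == sex].copy()
        spec = ModelSpec(
            response="area95_ha", transform="log",
            fixed="C(group, Treatment('low')) * C(period, Treatment('pre'))" + _year_term(dat),
            random=["site", "individual"])
        _fit(f"size_{sex}", dat, spec)

        dats = shifts[shifts["sex"] == sex].copy()
        dats = dats[dats["distance_m"] > 0]
        spec = ModelSpec(
            response="distance_m", transform="log",
            fixed="C(group, Treatment('low')) * C(contrast, Treatment('pre_to_early'))" + _year_term(dats),
            random=["site", "individual"])
        _fit(f"shift_{sex}", dats, spec)

    win = windows.copy()
    win = win[win["pressure"].notna() & (win["area95_ha"] > 0)]
    if len(win):
        win["log_pressure"] = np.log(win["pressure"] + log_pressure_offset)
        spec = ModelSpec(
            response="area95_ha", transform="log",
            fixed="log_pressure + C(sex, Treatment('F')) + median_day + window_length"
                  + _year_term(win),
            random=["site", "individual"])
        _fit("window_size", win, spec)

    stp = steps.copy()
    stp = stp[stp["previous_pressure"].notna() & (stp["distance_m"] > 0)]
    if len(stp):
        stp["log_pressure"] = np.log(stp["previous_pressure"] + log_pressure_offset)
        spec = ModelSpec(
            response="distance_m", transform="log",
            fixed="log_pressure + C(sex, Treatment('F')) + median_day + window_length"
                  + _year_term(stp),
            random=["site", "individual"])
        _fit("window_step", stp, spec)

    return results


def results_to_frame(results: dict[str, MixedPosteriorResults]) -> pd.DataFrame:
    """Stack model summaries into one long coefficient table."""
    frames = []
    for name, res in results.items():
        tab = res.summary()
        tab.insert(0, "model", name)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["model", "term", "estimate", "mean",
                                     "q2.5", "q97.5", "significant"])
    return pd.concat(frames, ignore_index=True)
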