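"""Sequential PERMANOVA on distance matrices, with subsample bootstrapping.

Permutational multivariate analysis of variance partitions the total sum of
squared inter-point distances among model terms via Gower's centered matrix
G = -(1/2) J D^2 J.  Terms enter sequentially (Type I): the SS of term k is
tr(H_k G) - tr(H_{k-1} G) for the nested hat matrices of the growing design,
and each pseudo-F tests the term against the full-model residual.  P-values
come from free permutation of the sample labels with the add-one convention,
so p is never exactly zero.

Because roost plots are sampled unevenly per individual, the study design
draws one plot per individual per season, runs the PERMANOVA, and repeats
the draw (1000 times by default), reporting the median pseudo-F with
2.5%/97.5% bounds and the median permutation p per term; a term is declared
significant when its median p falls below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy.spatial.distance import pdist, squareform

DEFAULT_VEG_VARS = [
    "warm_grass_pct", "cool_grass_pct", "bare_ground_pct", "litter_pct",
    "litter_depth_cm", "visual_obstruction",
]

DEFAULT_TERMS = ["risk", "sex", "risk:sex", "date_day"]


def distance_matrix(X: np.ndarray, metric: str = "standardized_euclidean") -> np.ndarray:
    """Pairwise distances between response rows.

    "standardized_euclidean" z-scores each column first (the variables mix
    percentages, centimeters and an obstruction index); "braycurtis"
    operates on the raw non-negative values.
    """
    X = np.asarray(X, dtype=float)
    if metric == "standardized_euclidean":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        return squareform(pdist(Z, metric="euclidean"))
    if metric == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    if metric == "braycurtis":
        if np.any(X < 0):
            raise ValueError("Bray-Curtis requires non-negative values")
        return squareform(pdist(X, metric="braycurtis"))
    raise ValueError(f"unknown distance metric: {metric}")


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis Q of X (H = Q Q^T)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


@dataclass
class PermanovaResults:
    """Per-term df, sequential SS, pseudo-F, R^2 and permutation p."""

    terms: list[str]
    df: np.ndarray
    ss: np.ndarray
    f: np.ndarray
    r2: np.ndarray
    p: np.ndarray
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "term": self.terms, "df": self.df, "ss": self.ss,
            "pseudo_F": self.f, "R2": self.r2, "p": self.p,
        })
        resid = pd.DataFrame({
            "term": ["Residual"], "df": [self.residual_df],
            "ss": [self.residual_ss],
            "pseudo_F": [np.nan], "R2": [self.residual_ss / self.total_ss],
            "p": [np.nan],
        })
        return pd.concat([tab, resid], ignore_index=True)


class Permanova:
    """Distance-matrix PERMANOVA model (adonis-style, sequential SS)."""

    def __init__(
        self,
        data: pd.DataFrame,
        response_cols: list[str] = DEFAULT_VEG_VARS,
        terms: list[str] = DEFAULT_TERMS,
        metric: str = "standardized_euclidean",
        distances: np.ndarray | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.terms = list(terms)
        if distances is not None:
            D = np.asarray(distances, dtype=float)
            if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
                raise ValueError("distance matrix must be symmetric with zero diagonal")
        else:
            D = distance_matrix(self.data[response_cols].to_numpy(), metric)
        if np.allclose(D, 0):
            raise ValueError("constant response matrix: zero total sum of squares")
        self.D = D
        self.G = _gower_center(D)
        # nested designs: intercept, then cumulative term formulas
        self._basis = []
        n = len(self.data)
        self._basis.append(_hat_basis(np.ones((n, 1))))
        for k in range(1, len(self.terms) + 1):
            rhs = " + ".join(self.terms[:k])
            X = np.asarray(patsy.dmatrix("1 + " + rhs, self.data))
            self._basis.append(_hat_basis(X))
        for name in self.terms:
            base = name.split(":")[0]
            if base in self.data.columns and self.data[base].nunique() < 2:
                raise ValueError(f"term '{name}': factor with a single level")

    def _term_traces(self, G: np.ndarray) -> np.ndarray:
        """tr(H_k G) for each nested design (including intercept-only)."""
        return np.array([np.sum(Q * (G @ Q)) for Q in self._basis])

    def fit(self, n_perm: int = 999, seed: int | None = None) -> PermanovaResults:
        n = self.G.shape[0]
        total = float(np.trace(self.G))
        tr = self._term_traces(self.G)
        ss = np.diff(tr)
        df = np.array([self._basis[k + 1].shape[1] - self._basis[k].shape[1]
                       for k in range(len(self.terms))])
        if np.any(df < 1):
            raise ValueError("a term adds no degrees of freedom (aliased)")
        resid_df = n - self._basis[-1].shape[1]
        resid_ss = total - float(ss.sum())
        if resid_df < 1:
            raise ValueError("saturated design: no residual degrees of freedom")
        f_obs = (ss / df) / (resid_ss / resid_df)

        rng = np.random.default_rng(seed)
        count = np.zeros(len(self.terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = self.G[np.ix_(perm, perm)]
            trp = self._term_traces(Gp)
            ssp = np.diff(trp)
            residp = total - float(ssp.sum())
            fp = (ssp / df) / (residp / resid_df)
            count += fp >= f_obs
        p = (1.0 + count) / (1.0 + n_perm)
        return PermanovaResults(
            terms=list(self.terms), df=df, ss=ss, f=f_obs,
            r2=ss / total, p=p, residual_df=int(resid_df),
            residual_ss=float(resid_ss), total_ss=total, n_permutations=n_perm)


def permanova(
    data: pd.DataFrame,
    response_cols: list[str] = DEFAULT_VEG_VARS,
    terms: list[str] = DEFAULT_TERMS,
    metric: str = "standardized_euclidean",
    n_perm: int = 999,
    seed: int | None = None,
    distances: np.ndarray | None = None,
) -> PermanovaResults:
    """One sequential PERMANOVA (see :class:`Permanova`)."""
    return Permanova(data, response_cols, terms, metric, distances).fit(
        n_perm=n_perm, seed=seed)


@dataclass
class BootPermanovaResults:
    """Subsample-bootstrap summary: median F and p with quantile bounds."""

    terms: list[str]
    f_median: np.ndarray
    f_q2_5: np.ndarray
    f_q97_5: np.ndarray
    p_median: np.ndarray
    p_q2_5: np.ndarray
    p_q97_5: np.ndarray
    significant: np.ndarray
    n_iterations: int
    f_draws: np.ndarray = field(repr=False, default=None)
    p_draws: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "F_median": self.f_median,
            "F_q2.5": self.f_q2_5,
            "F_q97.5": self.f_q97_5,
            "p_median": self.p_median,
            "p_q2.5": self.p_q2_5,
            "p_q97.5": self.p_q97_5,
            "significant": self.significant,
        })


MODEL_SELECTORS = {
    "pre": lambda df: (df["plot_type"] == "roost") & (df["season"] == "pre"),
    "within": lambda df: (df["plot_type"] == "roost") & (df["season"].isin(["early", "late"])),
    "nonuse": lambda df: df["plot_type"] == "nonuse",
}


def subsample_bootstrap(
    samples: pd.DataFrame,
    model: str,
    n_iter: int = 1000,
    n_perm: int = 999,
    response_cols: list[str] = DEFAULT_VEG_VARS,
    terms: list[str] = DEFAULT_TERMS,
    metric: str = "standardized_euclidean",
    seed: int | None = None,
) -> BootPermanovaResults:
    """Bootstrap the PERMANOVA over one-plot-per-individual-per-season draws.

    ``model`` selects the rows: "pre" (pre-season roosts), "within"
    (roosts during the hunting season) or "nonuse" (paired non-use plots,
    all seasons).  Each iteration draws one plot uniformly per
    individual x season cell, refits, and contributes one F and p per term.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if model not in MODEL_SELECTORS:
        raise ValueError(f"model must be one of {sorted(MODEL_SELECTORS)}")
    pool = samples[MODEL_SELECTORS[model](samples)].reset_index(drop=True)
    if len(pool) == 0:
        raise ValueError(f"no samples match model '{model}'")
    rng = np.random.default_rng(seed)
    groups = pool.groupby(["individual", "season"], sort=True).indices
    fs, ps = [], []
    for _ in range(n_iter):
        rows = [idx[rng.integers(len(idx))] for idx in groups.values()]
        sub = pool.loc[sorted(rows)]
        res = permanova(sub, response_cols=response_cols, terms=terms,
                        metric=metric, n_perm=n_perm,
                        seed=int(rng.integers(0, 2**31 - 1)))
        fs.append(res.f)
        ps.append(res.p)
    F = np.asarray(fs)
    P = np.asarray(ps)
    p_med = np.median(P, axis=0)
    return BootPermanovaResults(
        terms=list(terms),
        f_median=np.median(F, axis=0),
        f_q2_5=np.quantile(F, 0.025, axis=0),
        f_q97_5=np.quantile(F, 0.975, axis=0),
        p_median=p_med,
        p_q2_5=np.quantile(P, 0.025, axis=0),
        p_q97_5=np.quantile(P, 0.975, axis=0),
        significant=p_med < 0.05,
        n_iterations=n_iter,
        f_draws=F, p_draws=P)
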