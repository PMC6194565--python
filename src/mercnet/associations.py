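"""Regressions, correlations, ANOVA and soil-property PCA along the Hg gradient.

Community attributes (qPCR bacterial abundance, Shannon diversity, phylum
relative abundances, module profiles) are related to mercury variables with
ordinary least squares — linear or cubic in the predictor — plus pairwise
Pearson/Spearman correlation tables and one-way ANOVA with land use as the
fixed factor. Soil covariates are compressed to three principal components
for use as composite predictors downstream (e.g. in structural equation
models fitted elsewhere).

Mercury spans roughly two orders of magnitude, so Hg predictors are
log10-transformed by default before regression; the transform is a flag and
degrees of freedom do not depend on it. Cubic fits use a centred predictor
for conditioning — the F, p and R² are identical to the raw-power
parameterisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from mercnet.errors import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """OLS fit of an attribute on a (possibly log10) mercury predictor."""

    model: str  # "linear" or "cubic"
    response: str
    predictor: str
    params: np.ndarray  # intercept first, then increasing powers
    bse: np.ndarray
    df_model: int
    df_resid: int
    f: float
    p: float
    r2: float
    n: int

    @property
    def slope(self) -> float:
        """First-order coefficient."""
        return float(self.params[1])

    def slope_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return (self.slope - t * self.bse[1], self.slope + t * self.bse[1])


@dataclass
class AnovaResult:
    factor: str
    df_between: int
    df_within: int
    f: float
    p: float
    group_means: dict[str, float]


@dataclass
class CorrelationTable:
    """Attributes × environmental variables: coefficient and p matrices."""

    coef: pd.DataFrame
    p: pd.DataFrame
    method: str
    n: int
    flagged: list[str]


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame  # samples × components
    variance_explained: np.ndarray  # fraction per component
    dropped: list[str]


def fit_gradient(
    response: pd.Series,
    predictor: pd.Series,
    model: str = "linear",
    log10_predictor: bool = True,
    subset: pd.Series | np.ndarray | None = None,
) -> FitResult:
    """OLS of ``response`` on ``predictor`` (linear or cubic polynomial).

    ``subset`` is a boolean mask restricting the fit (e.g. one land use).
    Reports (df_model, df_resid), the overall F test, its p-value and R².
    """
    if model not in ("linear", "cubic"):
        raise ValueError(f"model must be 'linear' or 'cubic', got {model!r}")
    y = pd.Series(response).astype(float)
    x = pd.Series(predictor).astype(float)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        y, x = y[mask], x[mask]
    keep = y.notna() & x.notna()
    y, x = y[keep], x[keep]
    degree = 1 if model == "linear" else 3
    n = len(y)
    if n <= degree + 1:
        raise InsufficientDataError(f"need more than {degree + 1} points, got {n}")
    if not np.isfinite(x).all():
        raise ValueError("predictor contains non-finite values")
    if log10_predictor:
        if (x <= 0).any():
            raise ValueError("log10 transform requires a positive predictor")
        x = np.log10(x)
    if np.ptp(x.to_numpy()) == 0:
        raise InsufficientDataError("degenerate predictor: zero variance")
    xc = x - x.mean()
    design = np.column_stack([xc.to_numpy() ** k for k in range(1, degree + 1)])
    fit = sm.OLS(y.to_numpy(), sm.add_constant(design)).fit()
    return FitResult(
        model=model,
        response=str(response.name or "response"),
        predictor=str(predictor.name or "predictor"),
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        f=float(fit.fvalue),
        p=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        n=n,
    )


def attribute_correlations(
    attributes: pd.DataFrame,
    env: pd.DataFrame,
    method: str = "pearson",
) -> CorrelationTable:
    """Pairwise correlations between each attribute and each environmental variable.

    Pearson p-values come from the two-sided t test with n−2 df; Spearman
    matches the network-layer convention (average ranks, t approximation).
    Zero-variance columns yield coefficient 0, p 1, and are flagged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if not attributes.index.equals(env.index):
        raise ValueError("attributes and env must share an identical sample index")
    n = len(attributes)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {n}")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    coef = pd.DataFrame(index=attributes.columns, columns=env.columns, dtype=float)
    pmat = pd.DataFrame(index=attributes.columns, columns=env.columns, dtype=float)
    flagged: list[str] = []
    for col in list(attributes.columns) + list(env.columns):
        frame = attributes if col in attributes.columns else env
        if np.ptp(frame[col].to_numpy(dtype=float)) == 0 and col not in flagged:
            flagged.append(col)
    for a in attributes.columns:
        for e in env.columns:
            if a in flagged or e in flagged:
                coef.loc[a, e], pmat.loc[a, e] = 0.0, 1.0
                continue
            r, p = corr_fn(attributes[a].to_numpy(dtype=float), env[e].to_numpy(dtype=float))
            coef.loc[a, e], pmat.loc[a, e] = float(r), float(p)
    if flagged:
        logger.warning("zero-variance columns in correlation table: %s", flagged)
    return CorrelationTable(coef=coef, p=pmat, method=method, n=n, flagged=flagged)


def land_use_anova(attribute: pd.Series, meta: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA of a per-sample attribute with land use as the fixed factor.

    Samples are treated as independent observations (site nesting is
    deliberately ignored), so 141 samples in two groups give d.f. = 1, 139.
    """
    values = pd.Series(attribute).astype(float)
    land = meta.loc[values.index, "land_use"]
    groups = {lvl: values[land == lvl].to_numpy() for lvl in sorted(land.unique())}
    if len(groups) < 2:
        raise InsufficientDataError("both land-use levels must be present")
    for lvl, g in groups.items():
        if len(g) < 2:
            raise InsufficientDataError(f"land use {lvl!r} has fewer than 2 samples")
    f, p = stats.f_oneway(*groups.values())
    n = len(values)
    k = len(groups)
    return AnovaResult(
        factor="land_use",
        df_between=k - 1,
        df_within=n - k,
        f=float(f),
        p=float(p),
        group_means={lvl: float(np.mean(g)) for lvl, g in groups.items()},
    )


def soil_pca(soil_vars: pd.DataFrame, n_components: int = 3) -> PcaResult:
    """PCA of standardised soil variables; the top components summarise soil.

    Constant variables are dropped with a warning; missing values are
    mean-imputed (and logged) before standardisation.
    """
    from sklearn.decomposition import PCA

    df = soil_vars.astype(float).copy()
    if df.shape[1] < 4:
        raise InsufficientDataError("soil PCA expects at least 4 variables")
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.warning("mean-imputing %d missing soil values before PCA", n_missing)
        df = df.fillna(df.mean())
    dropped = [c for c in df.columns if np.ptp(df[c].to_numpy()) == 0]
    if dropped:
        logger.warning("dropping constant soil variables: %s", dropped)
        df = df.drop(columns=dropped)
    z = (df - df.mean()) / df.std(ddof=1)
    pca = PCA(n_components=min(n_components, z.shape[1]))
    scores = pca.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PcaResult(
        loadings=pd.DataFrame(pca.components_.T, index=df.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        variance_explained=np.asarray(pca.explained_variance_ratio_),
        dropped=dropped,
    )
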