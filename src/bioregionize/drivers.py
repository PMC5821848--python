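"""Attribute region membership to environmental predictors.

The chain: reduce each predictor family (current climate, topography,
vegetation) to its leading principal components; derive historical-climate
differences (current minus Last Glacial Maximum, averaged over circulation
models); fit multinomial logistic regressions of region membership on every
subset of the predictor terms; rank by small-sample-corrected AIC (AICc) with
Akaike weights and percent deviance explained; and decompose the best model's
explained deviance into unique and shared fractions of the climate /
topography / rivers / vegetation groups by inclusion–exclusion over fits on
all group unions.

The multinomial fit is parameterized with a designated reference class (one
linear predictor per non-reference class, softmax link).  An optional L2
ridge on non-intercept coefficients keeps estimates finite under (quasi-)
separation — e.g. when a river category perfectly predicts regions — while
the reported log-likelihood and deviance are always the *unpenalized* values
at the optimum, keeping AICc comparable across models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Group PCA and predictor assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPCA:
    """Scores, loadings and variance fractions of one predictor family.

    Input variables are standardized (mean 0, sd 1, ddof=1) before the
    eigen-decomposition, so the PCA operates on the correlation structure.
    Sign convention: within each axis the loading of largest magnitude is
    positive.
    """

    scores: pd.DataFrame          # cells × retained axes
    loadings: pd.DataFrame        # variables × retained axes
    variance_fractions: np.ndarray  # all axes
    dropped: tuple[str, ...] = ()


def group_pca(table: pd.DataFrame, n_axes: int = 2) -> GroupPCA:
    """PCA of one standardized variable group; returns the first n_axes."""
    if table.shape[1] < 2:
        raise ValueError("group_pca needs at least 2 variables")
    if table.shape[0] < 3:
        raise ValueError("group_pca needs at least 3 cells")
    if table.isna().any().any():
        raise ValueError("missing values in PCA input")
    sd = table.std(ddof=1)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        logger.warning("dropping constant columns from PCA: %s", list(dropped))
        table = table.loc[:, sd > 0]
    if n_axes > table.shape[1]:
        raise ValueError(
            f"n_axes={n_axes} exceeds the {table.shape[1]} usable variables"
        )
    z = (table - table.mean()) / table.std(ddof=1)
    pca = PCA(n_components=table.shape[1])
    scores = pca.fit_transform(z.to_numpy())
    comps = pca.components_          # (axes, variables)
    for a in range(comps.shape[0]):  # largest-magnitude loading positive
        j = int(np.argmax(np.abs(comps[a])))
        if comps[a, j] < 0:
            comps[a] *= -1.0
            scores[:, a] *= -1.0
    axis_names = [f"PC{a + 1}" for a in range(n_axes)]
    return GroupPCA(
        scores=pd.DataFrame(scores[:, :n_axes], index=table.index, columns=axis_names),
        loadings=pd.DataFrame(comps[:n_axes].T, index=table.columns, columns=axis_names),
        variance_fractions=pca.explained_variance_ratio_.copy(),
        dropped=dropped,
    )


def pc_variable_correlations(
    scores: pd.DataFrame, raw_table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and two-sided t-based p) between raw variables and PC axes.

    No multiplicity correction is applied.  Zero-variance variables yield
    missing correlations.
    """
    if len(scores) != len(raw_table):
        raise ValueError("scores and raw table must cover the same cells")
    rows = []
    for var in raw_table.columns:
        x = raw_table[var].to_numpy(dtype=float)
        for axis in scores.columns:
            y = scores[axis].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(x, y)
            rows.append({"variable": var, "axis": axis, "r": r, "p": p})
    return pd.DataFrame(rows)


def historical_difference(
    current: pd.Series, lgm_fields: pd.DataFrame | list[pd.Series]
) -> pd.Series:
    """Per-cell current − mean(LGM circulation models).

    Circulation models are averaged *before* differencing, so inter-model
    noise cancels rather than propagating into the historical-difference
    predictor.
    """
    if isinstance(lgm_fields, list):
        lgm_fields = pd.concat(lgm_fields, axis=1)
    if lgm_fields.shape[1] < 1:
        raise ValueError("need at least one LGM field")
    if not current.index.equals(lgm_fields.index):
        raise ValueError("current and LGM fields are not aligned on the same cells")
    return current - lgm_fields.mean(axis=1)


def build_predictor_table(lattice, env, n_axes: int = 2):
    """Assemble the per-cell predictor table used by the driver models.

    Columns: CURE.PC1/PC2 (current climate), TOPO.PC1/PC2 (topography),
    VEGE.PC1/PC2 (vegetation percentages), HDT and HDP (current-minus-LGM
    temperature and precipitation), RIVERS (river-bank category).  Returns
    (table, {"CURE": GroupPCA, "TOPO": ..., "VEGE": ...}).
    """
    t = env.table
    pcas = {
        "CURE": group_pca(t[list(env.climate_vars)], n_axes),
        "TOPO": group_pca(t[list(env.topo_vars)], n_axes),
        "VEGE": group_pca(t[list(env.veg_vars)], n_axes),
    }
    out = pd.DataFrame(index=t.index)
    for name, res in pcas.items():
        for axis in res.scores.columns:
            out[f"{name}.{axis}"] = res.scores[axis]
    out["HDT"] = historical_difference(
        t[env.current_temp_col], t[list(env.lgm_temp_cols)]
    )
    out["HDP"] = historical_difference(
        t[env.current_prec_col], t[list(env.lgm_prec_cols)]
    )
    out["RIVERS"] = pd.Series(
        np.asarray(lattice.river_bank_category, dtype=object), index=t.index
    )
    return out, pcas


#: default mapping of predictor terms to deviance-partition groups:
#: C = climate (current PCs + historical differences), T = topography,
#: R = riverine barriers, V = vegetation structure
DEFAULT_GROUPS = {
    "C": ["CURE.PC1", "CURE.PC2", "HDT", "HDP"],
    "T": ["TOPO.PC1", "TOPO.PC2"],
    "R": ["RIVERS"],
    "V": ["VEGE.PC1", "VEGE.PC2"],
}


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------

def _design_matrix(
    X: pd.DataFrame,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design with intercept, standardized continuous terms, and dummy-coded
    categoricals (reference = most frequent level).  Returns (D, column
    names, non-intercept mask for the ridge penalty)."""
    n = len(X)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(intercept)"]
    penalized: list[bool] = [False]
    for name in X.columns:
        col = X[name]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"constant continuous predictor {name!r}")
            cols.append((x - x.mean()) / sd)
            names.append(name)
            penalized.append(True)
        else:
            counts = col.value_counts()
            ref = counts.index[0]  # most frequent level is the reference
            for level in counts.index[1:]:
                cols.append((col == level).to_numpy(dtype=float))
                names.append(f"{name}[{level}]")
                penalized.append(True)
    return np.column_stack(cols), names, np.asarray(penalized)


@dataclass
class MultinomFit:
    """A fitted reference-class multinomial logistic regression.

    ``coefficients`` is a (K−1) × p DataFrame (rows: non-reference classes,
    columns: design terms including the intercept).  ``deviance`` is −2 times
    the *unpenalized* log-likelihood at the optimum; ``n_params`` counts the
    full (K−1) × p coefficient structure regardless of the ridge.
    """

    classes: tuple
    reference_class: object
    coefficients: pd.DataFrame
    log_likelihood: float
    n_params: int
    converged: bool
    ridge_lambda: float
    n_obs: int
    terms: tuple[str, ...]
    _design: np.ndarray = field(repr=False, default=None)
    _y_index: np.ndarray = field(repr=False, default=None)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    def predict_proba(self) -> np.ndarray:
        """Fitted class probabilities (n_obs × K, columns in self.classes
        order, reference class first)."""
        B = self.coefficients.to_numpy()
        z = np.column_stack(
            [np.zeros(self._design.shape[0]), self._design @ B.T]
        )
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def standard_errors(self) -> pd.DataFrame:
        """Maximum-likelihood standard errors from the observed information
        (unpenalized Hessian at the estimate)."""
        D = self._design
        P = self.predict_proba()[:, 1:]  # non-reference classes
        km1, p = self.coefficients.shape
        H = np.zeros((km1 * p, km1 * p))
        xxt = np.einsum("ia,ib->iab", D, D)
        for k in range(km1):
            for l in range(km1):
                w = P[:, k] * ((k == l) - P[:, l])
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = np.einsum(
                    "i,iab->ab", w, xxt
                )
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(km1, p)
        return pd.DataFrame(
            se, index=self.coefficients.index, columns=self.coefficients.columns
        )


def fit_multinomial(
    X: pd.DataFrame,
    y,
    ridge_lambda: float = 0.0,
    reference_class=None,
    maxiter: int = 1000,
) -> MultinomFit:
    """Maximize the multinomial log-likelihood with an optional L2 ridge.

    ``X`` holds the predictor terms (continuous columns are standardized,
    categorical columns dummy-coded against their most frequent level); an
    empty ``X`` fits the intercept-only null model.  ``reference_class``
    defaults to the most frequent region.  The ridge penalizes non-intercept
    coefficients only and exists to guarantee finite estimates under
    separation; the returned log-likelihood is unpenalized.
    """
    y = pd.Series(np.asarray(y, dtype=object))
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 region classes")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    if reference_class is None:
        reference_class = counts.index[0]
    others = [c for c in counts.index if c != reference_class]
    classes = (reference_class, *others)
    class_index = {c: i for i, c in enumerate(classes)}
    yi = y.map(class_index).to_numpy(dtype=int)

    D, names, pen_mask = _design_matrix(X)
    n, p = D.shape
    K = len(classes)
    km1 = K - 1
    Y = np.zeros((n, km1))
    for k in range(km1):
        Y[:, k] = yi == k + 1
    pen = np.tile(pen_mask, km1).astype(float).reshape(km1, p)

    def negloglik_grad(beta_flat: np.ndarray):
        B = beta_flat.reshape(km1, p)
        Z = D @ B.T                                   # (n, km1)
        lse = logsumexp(np.column_stack([np.zeros(n), Z]), axis=1)
        picked = np.where(yi > 0, Z[np.arange(n), np.maximum(yi - 1, 0)], 0.0)
        nll = -(picked - lse).sum()
        P = np.exp(Z - lse[:, None])                  # non-reference probs
        G = (P - Y).T @ D                             # (km1, p)
        nll += 0.5 * ridge_lambda * float(((B * pen) ** 2).sum())
        G = G + ridge_lambda * B * pen
        return nll, G.ravel()

    res = optimize.minimize(
        negloglik_grad,
        np.zeros(km1 * p),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": 1e-8, "ftol": 1e-12},
    )
    B = res.x.reshape(km1, p)
    Z = D @ B.T
    lse = logsumexp(np.column_stack([np.zeros(n), Z]), axis=1)
    picked = np.where(yi > 0, Z[np.arange(n), np.maximum(yi - 1, 0)], 0.0)
    ll = float((picked - lse).sum())
    # the optimizer's line search can give up within float precision of the
    # optimum; a small gradient is the criterion that actually matters
    _, g_final = negloglik_grad(res.x)
    converged = bool(res.success) or float(np.abs(g_final).max()) < 1e-4 * max(n, 1)
    if not converged:
        logger.warning(
            "multinomial fit did not fully converge (%s); terms=%s ridge=%g",
            res.message, list(X.columns), ridge_lambda,
        )
    return MultinomFit(
        classes=classes,
        reference_class=reference_class,
        coefficients=pd.DataFrame(B, index=list(others), columns=names),
        log_likelihood=ll,
        n_params=km1 * p,
        converged=converged,
        ridge_lambda=ridge_lambda,
        n_obs=n,
        terms=tuple(X.columns),
        _design=D,
        _y_index=yi,
    )


# ---------------------------------------------------------------------------
# Information criteria and model ranking
# ---------------------------------------------------------------------------

def aicc_value(log_likelihood: float, n_params: int, n: int) -> float:
    """AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1)."""
    if n - n_params - 1 <= 0:
        raise ValueError(
            f"sample size n={n} too small for n_params={n_params} (AICc undefined)"
        )
    aic = -2.0 * log_likelihood + 2.0 * n_params
    return aic + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)


def aicc(fit: MultinomFit, n: int | None = None) -> float:
    """Small-sample-corrected AIC of a fit (n defaults to the cell count)."""
    n = fit.n_obs if n is None else n
    return aicc_value(fit.log_likelihood, fit.n_params, n)


def akaike_weights(aicc_values) -> np.ndarray:
    """w_i = exp(−Δi/2) / Σ exp(−Δj/2) with Δi = AICc_i − min AICc."""
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0 or not np.isfinite(vals).all():
        raise ValueError("AICc values must be finite and non-empty")
    delta = vals - vals.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def percent_deviance_explained(fit: MultinomFit, null_fit: MultinomFit) -> float:
    """100 × (null deviance − model deviance) / null deviance."""
    if null_fit.deviance == 0:
        raise ValueError("null deviance is 0; %DE undefined")
    return 100.0 * (null_fit.deviance - fit.deviance) / null_fit.deviance


@dataclass(frozen=True)
class ModelRanking:
    """AICc-ordered all-subsets ranking.

    ``table`` columns: terms (string, '1' for intercept-only), n_terms, df
    (parameter count), aicc, delta_aicc, waicc, pct_deviance_explained.
    Weights are normalized over every fitted model.
    """

    table: pd.DataFrame
    best_terms: tuple[str, ...]
    best_fit: MultinomFit
    null_fit: MultinomFit


def dredge_models(
    X: pd.DataFrame,
    y,
    ridge_lambda: float = 0.0,
    reference_class=None,
    max_terms: int | None = None,
) -> ModelRanking:
    """Fit every subset of the predictor terms and rank by AICc.

    2^t fits for t terms (a categorical column counts as one term).  Ordering
    is deterministic: AICc ascending, ties broken by fewer terms, then by the
    lexicographic term string.  Models whose fit fails are recorded with
    missing AICc and excluded from the weights.
    """
    terms = list(X.columns)
    n = len(X)
    rows = []
    fits: dict[tuple[str, ...], MultinomFit] = {}
    for r in range(len(terms) + 1):
        if max_terms is not None and r > max_terms:
            break
        for subset in itertools.combinations(terms, r):
            try:
                fit = fit_multinomial(
                    X[list(subset)], y, ridge_lambda=ridge_lambda,
                    reference_class=reference_class,
                )
                a = aicc(fit, n)
            except Exception as exc:  # fit or AICc failure: record, exclude
                logger.warning("model %s failed: %s", subset or ("1",), exc)
                rows.append(
                    {"terms": " + ".join(subset) or "1", "n_terms": r,
                     "df": np.nan, "aicc": np.nan,
                     "pct_deviance_explained": np.nan}
                )
                continue
            fits[subset] = fit
            rows.append(
                {"terms": " + ".join(subset) or "1", "n_terms": r,
                 "df": fit.n_params, "aicc": a,
                 "pct_deviance_explained": np.nan}
            )
    table = pd.DataFrame(rows)
    null_fit = fits[()]
    ok = table["aicc"].notna()
    table.loc[ok, "delta_aicc"] = table.loc[ok, "aicc"] - table.loc[ok, "aicc"].min()
    w = akaike_weights(table.loc[ok, "aicc"].to_numpy())
    table.loc[ok, "waicc"] = w
    de = {
        " + ".join(s) or "1": percent_deviance_explained(f, null_fit)
        for s, f in fits.items()
    }
    table["pct_deviance_explained"] = table["terms"].map(de)
    table = table.sort_values(
        ["aicc", "n_terms", "terms"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    best_terms = tuple(
        t for t in terms if t in table.loc[0, "terms"].split(" + ")
    )
    return ModelRanking(
        table=table[
            ["terms", "n_terms", "df", "aicc", "delta_aicc", "waicc",
             "pct_deviance_explained"]
        ],
        best_terms=best_terms,
        best_fit=fits[best_terms],
        null_fit=null_fit,
    )


# ---------------------------------------------------------------------------
# Deviance partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviancePartition:
    """Unique and shared %DE fractions of predictor groups.

    ``fractions`` maps each non-empty group combination (names sorted and
    joined with '&', e.g. 'C', 'C&R') to the %DE attributable to exactly that
    combination; shared fractions may be negative.  The fractions sum to the
    full model's %DE by construction; ``unexplained`` is 100 − full %DE.
    """

    fractions: dict
    unexplained: float
    pct_de_full: float
    group_terms: dict


def partition_deviance(
    groups: dict[str, list[str]],
    X: pd.DataFrame,
    y,
    ridge_lambda: float = 0.0,
    reference_class=None,
) -> DeviancePartition:
    """Inclusion–exclusion deviance partition over predictor groups.

    Fits a multinomial model on every non-empty union of the (non-empty)
    groups, records each union's %DE, and solves for the unique/shared
    fractions: the fraction belonging to exactly the set S of groups is

        f(S) = Σ_{B ⊆ S} (−1)^{|S|−|B|} [R(G) − R(G∖B)],

    where R(A) is the %DE of the model on the union of groups in A and G is
    the full group set.  Groups with no terms contribute zero fractions.
    """
    nonempty = {g: t for g, t in groups.items() if t}
    if len(nonempty) < 2:
        raise ValueError("need at least 2 non-empty predictor groups")
    names = sorted(nonempty)
    null_fit = fit_multinomial(
        X[[]], y, ridge_lambda=ridge_lambda, reference_class=reference_class
    )

    de_cache: dict[frozenset, float] = {frozenset(): 0.0}

    def R(subset: frozenset) -> float:
        if subset not in de_cache:
            cols = [c for g in sorted(subset) for c in nonempty[g]]
            fit = fit_multinomial(
                X[cols], y, ridge_lambda=ridge_lambda,
                reference_class=reference_class,
            )
            de_cache[subset] = percent_deviance_explained(fit, null_fit)
        return de_cache[subset]

    G = frozenset(names)
    full = R(G)
    fractions: dict[str, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            S = frozenset(combo)
            f = 0.0
            for rb in range(len(combo) + 1):
                for sub in itertools.combinations(combo, rb):
                    B = frozenset(sub)
                    sign = (-1) ** (len(S) - len(B))
                    f += sign * (full - R(G - B))
            fractions["&".join(combo)] = f
    # zero fractions for combinations involving empty groups
    empty = sorted(g for g, t in groups.items() if not t)
    if empty:
        all_names = sorted(groups)
        for r in range(1, len(all_names) + 1):
            for combo in itertools.combinations(all_names, r):
                key = "&".join(combo)
                if key not in fractions:
                    fractions[key] = 0.0
    return DeviancePartition(
        fractions=fractions,
        unexplained=100.0 - full,
        pct_de_full=full,
        group_terms=dict(groups),
    )
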