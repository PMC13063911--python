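"""L1-penalized logistic regression ("LogitNet") under repeated nested CV.

The classifier minimizes

    (1/n) * logistic deviance + lambda * sum_j |beta_j|

with an unpenalized intercept, fitted along a decreasing penalty path of
100 log-spaced values from lambda_max (the smallest penalty that zeroes
every coefficient, known in closed form) down to lambda_max *
lambda_min_ratio, with warm starts. The solver is IRLS with cyclic
coordinate descent on the penalized weighted least-squares subproblem,
the standard glmnet scheme.

Evaluation is 10-times repeated nested cross-validation with five
stratified inner folds (choosing lambda by mean validation ROC-AUC, ties
to the sparser model) and five stratified outer folds (performance).
Preprocessing — an empirical quantile map to uniform [0, 1], or
standardize + PCA in the variant — is fitted inside each training portion
only. Feature importance is the selection frequency: in how many of the
repeats x outer_folds evaluations a feature kept a nonzero coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import QuantileTransformer, StandardScaler

__all__ = [
    "FeatureTable",
    "ModelConfig",
    "CVReport",
    "quantile_transform",
    "lasso_logistic_path",
    "lambda_max",
    "nested_cv",
    "metrics",
    "selection_frequency",
    "pca_pipeline",
    "single_feature_model",
]


@dataclass
class FeatureTable:
    """Feature matrix plus binary response (1 = shunt responder)."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).astype(int).ravel()
        if len(self.X) != len(self.y):
            raise ValueError("X and y have different lengths")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("response must be binary 0/1")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response_col: str = "response"):
        return cls(X=df.drop(columns=[response_col]), y=df[response_col].to_numpy())

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, features) -> "FeatureTable":
        missing = [f for f in features if f not in self.X.columns]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        return FeatureTable(X=self.X[list(features)].copy(), y=self.y.copy())


@dataclass
class ModelConfig:
    repeats: int = 10
    outer_folds: int = 5
    inner_folds: int = 5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    threshold: float = 0.5
    seed: int = 0
    pca_variant: bool = False
    variance_target: float = 0.95
    preprocess_global: bool = False  # fit the quantile map on all subjects
                                     # (the leakage-prone alternative reading)

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if not 0.0 < self.variance_target <= 1.0:
            raise ValueError("variance_target must be in (0, 1]")


@dataclass
class CVReport:
    """Everything recorded across repeats x outer_folds evaluations."""

    folds: pd.DataFrame            # one row per evaluation
    coefs: np.ndarray              # (n_eval, n_features) at the selected lambda
    feature_names: list[str]
    config: ModelConfig
    pooled_confusion: dict         # tp/fp/tn/fn summed over evaluations
    response_correlation: pd.Series  # Pearson r of each feature with y

    @property
    def n_evaluations(self) -> int:
        return len(self.folds)

    def aggregate(self) -> pd.DataFrame:
        cols = ["auc", "balanced_accuracy", "sensitivity", "specificity"]
        return self.folds[cols].agg(["mean", "std"]).T

    def to_json(self, path) -> None:
        import dataclasses
        import json

        payload = {
            "folds": self.folds.to_dict(orient="list"),
            "coefs": self.coefs.tolist(),
            "feature_names": self.feature_names,
            "config": dataclasses.asdict(self.config),
            "pooled_confusion": self.pooled_confusion,
            "response_correlation": self.response_correlation.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CVReport":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            folds=pd.DataFrame(payload["folds"]),
            coefs=np.asarray(payload["coefs"]),
            feature_names=payload["feature_names"],
            config=ModelConfig(**payload["config"]),
            pooled_confusion=payload["pooled_confusion"],
            response_correlation=pd.Series(payload["response_correlation"]),
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _fit_quantile(train: np.ndarray) -> QuantileTransformer:
    qt = QuantileTransformer(
        n_quantiles=min(1000, len(train)),
        output_distribution="uniform",
        subsample=1_000_000_000,
    )
    qt.fit(train)
    return qt


def quantile_transform(train: np.ndarray, test: np.ndarray):
    """Per-column empirical-quantile map to uniform [0, 1], estimated on
    the training rows only; test values interpolate through the training
    quantile function and clip to [0, 1]."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    qt = _fit_quantile(train)
    return qt.transform(train), qt.transform(test)


# ---------------------------------------------------------------------------
# LASSO-logistic path (coordinate descent)
# ---------------------------------------------------------------------------

def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with all coefficients zero:
    max_j |x_j . (y - ybar)| / n under the intercept-only fit."""
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def _lambda_grid(lmax: float, n_lambda: int, ratio: float) -> np.ndarray:
    return lmax * np.logspace(0.0, np.log10(ratio), n_lambda)


@numba.njit(cache=True)
def _cd_logistic_path(X, y, lambdas, max_irls, tol):  # pragma: no cover
    """IRLS + coordinate-descent solver for the whole penalty path.

    Warm starts across lambdas. Working weights are floored at 1e-5 (the
    glmnet convention) so the quadratic subproblem stays well-conditioned
    when probabilities saturate. The subproblem uses covariance updates —
    the Gram matrix X'WX is formed once per IRLS step, making each
    coordinate update O(p) instead of O(n). Soft-thresholding treats
    |gradient| <= lam*(1 + 1e-10) as zero, so the endpoint at lambda_max
    is exactly the null model despite round-off in weighted products.
    """
    n, p = X.shape
    nl = len(lambdas)
    B = np.zeros((nl, p))
    b0s = np.zeros(nl)
    beta = np.zeros(p)
    pbar = y.mean()
    b0 = np.log(pbar / (1.0 - pbar))
    zero_tol = 1.0 + 1e-10

    for li in range(nl):
        lam = lambdas[li]
        for _irls in range(max_irls):
            eta = b0 + X @ beta
            delta_out = 0.0
            prob = np.empty(n)
            w = np.empty(n)
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                pi = 1.0 / (1.0 + np.exp(-e))
                prob[i] = pi
                wi = pi * (1.0 - pi)
                w[i] = wi if wi > 1e-5 else 1e-5
            wsum = w.sum()
            Xw = X.T @ w
            G = (X * w.reshape(n, 1)).T @ X
            resid = y - prob
            g = X.T @ (w * eta + resid)
            swz = w @ eta + resid.sum()
            u = G @ beta
            sXwb = Xw @ beta

            for _sweep in range(1000):
                b0_new = (swz - sXwb) / wsum
                delta = abs(b0_new - b0)
                b0 = b0_new
                for j in range(p):
                    dj = G[j, j] / n
                    if dj <= 0.0:
                        continue
                    num = (g[j] - b0 * Xw[j] - u[j]) / n + dj * beta[j]
                    a = abs(num)
                    if a <= lam * zero_tol:
                        bj = 0.0
                    else:
                        s = 1.0 if num > 0.0 else -1.0
                        bj = s * (a - lam) / dj
                    step = bj - beta[j]
                    if step != 0.0:
                        for k in range(p):
                            u[k] += G[k, j] * step
                        sXwb += Xw[j] * step
                        if abs(step) > delta:
                            delta = abs(step)
                        beta[j] = bj
                if delta < tol:
                    break
            # IRLS convergence on the fitted linear predictor
            delta_out = 0.0
            eta_new = b0 + X @ beta
            for i in range(n):
                d = abs(eta_new[i] - eta[i])
                if d > delta_out:
                    delta_out = d
            if delta_out < 100.0 * tol:
                break
        B[li] = beta
        b0s[li] = b0
    return B, b0s


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
):
    """Coefficients along a decreasing penalty path with warm starts.

    Returns (lambdas, B, b0s): B has shape (n_lambda, p); the first path
    point is lambda_max, where every coefficient is exactly zero and the
    intercept equals log(p1 / (1 - p1)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if lambdas is None:
        lambdas = _lambda_grid(lambda_max(X, y), n_lambda, lambda_min_ratio)
    lambdas = np.ascontiguousarray(lambdas, dtype=float)
    B, b0s = _cd_logistic_path(
        np.ascontiguousarray(X), np.ascontiguousarray(y, dtype=float),
        lambdas, 30, 1e-7,
    )
    return lambdas, B, b0s


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    """ROC-AUC (rank / Mann-Whitney form with tie correction), balanced
    accuracy, sensitivity (responder = positive), specificity and the
    confusion counts at the given probability threshold."""
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute metrics")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "auc": float(auc),
        "balanced_accuracy": 0.5 * (sens + spec),
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _preprocessor(cfg: ModelConfig):
    """Returns fit(train)->state, transform(state, X)->X' closures for the
    configured preprocessing."""
    if cfg.pca_variant:
        def fit(tr):
            sc = StandardScaler().fit(tr)
            pca = PCA().fit(sc.transform(tr))
            cum = np.cumsum(pca.explained_variance_ratio_)
            m = int(np.searchsorted(cum, cfg.variance_target - 1e-12) + 1)
            m = min(m, pca.n_components_)
            return (sc, pca, m)

        def transform(state, X):
            sc, pca, m = state
            return pca.transform(sc.transform(X))[:, :m]

        return fit, transform

    def fit(tr):
        return _fit_quantile(tr)

    def transform(qt, X):
        return qt.transform(X)

    return fit, transform


def nested_cv(
    table: FeatureTable,
    cfg: ModelConfig | None = None,
    mask_test_features: float | None = None,
) -> CVReport:
    """Repeated stratified nested cross-validation of the LogitNet model.

    ``mask_test_features`` is a self-check hook: if set, every outer-test
    block is overwritten with that constant AFTER fold assignment; all
    training-side quantities (quantile maps, the penalty path, the
    selected lambda per fold) must be unchanged by construction, since
    preprocessing and fitting only ever see training rows.
    """
    cfg = cfg or ModelConfig()
    X_all = table.X.to_numpy(dtype=float)
    y_all = table.y
    n, p = X_all.shape
    fit_pre, apply_pre = _preprocessor(cfg)

    global_pre = fit_pre(X_all) if cfg.preprocess_global else None

    rng = np.random.default_rng(cfg.seed)
    records = []
    coefs = []
    for rep in range(cfg.repeats):
        outer_seed = int(rng.integers(0, 2**31 - 1))
        inner_seed = int(rng.integers(0, 2**31 - 1))
        outer = StratifiedKFold(cfg.outer_folds, shuffle=True, random_state=outer_seed)
        for k, (tr, te) in enumerate(outer.split(X_all, y_all)):
            Xtr_raw, ytr = X_all[tr], y_all[tr]
            Xte_raw, yte = X_all[te].copy(), y_all[te]
            if mask_test_features is not None:
                Xte_raw[:] = mask_test_features

            if cfg.preprocess_global:
                state = global_pre
            else:
                state = fit_pre(Xtr_raw)
            Xtr = apply_pre(state, Xtr_raw)
            lam_grid = _lambda_grid(
                lambda_max(Xtr, ytr), cfg.n_lambda, cfg.lambda_min_ratio
            )

            inner = StratifiedKFold(
                cfg.inner_folds, shuffle=True, random_state=inner_seed
            )
            inner_auc = np.zeros((cfg.inner_folds, len(lam_grid)))
            for i, (itr, ival) in enumerate(inner.split(Xtr_raw, ytr)):
                if cfg.preprocess_global:
                    istate = global_pre
                else:
                    istate = fit_pre(Xtr_raw[itr])
                Xi = apply_pre(istate, Xtr_raw[itr])
                Xv = apply_pre(istate, Xtr_raw[ival])
                _, B, b0s = lasso_logistic_path(Xi, ytr[itr], lambdas=lam_grid)
                val_scores = Xv @ B.T + b0s  # monotone in probability
                for li in range(len(lam_grid)):
                    inner_auc[i, li] = metrics(ytr[ival], val_scores[:, li])["auc"]
            mean_auc = inner_auc.mean(axis=0)
            # ties -> larger lambda (sparser model). Guard: on strongly
            # separable data the inner folds' own lambda_max can exceed the
            # outer-train lambda_max, so even the path head scores
            # perfectly inside while refitting to the null model outside;
            # among tied penalties take the largest whose outer-train refit
            # actually has active coefficients.
            tied = np.flatnonzero(mean_auc >= mean_auc.max() - 1e-12)
            _, B, b0s = lasso_logistic_path(
                Xtr, ytr, lambdas=lam_grid[: tied[-1] + 1]
            )
            best = int(tied[0])
            for idx in tied:
                if np.any(np.abs(B[idx]) > 1e-8):
                    best = int(idx)
                    break
            beta, b0 = B[best], b0s[best]
            Xte = apply_pre(state, Xte_raw)
            eta = b0 + Xte @ beta
            prob = 1.0 / (1.0 + np.exp(-eta))
            # rank on the linear predictor: monotone in probability but
            # immune to float saturation of the sigmoid on separable data
            thr_eta = float(np.log(cfg.threshold / (1.0 - cfg.threshold)))
            m = metrics(yte, eta, thr_eta)
            rec = {
                "repeat": rep, "fold": k,
                "n_train": len(tr), "n_test": len(te),
                "lambda": float(lam_grid[best]),
                "n_nonzero": int(np.sum(np.abs(beta) > 1e-8)),
                **m,
                # per-subject outputs so ROC figures need no recomputation
                "y_test": yte.tolist(),
                "prob": prob.tolist(),
            }
            if cfg.pca_variant:
                rec["n_components"] = state[2]
                # component-space coefficients, zero-padded to p columns
                padded = np.zeros(p)
                padded[: len(beta)] = beta
                coefs.append(padded)
            else:
                coefs.append(beta.copy())
            records.append(rec)

    folds = pd.DataFrame.from_records(records)
    pooled = {k: int(folds[k].sum()) for k in ("tp", "fn", "tn", "fp")}
    # descriptive Pearson r with the response, on the all-data quantile map
    qt = _fit_quantile(X_all)
    Xq = qt.transform(X_all)
    yc = y_all - y_all.mean()
    denom = np.linalg.norm(Xq - Xq.mean(axis=0), axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xq - Xq.mean(axis=0)).T @ yc / denom, 0.0)
    corr = pd.Series(r, index=table.feature_names)

    return CVReport(
        folds=folds,
        coefs=np.vstack(coefs),
        feature_names=table.feature_names,
        config=cfg,
        pooled_confusion=pooled,
        response_correlation=corr,
    )


def selection_frequency(report: CVReport) -> pd.DataFrame:
    """Features ranked by how many evaluations kept them (|coef| > 1e-8 at
    the selected lambda); ties broken alphabetically. Includes the
    descriptive Pearson correlation with the response."""
    freq = (np.abs(report.coefs) > 1e-8).sum(axis=0)
    df = pd.DataFrame({
        "feature": report.feature_names,
        "frequency": freq,
        "response_correlation": report.response_correlation.reindex(
            report.feature_names
        ).to_numpy(),
    })
    df = df.sort_values(
        ["frequency", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def pca_pipeline(table: FeatureTable, cfg: ModelConfig | None = None) -> CVReport:
    """The PCA comparison: standardize -> PCA (>= variance_target of total
    variance) -> same LogitNet path and nested CV."""
    cfg = replace(cfg or ModelConfig(), pca_variant=True)
    return nested_cv(table, cfg)


def single_feature_model(
    table: FeatureTable, feature: str, cfg: ModelConfig | None = None
) -> CVReport:
    """The identical protocol restricted to a single named feature."""
    return nested_cv(table.subset([feature]), cfg)
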