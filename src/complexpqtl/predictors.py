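"""Model zoo: genotype encodings, cross-validated elastic-net ensemble,
locally-connected non-linear network with integrated-gradients attribution,
top-variant selection, Bayesian optimization over the retained-variant
fraction, and interaction-constrained gradient boosting for decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold
from scipy import stats

from ._net import LocalNet, NetArch
from .assoc import _covariate_design
from .genio import MISSING, GenotypeMatrix

DEFAULT_EN_ALPHAS = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class EncodedDesign:
    """Genotype design matrix under a named encoding scheme.

    ``onehot`` expands each variant into 4 indicator columns
    (hom-ref, het, hom-alt, missing); ``additive`` keeps one mean-imputed
    dosage column per variant.  ``column_map`` maps every column back to its
    (variant id, genotype class) pair.
    """

    matrix: np.ndarray
    scheme: str
    column_map: list[tuple[str, str]]
    variant_ids: list[str]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def columns_for(self, variant: str) -> list[int]:
        return [i for i, (v, _) in enumerate(self.column_map) if v == variant]

    def subset_variants(self, variant_ids: Sequence[str]) -> "EncodedDesign":
        wanted = set(variant_ids)
        cols = [i for i, (v, _) in enumerate(self.column_map) if v in wanted]
        return EncodedDesign(
            self.matrix[:, cols],
            self.scheme,
            [self.column_map[i] for i in cols],
            [v for v in self.variant_ids if v in wanted],
        )


ONEHOT_CLASSES = ("hom_ref", "het", "hom_alt", "missing")


def encode(G: GenotypeMatrix, scheme: str) -> EncodedDesign:
    """Build an additive or one-hot genotype design (invertible column map).

    hom_ref is dosage 0 (two copies of allele2), hom_alt is dosage 2.
    """
    d = G.dosage
    ids = G.variant_ids()
    if scheme == "additive":
        return EncodedDesign(G.imputed(), "additive", [(v, "dosage") for v in ids], ids)
    if scheme == "onehot":
        n, m = d.shape
        mat = np.zeros((n, 4 * m))
        for c, dos in enumerate((0, 1, 2, MISSING)):
            mat[:, c::4] = d == dos
        cmap = [(v, cls) for v in ids for cls in ONEHOT_CLASSES]
        return EncodedDesign(mat, "onehot", cmap, ids)
    raise ValueError(f"unknown encoding scheme {scheme!r}")


@dataclass
class ModelBundle:
    """Fitted model with a uniform prediction contract.

    ``predict`` consumes a design matrix with the training column layout;
    ``input_gradient`` (when available) returns d(output)/d(input) per sample
    for attribution.
    """

    kind: str
    predict: Callable[[np.ndarray], np.ndarray]
    metadata: dict = field(default_factory=dict)
    model: Any = None
    input_gradient: Callable[[np.ndarray], np.ndarray] | None = None


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mu) / sd


def fit_elastic_net_cv(
    X: np.ndarray,
    y: np.ndarray,
    alphas: Sequence[float] = DEFAULT_EN_ALPHAS,
    n_lambda: int = 200,
    k_folds: int = 10,
    seed: int = 0,
    lambdas: Sequence[float] | None = None,
    max_iter: int = 2000,
) -> ModelBundle:
    """K-fold elastic net with per-fold (mixing, penalty) grid selection.

    Per fold, regularization paths are fit on the in-fold rows for every
    mixing value (``alphas``); the best (alpha, lambda) is chosen by held-out
    R2 and the final predictor averages the per-fold winners ("ensemble-like
    process across the CV runs").  A lambda of exactly 0 falls back to
    unpenalized least squares.  X is standardized internally.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k_folds:
        raise ValueError("need n >= k_folds")
    if np.var(y) == 0:
        raise ValueError("constant trait")

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_models = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train_i, val_i in kf.split(X):
            Xtr, ytr = X[train_i], y[train_i]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)  # constant columns -> coefficient 0
            Xtr_z = _standardize(Xtr, mu, sd)
            Xval_z = _standardize(X[val_i], mu, sd)
            y_mean = ytr.mean()
            ytr_c = ytr - y_mean

            best = None
            for l1_ratio in alphas:
                if lambdas is None:
                    lam_grid, coefs, _ = enet_path(
                        Xtr_z, ytr_c, l1_ratio=l1_ratio, n_alphas=n_lambda,
                        eps=1e-4, max_iter=max_iter,
                    )
                else:
                    lam_grid = np.asarray(list(lambdas), dtype=float)
                    cols = []
                    for lam in lam_grid:
                        if lam == 0.0:
                            coef, *_ = np.linalg.lstsq(Xtr_z, ytr_c, rcond=None)
                        else:
                            en = ElasticNet(
                                alpha=lam, l1_ratio=l1_ratio,
                                fit_intercept=False, max_iter=max_iter,
                            ).fit(Xtr_z, ytr_c)
                            coef = en.coef_
                        cols.append(coef)
                    coefs = np.stack(cols, axis=-1)
                preds = Xval_z @ coefs + y_mean  # (n_val, n_lambda)
                sse = ((preds - y[val_i][:, None]) ** 2).sum(axis=0)
                k = int(np.argmin(sse))
                score = -sse[k]
                if best is None or score > best[0]:
                    best = (score, l1_ratio, float(lam_grid[k]), coefs[:, k].copy())
            _, l1_ratio, lam, coef = best
            fold_models.append(
                {"mu": mu, "sd": sd, "y_mean": y_mean, "coef": coef,
                 "l1_ratio": l1_ratio, "lambda": lam}
            )

    def predict(X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        preds = [
            _standardize(X_new, fm["mu"], fm["sd"]) @ fm["coef"] + fm["y_mean"]
            for fm in fold_models
        ]
        return np.mean(preds, axis=0)

    mean_coef = np.mean(
        [fm["coef"] / fm["sd"] for fm in fold_models], axis=0
    )  # on the raw-X scale, for linear attribution

    def input_gradient(X_new: np.ndarray) -> np.ndarray:
        return np.broadcast_to(mean_coef, (len(X_new), len(mean_coef))).copy()

    return ModelBundle(
        kind="elastic_net",
        predict=predict,
        metadata={
            "seed": seed,
            "k_folds": k_folds,
            "chosen": [(fm["l1_ratio"], fm["lambda"]) for fm in fold_models],
        },
        model=fold_models,
        input_gradient=input_gradient,
    )


# ---------------------------------------------------------------------------
# Non-linear predictor
# ---------------------------------------------------------------------------


def covariate_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Numeric covariate design without intercept (dummy-coded categoricals)."""
    return _covariate_design(covariates, n)[:, 1:]


def fit_nonlinear_predictor(
    design: EncodedDesign,
    covariates: pd.DataFrame | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    arch: NetArch | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Train the locally-connected-then-dense network with early stopping.

    The first layer applies window-local weights to contiguous one-hot
    genotype columns (no weight sharing); dense layers consume the local
    features together with the covariates.  Deterministic under ``seed``.
    """
    if design.scheme != "onehot":
        raise ValueError("non-linear predictor expects a one-hot design")
    arch = arch or NetArch()
    y = np.asarray(y, dtype=float)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("validation split must be disjoint from training rows")

    Xg = design.matrix
    Xc_raw = covariate_matrix(covariates, Xg.shape[0])
    mu = Xc_raw[train_idx].mean(axis=0) if Xc_raw.shape[1] else np.zeros(0)
    sd = Xc_raw[train_idx].std(axis=0) if Xc_raw.shape[1] else np.ones(0)
    sd = np.where(sd == 0, 1.0, sd)
    Xc = (Xc_raw - mu) / sd if Xc_raw.shape[1] else Xc_raw

    y_mu = y[train_idx].mean()
    y_sd = y[train_idx].std() or 1.0

    net = LocalNet(Xg.shape[1], Xc.shape[1], arch, seed=seed)
    info = net.fit(
        Xg[train_idx], Xc[train_idx], (y[train_idx] - y_mu) / y_sd,
        Xg[val_idx], Xc[val_idx], (y[val_idx] - y_mu) / y_sd,
        seed=seed + 1,
    )

    n_cov = Xc.shape[1]

    def _split(X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X_new = np.asarray(X_new, dtype=float)
        if n_cov:
            return X_new[:, :-n_cov], (X_new[:, -n_cov:] - mu) / sd
        return X_new, np.zeros((len(X_new), 0))

    def predict(X_new: np.ndarray) -> np.ndarray:
        xg, xc = _split(X_new)
        return net.predict(xg, xc) * y_sd + y_mu

    def input_gradient(X_new: np.ndarray) -> np.ndarray:
        xg, xc = _split(X_new)
        dXg, dXc = net.input_gradient(xg, xc)
        if n_cov:
            return np.hstack([dXg, dXc / sd]) * y_sd
        return dXg * y_sd

    val_pred = predict(np.hstack([Xg[val_idx], Xc_raw[val_idx]]) if n_cov else Xg[val_idx])
    ss_res = float(((y[val_idx] - val_pred) ** 2).sum())
    ss_tot = float(((y[val_idx] - y[val_idx].mean()) ** 2).sum())
    return ModelBundle(
        kind="nonlinear_net",
        predict=predict,
        metadata={
            "seed": seed,
            "epochs": info["epochs"],
            "val_loss": info["val_loss"],
            "val_r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            "n_cov": n_cov,
            "column_map": design.column_map,
        },
        model=net,
        input_gradient=input_gradient,
    )


def design_with_covariates(
    design: EncodedDesign, covariates: pd.DataFrame | None
) -> np.ndarray:
    """Concatenate the genotype design with raw covariate columns (the input
    layout expected by nonlinear-predictor bundles)."""
    Xc = covariate_matrix(covariates, design.matrix.shape[0])
    return np.hstack([design.matrix, Xc]) if Xc.shape[1] else design.matrix


# ---------------------------------------------------------------------------
# Integrated gradients
# ---------------------------------------------------------------------------


@dataclass
class AttributionVector:
    """Per-column integrated-gradients attributions on an evaluation set."""

    attributions: np.ndarray  # (n_samples, n_columns)
    baseline: np.ndarray
    n_steps: int
    column_map: list[tuple[str, str]] | None = None

    def column_scores(self) -> np.ndarray:
        return np.abs(self.attributions).mean(axis=0)

    def variant_scores(self) -> pd.Series:
        """Mean absolute attribution per variant (over its columns, samples)."""
        if self.column_map is None:
            raise ValueError("no column map attached")
        scores = np.abs(self.attributions)
        by_variant: dict[str, list[int]] = {}
        for c, (v, _) in enumerate(self.column_map):
            by_variant.setdefault(v, []).append(c)
        return pd.Series(
            {v: float(scores[:, cols].mean()) for v, cols in by_variant.items()}
        )


def attribute_integrated_gradients(
    model: ModelBundle,
    X_val: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 64,
    column_map: list[tuple[str, str]] | None = None,
) -> AttributionVector:
    """Integrated gradients along the straight path from baseline to input.

    attribution_ij = (x_ij - baseline_j) * mean over midpoints of
    d f / d x_j; satisfies completeness as n_steps grows.  Default baseline
    is the all-zeros vector (zero one-hot, covariates at 0 of their raw
    scale unless a baseline is supplied).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if model.input_gradient is None:
        raise ValueError(f"model kind {model.kind!r} exposes no input gradients")
    X_val = np.asarray(X_val, dtype=float)
    if baseline is None:
        baseline = np.zeros(X_val.shape[1])
    baseline = np.asarray(baseline, dtype=float)
    if baseline.ndim == 1:
        baseline = np.broadcast_to(baseline, X_val.shape)
    diff = X_val - baseline
    grad_sum = np.zeros_like(X_val)
    for k in range(n_steps):
        alpha = (k + 0.5) / n_steps  # midpoint rule
        grad_sum += model.input_gradient(baseline + alpha * diff)
    attr = diff * grad_sum / n_steps
    cmap = column_map or model.metadata.get("column_map")
    return AttributionVector(attr, baseline[0].copy(), n_steps, cmap)


def select_top_snvs(attr_by_run: Sequence[AttributionVector], k: int = 128) -> list[str]:
    """Top-k variants by mean absolute attribution across runs.

    Ties at the boundary break toward the earlier variant (column-map order).
    """
    if not attr_by_run:
        raise ValueError("need at least one attribution vector")
    per_run = [a.variant_scores() for a in attr_by_run]
    order = list(per_run[0].index)
    mean_scores = pd.concat(per_run, axis=1).mean(axis=1).reindex(order)
    if k > len(order):
        warnings.warn(f"k={k} exceeds {len(order)} variants; returning all")
        k = len(order)
    idx_rank = {v: i for i, v in enumerate(order)}
    ranked = sorted(order, key=lambda v: (-mean_scores[v], idx_rank[v]))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Bayesian optimization over the top-variant fraction
# ---------------------------------------------------------------------------


@dataclass
class BoTrace:
    fractions: list[float] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)  # "seed" | "bo" | "failed"

    def best(self) -> tuple[float, float]:
        finite = [
            (f, s) for f, s, src in zip(self.fractions, self.scores, self.sources)
            if src != "failed"
        ]
        if not finite:
            raise RuntimeError("no successful objective evaluations")
        f, s = max(finite, key=lambda t: t[1])
        return f, s


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return sigma * (z * stats.norm.cdf(z) + stats.norm.pdf(z))


def bo_fraction_search(
    objective: Callable[[float], float],
    seeds: Sequence[float],
    n_iter: int = 10,
    seed: int = 0,
    bounds: tuple[float, float] = (0.01, 1.0),
) -> tuple[float, float, BoTrace]:
    """Sequential model-based search for the best retained-variant fraction.

    Seed fractions are evaluated first, then a Gaussian-process surrogate
    (Matern 5/2) proposes ``n_iter`` further fractions by expected
    improvement; if the surrogate cannot be fit, uniformly random candidates
    are used.  Non-finite objective values are recorded as failures and the
    search continues.  Returns (best_fraction, best_score, trace).
    """
    rng = np.random.default_rng(seed)
    trace = BoTrace()

    def evaluate(frac: float, source: str) -> None:
        frac = float(np.clip(frac, bounds[0], bounds[1]))
        try:
            score = float(objective(frac))
        except FloatingPointError:
            score = np.nan
        if not np.isfinite(score):
            trace.fractions.append(frac)
            trace.scores.append(np.nan)
            trace.sources.append("failed")
        else:
            trace.fractions.append(frac)
            trace.scores.append(score)
            trace.sources.append(source)

    for s in seeds:
        evaluate(s, "seed")

    for _ in range(n_iter):
        xs = [f for f, src in zip(trace.fractions, trace.sources) if src != "failed"]
        ys = [s for s, src in zip(trace.scores, trace.sources) if src != "failed"]
        cand = rng.uniform(bounds[0], bounds[1], size=256)
        if len(xs) >= 2 and np.std(ys) > 0:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gp = GaussianProcessRegressor(
                        kernel=Matern(length_scale=0.2, nu=2.5),
                        alpha=1e-6,
                        normalize_y=True,
                        random_state=seed,
                    ).fit(np.asarray(xs)[:, None], np.asarray(ys))
                mu, sigma = gp.predict(cand[:, None], return_std=True)
                ei = _expected_improvement(mu, sigma, max(ys))
                nxt = float(cand[int(np.argmax(ei))])
            except Exception:
                nxt = float(cand[0])
        else:
            nxt = float(cand[0])
        evaluate(nxt, "bo")

    best_f, best_s = trace.best()
    return best_f, best_s, trace


# ---------------------------------------------------------------------------
# Interaction-constrained boosting
# ---------------------------------------------------------------------------

BOOST_STAGES = ("base", "plus_gxg", "plus_gxe")


def fit_constrained_boost(
    G: GenotypeMatrix | np.ndarray,
    covariates: pd.DataFrame | None,
    y: np.ndarray,
    stage: str,
    params: dict | None = None,
    seed: int = 0,
    train_idx: np.ndarray | None = None,
) -> ModelBundle:
    """Gradient-boosted trees with stage-wise feature-interaction constraints.

    base: each variant isolated in its own interaction group; covariates may
    interact among themselves only.  plus_gxg: variants share one group,
    covariates another.  plus_gxe: unconstrained.  Early stopping on an
    internal validation fraction; deterministic under ``seed``.
    """
    if stage not in BOOST_STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {BOOST_STAGES}")
    y = np.asarray(y, dtype=float)
    g = G.imputed() if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    n, m = g.shape
    Xc = covariate_matrix(covariates, n)
    X = np.hstack([g, Xc]) if Xc.shape[1] else g
    cov_cols = list(range(m, m + Xc.shape[1]))

    if stage == "base":
        cst = [[j] for j in range(m)]
        if cov_cols:
            cst.append(cov_cols)
    elif stage == "plus_gxg":
        cst = [list(range(m))]
        if cov_cols:
            cst.append(cov_cols)
    else:
        cst = None

    defaults = dict(
        max_iter=300, learning_rate=0.1, max_leaf_nodes=31,
        early_stopping=True, validation_fraction=0.15, n_iter_no_change=15,
    )
    if params:
        defaults.update(params)
    model = HistGradientBoostingRegressor(
        random_state=seed, interaction_cst=cst, **defaults
    )
    rows = np.arange(n) if train_idx is None else np.asarray(train_idx)
    model.fit(X[rows], y[rows])

    def predict(X_new: np.ndarray) -> np.ndarray:
        return model.predict(np.asarray(X_new, dtype=float))

    bundle = ModelBundle(
        kind="boosted_tree",
        predict=predict,
        metadata={"stage": stage, "seed": seed, "n_variants": m,
                  "n_cov": Xc.shape[1], "n_iter": model.n_iter_},
        model=model,
    )
    bundle.predict_rows = lambda idx: model.predict(X[np.asarray(idx)])  # type: ignore[attr-defined]
    return bundle
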