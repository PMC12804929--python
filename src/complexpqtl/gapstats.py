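"""Performance-gap inference and decomposition: paired bootstrap model
comparison, FDR adjustment, gap-source classification, iterative linear
complexity, staged boosted decomposition, group-wise transfer evaluation,
and exact binomial (Clopper-Pearson) intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BootstrapSummary:
    """Paired model-comparison summary over B bootstrap resamples."""

    mean_r2_a: float
    mean_r2_b: float
    ci_r2_a: tuple[float, float]
    ci_r2_b: tuple[float, float]
    mean_rmse_a: float
    mean_rmse_b: float
    ci_rmse_a: tuple[float, float]
    ci_rmse_b: tuple[float, float]
    gap: float  # mean R2(a) - mean R2(b)
    significant_nonoverlap: bool
    empirical_p: float
    n_boot_effective: int
    fdr_q: float | None = None

    def to_dict(self) -> dict:
        return {
            "r2_a": {"mean": self.mean_r2_a, "ci": list(self.ci_r2_a)},
            "r2_b": {"mean": self.mean_r2_b, "ci": list(self.ci_r2_b)},
            "rmse_a": {"mean": self.mean_rmse_a, "ci": list(self.ci_rmse_a)},
            "rmse_b": {"mean": self.mean_rmse_b, "ci": list(self.ci_rmse_b)},
            "gap": self.gap,
            "significant_nonoverlap": self.significant_nonoverlap,
            "empirical_p": self.empirical_p,
            "n_boot_effective": self.n_boot_effective,
            "fdr_q": self.fdr_q,
        }


def _r2(y: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Coefficient of determination along the last axis."""
    sse = ((y - pred) ** 2).sum(axis=-1)
    sst = ((y - y.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    return 1.0 - sse / sst


def bootstrap_compare(
    y_true: np.ndarray,
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Paired bootstrap of R2 and RMSE for two prediction vectors.

    One resample-index vector per bootstrap is applied to both models.
    95% percentile CIs (2.5/97.5); ``gap`` is mean R2(a) - mean R2(b);
    significance requires non-overlapping R2 CIs with model a on top;
    empirical p is the proportion of resamples where R2(a) <= R2(b).
    Resamples with zero trait variance are skipped (logged in
    ``n_boot_effective``).
    """
    y_true = np.asarray(y_true, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    n = y_true.shape[0]
    if not (pred_a.shape[0] == pred_b.shape[0] == n):
        raise ValueError("prediction vectors must match y_true in length")
    if n < 10:
        raise ValueError("need at least 10 samples to bootstrap")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    yb = y_true[idx]
    ok = yb.var(axis=1) > 0
    n_eff = int(ok.sum())
    if n_eff == 0:
        raise ValueError("all bootstrap resamples have zero trait variance")
    if n_eff < n_boot:
        warnings.warn(f"skipped {n_boot - n_eff} zero-variance resamples")
    yb = yb[ok]
    pa = pred_a[idx][ok]
    pb = pred_b[idx][ok]

    r2a = _r2(yb, pa)
    r2b = _r2(yb, pb)
    rmse_a = np.sqrt(((yb - pa) ** 2).mean(axis=1))
    rmse_b = np.sqrt(((yb - pb) ** 2).mean(axis=1))

    def ci(v: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    ci_a, ci_b = ci(r2a), ci(r2b)
    mean_a, mean_b = float(r2a.mean()), float(r2b.mean())
    significant = bool(ci_a[0] > ci_b[1]) and mean_a > mean_b
    emp_p = float((r2a <= r2b).mean())
    return BootstrapSummary(
        mean_r2_a=mean_a,
        mean_r2_b=mean_b,
        ci_r2_a=ci_a,
        ci_r2_b=ci_b,
        mean_rmse_a=float(rmse_a.mean()),
        mean_rmse_b=float(rmse_b.mean()),
        ci_rmse_a=ci(rmse_a),
        ci_rmse_b=ci(rmse_b),
        gap=mean_a - mean_b,
        significant_nonoverlap=significant,
        empirical_p=emp_p,
        n_boot_effective=n_eff,
    )


def fdr_adjust(p_values: Sequence[float], clip_zeros_at: float | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    ``clip_zeros_at`` (e.g. 1/n_boot for bootstrap empirical p-values)
    replaces exact zeros before adjustment, since BH on exact zeros is
    degenerate.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if clip_zeros_at is not None:
        p = np.where(p == 0.0, clip_zeros_at, p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_gap_source(
    summary_full: BootstrapSummary,
    summary_cov_only: BootstrapSummary,
) -> str:
    """Attribute a significant non-linear gap to covariates or genetics.

    Returns ``"none"`` if the full-model gap is not significant;
    ``"covariate_nonlinearity"`` if the covariate-only non-linear-vs-linear
    gap reaches the full gap minus delta, where delta is the half-width of
    the full gap's bootstrap CI; else ``"genetic_or_other_nonlinearity"``.
    """
    if not summary_full.significant_nonoverlap:
        return "none"
    delta = 0.5 * (
        (summary_full.ci_r2_a[1] - summary_full.ci_r2_a[0]) / 2.0
        + (summary_full.ci_r2_b[1] - summary_full.ci_r2_b[0]) / 2.0
    )
    if summary_cov_only.gap >= summary_full.gap - delta:
        return "covariate_nonlinearity"
    return "genetic_or_other_nonlinearity"


@dataclass
class ComplexityLedger:
    """Ordered record of validation R2 as model terms are added."""

    entries: list[tuple[str, float, float]] = field(default_factory=list)

    def add(self, term: str, r2: float) -> None:
        prev = self.entries[-1][1] if self.entries else 0.0
        delta = r2 - prev if self.entries else 0.0
        self.entries.append((term, r2, delta))

    @property
    def terms(self) -> list[str]:
        return [t for t, _, _ in self.entries]

    def r2(self, term: str) -> float:
        return dict((t, r) for t, r, _ in self.entries)[term]

    def delta(self, term: str) -> float:
        return dict((t, d) for t, _, d in self.entries)[term]

    def telescoped(self) -> float:
        return sum(d for _, _, d in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["term", "r2", "delta_r2"])


def _ridge_fit_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_val: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """OLS with a tiny ridge for rank safety on expanded designs."""
    k = X_train.shape[1]
    A = X_train.T @ X_train + ridge * np.eye(k)
    beta = np.linalg.solve(A, X_train.T @ y_train)
    return X_val @ beta


DEFAULT_SCHEDULE = (
    "covariates+additive",
    "+nonlinear_covariates",
    "+onehot",
    "+exe",
    "+gxe",
    "+gxg",
)


def _complexity_design(
    term: str,
    g: np.ndarray,
    cov: np.ndarray,
    cov_names: list[str],
) -> list[np.ndarray]:
    """Incremental design-matrix blocks for each schedule term."""
    n, m = g.shape
    if term == "covariates+additive":
        return [np.ones((n, 1)), cov, g]
    if term == "+nonlinear_covariates":
        # squared and logistic transforms stand in for Age^2 / log(Age)-style terms
        return [np.hstack([cov**2, 1.0 / (1.0 + np.exp(-cov))])]
    if term == "+onehot":
        gi = np.clip(np.rint(g), 0, 2).astype(int)
        return [np.hstack([(gi == 1).astype(float), (gi == 2).astype(float)])]
    if term == "+exe":
        cols = []
        for a in range(cov.shape[1]):
            for b in range(a + 1, cov.shape[1]):
                cols.append((cov[:, a] * cov[:, b])[:, None])
        return [np.hstack(cols)] if cols else []
    if term == "+gxe":
        cols = [g * cov[:, [a]] for a in range(cov.shape[1])]
        return [np.hstack(cols)] if cols else []
    if term == "+gxg":
        cols = []
        for i in range(m):
            for j in range(i + 1, m):
                cols.append((g[:, i] * g[:, j])[:, None])
        return [np.hstack(cols)] if cols else []
    raise ValueError(f"unknown schedule term {term!r}")


def iterative_complexity(
    y: np.ndarray,
    G_sel,
    covariates: pd.DataFrame,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    ridge: float = 1e-8,
) -> ComplexityLedger:
    """Sequentially augment a linear model and track validation R2 per term.

    Starts from covariates plus additively coded genotypes, then adds
    non-linear covariate transforms, one-hot genotype encoding, ExE, GxE,
    and GxG product terms in schedule order, refitting a ridge-stabilized
    OLS at each step.
    """
    from .assoc import _covariate_design  # shared dummy-coding rules

    y = np.asarray(y, dtype=float)
    g = G_sel.imputed() if hasattr(G_sel, "imputed") else np.asarray(G_sel, float)
    cov_full = _covariate_design(covariates, len(y))[:, 1:]  # drop intercept col
    # standardize continuous blocks on train for conditioning
    mu = cov_full[train_idx].mean(axis=0)
    sd = cov_full[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    cov_z = (cov_full - mu) / sd

    ledger = ComplexityLedger()
    blocks: list[np.ndarray] = []
    for term in schedule:
        blocks.extend(
            _complexity_design(term, g, cov_z, list(covariates.columns))
        )
        X = np.hstack(blocks)
        pred = _ridge_fit_predict(X[train_idx], y[train_idx], X[val_idx], ridge)
        r2 = float(_r2(y[val_idx], pred))
        ledger.add(term, r2)
    return ledger


def decompose_stages(
    G_sel,
    covariates: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    seed: int = 0,
    boost_params: dict | None = None,
) -> dict:
    """Staged boosted decomposition: base -> +GxG -> +GxE.

    Fits interaction-constrained boosted models at each stage with identical
    seeds and early-stopping protocol; returns per-stage validation R2 and
    successive gains.
    """
    from .predictors import fit_constrained_boost

    y = np.asarray(y, dtype=float)
    out: dict = {"stages": {}, "gains": {}}
    prev = None
    for stage in ("base", "plus_gxg", "plus_gxe"):
        bundle = fit_constrained_boost(
            G_sel, covariates, y, stage=stage, seed=seed,
            train_idx=train_idx, params=boost_params,
        )
        pred = bundle.predict_rows(val_idx)
        r2 = float(_r2(y[val_idx], pred))
        out["stages"][stage] = r2
        if prev is not None:
            out["gains"][stage] = r2 - prev
        prev = r2
    return out


def transfer_gap(
    data: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]],
    n_boot: int = 1000,
    seed: int = 0,
    min_group_size: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-wise model-comparison gaps and their cross-group correlation.

    ``data`` maps group -> trait -> (y_true, pred_a, pred_b).  Per group and
    trait, the paired bootstrap gap is computed; when both mean R2 values are
    negative the gap is set to 0.  The second return value is the Pearson
    correlation of per-trait gaps between every pair of groups (NaN when
    undefined).  Groups with fewer than ``min_group_size`` samples are
    excluded with a warning.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for group, traits in data.items():
        for trait, (y, pa, pb) in traits.items():
            if len(y) < min_group_size:
                warnings.warn(f"group {group!r} trait {trait!r}: "
                              f"{len(y)} samples < {min_group_size}, excluded")
                continue
            s = bootstrap_compare(y, pa, pb, n_boot=n_boot, seed=seed)
            gap = s.gap
            if s.mean_r2_a < 0 and s.mean_r2_b < 0:
                gap = 0.0
            rows.append(
                {"group": group, "trait": trait, "r2_a": s.mean_r2_a,
                 "r2_b": s.mean_r2_b, "gap": gap,
                 "significant": s.significant_nonoverlap}
            )
    table = pd.DataFrame(rows)
    groups = sorted(table["group"].unique()) if not table.empty else []
    corr = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for a in groups:
        for b in groups:
            ga = table[table["group"] == a].set_index("trait")["gap"]
            gb = table[table["group"] == b].set_index("trait")["gap"]
            common = ga.index.intersection(gb.index)
            if len(common) >= 2 and ga[common].std() > 0 and gb[common].std() > 0:
                corr.loc[a, b] = float(np.corrcoef(ga[common], gb[common])[0, 1])
    return table, corr


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError("require 0 <= successes <= n and n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lower, upper


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Share as a percentage, rounded to ``decimals`` places."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, decimals)
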