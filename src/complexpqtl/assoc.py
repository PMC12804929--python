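"""Association scanning: per-variant additive OLS, GWAS-style pre-filtering,
per-genotype non-additivity tests, and the pairwise epistasis scan with
Bonferroni bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix


@dataclass
class AssocRecord:
    """Per-variant OLS result under a stated genotype coding."""

    variant: str
    coding: str  # {"additive", "onehot"}
    beta: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: float  # p of the primary term (additive slope / dominance contrast)
    estimable: bool = True
    term_p: dict[str, float] = field(default_factory=dict)
    notes: str = ""


@dataclass
class InteractionHit:
    variant_i: str
    variant_j: str
    chrom_i: str
    chrom_j: str
    beta: float
    se: float
    t: float
    p: float
    n_pairs_tested: int = 0
    bonferroni_threshold: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p < self.bonferroni_threshold)


def n_pairs(n_variants: int, n_traits: int = 1) -> int:
    """Total unordered variant pairs enumerated across traits."""
    if n_variants < 0 or n_traits < 0:
        raise ValueError("counts must be non-negative")
    return n_traits * comb(n_variants, 2)


def bonferroni_threshold(n_variants: int, n_traits: int = 1, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_traits * C(n_variants, 2))."""
    total = n_pairs(n_variants, n_traits)
    if total == 0:
        raise ValueError("no pairs to test")
    return alpha / total


def _covariate_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Numeric covariate design with intercept; categoricals are dummy-coded."""
    cols = [np.ones((n, 1))]
    if covariates is not None:
        num = covariates.select_dtypes(include=[np.number])
        if not num.empty:
            cols.append(num.to_numpy(dtype=float))
        cat = covariates.select_dtypes(exclude=[np.number])
        if not cat.empty:
            cols.append(pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float))
    return np.hstack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """OLS via pseudo-inverse: (beta, se, t, df_resid, XtX_inv)."""
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - np.linalg.matrix_rank(xtx)
    sigma2 = float(resid @ resid) / max(df, 1)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return beta, se, t, df, xtx_inv


def _t_pvalue(t: np.ndarray | float, df: int) -> np.ndarray | float:
    return 2.0 * stats.t.sf(np.abs(t), max(df, 1))


def gwas_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> list[AssocRecord]:
    """Additive-coded OLS of the trait on each variant, adjusting covariates.

    Uses Frisch-Waugh-Lovell: trait and dosage are residualized on the
    covariate design once, giving slopes, SEs, and t/p identical to the full
    joint OLS with exact residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = G.n_samples
    if y.shape[0] != n:
        raise ValueError("trait length does not match sample count")
    C = _covariate_design(covariates, n)
    rank_c = np.linalg.matrix_rank(C)
    # residualize on covariates
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    Gd = G.imputed()
    G_r = Gd - Q @ (Q.T @ Gd)

    gss = (G_r**2).sum(axis=0)
    df = n - rank_c - 1
    records: list[AssocRecord] = []
    gty = G_r.T @ y_r
    yss = float(y_r @ y_r)
    ids = G.variant_ids()
    for j in range(G.n_variants):
        if gss[j] <= 1e-12:
            records.append(
                AssocRecord(ids[j], "additive", {"g": 0.0}, {"g": np.nan},
                            {"g": 0.0}, 1.0, estimable=False,
                            notes="zero-variance variant")
            )
            continue
        beta = gty[j] / gss[j]
        rss = yss - beta * gty[j]
        sigma2 = max(rss, 0.0) / max(df, 1)
        se = float(np.sqrt(sigma2 / gss[j]))
        if se > 0:
            t = beta / se
            p = float(_t_pvalue(t, df))
        else:  # exact fit: zero residual variance
            t = np.inf if beta != 0 else 0.0
            p = 0.0 if beta != 0 else 1.0
        records.append(
            AssocRecord(ids[j], "additive", {"g": float(beta)}, {"g": se},
                        {"g": float(t)}, p)
        )
    return records


def prefilter(records: list[AssocRecord], p_threshold: float = 1e-3) -> list[str]:
    """Variants with p strictly below the threshold, order preserved."""
    return [r.variant for r in records if r.estimable and r.p < p_threshold]


def nonadditivity_ols(
    g: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant: str = "variant",
) -> AssocRecord:
    """Per-genotype OLS with homozygous-reference as the dropped level.

    Fits y ~ 1 + I(g==1) + I(g==2) + covariates and additionally reports a
    1-df dominance contrast p testing beta_het - beta_hom_alt/2 = 0
    (deviation of the heterozygote from the additive midpoint).
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    classes = [k for k in (0, 1, 2) if np.any(g == k)]
    if len(classes) < 2:
        raise ValueError("need >= 2 observed genotype classes")
    C = _covariate_design(covariates, n)

    indicator_cols = []
    present = []
    for k in (1, 2):
        col = (g == k).astype(float)
        if col.sum() > 0:
            indicator_cols.append(col[:, None])
            present.append(k)
    X = np.hstack([C[:, :1]] + indicator_cols + [C[:, 1:]])
    beta, se, t, df, xtx_inv = _ols(X, y)

    names = ["intercept"] + [f"g{k}" for k in present]
    betas = {names[i]: float(beta[i]) for i in range(len(names))}
    ses = {names[i]: float(se[i]) for i in range(len(names))}
    ts = {names[i]: float(t[i]) for i in range(len(names))}
    term_p = {
        names[i]: float(_t_pvalue(t[i], df)) for i in range(1, len(names))
    }

    notes = ""
    missing_classes = [k for k in (1, 2) if k not in present and np.any(g == k) is False]
    if len(present) < 2:
        notes = f"classes absent: {sorted(set((1, 2)) - set(present))}"

    # dominance contrast: c = [0, 1, -1/2, 0...] over (intercept, g1, g2)
    if present == [1, 2]:
        c = np.zeros(X.shape[1])
        c[1], c[2] = 1.0, -0.5
        est = float(c @ beta)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / max(df, 1)
        var_c = float(c @ xtx_inv @ c) * sigma2
        tc = est / np.sqrt(var_c) if var_c > 0 else 0.0
        p = float(_t_pvalue(tc, df))
    else:
        p = 1.0
        notes = (notes + "; " if notes else "") + "dominance contrast inestimable"
    return AssocRecord(variant, "onehot", betas, ses, ts, p,
                       estimable=(present == [1, 2]), term_p=term_p, notes=notes)


def interaction_scan(
    G_top: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    cross_chromosome_only: bool = False,
    n_pairs_total: int | None = None,
    max_pairs: int = 500_000,
) -> list[InteractionHit]:
    """Pairwise epistasis scan over all unordered variant pairs.

    For each pair: OLS with one-hot main effects for both variants plus a
    single product term of the additive dosage codings; the reported p is the
    two-sided t-test on the product coefficient.  The Bonferroni threshold
    divides ``alpha`` by ``n_pairs_total`` when given (pooled across traits),
    else by the number of pairs tested in this call.  Hits are sorted by p.
    """
    y = np.asarray(y, dtype=float)
    n = G_top.n_samples
    C = _covariate_design(covariates, n)
    Q, _ = np.linalg.qr(C)
    rank_c = np.linalg.matrix_rank(C)

    Gd = G_top.imputed()
    chroms = G_top.variants["chrom"].astype(str).tolist()
    ids = G_top.variant_ids()
    m = G_top.n_variants

    pair_list = [
        (i, j)
        for i, j in combinations(range(m), 2)
        if not cross_chromosome_only or chroms[i] != chroms[j]
    ]
    if len(pair_list) > max_pairs:
        raise ValueError(
            f"{len(pair_list)} pairs exceeds the configured budget {max_pairs}"
        )

    # residualize trait and all per-variant columns on covariates once
    y_r = y - Q @ (Q.T @ y)
    het = (np.rint(Gd) == 1).astype(float)
    hom = (np.rint(Gd) == 2).astype(float)
    het_r = het - Q @ (Q.T @ het)
    hom_r = hom - Q @ (Q.T @ hom)

    n_tested = 0
    hits: list[InteractionHit] = []
    for i, j in pair_list:
        cols = []
        for src, k in ((het, i), (hom, i), (het, j), (hom, j)):
            if src[:, k].sum() > 0:  # drop zero-observation classes
                cols.append((src is het, k))
        prod = Gd[:, i] * Gd[:, j]
        X_parts = [
            (het_r if is_het else hom_r)[:, k][:, None] for is_het, k in cols
        ]
        prod_r = prod - Q @ (Q.T @ prod)
        X = np.hstack(X_parts + [prod_r[:, None]])

        xtx = X.T @ X
        rank = np.linalg.matrix_rank(xtx)
        if rank < X.shape[1]:
            continue  # collinear pair (e.g., r^2 = 1): skipped
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (X.T @ y_r)
        resid = y_r - X @ beta
        df = n - rank_c - X.shape[1]
        sigma2 = float(resid @ resid) / max(df, 1)
        se = float(np.sqrt(max(xtx_inv[-1, -1], 0.0) * sigma2))
        n_tested += 1
        if se <= 0:
            continue
        t = float(beta[-1] / se)
        p = float(_t_pvalue(t, df))
        hits.append(
            InteractionHit(ids[i], ids[j], chroms[i], chroms[j],
                           float(beta[-1]), se, t, p)
        )

    denom = n_pairs_total if n_pairs_total is not None else max(n_tested, 1)
    threshold = alpha / denom
    for h in hits:
        h.n_pairs_tested = denom
        h.bonferroni_threshold = threshold
    hits.sort(key=lambda h: (h.p, h.variant_i, h.variant_j))
    return hits


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def records_to_frame(records: list[AssocRecord], G: GenotypeMatrix | None = None) -> pd.DataFrame:
    meta = {}
    if G is not None:
        meta = dict(zip(G.variant_ids(), zip(G.variants["chrom"], G.variants["pos"])))
    rows = []
    for r in records:
        chrom, pos = meta.get(r.variant, ("", -1))
        primary = "g" if r.coding == "additive" else "g1"
        rows.append(
            {
                "variant": r.variant,
                "chrom": chrom,
                "pos": pos,
                "coding": r.coding,
                "beta": r.beta.get(primary, np.nan),
                "se": r.se.get(primary, np.nan),
                "t": r.t.get(primary, np.nan),
                "p": r.p,
                "estimable": r.estimable,
            }
        )
    return pd.DataFrame(rows)


def write_summary_stats(records: list[AssocRecord], path: str | Path, G=None) -> None:
    records_to_frame(records, G).to_csv(path, sep="\t", index=False)


def hits_to_frame(hits: list[InteractionHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_i": h.variant_i,
                "variant_j": h.variant_j,
                "chrom_i": h.chrom_i,
                "chrom_j": h.chrom_j,
                "beta": h.beta,
                "se": h.se,
                "t": h.t,
                "p": h.p,
                "n_pairs_tested": h.n_pairs_tested,
                "bonferroni_threshold": h.bonferroni_threshold,
                "significant": h.significant,
            }
            for h in hits
        ]
    )


def interchromosomal_fraction(hits: list[InteractionHit], chrom_a: str, chrom_b: str) -> float:
    """Fraction of hits whose pair spans the two named chromosomes."""
    if not hits:
        raise ValueError("no hits to tabulate")
    match = sum(
        1
        for h in hits
        if {h.chrom_i, h.chrom_j} == {str(chrom_a), str(chrom_b)}
    )
    return match / len(hits)
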