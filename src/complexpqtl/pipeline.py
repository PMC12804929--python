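"""Per-trait orchestration: deterministic splits, GWAS pre-filtering,
multi-run non-linear training with attribution-guided Bayesian optimization
of the retained-variant fraction, test-set ensembling, and the elastic-net
benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import assoc
from ._net import NetArch
from .genio import GenotypeMatrix
from .predictors import (
    EncodedDesign,
    attribute_integrated_gradients,
    bo_fraction_search,
    design_with_covariates,
    encode,
    fit_elastic_net_cv,
    fit_nonlinear_predictor,
    select_top_snvs,
)


@dataclass
class SplitSpec:
    """Disjoint train/validation/test row partitions plus optional extra
    named test groups for transfer evaluation."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    extra_groups: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [self.train, self.validation, self.test, *self.extra_groups.values()]
        flat = np.concatenate([np.asarray(p) for p in parts])
        if len(np.unique(flat)) != len(flat):
            raise ValueError("split parts must be pairwise disjoint")


def make_splits(
    sample_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    group_labels: Sequence[str] | None = None,
    holdout_groups: Sequence[str] = (),
) -> SplitSpec:
    """Deterministic random partition into train/validation/test.

    Samples whose group label is in ``holdout_groups`` never enter train or
    validation; they form extra named test groups.
    """
    n = len(sample_ids)
    if n == 0:
        raise ValueError("no samples to split")
    if sum(fractions) > 1.0 + 1e-9:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(n)

    extra: dict[str, np.ndarray] = {}
    if group_labels is not None:
        labels = np.asarray(group_labels)
        held = np.zeros(n, dtype=bool)
        for g in holdout_groups:
            mask = labels == g
            extra[str(g)] = idx[mask]
            held |= mask
        idx = idx[~held]

    perm = rng.permutation(idx)
    n_train = int(round(fractions[0] * len(perm)))
    n_val = int(round(fractions[1] * len(perm)))
    n_test = int(round(fractions[2] * len(perm)))
    train = np.sort(perm[:n_train])
    val = np.sort(perm[n_train : n_train + n_val])
    test = np.sort(perm[n_train + n_val : n_train + n_val + n_test])
    for part, name in ((train, "train"), (val, "validation"), (test, "test")):
        if len(part) == 0:
            raise ValueError(f"empty {name} split")
    return SplitSpec(train, val, test, extra, seed)


@dataclass
class PipelineConfig:
    """Reproducible configuration snapshot for a per-trait run."""

    prefilter_p: float = 1e-3
    n_runs: int = 10
    n_shared_runs: int = 3
    base_seed: int = 0
    bo_n_iter: int = 5
    bo_seed_fractions: tuple[float, ...] = (0.25, 0.5, 1.0)
    attribution_steps: int = 32
    en_alphas: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    en_n_lambda: int = 100
    en_k_folds: int = 10
    linear_uses_all_variants: bool = True
    arch: NetArch = field(default_factory=NetArch)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["arch"] = asdict(self.arch)
        return d

    @classmethod
    def from_snapshot(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        arch = d.pop("arch", {})
        arch = {**arch, "hidden": tuple(arch.get("hidden", (128, 64)))}
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        cfg.arch = NetArch(**arch)
        return cfg


@dataclass
class PipelineResult:
    val_scores: list[float]
    variant_sets: list[list[str]]
    bo_trace: object | None
    ensemble_pred_nonlinear: np.ndarray
    ensemble_pred_linear: np.ndarray
    per_run_test_preds: list[np.ndarray]
    config_snapshot: dict
    test_idx: np.ndarray
    y_test: np.ndarray
    rows_touched_before_test: set[int]
    flags: list[str] = field(default_factory=list)
    gwas_records: list | None = None


def _covariates_only_design(n: int) -> EncodedDesign:
    # degenerate one-variant design so the net still trains on covariates
    return EncodedDesign(np.zeros((n, 4)), "onehot", [("_null", c) for c in
                        ("hom_ref", "het", "hom_alt", "missing")], ["_null"])


def run_trait_pipeline(
    G: GenotypeMatrix,
    S: pd.DataFrame,
    trait: np.ndarray,
    splits: SplitSpec,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """End-to-end per-trait run.

    (1) GWAS on training rows only, pre-filter at ``config.prefilter_p``;
    (2) the first ``n_shared_runs`` train the non-linear predictor on all
    pre-filtered variants with per-run seeds; (3) integrated-gradients
    attributions averaged over those runs rank variants; (4) Bayesian
    optimization selects the retained top-fraction on validation
    performance; (5) remaining runs train on the selected subset; (6) the
    ensemble is the mean test prediction over all runs; (7) the elastic-net
    benchmark sees the full variant set (no pre-filter) by default.
    """
    config = config or PipelineConfig()
    y = np.asarray(trait, dtype=float)
    if np.var(y[splits.train]) == 0:
        raise ValueError("trait is constant on the training split")

    touched: set[int] = set()
    flags: list[str] = []

    def track(idx) -> np.ndarray:
        idx = np.asarray(idx)
        touched.update(int(i) for i in idx)
        return idx

    train_idx = track(splits.train)
    val_idx = track(splits.validation)
    fit_idx = np.concatenate([train_idx, val_idx])

    # (1) GWAS pre-filter on the training rows only
    G_train = G.subset(sample_idx=train_idx)
    records = assoc.gwas_scan(G_train, y[train_idx], S.iloc[train_idx])
    selected = assoc.prefilter(records, config.prefilter_p)

    if not selected:
        flags.append("prefilter_empty:covariates_only")
        design_full = _covariates_only_design(G.n_samples)
    else:
        design_full = encode(G.subset(variant_idx=[
            G.variant_ids().index(v) for v in selected
        ]), "onehot")

    X_full = design_with_covariates(design_full, S)
    # IG baseline: all-zeros one-hot with covariates at training means
    n_geno_cols = design_full.matrix.shape[1]
    ig_baseline = np.zeros(X_full.shape[1])
    if X_full.shape[1] > n_geno_cols:
        ig_baseline[n_geno_cols:] = X_full[train_idx, n_geno_cols:].mean(axis=0)

    # (2) shared runs on every pre-filtered variant
    run_bundles = []
    val_scores: list[float] = []
    variant_sets: list[list[str]] = []
    attrs = []
    for run in range(config.n_shared_runs):
        seed = config.base_seed + run
        bundle = fit_nonlinear_predictor(
            design_full, S, y, train_idx, val_idx, arch=config.arch, seed=seed
        )
        run_bundles.append((bundle, design_full))
        val_scores.append(bundle.metadata["val_r2"])
        variant_sets.append(list(design_full.variant_ids))
        attrs.append(
            attribute_integrated_gradients(
                bundle, X_full[val_idx], baseline=ig_baseline,
                n_steps=config.attribution_steps,
            )
        )

    # (3)+(4) attribution ranking and BO over the retained fraction
    bo_trace = None
    design_selected = design_full
    if selected and len(design_full.variant_ids) > 1 and config.n_runs > config.n_shared_runs:
        ranking = select_top_snvs(attrs, k=len(design_full.variant_ids))

        def objective(fraction: float) -> float:
            k = max(1, int(round(fraction * len(ranking))))
            sub = design_full.subset_variants(ranking[:k])
            b = fit_nonlinear_predictor(
                sub, S, y, train_idx, val_idx, arch=config.arch,
                seed=config.base_seed + 1000,
            )
            return b.metadata["val_r2"]

        best_frac, _, bo_trace = bo_fraction_search(
            objective,
            seeds=config.bo_seed_fractions,
            n_iter=config.bo_n_iter,
            seed=config.base_seed,
        )
        k = max(1, int(round(best_frac * len(ranking))))
        design_selected = design_full.subset_variants(ranking[:k])

    # (5) remaining runs on the BO-selected subset
    for run in range(config.n_shared_runs, config.n_runs):
        seed = config.base_seed + run
        bundle = fit_nonlinear_predictor(
            design_selected, S, y, train_idx, val_idx, arch=config.arch, seed=seed
        )
        run_bundles.append((bundle, design_selected))
        val_scores.append(bundle.metadata["val_r2"])
        variant_sets.append(list(design_selected.variant_ids))

    rows_before_test = set(touched)

    # (6) test-set ensemble
    test_idx = np.asarray(splits.test)
    per_run_preds = []
    for bundle, design in run_bundles:
        X = design_with_covariates(design, S)
        per_run_preds.append(bundle.predict(X[test_idx]))
    ensemble_nl = np.mean(per_run_preds, axis=0)

    # (7) elastic-net benchmark (full variant set by default)
    if config.linear_uses_all_variants or not selected:
        G_lin = G
    else:
        G_lin = G.subset(variant_idx=[G.variant_ids().index(v) for v in selected])
    X_lin = design_with_covariates(encode(G_lin, "additive"), S)
    en = fit_elastic_net_cv(
        X_lin[fit_idx], y[fit_idx],
        alphas=config.en_alphas, n_lambda=config.en_n_lambda,
        k_folds=config.en_k_folds, seed=config.base_seed,
    )
    ensemble_lin = en.predict(X_lin[test_idx])

    return PipelineResult(
        val_scores=val_scores,
        variant_sets=variant_sets,
        bo_trace=bo_trace,
        ensemble_pred_nonlinear=ensemble_nl,
        ensemble_pred_linear=ensemble_lin,
        per_run_test_preds=per_run_preds,
        config_snapshot=config.snapshot(),
        test_idx=test_idx,
        y_test=y[test_idx],
        rows_touched_before_test=rows_before_test,
        flags=flags,
        gwas_records=records,
    )


def run_small_cohort_variant(
    G: GenotypeMatrix,
    S: pd.DataFrame,
    trait: np.ndarray,
    splits: SplitSpec,
    config: PipelineConfig | None = None,
    p_seed_thresholds: tuple[float, ...] = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4),
) -> PipelineResult:
    """Small-cohort protocol: 20 CV runs and BO seeded with fractions that
    correspond to GWAS p-value thresholds (most to least significant) before
    free search."""
    config = config or PipelineConfig()
    if config.n_runs == PipelineConfig.n_runs:
        config.n_runs = 20

    # derive seed fractions from the training-set GWAS p-value ranking
    y = np.asarray(trait, dtype=float)
    G_train = G.subset(sample_idx=splits.train)
    records = assoc.gwas_scan(G_train, y[splits.train], S.iloc[np.asarray(splits.train)])
    selected_p = sorted(r.p for r in records if r.estimable and r.p < config.prefilter_p)
    if selected_p:
        fracs = []
        for t in p_seed_thresholds:
            k = sum(p < t for p in selected_p)
            if k > 0:
                fracs.append(k / len(selected_p))
        seen = set()
        seed_fracs = tuple(f for f in fracs if not (f in seen or seen.add(f))) or (1.0,)
        config.bo_seed_fractions = seed_fracs
    return run_trait_pipeline(G, S, trait, splits, config)


def predictions_frame(result: PipelineResult, sample_ids: Sequence[str]) -> pd.DataFrame:
    ids = [sample_ids[i] for i in result.test_idx]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "y_true": result.y_test,
            "y_pred_nonlinear": result.ensemble_pred_nonlinear,
            "y_pred_linear": result.ensemble_pred_linear,
        }
    )
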