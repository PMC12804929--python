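"""Synthetic cohort generation: genotypes, covariates, and traits with
planted additive, dominance, epistatic, GxE, ExE, and non-linear covariate
components.

All generators are pure functions of their seed and configuration, and the
trait simulator returns a ground-truth ledger of the variance contributed by
every component on the realized sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .genio import MISSING, GenotypeMatrix, write_plink, write_table

# Named non-linear covariate functions usable in an EffectSpec; each maps a
# covariate DataFrame to one trait component vector, scaled by its weight.
COVARIATE_FN_REGISTRY: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    # logistic step in age that only applies to one sex (sex-gated menopause-like)
    "sex_gated_age_step": lambda S: S["sex"].to_numpy(float)
    / (1.0 + np.exp(-(S["age"].to_numpy(float) - 50.0) / 2.0)),
    "age_squared": lambda S: ((S["age"].to_numpy(float) - 55.0) / 10.0) ** 2,
    "log_age": lambda S: np.log(S["age"].to_numpy(float)),
    "age_sex_product": lambda S: S["sex"].to_numpy(float)
    * (S["age"].to_numpy(float) - 55.0)
    / 10.0,
}


class SpecificationError(ValueError):
    """An EffectSpec references unknown variants, covariates, or functions."""


@dataclass
class EffectSpec:
    """Ground-truth generative structure of a simulated trait.

    additive: (variant_index, beta per effect-allele count)
    dominance: (variant_index, (mean_g0, mean_g1, mean_g2)) genotype-class means
    epistatic: (variant_i, variant_j, 3x3 offset table indexed by genotypes)
    gxe: (variant_index, covariate_name, beta on dosage x covariate)
    exe: (covariate_a, covariate_b, beta on product)
    covariate_fns: (registry_name, weight) non-linear covariate components
    """

    additive: list[tuple[int, float]] = field(default_factory=list)
    dominance: list[tuple[int, tuple[float, float, float]]] = field(default_factory=list)
    epistatic: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    gxe: list[tuple[int, str, float]] = field(default_factory=list)
    exe: list[tuple[str, str, float]] = field(default_factory=list)
    covariate_fns: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    scale: str = "raw"  # {"raw", "log2like"}

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be >= 0")
        if self.scale not in ("raw", "log2like"):
            raise SpecificationError(f"unknown scale {self.scale!r}")
        self.epistatic = [
            (i, j, np.asarray(t, dtype=float)) for i, j, t in self.epistatic
        ]
        for i, j, t in self.epistatic:
            if t.shape != (3, 3) or not np.isfinite(t).all():
                raise SpecificationError("epistatic tables must be finite 3x3")

    def validate_against(self, G: GenotypeMatrix, S: pd.DataFrame) -> None:
        m = G.n_variants
        idxs = (
            [i for i, _ in self.additive]
            + [i for i, _ in self.dominance]
            + [k for i, j, _ in self.epistatic for k in (i, j)]
            + [i for i, _, _ in self.gxe]
        )
        for i in idxs:
            if not 0 <= i < m:
                raise SpecificationError(f"variant index {i} outside [0, {m})")
        covs = (
            [c for _, c, _ in self.gxe]
            + [c for pair in self.exe for c in pair[:2]]
        )
        for c in covs:
            if c not in S.columns:
                raise SpecificationError(f"unknown covariate {c!r}")
        for name, _ in self.covariate_fns:
            if name not in COVARIATE_FN_REGISTRY:
                raise SpecificationError(f"unknown covariate function {name!r}")

    def to_dict(self) -> dict:
        return {
            "additive": [[int(i), float(b)] for i, b in self.additive],
            "dominance": [[int(i), list(map(float, m))] for i, m in self.dominance],
            "epistatic": [
                [int(i), int(j), np.asarray(t, float).tolist()]
                for i, j, t in self.epistatic
            ],
            "gxe": [[int(i), c, float(b)] for i, c, b in self.gxe],
            "exe": [[a, b, float(w)] for a, b, w in self.exe],
            "covariate_fns": [[n, float(w)] for n, w in self.covariate_fns],
            "noise_sd": float(self.noise_sd),
            "scale": self.scale,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        return cls(
            additive=[tuple(x) for x in d.get("additive", [])],
            dominance=[(i, tuple(m)) for i, m in d.get("dominance", [])],
            epistatic=[(i, j, np.asarray(t)) for i, j, t in d.get("epistatic", [])],
            gxe=[tuple(x) for x in d.get("gxe", [])],
            exe=[tuple(x) for x in d.get("exe", [])],
            covariate_fns=[tuple(x) for x in d.get("covariate_fns", [])],
            noise_sd=d.get("noise_sd", 1.0),
            scale=d.get("scale", "raw"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class GenotypeSimConfig:
    n_samples: int
    n_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_decay: float = 0.0  # copy probability within a block
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")


def simulate_genotypes(config: GenotypeSimConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotype draws with optional block-LD and missingness.

    Each sample carries two haplotypes. Within an LD block, each haplotype
    copies the previous variant's allele with probability ``ld_decay`` and
    otherwise draws fresh from Bernoulli(MAF), giving a controllable
    first-order correlation; block boundaries reset the process.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    hap = np.empty((2, n, m), dtype=np.int8)
    fresh = (rng.random((2, n, m)) < maf[None, None, :]).astype(np.int8)
    if config.ld_decay > 0 and config.ld_block_size > 1:
        copy = rng.random((2, n, m)) < config.ld_decay
        hap[:, :, 0] = fresh[:, :, 0]
        for j in range(1, m):
            if j % config.ld_block_size == 0:  # block boundary: restart
                hap[:, :, j] = fresh[:, :, j]
            else:
                hap[:, :, j] = np.where(copy[:, :, j], hap[:, :, j - 1], fresh[:, :, j])
    else:
        hap = fresh
    dosage = (hap[0] + hap[1]).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage[miss] = MISSING

    chrom = 1 + (np.arange(m) * 22) // m  # spread variants over 22 autosomes
    variants = pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "id": [f"snp{j}" for j in range(m)],
            "cm": 0.0,
            "pos": np.arange(m) * 1000 + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosage, variants, samples)


def simulate_covariates(
    n_samples: int,
    n_pcs: int = 10,
    seed: int = 0,
    age_range: tuple[float, float] = (40.0, 70.0),
    n_centers: int = 3,
) -> pd.DataFrame:
    """Covariate table: continuous age, binary sex, categorical center, PCs."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {
        "age": rng.uniform(*age_range, size=n_samples),
        "sex": rng.integers(0, 2, size=n_samples).astype(float),
        "center": np.array(
            [f"center_{c}" for c in rng.integers(0, n_centers, size=n_samples)]
        ),
    }
    for k in range(n_pcs):
        data[f"pc{k + 1}"] = rng.standard_normal(n_samples)
    df = pd.DataFrame(data, index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"))
    return df


def log2like_warp(y: np.ndarray) -> np.ndarray:
    """Sign-preserving, strictly monotone log-like warp used to emulate a
    compressed (NPX-like) measurement scale."""
    return np.sign(y) * np.log2(1.0 + np.abs(y))


def simulate_trait(
    G: GenotypeMatrix,
    S: pd.DataFrame,
    spec: EffectSpec,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Build a trait as the sum of the specified components plus noise.

    Missing genotypes are mean-imputed before effect computation.  Returns
    the trait and a ledger with each component's realized variance on this
    sample set (raw scale, pre-warp).
    """
    spec.validate_against(G, S)
    rng = np.random.default_rng(seed)
    n = G.n_samples
    g = G.imputed()
    g_int = np.clip(np.rint(g), 0, 2).astype(int)  # class lookup for tables

    components: dict[str, np.ndarray] = {}

    if spec.additive:
        comp = np.zeros(n)
        for i, beta in spec.additive:
            comp += beta * g[:, i]
        components["additive"] = comp
    if spec.dominance:
        comp = np.zeros(n)
        for i, means in spec.dominance:
            comp += np.asarray(means, dtype=float)[g_int[:, i]]
        components["dominance"] = comp
    if spec.epistatic:
        comp = np.zeros(n)
        for i, j, table in spec.epistatic:
            comp += table[g_int[:, i], g_int[:, j]]
        components["epistatic"] = comp
    if spec.gxe:
        comp = np.zeros(n)
        for i, cov, beta in spec.gxe:
            comp += beta * g[:, i] * S[cov].to_numpy(float)
        components["gxe"] = comp
    if spec.exe:
        comp = np.zeros(n)
        for a, b, beta in spec.exe:
            comp += beta * S[a].to_numpy(float) * S[b].to_numpy(float)
        components["exe"] = comp
    if spec.covariate_fns:
        comp = np.zeros(n)
        for name, weight in spec.covariate_fns:
            comp += weight * COVARIATE_FN_REGISTRY[name](S)
        components["covariate_fns"] = comp

    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    components["noise"] = noise

    y = sum(components.values())
    ledger = {
        "component_variance": {k: float(np.var(v)) for k, v in components.items()},
        "noise_sd": float(spec.noise_sd),
        "total_variance_raw": float(np.var(y)),
        "scale": spec.scale,
        "seed": int(seed),
    }
    if spec.scale == "log2like":
        y = log2like_warp(y)
        ledger["total_variance_warped"] = float(np.var(y))
    return y, ledger


def write_study(
    G: GenotypeMatrix,
    S: pd.DataFrame,
    traits: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "study",
) -> dict[str, Path]:
    """Persist a simulated study: PLINK1 trio plus covariate/trait TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if list(S.index) != G.samples or list(traits.index) != G.samples:
        raise ValueError("covariate/trait tables must share the genotype sample order")
    plink_prefix = out_dir / prefix
    write_plink(G, plink_prefix)
    cov_path = out_dir / f"{prefix}.covariates.tsv"
    trait_path = out_dir / f"{prefix}.traits.tsv"
    write_table(S, cov_path)
    write_table(traits, trait_path)
    return {
        "bed": plink_prefix.with_suffix(".bed"),
        "bim": plink_prefix.with_suffix(".bim"),
        "fam": plink_prefix.with_suffix(".fam"),
        "covariates": cov_path,
        "traits": trait_path,
    }
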