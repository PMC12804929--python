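"""Genotype I/O, quality control, and trait normalization.

Implements a bit-exact PLINK1 .bed/.bim/.fam codec, the Hardy-Weinberg exact
test, sample/variant QC filtering with an auditable ledger, windowed LD
pruning, and rank-based inverse normal transformation.

Missing genotypes are represented by the sentinel ``MISSING`` (-1) and are
never silently imputed at this layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtri
from scipy.stats import rankdata

MISSING: int = -1

# 2-bit PLINK codes (SNP-major mode): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Internal dosage counts copies of allele1: hom A1 -> 2, het -> 1, hom A2 -> 0.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam file set is malformed or inconsistent."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant/sample metadata.

    ``dosage`` holds allele1 counts in {0, 1, 2} with ``MISSING`` (-1) for
    missing calls.  ``variants`` is a DataFrame with columns
    (chrom, id, cm, pos, a1, a2); ``samples`` is a list of sample ids.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        if len(set(self.samples)) != n:
            raise ValueError("sample ids must be unique")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        if (self.variants["pos"] < 0).any():
            raise ValueError("variant positions must be non-negative")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of allele1 among observed calls (NaN if none)."""
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def imputed(self) -> np.ndarray:
        """Float dosage with missing calls replaced by the variant mean."""
        d = self.dosage.astype(float)
        miss = self.dosage == MISSING
        d[miss] = np.nan
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(miss)
        d[idx] = col_mean[idx[1]]
        return d

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosage
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            variants = variants.iloc[variant_idx].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), variants.copy(), list(samples))


@dataclass(frozen=True)
class QcThresholds:
    """PLINK-convention QC cutoffs.

    mind/geno remove strictly-greater missingness; maf keeps >= threshold;
    hwe removes p strictly below threshold; kinship removes one member of
    each pair at or above the cutoff.
    """

    mind: float = 0.10
    geno: float = 0.01
    hwe_p: float = 1e-6
    maf: float = 0.005
    kinship: float = 0.0884

    def __post_init__(self) -> None:
        for name in ("mind", "geno", "hwe_p", "maf", "kinship"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcStep:
    name: str
    axis: str  # "samples" | "variants"
    removed: int


@dataclass
class QcReport:
    """Ordered ledger of QC removals; arithmetic must reconcile exactly."""

    initial_samples: int
    initial_variants: int
    steps: list[QcStep] = field(default_factory=list)

    def add(self, name: str, axis: str, removed: int) -> None:
        if axis not in ("samples", "variants"):
            raise ValueError(f"unknown axis {axis!r}")
        if removed < 0:
            raise ValueError("removed count must be non-negative")
        self.steps.append(QcStep(name, axis, removed))

    def remaining(self, axis: str) -> int:
        start = self.initial_samples if axis == "samples" else self.initial_variants
        return start - sum(s.removed for s in self.steps if s.axis == axis)

    @property
    def remaining_samples(self) -> int:
        return self.remaining("samples")

    @property
    def remaining_variants(self) -> int:
        return self.remaining("variants")

    def reconcile(self) -> bool:
        """True iff initial - sum(removed) = remaining >= 0 on both axes."""
        return self.remaining_samples >= 0 and self.remaining_variants >= 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "initial": {
                    "samples": self.initial_samples,
                    "variants": self.initial_variants,
                },
                "steps": [
                    {"name": s.name, "axis": s.axis, "removed": s.removed}
                    for s in self.steps
                ],
                "remaining": {
                    "samples": self.remaining_samples,
                    "variants": self.remaining_variants,
                },
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# PLINK1 codec
# ---------------------------------------------------------------------------


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as PLINK1 .bed/.bim/.fam (SNP-major)."""
    prefix = Path(prefix)
    if G.n_variants == 0:
        raise PlinkFormatError(f"{prefix}.bed: cannot write an empty variant set")
    if G.n_samples == 0:
        raise PlinkFormatError(f"{prefix}.fam: cannot write an empty sample set")
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n = G.n_samples
    n_bytes = (n + 3) // 4
    code = np.empty_like(G.dosage, dtype=np.uint8)
    for dos, c in _DOSAGE_TO_CODE.items():
        code[G.dosage == dos] = c
    # pack 4 samples per byte, first sample in lowest-order bits
    padded = np.zeros((n_bytes * 4, G.n_variants), dtype=np.uint8)
    padded[:n, :] = code
    shifted = (
        padded[0::4, :]
        | (padded[1::4, :] << 2)
        | (padded[2::4, :] << 4)
        | (padded[3::4, :] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(shifted.T.tobytes())  # variant-major byte order

    bim = G.variants[["chrom", "id", "cm", "pos", "a1", "a2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": G.samples,
            "iid": G.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK1 file set; inverse of :func:`write_plink`."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise PlinkFormatError(f"{p}: file not found")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(samples), len(bim)

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic/mode bytes {raw[:3].hex()} "
            f"(expected {_BED_MAGIC.hex()}, SNP-major)"
        )
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != n_bytes * m:
        raise PlinkFormatError(
            f"{bed_path}: payload is {payload.size} bytes, expected "
            f"{n_bytes * m} for {n} samples x {m} variants"
        )
    payload = payload.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = payload & 0b11
    codes[:, 1::4] = (payload >> 2) & 0b11
    codes[:, 2::4] = (payload >> 4) & 0b11
    codes[:, 3::4] = (payload >> 6) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(dosage, bim, samples)


def decode_bed_byte(byte: int, n_samples: int = 4) -> list[int]:
    """Decode one SNP-major .bed byte into up to 4 dosages (manual oracle aid)."""
    out = []
    for k in range(n_samples):
        out.append(int(_CODE_TO_DOSAGE[(byte >> (2 * k)) & 0b11]))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_het_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every attainable heterozygote count.

    Conditional on ``n`` genotypes and ``n_a`` copies of the rarer allele,
    P(n_het = h) = n! / (n_aa! h! n_bb!) * 2^h * n_a! n_b! / (2n)! with
    n_aa = (n_a - h)/2.  Returns (het_counts, log_probs).
    """
    n_b = 2 * n - n_a
    h = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    n_aa = (n_a - h) // 2
    n_bb = n - n_aa - h
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(h + 1)
        - gammaln(n_bb + 1)
        + h * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    # normalize defensively; the closed form already sums to 1
    logp -= np.log(np.exp(logp - logp.max()).sum()) + logp.max()
    return h, logp


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (given allele counts)
    whose probability does not exceed that of the observed count. Plain
    (not mid-p) formulation.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration
    h, logp = _hwe_het_log_probs(n, n_rare)
    probs = np.exp(logp)
    p_obs = probs[h == n_het][0]
    # tolerance guards against float ties, mirroring common implementations
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_exact_test_vector(counts: np.ndarray) -> np.ndarray:
    """Vector of HWE p-values for an (m, 3) array of genotype counts."""
    counts = np.asarray(counts)
    return np.array([hwe_exact_test(*row) for row in counts])


def _genotype_counts(G: GenotypeMatrix) -> np.ndarray:
    """(m, 3) counts of dosage 2 / 1 / 0 (hom-a1, het, hom-a2) per variant."""
    d = G.dosage
    return np.stack(
        [(d == 2).sum(axis=0), (d == 1).sum(axis=0), (d == 0).sum(axis=0)], axis=1
    )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


class EmptyResultError(RuntimeError):
    """All samples or all variants were removed by filtering."""


def read_kinship(path: str | Path) -> pd.DataFrame:
    """Square kinship matrix from tab-separated text with header ids."""
    k = pd.read_csv(path, sep="\t", index_col=0)
    if k.shape[0] != k.shape[1]:
        raise ValueError(f"{path}: kinship matrix is not square")
    return k


def _kinship_prune(kin: np.ndarray, threshold: float) -> list[int]:
    """Greedy removal: repeatedly drop the sample with the most remaining
    above-threshold pairs (ties -> smaller index) until none remain."""
    above = (kin >= threshold).astype(int)
    np.fill_diagonal(above, 0)
    removed: list[int] = []
    active = np.ones(above.shape[0], dtype=bool)
    while True:
        deg = (above * active).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = int(np.argmax(deg))  # argmax returns first (smallest) index on ties
        removed.append(worst)
        active[worst] = False
    return sorted(removed)


def qc_filter(
    G: GenotypeMatrix,
    thresholds: QcThresholds,
    kinship: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply QC filters in order: kinship, mind, geno, HWE, MAF.

    Returns the filtered matrix and a ledger whose arithmetic reconciles
    exactly at every step.
    """
    report = QcReport(G.n_samples, G.n_variants)

    # 1. relatedness
    if kinship is not None:
        kin = kinship.loc[G.samples, G.samples].to_numpy(dtype=float)
        drop = _kinship_prune(kin, thresholds.kinship)
        keep = np.setdiff1d(np.arange(G.n_samples), drop)
        report.add("kinship", "samples", len(drop))
        G = G.subset(sample_idx=keep)
    else:
        report.add("kinship", "samples", 0)

    # 2. per-sample missingness (mind): remove strictly-greater
    miss_frac = G.missing_mask().mean(axis=1)
    keep_s = np.where(miss_frac <= thresholds.mind)[0]
    report.add("mind", "samples", G.n_samples - len(keep_s))
    if len(keep_s) == 0:
        raise EmptyResultError("mind filter removed all samples")
    G = G.subset(sample_idx=keep_s)

    # 3. per-variant missingness (geno)
    vmiss = G.missing_mask().mean(axis=0)
    keep_v = np.where(vmiss <= thresholds.geno)[0]
    report.add("geno", "variants", G.n_variants - len(keep_v))
    if len(keep_v) == 0:
        raise EmptyResultError("geno filter removed all variants")
    G = G.subset(variant_idx=keep_v)

    # 4. HWE exact test: remove p strictly below threshold
    pvals = hwe_exact_test_vector(_genotype_counts(G))
    keep_v = np.where(pvals >= thresholds.hwe_p)[0]
    report.add("hwe", "variants", G.n_variants - len(keep_v))
    if len(keep_v) == 0:
        raise EmptyResultError("HWE filter removed all variants")
    G = G.subset(variant_idx=keep_v)

    # 5. MAF: keep >= threshold (inclusive boundary)
    maf = G.maf()
    keep_v = np.where(np.nan_to_num(maf, nan=-1.0) >= thresholds.maf)[0]
    report.add("maf", "variants", G.n_variants - len(keep_v))
    if len(keep_v) == 0:
        raise EmptyResultError("MAF filter removed all variants")
    G = G.subset(variant_idx=keep_v)

    return G, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(G: GenotypeMatrix, window: int, step: int, r2_max: float) -> np.ndarray:
    """Windowed pairwise LD pruning (indep-pairwise semantics).

    Slides a window of ``window`` variants by ``step``; within each window the
    earlier-indexed variant of any pair with squared dosage correlation
    exceeding ``r2_max`` is kept and the later one pruned.  Returns retained
    variant indices.
    """
    if not window >= step >= 1:
        raise ValueError("require window >= step >= 1")
    m = G.n_variants
    x = G.imputed()
    x = x - x.mean(axis=0)
    norms = np.sqrt((x**2).sum(axis=0))
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        for a_pos, i in enumerate(idx):
            if not keep[i]:
                continue
            for j in idx[a_pos + 1 :]:
                if not keep[j]:
                    continue
                denom = norms[i] * norms[j]
                if denom == 0:
                    continue
                r = float(x[:, i] @ x[:, j]) / denom
                if r * r > r2_max:
                    keep[j] = False
        if start + window >= m:
            break
        start += step
    return np.where(keep)[0]


# ---------------------------------------------------------------------------
# Inverse-rank normal transformation
# ---------------------------------------------------------------------------


def int_transform(x: Sequence[float] | np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset.

    z = ndtri((rank - c) / (n - 2c + 1)) over non-missing values; ties get
    average ranks; NaNs are preserved.
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    vals = x[obs]
    if vals.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(vals == vals[0]):
        raise ValueError("all-identical input: ranks undefined for normalization")
    ranks = rankdata(vals, method="average")
    out[obs] = ndtri((ranks - c) / (vals.size - 2 * c + 1))
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_table(path: str | Path, id_column: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    return df.set_index(id_column)


def write_table(df: pd.DataFrame, path: str | Path, id_column: str = "sample_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.rename_axis(id_column).reset_index().to_csv(path, sep="\t", index=False)
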