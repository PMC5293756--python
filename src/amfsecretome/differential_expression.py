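"""RPKM, the weighted beta-binomial proportion test, and DE calls.

Expression is normalized as RPKM (reads per kilobase of transcript per
million mapped reads).  Between-condition testing uses a proportion-based
statistic for count data: per sample the gene's count is treated as a
binomial draw from the library, replicate proportions within a group are
assumed Beta-distributed, and the extra-binomial (overdispersion) component
φ̂ is estimated by the method of moments.  Samples are weighted by
``w_i = N_i / (1 + φ̂ N_i)`` (inverse of the beta-binomial proportion
variance, up to the common factor π(1−π)), giving weighted group
proportions π̂ and a weighted t-type statistic

    t = (π̂₁ − π̂₂) / sqrt(V̂₁ + V̂₂),   V̂ = π̂(1−π̂) / Σ wᵢ,

referred to a t distribution with m₁ + m₂ − 2 degrees of freedom (a normal
reference when both groups are single samples).  With φ̂ = 0 the statistic
reduces exactly to the unpooled two-proportion z test.

DE calls follow fixed thresholds: fold change ≥ |2|, BH FDR ≤ 0.05, and a
mean raw-count difference of at least 10 reads between the compared
conditions.  Fold changes on RPKM group means are signed (−1/r below 1) and
extreme values (division by zero) are held as ±inf internally and rendered
as ±999999 in report tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ComparisonDesign",
    "Comparison",
    "ProportionTestResult",
    "DEThresholds",
    "FOLD_CHANGE_SENTINEL",
    "compute_rpkm",
    "proportion_test",
    "proportion_test_groups",
    "bh_fdr",
    "fold_change_signed",
    "render_fold_change",
    "call_de",
    "run_comparisons",
    "sample_qc",
]

FOLD_CHANGE_SENTINEL = 999999.0


@dataclass
class CountMatrix:
    """Raw gene × sample read counts with sample metadata.

    ``counts``: genes × samples non-negative integer DataFrame;
    ``samples``: DataFrame indexed like the count columns with columns
    ``condition`` and ``replicate`` (and optionally ``library_size``);
    ``lengths``: transcript length in nucleotides per gene.  Library sizes
    default to the column sums when not provided explicitly.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.samples = self.samples.loc[list(self.counts.columns)]
        self.lengths = self.lengths.loc[self.counts.index]
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if "library_size" not in self.samples.columns or self.samples["library_size"].isna().all():
            self.samples = self.samples.assign(library_size=self.counts.sum(axis=0))
        colsums = self.counts.sum(axis=0)
        if (self.samples["library_size"] < colsums).any():
            raise ValueError("library_size below column sum of counts")
        if (self.samples["library_size"] <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def condition_samples(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        if not mask.any():
            raise KeyError(f"no samples for condition {condition!r}")
        return list(self.samples.index[mask])


@dataclass(frozen=True)
class Comparison:
    test_condition: str
    label: str


@dataclass
class ComparisonDesign:
    """Which conditions are compared against the reference, and label roles.

    ``host_labels`` designates the in-planta (intraradical mycelium)
    comparisons; ``erm_labels`` / ``signal_labels`` the extraradical-mycelium
    and plant-signal treatments, used by downstream set classification.
    """

    reference_condition: str
    comparisons: list[Comparison]
    host_labels: frozenset[str] = frozenset()
    erm_labels: frozenset[str] = frozenset()
    signal_labels: frozenset[str] = frozenset()

    def validate(self, cm: CountMatrix) -> None:
        conditions = set(cm.samples["condition"])
        missing = {self.reference_condition} | {c.test_condition for c in self.comparisons}
        missing -= conditions
        if missing:
            raise ValueError(f"design conditions absent from count matrix: {sorted(missing)}")
        labels = {c.label for c in self.comparisons}
        for role in (self.host_labels, self.erm_labels, self.signal_labels):
            if set(role) - labels:
                raise ValueError(f"role labels {sorted(set(role) - labels)} not in comparisons")


@dataclass
class ProportionTestResult:
    p_hat_1: float
    p_hat_2: float
    phi_1: float
    phi_2: float
    weights_1: np.ndarray
    weights_2: np.ndarray
    variance_1: float
    variance_2: float
    t_statistic: float
    df: int  # 0 encodes the normal reference (single replicate per group)
    p_value: float


@dataclass(frozen=True)
class DEThresholds:
    fc: float = 2.0
    fdr: float = 0.05
    min_read_diff: float = 10.0
    expressed_min_mean_count: float = 5.0


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """RPKM[g, s] = counts[g, s] / (length_kb[g] × library_size_millions[s])."""
    libsizes = cm.samples["library_size"].to_numpy(dtype=float)
    if (libsizes <= 0).any():
        raise ValueError("zero library size")
    length_kb = cm.lengths.to_numpy(dtype=float) / 1000.0
    rpkm = cm.counts.to_numpy(dtype=float) / (length_kb[:, None] * (libsizes[None, :] / 1e6))
    return pd.DataFrame(rpkm, index=cm.counts.index, columns=cm.counts.columns)


def _group_stats(x: np.ndarray, N: np.ndarray):
    """Vectorized per-gene weighted group proportion, MoM overdispersion, variance.

    ``x``: genes × replicates counts; ``N``: matching library sizes.
    Returns (π̂, φ̂, V̂, w) with w of shape genes × replicates.
    """
    p = x / N
    m = x.shape[1]
    if m > 1:
        pbar = p.mean(axis=1)
        s2 = p.var(axis=1, ddof=1)
        denom = pbar * (1.0 - pbar)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = s2 / denom - (1.0 / N).mean(axis=1)
        phi = np.where(denom > 0, phi, 0.0)
        phi = np.maximum(phi, 0.0)
    else:
        phi = np.zeros(x.shape[0])
    w = N / (1.0 + phi[:, None] * N)
    wsum = w.sum(axis=1)
    pi_hat = (w * p).sum(axis=1) / wsum
    v = pi_hat * (1.0 - pi_hat) / wsum
    return pi_hat, phi, v, w


def proportion_test_groups(
    x1: np.ndarray, N1: np.ndarray, x2: np.ndarray, N2: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized weighted t-type proportion test across many genes.

    Arrays are genes × replicates.  Returns per-gene arrays ``t``, ``p``,
    ``pi1``, ``pi2``, ``phi1``, ``phi2``, ``v1``, ``v2``.  Genes with equal
    weighted proportions and zero variance (e.g. all-zero counts) get
    t = 0, p = 1.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    N1 = np.broadcast_to(np.asarray(N1, dtype=float), x1.shape)
    N2 = np.broadcast_to(np.asarray(N2, dtype=float), x2.shape)
    if (N1 < x1).any() or (N2 < x2).any():
        raise ValueError("library sizes must be at least the counts")
    pi1, phi1, v1, _ = _group_stats(x1, N1)
    pi2, phi2, v2, _ = _group_stats(x2, N2)
    vsum = v1 + v2
    diff = pi1 - pi2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(vsum)
        t = np.where(vsum > 0, t, np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    m1, m2 = x1.shape[1], x2.shape[1]
    df = m1 + m2 - 2
    if df >= 1:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((vsum == 0) & (diff == 0), 1.0, np.minimum(p, 1.0))
    return {
        "t": t, "p": p, "pi1": pi1, "pi2": pi2,
        "phi1": phi1, "phi2": phi2, "v1": v1, "v2": v2, "df": df,
    }


def proportion_test(
    counts_1: Sequence[float],
    counts_2: Sequence[float],
    libsizes_1: Sequence[float],
    libsizes_2: Sequence[float],
) -> ProportionTestResult:
    """Weighted t-type beta-binomial proportion test for one gene.

    Compares the proportion of the gene's reads in the libraries of group 1
    against group 2.  See the module docstring for the statistic.
    """
    x1 = np.asarray(counts_1, dtype=float)[None, :]
    x2 = np.asarray(counts_2, dtype=float)[None, :]
    N1 = np.asarray(libsizes_1, dtype=float)[None, :]
    N2 = np.asarray(libsizes_2, dtype=float)[None, :]
    if x1.shape != N1.shape or x2.shape != N2.shape:
        raise ValueError("counts and library sizes must have matching shapes")
    res = proportion_test_groups(x1, N1, x2, N2)
    pi1, phi1, v1, w1 = _group_stats(x1, N1)
    pi2, phi2, v2, w2 = _group_stats(x2, N2)
    m1, m2 = x1.shape[1], x2.shape[1]
    df = m1 + m2 - 2
    return ProportionTestResult(
        p_hat_1=float(pi1[0]), p_hat_2=float(pi2[0]),
        phi_1=float(phi1[0]), phi_2=float(phi2[0]),
        weights_1=w1[0], weights_2=w2[0],
        variance_1=float(v1[0]), variance_2=float(v2[0]),
        t_statistic=float(res["t"][0]), df=max(df, 0),
        p_value=float(res["p"][0]),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_change_signed(rpkm_test_mean: float, rpkm_ref_mean: float) -> float:
    """Signed fold change of group means: r if r ≥ 1 else −1/r.

    Division by zero yields ±inf (rendered as ±999999 in reports); 0/0 is
    undefined and returned as NaN.
    """
    if rpkm_test_mean < 0 or rpkm_ref_mean < 0:
        raise ValueError("group means must be non-negative")
    if rpkm_ref_mean == 0 and rpkm_test_mean == 0:
        return float("nan")
    if rpkm_ref_mean == 0:
        return float("inf")
    if rpkm_test_mean == 0:
        return float("-inf")
    r = rpkm_test_mean / rpkm_ref_mean
    return r if r >= 1.0 else -1.0 / r


def render_fold_change(fc: float) -> float | str:
    """Report rendering: ±inf becomes ±999999, NaN an empty field."""
    if math.isnan(fc):
        return ""
    if math.isinf(fc):
        return math.copysign(FOLD_CHANGE_SENTINEL, fc)
    return fc


def call_de(
    fold_change: float,
    q_value: float,
    mean_read_difference: float,
    thresholds: DEThresholds = DEThresholds(),
) -> str:
    """DE call: ``up`` / ``down`` / ``ns`` at the fixed thresholds.

    up iff FC ≥ +2 (inclusive), q ≤ 0.05 (inclusive) and |Δ mean raw
    counts| ≥ 10 (inclusive); down symmetric.
    """
    if math.isnan(fold_change):
        return "ns"
    if q_value > thresholds.fdr or abs(mean_read_difference) < thresholds.min_read_diff:
        return "ns"
    if fold_change >= thresholds.fc:
        return "up"
    if fold_change <= -thresholds.fc:
        return "down"
    return "ns"


def run_comparisons(
    cm: CountMatrix,
    design: ComparisonDesign,
    thresholds: DEThresholds = DEThresholds(),
) -> dict[str, pd.DataFrame]:
    """Run every comparison of the design against the reference condition.

    Returns one expression-result table per comparison label with columns
    ``gene_id``, RPKM group means, signed ``fold_change`` (±inf preserved;
    use :func:`render_fold_change` for report files), mean raw-count
    difference, ``t``, ``p_value``, ``q_value`` (BH within the comparison),
    ``call`` and expressed flags.
    """
    design.validate(cm)
    rpkm = compute_rpkm(cm)
    libsizes = cm.samples["library_size"]
    ref_samples = cm.condition_samples(design.reference_condition)
    x_ref = cm.counts[ref_samples].to_numpy(dtype=float)
    N_ref = libsizes.loc[ref_samples].to_numpy(dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for comp in design.comparisons:
        test_samples = cm.condition_samples(comp.test_condition)
        x_test = cm.counts[test_samples].to_numpy(dtype=float)
        N_test = libsizes.loc[test_samples].to_numpy(dtype=float)
        res = proportion_test_groups(x_test, N_test, x_ref, N_ref)
        q = bh_fdr(res["p"])
        rpkm_test = rpkm[test_samples].mean(axis=1).to_numpy()
        rpkm_ref = rpkm[ref_samples].mean(axis=1).to_numpy()
        fc = np.array([fold_change_signed(t, r) for t, r in zip(rpkm_test, rpkm_ref)])
        read_diff = x_test.mean(axis=1) - x_ref.mean(axis=1)
        calls = [
            call_de(f, qv, d, thresholds) for f, qv, d in zip(fc, q, read_diff)
        ]
        out[comp.label] = pd.DataFrame(
            {
                "gene_id": cm.gene_ids,
                "comparison_id": comp.label,
                "rpkm_mean_test": rpkm_test,
                "rpkm_mean_ref": rpkm_ref,
                "fold_change": fc,
                "mean_read_difference": read_diff,
                "t_statistic": res["t"],
                "p_value": res["p"],
                "q_value": q,
                "call": calls,
                "expressed_test": x_test.mean(axis=1) >= thresholds.expressed_min_mean_count,
                "expressed_ref": x_ref.mean(axis=1) >= thresholds.expressed_min_mean_count,
            }
        )
    return out


@dataclass
class QCResult:
    correlation: pd.DataFrame
    pc_coordinates: pd.DataFrame  # samples × (PC1, PC2)
    explained_variance_ratio: np.ndarray


def sample_qc(cm: CountMatrix) -> QCResult:
    """Replicate QC: sample correlation matrix and PCA of log2 counts.

    Pearson correlations between samples on log2(count+1); principal
    components of the centered sample × gene log matrix.  Constant samples
    produce NaN correlations (reported, not an error).
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("sample_qc requires at least 2 samples")
    logc = np.log2(cm.counts.to_numpy(dtype=float) + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(logc.T)
    corr_df = pd.DataFrame(corr, index=cm.counts.columns, columns=cm.counts.columns)
    X = logc.T - logc.T.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u[:, :2] * s[:2]
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    pc_df = pd.DataFrame(coords, index=cm.counts.columns, columns=["PC1", "PC2"])
    return QCResult(corr_df, pc_df, evr[:2])
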