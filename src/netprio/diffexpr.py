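"""Differential expression: normalization, moderated testing, FDR, DEG filter.

The testing scheme is a deliberately simple moderated two-sample comparison on
log2 counts-per-million: gene-wise residual variances are shrunk toward a
prior with ``prior_df`` pseudo-observations (s~2 = (d0*s0^2 + d*s^2)/(d0 + d))
and the t statistic uses the shrunken variance with d + d0 degrees of freedom.
With ``prior_df = 0`` it reduces exactly to the classical pooled two-sample t
test.  Precision weights are not modelled.

Also houses the RNA-integrity QC gate (RINe >= 7, 28S/18S > 2.0, DV200 > 70%)
and Benjamini–Hochberg adjustment shared by the other stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: DEG thresholds: |log2FC| >= 0.5 (inclusive) and FDR < 0.05 (strict).
LFC_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# RNA QC gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaQcRecord:
    """RNA-integrity metrics for one sample."""

    rine: float
    ratio_28s_18s: float
    dv200: float  # percent, in [0, 100]
    conc_ng_ul: float | None = None

    def __post_init__(self) -> None:
        for name in ("rine", "ratio_28s_18s", "dv200"):
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ValidationError(f"QC field {name} is missing or non-finite")
        if not 0.0 <= self.dv200 <= 100.0:
            raise ValidationError(f"dv200 must lie in [0, 100], got {self.dv200!r}")


def qc_gate(record: RnaQcRecord) -> tuple[bool, list[str]]:
    """Sample acceptance gate: RINe >= 7 (inclusive), 28S/18S > 2.0 and
    DV200 > 70% (both strict).  Returns (passed, failed criteria names)."""
    failures = []
    if not record.rine >= 7.0:
        failures.append("RINe")
    if not record.ratio_28s_18s > 2.0:
        failures.append("28S/18S")
    if not record.dv200 > 70.0:
        failures.append("DV200")
    return (not failures, failures)


# ---------------------------------------------------------------------------
# Abundance normalizations
# ---------------------------------------------------------------------------

def compute_fpkm(counts, lengths_bp, library_sizes) -> pd.DataFrame | np.ndarray:
    """Fragments per kilobase per million mapped reads.

    fpkm = count * 1e9 / (library_size * length_bp), with the per-sample
    library size conventionally the sample's total counts.
    """
    counts_arr = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lengths <= 0):
        raise ValidationError("gene lengths must be positive")
    if np.any(lib <= 0):
        raise ValidationError("library sizes must be positive")
    if counts_arr.ndim == 1:
        fpkm = counts_arr * 1e9 / (lib * lengths)
    else:
        fpkm = counts_arr * 1e9 / (lib[None, :] * lengths[:, None])
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)
    return fpkm


def log_cpm(counts, library_sizes, prior_count: float = 0.5):
    """log2 counts-per-million with a damping prior count.

    value = log2((count + prior) / (library_size + 2 * prior) * 1e6)
    """
    if prior_count <= 0:
        raise ValidationError("prior_count must be positive")
    counts_arr = np.asarray(counts, dtype=float)
    if np.any(counts_arr < 0):
        raise ValidationError("counts must be non-negative")
    lib = np.asarray(library_sizes, dtype=float)
    if counts_arr.ndim == 1:
        value = np.log2((counts_arr + prior_count) / (lib + 2 * prior_count) * 1e6)
    else:
        value = np.log2((counts_arr + prior_count) / (lib[None, :] + 2 * prior_count) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(value, index=counts.index, columns=counts.columns)
    return value


# ---------------------------------------------------------------------------
# Moderated test
# ---------------------------------------------------------------------------

def moderated_ttest(logcpm, group_labels, prior_df: float = 4.0,
                    prior_var: float | None = None) -> pd.DataFrame:
    """Per-gene moderated two-sample comparison on log-CPM values.

    log2fc is mean(treated) - mean(control).  The pooled residual variance is
    shrunk toward ``prior_var`` with ``prior_df`` prior degrees of freedom; by
    default ``prior_var`` is the mean of the gene-wise pooled variances (a
    method-of-moments location estimate for the variance prior).  Two-sided p
    from Student's t with d + d0 degrees of freedom.

    Returns a frame with columns log2fc, t, p, degenerate (flag for genes
    whose shrunken variance is zero).
    """
    mat = np.asarray(logcpm, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {list(groups)}")
    # 'control' first when present; otherwise first-seen order is the baseline
    if "control" in groups and groups[0] != "control":
        groups = np.array([g for g in groups if g == "control"] +
                          [g for g in groups if g != "control"])
    mask_ctrl = labels == groups[0]
    mask_trt = labels == groups[1]
    n1, n2 = int(mask_ctrl.sum()), int(mask_trt.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples")
    if prior_df < 0:
        raise ValidationError("prior_df must be >= 0")

    x_ctrl, x_trt = mat[:, mask_ctrl], mat[:, mask_trt]
    mean_ctrl, mean_trt = x_ctrl.mean(axis=1), x_trt.mean(axis=1)
    log2fc = mean_trt - mean_ctrl

    d = n1 + n2 - 2
    ss = x_ctrl.var(axis=1, ddof=1) * (n1 - 1) + x_trt.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if prior_var is None:
        prior_var = float(np.mean(s2)) if np.any(s2 > 0) else 0.0
    s2_tilde = (prior_df * prior_var + d * s2) / (prior_df + d)

    degenerate = s2_tilde <= 0
    se = np.sqrt(np.where(degenerate, np.nan, s2_tilde) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = log2fc / se
    df_total = d + prior_df
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)

    index = logcpm.index if isinstance(logcpm, pd.DataFrame) else pd.RangeIndex(mat.shape[0])
    return pd.DataFrame({"log2fc": log2fc, "t": t, "p": p, "degenerate": degenerate},
                        index=index)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    if isinstance(p_values, pd.Series):
        return pd.Series(adjusted, index=p_values.index, name="fdr")
    return adjusted


# ---------------------------------------------------------------------------
# DEG filter
# ---------------------------------------------------------------------------

def filter_degs(records: pd.DataFrame, lfc_threshold: float = LFC_THRESHOLD,
                fdr_threshold: float = FDR_THRESHOLD) -> tuple[set, set]:
    """Split a results frame into (up, down) DEG id sets.

    A gene is kept iff |log2fc| >= lfc_threshold (inclusive) and
    fdr < fdr_threshold (strict); direction follows the sign of log2fc.
    """
    for col in ("log2fc", "fdr"):
        if col not in records.columns:
            raise ValidationError(f"records must carry a {col!r} column")
    kept = (records["log2fc"].abs() >= lfc_threshold) & (records["fdr"] < fdr_threshold)
    up = set(records.index[kept & (records["log2fc"] > 0)])
    down = set(records.index[kept & (records["log2fc"] < 0)])
    return up, down


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

def de_analysis(counts: pd.DataFrame, lengths_bp: pd.Series, group_labels,
                prior_df: float = 4.0, prior_var: float | None = None,
                prior_count: float = 0.5,
                lfc_threshold: float = LFC_THRESHOLD,
                fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Full DE stage: log-CPM, moderated test, BH FDR, FPKM and DEG flags.

    FPKM uses each sample's total counts as its library size; the reported
    per-gene value is the mean FPKM across treated samples (the abundance
    later fed into the composite prioritization score).
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lcpm = log_cpm(counts, lib, prior_count=prior_count)
    result = moderated_ttest(lcpm, group_labels, prior_df=prior_df, prior_var=prior_var)
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    fpkm = compute_fpkm(counts, lengths_bp.loc[counts.index], lib)
    treated_cols = [c for c, g in zip(counts.columns, group_labels) if g == "treated"]
    result["fpkm"] = fpkm[treated_cols].mean(axis=1) if treated_cols else fpkm.mean(axis=1)
    up, down = filter_degs(result, lfc_threshold, fdr_threshold)
    result["de_flag"] = ["up" if g in up else "down" if g in down else "ns"
                         for g in result.index]
    return result
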