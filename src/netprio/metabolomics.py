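"""PLS-DA with VIP scoring, univariate statistics, and metabolite selection.

The multivariate model is a hand-written single-response PLS (PLS1) with
NIPALS-style sequential component extraction and deflation, fitted on
autoscaled log-free intensities with the class encoded 0/1 and centred.  For
a single response the weight vector of each component has the closed form
w_a = X_a' y_a / ||X_a' y_a||, which the iterative procedure reaches at its
first pass; deflation then removes the extracted component from X and y.

Variable importance in projection follows the standard definition

    VIP_j = sqrt( p * sum_a[ ssy_a * w_aj^2 ] / sum_a ssy_a )

with unit-norm weights, so mean_j(VIP_j^2) = 1 identically.

Selection applies the compound filter VIP > 1.5, p < 0.05, FDR < 0.05 and
raw-scale fold change > 2.0 (all strict; an optional two-sided mode also
admits FC < 0.5).  Univariate p-values come from Welch's t on log2
intensities.  Feature deduplication merges ions agreeing within a ppm mass
tolerance and a retention-time window, keeping the brightest member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError

logger = logging.getLogger(__name__)

VIP_THRESHOLD = 1.5
P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.05
FC_THRESHOLD = 2.0
PPM_TOLERANCE = 5.0
RT_TOLERANCE_MIN = 0.2


@dataclass
class PlsModel:
    """Fitted PLS1 discriminant model (on scaled, centred data)."""

    n_components: int
    x_weights: np.ndarray     # (p, A), unit-norm columns
    x_scores: np.ndarray      # (n, A)
    x_loadings: np.ndarray    # (p, A)
    y_loadings: np.ndarray    # (A,)
    ssy: np.ndarray           # (A,) response variance explained per component
    n_features: int
    feature_ids: list[str]
    dropped_features: list[str]


def _encode_labels(class_labels) -> np.ndarray:
    labels = np.asarray(class_labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    return (labels == classes[1]).astype(float)


def fit_plsda(X, class_labels, n_components: int = 2, scale: str = "uv") -> PlsModel:
    """Fit the PLS-DA model on a features x samples matrix.

    ``scale`` is one of ``"uv"`` (unit variance, the default), ``"pareto"``
    or ``"none"``.  Constant features are dropped with a warning.  The
    requested number of components may not exceed min(n_samples - 1,
    n_features).
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = [str(i) for i in X.index]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        feature_ids = [f"f{i}" for i in range(mat.shape[0])]
    y = _encode_labels(class_labels)
    if mat.shape[1] != y.size:
        raise ValidationError("class_labels length must match the number of samples")

    data = mat.T  # samples x features
    sd = data.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [fid for fid, ok in zip(feature_ids, keep) if not ok]
    if dropped:
        logger.warning("dropping %d constant feature(s) before scaling", len(dropped))
    data = data[:, keep]
    sd = sd[keep]
    kept_ids = [fid for fid, ok in zip(feature_ids, keep) if ok]

    n, p = data.shape
    if p == 0:
        raise ValidationError("no non-constant features remain")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must lie in [1, {max_comp}] for this data, got {n_components}")

    data = data - data.mean(axis=0)
    if scale == "uv":
        data = data / sd
    elif scale == "pareto":
        data = data / np.sqrt(sd)
    elif scale != "none":
        raise ValidationError(f"unknown scale mode {scale!r}")
    yc = y - y.mean()

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros(n_components)
    ssy = np.zeros(n_components)
    Xa, ya = data.copy(), yc.copy()
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValidationError(
                f"component {a + 1}: no residual X–y covariance to extract")
        w /= norm
        t = Xa @ w
        tt = t @ t
        p_load = Xa.T @ t / tt
        c = ya @ t / tt
        ssy[a] = c * c * tt
        W[:, a], T[:, a], P[:, a], C[a] = w, t, p_load, c
        Xa = Xa - np.outer(t, p_load)
        ya = ya - t * c

    return PlsModel(n_components=n_components, x_weights=W, x_scores=T,
                    x_loadings=P, y_loadings=C, ssy=ssy, n_features=p,
                    feature_ids=kept_ids, dropped_features=dropped)


def vip_scores(model: PlsModel) -> pd.Series:
    """Per-feature VIP scores of a fitted model (mean of squares is 1)."""
    total = model.ssy.sum()
    if total <= 0:
        raise ValidationError("model explains no response variance; VIP undefined")
    weighted = (model.x_weights ** 2) @ model.ssy
    vip = np.sqrt(model.n_features * weighted / total)
    return pd.Series(vip, index=model.feature_ids, name="vip")


def fold_change(X, class_labels) -> pd.Series:
    """Raw-scale fold change: mean(treated) / mean(control) per feature."""
    if isinstance(X, pd.DataFrame):
        mat, index = X.to_numpy(dtype=float), X.index
    else:
        mat = np.asarray(X, dtype=float)
        index = pd.RangeIndex(mat.shape[0])
    if np.any(mat <= 0):
        raise ValidationError("intensities must be strictly positive")
    labels = np.asarray(class_labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    if "control" in classes and classes[0] != "control":
        classes = np.array([c for c in classes if c == "control"] +
                           [c for c in classes if c != "control"])
    mean_ctrl = mat[:, labels == classes[0]].mean(axis=1)
    mean_trt = mat[:, labels == classes[1]].mean(axis=1)
    if np.any(mean_ctrl == 0):
        raise ValidationError("control mean of zero; fold change undefined")
    return pd.Series(mean_trt / mean_ctrl, index=index, name="fc")


def univariate_test(X, class_labels) -> pd.DataFrame:
    """Welch's two-sided t test on log2 intensities, with BH-adjusted FDR."""
    if isinstance(X, pd.DataFrame):
        mat, index = X.to_numpy(dtype=float), X.index
    else:
        mat = np.asarray(X, dtype=float)
        index = pd.RangeIndex(mat.shape[0])
    if np.any(mat <= 0):
        raise ValidationError("intensities must be strictly positive")
    labels = np.asarray(class_labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    g1 = np.log2(mat[:, labels == classes[0]])
    g2 = np.log2(mat[:, labels == classes[1]])
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValidationError("each class needs >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(g2, g1, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"p": p, "fdr": bh_adjust(p), "degenerate": degenerate},
                        index=index)


def select_metabolites(features: pd.DataFrame, vip_threshold: float = VIP_THRESHOLD,
                       p_threshold: float = P_THRESHOLD,
                       fdr_threshold: float = FDR_THRESHOLD,
                       fc_threshold: float = FC_THRESHOLD,
                       two_sided_fc: bool = False) -> pd.DataFrame:
    """Apply the compound selection filter; returns the selected rows.

    Keep iff VIP > 1.5 AND p < 0.05 AND FDR < 0.05 AND FC > 2.0 (all
    strict).  With ``two_sided_fc`` the effect criterion also admits
    FC < 1/fc_threshold (down-regulated metabolites).
    """
    for col in ("vip", "p", "fdr", "fc"):
        if col not in features.columns:
            raise ValidationError(f"features must carry a {col!r} column")
        if features[col].isna().any():
            raise ValidationError(f"column {col!r} has missing values")
    effect = features["fc"] > fc_threshold
    if two_sided_fc:
        effect |= features["fc"] < 1.0 / fc_threshold
    keep = ((features["vip"] > vip_threshold) & (features["p"] < p_threshold)
            & (features["fdr"] < fdr_threshold) & effect)
    return features.loc[keep]


def dedup_features(features: pd.DataFrame, ppm_tol: float = PPM_TOLERANCE,
                   rt_tol_min: float = RT_TOLERANCE_MIN) -> pd.DataFrame:
    """Merge redundant ions by mass accuracy and retention-time coherence.

    Features whose m/z difference is < ``ppm_tol`` parts-per-million
    (relative to the lower of the two masses) and whose retention times agree
    within ``rt_tol_min`` minutes are grouped transitively; the member with
    the highest mean intensity represents each group.  Expects columns
    ``mz``, ``rt`` and ``mean_intensity``.
    """
    for col in ("mz", "rt", "mean_intensity"):
        if col not in features.columns:
            raise ValidationError(f"features must carry a {col!r} column")
    idx = list(features.index)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = features.sort_values("mz")
    mz = order["mz"].to_numpy()
    rt = order["rt"].to_numpy()
    ids = list(order.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            lower = mz[i]  # sorted, so mz[i] <= mz[j]
            if (mz[j] - mz[i]) / lower * 1e6 >= ppm_tol:
                break
            if abs(rt[j] - rt[i]) <= rt_tol_min:
                ri, rj = find(ids[i]), find(ids[j])
                if ri != rj:
                    parent[rj] = ri
    groups: dict = {}
    for i in idx:
        groups.setdefault(find(i), []).append(i)
    survivors = [max(members, key=lambda m: (features.at[m, "mean_intensity"], str(m)))
                 for members in groups.values()]
    return features.loc[[i for i in idx if i in set(survivors)]]


def metabolomics_analysis(table: pd.DataFrame, class_labels=None,
                          n_components: int = 2, scale: str = "uv",
                          two_sided_fc: bool = False,
                          ppm_tol: float = PPM_TOLERANCE,
                          rt_tol_min: float = RT_TOLERANCE_MIN) -> pd.DataFrame:
    """Full metabolomics stage on a (feature_id x [mz, rt, samples]) table.

    Deduplicates redundant ions, fits the PLS-DA model, computes VIP, fold
    change and Welch statistics, and returns the per-feature table with a
    ``selected`` flag.  Class labels default to the sample-column prefixes
    (``control_*`` / ``treated_*``).
    """
    meta_cols = [c for c in ("mz", "rt") if c in table.columns]
    sample_cols = [c for c in table.columns if c not in meta_cols]
    if class_labels is None:
        class_labels = [c.rsplit("_", 1)[0] for c in sample_cols]
    X = table[sample_cols]

    work = table[meta_cols].copy()
    work["mean_intensity"] = X.mean(axis=1)
    if meta_cols == ["mz", "rt"]:
        deduped = dedup_features(work, ppm_tol=ppm_tol, rt_tol_min=rt_tol_min)
        X = X.loc[deduped.index]

    model = fit_plsda(X, class_labels, n_components=n_components, scale=scale)
    vip = vip_scores(model)
    fc = fold_change(X, class_labels)
    uni = univariate_test(X, class_labels)
    # constant features dropped by the fit get NaN VIP and are never selected
    out = pd.DataFrame({"vip": vip.reindex([str(i) for i in X.index]).to_numpy(),
                        "fc": fc.to_numpy(), "p": uni["p"].to_numpy(),
                        "fdr": uni["fdr"].to_numpy()}, index=X.index)
    for c in meta_cols:
        out[c] = table.loc[X.index, c]
    selected = select_metabolites(out.dropna(subset=["vip"]), two_sided_fc=two_sided_fc)
    out["selected"] = out.index.isin(selected.index)
    return out
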