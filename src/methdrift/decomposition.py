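"""Variance decomposition of the beta matrix.

PCA treats samples as observations and CpGs as variables (CpG-wise
mean-centred, no scaling, computed on beta values).  Each principal
component is then associated with sample covariates: one-way ANOVA for
categorical covariates, Spearman rank correlation (average ranks on ties)
for continuous ones — the standard scree-plot-with-covariates view of an
array study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PcaResult", "run_pca", "associate_pcs"]

#: covariates associated by default, with their type
DEFAULT_COVARIATES = {
    "passage": "continuous",
    "age": "continuous",
    "segment": "categorical",
    "sex": "categorical",
    "donor_id": "categorical",
    "cohort": "categorical",
}


@dataclass
class PcaResult:
    """Scores, loadings and variance fractions of a beta-matrix PCA.

    ``variance_fraction`` covers the full decomposition (sums to 1);
    ``scores`` / ``loadings`` carry the first ``n_components`` axes.  Sign
    convention: each PC is oriented so the largest-magnitude element of its
    loading vector is positive.
    """

    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # CpGs x PCs
    variance_fraction: np.ndarray  # full decomposition

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc": [f"PC{i + 1}" for i in range(len(self.variance_fraction))],
                "variance_fraction": self.variance_fraction,
            }
        )


def run_pca(
    beta: pd.DataFrame, n_components: int = 10, impute_missing: bool = False
) -> PcaResult:
    """PCA of a probes x samples beta matrix.

    Missing values are rejected unless ``impute_missing`` is set, in which
    case they are replaced by the probe mean.  If ``n_components`` exceeds
    the matrix rank bound it is truncated with a warning.
    """
    X = beta.to_numpy(dtype=float).T  # samples x CpGs
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.isnan(X).any():
        if not impute_missing:
            raise ValueError("beta matrix has missing values; set impute_missing=True")
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    X = X - X.mean(axis=0, keepdims=True)
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} truncated to rank bound {max_rank}",
            UserWarning,
            stacklevel=2,
        )
        n_components = max_rank
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    S, U, Vt = S[:max_rank], U[:, :max_rank], Vt[:max_rank]
    # orient each PC so its largest-|loading| element is positive
    for j in range(max_rank):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total = float((S**2).sum())
    var_frac = (S**2) / total if total > 0 else np.zeros(max_rank)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U * S)[:, :n_components], index=beta.columns, columns=pcs
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=beta.index, columns=pcs)
    return PcaResult(scores=scores, loadings=loadings, variance_fraction=var_frac)


def _associate_one(scores: np.ndarray, values: pd.Series, kind: str) -> tuple[float, float]:
    keep = values.notna().to_numpy()
    if keep.sum() < 3:
        return np.nan, np.nan
    s, v = scores[keep], values[keep]
    if kind == "continuous":
        x = pd.to_numeric(v, errors="coerce").to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(s[ok]) == 0:
            return np.nan, np.nan
        rho, p = stats.spearmanr(s[ok], x[ok])
        return float(rho), float(p)
    groups = [s[(v == lev).to_numpy()] for lev in pd.unique(v)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return np.nan, np.nan  # single-level covariate: association undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def associate_pcs(
    pca: PcaResult,
    sheet: pd.DataFrame,
    covariates: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Associate each PC with each covariate.

    ``covariates`` maps covariate name to ``"continuous"`` (Spearman) or
    ``"categorical"`` (one-way ANOVA); by default every entry of
    ``DEFAULT_COVARIATES`` present in the sheet is used.  Missing covariate
    values are dropped pairwise.  Returns a long DataFrame with columns
    ``pc, covariate, kind, statistic, p``.
    """
    if covariates is None:
        covariates = {k: v for k, v in DEFAULT_COVARIATES.items() if k in sheet.columns}
    unknown = set(covariates) - set(sheet.columns)
    if unknown:
        raise ValueError(f"covariates not in sample sheet: {sorted(unknown)}")
    sheet = sheet.set_index("sample_id").loc[pca.scores.index]
    rows = []
    for pc in pca.scores.columns:
        s = pca.scores[pc].to_numpy(dtype=float)
        for cov, kind in covariates.items():
            stat, p = _associate_one(s, sheet[cov], kind)
            rows.append({"pc": pc, "covariate": cov, "kind": kind, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
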