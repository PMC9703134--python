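"""Per-CpG passage-drift statistics and the three-way drift classification.

For every CpG the model regresses beta on passage number (ordinary least
squares, optionally with fixed-effect donor covariates), tests the
residuals for passage-dependent variance with a Breusch–Pagan test, and
computes the low/high-passage group difference delta-beta.  After
Benjamini–Hochberg adjustment, CpGs are flagged:

hypomethylated
    directional q < alpha and delta-beta < -threshold (methylation loss);
hypermethylated
    directional q < alpha and delta-beta > +threshold (methylation gain);
heteroskedastic
    Breusch–Pagan q < alpha (variance grows or shrinks with passage).

Flags are non-exclusive — a CpG may show both a trend and growing spread —
with a single primary label (directional beats heteroskedastic) for
display.  Everything else is ``stable``.

The entry point is the statsmodels-style pair
:class:`PassageDriftModel` -> :class:`PassageDriftResults`::

    model = PassageDriftModel(beta, sheet, design=PassageDesign())
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PassageDesign",
    "PassageDriftModel",
    "PassageDriftResults",
    "ConcordanceReport",
    "fit_passage_linear_model",
    "breusch_pagan",
    "delta_beta",
    "bh_fdr",
    "classify_cpgs",
    "cross_cohort_concordance",
]

_TINY_VAR = 1e-24  # residual variance below this is treated as exactly zero


@dataclass(frozen=True)
class PassageDesign:
    """Thresholds and grouping for the drift classification.

    ``low_passages`` / ``high_passages`` are inclusive passage ranges
    defining the delta-beta groups (defaults: 1-4 vs 5-16).
    ``delta_beta_mode`` selects the delta-beta definition: ``"group"`` is
    the high-group minus low-group mean; ``"model"`` is the fitted slope
    times the observed passage span.
    """

    low_passages: tuple[int, int] = (1, 4)
    high_passages: tuple[int, int] = (5, 16)
    donor_covariate: bool = False
    alpha: float = 0.05
    delta_beta_threshold: float = 0.15
    delta_beta_mode: str = "group"

    def __post_init__(self) -> None:
        lo, hi = self.low_passages, self.high_passages
        if lo[0] > lo[1] or hi[0] > hi[1]:
            raise ValueError("passage group ranges must be non-empty")
        if not (lo[1] < hi[0] or hi[1] < lo[0]):
            raise ValueError(f"low {lo} and high {hi} passage groups overlap")
        if self.delta_beta_mode not in ("group", "model"):
            raise ValueError(f"unknown delta_beta_mode {self.delta_beta_mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# elementary statistics


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    NaN entries propagate to NaN and do not count toward the number of
    tests; all q-values are capped at 1 and monotone in p-rank.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[valid] = out
    return q


def breusch_pagan(residuals, passage) -> tuple[float, float]:
    """Breusch–Pagan Lagrange-multiplier test for heteroskedasticity.

    Regresses squared residuals on passage; the studentized statistic
    ``LM = n * R^2`` of that auxiliary fit is referred to a chi-square
    with 1 degree of freedom.  Degenerate inputs (constant squared
    residuals) give ``(0.0, 1.0)``.
    """
    e2 = np.asarray(residuals, dtype=float) ** 2
    x = np.asarray(passage, dtype=float)
    n = e2.size
    ec = e2 - e2.mean()
    xc = x - x.mean()
    denom = (ec @ ec) * (xc @ xc)
    if denom <= _TINY_VAR:
        return 0.0, 1.0
    r = (ec @ xc) / np.sqrt(denom)
    lm = n * r * r
    return float(lm), float(stats.chi2.sf(lm, df=1))


def _design_matrix(
    passage: np.ndarray, donors: np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(passage, dtype=float), passage.astype(float)]
    names = ["intercept", "passage"]
    if donors is not None:
        levels = pd.unique(donors)
        for lev in levels[1:]:  # first donor absorbed by the intercept
            cols.append((donors == lev).astype(float))
            names.append(f"donor[{lev}]")
    return np.column_stack(cols), names


def _check_design(X: np.ndarray, names: list[str], donors: np.ndarray | None) -> None:
    if np.ptp(X[:, 1]) == 0:
        raise ValueError("passage is constant across samples; slope is not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if donors is not None:
            counts = pd.Series(donors).value_counts()
            lonely = counts.index[counts < 2].tolist()
            raise ValueError(
                "donor design matrix is rank deficient; donors confounded "
                f"with passage or singleton donors: {lonely}"
            )
        raise ValueError("design matrix is rank deficient")


def fit_passage_linear_model(
    betas, sheet: pd.DataFrame, donor_covariate: bool = False
) -> tuple[float, float, np.ndarray]:
    """OLS of one CpG's beta values on passage.

    ``betas`` is aligned to ``sheet`` rows (Series indexed by sample id, or
    array in sheet order).  Samples with missing beta are dropped.  Returns
    the passage coefficient, its two-sided t-test p-value, and the residual
    vector (NaN at dropped samples).
    """
    if isinstance(betas, pd.Series):
        y = betas.reindex(sheet["sample_id"]).to_numpy(dtype=float)
    else:
        y = np.asarray(betas, dtype=float)
        if y.size != len(sheet):
            raise ValueError("betas length does not match sample sheet")
    keep = ~np.isnan(y)
    passage = sheet["passage"].to_numpy(dtype=float)[keep]
    donors = sheet["donor_id"].to_numpy()[keep] if donor_covariate else None
    if keep.sum() < 3 or np.unique(passage).size < 2:
        raise ValueError("need >= 3 samples with at least 2 distinct passage values")
    X, names = _design_matrix(passage, donors)
    _check_design(X, names, donors)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more coefficients than samples")
    coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
    resid = y[keep] - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    slope = float(coef[1])
    if sigma2 <= _TINY_VAR:
        p = 1.0 if abs(slope) < 1e-12 else 0.0
    else:
        t = slope / np.sqrt(sigma2 * xtx_inv[1, 1])
        p = float(2.0 * stats.t.sf(abs(t), dof))
    residuals = np.full(y.shape, np.nan)
    residuals[keep] = resid
    return slope, p, residuals


def delta_beta(betas, sheet: pd.DataFrame, design: PassageDesign) -> float:
    """High-passage-group mean beta minus low-passage-group mean beta."""
    if isinstance(betas, pd.Series):
        y = betas.reindex(sheet["sample_id"]).to_numpy(dtype=float)
    else:
        y = np.asarray(betas, dtype=float)
    passage = sheet["passage"].to_numpy()
    low = (passage >= design.low_passages[0]) & (passage <= design.low_passages[1])
    high = (passage >= design.high_passages[0]) & (passage <= design.high_passages[1])
    if not low.any() or not high.any():
        raise ValueError(
            f"empty passage group (low {design.low_passages}: {low.sum()} samples, "
            f"high {design.high_passages}: {high.sum()} samples)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(y[high]) - np.nanmean(y[low]))


def classify_cpgs(stats_frame: pd.DataFrame, design: PassageDesign) -> pd.DataFrame:
    """Attach drift-class flags and a primary label to a statistics table.

    ``stats_frame`` needs columns ``slope_q``, ``bp_q`` and ``delta_beta``.
    """
    out = stats_frame.copy()
    thr, alpha = design.delta_beta_threshold, design.alpha
    sig_dir = out["slope_q"] < alpha
    out["hypo"] = sig_dir & (out["delta_beta"] < -thr)
    out["hyper"] = sig_dir & (out["delta_beta"] > thr)
    out["hetero"] = out["bp_q"] < alpha
    label = np.where(
        out["hypo"], "hypo",
        np.where(out["hyper"], "hyper", np.where(out["hetero"], "hetero", "stable")),
    )
    out["label"] = label
    return out


# ---------------------------------------------------------------------------
# model / results


class PassageDriftModel:
    """Mass per-CpG drift model for a beta matrix and its sample sheet.

    Parameters
    ----------
    beta
        Probes x samples DataFrame of beta values in [0, 1]; columns must
        match the sample sheet's ``sample_id`` set.
    sheet
        Sample sheet with ``sample_id``, ``donor_id``, ``passage``.
    design
        :class:`PassageDesign`; defaults match the standard low 1-4 vs
        high 5-16 split with alpha 0.05 and |delta-beta| threshold 0.15.

    The heavy lifting is a single matrix OLS shared across CpGs (the design
    matrix depends only on the sample sheet); CpGs with missing values fall
    back to a per-CpG fit on their complete samples.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        sheet: pd.DataFrame,
        design: PassageDesign | None = None,
    ) -> None:
        design = design or PassageDesign()
        if set(beta.columns) != set(sheet["sample_id"]):
            raise ValueError("beta matrix columns do not match sample sheet ids")
        self.beta = beta.loc[:, sheet["sample_id"].to_numpy()]
        self.sheet = sheet.reset_index(drop=True)
        self.design = design
        passage = self.sheet["passage"].to_numpy(dtype=float)
        if np.unique(passage).size < 2:
            raise ValueError("passage is constant across samples")
        self._passage = passage

    def fit(self) -> "PassageDriftResults":
        design = self.design
        Y = self.beta.to_numpy(dtype=float)
        m, n = Y.shape
        passage = self._passage
        donors = self.sheet["donor_id"].to_numpy() if design.donor_covariate else None
        X, names = _design_matrix(passage, donors)
        _check_design(X, names, donors)
        k = X.shape[1]
        dof = n - k
        if dof < 1:
            raise ValueError("not enough samples for the requested design")
        xtx_inv = np.linalg.inv(X.T @ X)
        proj = X @ xtx_inv  # n x k

        slope = np.full(m, np.nan)
        slope_p = np.full(m, np.nan)
        bp_lm = np.full(m, np.nan)
        bp_p = np.full(m, np.nan)

        complete = ~np.isnan(Y).any(axis=1)
        if complete.any():
            Yc = Y[complete]
            B = Yc @ proj  # m x k coefficients
            R = Yc - B @ X.T
            sigma2 = (R * R).sum(axis=1) / dof
            s = B[:, 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = s / np.sqrt(sigma2 * xtx_inv[1, 1])
            p = 2.0 * stats.t.sf(np.abs(t), dof)
            degenerate = sigma2 <= _TINY_VAR
            p[degenerate] = np.where(np.abs(s[degenerate]) < 1e-12, 1.0, 0.0)
            slope[complete], slope_p[complete] = s, p

            # Breusch–Pagan on all complete rows at once; passage is the
            # sole auxiliary regressor even when donors are in the mean model
            E2 = R * R
            ec = E2 - E2.mean(axis=1, keepdims=True)
            xc = passage - passage.mean()
            denom = (ec * ec).sum(axis=1) * (xc @ xc)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (ec @ xc) / np.sqrt(denom)
            lm = n * r * r
            lm[denom <= _TINY_VAR] = 0.0
            bp_lm[complete] = lm
            bp_p[complete] = stats.chi2.sf(lm, df=1)

        for i in np.flatnonzero(~complete):
            y = Y[i]
            keep = ~np.isnan(y)
            if keep.sum() < 3 or np.unique(passage[keep]).size < 2:
                continue  # stats stay NaN; q-values propagate NaN
            s_i, p_i, resid = fit_passage_linear_model(
                y, self.sheet, donor_covariate=design.donor_covariate
            )
            slope[i], slope_p[i] = s_i, p_i
            bp_lm[i], bp_p[i] = breusch_pagan(resid[keep], passage[keep])

        low = (passage >= design.low_passages[0]) & (passage <= design.low_passages[1])
        high = (passage >= design.high_passages[0]) & (passage <= design.high_passages[1])
        if not low.any() or not high.any():
            raise ValueError("a delta-beta passage group is empty")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if design.delta_beta_mode == "group":
                delta = np.nanmean(Y[:, high], axis=1) - np.nanmean(Y[:, low], axis=1)
            else:
                delta = slope * (passage.max() - passage.min())

        frame = pd.DataFrame(
            {
                "slope": slope,
                "slope_p": slope_p,
                "slope_q": bh_fdr(slope_p),
                "bp_lm": bp_lm,
                "bp_p": bp_p,
                "bp_q": bh_fdr(bp_p),
                "delta_beta": delta,
            },
            index=self.beta.index,
        )
        frame = classify_cpgs(frame, design)
        return PassageDriftResults(frame, design, n_samples=n)


@dataclass
class PassageDriftResults:
    """Per-CpG drift statistics, classification flags, and summaries."""

    frame: pd.DataFrame
    design: PassageDesign
    n_samples: int

    @property
    def n_cpgs(self) -> int:
        return len(self.frame)

    def class_counts(self) -> dict[str, int]:
        f = self.frame
        return {
            "hypo": int(f["hypo"].sum()),
            "hyper": int(f["hyper"].sum()),
            "hetero": int(f["hetero"].sum()),
            "stable": int((f["label"] == "stable").sum()),
        }

    def class_proportions(self) -> dict[str, float]:
        n = max(self.n_cpgs, 1)
        return {k: v / n for k, v in self.class_counts().items()}

    def summary(self) -> str:
        counts = self.class_counts()
        d = self.design
        lines = [
            "Passage drift classification",
            "=" * 44,
            f"CpGs tested:              {self.n_cpgs}",
            f"Samples:                  {self.n_samples}",
            f"Low/high passage groups:  {d.low_passages} / {d.high_passages}",
            f"alpha (BH-FDR):           {d.alpha}",
            f"|delta-beta| threshold:   {d.delta_beta_threshold} ({d.delta_beta_mode})",
            f"Donor covariate:          {d.donor_covariate}",
            "-" * 44,
        ]
        for cls in ("hypo", "hyper", "hetero", "stable"):
            pct = 100.0 * counts[cls] / max(self.n_cpgs, 1)
            lines.append(f"{cls + ':':<10} {counts[cls]:>8}  ({pct:5.2f}%)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")

    def probes_in_class(self, cls: str) -> pd.Index:
        if cls == "stable":
            return self.frame.index[self.frame["label"] == "stable"]
        return self.frame.index[self.frame[cls]]

    def score_against(self, truth: pd.DataFrame) -> dict[str, float]:
        """Sensitivity per class and directional false-discovery rate
        against a ground-truth table (``probe_id``, ``true_class``)."""
        t = truth.set_index("probe_id")["true_class"].reindex(self.frame.index)
        out: dict[str, float] = {}
        for cls in ("hypo", "hyper", "hetero"):
            planted = t == cls
            out[f"sensitivity_{cls}"] = (
                float(self.frame.loc[planted.to_numpy(), cls].mean())
                if planted.any()
                else np.nan
            )
        called_dir = self.frame["hypo"] | self.frame["hyper"]
        n_called = int(called_dir.sum())
        false = (self.frame["hypo"] & (t != "hypo")) | (self.frame["hyper"] & (t != "hyper"))
        out["directional_fdr"] = float(false.sum() / n_called) if n_called else np.nan
        out["n_directional_calls"] = n_called
        return out


# ---------------------------------------------------------------------------
# cross-cohort concordance


@dataclass
class ConcordanceReport:
    """Overlap of drift calls between two cohorts on shared probes."""

    n_shared: int
    class_overlap: pd.DataFrame
    sign_agreement: float
    delta_spearman_rho: float
    delta_spearman_p: float
    n_directional_union: int


def cross_cohort_concordance(
    a: PassageDriftResults, b: PassageDriftResults
) -> ConcordanceReport:
    """Compare two classifications over their shared probe universe.

    For each class, counts of calls in either cohort and in both; for CpGs
    directionally significant in either cohort, the fraction whose
    delta-betas agree in sign and the Spearman correlation of delta-betas.
    """
    fa, fb = a.frame, b.frame
    shared = fa.index.intersection(fb.index)
    if len(shared) == 0:
        raise ValueError("cohorts share no probes")
    fa, fb = fa.loc[shared], fb.loc[shared]
    rows = []
    for cls in ("hypo", "hyper", "hetero"):
        in_a, in_b = fa[cls], fb[cls]
        rows.append(
            {
                "class": cls,
                "n_a": int(in_a.sum()),
                "n_b": int(in_b.sum()),
                "n_both": int((in_a & in_b).sum()),
            }
        )
    union = (fa["hypo"] | fa["hyper"] | fb["hypo"] | fb["hyper"]).to_numpy()
    if union.any():
        da = fa.loc[union, "delta_beta"].to_numpy()
        db = fb.loc[union, "delta_beta"].to_numpy()
        agree = float(np.mean(np.sign(da) == np.sign(db)))
        if union.sum() > 1 and np.std(da) > 0 and np.std(db) > 0:
            rho, rho_p = stats.spearmanr(da, db)
        else:
            rho, rho_p = np.nan, np.nan
    else:
        agree, rho, rho_p = np.nan, np.nan, np.nan
    return ConcordanceReport(
        n_shared=len(shared),
        class_overlap=pd.DataFrame(rows),
        sign_agreement=agree,
        delta_spearman_rho=float(rho) if rho == rho else np.nan,
        delta_spearman_p=float(rho_p) if rho_p == rho_p else np.nan,
        n_directional_union=int(union.sum()),
    )
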