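"""Probe-level quality filtering and beta/M-value transforms.

Methylation arrays report a beta value per CpG (methylated fraction in
[0, 1]).  Before any passage analysis, probes are dropped if they assay a
polymorphic CpG, sit on a sex chromosome, can cross-hybridize to multiple
genomic locations, or fail detection in too many samples.  The M-value
``log2(beta / (1 - beta))`` is the variance-stabilised scale used for
simulation and optional modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterReport", "filter_probes", "beta_to_m", "m_to_beta"]

#: rule order determines first-match attribution in the report
FILTER_RULES = ("sex_chromosome", "polymorphic", "cross_hybridizing", "detection")

_SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y", "chrx", "chry", "x", "y"}


@dataclass
class FilterReport:
    """Per-rule tally of removed probes.

    Each removed probe is attributed to the first rule (in ``FILTER_RULES``
    order) that it triggers, so ``n_input == n_retained + sum(removed)``.
    The *retained set* itself is rule-order independent: a probe is kept iff
    it triggers no rule at all.
    """

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.n_retained + sum(self.removed.values())
        if total != self.n_input:
            raise ValueError(
                f"inconsistent report: {self.n_retained} retained + "
                f"{sum(self.removed.values())} removed != {self.n_input} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in FILTER_RULES]
        rows.append({"rule": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    sample_fraction: float = 0.01,
    strict_fraction: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop probes matching any exclusion rule.

    Parameters
    ----------
    beta
        Probes x samples beta matrix.
    annotation
        Probe annotation covering every probe in ``beta`` (columns
        ``chromosome``, ``polymorphic``, ``cross_hybridizing``).
    detection_p
        Optional probes x samples detection p-value matrix.  A probe is
        removed when its detection p exceeds ``p_threshold`` in more than
        ``sample_fraction`` of samples (``strict_fraction=False`` switches
        the comparison to >=, for the inclusive reading of "in 1% of
        samples").

    Returns
    -------
    (filtered beta matrix, FilterReport)
    """
    missing = beta.index.difference(annotation["probe_id"])
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes missing from annotation "
            f"(e.g. {list(missing[:3])})"
        )
    ann = annotation.set_index("probe_id").reindex(beta.index)

    chrom = ann["chromosome"].astype(str)
    sex = chrom.isin(_SEX_CHROMOSOMES).to_numpy()
    poly = ann.get("polymorphic", pd.Series(0, index=ann.index)).fillna(0).astype(bool).to_numpy()
    cross = (
        ann.get("cross_hybridizing", pd.Series(0, index=ann.index))
        .fillna(0).astype(bool).to_numpy()
    )
    if detection_p is not None:
        det = detection_p.reindex(index=beta.index, columns=beta.columns)
        frac_fail = (det > p_threshold).mean(axis=1).to_numpy()
        detect = (
            frac_fail > sample_fraction if strict_fraction else frac_fail >= sample_fraction
        )
    else:
        detect = np.zeros(len(beta), dtype=bool)

    rules = {
        "sex_chromosome": sex,
        "polymorphic": poly,
        "cross_hybridizing": cross,
        "detection": detect,
    }
    removed: dict[str, int] = {}
    already = np.zeros(len(beta), dtype=bool)
    for name in FILTER_RULES:
        hit = rules[name] & ~already
        removed[name] = int(hit.sum())
        already |= rules[name]
    kept = beta.loc[~already]
    report = FilterReport(n_input=len(beta), n_retained=len(kept), removed=removed)
    return kept, report


def beta_to_m(beta, eps: float = 1e-6):
    """M-value transform, ``log2(beta / (1 - beta))``, clipping at ``eps``."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    x = np.power(2.0, np.asarray(m, dtype=float))
    b = x / (1.0 + x)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index, name=m.name)
    return b
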