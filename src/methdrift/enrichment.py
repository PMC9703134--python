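"""Genomic-feature enrichment of drift CpG classes.

Enrichment of a CpG set in a genomic feature is measured against the
array's own probe distribution: draw many random probe lists of the same
size from a background universe, count feature overlaps per draw, and
express the observed count as a fold change over the resampled mean with
an empirical (plus-one corrected) p-value.

For directional drift classes the background is *feasibility corrected*:
a CpG whose baseline methylation is below the delta-beta threshold can
never lose that much methylation (and symmetrically for gains near 1), so
such probes are removed from the background before resampling.  The
heteroskedastic class keeps the full tested universe, since no delta-beta
constraint applies to it.

The module also hosts the replication-origin distance permutation test
(observed mean minimum distance to origin-peak boundaries vs resampled
means), colon-cancer DMR concordance, and the proximity-based CpG-to-gene
assignment with its gene-overlap fraction statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drift import PassageDriftResults, bh_fdr
from .io import IntervalTrack

__all__ = [
    "EnrichmentResult",
    "DistanceTestResult",
    "annotate_probes",
    "feasibility_background",
    "sampling_enrichment",
    "cdmr_concordance",
    "min_distance_to_boundaries",
    "distance_permutation_test",
    "cpg_to_gene",
    "gene_overlap_fraction",
]


def annotate_probes(annotation: pd.DataFrame, track: IntervalTrack) -> pd.Series:
    """Label each probe with the feature containing it, else ``"none"``.

    Positions are single-base points checked against half-open intervals
    (a probe at the start coordinate is inside; at the end coordinate it
    is not).  If several intervals contain a probe, the one with the
    smallest start (then lexically smallest label) wins.  Probes on
    chromosomes absent from the track get ``"none"`` with a warning.
    """
    labels = pd.Series("none", index=annotation["probe_id"].to_numpy(), dtype=object, name=track.name)
    track_chroms = track.chromosomes
    missing = set(annotation["chromosome"].astype(str)) - track_chroms
    if missing and len(track):
        warnings.warn(
            f"track {track.name!r} has no intervals on chromosome(s) "
            f"{sorted(missing)}; probes there annotated 'none'",
            UserWarning,
            stacklevel=2,
        )
    for chrom, sub in annotation.groupby("chromosome", sort=False):
        if str(chrom) not in track_chroms:
            continue
        ivs = track.intervals[track.intervals["chromosome"].astype(str) == str(chrom)]
        ivs = ivs.sort_values(["start", "label"], kind="mergesort")
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        labs = ivs["label"].to_numpy()
        pos = sub["position"].to_numpy()
        # non-overlapping fast path: containing interval is the nearest
        # preceding start; fall back to tree queries when intervals overlap
        non_overlapping = len(starts) < 2 or (starts[1:] >= ends[:-1]).all()
        if non_overlapping:
            k = np.searchsorted(starts, pos, side="right") - 1
            inside = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
            labels.loc[sub["probe_id"].to_numpy()[inside]] = labs[k[inside]]
        else:
            for pid, p in zip(sub["probe_id"], pos):
                hits = track.query(str(chrom), int(p))
                if len(hits):
                    best = hits.sort_values(["start", "label"], kind="mergesort").iloc[0]
                    labels.loc[pid] = best["label"]
    labels.index.name = "probe_id"
    return labels


def feasibility_background(
    baseline_beta: pd.Series,
    direction: str,
    threshold: float = 0.15,
    universe: pd.Index | None = None,
) -> tuple[pd.Index, int]:
    """Background probes that could achieve |delta-beta| >= threshold.

    ``direction="loss"`` excludes probes with baseline beta < threshold
    (they cannot lose that much methylation); ``direction="gain"`` excludes
    baseline beta > 1 - threshold.  Returns the retained probe index and
    the exclusion count.
    """
    if direction not in ("loss", "gain"):
        raise ValueError(f"direction must be 'loss' or 'gain', got {direction!r}")
    base = baseline_beta if universe is None else baseline_beta.reindex(universe)
    if base.isna().any():
        missing = base.index[base.isna()][:3].tolist()
        raise ValueError(f"baseline beta missing for universe probes (e.g. {missing})")
    # the achievable change is the baseline itself (loss) or its complement
    # (gain); keep probes whose achievable change reaches the threshold
    if direction == "loss":
        keep = base >= threshold
    else:
        keep = (1.0 - base) >= threshold
    retained = base.index[keep]
    if len(retained) == 0:
        raise ValueError(f"feasibility background for direction {direction!r} is empty")
    return retained, int((~keep).sum())


@dataclass
class EnrichmentResult:
    """Observed vs resampled feature counts for one target set.

    ``frame`` has one row per feature with the observed count, resampled
    expectation, fold change (observed / resampled mean), the SD across
    samplings of observed/sampled-count as the fold's SE, plus-one
    empirical enrichment and depletion p-values and their BH q-values.
    """

    frame: pd.DataFrame
    n_target: int
    n_background: int
    n_samplings: int
    sampled_counts: np.ndarray | None = None  # n_samplings x n_features

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", na_rep="NA", index=False)


def sampling_enrichment(
    target,
    background,
    annotation: pd.Series,
    n_samplings: int = 1000,
    seed: int | np.random.Generator | None = None,
    continuity: bool = False,
    keep_samples: bool = True,
) -> EnrichmentResult:
    """Resampling enrichment of ``target`` probes across feature labels.

    Draws ``n_samplings`` probe lists of size ``len(target)`` uniformly
    without replacement from ``background`` and compares per-feature
    counts.  Empirical p-values use the plus-one correction
    ``(1 + #extreme) / (1 + n_samplings)`` so they are never zero.
    ``continuity`` adds 0.5 to zero sampled counts when forming the
    per-sampling fold ratios; otherwise a zero resampled mean yields a NaN
    fold.
    """
    target = pd.Index(target)
    background = pd.Index(background)
    if len(target) == 0:
        raise ValueError("target set is empty")
    if not target.isin(background).all():
        stray = target[~target.isin(background)][:3].tolist()
        raise ValueError(
            f"target is not contained in background (e.g. {stray}); "
            "did the feasibility correction change the universe?"
        )
    if len(background) <= len(target):
        raise ValueError("background must be strictly larger than target")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lab_bg = annotation.reindex(background)
    if lab_bg.isna().any():
        raise ValueError("annotation missing for some background probes")
    cat = pd.Categorical(lab_bg)
    features = list(cat.categories)
    codes = cat.codes.astype(np.int64)
    n_feat = len(features)
    observed = np.bincount(
        pd.Categorical(annotation.reindex(target), categories=features).codes.astype(np.int64),
        minlength=n_feat,
    )

    k, m = len(target), len(background)
    counts = np.empty((n_samplings, n_feat), dtype=np.int64)
    for s in range(n_samplings):
        idx = rng.choice(m, size=k, replace=False)
        counts[s] = np.bincount(codes[idx], minlength=n_feat)

    expected = counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)
        denom = counts.astype(float)
        if continuity:
            denom = np.where(denom == 0, 0.5, denom)
            ratios = observed / denom
            se = ratios.std(axis=0, ddof=1)
        else:
            ratios = np.where(denom > 0, observed / np.where(denom == 0, np.nan, denom), np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                se = np.nanstd(ratios, axis=0, ddof=1)
    p_enrich = (1 + (counts >= observed).sum(axis=0)) / (1 + n_samplings)
    p_deplete = (1 + (counts <= observed).sum(axis=0)) / (1 + n_samplings)
    frame = pd.DataFrame(
        {
            "feature": features,
            "observed": observed,
            "expected": expected,
            "fold": fold,
            "fold_se": se,
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
            "q_enrich": bh_fdr(p_enrich),
            "q_deplete": bh_fdr(p_deplete),
        }
    )
    return EnrichmentResult(
        frame=frame,
        n_target=k,
        n_background=m,
        n_samplings=n_samplings,
        sampled_counts=counts if keep_samples else None,
    )


def cdmr_concordance(
    results: PassageDriftResults,
    probe_annotation: pd.DataFrame,
    cdmr_track: IntervalTrack,
    baseline_beta: pd.Series,
    threshold: float | None = None,
    n_samplings: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Enrichment of each drift class in colon-cancer DMRs by direction.

    Runs :func:`sampling_enrichment` of the hypo-, hyper- and
    heteroskedastic classes against the cDMR track (labels e.g.
    ``cdmr_loss`` / ``cdmr_gain``), with feasibility-corrected backgrounds
    for the directional classes.  Returns a long DataFrame (class x cDMR
    direction) with fold, SE, p/q and a ``same_direction`` flag marking
    the loss-with-loss / gain-with-gain cells.
    """
    thr = results.design.delta_beta_threshold if threshold is None else threshold
    labels = annotate_probes(probe_annotation, cdmr_track)
    universe = results.frame.index
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    directions = [l for l in cdmr_track.labels]
    rows = []
    for cls, feas in (("hypo", "loss"), ("hyper", "gain"), ("hetero", None)):
        target = results.probes_in_class(cls)
        if feas is None:
            background = universe
        else:
            background, _ = feasibility_background(baseline_beta, feas, thr, universe=universe)
        target = target.intersection(background)
        if len(target) == 0:
            for d in directions:
                rows.append(
                    {"class": cls, "cdmr_direction": d, "observed": np.nan,
                     "expected": np.nan, "fold": np.nan, "fold_se": np.nan,
                     "p_enrich": np.nan, "q_enrich": np.nan,
                     "same_direction": _same_direction(cls, d)}
                )
            continue
        res = sampling_enrichment(
            target, background, labels, n_samplings=n_samplings, seed=rng, keep_samples=False
        )
        sub = res.frame.set_index("feature")
        for d in directions:
            if d in sub.index:
                r = sub.loc[d]
                rows.append(
                    {"class": cls, "cdmr_direction": d, "observed": r["observed"],
                     "expected": r["expected"], "fold": r["fold"], "fold_se": r["fold_se"],
                     "p_enrich": r["p_enrich"], "q_enrich": r["q_enrich"],
                     "same_direction": _same_direction(cls, d)}
                )
    return pd.DataFrame(rows)


def _same_direction(cls: str, cdmr_label: str) -> bool:
    return (cls == "hypo" and "loss" in cdmr_label) or (cls == "hyper" and "gain" in cdmr_label)


def min_distance_to_boundaries(
    annotation: pd.DataFrame, peaks: IntervalTrack, zero_inside: bool = False
) -> pd.Series:
    """Minimum absolute distance (bp) from each probe to any peak boundary.

    Every peak start and end coordinate counts as a boundary, so a probe
    inside a peak gets its distance to the nearest edge — unless
    ``zero_inside`` is set, in which case probes within a peak score 0.
    Probes on chromosomes without peaks get NaN.
    """
    out = pd.Series(np.nan, index=annotation["probe_id"].to_numpy(), name="distance")
    for chrom, sub in annotation.groupby("chromosome", sort=False):
        bounds = peaks.boundaries(str(chrom))
        if bounds.size == 0:
            continue
        pos = sub["position"].to_numpy(dtype=np.int64)
        k = np.searchsorted(bounds, pos)
        left = np.where(k > 0, np.abs(pos - bounds[np.clip(k - 1, 0, None)]), np.iinfo(np.int64).max)
        right = np.where(k < bounds.size, np.abs(bounds[np.clip(k, 0, bounds.size - 1)] - pos), np.iinfo(np.int64).max)
        dist = np.minimum(left, right).astype(float)
        if zero_inside:
            ivs = peaks.intervals[peaks.intervals["chromosome"].astype(str) == str(chrom)]
            starts = np.sort(ivs["start"].to_numpy())
            ends = ivs.sort_values("start")["end"].to_numpy()
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            dist[inside] = 0.0
        out.loc[sub["probe_id"].to_numpy()] = dist
    out.index.name = "probe_id"
    return out


@dataclass
class DistanceTestResult:
    """Observed vs resampled mean minimum distances for a probe set."""

    observed_mean: float
    sampled_means: np.ndarray
    p_farther: float
    p_nearer: float
    n_target: int
    n_background: int

    @property
    def direction(self) -> str:
        return "farther" if self.observed_mean > float(np.mean(self.sampled_means)) else "nearer"


def distance_permutation_test(
    target,
    background,
    distances: pd.Series,
    n_samplings: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DistanceTestResult:
    """Permutation test of mean minimum distance for ``target`` probes.

    Compares the observed mean distance with the means of ``n_samplings``
    random same-size draws from ``background``; both one-sided plus-one
    empirical p-values are reported.
    """
    target = pd.Index(target)
    background = pd.Index(background)
    if len(target) == 0:
        raise ValueError("target set is empty")
    if not target.isin(background).all():
        raise ValueError("target is not contained in background")
    d = distances.reindex(background)
    if d.isna().any():
        raise ValueError(
            "distances undefined (NaN) for some background probes; restrict "
            "the background to chromosomes carrying peaks first"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = d.to_numpy(dtype=float)
    observed = float(d.reindex(target).mean())
    k, m = len(target), len(background)
    means = np.empty(n_samplings)
    for s in range(n_samplings):
        means[s] = vals[rng.choice(m, size=k, replace=False)].mean()
    # ties count as extreme; the tolerance absorbs summation-order noise
    tol = 1e-9 * max(1.0, abs(observed))
    p_far = float((1 + (means >= observed - tol).sum()) / (1 + n_samplings))
    p_near = float((1 + (means <= observed + tol).sum()) / (1 + n_samplings))
    return DistanceTestResult(
        observed_mean=observed,
        sampled_means=means,
        p_farther=p_far,
        p_nearer=p_near,
        n_target=k,
        n_background=m,
    )


def cpg_to_gene(annotation: pd.DataFrame, transcripts: IntervalTrack) -> pd.Series:
    """Assign each probe to the gene of its nearest transcript.

    Distance to a transcript ``[start, end)`` is 0 for probes inside,
    otherwise the gap to the nearest edge base.  Ties are broken by the
    smaller transcript start, then the lexically smaller gene id.  Exact
    all-pairs scan per chromosome, chunked over probes — fine at array
    scale.  Probes on chromosomes without transcripts get NaN.
    """
    if len(transcripts) == 0:
        raise ValueError("transcript track is empty")
    out = pd.Series(np.nan, index=annotation["probe_id"].to_numpy(), dtype=object, name="gene")
    for chrom, sub in annotation.groupby("chromosome", sort=False):
        ivs = transcripts.intervals[
            transcripts.intervals["chromosome"].astype(str) == str(chrom)
        ]
        if len(ivs) == 0:
            continue
        order = np.lexsort((ivs["label"].to_numpy(), ivs["start"].to_numpy()))
        starts = ivs["start"].to_numpy()[order].astype(np.int64)
        ends = ivs["end"].to_numpy()[order].astype(np.int64)
        genes = ivs["label"].to_numpy()[order]
        pos_all = sub["position"].to_numpy(dtype=np.int64)
        ids_all = sub["probe_id"].to_numpy()
        for lo in range(0, len(pos_all), 4096):
            pos = pos_all[lo : lo + 4096, None]
            dist = np.maximum.reduce(
                [starts[None, :] - pos, pos - (ends[None, :] - 1), np.zeros((pos.shape[0], len(starts)), dtype=np.int64)]
            )
            best = np.argmin(dist, axis=1)  # argmin takes the first minimum:
            out.loc[ids_all[lo : lo + 4096]] = genes[best]  # ties -> smallest start, then gene id
    out.index.name = "probe_id"
    return out


def gene_overlap_fraction(gene_list, passage_cpg_genes) -> float:
    """Fraction of ``gene_list`` genes associated with at least one
    passage-drift CpG (i.e. present in ``passage_cpg_genes``)."""
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene list is empty")
    return len(genes & set(passage_cpg_genes)) / len(genes)
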