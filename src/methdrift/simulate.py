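"""Synthetic organoid methylation cohorts with planted drift classes.

The generator emulates an Illumina-style methylation array study of
intestinal epithelial organoids sampled repeatedly over culture passages.
Each simulated CpG belongs to one of four ground-truth classes:

``stable``
    constant expected beta across passage;
``hypo`` / ``hyper``
    expected beta declines / rises approximately linearly with passage,
    reaching the configured full-range change ``delta_beta_effect``;
``hetero``
    constant expected beta with residual spread (logit-scale SD) growing
    linearly in passage — stochastic gain-or-loss without a mean trend.

Baseline methylation is drawn from a bimodal mixture (modes near 0.1 and
0.9 plus a minority mid-range component) as on real arrays.  Donor random
intercepts, a gut-segment effect on a subset of CpGs, and residual noise
are applied on the natural-logit scale and transformed back, so every beta
stays strictly inside (0, 1).

Donors are observed longitudinally: a donor's harvests alternate between an
early-passage window and a late-passage window, matching how culture-drift
cohorts pair low- and high-passage samples from the same line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntervalTrack

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_tracks",
    "REGULATORY_CATEGORIES",
]

#: the six regulatory classes used for feature annotation
REGULATORY_CATEGORIES = (
    "promoter",
    "promoter_flanking",
    "enhancer",
    "CTCF_binding",
    "TF_binding",
    "open_chromatin",
)

CLASSES = ("stable", "hypo", "hyper", "hetero")

# baseline beta mixture: (weight, a, b) of Beta components; low mode near
# 0.1, high mode near 0.9, minority mid-range — the classic array bimodal
_BASELINE_MIXTURE = ((0.38, 2.0, 18.0), (0.12, 6.0, 6.0), (0.50, 18.0, 2.0))

_MEAN_CLIP = 0.02  # expected beta kept inside [clip, 1-clip] before noise


@dataclass
class SimulationConfig:
    """Parameters of a simulated cohort.

    Defaults mirror the discovery-cohort design: 80 samples from 46 donors
    over passages 1-16, with directional/heteroskedastic CpG fractions at
    the proportions observed on real arrays (2.2% loss, 0.8% gain, 5.2%
    heteroskedastic) and a full-range directional effect of 0.25 beta
    units.  SDs are on the natural-logit scale.
    """

    n_cpgs: int = 20_000
    n_samples: int = 80
    n_donors: int = 46
    passage_range: tuple[int, int] = (1, 16)
    fraction_hypo: float = 0.022
    fraction_hyper: float = 0.008
    fraction_hetero: float = 0.052
    delta_beta_effect: float = 0.25
    hetero_sd_slope: float = 0.10
    donor_sd: float = 0.15
    base_noise_sd: float = 0.2
    segment_fraction: float = 0.10
    segment_effect: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.passage_range
        if not (1 <= lo <= hi):
            raise ValueError(f"passage_range {self.passage_range} is empty or invalid")
        total = self.fraction_hypo + self.fraction_hyper + self.fraction_hetero
        if min(self.fraction_hypo, self.fraction_hyper, self.fraction_hetero) < 0 or total > 1:
            raise ValueError(f"class fractions must be >= 0 and sum to <= 1 (got {total})")
        for name in ("hetero_sd_slope", "donor_sd", "base_noise_sd", "delta_beta_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_donors > self.n_samples:
            raise ValueError(f"n_donors ({self.n_donors}) > n_samples ({self.n_samples})")
        if self.n_donors < 1 or self.n_cpgs < 1 or self.n_samples < 1:
            raise ValueError("n_cpgs, n_samples and n_donors must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _passage_windows(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """Early and late harvest windows within the passage range."""
    span = hi - lo
    early_hi = lo + max(0, round(span * 0.2))
    late_lo = hi - max(0, round(span * 0.4))
    early = np.arange(lo, early_hi + 1)
    late = np.arange(max(late_lo, lo), hi + 1)
    return early, late


def _draw_baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in _BASELINE_MIXTURE])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    a = np.array([a for _, a, _ in _BASELINE_MIXTURE])[comp]
    b = np.array([b for _, _, b in _BASELINE_MIXTURE])[comp]
    return rng.beta(a, b)


def _draw_feasible_baselines(
    rng: np.random.Generator, n: int, low: float, high: float
) -> np.ndarray:
    """Mixture baselines rejected into [low, high] (feasibility for drift)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = _draw_baselines(rng, max(2 * (n - filled), 16))
        ok = cand[(cand >= low) & (cand <= high)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _mean_stable_location(target_mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Logit location mu with E[inv_logit(mu + sd*Z)] = target_mean.

    Newton iteration on Gauss–Hermite quadrature of the logit-normal mean;
    keeps the beta-scale expectation flat when the noise SD varies.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    weights = weights / weights.sum()
    mu = _logit(target_mean)
    for _ in range(8):
        z = mu[..., None] + sd[..., None] * nodes
        f = _inv_logit(z)
        g = (f * weights).sum(axis=-1) - target_mean
        dg = (f * (1.0 - f) * weights).sum(axis=-1)
        step = g / np.maximum(dg, 1e-12)
        mu = mu - np.clip(step, -4.0, 4.0)
        if np.max(np.abs(g)) < 1e-10:
            break
    return mu


def generate_cohort(
    config: SimulationConfig,
    ground_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Passing the ``ground_truth`` of a previous call replants the same CpG
    classes (by probe id) with fresh donors, baselines and noise —
    emulating an independent validation cohort assayed on the same array.

    Returns
    -------
    beta : DataFrame
        Probes x samples beta matrix, all values in (0, 1) (NaN where
        ``missing_rate`` applies).
    sheet : DataFrame
        Sample sheet with ``sample_id, donor_id, passage, segment, age,
        sex, cohort``.
    truth : DataFrame
        Ground truth with ``probe_id, true_class, true_effect`` — the
        planted full-range beta change for directional CpGs, the logit-SD
        slope for heteroskedastic ones, 0 otherwise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.passage_range
    span = max(hi - lo, 1)

    # --- sample sheet: donors observed at alternating early/late harvests
    donor_idx = np.arange(cfg.n_samples) % cfg.n_donors
    order_within_donor = np.arange(cfg.n_samples) // cfg.n_donors
    early, late = _passage_windows(lo, hi)
    take_early = (order_within_donor + donor_idx) % 2 == 0
    # harvests follow a balanced schedule cycling through each window's
    # passages, as a study protocol with planned harvest time points would
    passages = np.empty(cfg.n_samples, dtype=int)
    idx_early = np.flatnonzero(take_early)
    idx_late = np.flatnonzero(~take_early)
    passages[idx_early] = early[np.arange(idx_early.size) % early.size]
    passages[idx_late] = late[np.arange(idx_late.size) % late.size]
    donor_segment = np.where(np.arange(cfg.n_donors) % 2 == 0, "TI", "SC")
    donor_age = rng.integers(4, 19, size=cfg.n_donors)
    donor_sex = rng.choice(["F", "M"], size=cfg.n_donors)
    sheet = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(cfg.n_samples)],
            "donor_id": [f"D{d + 1:03d}" for d in donor_idx],
            "passage": passages.astype(int),
            "segment": donor_segment[donor_idx],
            "age": donor_age[donor_idx],
            "sex": donor_sex[donor_idx],
            "cohort": "sim",
        }
    )

    # --- per-CpG classes and baselines
    if ground_truth is not None:
        if len(ground_truth) != cfg.n_cpgs:
            raise ValueError(
                f"ground_truth has {len(ground_truth)} CpGs but config asks for {cfg.n_cpgs}"
            )
        classes = ground_truth["true_class"].to_numpy(dtype=object)
        probe_ids = ground_truth["probe_id"].to_numpy()
    else:
        n_hypo = round(cfg.fraction_hypo * cfg.n_cpgs)
        n_hyper = round(cfg.fraction_hyper * cfg.n_cpgs)
        n_hetero = round(cfg.fraction_hetero * cfg.n_cpgs)
        classes = np.array(
            ["hypo"] * n_hypo
            + ["hyper"] * n_hyper
            + ["hetero"] * n_hetero
            + ["stable"] * (cfg.n_cpgs - n_hypo - n_hyper - n_hetero)
        )
        classes = classes[rng.permutation(cfg.n_cpgs)]
        probe_ids = np.array([f"cg{i:07d}" for i in range(cfg.n_cpgs)])

    baseline = _draw_baselines(rng, cfg.n_cpgs)
    margin = 0.05
    is_hypo = classes == "hypo"
    is_hyper = classes == "hyper"
    is_hetero = classes == "hetero"
    if is_hypo.any():
        baseline[is_hypo] = _draw_feasible_baselines(
            rng, int(is_hypo.sum()), cfg.delta_beta_effect + margin, 1.0 - margin
        )
    if is_hyper.any():
        baseline[is_hyper] = _draw_feasible_baselines(
            rng, int(is_hyper.sum()), margin, 1.0 - cfg.delta_beta_effect - margin
        )
    if is_hetero.any():
        # stochastic fan-out without a trend needs room on both sides of the
        # baseline, so heteroskedastic CpGs sit at intermediate methylation
        # (as variably methylated CpGs do on real arrays)
        baseline[is_hetero] = _draw_feasible_baselines(
            rng, int(is_hetero.sum()), 0.25, 0.75
        )

    # --- expected beta per (CpG, sample): linear trend for directional CpGs
    frac = (passages - lo) / span  # 0 at first passage, 1 at last
    sign = np.where(is_hypo, -1.0, np.where(is_hyper, 1.0, 0.0))
    mean_beta = baseline[:, None] + np.outer(sign * cfg.delta_beta_effect, frac)
    np.clip(mean_beta, _MEAN_CLIP, 1.0 - _MEAN_CLIP, out=mean_beta)

    # --- logit-scale effects: donor intercepts, segment shift, noise
    donor_eff = rng.normal(0.0, cfg.donor_sd, size=(cfg.n_cpgs, cfg.n_donors))
    logit_mu = _logit(mean_beta) + donor_eff[:, donor_idx]

    n_seg = round(cfg.segment_fraction * cfg.n_cpgs)
    if n_seg and cfg.segment_effect > 0:
        seg_rows = rng.choice(cfg.n_cpgs, size=n_seg, replace=False)
        seg_sign = rng.choice([-1.0, 1.0], size=n_seg)
        is_ti = (sheet["segment"] == "TI").to_numpy()
        logit_mu[seg_rows] += np.outer(seg_sign * cfg.segment_effect, is_ti)

    sd = np.full((cfg.n_cpgs, cfg.n_samples), cfg.base_noise_sd)
    if is_hetero.any():
        sd[is_hetero] = cfg.base_noise_sd + cfg.hetero_sd_slope * (passages - lo)
        # logit-normal noise is mean-shifting on the beta scale when the
        # baseline sits off 0.5; recentre so heteroskedastic CpGs keep a
        # passage-constant expected beta (spread grows, no trend)
        logit_mu[is_hetero] = _mean_stable_location(
            mean_beta[is_hetero], sd[is_hetero]
        ) + (logit_mu[is_hetero] - _logit(mean_beta[is_hetero]))
    beta_values = _inv_logit(logit_mu + rng.normal(size=logit_mu.shape) * sd)

    if cfg.missing_rate > 0:
        mask = rng.random(beta_values.shape) < cfg.missing_rate
        beta_values = np.where(mask, np.nan, beta_values)

    beta = pd.DataFrame(beta_values, index=pd.Index(probe_ids, name="probe_id"), columns=sheet["sample_id"].to_numpy())
    true_effect = np.where(
        is_hypo | is_hyper, sign * cfg.delta_beta_effect,
        np.where(is_hetero, cfg.hetero_sd_slope, 0.0),
    )
    truth = pd.DataFrame(
        {"probe_id": probe_ids, "true_class": classes, "true_effect": true_effect}
    )
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# genomic tracks


def _lay_intervals(
    rng: np.random.Generator,
    labels: list[str],
    chroms: list[str],
    chrom_len: int,
    width: int,
    offset: int = 0,
) -> pd.DataFrame:
    """Place one interval per label entry, non-overlapping, across chroms."""
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, lab in enumerate(labels):
        per_chrom[chroms[i % len(chroms)]].append(lab)
    rows = []
    for chrom, labs in per_chrom.items():
        if not labs:
            continue
        gap = (chrom_len - 2 * offset) / len(labs)
        if gap < 1.5 * width:
            raise ValueError(
                f"genome too small: need {len(labs)} intervals of width {width} "
                f"on {chrom} of length {chrom_len}"
            )
        jitter = rng.integers(0, max(int(gap - width), 1), size=len(labs))
        for k, lab in enumerate(labs):
            start = int(offset + k * gap) + int(jitter[k])
            rows.append((chrom, start, start + width, lab))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "label"])


def generate_tracks(
    n_features: int,
    genome_length: int,
    ground_truth: pd.DataFrame,
    enrichment_plan: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    feature_width: int = 2_000,
    n_orc_peaks: int | None = None,
    n_cdmrs: int | None = None,
    n_transcripts: int | None = None,
) -> tuple[pd.DataFrame, dict[str, IntervalTrack]]:
    """Assign probe coordinates and fabricate annotation tracks.

    ``n_features`` regulatory intervals (cycled over the six regulatory
    categories) and the colon-cancer DMR intervals are laid out mutually
    non-overlapping on two chromosomes, so per-category background
    fractions are exact bp fractions.  ``enrichment_plan`` maps a
    ground-truth class to ``{category: fold}`` where category is a
    regulatory label or ``cdmr_loss`` / ``cdmr_gain``; probes of that class
    are placed inside the category at ``fold`` times the background rate.
    Replication-origin peaks and transcripts are placed independently.

    Returns the probe annotation (probe_id, chromosome, position, QC flags)
    and a dict of tracks: ``regulatory``, ``cdmr``, ``orc``,
    ``transcripts``.
    """
    if n_features < 0:
        raise ValueError("n_features must be >= 0")
    rng = np.random.default_rng(seed)
    plan = enrichment_plan or {}
    chroms = ["chr1", "chr2"]
    chrom_len = genome_length // len(chroms)

    n_orc = n_features // 2 if n_orc_peaks is None else n_orc_peaks
    n_cdmr = max(6, n_features // 6) if n_cdmrs is None else n_cdmrs
    n_tx = max(10, n_features // 2) if n_transcripts is None else n_transcripts

    reg_labels = [REGULATORY_CATEGORIES[i % len(REGULATORY_CATEGORIES)] for i in range(n_features)]
    cdmr_labels = (["cdmr_loss", "cdmr_gain"] * ((n_cdmr + 1) // 2))[:n_cdmr] if n_cdmr else []
    placement = _lay_intervals(rng, reg_labels + cdmr_labels, chroms, chrom_len, feature_width)
    is_cdmr = placement["label"].str.startswith("cdmr_")
    reg_df = placement[~is_cdmr].reset_index(drop=True)
    cdmr_df = placement[is_cdmr].reset_index(drop=True)

    # background fraction of the genome occupied by each placement bin
    bins = list(dict.fromkeys(placement["label"])) if len(placement) else []
    bin_frac = {
        b: (placement["label"] == b).sum() * feature_width / genome_length for b in bins
    }

    probe_ids = ground_truth["probe_id"].to_numpy()
    classes = ground_truth["true_class"].to_numpy()
    n_probes = len(probe_ids)
    chrom_of = np.empty(n_probes, dtype=object)
    pos_of = np.empty(n_probes, dtype=np.int64)

    placed_by_bin = {b: placement[placement["label"] == b].reset_index(drop=True) for b in bins}
    all_starts = {c: np.sort(placement.loc[placement["chromosome"] == c, "start"].to_numpy()) for c in chroms}
    all_ends = {c: np.sort(placement.loc[placement["chromosome"] == c, "end"].to_numpy()) for c in chroms}

    def _outside_position() -> tuple[str, int]:
        while True:
            c = chroms[rng.integers(len(chroms))]
            p = int(rng.integers(0, chrom_len))
            k = np.searchsorted(all_starts[c], p, side="right")
            if k == 0 or all_ends[c][k - 1] <= p:
                return c, p

    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        folds = plan.get(str(cls), {})
        probs = np.array([folds.get(b, 1.0) * bin_frac[b] for b in bins])
        if probs.sum() > 1.0:
            raise ValueError(
                f"genome too small for requested enrichment folds of class {cls!r} "
                f"(bin probabilities sum to {probs.sum():.3f})"
            )
        choice = rng.choice(
            len(bins) + 1, size=len(idx), p=np.append(probs, 1.0 - probs.sum())
        )
        for j, i in zip(choice, idx):
            if j == len(bins):
                chrom_of[i], pos_of[i] = _outside_position()
            else:
                sub = placed_by_bin[bins[j]]
                row = sub.iloc[int(rng.integers(len(sub)))]
                chrom_of[i] = row["chromosome"]
                pos_of[i] = int(rng.integers(row["start"], row["end"]))

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom_of,
            "position": pos_of,
            "polymorphic": 0,
            "cross_hybridizing": 0,
        }
    )

    tracks: dict[str, IntervalTrack] = {
        "regulatory": IntervalTrack("regulatory", reg_df),
        "cdmr": IntervalTrack("cdmr", cdmr_df)
        if len(cdmr_df)
        else IntervalTrack("cdmr", pd.DataFrame(columns=["chromosome", "start", "end", "label"])),
    }
    orc_labels = ["orc_peak"] * n_orc
    orc_df = _lay_intervals(rng, orc_labels, chroms, chrom_len, feature_width // 2, offset=feature_width // 3)
    tracks["orc"] = IntervalTrack("orc", orc_df)
    tx_labels = [f"GENE{i + 1:05d}" for i in range(n_tx)]
    tx_df = _lay_intervals(rng, tx_labels, chroms, chrom_len, feature_width * 5, offset=feature_width)
    tracks["transcripts"] = IntervalTrack("transcripts", tx_df)
    return annotation, tracks
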