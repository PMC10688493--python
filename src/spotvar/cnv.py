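"""Arm-level copy-number inference from spot expression.

Copy-number alterations shift the expression of many adjacent genes at
once, so a robust per-arm summary of per-gene log2 expression ratios
recovers arm-level gains and losses even though any single gene's
expression is noisy. The pipeline:

1. Convert UMI counts to log2 ratios, per gene, centered on the gene's
   median across spots (:func:`compute_log_ratios`).
2. Weight genes by an external expression-vs-copy-number correlation
   prior times within-dataset stability and expression level
   (:func:`compute_gene_weights`). Down-weighting co-regulated
   lineage-specific gene blocks is what keeps, e.g., a keratin cluster
   from masquerading as an amplification.
3. Summarize each arm per spot as the weighted median of its genes'
   ratios (:func:`arm_signals`); this per-arm log2 signal is written
   CNVsig throughout.
4. Drop spots with no UMIs on two or more arms; rescue them by pooling
   adjacent same-cluster spots until the pool exceeds 5000 UMIs
   (:func:`rescue_group_spots`).
5. Re-center all spots against a non-tumor reference pool
   (:func:`recenter`).
6. Score each spot's similarity to the DNA-derived profile: the sum of
   gene-count-weighted signals over DNA-called gain arms minus the sum
   over loss arms (:func:`similarity_score`), assess significance against
   a within-spot arm-label permutation null (:func:`permutation_null`),
   convert to q-values (:func:`q_values`), and bin spots from
   "likely tumor" to "not likely tumor" (:func:`categorize_spots`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SpotLayout, validate_arm_profile

__all__ = [
    "LogRatioMatrix",
    "ArmSignalMatrix",
    "SpotGroup",
    "compute_log_ratios",
    "compute_gene_weights",
    "weighted_median",
    "arm_signals",
    "filter_low_coverage_spots",
    "rescue_group_spots",
    "pool_groups",
    "recenter",
    "arm_weights",
    "similarity_score",
    "score_all",
    "permutation_null",
    "q_values",
    "categorize_spots",
    "DEFAULT_Q_CUTS",
    "DEFAULT_CATEGORY_LABELS",
]

DEFAULT_Q_CUTS = (0.05, 0.25, 0.5)
DEFAULT_CATEGORY_LABELS = (
    "likely_tumor",
    "probable_tumor",
    "possible_tumor",
    "not_likely_tumor",
)


@dataclass
class LogRatioMatrix:
    """Per-gene log2 expression ratios (kept genes x spots).

    ``ratios``/``scaled`` cover kept genes only; ``kept`` flags every
    input gene; ``counts`` retains the raw input matrix so downstream
    steps can compute raw per-arm UMI totals.
    """

    ratios: pd.DataFrame
    scaled: pd.DataFrame
    kept: pd.Series
    counts: pd.DataFrame
    pseudocount: float
    target_sum: float


@dataclass
class ArmSignalMatrix:
    """Per-spot, per-arm copy-number signal (CNVsig, a log2 ratio).

    Arms with fewer kept genes than the minimum are absent; spots with no
    usable data on an arm are NaN — missing, never zero. ``arm_umis``
    holds raw UMI totals over each arm's annotated genes, used for the
    low-coverage spot filter.
    """

    signal: pd.DataFrame  # spots x arms, NaN = missing
    n_genes_used: pd.Series  # per arm
    arm_umis: pd.DataFrame  # spots x arms (raw counts)
    total_umis: pd.Series  # per spot

    @property
    def spots(self) -> pd.Index:
        return self.signal.index

    @property
    def arms(self) -> pd.Index:
        return self.signal.columns


@dataclass(frozen=True)
class SpotGroup:
    """Adjacent, same-cluster spots pooled to rescue low-coverage data."""

    members: tuple[str, ...]
    cluster: int | None
    total_umis: int

    @property
    def name(self) -> str:
        return f"group:{self.members[0]}"


def compute_log_ratios(
    umi_matrix: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    min_detect_frac: float = 0.05,
    pseudocount: float = 1.0,
    target_sum: float = 1e4,
) -> LogRatioMatrix:
    """Median-centered log2 expression ratios per gene and spot.

    Each spot's counts are scaled to ``target_sum`` total; the ratio is
    ``log2((scaled + pseudocount) / median_over_spots(scaled + pseudocount))``.
    Genes detected in fewer than ``min_detect_frac`` of spots, or absent
    from the annotation, are dropped (``kept = False``).
    """
    counts = umi_matrix.astype(float)
    totals = counts.sum(axis=0)
    scale = totals.replace(0, np.nan)
    scaled = counts.div(scale, axis=1).mul(target_sum).fillna(0.0)

    detect_frac = (counts > 0).mean(axis=1)
    annotated = umi_matrix.index.isin(gene_annotation.index)
    kept = pd.Series(
        (detect_frac >= min_detect_frac).to_numpy() & annotated,
        index=umi_matrix.index,
        name="kept",
    )
    if not kept.any():
        raise ValueError("all genes filtered out; nothing to analyze")
    shifted = scaled.loc[kept] + pseudocount
    gene_median = shifted.median(axis=1)
    ratios = np.log2(shifted.div(gene_median, axis=0))
    return LogRatioMatrix(
        ratios=ratios,
        scaled=scaled.loc[kept],
        kept=kept,
        counts=umi_matrix,
        pseudocount=pseudocount,
        target_sum=target_sum,
    )


def compute_gene_weights(
    lrm: LogRatioMatrix, gene_annotation: pd.DataFrame, default_prior: float = 0.5
) -> pd.Series:
    """Per-gene weight = prior x stability x expression-level rank.

    * prior: externally supplied expression-vs-copy-number correlation
      prior from the annotation (``prior_weight``, default 0.5) — high for
      genes whose expression tracks DNA copy number in reference cohorts.
    * stability: 1 / (1 + CV^2) of the gene's scaled expression across
      spots — stable genes are more informative.
    * expression level: the gene's mean scaled expression mapped to its
      average rank in (0, 1] — better-expressed genes are more reliable.
    """
    genes = lrm.ratios.index
    prior = (
        gene_annotation["prior_weight"].reindex(genes).fillna(default_prior)
    )
    mean = lrm.scaled.mean(axis=1)
    std = lrm.scaled.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, (std / mean) ** 2, np.inf)
    stability = pd.Series(1.0 / (1.0 + cv2), index=genes)
    expr_rank = mean.rank(method="average") / len(genes)
    weights = (prior * stability * expr_rank).astype(float)
    weights.name = "weight"
    return weights


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: smallest value whose cumulative weight
    (after sorting by value) reaches half the total weight.

    Ties in value are resolved by first occurrence; with unit weights and
    odd n this is the ordinary median.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or v.size != w.size:
        raise ValueError("values and weights must be equal-length and non-empty")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, total / 2.0, side="left"))
    return float(v[order][idx])


def arm_signals(
    lrm: LogRatioMatrix,
    gene_weights: pd.Series,
    gene_annotation: pd.DataFrame,
    min_genes_per_arm: int = 10,
) -> ArmSignalMatrix:
    """CNVsig(spot, arm): weighted median of the arm's kept-gene ratios.

    Arms with fewer than ``min_genes_per_arm`` kept genes are excluded
    entirely. Spots with zero total UMIs carry all-missing rows: their
    ratios are a pseudocount artifact, not signal.
    """
    genes = lrm.ratios.index
    arms_of = gene_annotation["arm"].reindex(genes)
    arm_members = {
        arm: idx.tolist()
        for arm, idx in genes.groupby(arms_of).items()
        if len(idx) >= min_genes_per_arm
    }
    if not arm_members:
        raise ValueError(
            f"no chromosome arm has >= {min_genes_per_arm} kept genes"
        )
    arm_names = sorted(arm_members)
    spots = lrm.ratios.columns
    total_umis = lrm.counts.sum(axis=0).reindex(spots, fill_value=0)

    sig = np.full((len(spots), len(arm_names)), np.nan)
    ratio_values = lrm.ratios.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    nonzero = total_umis.to_numpy() > 0
    for j, arm in enumerate(arm_names):
        rows = [gene_pos[g] for g in arm_members[arm]]
        sub = ratio_values[rows, :]
        w = gene_weights.reindex(arm_members[arm]).to_numpy(dtype=float)
        if not np.isfinite(w).all() or w.sum() <= 0:
            raise ValueError(f"arm {arm}: invalid gene weights")
        for i in range(len(spots)):
            if nonzero[i]:
                sig[i, j] = weighted_median(sub[:, i], w)

    # raw UMI totals per arm use every annotated gene present in the matrix
    all_arms_of = gene_annotation["arm"].reindex(lrm.counts.index)
    arm_umis = (
        lrm.counts.groupby(all_arms_of).sum().T.reindex(columns=arm_names).fillna(0)
    ).astype(int)

    return ArmSignalMatrix(
        signal=pd.DataFrame(sig, index=spots, columns=arm_names),
        n_genes_used=pd.Series(
            {a: len(arm_members[a]) for a in arm_names}, name="n_genes"
        ),
        arm_umis=arm_umis.loc[spots],
        total_umis=total_umis.astype(int),
    )


def filter_low_coverage_spots(
    asm: ArmSignalMatrix,
) -> tuple[list[str], list[str]]:
    """Drop spots with zero UMIs on two or more chromosomal arms.

    Returns (kept, dropped) barcode lists; a single empty arm is
    tolerated.
    """
    zero_arms = (asm.arm_umis == 0).sum(axis=1)
    dropped = zero_arms.index[zero_arms >= 2].tolist()
    kept = zero_arms.index[zero_arms < 2].tolist()
    return kept, dropped


def rescue_group_spots(
    dropped: Sequence[str],
    layout: SpotLayout,
    clusters: pd.Series | None,
    umi_matrix: pd.DataFrame,
    umi_threshold: int = 5000,
) -> list[SpotGroup]:
    """Greedily pool adjacent, same-cluster dropped spots into groups
    whose UMI total exceeds ``umi_threshold`` (typically 2-10 spots).

    Seeds are picked by descending UMI count (ties by barcode order); a
    group repeatedly absorbs the still-ungrouped dropped neighbour of any
    member that shares the seed's cluster and has the highest UMI count,
    until the pooled total exceeds the threshold or no eligible neighbour
    remains. Groups that never clear the threshold are discarded.
    Deterministic for fixed inputs.
    """
    if clusters is None:
        clusters = layout.clusters
    totals = umi_matrix.sum(axis=0)
    ungrouped = {b for b in dropped if b in layout}
    groups: list[SpotGroup] = []

    def umis(b: str) -> int:
        return int(totals.get(b, 0))

    def cluster_of(b: str):
        val = clusters.get(b) if b in clusters.index else None
        return None if pd.isna(val) else int(val)

    while ungrouped:
        seed = max(sorted(ungrouped), key=umis)  # ties -> first in barcode order
        seed_cluster = cluster_of(seed)
        members = [seed]
        ungrouped.discard(seed)
        total = umis(seed)
        while total <= umi_threshold:
            frontier = {
                nb
                for m in members
                for nb in layout.neighbors(m)
                if nb in ungrouped and cluster_of(nb) == seed_cluster
            }
            if not frontier:
                break
            nxt = max(sorted(frontier), key=umis)
            members.append(nxt)
            ungrouped.discard(nxt)
            total += umis(nxt)
        if total > umi_threshold:
            groups.append(SpotGroup(tuple(members), seed_cluster, total))
    return groups


def pool_groups(
    umi_matrix: pd.DataFrame, groups: Sequence[SpotGroup]
) -> pd.DataFrame:
    """Append one pooled pseudo-spot column per rescue group."""
    pooled = {
        g.name: umi_matrix[list(g.members)].sum(axis=1) for g in groups
    }
    if not pooled:
        return umi_matrix
    return pd.concat([umi_matrix, pd.DataFrame(pooled)], axis=1)


def recenter(asm: ArmSignalMatrix, reference_spots: Iterable[str]) -> ArmSignalMatrix:
    """Subtract the reference pool's per-arm median signal from all spots.

    The log ratios are centered on the whole-dataset median, so a clonal
    alteration shows up half in tumor spots and half (with opposite sign)
    in normal spots; re-centering on a non-tumor pool puts zero at true
    copy-neutral.
    """
    ref = [s for s in reference_spots]
    if not ref:
        raise ValueError("empty reference pool")
    missing = set(ref) - set(asm.spots)
    if missing:
        raise ValueError(f"reference spots absent from signal matrix: {sorted(missing)[:5]}")
    ref_median = asm.signal.loc[ref].median(axis=0, skipna=True)
    return ArmSignalMatrix(
        signal=asm.signal.sub(ref_median, axis=1),
        n_genes_used=asm.n_genes_used,
        arm_umis=asm.arm_umis,
        total_umis=asm.total_umis,
    )


def arm_weights(
    gene_annotation: pd.DataFrame, kept_genes: Iterable[str]
) -> pd.Series:
    """Wt per arm: kept-gene count divided by the largest arm's count.

    Down-weights small arms whose signal rests on few genes.
    """
    kept = pd.Index(kept_genes)
    counts = gene_annotation["arm"].reindex(kept).value_counts()
    if counts.empty:
        raise ValueError("no kept genes with arm annotation")
    wt = (counts / counts.max()).astype(float)
    wt.name = "Wt"
    return wt.sort_index()


def _profile_vector(
    arms: pd.Index, dna_profile: Mapping[str, str], wt: pd.Series
) -> np.ndarray:
    """Signed weight vector: +Wt on gain arms, -Wt on loss arms, else 0."""
    prof = validate_arm_profile(dna_profile)
    c = np.zeros(len(arms))
    for i, arm in enumerate(arms):
        direction = prof.get(arm, "neutral")
        if direction == "gain":
            c[i] = wt.get(arm, 0.0)
        elif direction == "loss":
            c[i] = -wt.get(arm, 0.0)
    return c


def similarity_score(
    spot_signal: pd.Series, dna_profile: Mapping[str, str], wt: pd.Series
) -> float:
    """Score = sum of weighted gains - sum of weighted losses.

    A spot whose signal matches the DNA profile (up on gain arms, down on
    loss arms) scores positive. Arms missing from the signal contribute
    zero; if every non-neutral profile arm is missing the score is
    undefined and an error is raised.
    """
    prof = validate_arm_profile(dna_profile)
    informative = [a for a, d in prof.items() if d != "neutral"]
    present = [
        a for a in informative
        if a in spot_signal.index and np.isfinite(spot_signal.get(a, np.nan))
    ]
    if not present:
        raise ValueError("every non-neutral profile arm is missing from the signal")
    c = _profile_vector(spot_signal.index, prof, wt)
    x = spot_signal.to_numpy(dtype=float)
    return float(np.nansum(c * x))


def score_all(
    asm: ArmSignalMatrix, dna_profile: Mapping[str, str], wt: pd.Series
) -> pd.Series:
    """Similarity score for every spot in the matrix."""
    scores = pd.Series(
        [similarity_score(asm.signal.loc[s], dna_profile, wt) for s in asm.spots],
        index=asm.spots,
        name="score",
    )
    return scores


def permutation_null(
    asm: ArmSignalMatrix,
    dna_profile: Mapping[str, str],
    wt: pd.Series,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null similarity scores from within-spot arm-label permutation.

    For each spot, the observed arm-signal values are shuffled across the
    (non-missing) arm labels ``n_perm`` times — preserving the spot's
    value multiset while destroying its genomic arrangement — and each
    permutation is scored against the DNA profile. Returns
    ``n_perm * n_spots`` scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    c = _profile_vector(asm.arms, dna_profile, wt)
    out = np.empty(len(asm.spots) * n_perm)
    pos = 0
    sig = asm.signal.to_numpy(dtype=float)
    for i in range(sig.shape[0]):
        row = sig[i]
        mask = np.isfinite(row)
        x = row[mask]
        cm = c[mask]
        if x.size == 0:
            out[pos:pos + n_perm] = 0.0
        else:
            perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
            out[pos:pos + n_perm] = perms @ cm
        pos += n_perm
    return out


def q_values(
    observed: pd.Series, null: np.ndarray, null_inflation: float = 100.0
) -> pd.Series:
    """Permutation q-value per spot.

    At each score threshold s: false positives = (# null scores >= s)
    divided by the inflation factor (the null holds ``null_inflation``
    times more points than the observed data); total positives =
    # observed scores >= s. The spot's q is the minimum of FP/TP over all
    thresholds that include it (thresholds at or below its own score) —
    the usual q-value monotonization, which makes q non-increasing in
    score — capped at 1.
    Ties are counted inclusively on both sides; TP >= 1 always (the spot
    itself).
    """
    if len(null) == 0:
        raise ValueError("empty null sample")
    null_sorted = np.sort(np.asarray(null, dtype=float))
    obs = observed.to_numpy(dtype=float)
    obs_sorted = np.sort(obs)
    n_null_ge = len(null_sorted) - np.searchsorted(null_sorted, obs, side="left")
    n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, obs, side="left")
    raw = np.minimum(1.0, (n_null_ge / null_inflation) / n_obs_ge)
    # min over all thresholds <= each spot's score: cumulative minimum
    # along ascending score order
    order = np.argsort(obs, kind="stable")
    q = np.empty_like(raw)
    q[order] = np.minimum.accumulate(raw[order])
    return pd.Series(q, index=observed.index, name="q_value")


def categorize_spots(
    scores: pd.Series,
    qvals: pd.Series,
    q_cuts: Sequence[float] = DEFAULT_Q_CUTS,
    labels: Sequence[str] = DEFAULT_CATEGORY_LABELS,
) -> pd.DataFrame:
    """Bin spots into ordered tumor-likelihood categories by q-value.

    ``q <= q_cuts[0]`` is the most tumor-like bin; within each bin spots
    are ranked by descending score. Returns a DataFrame (barcode index)
    with score, q_value, category columns, ordered for display.
    """
    cuts = list(q_cuts)
    if cuts != sorted(cuts):
        raise ValueError("q_cuts must be sorted ascending")
    if len(labels) != len(cuts) + 1:
        raise ValueError("need len(q_cuts) + 1 category labels")
    q = qvals.reindex(scores.index)
    bins = np.searchsorted(cuts, q.to_numpy(), side="left")
    df = pd.DataFrame(
        {
            "score": scores,
            "q_value": q,
            "category": [labels[b] for b in bins],
        }
    )
    df["_bin"] = bins
    df = df.sort_values(
        ["_bin", "score"], ascending=[True, False], kind="stable"
    ).drop(columns="_bin")
    return df
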