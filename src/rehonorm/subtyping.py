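"""Deviation-based patient subtyping and stability validation.

Subtypes are discovered by Euclidean k-means on region-level Z-deviation
maps.  The number of clusters is chosen by a majority vote over a battery
of eleven cluster-validity indices (silhouette, Calinski-Harabasz,
Davies-Bouldin, Dunn, gap statistic, Hartigan, Krzanowski-Lai, C-index,
McClain-Rao, Ratkowsky-Lance, Ball-Hall); each index votes for the k that
optimizes its own criterion and ties go to the smallest k.

Stability is validated by per-site clustering, leave-one-site-out
reclustering, and subgroup reruns (sex, median age split, clinical
subgroups), each compared with the primary labels via the label-overlap
rate after optimal alignment and the adjusted Rand index (ARI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

log = logging.getLogger(__name__)

DEFAULT_INDEX_BATTERY = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "gap",
    "hartigan",
    "krzanowski_lai",
    "c_index",
    "mcclain_rao",
    "ratkowsky_lance",
    "ball_hall",
)


@dataclass
class KSelectionReport:
    k_range: tuple[int, int]
    votes: dict[str, int]           # index name -> chosen k
    winning_k: int
    tally: dict[int, int]           # k -> number of votes


@dataclass
class SubtypeResult:
    labels: pd.Series               # subject_id -> 1..k
    centroids: np.ndarray           # k x n_features
    k: int
    inertia: float
    within_distance_mean: float
    between_distance_mean: float
    seed: int
    n_restarts: int


@dataclass
class ValidationReport:
    fold_overlap: dict               # fold name -> overlap rate (%)
    fold_ari: dict = field(default_factory=dict)
    failed_folds: list = field(default_factory=list)
    min_overlap: float = float("nan")
    mean_overlap: float = float("nan")
    site_filter_n: int | None = None


# ---------------------------------------------------------------------------
# core clustering

def cluster_subjects(
    z: pd.DataFrame, k: int, n_restarts: int = 50, seed: int = 0
) -> SubtypeResult:
    """Euclidean k-means, best of ``n_restarts`` k-means++ starts."""
    if k < 2:
        raise ValueError("k must be >= 2")
    x = z.to_numpy(dtype=float)
    if k > len(x):
        raise ValueError("k exceeds number of subjects")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, init="k-means++",
        random_state=seed % (2**31),
    ).fit(x)
    labels = pd.Series(km.labels_ + 1, index=z.index, name="subtype")
    d_within, d_between = [], []
    dist = squareform(pdist(x))
    lab = km.labels_
    for i in range(len(x)):
        same = lab == lab[i]
        same[i] = False
        if same.any():
            d_within.append(dist[i, same].mean())
        if (~same & (np.arange(len(x)) != i)).any():
            d_between.append(dist[i, lab != lab[i]].mean())
    return SubtypeResult(
        labels=labels,
        centroids=km.cluster_centers_,
        k=k,
        inertia=float(km.inertia_),
        within_distance_mean=float(np.mean(d_within)),
        between_distance_mean=float(np.mean(d_between)),
        seed=seed,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# validity indices

def _wcss(x: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        tot += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(tot)


def _dunn(dist: np.ndarray, labels: np.ndarray) -> float:
    clusters = np.unique(labels)
    diam = max(
        dist[np.ix_(labels == c, labels == c)].max() for c in clusters
    )
    sep = min(
        dist[np.ix_(labels == a, labels == b)].min()
        for i, a in enumerate(clusters)
        for b in clusters[i + 1:]
    )
    return sep / diam if diam > 0 else np.inf


def _c_index(dist_sorted: np.ndarray, dist: np.ndarray, labels: np.ndarray) -> float:
    within_mask = np.zeros_like(dist, dtype=bool)
    for c in np.unique(labels):
        idx = labels == c
        within_mask[np.ix_(idx, idx)] = True
    iu = np.triu_indices_from(dist, k=1)
    w = within_mask[iu]
    s = dist[iu][w].sum()
    n_w = int(w.sum())
    s_min = dist_sorted[:n_w].sum()
    s_max = dist_sorted[-n_w:].sum()
    if s_max == s_min:
        return 0.0
    return float((s - s_min) / (s_max - s_min))


def _mcclain_rao(dist: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(dist, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    d = dist[iu]
    mean_within = d[same].mean()
    mean_between = d[~same].mean()
    return float(mean_within / mean_between)


def _ratkowsky_lance(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    grand = x.mean(axis=0)
    tss = ((x - grand) ** 2).sum(axis=0)
    bgss = np.zeros(x.shape[1])
    for c in np.unique(labels):
        pts = x[labels == c]
        bgss += len(pts) * (pts.mean(axis=0) - grand) ** 2
    ok = tss > 0
    return float(np.mean(np.sqrt(bgss[ok] / tss[ok])) / np.sqrt(k))


def _gap_statistic(
    x: np.ndarray,
    ks: list[int],
    wcss_by_k: dict[int, float],
    rng: np.random.Generator,
    n_refs: int = 5,
) -> tuple[dict[int, float], dict[int, float]]:
    """Tibshirani gap: E*[log W_k] - log W_k over uniform references."""
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_w_ref = {k: [] for k in ks}
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, x.shape)
        for k in ks:
            km = KMeans(n_clusters=k, n_init=3,
                        random_state=int(rng.integers(2**31))).fit(ref)
            log_w_ref[k].append(np.log(km.inertia_))
    gap, s_k = {}, {}
    for k in ks:
        ref_logs = np.asarray(log_w_ref[k])
        gap[k] = float(ref_logs.mean() - np.log(wcss_by_k[k]))
        s_k[k] = float(ref_logs.std(ddof=0) * np.sqrt(1 + 1 / n_refs))
    return gap, s_k


def select_k(
    z: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    index_battery=DEFAULT_INDEX_BATTERY,
    seed: int = 0,
    n_restarts: int = 10,
    gap_refs: int = 5,
) -> KSelectionReport:
    """Majority-vote selection of the number of clusters.

    Every index in the battery is evaluated on k-means solutions over
    ``k_range`` and votes for the k optimizing its criterion; the winner is
    the modal k, ties resolved toward the smallest k.  Difference-based
    rules (Hartigan, Krzanowski-Lai, Ball-Hall) additionally use the k-1
    and k+1 solutions at the range boundaries.
    """
    if not index_battery:
        raise ValueError("index battery is empty")
    kmin, kmax = k_range
    x = z.to_numpy(dtype=float)
    n, p = x.shape
    if n <= kmax:
        raise ValueError("need more subjects than the largest candidate k")
    rng = np.random.default_rng(seed)

    ks = list(range(kmin, kmax + 1))
    ks_ext = list(range(max(kmin - 1, 1), kmax + 2))
    labels_by_k: dict[int, np.ndarray] = {}
    wcss_by_k: dict[int, float] = {}
    grand = x.mean(axis=0)
    wcss_by_k[1] = float(((x - grand) ** 2).sum())
    for k in ks_ext:
        if k == 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**31)).fit(x)
        labels_by_k[k] = km.labels_
        wcss_by_k[k] = float(km.inertia_)

    dist = squareform(pdist(x))
    iu = np.triu_indices_from(dist, k=1)
    dist_sorted = np.sort(dist[iu])

    scores: dict[str, dict[int, float]] = {name: {} for name in index_battery}
    for k in ks:
        lab = labels_by_k[k]
        for name in index_battery:
            if name == "silhouette":
                scores[name][k] = silhouette_score(x, lab)
            elif name == "calinski_harabasz":
                scores[name][k] = calinski_harabasz_score(x, lab)
            elif name == "davies_bouldin":
                scores[name][k] = davies_bouldin_score(x, lab)
            elif name == "dunn":
                scores[name][k] = _dunn(dist, lab)
            elif name == "c_index":
                scores[name][k] = _c_index(dist_sorted, dist, lab)
            elif name == "mcclain_rao":
                scores[name][k] = _mcclain_rao(dist, lab)
            elif name == "ratkowsky_lance":
                scores[name][k] = _ratkowsky_lance(x, lab, k)

    votes: dict[str, int] = {}
    maximize = {"silhouette", "calinski_harabasz", "dunn", "ratkowsky_lance"}
    minimize = {"davies_bouldin", "c_index", "mcclain_rao"}
    for name in index_battery:
        if name in maximize:
            votes[name] = max(ks, key=lambda k: (scores[name][k], -k))
        elif name in minimize:
            votes[name] = min(ks, key=lambda k: (scores[name][k], k))

    if "gap" in index_battery:
        gap, s_k = _gap_statistic(x, ks + [kmax + 1], wcss_by_k, rng, n_refs=gap_refs)
        chosen = None
        for k in ks:
            if gap[k] >= gap[k + 1] - s_k[k + 1]:
                chosen = k
                break
        votes["gap"] = chosen if chosen is not None else max(ks, key=lambda k: gap[k])

    if "hartigan" in index_battery:
        # H(k) = (W_k / W_{k+1} - 1)(n - k - 1); smallest k with H <= 10,
        # else the k with the largest drop H(k-1) - H(k)
        h = {
            k: (wcss_by_k[k] / wcss_by_k[k + 1] - 1.0) * (n - k - 1)
            for k in range(max(kmin - 1, 1), kmax + 1)
        }
        small = [k for k in ks if h[k] <= 10]
        if small:
            votes["hartigan"] = small[0]
        else:
            votes["hartigan"] = max(
                [k for k in ks if k - 1 in h], key=lambda k: (h[k - 1] - h[k], -k)
            )

    if "krzanowski_lai" in index_battery:
        def diff(k):
            return (k - 1) ** (2 / p) * wcss_by_k[k - 1] - k ** (2 / p) * wcss_by_k[k]
        kl = {}
        for k in ks:
            if k - 1 < 1:
                continue
            denom = abs(diff(k + 1))
            kl[k] = abs(diff(k)) / denom if denom > 0 else np.inf
        votes["krzanowski_lai"] = max(kl, key=lambda k: (kl[k], -k))

    if "ball_hall" in index_battery:
        bh = {k: wcss_by_k[k] / k for k in range(max(kmin - 1, 1), kmax + 1)}
        votes["ball_hall"] = max(
            [k for k in ks if k - 1 in bh], key=lambda k: (bh[k - 1] - bh[k], -k)
        )

    winning_k, tally = majority_vote(votes)
    return KSelectionReport(
        k_range=k_range, votes=votes, winning_k=winning_k, tally=tally
    )


def majority_vote(votes: dict[str, int]) -> tuple[int, dict[int, int]]:
    """Winning k = modal vote; ties resolved toward the smallest k."""
    if not votes:
        raise ValueError("no votes cast")
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    best = max(tally.values())
    return min(k for k, v in tally.items() if v == best), tally


# ---------------------------------------------------------------------------
# agreement measures

def align_labels(reference: pd.Series, candidate: pd.Series):
    """Optimally permute candidate cluster names to match the reference.

    Returns ``(aligned_candidate, overlap_rate)`` on the common subjects;
    the permutation maximizes total agreement via optimal assignment on
    the confusion matrix.
    """
    common = reference.index.intersection(candidate.index)
    if len(common) == 0:
        raise ValueError("label series share no subjects")
    ref = reference.loc[common].to_numpy()
    cand = candidate.loc[common].to_numpy()
    ref_vals, ref_codes = np.unique(ref, return_inverse=True)
    cand_vals, cand_codes = np.unique(cand, return_inverse=True)
    size = max(len(ref_vals), len(cand_vals))
    conf = np.zeros((size, size))
    np.add.at(conf, (cand_codes, ref_codes), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = {}
    for r, c in zip(rows, cols):
        if r < len(cand_vals):
            mapping[cand_vals[r]] = ref_vals[c] if c < len(ref_vals) else cand_vals[r]
    aligned_all = candidate.map(lambda v: mapping.get(v, v))
    overlap = 100.0 * float(
        (aligned_all.loc[common].to_numpy() == ref).mean()
    )
    return aligned_all, overlap


def adjusted_rand(labels_a, labels_b) -> float:
    """Pair-counting adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def network_aggregate(z: pd.DataFrame, region_to_network: pd.Series) -> pd.DataFrame:
    """Average region Z columns into network columns (subjects x networks)."""
    missing = [c for c in z.columns if c not in region_to_network.index]
    if missing:
        raise ValueError(f"regions missing from network map: {missing[:3]} ...")
    groups = region_to_network.loc[z.columns]
    return z.T.groupby(groups).mean().T


# ---------------------------------------------------------------------------
# stability validation

def site_filters(cohort: pd.DataFrame, min_site_n: int) -> pd.DataFrame:
    """Drop subjects from sites with fewer than ``min_site_n`` members."""
    counts = cohort["site_id"].value_counts()
    keep_sites = counts[counts >= min_site_n].index
    out = cohort[cohort["site_id"].isin(keep_sites)]
    dropped = len(cohort) - len(out)
    if dropped:
        log.info(
            "site_filters: dropped %d subjects from %d sites below n=%d",
            dropped, cohort["site_id"].nunique() - out["site_id"].nunique(), min_site_n,
        )
    if len(out) == 0:
        raise ValueError("site filter removed every subject")
    return out


def leave_one_site_out(
    z: pd.DataFrame,
    sites: pd.Series,
    k: int,
    seed: int = 0,
    primary: SubtypeResult | None = None,
    n_restarts: int = 50,
) -> ValidationReport:
    """Recluster with each site held out; compare to the primary labels.

    For every site s the remaining subjects are reclustered with the same
    k and seed policy, the labels are aligned to the primary labels on the
    shared subjects, and the overlap rate is recorded.  A fold whose
    clustering degenerates is recorded as failed rather than dropped
    silently.
    """
    sites = sites.loc[z.index]
    unique_sites = sorted(pd.unique(sites))
    if len(unique_sites) < 3:
        raise ValueError("leave-one-site-out needs >= 3 sites")
    if primary is None:
        primary = cluster_subjects(z, k, n_restarts=n_restarts, seed=seed)

    overlaps, aris, failed = {}, {}, []
    for s in unique_sites:
        keep = sites != s
        sub = z.loc[keep]
        if len(sub) == len(z):
            overlaps[s] = 100.0
            aris[s] = 1.0
            continue
        try:
            res = cluster_subjects(sub, k, n_restarts=n_restarts, seed=seed)
        except ValueError as exc:
            failed.append((s, str(exc)))
            continue
        if res.labels.nunique() < k:
            failed.append((s, "a cluster emptied"))
            continue
        aligned, overlap = align_labels(primary.labels, res.labels)
        overlaps[s] = overlap
        aris[s] = adjusted_rand(
            primary.labels.loc[sub.index].to_numpy(), res.labels.to_numpy()
        )
    vals = list(overlaps.values())
    return ValidationReport(
        fold_overlap=overlaps,
        fold_ari=aris,
        failed_folds=failed,
        min_overlap=float(np.min(vals)) if vals else float("nan"),
        mean_overlap=float(np.mean(vals)) if vals else float("nan"),
    )


def per_site_clustering(
    z: pd.DataFrame,
    sites: pd.Series,
    k: int,
    primary: SubtypeResult,
    seed: int = 0,
    min_site_n: int = 10,
    n_restarts: int = 50,
) -> ValidationReport:
    """Cluster each site separately and compare to the primary labels."""
    sites = sites.loc[z.index]
    overlaps, aris, failed = {}, {}, []
    for s in sorted(pd.unique(sites)):
        sub = z.loc[sites == s]
        if len(sub) < max(k + 1, min_site_n):
            failed.append((s, f"site too small (n={len(sub)})"))
            continue
        res = cluster_subjects(sub, k, n_restarts=n_restarts, seed=seed)
        _, overlap = align_labels(primary.labels, res.labels)
        overlaps[s] = overlap
        aris[s] = adjusted_rand(
            primary.labels.loc[sub.index].to_numpy(), res.labels.to_numpy()
        )
    vals = list(overlaps.values())
    return ValidationReport(
        fold_overlap=overlaps,
        fold_ari=aris,
        failed_folds=failed,
        min_overlap=float(np.min(vals)) if vals else float("nan"),
        mean_overlap=float(np.mean(vals)) if vals else float("nan"),
    )


def subgroup_validation(
    z: pd.DataFrame,
    cohort: pd.DataFrame,
    primary: SubtypeResult,
    seed: int = 0,
    n_restarts: int = 50,
) -> ValidationReport:
    """Recluster within standard subgroups and compare to primary labels.

    Subgroups: male, female, young/old (median age split), and the FEDN,
    recurrent, and medicated clinical subgroups when present.  Subgroups
    smaller than k + 1 are skipped with a warning.
    """
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    cohort = cohort.loc[z.index]
    median_age = cohort["age"].median()
    groups = {
        "male": cohort["sex"] == "M",
        "female": cohort["sex"] == "F",
        "young": cohort["age"] <= median_age,
        "old": cohort["age"] > median_age,
    }
    if "episode_status" in cohort:
        for status in ("FEDN", "recurrent", "medicated"):
            groups[status] = cohort["episode_status"] == status

    overlaps, aris, failed = {}, {}, []
    for name, mask in groups.items():
        sub = z.loc[mask.to_numpy()]
        if len(sub) <= primary.k:
            warnings.warn(f"subgroup {name!r} too small; skipped", stacklevel=2)
            failed.append((name, f"n={len(sub)}"))
            continue
        res = cluster_subjects(sub, primary.k, n_restarts=n_restarts, seed=seed)
        _, overlap = align_labels(primary.labels, res.labels)
        overlaps[name] = overlap
        aris[name] = adjusted_rand(
            primary.labels.loc[sub.index].to_numpy(), res.labels.to_numpy()
        )
    vals = list(overlaps.values())
    return ValidationReport(
        fold_overlap=overlaps,
        fold_ari=aris,
        failed_folds=failed,
        min_overlap=float(np.min(vals)) if vals else float("nan"),
        mean_overlap=float(np.mean(vals)) if vals else float("nan"),
    )
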