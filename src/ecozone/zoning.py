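"""Unsupervised delineation of ecological zones.

Sites are clustered on the z-scored key features (the forest-selected
environmental factors plus richness) with agglomerative hierarchical
clustering — Ward linkage on Euclidean distance by default, complete or
average linkage selectable.  The tree is cut at every candidate cluster
count k and the mean silhouette coefficient picks k* (ties resolved toward
the smaller, more parsimonious k).  Zone differences are validated per
feature with the Kruskal-Wallis rank test, and nutrient stoichiometry is
summarized as per-site TN:TP ratios grouped by zone and by channel type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

LINKAGES = ("ward", "complete", "average")

# atomic masses for the mass -> molar N:P conversion
_MASS_N = 14.007
_MASS_P = 30.974


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class ZoningInput:
    """Z-scored site x feature matrix with the recorded transformation."""

    z: pd.DataFrame
    center: pd.Series
    scale: pd.Series

    def inverse(self) -> pd.DataFrame:
        return self.z * self.scale + self.center


def standardize_features(matrix: pd.DataFrame) -> ZoningInput:
    """Z-score each column (population SD); constant columns are rejected."""
    if matrix.isna().any().any():
        bad = list(matrix.columns[matrix.isna().any()])
        raise ValueError(f"missing values in feature columns {bad}")
    center = matrix.mean(axis=0)
    scale = matrix.std(axis=0, ddof=0)
    constant = list(scale.index[scale == 0])
    if constant:
        raise ValueError(f"constant feature columns cannot be standardized: {constant}")
    z = (matrix - center) / scale
    return ZoningInput(z=z, center=center, scale=scale)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette_mean(z: ZoningInput | pd.DataFrame, labels) -> float:
    """Mean silhouette coefficient over sites, Euclidean distance.

    Sites in singleton zones contribute 0, as do coincident points where
    both the within- and nearest-other-zone mean distances vanish.
    """
    zmat = z.z if isinstance(z, ZoningInput) else z
    X = zmat.to_numpy(dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single zone")
    if any((labels == u).sum() == 0 for u in uniq):  # pragma: no cover - unique() precludes
        raise ValueError("empty zone")
    D = squareform(pdist(X))
    n = len(labels)
    scores = np.zeros(n)
    masks = {u: labels == u for u in uniq}
    for i in range(n):
        own = masks[labels[i]]
        size_own = own.sum()
        if size_own == 1:
            continue  # singleton contributes 0
        a = D[i, own].sum() / (size_own - 1)
        b = min(D[i, masks[u]].mean() for u in uniq if u != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


# ---------------------------------------------------------------------------
# hierarchical zoning
# ---------------------------------------------------------------------------

@dataclass
class ZoningResult:
    """Zone labels with the silhouette-by-k curve and the merge history."""

    labels: pd.Series              # site -> zone in 1..k_star
    k_star: int
    silhouette_by_k: dict[int, float]
    linkage: np.ndarray = field(repr=False)   # scipy linkage matrix
    site_ids: list[str] = field(default_factory=list)
    kw: pd.DataFrame | None = None            # per-feature (H, p)
    overall_valid: bool | None = None

    def linkage_table(self) -> pd.DataFrame:
        rows = [
            {"step": i, "left": int(l), "right": int(r), "height": h, "size": int(s)}
            for i, (l, r, h, s) in enumerate(self.linkage)
        ]
        return pd.DataFrame(rows).set_index("step")

    def to_newick(self) -> str:
        """Merge history as a Newick string (leaf names = site ids)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return f"{self.site_ids[node.id]}:{node.dist:.6g}"
            left, right = walk(node.left), walk(node.right)
            return f"({left},{right}):{node.dist:.6g}"

        body = walk(tree)
        # strip the root's branch length
        return body.rsplit(":", 1)[0] + ";"


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel zones 1..k in order of first appearance along the site order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def hierarchical_zoning(
    z: ZoningInput,
    k_min: int = 2,
    k_max: int | None = None,
    linkage: str = "ward",
) -> ZoningResult:
    """Cluster sites once, score every k in [k_min, k_max], pick k* by silhouette."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    X = z.z.to_numpy(dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError(f"need at least 3 sites to cluster, got {n}")
    if k_max is None:
        k_max = min(8, n - 1)
    if not (2 <= k_min <= k_max < n):
        raise ValueError(f"need 2 <= k_min <= k_max < n_sites, got [{k_min}, {k_max}], n={n}")
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:  # degenerate cut (all ties) — skip
            continue
        labels_by_k[k] = lab
        sil[k] = silhouette_mean(z, lab)
    best = max(sil, key=lambda k: (sil[k], -k))  # ties -> smaller k
    ties = [k for k, v in sil.items() if v == sil[best] and k != best]
    if ties:
        logger.info("silhouette tie between k=%s; choosing k=%d", [best] + ties, best)
    labels = pd.Series(
        _canonical_labels(labels_by_k[best]), index=z.z.index, name="zone"
    )
    return ZoningResult(
        labels=labels, k_star=best, silhouette_by_k=sil, linkage=Z,
        site_ids=list(z.z.index),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis validation
# ---------------------------------------------------------------------------

def kruskal_wallis_validation(
    features: pd.DataFrame,
    labels: pd.Series,
    primary: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool]:
    """Rank-based H test (tie-corrected) of zone differences per feature.

    Returns the per-feature (H, p) table and an overall flag that is true
    when every feature in ``primary`` (default: all features) rejects at
    ``alpha``.  Features constant across all sites have undefined H and are
    reported with NaN.
    """
    labels = labels.loc[features.index]
    groups = {z: features.index[labels == z] for z in sorted(labels.unique())}
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two zones")
    for z, idx in groups.items():
        if len(idx) < 2:
            logger.warning("zone %s has a single site; KW power is limited", z)
    rows = []
    for col in features.columns:
        samples = [features.loc[idx, col].to_numpy(dtype=float) for idx in groups.values()]
        if np.ptp(features[col].to_numpy(dtype=float)) == 0:
            rows.append({"feature": col, "H": np.nan, "p": np.nan})
            continue
        H, p = stats.kruskal(*samples)
        rows.append({"feature": col, "H": float(H), "p": float(p)})
    table = pd.DataFrame(rows).set_index("feature")
    primary = list(features.columns) if primary is None else primary
    ps = table.loc[primary, "p"]
    overall = bool(ps.notna().all() and (ps < alpha).all())
    return table, overall


# ---------------------------------------------------------------------------
# N:P stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class NPReport:
    """Per-site TN:TP ratios plus grouped summaries."""

    per_site: pd.DataFrame         # site_id -> np_ratio, zone, channel, flagged
    by_zone: pd.DataFrame
    by_channel: pd.DataFrame | None
    molar: bool = False


def _np_summary(df: pd.DataFrame, key: str) -> pd.DataFrame:
    ok = df[~df["flagged"]]
    g = ok.groupby(key)["np_ratio"]
    out = g.agg(
        mean="mean", median="median",
        q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
        n="count",
    )
    return out


def np_ratio(
    environment: pd.DataFrame,
    labels: pd.Series,
    channel: pd.Series | None = None,
    molar: bool = False,
) -> NPReport:
    """TN/TP per site (mass basis; molar behind ``molar=True``) with summaries.

    Sites with non-positive TP are flagged and excluded from summaries with
    a warning, never silently dropped.
    """
    for col in ("TN", "TP"):
        if col not in environment.columns:
            raise KeyError(f"environment table lacks required column {col!r}")
    tn = environment["TN"].astype(float)
    tp = environment["TP"].astype(float)
    flagged = tp <= 0
    if flagged.any():
        logger.warning(
            "N:P undefined at %d site(s) with TP <= 0: %s",
            int(flagged.sum()), list(environment.index[flagged]),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tn / tp
    if molar:
        ratio = ratio * _MASS_P / _MASS_N
    per_site = pd.DataFrame(
        {
            "np_ratio": ratio.where(~flagged),
            "zone": labels.loc[environment.index],
            "flagged": flagged,
        }
    )
    if channel is not None:
        per_site["channel"] = channel.loc[environment.index]
    by_zone = _np_summary(per_site, "zone")
    by_channel = _np_summary(per_site, "channel") if channel is not None else None
    return NPReport(per_site=per_site, by_zone=by_zone, by_channel=by_channel, molar=molar)


# ---------------------------------------------------------------------------
# per-zone feature summaries
# ---------------------------------------------------------------------------

def zone_summary(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Boxplot-style summary (min, Q1, median, mean, Q3, max, n) per zone x feature."""
    labels = labels.loc[features.index]
    rows = []
    for zone in sorted(labels.unique()):
        sub = features.loc[labels == zone]
        for col in features.columns:
            v = sub[col].to_numpy(dtype=float)
            rows.append(
                {
                    "zone": zone, "feature": col,
                    "min": v.min(), "q1": np.percentile(v, 25),
                    "median": np.percentile(v, 50), "mean": v.mean(),
                    "q3": np.percentile(v, 75), "max": v.max(), "n": len(v),
                }
            )
    return pd.DataFrame(rows).set_index(["zone", "feature"])
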