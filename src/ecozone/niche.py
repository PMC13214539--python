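"""Niche statistics on percentile-binned environmental gradients.

Each environmental gradient (DO, pH, WT, nutrients, silica) is discretized
into ``R`` *resource states* (default 5) by percentile cut points over the
sites.  A species' *utilization profile* along a gradient is the share of its
total abundance found at sites of each state:

    P_ij = (sum of abundance of species i at sites in state j) / n_i

Two classical indices are computed from the profiles:

* Levins niche breadth  ``B_i = 1 / sum_j P_ij**2``  — ranges from 1
  (specialist, all abundance in one state) to R (perfect generalist).
* Pianka niche overlap  ``O_ik = sum_j P_ij P_kj / sqrt(sum_j P_ij**2 *
  sum_j P_kj**2)`` — the cosine similarity of two profiles, in [0, 1].

Because pairwise Pianka values are bounded by 1 while community-level
reporting wants a per-species summary, overlap is also aggregated as the
per-species *total* ``sum_{k != i} O_ik`` per gradient (bounded by the number
of other species), and both breadth and overlap get a per-species mean over
gradients (Mean-S), a per-gradient mean over species (Mean-R), and dense
descending ranks.

The module also provides the breadth-vs-overlap OLS regression and the
abundance-weighted site-level niche features consumed by the richness-driver
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import validate_community
from .io import check_matched_sites

logger = logging.getLogger(__name__)

N_STATES = 5


# ---------------------------------------------------------------------------
# resource-state discretization
# ---------------------------------------------------------------------------

@dataclass
class ResourceStates:
    """Percentile binning of every gradient into ``R`` ordered states.

    ``edges[g]`` holds the R-1 interior percentile cut points of gradient
    ``g`` (linear-interpolation percentile definition); ``states`` maps each
    site to a state index in ``1..R`` per gradient.  A site whose value falls
    exactly on a cut point takes the lower state.
    """

    edges: dict[str, np.ndarray]
    states: pd.DataFrame  # site x gradient, int in 1..R
    R: int = N_STATES

    @property
    def gradients(self) -> list[str]:
        return list(self.states.columns)


def bin_resource_states(environment: pd.DataFrame, R: int = N_STATES) -> ResourceStates:
    """Assign every site to one of ``R`` percentile states per gradient."""
    if R < 2:
        raise ValueError(f"need at least 2 resource states, got R={R}")
    if environment.shape[0] < R:
        raise ValueError(
            f"need at least R={R} sites to define {R} percentile states, "
            f"got {environment.shape[0]}"
        )
    if environment.isna().any().any():
        bad = list(environment.columns[environment.isna().any()])
        raise ValueError(f"missing environment values in gradients {bad}")
    edges: dict[str, np.ndarray] = {}
    states = {}
    q = 100.0 * np.arange(1, R) / R
    for g in environment.columns:
        col = environment[g].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"gradient {g!r} is constant; resource states undefined")
        cuts = np.percentile(col, q)  # linear interpolation between order stats
        # value <= cuts[j-1] -> state j; ties on a cut share the lower state
        states[g] = np.searchsorted(cuts, col, side="left") + 1
        edges[g] = cuts
    state_df = pd.DataFrame(states, index=environment.index)
    return ResourceStates(edges=edges, states=state_df, R=R)


# ---------------------------------------------------------------------------
# utilization profiles
# ---------------------------------------------------------------------------

@dataclass
class UtilizationProfile:
    """Per-species, per-gradient abundance share across resource states.

    ``P`` has shape (n_species, n_gradients, R); rows of species with nonzero
    total abundance sum to 1 along the state axis.  Species with zero total
    abundance are listed in ``excluded`` and carry all-zero profiles.
    """

    species: list[str]
    gradients: list[str]
    P: np.ndarray
    R: int
    excluded: list[str] = field(default_factory=list)

    def frame(self, gradient: str) -> pd.DataFrame:
        """Profile matrix (species x state) for one gradient."""
        gi = self.gradients.index(gradient)
        return pd.DataFrame(
            self.P[:, gi, :], index=self.species,
            columns=[f"state_{j}" for j in range(1, self.R + 1)],
        )

    def active(self) -> "UtilizationProfile":
        """Copy restricted to species with nonzero abundance."""
        keep = [i for i, s in enumerate(self.species) if s not in set(self.excluded)]
        return UtilizationProfile(
            species=[self.species[i] for i in keep],
            gradients=self.gradients,
            P=self.P[keep],
            R=self.R,
            excluded=[],
        )


def utilization_profile(
    community: pd.DataFrame,
    states: ResourceStates,
    taxa: list[str] | None = None,
) -> UtilizationProfile:
    """Build utilization profiles for ``taxa`` (default: every taxon)."""
    validate_community(community)
    check_matched_sites([community, states.states])
    community = community.loc[states.states.index]
    if taxa is None:
        taxa = list(community.columns)
    else:
        missing = set(taxa) - set(community.columns)
        if missing:
            raise KeyError(f"taxa absent from community matrix: {sorted(missing)}")
    abund = community[taxa].to_numpy(dtype=float).T  # species x site
    totals = abund.sum(axis=1)
    gradients = states.gradients
    P = np.zeros((len(taxa), len(gradients), states.R))
    for gi, g in enumerate(gradients):
        site_state = states.states[g].to_numpy()
        for j in range(1, states.R + 1):
            P[:, gi, j - 1] = abund[:, site_state == j].sum(axis=1)
    nonzero = totals > 0
    P[nonzero] /= totals[nonzero, None, None]
    excluded = [t for t, ok in zip(taxa, nonzero) if not ok]
    if excluded:
        logger.warning("excluding %d zero-abundance species from niche statistics", len(excluded))
    return UtilizationProfile(species=list(taxa), gradients=list(gradients),
                              P=P, R=states.R, excluded=excluded)


# ---------------------------------------------------------------------------
# Levins breadth
# ---------------------------------------------------------------------------

def _dense_rank_desc(values: pd.Series) -> pd.Series:
    return values.rank(method="dense", ascending=False).astype(int)


@dataclass
class NicheBreadthTable:
    """Levins breadth per species per gradient with Mean-S/Mean-R summaries."""

    B: pd.DataFrame                # species x gradient, in [1, R]
    mean_s: pd.Series              # per-species mean over gradients
    mean_r: pd.Series              # per-gradient mean over species
    rank_s: pd.Series
    rank_r: pd.Series
    R: int


def levins_breadth(profile: UtilizationProfile) -> NicheBreadthTable:
    """Levins breadth ``B = 1 / sum_j P_j^2`` for every species and gradient."""
    prof = profile.active()
    if not prof.species:
        raise ValueError("no species with nonzero abundance; breadth undefined")
    denom = (prof.P ** 2).sum(axis=2)
    B = pd.DataFrame(1.0 / denom, index=prof.species, columns=prof.gradients)
    B.index.name = "species"
    mean_s = B.mean(axis=1)
    mean_r = B.mean(axis=0)
    return NicheBreadthTable(
        B=B, mean_s=mean_s, mean_r=mean_r,
        rank_s=_dense_rank_desc(mean_s), rank_r=_dense_rank_desc(mean_r),
        R=prof.R,
    )


# ---------------------------------------------------------------------------
# Pianka overlap
# ---------------------------------------------------------------------------

@dataclass
class NicheOverlapResult:
    """Pairwise Pianka overlap per gradient plus per-species totals.

    ``pairwise[g]`` is the symmetric species x species overlap matrix on
    gradient ``g`` (unit diagonal); ``totals`` holds, per species and
    gradient, the sum of overlaps with every *other* species — the
    community-level overlap summary, bounded by ``n_species - 1``.
    """

    pairwise: dict[str, pd.DataFrame]
    totals: pd.DataFrame           # species x gradient
    mean_s: pd.Series
    mean_r: pd.Series
    rank_s: pd.Series
    rank_r: pd.Series


def pianka_overlap(profile: UtilizationProfile) -> NicheOverlapResult:
    """Pairwise Pianka overlap matrices and per-species totals."""
    prof = profile.active()
    if len(prof.species) < 2:
        raise ValueError("niche overlap needs at least two species with nonzero abundance")
    pairwise: dict[str, pd.DataFrame] = {}
    totals = np.zeros((len(prof.species), len(prof.gradients)))
    for gi, g in enumerate(prof.gradients):
        M = prof.P[:, gi, :]                     # species x state
        norms = np.sqrt((M ** 2).sum(axis=1))
        O = (M @ M.T) / np.outer(norms, norms)
        np.fill_diagonal(O, 1.0)
        O = np.clip(O, 0.0, 1.0)
        O = (O + O.T) / 2.0                      # enforce exact symmetry
        pairwise[g] = pd.DataFrame(O, index=prof.species, columns=prof.species)
        totals[:, gi] = O.sum(axis=1) - 1.0
    totals_df = pd.DataFrame(totals, index=prof.species, columns=prof.gradients)
    totals_df.index.name = "species"
    mean_s = totals_df.mean(axis=1)
    mean_r = totals_df.mean(axis=0)
    return NicheOverlapResult(
        pairwise=pairwise, totals=totals_df, mean_s=mean_s, mean_r=mean_r,
        rank_s=_dense_rank_desc(mean_s), rank_r=_dense_rank_desc(mean_r),
    )


# ---------------------------------------------------------------------------
# report aggregation (species x gradient matrices with Mean-S / Mean-R / ranks)
# ---------------------------------------------------------------------------

def _report_frame(matrix: pd.DataFrame, mean_s, mean_r, rank_s, rank_r) -> pd.DataFrame:
    rep = matrix.copy()
    rep["Mean-S"] = mean_s
    rep["Rank"] = rank_s
    bottom = pd.DataFrame(
        [mean_r.reindex(matrix.columns), rank_r.reindex(matrix.columns)],
        index=["MEAN-R", "RANK"],
    )
    rep = pd.concat([rep, bottom])
    return rep


def aggregate_niche(
    breadth: NicheBreadthTable, overlap: NicheOverlapResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Breadth and overlap report tables (Mean-S column, MEAN-R/RANK rows)."""
    if list(breadth.B.index) != list(overlap.totals.index) or list(
        breadth.B.columns
    ) != list(overlap.totals.columns):
        raise ValueError("breadth and overlap tables cover different species/gradients")
    breadth_rep = _report_frame(
        breadth.B, breadth.mean_s, breadth.mean_r, breadth.rank_s, breadth.rank_r
    )
    overlap_rep = _report_frame(
        overlap.totals, overlap.mean_s, overlap.mean_r, overlap.rank_s, overlap.rank_r
    )
    return breadth_rep, overlap_rep


# ---------------------------------------------------------------------------
# breadth-overlap regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def breadth_overlap_regression(
    mean_breadth: pd.Series | np.ndarray, mean_overlap: pd.Series | np.ndarray
) -> RegressionSummary:
    """OLS of per-species mean overlap on mean breadth (slope, R², two-sided p)."""
    x = np.asarray(mean_breadth, dtype=float)
    y = np.asarray(mean_overlap, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("mean_breadth and mean_overlap must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("regression needs at least 3 species")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor: breadth values are all equal")
    if np.ptp(y) == 0:
        # degenerate null fit: a constant response carries no slope signal
        return RegressionSummary(slope=0.0, intercept=float(y[0]), r2=0.0, p=1.0, n=len(x))
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue**2), p=float(fit.pvalue), n=len(x),
    )


# ---------------------------------------------------------------------------
# site-level niche features for the richness-driver model
# ---------------------------------------------------------------------------

def site_niche_features(
    community: pd.DataFrame,
    breadth: NicheBreadthTable,
    overlap: NicheOverlapResult,
) -> pd.DataFrame:
    """Abundance-weighted site means of species niche breadth and overlap.

    For each site, the species covered by the niche tables that are present
    there are weighted by their local abundance; the weighted means of the
    species-level Mean-S breadth and Mean-S total overlap become the site's
    ``niche_breadth`` and ``niche_overlap`` features.  Sites where none of the
    covered species occur get 0 for both.
    """
    validate_community(community)
    species = list(breadth.B.index)
    sub = community[species].to_numpy(dtype=float)
    weights = sub / np.where(sub.sum(axis=1) > 0, sub.sum(axis=1), 1.0)[:, None]
    nb = weights @ breadth.mean_s.to_numpy()
    no = weights @ overlap.mean_s.to_numpy()
    out = pd.DataFrame(
        {"niche_breadth": nb, "niche_overlap": no}, index=community.index
    )
    out.index.name = "site_id"
    return out
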