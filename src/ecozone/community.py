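"""Community-level statistics: dominance-based representative-species
selection and per-site species richness.

The community matrix is a site x taxon table of non-negative abundances
(individual counts or cell densities; the indices are unit-agnostic).

Dominance follows McNaughton: for taxon *i*,

    Y_i = (n_i / N) * f_i

with ``n_i`` the taxon's total abundance over all sites, ``N`` the grand
total, and ``f_i`` the fraction of sites where the taxon occurs (abundance
strictly > 0).  Taxa with ``Y_i`` at or above a threshold (default 0.02) are
flagged as *representative* species and feed the niche-statistics stage.

Richness uses Margalef's sample-size-adjusted index per site,

    D = (S - 1) / ln(N_site)

with ``S`` the number of taxa present and ``N_site`` the site's total
abundance; degenerate sites (``S <= 1`` or ``N_site <= 1``) get ``D = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DOMINANCE_THRESHOLD = 0.02


def validate_community(community: pd.DataFrame) -> None:
    """Check the community-matrix invariants, raising ``ValueError`` on breach."""
    if community.shape[0] < 1 or community.shape[1] < 1:
        raise ValueError("community matrix needs at least one site and one taxon")
    if community.index.duplicated().any():
        raise ValueError("duplicated site identifiers in community matrix")
    if community.columns.duplicated().any():
        raise ValueError("duplicated taxon identifiers in community matrix")
    values = community.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("community matrix contains missing values")
    if (values < 0).any():
        raise ValueError("community matrix contains negative abundances")


def dominance_index(
    community: pd.DataFrame, threshold: float = DOMINANCE_THRESHOLD
) -> pd.DataFrame:
    """Per-taxon dominance table: ``n_i``, ``f_i``, ``Y`` and representativeness.

    Parameters
    ----------
    community
        Site x taxon abundance matrix.
    threshold
        Representativeness cut on Y (fraction scale), ``0 < threshold < 1``.

    Returns
    -------
    DataFrame indexed by taxon with columns ``n_i, f_i, Y, Y_percent,
    representative``, sorted by Y descending with ties broken by taxon label.
    ``Y_percent`` is the same index on the x100 display scale.
    """
    validate_community(community)
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    n_i = community.sum(axis=0)
    total = float(n_i.sum())
    if total == 0:
        raise ValueError("dominance undefined: community matrix is all zeros (N = 0)")
    f_i = (community > 0).mean(axis=0)
    y = (n_i / total) * f_i
    out = pd.DataFrame(
        {
            "n_i": n_i,
            "f_i": f_i,
            "Y": y,
            "Y_percent": 100.0 * y,
            "representative": y >= threshold,
        }
    )
    out.index.name = "taxon"
    # stable sort: Y descending, taxon label ascending on ties
    out = out.sort_index().sort_values("Y", ascending=False, kind="mergesort")
    return out


def representative_taxa(dominance: pd.DataFrame) -> list[str]:
    """Taxon labels flagged representative, in dominance order."""
    return list(dominance.index[dominance["representative"]])


def margalef_richness(community: pd.DataFrame) -> pd.DataFrame:
    """Per-site richness table with ``S``, ``N_site`` and Margalef ``D``."""
    validate_community(community)
    s = (community > 0).sum(axis=1)
    n_site = community.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (s - 1) / np.log(n_site.to_numpy(dtype=float))
    d = pd.Series(d, index=community.index)
    d[(s <= 1) | (n_site <= 1)] = 0.0
    out = pd.DataFrame({"S": s, "N_site": n_site, "D": d})
    out.index.name = "site_id"
    return out
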