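"""Synthetic community + environment generator with known ground truth.

The generator emulates the sampling design of a large-river phytoplankton
survey: 26 sites partitioned into three spatially coherent zones of 5, 6 and
15 sites along an upstream-downstream transect, 11 correlated physicochemical
gradients whose zone means are separated by a configurable multiple of the
within-zone spread (default 3 SD), and 89 taxa whose expected abundances
follow Gaussian niche-response curves over the gradients with Poisson (or
negative-binomial) count noise.  A configurable fraction of taxa (default
0.35, mimicking diatom dominance) receives a larger abundance scale so a
single group dominates total abundance.

Richness is made to covary with a designated driver subset of the gradients
(default WT, TN, TP, pH): most taxa have their niche centers on the driver
gradients drawn near the driver values of a designated species-rich zone, so
sites whose driver values sit near that optimum support more taxa.  Niche
centers on the remaining (decoy) gradients are scattered uniformly with
broad widths, leaving them without a direct effect on richness.

Every quantity a downstream stage estimates — zone labels, niche centers and
widths, the driver set, the expected abundance surface — is returned as
ground truth, and identical seeds reproduce identical datasets byte for
byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .io import GRADIENTS

# per-gradient defaults: realistic large-river values (concentrations mg/L,
# WT degC, pH unitless).  `_ZONE_PATTERN` gives each zone's offset from the
# base mean in units of (zone_sep * zone_sd): monotone warming downstream,
# slight downstream acidification, nutrients high upstream / low midstream.
_BASE_MEAN = {
    "DO": 8.8, "pH": 7.9, "WT": 12.0, "TC": 28.0, "DOC": 2.0, "TN": 1.6,
    "DTN": 1.3, "TP": 0.018, "DTP": 0.009, "TSi": 4.0, "DSi": 3.2,
}
_ZONE_SD = {
    "DO": 0.4, "pH": 0.15, "WT": 1.5, "TC": 2.0, "DOC": 0.25, "TN": 0.12,
    "DTN": 0.10, "TP": 0.003, "DTP": 0.0015, "TSi": 0.35, "DSi": 0.30,
}
_ZONE_PATTERN = {
    "DO": (2, 1, 0), "pH": (2, 1, 0), "WT": (0, 1, 2), "TC": (0, 1, 2),
    "DOC": (0, 1, 2), "TN": (2, 0, 1), "DTN": (2, 0, 1), "TP": (2, 0, 1),
    "DTP": (2, 0, 1), "TSi": (0, 2, 1), "DSi": (0, 2, 1),
}

DEFAULT_DRIVERS = ("WT", "TN", "TP", "pH")


@dataclass
class SyntheticConfig:
    """Parameters of the planted study design.

    Niche geometry is parameterized in units of the inter-zone step
    (``zone_sep * zone_sd`` per gradient): ``niche_width_range`` bounds the
    response widths of taxa focused on the rich zone, ``broad_width_range``
    those of unfocused taxa, and ``niche_center_range`` extends the uniform
    center draw beyond the span of the zone means.
    """

    n_sites: int = 26
    n_taxa: int = 89
    n_zones: int = 3
    zone_sizes: tuple[int, ...] = (5, 6, 15)
    gradient_names: tuple[str, ...] = tuple(GRADIENTS)
    zone_means: np.ndarray | None = None     # (n_zones, n_gradients); default built
    zone_sd: np.ndarray | None = None        # per-gradient within-zone SD
    zone_sep: float = 3.0                    # zone-mean separation in SD units
    env_latent_corr: float = 0.5             # within-site cross-gradient correlation
    driver_set: tuple[str, ...] = DEFAULT_DRIVERS
    # sign of each driver's effect on richness (+1: richer at high values);
    # drivers not listed default to +1
    driver_direction: dict[str, int] = field(
        default_factory=lambda: {"WT": 1, "pH": -1, "TN": -1, "TP": -1}
    )
    focus_fraction: float = 0.8              # taxa with directional driver niches
    niche_center_range: tuple[float, float] = (-1.0, 1.0)
    niche_width_range: tuple[float, float] = (1.0, 3.0)
    broad_width_range: tuple[float, float] = (3.0, 6.0)
    abundance_scale: float = 10_000.0        # expected total individuals per site
    dominant_fraction: float = 0.35          # diatom-dominance mimicry
    dominant_boost: float = 10.0
    noise_model: str = "poisson"             # or "nbinom"
    dispersion: float = 5.0                  # nbinom size parameter
    seed: int = 1

    def validate(self) -> None:
        if self.n_zones < 2:
            raise ValueError(f"need at least 2 zones, got {self.n_zones}")
        if self.n_zones > self.n_sites:
            raise ValueError(
                f"n_zones={self.n_zones} exceeds n_sites={self.n_sites}"
            )
        if len(self.zone_sizes) != self.n_zones:
            raise ValueError("zone_sizes length must equal n_zones")
        if sum(self.zone_sizes) != self.n_sites:
            raise ValueError(
                f"zone_sizes {self.zone_sizes} must sum to n_sites={self.n_sites}"
            )
        if min(self.zone_sizes) < 1:
            raise ValueError("every zone needs at least one site")
        for lo, hi in (self.niche_width_range, self.broad_width_range):
            if not (0 < lo <= hi):
                raise ValueError("niche widths must be positive")
        if self.abundance_scale <= 0:
            raise ValueError("abundance_scale must be positive")
        if self.noise_model not in ("poisson", "nbinom"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        unknown = set(self.driver_set) - set(self.gradient_names)
        if unknown:
            raise ValueError(f"driver_set not among gradients: {sorted(unknown)}")

    def resolved_zone_means(self) -> np.ndarray:
        if self.zone_means is not None:
            zm = np.asarray(self.zone_means, dtype=float)
            if zm.shape != (self.n_zones, len(self.gradient_names)):
                raise ValueError("zone_means must have shape (n_zones, n_gradients)")
            return zm
        sd = self.resolved_zone_sd()
        zm = np.zeros((self.n_zones, len(self.gradient_names)))
        for gi, g in enumerate(self.gradient_names):
            base = _BASE_MEAN.get(g, 1.0)
            pattern = _ZONE_PATTERN.get(g, tuple(range(3)))
            offs = [pattern[z % len(pattern)] + 3 * (z // len(pattern)) for z in range(self.n_zones)]
            zm[:, gi] = base + np.asarray(offs, dtype=float) * self.zone_sep * sd[gi]
        return zm

    def resolved_zone_sd(self) -> np.ndarray:
        if self.zone_sd is not None:
            sd = np.asarray(self.zone_sd, dtype=float)
            if sd.shape == ():
                sd = np.full(len(self.gradient_names), float(sd))
            if sd.shape != (len(self.gradient_names),):
                raise ValueError("zone_sd must be scalar or per-gradient")
            if (sd < 0).any():
                raise ValueError("zone_sd must be non-negative")
            return sd
        return np.array([_ZONE_SD.get(g, 0.1) for g in self.gradient_names])


@dataclass
class SyntheticDataset:
    """A generated survey with its complete ground truth."""

    community: pd.DataFrame            # site x taxon counts
    environment: pd.DataFrame          # site x gradient measurements
    sites: pd.DataFrame                # lon, lat, channel
    zone_truth: pd.Series              # site -> planted zone (1-based)
    niche_truth: dict[str, pd.DataFrame]   # "center" and "width", taxa x gradients
    driver_truth: list[str]
    expected_abundance: pd.DataFrame = None   # site x taxon Poisson means
    expected_richness: pd.Series = None       # E[#taxa observed] per site
    config: SyntheticConfig = None

    def validate(self) -> None:
        _io.check_matched_sites(
            [self.community, self.environment, self.sites, self.zone_truth]
        )
        if (self.community.to_numpy() < 0).any():
            raise ValueError("negative abundances in synthetic community")


def _draw_widths(rng: np.random.Generator, bounds: tuple[float, float], size) -> np.ndarray:
    lo, hi = bounds
    if np.isinf(lo):  # flat-response limit: every taxon indifferent to the gradient
        return np.full(size, np.inf)
    return rng.uniform(lo, hi, size=size)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw one survey from the planted design; identical seed, identical data."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = len(config.gradient_names)
    n = config.n_sites

    site_ids = [f"S{i + 1:02d}" for i in range(n)]
    zone_of_site = np.repeat(np.arange(config.n_zones), config.zone_sizes)

    # --- environment: per-zone means + correlated within-zone noise -------
    zone_means = config.resolved_zone_means()
    sd = config.resolved_zone_sd()
    rho = config.env_latent_corr
    # zone-level latent factor shared by every gradient of a zone's sites:
    # gradients co-vary geographically without elongating within-zone scatter
    latent = rng.standard_normal(config.n_zones)
    eps = rng.standard_normal((n, G))
    noise = np.sqrt(rho) * latent[zone_of_site, None] + np.sqrt(1 - rho) * eps
    env_values = zone_means[zone_of_site] + sd[None, :] * noise
    environment = pd.DataFrame(
        env_values, index=site_ids, columns=list(config.gradient_names)
    )
    environment.index.name = "site_id"

    # --- niche parameters --------------------------------------------------
    # per-gradient length scale: the inter-zone step (falls back to 1 when
    # zone_sd is degenerate zero)
    step = np.where(sd > 0, config.zone_sep * sd, 1.0)
    span_lo = zone_means.min(axis=0)
    span_hi = zone_means.max(axis=0)
    is_driver = np.array([g in config.driver_set for g in config.gradient_names])
    focused = rng.random(config.n_taxa) < config.focus_fraction

    centers = np.empty((config.n_taxa, G))
    widths = np.empty((config.n_taxa, G))
    lo_c, hi_c = config.niche_center_range
    uniform_centers = rng.uniform(
        span_lo[None, :] + lo_c * step[None, :],
        span_hi[None, :] + hi_c * step[None, :],
        size=(config.n_taxa, G),
    )
    # focused taxa get driver optima just beyond the rich end of the observed
    # range, so expected richness is monotone in every driver's site value
    direction = np.array(
        [config.driver_direction.get(g, 1) if g in config.driver_set else 1
         for g in config.gradient_names],
        dtype=float,
    )
    rich_edge = np.where(direction > 0, span_hi, span_lo)
    offset = rng.uniform(0.5, 1.5, size=(config.n_taxa, G))
    directional_centers = rich_edge[None, :] + direction[None, :] * offset * step[None, :]
    narrow = _draw_widths(rng, config.niche_width_range, (config.n_taxa, G))
    broad = _draw_widths(rng, config.broad_width_range, (config.n_taxa, G))

    # drivers of focused taxa: directional optima with narrow widths;
    # everything else: scattered centers, broad (weak) responses
    target = focused[:, None] & is_driver[None, :]
    centers[:] = np.where(target, directional_centers, uniform_centers)
    widths[:] = np.where(target, narrow, broad) * step[None, :]

    # --- expected abundances and counts ------------------------------------
    taxon_ids = [f"T{i + 1:03d}" for i in range(config.n_taxa)]
    log_resp = -(((env_values[None, :, :] - centers[:, None, :]) ** 2)
                 / (2.0 * widths[:, None, :] ** 2)).sum(axis=2)   # taxa x sites
    resp = np.exp(log_resp)
    mass = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_taxa)
    n_dom = int(round(config.dominant_fraction * config.n_taxa))
    dominant = rng.choice(config.n_taxa, size=n_dom, replace=False)
    mass[dominant] *= config.dominant_boost
    weighted = mass[:, None] * resp
    denom = weighted.sum(axis=0).mean()
    lam = config.abundance_scale * weighted / denom               # taxa x sites

    if config.noise_model == "poisson":
        counts = rng.poisson(lam)
    else:
        k = config.dispersion
        counts = rng.negative_binomial(k, k / (k + lam))

    community = pd.DataFrame(counts.T, index=site_ids, columns=taxon_ids)
    community.index.name = "site_id"

    # --- site metadata: a jittered upstream-downstream transect -------------
    t = np.linspace(0.0, 1.0, n)
    sites = pd.DataFrame(
        {
            "lon": np.round(97.5 + 8.5 * t + rng.normal(0, 0.15, n), 5),
            "lat": np.round(32.5 - 3.5 * t + rng.normal(0, 0.15, n), 5),
            "channel": np.where(rng.random(n) < 0.6, "mainstream", "tributary"),
        },
        index=site_ids,
    )
    sites.index.name = "site_id"

    zone_truth = pd.Series(zone_of_site + 1, index=site_ids, name="zone")
    zone_truth.index.name = "site_id"
    niche_truth = {
        "center": pd.DataFrame(centers, index=taxon_ids, columns=list(config.gradient_names)),
        "width": pd.DataFrame(widths, index=taxon_ids, columns=list(config.gradient_names)),
    }
    expected_abundance = pd.DataFrame(lam.T, index=site_ids, columns=taxon_ids)
    expected_richness = pd.Series(
        (1.0 - np.exp(-lam)).sum(axis=0), index=site_ids, name="expected_richness"
    )
    dataset = SyntheticDataset(
        community=community, environment=environment, sites=sites,
        zone_truth=zone_truth, niche_truth=niche_truth,
        driver_truth=[g for g in config.gradient_names if g in config.driver_set],
        expected_abundance=expected_abundance,
        expected_richness=expected_richness,
        config=config,
    )
    dataset.validate()
    return dataset


def write_fixture(dataset: SyntheticDataset, directory: str | os.PathLike) -> list[Path]:
    """Emit community/environment/sites/truth CSVs; lossless io round trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("community.csv", dataset.community),
        ("environment.csv", dataset.environment),
        ("sites.csv", dataset.sites),
        ("truth.csv", dataset.zone_truth.to_frame()),
    ):
        path = directory / name
        try:
            _io.write_table(frame, path)
        except OSError as exc:
            raise OSError(f"failed writing fixture file {path}: {exc}") from exc
        written.append(path)
    return written


def read_fixture(directory: str | os.PathLike) -> SyntheticDataset:
    """Re-read a written fixture (ground-truth niche surfaces are not stored)."""
    directory = Path(directory)
    return SyntheticDataset(
        community=_io.read_community(directory / "community.csv"),
        environment=_io.read_environment(directory / "environment.csv"),
        sites=_io.read_sites(directory / "sites.csv"),
        zone_truth=_io.read_truth(directory / "truth.csv"),
        niche_truth={},
        driver_truth=[],
    )
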