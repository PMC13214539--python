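"""One-command orchestration of the zoning framework.

Stages run in the order the method is defined: community metrics (dominance,
richness) -> niche statistics on percentile resource states -> random-forest
richness-driver attribution and key-factor selection -> hierarchical zoning
with silhouette-selected k, Kruskal-Wallis validation and N:P stoichiometry.
Every stage writes its CSV artifacts into the output directory and the run
ends with a machine-readable manifest (input checksums, config echo, library
versions, per-output checksums).  A fixed seed makes the whole run, manifest
included, byte-identical across repeats; one seed governs every stochastic
stage through derived substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, community, importance, io, niche, synthetic, zoning

logger = logging.getLogger(__name__)

STAGES = ("simulate", "metrics", "niche", "importance", "zone")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; file-based inputs or the synthetic study design."""

    community_path: str | None = None
    environment_path: str | None = None
    sites_path: str | None = None
    synthetic: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "ecozone_out"
    seed: int = 1
    n_states: int = 5
    dominance_threshold: float = 0.02
    include_all_taxa: bool = False
    n_tree: int = importance.DEFAULT_N_TREE
    n_rep: int = importance.DEFAULT_N_REP
    n_perm: int = 99
    top_k: int = 7
    k_min: int = 2
    k_max: int | None = None
    linkage: str = "ward"
    molar_np: bool = False
    impute: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        file_mode = self.community_path is not None
        if file_mode:
            for label, p in (
                ("community", self.community_path),
                ("environment", self.environment_path),
            ):
                if p is None:
                    raise ValueError(f"file-based run needs a {label} path")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label} file not found: {p}")
            if self.sites_path is not None and not Path(self.sites_path).exists():
                raise FileNotFoundError(f"sites file not found: {self.sites_path}")


# ---------------------------------------------------------------------------
# input validation report
# ---------------------------------------------------------------------------

def validate_inputs(
    community_path: str | Path,
    environment_path: str | Path,
    sites_path: str | Path | None = None,
) -> list[dict[str, Any]]:
    """Schema / range checks on input files; violations reported, not raised."""
    violations: list[dict[str, Any]] = []

    def report(file: str, where: str, message: str) -> None:
        violations.append({"file": file, "where": where, "message": message})

    comm = pd.read_csv(community_path)
    env = pd.read_csv(environment_path)
    for name, df in (("community", comm), ("environment", env)):
        if df.columns.empty or df.columns[0] != "site_id":
            report(name, "header", "first column must be 'site_id'")
            return violations
    comm = comm.set_index("site_id")
    env = env.set_index("site_id")

    for name, df in (("community", comm), ("environment", env)):
        dupes = df.index[df.index.duplicated()].unique()
        for d in dupes:
            report(name, f"site_id={d}", "duplicated site identifier")
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            for sid in df.index[vals.isna() & df[col].notna()]:
                report(name, f"site_id={sid}, column={col}", "non-numeric value")

    comm_num = comm.apply(pd.to_numeric, errors="coerce")
    for col in comm_num.columns:
        for sid in comm_num.index[comm_num[col] < 0]:
            report("community", f"site_id={sid}, column={col}", "negative abundance")

    env_num = env.apply(pd.to_numeric, errors="coerce")
    if "pH" in env_num.columns:
        bad = env_num.index[(env_num["pH"] < 0) | (env_num["pH"] > 14)]
        for sid in bad:
            report("environment", f"site_id={sid}, column=pH", "pH outside [0, 14]")
    for col in env_num.columns:
        if col == "pH":
            continue
        for sid in env_num.index[env_num[col] < 0]:
            report("environment", f"site_id={sid}, column={col}", "negative concentration")

    diff = set(comm.index.astype(str)).symmetric_difference(env.index.astype(str))
    if diff:
        report(
            "community/environment", "site sets",
            f"site-set mismatch; symmetric difference: {sorted(diff)}",
        )
    if sites_path is not None:
        sites = pd.read_csv(sites_path)
        if sites.columns.empty or sites.columns[0] != "site_id":
            report("sites", "header", "first column must be 'site_id'")
        elif "channel" in sites.columns:
            bad = ~sites["channel"].isin(["mainstream", "tributary"])
            for sid in sites.loc[bad, "site_id"]:
                report("sites", f"site_id={sid}, column=channel",
                       "channel must be 'mainstream' or 'tributary'")
    return violations


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, outputs: list[Path], index_label="site_id") -> None:
    io.write_table(df, path, index_label=index_label)
    outputs.append(path)


def run_pipeline(config: PipelineConfig, upto: str = "zone") -> Path:
    """Execute the framework end to end, returning the artifact directory.

    ``upto`` truncates the run after a named stage (``metrics``, ``niche``,
    ``importance`` or ``zone``); the manifest is written either way.
    """
    config.validate()
    if upto not in STAGES[1:]:
        raise ValueError(f"upto must be one of {STAGES[1:]}, got {upto!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict[str, Any] = {
        "package": "ecozone",
        "version": __version__,
        "seed": config.seed,
        # out_dir is a placement detail, not part of the run's identity; leaving
        # it out keeps manifests byte-identical across reruns in new locations
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "out_dir"
        },
        "versions": _library_versions(),
        "stages": [],
    }
    stage_order = STAGES[1 : STAGES[1:].index(upto) + 2]

    try:
        state = _load_or_simulate(config, out, outputs, manifest)
        for stage in stage_order:
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](state, config, out, outputs)
            elapsed = time.perf_counter() - t0
            logger.info("stage %-10s done in %.2fs", stage, elapsed)
            manifest["stages"].append(stage)
    except PipelineError:
        (out / "PARTIAL.txt").write_text("run aborted; outputs are partial\n")
        raise
    except Exception as exc:  # pragma: no cover - defensive
        (out / "PARTIAL.txt").write_text("run aborted; outputs are partial\n")
        raise PipelineError("unknown", str(exc)) from exc

    manifest["results"] = state.get("summary", {})
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outputs)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _load_or_simulate(
    config: PipelineConfig, out: Path, outputs: list[Path], manifest: dict
) -> dict[str, Any]:
    state: dict[str, Any] = {"summary": {}}
    try:
        if config.community_path is not None:
            state["community"] = io.read_community(config.community_path)
            state["environment"] = io.read_environment(config.environment_path)
            state["sites"] = (
                io.read_sites(config.sites_path) if config.sites_path else None
            )
            manifest["inputs"] = {
                Path(p).name: _sha256(Path(p))
                for p in (config.community_path, config.environment_path, config.sites_path)
                if p
            }
            io.check_matched_sites(
                [f for f in (state["community"], state["environment"], state["sites"])
                 if f is not None]
            )
        else:
            syn_kwargs = dict(config.synthetic)
            syn_kwargs.setdefault("seed", config.seed)
            dataset = synthetic.generate_dataset(synthetic.SyntheticConfig(**syn_kwargs))
            fixture_dir = out / "fixture"
            written = synthetic.write_fixture(dataset, fixture_dir)
            outputs.extend(written)
            state.update(
                community=dataset.community,
                environment=dataset.environment,
                sites=dataset.sites,
                dataset=dataset,
            )
            manifest["inputs"] = {p.name: _sha256(p) for p in written}
        env = state["environment"]
        if env.isna().any().any():
            if not config.impute:
                bad = list(env.columns[env.isna().any()])
                raise ValueError(
                    f"missing environment values in {bad}; enable impute to fill medians"
                )
            logger.warning("imputing missing environment values with per-gradient medians")
            state["environment"] = env.fillna(env.median())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    return state


def _stage_metrics(state, config, out: Path, outputs) -> None:
    try:
        dom = community.dominance_index(state["community"], config.dominance_threshold)
        rich = community.margalef_richness(state["community"])
        _write(dom, out / "dominance.csv", outputs, index_label="taxon")
        _write(rich, out / "richness.csv", outputs)
        state["dominance"] = dom
        state["richness"] = rich
        state["summary"]["n_representative"] = int(dom["representative"].sum())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("metrics", str(exc)) from exc


def _stage_niche(state, config, out: Path, outputs) -> None:
    try:
        taxa = (
            None
            if config.include_all_taxa
            else community.representative_taxa(state["dominance"])
        )
        states = niche.bin_resource_states(state["environment"], R=config.n_states)
        profile = niche.utilization_profile(state["community"], states, taxa=taxa)
        breadth = niche.levins_breadth(profile)
        overlap = niche.pianka_overlap(profile)
        breadth_rep, overlap_rep = niche.aggregate_niche(breadth, overlap)
        _write(breadth_rep, out / "breadth.csv", outputs, index_label="species")
        _write(overlap_rep, out / "overlap.csv", outputs, index_label="species")
        for g, mat in overlap.pairwise.items():
            _write(mat, out / f"pairwise_overlap_{g}.csv", outputs, index_label="species")
        reg = niche.breadth_overlap_regression(breadth.mean_s, overlap.mean_s)
        (out / "breadth_overlap_regression.json").write_text(
            json.dumps(dataclasses.asdict(reg), indent=2, sort_keys=True) + "\n"
        )
        outputs.append(out / "breadth_overlap_regression.json")
        # site-level niche features for the richness-driver model: computed
        # over ALL taxa so every site is covered even if no representative
        # species occurs there
        all_profile = niche.utilization_profile(state["community"], states, taxa=None)
        all_breadth = niche.levins_breadth(all_profile)
        all_overlap = niche.pianka_overlap(all_profile)
        site_feats = niche.site_niche_features(
            state["community"], all_breadth, all_overlap
        )
        _write(site_feats, out / "site_niche.csv", outputs)
        state.update(
            resource_states=states, profile=profile, breadth=breadth,
            overlap=overlap, regression=reg, site_niche=site_feats,
        )
        state["summary"]["breadth_overlap_r2"] = reg.r2
        state["summary"]["breadth_overlap_p"] = reg.p
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("niche", str(exc)) from exc


def _stage_importance(state, config, out: Path, outputs) -> None:
    try:
        features = pd.concat([state["environment"], state["site_niche"]], axis=1)
        target = state["richness"]["D"]
        rf_seed = int(np.random.default_rng([config.seed, 101]).integers(2**31))
        result = importance.rf_importance(
            features, target, n_tree=config.n_tree, n_rep=config.n_rep, seed=rf_seed
        )
        perm_seed = int(np.random.default_rng([config.seed, 102]).integers(2**31))
        importance.permutation_significance(
            features, result, n_perm=config.n_perm, seed=perm_seed
        )
        selected = importance.select_features(result, top_k=config.top_k)
        _write(result.table, out / "importance.csv", outputs, index_label="feature")
        meta = {
            "seed": config.seed, "n_tree": config.n_tree, "n_rep": config.n_rep,
            "n_perm": config.n_perm, "oob_r2": result.model_r2,
            "selected": selected,
        }
        (out / "importance_meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        outputs.append(out / "importance_meta.json")
        state["importance"] = result
        state["selected"] = selected
        state["features"] = features
        state["summary"]["oob_r2"] = result.model_r2
        state["summary"]["selected_features"] = selected
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("importance", str(exc)) from exc


def _stage_zone(state, config, out: Path, outputs) -> None:
    try:
        matrix = state["features"][state["selected"]].copy()
        matrix["D"] = state["richness"]["D"]
        z = zoning.standardize_features(matrix)
        result = zoning.hierarchical_zoning(
            z, k_min=config.k_min, k_max=config.k_max, linkage=config.linkage
        )
        kw_table, overall = zoning.kruskal_wallis_validation(matrix, result.labels)
        result.kw = kw_table
        result.overall_valid = overall
        _write(result.labels.to_frame(), out / "zones.csv", outputs)
        sil = pd.DataFrame(
            {"mean_silhouette": pd.Series(result.silhouette_by_k)}
        ).rename_axis("k")
        _write(sil, out / "silhouette.csv", outputs, index_label="k")
        _write(result.linkage_table(), out / "linkage.csv", outputs, index_label="step")
        (out / "dendrogram.nwk").write_text(result.to_newick() + "\n")
        outputs.append(out / "dendrogram.nwk")
        _write(kw_table, out / "kw_report.csv", outputs, index_label="feature")
        channel = (
            state["sites"]["channel"]
            if state.get("sites") is not None and "channel" in state["sites"]
            else None
        )
        np_rep = zoning.np_ratio(
            state["environment"], result.labels, channel=channel, molar=config.molar_np
        )
        _write(np_rep.per_site, out / "np_ratio.csv", outputs)
        _write(np_rep.by_zone, out / "np_by_zone.csv", outputs, index_label="zone")
        if np_rep.by_channel is not None:
            _write(np_rep.by_channel, out / "np_by_channel.csv", outputs,
                   index_label="channel")
        summary = zoning.zone_summary(matrix, result.labels)
        _write(summary, out / "zone_summary.csv", outputs, index_label=["zone", "feature"])
        state["zoning"] = result
        state["np_report"] = np_rep
        counts = result.labels.value_counts().sort_index()
        state["summary"].update(
            k_star=result.k_star,
            zone_sizes=[int(c) for c in counts],
            silhouette_at_k_star=result.silhouette_by_k[result.k_star],
            kw_overall_valid=bool(overall),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("zone", str(exc)) from exc


_STAGE_FUNCS = {
    "metrics": _stage_metrics,
    "niche": _stage_niche,
    "importance": _stage_importance,
    "zone": _stage_zone,
}
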