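"""End-to-end orchestration: ingest/simulate -> vulnerability -> trade-off ->
feasibility -> consistency -> regression.

Each stage is a pure function from files already in the run directory (plus
the run configuration) to new files, so any stage can be re-run from cached
upstream artifacts and reproduce its outputs byte-identically given the
same seeds.  Per-unit random seeds are derived from the master seed by
hashing stage and network labels, and are all recorded in the run summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consistency import consistency_summary, run_consistency
from .glv import add_degree_columns, estimate_delta, network_feasibility_run
from .network_io import (
    WeightedBipartiteNetwork,
    assemble_link_table,
    read_incidence_matrix,
    read_link_table,
    read_taxonomy,
    write_incidence_matrix,
    write_link_table,
    write_taxonomy,
)
from .regression import diagnostic_regressions, fit_vulnerability_model
from .synthetic import MetawebConfig, generate_metaweb
from .vulnerability import annotate_link_table

logger = logging.getLogger(__name__)


def seed_for(master_seed: int, *labels: str) -> int:
    """Deterministic per-unit seed below 2**31, derived from stage labels."""
    h = zlib.crc32("/".join(labels).encode())
    return int((master_seed * 2_654_435_761 + h) % (2**31))


@dataclass
class RunConfig:
    """Full-pipeline configuration.

    Either ``synthetic`` holds a :class:`MetawebConfig`, or ``network_files``
    lists ``{path, network_id, network_type}`` records and ``taxonomy_path``
    points at a species/guild/genus/family/order CSV.
    """

    output_dir: str = "results/run"
    seed: int = 0
    synthetic: MetawebConfig | None = None
    network_files: list[dict] = field(default_factory=list)
    taxonomy_path: str | None = None
    rho: float = 0.0
    delta_mode: str = "estimate"  # or "fixed"
    delta_values: list[float] = field(default_factory=list)
    estimator: str = "center_deviation"
    n_directions: int = 2000
    n_null: int = 200
    levels: list[str] = field(default_factory=lambda: ["genus", "family", "order"])
    properties: list[str] = field(
        default_factory=lambda: ["vulnerability", "feasibility_contribution"]
    )

    def __post_init__(self) -> None:
        if self.delta_mode not in ("estimate", "fixed"):
            raise ValueError("delta_mode must be 'estimate' or 'fixed'")
        if self.delta_mode == "fixed" and not self.delta_values:
            raise ValueError("delta_mode='fixed' requires delta_values")
        if self.synthetic is None and not self.network_files:
            raise ValueError("provide either a synthetic config or network_files")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("synthetic") is not None:
            raw["synthetic"] = MetawebConfig(**raw["synthetic"])
        return cls(**raw)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_networks(outdir: Path) -> list[WeightedBipartiteNetwork]:
    index = pd.read_csv(outdir / "networks_index.csv")
    return [
        read_incidence_matrix(outdir / row.path, row.network_id, row.network_type)
        for row in index.itertuples()
    ]


# ---------------------------------------------------------------------------
# stages


def stage_ingest(config: RunConfig, outdir: Path) -> list[WeightedBipartiteNetwork]:
    """Simulate or read the networks and taxonomy; write canonical copies."""
    (outdir / "networks").mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        nets, taxonomy, truth = generate_metaweb(config.synthetic)
        truth.link_truths.to_csv(outdir / "link_truths.csv", index=False)
        truth.interaction_latents.to_csv(outdir / "interaction_latents.csv", index=False)
    else:
        nets = [
            read_incidence_matrix(rec["path"], rec["network_id"], rec["network_type"])
            for rec in config.network_files
        ]
        taxonomy = read_taxonomy(config.taxonomy_path)
    index_rows = []
    for net in nets:
        rel = f"networks/{net.network_id}.csv"
        write_incidence_matrix(net, outdir / rel)
        index_rows.append(
            {"network_id": net.network_id, "network_type": net.network_type, "path": rel}
        )
    pd.DataFrame(index_rows).to_csv(outdir / "networks_index.csv", index=False)
    write_taxonomy(taxonomy, outdir / "taxonomy.csv")
    table = assemble_link_table(nets)
    write_link_table(table, outdir / "link_table.csv")
    return nets


def stage_vulnerability(outdir: Path) -> pd.DataFrame:
    nets = _load_networks(outdir)
    table = read_link_table(outdir / "link_table.csv")
    table = annotate_link_table(table, nets)
    table = add_degree_columns(table, nets)
    write_link_table(table, outdir / "link_table.csv")
    return table


def stage_delta(config: RunConfig, outdir: Path) -> float:
    table = read_link_table(outdir / "link_table.csv")
    if config.delta_mode == "fixed":
        delta = float(config.delta_values[0])
        report = {"mode": "fixed", "delta": delta}
    else:
        res = estimate_delta(table)
        delta = res.delta
        report = {
            "mode": "estimate",
            "delta": delta,
            "intercept_plants": res.intercept_plants,
            "intercept_animals": res.intercept_animals,
            "n_obs": res.n_obs,
        }
    _json_dump(report, outdir / "delta.json")
    return delta


def stage_feasibility(config: RunConfig, outdir: Path) -> pd.DataFrame:
    delta = json.loads((outdir / "delta.json").read_text())["delta"]
    nets = _load_networks(outdir)
    table = read_link_table(outdir / "link_table.csv")
    diagnostics = []
    for net in nets:
        net_seed = seed_for(config.seed, "feasibility", net.network_id)
        result, diag = network_feasibility_run(
            net,
            rho=config.rho,
            delta=delta,
            estimator=config.estimator,
            n_directions=config.n_directions,
            seed=net_seed,
        )
        mask = table["network_id"] == net.network_id
        table.loc[mask, "I_percent"] = result["I_percent"].to_numpy()
        table.loc[mask, "excluded"] = result["excluded"].to_numpy()
        diagnostics.append(diag)
    write_link_table(table, outdir / "link_table.csv")
    _json_dump({"rho": config.rho, "delta": delta, "networks": diagnostics},
               outdir / "feasibility_summary.json")
    return table


def stage_consistency(config: RunConfig, outdir: Path) -> pd.DataFrame:
    table = read_link_table(outdir / "link_table.csv")
    taxonomy = read_taxonomy(outdir / "taxonomy.csv")
    frames = []
    for prop in config.properties:
        for level in config.levels:
            res = run_consistency(
                table,
                taxonomy,
                property_name=prop,
                level=level,
                n_null=config.n_null,
                seed=seed_for(config.seed, "consistency", prop, level),
            )
            if not res.empty:
                res.to_csv(outdir / f"consistency_{prop}_{level}.csv", index=False)
                frames.append(res)
    if not frames:
        pd.DataFrame().to_csv(outdir / "consistency_summary.csv", index=False)
        return pd.DataFrame()
    all_res = pd.concat(frames, ignore_index=True)
    consistency_summary(all_res).to_csv(outdir / "consistency_summary.csv", index=False)
    return all_res


def stage_regress(config: RunConfig, outdir: Path) -> dict:
    table = read_link_table(outdir / "link_table.csv")
    report: dict = {}
    try:
        main = fit_vulnerability_model(table)
        report["vulnerability_model"] = main.to_dict()
        report["diagnostics"] = {k: v.to_dict() for k, v in diagnostic_regressions(table).items()}
        report["empty_input"] = False
    except ValueError as err:
        report["empty_input"] = True
        report["reason"] = str(err)
    _json_dump(report, outdir / "model_report.json")
    return report


# ---------------------------------------------------------------------------
# full run


@dataclass
class ArtifactBundle:
    """In-memory handles to the artifacts a full run produced."""

    outdir: Path
    link_table: pd.DataFrame
    delta: float
    consistency: pd.DataFrame
    model_report: dict
    run_summary: dict


def run_full(config: RunConfig) -> ArtifactBundle:
    """Execute all stages in order and write a run summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_names = []

    def run_stage(name, fn, *args):
        stage_names.append(name)
        try:
            return fn(*args)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    nets = run_stage("ingest", stage_ingest, config, outdir)
    run_stage("vulnerability", stage_vulnerability, outdir)
    delta = run_stage("delta", stage_delta, config, outdir)
    table = run_stage("feasibility", stage_feasibility, config, outdir)
    consistency = run_stage("consistency", stage_consistency, config, outdir)
    report = run_stage("regress", stage_regress, config, outdir)

    feas = json.loads((outdir / "feasibility_summary.json").read_text())
    summary = {
        "linkrisk_version": __version__,
        "stages": stage_names,
        "seed": config.seed,
        "rho": config.rho,
        "delta": delta,
        "delta_mode": config.delta_mode,
        "estimator": config.estimator,
        "n_directions": config.n_directions,
        "n_null": config.n_null,
        "n_networks": len(nets),
        "n_links": int(len(table)),
        "n_excluded_links": int(table["excluded"].sum()),
        "n_included_links": int((~table["excluded"]).sum()),
        "gamma0_per_network": {d["network_id"]: d["gamma0"] for d in feas["networks"]},
        "stage_seeds": {
            "feasibility": {
                n.network_id: seed_for(config.seed, "feasibility", n.network_id) for n in nets
            },
            "consistency": {
                f"{p}/{l}": seed_for(config.seed, "consistency", p, l)
                for p in config.properties
                for l in config.levels
            },
        },
    }
    _json_dump(summary, outdir / "run_summary.json")
    return ArtifactBundle(
        outdir=outdir,
        link_table=table,
        delta=delta,
        consistency=consistency,
        model_report=report,
        run_summary=summary,
    )


def run_delta_sweep(config: RunConfig, delta_values: list[float]) -> pd.DataFrame:
    """Refit feasibility + the mixed model across a grid of trade-off values.

    Reuses the ingest/vulnerability stages once and reports, per delta, the
    vulnerability-contribution slope and variance explained — the mechanism
    for asking over which trade-off regime vulnerable links contribute most.
    """
    base = dataclasses.replace(config, delta_mode="fixed", delta_values=[delta_values[0]])
    outdir = Path(base.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_ingest(base, outdir)
    stage_vulnerability(outdir)
    rows = []
    for dv in delta_values:
        cfg = dataclasses.replace(config, delta_mode="fixed", delta_values=[float(dv)])
        stage_delta(cfg, outdir)
        stage_feasibility(cfg, outdir)
        report = stage_regress(cfg, outdir)
        model = report.get("vulnerability_model", {})
        rows.append(
            {
                "delta": float(dv),
                "slope": model.get("slope", np.nan),
                "slope_se": model.get("slope_se", np.nan),
                "r2_marginal": model.get("r2_marginal", np.nan),
                "n_included": model.get("n_obs", 0),
            }
        )
    sweep = pd.DataFrame(rows)
    sweep.to_csv(outdir / "delta_sweep.csv", index=False)
    return sweep


def run_empirical(
    networks_dir: str | Path,
    taxonomy_path: str | Path | None = None,
    **config_kwargs,
) -> ArtifactBundle:
    """Run the full pipeline on a directory of incidence-matrix CSVs.

    Network type is taken from a ``manifest.csv`` (columns: file,
    network_id, network_type) if present, else inferred as pollination.
    Intended for web-of-life style downloads.
    """
    networks_dir = Path(networks_dir)
    manifest = networks_dir / "manifest.csv"
    if manifest.exists():
        man = pd.read_csv(manifest)
        files = [
            {
                "path": str(networks_dir / r.file),
                "network_id": str(r.network_id),
                "network_type": str(r.network_type),
            }
            for r in man.itertuples()
        ]
    else:
        files = [
            {"path": str(p), "network_id": p.stem, "network_type": "pollination"}
            for p in sorted(networks_dir.glob("*.csv"))
        ]
    if taxonomy_path is None:
        taxonomy_path = networks_dir / "taxonomy.csv"
    config = RunConfig(
        network_files=files, taxonomy_path=str(taxonomy_path), **config_kwargs
    )
    return run_full(config)
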