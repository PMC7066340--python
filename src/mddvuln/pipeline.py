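"""Command-line pipeline tying the stages into one reproducible workflow.

Subcommands
-----------
synth        generate a cohort CSV (seeded, or the deterministic reference)
score        stratify a cohort CSV into bands; write classification + summary
estimate     turn a cohort summary into model parameters
simulate     integrate the compartmental model and write a trajectory CSV
equilibrium  cubic/Vieta/Jacobian stability report for a parameter set
sweep        terminal fractions along a grid of one parameter
run          full pipeline driven by a YAML/JSON config, with a manifest

Every ``run`` output is listed in a manifest JSON with its SHA-256 digest,
so reruns under the same config and seed can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from .dynamics import integrate, sweep as run_sweep
from .equilibrium import stability_analysis
from .estimation import (
    EstimationConfig,
    ModelParameters,
    StateFractions,
    estimate_all,
)
from .stratification import (
    CohortSummary,
    ScoringScheme,
    classify_participant,
    default_scheme,
    summarize_cohort,
)
from .synth import SynthConfig, cohort_from_csv, cohort_to_csv, generate_cohort, reference_cohort

log = logging.getLogger("mddvuln")


def _setup_logging(verbose: int) -> None:
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(
        stream=sys.stderr, level=level,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _load_scheme(path: Path | None) -> ScoringScheme:
    if path is None:
        return default_scheme()
    return ScoringScheme.from_dict(_load_config(path))


def _display(value: float) -> float:
    return round(value, 4)


# ---------------------------------------------------------------------------
# Stage functions (importable without click)
# ---------------------------------------------------------------------------


def score_cohort(records, scheme, class_csv: Path, summary_json: Path) -> CohortSummary:
    """Classify every record, write the per-participant CSV and summary JSON."""
    import pandas as pd

    rows = []
    for rec in records:
        state, band = classify_participant(rec, scheme)
        rows.append(
            {"id": rec.id, "band": band, "total": state.total,
             "state": "-".join(state.levels)}
        )
    pd.DataFrame(rows).to_csv(class_csv, index=False)
    summary = summarize_cohort(records, scheme)
    summary.to_json(summary_json)
    return summary


def run_pipeline(config_path: Path) -> dict:
    """Execute synth/ingest -> stratify -> estimate -> simulate -> equilibrium.

    Returns the run manifest (also written next to the outputs).  The
    pipeline is idempotent: identical config and seed give byte-identical
    outputs apart from the manifest timestamp.
    """
    config_path = Path(config_path)
    cfg = _load_config(config_path)
    if not isinstance(cfg, dict):
        raise click.ClickException("config must be a mapping")
    if "cohort_csv" not in cfg and "synth" not in cfg:
        raise click.ClickException(
            "config must provide either a 'cohort_csv' input or a 'synth' section"
        )
    outdir = Path(cfg.get("outdir", "mddvuln_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = _load_scheme(Path(cfg["scheme"]) if "scheme" in cfg else None)
    seed = int(cfg.get("seed", 0))

    manifest: dict = {
        "package_version": __version__,
        "config_path": str(config_path),
        "config": cfg,
        "seed": seed,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "outputs": {},
    }

    def record_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    # -- stage 1: cohort ----------------------------------------------------
    if "cohort_csv" in cfg:
        records = cohort_from_csv(cfg["cohort_csv"])
        manifest["stages"]["cohort"] = {"source": cfg["cohort_csv"], "n": len(records)}
        manifest["outputs"]["cohort_input"] = {
            "path": str(cfg["cohort_csv"]), "sha256": _sha256(Path(cfg["cohort_csv"]))
        }
    else:
        synth_cfg = cfg.get("synth", {})
        if synth_cfg.get("reference", False):
            records = reference_cohort()
        else:
            sc = SynthConfig(**{**synth_cfg, "seed": seed})
            records = generate_cohort(sc, scheme)
        cohort_csv = outdir / "cohort.csv"
        cohort_to_csv(records, cohort_csv)
        record_output("cohort_csv", cohort_csv)
        manifest["stages"]["cohort"] = {"source": "synth", "n": len(records)}

    # -- stage 2: stratify --------------------------------------------------
    class_csv = outdir / "classification.csv"
    summary_json = outdir / "summary.json"
    summary = score_cohort(records, scheme, class_csv, summary_json)
    record_output("classification_csv", class_csv)
    record_output("summary_json", summary_json)
    manifest["stages"]["stratify"] = {"band_counts": dict(summary.band_counts)}

    # -- stage 3: estimate --------------------------------------------------
    est_cfg = EstimationConfig(**cfg.get("estimation", {}))
    report = estimate_all(summary, est_cfg)
    params_json = outdir / "parameters.json"
    with open(params_json, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    record_output("parameters_json", params_json)
    manifest["stages"]["estimate"] = {"params_display": {
        k: _display(v) for k, v in report.params.to_dict().items()
    }}

    # -- stage 4: simulate --------------------------------------------------
    sim_cfg = cfg.get("simulate", {})
    init = sim_cfg.get("init")
    init = StateFractions(*init) if init is not None else report.fractions
    traj = integrate(
        report.params,
        init,
        t_end=sim_cfg.get("t_end"),
        rtol=sim_cfg.get("rtol", 1e-8),
        atol=sim_cfg.get("atol", 1e-10),
        normalize_entry=sim_cfg.get("normalize_entry", False),
    )
    traj_csv = outdir / "trajectory.csv"
    traj.to_csv(traj_csv)
    record_output("trajectory_csv", traj_csv)
    manifest["stages"]["simulate"] = {
        "t_end": traj.solver_meta["t_end"],
        "converged": bool(traj.converged),
        "terminal": [float(v) for v in traj.terminal],
    }

    # -- stage 5: equilibrium ----------------------------------------------
    stab = stability_analysis(report.params)
    stab_json = outdir / "stability.json"
    stab.to_json(stab_json)
    record_output("stability_json", stab_json)
    manifest["stages"]["equilibrium"] = {"stable": stab.stable}

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", count=True, help="Increase log verbosity.")
@click.version_option(version=__version__)
def cli(verbose: int) -> None:
    """Vulnerability stratification and dynamics of adolescent MDD."""
    _setup_logging(verbose)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True, path_type=Path),
              help="SynthConfig YAML/JSON.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--reference", "reference", is_flag=True,
              help="Write the deterministic reference cohort (ignores seed).")
@click.option("--out", type=click.Path(path_type=Path), required=True)
def synth(config_path, seed, reference, out):
    """Generate a synthetic cohort CSV."""
    if reference:
        records = reference_cohort()
    else:
        kwargs = _load_config(config_path) if config_path else {}
        kwargs["seed"] = seed
        records = generate_cohort(SynthConfig(**kwargs))
    cohort_to_csv(records, out)
    log.info("wrote %d records to %s", len(records), out)


@cli.command()
@click.argument("cohort_csv", type=click.Path(exists=True, path_type=Path))
@click.option("--scheme", "scheme_path", type=click.Path(exists=True, path_type=Path))
@click.option("--out-classification", type=click.Path(path_type=Path), required=True)
@click.option("--out-summary", type=click.Path(path_type=Path), required=True)
def score(cohort_csv, scheme_path, out_classification, out_summary):
    """Stratify a cohort CSV into vulnerability bands."""
    records = cohort_from_csv(cohort_csv)
    summary = score_cohort(records, _load_scheme(scheme_path),
                           out_classification, out_summary)
    click.echo(json.dumps(summary.band_counts))


@cli.command()
@click.argument("summary_json", type=click.Path(exists=True, path_type=Path))
@click.option("--config", "config_path", type=click.Path(exists=True, path_type=Path),
              help="EstimationConfig YAML/JSON.")
@click.option("--out", type=click.Path(path_type=Path), required=True)
def estimate(summary_json, config_path, out):
    """Estimate model parameters from a cohort summary JSON."""
    summary = CohortSummary.from_json(summary_json)
    est_cfg = EstimationConfig(**(_load_config(config_path) if config_path else {}))
    report = estimate_all(summary, est_cfg)
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    click.echo(json.dumps({k: _display(v) for k, v in report.params.to_dict().items()}))


def _load_params(path: Path) -> ModelParameters:
    d = _load_config(path)
    if "params" in d:  # accept a full estimation report
        d = d["params"]
    return ModelParameters.from_dict(d)


@cli.command()
@click.argument("params_json", type=click.Path(exists=True, path_type=Path))
@click.option("--init", nargs=3, type=float, default=None,
              help="Initial fractions x y z (default: cohort initial values).")
@click.option("--t-end", type=float, default=None,
              help="Horizon in days (default: adaptive until steady).")
@click.option("--normalize-entry", is_flag=True,
              help="Rescale (a, b, c) to sum to 1 before integrating.")
@click.option("--out", type=click.Path(path_type=Path), required=True)
def simulate(params_json, init, t_end, normalize_entry, out):
    """Integrate the model and write a t,x,y,z trajectory CSV."""
    from .estimation import STUDY_INITIAL_FRACTIONS

    p = _load_params(params_json)
    init_s = StateFractions(*init) if init else STUDY_INITIAL_FRACTIONS
    traj = integrate(p, init_s, t_end=t_end, normalize_entry=normalize_entry)
    traj.to_csv(out)
    click.echo(json.dumps({
        "t_end": traj.solver_meta["t_end"],
        "terminal": [float(v) for v in traj.terminal],
        "converged": bool(traj.converged),
    }))


@cli.command("equilibrium")
@click.argument("params_json", type=click.Path(exists=True, path_type=Path))
@click.option("--out", type=click.Path(path_type=Path), required=True)
def equilibrium_cmd(params_json, out):
    """Write a stability/equilibrium report JSON for a parameter set."""
    from .equilibrium import (
        cubic_coefficients, positivity_conditions, solve_equilibrium_y, vieta,
    )

    p = _load_params(params_json)
    stab = stability_analysis(p)
    coeffs = cubic_coefficients(p)
    report = stab.to_dict()
    report["cubic_coefficients"] = list(coeffs.as_tuple())
    report["vieta"] = asdict(vieta(coeffs))
    report["positivity"] = list(positivity_conditions(p))
    report["roots"] = [
        {"y": r.y, "admissible": r.admissible, "residual": r.residual}
        for r in solve_equilibrium_y(p)
    ]
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    click.echo(json.dumps({"stable": report["stable"],
                           "eigenvalues": report["eigenvalues"]}))


@cli.command("sweep")
@click.argument("params_json", type=click.Path(exists=True, path_type=Path))
@click.option("--param", "param_name", required=True,
              type=click.Choice(["delta", "epsilon", "alpha", "beta"]))
@click.option("--grid", required=True,
              help="Comma-separated values, e.g. '0.1,0.2,0.4'.")
@click.option("--init", nargs=3, type=float, default=None)
@click.option("--t-end", type=float, default=None)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def sweep_cmd(params_json, param_name, grid, init, t_end, out):
    """Terminal fractions along a grid of one parameter; writes a CSV."""
    from .estimation import STUDY_INITIAL_FRACTIONS

    p = _load_params(params_json)
    values = np.array([float(v) for v in grid.split(",")])
    init_s = StateFractions(*init) if init else STUDY_INITIAL_FRACTIONS
    table = run_sweep(p, param_name, values, init_s, t_end=t_end)
    table.to_csv(out, index=False)
    click.echo(table.to_string(index=False))


@cli.command()
@click.argument("config_path", type=click.Path(exists=True, path_type=Path))
def run(config_path):
    """Run the full pipeline from a YAML/JSON config."""
    manifest = run_pipeline(config_path)
    click.echo(json.dumps(
        {"outdir": str(Path(manifest["config"].get("outdir", "mddvuln_run"))),
         "band_counts": manifest["stages"]["stratify"]["band_counts"],
         "stable": manifest["stages"]["equilibrium"]["stable"]}
    ))


def main() -> None:  # pragma: no cover - console-script shim
    cli()
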