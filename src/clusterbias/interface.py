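"""Command-line entry points tying the modules into the analysis workflow.

Subcommands::

    clusterbias fit         fit the baseline invariance model to a CSV
    clusterbias test-bias   run the full cluster-bias testing sequence
    clusterbias simulate    write a synthetic dataset from a design config
    clusterbias power-study Monte-Carlo rejection rate for a design

Data are long-format CSV (comma separator, header row, UTF-8, "." decimal);
identifier columns are read as strings.  Every artifact embeds the
configuration and seed that produced it.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import yaml

from . import engine, inference, simulate as sim
from .engine import FitOptions
from .model_spec import build_cluster_bias_models

logger = logging.getLogger("clusterbias")


def _setup_logging(verbose: int) -> None:
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")


def _parse_doublets(text: str | None) -> list:
    """'1,2;5,6' -> [[0, 1], [4, 5]] (CLI uses 1-based indicator numbers)."""
    if not text:
        return []
    out = []
    for grp in text.split(";"):
        members = [int(tok) - 1 for tok in grp.split(",") if tok.strip()]
        out.append(members)
    return out


def _load_config(path: str | None) -> dict:
    if not path:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise click.ClickException(f"config {path} must be a mapping")
    return cfg


def _validated_alpha(alpha: float) -> float:
    if not (0 < alpha < 1):
        raise click.ClickException(f"alpha must be in (0, 1), got {alpha}")
    return alpha


def _read_data(cfg: dict):
    for key in ("data", "class_col", "indicators"):
        if not cfg.get(key):
            raise click.ClickException(f"missing required setting: {key}")
    indicators = cfg["indicators"]
    if isinstance(indicators, str):
        indicators = [c.strip() for c in indicators.split(",") if c.strip()]
    try:
        return engine.preprocess(
            cfg["data"],
            cfg.get("school_col"),
            cfg["class_col"],
            indicators,
            cfg.get("missing_class_policy", "pool"),
        )
    except KeyError as exc:
        raise click.ClickException(str(exc))
    except ValueError as exc:
        raise click.ClickException(str(exc))


def _write_artifacts(outdir: str, stem: str, payload: dict, text: str | None = None) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / f"{stem}.json"
    with open(jpath, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
    if text is not None:
        with open(out / f"{stem}.txt", "w") as fh:
            fh.write(text + "\n")
    return jpath


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _common_cfg(config, data, school_col, class_col, indicators, alpha, seed, out):
    cfg = _load_config(config)
    for key, val in (
        ("data", data),
        ("school_col", school_col),
        ("class_col", class_col),
        ("indicators", indicators),
        ("alpha", alpha),
        ("seed", seed),
        ("out", out),
    ):
        if val is not None:
            cfg[key] = val
    cfg.setdefault("alpha", 0.05)
    cfg.setdefault("seed", 0)
    cfg.setdefault("out", "clusterbias_out")
    cfg["alpha"] = _validated_alpha(float(cfg["alpha"]))
    return cfg


_shared_options = [
    click.option("--config", type=click.Path(exists=True), default=None, help="YAML config file."),
    click.option("--data", type=click.Path(exists=True), default=None, help="Long-format CSV."),
    click.option("--school-col", default=None, help="School identifier column (omit for two-level data)."),
    click.option("--class-col", default=None, help="Class identifier column."),
    click.option("--indicators", default=None, help="Comma-separated indicator columns."),
    click.option("--alpha", type=float, default=None, help="Significance level (default 0.05)."),
    click.option("--seed", type=int, default=None, help="Random seed (default 0)."),
    click.option("--out", default=None, help="Output directory."),
    click.option("-v", "--verbose", count=True),
]


def _apply(options):
    def deco(f):
        for opt in reversed(options):
            f = opt(f)
        return f

    return deco


@click.group()
def main():
    """Multilevel factor models and the test for cluster bias."""


@main.command("fit")
@_apply(_shared_options)
@click.option("--doublets", default=None, help="1-based doublet sets, e.g. '1,2' or '1,2;5,6'.")
def cmd_fit(config, data, school_col, class_col, indicators, alpha, seed, out, verbose, doublets):
    """Fit the baseline invariance model (equal loadings across levels)."""
    _setup_logging(verbose)
    cfg = _common_cfg(config, data, school_col, class_col, indicators, alpha, seed, out)
    if doublets is not None:
        cfg["doublets"] = doublets
    hdata = _read_data(cfg)
    dsets = (
        _parse_doublets(cfg.get("doublets"))
        if isinstance(cfg.get("doublets"), str)
        else cfg.get("doublets", [])
    )
    models = build_cluster_bias_models(
        hdata.p, dsets, n_levels=hdata.n_levels, indicator_names=hdata.indicator_names
    )
    fit = engine.fit_ml(models.baseline, hdata, FitOptions(seed=int(cfg["seed"])))
    payload = {"config": cfg, "summary": hdata.summary(), "fit": fit.to_dict()}
    text = fit.to_frame().to_string(index=False)
    path = _write_artifacts(cfg["out"], "fit", payload, text)
    click.echo(f"loglik {fit.loglik:.2f}  converged={fit.converged}  -> {path}")
    sys.exit(0 if fit.converged else 1)


@main.command("test-bias")
@_apply(_shared_options)
@click.option("--doublets", default=None, help="1-based doublet sets, e.g. '1,2'.")
def cmd_test_bias(config, data, school_col, class_col, indicators, alpha, seed, out, verbose, doublets):
    """Run the full cluster-bias testing sequence and render the reports."""
    _setup_logging(verbose)
    cfg = _common_cfg(config, data, school_col, class_col, indicators, alpha, seed, out)
    if doublets is not None:
        cfg["doublets"] = doublets
    hdata = _read_data(cfg)
    dsets = (
        _parse_doublets(cfg.get("doublets"))
        if isinstance(cfg.get("doublets"), str)
        else cfg.get("doublets", [])
    )
    report = inference.cluster_bias_test(
        hdata, dsets, alpha=cfg["alpha"], options=FitOptions(seed=int(cfg["seed"]))
    )
    payload = {"config": cfg, "summary": hdata.summary(), "report": report.to_dict()}
    text = report.to_text()
    path = _write_artifacts(cfg["out"], "cluster_bias", payload, text)
    click.echo(text)
    click.echo(f"-> {path}")
    sys.exit(0 if not report.unavailable else 1)


def _design_from_cfg(cfg: dict) -> sim.SimulationDesign:
    block = cfg.get("simulation")
    if not block:
        raise click.ClickException("missing required setting: simulation")
    try:
        doublets = [
            sim.DoubletTruth(tuple(d["indicators"]), tuple(d["variances"]))
            for d in block.get("doublets", [])
        ]
        return sim.SimulationDesign(
            n_schools=block.get("n_schools", 1),
            classes_per_school=block["classes_per_school"],
            students_per_class=block["students_per_class"],
            loadings=block["loadings"],
            phi=block["phi"],
            residual_var=block["residual_var"],
            intercepts=block.get("intercepts"),
            doublets=doublets,
            loading_sd_level2=block.get("loading_sd_level2", 0.0),
            n_levels=block.get("n_levels", 3),
            seed=int(cfg.get("seed", block.get("seed", 0))),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise click.ClickException(f"invalid simulation design: {exc}")


@main.command("simulate")
@click.option("--config", type=click.Path(exists=True), required=True, help="YAML with a simulation block.")
@click.option("--seed", type=int, default=None)
@click.option("--out", default="clusterbias_out")
@click.option("-v", "--verbose", count=True)
def cmd_simulate(config, seed, out, verbose):
    """Write a synthetic dataset as CSV plus a provenance sidecar JSON."""
    _setup_logging(verbose)
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    design = _design_from_cfg(cfg)
    data = sim.simulate_dataset(design)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "simulated.csv"
    data.to_dataframe().to_csv(csv_path, index=False)
    provenance = {
        "seed": design.seed,
        "design": {
            "n_schools": design.n_schools,
            "n_levels": design.n_levels,
            "p": design.p,
            "loadings": design.loadings.tolist(),
            "phi": list(design.phi),
            "residual_var": [v.tolist() for v in design.residual_var],
        },
        "summary": data.summary(),
    }
    with open(outdir / "simulated.provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=_json_default)
    click.echo(f"{data.n} rows -> {csv_path}")


@main.command("power-study")
@click.option("--config", type=click.Path(exists=True), required=True, help="YAML with a simulation block.")
@click.option("--replicates", type=int, default=100)
@click.option("--tested-level", type=int, default=2)
@click.option("--alpha", type=float, default=0.05)
@click.option("--seed", type=int, default=None)
@click.option("--out", default="clusterbias_out")
@click.option("-v", "--verbose", count=True)
def cmd_power_study(config, replicates, tested_level, alpha, seed, out, verbose):
    """Monte-Carlo rejection rate of the difference test for a design."""
    _setup_logging(verbose)
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    _validated_alpha(alpha)
    design = _design_from_cfg(cfg)
    null_at_level = not np.any(design.residual_var[tested_level - 1])
    runner = sim.type1_error_study if null_at_level else sim.power_study
    result = runner(design, replicates, alphas=(alpha,), tested_level=tested_level)
    payload = {"config": cfg, "study": result.to_dict()}
    text = result.summary()
    path = _write_artifacts(out, "study", payload, text)
    click.echo(text)
    click.echo(f"-> {path}")
    sys.exit(1 if result.unreliable else 0)


if __name__ == "__main__":
    main()
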