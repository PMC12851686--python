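"""End-to-end orchestration: one config file drives all analysis stages.

A run takes either a synthetic scenario or existing burden/population CSVs,
then executes age-standardized trend summaries (EAPC), joinpoint segmented
trends, change decomposition, the QCI, and ARIMA projection, writing one
tidy CSV per stage into a run directory together with a JSON manifest
(config hash, file digests, seeds, version, timestamps). Identical config
and seed reproduce identical output digests; a stage failure halts the run
with the failing stage named, retaining earlier outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .io import read_burden_csv, write_burden_csv
from .decompose import decompose_table
from .forecast import fit_arima
from .joinpoint import fit_joinpoint
from .qci import compute_qci, compute_ratios
from .schema import AGE_STD
from .synthetic import ScenarioConfig, generate_burden, generate_population
from .trends import eapc_table


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str
    outputs: dict[str, str]  # stage -> path
    digests: dict[str, str]  # path -> sha256
    input_digests: dict[str, str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute every configured stage; returns the run manifest.

    See the packaged example configs for the accepted layout: a ``scenario``
    section (synthetic run) or an ``inputs`` section (CSV ingestion), plus
    optional per-stage sections ``trends``, ``joinpoint``, ``decompose``,
    ``qci`` and ``forecast``.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{config_path} did not parse to a mapping")
    seed = int(cfg.get("seed", 0))
    run_dir = Path(out_dir or cfg.get("run_dir", "burdenqci_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    outputs: dict[str, str] = {}
    input_digests: dict[str, str] = {}

    # --- ingest or simulate -------------------------------------------------
    try:
        if "scenario" in cfg:
            scenario = ScenarioConfig(**{**cfg["scenario"], "seed": seed})
            pop = generate_population(scenario)
            burden = generate_burden(scenario, pop)
            pop_path = run_dir / "population.csv"
            pop.to_csv(pop_path, index=False, float_format="%.6g")
            burden_path = write_burden_csv(burden, run_dir / "burden.csv")
            outputs["simulate"] = str(burden_path)
            outputs["population"] = str(pop_path)
        elif "inputs" in cfg:
            burden_path = Path(cfg["inputs"]["burden_csv"])
            burden = read_burden_csv(burden_path)
            input_digests[str(burden_path)] = _sha256(burden_path)
            pop = None
            if cfg["inputs"].get("population_csv"):
                pop_path = Path(cfg["inputs"]["population_csv"])
                pop = pd.read_csv(pop_path)
                input_digests[str(pop_path)] = _sha256(pop_path)
        else:
            raise ValueError("config needs a 'scenario' or 'inputs' section")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate/ingest", str(exc)) from exc

    # --- trends -------------------------------------------------------------
    if cfg.get("trends", {}) is not None:
        try:
            opts = cfg.get("trends") or {}
            table = eapc_table(
                burden,
                measures=opts.get("measures"),
                locations=opts.get("locations"),
                sexes=tuple(opts.get("sexes", ("both",))),
            )
            path = run_dir / "eapc.csv"
            table.to_csv(path, index=False, float_format="%.6g")
            outputs["trends"] = str(path)
        except Exception as exc:
            raise PipelineError("trends", str(exc)) from exc

    # --- joinpoint ----------------------------------------------------------
    if "joinpoint" in cfg:
        try:
            opts = cfg["joinpoint"] or {}
            rows = []
            for (m, loc, sex), grp in _asr_groups(burden, opts):
                grp = grp.sort_values("year")
                model = fit_joinpoint(
                    grp["year"].to_numpy(),
                    grp["val"].to_numpy(),
                    max_joinpoints=int(opts.get("max_joinpoints", 2)),
                    n_perm=int(opts.get("n_perm", 199)),
                    alpha=float(opts.get("alpha", 0.05)),
                    seed=seed,
                )
                for seg in model.apcs:
                    rows.append(
                        {
                            "measure": m,
                            "location": loc,
                            "sex": sex,
                            "segment_start": seg["start"],
                            "segment_end": seg["end"],
                            "apc": seg["apc"],
                            "ci_low": seg["ci_low"],
                            "ci_high": seg["ci_high"],
                            "aapc": model.aapc["aapc"],
                            "aapc_p": model.aapc["p_value"],
                            "n_joinpoints": len(model.joinpoints),
                            "permutation_p": model.permutation_p,
                        }
                    )
            path = run_dir / "joinpoint.csv"
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
            outputs["joinpoint"] = str(path)
        except Exception as exc:
            raise PipelineError("joinpoint", str(exc)) from exc

    # --- decomposition ------------------------------------------------------
    if "decompose" in cfg:
        try:
            opts = cfg["decompose"] or {}
            if pop is None:
                raise ValueError("decomposition requires a population table")
            year0 = int(opts.get("year0", burden["year"].min()))
            year1 = int(opts.get("year1", burden["year"].max()))
            rows = []
            measures = opts.get("measures") or sorted(burden["measure"].unique())
            sexes = opts.get("sexes") or ["both"]
            for loc in sorted(burden["location"].unique()):
                for m in measures:
                    for sex in sexes:
                        res = decompose_table(burden, pop, m, loc, sex, year0, year1)
                        rows.append(
                            {
                                "measure": m,
                                "location": loc,
                                "sex": sex,
                                "year0": year0,
                                "year1": year1,
                                "delta_total": res.delta_total,
                                "delta_epi": res.delta_epi,
                                "delta_age": res.delta_age,
                                "delta_pop": res.delta_pop,
                            }
                        )
            path = run_dir / "decomposition.csv"
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
            outputs["decompose"] = str(path)
        except Exception as exc:
            raise PipelineError("decompose", str(exc)) from exc

    # --- qci ----------------------------------------------------------------
    if "qci" in cfg:
        try:
            opts = cfg["qci"] or {}
            ratios = compute_ratios(
                burden, daly_denominator=opts.get("daly_denominator", "prevalence")
            )
            res = compute_qci(ratios, log_transform=bool(opts.get("log", False)))
            tidy = ratios.values.copy()
            tidy["pca_score"] = res.pca_score
            tidy["qci"] = res.qci
            path = run_dir / "qci.csv"
            tidy.reset_index().to_csv(path, index=False, float_format="%.6g")
            outputs["qci"] = str(path)
        except Exception as exc:
            raise PipelineError("qci", str(exc)) from exc

    # --- forecast -----------------------------------------------------------
    if "forecast" in cfg:
        try:
            opts = cfg["forecast"] or {}
            horizon = int(opts.get("horizon", burden["year"].max() + 10))
            frames = []
            for (m, loc, sex), grp in _asr_groups(burden, opts):
                grp = grp.sort_values("year")
                fit = fit_arima(
                    grp["year"].to_numpy(),
                    grp["val"].to_numpy(),
                    horizon=horizon,
                    p_max=int(opts.get("p_max", 2)),
                    q_max=int(opts.get("q_max", 2)),
                    criterion=opts.get("criterion", "aic"),
                )
                fc = fit.forecasts.copy()
                fc.insert(0, "measure", m)
                fc.insert(1, "location", loc)
                fc.insert(2, "sex", sex)
                fc["order"] = str(fit.order)
                frames.append(fc)
            path = run_dir / "forecast.csv"
            pd.concat(frames).to_csv(path, index=False, float_format="%.6g")
            outputs["forecast"] = str(path)
        except Exception as exc:
            raise PipelineError("forecast", str(exc)) from exc

    digests = {p: _sha256(Path(p)) for p in outputs.values()}
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=seed,
        version=__version__,
        started=started,
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=outputs,
        digests=digests,
        input_digests=input_digests,
    )
    manifest.to_json(run_dir / "manifest.json")
    return manifest


def _asr_groups(burden: pd.DataFrame, opts: dict):
    sub = burden[(burden["age"] == AGE_STD) & (burden["metric"] == "rate")]
    measures = opts.get("measures")
    sexes = opts.get("sexes", ["both"])
    for key, grp in sub.groupby(["measure", "location", "sex"]):
        m, loc, sex = key
        if measures is not None and m not in measures:
            continue
        if sexes is not None and sex not in sexes:
            continue
        yield key, grp
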