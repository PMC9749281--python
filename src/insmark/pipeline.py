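"""End-to-end pipeline with reproducible run manifests.

``run_pipeline`` executes the full workflow — simulate or ingest, panel,
(optional) screening and cutpoint construction, scoring, evaluation,
optional split validation — writing every intermediate artifact plus a
:class:`RunManifest` that fingerprints inputs, configuration and seeds.
Stage failures raise :class:`StageError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .data_model import Cohort, read_cohort, write_cohort
from .model import INSModel
from .scoring import INSConfig, INS_2022
from .synthetic import SimConfig, simulate_cohort

__all__ = ["RunManifest", "StageError", "run_pipeline"]

log = logging.getLogger("insmark")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    seed: int | None
    config_hash: str
    input_fingerprint: str
    stage_timings: dict[str, float] = field(default_factory=dict)
    output_paths: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _hash_config(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _fingerprint_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path,
                 seed: int | None = None) -> tuple[object, RunManifest]:
    """Run the full workflow from a config mapping.

    Config keys (all optional except one of ``input``/``simulate``):

    * ``input``: {"path": csv, "schema": schema-config path or mapping}
    * ``simulate``: SimConfig field overrides (``n``, ``log_hr_per_point``...)
    * ``select``: bool — re-derive components/thresholds from the data
    * ``use_lasso``: bool — include the L1 screen during selection
    * ``horizon``: months for cNRI/IDI and AUC(t) (default 36)
    * ``n_bootstrap``: resampling size for CIs (default 200)
    * ``adjusted``: fit the covariate-adjusted Cox model b (default True)
    * ``split``: {"ratio": 0.7} — run the randomized internal validation

    Returns (INSResults, RunManifest); the manifest and all artifacts are
    written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    paths: dict[str, str] = {}
    manifest = RunManifest(version=__version__, seed=seed,
                           config_hash=_hash_config(config),
                           input_fingerprint="", stage_timings=timings,
                           output_paths=paths)

    def stage(name):
        class _T:
            def __enter__(self):
                log.info("[%s] start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, et, ev, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if et is None:
                    log.info("[%s] done in %.2fs", name, timings[name])
        return _T()

    # ---- input or simulation
    try:
        with stage("input"):
            if "input" in config:
                src = Path(config["input"]["path"])
                cohort = read_cohort(src, config["input"].get("schema"))
                manifest.input_fingerprint = _fingerprint_file(src)
            elif "simulate" in config or seed is not None:
                sim_kwargs = dict(config.get("simulate", {}))
                cfg = SimConfig(**sim_kwargs)
                cohort, truth = simulate_cohort(cfg, seed=seed)
                manifest.input_fingerprint = f"simulated:seed={cohort.provenance}"
                p = out / "synthetic_cohort.csv"
                write_cohort(cohort, p)
                paths["cohort"] = str(p)
            else:
                raise ValueError("config must provide 'input' or 'simulate'")
    except Exception as exc:
        raise StageError("input", exc) from exc

    # ---- fit
    try:
        with stage("fit"):
            score_cfg = INS_2022
            if "score_config" in config:
                score_cfg = INSConfig.from_mapping(
                    config["score_config"]["components"],
                    name=config["score_config"].get("name", "custom"))
            model = INSModel(cohort, score_config=score_cfg,
                             horizon=float(config.get("horizon", 36.0)))
            results = model.fit(seed=seed,
                                select=bool(config.get("select", False)),
                                use_lasso=bool(config.get("use_lasso", False)),
                                n_bootstrap=int(config.get("n_bootstrap", 200)),
                                adjusted=bool(config.get("adjusted", True)))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fit", exc) from exc

    # ---- artifacts
    try:
        with stage("write"):
            results.panel.to_csv(out / "panel.csv", index=False)
            results.scored.to_csv(out / "scored.csv", index=False)
            paths["panel"] = str(out / "panel.csv")
            paths["scored"] = str(out / "scored.csv")
            (out / "validation.json").write_text(results.validation.to_json())
            paths["validation"] = str(out / "validation.json")
            if results.eval_report is not None:
                (out / "report.json").write_text(results.eval_report.to_json())
                (out / "report.md").write_text(results.eval_report.to_markdown())
                paths["report"] = str(out / "report.json")
    except Exception as exc:
        raise StageError("write", exc) from exc

    # ---- optional split validation
    if "split" in config:
        try:
            with stage("split_validate"):
                parts = model.split_validate(
                    ratio=float(config["split"].get("ratio", 0.7)), seed=seed,
                    n_bootstrap=int(config.get("n_bootstrap", 200)),
                    adjusted=bool(config.get("adjusted", True)))
                for label, res in parts.items():
                    if res.eval_report is not None:
                        p = out / f"report_validation_{label}.json"
                        p.write_text(res.eval_report.to_json())
                        paths[f"validation_{label}"] = str(p)
        except Exception as exc:
            raise StageError("split_validate", exc) from exc

    (out / "manifest.json").write_text(manifest.to_json())
    paths["manifest"] = str(out / "manifest.json")
    return results, manifest
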