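"""End-to-end orchestration: simulate/load -> score -> models -> network -> loops.

Stage outputs are plain CSV/JSON/GraphML files in the output directory and are
byte-deterministic for a fixed config and seed (wall-clock runtimes go to the
Markdown summary and the log only).  A single global seed is fanned out to the
stochastic stages through a fixed counter scheme so stages stay independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .catalog import SHAME_ITEM, SymptomCatalog, default_catalog
from .io import load_study, write_frequency_table, write_pcr_table
from .loops import compute_loop_census, loop_burden_association, symptom_involvement
from .network import build_mean_network, permutation_null, plot_network
from .records import ParticipantRecord, subset_frequency_score
from .regression import (
    fit_mediation,
    fit_moderated_mediation,
    fit_moderation,
    incremental_regression,
    simple_slope_contrast_d,
)
from .scoring import cause_effect_table, pcr_subset_score
from .simulate import SimulationConfig, simulate_population

logger = logging.getLogger(__name__)

ALL_STAGES = ("data", "score", "models", "network", "loops")

_STAGE_SEED_OFFSET = {"data": 1, "models": 2, "network": 3, "loops": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to a per-stage seed (kept below 2**31)."""
    return (seed * 1_000_003 + _STAGE_SEED_OFFSET.get(stage, 0)) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    seed: int
    out_dir: str = "results/pipeline"
    stages: Sequence[str] = ALL_STAGES
    n_participants: int = 300  # when simulating
    frequencies_csv: str | None = None  # set both to load real data instead
    pcr_csv: str | None = None
    edge_cutoff_light: float = 3.0
    edge_cutoff_dark: float = 4.5
    loop_cutoff: float = 4.5
    max_loop_len: int = 4
    min_edge_n: int = 1
    n_boot: int = 5000
    n_perm: int = 1000
    ci_level: float = 0.95
    make_figure: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 <= self.loop_cutoff <= 10:
            raise ValueError("loop_cutoff must lie in [0, 10]")
        if (self.frequencies_csv is None) != (self.pcr_csv is None):
            raise ValueError("provide both frequencies_csv and pcr_csv, or neither")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _dump_json(payload: Any, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))


def _series(records: Sequence[ParticipantRecord], fn) -> np.ndarray:
    return np.array([float(v) if (v := fn(r)) is not None else np.nan for r in records])


def study_variables(
    records: Sequence[ParticipantRecord], catalog: SymptomCatalog
) -> dict[str, np.ndarray]:
    """The frequency and PCR composites the regression designs use."""
    shame_freq = []
    for r in records:
        v = r.frequencies[SHAME_ITEM]
        shame_freq.append(float(v) if isinstance(v, int) else np.nan)
    return {
        "ANX_FREQ": _series(records, lambda r: subset_frequency_score(r, "ANX", catalog)),
        "REEXP_FREQ": _series(records, lambda r: subset_frequency_score(r, "REEXP", catalog)),
        "DEP_FREQ": _series(records, lambda r: subset_frequency_score(r, "DEP", catalog)),
        "SHAME_FREQ": np.array(shame_freq),
        "PCR_ANX_DEP": _series(
            records, lambda r: pcr_subset_score(r, "ANX", "DEP", catalog)
        ),
        "PCR_REEXP_DEP": _series(
            records, lambda r: pcr_subset_score(r, "REEXP", "DEP", catalog)
        ),
        "PCR_SHAME_REEXP": _series(
            records, lambda r: pcr_subset_score(r, [SHAME_ITEM], "REEXP", catalog)
        ),
    }


def study_models(
    records: Sequence[ParticipantRecord],
    catalog: SymptomCatalog,
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, Any]:
    """Run the three regression designs on the standard variable roles.

    Per predictor family (reexperiencing, anxiety): moderation of the
    depression prediction by the matching PCR composite, the incremental
    alternative, and PCR-as-mediator.  Plus: reexperiencing mediating the
    guilt/shame -> depression path, moderated on both stages by PCR
    composites.  Models that cannot be fit on the available cases report the
    reason instead of aborting the stage.
    """
    v = study_variables(records, catalog)
    results: dict[str, Any] = {}

    def attempt(name: str, fn) -> None:
        try:
            results[name] = fn()
        except ValueError as err:
            logger.warning("model %s not estimable: %s", name, err)
            results[name] = {"error": str(err)}

    for tag, freq, pcr in (
        ("reexp", "REEXP_FREQ", "PCR_REEXP_DEP"),
        ("anx", "ANX_FREQ", "PCR_ANX_DEP"),
    ):
        def run_moderation(freq=freq, pcr=pcr):
            fit = fit_moderation(v[freq], v[pcr], v["DEP_FREQ"], level=level)
            out = dataclasses.asdict(fit)
            out["simple_slope_contrast_d"] = simple_slope_contrast_d(fit)
            return out

        attempt(f"moderation_{tag}", run_moderation)
        attempt(
            f"incremental_{tag}",
            lambda freq=freq, pcr=pcr: incremental_regression(
                v[freq], v[pcr], v["DEP_FREQ"]
            ),
        )
        attempt(
            f"mediation_pcr_{tag}",
            lambda freq=freq, pcr=pcr: fit_mediation(
                v[freq], v[pcr], v["DEP_FREQ"],
                n_boot=n_boot, seed=stage_seed(seed, "models"), level=level,
            ),
        )

    attempt(
        "mediation_shame_reexp_dep",
        lambda: fit_mediation(
            v["SHAME_FREQ"], v["REEXP_FREQ"], v["DEP_FREQ"],
            n_boot=n_boot, seed=stage_seed(seed, "models"), level=level,
        ),
    )
    attempt(
        "moderated_mediation",
        lambda: fit_moderated_mediation(
            v["SHAME_FREQ"], v["PCR_SHAME_REEXP"], v["REEXP_FREQ"],
            v["PCR_REEXP_DEP"], v["DEP_FREQ"],
            n_boot=n_boot, seed=stage_seed(seed, "models"), level=level,
        ),
    )
    return results


def run_pipeline(
    config: PipelineConfig, catalog: SymptomCatalog | None = None
) -> dict[str, Any]:
    """Execute the requested stages and write the report bundle.

    Returns the summary dict (also written as summary.json; runtimes go to
    summary.md so the JSON outputs stay byte-deterministic).
    """
    catalog = catalog or default_catalog()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    summary: dict[str, Any] = {
        "pcrnet_version": __version__,
        "seed": config.seed,
        "stages": stages,
        "outputs": {},
    }
    runtimes: dict[str, float] = {}

    def finish(stage: str, started: float, **outputs: str) -> None:
        runtimes[stage] = time.perf_counter() - started
        summary["outputs"][stage] = dict(outputs)
        logger.info("stage %s done in %.2fs: %s", stage, runtimes[stage], outputs)

    # -- data ------------------------------------------------------------
    t0 = time.perf_counter()
    catalog.save(out / "catalog.json")
    if config.frequencies_csv:
        records = load_study(config.frequencies_csv, config.pcr_csv, catalog)
        summary["data_source"] = "loaded"
    else:
        sim = SimulationConfig(
            n_participants=config.n_participants, seed=stage_seed(config.seed, "data")
        )
        records, truth = simulate_population(sim, catalog)
        truth.to_json(out / "truth.json")
        summary["data_source"] = "simulated"
    write_frequency_table(records, out / "frequencies.csv")
    write_pcr_table(records, out / "pcr.csv")
    summary["n_participants"] = len(records)
    finish("data", t0, frequencies="frequencies.csv", pcr="pcr.csv")

    # -- score -----------------------------------------------------------
    if "score" in stages:
        t0 = time.perf_counter()
        try:
            table = cause_effect_table(records, catalog)
            table.to_csv(out / "cause_effect_table.csv")
        except Exception as err:
            raise RuntimeError(f"stage 'score' failed: {err}") from err
        finish("score", t0, table="cause_effect_table.csv")

    # -- models ----------------------------------------------------------
    if "models" in stages:
        t0 = time.perf_counter()
        try:
            models = study_models(
                records, catalog,
                n_boot=config.n_boot, seed=config.seed, level=config.ci_level,
            )
            _dump_json(models, out / "models.json")
        except Exception as err:
            raise RuntimeError(f"stage 'models' failed: {err}") from err
        finish("models", t0, models="models.json")

    # -- network ---------------------------------------------------------
    if "network" in stages:
        t0 = time.perf_counter()
        try:
            net = build_mean_network(records, min_n=config.min_edge_n, catalog=catalog)
            net.to_edgelist_csv(out / "network_edges.csv")
            net.to_graphml(out / "network.graphml")
            # the null permutes all observed mean scores, not just displayed edges
            report = permutation_null(
                net, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "network"),
            )
            report.table.to_csv(out / "centrality.csv")
            if config.make_figure:
                plot_network(
                    net, out / "network.png",
                    seed=stage_seed(config.seed, "network"),
                    light_cutoff=config.edge_cutoff_light,
                    dark_cutoff=config.edge_cutoff_dark,
                )
        except Exception as err:
            raise RuntimeError(f"stage 'network' failed: {err}") from err
        finish("network", t0, edges="network_edges.csv", centrality="centrality.csv")

    # -- loops -----------------------------------------------------------
    if "loops" in stages:
        t0 = time.perf_counter()
        try:
            census = compute_loop_census(
                records, cutoff=config.loop_cutoff, max_len=config.max_loop_len
            )
            census.per_participant.to_csv(out / "loops_participants.csv")
            involvement = symptom_involvement(census, records)
            involvement.to_csv(out / "loops_involvement.csv")
            association = loop_burden_association(census, records)
            _dump_json(
                {
                    "association": association,
                    "total_incidences": census.total_incidences,
                    "unique_loop_types": census.unique_loop_types,
                },
                out / "loops_association.json",
            )
        except Exception as err:
            raise RuntimeError(f"stage 'loops' failed: {err}") from err
        finish(
            "loops", t0,
            participants="loops_participants.csv",
            association="loops_association.json",
        )

    _dump_json(summary, out / "summary.json")
    lines = [
        "# pcrnet pipeline summary",
        "",
        f"- version: {__version__}",
        f"- seed: {config.seed}",
        f"- participants: {summary['n_participants']} ({summary['data_source']})",
        f"- stages: {', '.join(stages)}",
        "",
        "| stage | runtime (s) | outputs |",
        "|---|---|---|",
    ]
    for stage, rt in runtimes.items():
        outputs = ", ".join(summary["outputs"].get(stage, {}).values())
        lines.append(f"| {stage} | {rt:.2f} | {outputs} |")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return summary
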