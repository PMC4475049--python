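"""Delimited-table readers/writers, result reports and the pipeline runner.

All tables are UTF-8 delimited text (comma or tab, auto-detected unless a
delimiter is given) with strict named-column schemas: the source tables in
this domain are heterogeneous literature compilations, so malformed rows
are collected into a rejects report with line numbers rather than silently
dropped.  Result reports are written as deterministic JSON (stable key
order, no timestamps) plus a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import SchemaError, ThermopairError, ValidationError
from .inference import (
    CorrelationResult,
    LRTestResult,
    MixedModelFit,
    TTestResult,
    difference_correlation,
    lr_test_sequence,
    nested_taxonomy_lmm,
    paired_lmm,
    status_t_test,
)
from .pairs import match_pairs, pair_differences, pairs_to_frame, pairs_to_long, records_from_frame
from .thermal import DevelopmentObservation, estimate_thermal_requirements

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = [
    "species_id", "population_id", "study_id", "stage",
    "temperature_c", "development_time_d",
]


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ThermopairError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if frame.empty and frame.columns.empty:
        raise SchemaError(f"{path}: empty file")
    return frame


def read_observations(
    path: str | Path, delimiter: str | None = None
) -> tuple[list[DevelopmentObservation], pd.DataFrame]:
    """Read rearing records; returns (valid records, rejects with line numbers)."""
    frame = _read_table(path, delimiter)
    missing = set(OBSERVATION_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")

    records: list[DevelopmentObservation] = []
    rejects: list[dict] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header on line 1
        try:
            records.append(
                DevelopmentObservation(
                    species_id=str(row["species_id"]),
                    population_id=str(row["population_id"]),
                    study_id=str(row["study_id"]),
                    stage=str(row["stage"]),
                    temperature=float(row["temperature_c"]),
                    development_time=float(row["development_time_d"]),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
    rejects_frame = pd.DataFrame(rejects, columns=["line", "reason"])
    if len(rejects_frame):
        logger.warning("%s: %d malformed row(s) rejected", path, len(rejects_frame))
    assert len(records) + len(rejects_frame) == len(frame)
    return records, rejects_frame


def read_species_traits(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a species trait table (taxonomy, continent, status, LDT/SET)."""
    frame = _read_table(path, delimiter)
    required = {"species_id", "order", "family", "genus", "continent", "invasive"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    frame.to_csv(path, sep=delimiter, index=False)


def _as_record(result) -> dict:
    rec = {
        k: v
        for k, v in dataclasses.asdict(result).items()
        if not k.startswith("_") and not isinstance(v, (pd.DataFrame,))
    }
    rec["result_type"] = type(result).__name__
    return rec


def write_results_report(results: dict, path: str | Path) -> None:
    """Write analyses as deterministic JSON plus a .txt human summary.

    ``results`` maps analysis names to result dataclasses (or plain dicts).
    The JSON is reproducible byte for byte from identical inputs: keys are
    sorted and no timestamps are embedded; the package version and a hash
    of the payload are stamped in for provenance.
    """
    path = Path(path)
    payload = {}
    for name in sorted(results):
        r = results[name]
        payload[name] = _as_record(r) if dataclasses.is_dataclass(r) else r
    body = json.dumps(payload, sort_keys=True, indent=2, default=float)
    digest = hashlib.sha256(body.encode()).hexdigest()[:16]
    doc = {"version": __version__, "content_hash": digest, "analyses": payload}
    path.write_text(json.dumps(doc, sort_keys=True, indent=2, default=float) + "\n")

    lines = [f"thermopair {__version__} results (hash {digest})", ""]
    for name, rec in payload.items():
        lines.append(f"[{name}]")
        if isinstance(rec, dict):
            for k in sorted(rec):
                if k == "result_type":
                    continue
                v = rec[k]
                lines.append(f"  {k} = {v:.6g}" if isinstance(v, float) else f"  {k} = {v}")
        lines.append("")
    path.with_suffix(".txt").write_text("\n".join(lines))


def read_results_report(path: str | Path) -> dict:
    """Parse a JSON results report back into plain dicts."""
    return json.loads(Path(path).read_text())["analyses"]


RESULT_TYPES = {
    "TTestResult": TTestResult,
    "MixedModelFit": MixedModelFit,
    "LRTestResult": LRTestResult,
    "CorrelationResult": CorrelationResult,
}


def record_to_result(rec: dict):
    """Rehydrate a report record into its result dataclass."""
    cls = RESULT_TYPES[rec["result_type"]]
    kwargs = {k: v for k, v in rec.items() if k != "result_type"}
    return cls(**kwargs)


# --------------------------------------------------------------------- #
# configuration and pipeline


@dataclass
class RunConfig:
    """Full-pipeline configuration; unknown keys are rejected on load."""

    observations: str
    species_meta: str
    output_dir: str = "thermopair_out"
    delimiter: str | None = None
    min_temperatures: int = 3
    outlier_k: float = 3.0
    analyses: list[str] = field(
        default_factory=lambda: ["t", "paired-lmm", "nested-lmm", "lr", "correlation"]
    )
    reml: bool = True
    accumulation_method: str = "single_sine"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def compare_analyses(
    pairs, species_table: pd.DataFrame, trait: str, analyses: list[str]
) -> dict:
    """Run the requested analyses for one trait on assembled pairs."""
    results: dict = {}
    long = pairs_to_long(pairs, trait)
    diffs = pair_differences(pairs)
    trait_col = "ldt_c" if trait == "ldt" else "set_dd"
    species = species_table.dropna(subset=[trait_col]).rename(columns={trait_col: "value"})
    species = species.assign(status=species["invasive"].astype(int))

    if "t" in analyses:
        results[f"{trait}_t_pooled"] = status_t_test(
            long["value"].to_numpy(), long["status"].to_numpy(),
            variant="pooled_two_sample",
        )
        results[f"{trait}_t_paired"] = status_t_test(
            long["value"].to_numpy(), long["status"].to_numpy(),
            long["pair_id"].to_numpy(), variant="paired_differences",
        )
    if "paired-lmm" in analyses:
        results[f"{trait}_paired_lmm"] = paired_lmm(long)
    if "nested-lmm" in analyses:
        results[f"{trait}_nested_lmm"] = nested_taxonomy_lmm(species, "family_in_order")
    if "lr" in analyses:
        for lr in lr_test_sequence(species):
            results[f"{trait}_lr_{lr.model_alt}"] = lr
    if "correlation" in analyses and trait == "ldt" and diffs["d_set"].notna().sum() >= 3:
        results["difference_correlation"] = difference_correlation(diffs)
    return results


def run_pipeline(config: RunConfig) -> Path:
    """Estimate thermal requirements, assemble pairs, run the analyses.

    Returns the path of the JSON results report.  Per-stage artifacts
    (thermal-requirements table, pair table, rejects) are written into
    ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, rejects = read_observations(config.observations, config.delimiter)
    if rejects is not None and len(rejects):
        write_table(rejects, out / "rejects.csv")
    logger.info("read %d observation(s), %d reject(s)", len(records), len(rejects))

    requirements = estimate_thermal_requirements(
        records, min_temperatures=config.min_temperatures, outlier_k=config.outlier_k
    )
    tr_frame = pd.DataFrame(
        {
            "species_id": [t.species_id for t in requirements],
            "stage": [t.stage for t in requirements],
            "ldt_c": [t.ldt for t in requirements],
            "set_dd": [t.set_dd for t in requirements],
            "se_ldt": [t.se_ldt for t in requirements],
            "se_set": [t.se_set for t in requirements],
            "n_sources": [t.n_sources for t in requirements],
            "source": [t.source for t in requirements],
        }
    )
    write_table(tr_frame, out / "thermal_requirements.csv")

    meta = read_species_traits(config.species_meta, config.delimiter)
    merged = meta.merge(
        tr_frame[["species_id", "ldt_c", "set_dd"]], on="species_id", how="left"
    )
    pairs = match_pairs(records_from_frame(merged))
    logger.info(
        "formed %d pair(s); rank tally: %s",
        len(pairs),
        pd.Series([p.relatedness_rank for p in pairs]).value_counts().to_dict(),
    )
    write_table(pairs_to_frame(pairs), out / "pairs.csv")

    results: dict = {}
    for trait in ("ldt", "set"):
        if trait == "set" and all(p.d_set is None for p in pairs):
            continue
        results.update(compare_analyses(pairs, merged, trait, config.analyses))
    report = out / "results.json"
    write_results_report(results, report)
    return report
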