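"""End-to-end orchestration: synthesize -> explain -> grade -> agree.

Each stage reads and writes plain files (PNG, CSV, JSON) under the run's
output directory so stages can be re-run independently, and records a
provenance block (config hash, seed, package version) alongside its output.
A full run is reproducible bit-for-bit from (config, seed); CSV floats are
rounded before writing.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import aggregate_table, build_confusion, combined_rate, make_records, rank_techniques
from .clinical import CRITERIA, grade_lesion
from .config import RunConfig
from .errors import InputError
from .io_utils import load_cohort, render_map, save_cohort, save_map, _save_png
from .map_grading import grade_map
from .model_adapter import FixtureModel
from .published import check_published_percentages
from .saliency import compute_map
from .synthesis import make_cohort

__all__ = ["run_synth", "run_explain", "run_grade", "run_agree", "run_report"]

log = logging.getLogger("dermxai")


def _setup_logging(quiet: bool) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.WARNING if quiet else logging.INFO)


def _provenance(config: RunConfig, stage: str, outdir: Path, **extra) -> None:
    block = {
        "stage": stage,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        **extra,
    }
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(block, indent=1))


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _grade_str(g: int | None) -> str:
    return "NA" if g is None else str(int(g))


def _grade_val(s) -> int | None:
    if s is None or (isinstance(s, float) and np.isnan(s)) or str(s) == "NA":
        return None
    return int(s)


def run_synth(config: RunConfig, quiet: bool = False) -> Path:
    """Generate the lesion cohort; writes PNG triples + manifest."""
    _setup_logging(quiet)
    t0 = time.perf_counter()
    out = _outdir(config)
    lesions = make_cohort(
        config.n_lesions,
        seed=config.seed,
        canvas=config.canvas,
        na_fraction=config.na_fraction,
    )
    manifest = save_cohort(lesions, out / "cohort")
    config.write_yaml(out / "config.yaml")
    _provenance(config, "synth", out, n_lesions=len(lesions))
    log.info(
        "synth: %d lesions (seed %d) -> %s [%.1fs]",
        len(lesions), config.seed, manifest.parent, time.perf_counter() - t0,
    )
    return manifest


def build_model(config: RunConfig) -> FixtureModel:
    """The run's classifier: a seeded fixture CNN at the cohort resolution."""
    h, w = config.canvas
    return FixtureModel.from_seed(
        config.model_seed, input_shape=(h, w, 3), channels=(4, 4), strides=(2, 2)
    )


def run_explain(config: RunConfig, quiet: bool = False) -> Path:
    """Compute one saliency map per (lesion, technique); writes PNG + JSON."""
    _setup_logging(quiet)
    t0 = time.perf_counter()
    out = _outdir(config)
    ids, lesions = load_cohort(out / "cohort")
    model = build_model(config)
    map_dir = out / "maps"
    map_dir.mkdir(exist_ok=True)
    n = 0
    for lesion_id, lesion in zip(ids, lesions):
        for technique in config.techniques:
            smap = compute_map(
                technique,
                model,
                lesion.image,
                class_index=config.melanoma_class,
                layer=config.layer,
                mask=lesion.mask,
                n_segments=config.lime_segments,
                n_samples=config.lime_samples,
                sigma=config.lime_sigma,
                seed=config.seed,
            )
            save_map(smap, map_dir / f"{lesion_id}.{technique}.png", seed=config.seed)
            if config.render:
                _save_png(render_map(smap), map_dir / f"{lesion_id}.{technique}.render.png")
            n += 1
    _provenance(config, "explain", out, n_maps=n)
    log.info("explain: %d maps [%.1fs]", n, time.perf_counter() - t0)
    return map_dir


def run_grade(config: RunConfig, mode: str, quiet: bool = False) -> Path:
    """Grade the cohort (mode='clinical') or the maps (mode='map') to CSV.

    The algorithmic grader is duplicated ``n_graders`` times (identical
    rows) so denominators match a multi-grader reader-study layout.
    Clinical grading also stores each lesion's derived color-abnormality
    map, which map-mode color grading then scores against.
    """
    _setup_logging(quiet)
    t0 = time.perf_counter()
    out = _outdir(config)
    ids, lesions = load_cohort(out / "cohort")

    if mode == "clinical":
        rows = []
        abn_dir = out / "derived_abnormality"
        abn_dir.mkdir(exist_ok=True)
        for lesion_id, lesion in zip(ids, lesions):
            grades = grade_lesion(lesion.image, lesion.mask, seed=config.seed)
            _save_png(grades["abnormality_map"], abn_dir / f"{lesion_id}.png")
            for grader in range(1, config.n_graders + 1):
                for criterion in CRITERIA:
                    rows.append(
                        {
                            "lesion_id": lesion_id,
                            "grader_id": grader,
                            "criterion": criterion,
                            "grade": _grade_str(grades[criterion]),
                        }
                    )
        path = out / "clinical_grades.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
    elif mode == "map":
        from PIL import Image

        from .io_utils import load_map

        clinical_path = out / "clinical_grades.csv"
        if not clinical_path.exists():
            raise IOError(f"missing clinical grades {clinical_path}; grade clinical first")
        clinical = pd.read_csv(clinical_path, dtype={"grade": str})
        border = {
            r["lesion_id"]: _grade_val(r["grade"])
            for _, r in clinical[clinical["criterion"] == "border"].iterrows()
        }
        rows = []
        for lesion_id, lesion in zip(ids, lesions):
            abn_path = out / "derived_abnormality" / f"{lesion_id}.png"
            if not abn_path.exists():
                raise IOError(f"missing derived abnormality map {abn_path}")
            abn = np.asarray(Image.open(abn_path), dtype=float) > 127
            for technique in config.techniques:
                map_path = out / "maps" / f"{lesion_id}.{technique}.png"
                if not map_path.exists():
                    raise IOError(f"missing saliency map {map_path}")
                smap = load_map(map_path)
                grades = grade_map(smap, lesion.mask, border.get(lesion_id), abn)
                for grader in range(1, config.n_graders + 1):
                    for criterion in CRITERIA:
                        rows.append(
                            {
                                "lesion_id": lesion_id,
                                "grader_id": grader,
                                "technique": technique,
                                "criterion": criterion,
                                "grade": _grade_str(grades[criterion]),
                            }
                        )
        path = out / "map_grades.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise InputError(f"unknown grading mode {mode!r}; use 'clinical' or 'map'")

    _provenance(config, f"grade_{mode}", out, n_rows=len(rows))
    log.info("grade(%s): %d rows [%.1fs]", mode, len(rows), time.perf_counter() - t0)
    return path


def run_agree(config: RunConfig, quiet: bool = False) -> dict:
    """Join the grade CSVs into agreement records and write the report bundle.

    Outputs: agreement records CSV, table CSV (2-decimal percentages),
    per-(technique, criterion) confusion CSVs, and a JSON summary with
    combined rates and the technique ranking.
    """
    _setup_logging(quiet)
    t0 = time.perf_counter()
    out = _outdir(config)
    clinical = pd.read_csv(out / "clinical_grades.csv", dtype={"grade": str})
    maps = pd.read_csv(out / "map_grades.csv", dtype={"grade": str})
    if set(clinical["lesion_id"]) != set(maps["lesion_id"]):
        raise InputError("clinical and map grade files cover different lesion ids")

    clin_idx = {
        (r["lesion_id"], r["grader_id"], r["criterion"]): _grade_val(r["grade"])
        for _, r in clinical.iterrows()
    }
    rows = []
    for _, r in maps.iterrows():
        key = (r["lesion_id"], r["grader_id"], r["criterion"])
        if key not in clin_idx:
            raise InputError(f"map grade without clinical counterpart: {key}")
        rows.append(
            {
                "lesion_id": r["lesion_id"],
                "grader_id": r["grader_id"],
                "technique": r["technique"],
                "criterion": r["criterion"],
                "clinical": clin_idx[key],
                "map": _grade_val(r["grade"]),
            }
        )
    records = make_records(rows)
    records.to_csv(out / "agreement_records.csv", index=False)

    table = aggregate_table(records)
    rounded = table.copy()
    for col in rounded.columns:
        if col.endswith("_pct"):
            rounded[col] = rounded[col].round(2)
    rounded.to_csv(out / "agreement_table.csv")

    conf_dir = out / "confusion"
    conf_dir.mkdir(exist_ok=True)
    for (technique, criterion), matrix in build_confusion(records).items():
        pd.DataFrame(
            matrix,
            index=[f"clinical_{g}" for g in range(3)],
            columns=[f"map_{g}" for g in range(3)],
        ).to_csv(conf_dir / f"{technique}.{criterion}.csv")

    techniques = sorted({t for (_, t) in table.index})
    summary = {
        "combined_rates": {t: combined_rate(table, t) for t in techniques},
        "ranking": rank_techniques(table),
        "denominators": {
            c: int(table.loc[(c, techniques[0]), "n"])
            for c in ("asymmetry", "border", "color", "TOTAL")
            if (c, techniques[0]) in table.index
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    _provenance(config, "agree", out, n_records=len(records))
    log.info("agree: %d records, ranking %s [%.1fs]",
             len(records), summary["ranking"], time.perf_counter() - t0)
    return summary


def run_report(quiet: bool = False) -> dict:
    """Validate the agreement arithmetic on the published reader-study counts.

    Recomputes the published agreement table from its counts and returns the
    combined rates, ranking, denominators and any percentage errata.
    """
    _setup_logging(quiet)
    from .published import published_table

    table = published_table()
    techniques = sorted({t for (_, t) in table.index})
    report = {
        "combined_rates": {t: combined_rate(table, t) for t in techniques},
        "ranking": rank_techniques(table),
        "denominators": {
            c: int(table.loc[(c, techniques[0]), "n"])
            for c in ("asymmetry", "border", "color", "TOTAL")
        },
        "errata": check_published_percentages(table),
    }
    log.info("report: ranking %s", report["ranking"])
    return report
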