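"""End-to-end pipeline: quarterly files -> cohort -> signals -> onset.

Stages run in the fixed order load -> deduplicate -> drug match -> PS
filter -> signal screen (PT and SOC) -> time-to-onset -> descriptives
(+ optional subgroup screens).  All artifacts are written atomically:
outputs land in a temporary sibling directory that replaces the final
output directory only when every stage has succeeded, so a failed run
never leaves a partial artifact set behind.  A run manifest records
input checksums, the config snapshot and the report-count funnel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CohortBuild,
    background_pairs,
    build_cohort,
    cohort_frame,
    cohort_pairs,
)
from .descriptives import (
    age_subgroups,
    profile,
    profile_frame,
    sex_subgroups,
    subgroup_screen,
)
from .faers_io import (
    RawTable,
    read_faers_table,
    read_pt_soc_map,
    TABLE_KINDS,
)
from .signal_stats import BcpnnPriors, DEFAULT_PRIORS, metrics_frame, screen
from .time_to_onset import compute_onsets, fit_weibull, onset_summary

log = logging.getLogger("faersig")

#: Organ classes dominated by the underlying disease rather than the drug
#: are excluded from the final intersection by default; fully configurable.
DEFAULT_SOC_EXCLUSIONS: tuple[str, ...] = (
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
)


class PipelineError(RuntimeError):
    """Fatal pipeline failure; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    quarters_dir: str | Path
    drug_terms: list[str]
    meddra_map_path: str | Path | None = None
    soc_exclusions: tuple[str, ...] = DEFAULT_SOC_EXCLUSIONS
    output_dir: str | Path = "faersig_out"
    seed: int = 0
    subgroups: tuple[str, ...] = ("sex", "age")  # subset of {"sex", "age"}
    levels: tuple[str, ...] = ("pt", "soc")
    zero_cell_correction: bool = False
    bcpnn_priors: BcpnnPriors = field(default_factory=BcpnnPriors)

    def __post_init__(self) -> None:
        if not self.drug_terms:
            raise ValueError("at least one drug search term is required")


def _find_table_files(quarters_dir: Path) -> dict[str, list[Path]]:
    found: dict[str, list[Path]] = {k: [] for k in TABLE_KINDS}
    for path in sorted(quarters_dir.rglob("*")):
        if not path.is_file() or path.suffix.lower() != ".txt":
            continue
        stem = path.name.lower()
        for kind in TABLE_KINDS:
            if stem.startswith(kind.lower()):
                found[kind].append(path)
    return found


def load_quarters(quarters_dir: str | Path) -> tuple[dict[str, pd.DataFrame], list[Path]]:
    """Read and concatenate every quarterly file under ``quarters_dir``.

    Files are matched by name prefix (demo*, drug*, ...; case-insensitive,
    ``.txt``).  Tables from different quarters are aligned on the union of
    their columns, absent fields padded as missing.
    """
    quarters_dir = Path(quarters_dir)
    files = _find_table_files(quarters_dir)
    missing = [k for k, v in files.items() if not v]
    if missing:
        raise PipelineError(
            "load", f"no files found for table(s) {', '.join(missing)} in {quarters_dir}"
        )
    tables: dict[str, pd.DataFrame] = {}
    all_files: list[Path] = []
    for kind in TABLE_KINDS:
        parts = []
        for path in files[kind]:
            parts.append(read_faers_table(path, kind).to_frame())
            all_files.append(path)
        df = pd.concat(parts, ignore_index=True) if len(parts) > 1 else parts[0]
        tables[kind] = df.fillna("")
    return tables, all_files


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Raises :class:`PipelineError` with the failing stage name on any
    fatal error; an empty cohort (no PS reports for the search terms) is
    reported as stage ``cohort``.
    """
    out_dir = Path(config.output_dir)
    tmp_dir = out_dir.parent / (out_dir.name + ".tmp")
    if tmp_dir.exists():
        shutil.rmtree(tmp_dir)
    tmp_dir.mkdir(parents=True)

    try:
        manifest = _run_into(config, tmp_dir)
    except Exception:
        shutil.rmtree(tmp_dir, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    tmp_dir.replace(out_dir)
    return manifest


def _run_into(config: PipelineConfig, out: Path) -> dict:
    tables, input_files = load_quarters(config.quarters_dir)
    log.info("stage=load demo_rows=%d", len(tables["DEMO"]))

    mapping: dict[str, str] = {}
    if config.meddra_map_path is not None:
        mapping = read_pt_soc_map(config.meddra_map_path)

    try:
        build: CohortBuild = build_cohort(tables, config.drug_terms)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("cohort", str(exc)) from exc
    log.info(
        "stage=cohort retained=%d matched=%d ps=%d",
        build.counts["deduplicated"],
        build.counts["matched"],
        build.counts["ps_filtered"],
    )
    if not build.cases:
        raise PipelineError("cohort", "no matching PS reports")

    cohort_frame(build.cases).to_csv(out / "cohort.csv", index=False)

    cp = cohort_pairs(build.cases)
    bp = background_pairs(tables["REAC"], build.retained_ids, build.ps_ids)

    screens = {}
    for level in config.levels:
        res = screen(
            cp,
            bp,
            pt_soc_map=mapping,
            level=level.upper(),
            soc_exclusions=config.soc_exclusions,
            priors=config.bcpnn_priors,
            haldane=config.zero_cell_correction,
        )
        screens[level.lower()] = res
        metrics_frame(res).to_csv(out / f"signals_{level.lower()}.csv", index=False)
        log.info(
            "stage=screen level=%s terms=%d all4=%d",
            level.lower(),
            len(res.metrics),
            res.venn["all4"],
        )
    venn = {lvl: res.venn for lvl, res in screens.items()}
    (out / "venn.json").write_text(json.dumps(venn, indent=1), encoding="utf-8")

    # Time to onset
    onsets, tally = compute_onsets(build.cases, tables["THER"])
    pd.DataFrame(
        {
            "primaryid": [o.primaryid for o in onsets],
            "onset_days": [o.onset_days for o in onsets],
        }
    ).to_csv(out / "tto.csv", index=False)
    log.info("stage=tto retained=%d excluded=%d", len(onsets), sum(tally.values()))

    weibull_row: dict[str, object] = {"cases": len(onsets)}
    if onsets:
        s = onset_summary(onsets)
        pd.DataFrame(
            [
                {"bin": label, "count": count, "percent": round(pct, 1)}
                for label, count, pct in s.bins
            ]
        ).to_csv(out / "onset_bins.csv", index=False)
        weibull_row.update(
            median=s.median, q1=s.q1, q3=s.q3, min=s.min, max=s.max
        )
    try:
        fit = fit_weibull(onsets)
        weibull_row.update(
            scale_alpha=fit.scale_alpha,
            scale_lo95=fit.scale_ci95[0],
            scale_hi95=fit.scale_ci95[1],
            shape_beta=fit.shape_beta,
            shape_lo95=fit.shape_ci95[0],
            shape_hi95=fit.shape_ci95[1],
            failure_type=fit.failure_type,
        )
    except ValueError as exc:
        weibull_row.update(failure_type="", note=str(exc))
        log.info("stage=tto weibull_skipped reason=%s", exc)
    pd.DataFrame([weibull_row]).to_csv(out / "weibull.csv", index=False)

    # Descriptive profile + subgroups
    profile_frame(profile(build.cases)).to_csv(out / "profile.csv", index=False)

    bg_attrs = _background_attrs(tables["DEMO"], build.retained_ids, build.ps_ids)
    specs = []
    if "sex" in config.subgroups:
        specs.extend(sex_subgroups())
    if "age" in config.subgroups:
        specs.extend(age_subgroups())
    for spec in specs:
        res = subgroup_screen(
            build.cases,
            bg_attrs,
            bp,
            spec,
            pt_soc_map=mapping,
            level="PT",
            soc_exclusions=config.soc_exclusions,
            priors=config.bcpnn_priors,
            haldane=config.zero_cell_correction,
        )
        metrics_frame(res).to_csv(out / f"{spec.name}_signals.csv", index=False)
        log.info("stage=subgroup name=%s terms=%d", spec.name, len(res.metrics))

    manifest = {
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in input_files},
        "config": _config_snapshot(config),
        "funnel": {
            "loaded": build.counts["loaded"],
            "deduplicated": build.counts["deduplicated"],
            "matched": build.counts["matched"],
            "ps_filtered": build.counts["ps_filtered"],
            "with_onset": len(onsets),
        },
        "tto_exclusions": tally,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def _background_attrs(
    demo: pd.DataFrame, retained_ids: set[str], cohort_ids: set[str]
) -> pd.DataFrame:
    from .cohort import normalize_age

    pid = demo["primaryid"].astype(str)
    keep = pid.isin(retained_ids) & ~pid.isin(cohort_ids)
    sub = demo.loc[keep, ["primaryid", "sex", "age", "age_cod"]].astype(str)
    sex = sub["sex"].str.strip().str.upper().map({"F": "female", "M": "male"}).fillna("unknown")
    ages = [
        normalize_age(a, c) for a, c in zip(sub["age"], sub["age_cod"])
    ]
    return pd.DataFrame(
        {"primaryid": sub["primaryid"].to_numpy(), "sex": sex.to_numpy(), "age_years": ages}
    )


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["quarters_dir"] = str(snap["quarters_dir"])
    snap["output_dir"] = str(snap["output_dir"])
    if snap["meddra_map_path"] is not None:
        snap["meddra_map_path"] = str(snap["meddra_map_path"])
    snap["soc_exclusions"] = list(snap["soc_exclusions"])
    snap["subgroups"] = list(snap["subgroups"])
    snap["levels"] = list(snap["levels"])
    return snap
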