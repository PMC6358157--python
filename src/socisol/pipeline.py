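"""End-to-end orchestration: validate -> score -> link -> filter ->
describe -> model -> report.

The report bundle is a directory of TSV tables (sample description,
FSA descriptives, prevalence tables, correlations, AOR tables), JSON fit
objects, and an explicit analytic-N accounting log (total sample,
post-small-FSA-filter, per-outcome complete cases).  Given a seed the
bundle is deterministic byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptives, geolink, glmm, io, scoring
from . import synthetic as synth

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "score_participants"]

log = logging.getLogger("socisol")

GROUPINGS = ("age_group", "sex", "marital_status", "living_alone",
             "education_binary", "income_band", "functional_binary", "urban_rural")
#: groupings definitionally entangled with the isolation index, omitted
#: from its prevalence tables
ISOLATION_EXCLUDED_GROUPINGS = ("marital_status", "living_alone")


@dataclass
class PipelineConfig:
    participants_path: str | None = None
    census_path: str | None = None
    synthetic: bool = True
    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    seed: int | None = None          # overrides sim.seed when set
    cutoff: int = 3                  # primary isolation cut-off
    sensitivity_cutoff: int | None = 2
    min_fsa_size: int = 10
    outcomes: tuple[str, ...] = ("isolated", "lonely")
    strata: tuple[str, ...] = ("total", "women", "men")
    n_nodes: int = 15
    fit_models: bool = True
    #: also refit the model sequence at the sensitivity cut-off
    sensitivity_models: bool = False
    out_dir: str = "socisol_out"


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from TOML (section [pipeline], [sim])."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_kwargs = raw.get("sim", {})
    sim = synth.SimulationConfig(**sim_kwargs)
    pipe_kwargs = raw.get("pipeline", {})
    for key in ("outcomes", "strata"):
        if key in pipe_kwargs:
            pipe_kwargs[key] = tuple(pipe_kwargs[key])
    return PipelineConfig(sim=sim, **pipe_kwargs)


def score_participants(participants: pd.DataFrame, *, cutoff: int = 3,
                       sensitivity_cutoff: int | None = None) -> pd.DataFrame:
    """Attach derived outcomes and covariates to the raw participant table."""
    scored = participants.copy()
    idx = scoring.compute_isolation_index(participants)
    for col in idx.columns:
        scored[col] = idx[col]
    scored["isolated"] = scoring.classify_isolated(idx["index"], cutoff)
    if sensitivity_cutoff is not None:
        scored[f"isolated_c{sensitivity_cutoff}"] = scoring.classify_isolated(
            idx["index"], sensitivity_cutoff)
    scored["lonely"] = scoring.classify_lonely(participants["cesd_lonely"])
    cov = scoring.derive_covariates(participants)
    for col in cov.columns:
        if col not in scored.columns:
            scored[col] = cov[col]
    return scored


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _sample_description(records: pd.DataFrame) -> pd.DataFrame:
    """Weighted sample composition: share (in %) of each covariate level."""
    rows = []
    for g in GROUPINGS:
        col = records[g]
        levels = list(col.dtype.categories) if isinstance(col.dtype, pd.CategoricalDtype) \
            else sorted(col.dropna().unique(), key=str)
        for lev in levels:
            tmp = records.assign(_ind=(col == lev).astype(float))
            tab = descriptives.weighted_prevalence(tmp, "_ind")
            rows.append({"grouping": g, "level": str(lev),
                         "weighted_pct": tab.at[0, "weighted_pct"],
                         "se_pct": tab.at[0, "se_pct"],
                         "unweighted_n": int((col == lev).sum())})
    w = records["weight"].to_numpy(dtype=float)
    cc = records["chronic_count"].to_numpy(dtype=float)
    mean = float((w * cc).sum() / w.sum())
    se = float(np.sqrt(((w * (cc - mean)) ** 2).sum()) / w.sum())
    rows.append({"grouping": "chronic_count", "level": "mean",
                 "weighted_pct": mean, "se_pct": se, "unweighted_n": len(records)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns a dict with the analytic records, fits, accounting and the
    list of files written.  Any stage failure raises with a stage-named
    message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    accounting: dict = {}

    def emit(df, name):
        path = out_dir / name
        _write_tsv(df, path)
        files.append(name)

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.synthetic:
            sim = config.sim
            if config.seed is not None:
                sim = replace(sim, seed=int(config.seed))
            participants, census, truth = synth.generate_tables(sim)
            io.write_participants(participants, out_dir / "participants.csv")
            io.write_census(census, out_dir / "census.csv")
            _json_dump(truth, out_dir / "truth.json")
            files += ["participants.csv", "census.csv", "truth.json"]
        else:
            if not (config.participants_path and config.census_path):
                raise ValueError("participants_path and census_path required "
                                 "when synthetic=False")
            participants = io.read_participants(config.participants_path)
            census = io.read_census(config.census_path)
    except Exception as exc:
        raise RuntimeError(f"[stage: inputs] {exc}") from exc

    # ---- stage: validate + score --------------------------------------
    try:
        scoring.validate_participants(participants, strict=True)
        scored = score_participants(participants, cutoff=config.cutoff,
                                    sensitivity_cutoff=config.sensitivity_cutoff)
    except Exception as exc:
        raise RuntimeError(f"[stage: score] {exc}") from exc

    # ---- stage: link + filter -----------------------------------------
    try:
        linked, link_report = geolink.link_fsa(scored, census)
        records, link_report = geolink.filter_small_fsas(
            linked, config.min_fsa_size, report=link_report)
    except Exception as exc:
        raise RuntimeError(f"[stage: geolink] {exc}") from exc

    accounting["n_total"] = int(len(participants))
    accounting["n_unmatched_fsa"] = link_report.n_unmatched
    accounting["n_small_fsas_dropped"] = link_report.n_fsas_dropped
    accounting["n_dropped_small_fsa"] = link_report.n_participants_dropped
    accounting["n_analytic"] = int(len(records))
    accounting["n_fsas_analytic"] = int(records["fsa_code"].nunique())
    for outcome in ("isolated", "lonely"):
        accounting[f"n_{outcome}_nonmissing"] = int(records[outcome].notna().sum())
    log.info("analytic sample: %(n_analytic)d participants in %(n_fsas_analytic)d FSAs",
             accounting)

    # ---- stage: descriptives ------------------------------------------
    try:
        emit(_sample_description(records), "sample_description.tsv")
        retained = census[census["fsa_code"].isin(records["fsa_code"].unique())]
        emit(geolink.fsa_descriptives(retained), "fsa_descriptives.tsv")

        outcome_cols = {"isolated": "isolated", "lonely": "lonely"}
        if config.sensitivity_cutoff is not None:
            outcome_cols[f"isolated_c{config.sensitivity_cutoff}"] = \
                f"isolated_c{config.sensitivity_cutoff}"
        prev_frames = {}
        for name, col in outcome_cols.items():
            frames = []
            for stratum in config.strata:
                frames.append(descriptives.weighted_prevalence(
                    records, col, stratum=stratum))
                for g in GROUPINGS:
                    if name.startswith("isolated") and g in ISOLATION_EXCLUDED_GROUPINGS:
                        continue
                    if g == "sex" and stratum != "total":
                        continue
                    frames.append(descriptives.weighted_prevalence(
                        records, col, by=g, stratum=stratum))
            prev_frames[name] = pd.concat(frames, ignore_index=True)
            emit(prev_frames[name], f"prevalence_{name}.tsv")

        corr = descriptives.fsa_outcome_correlations(
            records, list(geolink.CENSUS_MEASURES), list(outcome_cols.values()),
            exclude={c: ["pct_living_alone"] for c in outcome_cols.values()
                     if c.startswith("isolated")},
        )
        emit(corr, "correlations.tsv")
    except Exception as exc:
        raise RuntimeError(f"[stage: descriptives] {exc}") from exc

    # ---- stage: models -------------------------------------------------
    fits_all: dict[str, dict] = {}
    if config.fit_models:
        try:
            model_outcomes = list(config.outcomes)
            for outcome in model_outcomes:
                fits = glmm.run_model_sequence(records, outcome,
                                               n_nodes=config.n_nodes,
                                               strata=config.strata)
                fits_all[outcome] = fits
                emit(glmm.sequence_table(fits), f"aor_{outcome}.tsv")
                _json_dump({f"{m}_{s}": fit.as_dict()
                            for (m, s), fit in fits.items()},
                           out_dir / f"fits_{outcome}.json")
                files.append(f"fits_{outcome}.json")
                for (m, s), fit in fits.items():
                    accounting[f"n_model_{outcome}_{m}_{s}"] = fit.n_used
                    if not fit.converged:
                        log.warning("non-convergence: %s %s %s", outcome, m, s)
            if config.sensitivity_models and config.sensitivity_cutoff is not None:
                col = f"isolated_c{config.sensitivity_cutoff}"
                rec2 = records.rename(columns={"isolated": "_primary",
                                               col: "isolated"})
                fits = glmm.run_model_sequence(rec2, "isolated",
                                               n_nodes=config.n_nodes,
                                               strata=config.strata)
                fits_all[col] = fits
                emit(glmm.sequence_table(fits), f"aor_{col}.tsv")
                _json_dump({f"{m}_{s}": fit.as_dict()
                            for (m, s), fit in fits.items()},
                           out_dir / f"fits_{col}.json")
                files.append(f"fits_{col}.json")
        except Exception as exc:
            raise RuntimeError(f"[stage: models] {exc}") from exc

    _json_dump(accounting, out_dir / "accounting.json")
    files.append("accounting.json")
    _json_dump({"files": sorted(files)}, out_dir / "manifest.json")
    files.append("manifest.json")

    return {"records": records, "fits": fits_all, "accounting": accounting,
            "files": sorted(files), "out_dir": str(out_dir)}
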