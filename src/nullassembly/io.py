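"""Readers, writers, configuration, and report assembly.

Matrices and tables travel as RFC-4180-style CSV (tab accepted via the
``delimiter`` argument).  A presence-absence file has site labels in the
header row and species labels in the first column; a missing cell is an
error, never an implicit 0 — absence is data here.  All labels are
case-sensitive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cooccurrence import CooccurrenceSummary, PairResult
from .datatypes import (
    BodyMassTable,
    GuildTable,
    IslandAttributes,
    PresenceAbsenceMatrix,
    QuadratCounts,
    ValidationError,
)
from .sad import SADFit
from .size_structure import CorrelationReport, VRatioResult

log = logging.getLogger("nullassembly")


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-wide thresholds and randomization settings."""

    alpha: float = 0.05
    random_band: float = 0.1
    min_expected: float = 1.0
    n_iter: int = 1000
    n_hypothetical: int = 5
    vratio_ddof: int = 1
    seed: int = 0


def read_config(path: str | Path) -> AnalysisConfig:
    """YAML (or JSON, a YAML subset) config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(allowed)}")
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# presence-absence matrices


def read_presence_absence(
    path: str | Path, delimiter: str = ","
) -> PresenceAbsenceMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    species = [str(s) for s in df.index]
    sites = [str(s) for s in df.columns]
    cells = np.zeros((len(species), len(sites)), dtype=np.int8)
    for i, sp in enumerate(species):
        for j, site in enumerate(sites):
            raw = df.iat[i, j].strip()
            if raw not in ("0", "1"):
                raise ValidationError(
                    f"non-binary cell at species {sp!r}, site {site!r}: {raw!r}"
                )
            cells[i, j] = int(raw)
    matrix = PresenceAbsenceMatrix(
        species_labels=tuple(species), site_labels=tuple(sites), cells=cells
    )
    log.info(
        "read presence-absence %s: %d species x %d sites",
        path, matrix.n_species, matrix.n_sites,
    )
    return matrix


def write_presence_absence(
    matrix: PresenceAbsenceMatrix, path: str | Path, delimiter: str = ","
) -> None:
    df = pd.DataFrame(
        matrix.cells, index=list(matrix.species_labels), columns=list(matrix.site_labels)
    )
    df.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# trait / attribute tables


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_guild_table(path: str | Path, delimiter: str = ",") -> GuildTable:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ("species", "habitat", "activity"), path)
    return GuildTable(
        species=tuple(df["species"].astype(str)),
        habitat=tuple(df["habitat"].astype(str)),
        activity=tuple(df["activity"].astype(str)),
    )


def read_body_mass(path: str | Path, delimiter: str = ",") -> BodyMassTable:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ("species", "mass"), path)
    return BodyMassTable(
        species=tuple(df["species"].astype(str)),
        mass=tuple(df["mass"].astype(float)),
    )


def read_island_attributes(path: str | Path, delimiter: str = ",") -> IslandAttributes:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ("island", "area", "richness"), path)
    return IslandAttributes(
        island=tuple(df["island"].astype(str)),
        area=tuple(df["area"].astype(float)),
        richness=tuple(df["richness"].astype(int)),
    )


def read_quadrat_counts(path: str | Path, delimiter: str = ",") -> QuadratCounts:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ("community", "quadrat", "species", "count"), path)
    return QuadratCounts(
        community=tuple(df["community"].astype(str)),
        quadrat=tuple(df["quadrat"].astype(str)),
        species=tuple(df["species"].astype(str)),
        count=tuple(df["count"].astype(int)),
    )


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# result frames and report assembly


def pair_results_frame(results: Iterable[PairResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def summary_frame(summaries: Mapping[str, CooccurrenceSummary]) -> pd.DataFrame:
    """One row per analysis, column layout of a co-occurrence summary table."""
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "analysis": name,
                "species": s.n_species,
                "sites": s.n_sites,
                "pairs_total": s.n_pairs_total,
                "removed": s.n_removed,
                "positive": s.n_positive,
                "negative": s.n_negative,
                "random": s.n_random,
                "unclassifiable": s.n_unclassifiable,
            }
        )
    return pd.DataFrame(rows)


def sad_ranking_frame(fits: Sequence[SADFit]) -> pd.DataFrame:
    """Model-selection table: one row per model, ascending AIC."""
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model,
                "fixed": "; ".join(f"{k}={v:g}" for k, v in f.fixed.items()) or "None",
                "coefficients": "; ".join(
                    f"{k}={v:.4g} (±{se:.3g})" for k, (v, se) in f.estimates.items()
                ),
                "loglik": f.loglik,
                "df": f.df,
                "aic": f.aic,
                "delta_aic": f.delta_aic,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


def vratio_frame(results: Sequence[VRatioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "community": r.community,
                "richness": r.richness,
                "observed_v": r.observed_v,
                "null_mean": r.null_mean,
                "null_var": r.null_var,
                "p_lower": r.p_lower,
                "p_upper": r.p_upper,
                "ses": r.ses,
                "n_iter": r.n_iter,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def write_report(
    out_dir: str | Path,
    *,
    config: AnalysisConfig,
    pair_results: Mapping[str, Sequence[PairResult]] | None = None,
    summaries: Mapping[str, CooccurrenceSummary] | None = None,
    sad_rankings: Mapping[str, Sequence[SADFit]] | None = None,
    vratio_results: Sequence[VRatioResult] | None = None,
    correlation: CorrelationReport | None = None,
    extra_metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write delimited result tables plus a run-metadata block.

    Returns the mapping of logical names to written paths.  At least one
    stage result must be present.
    """
    if not any((pair_results, summaries, sad_rankings, vratio_results, correlation)):
        raise ValueError("no stage results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if pair_results:
        for name, res in pair_results.items():
            p = out / f"pairs_{name}.csv"
            write_table(pair_results_frame(res), p)
            written[f"pairs_{name}"] = p
    if summaries:
        p = out / "cooccurrence_summary.csv"
        write_table(summary_frame(summaries), p)
        written["cooccurrence_summary"] = p
    if sad_rankings:
        for name, fits in sad_rankings.items():
            p = out / f"sad_ranking_{name}.csv"
            write_table(sad_ranking_frame(fits), p)
            written[f"sad_ranking_{name}"] = p
    if vratio_results:
        p = out / "vratio.csv"
        write_table(vratio_frame(vratio_results), p)
        written["vratio"] = p
    if correlation:
        p = out / "richness_vratio_correlation.csv"
        write_table(pd.DataFrame([asdict(correlation)]), p)
        written["correlation"] = p

    meta = {"config": asdict(config)}
    if extra_metadata:
        meta.update({k: v for k, v in extra_metadata.items()})
    p = out / "run_metadata.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(meta)), fh, sort_keys=False)
    written["metadata"] = p
    return written
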