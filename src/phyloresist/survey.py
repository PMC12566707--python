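"""Stratified vegetation-survey data model and species importance values.

A plot survey records, separately for the tree, shrub and herb layers, each
species' abundance (individuals or ramets), its dominance (basal area for
trees, percent cover for the understory) and in how many nested subplots it
occurred.  The importance value (IV) of a species in a plot layer is the mean
of its relative density, relative dominance and relative frequency, each
expressed in percent, so the IVs of one layer always sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import FormatError, ValidationError

LAYERS = ("tree", "shrub", "herb")
STAGES = ("BF", "LM", "HM", "MB")
#: gradient order of the four expansion stages: bamboo-free, low mixture,
#: high mixture, monoculture
STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}

SURVEY_COLUMNS = (
    "plot_id",
    "stage",
    "layer",
    "species",
    "count",
    "dominance",
    "subplot_hits",
    "n_subplots",
)
COVARIATE_COLUMNS = ("plot_id", "cover", "pH", "TOC", "TN", "TP")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' observation in one layer of one plot.

    ``dominance`` is basal area (cm^2) in the tree layer and percent cover in
    the shrub and herb layers; ``subplot_hits`` counts the nested subplots or
    quadrats in which the species occurred, out of ``n_subplots`` surveyed.
    """

    species: str
    layer: str
    count: int
    dominance: float
    subplot_hits: int
    n_subplots: int

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.count < 1:
            raise ValidationError(f"{self.species}: count must be >= 1, got {self.count}")
        if self.dominance < 0:
            raise ValidationError(f"{self.species}: dominance must be >= 0")
        if self.n_subplots < 1:
            raise ValidationError(f"{self.species}: n_subplots must be >= 1")
        if not 0 <= self.subplot_hits <= self.n_subplots:
            raise ValidationError(
                f"{self.species}: subplot_hits {self.subplot_hits} outside "
                f"[0, {self.n_subplots}]"
            )

    @property
    def frequency(self) -> float:
        """Fraction of subplots occupied (tree layer: plot-level presence)."""
        if self.layer == "tree":
            return 1.0
        return self.subplot_hits / self.n_subplots


@dataclass
class PlotSurvey:
    """All records of one plot plus its covariates."""

    plot_id: str
    stage: str
    invader_cover: float
    soil: dict = field(default_factory=dict)
    records: list = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not 0.0 <= self.invader_cover <= 1.0:
            raise ValidationError(
                f"plot {self.plot_id}: invader_cover {self.invader_cover} outside [0, 1]"
            )
        for v in self.soil.values():
            if v is None or pd.isna(v):
                raise ValidationError(f"plot {self.plot_id}: non-finite covariate")
        seen = set()
        for r in self.records:
            key = (r.species, r.layer)
            if key in seen:
                raise ValidationError(
                    f"plot {self.plot_id}: duplicate record for {key[0]!r} in {key[1]} layer"
                )
            seen.add(key)

    def layer_records(self, layer: str) -> list:
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer {layer!r}")
        return [r for r in self.records if r.layer == layer]

    def species(self, layer: str | None = None) -> list[str]:
        recs = self.records if layer is None else self.layer_records(layer)
        return sorted({r.species for r in recs})


@dataclass(frozen=True)
class ImportanceValue:
    species: str
    layer: str
    plot_id: str
    rel_density: float
    rel_dominance: float
    rel_frequency: float
    iv: float


def read_survey(path, covariates_path=None) -> list[PlotSurvey]:
    """Read a tidy survey table (CSV or TSV) into one :class:`PlotSurvey` per plot.

    Parameters
    ----------
    path
        Delimited text file with columns ``plot_id, stage, layer, species,
        count, dominance, subplot_hits, n_subplots``.
    covariates_path
        Optional CSV keyed by ``plot_id`` with columns ``cover, pH, TOC, TN,
        TP``.  Without it, cover defaults from the stage label midpoints and
        soil is left empty.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    dup = df.duplicated(subset=["plot_id", "layer", "species"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate row for plot {row['plot_id']!r}, layer {row['layer']!r}, "
            f"species {row['species']!r}"
        )
    if (df["count"] < 0).any() or (df["dominance"] < 0).any():
        raise ValidationError("negative count or dominance in survey table")

    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
        if missing:
            raise FormatError(
                f"{covariates_path}: missing required column(s) {', '.join(missing)}"
            )
        cov = cov.set_index("plot_id")

    stage_default_cover = {"BF": 0.0, "LM": 0.30, "HM": 0.70, "MB": 1.0}
    surveys = []
    for plot_id, grp in df.groupby("plot_id", sort=True):
        stage = str(grp["stage"].iloc[0])
        if (grp["stage"] != stage).any():
            raise ValidationError(f"plot {plot_id!r}: inconsistent stage labels")
        if stage not in STAGES:
            raise ValidationError(f"plot {plot_id!r}: unknown stage {stage!r}")
        if cov is not None:
            if plot_id not in cov.index:
                raise ValidationError(f"plot {plot_id!r} missing from covariate table")
            row = cov.loc[plot_id]
            cover = float(row["cover"])
            soil = {k: float(row[k]) for k in ("pH", "TOC", "TN", "TP")}
        else:
            cover = stage_default_cover[stage]
            soil = {}
        records = [
            SpeciesRecord(
                species=str(r.species),
                layer=str(r.layer),
                count=int(r.count),
                dominance=float(r.dominance),
                subplot_hits=int(r.subplot_hits),
                n_subplots=int(r.n_subplots),
            )
            for r in grp.sort_values(["layer", "species"]).itertuples()
        ]
        surveys.append(
            PlotSurvey(
                plot_id=str(plot_id), stage=stage, invader_cover=cover,
                soil=soil, records=records,
            )
        )
    surveys.sort(key=lambda s: (STAGE_ORDER[s.stage], s.plot_id))
    return surveys


def write_survey(surveys: Sequence[PlotSurvey], path, covariates_path=None) -> None:
    """Write surveys back to the tidy CSV (and optionally the covariate CSV)."""
    rows = [
        {
            "plot_id": s.plot_id,
            "stage": s.stage,
            "layer": r.layer,
            "species": r.species,
            "count": r.count,
            "dominance": r.dominance,
            "subplot_hits": r.subplot_hits,
            "n_subplots": r.n_subplots,
        }
        for s in surveys
        for r in s.records
    ]
    pd.DataFrame(rows, columns=list(SURVEY_COLUMNS)).to_csv(path, index=False)
    if covariates_path is not None:
        cov_rows = [
            {"plot_id": s.plot_id, "cover": s.invader_cover, **s.soil} for s in surveys
        ]
        pd.DataFrame(cov_rows, columns=list(COVARIATE_COLUMNS)).to_csv(
            covariates_path, index=False
        )


def importance_values(plot: PlotSurvey, layer: str) -> list[ImportanceValue]:
    """Per-species importance values for one layer of one plot.

    IV = (relative density + relative dominance + relative frequency) / 3,
    each component in percent.  Relative frequency divides each species'
    subplot occupancy fraction by the sum of those fractions over species; in
    the tree layer, surveyed at whole-plot grain, every species present has
    frequency 1 so the component reduces to 100/S.
    """
    records = sorted(plot.layer_records(layer), key=lambda r: r.species)
    if not records:
        return []
    total_n = sum(r.count for r in records)
    total_dom = sum(r.dominance for r in records)
    total_freq = sum(r.frequency for r in records)
    if total_dom <= 0:
        raise ValidationError(
            f"plot {plot.plot_id}, {layer} layer: zero total dominance with "
            f"{total_n} individuals (degenerate survey)"
        )
    if total_freq <= 0:
        raise ValidationError(
            f"plot {plot.plot_id}, {layer} layer: zero total frequency"
        )
    out = []
    for r in records:
        rd = 100.0 * r.count / total_n
        rdom = 100.0 * r.dominance / total_dom
        rf = 100.0 * r.frequency / total_freq
        out.append(
            ImportanceValue(
                species=r.species,
                layer=layer,
                plot_id=plot.plot_id,
                rel_density=rd,
                rel_dominance=rdom,
                rel_frequency=rf,
                iv=(rd + rdom + rf) / 3.0,
            )
        )
    return out


def iv_table(surveys: Sequence[PlotSurvey], layer: str) -> pd.DataFrame:
    """Plots x species matrix of IV (percent) for one layer; absent -> 0."""
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}")
    data = {}
    for s in surveys:
        data[s.plot_id] = {v.species: v.iv for v in importance_values(s, layer)}
    df = pd.DataFrame.from_dict(data, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "plot_id"
    return df


def stage_mean_iv(surveys: Sequence[PlotSurvey], layer: str) -> pd.DataFrame:
    """Species x stage table of mean IV, absences counted as IV = 0.

    Rows are ordered by descending overall mean IV, ties broken
    alphabetically; columns follow the gradient order BF, LM, HM, MB.
    """
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}")
    per_plot = iv_table(surveys, layer)
    stages = pd.Series({s.plot_id: s.stage for s in surveys})
    means = per_plot.groupby(stages).mean().T  # species x stage
    cols = [s for s in STAGES if s in means.columns]
    means = means[cols]
    overall = means.mean(axis=1)
    order = sorted(means.index, key=lambda sp: (-overall[sp], sp))
    means = means.loc[order]
    means.index.name = "species"
    return means


def community_matrix(
    surveys: Sequence[PlotSurvey], layer: str, value: str = "count"
) -> pd.DataFrame:
    """Plots x species abundance (or IV) matrix for one layer.

    ``value``: ``"count"`` uses raw abundances, ``"iv"`` importance values.
    """
    if value == "iv":
        return iv_table(surveys, layer)
    if value != "count":
        raise ValidationError(f"unknown value kind {value!r}; use 'count' or 'iv'")
    data = {
        s.plot_id: {r.species: r.count for r in s.layer_records(layer)} for s in surveys
    }
    df = pd.DataFrame.from_dict(data, orient="index").fillna(0).astype(int)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "plot_id"
    return df


def iv_dataframe(surveys: Sequence[PlotSurvey]) -> pd.DataFrame:
    """Tidy dataframe of all importance values across plots and layers."""
    rows = []
    for s in surveys:
        for layer in LAYERS:
            for v in importance_values(s, layer) if s.layer_records(layer) else []:
                rows.append(
                    {
                        "plot_id": v.plot_id,
                        "stage": s.stage,
                        "layer": v.layer,
                        "species": v.species,
                        "rel_density": v.rel_density,
                        "rel_dominance": v.rel_dominance,
                        "rel_frequency": v.rel_frequency,
                        "iv": v.iv,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "stage", "layer", "species",
            "rel_density", "rel_dominance", "rel_frequency", "iv",
        ],
    )
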