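"""Phylogenetically weighted species Resistance Index (RI).

For each species i occurring in at least 3 of the 4 expansion stages, the
Theil-Sen slope beta_i of its importance value against invader cover (scaled
0-1, with IV = 0 in plots where the species is absent) is divided by its
patristic distance D_i to the focal invader:

    RI_i = beta_i / D_i

Raw RI values are z-standardized within each layer (sample sd, ddof = 1) and
classified: Resistant if the z-score is >= +1, Susceptible if <= -1, Neutral
otherwise.  Dividing by D_i encodes the expectation that a decline of equal
magnitude signals stronger displacement in a close relative of the invader
than in a distant one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .survey import LAYERS, STAGES, PlotSurvey, iv_table, stage_mean_iv
from .tree import Phylogeny
from .trends import theil_sen

RESISTANT, NEUTRAL, SUSCEPTIBLE = "Resistant", "Neutral", "Susceptible"


@dataclass(frozen=True)
class ResistanceRecord:
    """Per-species RI result (one layer)."""

    species: str
    layer: str
    beta: float
    dist_to_invader: float
    ri_raw: float
    ri_z: float = float("nan")
    klass: str = NEUTRAL
    n_stages_present: int = 0
    degenerate: bool = False


def stage_filter(stage_mean_ivs: Mapping[str, float] | Sequence[float]) -> bool:
    """True iff the species' mean IV is positive in at least 3 of the 4 stages."""
    if isinstance(stage_mean_ivs, Mapping):
        vals = [stage_mean_ivs[s] for s in STAGES]
    else:
        vals = list(stage_mean_ivs)
    if len(vals) != len(STAGES):
        raise ValidationError(f"need one mean IV per stage ({len(STAGES)})")
    return sum(v > 0 for v in vals) >= 3


def species_beta(iv_by_plot: Sequence[float], cover: Sequence[float]) -> float:
    """Theil-Sen slope of a species' IV against invader cover over all plots.

    ``iv_by_plot`` must already contain 0 for plots where the species is
    absent — monotone disappearance then yields a negative slope.
    """
    return theil_sen(cover, iv_by_plot).slope


def resistance_index(beta: float, dist: float) -> float:
    """RI = beta / distance-to-invader; requires a strictly positive distance."""
    if not dist > 0:
        raise ValidationError(
            f"distance to invader must be > 0, got {dist!r} "
            "(the invader itself is excluded from RI)"
        )
    return beta / dist


def standardize_and_classify(
    records: Sequence[ResistanceRecord], ddof: int = 1
) -> list[ResistanceRecord]:
    """Within-layer z-standardization of raw RI and the +/-1 classification.

    A layer whose raw RI values have zero spread (or a single species) has no
    meaningful z-scale: all its records come back Neutral with
    ``degenerate=True``.
    """
    out: list[ResistanceRecord] = []
    for layer in sorted({r.layer for r in records}):
        layer_recs = [r for r in records if r.layer == layer]
        ri = np.array([r.ri_raw for r in layer_recs], dtype=float)
        sd = ri.std(ddof=ddof) if ri.size > ddof else 0.0
        if not np.isfinite(sd) or sd <= 0:
            out.extend(
                replace(r, ri_z=0.0, klass=NEUTRAL, degenerate=True) for r in layer_recs
            )
            continue
        mean = ri.mean()
        for r in layer_recs:
            z = (r.ri_raw - mean) / sd
            klass = RESISTANT if z >= 1.0 else SUSCEPTIBLE if z <= -1.0 else NEUTRAL
            out.append(replace(r, ri_z=float(z), klass=klass))
    return out


class ResistanceModel:
    """Resistance-index analysis of a survey set against a phylogeny.

    Parameters
    ----------
    surveys
        The plot surveys (all stages).
    tree
        Rooted phylogeny whose tips cover the surveyed species and the
        invader.
    invader
        Tip label of the focal invader.
    layers
        Layers to analyse (default: all three).
    use_stage_means
        If True, slopes are fitted to the 4 stage-mean points instead of all
        plots (sensitivity analysis); default False fits across all plots.
    """

    def __init__(
        self,
        surveys: Sequence[PlotSurvey],
        tree: Phylogeny,
        invader: str,
        layers: Sequence[str] = LAYERS,
        ddof: int = 1,
        use_stage_means: bool = False,
        prune_missing: bool = False,
    ):
        if invader not in tree.tips:
            raise ValidationError(f"invader {invader!r} is not a tip of the tree")
        self.surveys = list(surveys)
        self.tree = tree
        self.invader = invader
        self.layers = list(layers)
        self.ddof = ddof
        self.use_stage_means = use_stage_means
        self.prune_missing = prune_missing

    def fit(self) -> "ResistanceResults":
        records: list[ResistanceRecord] = []
        skipped: list[dict] = []
        cover = np.array([s.invader_cover for s in self.surveys], dtype=float)
        stage_of = {s.plot_id: s.stage for s in self.surveys}
        for layer in self.layers:
            ivs = iv_table(self.surveys, layer)
            means = stage_mean_iv(self.surveys, layer)
            for species in ivs.columns:
                if species == self.invader:
                    skipped.append(
                        {"species": species, "layer": layer, "reason": "focal invader"}
                    )
                    continue
                stage_means = {
                    s: (means.loc[species, s] if s in means.columns else 0.0)
                    for s in STAGES
                }
                n_present = sum(v > 0 for v in stage_means.values())
                if not stage_filter(stage_means):
                    skipped.append(
                        {
                            "species": species,
                            "layer": layer,
                            "reason": f"present in only {n_present} stage(s)",
                        }
                    )
                    continue
                if species not in self.tree.tips:
                    if self.prune_missing:
                        skipped.append(
                            {"species": species, "layer": layer, "reason": "not in tree (pruned)"}
                        )
                        continue
                    raise ValidationError(
                        f"species {species!r} missing from the tree "
                        "(pass prune_missing=True to drop it)"
                    )
                if self.use_stage_means:
                    stage_cover = (
                        pd.Series(cover, index=[s.plot_id for s in self.surveys])
                        .groupby(pd.Series(stage_of))
                        .mean()
                    )
                    x = stage_cover[list(STAGES)].to_numpy()
                    y = np.array([stage_means[s] for s in STAGES])
                else:
                    x = cover
                    y = ivs[species].to_numpy()
                beta = species_beta(y, x)
                dist = float(self.tree.distance_to(self.invader, [species]).iloc[0])
                records.append(
                    ResistanceRecord(
                        species=species,
                        layer=layer,
                        beta=beta,
                        dist_to_invader=dist,
                        ri_raw=resistance_index(beta, dist),
                        n_stages_present=n_present,
                    )
                )
        records = standardize_and_classify(records, ddof=self.ddof)
        return ResistanceResults(self, records, skipped)


class ResistanceResults:
    """Fitted per-species resistance records with export helpers."""

    def __init__(self, model: ResistanceModel, records, skipped):
        self.model = model
        self.records = records
        self.skipped = skipped

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "species": r.species,
                    "layer": r.layer,
                    "beta": r.beta,
                    "dist_to_invader": r.dist_to_invader,
                    "ri_raw": r.ri_raw,
                    "ri_z": r.ri_z,
                    "class": r.klass,
                    "n_stages_present": r.n_stages_present,
                }
                for r in self.records
            ]
        )
        if not df.empty:
            df = df.sort_values(["layer", "ri_z"], ascending=[True, False]).reset_index(
                drop=True
            )
        return df

    @property
    def metadata(self) -> dict:
        return {
            "invader": self.model.invader,
            "ddof": self.model.ddof,
            "stage_filter": "mean stage IV > 0 in >= 3 of 4 stages",
            "cover_scaling": "invader cover in [0, 1]",
            "slope_points": "stage means" if self.model.use_stage_means else "all plots",
            "n_species": len(self.records),
            "n_skipped": len(self.skipped),
        }

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Resistance Index results",
            f"  invader: {self.model.invader}",
            f"  species scored: {len(df)}  (skipped: {len(self.skipped)})",
        ]
        for layer in self.model.layers:
            sub = df[df["layer"] == layer]
            if sub.empty:
                continue
            counts = sub["class"].value_counts()
            lines.append(
                f"  {layer:>5}: {len(sub):3d} species | "
                f"Resistant {counts.get(RESISTANT, 0)}, "
                f"Neutral {counts.get(NEUTRAL, 0)}, "
                f"Susceptible {counts.get(SUSCEPTIBLE, 0)}"
            )
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            lines.append(df.round(4).to_string(index=False))
        return "\n".join(lines)
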