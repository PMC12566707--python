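"""End-to-end orchestration: generate/read -> IV -> diversity -> phylogenetic
structure -> trends -> resistance -> ordination, with a reproducible run
manifest.

Each stage writes its own file into the run directory and never rewrites an
upstream output.  The manifest records the configuration, seeds and output
checksums, and suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_profile
from .exceptions import ValidationError
from .ordination import RDA, variance_partition
from .resistance import ResistanceModel
from .structure import plot_seed, ses_structure
from .survey import (
    LAYERS,
    STAGES,
    PlotSurvey,
    community_matrix,
    iv_dataframe,
    read_survey,
    stage_mean_iv,
)
from .synthetic import INVADER, GeneratorConfig, generate_dataset
from .trends import bh_fdr, kruskal_dunn, mann_kendall
from .tree import Phylogeny, read_newick

log = logging.getLogger("phyloresist")

DIVERSITY_INDICES = ("richness", "margalef", "simpson", "shannon", "pielou")
PHYLO_INDICES = ("pd", "nri", "nti")


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run."""

    out_dir: str = "run"
    survey_path: str | None = None       #: tidy survey CSV (None -> synthetic)
    covariates_path: str | None = None
    tree_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    invader: str = INVADER
    seed: int = 20251021
    n_randomizations: int = 999
    pd_include_root: bool = True
    include_invader: bool = True  #: count the invader in its layer's diversity
    ri_ddof: int = 1
    ri_use_stage_means: bool = False
    rda_permutations: int = 999
    prune_missing: bool = False


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _layer_counts(survey: PlotSurvey, layer: str, invader: str, include_invader: bool):
    recs = survey.layer_records(layer)
    if not include_invader:
        recs = [r for r in recs if r.species != invader]
    return {r.species: r.count for r in recs}


def diversity_table(
    surveys: Sequence[PlotSurvey], invader: str = INVADER, include_invader: bool = True
) -> pd.DataFrame:
    """Per-(plot, layer) taxonomic alpha-diversity indices."""
    rows = []
    for s in surveys:
        for layer in LAYERS:
            counts = _layer_counts(s, layer, invader, include_invader)
            if not counts:
                continue
            prof = diversity_profile(list(counts.values()))
            rows.append(
                {"plot_id": s.plot_id, "stage": s.stage, "layer": layer,
                 "cover": s.invader_cover, **prof.as_dict()}
            )
    return pd.DataFrame(rows)


def phylo_table(
    surveys: Sequence[PlotSurvey],
    tree: Phylogeny,
    invader: str = INVADER,
    include_invader: bool = True,
    n_randomizations: int = 999,
    seed: int = 20251021,
    pd_include_root: bool = True,
    prune_missing: bool = False,
) -> pd.DataFrame:
    """Per-(plot, layer) PD, MPD/MNTD observations and NRI/NTI z-scores.

    The null pool of each layer is the set of species observed in that layer
    across all plots (the layer's community-matrix column set).
    """
    rows = []
    for layer in LAYERS:
        cm = community_matrix(surveys, layer)
        pool = [sp for sp in cm.columns if include_invader or sp != invader]
        missing = sorted(set(pool) - tree.tips)
        if missing:
            if not prune_missing:
                raise ValidationError(
                    f"{layer} layer species missing from tree: {', '.join(missing)}"
                )
            log.warning("%s layer: pruning %d species absent from tree", layer, len(missing))
            pool = [sp for sp in pool if sp not in missing]
        if not pool:
            log.warning("%s layer empty after pruning; stage skipped", layer)
            continue
        d = tree.patristic_distances(pool)
        stage_of = {s.plot_id: s.stage for s in surveys}
        cover_of = {s.plot_id: s.invader_cover for s in surveys}
        for plot_id, row in cm.iterrows():
            comm = [sp for sp in pool if row.get(sp, 0) > 0]
            if not comm:
                continue
            pd_val = tree.faith_pd(comm, include_root=pd_include_root)
            ses = ses_structure(
                d, comm, n_rand=n_randomizations, seed=plot_seed(seed, f"{plot_id}|{layer}")
            )
            rows.append(
                {
                    "plot_id": plot_id,
                    "stage": stage_of[plot_id],
                    "layer": layer,
                    "cover": cover_of[plot_id],
                    "richness": len(comm),
                    "pd": pd_val,
                    "mpd_obs": ses.mpd_obs,
                    "mntd_obs": ses.mntd_obs,
                    "nri": ses.nri,
                    "nti": ses.nti,
                    "n_randomizations": ses.n_randomizations,
                    "degenerate": ses.degenerate,
                }
            )
    return pd.DataFrame(rows)


def trend_table(metrics: pd.DataFrame, value_columns: Sequence[str]) -> pd.DataFrame:
    """Theil-Sen + Mann-Kendall of each index against cover, BH within layer."""
    rows = []
    for layer, sub in metrics.groupby("layer"):
        layer_rows = []
        for col in value_columns:
            if col not in sub.columns:
                continue
            res = mann_kendall(sub["cover"].to_numpy(), sub[col].to_numpy())
            layer_rows.append(
                {"layer": layer, "index": col, "slope": res.slope, "tau": res.tau,
                 "s_statistic": res.s_statistic, "p_value": res.p_value, "n": res.n}
            )
        padj = bh_fdr([r["p_value"] for r in layer_rows])
        for r, pa in zip(layer_rows, padj):
            r["p_adjusted"] = float(pa)
        rows.extend(layer_rows)
    return pd.DataFrame(rows)


def stage_comparison_table(metrics: pd.DataFrame, value_columns: Sequence[str]):
    """Kruskal-Wallis + Dunn(BH) per (layer, index); returns (kw, dunn) frames."""
    kw_rows, dunn_rows = [], []
    for layer, sub in metrics.groupby("layer"):
        for col in value_columns:
            if col not in sub.columns:
                continue
            groups = {
                s: sub.loc[sub["stage"] == s, col].to_numpy()
                for s in STAGES
                if (sub["stage"] == s).any()
            }
            if len(groups) < 2:
                continue
            res = kruskal_dunn(groups)
            kw_rows.append(
                {"layer": layer, "index": col, "kw_statistic": res.kw_statistic,
                 "kw_p": res.kw_p,
                 "letters": " ".join(f"{k}:{v}" for k, v in res.letters.items())}
            )
            for a, b, z, p, pa in res.pairwise:
                dunn_rows.append(
                    {"layer": layer, "index": col, "stage_a": a, "stage_b": b,
                     "z": z, "p": p, "p_adjusted": pa}
                )
    return pd.DataFrame(kw_rows), pd.DataFrame(dunn_rows)


def ordination_per_layer(
    metrics: pd.DataFrame,
    surveys: Sequence[PlotSurvey],
    n_permutations: int = 999,
    seed: int = 20251021,
) -> dict:
    """RDA (Shannon, PD, NTI ~ cover + soil) and VPA for each layer."""
    cov = pd.DataFrame(
        [
            {"plot_id": s.plot_id, "cover": s.invader_cover, **s.soil}
            for s in surveys
        ]
    ).set_index("plot_id")
    out = {}
    for layer, sub in metrics.groupby("layer"):
        sub = sub.set_index("plot_id")
        needed = ["shannon", "pd", "nti"]
        if not all(c in sub.columns for c in needed):
            continue
        common = [p for p in cov.index if p in sub.index]
        Y = sub.loc[common, needed]
        X = cov.loc[common, ["cover", "pH", "TOC", "TN", "TP"]]
        if Y[needed].std(ddof=1).min() == 0:
            log.warning("%s layer: constant response column; ordination skipped", layer)
            continue
        res = RDA(Y, X).fit(n_permutations=n_permutations, seed=seed)
        vpa = variance_partition(Y, X[["cover"]], X[["pH", "TOC", "TN", "TP"]])
        out[layer] = {
            "rda": res,
            "vpa": vpa,
        }
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write outputs plus a manifest; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    if config.survey_path is None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        surveys, tree, truth = generate_dataset(gen)
        truth.to_json(out / "truth.json")
        from .survey import write_survey

        write_survey(surveys, out / "survey.csv", out / "covariates.csv")
        tree.write_newick(out / "tree.nwk")
        log.info("generate: 16 synthetic plots written")
    else:
        surveys = read_survey(config.survey_path, config.covariates_path)
        if config.tree_path is None:
            raise ValidationError("tree_path required when reading a survey file")
        tree = read_newick(config.tree_path)

    observed = {r.species for s in surveys for r in s.records}
    missing = sorted(observed - tree.tips)
    if missing and not config.prune_missing:
        raise ValidationError(
            "species absent from tree: " + ", ".join(missing)
            + " (set prune_missing to drop them from phylogenetic metrics)"
        )

    ivs = iv_dataframe(surveys)
    ivs.to_csv(out / "importance_values.csv", index=False)
    for layer in LAYERS:
        stage_mean_iv(surveys, layer).to_csv(out / f"stage_mean_iv_{layer}.csv")

    div = diversity_table(surveys, config.invader, config.include_invader)
    div.to_csv(out / "diversity.csv", index=False)

    phylo = phylo_table(
        surveys, tree,
        invader=config.invader,
        include_invader=config.include_invader,
        n_randomizations=config.n_randomizations,
        seed=config.seed,
        pd_include_root=config.pd_include_root,
        prune_missing=config.prune_missing,
    )
    phylo.to_csv(out / "phylo_structure.csv", index=False)

    metrics = div.merge(
        phylo[["plot_id", "layer", "pd", "mpd_obs", "mntd_obs", "nri", "nti"]],
        on=["plot_id", "layer"],
        how="left",
    )
    all_indices = list(DIVERSITY_INDICES) + list(PHYLO_INDICES)
    trends = trend_table(metrics, all_indices)
    trends.to_csv(out / "trends.csv", index=False)
    kw, dunn = stage_comparison_table(metrics, all_indices)
    kw.to_csv(out / "kruskal.csv", index=False)
    dunn.to_csv(out / "dunn.csv", index=False)

    soil_metrics = pd.DataFrame(
        [
            {"plot_id": s.plot_id, "stage": s.stage, "layer": "soil",
             "cover": s.invader_cover, **s.soil}
            for s in surveys
        ]
    )
    trend_table(soil_metrics, ["pH", "TOC", "TN", "TP"]).to_csv(
        out / "soil_trends.csv", index=False
    )

    ri = ResistanceModel(
        surveys, tree, config.invader,
        ddof=config.ri_ddof,
        use_stage_means=config.ri_use_stage_means,
        prune_missing=config.prune_missing,
    ).fit()
    ri.frame.to_csv(out / "resistance.csv", index=False)
    (out / "resistance_meta.json").write_text(
        json.dumps({**ri.metadata, "seed": config.seed}, indent=1)
    )

    ords = ordination_per_layer(
        metrics, surveys, n_permutations=config.rda_permutations, seed=config.seed
    )
    ord_payload = {}
    vpa_rows = []
    for layer, d in ords.items():
        res = d["rda"]
        vpa = d["vpa"]
        ord_payload[layer] = {
            **res.as_dict(),
            "vpa": vpa.as_dict(),
            "vpa_clamped": vpa.clamped(),
            "vpa_of_explained": vpa.of_explained(),
        }
        vpa_rows.append({"layer": layer, **vpa.as_dict()})
        res.biplot_scores().to_csv(out / f"rda_biplot_{layer}.csv")
    (out / "ordination.json").write_text(json.dumps(ord_payload, indent=1))
    pd.DataFrame(vpa_rows).to_csv(out / "vpa.csv", index=False)

    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_randomizations": config.n_randomizations,
        "rda_permutations": config.rda_permutations,
        "pd_include_root": config.pd_include_root,
        "include_invader": config.include_invader,
        "ri_ddof": config.ri_ddof,
        "bh_scope": "within each (layer x index-family) test family",
        "generator": dataclasses.asdict(config.generator)
        if config.survey_path is None
        else None,
        "inputs": {
            "survey": config.survey_path,
            "covariates": config.covariates_path,
            "tree": config.tree_path,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for name, digest in manifest["outputs"].items():
        log.info("stage output %s sha256=%s", name, digest[:12])
    return out
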