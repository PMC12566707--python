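"""Synthetic invader-expansion gradient with known ground truth.

The generator emulates the sampling design the analysis assumes: 4 expansion
stages (bamboo-free BF, low-mixture LM, high-mixture HM, monoculture MB) x 4
replicate plots, an invader whose tree-layer stem share equals the plot's
cover value (stage means 0, 0.30, 0.70, 1.0 with jitter), three species
response archetypes (declining, flat, increasing IV vs. cover) in the
understory layers, soil covariates trending linearly with cover, and a
random ultrametric phylogeny on which the invader has both close and distant
relatives in every layer.

Every dataset is a deterministic function of (config, seed) and ships with a
:class:`SyntheticTruth` record of the latent targets, true slopes, distances
and intended resistance classes, so downstream estimators can be scored
against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .exceptions import ValidationError
from .survey import LAYERS, STAGES, PlotSurvey, SpeciesRecord, write_survey
from .tree import Phylogeny

INVADER = "Phyllostachys_edulis"


@dataclass
class GeneratorConfig:
    """Defaults mirror the field design the analysis expects.

    Stage cover means (0, 0.30, 0.70, 1.0) follow the BF/LM/HM/MB definition
    of expansion intensity; soil intercept/slope/sd triples reproduce the
    observed stage-mean trends (pH rising 4.39 -> 5.24, TOC and TN falling,
    TP flat); archetype slope magnitudes are 20 (decliners) and 15
    (increasers) IV-points per unit cover, with 3 decliners and 4 increasers
    per understory layer so the layer IV total stays exactly 100 at every
    cover.
    """

    seed: int = 20251021
    reps_per_stage: int = 4
    cover_means: tuple = (0.0, 0.30, 0.70, 1.0)
    cover_jitter_sd: float = 0.03
    species_per_layer: dict = field(
        default_factory=lambda: {"tree": 20, "shrub": 30, "herb": 30}
    )
    n_decliners: int = 3          #: understory decliners per layer
    n_increasers: int = 4         #: understory increasers per layer
    decliner_magnitude: float = 20.0   #: |beta| of decliners, IV-points per unit cover
    increaser_magnitude: float = 15.0  #: |beta| of increasers
    slope_heterogeneity: float = 0.25  #: +/- relative spread of per-species slopes
    iv_noise_sd: float = 1.0      #: sd of plot-level IV noise, IV points
    presence_min_iv: float = 0.05  #: noisy targets below this are treated as absent
    individuals_per_layer: dict = field(
        default_factory=lambda: {"tree": 120, "shrub": 240, "herb": 600}
    )
    subplots_per_layer: dict = field(
        default_factory=lambda: {"tree": 1, "shrub": 5, "herb": 25}
    )
    total_dominance: dict = field(
        default_factory=lambda: {"tree": 10000.0, "shrub": 120.0, "herb": 120.0}
    )
    soil_model: dict = field(
        default_factory=lambda: {
            "pH": (4.39, 0.85, 0.13),
            "TOC": (30.74, -13.67, 2.0),
            "TN": (2.13, -0.65, 0.18),
            "TP": (0.225, 0.0, 0.045),
        }
    )
    birth_rate: float = 1.0
    tree_depth: float = 200.0     #: root-to-tip depth of the ultrametric tree
    min_distance_spread: float = 4.0  #: required max/min distance-to-invader per layer

    def validate(self) -> None:
        if list(self.cover_means) != sorted(self.cover_means):
            raise ValidationError("cover means must be strictly increasing")
        if self.iv_noise_sd < 0 or self.cover_jitter_sd < 0:
            raise ValidationError("noise sds must be >= 0")
        for layer in LAYERS:
            if self.species_per_layer[layer] < 2:
                raise ValidationError("need >= 2 species per layer")
        for layer in ("shrub", "herb"):
            n_neutral = (
                self.species_per_layer[layer] - self.n_decliners - self.n_increasers
            )
            if n_neutral < 1:
                raise ValidationError("archetype counts exceed layer species count")
            if (
                self.n_decliners * self.decliner_magnitude
                + 0.0  # increasers contribute 0 at cover 0
                > 100.0
            ):
                raise ValidationError("decliner IV budget exceeds 100")
            if self.n_increasers * self.increaser_magnitude > 100.0:
                raise ValidationError("increaser IV budget exceeds 100")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    species: pd.DataFrame  #: layer, archetype, true_beta, dist_to_invader, true_ri, true_ri_z, true_class
    covers: dict           #: plot_id -> cover
    targets: dict          #: plot_id -> layer -> {species: latent target IV before noise}
    config: GeneratorConfig

    def to_json(self, path) -> None:
        payload = {
            "species": self.species.to_dict(orient="records"),
            "covers": self.covers,
            "targets": self.targets,
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _interleaved_layers(sizes: dict) -> list[str]:
    """Order layer slots so each layer samples the whole distance range."""
    slots = []
    for layer in LAYERS:
        n = sizes[layer]
        slots += [((i + 0.5) / n, layer) for i in range(n)]
    slots.sort(key=lambda t: t[0])
    return [layer for _, layer in slots]


def generate_tree(config: GeneratorConfig | None = None) -> Phylogeny:
    """Random ultrametric phylogeny over all species plus the invader.

    Tip names encode the layer (``tree_sp01`` ...); the invader is placed at
    the tip with the closest relative so that within-layer distances to it
    span at least :attr:`GeneratorConfig.min_distance_spread`-fold.
    """
    config = config or GeneratorConfig()
    config.validate()
    n_tips = sum(config.species_per_layer.values()) + 1
    for attempt in range(10):
        rnd = random.Random(int(config.seed) + 7919 * attempt)
        t = treesim.birth_death_tree(
            birth_rate=config.birth_rate,
            death_rate=0.0,
            num_extant_tips=n_tips,
            rng=rnd,
        )
        # the simulation stops at a speciation event, so the youngest pair has
        # zero-length pendant edges; extend all tips equally (stays ultrametric)
        depth = max(leaf.distance_from_root() for leaf in t.leaf_node_iter())
        for leaf in t.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + 0.01 * depth
        depth = max(leaf.distance_from_root() for leaf in t.leaf_node_iter())
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= config.tree_depth / depth
        phylo = Phylogeny(t)
        labels = sorted(phylo.tips)
        d = phylo.patristic_distances(labels)
        dm = d.to_numpy().copy()
        np.fill_diagonal(dm, np.inf)
        # candidate invaders ordered by decreasing nearest-relative distance:
        # the first that still yields the required within-layer spread keeps
        # RI denominators well away from zero
        nn = dm.min(axis=1)
        layer_seq = _interleaved_layers(config.species_per_layer)
        for cand in np.argsort(-nn):
            invader_old = labels[int(cand)]
            others = d.loc[invader_old].drop(invader_old).sort_values()
            per_layer_dists: dict[str, list] = {layer: [] for layer in LAYERS}
            assignment = {}
            counters = {layer: 0 for layer in LAYERS}
            for old, layer in zip(others.index, layer_seq):
                counters[layer] += 1
                assignment[old] = f"{layer}_sp{counters[layer]:02d}"
                per_layer_dists[layer].append(others[old])
            if all(
                max(v) / min(v) >= config.min_distance_spread
                for v in per_layer_dists.values()
            ):
                mapping = {invader_old: INVADER, **assignment}
                for leaf in t.leaf_node_iter():
                    leaf.taxon.label = mapping[leaf.taxon.label]
                return Phylogeny(t)
    raise ValidationError(
        "could not place the invader with the required distance spread"
    )  # pragma: no cover - retries virtually always suffice


def _split_weights(rng, n: int, heterogeneity: float) -> np.ndarray:
    """Per-species weights around 1 that sum exactly to n."""
    w = rng.uniform(1.0 - heterogeneity, 1.0 + heterogeneity, size=n)
    return w * n / w.sum()


def _assign_archetypes(rng, species: list[str], dists: np.ndarray, config) -> dict:
    """Stratify decliner/increaser assignment over distance-to-invader quartiles."""
    order = np.argsort(dists)
    quartiles = np.array_split(order, 4)
    roles = {}
    pool_d, pool_i = config.n_decliners, config.n_increasers
    # spread the strong archetypes one quartile at a time, shuffled
    slots = []
    for qi, q in enumerate(quartiles):
        slots.append(list(q))
    for role, count in (("decliner", pool_d), ("increaser", pool_i)):
        for k in range(count):
            q = slots[k % 4]
            if not q:
                q = max(slots, key=len)
            pick = q.pop(rng.integers(len(q)))
            roles[species[pick]] = role
    for sp in species:
        roles.setdefault(sp, "neutral")
    return roles


def _layer_targets(config, rng, layer: str, species: list[str], dists: np.ndarray):
    """Per-species latent IV target functions of cover; returns (roles, amps, base)."""
    if layer == "tree":
        # invader takes share = cover; all natives decline proportionally
        b = _split_weights(rng, len(species), config.slope_heterogeneity)
        b = b / b.sum()  # baseline shares at cover 0
        roles = {sp: "decliner" for sp in species}
        amps = {sp: 100.0 * b[i] for i, sp in enumerate(species)}
        return roles, amps
    roles = _assign_archetypes(rng, species, dists, config)
    decl = [sp for sp in species if roles[sp] == "decliner"]
    incr = [sp for sp in species if roles[sp] == "increaser"]
    neut = [sp for sp in species if roles[sp] == "neutral"]
    wd = _split_weights(rng, len(decl), config.slope_heterogeneity)
    wi = _split_weights(rng, len(incr), config.slope_heterogeneity)
    wn = _split_weights(rng, len(neut), config.slope_heterogeneity)
    budget_strong = config.n_decliners * config.decliner_magnitude
    neutral_total = 100.0 - budget_strong
    amps = {}
    for sp, w in zip(decl, wd):
        amps[sp] = config.decliner_magnitude * w
    for sp, w in zip(incr, wi):
        amps[sp] = config.increaser_magnitude * w
    for sp, w in zip(neut, wn):
        amps[sp] = neutral_total * w / len(neut)
    return roles, amps


def _target_iv(role: str, amp: float, cover: float, layer: str) -> float:
    if role == "decliner":
        return amp * (1.0 - cover)
    if role == "increaser":
        return amp * cover
    return amp  # neutral: flat


def _true_beta(role: str, amp: float, layer: str) -> float:
    if layer == "tree":
        # tree-layer IV = (2*share*100 + 100/S)/3 with share = (amp/100)(1-c),
        # so the IV slope against cover is -2*amp/3
        return -2.0 * amp / 3.0
    if role == "decliner":
        return -amp
    if role == "increaser":
        return amp
    return 0.0


def _tree_layer_iv_targets(shares: dict) -> dict:
    """IV targets implied by stem shares under plot-grain frequency.

    In the tree layer relative frequency is 100/S for every present species,
    so IV = (2 * share * 100 + 100/S)/3 when density and dominance both carry
    the stem share."""
    present = {sp: s for sp, s in shares.items() if s > 0}
    S = len(present)
    return {
        sp: ((200.0 * s + 100.0 / S) / 3.0 if s > 0 else 0.0)
        for sp, s in shares.items()
    }


def _backsolve_layer(rng, config, layer: str, shares: dict) -> list[SpeciesRecord]:
    """Construct integer counts/hits and continuous dominance realizing the shares.

    Counts and subplot hits are honest integers; the continuous dominance
    column absorbs their discretization so the realized IV matches the
    latent target wherever non-negativity allows.  In the understory
    ``shares`` are IV shares and rel_dom = 3*share - rel_density -
    rel_frequency; in the tree layer ``shares`` are stem shares, frequency
    is plot-grain presence, and rel_dom = 2*share - rel_density.
    """
    species = sorted(shares)
    s = np.array([shares[sp] for sp in species])
    s = s / s.sum()
    n_total = config.individuals_per_layer[layer]
    n_sub = config.subplots_per_layer[layer]
    counts = np.maximum(1, np.rint(s * n_total)).astype(int)
    rel_d = counts / counts.sum()
    if layer == "tree":
        hits = np.ones_like(counts)
        dom = np.maximum(0.0, 2.0 * s - rel_d)
    else:
        hits = np.clip(np.rint(n_sub * s / s.max()), 1, n_sub).astype(int)
        freq = hits / n_sub
        rel_f = freq / freq.sum()
        dom = np.maximum(0.0, 3.0 * s - rel_d - rel_f)
    if dom.sum() <= 0:
        dom = s.copy()
    dom = dom / dom.sum() * config.total_dominance[layer]
    return [
        SpeciesRecord(
            species=sp,
            layer=layer,
            count=int(c),
            dominance=float(dv),
            subplot_hits=int(h),
            n_subplots=int(n_sub),
        )
        for sp, c, dv, h in zip(species, counts, dom, hits)
    ]


def generate_surveys(
    config: GeneratorConfig | None = None, tree: Phylogeny | None = None
) -> tuple[list[PlotSurvey], SyntheticTruth]:
    """Generate the 16-plot gradient and its ground truth.

    The MB (monoculture) tree layer contains the invader only; understory
    layers carry the archetype mixture in every stage.
    """
    config = config or GeneratorConfig()
    config.validate()
    if tree is None:
        tree = generate_tree(config)
    rng = np.random.default_rng([int(config.seed), 11])

    layer_species = {
        layer: sorted(t for t in tree.tips if t.startswith(layer + "_sp"))
        for layer in LAYERS
    }
    for layer in LAYERS:
        if len(layer_species[layer]) != config.species_per_layer[layer]:
            raise ValidationError(
                f"tree tips do not match configured {layer}-layer species count"
            )
    dist = {
        layer: tree.distance_to(INVADER, layer_species[layer]) for layer in LAYERS
    }

    roles_all, amps_all = {}, {}
    for layer in LAYERS:
        roles, amps = _layer_targets(
            config, rng, layer, layer_species[layer], dist[layer].to_numpy()
        )
        roles_all[layer] = roles
        amps_all[layer] = amps

    covers = {}
    for si, stage in enumerate(STAGES):
        for rep in range(1, config.reps_per_stage + 1):
            c = rng.normal(config.cover_means[si], config.cover_jitter_sd)
            covers[f"{stage}{rep}"] = float(np.clip(c, 0.0, 1.0))

    surveys: list[PlotSurvey] = []
    targets_by_plot: dict = {}
    for plot_id, cover in covers.items():
        stage = plot_id[:2]
        soil = {}
        for key, (icpt, slope, sd) in config.soil_model.items():
            soil[key] = float(icpt + slope * cover + rng.normal(0.0, sd))
        records: list[SpeciesRecord] = []
        targets_by_plot[plot_id] = {}
        for layer in LAYERS:
            if layer == "tree":
                # latent stem shares: invader takes `cover`, natives split the rest
                shares = {
                    sp: (amps_all[layer][sp] / 100.0) * (1.0 - cover)
                    for sp in layer_species[layer]
                }
                if stage == "MB":
                    # complete canopy takeover at the terminal stage
                    shares = {sp: 0.0 for sp in shares}
                shares[INVADER] = cover
                targets = _tree_layer_iv_targets(shares)
            else:
                targets = {
                    sp: _target_iv(roles_all[layer][sp], amps_all[layer][sp], cover, layer)
                    for sp in layer_species[layer]
                }
            targets_by_plot[plot_id][layer] = dict(targets)
            noisy = {}
            for sp, t in targets.items():
                if t <= 0:
                    continue
                v = t + rng.normal(0.0, config.iv_noise_sd)
                if v >= config.presence_min_iv:
                    noisy[sp] = v
            if not noisy:
                # never expected: each layer always has positive targets
                raise ValidationError(f"empty {layer} layer in plot {plot_id}")
            if layer == "tree":
                # invert IV back to stem shares; presence implies
                # IV >= (100/S)/3 (the frequency floor), so sub-floor draws
                # stay present at a vanishing stem share and realize the
                # floor, as a lone stem of a rare canopy species would
                S = len(noisy)
                noisy = {
                    sp: max((3.0 * v - 100.0 / S) / 200.0, 1e-4)
                    for sp, v in noisy.items()
                }
            records.extend(_backsolve_layer(rng, config, layer, noisy))
        surveys.append(
            PlotSurvey(
                plot_id=plot_id, stage=stage, invader_cover=cover,
                soil=soil, records=records,
            )
        )

    rows = []
    for layer in LAYERS:
        ri_raw = {
            sp: _true_beta(roles_all[layer][sp], amps_all[layer][sp], layer)
            / float(dist[layer][sp])
            for sp in layer_species[layer]
        }
        vals = np.array(list(ri_raw.values()))
        mean, sd = vals.mean(), vals.std(ddof=1)
        for sp in layer_species[layer]:
            z = 0.0 if sd <= 0 else (ri_raw[sp] - mean) / sd
            klass = "Resistant" if z >= 1 else "Susceptible" if z <= -1 else "Neutral"
            rows.append(
                {
                    "species": sp,
                    "layer": layer,
                    "archetype": roles_all[layer][sp],
                    "true_beta": _true_beta(roles_all[layer][sp], amps_all[layer][sp], layer),
                    "dist_to_invader": float(dist[layer][sp]),
                    "true_ri": ri_raw[sp],
                    "true_ri_z": float(z),
                    "true_class": klass,
                }
            )
    truth = SyntheticTruth(
        species=pd.DataFrame(rows),
        covers=covers,
        targets=targets_by_plot,
        config=config,
    )
    return surveys, truth


def generate_dataset(config: GeneratorConfig | None = None):
    """Convenience: (surveys, tree, truth) for one config."""
    config = config or GeneratorConfig()
    tree = generate_tree(config)
    surveys, truth = generate_surveys(config, tree)
    return surveys, tree, truth


def write_dataset(out_dir, config: GeneratorConfig | None = None) -> dict:
    """Write survey CSV, covariate CSV, newick tree and truth JSON to a directory."""
    config = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    surveys, tree, truth = generate_dataset(config)
    paths = {
        "survey": out / "survey.csv",
        "covariates": out / "covariates.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    write_survey(surveys, paths["survey"], paths["covariates"])
    tree.write_newick(paths["tree"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
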