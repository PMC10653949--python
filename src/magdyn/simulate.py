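"""Synthetic longitudinal two-species microbiome studies with ground truth.

The generator emulates the structure of a captivity experiment in which
two host species with contrasting gut-microbiome richness are exposed to
the same sequence of environmental treatments, with faecal samples taken
at the end of each treatment:

* two species archetypes — a high-richness community (default 60 MAGs)
  and a low-richness one (default 15 MAGs), mirroring the published
  contrast between a generalist rodent and a specialist shrew at desk
  scale;
* individuals nested in cages nested in species; five treatments sampled
  once per individual (acclimation, heat, cold, diet change, return to
  baseline);
* per-MAG log-normal baseline abundances with MAG-specific cage and
  individual random intercepts, multiplicative treatment effects on the
  latent scale, and multinomial read sampling at variable depth;
* a designated *responder* MAG in the low-richness species with large,
  coherent treatment effects (up under heat, collapse under cold,
  recovery under diet) whose genome is enriched for a set of injected
  metabolic functions — the low-richness community's functional capacity
  therefore tracks the responder's abundance;
* phylogenetically autocorrelated gene content: presence/absence evolves
  along a Yule tree under a two-state Markov process whose switch rate is
  inversely proportional to the phylogenetic-signal parameter, plus
  whole-pathway gene blocks shared across clades at a configurable
  redundancy level;
* genome completeness drawn uniformly from [0.7, 1.0], with observed gene
  sets thinned accordingly, so completeness adjustment is exercised.

Everything is driven by a single seed through spawned child generators:
the same configuration always yields a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountTable,
    MagRecord,
    Phylogeny,
    validate_metadata,
    write_annotations,
    write_count_table,
    write_mag_quality,
    write_metadata,
)
from .distill import PathwayDefinition, save_pathway_db

__all__ = [
    "SpeciesConfig",
    "SyntheticConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_phylogeny",
    "generate_pathway_db",
    "generate_gene_content",
    "generate_counts",
    "generate_study",
    "default_config",
    "null_config",
]

DEFAULT_TREATMENTS = ("Acclimation", "Heat", "Cold", "Diet", "Return")

# log-scale multiplicative effects of each treatment on the responder MAG:
# bloom under heat, collapse under cold, recovery under the diet change
DEFAULT_RESPONDER_EFFECTS = {
    "Acclimation": 0.0,
    "Heat": 1.5,
    "Cold": -2.5,
    "Diet": 1.2,
    "Return": 0.0,
}


@dataclass(frozen=True)
class SpeciesConfig:
    """One host-species archetype."""

    name: str
    n_mags: int
    n_individuals: int = 12
    n_cages: int = 4
    baseline_sd: float = 1.5  # dispersion of baseline log abundances
    phylo_signal: float = 2.0  # higher -> more clade-conserved gene content
    redundancy_level: float = 0.25  # prob. a pathway's gene block is shared by all MAGs
    response: str = "incoherent"  # "directional" | "incoherent" | "null"
    incoherent_sd: float = 0.25  # sd of per-individual treatment wobble

    def __post_init__(self):
        if self.n_mags < 2 or self.n_individuals < 1 or self.n_cages < 1:
            raise ValueError("species counts must be >= 1 (>= 2 MAGs)")
        if self.response not in ("directional", "incoherent", "null"):
            raise ValueError(f"unknown response mode {self.response!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full study configuration; identical config + seed => identical bundle."""

    seed: int = 0
    species: tuple = (
        SpeciesConfig(name="highdiv", n_mags=60, response="incoherent"),
        SpeciesConfig(name="lowdiv", n_mags=15, response="directional"),
    )
    treatments: tuple = DEFAULT_TREATMENTS
    n_pathways: int = 56
    n_functions: int = 14
    n_injected_functions: int = 3
    responder_effects: tuple = tuple(sorted(DEFAULT_RESPONDER_EFFECTS.items()))
    depth_range: tuple = (50_000, 150_000)
    sd_individual: float = 0.3
    sd_cage: float = 0.2
    sd_noise: float = 0.4

    def responder_effect_map(self) -> dict:
        return dict(self.responder_effects)

    def __post_init__(self):
        if len(self.treatments) < 2:
            raise ValueError("need at least 2 treatments")
        effects = dict(self.responder_effects)
        unknown = set(effects) - set(self.treatments)
        if unknown:
            raise ValueError(f"responder effects reference unknown treatments: {unknown}")
        if not all(np.isfinite(list(effects.values()))):
            raise ValueError("responder effects must be finite")


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery tests."""

    species_archetypes: dict  # species name -> response mode
    responder_mag: str | None
    responder_effects: dict  # treatment -> log-scale multiplier
    injected_functions: list  # function ids enriched in the responder

    def validate(self, mag_ids, treatments, function_ids) -> None:
        if self.responder_mag is not None and self.responder_mag not in mag_ids:
            raise ValueError(f"responder {self.responder_mag!r} not among MAGs")
        unknown = set(self.responder_effects) - set(treatments)
        if unknown:
            raise ValueError(f"effects reference unknown treatments: {unknown}")
        unknown = set(self.injected_functions) - set(function_ids)
        if unknown:
            raise ValueError(f"injected functions not in the pathway DB: {unknown}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class StudyBundle:
    """All files of one synthetic study, cross-referenced and writable."""

    config: SyntheticConfig
    counts: CountTable
    metadata: pd.DataFrame
    tree: Phylogeny
    mags: list  # MagRecord with observed (thinned) gene sets
    true_genes: dict  # mag_id -> frozenset of true gene identifiers
    pathway_db: list
    ground_truth: GroundTruth

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "tree": outdir / "tree.nwk",
            "annotations": outdir / "annotations.tsv",
            "mag_quality": outdir / "mag_quality.tsv",
            "pathway_db": outdir / "pathway_db.json",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_count_table(self.counts, paths["counts"])
        write_metadata(self.metadata, paths["metadata"])
        with open(paths["tree"], "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        write_annotations({m.mag_id: m.genes for m in self.mags}, paths["annotations"])
        write_mag_quality(self.mags, paths["mag_quality"])
        save_pathway_db(self.pathway_db, paths["pathway_db"])
        self.ground_truth.to_json(paths["ground_truth"])
        return paths

    def species_of_mag(self) -> dict:
        out = {}
        for sp in self.config.species:
            for m in self.mags:
                if m.mag_id.startswith(f"{sp.name}_"):
                    out[m.mag_id] = sp.name
        return out


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def _yule_newick(n: int, rng: np.random.Generator, prefix: str) -> str:
    """Pure-birth tree as a Newick core string (no trailing ';')."""
    if n < 2:
        raise ValueError("a tree needs at least 2 tips")
    # node: [children or tip index, birth_time]; grown forward in time
    next_tip = 0
    root = {"children": [], "t": 0.0}
    active = []
    for _ in range(2):
        child = {"parent": root, "t": 0.0, "children": []}
        root["children"].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node["split_t"] = t
        for _ in range(2):
            child = {"parent": node, "t": t, "children": []}
            node["children"].append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n)

    labels = iter(f"{prefix}{i + 1:04d}" for i in range(n))

    def render(node) -> str:
        if not node["children"]:
            length = t_end - node["t"]
            return f"{next(labels)}:{length:.6f}"
        inner = ",".join(render(c) for c in node["children"])
        length = node["split_t"] - node["t"]
        return f"({inner}):{length:.6f}"

    return "(" + ",".join(render(c) for c in root["children"]) + ")"


def generate_phylogeny(n_mags: int, seed, prefix: str = "mag_") -> Phylogeny:
    """Random pure-birth (Yule) tree with exponential waiting times."""
    rng = np.random.default_rng(seed)
    return Phylogeny.from_newick(_yule_newick(n_mags, rng, prefix) + ";")


# ---------------------------------------------------------------------------
# pathway database
# ---------------------------------------------------------------------------


def generate_pathway_db(
    n_pathways: int, n_functions: int = 14, seed=0
) -> list:
    """Random pathway DB: 2-6 steps, 1-3 alternatives, 1-2 identifiers each.

    Identifiers come from a synthetic KO-like namespace and are unique to
    their combination; pathways are assigned round-robin to function
    categories so every function is populated when n_pathways >= n_functions.
    """
    rng = np.random.default_rng(seed)
    gene_counter = 0
    db = []
    for i in range(n_pathways):
        function_id = f"F{(i % n_functions) + 1:02d}"
        steps = []
        for _ in range(int(rng.integers(2, 7))):
            alternatives = []
            for _ in range(int(rng.integers(1, 4))):
                combo = []
                for _ in range(int(rng.integers(1, 3))):
                    gene_counter += 1
                    combo.append(f"K{gene_counter:05d}")
                alternatives.append(frozenset(combo))
            steps.append(tuple(alternatives))
        db.append(
            PathwayDefinition(
                pathway_id=f"P{i + 1:03d}", function_id=function_id, steps=tuple(steps)
            )
        )
    return db


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------


def _pathway_genes(pathway: PathwayDefinition) -> list:
    genes = set()
    for step in pathway.steps:
        for combo in step:
            genes |= combo
    return sorted(genes)


def generate_gene_content(
    tree: Phylogeny,
    db: list,
    signal: float = 2.0,
    redundancy_level: float = 0.25,
    seed=0,
) -> tuple[dict, dict, dict]:
    """Evolve gene presence along the tree; returns (true, observed, completeness).

    Presence/absence of every gene follows a symmetric two-state Markov
    process with switch rate 1/signal per unit branch length, so high
    signal yields clade-conserved gene blocks.  With probability
    ``redundancy_level`` a pathway's entire gene block is shared by every
    MAG, raising functional redundancy across clades.  Observed gene sets
    are the true sets thinned by uniform dropout at rate (1 - completeness),
    completeness ~ U[0.7, 1.0].
    """
    if signal <= 0:
        raise ValueError("phylogenetic signal must be > 0")
    rng = np.random.default_rng(seed)
    genes = sorted({g for p in db for g in _pathway_genes(p)})
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    rate = 1.0 / signal

    shared = np.zeros(n_genes, dtype=bool)
    for p in db:
        if rng.random() < redundancy_level:
            for g in _pathway_genes(p):
                shared[gene_index[g]] = True

    tips = tree.tip_labels
    states: dict[int, np.ndarray] = {}
    true_sets: dict[str, set] = {}
    root = tree.tree.seed_node
    states[id(root)] = rng.random(n_genes) < 0.5
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_switch = 0.5 * (1.0 - np.exp(-2.0 * rate * t))
        flips = rng.random(n_genes) < p_switch
        state = parent_state ^ flips
        states[id(node)] = state
        if node.is_leaf():
            present = state | shared
            true_sets[node.taxon.label] = {genes[i] for i in np.flatnonzero(present)}
    # deterministic tip order for the dropout draws
    completeness = {}
    observed = {}
    for label in tips:
        c = float(rng.uniform(0.7, 1.0))
        completeness[label] = c
        keep = rng.random(len(true_sets[label])) < c
        ordered = sorted(true_sets[label])
        observed[label] = {g for g, k in zip(ordered, keep) if k}
    true_frozen = {k: frozenset(v) for k, v in true_sets.items()}
    observed_frozen = {k: frozenset(v) for k, v in observed.items()}
    return true_frozen, observed_frozen, completeness


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _species_design(sp: SpeciesConfig, treatments) -> pd.DataFrame:
    rows = []
    for i in range(sp.n_individuals):
        ind = f"{sp.name}_ind{i + 1:02d}"
        cage = f"{sp.name}_cage{(i % sp.n_cages) + 1}"
        for t, treatment in enumerate(treatments, start=1):
            rows.append(
                {
                    "sample_id": f"{ind}_t{t}",
                    "individual_id": ind,
                    "cage_id": cage,
                    "species": sp.name,
                    "treatment": treatment,
                    "time_index": t,
                }
            )
    return pd.DataFrame(rows)


def generate_counts(
    config: SyntheticConfig,
    mag_ids_by_species: dict,
    seed,
    responder_by_species: dict | None = None,
    baseline_mu_by_species: dict | None = None,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Draw the count table, metadata and ground truth for a configuration.

    ``mag_ids_by_species`` maps species name to its ordered MAG id list;
    ``responder_by_species`` optionally fixes which MAG is the directional
    responder (defaults to the first MAG of each directional species);
    ``baseline_mu_by_species`` optionally fixes the per-MAG baseline log
    abundances instead of drawing them, pinning the study-level estimands
    across independent replicate draws.
    """
    rng = np.random.default_rng(seed)
    treatments = list(config.treatments)
    effects = config.responder_effect_map()
    all_mags = [m for sp in config.species for m in mag_ids_by_species[sp.name]]
    col_index = {m: i for i, m in enumerate(all_mags)}

    meta_frames = []
    count_rows = {}
    responder = None
    for sp in config.species:
        mags = mag_ids_by_species[sp.name]
        S = len(mags)
        mu = rng.normal(0.0, sp.baseline_sd, size=S)
        if baseline_mu_by_species and sp.name in baseline_mu_by_species:
            mu = np.asarray(baseline_mu_by_species[sp.name], dtype=float).copy()
        sp_responder_idx = None
        if sp.response == "directional":
            rid = (responder_by_species or {}).get(sp.name, mags[0])
            sp_responder_idx = mags.index(rid)
            responder = rid
            # make the responder a dominant community member at baseline
            mu[sp_responder_idx] = mu.max() + 0.3
        design = _species_design(sp, treatments)
        meta_frames.append(design)
        cage_eff = {
            c: rng.normal(0.0, config.sd_cage, size=S)
            for c in sorted(design["cage_id"].unique())
        }
        ind_eff = {
            i: rng.normal(0.0, config.sd_individual, size=S)
            for i in sorted(design["individual_id"].unique())
        }
        wobble = {}
        if sp.response == "incoherent":
            for ind in sorted(design["individual_id"].unique()):
                for tr in treatments:
                    wobble[(ind, tr)] = rng.normal(0.0, sp.incoherent_sd, size=S)
        for _, row in design.iterrows():
            loglam = (
                mu
                + cage_eff[row["cage_id"]]
                + ind_eff[row["individual_id"]]
                + rng.normal(0.0, config.sd_noise, size=S)
            )
            if sp.response == "directional":
                loglam[sp_responder_idx] += effects.get(row["treatment"], 0.0)
            elif sp.response == "incoherent":
                loglam += wobble[(row["individual_id"], row["treatment"])]
            p = np.exp(loglam - loglam.max())
            p /= p.sum()
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            sample_counts = np.zeros(len(all_mags), dtype=np.int64)
            sample_counts[[col_index[m] for m in mags]] = rng.multinomial(depth, p)
            count_rows[row["sample_id"]] = sample_counts

    metadata = validate_metadata(pd.concat(meta_frames, ignore_index=True))
    counts = CountTable(
        pd.DataFrame.from_dict(count_rows, orient="index", columns=all_mags).loc[
            metadata["sample_id"]
        ]
    )
    truth = GroundTruth(
        species_archetypes={sp.name: sp.response for sp in config.species},
        responder_mag=responder,
        responder_effects=effects if responder is not None else {},
        injected_functions=[],
    )
    return counts, metadata, truth


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def _join_newick(cores: list[str], stem: float = 1.0) -> str:
    joined = ",".join(f"{c}:{stem:.6f}" for c in cores)
    return f"({joined});"


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate a complete, internally consistent synthetic study bundle."""
    n_species = len(config.species)
    children = np.random.SeedSequence(config.seed).spawn(4 + 2 * n_species)
    counts_seed = children[1 + 2 * n_species]
    length_seed = children[2 + 2 * n_species]
    inject_seed = children[3 + 2 * n_species]
    db = generate_pathway_db(config.n_pathways, config.n_functions, seed=children[0])
    function_ids = sorted({p.function_id for p in db})

    injected = function_ids[:: max(1, len(function_ids) // config.n_injected_functions)][
        : config.n_injected_functions
    ]
    injected_pathways = [p for p in db if p.function_id in injected]

    tree_cores = []
    mag_ids_by_species = {}
    true_genes: dict[str, frozenset] = {}
    observed_genes: dict[str, frozenset] = {}
    completeness: dict[str, float] = {}
    for k, sp in enumerate(config.species):
        rng_tree = np.random.default_rng(children[1 + 2 * k])
        core = _yule_newick(sp.n_mags, rng_tree, prefix=f"{sp.name}_mag")
        tree_cores.append(core)
        sp_tree = Phylogeny.from_newick(core + ";")
        t_genes, o_genes, comp = generate_gene_content(
            sp_tree,
            db,
            signal=sp.phylo_signal,
            redundancy_level=sp.redundancy_level,
            seed=children[2 + 2 * k],
        )
        mag_ids_by_species[sp.name] = list(sp_tree.tip_labels)
        true_genes.update(t_genes)
        observed_genes.update(o_genes)
        completeness.update(comp)

    # responder trait injection: the directional species' responder carries the
    # full gene complement of the injected functions, while its neighbours are
    # depleted in those genes, so community capacity tracks the responder
    responder_by_species = {}
    inject_rng = np.random.default_rng(inject_seed)
    for sp in config.species:
        if sp.response != "directional":
            continue
        mags = mag_ids_by_species[sp.name]
        responder = mags[0]
        responder_by_species[sp.name] = responder
        inj_genes = {g for p in injected_pathways for g in _pathway_genes(p)}
        for mag in mags:
            t_set = set(true_genes[mag])
            o_set = set(observed_genes[mag])
            if mag == responder:
                t_set |= inj_genes
                # observed set still reflects completeness dropout
                keep = inject_rng.random(len(inj_genes)) < completeness[mag]
                o_set |= {g for g, k in zip(sorted(inj_genes), keep) if k}
            else:
                drop = {
                    g for g in sorted(inj_genes & t_set) if inject_rng.random() < 0.8
                }
                t_set -= drop
                o_set -= drop
            true_genes[mag] = frozenset(t_set)
            observed_genes[mag] = frozenset(o_set)

    tree = Phylogeny.from_newick(_join_newick(tree_cores))
    counts, metadata, truth = generate_counts(
        config,
        mag_ids_by_species,
        seed=counts_seed,
        responder_by_species=responder_by_species,
    )
    truth.injected_functions = list(injected) if responder_by_species else []
    truth.validate(tree.tip_labels, config.treatments, function_ids)

    length_rng = np.random.default_rng(length_seed)
    mags = [
        MagRecord(
            mag_id=mid,
            genome_length=int(length_rng.integers(1_500_000, 6_000_000)),
            completeness=completeness[mid],
            contamination=float(length_rng.uniform(0.0, 0.05)),
            genes=observed_genes[mid],
        )
        for mid in tree.tip_labels
    ]
    return StudyBundle(
        config=config,
        counts=counts,
        metadata=metadata,
        tree=tree,
        mags=mags,
        true_genes=true_genes,
        pathway_db=db,
        ground_truth=truth,
    )


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default two-archetype study configuration."""
    return SyntheticConfig(seed=seed, **overrides)


def null_config(seed: int = 0) -> SyntheticConfig:
    """Both species null (no treatment effects anywhere): for calibration."""
    return SyntheticConfig(
        seed=seed,
        species=(
            SpeciesConfig(name="highdiv", n_mags=60, response="null"),
            SpeciesConfig(name="lowdiv", n_mags=15, response="null"),
        ),
    )
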