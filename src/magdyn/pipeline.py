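"""End-to-end orchestration of the analysis stages.

``run_all`` drives the full sequence — quality filtering, normalisation,
trait distillation, diversity partitioning, redundancy, PERMANOVA/CAP and
CWM trajectories — over a study bundle (synthetic or loaded from files),
running every inferential stage separately per host species.  Each stage's
tables are written as TSV together with a JSON manifest recording the
seed, the parameters in force and a checksum per output file, so reruns at
the same seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .community import Cap, Permanova
from .distill import distill_genomes, distill_mci, load_pathway_db
from .diversity import (
    COMPONENTS,
    alpha_diversity_table,
    gower_distance,
    turnover_distance_matrix,
    turnover_series,
)
from .dynamics import (
    CwmTrajectories,
    community_weighted_means,
    detect_shifts,
    filter_prevalent,
)
from .redundancy import redundancy_diversity_relation, redundancy_table
from .simulate import StudyBundle

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_bundle", "run_all", "stage_seeds"]


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage child seeds from one global seed.

    Used by both ``run_all`` and the CLI subcommands so that chained
    stage runs reproduce the end-to-end pipeline exactly.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("permanova", "bootstrap", "correlation")
    return {
        name: int(s.generate_state(1)[0] % 2**31) for name, s in zip(names, children)
    }


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    seed: int
    outdir: str | Path = "magdyn_results"
    components: tuple = COMPONENTS
    q: float = 1.0
    n_perm: int = 999
    n_boot: int = 2000
    interval_level: float = 0.90
    prevalence: float = 0.001
    min_completeness: float = 0.70
    max_contamination: float = 0.10
    force: bool = False

    def __post_init__(self):
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown diversity components: {sorted(unknown)}")


@dataclass
class LoadedBundle:
    """A study loaded from files (mirrors the synthetic bundle's surface)."""

    counts: mio.CountTable
    metadata: pd.DataFrame
    tree: mio.Phylogeny | None
    mags: list
    pathway_db: list


def load_bundle(
    counts_path, metadata_path, quality_path, annotations_path, pathway_db_path,
    tree_path=None,
) -> LoadedBundle:
    """Load a study from its TSV/Newick/JSON files, reconciling identifiers."""
    counts = mio.read_count_table(counts_path)
    metadata = mio.read_metadata(metadata_path)
    annotations = mio.read_annotations(annotations_path)
    mags = mio.read_mag_quality(quality_path, annotations=annotations)
    db = load_pathway_db(pathway_db_path)
    tree = mio.read_newick(tree_path) if tree_path else None
    known = {m.mag_id for m in mags}
    orphans = [m for m in counts.mag_ids if m not in known]
    if orphans:
        raise ValueError(f"count table MAGs without quality records: {orphans}")
    if tree is not None:
        missing = [m for m in counts.mag_ids if m not in set(tree.tip_labels)]
        if missing:
            raise ValueError(f"count table MAGs missing from the tree: {missing}")
    extra = [s for s in counts.sample_ids if s not in set(metadata["sample_id"])]
    if extra:
        raise ValueError(f"count table samples without metadata: {extra}")
    return LoadedBundle(counts=counts, metadata=metadata, tree=tree, mags=mags, pathway_db=db)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _square_to_long(df: pd.DataFrame, value_name: str) -> pd.DataFrame:
    out = df.stack().rename(value_name).rename_axis(["sample_a", "sample_b"]).reset_index()
    return out


def run_all(bundle: StudyBundle | LoadedBundle, config: RunConfig) -> dict:
    """Run every stage over the bundle; returns the in-memory results.

    Writes one TSV per stage plus ``manifest.json`` and a human-readable
    ``summary.txt`` under ``config.outdir``.  Species are analysed
    separately throughout the inferential stages.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.force:
        raise FileExistsError(
            f"{outdir} is not empty; pass force=True (--force) to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    perm_seed, boot_seed, corr_seed = (
        seeds["permanova"], seeds["bootstrap"], seeds["correlation"]
    )

    # --- genome quality filter and normalisation -------------------------
    kept = mio.filter_mags_by_quality(
        bundle.mags, config.min_completeness, config.max_contamination
    )
    kept_ids = [m.mag_id for m in kept if m.mag_id in set(bundle.counts.mag_ids)]
    counts = mio.CountTable(bundle.counts.df.loc[:, kept_ids])
    rpm = mio.counts_to_rpm(counts, kept)
    logger.info("quality filter kept %d/%d MAGs", len(kept), len(bundle.mags))

    # --- trait distillation ---------------------------------------------
    gifts = distill_genomes(kept, bundle.pathway_db, adjust=True)
    mci = distill_mci(gifts, bundle.pathway_db)

    meta = bundle.metadata.set_index("sample_id").loc[counts.sample_ids]
    tables: dict[str, pd.DataFrame] = {
        "gift": gifts.rename_axis("mag_id").reset_index(),
        "mci": mci.rename_axis("mag_id").reset_index(),
    }
    results: dict = {"gifts": gifts, "mci": mci, "per_species": {}}
    alpha_frames, turnover_frames, permanova_rows = [], [], []
    cap_frames, redundancy_frames, relation_rows = [], [], []
    trajectory_frames, shift_frames = [], []

    for species, sp_meta in meta.groupby("species", sort=False):
        sp_samples = list(sp_meta.index)
        sp_counts = counts.df.loc[sp_samples]
        present = sp_counts.columns[sp_counts.sum(axis=0) > 0]
        sp_rel = mio.counts_to_relative(mio.CountTable(sp_counts.loc[:, present]))
        sp_mci = mci.loc[present]
        distances = gower_distance(sp_mci)
        sp_res: dict = {"samples": sp_samples, "mags": list(present)}

        alpha = alpha_diversity_table(
            sp_rel, components=config.components, q=config.q,
            tree=bundle.tree, distances=distances,
        )
        alpha.insert(0, "species", species)
        alpha_frames.append(alpha)
        sp_res["alpha"] = alpha

        rel_df = sp_rel.to_relative().df
        for individual, ind_meta in sp_meta.groupby("individual_id", sort=False):
            ordered = ind_meta.sort_values("time_index").index
            for component in config.components:
                series = turnover_series(
                    rel_df.loc[ordered], component, q=config.q,
                    tree=bundle.tree, distances=distances,
                )
                rows = [
                    {
                        "species": species,
                        "individual_id": individual,
                        "component": component,
                        "kind": f"consecutive_{i + 1}",
                        "turnover": value,
                    }
                    for i, value in enumerate(series["consecutive"])
                ]
                rows.append(
                    {
                        "species": species,
                        "individual_id": individual,
                        "component": component,
                        "kind": "overall",
                        "turnover": series["overall"],
                    }
                )
                turnover_frames.append(pd.DataFrame(rows))

        sp_res["permanova"] = {}
        sp_res["cap"] = {}
        for component in config.components:
            dmat = turnover_distance_matrix(
                sp_rel, component, q=config.q, tree=bundle.tree, distances=distances
            )
            res = Permanova(
                dmat, sp_meta["treatment"], strata=sp_meta["individual_id"]
            ).fit(n_permutations=config.n_perm, seed=perm_seed)
            permanova_rows.append(
                {
                    "species": species,
                    "component": component,
                    "pseudo_F": res.pseudo_f,
                    "R2": res.r_squared,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )
            sp_res["permanova"][component] = res
            cap_res = Cap(dmat, sp_meta["treatment"]).fit()
            scores = cap_res.site_scores.copy()
            scores.insert(0, "species", species)
            scores.insert(1, "component", component)
            scores.insert(2, "treatment", sp_meta["treatment"].to_numpy())
            cap_frames.append(scores.rename_axis("sample_id").reset_index())
            sp_res["cap"][component] = cap_res

        red = redundancy_table(rel_df, distances)
        red.insert(0, "species", species)
        redundancy_frames.append(red)
        sp_res["redundancy"] = red
        relation = redundancy_diversity_relation(rel_df, distances, seed=corr_seed)
        relation_rows.append(
            {
                "species": species,
                "pearson_r": relation["pearson_r"],
                "pearson_p": relation["pearson_p"],
                "spearman_rho": relation["spearman_rho"],
                "spearman_p": relation["spearman_p"],
            }
        )

        prevalent = filter_prevalent(sp_rel, config.prevalence)
        cwm = community_weighted_means(prevalent, sp_mci)
        traj = CwmTrajectories(cwm, sp_meta.reset_index()).fit(
            n_boot=config.n_boot, level=config.interval_level, seed=boot_seed
        )
        ttab = traj.table.copy()
        ttab.insert(0, "species", species)
        trajectory_frames.append(ttab)
        shifts = detect_shifts(traj)
        if not shifts.empty:
            shifts.insert(0, "species", species)
        shift_frames.append(shifts)
        sp_res["trajectories"] = traj
        sp_res["shifts"] = shifts
        results["per_species"][species] = sp_res

    tables["alpha_diversity"] = pd.concat(alpha_frames, ignore_index=True)
    tables["turnover_individual"] = pd.concat(turnover_frames, ignore_index=True)
    tables["permanova"] = pd.DataFrame(permanova_rows)
    tables["cap_scores"] = pd.concat(cap_frames, ignore_index=True)
    tables["redundancy"] = pd.concat(redundancy_frames, ignore_index=True)
    tables["redundancy_correlation"] = pd.DataFrame(relation_rows)
    tables["cwm_trajectories"] = pd.concat(trajectory_frames, ignore_index=True)
    tables["shifts"] = pd.concat(shift_frames, ignore_index=True)

    try:
        from importlib.metadata import version as _pkg_version

        own_version = _pkg_version("magdyn")
    except Exception:  # pragma: no cover - metadata unavailable in odd installs
        own_version = "unknown"
    manifest = {
        "seed": config.seed,
        "versions": {
            "magdyn": own_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_seeds": {"permanova": perm_seed, "bootstrap": boot_seed, "correlation": corr_seed},
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "conventions": {
            "completeness_adjustment": "gift / completeness, capped at 1",
            "functional_turnover_normalization": "(beta - 1) / (N^2 - 1)",
            "permutation_scheme": "free relabelling of treatments within each individual",
        },
    }
    written = mio.write_results(tables, outdir, manifest)
    manifest["checksums"] = {p.name: _checksum(p) for p in written if p.suffix == ".tsv"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write("magdyn pipeline summary\n=======================\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"MAGs kept by quality filter: {len(kept)}/{len(bundle.mags)}\n\n")
        fh.write("PERMANOVA (treatment, strata = individual):\n")
        fh.write(tables["permanova"].to_string(index=False))
        fh.write("\n\nmean consecutive turnover by species/component:\n")
        cons = tables["turnover_individual"]
        cons = cons[cons["kind"].str.startswith("consecutive")]
        fh.write(
            cons.groupby(["species", "component"])["turnover"].mean().to_string()
        )
        fh.write("\n\ndetected CWM shifts (non-overlapping intervals):\n")
        flagged = tables["shifts"]
        flagged = flagged[flagged["shift"]] if not flagged.empty else flagged
        fh.write(flagged.to_string(index=False) if not flagged.empty else "none")
        fh.write("\n")

    results["tables"] = tables
    results["manifest"] = manifest
    return results
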