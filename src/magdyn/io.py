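"""Readers, writers and containers for the study's external tables and tree.

All tabular files are TSV (UTF-8, '.' decimal) with samples as rows and MAGs
as columns.  Genome completeness and contamination are stored internally as
fractions in [0, 1]; readers accept percentage columns (values > 1) and
convert them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MagRecord",
    "CountTable",
    "AbundanceTable",
    "Phylogeny",
    "read_count_table",
    "write_count_table",
    "read_mag_quality",
    "write_mag_quality",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_newick",
    "filter_mags_by_quality",
    "counts_to_rpm",
    "counts_to_relative",
    "write_results",
]

METADATA_COLUMNS = (
    "sample_id",
    "individual_id",
    "cage_id",
    "species",
    "treatment",
    "time_index",
)


@dataclass(frozen=True)
class MagRecord:
    """One metagenome-assembled genome (MAG) and its quality statistics.

    Parameters
    ----------
    mag_id : str
        Unique genome identifier.
    genome_length : int
        Assembly length in base pairs (> 0).
    completeness : float
        Estimated genome completeness as a fraction in [0, 1].
    contamination : float
        Estimated contamination as a fraction (>= 0).
    genes : frozenset of str
        Gene identifiers annotated on the genome (KO-like strings).
    taxonomy : str, optional
        Free-text taxonomic label.
    """

    mag_id: str
    genome_length: int
    completeness: float
    contamination: float
    genes: frozenset = field(default_factory=frozenset)
    taxonomy: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError(
                f"MAG {self.mag_id!r}: completeness {self.completeness} not in [0, 1]"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"MAG {self.mag_id!r}: contamination {self.contamination} < 0"
            )
        if self.genome_length <= 0:
            raise ValueError(
                f"MAG {self.mag_id!r}: genome_length {self.genome_length} must be > 0"
            )
        object.__setattr__(self, "genes", frozenset(self.genes))


class CountTable:
    """Sample x MAG read-count matrix.

    Wraps a pandas DataFrame with integer, non-negative entries; ``depth`` is
    the per-sample total read count (row sums).
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated MAG ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise ValueError("count table must hold integer counts")
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[bad[0]]!r}, MAG {df.columns[bad[1]]!r}"
            )
        self.df = df.astype(np.int64)

    @property
    def sample_ids(self) -> list:
        return list(self.df.index)

    @property
    def mag_ids(self) -> list:
        return list(self.df.columns)

    @property
    def depth(self) -> pd.Series:
        """Total reads per sample."""
        return self.df.sum(axis=1)

    def __eq__(self, other):
        return isinstance(other, CountTable) and self.df.equals(other.df)


class AbundanceTable:
    """Normalized sample x MAG abundances.

    ``mode`` is ``"relative"`` (rows sum to 1) or ``"rpm"`` (reads per million,
    rows sum to 1e6).  All-zero rows are permitted and preserved.
    """

    _TARGETS = {"relative": (1.0, 1e-9), "rpm": (1e6, 1e-3)}

    def __init__(self, df: pd.DataFrame, mode: str):
        if mode not in self._TARGETS:
            raise ValueError(f"unknown abundance mode {mode!r}")
        values = df.to_numpy(dtype=float)
        if values.size and (values < 0).any():
            raise ValueError("abundances must be non-negative")
        target, tol = self._TARGETS[mode]
        sums = values.sum(axis=1)
        nonzero = sums > 0
        if values.size and not np.allclose(sums[nonzero], target, atol=tol, rtol=0):
            raise ValueError(f"{mode} rows must sum to {target}")
        self.df = df.astype(float)
        self.mode = mode

    @property
    def sample_ids(self) -> list:
        return list(self.df.index)

    @property
    def mag_ids(self) -> list:
        return list(self.df.columns)

    def to_relative(self) -> "AbundanceTable":
        """Re-close every non-zero row to sum 1."""
        sums = self.df.sum(axis=1)
        out = self.df.div(sums.where(sums > 0, 1.0), axis=0)
        return AbundanceTable(out, "relative")


class Phylogeny:
    """Rooted tree over MAGs with non-negative branch lengths.

    A thin wrapper over a :class:`dendropy.Tree` that also exposes the
    branch-incidence structure needed by phylogenetic Hill numbers: for each
    edge, its length and the set of tip labels below it.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise ValueError("phylogeny must have at least 2 tips")
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels in phylogeny")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    "phylogeny must carry branch lengths on every edge"
                )
            if edge.length < 0:
                raise ValueError("negative branch length in phylogeny")
        self.tree = tree
        self.tip_labels = tips

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def branch_arrays(self, tip_order: list) -> tuple[np.ndarray, np.ndarray]:
        """Branch lengths and tip-incidence for a given tip ordering.

        Returns ``(lengths, incidence)`` where ``lengths`` has one entry per
        edge and ``incidence[b, i]`` is True when tip ``tip_order[i]`` descends
        from edge ``b``.  Raises if any requested tip is absent.
        """
        missing = set(tip_order) - set(self.tip_labels)
        if missing:
            raise ValueError(
                f"tips absent from phylogeny: {sorted(missing)}"
            )
        index = {label: i for i, label in enumerate(tip_order)}
        lengths = []
        rows = []
        # post-order accumulation of descendant tip sets per edge
        below: dict[int, np.ndarray] = {}
        for node in self.tree.postorder_node_iter():
            mask = np.zeros(len(tip_order), dtype=bool)
            if node.is_leaf():
                i = index.get(node.taxon.label)
                if i is not None:
                    mask[i] = True
            else:
                for child in node.child_nodes():
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node is not self.tree.seed_node and node.edge.length is not None:
                lengths.append(node.edge.length)
                rows.append(mask)
        return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)


def read_count_table(path) -> CountTable:
    """Read a TSV read-count table (first column sample ids, header MAG ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: count table has no data rows")
    for col in df.columns:
        cells = df[col]
        numeric = pd.to_numeric(cells, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-integer count at sample {row!r}, MAG {col!r}"
            )
    return CountTable(df.astype(np.int64))


def write_count_table(counts: CountTable, path) -> None:
    counts.df.to_csv(path, sep="\t", index_label="sample_id")


def _as_fraction(series: pd.Series) -> pd.Series:
    """Convert percentage-scale columns (any value > 1) to fractions."""
    if (series > 1.0).any():
        return series / 100.0
    return series


def read_mag_quality(path, annotations: dict | None = None) -> list[MagRecord]:
    """Read a MAG quality table (mag_id, genome_length, completeness, contamination).

    Completeness/contamination may be on a percent scale; they are converted
    to fractions.  ``annotations`` optionally attaches gene sets per MAG.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"mag_id", "genome_length", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    comp = _as_fraction(df["completeness"].astype(float))
    cont = _as_fraction(df["contamination"].astype(float))
    records = []
    for i, row in df.iterrows():
        genes = frozenset((annotations or {}).get(row["mag_id"], ()))
        records.append(
            MagRecord(
                mag_id=str(row["mag_id"]),
                genome_length=int(row["genome_length"]),
                completeness=float(comp.iloc[i]),
                contamination=float(cont.iloc[i]),
                genes=genes,
                taxonomy=str(row["taxonomy"]) if "taxonomy" in df.columns else None,
            )
        )
    return records


def write_mag_quality(mags: list[MagRecord], path) -> None:
    pd.DataFrame(
        {
            "mag_id": [m.mag_id for m in mags],
            "genome_length": [m.genome_length for m in mags],
            "completeness": [m.completeness for m in mags],
            "contamination": [m.contamination for m in mags],
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict[str, frozenset]:
    """Read a gene-annotation TSV: mag_id <tab> comma-separated identifiers."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"mag_id", "genes"} <= set(df.columns):
        raise ValueError(f"{path}: annotation table needs 'mag_id' and 'genes' columns")
    out = {}
    for _, row in df.iterrows():
        genes = frozenset(g for g in row["genes"].split(",") if g)
        out[row["mag_id"]] = genes
    return out


def write_annotations(annotations: dict, path) -> None:
    pd.DataFrame(
        {
            "mag_id": list(annotations),
            "genes": [",".join(sorted(v)) for v in annotations.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the sample-metadata invariants and return the frame.

    Each (individual, time_index) pair must be unique; individuals must nest
    within a single cage; cages within a single species.
    """
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in metadata")
    pairs = df[["individual_id", "time_index"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (individual, time_index) pair: {dup}")
    for child, parent in (("individual_id", "cage_id"), ("cage_id", "species")):
        n_parents = df.groupby(child)[parent].nunique()
        broken = n_parents[n_parents > 1]
        if not broken.empty:
            raise ValueError(
                f"{child} values span multiple {parent} levels: {list(broken.index)}"
            )
    df = df.copy()
    df["time_index"] = df["time_index"].astype(int)
    return df


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype={"time_index": int}))


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def filter_mags_by_quality(
    mags: list[MagRecord],
    min_completeness: float = 0.70,
    max_contamination: float = 0.10,
) -> list[MagRecord]:
    """Keep MAGs with completeness >= threshold and contamination strictly below.

    Defaults correspond to the usual medium-quality screen: at least 70%
    complete and less than 10% contaminated.  Order is preserved and the
    operation is idempotent.
    """
    if not 0.0 <= min_completeness <= 1.0 or not 0.0 <= max_contamination <= 1.0:
        raise ValueError("quality thresholds must be fractions in [0, 1]")
    return [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination < max_contamination
    ]


def counts_to_rpm(counts: CountTable, mags: list[MagRecord]) -> AbundanceTable:
    """Normalize counts for genome length and depth (reads per million).

    Per sample, counts are divided by genome length and the length-corrected
    values rescaled to sum to 1e6.  All-zero samples stay all-zero (warned).
    """
    by_id = {m.mag_id: m for m in mags}
    missing = [mid for mid in counts.mag_ids if mid not in by_id]
    if missing:
        raise KeyError(f"no genome length for MAGs: {missing}")
    lengths = np.array([by_id[mid].genome_length for mid in counts.mag_ids], float)
    v = counts.df.to_numpy(float) / lengths
    sums = v.sum(axis=1)
    zero_rows = sums == 0
    if zero_rows.any():
        ids = [counts.sample_ids[i] for i in np.flatnonzero(zero_rows)]
        logger.warning("all-zero samples left unnormalized: %s", ids)
        warnings.warn(f"all-zero samples left unnormalized: {ids}")
    rpm = np.where(zero_rows[:, None], 0.0, 1e6 * v / np.where(sums == 0, 1, sums)[:, None])
    df = pd.DataFrame(rpm, index=counts.df.index, columns=counts.df.columns)
    return AbundanceTable(df, "rpm")


def counts_to_relative(counts: CountTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (no length correction)."""
    v = counts.df.to_numpy(float)
    sums = v.sum(axis=1)
    rel = np.where(sums[:, None] == 0, 0.0, v / np.where(sums == 0, 1, sums)[:, None])
    df = pd.DataFrame(rel, index=counts.df.index, columns=counts.df.columns)
    return AbundanceTable(df, "relative")


def write_results(tables: dict[str, pd.DataFrame], outdir, manifest: dict) -> list[Path]:
    """Write result tables as TSV plus a JSON run manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    written.append(mpath)
    return written
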