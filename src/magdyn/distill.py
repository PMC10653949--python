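"""Distillation of genome annotations into functional-capacity scores.

A pathway is an ordered list of steps; each step lists alternative
identifier combinations, and a combination is a set of gene identifiers
that are all required.  A genome's score for one pathway (its
genome-inferred functional trait, GIFT) is the mean over steps of the best
fraction-present among the step's alternatives, so it ranges from 0 (no
pathway gene present) to 1 (every step fully satisfied).  GIFTs are
averaged within broader metabolic function categories to give per-genome
metabolic capacity indices (MCIs).

For a two-identifier step the fraction-present rule reduces to the familiar
complete / half-complete / empty scoring; larger combinations receive
proportional partial credit.

Because reconstructed genomes are incomplete, raw GIFTs are biased
downward.  Under uniformly random gene loss the expected observed score is
the true score times completeness, so the default adjustment divides by
completeness and caps at 1; it is pluggable for other conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .io import MagRecord

__all__ = [
    "PathwayDefinition",
    "load_pathway_db",
    "save_pathway_db",
    "score_step",
    "score_gift",
    "adjust_for_completeness",
    "distill_genome",
    "distill_genomes",
    "distill_mci",
]

DEFAULT_FUNCTION_COUNT = 14


@dataclass(frozen=True)
class PathwayDefinition:
    """One metabolic pathway: ordered steps of alternative gene combinations."""

    pathway_id: str
    function_id: str
    steps: tuple  # tuple of steps; step = tuple of frozenset of identifiers

    def __post_init__(self):
        if len(self.steps) == 0:
            raise ValueError(f"pathway {self.pathway_id!r} has no steps")
        norm = []
        for si, step in enumerate(self.steps):
            if len(step) == 0:
                raise ValueError(
                    f"pathway {self.pathway_id!r} step {si} has no alternatives"
                )
            alts = []
            for combo in step:
                combo = frozenset(combo)
                if not combo:
                    raise ValueError(
                        f"pathway {self.pathway_id!r} step {si} has an empty combination"
                    )
                alts.append(combo)
            norm.append(tuple(alts))
        object.__setattr__(self, "steps", tuple(norm))


def load_pathway_db(path) -> list[PathwayDefinition]:
    """Load a pathway database from JSON.

    Schema: a list of objects ``{"pathway_id", "function_id", "steps"}`` where
    ``steps`` is a list (steps) of lists (alternatives) of lists (required
    identifiers).
    """
    with open(path) as fh:
        raw = json.load(fh)
    db = []
    for entry in raw:
        try:
            db.append(
                PathwayDefinition(
                    pathway_id=entry["pathway_id"],
                    function_id=entry["function_id"],
                    steps=tuple(
                        tuple(frozenset(c) for c in step) for step in entry["steps"]
                    ),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            pid = entry.get("pathway_id", "<missing id>") if isinstance(entry, dict) else "<malformed>"
            raise ValueError(f"invalid pathway definition {pid!r}: {exc}") from exc
    return db


def save_pathway_db(db: Iterable[PathwayDefinition], path) -> None:
    payload = [
        {
            "pathway_id": p.pathway_id,
            "function_id": p.function_id,
            "steps": [[sorted(c) for c in step] for step in p.steps],
        }
        for p in db
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def score_step(step, genes: set | frozenset) -> float:
    """Best fraction-present over the step's alternative combinations."""
    best = 0.0
    for combo in step:
        present = sum(1 for g in combo if g in genes)
        best = max(best, present / len(combo))
    return best


def score_gift(pathway: PathwayDefinition, genes: set | frozenset) -> float:
    """Pathway completeness score: mean of step scores, in [0, 1]."""
    return float(np.mean([score_step(step, genes) for step in pathway.steps]))


def adjust_for_completeness(gift: float, completeness: float) -> float:
    """Correct a raw score for genome incompleteness: min(1, gift/completeness)."""
    if completeness <= 0.0 or completeness > 1.0:
        raise ValueError(f"completeness must be in (0, 1], got {completeness}")
    return min(1.0, gift / completeness)


def distill_genome(
    mag: MagRecord,
    db: list[PathwayDefinition],
    adjust: bool = True,
    adjustment: Callable[[float, float], float] = adjust_for_completeness,
) -> pd.Series:
    """Score one genome against every pathway; returns a Series over pathway ids."""
    scores = {}
    for pathway in db:
        s = score_gift(pathway, mag.genes)
        if adjust:
            s = adjustment(s, mag.completeness)
        scores[pathway.pathway_id] = s
    return pd.Series(scores, name=mag.mag_id)


def distill_genomes(
    mags: list[MagRecord],
    db: list[PathwayDefinition],
    adjust: bool = True,
    adjustment: Callable[[float, float], float] = adjust_for_completeness,
) -> pd.DataFrame:
    """GIFT matrix (MAGs x pathways) for a genome catalogue."""
    rows = [distill_genome(m, db, adjust=adjust, adjustment=adjustment) for m in mags]
    return pd.DataFrame(rows)


def distill_mci(
    gifts: pd.DataFrame,
    pathway_to_function: Mapping[str, str] | list[PathwayDefinition],
) -> pd.DataFrame:
    """Average GIFTs within each function category (MAGs x functions).

    ``pathway_to_function`` may be a mapping or the pathway database itself.
    Every GIFT column must map to exactly one function.
    """
    if not isinstance(pathway_to_function, Mapping):
        pathway_to_function = {p.pathway_id: p.function_id for p in pathway_to_function}
    unmapped = [c for c in gifts.columns if c not in pathway_to_function]
    if unmapped:
        raise KeyError(f"pathways not mapped to a function: {unmapped}")
    groups = gifts.T.groupby([pathway_to_function[c] for c in gifts.columns])
    mci = groups.mean().T
    return mci.sort_index(axis=1)
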