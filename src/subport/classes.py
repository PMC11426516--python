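"""Mapping substrates to the seven transport substrate classes.

Transport substrates are conventionally grouped into seven classes:
cations, anions, sugars, amino acids/oligopeptides, proteins/mRNA,
electrons, and other substrates.  A molecule is classified by (in order):
a manual override table; a breadth-first ancestor search of its ChEBI
parent terms against packaged per-class anchor-term sets; a sugar naming
rule (name ending in "ose" with a formula containing only C, H and O); and
a fallback to "other" only when both name and formula are known.  Anything
else stays unclassified.  The anchor table ships with the package and is
editable — manual curation happens through the override table.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import InteractionPair, Label, MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SubstrateClass",
    "CLASS_PRIORITY",
    "load_default_anchors",
    "map_chebi_to_class",
    "build_class_dataset",
    "class_weights",
]


class SubstrateClass(str, Enum):
    CATION = "cation"
    ANION = "anion"
    SUGAR = "sugar"
    AMINO_ACID_OLIGOPEPTIDE = "amino_acid_oligopeptide"
    PROTEIN_MRNA = "protein_mrna"
    ELECTRON = "electron"
    OTHER = "other"


#: Tie-break order when ancestors of a molecule hit anchors of several
#: classes at the same BFS depth.
CLASS_PRIORITY = (
    SubstrateClass.CATION,
    SubstrateClass.ANION,
    SubstrateClass.SUGAR,
    SubstrateClass.AMINO_ACID_OLIGOPEPTIDE,
    SubstrateClass.PROTEIN_MRNA,
    SubstrateClass.ELECTRON,
)

_MAX_ANCESTOR_DEPTH = 30
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def load_default_anchors() -> dict[str, SubstrateClass]:
    """Packaged anchor-term table: ChEBI accession -> substrate class."""
    with resources.files("subport.data").joinpath("class_anchors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return {
        row["chebi_id"]: SubstrateClass(row["class"]) for _, row in df.iterrows()
    }


def _formula_is_cho(formula: str) -> bool:
    elements = set()
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.group(0):
            elements.add(match.group(1))
    return bool(elements) and elements <= {"C", "H", "O"}


def map_chebi_to_class(
    molecule: MoleculeRecord,
    ontology: Mapping[str, Sequence[str]],
    overrides: Optional[Mapping[str, SubstrateClass]] = None,
    anchors: Optional[Mapping[str, SubstrateClass]] = None,
) -> Optional[SubstrateClass]:
    """Classify one molecule, or return None when it stays unclassified.

    ``ontology`` maps a ChEBI accession to its parent accessions.  The
    ancestor search is breadth-first from the molecule's own term, capped at
    depth 30; the nearest anchor hit wins, with ties resolved by the fixed
    class priority.  A parent chain that revisits the molecule's own term is
    a cyclic graph and raises.
    """
    overrides = overrides or {}
    if molecule.chebi_id in overrides:
        return overrides[molecule.chebi_id]
    anchors = anchors if anchors is not None else load_default_anchors()
    level = [molecule.chebi_id]
    visited = {molecule.chebi_id}
    depth = 0
    while level and depth <= _MAX_ANCESTOR_DEPTH:
        hits = [anchors[term] for term in level if term in anchors]
        if hits:
            # nearest anchors win; priority order breaks same-depth ties
            for cls in CLASS_PRIORITY:
                if cls in hits:
                    return cls
        next_level: list[str] = []
        for term in level:
            for parent in ontology.get(term, ()):
                if parent == molecule.chebi_id:
                    raise ValueError(f"cyclic ChEBI parent graph at {molecule.chebi_id}")
                if parent not in visited:
                    visited.add(parent)
                    next_level.append(parent)
        level = next_level
        depth += 1
    if (
        molecule.name is not None
        and molecule.name.lower().endswith("ose")
        and molecule.formula is not None
        and _formula_is_cho(molecule.formula)
    ):
        return SubstrateClass.SUGAR
    if molecule.name is not None and molecule.formula is not None:
        return SubstrateClass.OTHER
    return None


def build_class_dataset(
    positives: Sequence[InteractionPair],
    class_map: Mapping[str, Optional[SubstrateClass]],
) -> pd.DataFrame:
    """One (transporter, class) row per unambiguously classified transporter.

    A transporter is kept only when its positive substrates map to exactly
    one distinct class; transporters with no classified substrate or with
    two or more distinct classes are dropped (counts logged).
    """
    classes_per_transporter: dict[str, set[SubstrateClass]] = defaultdict(set)
    for p in positives:
        if p.label is not Label.POSITIVE:
            continue
        cls = class_map.get(p.chebi_id)
        if cls is not None:
            classes_per_transporter[p.transporter_id].add(cls)
    all_transporters = {p.transporter_id for p in positives}
    rows = []
    n_none = n_multi = 0
    for tid in sorted(all_transporters):
        classes = classes_per_transporter.get(tid, set())
        if len(classes) == 0:
            n_none += 1
        elif len(classes) > 1:
            n_multi += 1
        else:
            rows.append({"transporter_id": tid, "substrate_class": next(iter(classes)).value})
    logger.info(
        "class dataset: kept %d transporters, dropped %d (no class) + %d (multiple classes)",
        len(rows),
        n_none,
        n_multi,
    )
    return pd.DataFrame(rows, columns=["transporter_id", "substrate_class"])


def class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Inverse-frequency class weights, normalized to mean 1 across classes."""
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    counts = Counter(labels)
    if len(counts) == 1:
        logger.warning("only one class present; weight 1")
        return {next(iter(counts)): 1.0}
    raw = {cls: 1.0 / n for cls, n in counts.items()}
    mean = sum(raw.values()) / len(raw)
    return {cls: w / mean for cls, w in raw.items()}
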