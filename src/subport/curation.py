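"""Curation of experimentally supported transporter-substrate pairs.

Positive pairs come from two kinds of input: GO annotation files (GAF
dialect), where a transport-related GO term implies a substrate via a
user-supplied term-to-ChEBI map and only experimentally evidenced records
are kept; and UniProt-style TSV dumps, where RHEA reaction identifiers are
resolved to substrate ChEBI accessions through a RHEA-to-ChEBI map.  The two
sources are merged with deduplication on the (transporter, molecule) key,
and quality filters remove proton substrates, structure-less molecules and
protein fragments.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.UniProt import GOA

from .records import (
    CurationConfig,
    DomainOfLife,
    InteractionPair,
    Label,
    MoleculeRecord,
    Provenance,
    SubcellularLocation,
    TCClass,
    TransporterRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "parse_go_annotations",
    "parse_uniprot_entries",
    "parse_tcdb",
    "merge_and_deduplicate",
    "apply_quality_filters",
    "label_thermostability_hits",
    "pairs_to_frame",
    "write_pair_table",
    "read_pair_table",
]

#: Column names expected in UniProt-style TSV dumps.
UNIPROT_COLUMNS = {
    "accession": "accession",
    "sequence": "sequence",
    "rhea_ids": "rhea_ids",
    "domain": "domain",
    "location": "location",
    "tc_number": "tc_number",
}


def parse_go_annotations(
    gaf_file,
    transporter_go_terms: Mapping[str, str],
    config: CurationConfig = CurationConfig(),
) -> list[InteractionPair]:
    """Extract positive pairs from a GO annotation file.

    Only records whose GO term appears in ``transporter_go_terms`` (mapping a
    transport GO term to the substrate's ChEBI accession) and whose evidence
    code is experimental are retained.  Malformed lines are skipped with a
    warning; an unreadable file raises.
    """
    pairs: list[InteractionPair] = []
    seen: set[tuple[str, str]] = set()
    with open(gaf_file) as handle:
        # gafiterator raises on a truncated record; guard per-record so one
        # malformed line does not abort the whole file.
        iterator = GOA.gafiterator(handle)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # malformed line
                logger.warning("skipping malformed GAF record: %s", exc)
                continue
            go_term = rec.get("GO_ID")
            evidence = rec.get("Evidence")
            accession = rec.get("DB_Object_ID")
            if not go_term or not evidence or not accession:
                logger.warning("skipping incomplete GAF record: %r", rec)
                continue
            if go_term not in transporter_go_terms:
                continue
            if evidence not in config.experimental_evidence_codes:
                continue
            chebi_id = transporter_go_terms[go_term]
            key = (accession, chebi_id)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                InteractionPair(
                    transporter_id=accession,
                    chebi_id=chebi_id,
                    label=Label.POSITIVE,
                    provenance=Provenance.GO,
                    evidence=evidence,
                )
            )
    return pairs


def _parse_enum(value, enum_cls, default):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return default
    try:
        return enum_cls(str(value))
    except ValueError:
        return default


def parse_uniprot_entries(
    uniprot_table,
    rhea_chebi_map: Mapping[str, Sequence[str]],
) -> tuple[list[TransporterRecord], list[InteractionPair]]:
    """Parse a UniProt-style TSV dump into records and positive pairs.

    One :class:`TransporterRecord` per accession; one positive pair per
    (accession, substrate) reachable through the RHEA-to-ChEBI map.  RHEA IDs
    absent from the map are skipped with a warning.  Duplicate accessions are
    a fatal error (accessions must be unique within a dataset).
    """
    df = pd.read_csv(uniprot_table, sep="\t", dtype=str)
    if "sequence" not in df.columns:
        raise ValueError("UniProt table is missing the required 'sequence' column")
    if "accession" not in df.columns:
        raise ValueError("UniProt table is missing the required 'accession' column")
    dupes = df["accession"][df["accession"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate accession rows: {sorted(set(dupes))}")

    records: list[TransporterRecord] = []
    pairs: list[InteractionPair] = []
    for row in df.itertuples(index=False):
        accession = row.accession
        record = TransporterRecord(
            uniprot_id=accession,
            sequence=row.sequence,
            domain_of_life=_parse_enum(
                getattr(row, "domain", None), DomainOfLife, DomainOfLife.UNKNOWN
            ),
            subcellular_location=_parse_enum(
                getattr(row, "location", None),
                SubcellularLocation,
                SubcellularLocation.UNKNOWN_AMBIGUOUS,
            ),
            tc_class=_parse_enum(getattr(row, "tc_number", None), TCClass, TCClass.UNKNOWN),
        )
        records.append(record)
        rhea_field = getattr(row, "rhea_ids", None)
        if rhea_field is None or pd.isna(rhea_field) or rhea_field == "":
            continue
        seen: set[str] = set()
        for rhea_id in str(rhea_field).split(";"):
            rhea_id = rhea_id.strip()
            if not rhea_id:
                continue
            if rhea_id not in rhea_chebi_map:
                logger.warning("%s: RHEA ID %s not in map, skipped", accession, rhea_id)
                continue
            for chebi_id in rhea_chebi_map[rhea_id]:
                if chebi_id in seen:
                    continue
                seen.add(chebi_id)
                pairs.append(
                    InteractionPair(
                        transporter_id=accession,
                        chebi_id=chebi_id,
                        label=Label.POSITIVE,
                        provenance=Provenance.UNIPROT,
                        evidence=rhea_id,
                    )
                )
    return records, pairs


def parse_tcdb(*args, **kwargs):
    """Deliberately unimplemented TCDB reader.

    Transporter Classification Database annotations were assessed as largely
    lacking experimental support (over half of the referenced entries carry
    low curation scores), so TCDB ingestion is excluded from this pipeline by
    design rather than by omission.
    """
    raise NotImplementedError(
        "TCDB ingestion is intentionally not implemented: TCDB substrate "
        "annotations are largely not experimentally validated and were "
        "excluded from the curated dataset by design."
    )


def merge_and_deduplicate(
    pair_lists: Sequence[Sequence[InteractionPair]],
    preferred_order: Sequence[Provenance] = (Provenance.UNIPROT, Provenance.GO),
) -> list[InteractionPair]:
    """Union pair lists, keeping one record per (transporter, molecule) key.

    When a key occurs in several sources, the pair whose provenance comes
    first in ``preferred_order`` wins (defaults to UniProt over GO, UniProt
    entries being restricted to top-score manual curation); unknown
    provenances rank last.  Output order follows first occurrence.
    """
    rank = {p: i for i, p in enumerate(preferred_order)}
    best: dict[tuple[str, str], InteractionPair] = {}
    order: list[tuple[str, str]] = []
    for pairs in pair_lists:
        for pair in pairs:
            if pair.key not in best:
                best[pair.key] = pair
                order.append(pair.key)
            else:
                incumbent = best[pair.key]
                if rank.get(pair.provenance, len(rank)) < rank.get(
                    incumbent.provenance, len(rank)
                ):
                    best[pair.key] = pair
    return [best[k] for k in order]


def apply_quality_filters(
    pairs: Sequence[InteractionPair],
    transporters: Mapping[str, TransporterRecord],
    molecules: Mapping[str, MoleculeRecord],
    config: CurationConfig = CurationConfig(),
) -> list[InteractionPair]:
    """Drop pairs failing the structural and sequence-length quality filters.

    Removes pairs whose molecule has no structure string (InChI or SMILES),
    whose substrate is in the excluded set (the proton by default), or whose
    transporter sequence is shorter than ``min_sequence_length`` residues
    (protein fragments).  Order is preserved; a pair referencing an unknown
    transporter or molecule is a fatal error.
    """
    kept: list[InteractionPair] = []
    counts = Counter()
    for pair in pairs:
        if pair.transporter_id not in transporters:
            raise KeyError(f"pair references unknown transporter {pair.transporter_id!r}")
        if pair.chebi_id not in molecules:
            raise KeyError(f"pair references unknown molecule {pair.chebi_id!r}")
        mol = molecules[pair.chebi_id]
        if pair.chebi_id in config.excluded_chebi_ids:
            counts["excluded_chebi"] += 1
            continue
        if not mol.has_structure:
            counts["no_structure"] += 1
            continue
        if len(transporters[pair.transporter_id].sequence) < config.min_sequence_length:
            counts["short_sequence"] += 1
            continue
        kept.append(pair)
    logger.info(
        "quality filters: kept %d of %d pairs (removed: %s)",
        len(kept),
        len(pairs),
        dict(counts) or "none",
    )
    return kept


def label_thermostability_hits(
    tm_table: pd.DataFrame,
    config: CurationConfig = CurationConfig(),
) -> pd.DataFrame:
    """Label compounds from a thermal-shift screen as candidate substrates.

    ``tm_table`` must have columns ``compound`` and ``delta_tm`` (mean shift
    of apparent melting temperature in °C relative to the apo protein).  A
    compound is a candidate substrate when its mean shift is at least
    ``delta_tm_threshold`` (inclusive; default 1 °C).
    """
    values = pd.to_numeric(tm_table["delta_tm"], errors="coerce")
    if values.isna().any():
        bad = tm_table.loc[values.isna(), "compound"].tolist()
        raise ValueError(f"non-numeric delta_tm for compounds: {bad}")
    out = tm_table[["compound"]].copy()
    out["candidate_substrate"] = (values >= config.delta_tm_threshold).to_numpy()
    return out


# ---------------------------------------------------------------------------
# pair-table I/O (the canonical on-disk exchange format between stages)

PAIR_COLUMNS = ["transporter_id", "chebi_id", "label", "provenance", "evidence"]


def pairs_to_frame(pairs: Iterable[InteractionPair]) -> pd.DataFrame:
    rows = [
        (p.transporter_id, p.chebi_id, p.label.value, p.provenance.value, p.evidence or "")
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pair_table(pairs: Iterable[InteractionPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> list[InteractionPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        InteractionPair(
            transporter_id=r.transporter_id,
            chebi_id=r.chebi_id,
            label=Label(r.label),
            provenance=Provenance(r.provenance),
            evidence=r.evidence or None,
        )
        for r in df.itertuples(index=False)
    ]
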