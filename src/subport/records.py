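"""Core domain records for the transporter-substrate prediction pipeline.

A *transporter* is a membrane protein identified by a UniProt-style accession
with an amino-acid sequence and optional metadata used only for stratified
evaluation (domain of life, subcellular location, transporter class).  A
*molecule* is a small-molecule substrate candidate identified by a ChEBI
accession with at least one structure string (InChI or SMILES) when it is
structure-mapped.  An *interaction pair* is the unit of training and
evaluation: a (transporter, molecule) pair labeled positive (experimentally
supported substrate) or negative (sampled non-substrate).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "DomainOfLife",
    "SubcellularLocation",
    "TCClass",
    "Label",
    "Provenance",
    "TransporterRecord",
    "MoleculeRecord",
    "InteractionPair",
    "CurationConfig",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class DomainOfLife(str, Enum):
    BACTERIA = "Bacteria"
    EUKARYA = "Eukarya"
    ARCHAEA = "Archaea"
    UNKNOWN = "unknown"


class SubcellularLocation(str, Enum):
    CELL_MEMBRANE = "cell_membrane"
    NUCLEUS_MEMBRANE = "nucleus_membrane"
    ORGANELLE_MEMBRANE = "organelle_membrane"
    UNKNOWN_AMBIGUOUS = "unknown_ambiguous"


class TCClass(str, Enum):
    """Top-level transporter-classification mechanism class.

    1 = channels/pores, 2 = electrochemical potential-driven transporters,
    3 = primary active transporters, 4 = group translocators.
    """

    CHANNEL = "1"
    ELECTROCHEMICAL = "2"
    PRIMARY_ACTIVE = "3"
    GROUP_TRANSLOCATOR = "4"
    UNKNOWN = "unknown"


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Provenance(str, Enum):
    GO = "GO"
    UNIPROT = "UniProt"
    SAMPLED = "sampled"


@dataclass(frozen=True)
class TransporterRecord:
    uniprot_id: str
    sequence: str
    domain_of_life: DomainOfLife = DomainOfLife.UNKNOWN
    subcellular_location: SubcellularLocation = SubcellularLocation.UNKNOWN_AMBIGUOUS
    tc_class: TCClass = TCClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.uniprot_id:
            raise ValueError("uniprot_id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.uniprot_id}: sequence must be nonempty")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.uniprot_id}: invalid residues {sorted(bad)} "
                "(expected uppercase standard amino acids or X)"
            )


@dataclass(frozen=True)
class MoleculeRecord:
    chebi_id: str
    name: Optional[str] = None
    formula: Optional[str] = None
    inchi: Optional[str] = None
    smiles: Optional[str] = None
    parent_chebi_ids: tuple[str, ...] = ()
    canonical_smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chebi_id:
            raise ValueError("chebi_id must be nonempty")

    @property
    def has_structure(self) -> bool:
        return self.inchi is not None or self.smiles is not None


@dataclass(frozen=True)
class InteractionPair:
    transporter_id: str
    chebi_id: str
    label: Label
    provenance: Provenance
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label is Label.NEGATIVE and self.provenance is not Provenance.SAMPLED:
            raise ValueError(
                f"({self.transporter_id}, {self.chebi_id}): negative pairs must "
                "carry provenance 'sampled'"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.transporter_id, self.chebi_id)


#: ChEBI accessions for the proton (CHEBI:15378 hydron / CHEBI:24636 proton);
#: transport annotations with a proton substrate mostly reflect symport or
#: antiport where the proton is not the primary cargo, so they are excluded.
DEFAULT_EXCLUDED_CHEBI = frozenset({"CHEBI:15378", "CHEBI:24636"})

#: GO evidence codes counted as experimental (the experimental evidence
#: category plus its high-throughput counterparts).
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
)


@dataclass(frozen=True)
class CurationConfig:
    """Quality-filter thresholds for dataset curation.

    min_sequence_length drops protein fragments; delta_tm_threshold is the
    minimum mean melting-temperature shift (°C, inclusive) that labels a
    compound as a candidate substrate in thermostability screens.
    """

    min_sequence_length: int = 30
    excluded_chebi_ids: frozenset[str] = DEFAULT_EXCLUDED_CHEBI
    experimental_evidence_codes: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES
    delta_tm_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.min_sequence_length < 1:
            raise ValueError("min_sequence_length must be >= 1")
        if not self.delta_tm_threshold > 0:
            raise ValueError("delta_tm_threshold must be > 0")
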