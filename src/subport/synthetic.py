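"""Synthetic worlds for end-to-end pipeline testing without downloads.

A synthetic world has the statistical structure the pipeline assumes of
real data: protein *families* (one random ancestor per family, members
derived by independent per-residue substitutions, so within-family identity
is high and cross-family identity is at the random-sequence baseline), a
molecule library drawn from a packaged pool of real, chemically coherent
SMILES *groups* (sugars, amino acids, nucleosides, organic acids, ions —
within-group fingerprint similarity exceeds between-group similarity), and
a ground-truth rule assigning each family a substrate group from which its
members' positive substrates are drawn.  The generator emulates dataset
structure, not transporter biochemistry: it exists to validate computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    DomainOfLife,
    InteractionPair,
    Label,
    MoleculeRecord,
    Provenance,
    SubcellularLocation,
    TCClass,
    TransporterRecord,
)

__all__ = [
    "SMILES_POOL",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "generate_protein_families",
    "generate_molecule_library",
    "generate_interactions",
    "generate_world",
    "write_fixture_bundle",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Packaged pool of real, valid SMILES grouped into structurally coherent
#: sub-pools.  Entries are (name, smiles); formulas are derived with RDKit
#: at generation time.
SMILES_POOL: dict[str, list[tuple[str, str]]] = {
    "sugar": [
        # SMILES are written without stereocenters; entries are chosen to be
        # constitutionally distinct so canonicalization keeps them apart
        ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
        ("fructose", "OCC1(O)OC(CO)C(O)C1O"),
        ("ribose", "OCC1OC(O)C(O)C1O"),
        ("xylose", "OC1COC(O)C(O)C1O"),
        ("deoxyribose", "OCC1OC(O)CC1O"),
        ("rhamnose", "CC1OC(O)C(O)C(O)C1O"),
        ("glucuronate", "OC1OC(C(=O)O)C(O)C(O)C1O"),
        ("sucrose", "OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O"),
        ("lactose", "OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O"),
        ("trehalose", "OCC1OC(OC2OC(CO)C(O)C(O)C2O)C(O)C(O)C1O"),
        ("sorbitol", "OCC(O)C(O)C(O)C(O)CO"),
        ("ribitol", "OCC(O)C(O)C(O)CO"),
        ("erythritol", "OCC(O)C(O)CO"),
        ("glycerol", "OCC(O)CO"),
        ("myo-inositol", "OC1C(O)C(O)C(O)C(O)C1O"),
        ("sedoheptulose", "OCC(O)C(O)C(O)C(O)C(=O)CO"),
    ],
    "amino_acid": [
        ("glycine", "NCC(=O)O"),
        ("alanine", "CC(N)C(=O)O"),
        ("serine", "OCC(N)C(=O)O"),
        ("cysteine", "NC(CS)C(=O)O"),
        ("threonine", "CC(O)C(N)C(=O)O"),
        ("valine", "CC(C)C(N)C(=O)O"),
        ("leucine", "CC(C)CC(N)C(=O)O"),
        ("isoleucine", "CCC(C)C(N)C(=O)O"),
        ("proline", "OC(=O)C1CCCN1"),
        ("methionine", "CSCCC(N)C(=O)O"),
        ("phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
        ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
        ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
        ("aspartate", "NC(CC(=O)O)C(=O)O"),
        ("glutamate", "NC(CCC(=O)O)C(=O)O"),
        ("lysine", "NCCCCC(N)C(=O)O"),
        ("arginine", "NC(CCCNC(=N)N)C(=O)O"),
        ("histidine", "NC(Cc1c[nH]cn1)C(=O)O"),
        ("glutamine", "NC(=O)CCC(N)C(=O)O"),
        ("asparagine", "NC(=O)CC(N)C(=O)O"),
    ],
    "nucleoside": [
        ("adenine", "Nc1ncnc2[nH]cnc12"),
        ("guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1"),
        ("cytosine", "Nc1cc[nH]c(=O)n1"),
        ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
        ("thymine", "Cc1c[nH]c(=O)[nH]c1=O"),
        ("hypoxanthine", "O=c1[nH]cnc2[nH]cnc12"),
        ("adenosine", "Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O"),
        ("guanosine", "Nc1nc2c(ncn2C2OC(CO)C(O)C2O)c(=O)[nH]1"),
        ("uridine", "OCC1OC(n2ccc(=O)[nH]c2=O)C(O)C1O"),
        ("cytidine", "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1"),
        ("inosine", "OCC1OC(n2cnc3c2nc[nH]c3=O)C(O)C1O"),
        ("thymidine", "Cc1cn(C2CC(O)C(CO)O2)c(=O)[nH]c1=O"),
    ],
    "organic_acid": [
        ("acetate", "CC(=O)O"),
        ("formate", "OC=O"),
        ("propionate", "CCC(=O)O"),
        ("butyrate", "CCCC(=O)O"),
        ("lactate", "CC(O)C(=O)O"),
        ("pyruvate", "CC(=O)C(=O)O"),
        ("succinate", "OC(=O)CCC(=O)O"),
        ("fumarate", "OC(=O)C=CC(=O)O"),
        ("malate", "OC(=O)CC(O)C(=O)O"),
        ("citrate", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
        ("oxaloacetate", "OC(=O)CC(=O)C(=O)O"),
        ("2-oxoglutarate", "OC(=O)CCC(=O)C(=O)O"),
        ("glycolate", "OCC(=O)O"),
        ("benzoate", "OC(=O)c1ccccc1"),
    ],
    "ion": [
        ("sodium", "[Na+]"),
        ("potassium", "[K+]"),
        ("calcium", "[Ca+2]"),
        ("magnesium", "[Mg+2]"),
        ("chloride", "[Cl-]"),
        ("zinc", "[Zn+2]"),
        ("iron(2+)", "[Fe+2]"),
        ("ammonium", "[NH4+]"),
        ("nitrate", "[O-][N+](=O)[O-]"),
        ("sulfate", "[O-]S(=O)(=O)[O-]"),
        ("hydrogenphosphate", "OP(=O)([O-])[O-]"),
        ("bicarbonate", "OC(=O)[O-]"),
    ],
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Shape and noise parameters of a synthetic world.

    Defaults produce the standard test world: 10 families of 10 members
    derived from 150-residue ancestors at a 5% per-residue substitution
    rate, 5 molecule groups of 8, 5 substrates per family, no label noise.
    """

    n_families: int = 10
    members_per_family: int = 10
    ancestor_length: int = 150
    within_family_substitution_rate: float = 0.05
    n_molecule_groups: int = 5
    molecules_per_group: int = 8
    substrates_per_family: int = 5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_family_substitution_rate", "label_noise"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "n_families",
            "members_per_family",
            "ancestor_length",
            "n_molecule_groups",
            "molecules_per_group",
            "substrates_per_family",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.substrates_per_family > self.molecules_per_group:
            raise ValueError("substrates_per_family cannot exceed molecules_per_group")


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    transporters: list[TransporterRecord]
    family_of: dict[str, int]
    molecules: list[MoleculeRecord]
    group_of: dict[str, str]
    positives: list[InteractionPair]
    truth: dict[int, list[str]]  # family -> true substrate ChEBI accessions


def generate_protein_families(
    config: SyntheticWorldConfig,
) -> tuple[list[TransporterRecord], dict[str, int]]:
    """Random ancestor per family; members by independent substitutions.

    Metadata (domain of life, location, TC class) is assigned round-robin —
    it exists purely to exercise stratified evaluation, with no biological
    meaning.  Accessions are ``F{family:02d}M{member:02d}``.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    domains = [DomainOfLife.BACTERIA, DomainOfLife.EUKARYA, DomainOfLife.ARCHAEA]
    locations = [
        SubcellularLocation.CELL_MEMBRANE,
        SubcellularLocation.NUCLEUS_MEMBRANE,
        SubcellularLocation.ORGANELLE_MEMBRANE,
        SubcellularLocation.UNKNOWN_AMBIGUOUS,
    ]
    tc_classes = [
        TCClass.CHANNEL,
        TCClass.ELECTROCHEMICAL,
        TCClass.PRIMARY_ACTIVE,
        TCClass.GROUP_TRANSLOCATOR,
    ]
    records: list[TransporterRecord] = []
    family_of: dict[str, int] = {}
    counter = 0
    for fam in range(config.n_families):
        ancestor = rng.choice(alphabet, size=config.ancestor_length)
        for member in range(config.members_per_family):
            seq = ancestor.copy()
            mask = rng.random(config.ancestor_length) < config.within_family_substitution_rate
            for pos in np.flatnonzero(mask):
                choices = [a for a in AMINO_ACIDS if a != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
            accession = f"F{fam:02d}M{member:02d}"
            records.append(
                TransporterRecord(
                    uniprot_id=accession,
                    sequence="".join(seq),
                    domain_of_life=domains[counter % len(domains)],
                    subcellular_location=locations[counter % len(locations)],
                    tc_class=tc_classes[counter % len(tc_classes)],
                )
            )
            family_of[accession] = fam
            counter += 1
    return records, family_of


def generate_molecule_library(
    config: SyntheticWorldConfig,
) -> tuple[list[MoleculeRecord], dict[str, str]]:
    """Draw the molecule library from the packaged structurally coherent pool.

    Each world group is sampled (without replacement, seeded) from one
    sub-pool, cycling through sub-pools when the world wants more groups
    than the pool has.  Synthetic ChEBI-style accessions ``CHEBI:SYN####``
    keep the records format-compatible with real inputs.
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    rng = np.random.default_rng(config.seed + 1)
    pool_names = list(SMILES_POOL)
    records: list[MoleculeRecord] = []
    group_of: dict[str, str] = {}
    used: dict[str, list[int]] = {g: [] for g in pool_names}
    counter = 0
    for g in range(config.n_molecule_groups):
        pool_name = pool_names[g % len(pool_names)]
        pool = SMILES_POOL[pool_name]
        available = [i for i in range(len(pool)) if i not in used[pool_name]]
        if len(available) < config.molecules_per_group:
            raise ValueError(
                f"sub-pool {pool_name!r} exhausted: wanted {config.molecules_per_group}, "
                f"have {len(available)}"
            )
        picks = rng.choice(available, size=config.molecules_per_group, replace=False)
        used[pool_name].extend(int(i) for i in picks)
        for i in picks:
            name, smiles = pool[int(i)]
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # the pool is validated by tests; guard anyway
                raise ValueError(f"invalid pooled SMILES for {name}: {smiles}")
            accession = f"CHEBI:SYN{counter:04d}"
            records.append(
                MoleculeRecord(
                    chebi_id=accession,
                    name=name,
                    formula=rdMolDescriptors.CalcMolFormula(mol),
                    smiles=smiles,
                )
            )
            group_of[accession] = f"group{g}"
            counter += 1
    return records, group_of


def generate_interactions(
    transporters: Sequence[TransporterRecord],
    family_of: dict[str, int],
    molecules: Sequence[MoleculeRecord],
    group_of: dict[str, str],
    config: SyntheticWorldConfig,
) -> tuple[list[InteractionPair], dict[int, list[str]]]:
    """Positive pairs from the family -> substrate-group truth map.

    Family ``f`` is assigned group ``f mod n_groups`` and
    ``substrates_per_family`` molecules drawn from it; every family member
    is positive for each of those substrates.  A ``label_noise`` fraction of
    pairs has its molecule swapped for a random out-of-truth molecule
    (inconsistent with the truth map but still labeled positive).
    Provenance alternates GO/UniProt to exercise merging and provenance
    reporting downstream.
    """
    rng = np.random.default_rng(config.seed + 2)
    groups: dict[str, list[str]] = {}
    for m in molecules:
        groups.setdefault(group_of[m.chebi_id], []).append(m.chebi_id)
    group_names = sorted(groups)
    truth: dict[int, list[str]] = {}
    for fam in range(config.n_families):
        group = groups[group_names[fam % len(group_names)]]
        picks = rng.choice(len(group), size=config.substrates_per_family, replace=False)
        truth[fam] = [group[int(i)] for i in picks]
    all_ids = [m.chebi_id for m in molecules]
    pairs: list[InteractionPair] = []
    counter = 0
    for rec in transporters:
        fam = family_of[rec.uniprot_id]
        for chebi_id in truth[fam]:
            molecule = chebi_id
            if rng.random() < config.label_noise:
                outside = [m for m in all_ids if m not in truth[fam]]
                molecule = outside[int(rng.integers(len(outside)))]
            pairs.append(
                InteractionPair(
                    transporter_id=rec.uniprot_id,
                    chebi_id=molecule,
                    label=Label.POSITIVE,
                    provenance=Provenance.GO if counter % 2 == 0 else Provenance.UNIPROT,
                    evidence="IDA" if counter % 2 == 0 else "RHEA:SYN",
                )
            )
            counter += 1
    # molecule swaps can collide with an existing pair; deduplicate on key
    seen: set[tuple[str, str]] = set()
    unique = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            unique.append(p)
    return unique, truth


def generate_world(config: SyntheticWorldConfig = SyntheticWorldConfig()) -> SyntheticWorld:
    """Generate a complete seeded synthetic world."""
    transporters, family_of = generate_protein_families(config)
    molecules, group_of = generate_molecule_library(config)
    positives, truth = generate_interactions(
        transporters, family_of, molecules, group_of, config
    )
    return SyntheticWorld(
        config=config,
        transporters=transporters,
        family_of=family_of,
        molecules=molecules,
        group_of=group_of,
        positives=positives,
        truth=truth,
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(world: SyntheticWorld, out_dir) -> dict:
    """Write the world in the pipeline's standard input formats.

    Emits transporter FASTA, a UniProt-style TSV, a molecule TSV, the
    positive-pair TSV, a toy GAF file restricted to the GO-provenance pairs,
    a toy term-to-ChEBI map and a trivial ontology TSV, plus a manifest JSON
    with the seed and per-file checksums.  Re-reading the bundle reproduces
    the same pair set.
    """
    from .curation import pairs_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fasta = out / "transporters.fasta"
    with fasta.open("w") as fh:
        for rec in world.transporters:
            fh.write(f">{rec.uniprot_id}\n{rec.sequence}\n")

    uniprot = out / "transporters.tsv"
    pd.DataFrame(
        [
            {
                "accession": r.uniprot_id,
                "sequence": r.sequence,
                "rhea_ids": "",
                "domain": r.domain_of_life.value,
                "location": r.subcellular_location.value,
                "tc_number": r.tc_class.value,
            }
            for r in world.transporters
        ]
    ).to_csv(uniprot, sep="\t", index=False)

    mol_table = out / "molecules.tsv"
    pd.DataFrame(
        [
            {
                "chebi_id": m.chebi_id,
                "name": m.name,
                "formula": m.formula,
                "smiles": m.smiles,
                "group": world.group_of[m.chebi_id],
            }
            for m in world.molecules
        ]
    ).to_csv(mol_table, sep="\t", index=False)

    pair_table = out / "positive_pairs.tsv"
    pairs_to_frame(world.positives).to_csv(pair_table, sep="\t", index=False)

    # toy GAF: one synthetic GO term per molecule; only GO-provenance pairs
    term_of = {
        m.chebi_id: f"GO:9{i:06d}" for i, m in enumerate(world.molecules)
    }
    gaf = out / "annotations.gaf"
    with gaf.open("w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for p in world.positives:
            if p.provenance is not Provenance.GO:
                continue
            fields = [
                "SYN",  # DB
                p.transporter_id,  # DB_Object_ID
                p.transporter_id,  # DB_Object_Symbol
                "enables",  # Qualifier
                term_of[p.chebi_id],  # GO_ID
                "SYN:0000",  # DB:Reference
                p.evidence or "IDA",  # Evidence
                "",  # With
                "F",  # Aspect
                "",  # DB_Object_Name
                "",  # Synonym
                "protein",  # DB_Object_Type
                "taxon:0",  # Taxon_ID
                "20240101",  # Date
                "SYN",  # Assigned_By
                "",  # Annotation_Extension
                "",  # Gene_Product_Form_ID
            ]
            fh.write("\t".join(fields) + "\n")

    term_map = out / "go_term_map.tsv"
    pd.DataFrame(
        [{"go_term": t, "chebi_id": c} for c, t in term_of.items()]
    ).to_csv(term_map, sep="\t", index=False)

    ontology = out / "ontology.tsv"
    pd.DataFrame(
        [{"child": m.chebi_id, "parent": f"CHEBI:GRP-{world.group_of[m.chebi_id]}"}
         for m in world.molecules]
    ).to_csv(ontology, sep="\t", index=False)

    files = [fasta, uniprot, mol_table, pair_table, gaf, term_map, ontology]
    manifest = {
        "seed": world.config.seed,
        "config": {
            k: getattr(world.config, k)
            for k in (
                "n_families",
                "members_per_family",
                "ancestor_length",
                "within_family_substitution_rate",
                "n_molecule_groups",
                "molecules_per_group",
                "substrates_per_family",
                "label_noise",
            )
        },
        "files": {f.name: _checksum(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
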