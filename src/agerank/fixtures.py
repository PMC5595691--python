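"""Deterministic synthetic fixture generator.

Emulates the pre-assembled inputs of a ranking run: protein families
aligned across five species, ligand-contact lists, domain annotations,
compound annotations, aging-evidence rows and compound-target links.

Family sequences evolve from a random root by per-site substitution at
species-specific rates: invertebrate branches mutate at the full
``mutation_rate``, mammalian branches at a third of it, and binding-site
positions at a fifth of the branch rate — mimicking the empirical pattern
that drug binding sites (kinase pockets in particular) are better conserved
than the rest of the protein.  Substitutions are drawn uniformly over the
19 alternative residues.  Alignments are emitted gapless, so alignment
columns coincide with reference positions.

Alongside the input files the generator writes expected score breakdowns
computed by the independent straight-line oracle (:mod:`agerank.oracle`),
enabling dual-implementation equivalence checks.
"""

from __future__ import annotations

import json
import string
from pathlib import Path

import numpy as np

from agerank.config import RankingConfig, TARGET_SPECIES
from agerank.conservation import BindingSiteContacts, DomainAnnotation
from agerank.io import (
    write_compounds_tsv,
    write_contacts_tsv,
    write_domains_tsv,
    write_evidence_tsv,
    write_links_tsv,
)
from agerank.oracle import oracle_breakdowns
from agerank.scoring import CompoundRecord, CompoundTargetLink, EvidenceAnnotation

__all__ = ["generate_fixtures"]

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_SPECIES_BRANCHES = ("mmusculus", "rnorvegicus", "dmelanogaster", "celegans")
_EVIDENCE_CATEGORIES = (
    "experimental",
    "computational",
    "author_curator",
    "automatic_or_none",
)


def _mutate(
    rng: np.random.Generator,
    root: np.ndarray,
    rate: float,
    site_positions: set[int],
    site_rate: float,
) -> np.ndarray:
    seq = root.copy()
    for i in range(len(seq)):
        r = site_rate if (i + 1) in site_positions else rate
        if rng.random() < r:
            alternatives = _RESIDUES[_RESIDUES != seq[i]]
            seq[i] = rng.choice(alternatives)
    return seq


def _het_codes(rng: np.random.Generator, n: int) -> list[str]:
    alphabet = string.ascii_uppercase + string.digits
    codes: set[str] = set()
    while len(codes) < n:
        codes.add("".join(rng.choice(list(alphabet), size=3)))
    return sorted(codes)


def generate_fixtures(
    out_dir: str | Path,
    seed: int,
    n_families: int = 5,
    n_compounds: int = 20,
    mutation_rate: float = 0.35,
    site_size: int = 10,
    seq_length: int = 300,
    orphan_family_fraction: float = 0.2,
) -> dict:
    """Write a complete synthetic input set plus expected breakdowns.

    ``mutation_rate`` is the per-site substitution probability on
    invertebrate branches; ``site_size`` the number of ligand contacts per
    structure.  A fraction of families (``orphan_family_fraction``) lacks
    one invertebrate species, so compounds targeting only those families
    exercise the no-homologue exclusion path.  Returns the raw fixture
    description including the oracle's expected scores per species.
    """
    if site_size <= 0:
        raise ValueError("site_size must be positive")
    if n_families <= 0 or n_compounds <= 0:
        raise ValueError("n_families and n_compounds must be positive")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    (out_dir / "families").mkdir(parents=True, exist_ok=True)

    raw: dict = {
        "families": {},
        "contacts": {},
        "compounds": {},
        "evidence": {},
        "links": [],
    }

    # --- families, domains, per-family aging target proteins ---
    family_ids = [f"FAM{i:03d}" for i in range(1, n_families + 1)]
    orphan_species: dict[str, str | None] = {}
    for idx, fam_id in enumerate(family_ids):
        root = rng.choice(_RESIDUES, size=seq_length)
        d_start = int(rng.integers(20, 61))
        d_len = int(rng.integers(150, 221))
        d_end = min(seq_length, d_start + d_len)
        domains = [(d_start, d_end)]

        # contacts are drawn later per structure, but site positions used
        # for conservation-aware mutation come from a family-wide pocket
        pocket = sorted(
            int(p) for p in rng.choice(
                np.arange(d_start, d_end + 1), size=min(30, d_end - d_start),
                replace=False,
            )
        )
        pocket_set = set(pocket)

        # some families lack one invertebrate: their compounds are
        # unrankable for that species
        orphan = None
        if idx < int(round(orphan_family_fraction * n_families)):
            orphan = TARGET_SPECIES[idx % 2]
        orphan_species[fam_id] = orphan

        ref_id = f"{fam_id}_HUMAN"
        seqs = {ref_id: "".join(root)}
        species_of = {ref_id: "hsapiens"}
        for sp in _SPECIES_BRANCHES:
            if sp == orphan:
                continue
            rate = mutation_rate if sp in TARGET_SPECIES else mutation_rate / 3.0
            member = f"{fam_id}_{sp.upper()}"
            seqs[member] = "".join(
                _mutate(rng, root, rate, pocket_set, rate / 5.0)
            )
            species_of[member] = sp
        raw["families"][fam_id] = {
            "ref_id": ref_id,
            "seqs": seqs,
            "species_of": species_of,
            "domains": domains,
            "pocket": pocket,
        }
        raw["evidence"][f"TP_{fam_id}"] = {
            "category": str(rng.choice(_EVIDENCE_CATEGORIES)),
            "via_orthologue": bool(rng.random() < 0.5),
            "n_identifier_mappings": int(rng.poisson(0.5)),
            "genage": bool(rng.random() < 0.3),
        }

    # --- compounds and links ---
    structure_no = 0
    for het in _het_codes(rng, n_compounds):
        raw["compounds"][het] = {
            "names": [f"compound-{het.lower()}"] if rng.random() < 0.4 else [],
            "lipinski": (
                float(np.round(rng.normal(400.0, 120.0), 1)),
                float(np.round(rng.normal(3.0, 1.5), 2)),
                int(rng.poisson(2)),
                int(rng.poisson(6)),
            ),
            "purchasable": bool(rng.random() < 0.6),
            "approval": str(
                rng.choice(
                    ["chembl_drug", "drugbank_only", "none"], p=[0.25, 0.35, 0.4]
                )
            ),
            "burns_score": float(np.round(rng.normal(4.0, 2.0), 3)),
        }
        n_links = int(rng.integers(1, 3))
        fams = rng.choice(family_ids, size=n_links, replace=False)
        for fam_id in fams:
            fam = raw["families"][fam_id]
            structure_no += 1
            structure_id = f"S{structure_no:04d}"
            # ligand contacts: mostly pocket residues, occasionally one
            # residue outside all domains to exercise the window rule
            site = sorted(
                int(p)
                for p in rng.choice(fam["pocket"], size=site_size, replace=False)
            )
            d_start, d_end = fam["domains"][0]
            outside = [
                p for p in range(1, len(fam["seqs"][fam["ref_id"]]) + 1)
                if p < d_start or p > d_end
            ]
            if outside and rng.random() < 0.2:
                site[-1] = int(rng.choice(outside))
                site = sorted(set(site))
            raw["contacts"][structure_id] = site
            raw["links"].append(
                {
                    "het_code": het,
                    "target_protein_id": f"TP_{fam_id}",
                    "structure_id": structure_id,
                    "family_id": str(fam_id),
                    "log_affinity": float(np.round(rng.normal(7.0, 0.7), 4)),
                }
            )

    _write_files(raw, out_dir, seed)

    raw["expected"] = {
        sp: oracle_breakdowns(raw, sp) for sp in TARGET_SPECIES
    }
    for sp in TARGET_SPECIES:
        with open(out_dir / f"expected_scores_{sp}.json", "w") as fh:
            json.dump(raw["expected"][sp], fh, indent=1, sort_keys=True)
            fh.write("\n")
    return raw


def _write_files(raw: dict, out_dir: Path, seed: int) -> None:
    from agerank.conservation import AlignedFamily
    from agerank.io import write_family_fasta

    domains = {}
    for fam_id, fam in sorted(raw["families"].items()):
        family = AlignedFamily(
            family_id=fam_id,
            ref_id=fam["ref_id"],
            aligned_seqs=fam["seqs"],
            species_of=fam["species_of"],
        )
        write_family_fasta(family, out_dir / "families" / f"{fam_id}.fasta")
        domains[fam["ref_id"]] = DomainAnnotation(list(fam["domains"]))
    write_domains_tsv(domains, out_dir / "domains.tsv")

    contacts = {}
    for link in raw["links"]:
        sid = link["structure_id"]
        contacts[(sid, link["het_code"])] = BindingSiteContacts(
            sid, link["het_code"], list(raw["contacts"][sid])
        )
    write_contacts_tsv(contacts, out_dir / "contacts.tsv")

    compounds = {}
    for het, c in sorted(raw["compounds"].items()):
        compounds[het] = CompoundRecord(
            het_code=het,
            names=list(c["names"]),
            lipinski_descriptors=tuple(c["lipinski"]),
            purchasable=c["purchasable"],
            approval=c["approval"],
            burns_score=c["burns_score"],
        )
    write_compounds_tsv(compounds, out_dir / "compounds.tsv")

    evidence = {}
    for pid, e in sorted(raw["evidence"].items()):
        evidence[pid] = EvidenceAnnotation(
            protein_id=pid,
            category=e["category"],
            via_orthologue=e["via_orthologue"],
            n_identifier_mappings=e["n_identifier_mappings"],
            genage=e["genage"],
        )
    write_evidence_tsv(evidence, out_dir / "evidence.tsv")

    links = [
        CompoundTargetLink(
            het_code=ln["het_code"],
            target_protein_id=ln["target_protein_id"],
            structure_id=ln["structure_id"],
            log_affinity=ln["log_affinity"],
            family_id=ln["family_id"],
        )
        for ln in raw["links"]
    ]
    write_links_tsv(links, out_dir / "links.tsv")

    for sp in TARGET_SPECIES:
        RankingConfig(species=sp).to_yaml(out_dir / f"config_{sp}.yaml")
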