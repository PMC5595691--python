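"""Readers and writers for all flat-file inputs, plus the run manifest.

File conventions (all coordinates 1-based, all tables tab-separated with a
header row):

* family alignments: aligned FASTA, one file per family, headers
  ``member_id|species``; the FIRST record is the structure-bearing
  reference sequence.
* contacts: ``structure_id  het_code  position`` (one row per contact
  residue, positions on the ungapped reference).
* domains: ``member_id  start  end`` (structural-domain intervals of the
  reference sequence).
* compounds: ``het_code  names  lipinski_violations  mw  logp  hbd  hba
  purchasable  approval  burns_score  n_aging_targets`` (names
  ``;``-separated; either the violation count or the four descriptors may
  be empty; ``burns_score``/``n_aging_targets`` may be empty).
* evidence: ``protein_id  category  via_orthologue  n_identifier_mappings
  genage``.
* links: ``het_code  target_protein_id  structure_id  family_id  kd_molar
  log_affinity`` (exactly one of the last two per row).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from agerank import __version__
from agerank.config import DEFAULT_SPECIES_VOCABULARY
from agerank.conservation import (
    AlignedFamily,
    BindingSiteContacts,
    DomainAnnotation,
)
from agerank.scoring import (
    CompoundRecord,
    CompoundTargetLink,
    EvidenceAnnotation,
    log_affinity_from_kd,
)

__all__ = [
    "TableFormatError",
    "read_family_fasta",
    "write_family_fasta",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "read_domains_tsv",
    "write_domains_tsv",
    "read_compounds_tsv",
    "write_compounds_tsv",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "read_links_tsv",
    "write_links_tsv",
    "RunManifest",
]


class TableFormatError(ValueError):
    """An input table violates its documented schema."""


def read_family_fasta(
    path: str | Path,
    species_vocabulary: tuple[str, ...] = DEFAULT_SPECIES_VOCABULARY,
) -> AlignedFamily:
    """Read one aligned family; the file stem is the family id."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise TableFormatError(f"{path}: empty family file")
    aligned: dict[str, str] = {}
    species: dict[str, str] = {}
    ref_id = None
    for rec in records:
        if "|" not in rec.id:
            raise TableFormatError(
                f"{path}: header {rec.id!r} not in 'member_id|species' form"
            )
        member, sp = rec.id.rsplit("|", 1)
        if sp not in species_vocabulary:
            raise TableFormatError(f"{path}: unknown species tag {sp!r}")
        if member in aligned:
            raise TableFormatError(f"{path}: duplicate member id {member!r}")
        aligned[member] = str(rec.seq).upper()
        species[member] = sp
        if ref_id is None:
            ref_id = member
    lengths = {m: len(s) for m, s in aligned.items()}
    if len(set(lengths.values())) > 1:
        ref_len = lengths[ref_id]
        bad = next(m for m, n in lengths.items() if n != ref_len)
        raise TableFormatError(
            f"{path}: ragged alignment, member {bad!r} has length "
            f"{lengths[bad]} != {ref_len}"
        )
    return AlignedFamily(
        family_id=path.stem, ref_id=ref_id, aligned_seqs=aligned, species_of=species
    )


def write_family_fasta(family: AlignedFamily, path: str | Path) -> None:
    order = [family.ref_id] + sorted(
        m for m in family.aligned_seqs if m != family.ref_id
    )
    records = [
        SeqRecord(
            Seq(family.aligned_seqs[m]),
            id=f"{m}|{family.species_of[m]}",
            description="",
        )
        for m in order
    ]
    SeqIO.write(records, str(path), "fasta")


def _load_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty table") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    return df


def _row_err(path, idx, msg) -> TableFormatError:
    # +2: header line plus 1-based numbering
    return TableFormatError(f"{path}, line {idx + 2}: {msg}")


def read_contacts_tsv(path: str | Path) -> dict[tuple[str, str], BindingSiteContacts]:
    """Contacts keyed by (structure_id, het_code)."""
    df = _load_table(path, ("structure_id", "het_code", "position"))
    grouped: dict[tuple[str, str], list[int]] = {}
    for idx, row in df.iterrows():
        try:
            pos = int(row["position"])
        except ValueError:
            raise _row_err(path, idx, f"non-integer position {row['position']!r}")
        if pos < 1:
            raise _row_err(path, idx, f"position must be >= 1, got {pos}")
        grouped.setdefault((row["structure_id"], row["het_code"]), []).append(pos)
    return {
        (sid, het): BindingSiteContacts(sid, het, positions)
        for (sid, het), positions in grouped.items()
    }


def write_contacts_tsv(
    contacts: dict[tuple[str, str], BindingSiteContacts], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("structure_id\thet_code\tposition\n")
        for (sid, het), c in sorted(contacts.items()):
            for p in c.contact_positions:
                fh.write(f"{sid}\t{het}\t{p}\n")


def read_domains_tsv(path: str | Path) -> dict[str, DomainAnnotation]:
    df = _load_table(path, ("member_id", "start", "end"))
    grouped: dict[str, list[tuple[int, int]]] = {}
    for idx, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            raise _row_err(path, idx, "non-integer domain bounds")
        if start < 1 or start > end:
            raise _row_err(path, idx, f"invalid interval ({start}, {end})")
        grouped.setdefault(row["member_id"], []).append((start, end))
    return {m: DomainAnnotation(iv) for m, iv in grouped.items()}


def write_domains_tsv(domains: dict[str, DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\tstart\tend\n")
        for member, ann in sorted(domains.items()):
            for start, end in ann.intervals:
                fh.write(f"{member}\t{start}\t{end}\n")


_COMPOUND_COLUMNS = (
    "het_code",
    "names",
    "lipinski_violations",
    "mw",
    "logp",
    "hbd",
    "hba",
    "purchasable",
    "approval",
    "burns_score",
    "n_aging_targets",
)


def read_compounds_tsv(path: str | Path) -> dict[str, CompoundRecord]:
    df = _load_table(path, _COMPOUND_COLUMNS)
    compounds: dict[str, CompoundRecord] = {}
    for idx, row in df.iterrows():
        het = row["het_code"]
        if het in compounds:
            raise _row_err(path, idx, f"duplicate compound {het!r}")
        try:
            violations = (
                int(row["lipinski_violations"])
                if row["lipinski_violations"] != ""
                else None
            )
            descr = None
            if row["mw"] != "":
                descr = (
                    float(row["mw"]),
                    float(row["logp"]),
                    int(row["hbd"]),
                    int(row["hba"]),
                )
            burns = float(row["burns_score"]) if row["burns_score"] != "" else None
            n_targets = (
                int(row["n_aging_targets"])
                if row["n_aging_targets"] != ""
                else None
            )
            compounds[het] = CompoundRecord(
                het_code=het,
                names=[n for n in row["names"].split(";") if n],
                lipinski_violations=violations,
                lipinski_descriptors=descr,
                purchasable=row["purchasable"] in ("1", "true", "True"),
                approval=row["approval"],
                burns_score=burns,
                n_aging_targets=n_targets,
            )
        except ValueError as exc:
            raise _row_err(path, idx, str(exc))
    return compounds


def write_compounds_tsv(compounds: dict[str, CompoundRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COMPOUND_COLUMNS) + "\n")
        for het, c in sorted(compounds.items()):
            descr = c.lipinski_descriptors
            fh.write(
                "\t".join(
                    [
                        het,
                        ";".join(c.names),
                        "" if c.lipinski_violations is None else str(c.lipinski_violations),
                        "" if descr is None else repr(descr[0]),
                        "" if descr is None else repr(descr[1]),
                        "" if descr is None else str(descr[2]),
                        "" if descr is None else str(descr[3]),
                        "1" if c.purchasable else "0",
                        c.approval,
                        "" if c.burns_score is None else repr(c.burns_score),
                        "" if c.n_aging_targets is None else str(c.n_aging_targets),
                    ]
                )
                + "\n"
            )


def read_evidence_tsv(path: str | Path) -> dict[str, EvidenceAnnotation]:
    df = _load_table(
        path,
        ("protein_id", "category", "via_orthologue", "n_identifier_mappings", "genage"),
    )
    evidence: dict[str, EvidenceAnnotation] = {}
    for idx, row in df.iterrows():
        pid = row["protein_id"]
        if pid in evidence:
            raise _row_err(path, idx, f"duplicate protein {pid!r}")
        try:
            evidence[pid] = EvidenceAnnotation(
                protein_id=pid,
                category=row["category"],
                via_orthologue=row["via_orthologue"] in ("1", "true", "True"),
                n_identifier_mappings=int(row["n_identifier_mappings"]),
                genage=row["genage"] in ("1", "true", "True"),
            )
        except ValueError as exc:
            raise _row_err(path, idx, str(exc))
    return evidence


def write_evidence_tsv(evidence: dict[str, EvidenceAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcategory\tvia_orthologue\tn_identifier_mappings\tgenage\n")
        for pid, e in sorted(evidence.items()):
            fh.write(
                f"{pid}\t{e.category}\t{int(e.via_orthologue)}\t"
                f"{e.n_identifier_mappings}\t{int(e.genage)}\n"
            )


def read_links_tsv(path: str | Path) -> list[CompoundTargetLink]:
    df = _load_table(
        path,
        ("het_code", "target_protein_id", "structure_id", "family_id",
         "kd_molar", "log_affinity"),
    )
    links = []
    for idx, row in df.iterrows():
        has_kd = row["kd_molar"] != ""
        has_log = row["log_affinity"] != ""
        if has_kd == has_log:
            raise _row_err(
                path, idx, "exactly one of kd_molar / log_affinity must be given"
            )
        try:
            if has_kd:
                log_aff = log_affinity_from_kd(float(row["kd_molar"]))
            else:
                log_aff = float(row["log_affinity"])
            if not math.isfinite(log_aff):
                raise ValueError(f"non-finite affinity {log_aff}")
            links.append(
                CompoundTargetLink(
                    het_code=row["het_code"],
                    target_protein_id=row["target_protein_id"],
                    structure_id=row["structure_id"],
                    log_affinity=log_aff,
                    family_id=row["family_id"],
                )
            )
        except ValueError as exc:
            raise _row_err(path, idx, str(exc))
    return links


def write_links_tsv(links: list[CompoundTargetLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "het_code\ttarget_protein_id\tstructure_id\tfamily_id\t"
            "kd_molar\tlog_affinity\n"
        )
        for ln in links:
            fh.write(
                f"{ln.het_code}\t{ln.target_protein_id}\t{ln.structure_id}\t"
                f"{ln.family_id}\t\t{ln.log_affinity!r}\n"
            )


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Digest record tying one output set to its exact inputs."""

    tool_version: str = __version__
    config_digest: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def collect(
        cls,
        config_path: str | Path | None,
        input_paths: dict[str, str | Path],
        seed: int | None = None,
    ) -> "RunManifest":
        cfg_digest = (
            _sha256_file(Path(config_path)) if config_path is not None else ""
        )
        digests = {
            name: _sha256_file(Path(p)) for name, p in sorted(input_paths.items())
        }
        return cls(config_digest=cfg_digest, input_digests=digests, seed=seed)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool_version": self.tool_version,
                    "config_digest": self.config_digest,
                    "input_digests": self.input_digests,
                    "seed": self.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
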