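"""End-to-end ranking pipeline: inputs -> homologue selection -> factors ->
composite scores -> ranking, report cards and manifest."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from agerank.config import RankingConfig
from agerank.conservation import (
    AlignedFamily,
    BindingSiteContacts,
    DomainAnnotation,
    SpeciesAbsentError,
    binding_site_conservation,
    contacts_to_columns,
    domain_conservation,
    global_identity,
    scoring_regions,
    select_homologue,
    site_identity,
)
from agerank.grantham import default_matrix
from agerank.io import (
    RunManifest,
    read_compounds_tsv,
    read_contacts_tsv,
    read_domains_tsv,
    read_evidence_tsv,
    read_family_fasta,
    read_links_tsv,
)
from agerank.ranking import (
    CompoundDisplay,
    RankedEntry,
    rank_compounds,
    render_report_card,
    write_ranking_tsv,
)
from agerank.scoring import (
    CompoundRecord,
    CompoundTargetLink,
    EvidenceAnnotation,
    FactorSet,
    ScoreBreakdown,
    affinity_factor,
    aggregate_targets,
    aging_implication,
    approval_bonus,
    bioavailability_factor,
    composite_score,
    go_evidence_score,
    lipinski_loss,
    promiscuity_loss,
    purchase_bonus,
)

logger = logging.getLogger("agerank")

__all__ = ["InputSet", "PipelineResult", "load_inputs", "run_pipeline", "write_outputs"]


@dataclass
class InputSet:
    """All in-memory inputs of one ranking run."""

    families: dict[str, AlignedFamily]
    contacts: dict[tuple[str, str], BindingSiteContacts]
    domains: dict[str, DomainAnnotation]
    compounds: dict[str, CompoundRecord]
    evidence: dict[str, EvidenceAnnotation]
    links: list[CompoundTargetLink]


@dataclass
class PipelineResult:
    """Ranking plus the bookkeeping needed for auditing a run."""

    species: str
    ranking: list[RankedEntry]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    manifest: RunManifest | None = None

    @property
    def n_ranked(self) -> int:
        return len(self.ranking)


def load_inputs(in_dir: str | Path) -> InputSet:
    """Load the documented flat-file layout from one directory.

    Expects ``families/*.fasta`` plus ``contacts.tsv``, ``domains.tsv``,
    ``compounds.tsv``, ``evidence.tsv`` and ``links.tsv``.
    """
    in_dir = Path(in_dir)
    families = {}
    for fasta in sorted((in_dir / "families").glob("*.fasta")):
        fam = read_family_fasta(fasta)
        families[fam.family_id] = fam
    if not families:
        raise FileNotFoundError(f"no family FASTA files under {in_dir/'families'}")
    return InputSet(
        families=families,
        contacts=read_contacts_tsv(in_dir / "contacts.tsv"),
        domains=read_domains_tsv(in_dir / "domains.tsv"),
        compounds=read_compounds_tsv(in_dir / "compounds.tsv"),
        evidence=read_evidence_tsv(in_dir / "evidence.tsv"),
        links=read_links_tsv(in_dir / "links.tsv"),
    )


def _evidence_for(inputs: InputSet, protein_id: str) -> EvidenceAnnotation:
    ann = inputs.evidence.get(protein_id)
    if ann is None:
        logger.warning(
            "no aging-evidence row for %s; assuming automatic annotation",
            protein_id,
        )
        ann = EvidenceAnnotation(protein_id=protein_id)
    return ann


def score_compound(
    het: str,
    inputs: InputSet,
    cfg: RankingConfig,
) -> tuple[ScoreBreakdown, CompoundDisplay]:
    """Score one compound for ``cfg.species``.

    Raises :class:`SpeciesAbsentError` when no target family of the
    compound has a homologue in the species.
    """
    compound = inputs.compounds[het]
    links = [ln for ln in inputs.links if ln.het_code == het]
    if not links:
        raise ValueError(f"compound {het!r} has no target links")
    matrix = default_matrix()

    per_target: list[tuple[float, float, float, float]] = []
    display_candidates: list[tuple[float, CompoundDisplay]] = []
    targets: set[str] = set()
    for link in links:
        family = inputs.families[link.family_id]
        key = (link.structure_id, het)
        if key not in inputs.contacts:
            raise ValueError(
                f"no ligand contacts for structure {link.structure_id}, "
                f"compound {het}"
            )
        contacts = inputs.contacts[key]
        site_cols = contacts_to_columns(family, contacts)
        try:
            member = select_homologue(family, cfg.species, site_cols, matrix)
        except SpeciesAbsentError:
            logger.debug(
                "compound %s: family %s has no %s member",
                het, link.family_id, cfg.species,
            )
            continue
        targets.add(link.target_protein_id)
        domains = inputs.domains.get(family.ref_id, DomainAnnotation([]))
        regions = scoring_regions(
            contacts, domains, family.ref_ungapped_length(), cfg.domain_window
        )
        dom = domain_conservation(family, member, regions, cfg.domain_logistic, matrix)
        site = binding_site_conservation(
            family, member, site_cols, matrix, cfg.k_rounding
        )
        aff = affinity_factor(link.log_affinity, cfg)
        ann = _evidence_for(inputs, link.target_protein_id)
        aging = aging_implication(
            go_evidence_score(ann), ann.n_identifier_mappings, cfg
        )
        per_target.append((dom, site, aff, aging))
        display_candidates.append(
            (
                site,
                CompoundDisplay(
                    names=list(compound.names),
                    targets=[],
                    global_identity=global_identity(
                        family,
                        member,
                        cfg.identity_denominator == "alignment",
                    ),
                    site_identity=site_identity(family, member, site_cols),
                ),
            )
        )
        logger.debug(
            "compound %s target %s via %s: domain=%.4f site=%.4f "
            "affinity=%.4f aging=%.4f",
            het, link.target_protein_id, member, dom, site, aff, aging,
        )

    if not per_target:
        raise SpeciesAbsentError(
            f"compound {het!r}: no target family has a {cfg.species} homologue"
        )

    dom, site, aff, aging = aggregate_targets(per_target)
    factors = FactorSet(
        aging=aging,
        domain_cons=dom,
        site_cons=site,
        affinity=aff,
        bioavailability=bioavailability_factor(
            cfg.species, compound.burns_score, cfg
        ),
    )
    # promiscuity counts every distinct aging-related protein the compound
    # is crystallized with, whether or not it has a homologue in this species
    n_targets = (
        compound.n_aging_targets
        if compound.n_aging_targets is not None
        else len({ln.target_protein_id for ln in links})
    )
    breakdown = composite_score(
        factors,
        lipinski=lipinski_loss(compound.violation_count()),
        promiscuity=promiscuity_loss(n_targets, cfg),
        purchase=purchase_bonus(compound.purchasable),
        approval=approval_bonus(compound.approval),
    )
    # display identities come from the best-conserved binding site
    display = max(display_candidates, key=lambda c: c[0])[1]
    display.targets = sorted(targets)
    return breakdown, display


def run_pipeline(inputs: InputSet, cfg: RankingConfig) -> PipelineResult:
    """Score and rank every rankable compound for the configured species.

    Compounds whose target families all lack a homologue in the species
    are excluded and recorded (reason ``no_homologue``); compounds with
    missing or invalid inputs are recorded as ``invalid``.
    """
    breakdowns: dict[str, ScoreBreakdown] = {}
    display: dict[str, CompoundDisplay] = {}
    excluded: list[tuple[str, str]] = []
    for het in sorted(inputs.compounds):
        try:
            bd, disp = score_compound(het, inputs, cfg)
        except SpeciesAbsentError:
            logger.info("excluding %s: no %s homologue", het, cfg.species)
            excluded.append((het, "no_homologue"))
            continue
        except ValueError as exc:
            logger.warning("excluding %s: %s", het, exc)
            excluded.append((het, "invalid"))
            continue
        breakdowns[het] = bd
        display[het] = disp
    if not breakdowns:
        logger.warning("no compound survived filtering for %s", cfg.species)
    ranking = rank_compounds(breakdowns, display)
    return PipelineResult(species=cfg.species, ranking=ranking, excluded=excluded)


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    manifest: RunManifest | None = None,
    html: bool = False,
) -> None:
    """Write ranking TSV, JSON (optionally HTML) report cards, the exclusion
    log and the manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_ranking_tsv(result.ranking, out_dir / f"ranking_{result.species}.tsv")
    cards = out_dir / "report_cards"
    cards.mkdir(exist_ok=True)
    for entry in result.ranking:
        (cards / f"{entry.het_code}_{result.species}.json").write_text(
            render_report_card(entry, "json") + "\n"
        )
        if html:
            (cards / f"{entry.het_code}_{result.species}.html").write_text(
                render_report_card(entry, "html")
            )
    with open(out_dir / f"excluded_{result.species}.tsv", "w") as fh:
        fh.write("het_code\treason\n")
        for het, reason in result.excluded:
            fh.write(f"{het}\t{reason}\n")
    if manifest is not None:
        manifest.to_json(out_dir / "manifest.json")
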