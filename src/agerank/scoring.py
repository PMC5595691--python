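"""Factor and term computations and the composite ranking score.

The ranking score for one compound in one target species is

    score = clip01( aging * domain_cons * site_cons * affinity * bioavail
                    + lipinski_loss + promiscuity_loss
                    + purchase_bonus + approval_bonus )

with the five factors in [0, 1] multiplicatively linked (a weak factor
cannot be compensated by a strong one) and four small additive terms for
drug-likeness, promiscuity, purchasability and approval status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

from agerank.config import (
    FACTOR_NAMES,
    TERM_NAMES,
    LogisticParams,
    RankingConfig,
)

__all__ = [
    "EvidenceAnnotation",
    "CompoundRecord",
    "CompoundTargetLink",
    "FactorSet",
    "ScoreBreakdown",
    "logistic",
    "go_evidence_score",
    "aging_implication",
    "log_affinity_from_kd",
    "affinity_factor",
    "bioavailability_factor",
    "lipinski_violations",
    "lipinski_loss",
    "promiscuity_loss",
    "purchase_bonus",
    "approval_bonus",
    "aggregate_targets",
    "composite_score",
    "tailored_score",
]

EVIDENCE_CATEGORIES = (
    "experimental",
    "computational",
    "author_curator",
    "automatic_or_none",
)

APPROVAL_STATUSES = ("chembl_drug", "drugbank_only", "none")


@dataclass(frozen=True)
class EvidenceAnnotation:
    """Provenance of the aging association of one target protein.

    ``category`` is the Gene Ontology evidence class; ``via_orthologue``
    marks annotations transferred from an orthologue rather than observed
    on the protein itself; ``n_identifier_mappings`` counts identifier
    mapping steps from the evidence source to the target protein; ``genage``
    marks membership in the GenAge curated database of aging genes.
    """

    protein_id: str
    category: str = "automatic_or_none"
    via_orthologue: bool = False
    n_identifier_mappings: int = 0
    genage: bool = False

    def __post_init__(self) -> None:
        if self.category not in EVIDENCE_CATEGORIES:
            raise ValueError(f"invalid evidence category: {self.category!r}")
        if self.n_identifier_mappings < 0:
            raise ValueError("n_identifier_mappings must be >= 0")


@dataclass
class CompoundRecord:
    """Per-compound annotations independent of any single target."""

    het_code: str
    names: list[str] = field(default_factory=list)
    #: Either a precomputed violation count or the four descriptors
    #: (molecular weight / Da, logP, H-bond donors, H-bond acceptors).
    lipinski_violations: Optional[int] = None
    lipinski_descriptors: Optional[tuple[float, float, int, int]] = None
    purchasable: bool = False
    approval: str = "none"
    burns_score: Optional[float] = None
    #: Distinct aging-related proteins the compound is crystallized with;
    #: when None, derived from the link table at ranking time.
    n_aging_targets: Optional[int] = None

    def __post_init__(self) -> None:
        if self.approval not in APPROVAL_STATUSES:
            raise ValueError(f"invalid approval status: {self.approval!r}")
        if self.n_aging_targets is not None and self.n_aging_targets < 0:
            raise ValueError("n_aging_targets must be >= 0")
        if self.lipinski_violations is not None and self.lipinski_violations < 0:
            raise ValueError("lipinski violation count must be >= 0")

    def violation_count(self) -> int:
        if self.lipinski_violations is not None:
            return self.lipinski_violations
        if self.lipinski_descriptors is not None:
            return lipinski_violations(*self.lipinski_descriptors)
        raise ValueError(
            f"compound {self.het_code}: neither Lipinski violation count "
            "nor descriptors available"
        )


@dataclass(frozen=True)
class CompoundTargetLink:
    """One (compound, target protein, structure) association.

    ``log_affinity`` is the predicted log-binding affinity
    (-log10 Kd with Kd in molar, i.e. pKd; machine-learned
    structure-based prediction consumed as an input scalar).
    """

    het_code: str
    target_protein_id: str
    structure_id: str
    log_affinity: float
    family_id: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_affinity):
            raise ValueError("log_affinity must be finite")


@dataclass
class FactorSet:
    """The five multiplicative factors, each in [0, 1]."""

    aging: float
    domain_cons: float
    site_cons: float
    affinity: float
    bioavailability: float

    def __post_init__(self) -> None:
        for name in FACTOR_NAMES:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ValueError(f"factor {name} outside [0,1]: {v}")

    def product(self) -> float:
        return (
            self.aging
            * self.domain_cons
            * self.site_cons
            * self.affinity
            * self.bioavailability
        )


@dataclass
class ScoreBreakdown:
    """Factors, terms and the final clipped score for one compound."""

    factors: FactorSet
    lipinski_loss: float = 0.0
    promiscuity_loss: float = 0.0
    purchase_bonus: float = 0.0
    approval_bonus: float = 0.0
    final: float = 0.0

    def __post_init__(self) -> None:
        if self.lipinski_loss > 0 or self.promiscuity_loss > 0:
            raise ValueError("losses must be <= 0")
        if self.purchase_bonus < 0 or self.approval_bonus < 0:
            raise ValueError("bonuses must be >= 0")

    def terms_sum(self) -> float:
        return (
            self.lipinski_loss
            + self.promiscuity_loss
            + self.purchase_bonus
            + self.approval_bonus
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScoreBreakdown":
        raw = dict(raw)
        raw["factors"] = FactorSet(**raw["factors"])
        return cls(**raw)


def _clip01(x: float) -> float:
    return max(min(x, 1.0), 0.0)


def logistic(x: float, location: float, scale: float) -> float:
    """Standard logistic 1/(1 + exp(-(x - location)/scale)), on (0, 1).

    Strictly increasing in ``x`` with value 0.5 at ``x == location``.
    """
    if scale <= 0:
        raise ValueError(f"logistic scale must be > 0, got {scale}")
    z = (x - location) / scale
    if z < -700.0:  # exp(-z) would overflow; the true value underflows to 0
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


#: GO-evidence score by (category, via-orthologue) — smaller is stronger
#: evidence.  The aging factor subtracts from 1, so experimental evidence
#: (0.01/0.02) leaves the factor near its maximum.
_EVIDENCE_SCORES = {
    ("experimental", False): 0.01,
    ("experimental", True): 0.02,
    ("computational", False): 0.15,
    ("computational", True): 0.16,
    ("author_curator", False): 0.16,
    ("author_curator", True): 0.16,
    ("automatic_or_none", False): 0.28,
    ("automatic_or_none", True): 0.29,
}

GENAGE_EVIDENCE_SCORE = 0.01


def go_evidence_score(ann: EvidenceAnnotation) -> float:
    """Evidence score of an aging annotation; GenAge membership forces 0.01."""
    if ann.genage:
        return GENAGE_EVIDENCE_SCORE
    return _EVIDENCE_SCORES[(ann.category, ann.via_orthologue)]


def aging_implication(
    ev_score: float,
    n_mappings: int,
    cfg: RankingConfig | None = None,
) -> float:
    """Aging-implication factor: closeness of the target to direct aging evidence.

    Default reading: ``1 - (ev + w*m)/2`` with ``w`` the mapping penalty
    weight (0.1) and ``m`` the number of identifier-mapping steps; an
    alternative reading ``1 - ev - w*m/2`` is selectable via
    ``cfg.aging_formula``.  Floored at 0.
    """
    cfg = cfg or RankingConfig()
    if not 0.0 <= ev_score <= 1.0:
        raise ValueError(f"evidence score outside [0,1]: {ev_score}")
    w = cfg.mapping_penalty_weight
    if cfg.aging_formula == "half_total":
        value = 1.0 - (ev_score + w * n_mappings) / 2.0
    else:  # half_mappings
        value = 1.0 - ev_score - w * n_mappings / 2.0
    return max(value, 0.0)


def log_affinity_from_kd(kd_molar: float) -> float:
    """pKd = -log10(Kd [M]); e.g. 100 nM -> 7."""
    if kd_molar <= 0:
        raise ValueError(f"Kd must be positive, got {kd_molar}")
    return -math.log10(kd_molar)


def affinity_factor(log_affinity: float, cfg: RankingConfig | None = None) -> float:
    """Binding-affinity factor: logistic(pKd; 5, 1) by default."""
    p = (cfg or RankingConfig()).affinity_logistic
    return logistic(log_affinity, p.location, p.scale)


def bioavailability_factor(
    species: str,
    burns_score: Optional[float] = None,
    cfg: RankingConfig | None = None,
) -> float:
    """Bioavailability factor per species.

    For species with a bioaccumulation predictor (*C. elegans*):
    ``logistic(burns; 4, 2.25) * 0.8 + 0.2``, ranging over (0.2, 1.0).
    Other target species (*D. melanogaster*) use the constant stand-in 0.9.
    """
    cfg = cfg or RankingConfig()
    if species in cfg.bioavailability_predictor_species:
        if burns_score is None:
            raise ValueError(
                f"bioavailability for {species} requires a predictor score"
            )
        p = cfg.bioavailability_logistic
        return logistic(burns_score, p.location, p.scale) * 0.8 + 0.2
    return cfg.bioavailability_constant


def lipinski_violations(mw: float, logp: float, hbd: int, hba: int) -> int:
    """Count violations of the rule of five.

    Rules: molecular weight < 500 Da, logP <= 5, H-bond donors <= 5,
    H-bond acceptors <= 10; one violation per broken rule.
    """
    for v in (mw, logp):
        if not math.isfinite(v):
            raise ValueError("descriptors must be finite")
    return int(mw >= 500) + int(logp > 5) + int(hbd > 5) + int(hba > 10)


def lipinski_loss(n_violations: int) -> float:
    """Drug-likeness loss: -n/20, i.e. -0.05 per violated rule."""
    if n_violations < 0:
        raise ValueError("violation count must be >= 0")
    return -n_violations / 20.0


def promiscuity_loss(n_targets: int, cfg: RankingConfig | None = None) -> float:
    """Promiscuity loss -logistic(n; 7, 1)/5: specific binders lose ~0,
    omnipresent metabolites approach -0.2."""
    if n_targets < 0:
        raise ValueError("target count must be >= 0")
    p = (cfg or RankingConfig()).promiscuity_logistic
    return -logistic(float(n_targets), p.location, p.scale) / 5.0


def purchase_bonus(purchasable: bool) -> float:
    """+0.1 for compounds listed in a commercial-availability database."""
    return 0.1 if purchasable else 0.0


def approval_bonus(status: str) -> float:
    """+0.1 for ChEMBL-designated drugs, +0.075 for DrugBank-only entries."""
    if status not in APPROVAL_STATUSES:
        raise ValueError(f"invalid approval status: {status!r}")
    return {"chembl_drug": 0.1, "drugbank_only": 0.075, "none": 0.0}[status]


def aggregate_targets(
    per_target: Sequence[tuple[float, ...]],
) -> tuple[float, ...]:
    """Element-wise maximum of per-target factor tuples.

    For compounds binding several aging-related proteins, the best
    (maximum) domain conservation, binding-site conservation and binding
    affinity across targets are used; an optional fourth element (aging
    implication) is aggregated by maximum as well.
    """
    if not per_target:
        raise ValueError("aggregate_targets requires at least one target")
    width = len(per_target[0])
    if any(len(t) != width for t in per_target):
        raise ValueError("ragged per-target factor tuples")
    return tuple(max(t[i] for t in per_target) for i in range(width))


def composite_score(
    factors: FactorSet,
    lipinski: float = 0.0,
    promiscuity: float = 0.0,
    purchase: float = 0.0,
    approval: float = 0.0,
) -> ScoreBreakdown:
    """Combine factors and terms into the final clipped ranking score."""
    breakdown = ScoreBreakdown(
        factors=factors,
        lipinski_loss=lipinski,
        promiscuity_loss=promiscuity,
        purchase_bonus=purchase,
        approval_bonus=approval,
    )
    breakdown.final = _clip01(factors.product() + breakdown.terms_sum())
    return breakdown


def tailored_score(
    breakdown: ScoreBreakdown,
    factor_weights: dict[str, float] | None = None,
    term_weights: dict[str, float] | None = None,
) -> float:
    """Reweighted score: factors enter as factor**w, terms scaled by w.

    A factor weight of 0 excludes that factor (neutral contribution 1);
    all weights 1 reproduces the standard composite score exactly.
    """
    fw = {name: 1.0 for name in FACTOR_NAMES}
    fw.update(factor_weights or {})
    tw = {name: 1.0 for name in TERM_NAMES}
    tw.update(term_weights or {})
    for name, w in {**fw, **tw}.items():
        if w < 0:
            raise ValueError(f"negative weight for {name}: {w}")
    product = 1.0
    for name in FACTOR_NAMES:
        base = getattr(breakdown.factors, name)
        w = fw[name]
        if w == 0:
            continue
        product *= base**w
    terms = sum(getattr(breakdown, name) * tw[name] for name in TERM_NAMES)
    return _clip01(product + terms)
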