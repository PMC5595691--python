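"""Run configuration: species, transform parameters, weights and switches."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Species tags accepted in alignment headers and tables.
DEFAULT_SPECIES_VOCABULARY = (
    "hsapiens",
    "mmusculus",
    "rnorvegicus",
    "dmelanogaster",
    "celegans",
)

#: The two species compounds are ranked for.
TARGET_SPECIES = ("celegans", "dmelanogaster")

FACTOR_NAMES = ("aging", "domain_cons", "site_cons", "affinity", "bioavailability")
TERM_NAMES = ("lipinski_loss", "promiscuity_loss", "purchase_bonus", "approval_bonus")


@dataclass
class LogisticParams:
    """Location ``l`` and scale ``s`` of 1/(1+exp(-(x-l)/s))."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"logistic scale must be > 0, got {self.scale}")


@dataclass
class RankingConfig:
    """All tunable parameters of the ranking procedure.

    Defaults reproduce the published procedure: logistic transforms with
    (location, scale) of (5, 1) for binding affinity, (0.6, 0.1) for domain
    conservation, (7, 1) for promiscuity and (4, 2.25) for the *C. elegans*
    bioavailability predictor score; a constant 0.9 bioavailability stand-in
    for *D. melanogaster*; a +-50 residue window around binding-site contacts
    falling outside annotated domains; and the lowest-half ("50% most
    dissimilar") rule for binding-site conservation.
    """

    species: str = "dmelanogaster"

    affinity_logistic: LogisticParams = field(
        default_factory=lambda: LogisticParams(5.0, 1.0)
    )
    domain_logistic: LogisticParams = field(
        default_factory=lambda: LogisticParams(0.6, 0.1)
    )
    promiscuity_logistic: LogisticParams = field(
        default_factory=lambda: LogisticParams(7.0, 1.0)
    )
    bioavailability_logistic: LogisticParams = field(
        default_factory=lambda: LogisticParams(4.0, 2.25)
    )
    #: Constant bioavailability used for species without a predictor.
    bioavailability_constant: float = 0.9
    #: Species whose bioavailability uses the predictor-scaled transform.
    bioavailability_predictor_species: tuple[str, ...] = ("celegans",)

    #: Penalty weight per identifier-mapping step in the aging factor.
    mapping_penalty_weight: float = 0.1
    #: "half_total": 1 - (ev + w*m)/2  (default reading);
    #: "half_mappings": 1 - ev - w*m/2 (alternative reading).
    aging_formula: str = "half_total"

    #: Window (residues) around contacts outside annotated domains.
    domain_window: int = 50
    #: "floor" or "ceil" for k = N/2 in the lowest-half site rule.
    k_rounding: str = "floor"
    #: Identity denominator: "reference" (reference non-gap columns) or
    #: "alignment" (all considered columns incl. reference gaps).
    identity_denominator: str = "reference"

    #: Per-factor exponents and per-term multipliers for tailored rankings.
    factor_weights: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in FACTOR_NAMES}
    )
    term_weights: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in TERM_NAMES}
    )

    species_vocabulary: tuple[str, ...] = DEFAULT_SPECIES_VOCABULARY

    def __post_init__(self) -> None:
        if self.aging_formula not in ("half_total", "half_mappings"):
            raise ValueError(f"unknown aging formula: {self.aging_formula!r}")
        if self.k_rounding not in ("floor", "ceil"):
            raise ValueError(f"unknown k rounding mode: {self.k_rounding!r}")
        if self.identity_denominator not in ("reference", "alignment"):
            raise ValueError(
                f"unknown identity denominator: {self.identity_denominator!r}"
            )
        if self.domain_window < 0:
            raise ValueError("domain window must be >= 0")
        for name, w in {**self.factor_weights, **self.term_weights}.items():
            if w < 0:
                raise ValueError(f"negative weight for {name}: {w}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RankingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "affinity_logistic",
            "domain_logistic",
            "promiscuity_logistic",
            "bioavailability_logistic",
        ):
            if key in raw:
                raw[key] = LogisticParams(**raw[key])
        for key in ("bioavailability_predictor_species", "species_vocabulary"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for key, val in raw.items():
            if isinstance(val, tuple):
                raw[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)
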