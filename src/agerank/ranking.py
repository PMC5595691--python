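"""Rankings, score-distribution cutoffs and per-compound report cards."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

from agerank.scoring import ScoreBreakdown

__all__ = [
    "RankedEntry",
    "rank_compounds",
    "score_cutoffs",
    "render_report_card",
    "write_ranking_tsv",
    "read_ranking_tsv",
]

#: Ranking-table columns, mirroring the standard compound-ranking layout.
TABLE_COLUMNS = (
    "rank",
    "het_code",
    "name",
    "targets",
    "global_identity",
    "site_identity",
    "aging",
    "domain_cons",
    "site_cons",
    "affinity",
    "bioavailability",
    "lipinski_loss",
    "promiscuity_loss",
    "purchase_bonus",
    "approval_bonus",
    "final",
)


@dataclass
class RankedEntry:
    """One compound's position and full score breakdown in a ranking."""

    rank: int
    het_code: str
    names: list[str]
    targets: list[str]
    global_identity: int
    site_identity: int
    breakdown: ScoreBreakdown

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RankedEntry":
        raw = dict(raw)
        raw["breakdown"] = ScoreBreakdown.from_dict(raw["breakdown"])
        return cls(**raw)


@dataclass
class CompoundDisplay:
    """Display metadata attached to a breakdown when building a ranking."""

    names: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    global_identity: int = 0
    site_identity: int = 0


def rank_compounds(
    breakdowns: Mapping[str, ScoreBreakdown] | Iterable[tuple[str, ScoreBreakdown]],
    display: Mapping[str, CompoundDisplay] | None = None,
) -> list[RankedEntry]:
    """Order compounds by decreasing final score.

    Ties are broken by ascending HET code and receive distinct consecutive
    ranks.  ``display`` optionally supplies names/targets/identity columns
    per HET code.
    """
    if isinstance(breakdowns, Mapping):
        pairs = list(breakdowns.items())
    else:
        pairs = list(breakdowns)
        seen: set[str] = set()
        for het, _ in pairs:
            if het in seen:
                raise ValueError(f"duplicate compound code in ranking: {het!r}")
            seen.add(het)
    pairs.sort(key=lambda kv: (-kv[1].final, kv[0]))
    display = display or {}
    entries = []
    for rank, (het, bd) in enumerate(pairs, start=1):
        meta = display.get(het, CompoundDisplay())
        entries.append(
            RankedEntry(
                rank=rank,
                het_code=het,
                names=list(meta.names),
                targets=list(meta.targets),
                global_identity=meta.global_identity,
                site_identity=meta.site_identity,
                breakdown=bd,
            )
        )
    return entries


def score_cutoffs(ranking: list[RankedEntry]) -> tuple[float, float]:
    """(top-15 cutoff, top-10% cutoff) of a ranking.

    The top-15 cutoff is the score at rank min(15, N); the top-10% cutoff
    the score at rank max(1, floor(N/10)).
    """
    if not ranking:
        raise ValueError("cannot compute cutoffs of an empty ranking")
    n = len(ranking)
    top15 = ranking[min(15, n) - 1].breakdown.final
    top10pct = ranking[max(1, n // 10) - 1].breakdown.final
    return top15, top10pct


def _fmt2(x: float) -> str:
    return f"{x:.2f}"


def _entry_json_obj(entry: RankedEntry) -> dict:
    obj = entry.to_dict()
    obj["final_display"] = _fmt2(entry.breakdown.final)
    obj["final_6dp"] = round(entry.breakdown.final, 6)
    return obj


def render_report_card(entry: RankedEntry, fmt: str = "json") -> str:
    """Render one compound's report card.

    Formats: ``json`` (full precision, round-trips to an identical entry),
    ``html`` (static card, 2-decimal display) and ``tsv-row`` (one
    ranking-table row with the standard 16 columns).
    """
    if fmt == "json":
        return json.dumps(
            _entry_json_obj(entry), sort_keys=True, separators=(",", ":")
        )
    if fmt == "tsv-row":
        return "\t".join(_tsv_fields(entry, display=True))
    if fmt == "html":
        return _render_html(entry)
    raise ValueError(f"unknown report-card format: {fmt!r}")


def entry_from_report_card(doc: str) -> RankedEntry:
    """Inverse of the JSON report card."""
    obj = json.loads(doc)
    obj.pop("final_display", None)
    obj.pop("final_6dp", None)
    return RankedEntry.from_dict(obj)


def _render_html(entry: RankedEntry) -> str:
    bd = entry.breakdown
    f = bd.factors
    rows = [
        ("Rank", str(entry.rank)),
        ("PDB HET code", entry.het_code),
        ("Name", "; ".join(entry.names) or "NA"),
        ("Targets", ", ".join(entry.targets)),
        ("Global identity", f"{entry.global_identity}%"),
        ("Binding-site identity", f"{entry.site_identity}%"),
        ("Aging implication", _fmt2(f.aging)),
        ("Domain conservation", _fmt2(f.domain_cons)),
        ("Binding-site conservation", _fmt2(f.site_cons)),
        ("Binding affinity", _fmt2(f.affinity)),
        ("Bioavailability", _fmt2(f.bioavailability)),
        ("Lipinski loss", _fmt2(bd.lipinski_loss)),
        ("Promiscuity loss", _fmt2(bd.promiscuity_loss)),
        ("Purchasability bonus", _fmt2(bd.purchase_bonus)),
        ("Drug approval bonus", _fmt2(bd.approval_bonus)),
        ("Final score", _fmt2(bd.final)),
    ]
    body = "\n".join(
        f"    <tr><th>{k}</th><td>{v}</td></tr>" for k, v in rows
    )
    links = (
        f'    <p><a href="https://www.rcsb.org/ligand/{entry.het_code}">PDB '
        f"ligand {entry.het_code}</a></p>"
    )
    return (
        "<!DOCTYPE html>\n<html>\n<head><meta charset='utf-8'>"
        f"<title>Report card {entry.het_code}</title></head>\n<body>\n"
        f"  <h1>Compound {entry.het_code}</h1>\n  <table>\n{body}\n  </table>\n"
        f"{links}\n</body>\n</html>\n"
    )


def _tsv_fields(entry: RankedEntry, display: bool) -> list[str]:
    bd = entry.breakdown
    f = bd.factors
    num = _fmt2 if display else repr
    return [
        str(entry.rank),
        entry.het_code,
        ";".join(entry.names),
        ";".join(entry.targets),
        str(entry.global_identity),
        str(entry.site_identity),
        num(f.aging),
        num(f.domain_cons),
        num(f.site_cons),
        num(f.affinity),
        num(f.bioavailability),
        num(bd.lipinski_loss),
        num(bd.promiscuity_loss),
        num(bd.purchase_bonus),
        num(bd.approval_bonus),
        num(bd.final),
    ]


def write_ranking_tsv(entries: list[RankedEntry], path: str | Path) -> None:
    """Write a ranking at full float precision (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for entry in entries:
            fh.write("\t".join(_tsv_fields(entry, display=False)) + "\n")


class RankingParseError(ValueError):
    """A ranking TSV line could not be parsed; carries the line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def read_ranking_tsv(path: str | Path) -> list[RankedEntry]:
    """Inverse of :func:`write_ranking_tsv`."""
    from agerank.scoring import FactorSet

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != list(TABLE_COLUMNS):
        raise RankingParseError(1, "missing or malformed header")
    entries = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(TABLE_COLUMNS):
            raise RankingParseError(
                line_no,
                f"expected {len(TABLE_COLUMNS)} columns, got {len(fields)}",
            )
        try:
            factors = FactorSet(
                aging=float(fields[6]),
                domain_cons=float(fields[7]),
                site_cons=float(fields[8]),
                affinity=float(fields[9]),
                bioavailability=float(fields[10]),
            )
            bd = ScoreBreakdown(
                factors=factors,
                lipinski_loss=float(fields[11]),
                promiscuity_loss=float(fields[12]),
                purchase_bonus=float(fields[13]),
                approval_bonus=float(fields[14]),
                final=float(fields[15]),
            )
            entries.append(
                RankedEntry(
                    rank=int(fields[0]),
                    het_code=fields[1],
                    names=[n for n in fields[2].split(";") if n],
                    targets=[t for t in fields[3].split(";") if t],
                    global_identity=int(fields[4]),
                    site_identity=int(fields[5]),
                    breakdown=bd,
                )
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, RankingParseError):
                raise
            raise RankingParseError(line_no, str(exc)) from exc
    return entries
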