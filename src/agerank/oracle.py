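"""Straight-line reference recomputation of every ranking formula.

This module deliberately re-derives all factors and the composite score
from raw fixture data with no code shared with :mod:`agerank.scoring` or
:mod:`agerank.conservation`, so that the pipeline can be validated against
an independent second implementation.  It only handles the fixture
conventions (gapless alignments, standard residues, one structure per
link); the production modules are the general implementation.
"""

from __future__ import annotations

import math
from importlib import resources


def _load_distances() -> dict[tuple[str, str], int]:
    text = resources.files("agerank.data").joinpath("grantham_distance.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    dist = {}
    for line in lines[1:]:
        fields = line.split("\t")
        for col, val in zip(header, fields[1:]):
            dist[(fields[0], col)] = int(val)
    return dist


def oracle_breakdowns(raw: dict, species: str) -> dict:
    """Expected scores for one species from the raw fixture description.

    ``raw`` is the plain-data fixture structure produced by the generator
    (families with ungapped member sequences, per-link contacts and log
    affinities, compound annotations, evidence rows).  Returns
    ``{"scores": {het: {...}}, "excluded": [het, ...]}``.
    """
    dist = _load_distances()

    def sim(a: str, b: str) -> float:
        return 1.0 - dist[(a, b)] / 215.0

    def logi(x: float, l: float, s: float) -> float:
        return 1.0 / (1.0 + math.exp(-(x - l) / s))

    scores: dict[str, dict] = {}
    excluded: list[str] = []
    for het in sorted(raw["compounds"]):
        comp = raw["compounds"][het]
        per_target = []
        for link in raw["links"]:
            if link["het_code"] != het:
                continue
            fam = raw["families"][link["family_id"]]
            members = sorted(
                m
                for m, sp in fam["species_of"].items()
                if sp == species and m != fam["ref_id"]
            )
            if not members:
                continue
            ref = fam["seqs"][fam["ref_id"]]
            site = sorted(raw["contacts"][link["structure_id"]])

            # representative homologue: fewest site gaps (none here), then
            # highest mean site similarity, then identity, then first id
            def key(m):
                seq = fam["seqs"][m]
                sims = [sim(ref[p - 1], seq[p - 1]) for p in site]
                ident = sum(ref[p - 1] == seq[p - 1] for p in site) / len(site)
                return (0, -(sum(sims) / len(sims)), -ident, m)

            member = min(members, key=key)
            seq = fam["seqs"][member]

            # binding-site conservation: mean of the floor(N/2) lowest sims
            sims = sorted(sim(ref[p - 1], seq[p - 1]) for p in site)
            k = max(1, len(sims) // 2)
            site_cons = sum(sims[:k]) / k

            # domain regions: whole domains holding a contact, +-50 windows
            # for contacts outside every domain, merged union
            pieces = []
            for start, end in fam["domains"]:
                if any(start <= p <= end for p in site):
                    pieces.append((start, end))
            for p in site:
                if not any(s <= p <= e for s, e in fam["domains"]):
                    pieces.append((max(1, p - 50), min(len(ref), p + 50)))
            positions = sorted(
                {q for s, e in pieces for q in range(s, e + 1)}
            )
            dom_sim = sum(
                sim(ref[q - 1], seq[q - 1]) for q in positions
            ) / len(positions)
            dom_cons = logi(dom_sim, 0.6, 0.1)

            affinity = logi(link["log_affinity"], 5.0, 1.0)

            ev = raw["evidence"][link["target_protein_id"]]
            if ev["genage"]:
                ev_score = 0.01
            else:
                ev_score = {
                    ("experimental", False): 0.01,
                    ("experimental", True): 0.02,
                    ("computational", False): 0.15,
                    ("computational", True): 0.16,
                    ("author_curator", False): 0.16,
                    ("author_curator", True): 0.16,
                    ("automatic_or_none", False): 0.28,
                    ("automatic_or_none", True): 0.29,
                }[(ev["category"], ev["via_orthologue"])]
            aging = max(
                0.0, 1.0 - (ev_score + 0.1 * ev["n_identifier_mappings"]) / 2.0
            )
            per_target.append((dom_cons, site_cons, affinity, aging))

        if not per_target:
            excluded.append(het)
            continue

        dom_cons = max(t[0] for t in per_target)
        site_cons = max(t[1] for t in per_target)
        affinity = max(t[2] for t in per_target)
        aging = max(t[3] for t in per_target)

        if species == "celegans":
            bio = logi(comp["burns_score"], 4.0, 2.25) * 0.8 + 0.2
        else:
            bio = 0.9

        mw, logp, hbd, hba = comp["lipinski"]
        n_viol = (mw >= 500) + (logp > 5) + (hbd > 5) + (hba > 10)
        lip = -n_viol / 20.0
        n_targets = len(
            {
                link["target_protein_id"]
                for link in raw["links"]
                if link["het_code"] == het
            }
        )
        prom = -logi(float(n_targets), 7.0, 1.0) / 5.0
        buy = 0.1 if comp["purchasable"] else 0.0
        appr = {"chembl_drug": 0.1, "drugbank_only": 0.075, "none": 0.0}[
            comp["approval"]
        ]

        product = aging * dom_cons * site_cons * affinity * bio
        final = max(min(product + (lip + prom + buy + appr), 1.0), 0.0)
        scores[het] = {
            "aging": aging,
            "domain_cons": dom_cons,
            "site_cons": site_cons,
            "affinity": affinity,
            "bioavailability": bio,
            "lipinski_loss": lip,
            "promiscuity_loss": prom,
            "purchase_bonus": buy,
            "approval_bonus": appr,
            "final": final,
        }
    return {"scores": scores, "excluded": excluded}
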