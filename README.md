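# agerank

Rank drug-like compounds by their likelihood of modulating aging in the
invertebrate model organisms *Caenorhabditis elegans* and *Drosophila
melanogaster*.

Aging research needs pharmacological probes, but compound binding data
exist almost exclusively for mammalian proteins. `agerank` transfers that
knowledge across species: given compounds with solved complex structures
on aging-associated mammalian targets, it asks how likely each compound is
to keep working on the worm or fly orthologue — and to be worth testing in
a lifespan experiment at all.

## The scoring function

For each compound and target species the package computes a bounded
empirical score

```
score = clip_[0,1]( Aging · DomainCons · SiteCons · Affinity · Bioavail
                    + Lipinski_loss + Promiscuity_loss
                    + Purchase_bonus + Approval_bonus )
```

The five factors are multiplicative — a compound that fails any one of
them (an unconserved binding site, millimolar affinity, no bioavailability)
cannot be rescued by the others:

* **Aging implication** `1 − (ev + 0.1·m)/2`, from the Gene Ontology
  evidence class `ev` of the target's aging annotation (experimental 0.01
  … automatic 0.29; GenAge membership forces 0.01) and the number of
  identifier-mapping steps `m`.
* **Domain conservation** `logistic(s̄; 0.6, 0.1)`, where `s̄` is the mean
  Grantham-based similarity (`1 − d/215`) between the structure's sequence
  and the species orthologue over every domain touching the ligand, with a
  ±50-residue window around contacts outside annotated domains.
* **Binding-site conservation** — mean Grantham similarity of the 50 %
  *most dissimilar* ligand-contact positions (the conserved half of a
  typical site is uninformative).
* **Binding affinity** `logistic(pKd; 5, 1)` of the predicted log-binding
  affinity (e.g. 100 nM → pKd 7 → 0.88).
* **Bioavailability** — `logistic(burns; 4, 2.25)·0.8 + 0.2` from the
  worm bioaccumulation predictor score for *C. elegans*; a fixed 0.9
  stand-in for *D. melanogaster*, where no predictor exists.

The additive terms are small nudges: −0.05 per violated Lipinski rule,
−logistic(#targets; 7, 1)/5 for promiscuous binders, +0.1 if purchasable,
+0.1 / +0.075 for approved drugs / DrugBank entries.

Orthologues are chosen per family and species by fewest alignment gaps in
the binding site, then highest site similarity and identity. Compounds
whose target families have no orthologue in the species are excluded and
logged.

## Worked example

Generate a deterministic synthetic dataset (aligned families, contacts,
domains, compounds, evidence, links) and rank it for the worm:

```
$ agerank simulate --seed 1 --out-dir demo_in --n-families 2 --n-compounds 4
wrote synthetic inputs under demo_in
$ agerank rank --in-dir demo_in --out-dir demo_out --species celegans
ranked 4 compounds for celegans (0 excluded); top-15 cutoff 0.46, top-10% cutoff 0.63
```

`demo_out/ranking_celegans.tsv` holds the full-precision ranking;
compounds whose target families lack a worm orthologue would be listed
with a reason in `demo_out/excluded_celegans.tsv`. A report card for the
top compound:

```
$ agerank report --ranking-tsv demo_out/ranking_celegans.tsv --het Q1E --fmt tsv-row
1	Q1E	compound-q1e	TP_FAM002	66	100	0.92	0.93	1.00	0.87	0.65	-0.05	-0.00	0.10	0.10	0.63
```

reading: rank 1, target TP_FAM002, 66 % global / 100 % binding-site
identity, then aging implication 0.92, domain conservation 0.93, a fully
conserved binding site (1.00), affinity 0.87, bioavailability 0.65 (the
predictor score is the limiting factor for the worm), one Lipinski
violation (−0.05), negligible promiscuity loss, purchasable (+0.10),
an approved drug (+0.10), final score 0.63.

The same data can be scored per compound (`agerank score`), validated
(`agerank validate-tables`), or re-ranked with tailored factor weights via
the library (`agerank.scoring.tailored_score`).

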