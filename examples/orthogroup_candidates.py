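"""Orthogroup pattern classes, candidate genes and term enrichment.

Classifies a handful of orthogroups across four kleptoplastic slugs plus a
sea-hare outgroup, intersects the kleptoplast-specific class with a DEG set,
and tests a functional term for enrichment.
"""

from kleptoscreen import (
    Orthogroup,
    candidate_genes,
    classify_patterns,
    hypergeom_enrichment,
)

KLEPTO = {"Ecla", "Echl", "Pocc", "Emar"}
OUT = {"Acal"}
SP = sorted(KLEPTO | OUT)


def og(og_id, **members):
    return Orthogroup(og_id, tuple((s, tuple(members.get(s, ()))) for s in SP))


ogs = [
    og("OG1", Ecla=["lectin1", "lectin2"], Echl=["e1"], Pocc=["p1"], Emar=["m1"]),
    og("OG2", Ecla=["actin"], Echl=["e2"], Pocc=["p2"], Emar=["m2"], Acal=["a1"]),
    og("OG3", Ecla=["ros1"], Echl=["e3"], Pocc=["p3"], Emar=["m3"]),
    og("OG4", Ecla=["orphan"]),
]
patterns = classify_patterns(ogs, KLEPTO, OUT)
for p in patterns:
    print(p.og_id, "->", p.pattern)

degs = {"lectin1", "ros1", "actin"}
cands = candidate_genes(patterns, {o.og_id: o for o in ogs}, "Ecla", degs)
print("\nkleptoplast-specific DEG candidates:", sorted(cands["klepto_specific"]))

background = {"lectin1", "lectin2", "actin", "ros1", "orphan", "hk1", "hk2", "hk3"}
terms = {"lectin1": ["GO:ROS"], "ros1": ["GO:ROS"], "hk1": ["GO:ROS"]}
enrich = hypergeom_enrichment(cands["klepto_specific"], terms, background)
print("\n", enrich.to_string(index=False))
# Orthogroups present in all four kleptoplastic species but absent from the
# outgroup are the candidate gene families; genes there that are also
# fed-stage DEGs are the kleptoplasty candidates, and the hypergeometric
# upper tail scores which functional terms they over-represent.
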