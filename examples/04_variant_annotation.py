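"""Predict consequence classes for homeodomain missense variants.

Hosts are synthetic stand-in domains carrying the relevant wild-type
residues (the CRX-type host has the inhibitory E4 and a K50). Calls
separate variants expected to change dimer cooperativity from those
expected to impair DNA binding outright.
"""

from hdcoop import HDSequence, VariantRecord, annotate_batch, default_ruleset

SCAFFOLD = list("A" * 60)
for pos, aa in {2: "R", 3: "R", 4: "N", 5: "R", 26: "P", 28: "V", 32: "E",
                42: "E", 43: "A", 44: "R", 46: "Q", 50: "Q", 51: "N"}.items():
    SCAFFOLD[pos - 1] = aa


def host(name, **subs):
    residues = list(SCAFFOLD)
    for key, aa in subs.items():
        residues[int(key[1:]) - 1] = aa
    return HDSequence(name, "PairedLike", "".join(residues))


hosts = [host("PHOX2B"), host("CRX", p4="E", p50="K")]
variants = [
    VariantRecord("PHOX2B", 44, "R", "Q", disease="central hypoventilation"),
    VariantRecord("PHOX2B", 44, "R", "G", disease="neuroblastoma/Hirschsprung"),
    VariantRecord("CRX", 4, "E", "K", disease="Leber congenital amaurosis"),
    VariantRecord("CRX", 3, "R", "W", disease="cone-rod dystrophy"),
]

batch = annotate_batch(variants, hosts, default_ruleset())
for call in batch.calls:
    print(f"{call.variant.label:>14}  ->  {call.category:24}  {call.rationale}")
print("\ncounts:", batch.counts)
# Same position, different outcome: R44Q breaks a cooperativity rule while
# R44G puts a helix-breaking glycine into the recognition helix.
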