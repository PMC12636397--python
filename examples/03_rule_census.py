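"""Apply the 11 cooperativity rules to the Engrailed homeodomain.

Engrailed (an ANTP-class factor) binds TAAT monomer sites but cannot
dimerize cooperatively on the palindromic P3 site; the rule census shows
which residues are responsible and how many substitutions would be needed.
"""

from hdcoop import HDSequence, default_ruleset, evaluate_rules, min_changes_to_cooperative

ENGRAILED_HD = "EKRPRTAFSSEQLARLKREFNENRYLTERRRQQLSSELGLNEAQIKIWFQNKRAKIKKST"
en = HDSequence("EN1", "ANTP", ENGRAILED_HD)

rules = default_ruleset()
ev = evaluate_rules(en, rules)
print("violated rules:")
for v in ev.violations:
    print(f"  {v.observed}{v.rule.hd_position}: {v.rule.describe()}")

print(
    f"\nminimum substitutions to satisfy all critical rules: "
    f"{min_changes_to_cooperative(en, rules, 'critical_only')}"
)
print(
    f"minimum substitutions to satisfy every rule:           "
    f"{min_changes_to_cooperative(en, rules, 'all_rules')}"
)
# Four critical conflicts (L26, Q32, Q44, K46) keep Engrailed off P3 sites.
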