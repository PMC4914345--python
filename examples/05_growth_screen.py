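"""Secondary screen: hit calling on the packaged siRNA growth table.

Loads the packaged 29-siRNA x 6-cell-line relative-growth table, calls
siRNAs critical when growth is <= 66% in at least two of three basal-like
lines, and classifies specificity by how many luminal lines are also
reduced.
"""

from tfscreen import call_critical, classify_all, load_sirna_screen

table, groups = load_sirna_screen()
critical = call_critical(table, groups)
calls = classify_all(table, groups)

print(calls.sort_values(["label", "n_blbc_reduced"]).to_string())
print(f"\ncritical TFs ({len(critical)}): {sorted(critical)}")
print("class counts:", calls["label"].value_counts().to_dict())
# 8 TFs suppress growth by at least one third in >=2 basal-like lines; MYC,
# CDC5L and NFKB2 also hit >=2 luminal lines (general growth factors), four
# hit exactly one, and SOX11 is the sole basal-like-specific hit.
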