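"""Categorize the bundled published winning-TF counts by group presence.

The package ships the per-cancer deregulation counts of 34 published winning
transcription factors (lung cancer out of 10 datasets, breast cancer and
leukemia out of 5 each). Their group-presence partition is a fixed,
reproducible summary of that table.
"""

from degnet import categorize_table, load_winning_tf_counts

df = load_winning_tf_counts()
hist = categorize_table(zip(df["lc"], df["bc"], df["lk"]))
for pattern, count in hist.items():
    if count:
        print(f"{pattern:9s} {count:2d} TFs")
# 13 TFs deregulated in all three cancers, 9 in lung+breast only,
# 6 in lung+leukemia only, 6 in lung cancer alone.
print(f"\ntop row: ZBTB16 with {df.loc['ZBTB16', 'total']} deregulated "
      f"datasets (9 LC + 4 BC + 3 LK)")
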