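"""Generate the default synthetic produce-sample table.

Builds the 791-sample dataset whose structure mirrors the published
market survey: 7 crops x 2 production systems with the published cell
counts, 99 producer companies, and delta15N calibrated to 1.84 per mil
(conventional) vs 5.98 per mil (organic).
"""

from isoscreen import default_config, generate

cfg = default_config(seed=1)
table = generate(cfg)

print(f"rows: {len(table)}   crops: {table.crop.nunique()}   "
      f"companies: {table.company.nunique()}")
print("\nper-system delta15N (per mil):")
print(table.groupby("system")["d15n"].agg(["count", "mean", "std"]).round(2))
print(f"\noverall delta15N mean: {table.d15n.mean():.2f} per mil "
      "(calibration target ~4.04)")
print("\nfirst rows:")
print(table.head(3).to_string(index=False))
# The organic/conventional gap of ~4 per mil is the core signal: organic
# fertilizers are 15N-enriched, synthetic N sits near atmospheric 0.
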