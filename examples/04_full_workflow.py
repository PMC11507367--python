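"""End-to-end closed loop: simulate, select, cross-match to in-gel, identify.

Marker features are planted with m/z values of real theoretical milk-peptide
variants, so the identification stage can be checked against the generator's
ground truth.
"""

import spoilmark as sm

proteins = sm.load_milk_proteins()
config = sm.SyntheticConfig(seed=1)
table, truth = sm.generate_timecourse(config, proteins=proteins)
bands = sm.generate_ingel(config, table, truth)

report = sm.run_insolution(table, sm.PipelineConfig(seed=42))
band_tables = {label: band for label, (band, _blank) in bands.items()}
final = sm.crosslink_and_identify(report, band_tables, proteins,
                                  sm.PipelineConfig(seed=42))

print(f"selected: {len(final.selected)} features; "
      f"cross-links into bands: {len(final.crossmatch)}; "
      f"features with a peptide match: "
      f"{final.stage_counts['identified_features']}")

ok = 0
selected = set(final.selected["feature_id"])
for fid, planted in truth.peptide_assignments.items():
    if fid not in selected:
        continue
    sub = final.identifications.query(
        "feature_id == @fid and sequence == @planted.peptide.sequence")
    ok += bool(len(sub))
print(f"planted peptides re-identified with the correct sequence: {ok}/"
      f"{sum(f in selected for f in truth.peptide_assignments)}")

print("\nexample cross-link annotations (in-gel partner of a selected feature):")
print(final.crossmatch.head(3).to_string(index=False))
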