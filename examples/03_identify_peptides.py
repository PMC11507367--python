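"""Identify the three published marker features as alpha-S1-casein peptides.

The features (printed m/z, charge) are matched against an in-silico digest
of the seven milk proteins: tryptic cleavage with two missed cleavages plus
endogenous-protease cleavage next to A/V/L/I/P/M/F/W/G/Q/T, ten variable
modifications, 0.002% relative neutral-mass tolerance.
"""

import spoilmark as sm

proteins = sm.load_milk_proteins()
database = sm.build_database(proteins)
print(f"theoretical database: {len(database):,} peptide variants "
      f"from {len(proteins)} proteins")

features = [sm.Feature(r.feature_id, r.mz, r.rt, int(r.charge))
            for r in sm.IDENTIFIED_FEATURES.itertuples()]
matches = sm.match_features(features, database)

for feat in features:
    best = [m for m in matches if m.feature_id == feat.id][:3]
    print(f"\n{feat.id} (m/z {feat.mz}, z={feat.charge}):")
    for m in best:
        mods = ", ".join(n for n, _ in m.peptide.modifications) or "unmodified"
        print(f"  {m.peptide.sequence:<18} {m.peptide.protein} "
              f"{m.peptide.start}-{m.peptide.end}  {mods:<20} "
              f"{m.relative_deviation * 1e6:+6.1f} ppm")

# Every feature keeps a match to the alpha-S1-casein assignment (PLW
# 212-214; phospho-FSDIPNPIGSENSEK 194-208 at charges 2 and 3) within the
# 20 ppm window; additional isobaric candidates are listed nearest-first,
# which is why mass alone cannot finalise an identification.
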