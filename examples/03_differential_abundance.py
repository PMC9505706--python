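"""Find differentially abundant genera and check them against ground truth.

The synthetic cohort plants known fold changes (23x, 13x, 7x enrichments and
0.17-0.34x depletions) into specific genera; the differential-abundance
table should flag exactly those.
"""

from taxrisk import collapse_to_genus, diff_abundance_table
from taxrisk.group_stats import diff_table_to_frame
from taxrisk.synth import clinical_spec, planted_genera, simulate_cohort

spec = clinical_spec(n_control=60, n_case=60)
table, metadata = simulate_cohort(spec, seed=3)
counts, _ = collapse_to_genus(table)
rel = counts.div(counts.sum(axis=1), axis=0)

rows = diff_abundance_table(rel, metadata, rank="genus", design="kw_mwu_bh")
frame = diff_table_to_frame(rows).set_index("taxon")

truth = planted_genera(spec)
print("planted effects vs what the table reports:")
cols = ["fold_change", "p_value", "adjusted_p", "significant"]
print(frame.loc[list(truth), cols].round(4).assign(
    planted_fold=list(truth.values())), "\n")

n_sig = int(frame["significant"].sum())
print(f"{n_sig} of {len(frame)} genera flagged at BH-adjusted p < 0.05.")
print("Estimated fold changes sit near the planted values (compressed a")
print("little by per-sample renormalisation); unplanted genera should be")
print("flagged at roughly the false-discovery rate.")
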