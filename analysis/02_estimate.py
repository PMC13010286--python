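"""Estimate occupancies from the simulated study and benchmark them.

Runs the estimation pipeline (S/N > 5 in both channels, per-protein median
H/L per mix point, s = r/median inversion, cross-point median, replicate
mean) on results/sim/, compares against the ground-truth side-car, and
writes the per-protein table plus an accuracy summary under
results/estimates/.

Note: the simulation includes 2% nonspecific carryover, so raw estimates
carry the expected upward bias of ~f_ns(1−s); 03_binding_control.py removes
it.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from parstoich import quantio, stoichiometry as st

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "estimates"
OUT.mkdir(parents=True, exist_ok=True)

records = quantio.read_quant_table(BASE / "sim" / "titration_quant.tsv")
designs = quantio.read_mix_design(BASE / "sim" / "mix_design.tsv")
refs = quantio.read_reference_lists(BASE / "sim" / "reference_proteins.txt")

filtered, report = st.filter_peptides(records, refs, st.FilterConfig())
print("filter attrition:", report.as_dict())
rollup = st.rollup_protein_ratios(filtered)
per_rep = st.estimate_stoichiometries(rollup, designs)
combined, repro = st.combine_replicates(per_rep)
st.write_estimates_table(combined, OUT / "estimates.tsv", designs)

summary = st.summarize_distribution(combined)
truth = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t", dtype={"protein_id": str})
tmap = dict(zip(truth["protein_id"], truth["true_stoichiometry"]))
errs = np.array([abs(e.final / tmap[e.protein_id] - 1) for e in combined])
r = np.corrcoef(
    np.log10([e.final for e in combined]),
    np.log10([tmap[e.protein_id] for e in combined]),
)[0, 1]

pd.Series(
    {
        "n_quantified": summary.n_proteins,
        "median_percent": summary.median_percent,
        "mean_percent": summary.mean_percent,
        **summary.bucket_counts,
        "replicate_overlap": repro.n_overlap,
        "replicate_log10_pearson": repro.pearson_log10,
        "median_rel_error_vs_truth": float(np.median(errs)),
        "truth_log10_pearson": float(r),
    }
).to_csv(OUT / "accuracy_summary.tsv", sep="\t", header=False)

print(
    f"quantified {summary.n_proteins} proteins; cohort median {summary.median_percent:.2f}% "
    f"mean {summary.mean_percent:.2f}%"
)
print(
    f"accuracy vs truth: median relative error {np.median(errs):.1%}, "
    f"log10 Pearson r = {r:.4f}"
)
print(
    f"replicates: overlap {repro.n_overlap}, log10 Pearson r = {repro.pearson_log10:.4f}"
)
print(f"wrote {OUT/'estimates.tsv'} and {OUT/'accuracy_summary.tsv'}")
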