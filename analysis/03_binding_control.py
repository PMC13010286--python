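"""Quantify nonspecific bead binding from the 1:1 control and correct.

The simulated heavy channel is unmodified (its only route onto the beads is
nonspecific carryover, here 2%), so the per-protein median heavy/light
control ratio identifies f_ns = control_hl × s_obs; this script applies the
correction s = (s_obs − f̂_ns)/(1 − f̂_ns) to the raw estimates from
02_estimate.py and reports how much of the raw upward bias it removes. It
also runs the two-round depletion check for the enrichment-completeness
assumption.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from parstoich import controls as ctl, quantio, simulate as sim, stoichiometry as st

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "control"
OUT.mkdir(parents=True, exist_ok=True)

control_records = quantio.read_quant_table(BASE / "sim" / "control_quant.tsv")
refs = quantio.read_reference_lists(BASE / "sim" / "reference_proteins.txt")
results = ctl.nonspecific_binding(
    control_records, refs, st.FilterConfig(require_protein_in_reference=False)
)
by_pid = {r.protein_id: r for r in results}
ctl.write_control_table(results, OUT / "control_results.tsv")

est = pd.read_csv(BASE / "estimates" / "estimates.tsv", sep="\t", dtype={"protein_id": str})
truth = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t", dtype={"protein_id": str})
merged = est.merge(truth, on="protein_id")

corrected = []
for row in merged.itertuples(index=False):
    raw = st.finalize_stoichiometry(row.protein_id, {"raw": row.s_final_percent / 100.0})
    fixed = ctl.correct_stoichiometry(raw, by_pid[row.protein_id])
    corrected.append(fixed.final)
merged["s_corrected_percent"] = 100.0 * np.array(corrected)
merged.to_csv(OUT / "corrected_estimates.tsv", sep="\t", index=False)

raw_err = np.abs(merged["s_final_percent"] / (100 * merged["true_stoichiometry"]) - 1)
cor_err = np.abs(merged["s_corrected_percent"] / (100 * merged["true_stoichiometry"]) - 1)
fns_hat = np.median(
    [ctl.estimate_nonspecific_fraction(by_pid[p].control_hl, s / 100.0)
     for p, s in zip(merged["protein_id"], merged["s_final_percent"])]
)
print(f"{len(results)} proteins in control; median inferred f_ns = {fns_hat:.4f} (true 0.02)")
print(
    f"median relative error: raw {np.median(raw_err):.1%} -> corrected {np.median(cor_err):.1%}"
)
low = merged["true_stoichiometry"] < 0.02
print(
    "note: residual error concentrates where s << f_ns "
    f"(median corrected error {np.median(cor_err[low]):.1%} for s < 2%, "
    f"{np.median(cor_err[~low]):.1%} above) — subtracting the carryover "
    "amplifies measurement noise at the low-occupancy end"
)

report = ctl.depletion_check(sim.simulate_depletion_series(
    sim.SimConfig(n_proteins=1, enrichment_efficiency=1.0), 2
), e_hypothesis=1.0)
print(
    f"depletion check: observed {report.observed}, fitted efficiency {report.fitted_e:.3f} "
    "(complete recovery)"
)
print(f"wrote tables under {OUT}")
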