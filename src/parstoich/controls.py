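"""Control experiments: nonspecific bead binding and bead depletion.

The 1:1 SILAC control mixes equal lysate masses of heavy (PARP-inhibited, no
modification — anything it leaves on the beads is nonspecific) and light
(modified) cells before enrichment. For a peptide of a modified protein the
heavy peak then reports pure nonspecific carryover and the light peak the
enriched signal, so the per-protein median heavy/light ratio

    control_hl = f_ns / (e·s + f_ns·(1−s))

quantifies nonspecific binding. With complete enrichment (e = 1) the raw
titration estimate is s_obs = s + f_ns·(1−s); since control_hl·s_obs = f_ns,
the contamination is identifiable from the two measurements and

    s = (s_obs − f_ns) / (1 − f_ns)

inverts it exactly. Correction is OFF by default — the raw estimator is the
reference behaviour, the control is first of all a purity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import ReferenceLists
from .stoichiometry import FilterConfig, StoichEstimate

__all__ = [
    "BindingControlResult",
    "DepletionReport",
    "nonspecific_binding",
    "estimate_nonspecific_fraction",
    "correct_stoichiometry",
    "depletion_check",
    "control_results_to_frame",
    "write_control_table",
]


@dataclass
class BindingControlResult:
    """Per-protein outcome of the 1:1 control pull-down.

    ``control_hl`` = 0 means no detectable nonspecific binding (no heavy
    signal for any peptide). ``est_nonspecific_fraction`` stays None until a
    matching occupancy estimate makes the inversion possible.
    """

    protein_id: str
    control_hl: float
    n_peptides: int
    est_nonspecific_fraction: float | None = None


def nonspecific_binding(
    control_records: pd.DataFrame,
    refs: ReferenceLists | None,
    cfg: FilterConfig,
) -> list[BindingControlResult]:
    """Quantify nonspecific binding per protein from the 1:1 control table.

    Filtering follows the main pipeline where it can: the light channel must
    be present with S/N > cfg.snr_min, site peptides are excluded, and the
    reference-membership rule applies only if enabled in ``cfg``. The
    both-channels rule cannot apply here — an absent heavy peak *is* the
    result (zero nonspecific binding) — so a heavy peak that is missing or
    fails the S/N threshold contributes a ratio of 0.
    """
    rec = control_records
    keep = rec["area_light"].notna() & (rec["snr_light"] > cfg.snr_min)
    if cfg.require_protein_in_reference:
        if refs is None:
            raise ValueError("reference lists required when membership rule is on")
        keep &= rec["protein_id"].str.upper().isin(refs.parylated_proteins)
    if cfg.exclude_site_peptides and refs is not None:
        keep &= ~rec["peptide_seq"].str.upper().isin(refs.excluded_site_peptides)
    rec = rec.loc[keep.fillna(False)].copy()
    heavy_ok = rec["area_heavy"].notna() & (rec["snr_heavy"] > cfg.snr_min)
    rec["hl_ratio"] = np.where(heavy_ok, rec["area_heavy"] / rec["area_light"], 0.0)
    results = [
        BindingControlResult(
            protein_id=str(pid),
            control_hl=float(grp["hl_ratio"].median()),
            n_peptides=int(len(grp)),
        )
        for pid, grp in rec.groupby("protein_id", sort=True)
    ]
    return results


def estimate_nonspecific_fraction(control_hl: float, s_obs: float) -> float:
    """f̂_ns = control_hl · s_obs (exact under complete enrichment)."""
    return control_hl * s_obs


def correct_stoichiometry(
    estimate: StoichEstimate, control: BindingControlResult
) -> StoichEstimate:
    """Remove the nonspecific-binding contribution from a final estimate.

    Returns a new estimate with final = (s_obs − f̂_ns)/(1 − f̂_ns) and flag
    ``ns_corrected``; if the inferred contamination exceeds the observation
    the corrected value is 0 with flag ``overcorrected``. Per-mix-point
    values are left raw. An f̂_ns ≥ 1 is unphysical and raises.
    """
    if estimate.protein_id != control.protein_id:
        raise ValueError(
            f"protein mismatch: estimate {estimate.protein_id!r} vs "
            f"control {control.protein_id!r}"
        )
    f_ns = estimate_nonspecific_fraction(control.control_hl, estimate.final)
    if f_ns >= 1.0:
        raise ValueError(
            f"{estimate.protein_id}: inferred nonspecific fraction {f_ns:.3g} >= 1"
        )
    flags = set(estimate.flags) | {"ns_corrected"}
    if f_ns >= estimate.final:
        corrected = 0.0
        if f_ns > 0:
            flags.add("overcorrected")
    else:
        corrected = (estimate.final - f_ns) / (1.0 - f_ns)
    return replace(
        estimate,
        final=corrected,
        flags=flags,
        per_ratio=dict(estimate.per_ratio),
        replicate_values=dict(estimate.replicate_values),
    )


@dataclass
class DepletionReport:
    """Fit of sequential-depletion measurements to (1−e)^k."""

    observed: list[float]
    e_hypothesis: float | None
    expected: list[float] | None
    fitted_e: float
    fitted_e_ci: tuple[float, float] | None
    log_rmse: float | None


def depletion_check(
    observed_fractions: list[float], e_hypothesis: float | None = None
) -> DepletionReport:
    """Compare remaining-signal fractions after rounds k = 1..K to the
    geometric model (1−e)^k and fit e by least squares on the log scale
    (slope through the origin of log f_k against k).

    Fractions at or below zero (complete depletion) cannot enter the log
    fit; if none are positive the fitted efficiency is exactly 1.
    """
    if not observed_fractions:
        raise ValueError("need at least one depletion round")
    ks = np.arange(1, len(observed_fractions) + 1, dtype=float)
    obs = np.asarray(observed_fractions, dtype=float)
    pos = obs > 0
    if not pos.any():
        fitted_e, ci, rmse = 1.0, None, None
    else:
        y = np.log(obs[pos])
        k = ks[pos]
        slope = float(np.sum(k * y) / np.sum(k * k))
        fitted_e = 1.0 - math.exp(slope)
        resid = y - slope * k
        rmse = float(np.sqrt(np.mean(resid**2)))
        ci = None
        if pos.sum() > 1:
            df = int(pos.sum()) - 1
            sigma2 = float(np.sum(resid**2)) / df
            se = math.sqrt(sigma2 / float(np.sum(k * k)))
            tq = float(stats.t.ppf(0.975, df))
            lo, hi = slope - tq * se, slope + tq * se
            ci = (1.0 - math.exp(hi), 1.0 - math.exp(lo))
    expected = None
    if e_hypothesis is not None:
        expected = [(1.0 - e_hypothesis) ** k for k in range(1, len(obs) + 1)]
    return DepletionReport(
        observed=list(map(float, obs)),
        e_hypothesis=e_hypothesis,
        expected=expected,
        fitted_e=float(fitted_e),
        fitted_e_ci=ci,
        log_rmse=rmse,
    )


def control_results_to_frame(results: list[BindingControlResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "control_hl": [r.control_hl for r in results],
            "n_peptides": [r.n_peptides for r in results],
            "est_nonspecific_fraction": [
                r.est_nonspecific_fraction if r.est_nonspecific_fraction is not None else math.nan
                for r in results
            ],
        }
    )


def write_control_table(results: list[BindingControlResult], path) -> None:
    control_results_to_frame(results).to_csv(path, sep="\t", index=False, na_rep="")
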