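"""Occupancy estimation from SILAC titration quant tables.

The estimator is deliberately simple and robust:

1. filter peptide observations (S/N > 5 in both channels by default,
   protein on the curated PARylated-protein list, peptides carrying known
   modification sites excluded);
2. per (protein, mix point, replicate), take the **median** of the
   per-peptide heavy/light area ratios, m;
3. invert the titration: occupancy at mix ratio r is s_r = r / m;
4. the **median of s_r across mix points** is the protein's final
   occupancy, and replicates are merged (mean over replicates by default);
5. summarise the cohort distribution in percent.

Estimates above 100% are kept and flagged, never clamped — an s_r > 1 is a
calibration alarm, not a rounding issue. Mix points where a channel fell
outside the detector's range are simply absent from the median, which is
exactly why the titration uses several mix ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantio import MixDesign, ReferenceLists

__all__ = [
    "FilterConfig",
    "FilterReport",
    "StoichEstimate",
    "ReproducibilityReport",
    "DistributionSummary",
    "filter_peptides",
    "rollup_protein_ratios",
    "per_ratio_stoichiometry",
    "finalize_stoichiometry",
    "estimate_stoichiometries",
    "combine_replicates",
    "summarize_distribution",
    "estimates_to_frame",
    "write_estimates_table",
]


@dataclass(frozen=True)
class FilterConfig:
    """Peptide retention rules.

    ``snr_mode='both'`` demands S/N > snr_min in the heavy *and* the light
    channel (the stricter reading, default); ``'either'`` accepts one passing
    channel. The threshold is strict (>, not >=). Rows always need both
    channels present — a ratio cannot be formed otherwise.
    """

    snr_min: float = 5.0
    snr_mode: str = "both"
    require_protein_in_reference: bool = True
    exclude_site_peptides: bool = True

    def __post_init__(self) -> None:
        if not self.snr_min > 0:
            raise ValueError("snr_min must be > 0")
        if self.snr_mode not in ("both", "either"):
            raise ValueError("snr_mode must be 'both' or 'either'")


@dataclass
class FilterReport:
    """Attrition counts per rejection rule (a row is counted once, under the
    first rule it fails; rules applied in the order listed)."""

    n_input: int = 0
    n_retained: int = 0
    rejected_missing_channel: int = 0
    rejected_snr: int = 0
    rejected_not_in_reference: int = 0
    rejected_site_peptide: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


@dataclass
class StoichEstimate:
    """Per-protein occupancy estimate.

    ``per_ratio`` maps mix label → s_r; ``final`` is the median over the
    available mix points (or, after replicate merging, the combined value).
    Flags: ``single_mix_point`` (only one usable mix point),
    ``exceeds_one`` (some s_r > 1), ``sparse_peptides`` (some contributing
    mix-point median rests on a single peptide), plus correction flags added
    by the controls module.
    """

    protein_id: str
    per_ratio: dict[str, float]
    final: float
    n_mix_points: int
    flags: set[str] = field(default_factory=set)
    replicate_values: dict[str, float] = field(default_factory=dict)

    @property
    def final_percent(self) -> float:
        return 100.0 * self.final


@dataclass
class ReproducibilityReport:
    n_per_replicate: dict[str, int]
    n_union: int
    n_overlap: int
    pearson_log10: float | None


@dataclass
class DistributionSummary:
    """Cohort summary in percent, plus strict-threshold bucket counts
    (``'>5%'`` counts strictly greater, ``'<1%'`` strictly less)."""

    n_proteins: int
    median_percent: float
    mean_percent: float
    min_percent: float
    max_percent: float
    bucket_counts: dict[str, int]


def filter_peptides(
    records: pd.DataFrame,
    refs: ReferenceLists | None,
    cfg: FilterConfig,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the retention rules; returns (retained rows, attrition report).

    ``refs`` may be None only when both reference-dependent rules are
    disabled in ``cfg``. Filtering is idempotent. An empty result is allowed.
    """
    if refs is None and (cfg.require_protein_in_reference or cfg.exclude_site_peptides):
        raise ValueError("reference lists required by the active filter rules")
    report = FilterReport(n_input=len(records))
    both_present = records["area_heavy"].notna() & records["area_light"].notna()
    if cfg.snr_mode == "both":
        snr_ok = (records["snr_heavy"] > cfg.snr_min) & (records["snr_light"] > cfg.snr_min)
    else:
        snr_ok = (records["snr_heavy"] > cfg.snr_min) | (records["snr_light"] > cfg.snr_min)
    snr_ok = snr_ok.fillna(False)
    in_ref = (
        records["protein_id"].str.upper().isin(refs.parylated_proteins)
        if cfg.require_protein_in_reference
        else pd.Series(True, index=records.index)
    )
    not_site = (
        ~records["peptide_seq"].str.upper().isin(refs.excluded_site_peptides)
        if cfg.exclude_site_peptides
        else pd.Series(True, index=records.index)
    )
    report.rejected_missing_channel = int((~both_present).sum())
    report.rejected_snr = int((both_present & ~snr_ok).sum())
    report.rejected_not_in_reference = int((both_present & snr_ok & ~in_ref).sum())
    report.rejected_site_peptide = int((both_present & snr_ok & in_ref & ~not_site).sum())
    keep = both_present & snr_ok & in_ref & not_site
    report.n_retained = int(keep.sum())
    return records.loc[keep].copy(), report


def rollup_protein_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Median per-peptide heavy/light ratio per (protein, mix point, replicate).

    Every observation row contributes one ratio (duplicate sequences are
    separate observations); the even-count median is the mean of the two
    middle values. Rows without a usable light area are skipped.
    Returns columns [protein_id, mix_label, replicate, median_hl, n_peptides].
    """
    usable = records.loc[
        records["area_light"].notna() & (records["area_light"] > 0) & records["area_heavy"].notna()
    ].copy()
    if usable.empty:
        return pd.DataFrame(columns=["protein_id", "mix_label", "replicate", "median_hl", "n_peptides"])
    usable["hl_ratio"] = usable["area_heavy"] / usable["area_light"]
    grouped = (
        usable.groupby(["protein_id", "mix_label", "replicate"], sort=True)["hl_ratio"]
        .agg(median_hl="median", n_peptides="size")
        .reset_index()
    )
    grouped["n_peptides"] = grouped["n_peptides"].astype(int)
    return grouped


def per_ratio_stoichiometry(
    mix_label: str, median_hl: float, design: MixDesign
) -> float:
    """Occupancy at one mix point: s_r = r / m, with r the heavy:light
    lysate-mass mix ratio and m the protein's median heavy/light peak-area
    ratio at that point."""
    if mix_label != design.mix_label:
        raise ValueError(
            f"mix label mismatch: summary has {mix_label!r}, design is {design.mix_label!r}"
        )
    if not median_hl > 0:
        raise ValueError("median H/L ratio must be > 0")
    return design.ratio_r / median_hl


def finalize_stoichiometry(
    protein_id: str,
    per_ratio: dict[str, float],
    sparse_points: set[str] | None = None,
) -> StoichEstimate:
    """Final occupancy = median of the per-mix-point values; quality flags
    attached per the rules in :class:`StoichEstimate`."""
    if not per_ratio:
        raise ValueError(f"{protein_id}: no valid mix point")
    values = np.array(sorted(per_ratio.values()), dtype=float)
    flags: set[str] = set()
    if len(values) == 1:
        flags.add("single_mix_point")
    if (values > 1.0).any():
        flags.add("exceeds_one")
    if sparse_points:
        flags.add("sparse_peptides")
    return StoichEstimate(
        protein_id=protein_id,
        per_ratio=dict(per_ratio),
        final=float(np.median(values)),
        n_mix_points=len(values),
        flags=flags,
    )


def estimate_stoichiometries(
    rollup: pd.DataFrame,
    designs: list[MixDesign],
) -> dict[str, list[StoichEstimate]]:
    """Turn a ratio rollup into per-replicate occupancy estimates.

    Returns {replicate → [StoichEstimate, ...]}. Mix labels in the rollup
    that have no design entry raise; proteins end up with whatever subset of
    mix points survived detection and filtering.
    """
    by_label = {d.mix_label: d for d in designs}
    unknown = set(rollup["mix_label"]) - set(by_label)
    if unknown:
        raise ValueError(f"mix labels missing from the design: {sorted(unknown)}")
    out: dict[str, list[StoichEstimate]] = {}
    for (replicate, protein_id), grp in rollup.groupby(["replicate", "protein_id"], sort=True):
        per_ratio: dict[str, float] = {}
        sparse: set[str] = set()
        for row in grp.itertuples(index=False):
            per_ratio[row.mix_label] = per_ratio_stoichiometry(
                row.mix_label, row.median_hl, by_label[row.mix_label]
            )
            if row.n_peptides < 2:
                sparse.add(row.mix_label)
        out.setdefault(str(replicate), []).append(
            finalize_stoichiometry(str(protein_id), per_ratio, sparse)
        )
    return out


def combine_replicates(
    per_replicate: dict[str, list[StoichEstimate]],
    mode: str = "union_mean",
) -> tuple[list[StoichEstimate], ReproducibilityReport]:
    """Merge replicate estimates into one value per protein.

    Modes: ``union_mean`` (default — report a protein seen in any replicate,
    value = mean of its replicate finals), ``intersection_mean`` (proteins
    seen in every replicate only), ``pooled_median`` (union membership,
    median of replicate finals). The report carries the overlap count —
    proteins present in all replicates — and the Pearson correlation of
    log10 occupancies on the overlap of the first two replicates (absent
    when fewer than two overlapping proteins or fewer than two replicates).
    """
    if mode not in ("union_mean", "intersection_mean", "pooled_median"):
        raise ValueError(f"unknown replicate-merge mode {mode!r}")
    if not per_replicate:
        raise ValueError("at least one replicate required")
    replicates = sorted(per_replicate)
    maps = {r: {e.protein_id: e for e in per_replicate[r]} for r in replicates}
    union = sorted(set().union(*(maps[r] for r in replicates)))
    overlap = sorted(set.intersection(*(set(maps[r]) for r in replicates)))

    pearson = None
    if len(replicates) >= 2:
        a, b = maps[replicates[0]], maps[replicates[1]]
        shared = sorted(set(a) & set(b))
        if len(shared) >= 2:
            xa = np.log10([a[p].final for p in shared])
            xb = np.log10([b[p].final for p in shared])
            if np.std(xa) > 0 and np.std(xb) > 0:
                pearson = float(np.corrcoef(xa, xb)[0, 1])

    members = overlap if mode == "intersection_mean" else union
    combined: list[StoichEstimate] = []
    for pid in members:
        ests = [maps[r][pid] for r in replicates if pid in maps[r]]
        finals = [e.final for e in ests]
        value = float(np.median(finals)) if mode == "pooled_median" else float(np.mean(finals))
        per_ratio: dict[str, list[float]] = {}
        for e in ests:
            for label, s_r in e.per_ratio.items():
                per_ratio.setdefault(label, []).append(s_r)
        combined.append(
            StoichEstimate(
                protein_id=pid,
                per_ratio={lb: float(np.mean(v)) for lb, v in per_ratio.items()},
                final=value,
                n_mix_points=max(e.n_mix_points for e in ests),
                flags=set().union(*(e.flags for e in ests)),
                replicate_values={r: maps[r][pid].final for r in replicates if pid in maps[r]},
            )
        )
    report = ReproducibilityReport(
        n_per_replicate={r: len(per_replicate[r]) for r in replicates},
        n_union=len(union),
        n_overlap=len(overlap),
        pearson_log10=pearson,
    )
    return combined, report


def summarize_distribution(
    estimates: list[StoichEstimate],
    over_thresholds_percent: tuple[float, ...] = (5.0,),
    under_thresholds_percent: tuple[float, ...] = (1.0,),
) -> DistributionSummary:
    """Cohort distribution of final occupancies, in percent."""
    if not estimates:
        raise ValueError("no estimates to summarise")
    pct = np.array([e.final_percent for e in estimates])
    buckets: dict[str, int] = {}
    for t in over_thresholds_percent:
        buckets[f">{t:g}%"] = int((pct > t).sum())
    for t in under_thresholds_percent:
        buckets[f"<{t:g}%"] = int((pct < t).sum())
    return DistributionSummary(
        n_proteins=len(pct),
        median_percent=float(np.median(pct)),
        mean_percent=float(np.mean(pct)),
        min_percent=float(pct.min()),
        max_percent=float(pct.max()),
        bucket_counts=buckets,
    )


def estimates_to_frame(
    estimates: list[StoichEstimate], designs: list[MixDesign] | None = None
) -> pd.DataFrame:
    """Tabular form of a list of estimates (occupancies in percent)."""
    labels = (
        [d.mix_label for d in designs]
        if designs
        else sorted({lb for e in estimates for lb in e.per_ratio})
    )
    rows = []
    for e in sorted(estimates, key=lambda x: x.protein_id):
        row = {
            "protein_id": e.protein_id,
            "s_final_percent": e.final_percent,
            "n_mix_points": e.n_mix_points,
        }
        for lb in labels:
            row[f"s_percent[{lb}]"] = (
                100.0 * e.per_ratio[lb] if lb in e.per_ratio else math.nan
            )
        for rep, val in sorted(e.replicate_values.items()):
            row[f"s_percent[{rep}]"] = 100.0 * val
        row["flags"] = ";".join(sorted(e.flags))
        rows.append(row)
    return pd.DataFrame(rows)


def write_estimates_table(
    estimates: list[StoichEstimate], path, designs: list[MixDesign] | None = None
) -> None:
    estimates_to_frame(estimates, designs).to_csv(path, sep="\t", index=False, na_rep="")
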