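"""Readers and writers for the pipeline's tabular inputs.

All tables are plain tab-delimited text. The central format is the peptide
quantification table: one row per SILAC peptide observation with integrated
peak areas and signal-to-noise (S/N) values for the heavy and light channel.
A channel that was not detected is encoded as an *empty* field — never as 0;
an explicit zero area is a validation error, because "below the detection
limit" and "measured as zero" are different facts.

The heavy/light orientation is fixed everywhere: mix ratios are
heavy-lysate-mass over light-lysate-mass, peak-area ratios are heavy over
light.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "QUANT_COLUMNS",
    "MixDesign",
    "ReferenceLists",
    "QuantTableError",
    "read_quant_table",
    "write_quant_table",
    "validate_quant_frame",
    "read_mix_design",
    "write_mix_design",
    "read_reference_lists",
    "read_annotation_table",
    "write_annotation_table",
]

#: Required columns of a peptide quantification table, in canonical order.
QUANT_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "mix_label",
    "replicate",
    "area_heavy",
    "area_light",
    "snr_heavy",
    "snr_light",
]

_AREA_SNR_PAIRS = [("area_heavy", "snr_heavy"), ("area_light", "snr_light")]


class QuantTableError(ValueError):
    """Schema or content violation in a tabular input file."""


@dataclass(frozen=True)
class MixDesign:
    """One titration point: heavy and light lysate protein masses.

    ``ratio_r`` is the dimensionless heavy:light mass quotient (e.g. 1/2000
    for 5 ug heavy against 10 mg light); it is always computed from the
    masses and must lie in (0, 1) — the heavy (unenriched) channel is the
    minority channel by design.
    """

    mix_label: str
    heavy_mass_ug: float
    light_mass_ug: float

    def __post_init__(self) -> None:
        if not (self.heavy_mass_ug > 0 and self.light_mass_ug > 0):
            raise ValueError(
                f"mix point {self.mix_label!r}: masses must be positive "
                f"(heavy={self.heavy_mass_ug}, light={self.light_mass_ug})"
            )
        if not self.heavy_mass_ug < self.light_mass_ug:
            raise ValueError(
                f"mix point {self.mix_label!r}: heavy mass must be smaller than "
                "light mass (ratio_r must lie in (0,1))"
            )

    @property
    def ratio_r(self) -> float:
        return self.heavy_mass_ug / self.light_mass_ug


@dataclass(frozen=True)
class ReferenceLists:
    """Curated accessions of known PARylated proteins plus peptide sequences
    that contain known PARylation sites (excluded from quantification because
    the modified form migrates differently)."""

    parylated_proteins: frozenset[str]
    excluded_site_peptides: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.parylated_proteins:
            raise ValueError("reference protein list must not be empty")


def validate_quant_frame(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a peptide-quant DataFrame in place and return it.

    Checks the schema and the per-row invariants: an area is present iff its
    S/N is present, at least one channel is present, present areas are
    strictly positive and present S/N values non-negative. Raises
    :class:`QuantTableError` naming the first offending row (1-based data row
    numbers, header excluded).
    """
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise QuantTableError(f"{source}: missing required column(s) {missing}")
    df = df[QUANT_COLUMNS].copy()
    for col in QUANT_COLUMNS[4:]:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise QuantTableError(f"{source}: non-numeric value in column {col}: {exc}") from exc
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        has = {}
        for area_col, snr_col in _AREA_SNR_PAIRS:
            area = getattr(row, area_col)
            snr = getattr(row, snr_col)
            a_present, s_present = not _isna(area), not _isna(snr)
            if a_present != s_present:
                raise QuantTableError(
                    f"{source}: row {idx}: {area_col} and {snr_col} must be "
                    "present together or absent together"
                )
            if a_present:
                if not area > 0:
                    raise QuantTableError(
                        f"{source}: row {idx}: {area_col} must be > 0 when present "
                        "(use an empty field for an undetected channel)"
                    )
                if snr < 0:
                    raise QuantTableError(f"{source}: row {idx}: {snr_col} must be >= 0")
            has[area_col] = a_present
        if not any(has.values()):
            raise QuantTableError(f"{source}: row {idx}: at least one channel must be present")
        if not str(getattr(row, "protein_id")) or not str(getattr(row, "peptide_seq")):
            raise QuantTableError(f"{source}: row {idx}: empty protein_id or peptide_seq")
    return df


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def read_quant_table(path) -> pd.DataFrame:
    """Read and validate a peptide quantification TSV.

    Missing channels (empty fields) come back as NaN, never 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str, 3: str})
    return validate_quant_frame(df, source=str(path))


def write_quant_table(df: pd.DataFrame, path) -> None:
    """Write a peptide quantification TSV (canonical columns only).

    Extra columns — e.g. the simulator's hidden ground-truth columns — are
    dropped so that downstream consumers can never see them.
    """
    out = validate_quant_frame(df.copy(), source="<write>")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_mix_design(path) -> list[MixDesign]:
    """Read a titration design TSV with columns [mix_label, heavy_ug, light_mg].

    Masses mirror the experiment's bench units — heavy in micrograms, light in
    milligrams — and are normalised to micrograms internally; ``ratio_r`` is
    derived from the masses.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["mix_label", "heavy_ug", "light_mg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantTableError(f"{path}: missing required column(s) {missing}")
    designs: list[MixDesign] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        label = str(row.mix_label)
        if label in seen:
            raise QuantTableError(f"{path}: row {idx}: duplicate mix_label {label!r}")
        seen.add(label)
        try:
            heavy = float(row.heavy_ug)
            light = float(row.light_mg) * 1000.0
        except (TypeError, ValueError) as exc:
            raise QuantTableError(f"{path}: row {idx}: non-numeric mass") from exc
        try:
            designs.append(MixDesign(label, heavy, light))
        except ValueError as exc:
            raise QuantTableError(f"{path}: row {idx}: {exc}") from exc
    if not designs:
        raise QuantTableError(f"{path}: empty mix design")
    return designs


def write_mix_design(designs: list[MixDesign], path) -> None:
    pd.DataFrame(
        {
            "mix_label": [d.mix_label for d in designs],
            "heavy_ug": [d.heavy_mass_ug for d in designs],
            "light_mg": [d.light_mass_ug / 1000.0 for d in designs],
        }
    ).to_csv(path, sep="\t", index=False)


def _read_list(path) -> set[str]:
    entries: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                entries.add(line.upper())
    return entries


def read_reference_lists(protein_path, site_peptide_path=None) -> ReferenceLists:
    """Read the known-PARylated-protein accession list and (optionally) the
    list of peptide sequences carrying known PARylation sites.

    Plain text, one entry per line, ``#`` comments allowed; entries are
    upper-cased and deduplicated. An empty protein list is an error; an empty
    (or absent) site-peptide file just means no exclusions.
    """
    proteins = _read_list(protein_path)
    if not proteins:
        raise QuantTableError(f"{protein_path}: reference protein list is empty")
    peptides = _read_list(site_peptide_path) if site_peptide_path is not None else set()
    return ReferenceLists(frozenset(proteins), frozenset(peptides))


def read_annotation_table(path) -> dict[str, set[str]]:
    """Read a flat protein→term annotation table (TSV: protein_id, term).

    Returns a mapping from protein accession to its set of term identifiers;
    proteins with no terms are simply absent from the mapping.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "term"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantTableError(f"{path}: missing required column(s) {missing}")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        pid, term = str(row.protein_id).strip(), str(row.term).strip()
        if pid and term:
            mapping.setdefault(pid, set()).add(term)
    return mapping


def write_annotation_table(mapping: dict[str, set[str]], path) -> None:
    rows = [(p, t) for p in sorted(mapping) for t in sorted(mapping[p])]
    pd.DataFrame(rows, columns=["protein_id", "term"]).to_csv(path, sep="\t", index=False)
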