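"""Synthetic SILAC titration experiments with known ground truth.

The generator emulates the measurement chain of a titration-based occupancy
experiment for protein poly-ADP-ribosylation (PARylation):

* two SILAC channels — light cells carry the modification, heavy cells are
  PARP-inhibited and therefore unmodified;
* boronate-affinity enrichment of the PARylated fraction from the light
  lysate with efficiency ``e`` (default complete), plus a nonspecific
  carryover fraction ``f_ns`` of the *unmodified* pool;
* Lys-C digestion under heavy-Lys labeling, so every informative peptide
  ends in exactly one lysine;
* mixing of the enriched light peptides with unenriched heavy peptides at a
  series of heavy:light lysate-mass ratios r (the four-point design below);
* an integrating detector with a finite dynamic range (default 5000: the
  minor peak of a SILAC pair vanishes once the major/minor ratio exceeds it)
  and an absolute noise floor with a minimum reportable S/N;
* independent multiplicative lognormal noise on every reported peak area.

For a protein with true occupancy ``s``, light-channel signal is
proportional to ``L · (e·s + f_ns·(1−s))`` and heavy-channel signal to
``H``, so in the clean limit the heavy/light area ratio is ``r/s`` — the
identity the downstream estimator inverts.

Each simulated table carries two hidden columns (``true_s``,
``expected_hl``) for test oracles only; the table writer strips them, and
the estimation pipeline never reads them.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantio import QUANT_COLUMNS, MixDesign

__all__ = [
    "SimConfig",
    "GroundTruthProtein",
    "TABLE1_DESIGN",
    "TRUTH_COLUMNS",
    "simulate_ground_truth",
    "simulate_titration_experiment",
    "simulate_binding_control",
    "simulate_depletion_series",
    "truth_table",
    "write_truth_table",
    "read_truth_table",
]

#: The four-point titration design used throughout: heavy:light mix ratios
#: 1:2000 (5 ug : 10 mg), 1:800 (12.5 ug : 10 mg), 1:200 (100 ug : 20 mg)
#: and 1:50 (200 ug : 10 mg).
TABLE1_DESIGN = [
    MixDesign("1:2000", 5.0, 10_000.0),
    MixDesign("1:800", 12.5, 10_000.0),
    MixDesign("1:200", 100.0, 20_000.0),
    MixDesign("1:50", 200.0, 10_000.0),
]

TRUTH_COLUMNS = ["true_s", "expected_hl"]

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K (C-terminal only), no R bias concerns


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Occupancies are drawn log-uniformly over ``stoich_range`` (default
    0.01%–35.5%, three orders of magnitude). ``area_scale`` sets the detector
    response in peak-area units per microgram of lysate per unit relative
    abundance; together with ``noise_floor`` it fixes the absolute S/N scale.
    """

    n_proteins: int = 300
    stoich_range: tuple[float, float] = (1e-4, 0.355)
    abundance_sigma: float = 1.0
    peptides_per_protein_range: tuple[int, int] = (4, 12)
    ionization_sigma: float = 0.5
    ratio_cv: float = 0.2
    noise_floor: float = 1.0
    area_scale: float = 100.0
    dynamic_range: float = 5000.0
    snr_detect_min: float = 3.0
    enrichment_efficiency: float = 1.0
    nonspecific_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stoich_range
        if not (0 < lo <= hi < 1):
            raise ValueError("stoich_range must satisfy 0 < lo <= hi < 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.dynamic_range > 1:
            raise ValueError("dynamic_range must be > 1")
        if not (0 <= self.enrichment_efficiency <= 1):
            raise ValueError("enrichment_efficiency must lie in [0, 1]")
        if not (0 <= self.nonspecific_fraction < 1):
            raise ValueError("nonspecific_fraction must lie in [0, 1)")
        for name in ("abundance_sigma", "ionization_sigma", "ratio_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_floor <= 0 or self.area_scale <= 0:
            raise ValueError("noise_floor and area_scale must be > 0")
        if self.snr_detect_min <= 0:
            raise ValueError("snr_detect_min must be > 0")
        p_lo, p_hi = self.peptides_per_protein_range
        if not (1 <= p_lo <= p_hi):
            raise ValueError("peptides_per_protein_range must be an increasing pair >= 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruthProtein:
    """A simulated protein: true occupancy, relative abundance, and its
    Lys-C peptides with per-peptide ionization response factors."""

    protein_id: str
    true_stoichiometry: float
    abundance: float
    peptides: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 < self.true_stoichiometry < 1):
            raise ValueError("true_stoichiometry must lie in (0, 1)")
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        for seq, factor in self.peptides:
            if "K" not in seq:
                raise ValueError(f"peptide {seq!r} carries no Lys — SILAC-silent")
            if factor <= 0:
                raise ValueError("ionization factors must be > 0")


def _rng(config: SimConfig, *labels: str) -> np.random.Generator:
    """Deterministic child generator: seed stream from config.seed plus a
    CRC32 of each label (stable across runs and platforms)."""
    return np.random.default_rng([config.seed] + [zlib.crc32(l.encode()) for l in labels])


def simulate_ground_truth(config: SimConfig) -> list[GroundTruthProtein]:
    """Draw a synthetic proteome.

    Occupancies log-uniform over ``config.stoich_range``; abundances
    lognormal(0, abundance_sigma); 4–12 tryptic-like peptides per protein,
    each ending in the single labeled Lys, with lognormal ionization factors.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config, "ground_truth")
    lo, hi = config.stoich_range
    log_s = rng.uniform(math.log10(lo), math.log10(hi), size=config.n_proteins)
    abundances = rng.lognormal(0.0, config.abundance_sigma, size=config.n_proteins)
    p_lo, p_hi = config.peptides_per_protein_range
    proteins = []
    for i in range(config.n_proteins):
        n_pep = int(rng.integers(p_lo, p_hi + 1))
        peptides = []
        for j in range(n_pep):
            length = int(rng.integers(7, 20))
            body = "".join(rng.choice(_AMINO_ACIDS, size=length))
            factor = float(rng.lognormal(0.0, config.ionization_sigma))
            peptides.append((body + "K", factor))
        proteins.append(
            GroundTruthProtein(
                protein_id=f"SIM{i:05d}",
                true_stoichiometry=float(10.0 ** log_s[i]),
                abundance=float(abundances[i]),
                peptides=tuple(peptides),
            )
        )
    return proteins


def _light_fraction(s: float, config: SimConfig) -> float:
    """Fraction of a protein's light-channel pool that the pull-down retains:
    the enriched modified fraction plus nonspecific carryover of the
    unmodified fraction."""
    e, f_ns = config.enrichment_efficiency, config.nonspecific_fraction
    return e * s + f_ns * (1.0 - s)


def _observe_pair(
    base_heavy: float,
    base_light: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[float, float, float, float] | None:
    """Apply the detector model to one noiseless SILAC pair.

    A channel is missing when its noiseless area falls below
    noise_floor·snr_detect_min, or when it is the minor peak of the pair and
    the major/minor ratio exceeds the dynamic range. Reported areas carry
    multiplicative lognormal noise (median-preserving); S/N is reported area
    over the noise floor. Returns (area_h, area_l, snr_h, snr_l) with NaN for
    missing channels, or None when both channels vanish.
    """
    floor = config.noise_floor * config.snr_detect_min
    det_h = base_heavy >= floor
    det_l = base_light >= floor
    if det_h and det_l:
        major, minor = max(base_heavy, base_light), min(base_heavy, base_light)
        if minor > 0 and major / minor > config.dynamic_range:
            if base_heavy < base_light:
                det_h = False
            else:
                det_l = False
    if not (det_h or det_l):
        return None
    sigma = math.sqrt(math.log1p(config.ratio_cv**2))
    out = []
    for detected, base in ((det_h, base_heavy), (det_l, base_light)):
        # one noise draw per channel regardless of detection, so the random
        # stream stays aligned when a detection flag flips
        z = rng.standard_normal() if sigma > 0 else 0.0
        out.append(base * math.exp(sigma * z) if detected else math.nan)
    area_h, area_l = out
    snr_h = area_h / config.noise_floor if det_h else math.nan
    snr_l = area_l / config.noise_floor if det_l else math.nan
    return area_h, area_l, snr_h, snr_l


def _assemble(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=QUANT_COLUMNS + TRUTH_COLUMNS)
    for col in QUANT_COLUMNS[4:] + TRUTH_COLUMNS:
        df[col] = df[col].astype(float)
    return df


def simulate_titration_experiment(
    truth: list[GroundTruthProtein],
    design: list[MixDesign],
    config: SimConfig,
    replicate_label: str = "set1",
) -> pd.DataFrame:
    """Simulate the full titration run for one replicate.

    At a mix point with heavy mass H and light mass L (r = H/L), the light
    area of a peptide is proportional to ionization·abundance·L·(e·s +
    f_ns·(1−s)) and the heavy area to ionization·abundance·H; the detector
    model above decides which channels are reported. Rows where both channels
    vanish are not emitted.
    """
    if not design:
        raise ValueError("titration design must contain at least one mix point")
    for d in design:
        if not (0 < d.ratio_r < 1):
            raise ValueError(f"mix point {d.mix_label!r}: ratio_r must lie in (0,1)")
    rng = _rng(config, "titration", replicate_label)
    rows: list[dict] = []
    for protein in truth:
        s = protein.true_stoichiometry
        lf = _light_fraction(s, config)
        for seq, ion in protein.peptides:
            gain = config.area_scale * protein.abundance * ion
            for d in design:
                base_h = gain * d.heavy_mass_ug
                base_l = gain * d.light_mass_ug * lf
                obs = _observe_pair(base_h, base_l, config, rng)
                if obs is None:
                    continue
                area_h, area_l, snr_h, snr_l = obs
                rows.append(
                    {
                        "protein_id": protein.protein_id,
                        "peptide_seq": seq,
                        "mix_label": d.mix_label,
                        "replicate": replicate_label,
                        "area_heavy": area_h,
                        "area_light": area_l,
                        "snr_heavy": snr_h,
                        "snr_light": snr_l,
                        "true_s": s,
                        "expected_hl": (d.ratio_r / lf) if lf > 0 else math.inf,
                    }
                )
    return _assemble(rows)


def simulate_binding_control(
    truth: list[GroundTruthProtein],
    config: SimConfig,
    mass_ug: float = 5000.0,
    replicate_label: str = "control",
) -> pd.DataFrame:
    """Simulate the 1:1 nonspecific-binding control pull-down.

    Equal lysate masses of heavy (PARP-inhibited, unmodified — its only route
    onto the beads is nonspecific binding, signal ∝ f_ns) and light
    (modified, signal ∝ e·s + f_ns·(1−s)) are enriched together. In the
    clean limit the per-peptide heavy/light ratio is
    f_ns / (e·s + f_ns·(1−s)).
    """
    rng = _rng(config, "binding_control", replicate_label)
    rows: list[dict] = []
    for protein in truth:
        s = protein.true_stoichiometry
        lf = _light_fraction(s, config)
        for seq, ion in protein.peptides:
            gain = config.area_scale * protein.abundance * ion * mass_ug
            base_h = gain * config.nonspecific_fraction
            base_l = gain * lf
            obs = _observe_pair(base_h, base_l, config, rng)
            if obs is None:
                continue
            area_h, area_l, snr_h, snr_l = obs
            rows.append(
                {
                    "protein_id": protein.protein_id,
                    "peptide_seq": seq,
                    "mix_label": "1:1",
                    "replicate": replicate_label,
                    "area_heavy": area_h,
                    "area_light": area_l,
                    "snr_heavy": snr_h,
                    "snr_light": snr_l,
                    "true_s": s,
                    "expected_hl": (config.nonspecific_fraction / lf) if lf > 0 else math.inf,
                }
            )
    return _assemble(rows)


def simulate_depletion_series(
    config: SimConfig, n_rounds: int, noise_cv: float = 0.0
) -> list[float]:
    """Remaining PAR signal in the supernatant after each of ``n_rounds``
    sequential bead incubations: (1−e)^k, optionally with multiplicative
    lognormal noise on each measured fraction."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    e = config.enrichment_efficiency
    fractions = [(1.0 - e) ** k for k in range(1, n_rounds + 1)]
    if noise_cv > 0:
        rng = _rng(config, "depletion")
        sigma = math.sqrt(math.log1p(noise_cv**2))
        fractions = [f * math.exp(sigma * rng.standard_normal()) for f in fractions]
    return fractions


def truth_table(truth: list[GroundTruthProtein]) -> pd.DataFrame:
    """Protein-level ground-truth side-car (for tests and accuracy reports)."""
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in truth],
            "true_stoichiometry": [p.true_stoichiometry for p in truth],
            "abundance": [p.abundance for p in truth],
            "n_peptides": [len(p.peptides) for p in truth],
        }
    )


def write_truth_table(truth: list[GroundTruthProtein], path) -> None:
    truth_table(truth).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str})
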