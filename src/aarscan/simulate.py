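"""Synthetic sequence families and measurement tables with known truth.

Every pipeline stage gets a recovery test from this module without any
external data:

* :func:`generate_family` builds a two-group protein family (marine-like
  in-group vs freshwater-like out-group) from a random root sequence with
  i.i.d. background substitutions, then overwrites a set of *planted*
  diagnostic positions: the in-group always carries one designated residue
  there, the out-group draws from a disjoint residue set.  At background
  probability 0 the strict scan must recover exactly the planted columns.
* :func:`generate_measurements` emits replicate-level hydrocarbon and
  western-blot tables around known per-variant truths: band volumes and
  hydrocarbon totals get multiplicative lognormal noise (both are positive
  intensity measurements), and the three-analyte split is a Dirichlet draw
  around a habitat-dependent mean triple — marine-like variants lean to
  pentadecane, freshwater-like ones to heptadecene, mirroring the C16/C18
  substrate-preference dichotomy.

This is deliberately not a phylogenetically realistic simulator (no rate
heterogeneity, no empirical substitution model, no indel process by
default); it reproduces only the statistical structure the analysis
assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, GAP, Msa, SequenceRecord

_LETTERS = np.array(list(AMINO_ACIDS))


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class PlantedPosition:
    """One diagnostic column: (1-based position, in-group residue, out-group set)."""

    position: int
    ingroup_residue: str
    outgroup_residues: tuple[str, ...]

    def __post_init__(self) -> None:
        self.outgroup_residues = tuple(self.outgroup_residues)
        if self.position < 1:
            raise ConfigError("planted positions are 1-based")
        if self.ingroup_residue in self.outgroup_residues:
            raise ConfigError(
                f"position {self.position}: in-group residue "
                f"{self.ingroup_residue!r} also in the out-group set"
            )
        if not self.outgroup_residues:
            raise ConfigError(f"position {self.position}: empty out-group residue set")


@dataclass
class FamilyConfig:
    """Shape of the synthetic protein family.

    Defaults emulate the real study family: 341-residue AAR-like
    sequences, a 2-member in-group vs 6-member out-group, 11 planted
    diagnostic positions and a 5% per-site background substitution rate.
    """

    length: int = 341
    n_ingroup: int = 2
    n_outgroup: int = 6
    planted: tuple[PlantedPosition, ...] | None = None
    n_planted: int = 11
    background_substitution: float = 0.05
    gap_probability: float = 0.0
    ingroup_habitat: str = "marine"
    outgroup_habitat: str = "freshwater"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_ingroup < 1 or self.n_outgroup < 1:
            raise ConfigError("length and group sizes must be positive")
        if not 0.0 <= self.background_substitution <= 1.0:
            raise ConfigError("background substitution must be a probability")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ConfigError("gap probability must be a probability")
        if self.planted is not None:
            positions = [p.position for p in self.planted]
            if len(set(positions)) != len(positions):
                raise ConfigError("planted positions must be distinct")
            if max(positions) > self.length:
                raise ConfigError("planted position beyond sequence length")
        elif not 0 <= self.n_planted <= self.length:
            raise ConfigError("n_planted out of range")


@dataclass
class VariantTruth:
    """Ground-truth parameters of one simulated variant."""

    variant_id: str
    habitat: str
    activity: float
    expression: float
    solubility: float  # soluble fraction in [0, 1]
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.activity < 0 or self.expression < 0:
            raise ConfigError("activity and expression must be non-negative")
        if not 0.0 <= self.solubility <= 1.0:
            raise ConfigError("solubility is a fraction in [0, 1]")


@dataclass
class MeasurementConfig:
    """Noise model and truth set for the measurement generator.

    The habitat mean fraction triples encode the substrate-preference
    dichotomy: marine-like variants centred on (0.75, 0.20, 0.05) for
    (pentadecane, heptadecene, heptadecane), freshwater-like on
    (0.15, 0.77, 0.08) — pentadecane roughly 20% of heptadecene.
    ``dirichlet_concentration=None`` means no fraction noise (the infinite-
    concentration limit); ``noise_cv`` is the lognormal coefficient of
    variation applied to band volumes and hydrocarbon totals.
    """

    variants: tuple[VariantTruth, ...] | None = None
    n_variants: int = 8
    reference_id: str = "ref"
    marine_fractions: tuple[float, float, float] = (0.75, 0.20, 0.05)
    freshwater_fractions: tuple[float, float, float] = (0.15, 0.77, 0.08)
    dirichlet_concentration: float | None = 300.0
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for triple in (self.marine_fractions, self.freshwater_fractions):
            if abs(sum(triple) - 1.0) > 1e-9:
                raise ConfigError(f"mean fraction triple {triple} must sum to 1")
            if min(triple) < 0:
                raise ConfigError("mean fractions must be non-negative")
        if self.noise_cv < 0:
            raise ConfigError("noise CV must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("need at least 1 replicate")
        if self.dirichlet_concentration is not None and self.dirichlet_concentration <= 0:
            raise ConfigError("Dirichlet concentration must be positive")


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    planted: tuple[PlantedPosition, ...] = ()
    habitats: dict[str, str] = field(default_factory=dict)
    variants: dict[str, VariantTruth] = field(default_factory=dict)
    fraction_means: dict[str, tuple[float, ...]] = field(default_factory=dict)

    @property
    def planted_positions(self) -> list[int]:
        return sorted(p.position for p in self.planted)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [
                {
                    "position": p.position,
                    "ingroup_residue": p.ingroup_residue,
                    "outgroup_residues": list(p.outgroup_residues),
                }
                for p in self.planted
            ],
            "habitats": self.habitats,
            "variants": {
                vid: {
                    "habitat": v.habitat,
                    "activity": v.activity,
                    "expression": v.expression,
                    "solubility": v.solubility,
                    "below_detection": v.below_detection,
                }
                for vid, v in self.variants.items()
            },
            "fraction_means": {k: list(v) for k, v in self.fraction_means.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _plant_positions(cfg: FamilyConfig, rng: np.random.Generator) -> tuple[PlantedPosition, ...]:
    if cfg.planted is not None:
        return tuple(cfg.planted)
    positions = rng.choice(cfg.length, size=cfg.n_planted, replace=False) + 1
    planted = []
    for pos in sorted(int(p) for p in positions):
        picks = rng.choice(len(_LETTERS), size=3, replace=False)
        planted.append(
            PlantedPosition(
                position=pos,
                ingroup_residue=str(_LETTERS[picks[0]]),
                outgroup_residues=(str(_LETTERS[picks[1]]), str(_LETTERS[picks[2]])),
            )
        )
    return tuple(planted)


def generate_family(
    cfg: FamilyConfig,
) -> tuple[list[SequenceRecord], Msa, GroundTruth]:
    """Simulate the two-group family; same seed, same output.

    The first in-group member (``M01``) is gapless and serves as the
    natural numbering reference even when gap injection is enabled.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = _plant_positions(cfg, rng)
    root = rng.choice(len(_LETTERS), size=cfg.length)

    def derive(is_ingroup: bool) -> np.ndarray:
        seq = root.copy()
        mask = rng.random(cfg.length) < cfg.background_substitution
        # replacement drawn from the 19 letters other than the current one
        offsets = rng.integers(1, len(_LETTERS), size=int(mask.sum()))
        seq[mask] = (seq[mask] + offsets) % len(_LETTERS)
        letters = _LETTERS[seq].copy()
        for p in planted:
            if is_ingroup:
                letters[p.position - 1] = p.ingroup_residue
            else:
                letters[p.position - 1] = p.outgroup_residues[
                    int(rng.integers(len(p.outgroup_residues)))
                ]
        return letters

    records: list[SequenceRecord] = []
    rows: list[tuple[str, str]] = []
    habitats: dict[str, str] = {}
    planted_cols = {p.position - 1 for p in planted}
    names = [(f"M{i + 1:02d}", True) for i in range(cfg.n_ingroup)] + [
        (f"F{i + 1:02d}", False) for i in range(cfg.n_outgroup)
    ]
    for idx, (vid, is_ingroup) in enumerate(names):
        letters = derive(is_ingroup)
        row = letters.copy()
        if cfg.gap_probability > 0 and idx > 0:
            gap_mask = rng.random(cfg.length) < cfg.gap_probability
            gap_mask[list(planted_cols)] = False
            row[gap_mask] = GAP
        habitat = cfg.ingroup_habitat if is_ingroup else cfg.outgroup_habitat
        records.append(
            SequenceRecord(vid, "".join(ch for ch in row if ch != GAP), habitat=habitat)
        )
        rows.append((vid, "".join(row)))
        habitats[vid] = habitat
    truth = GroundTruth(planted=planted, habitats=habitats)
    return records, Msa(rows), truth


def _default_variants(cfg: MeasurementConfig, rng: np.random.Generator) -> tuple[VariantTruth, ...]:
    """Reference plus alternating marine/freshwater variants.

    True relative activities are log-uniform on [0.05, 1.5] (the observed
    span of relative activities across the real enzyme panel), expression
    log-uniform on [0.3, 3], solubility uniform on [0.1, 0.9].
    """
    variants = [
        VariantTruth(cfg.reference_id, "freshwater", activity=1.0, expression=1.0, solubility=0.6)
    ]
    for i in range(cfg.n_variants - 1):
        habitat = "marine" if i % 2 == 0 else "freshwater"
        variants.append(
            VariantTruth(
                variant_id=f"v{i + 1:03d}",
                habitat=habitat,
                activity=float(np.exp(rng.uniform(np.log(0.05), np.log(1.5)))),
                expression=float(np.exp(rng.uniform(np.log(0.3), np.log(3.0)))),
                solubility=float(rng.uniform(0.1, 0.9)),
            )
        )
    return tuple(variants)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_measurements(
    cfg: MeasurementConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate hydrocarbon and blot tables around known truths.

    Per replicate: soluble volume = expression x solubility x LN(cv),
    insoluble = expression x (1 - solubility) x LN(cv), hydrocarbon total =
    activity x expression x solubility x LN(cv), split across the three
    analytes by a Dirichlet draw around the habitat mean triple.  Variants
    flagged below detection emit ``soluble_detected=False``.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = cfg.variants if cfg.variants is not None else _default_variants(cfg, rng)
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate variant ids")
    if cfg.reference_id not in ids:
        raise ConfigError(f"reference {cfg.reference_id!r} not among the variants")

    means = {
        "marine": np.array(cfg.marine_fractions),
        "freshwater": np.array(cfg.freshwater_fractions),
        "both": (np.array(cfg.marine_fractions) + np.array(cfg.freshwater_fractions)) / 2.0,
    }
    hydro_rows, blot_rows = [], []
    truth = GroundTruth()
    for v in variants:
        mean_triple = means.get(v.habitat, means["freshwater"])
        truth.variants[v.variant_id] = v
        truth.habitats[v.variant_id] = v.habitat
        truth.fraction_means[v.variant_id] = tuple(float(x) for x in mean_triple)
        soluble_truth = v.expression * v.solubility
        noise = _lognormal_factor(rng, cfg.noise_cv, 3 * cfg.n_replicates).reshape(
            cfg.n_replicates, 3
        )
        for rep in range(1, cfg.n_replicates + 1):
            s_vol = soluble_truth * noise[rep - 1, 0]
            p_vol = v.expression * (1.0 - v.solubility) * noise[rep - 1, 1]
            total_h = v.activity * soluble_truth * noise[rep - 1, 2]
            if cfg.dirichlet_concentration is None:
                split = mean_triple
            else:
                alpha = np.clip(mean_triple, 1e-12, None) * cfg.dirichlet_concentration
                split = rng.dirichlet(alpha)
            amounts = total_h * split
            hydro_rows.append(
                {
                    "variant_id": v.variant_id,
                    "replicate": rep,
                    "amount_c15": amounts[0],
                    "amount_c17_1": amounts[1],
                    "amount_c17_0": amounts[2],
                }
            )
            blot_rows.append(
                {
                    "variant_id": v.variant_id,
                    "replicate": rep,
                    "soluble_volume": 0.0 if v.below_detection else s_vol,
                    "insoluble_volume": p_vol,
                    "soluble_detected": not v.below_detection,
                    "insoluble_detected": True,
                }
            )
    return pd.DataFrame(hydro_rows), pd.DataFrame(blot_rows), truth


def variants_from_family(
    records: list[SequenceRecord],
    reference_id: str | None = None,
    seed: int = 0,
) -> tuple[VariantTruth, ...]:
    """Ground-truth measurement parameters keyed by family sequence ids.

    The reference (first family member by default) gets truth 1/1/0.6;
    the rest draw from the same distributions as :func:`_default_variants`.
    """
    rng = np.random.default_rng(seed)
    reference_id = reference_id or records[0].id
    if reference_id not in {r.id for r in records}:
        raise ConfigError(f"reference {reference_id!r} not in the family")
    out = []
    for r in records:
        if r.id == reference_id:
            out.append(VariantTruth(r.id, r.habitat, activity=1.0, expression=1.0, solubility=0.6))
        else:
            out.append(
                VariantTruth(
                    variant_id=r.id,
                    habitat=r.habitat,
                    activity=float(np.exp(rng.uniform(np.log(0.05), np.log(1.5)))),
                    expression=float(np.exp(rng.uniform(np.log(0.3), np.log(3.0)))),
                    solubility=float(rng.uniform(0.1, 0.9)),
                )
            )
    return tuple(out)


def write_dataset(
    out_dir: str | Path,
    family_cfg: FamilyConfig,
    measurement_cfg: MeasurementConfig,
) -> dict[str, Path]:
    """Write a complete synthetic dataset in the pipeline's input dialects.

    When the measurement config carries no explicit variant truths, they
    are derived from the family so that sequence and measurement ids match
    and the correlation stage can join them.
    """
    import dataclasses

    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, msa, fam_truth = generate_family(family_cfg)
    if measurement_cfg.variants is None:
        family_ids = {r.id for r in records}
        ref = (
            measurement_cfg.reference_id
            if measurement_cfg.reference_id in family_ids
            else records[0].id
        )
        measurement_cfg = dataclasses.replace(
            measurement_cfg,
            reference_id=ref,
            variants=variants_from_family(records, ref, seed=measurement_cfg.seed),
        )
    hydro, blot, meas_truth = generate_measurements(measurement_cfg)
    paths = {
        "sequences": out / "sequences.fasta",
        "msa": out / "alignment.afa",
        "habitat": out / "habitat.tsv",
        "hydrocarbons": out / "hydrocarbons.tsv",
        "blots": out / "blots.tsv",
        "family_truth": out / "family_truth.json",
        "measurement_truth": out / "measurement_truth.json",
    }
    _io.write_fasta(records, paths["sequences"])
    _io.write_alignment(msa, paths["msa"])
    _io.write_habitat_table(fam_truth.habitats, paths["habitat"])
    hydro.to_csv(paths["hydrocarbons"], sep="\t", index=False, float_format="%.10g")
    blot.to_csv(paths["blots"], sep="\t", index=False)
    fam_truth.to_json(paths["family_truth"])
    meas_truth.to_json(paths["measurement_truth"])
    return paths
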