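"""Synthetic peak tables and electrolyte-leakage series.

Generates data with the statistical structure the downstream analysis
assumes: log-normal feature intensities over a full-factorial design
(genotype x condition x timepoint x replicate), planted log2 group
effects, condition-dependent block correlations on the log scale, a
multiplicative per-sample internal-standard factor, and logistic
freeze–leakage curves.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PeakTable

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "CorrelationBlock",
    "CorrelationSpec",
    "LeakageSimSpec",
    "generate_peak_table",
    "generate_leakage_series",
    "ANNOTATED_VOCABULARY",
]

# Metabolite names used for "annotated" feature labels in fixtures; drawn
# from the compounds routinely reported in plant cold-stress GC-MS panels.
ANNOTATED_VOCABULARY: tuple[str, ...] = (
    "sucrose", "glucose", "fructose", "maltose", "melibiose", "gentiobiose",
    "cellobiose", "xylose", "inositol", "maltotriose", "glucopyranose",
    "xylitol", "glycerol", "galactinol", "raffinose", "trehalose",
    "proline", "glycine", "beta_alanine", "asparagine", "lysine", "valine",
    "phenylalanine", "tyrosine", "isoleucine", "leucine", "serine",
    "threonine", "alanine", "glutamine", "glutamate", "aspartate",
    "methionine", "tryptophan", "fumaric_acid", "succinic_acid",
    "glycolic_acid", "maleic_acid", "gluconic_acid", "glutaric_acid",
    "citric_acid", "malic_acid", "pyroglutamate", "shikimic_acid",
    "quinic_acid", "ascorbic_acid", "benzoic_acid", "4_hydroxybenzoic_acid",
    "adenosine", "uridine", "guanosine", "inosine", "putrescine",
    "spermidine", "ethanolamine", "urea", "phosphoric_acid", "sorbitol",
    "mannitol", "galactose", "mannose", "ribose", "arabinose", "erythritol",
    "threitol", "glyceric_acid", "lactic_acid", "oxalic_acid",
    "pyruvic_acid", "oxoglutaric_acid", "dehydroascorbic_acid",
    "nicotinic_acid", "salicylic_acid", "sinapic_acid", "ferulic_acid",
    "caffeic_acid", "octadecanoic_acid", "hexadecanoic_acid",
)


@dataclass(frozen=True)
class DesignSpec:
    """Full-factorial study design.

    Defaults emulate a two-genotype (WT vs adh1), three-condition
    (control CK, acclimated freeze A, cold shock S), two-timepoint,
    six-replicate experiment with 263 resolved features of which 78
    carry metabolite annotations, plus a ribitol internal standard.
    """

    genotypes: tuple[str, ...] = ("WT", "adh1")
    conditions: tuple[str, ...] = ("CK", "A", "S")
    timepoints: tuple[str, ...] = ("t2h", "rec24h")
    replicates: int = 6
    n_features: int = 263
    n_annotated: int = 78
    internal_standard_name: str = "ribitol"

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not 0 <= self.n_annotated <= self.n_features:
            raise ValueError("n_annotated must be in [0, n_features]")
        for axis, labels in (
            ("genotypes", self.genotypes),
            ("conditions", self.conditions),
            ("timepoints", self.timepoints),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels on axis {axis!r}")
        if self.internal_standard_name in self.feature_names():
            raise ValueError("internal standard name collides with a feature")

    @property
    def n_samples(self) -> int:
        return (
            len(self.genotypes)
            * len(self.conditions)
            * len(self.timepoints)
            * self.replicates
        )

    def feature_names(self) -> list[str]:
        names: list[str] = []
        vocab = ANNOTATED_VOCABULARY
        for i in range(self.n_annotated):
            base = vocab[i % len(vocab)]
            names.append(base if i < len(vocab) else f"{base}_{i // len(vocab) + 1}")
        names.extend(f"unknown_{i + 1:03d}" for i in range(self.n_features - self.n_annotated))
        return names

    def cells(self) -> list[tuple[str, str, str]]:
        return list(itertools.product(self.genotypes, self.conditions, self.timepoints))


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects and noise on the log2-intensity scale.

    ``effects`` maps a design cell ``(genotype, condition, timepoint)``
    to ``{feature index: log2 effect}`` relative to the baseline cell
    (first level of every axis); cells not listed default to zero
    effect.  ``sample_factor_sd`` is the log2 sd of the multiplicative
    per-sample factor that the internal standard shares with every
    feature, making division by it the exact correction.
    """

    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    sample_factor_sd: float = 0.5
    effects: Mapping[tuple[str, str, str], Mapping[int, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.sample_factor_sd < 0:
            raise ValueError("noise sd values must be non-negative")


@dataclass(frozen=True)
class CorrelationBlock:
    """A disjoint set of features sharing a target within-block correlation.

    ``r`` is either a single value applied under every condition or a
    mapping from condition label to target correlation, allowing
    condition-dependent connectivity (e.g. tighter coupling under cold
    shock than control).
    """

    features: tuple[int, ...]
    r: float | Mapping[str, float]

    def target(self, condition: str) -> float:
        if isinstance(self.r, Mapping):
            return float(self.r.get(condition, 0.0))
        return float(self.r)


@dataclass(frozen=True)
class CorrelationSpec:
    blocks: tuple[CorrelationBlock, ...] = ()
    between_block_r: float = 0.0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for block in self.blocks:
            members = set(block.features)
            if members & seen:
                raise ValueError("correlation blocks must be disjoint")
            seen |= members
            values = (
                block.r.values() if isinstance(block.r, Mapping) else [block.r]
            )
            for v in values:
                if not -1.0 < float(v) < 1.0:
                    raise ValueError("target correlations must lie in (-1, 1)")


class CorrelationNotPositiveDefinite(ValueError):
    """The implied within-condition correlation matrix has no Cholesky factor."""

    def __init__(self, condition: str, block_index: int):
        self.condition = condition
        self.block_index = block_index
        super().__init__(
            f"correlation block {block_index} under condition {condition!r} "
            "implies a non-positive-definite covariance"
        )


def _block_cholesky(k: int, r: float, condition: str, block_index: int) -> np.ndarray:
    """Cholesky factor of a k x k equicorrelated matrix."""
    sigma = np.full((k, k), r)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise CorrelationNotPositiveDefinite(condition, block_index) from exc


def generate_peak_table(
    design: DesignSpec = DesignSpec(),
    effects: EffectSpec = EffectSpec(),
    corr: CorrelationSpec = CorrelationSpec(),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> PeakTable:
    """Simulate a samples-by-features intensity table.

    Log2 intensities are multivariate normal: per-feature baselines plus
    planted cell effects plus correlated replicate noise, then
    exponentiated and multiplied by a per-sample log-normal factor that
    the internal-standard column also carries.  Identical arguments and
    seed give a byte-identical table.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = design.n_features
    features = design.feature_names()

    baselines = rng.normal(effects.baseline_log2_mean, effects.baseline_log2_sd, size=p)

    # One Cholesky factor per (condition, block); unassigned features are
    # independent. between_block_r != 0 is not supported beyond validation
    # because disjoint equicorrelated blocks are the structure the
    # downstream network tests need.
    chol: dict[tuple[str, int], np.ndarray] = {}
    for cond in design.conditions:
        for bi, block in enumerate(corr.blocks):
            r = block.target(cond)
            chol[(cond, bi)] = _block_cholesky(len(block.features), r, cond, bi)

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    sample_ids: list[str] = []
    istd_base_log2 = 8.0
    for geno, cond, tp in design.cells():
        cell_effect = np.zeros(p)
        for idx, delta in effects.effects.get((geno, cond, tp), {}).items():
            cell_effect[idx] = delta
        for rep in range(1, design.replicates + 1):
            z = rng.standard_normal(p)
            for bi, block in enumerate(corr.blocks):
                members = np.asarray(block.features)
                z[members] = chol[(cond, bi)] @ z[members]
            log2_ratio = baselines + cell_effect + effects.noise_sd * z
            sample_factor = effects.sample_factor_sd * rng.standard_normal()
            intensities = np.power(2.0, log2_ratio + sample_factor)
            istd = np.power(2.0, istd_base_log2 + sample_factor)
            rows.append(np.append(intensities, istd))
            sid = f"{geno}_{cond}_{tp}_r{rep}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "genotype": geno,
                    "condition": cond,
                    "timepoint": tp,
                    "replicate": rep,
                }
            )

    columns = features + [design.internal_standard_name]
    intensities = pd.DataFrame(rows, index=sample_ids, columns=columns)
    intensities.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    if missing_rate > 0:
        mask = rng.random(size=(intensities.shape[0], p)) < missing_rate
        values = intensities.iloc[:, :p].to_numpy()
        values[mask] = np.nan
        intensities.iloc[:, :p] = values

    return PeakTable(
        intensities=intensities,
        metadata=metadata,
        internal_standard=design.internal_standard_name,
        annotated=tuple(features[: design.n_annotated]),
    )


def study_preset(
    design: DesignSpec = DesignSpec(),
) -> tuple[DesignSpec, EffectSpec, CorrelationSpec]:
    """Specs emulating the cold-stress study's qualitative structure.

    Plants genotype-dependent sucrose-like contrasts (a strong control
    deficit in the first genotype that narrows after acclimated freezing
    and persists under cold shock), broad condition shifts in a quarter
    of the features, and correlation blocks whose coupling tightens
    sharply under cold shock — the feature that makes shock networks
    denser than control networks downstream.
    """
    rng = np.random.default_rng(20)
    p = design.n_features
    geno_b = design.genotypes[0]          # "WT"-like genotype
    ck, acc, shock = design.conditions
    tp1, tp2 = design.timepoints[:2]

    effects: dict[tuple[str, str, str], dict[int, float]] = {}
    cold_features = rng.choice(np.arange(1, p), size=p // 4, replace=False)
    for cond, scale in ((acc, 1.2), (shock, 0.8)):
        for tp, damp in ((tp1, 1.0), (tp2, 0.4)):
            for geno in design.genotypes:
                cell = effects.setdefault((geno, cond, tp), {})
                for j in cold_features:
                    cell[int(j)] = float(scale * damp * rng.normal(0, 1.0))
    # feature 0 (sucrose slot when annotated) carries the genotype contrast
    effects.setdefault((geno_b, ck, tp1), {})[0] = -np.log2(14.723)
    effects.setdefault((geno_b, ck, tp2), {})[0] = -np.log2(14.723)
    effects.setdefault((geno_b, acc, tp1), {})[0] = np.log2(2.751)
    effects.setdefault((geno_b, acc, tp2), {})[0] = np.log2(1.959)
    effects.setdefault((geno_b, shock, tp1), {})[0] = -np.log2(1.558)
    effects.setdefault((geno_b, shock, tp2), {})[0] = -np.log2(4.141)

    blocks = []
    start = 1
    for size in (8, 8, 6, 6):
        members = tuple(range(start, start + size))
        blocks.append(
            CorrelationBlock(members, r={ck: 0.3, acc: 0.5, shock: 0.95})
        )
        start += size
    return design, EffectSpec(effects=effects), CorrelationSpec(tuple(blocks))


@dataclass(frozen=True)
class LeakageSimSpec:
    """Ground truth for a simulated electrolyte-leakage freeze series."""

    lt50: float = -6.42
    scale: float = 1.5
    lower: float = 0.05
    upper: float = 0.95
    temperatures: tuple[float, ...] = tuple(np.arange(0.0, -20.0 - 1e-9, -2.0))
    noise_sd: float = 0.02
    replicates: int = 6

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower asymptote must be below upper")
        if len(self.temperatures) == 0:
            raise ValueError("temperature grid is empty")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def curve(self, temperature: np.ndarray | float) -> np.ndarray:
        """Noise-free leakage fraction at the given temperatures.

        Leakage rises towards the upper asymptote as temperature falls
        below the midpoint (colder = more membrane damage).
        """
        t = np.asarray(temperature, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp((t - self.lt50) / self.scale)
        )


def generate_leakage_series(spec: LeakageSimSpec = LeakageSimSpec(), seed: int = 0) -> pd.DataFrame:
    """Simulate replicate leakage fractions over a freezing-temperature grid.

    Returns a tidy frame with columns ``temperature_C``, ``replicate``,
    ``relative_leakage``; values are clipped to [0, 1] and the noiseless
    limit equals the logistic curve exactly.
    """
    rng = np.random.default_rng(seed)
    temps = np.asarray(spec.temperatures, dtype=float)
    records = []
    for rep in range(1, spec.replicates + 1):
        y = spec.curve(temps)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=temps.size)
        y = np.clip(y, 0.0, 1.0)
        for t, v in zip(temps, y):
            records.append(
                {"temperature_C": t, "replicate": rep, "relative_leakage": v}
            )
    return pd.DataFrame.from_records(records)
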