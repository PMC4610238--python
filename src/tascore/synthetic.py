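"""Synthetic drug screens with planted ground truth.

Emulates the structure of a multi-dose viability screen run on a compound
panel with overlapping target sets: samples fall into sub-populations that
share planted target addictions, one target's addiction is coupled to a
binary biomarker label (mimicking an activating mutation such as a kinase
ITD), and each sample x compound pair yields a short serial-dilution
viability series normalised to no-drug controls.

The generative model is deliberately simple and fully declared:

* a bipartite compound -> target network with per-compound target counts
  drawn uniformly from a configured range, targets sampled without
  replacement from a shared pool (overlap between compounds arises from the
  shared pool, producing polypharmacology);
* per sample and compound, a true IC50 shifted down from a common baseline
  by the sample's strongest addiction among the compound's targets:

      IC50[s, c] = base_IC50 * 10^(-addiction_effect * max_t a[s, t]),

  so addiction monotonically increases potency;
* viability = 100 - logistic inhibition at each dose + additive Gaussian
  noise, clipped to [-10, 120]% (raw normalised screens stray outside
  [0, 100]).

Identical configurations produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, logistic_inhibition
from .errors import InvalidConfigError
from .network import TargetNetwork

VIABILITY_CLIP = (-10.0, 120.0)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_network", "simulate_screen"]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic screen.

    Defaults mirror a small kinase-inhibitor screen: four serial ten-fold
    dilutions spanning 1-1000 nM, a ~40-compound panel over ~25 targets,
    three addiction sub-populations and 5% viability noise.  The baseline
    IC50 sits one decade above the top dose so unaddicted pairs respond
    weakly; ``addiction_effect`` is the log10 IC50 shift per unit planted
    addiction (default 2 decades, a strong but realistic potency gain for a
    genuinely addicted sample).
    """

    n_samples: int = 60
    n_compounds: int = 40
    n_targets: int = 25
    n_clusters: int = 3
    targets_per_compound: tuple[int, int] = (1, 4)
    n_doses: int = 4
    dose_range: tuple[float, float] = (1.0, 1000.0)
    addiction_effect: float = 2.0
    noise_sd: float = 5.0
    biomarker_target: str | None = None  # default: first target id
    seed: int = 0
    # secondary knobs of the generative model
    targets_per_cluster: int = 3
    biomarker_positive_fraction: float = 0.5
    biomarker_addiction: float = 1.0
    base_ic50_nM: float | None = None  # default: 10x the top dose
    rmax: float = 100.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_compounds": self.n_compounds,
            "n_targets": self.n_targets,
            "n_clusters": self.n_clusters,
            "n_doses": self.n_doses,
        }
        for name, v in counts.items():
            if v < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {v}")
        lo, hi = self.targets_per_compound
        if not (1 <= lo <= hi):
            raise InvalidConfigError("targets_per_compound must satisfy 1 <= lo <= hi")
        if hi > self.n_targets:
            raise InvalidConfigError(
                f"targets_per_compound max {hi} exceeds n_targets {self.n_targets}"
            )
        if not self.dose_range[0] < self.dose_range[1]:
            raise InvalidConfigError("dose_range min must be < max")
        if self.dose_range[0] <= 0:
            raise InvalidConfigError("doses must be positive (nM)")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.n_clusters > self.n_samples:
            raise InvalidConfigError("n_clusters cannot exceed n_samples")
        if not 0.0 <= self.biomarker_positive_fraction <= 1.0:
            raise InvalidConfigError("biomarker_positive_fraction must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i+1:03d}" for i in range(self.n_samples)]

    @property
    def compound_ids(self) -> list[str]:
        return [f"C{i+1:03d}" for i in range(self.n_compounds)]

    @property
    def target_ids(self) -> list[str]:
        return [f"T{i+1:03d}" for i in range(self.n_targets)]

    @property
    def resolved_biomarker_target(self) -> str:
        return self.biomarker_target or self.target_ids[0]

    @property
    def doses_nM(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.dose_range[0]), np.log10(self.dose_range[1]), self.n_doses
        )

    @property
    def resolved_base_ic50_nM(self) -> float:
        return self.base_ic50_nM if self.base_ic50_nM is not None else 10.0 * self.dose_range[1]


@dataclass
class GroundTruth:
    """Planted truth of a synthetic screen."""

    addiction: pd.DataFrame  # samples x targets, nonnegative
    cluster_labels: pd.Series  # sample -> 1..n_clusters
    biomarker_labels: pd.Series  # sample -> "positive" | "negative"
    true_ic50_nM: pd.DataFrame  # samples x compounds

    def __post_init__(self) -> None:
        if (self.addiction.to_numpy() < 0).any():
            raise InvalidConfigError("planted addictions must be nonnegative")


def _network_rng(config: SimulationConfig) -> np.random.Generator:
    # separate stream so the network is identical whether or not a screen
    # is simulated on top of it
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1]))


def simulate_network(config: SimulationConfig) -> TargetNetwork:
    """Random bipartite compound -> target network.

    Each compound receives a uniform number of targets in
    ``targets_per_compound``, sampled without replacement from the pool.
    Every compound has >= 1 target by construction; targets never hit by a
    compound are absent from the network.
    """
    rng = _network_rng(config)
    lo, hi = config.targets_per_compound
    targets = np.array(config.target_ids)
    target_sets: dict[str, list[str]] = {}
    for c in config.compound_ids:
        k = int(rng.integers(lo, hi + 1))
        target_sets[c] = list(rng.choice(targets, size=k, replace=False))
    # the biomarker label is coupled to one target's addiction, which is
    # vacuous if no compound hits that target: repoint one edge of the
    # first compound (degree-preserving) when needed
    biomarker = config.resolved_biomarker_target
    if all(biomarker not in ts for ts in target_sets.values()):
        first = config.compound_ids[0]
        target_sets[first][0] = biomarker
    records = [
        {"compound_id": c, "target_id": t, "sources": "synthetic"}
        for c in config.compound_ids
        for t in sorted(set(target_sets[c]))
    ]
    return TargetNetwork(edges=pd.DataFrame(records))


def _planted_addiction(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    samples = config.sample_ids
    targets = config.target_ids
    biomarker = config.resolved_biomarker_target

    # round-robin cluster assignment keeps cluster sizes balanced
    cluster_labels = pd.Series(
        [(i % config.n_clusters) + 1 for i in range(config.n_samples)],
        index=samples,
        name="cluster",
    )
    addiction = pd.DataFrame(0.0, index=samples, columns=targets)

    # each cluster is addicted to its own targets; the biomarker target is
    # reserved so cluster structure cannot leak into the biomarker signal
    pool = [t for t in targets if t != biomarker]
    rng.shuffle(pool)
    per = min(config.targets_per_cluster, max(1, len(pool) // config.n_clusters))
    for k in range(config.n_clusters):
        chosen = pool[k * per : (k + 1) * per]
        if not chosen:  # more clusters than spare targets: reuse cyclically
            chosen = [pool[k % len(pool)]]
        members = cluster_labels.index[cluster_labels == k + 1]
        addiction.loc[members, chosen] = 1.0

    n_pos = int(round(config.biomarker_positive_fraction * config.n_samples))
    pos = rng.choice(config.n_samples, size=n_pos, replace=False)
    biomarker_labels = pd.Series("negative", index=samples, name="biomarker")
    biomarker_labels.iloc[pos] = "positive"
    addiction.loc[biomarker_labels == "positive", biomarker] = config.biomarker_addiction

    return GroundTruth(
        addiction=addiction,
        cluster_labels=cluster_labels,
        biomarker_labels=biomarker_labels,
        true_ic50_nM=pd.DataFrame(),  # filled in by simulate_screen
    )


def simulate_screen(
    config: SimulationConfig,
) -> tuple[list[DoseResponseSeries], GroundTruth, TargetNetwork]:
    """Full synthetic screen: dilution series, ground truth and network.

    Returns one viability-derived inhibition series per sample x compound
    pair, the planted addiction matrix with cluster and biomarker labels and
    true IC50s, and the drug-target network the responses were generated
    through.
    """
    network = simulate_network(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    truth = _planted_addiction(config, rng)

    doses = config.doses_nM
    x = np.log10(doses)
    base_m = np.log10(config.resolved_base_ic50_nM)
    membership = network.membership()  # compounds x targets

    addiction = truth.addiction
    # strongest addiction among each compound's targets, per sample
    a = addiction[membership.columns].to_numpy()  # samples x targets (network order)
    m = membership.to_numpy()  # compounds x targets
    max_add = (a[:, None, :] * m[None, :, :]).max(axis=2)  # samples x compounds
    true_m = base_m - config.addiction_effect * max_add  # log10 IC50 nM
    truth.true_ic50_nM = pd.DataFrame(
        10.0**true_m, index=addiction.index, columns=membership.index
    )

    series: list[DoseResponseSeries] = []
    n_s, n_c = true_m.shape
    noise = rng.normal(0.0, config.noise_sd, size=(n_s, n_c, config.n_doses)) if config.noise_sd > 0 else np.zeros((n_s, n_c, config.n_doses))
    sample_ids = list(addiction.index)
    compound_ids = list(membership.index)
    for i, s in enumerate(sample_ids):
        for j, c in enumerate(compound_ids):
            inhibition = logistic_inhibition(x, config.rmax, config.slope, true_m[i, j])
            viability = 100.0 - inhibition + noise[i, j]
            viability = np.clip(viability, *VIABILITY_CLIP)
            series.append(
                DoseResponseSeries.from_viability(s, c, doses, viability)
            )
    return series, truth, network


def screen_long_table(series: list[DoseResponseSeries]) -> pd.DataFrame:
    """Long-format table of a screen (sample, compound, dose, viability %)."""
    rows = []
    for s in series:
        for conc, inh in zip(s.concentrations_nM, s.responses):
            rows.append((s.sample_id, s.compound_id, conc, 100.0 - inh))
    return pd.DataFrame(
        rows, columns=["sample_id", "compound_id", "concentration_nM", "viability_pct"]
    )
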