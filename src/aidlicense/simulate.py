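"""Synthetic data generators with known ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — negative-binomially distributed spectral counts with planted
fold-reductions in two mutant baits, point-mutated clone sequences with
WRC/GYW-biased rates, Poisson colony counts, and log-linear Ct responses —
so every stage is testable without external data.

All randomness flows through explicit seeds (`numpy.random.default_rng`);
no global RNG state is touched.  The negative binomial is parameterised as
variance = mu + dispersion * mu^2 throughout, matching the count test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assays import FluctuationExperiment
from .bioid import SpectralCountMatrix
from .chip import QpcrRun
from .shm import CloneSet, MutationRecord, classify_mutation, hotspot_positions

BIRA_PREY_ID = "BIRA_STAR"

__all__ = [
    "BIRA_PREY_ID",
    "BioidSimConfig",
    "ShmSimConfig",
    "SimTruth",
    "gen_bioid",
    "gen_shm_clones",
    "gen_fluctuation",
    "gen_qpcr",
]


@dataclass
class BioidSimConfig:
    """Parameters of the synthetic BioID spectral-count experiment.

    Defaults mirror the planted-recovery study conditions used throughout
    the test suite: 500 preys, 20 planted 8-fold reductions, base mean 50,
    dispersion 0.05, 3 replicates per bait.  ``mean_sdlog`` spreads
    per-prey abundances log-normally so the ratio-intensity plane has a
    realistic dynamic range.
    """

    n_preys: int = 500
    n_planted: int = 20
    effect_size: float = 8.0  # fold-reduction in both mutant baits
    base_mean: float = 50.0  # median expected raw spectral count of a prey
    dispersion: float = 0.05  # variance = mu + dispersion * mu^2
    n_replicates: int = 3
    birA_mean: float = 200.0  # BirA* self-biotinylation row
    a2_background_frac: float = 0.1  # APOBEC2 bait signal as fraction of WT
    mean_sdlog: float = 1.0  # log-scale sd of per-prey abundance spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_preys:
            raise ValueError("n_planted > n_preys")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.base_mean, self.birA_mean) <= 0:
            raise ValueError("means must be positive")
        if self.a2_background_frac <= 0:
            raise ValueError("a2_background_frac must be positive")


@dataclass
class ShmSimConfig:
    """Parameters of the synthetic clone-sequencing experiment."""

    reference: str
    n_clones: int = 50
    per_base_rate: float = 1e-3  # substitution probability off-hotspot
    hotspot_multiplier: float = 5.0  # rate multiplier at WRC/GYW C:G sites
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        if set(self.reference) - set("ACGT"):
            raise ValueError("reference must be over {A,C,G,T}")
        if not 0 <= self.per_base_rate <= 1:
            raise ValueError("per_base_rate must be in [0, 1]")
        if self.per_base_rate * self.hotspot_multiplier > 1:
            raise ValueError("effective hotspot rate exceeds 1")


@dataclass
class SimTruth:
    """Ground truth planted by a generator."""

    planted_preys: set[str] = field(default_factory=set)
    planted_mutations: list[MutationRecord] = field(default_factory=list)
    true_frequency: float | None = None
    true_fractions: dict[str, float] = field(default_factory=dict)
    igg_fractions: dict[str, float] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """NB draw with variance = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def gen_bioid(config: BioidSimConfig) -> tuple[SpectralCountMatrix, SimTruth]:
    """Synthetic spectral-count matrix for baits WT, MUT1, MUT2 and A2.

    Planted preys have their expected BirA*-normalised signal reduced
    ``effect_size``-fold in both mutants; the APOBEC2 control carries
    ``a2_background_frac`` of the WT signal for every prey; a dedicated
    BirA* row (never zero) is present in every sample.
    """
    rng = np.random.default_rng(config.seed)
    prey_ids = [f"PREY{i + 1:04d}" for i in range(config.n_preys)]
    planted = set(
        rng.choice(prey_ids, size=config.n_planted, replace=False).tolist()
    )
    base = config.base_mean * np.exp(
        rng.normal(0.0, config.mean_sdlog, config.n_preys)
    )
    is_planted = np.array([p in planted for p in prey_ids])

    means = {}
    means["WT"] = base
    reduced = np.where(is_planted, base / config.effect_size, base)
    means["MUT1"] = reduced
    means["MUT2"] = reduced
    means["A2"] = config.a2_background_frac * base

    columns, data = [], []
    for bait in ("WT", "MUT1", "MUT2", "A2"):
        for rep in range(1, config.n_replicates + 1):
            columns.append((f"{bait}.{rep}", bait, rep))
            prey_counts = _nb_draw(rng, means[bait], config.dispersion)
            birA = 0
            while birA == 0:  # bait fusion always self-biotinylates
                birA = int(_nb_draw(rng, config.birA_mean, config.dispersion))
            data.append(np.concatenate([[birA], prey_counts]))

    counts = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index([BIRA_PREY_ID] + prey_ids, name="prey_id"),
        columns=[c[0] for c in columns],
        dtype=int,
    )
    samples = pd.DataFrame(
        {"bait": [c[1] for c in columns], "replicate": [c[2] for c in columns]},
        index=pd.Index([c[0] for c in columns], name="sample_id"),
    )
    matrix = SpectralCountMatrix(counts=counts, samples=samples,
                                 birA_prey_id=BIRA_PREY_ID)
    return matrix, SimTruth(planted_preys=planted)


def gen_shm_clones(config: ShmSimConfig) -> tuple[CloneSet, SimTruth]:
    """Point-mutated clones of a reference with WRC/GYW-hotspot rate bias.

    Each position mutates independently with probability ``per_base_rate``
    (times ``hotspot_multiplier`` at hotspot C/G sites); the substituted
    base is uniform over the three alternatives.  The truth lists every
    introduced change with its hotspot class.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    L = len(ref)
    rates = np.full(L, config.per_base_rate)
    rates[hotspot_positions(ref)] *= config.hotspot_multiplier

    alternatives = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    clones, truth = [], []
    for i in range(config.n_clones):
        cid = f"CLONE{i + 1:03d}"
        seq = list(ref)
        hits = np.nonzero(rng.random(L) < rates)[0]
        for pos in hits:
            obs = alternatives[ref[pos]][rng.integers(3)]
            seq[pos] = obs
            truth.append(
                MutationRecord(
                    clone_id=cid,
                    position=int(pos) + 1,
                    ref_base=ref[pos],
                    obs_base=obs,
                    mut_class=classify_mutation(ref, int(pos) + 1),
                )
            )
        clones.append((cid, "".join(seq)))
    return CloneSet(reference=ref, clones=clones), SimTruth(
        planted_mutations=truth
    )


def gen_fluctuation(
    freq_per_1e9: float,
    n_cultures: int = 5,
    ampR_mean: float = 1e8,
    seed: int = 0,
    construct: str = "AID",
    experiment_id: str = "exp1",
) -> tuple[FluctuationExperiment, SimTruth]:
    """Poisson colony counts for independent cultures at a known mutation
    frequency: rifR ~ Poisson(freq_per_1e9 * ampR / 1e9)."""
    if freq_per_1e9 < 0:
        raise ValueError("frequency must be >= 0")
    rng = np.random.default_rng(seed)
    cultures = []
    for _ in range(n_cultures):
        amp = 0
        while amp == 0:
            amp = int(rng.poisson(ampR_mean))
        rif = int(rng.poisson(freq_per_1e9 * amp / 1e9))
        cultures.append((rif, amp))
    exp = FluctuationExperiment(
        construct=construct, cultures=cultures, experiment_id=experiment_id
    )
    return exp, SimTruth(true_frequency=freq_per_1e9)


def gen_qpcr(
    true_fractions: Mapping[str, float],
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    input_fraction: float = 0.1,
    igg_percent: float = 0.05,
    dilutions: tuple[float, ...] = (1.0, 0.1, 0.01),
    intercept_ct: float = 20.0,
) -> tuple[QpcrRun, SimTruth]:
    """Synthetic qPCR plate: input dilution standards plus IP and IgG wells.

    ``true_fractions`` maps amplicon -> true IP %-input.  Ct responses are
    log-linear, Ct = a - log(q)/log(efficiency) + N(0, noise_sd), with
    ``efficiency`` the per-cycle amplification factor (2 = perfect
    doubling) and quantity 1 assigned to the undiluted input standard,
    which represents ``input_fraction`` of the IP chromatin.
    """
    if not 1 < efficiency <= 2:
        raise ValueError("efficiency must be in (1, 2]")
    if any(v <= 0 for v in true_fractions.values()):
        raise ValueError("true fractions must be positive")
    if len(dilutions) < 3:
        raise ValueError("need a >= 3-point dilution series")
    rng = np.random.default_rng(seed)
    log_eff = np.log(efficiency)

    def ct_of(q: float) -> float:
        return intercept_ct - np.log(q) / log_eff + rng.normal(0.0, noise_sd)

    rows = []
    igg_map = {}
    for amplicon, pct in true_fractions.items():
        for d in dilutions:
            rows.append((amplicon, "standard", d, ct_of(d)))
        q_ip = (pct / 100.0) / input_fraction
        rows.append((amplicon, "IP", np.nan, ct_of(q_ip)))
        q_igg = (igg_percent / 100.0) / input_fraction
        rows.append((amplicon, "IgG", np.nan, ct_of(q_igg)))
        igg_map[amplicon] = igg_percent
    run = QpcrRun(
        measurements=pd.DataFrame(
            rows, columns=["amplicon", "sample_kind", "dilution", "ct"]
        ),
        input_fraction=input_fraction,
    )
    return run, SimTruth(true_fractions=dict(true_fractions),
                         igg_fractions=igg_map)
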