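"""Simulation of genotype panels and phenotypes with controlled architecture.

Backgrounds are independent HWE SNPs with no phenotype association; causal
SNPs are appended with main and/or pairwise-interaction effects calibrated so
each term explains a stated fraction of unit phenotypic variance.  With the
centered dosage c_j = g_j - 2 p_j (variance 2 p_j q_j under HWE) and product
term c_j c_k (variance 2 p_j q_j * 2 p_k q_k for independent SNPs),

    beta_j  = sqrt(h2_j / (2 p_j q_j))
    beta_jk = sqrt(h2_jk / (2 p_j q_j * 2 p_k q_k))

and the residual is Normal(0, 1 - sum h2), so each term's expected share of
var(y) = 1 equals its h2.  Coefficients are fixed; the realized share varies
by replicate around its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, Phenotype

__all__ = ["CausalSnp", "SimulationScenario", "SimulatedDataset",
           "simulate_background", "calibrate_effects", "simulate_phenotype",
           "simulate_dataset", "scenario_main_effect",
           "scenario_interaction"]


@dataclass(frozen=True)
class CausalSnp:
    maf: float
    h2: float  # fraction of phenotypic variance from the main effect

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"causal MAF must be in (0, 0.5], got {self.maf}")
        if self.h2 < 0.0:
            raise ValueError("main-effect variance fraction must be >= 0")


@dataclass(frozen=True)
class SimulationScenario:
    """Declarative description of one simulation cell."""

    causal_snps: tuple = ()
    interaction_pairs: tuple = ()  # (j, k, h2_jk) into causal_snps
    n_subjects: int = 2000
    n_background: int = 3000
    background_maf_range: tuple = (0.05, 0.5)
    label: str = ""

    def __post_init__(self):
        lo, hi = self.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("background MAF range must lie in (0, 0.5]")
        for j, k, h2 in self.interaction_pairs:
            if h2 <= 0.0:
                raise ValueError("interaction variance fraction must be > 0")
            for idx in (j, k):
                if not 0 <= idx < len(self.causal_snps):
                    raise ValueError(
                        f"interaction index {idx} is not a declared causal SNP")
        if self.total_h2 >= 1.0:
            raise ValueError(
                f"variance fractions sum to {self.total_h2} >= 1")

    @property
    def total_h2(self) -> float:
        return (sum(s.h2 for s in self.causal_snps)
                + sum(h2 for _, _, h2 in self.interaction_pairs))


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotype: Phenotype
    causal_indices: np.ndarray      # columns of the causal SNPs
    causal_ids: np.ndarray
    beta_main: np.ndarray
    beta_interaction: np.ndarray
    scenario: SimulationScenario = None


def scenario_main_effect(maf: float, h2: float, **kw) -> SimulationScenario:
    """One additive causal SNP against the null background."""
    return SimulationScenario(causal_snps=(CausalSnp(maf, h2),),
                              label=f"main maf={maf} h2={h2}", **kw)


def scenario_interaction(h2_main1: float, h2_main2: float, h2_int: float,
                         maf: float = 0.5, **kw) -> SimulationScenario:
    """Two interacting causal SNPs (SNP2's main effect may be zero)."""
    return SimulationScenario(
        causal_snps=(CausalSnp(maf, h2_main1), CausalSnp(maf, h2_main2)),
        interaction_pairs=((0, 1, h2_int),),
        label=f"interaction {h2_main1}/{h2_main2}/{h2_int}", **kw)


def simulate_background(n: int, p: int, maf_range=(0.05, 0.5),
                        seed=None) -> GenotypeMatrix:
    """Independent HWE SNPs, per-SNP MAF uniform on ``maf_range``.

    Genotypes are Binomial(2, MAF) per subject; no phenotype linkage.
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    maf = rng.uniform(lo, hi, size=p)
    dos = rng.binomial(2, maf, size=(n, p)).astype(np.float64)
    ids = [f"bg{j + 1}" for j in range(p)]
    return GenotypeMatrix(dos, ids, ["1"] * p, np.arange(1, p + 1))


def calibrate_effects(scenario: SimulationScenario
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients giving each causal term its target variance fraction."""
    beta_main = np.array([np.sqrt(s.h2 / (2.0 * s.maf * (1.0 - s.maf)))
                          for s in scenario.causal_snps])
    beta_int = np.empty(len(scenario.interaction_pairs))
    for i, (j, k, h2) in enumerate(scenario.interaction_pairs):
        vj = 2.0 * scenario.causal_snps[j].maf * (1 - scenario.causal_snps[j].maf)
        vk = 2.0 * scenario.causal_snps[k].maf * (1 - scenario.causal_snps[k].maf)
        beta_int[i] = np.sqrt(h2 / (vj * vk))
    return beta_main, beta_int


def simulate_phenotype(background: GenotypeMatrix,
                       scenario: SimulationScenario,
                       seed=None) -> SimulatedDataset:
    """Draw causal genotypes, append them, and generate the phenotype.

    y = sum_j beta_j c_j + sum_jk beta_jk c_j c_k + e with centered causal
    dosages c and e ~ Normal(0, 1 - sum h2).
    """
    rng = np.random.default_rng(seed)
    n = background.n_subjects
    q = len(scenario.causal_snps)
    beta_main, beta_int = calibrate_effects(scenario)
    causal = np.empty((n, q))
    centered = np.empty((n, q))
    for j, snp in enumerate(scenario.causal_snps):
        gj = rng.binomial(2, snp.maf, size=n).astype(np.float64)
        causal[:, j] = gj
        centered[:, j] = gj - 2.0 * snp.maf
    y = centered @ beta_main
    for i, (j, k, _) in enumerate(scenario.interaction_pairs):
        y = y + beta_int[i] * centered[:, j] * centered[:, k]
    resid_sd = np.sqrt(1.0 - scenario.total_h2)
    y = y + rng.normal(0.0, resid_sd, size=n)

    pos0 = background.pos[background.chrom == "1"]
    next_pos = (pos0.max() if pos0.size else 0) + 1
    ids = [f"causal{j + 1}" for j in range(q)]
    g = GenotypeMatrix(
        np.concatenate([background.dosages, causal], axis=1),
        np.concatenate([background.snp_ids, ids]),
        np.concatenate([background.chrom, np.array(["1"] * q, dtype=object)]),
        np.concatenate([background.pos, np.arange(next_pos, next_pos + q)]),
        sample_ids=background.sample_ids)
    return SimulatedDataset(genotypes=g,
                            phenotype=Phenotype(y, ids=background.sample_ids),
                            causal_indices=np.arange(background.n_snps,
                                                     background.n_snps + q),
                            causal_ids=np.asarray(ids, dtype=object),
                            beta_main=beta_main, beta_interaction=beta_int,
                            scenario=scenario)


def simulate_dataset(scenario: SimulationScenario, seed=None
                     ) -> SimulatedDataset:
    """Background + causal SNPs + phenotype from one master seed.

    The master seed spawns independent streams for the background panel and
    for the causal/noise draw, so the same seed reproduces the dataset
    bit-for-bit.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    s_bg, s_ph = ss.spawn(2)
    bg = simulate_background(scenario.n_subjects, scenario.n_background,
                             scenario.background_maf_range, seed=s_bg)
    return simulate_phenotype(bg, scenario, seed=s_ph)
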