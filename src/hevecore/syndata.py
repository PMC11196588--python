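"""Synthetic genotype panels with two-level population structure.

The generator emulates the statistical shape of a germplasm SNP panel:
a small number of diverged subpopulations, optional admixture, sparse
missing genotypes and the occasional sample that fails entirely.
Divergence follows the Balding–Nichols model: given an ancestral allele
frequency ``p`` and a divergence parameter ``F`` (an FST), each
subpopulation's frequency is drawn from

    Beta(p (1 - F) / F, (1 - p) (1 - F) / F),

whose mean is ``p`` and variance ``F p (1 - p)``.  Each individual's
genotype at a locus is Binomial(2, sum_k q_ik p_lk) with ``q_i`` its
ancestry proportions.  Missingness is MCAR.

Defaults mirror a panel of 195 accessions split 169/26 genotyped at 99
biallelic SNPs with mild divergence and ~3% missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import LOCUS_COLUMNS, MISSING, GenotypePanel


@dataclass
class SimulationConfig:
    """Parameters of a synthetic genotype panel.

    Attributes
    ----------
    n_samples_per_pop : tuple of int
        Samples in each subpopulation (default 169 and 26).
    n_loci : int
        Number of biallelic SNP loci.
    fst : float
        Balding–Nichols divergence in [0, 1); 0 means no structure.
    maf_floor : float
        Minimum ancestral minor-allele frequency; ancestral frequencies are
        uniform on [maf_floor, 1 - maf_floor].
    admixture_alpha : float
        Symmetric Dirichlet concentration for individual ancestry rows;
        0 disables admixture (each sample is purely its subpopulation).
    missing_rate : float
        Per-genotype MCAR missingness probability.
    n_fully_missing_samples : int
        Samples whose every genotype is set missing (assay failures).
    depth_mean : float or None
        If set, per-genotype depths are Poisson with this mean.
    seed : int
        Seed for all randomness; runs are bit-reproducible given it.
    chrom_length : int
        Length in bp of the single synthetic chromosome.
    """

    n_samples_per_pop: tuple[int, ...] = (169, 26)
    n_loci: int = 99
    fst: float = 0.05
    maf_floor: float = 0.05
    admixture_alpha: float = 0.0
    missing_rate: float = 0.03
    n_fully_missing_samples: int = 0
    depth_mean: float | None = None
    seed: int = 0
    chrom_length: int = 200_000_000

    def __post_init__(self) -> None:
        self.n_samples_per_pop = tuple(int(n) for n in self.n_samples_per_pop)
        if any(n <= 0 for n in self.n_samples_per_pop):
            raise ValueError("subpopulation sizes must be positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if not 0 < self.maf_floor <= 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5]")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_fully_missing_samples < 0:
            raise ValueError("n_fully_missing_samples must be >= 0")
        if self.n_fully_missing_samples >= sum(self.n_samples_per_pop):
            raise ValueError("cannot blank every sample")
        if self.n_loci > self.chrom_length:
            raise ValueError("chrom_length too short for n_loci distinct positions")


@dataclass
class GroundTruth:
    """What the simulator actually drew, for recovery tests.

    ``q_true`` rows sum to one; ``p_pop`` is loci x K.
    """

    pop_labels: np.ndarray
    q_true: np.ndarray
    p_anc: np.ndarray
    p_pop: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, GroundTruth]:
    """Draw a genotype panel and its generating parameters."""
    rng = np.random.default_rng(config.seed)
    k = len(config.n_samples_per_pop)
    n = sum(config.n_samples_per_pop)
    m = config.n_loci

    p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)
    if config.fst == 0.0:
        p_pop = np.tile(p_anc[:, None], (1, k))
    else:
        scale = (1.0 - config.fst) / config.fst
        p_pop = rng.beta(p_anc[:, None] * scale, (1.0 - p_anc[:, None]) * scale,
                         size=(m, k))

    pop_labels = np.repeat(np.arange(k), config.n_samples_per_pop)
    if config.admixture_alpha > 0:
        q_true = rng.dirichlet(np.full(k, config.admixture_alpha), size=n)
    else:
        q_true = np.zeros((n, k))
        q_true[np.arange(n), pop_labels] = 1.0

    freq = q_true @ p_pop.T  # samples x loci expected allele frequency
    G = rng.binomial(2, freq).astype(np.int8)

    if config.missing_rate > 0:
        G[rng.random(G.shape) < config.missing_rate] = MISSING
    blanked = np.array([], dtype=int)
    if config.n_fully_missing_samples > 0:
        blanked = rng.choice(n, size=config.n_fully_missing_samples, replace=False)
        G[blanked] = MISSING

    positions = _distinct_sorted_positions(rng, m, config.chrom_length)
    ref, alt = _ref_alt_bases(rng, m)
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions,
            "id": [f"snp{j + 1}" for j in range(m)],
            "ref": ref,
            "alt": alt,
        },
        columns=LOCUS_COLUMNS,
    )
    sample_ids = [f"S{i + 1}" for i in range(n)]
    DP = None
    if config.depth_mean is not None:
        DP = rng.poisson(config.depth_mean, size=G.shape).astype(np.int32)
    panel = GenotypePanel(sample_ids, loci, G, DP)
    truth = GroundTruth(pop_labels, q_true, p_anc, p_pop, sample_ids)
    return panel, truth


def _distinct_sorted_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    pos: set[int] = set()
    while len(pos) < m:
        draw = rng.integers(1, length + 1, size=2 * (m - len(pos)))
        pos.update(int(x) for x in draw)
    return np.sort(np.array(list(pos), dtype=np.int64))[:m]


def _ref_alt_bases(rng: np.random.Generator, m: int) -> tuple[list[str], list[str]]:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_off = rng.integers(1, 4, size=m)
    alt_idx = (ref_idx + alt_off) % 4
    return bases[ref_idx].tolist(), bases[alt_idx].tolist()


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as tab-separated tables under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n, k = truth.q_true.shape
    ids = truth.sample_ids or [f"S{i + 1}" for i in range(n)]
    samples = pd.DataFrame({"sample": ids, "pop": truth.pop_labels})
    for j in range(k):
        samples[f"q{j}"] = truth.q_true[:, j]
    samples.to_csv(path / "samples.tsv", sep="\t", index=False, float_format="%.17g")
    freqs = pd.DataFrame({"p_anc": truth.p_anc})
    for j in range(k):
        freqs[f"p_pop{j}"] = truth.p_pop[:, j]
    freqs.to_csv(path / "frequencies.tsv", sep="\t", index=False, float_format="%.17g")


def read_truth(path: str | Path) -> GroundTruth:
    """Inverse of :func:`write_truth`."""
    path = Path(path)
    samples = pd.read_csv(path / "samples.tsv", sep="\t")
    freqs = pd.read_csv(path / "frequencies.tsv", sep="\t")
    qcols = [c for c in samples.columns if c.startswith("q")]
    pcols = [c for c in freqs.columns if c.startswith("p_pop")]
    return GroundTruth(
        pop_labels=samples["pop"].to_numpy(),
        q_true=samples[qcols].to_numpy(),
        p_anc=freqs["p_anc"].to_numpy(),
        p_pop=freqs[pcols].to_numpy(),
        sample_ids=samples["sample"].astype(str).tolist(),
    )
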