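"""Synthetic F2-family pool datasets: pool frequencies, phenotypes, read counts.

The generative chain mirrors a pooled genotyping-by-sequencing experiment:

1. each family's true pool allele frequency is k/4 with allele dose
   k ~ Binomial(4, p);
2. the family phenotype is P = mu + b * g_true + e with Gaussian
   environmental noise e;
3. sequencing depth per family is constant or Poisson, and the reads
   supporting the counted allele are Binomial(depth, g'), where g' folds an
   optional symmetric per-read error rate into the success probability;
4. optionally the observed frequency is "called" to the nearest quarter,
   mimicking a hard tetraploid genotype call.

All draws come from a :class:`numpy.random.Generator`; passing an integer
seeds a fresh generator, so every function is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .popgen import TwoLocusModel, _check_freq

__all__ = [
    "DepthModel",
    "ErrorModel",
    "ReadCounts",
    "simulate_pools",
    "simulate_phenotypes",
    "simulate_read_counts",
    "call_genotype",
    "simulate_two_locus_pools",
    "simulate_dataset",
    "write_dataset",
    "DATASET_COLUMNS",
]

#: Required columns of the TSV dataset format (two-locus files add s1_B, s2_B).
DATASET_COLUMNS = ["family_id", "s1", "s2", "depth", "phenotype"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DepthModel:
    """Per-family total sequencing depth: fixed, or Poisson with mean `value`.

    Poisson draws of zero are kept as missing families (no redraw); the
    association step drops them and reports how many were lost.
    """

    kind: str = "constant"
    value: float = 7.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "poisson"):
            raise ValueError(f"kind must be 'constant' or 'poisson', got {self.kind!r}")
        if self.value <= 0:
            raise ValueError(f"depth value must be > 0, got {self.value}")

    @property
    def mean_depth(self) -> float:
        return float(self.value)

    def draw(self, n: int, rng) -> np.ndarray:
        rng = _as_rng(rng)
        if self.kind == "constant":
            return np.full(n, int(round(self.value)), dtype=np.int64)
        return rng.poisson(self.value, size=n)

    def missing_prob(self) -> float:
        """Probability a family yields zero reads (e^-lambda under Poisson)."""
        if self.kind == "constant":
            return 0.0
        return float(np.exp(-self.value))


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing noise beyond binomial sampling.

    per_read_error: probability a read reports the wrong allele
    (symmetric flips, so the binomial success probability becomes
    g(1-eps) + (1-g)eps).  call_genotypes: round observed frequencies to
    the nearest quarter before analysis.
    """

    per_read_error: float = 0.0
    call_genotypes: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_read_error < 0.5:
            raise ValueError(
                f"per_read_error must lie in [0, 0.5), got {self.per_read_error}"
            )


@dataclass
class ReadCounts:
    """Per-family allele read counts for one locus (column-wise arrays).

    ``g_obs`` is S1/S_T, with NaN where the family received zero reads.
    """

    s1: np.ndarray
    s2: np.ndarray
    family_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=np.int64)
        self.s2 = np.asarray(self.s2, dtype=np.int64)
        if np.any(self.s1 < 0) or np.any(self.s2 < 0):
            raise ValueError("read counts must be nonnegative")
        if self.family_id is None:
            self.family_id = np.arange(len(self.s1))

    def __len__(self) -> int:
        return len(self.s1)

    @property
    def depth(self) -> np.ndarray:
        return self.s1 + self.s2

    @property
    def g_obs(self) -> np.ndarray:
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(depth > 0, self.s1 / np.maximum(depth, 1), np.nan)
        return g

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.depth == 0))


def simulate_pools(n: int, p: float, seed=None) -> np.ndarray:
    """Draw n true pool allele frequencies, i.i.d. on {0, 1/4, 1/2, 3/4, 1}.

    The allele dose per family is Binomial(4, p): four parental allele
    copies sampled from a Hardy-Weinberg population.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _check_freq(p)
    rng = _as_rng(seed)
    return rng.binomial(4, p, size=n) / 4.0


def simulate_phenotypes(g_true: np.ndarray, model, seed=None) -> np.ndarray:
    """Family phenotypes P = mu + b * g_true + Normal(0, sigma_e^2)."""
    rng = _as_rng(seed)
    g = np.asarray(g_true, dtype=float)
    return model.mu + model.b * g + rng.normal(0.0, model.sigma_e, size=g.shape)


def simulate_read_counts(
    g_true: np.ndarray,
    depth_model: DepthModel = DepthModel(),
    error_model: ErrorModel = ErrorModel(),
    seed=None,
) -> ReadCounts:
    """Sequence each pool: depth per the depth model, reads by binomial sampling.

    With per-read error eps, a read reports the counted allele with
    probability g' = g(1-eps) + (1-g)eps — distributionally identical to
    flipping each read independently, without materializing reads.
    """
    rng = _as_rng(seed)
    g = np.asarray(g_true, dtype=float)
    depth = depth_model.draw(g.size, rng)
    eps = error_model.per_read_error
    g_eff = g * (1.0 - eps) + (1.0 - g) * eps
    s1 = rng.binomial(depth, g_eff)
    return ReadCounts(s1=s1, s2=depth - s1)


def call_genotype(g_obs) -> np.ndarray | float:
    """Force observed frequencies to the nearest quarter.

    Midpoints (0.125, 0.375, 0.625, 0.875) round up; NaN (missing) passes
    through.  Accepts scalars or arrays.
    """
    g = np.asarray(g_obs, dtype=float)
    finite = g[~np.isnan(g)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("observed frequencies must lie in [0, 1]")
    called = np.floor(g * 4.0 + 0.5) / 4.0
    called = np.where(np.isnan(g), np.nan, np.clip(called, 0.0, 1.0))
    if np.isscalar(g_obs) or np.ndim(g_obs) == 0:
        return float(called)
    return called


def simulate_two_locus_pools(
    n: int, model: TwoLocusModel, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Pool frequencies (g_A, g_B) at a causal and a linked marker locus.

    Each family receives four haplotypes drawn i.i.d. from the model's
    haplotype frequencies; the pool frequency at each locus is the count of
    allele-1 haplotypes over four.  The haplotype-level LD correlation r
    propagates unchanged to the pool frequencies.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    counts = rng.multinomial(4, model.haplotype_probs, size=n)
    g_a = (counts[:, 0] + counts[:, 1]) / 4.0
    g_b = (counts[:, 0] + counts[:, 2]) / 4.0
    return g_a, g_b


def simulate_dataset(
    n: int,
    model,
    depth_model: DepthModel = DepthModel(),
    error_model: ErrorModel = ErrorModel(),
    seed=None,
    ld_r: float | None = None,
    marker_depth_model: DepthModel | None = None,
) -> pd.DataFrame:
    """One complete synthetic experiment as a tidy table.

    One row per family: read counts, depth, phenotype.  In two-locus mode
    (``ld_r`` given) the phenotype is driven by the causal locus while the
    extra columns ``s1_B``/``s2_B`` hold marker-locus counts sequenced at
    ``marker_depth_model`` (defaults to ``depth_model``).
    """
    from .popgen import haplotype_frequencies

    rng = _as_rng(seed)
    if ld_r is None:
        g_true = simulate_pools(n, model.p, rng)
        phenotypes = simulate_phenotypes(g_true, model, rng)
        reads = simulate_read_counts(g_true, depth_model, error_model, rng)
        frame = pd.DataFrame(
            {
                "family_id": [f"F{i:05d}" for i in range(n)],
                "s1": reads.s1,
                "s2": reads.s2,
                "depth": reads.depth,
                "phenotype": phenotypes,
            }
        )
        return frame

    two = haplotype_frequencies(model.p, model.p, ld_r)
    g_a, g_b = simulate_two_locus_pools(n, two, rng)
    phenotypes = simulate_phenotypes(g_a, model, rng)
    reads_a = simulate_read_counts(g_a, depth_model, error_model, rng)
    marker_dm = marker_depth_model if marker_depth_model is not None else depth_model
    reads_b = simulate_read_counts(g_b, marker_dm, error_model, rng)
    return pd.DataFrame(
        {
            "family_id": [f"F{i:05d}" for i in range(n)],
            "s1": reads_a.s1,
            "s2": reads_a.s2,
            "depth": reads_a.depth,
            "phenotype": phenotypes,
            "s1_B": reads_b.s1,
            "s2_B": reads_b.s2,
        }
    )


def write_dataset(frame: pd.DataFrame, path) -> None:
    """Write the TSV dataset format (UTF-8, tab-separated, header row).

    Round-trips losslessly with :func:`poolassoc.io.read_dataset`; families
    with zero depth keep counts 0/0 and are flagged missing by the reader.
    """
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees a lossless float round-trip through text
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
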