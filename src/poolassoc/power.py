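"""Monte-Carlo power and effect-recovery studies over pooled-sequencing designs.

A design point fixes sample size, depth model, allele frequency,
environmental SD, true effect, optional marker-locus LD, error model and
significance level.  Each replicate simulates a full experiment — pool
frequencies, phenotypes, read counts, optional genotype calling — and runs
the phenotype-on-frequency regression; power is the fraction of replicates
whose slope t-test falls below alpha.

Replicate ``i`` of design ``j`` draws from the dedicated substream
``SeedSequence((master_seed, j, i))``: runs are deterministic given the
master seed, designs can share random numbers by sharing ``j``, and
replicates are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .association import correct_attenuation, fit_regression
from .popgen import LocusModel, haplotype_frequencies
from .simulate import (
    DepthModel,
    ErrorModel,
    call_genotype,
    simulate_phenotypes,
    simulate_pools,
    simulate_read_counts,
    simulate_two_locus_pools,
)

__all__ = [
    "DesignPoint",
    "PowerStudyResult",
    "EffectStudyResult",
    "run_power",
    "run_two_locus_power",
    "run_effect_study",
    "fixed_budget_grid",
    "error_stacking_study",
    "budget_grid_designs",
    "ld_grid_designs",
    "attenuation_grid_designs",
    "power_table",
    "BUDGET_PAIRS",
]

#: (n_families, depth) pairs spending an almost equal number of reads
#: (12,000-15,000 read-families): large-n/shallow through small-n/deep.
BUDGET_PAIRS = [(4000, 3), (2000, 7), (1000, 15), (500, 30)]


@dataclass(frozen=True)
class DesignPoint:
    """One experimental design for a pooled-sequencing association study."""

    n_families: int
    depth_model: DepthModel
    p: float
    sigma_e: float
    b: float = 1.0
    mu: float = 0.0
    ld_r: float | None = None
    marker_depth_model: DepthModel | None = None
    error_model: ErrorModel = field(default_factory=ErrorModel)
    alpha: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_families < 3:
            raise ValueError("need at least 3 families")

    @property
    def effort(self) -> float:
        """Sequencing budget proxy: families x mean depth (read-families)."""
        return self.n_families * self.depth_model.mean_depth

    @property
    def locus_model(self) -> LocusModel:
        return LocusModel(p=self.p, b=self.b, mu=self.mu, sigma_e=self.sigma_e)


@dataclass(frozen=True)
class PowerStudyResult:
    """Estimated power at one design, with its Monte-Carlo standard error."""

    design: DesignPoint
    n_reps: int
    n_significant: int
    power: float
    mc_se: float
    seed: int

    def __str__(self) -> str:
        return (
            f"power={self.power:.3f} (MC SE {self.mc_se:.3f}, "
            f"{self.n_significant}/{self.n_reps} significant)"
        )


@dataclass(frozen=True)
class EffectStudyResult:
    """Replicate distribution of raw and attenuation-corrected slopes."""

    design: DesignPoint
    n_reps: int
    mean_b_hat: float
    sd_b_hat: float
    mean_b_corrected: float
    sd_b_corrected: float
    expected_attenuation: float
    seed: int


def _rep_rng(seed: int, design_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(design_index), int(rep)))
    )


def _one_replicate(design: DesignPoint, rng) -> tuple:
    """Simulate one experiment; return (fit result, per-family depths)."""
    model = design.locus_model
    if design.ld_r is None:
        g_true = simulate_pools(design.n_families, design.p, rng)
        phen = simulate_phenotypes(g_true, model, rng)
        reads = simulate_read_counts(
            g_true, design.depth_model, design.error_model, rng
        )
    else:
        two = haplotype_frequencies(design.p, design.p, design.ld_r)
        g_a, g_b = simulate_two_locus_pools(design.n_families, two, rng)
        phen = simulate_phenotypes(g_a, model, rng)
        marker_dm = design.marker_depth_model or design.depth_model
        reads = simulate_read_counts(g_b, marker_dm, design.error_model, rng)
    g_obs = reads.g_obs
    if design.error_model.call_genotypes:
        g_obs = call_genotype(g_obs)
    return fit_regression(phen, g_obs), reads.depth


def run_power(
    design: DesignPoint, n_reps: int = 1000, seed: int = 0, design_index: int = 0
) -> PowerStudyResult:
    """Estimate power at one design from ``n_reps`` simulated experiments."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_sig = 0
    for i in range(n_reps):
        rng = _rep_rng(seed, design_index, i)
        fit, _ = _one_replicate(design, rng)
        if fit.p_value < design.alpha:
            n_sig += 1
    power = n_sig / n_reps
    mc_se = float(np.sqrt(power * (1.0 - power) / n_reps))
    return PowerStudyResult(design, n_reps, n_sig, power, mc_se, seed)


def run_two_locus_power(
    design: DesignPoint, n_reps: int = 1000, seed: int = 0, design_index: int = 0
) -> PowerStudyResult:
    """Power when regressing on a marker in LD with the causal locus.

    The design must carry ``ld_r``; the phenotype is generated from the
    causal locus while the regression sees the marker locus sequenced at
    ``marker_depth_model``.  With ``ld_r`` unset, :func:`run_power` analyses
    the causal locus itself.
    """
    if design.ld_r is None:
        raise ValueError("design must set ld_r for a two-locus power study")
    return run_power(design, n_reps=n_reps, seed=seed, design_index=design_index)


def run_effect_study(
    design: DesignPoint, n_reps: int = 1000, seed: int = 0, design_index: int = 0
) -> EffectStudyResult:
    """Replicate the slope estimator to measure attenuation and its correction.

    Returns the replicate mean and SD of the raw slope (expected near
    b / (1 + 3/S_T)) and of the corrected slope (expected near b).
    """
    b_hat = np.empty(n_reps)
    b_corr = np.empty(n_reps)
    for i in range(n_reps):
        rng = _rep_rng(seed, design_index, i)
        fit, depths = _one_replicate(design, rng)
        fit = correct_attenuation(fit, depths)
        b_hat[i] = fit.b_hat
        b_corr[i] = fit.b_corrected
    from .popgen import attenuation_factor

    expected = attenuation_factor(design.depth_model.mean_depth) * design.b
    return EffectStudyResult(
        design=design,
        n_reps=n_reps,
        mean_b_hat=float(b_hat.mean()),
        sd_b_hat=float(b_hat.std(ddof=1)),
        mean_b_corrected=float(b_corr.mean()),
        sd_b_corrected=float(b_corr.std(ddof=1)),
        expected_attenuation=expected,
        seed=seed,
    )


def fixed_budget_grid(
    total_effort: float,
    designs: Sequence[DesignPoint],
    n_reps: int = 1000,
    seed: int = 0,
    effort_tolerance: float = 0.25,
) -> list[PowerStudyResult]:
    """Power across designs spending (almost) the same number of reads.

    Every design's effort (families x mean depth) must lie within
    ``effort_tolerance`` of ``total_effort``; results are ordered by effort,
    then sample size, so the large-n/shallow end comes first.
    """
    if not designs:
        raise ValueError("empty design grid")
    for d in designs:
        if abs(d.effort - total_effort) > effort_tolerance * total_effort:
            raise ValueError(
                f"design effort {d.effort:g} outside +/-{effort_tolerance:.0%} "
                f"of budget {total_effort:g} (n={d.n_families}, "
                f"depth={d.depth_model.mean_depth:g})"
            )
    ordered = sorted(
        enumerate(designs), key=lambda t: (t[1].effort, t[1].n_families)
    )
    return [
        run_power(d, n_reps=n_reps, seed=seed, design_index=j)
        for j, d in ordered
    ]


def error_stacking_study(
    designs: Sequence[DesignPoint], n_reps: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Power under successively richer noise models, Poisson depth throughout.

    Three layers per design: (i) binomial read sampling only, (ii) plus a
    10 % per-read sequencing error, (iii) plus hard genotype calling to
    quarters.  Returns a long-format table, one row per (design, layer).
    """
    layers = [
        ("binomial", ErrorModel()),
        ("binomial+read_error", ErrorModel(per_read_error=0.10)),
        (
            "binomial+read_error+calling",
            ErrorModel(per_read_error=0.10, call_genotypes=True),
        ),
    ]
    rows = []
    for j, base in enumerate(designs):
        depth_model = DepthModel("poisson", base.depth_model.mean_depth)
        for layer_name, err in layers:
            design = replace(
                base, depth_model=depth_model, error_model=err,
                label=base.label or f"design{j}",
            )
            res = run_power(design, n_reps=n_reps, seed=seed, design_index=j)
            rows.append(_result_row(res) | {"error_layer": layer_name})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Preset design grids


def budget_grid_designs(
    p: float, sigma_e: float = 4.0, b: float = 1.0, alpha: float = 0.05,
    poisson_depth: bool = False,
) -> list[DesignPoint]:
    """The standard fixed-budget grid: (4000, 3), (2000, 7), (1000, 15), (500, 30)."""
    kind = "poisson" if poisson_depth else "constant"
    return [
        DesignPoint(
            n_families=n,
            depth_model=DepthModel(kind, depth),
            p=p,
            sigma_e=sigma_e,
            b=b,
            alpha=alpha,
            label=f"n{n}_d{depth}",
        )
        for n, depth in BUDGET_PAIRS
    ]


def ld_grid_designs(
    n_families: int = 2000,
    b: float = 1.0,
    alpha: float = 0.05,
    sigma_e_levels: Sequence[float] = (2.0, 4.0),
    p_levels: Sequence[float] = (0.1, 0.3, 0.5),
    ld_depth_pairs: Sequence[tuple[float, int]] = ((0.95, 7), (0.7, 15), (0.3, 30)),
    causal_depth: int = 7,
) -> list[DesignPoint]:
    """Marker-density grid: stronger LD with shallower depth at fixed budget.

    Halving SNP density (weaker LD: r = 0.95, 0.7, 0.3) buys a doubling of
    marker depth (7, 15, 30).  A causal-locus design (no LD, sequenced at
    ``causal_depth``) is appended per (sigma_e, p) cell as the ceiling.
    """
    designs = []
    for sigma_e in sigma_e_levels:
        for p in p_levels:
            for r, depth in ld_depth_pairs:
                designs.append(
                    DesignPoint(
                        n_families=n_families,
                        depth_model=DepthModel("constant", depth),
                        marker_depth_model=DepthModel("constant", depth),
                        p=p,
                        sigma_e=sigma_e,
                        b=b,
                        ld_r=r,
                        alpha=alpha,
                        label=f"sd{sigma_e:g}_p{p:g}_r{r:g}_d{depth}",
                    )
                )
            designs.append(
                DesignPoint(
                    n_families=n_families,
                    depth_model=DepthModel("constant", causal_depth),
                    p=p,
                    sigma_e=sigma_e,
                    b=b,
                    alpha=alpha,
                    label=f"sd{sigma_e:g}_p{p:g}_causal_d{causal_depth}",
                )
            )
    return designs


def attenuation_grid_designs(
    n_families: int = 4000,
    sigma_e: float = 4.0,
    b: float = 1.0,
    p_levels: Sequence[float] = (0.1, 0.3, 0.5),
    depths: Sequence[int] = (3, 7, 15, 30),
) -> list[DesignPoint]:
    """Grid for the attenuation study: slope bias across depth x frequency."""
    return [
        DesignPoint(
            n_families=n_families,
            depth_model=DepthModel("constant", depth),
            p=p,
            sigma_e=sigma_e,
            b=b,
            label=f"p{p:g}_d{depth}",
        )
        for p in p_levels
        for depth in depths
    ]


def _result_row(res: PowerStudyResult) -> dict:
    d = res.design
    return {
        "label": d.label,
        "n_families": d.n_families,
        "depth_kind": d.depth_model.kind,
        "mean_depth": d.depth_model.mean_depth,
        "p": d.p,
        "sigma_e": d.sigma_e,
        "b": d.b,
        "ld_r": d.ld_r if d.ld_r is not None else np.nan,
        "per_read_error": d.error_model.per_read_error,
        "call_genotypes": d.error_model.call_genotypes,
        "alpha": d.alpha,
        "effort": d.effort,
        "n_reps": res.n_reps,
        "n_significant": res.n_significant,
        "power": res.power,
        "mc_se": res.mc_se,
        "seed": res.seed,
    }


def power_table(results: Sequence[PowerStudyResult]) -> pd.DataFrame:
    """Long-format table of power results, one row per design."""
    return pd.DataFrame([_result_row(r) for r in results])
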