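"""Synthetic doubled-haploid populations, multi-environment trials, and
GBS-style missingness.

The generator emulates a single biparental cross of a self-pollinating
cereal: the two inbred parents are fixed for alternate alleles at every
marker, so the F1 is heterozygous everywhere and each DH line is a doubled
F1 gamete — fully homozygous, with every marker segregating at expected
frequency 0.5.  Crossovers follow the Haldane (no-interference) model, whose
closed-form recombination fraction r = 0.5 (1 - exp(-2 d / 100)) for two
loci d centimorgans apart makes the recombination machinery directly
testable.

Trials span two years with distinct yield means, a line-by-year interaction
(G-by-E), plot residuals with replication, a heading-date covariate
correlated with genetic merit, and year-2 rust severity/incidence scores
correlated with the non-genetic part of yield.  Missingness mimics
genotyping-by-sequencing: per-marker call rates are drawn from a Beta
distribution (heavy-tailed, as GBS coverage profiles are), and calls are
dropped independently within a marker.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix

__all__ = [
    "SimConfig",
    "DHPopulation",
    "simulate_dh_genotypes",
    "assign_genetic_architecture",
    "simulate_trials",
    "mask_genotypes",
    "simulate_population",
    "gxe_sd_for_between_year_correlation",
    "haldane_recombination_fraction",
]

#: default two-year grain-yield means (kg/ha) of the emulated trials
DEFAULT_YEAR_MEANS = (1579.73, 2228.03)
#: default two-year heading-date means (days)
DEFAULT_HD_MEANS = (170.37, 161.81)
#: default target correlation between the two years' line means
DEFAULT_BETWEEN_YEAR_RHO = 0.417


def haldane_recombination_fraction(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction between loci ``d_cM`` centimorgans apart."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


def gxe_sd_for_between_year_correlation(
    rho: float, h2: float, resid_sd: float, n_reps: int
) -> float:
    """Line-by-year interaction SD giving a target between-year correlation.

    With purely additive genetics scaled to heritability
    ``h2 = var_g / (var_g + resid_sd^2 / n_reps)`` (G-by-E excluded from the
    heritability denominator), the correlation between the two years' line
    means is ``rho = var_g / (var_g + gxe_sd^2 + resid_sd^2 / n_reps)``;
    solving for ``gxe_sd`` gives the closed form used here.
    """
    if not 0 < rho < 1 or not 0 < h2 < 1:
        raise ValueError("rho and h2 must lie in (0, 1)")
    noise = resid_sd**2 / n_reps
    var_g = h2 * noise / (1.0 - h2)
    gxe_var = var_g * (1.0 / rho - 1.0) - noise
    if gxe_var < 0:
        raise ValueError(
            f"target correlation {rho} unreachable: it exceeds the heritability "
            f"ceiling {var_g / (var_g + noise):.3f}"
        )
    return float(np.sqrt(gxe_var))


@dataclass
class SimConfig:
    """Study conditions for one synthetic DH population.

    Defaults emulate a ~257-line winter-wheat DH panel: two trial years with
    means 1579.73 and 2228.03 kg/ha, two replicates per line-year, mean SNP
    call rate 0.6, heritability 0.5 on a line-mean basis, and a line-by-year
    interaction tuned (closed form) so the between-year correlation of line
    means is about 0.417.
    """

    n_lines: int = 257
    chromosomes: tuple[float, ...] = tuple([150.0] * 21)  # map lengths, cM
    markers_per_chromosome: int = 270
    # optional explicit marker positions (cM) per chromosome; None = even spacing
    marker_positions: tuple[tuple[float, ...], ...] | None = None
    n_qtl: int = 300  # yield treated as polygenic
    epistasis_fraction: float = 0.0
    h2: float = 0.5  # var_g / (var_g + resid_sd^2 / n_reps), per year
    year_means: tuple[float, ...] = DEFAULT_YEAR_MEANS
    gxe_sd: float | None = None  # None -> tuned for between_year_rho
    between_year_rho: float = DEFAULT_BETWEEN_YEAR_RHO
    resid_sd: float = 250.0  # plot residual SD, kg/ha
    n_reps: int = 2
    call_rate_mean: float = 0.6
    call_rate_spread: float = 0.15  # SD of the Beta call-rate distribution
    hd_year_means: tuple[float, ...] = DEFAULT_HD_MEANS
    hd_genetic_cor: float = 0.3  # correlation of heading date with genetic value
    hd_sd: float = 2.0  # days
    rust_cor: float = 0.5  # |cor| of rust with the non-genetic yield deviation
    gxe_mode: str = "genetic"  # "genetic" (QTL-by-year effects) | "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 <= self.epistasis_fraction < 1.0:
            raise ValueError("epistasis_fraction must lie in [0, 1)")
        if self.resid_sd < 0 or (self.gxe_sd is not None and self.gxe_sd < 0):
            raise ValueError("standard deviations must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 <= self.call_rate_mean <= 1.0) or self.call_rate_spread < 0:
            raise ValueError("call-rate parameters must lie in [0, 1]")
        if self.gxe_mode not in ("genetic", "iid"):
            raise ValueError(f"unknown gxe_mode {self.gxe_mode!r}")
        if len(self.year_means) < 1:
            raise ValueError("at least one trial year required")

    @property
    def n_years(self) -> int:
        return len(self.year_means)

    def resolved_gxe_sd(self) -> float:
        if self.gxe_sd is not None:
            return self.gxe_sd
        return gxe_sd_for_between_year_correlation(
            self.between_year_rho, self.h2, self.resid_sd, self.n_reps
        )

    def rng(self, stage: str) -> np.random.Generator:
        """Independent per-stage stream derived from the single global seed."""
        tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF  # stable across processes
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class DHPopulation:
    """A simulated DH panel: genotypes, genetic map, and trait architecture."""

    genotypes: MarkerMatrix
    genetic_map: pd.DataFrame  # columns: marker, chromosome, cM
    qtl_effects: pd.DataFrame | None = None  # additive + epistatic terms
    qtl_indices: np.ndarray | None = None  # column indices of causal markers
    true_genetic_values: np.ndarray | None = None  # (n_lines,) total genetic value
    true_additive_values: np.ndarray | None = None


def simulate_dh_genotypes(config: SimConfig) -> DHPopulation:
    """Simulate DH genotypes as doubled F1 gametes under Haldane crossovers.

    Markers are evenly spaced along each chromosome.  Every genotype code is
    -1 or +1 (fully homozygous), and each marker segregates at expected
    frequency 0.5 because the parents carry alternate alleles throughout.
    """
    rng = config.rng("genotypes")
    n = config.n_lines
    cols: list[np.ndarray] = []
    marker_ids: list[str] = []
    map_rows: list[tuple[str, int, float]] = []
    for c, length in enumerate(config.chromosomes, start=1):
        if config.marker_positions is not None:
            pos = np.asarray(config.marker_positions[c - 1], dtype=float)
            m = pos.size
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"chromosome {c}: marker positions must be sorted")
        else:
            m = config.markers_per_chromosome
            if m > 1 and length <= 0:
                raise ValueError(
                    f"chromosome {c}: non-positive map length with {m} markers"
                )
            pos = np.linspace(0.0, length, m) if m > 1 else np.array([0.0])
        # doubled gamete: start allele +-1, switch between adjacent markers
        # with the Haldane recombination fraction for their map distance
        r = haldane_recombination_fraction(np.diff(pos))
        start = rng.choice([-1.0, 1.0], size=n)
        switches = rng.random((n, m - 1)) < r  # (n, m-1)
        flips = np.cumsum(switches, axis=1) % 2
        chrom = np.column_stack([start, start[:, None] * np.where(flips, -1.0, 1.0)])
        cols.append(chrom)
        for k in range(m):
            marker_ids.append(f"c{c}m{k + 1}")
            map_rows.append((f"c{c}m{k + 1}", c, float(pos[k])))
    values = np.concatenate(cols, axis=1)
    line_ids = [f"DH{i + 1:04d}" for i in range(n)]
    gmap = pd.DataFrame(map_rows, columns=["marker", "chromosome", "cM"])
    return DHPopulation(MarkerMatrix(line_ids, marker_ids, values), gmap)


def assign_genetic_architecture(pop: DHPopulation, config: SimConfig) -> DHPopulation:
    """Sample QTL, additive and epistatic effects, and scale genetic values.

    ``n_qtl`` markers become causal with standard-normal additive effects;
    ``epistasis_fraction`` of the genetic variance is carried by products of
    random QTL pairs.  The two components are rescaled empirically so the
    realized additive variance satisfies the heritability target
    ``h2 = var_add / (var_g + resid_sd^2 / n_reps)``.
    """
    rng = config.rng("architecture")
    V = pop.genotypes.values
    n, m = V.shape
    if config.n_qtl > m:
        raise ValueError(f"n_qtl={config.n_qtl} exceeds marker count {m}")
    if config.n_qtl == 0:
        zero = np.zeros(n)
        return replace(
            pop,
            qtl_effects=pd.DataFrame(columns=["term", "effect"]),
            qtl_indices=np.array([], dtype=int),
            true_genetic_values=zero,
            true_additive_values=zero.copy(),
        )
    f = config.epistasis_fraction
    if config.h2 >= 1.0 - f:
        raise ValueError(
            f"h2={config.h2} unreachable with epistasis_fraction={f}: "
            f"additive variance cannot exceed (1 - f) of genetic variance"
        )
    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    add_eff = rng.standard_normal(config.n_qtl)
    additive = V[:, qtl] @ add_eff
    additive -= additive.mean()
    var_add = float(additive.var())
    if var_add == 0:
        raise ValueError("degenerate population: no additive variance realized")

    noise = config.resid_sd**2 / config.n_reps
    if noise > 0:
        target_var_add = config.h2 * noise / (1.0 - config.h2 - f)
        s_add = np.sqrt(target_var_add / var_add)
        additive *= s_add
        add_eff *= s_add
    else:
        # noise-free data: any genetic variance satisfies the heritability
        # target, so the raw scale is kept
        target_var_add = var_add

    rows = [
        {"term": pop.genotypes.marker_ids[q], "effect": e}
        for q, e in zip(qtl, add_eff)
    ]
    epistatic = np.zeros(n)
    if f > 0:
        n_pairs = max(2, config.n_qtl // 2)
        pairs = rng.choice(config.n_qtl, size=(n_pairs, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        epi_eff = rng.standard_normal(len(pairs))
        epistatic = (V[:, qtl[pairs[:, 0]]] * V[:, qtl[pairs[:, 1]]]) @ epi_eff
        epistatic -= epistatic.mean()
        target_var_epi = target_var_add * f / (1.0 - f)
        s_epi = np.sqrt(target_var_epi / epistatic.var())
        epistatic *= s_epi
        epi_eff *= s_epi
        ids = pop.genotypes.marker_ids
        rows += [
            {"term": f"{ids[qtl[a]]}x{ids[qtl[b]]}", "effect": e}
            for (a, b), e in zip(pairs, epi_eff)
        ]
    genetic = additive + epistatic
    return replace(
        pop,
        qtl_effects=pd.DataFrame(rows),
        qtl_indices=qtl,
        true_genetic_values=genetic,
        true_additive_values=additive,
    )


def simulate_trials(pop: DHPopulation, config: SimConfig) -> pd.DataFrame:
    """Simulate plot-level trials and covariates for every year.

    Plot yield = year mean + genetic value + line-by-year interaction (SD
    ``gxe_sd``) + plot residual (SD ``resid_sd``).  With the default
    ``gxe_mode="genetic"`` the interaction is marker-associated: the causal
    loci receive fresh effects each year (QTL-by-year), scaled to
    ``gxe_sd`` — so part of what a within-year model learns is year-specific
    genetic signal that does not transfer to the other year, which is what
    makes within-year cross-validation look optimistic relative to
    cross-year prediction.  ``gxe_mode="iid"`` draws the interaction as
    line-by-year noise instead.  Heading date is a year
    offset plus a component correlated ``hd_genetic_cor`` with genetic value;
    rust severity (0-9 integer scale) and incidence (percent) are generated
    for year 2 only, correlated ``rust_cor`` with the non-genetic deviation
    of the year-2 line mean.  Returns a long plot-level table with columns
    line, year, rep, yield, HD, RS5, RI5, RS11, RI11.
    """
    if pop.true_genetic_values is None:
        raise ValueError("assign_genetic_architecture must run before simulate_trials")
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = config.rng("trials")
    n = config.n_lines
    gxe_sd = config.resolved_gxe_sd()
    g = pop.true_genetic_values
    records: list[pd.DataFrame] = []
    hd_means = config.hd_year_means
    qtl = pop.qtl_indices
    for y, mu in enumerate(config.year_means, start=1):
        if config.gxe_mode == "genetic" and qtl is not None and qtl.size > 0 and gxe_sd > 0:
            # QTL-by-year: fresh effects at the causal loci, rescaled so the
            # interaction SD among lines is exactly gxe_sd
            raw = pop.genotypes.values[:, qtl] @ rng.standard_normal(qtl.size)
            raw -= raw.mean()
            sd = raw.std()
            gxe = raw * (gxe_sd / sd) if sd > 0 else rng.normal(0.0, gxe_sd, size=n)
        else:
            gxe = rng.normal(0.0, gxe_sd, size=n)
        resid = rng.normal(0.0, config.resid_sd, size=(n, config.n_reps))
        # heading date: per-line (year-constant within line), genetic correlation
        g_std = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(n)
        hd_noise = rng.standard_normal(n)
        hd_mean = hd_means[(y - 1) % len(hd_means)]
        hd = hd_mean + config.hd_sd * (
            config.hd_genetic_cor * g_std
            + np.sqrt(1.0 - config.hd_genetic_cor**2) * hd_noise
        )
        # rust scored in year 2 only, at two time points
        if y == 2:
            dev = gxe + resid.mean(axis=1)  # non-genetic deviation of line mean
            dev_std = (dev - dev.mean()) / dev.std() if dev.std() > 0 else np.zeros(n)
            rho = config.rust_cor
            latent5 = rho * dev_std + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            latent11 = 0.8 * latent5 + 0.6 * rng.standard_normal(n)
            # severity on the basic 0-to-9 scale; incidence as a percentage;
            # the second time point is shifted upward (disease progresses)
            rs5 = np.clip(np.round(3.0 + 1.5 * latent5), 0, 9)
            rs11 = np.clip(np.round(4.5 + 1.5 * latent11), 0, 9)
            ri5 = np.clip(30.0 + 15.0 * latent5, 0, 100)
            ri11 = np.clip(45.0 + 15.0 * latent11, 0, 100)
        else:
            rs5 = rs11 = ri5 = ri11 = np.full(n, np.nan)
        for rep in range(1, config.n_reps + 1):
            records.append(
                pd.DataFrame(
                    {
                        "line": pop.genotypes.line_ids,
                        "year": y,
                        "rep": rep,
                        "yield": mu + g + gxe + resid[:, rep - 1],
                        "HD": hd,
                        "RS5": rs5,
                        "RI5": ri5,
                        "RS11": rs11,
                        "RI11": ri11,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def line_means(trials: pd.DataFrame, columns: tuple[str, ...] = ("yield",)) -> pd.DataFrame:
    """Per-line, per-year phenotype means over replicates (long -> wide rows)."""
    keep = ["line", "year", *columns]
    extra = [c for c in ("HD", "RS5", "RI5", "RS11", "RI11") if c in trials and c not in keep]
    return (
        trials.groupby(["line", "year"], sort=False)[list(columns) + extra]
        .mean()
        .reset_index()
    )


def mask_genotypes(M: MarkerMatrix, config: SimConfig) -> MarkerMatrix:
    """Apply GBS-like missingness: Beta-distributed per-marker call rates.

    Each marker draws a call rate from Beta(mean ``call_rate_mean``, SD
    ``call_rate_spread``); entries go missing independently at one minus the
    call rate.  Deterministic under the config seed.
    """
    mean, sd = config.call_rate_mean, config.call_rate_spread
    if not 0.0 <= mean <= 1.0:
        raise ValueError("call_rate_mean must lie in [0, 1]")
    rng = config.rng("masking")
    V = M.values.copy()
    n, m = V.shape
    if sd == 0 or mean in (0.0, 1.0):
        rates = np.full(m, mean)
    else:
        # Beta with given mean/SD; cap the SD at the feasible maximum
        max_var = mean * (1.0 - mean)
        var = min(sd**2, 0.95 * max_var)
        nu = mean * (1.0 - mean) / var - 1.0
        rates = rng.beta(mean * nu, (1.0 - mean) * nu, size=m)
    drop = rng.random((n, m)) >= rates
    V[drop] = np.nan
    return MarkerMatrix(list(M.line_ids), list(M.marker_ids), V)


def simulate_population(config: SimConfig) -> tuple[DHPopulation, pd.DataFrame, MarkerMatrix]:
    """End-to-end convenience: genotypes, architecture, trials, masking.

    Returns ``(population, plot-level trials, masked genotypes)``; the
    population carries the complete (unmasked) matrix and the truth values.
    """
    pop = simulate_dh_genotypes(config)
    pop = assign_genetic_architecture(pop, config)
    trials = simulate_trials(pop, config)
    masked = mask_genotypes(pop.genotypes, config)
    return pop, trials, masked


# ---------------------------------------------------------------------------
# file outputs (plain text) for recovery tests and CLI runs
# ---------------------------------------------------------------------------

def write_population(
    pop: DHPopulation, trials: pd.DataFrame, masked: MarkerMatrix, outdir: str | Path
) -> None:
    from .genotypes import write_genotype_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_tsv(masked, outdir / "genotypes.tsv")
    pop.genetic_map.to_csv(outdir / "genetic_map.tsv", sep="\t", index=False)
    trials.to_csv(outdir / "phenotypes.csv", index=False, na_rep="NA")
    if pop.true_genetic_values is not None:
        pd.DataFrame(
            {"line": pop.genotypes.line_ids, "genetic_value": pop.true_genetic_values}
        ).to_csv(outdir / "truth.csv", index=False)
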