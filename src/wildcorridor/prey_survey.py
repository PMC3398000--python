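"""Pellet-count analysis for ungulate prey abundance and habitat ranking.

Relative abundance of tiger prey (chital, sambar, wild boar, gaur, barking
deer, chowsingha, nilgai) is indexed by pellet-group counts in 10 m x 2 m
belt-transect plots, stratified by habitat class. Per-(habitat, species)
mean densities with standard errors are converted to per-hectare figures
(x 500, since one plot is 20 m2), habitats are ranked per species by
density (rank 1 = densest; zero density shares the worst rank), and the
per-species ranks are summed into a cumulative habitat preference order.
Zero-count profiles report, per species, how many plots recorded no pellet
group at all — a coarse landscape-wide abundance comparison.

Field protocol encoded in :func:`latrine_rule`: a pellet group is a cluster
of more than five pellets from one defecation; for the latrine-forming
species (nilgai, chowsingha) all groups at one spot collapse to a single
pellet group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLOT_AREA_M2 = 20.0  # 10 m x 2 m belt plot
HECTARE_M2 = 10_000.0
PLOTS_PER_HECTARE = HECTARE_M2 / PLOT_AREA_M2  # 500

MIN_PELLETS_PER_GROUP = 5  # a group must number more than this
LATRINE_SPECIES = frozenset({"nilgai", "chowsingha"})

SPECIES = (
    "chital",
    "sambar",
    "wild_boar",
    "gaur",
    "barking_deer",
    "chowsingha",
    "nilgai",
)


@dataclass
class PelletPlot:
    """One belt-transect plot: transect id, habitat class, per-species counts."""

    transect_id: str
    habitat: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {sp!r} must be a non-negative integer")


@dataclass(frozen=True)
class SurveyDesign:
    """Belt-transect survey layout; defaults follow the field protocol."""

    n_transects: int = 79
    plots_per_transect: int = 5
    plot_spacing: float = 100.0
    transect_length: float = 500.0

    @property
    def total_plots(self) -> int:
        return self.n_transects * self.plots_per_transect


@dataclass
class HabitatRanking:
    per_species_rank: pd.DataFrame  # habitat x species
    cumulative: pd.Series  # habitat -> sum of ranks
    order: list[str]  # ascending cumulative rank (most preferred first)


def plots_to_frame(plots: list[PelletPlot]) -> pd.DataFrame:
    rows = [
        {"transect_id": p.transect_id, "habitat": p.habitat, **p.counts}
        for p in plots
    ]
    df = pd.DataFrame(rows)
    species_cols = [c for c in df.columns if c not in ("transect_id", "habitat")]
    df[species_cols] = df[species_cols].fillna(0).astype(int)
    return df


def density_per_plot(plots: list[PelletPlot]) -> pd.DataFrame:
    """Mean pellet groups per plot and SE, per (habitat, species).

    SE = sample (n-1) standard deviation / sqrt(n_plots); undefined (NaN)
    for single-plot strata. Returns a long-format frame with columns
    habitat, species, n_plots, mean, se.
    """
    if not plots:
        raise ValueError("density_per_plot: no plots")
    df = plots_to_frame(plots)
    species_cols = [c for c in df.columns if c not in ("transect_id", "habitat")]
    long = df.melt(
        id_vars=["habitat"],
        value_vars=species_cols,
        var_name="species",
        value_name="count",
    )
    out = (
        long.groupby(["habitat", "species"], sort=True)["count"]
        .agg(n_plots="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n_plots"])
    return out.drop(columns="sd")


def density_per_hectare(mean_per_plot: float | np.ndarray) -> float | np.ndarray:
    """Convert pellet groups per 20 m2 plot to pellet groups per hectare (x500)."""
    arr = np.asarray(mean_per_plot, dtype=float)
    if np.any(arr < 0):
        raise ValueError("density cannot be negative")
    out = arr * PLOTS_PER_HECTARE
    return float(out) if np.isscalar(mean_per_plot) or out.ndim == 0 else out


def rank_habitats(densities: pd.DataFrame) -> HabitatRanking:
    """Rank habitats per species by pellet density and sum to a cumulative order.

    ``densities`` is a habitat x species table. Within a species, the
    densest habitat gets rank 1; ties share the mean of their rank
    positions; zero densities sit at (and share) the worst rank. An
    all-zero species contributes equal ranks to every habitat. The
    cumulative order sorts ascending (lowest total = most preferred),
    ties broken alphabetically for determinism.
    """
    if densities.shape[0] < 2:
        raise ValueError("rank_habitats needs at least two habitats")
    ranks = densities.rank(axis=0, ascending=False, method="average")
    cumulative = ranks.sum(axis=1)
    order = cumulative.sort_index().sort_values(kind="stable").index.tolist()
    return HabitatRanking(ranks, cumulative, order)


def zero_counts(plots: list[PelletPlot]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plots with no pellet group, per species: by habitat and overall.

    Returns (per-habitat frame with n_zero and pct_zero per species,
    overall one-row frame with n_zero and pct_zero over all plots).
    """
    df = plots_to_frame(plots)
    species_cols = [c for c in df.columns if c not in ("transect_id", "habitat")]
    zero = df[species_cols] == 0
    by_hab = zero.groupby(df["habitat"]).agg(["sum", "mean"])
    by_hab.columns = [f"{sp}_{'n_zero' if st == 'sum' else 'pct_zero'}" for sp, st in by_hab.columns]
    pct_cols = [c for c in by_hab.columns if c.endswith("pct_zero")]
    by_hab[pct_cols] = by_hab[pct_cols] * 100.0
    overall = pd.DataFrame(
        {
            **{f"{sp}_n_zero": [int(zero[sp].sum())] for sp in species_cols},
            **{f"{sp}_pct_zero": [float(zero[sp].mean() * 100.0)] for sp in species_cols},
        },
        index=["all"],
    )
    return by_hab, overall


@dataclass(frozen=True)
class PelletObservation:
    """One raw field record: a candidate pellet group before protocol filtering."""

    species: str
    n_pellets: int
    site_id: str  # co-location key for latrine collapsing


def latrine_rule(observations: list[PelletObservation]) -> dict[str, int]:
    """Apply the field protocol to raw observations, returning per-species counts.

    Clusters of five or fewer pellets are discarded; for latrine-forming
    species every surviving observation at one site counts as a single
    pellet group.
    """
    counts: dict[str, int] = {}
    latrine_seen: set[tuple[str, str]] = set()
    for obs in observations:
        if obs.n_pellets <= MIN_PELLETS_PER_GROUP:
            continue
        if obs.species in LATRINE_SPECIES:
            key = (obs.species, obs.site_id)
            if key in latrine_seen:
                continue
            latrine_seen.add(key)
        counts[obs.species] = counts.get(obs.species, 0) + 1
    return counts
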