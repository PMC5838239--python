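"""Synthetic data generators with known ground truth.

Every external input of the analysis pipeline has a generator here, so all
downstream summaries can be tested against planted truth without any field
or sequencing data:

* :func:`gen_survey` — a station survey emulating a 32-station spring
  cruise: Bernoulli presence, truncated-lognormal bloom abundances spanning
  trace to multi-million cells L⁻¹, quota-consistent POC/BSi contributions.
* :func:`gen_ribotypes` — multi-sample, multi-genus ribotype read-count
  tables with Dirichlet-multinomial structure over depth layers and size
  fractions, with planted genus abundance ranks verified on the realised
  table.
* :func:`gen_nutrient_profiles` — Si and N depth profiles for
  no/low/high-convection station clusters, with a configurable surface
  Si:N uplift for the deeply mixed cluster.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bloom_metrics import QuotaSpec, cells_to_biomass
from .metabarcode import DIATOM_GROUP, PHOTOSYNTHETIC_GROUPS, genus_rank

__all__ = [
    "SurveyGenSpec",
    "SurveyTruth",
    "RibotypeGenSpec",
    "RibotypeTruth",
    "NutrientProfileGenSpec",
    "gen_survey",
    "gen_ribotypes",
    "gen_nutrient_profiles",
    "si_n_ratio",
    "si_n_uplift",
]


# ---------------------------------------------------------------------------
# station survey
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyGenSpec:
    """Specification of a synthetic station survey.

    Present stations (Bernoulli ``presence_prob``) draw cell concentrations
    from a lognormal truncated to ``abundance_bounds``; their fractional
    contribution to diatom abundance is Beta-distributed with mean
    ``contrib_mean``.  POC and BSi backgrounds are lognormal so that the
    planted percentage contributions are known exactly.  Defaults emulate
    the DeWeX leg-2 marginals: 32 stations, 17/32 presence, abundances
    between 5×10³ and 6×10⁶ cells L⁻¹.
    """

    n_stations: int = 32
    presence_prob: float = 17.0 / 32.0
    meanlog: float = 11.7
    sdlog: float = 2.4
    abundance_bounds: tuple[float, float] = (5e3, 6e6)
    contrib_mean: float = 0.92
    contrib_conc: float = 6.0
    poc_background_meanlog: float = 2.3    # ln µmol C L⁻¹ (~10 µM median)
    poc_background_sdlog: float = 0.4
    bsi_background_meanlog: float = -1.2   # ln µmol Si L⁻¹ (~0.3 µM median)
    bsi_background_sdlog: float = 0.5
    quota: QuotaSpec = field(default_factory=QuotaSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.presence_prob <= 1:
            raise ValueError("presence_prob must lie in [0, 1]")
        lo, hi = self.abundance_bounds
        if not 0 < lo < hi:
            raise ValueError("infeasible abundance truncation bounds")
        if not 0 < self.contrib_mean < 1:
            raise ValueError("contrib_mean must lie in (0, 1)")


@dataclass
class SurveyTruth:
    """Planted ground truth of one synthetic survey realisation."""

    presence: np.ndarray            # bool per station
    contributions: np.ndarray       # diatom-abundance fraction, NaN if absent
    pct_poc: np.ndarray             # planted % of POC, NaN if absent
    pct_bsi: np.ndarray
    presence_prob: float
    contrib_mean: float


def _truncated_lognormal(rng, n, meanlog, sdlog, lo, hi):
    a = (np.log(lo) - meanlog) / sdlog
    b = (np.log(hi) - meanlog) / sdlog
    dist = stats.truncnorm(a, b, loc=meanlog, scale=sdlog)
    return np.exp(dist.ppf(rng.uniform(size=n)))


def gen_survey(spec: SurveyGenSpec = SurveyGenSpec()):
    """Generate a synthetic station survey table and its ground truth.

    Returns ``(table, truth)`` where ``table`` follows the survey schema
    (date, station, latitude, longitude, minidiscus_cells,
    pct_diatom_abundance, pct_poc, pct_bsi) and ``truth`` is a
    :class:`SurveyTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_stations
    present = rng.uniform(size=n) < spec.presence_prob
    cells = np.zeros(n)
    cells[present] = np.round(
        _truncated_lognormal(rng, int(present.sum()), spec.meanlog, spec.sdlog,
                             *spec.abundance_bounds)
    )

    a = spec.contrib_mean * spec.contrib_conc
    b = (1 - spec.contrib_mean) * spec.contrib_conc
    contrib = np.full(n, np.nan)
    contrib[present] = rng.beta(a, b, size=int(present.sum()))

    poc_bg = np.exp(rng.normal(spec.poc_background_meanlog,
                               spec.poc_background_sdlog, size=n))
    bsi_bg = np.exp(rng.normal(spec.bsi_background_meanlog,
                               spec.bsi_background_sdlog, size=n))
    cells_c, cells_si = cells_to_biomass(cells, spec.quota)
    pct_poc = np.where(cells > 0, 100.0 * cells_c / (poc_bg + cells_c), 0.0)
    pct_bsi = np.where(cells > 0, 100.0 * cells_si / (bsi_bg + cells_si), 0.0)

    start = pd.Timestamp("2013-04-05")
    dates = [start + pd.Timedelta(days=int(i * 19 / max(n - 1, 1))) for i in range(n)]
    table = pd.DataFrame(
        {
            "date": dates,
            "station": np.arange(1, n + 1),
            "latitude": np.round(rng.uniform(40.0, 43.7, size=n), 2),
            "longitude": np.round(rng.uniform(3.5, 8.6, size=n), 2),
            "minidiscus_cells": cells.astype(int),
            "pct_diatom_abundance": np.where(present, np.round(100 * contrib, 1), 0.0),
            "pct_poc": np.round(pct_poc, 1),
            "pct_bsi": np.round(pct_bsi, 1),
        }
    )
    truth = SurveyTruth(
        presence=present,
        contributions=contrib,
        pct_poc=np.where(present, pct_poc, np.nan),
        pct_bsi=np.where(present, pct_bsi, np.nan),
        presence_prob=spec.presence_prob,
        contrib_mean=spec.contrib_mean,
    )
    return table, truth


# ---------------------------------------------------------------------------
# ribotype tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RibotypeGenSpec:
    """Specification of a synthetic ribotype read-count table.

    Reads per sample are negative-binomial; genus proportions per sample
    are Dirichlet around a layer-specific concentration vector in which the
    target genus is planted at ``planted_ranks[layer]`` among the diatom
    genera (``"photic"`` plants the same position in both SRF and DCM).
    Genus reads are subdivided over that genus's ribotypes; every ribotype
    receives at least one read in any sample where the genus has at least
    as many reads as ribotypes, so planted ribotype richness is exactly
    recoverable on sufficiently deep tables.
    """

    n_diatom_genera: int = 25
    target_genus: str = "Minidiscus"
    samples_per_stratum: int = 3
    depth_layers: tuple = ("SRF", "DCM", "MESO")
    size_fractions: tuple = ("0.8-5", "5-20", "20-180", "180-2000")
    planted_ranks: dict = field(default_factory=lambda: {"photic": 21, "MESO": 8})
    weight_decay: float = 0.82
    dirichlet_scale: float = 400.0
    photo_to_diatom_ratio: float = 1.0
    reads_mean: float = 2000.0
    reads_dispersion: float = 5.0
    ribotypes_target: int = 30
    ribotypes_other: int = 8
    max_attempts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for rank in self.planted_ranks.values():
            if not 1 <= rank <= self.n_diatom_genera:
                raise ValueError("planted rank unreachable for genus pool size")
        if not 0 < self.weight_decay < 1:
            raise ValueError("weight_decay must lie in (0, 1)")


@dataclass
class RibotypeTruth:
    """Planted ground truth of one ribotype-table realisation."""

    planted_ranks: dict
    diatom_genera: list
    ribotypes_per_genus: dict
    attempts: int


_OTHER_GROUPS = tuple(sorted(PHOTOSYNTHETIC_GROUPS - {DIATOM_GROUP}))


def _layer_weights(spec: RibotypeGenSpec, layer: str) -> dict:
    """Diatom genus weight vector with the target planted at its rank."""
    rank = None
    for key, r in spec.planted_ranks.items():
        if key == layer or (key == "photic" and layer in ("SRF", "DCM")):
            rank = r
    if rank is None:
        rank = spec.n_diatom_genera // 2 + 1
    decay = spec.weight_decay
    w = decay ** np.arange(spec.n_diatom_genera)
    others = [f"Diatom_{i:02d}" for i in range(1, spec.n_diatom_genera)]
    names = others[: rank - 1] + [spec.target_genus] + others[rank - 1:]
    return dict(zip(names, w))


def _split_reads(rng, total: int, n_ribo: int) -> np.ndarray:
    """Split ``total`` reads over ribotypes, covering all when possible."""
    if total >= n_ribo:
        base = np.ones(n_ribo, dtype=int)
        extra = rng.multinomial(total - n_ribo, np.full(n_ribo, 1.0 / n_ribo))
        return base + extra
    return rng.multinomial(total, np.full(n_ribo, 1.0 / n_ribo))


def gen_ribotypes(spec: RibotypeGenSpec = RibotypeGenSpec()):
    """Generate a ribotype table honouring the planted genus ranks.

    Returns ``(table, truth)``.  The realised table is checked against every
    planted rank (pooled reads within the depth selection); a fresh draw is
    attempted up to ``spec.max_attempts`` times before signalling an
    infeasible spec.
    """
    diatom_genera = [spec.target_genus] + [
        f"Diatom_{i:02d}" for i in range(1, spec.n_diatom_genera)
    ]
    n_other = len(_OTHER_GROUPS)
    other_genera = [f"Photo_{g[:6]}" for g in _OTHER_GROUPS]
    ribo_counts = {g: (spec.ribotypes_target if g == spec.target_genus
                       else spec.ribotypes_other) for g in diatom_genera}
    ribo_counts.update({g: spec.ribotypes_other for g in other_genera})

    for attempt in range(1, spec.max_attempts + 1):
        rng = np.random.default_rng((spec.seed, attempt))
        rows = []
        sample_no = itertools.count(1)
        for layer in spec.depth_layers:
            dia_w = _layer_weights(spec, layer)
            names = list(dia_w) + other_genera
            w = np.array(list(dia_w.values()), dtype=float)
            w /= w.sum()
            w_other = np.full(n_other, spec.photo_to_diatom_ratio / max(n_other, 1))
            weights = np.concatenate([w, w_other])
            alpha = spec.dirichlet_scale * weights / weights.sum()
            for fraction in spec.size_fractions:
                for _ in range(spec.samples_per_stratum):
                    sid = f"S{next(sample_no):03d}"
                    p = rng.dirichlet(alpha)
                    k = spec.reads_dispersion
                    nb_p = k / (k + spec.reads_mean)
                    total = int(rng.negative_binomial(k, nb_p))
                    if total == 0:
                        continue
                    genus_reads = rng.multinomial(total, p)
                    for genus, reads in zip(names, genus_reads):
                        if reads == 0:
                            continue
                        group = (DIATOM_GROUP if genus in dia_w
                                 else _OTHER_GROUPS[other_genera.index(genus)])
                        per_ribo = _split_reads(rng, int(reads), ribo_counts[genus])
                        for j, r in enumerate(per_ribo):
                            if r > 0:
                                rows.append((sid, layer, fraction, group, genus,
                                             f"{genus}_rt{j:04d}", int(r)))
        table = pd.DataFrame(
            rows,
            columns=["sample", "depth_layer", "size_fraction", "taxon_group",
                     "genus", "ribotype", "reads"],
        )
        ok = all(
            genus_rank(table, spec.target_genus, depth_layer=key, among="diatoms")
            == rank
            for key, rank in spec.planted_ranks.items()
        )
        if ok:
            truth = RibotypeTruth(
                planted_ranks=dict(spec.planted_ranks),
                diatom_genera=diatom_genera,
                ribotypes_per_genus=dict(ribo_counts),
                attempts=attempt,
            )
            return table, truth
    raise RuntimeError(
        f"planted ranks not realised after {spec.max_attempts} attempts; "
        "spec likely infeasible (ranks too deep for the concentration scale)"
    )


# ---------------------------------------------------------------------------
# nutrient profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NutrientProfileGenSpec:
    """Specification of synthetic Si/N depth profiles per convection cluster.

    Surface-layer (0–50 m) means default to the observed cluster values:
    deeply convective stations 7.7 µM Si / 8.4 µM N (fully mixed, uniform
    with depth), weakly- and non-convective stations 2.1 µM Si / 2.7 µM N
    at the surface with a nutricline toward the deep values.  The NC
    cluster reuses the LC surface values (no separate observation exists).
    ``si_n_uplift``, when set, re-plants the HC surface Si so the HC
    surface Si:N exceeds the LC ratio by exactly that factor in
    expectation; left ``None``, the observed concentrations imply an
    uplift of ~17.9 %.
    """

    clusters: tuple = ("NC", "LC", "HC")
    depths: tuple = tuple(range(0, 210, 10))
    hc_surface: tuple[float, float] = (7.7, 8.4)   # (Si, N) µM
    lc_surface: tuple[float, float] = (2.1, 2.7)
    si_n_uplift: float | None = None
    nutricline_top: float = 50.0
    nutricline_bottom: float = 150.0
    noise_sd: float = 0.0
    seed: int = 0

    def hc_surface_si(self) -> float:
        if self.si_n_uplift is None:
            return self.hc_surface[0]
        lc_ratio = self.lc_surface[0] / self.lc_surface[1]
        return (1.0 + self.si_n_uplift) * lc_ratio * self.hc_surface[1]


def gen_nutrient_profiles(spec: NutrientProfileGenSpec = NutrientProfileGenSpec()) -> pd.DataFrame:
    """Generate a long-format profile table (cluster, depth, NO3, SiOH4)."""
    rng = np.random.default_rng(spec.seed)
    depths = np.asarray(spec.depths, dtype=float)
    deep_si, deep_n = spec.hc_surface_si(), spec.hc_surface[1]
    frames = []
    for cluster in spec.clusters:
        if cluster == "HC":
            si = np.full_like(depths, spec.hc_surface_si())
            n = np.full_like(depths, spec.hc_surface[1])
        elif cluster in ("LC", "NC"):
            surf_si, surf_n = spec.lc_surface
            t = np.clip((depths - spec.nutricline_top)
                        / (spec.nutricline_bottom - spec.nutricline_top), 0, 1)
            si = surf_si + t * (deep_si - surf_si)
            n = surf_n + t * (deep_n - surf_n)
        else:
            raise ValueError(f"unknown cluster {cluster!r}")
        if spec.noise_sd > 0:
            si = np.maximum(0.0, si + rng.normal(0, spec.noise_sd, size=si.shape))
            n = np.maximum(0.0, n + rng.normal(0, spec.noise_sd, size=n.shape))
        frames.append(pd.DataFrame(
            {"cluster": cluster, "depth": depths, "NO3": n, "SiOH4": si}))
    return pd.concat(frames, ignore_index=True)


def si_n_ratio(profiles: pd.DataFrame, cluster: str,
               layer: tuple[float, float] = (0.0, 50.0)) -> float:
    """Layer-mean molar Si:N ratio of one cluster (ratio of layer means)."""
    sel = profiles[
        (profiles["cluster"] == cluster)
        & (profiles["depth"] >= layer[0])
        & (profiles["depth"] <= layer[1])
    ]
    if len(sel) == 0:
        raise ValueError(f"no profile points for cluster {cluster!r} in layer")
    mean_n = sel["NO3"].mean()
    if mean_n <= 0:
        raise ValueError("layer-mean N is zero; ratio undefined")
    return float(sel["SiOH4"].mean() / mean_n)


def si_n_uplift(profiles: pd.DataFrame, high: str = "HC", low: str = "LC",
                layer: tuple[float, float] = (0.0, 50.0)) -> float:
    """Fractional excess of the high-convection surface Si:N over the low."""
    return si_n_ratio(profiles, high, layer) / si_n_ratio(profiles, low, layer) - 1.0
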