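"""Synthetic study generator with known ground truth.

Emulates the proprietary study inputs -- branded-product composition
tables, commitment score sheets, a year of supermarket flyers and an
outlet/school road network -- so every downstream stage is testable
offline.

The latent model.  Each company carries a healthiness latent
``theta ~ N(0, 1)`` that shifts its portfolio's nutrient draws (higher
theta: less sugar/salt/saturated fat, more fibre and fruit/veg, fewer
ultra-processing markers).  A second latent drives commitment scores; it
is correlated with theta so that the rank correlation between the two
equals the ``coupling`` parameter (via the Gaussian-copula mapping
``r = 2 sin(pi * coupling / 6)``).  ``coupling = 0`` therefore generates
commitments independent of practices -- the null regime -- while
``coupling = 1`` with ``noise_sd = 0`` makes commitment rankings and
portfolio-healthiness rankings coincide exactly.

Product variety within a portfolio uses stratified normal quantiles, so
with ``noise_sd = 0`` a portfolio is a deterministic function of
(theta, size, category draw); ``noise_sd`` adds jitter on top of both
channels.  Nutrients are truncated log-normals per category with
medians placed so that default portfolios land in the qualitative
regime reported for real portfolios (majority ultra-processed, majority
not permitted to be marketed to children).

Determinism: every stage derives its generator from the single config
seed via named substreams, so identical configs produce byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit, logit, ndtri

from .commitment_scoring import DOMAINS, INDUSTRIES
from .nutrient_profiling import WHORuleTable

__all__ = [
    "StudyConfig",
    "GeoConfig",
    "FlyerConfig",
    "LatentCompany",
    "StudyBundle",
    "generate_study",
    "generate_companies",
    "generate_portfolio",
    "generate_portfolios",
    "generate_commitments",
    "generate_flyers",
    "generate_geo",
    "DEFAULT_CATEGORIES",
]

# named RNG substreams (spawn keys off the config seed)
_STREAM_COMPANIES = 1
_STREAM_PORTFOLIO = 2
_STREAM_SHEETS = 3
_STREAM_FLYERS = 4
_STREAM_GEO = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Category library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySpec:
    """Generator parameters for one product category.

    ``nutrients`` maps nutrient column -> (median, log-sigma, loading);
    a product with unhealthiness latent ``x`` draws
    ``median * exp(sigma * loading * x + jitter)``.  ``marker_cut`` is
    the latent threshold above which the product carries a group-4
    ingredient marker.
    """

    who_category: str
    is_beverage: bool = False
    is_cheese: bool = False
    is_added_fat: bool = False
    nutrients: dict = None
    fv_base: float = 0.05  # baseline fruit/veg fraction (of 1)
    marker_cut: float = 9.0  # +9: never marked
    added_sugar_frac: float = 0.0


def _n(energy, sugars, satfat, totfat, sodium, fibre, protein):
    """Nutrient table: median values with shared sigmas/loadings."""
    return {
        "energy_kj": (energy, 0.25, 0.5),
        "sugars_g": (sugars, 0.45, 1.0),
        "saturated_fat_g": (satfat, 0.45, 0.9),
        "total_fat_g": (totfat, 0.40, 0.6),
        "sodium_mg": (sodium, 0.35, 0.9),
        "fibre_g": (fibre, 0.40, -0.7),
        # protein is deliberately decoupled from the healthiness axis:
        # as a favourable Nutri-Score component a positive loading would
        # break monotonicity of the score in the latent
        "protein_g": (protein, 0.30, 0.0),
    }


DEFAULT_CATEGORIES: dict[str, CategorySpec] = {
    "other_beverages": CategorySpec(
        who_category="other_beverages", is_beverage=True,
        nutrients=_n(160, 8.5, 0.1, 0.1, 15, 0.1, 0.3),
        fv_base=0.05, marker_cut=9.0, added_sugar_frac=0.95,
    ),
    "yoghurts": CategorySpec(
        who_category="yoghurts",
        nutrients=_n(400, 9.5, 2.2, 3.0, 55, 0.4, 4.0),
        fv_base=0.08, marker_cut=-0.2, added_sugar_frac=0.55,
    ),
    "breakfast_cereals": CategorySpec(
        who_category="breakfast_cereals",
        nutrients=_n(1600, 16, 1.3, 6.0, 400, 5.0, 8.5),
        fv_base=0.02, marker_cut=-0.6, added_sugar_frac=0.7,
    ),
    "savoury_snacks": CategorySpec(
        who_category="savoury_snacks",
        nutrients=_n(2100, 2.5, 3.0, 25.0, 600, 3.5, 6.5),
        fv_base=0.02, marker_cut=-1.2,
    ),
    "ready_made": CategorySpec(
        who_category="ready_made",
        nutrients=_n(550, 3.5, 2.2, 7.0, 380, 1.8, 6.0),
        fv_base=0.20, marker_cut=-0.5, added_sugar_frac=0.3,
    ),
    "processed_meat": CategorySpec(
        who_category="processed_meat",
        nutrients=_n(1000, 1.2, 5.5, 15.0, 750, 0.3, 15.0),
        fv_base=0.01, marker_cut=-0.7, added_sugar_frac=0.1,
    ),
    "cheese": CategorySpec(
        who_category="cheese", is_cheese=True,
        nutrients=_n(1400, 0.8, 14.0, 23.0, 680, 0.05, 22.0),
        fv_base=0.01, marker_cut=0.3,
    ),
    "bread": CategorySpec(
        who_category="bread",
        nutrients=_n(1050, 3.2, 0.6, 2.5, 420, 3.8, 8.5),
        fv_base=0.02, marker_cut=0.0, added_sugar_frac=0.3,
    ),
    "chocolate_confectionery": CategorySpec(
        who_category="chocolate_confectionery",
        nutrients=_n(2150, 47, 10.0, 28.0, 70, 2.2, 5.5),
        fv_base=0.02, marker_cut=-1.5, added_sugar_frac=0.9,
    ),
    "fresh_fruit_veg": CategorySpec(
        who_category="fresh_fruit_veg",
        nutrients=_n(170, 4.5, 0.1, 0.3, 8, 2.4, 1.2),
        fv_base=0.96, marker_cut=9.0,
    ),
}

_DEFAULT_MIX = {
    "ready_made": 0.14,
    "yoghurts": 0.12,
    "breakfast_cereals": 0.10,
    "savoury_snacks": 0.10,
    "processed_meat": 0.12,
    "cheese": 0.08,
    "bread": 0.12,
    "chocolate_confectionery": 0.10,
    "other_beverages": 0.07,
    "fresh_fruit_veg": 0.05,
}

# domain-specific offsets on the commitment logit (accessibility lags,
# corporate strategy leads -- for realistic spread across domains)
_DOMAIN_OFFSETS = {
    "corporate_strategy": 0.5,
    "product_formulation": 0.0,
    "nutrition_labelling": -0.2,
    "promotion": 0.0,
    "accessibility": -1.2,
    "relationships": -0.3,
}

INDICATORS_PER_DOMAIN = 5


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class GeoConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    grid_nx: int = Field(default=15, ge=2)
    grid_ny: int = Field(default=15, ge=2)
    edge_len_m: float = Field(default=150.0, gt=0)
    outlets_per_company: int = Field(default=10, ge=1)
    n_schools: int = Field(default=25, ge=2)
    drop_edge_frac: float = Field(default=0.0, ge=0, le=0.4)


class FlyerConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    promos_per_week: tuple[int, int] = (8, 20)
    p_cover: float = Field(default=0.15, ge=0, le=1)
    p_upf: float = Field(default=0.52, ge=0, le=1)
    p_fresh_fruit_veg: float = Field(default=0.08, ge=0, le=1)
    p_character: float = Field(default=0.05, ge=0, le=1)
    p_premium: float = Field(default=0.20, ge=0, le=1)
    p_nutriscore_shown: float = Field(default=0.02, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "FlyerConfig":
        lo, hi = self.promos_per_week
        if lo < 1 or hi < lo:
            raise ValueError("promos_per_week: lower bound must be >= 1 and <= upper bound")
        if self.p_upf > 1.0 - self.p_fresh_fruit_veg + 1e-12:
            raise ValueError("p_upf cannot exceed 1 - p_fresh_fruit_veg")
        return self


class StudyConfig(BaseModel):
    """Full generator configuration; identical configs generate
    byte-identical bundles."""

    model_config = ConfigDict(frozen=True)

    n_companies: dict[str, int] = Field(
        default={"manufacturer": 19, "supermarket": 5, "quick_service": 7}
    )
    portfolio_size_range: tuple[int, int] = (10, 60)
    category_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_MIX))
    coupling: float = Field(default=0.0, ge=-1, le=1)
    noise_sd: float = Field(default=0.25, ge=0)
    seed: int = 0
    n_flyer_weeks: int = Field(default=52, ge=1)
    geo: GeoConfig = GeoConfig()
    flyers: FlyerConfig = FlyerConfig()
    # generator shape constants
    portfolio_shift: float = Field(default=1.1, gt=0)
    commit_slope: float = Field(default=1.2, gt=0)
    participation_rate: float = Field(default=0.58, ge=0, le=1)
    label_base_rate: float = Field(default=0.10, ge=0, le=1)

    @field_validator("n_companies")
    @classmethod
    def _industries(cls, v):
        unknown = set(v) - set(INDUSTRIES)
        if unknown:
            raise ValueError(f"n_companies: unknown industry {sorted(unknown)[0]!r}")
        if any(c < 0 for c in v.values()):
            raise ValueError("n_companies: counts must be >= 0")
        if sum(v.values()) < 1:
            raise ValueError("n_companies: need at least one company")
        return {ind: int(v.get(ind, 0)) for ind in INDUSTRIES}

    @field_validator("portfolio_size_range")
    @classmethod
    def _size_range(cls, v):
        lo, hi = v
        if lo < 1:
            raise ValueError("portfolio_size_range: lower bound must be >= 1")
        if hi < lo:
            raise ValueError("portfolio_size_range: upper bound below lower bound")
        return (int(lo), int(hi))

    @field_validator("category_mix")
    @classmethod
    def _mix(cls, v):
        if not v:
            raise ValueError("category_mix: empty")
        unknown = set(v) - set(DEFAULT_CATEGORIES)
        if unknown:
            raise ValueError(f"category_mix: unknown category {sorted(unknown)[0]!r}")
        if any(w < 0 for w in v.values()):
            raise ValueError("category_mix: negative weight")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix: weights must sum to 1")
        return dict(v)


@dataclass(frozen=True)
class LatentCompany:
    """Ground-truth latent state of one generated company."""

    company_id: str
    industry: str
    theta: float  # latent healthiness driving the portfolio
    commitment_latent: float  # latent driving commitment scores
    participated: bool
    seed_index: int  # position in the generation order; keys RNG substreams

    def __post_init__(self):
        if self.industry not in INDUSTRIES:
            raise ValueError(f"unknown industry '{self.industry}'")
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")


# ---------------------------------------------------------------------------
# Companies
# ---------------------------------------------------------------------------

_PREFIX = {"manufacturer": "M", "supermarket": "S", "quick_service": "Q"}


def generate_companies(config: StudyConfig) -> list[LatentCompany]:
    """Draw company latents; commitment latent has rank correlation
    ``coupling`` with theta (Gaussian copula)."""
    rng = _rng(config.seed, _STREAM_COMPANIES)
    r = 2.0 * math.sin(math.pi * config.coupling / 6.0)
    companies = []
    idx = 0
    for industry in INDUSTRIES:
        for k in range(config.n_companies[industry]):
            theta = rng.standard_normal()
            z = rng.standard_normal()
            u = r * theta + math.sqrt(max(0.0, 1.0 - r * r)) * z
            participated = bool(rng.random() < config.participation_rate)
            companies.append(
                LatentCompany(
                    company_id=f"{_PREFIX[industry]}{k + 1:02d}",
                    industry=industry,
                    theta=float(theta),
                    commitment_latent=float(u),
                    participated=participated,
                    seed_index=idx,
                )
            )
            idx += 1
    return companies


def truth_frame(config: StudyConfig, companies: list[LatentCompany]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "company_id": [c.company_id for c in companies],
            "industry": [c.industry for c in companies],
            "theta": np.round([c.theta for c in companies], 10),
            "commitment_latent": np.round([c.commitment_latent for c in companies], 10),
            "participated": [c.participated for c in companies],
            "coupling": config.coupling,
            "noise_sd": config.noise_sd,
        }
    )


# ---------------------------------------------------------------------------
# Portfolios
# ---------------------------------------------------------------------------


def _category_assignment(m: int, mix: dict[str, float]) -> list[str]:
    """Deterministic category composition for a portfolio of size ``m``.

    Counts follow the mix by largest remainder; each category's products
    are spread systematically across the quantile positions.  Keeping
    the composition deterministic confines all idiosyncratic variation
    to ``noise_sd``, so a zero-noise study is an exact function of the
    company latents.
    """
    names = sorted(mix)
    weights = np.array([mix[n] for n in names], float)
    weights = weights / weights.sum()
    ideal = m * weights
    counts = np.floor(ideal).astype(int)
    remainder_order = np.argsort(-(ideal - counts), kind="stable")
    for i in remainder_order[: m - counts.sum()]:
        counts[i] += 1
    keyed = []
    for name, c in zip(names, counts):
        for r in range(c):
            keyed.append(((r + 0.5) / c, name))
    keyed.sort()
    return [name for _, name in keyed]


def generate_portfolio(company: LatentCompany, config: StudyConfig) -> pd.DataFrame:
    """Products of one company in the ``products.csv`` schema.

    Product variety uses stratified normal quantiles; higher theta
    shifts every product toward the healthy end of its category.
    """
    rng = _rng(config.seed, _STREAM_PORTFOLIO, company.seed_index)
    lo, hi = config.portfolio_size_range
    m = int(rng.integers(lo, hi + 1))
    cats = _category_assignment(m, config.category_mix)

    # stratified product-variety quantiles; jitter scales with noise_sd
    q = ndtri((np.arange(m) + 0.5) / m)
    x = q - config.portfolio_shift * company.theta + config.noise_sd * rng.standard_normal(m)

    nutrient_names = list(next(iter(DEFAULT_CATEGORIES.values())).nutrients)
    medians = np.empty((m, len(nutrient_names)))
    sigmas = np.empty_like(medians)
    loadings = np.empty_like(medians)
    fv_base = np.empty(m)
    marker_cut = np.empty(m)
    sugar_frac = np.empty(m)
    for j, cat in enumerate(cats):
        spec = DEFAULT_CATEGORIES[cat]
        for k, nutrient in enumerate(nutrient_names):
            medians[j, k], sigmas[j, k], loadings[j, k] = spec.nutrients[nutrient]
        fv_base[j] = min(max(spec.fv_base, 1e-6), 1 - 1e-6)
        marker_cut[j] = spec.marker_cut
        sugar_frac[j] = spec.added_sugar_frac

    jitter = config.noise_sd * 0.5 * rng.standard_normal(medians.shape)
    values = medians * np.exp(sigmas * (loadings * x[:, None] + jitter))
    cols = dict(zip(nutrient_names, values.T))
    fv = 100.0 * expit(logit(fv_base) - 0.9 * x + config.noise_sd * rng.standard_normal(m))

    flavoured = x > marker_cut
    coloured = x > marker_cut + 0.8
    markers = [
        "|".join(mk for mk, on in (("flavouring", f), ("colour", c)) if on)
        for f, c in zip(flavoured, coloured)
    ]
    label_p = config.label_base_rate + 0.25 * expit(company.commitment_latent)
    specs = [DEFAULT_CATEGORIES[c] for c in cats]
    return pd.DataFrame(
        {
            "product_id": [f"{company.company_id}-P{j + 1:03d}" for j in range(m)],
            "company_id": company.company_id,
            "name": [f"{c} {j + 1}" for j, c in enumerate(cats)],
            "who_category": [s.who_category for s in specs],
            "is_beverage": [s.is_beverage for s in specs],
            "is_cheese": [s.is_cheese for s in specs],
            "is_added_fat": [s.is_added_fat for s in specs],
            "is_water": False,
            "energy_kj": np.round(cols["energy_kj"], 4),
            "sugars_g": np.round(cols["sugars_g"], 4),
            "saturated_fat_g": np.round(cols["saturated_fat_g"], 4),
            "total_fat_g": np.round(
                np.maximum(cols["total_fat_g"], cols["saturated_fat_g"]), 4
            ),
            "fibre_g": np.round(cols["fibre_g"], 4),
            "protein_g": np.round(cols["protein_g"], 4),
            "sodium_mg": np.round(cols["sodium_mg"], 4),
            "salt_g": np.nan,
            "added_sugars_g": np.round(sugar_frac * cols["sugars_g"], 4),
            "fruit_veg_pct": np.round(np.clip(fv, 0.0, 100.0), 4),
            "ingredient_markers": markers,
            "nova_group_override": np.nan,
            "displays_nutriscore": rng.random(m) < label_p,
        }
    )


def generate_portfolios(config: StudyConfig, companies: list[LatentCompany]) -> pd.DataFrame:
    frames = [generate_portfolio(c, config) for c in companies]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Commitment sheets
# ---------------------------------------------------------------------------


def generate_commitments(config: StudyConfig, companies: list[LatentCompany]) -> pd.DataFrame:
    """Indicator-level scores for both stages of every company.

    Participants receive a verification uplift over the public-only
    stage; non-participants keep identical scores at both stages.
    """
    rows = []
    for company in companies:
        rng = _rng(config.seed, _STREAM_SHEETS, company.seed_index)
        uplift = float(rng.uniform(0.15, 0.45)) if company.participated else 0.0
        for domain in DOMAINS:
            offset = _DOMAIN_OFFSETS[domain]
            for k in range(INDICATORS_PER_DOMAIN):
                max_score = 10.0 if k % 2 else 5.0
                applicable = not (
                    company.industry == "manufacturer"
                    and domain == "accessibility"
                    and k == INDICATORS_PER_DOMAIN - 1
                )
                eps = rng.standard_normal()
                frac = expit(
                    config.commit_slope * company.commitment_latent
                    + offset
                    + config.noise_sd * eps
                )
                raw = round(max_score * float(frac), 4) if applicable else 0.0
                for stage in ("public_only", "verified"):
                    staged = raw + uplift * (max_score - raw) if stage == "verified" else raw
                    rows.append(
                        {
                            "company_id": company.company_id,
                            "industry": company.industry,
                            "stage": stage,
                            "domain": domain,
                            "indicator_id": f"{domain[:4]}_{k + 1}",
                            "raw": round(staged, 4) if applicable else 0.0,
                            "max": max_score,
                            "applicable": applicable,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flyers
# ---------------------------------------------------------------------------


def generate_flyers(config: StudyConfig, companies: list[LatentCompany]) -> pd.DataFrame:
    """One year of weekly flyer promotions per supermarket.

    ``p_upf`` is the marginal ultra-processed share across all
    promotions (fresh fruit/veg promotions are never ultra-processed,
    so the conditional rate is adjusted upward).
    """
    fc = config.flyers
    rng = _rng(config.seed, _STREAM_FLYERS)
    supermarkets = [c for c in companies if c.industry == "supermarket"]
    names = sorted(n for n in config.category_mix if n != "fresh_fruit_veg")
    weights = np.array([config.category_mix[n] for n in names])
    weights = weights / weights.sum()
    p_upf_cond = fc.p_upf / (1.0 - fc.p_fresh_fruit_veg) if fc.p_fresh_fruit_veg < 1 else 0.0
    rows = []
    for company in supermarkets:
        for week in range(1, config.n_flyer_weeks + 1):
            n = int(rng.integers(fc.promos_per_week[0], fc.promos_per_week[1] + 1))
            for _ in range(n):
                fresh = bool(rng.random() < fc.p_fresh_fruit_veg)
                if fresh:
                    cat, nova = "fresh_fruit_veg", 1
                else:
                    cat = str(rng.choice(names, p=weights))
                    # non-UPF promotions are capped at group 3 so p_upf
                    # stays the marginal ultra-processed share
                    nova = 4 if rng.random() < p_upf_cond else 3
                shown = rng.random() < fc.p_nutriscore_shown
                rows.append(
                    {
                        "supermarket_id": company.company_id,
                        "week": week,
                        "placement": "cover" if rng.random() < fc.p_cover else "inside",
                        "product_id": "",
                        "who_category": DEFAULT_CATEGORIES[cat].who_category,
                        "nova_group": nova,
                        "nutriscore_class": str(rng.choice(list("ABCDE"))) if shown else "",
                        "has_promotional_character": bool(rng.random() < fc.p_character),
                        "has_premium_offer": bool(rng.random() < fc.p_premium),
                        "is_fresh_fruit_veg": fresh,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Geo scene
# ---------------------------------------------------------------------------


def generate_geo(
    config: StudyConfig, companies: list[LatentCompany]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Grid road network with outlets (quick-service) and schools.

    Edge lengths are the grid spacing inflated by a random detour factor
    (always >= the Euclidean distance).  Returns the
    (geo_nodes, geo_edges, geo_points) frames.
    """
    gc = config.geo
    rng = _rng(config.seed, _STREAM_GEO)
    node_ids, xs, ys = [], [], []
    for r in range(gc.grid_ny):
        for c in range(gc.grid_nx):
            node_ids.append(f"n{r}_{c}")
            xs.append(c * gc.edge_len_m)
            ys.append(r * gc.edge_len_m)
    nodes = pd.DataFrame({"node_id": node_ids, "x": xs, "y": ys})

    edges = []
    for r in range(gc.grid_ny):
        for c in range(gc.grid_nx):
            if c + 1 < gc.grid_nx:
                edges.append((f"n{r}_{c}", f"n{r}_{c + 1}"))
            if r + 1 < gc.grid_ny:
                edges.append((f"n{r}_{c}", f"n{r + 1}_{c}"))
    keep = rng.random(len(edges)) >= gc.drop_edge_frac
    factors = rng.uniform(1.0, 1.25, size=len(edges))
    edges_df = pd.DataFrame(
        {
            "u": [e[0] for e in edges],
            "v": [e[1] for e in edges],
            "length_m": np.round(gc.edge_len_m * factors, 4),
        }
    )[keep].reset_index(drop=True)

    points = []
    quick = [c for c in companies if c.industry == "quick_service"]
    for company in quick:
        chosen = rng.choice(len(node_ids), size=gc.outlets_per_company, replace=False)
        for i, node_idx in enumerate(chosen):
            points.append(
                {
                    "kind": "outlet",
                    "point_id": f"{company.company_id}-O{i + 1:02d}",
                    "company_id": company.company_id,
                    "level": "",
                    "node_id": node_ids[node_idx],
                    "x": xs[node_idx],
                    "y": ys[node_idx],
                }
            )
    school_nodes = rng.choice(len(node_ids), size=gc.n_schools, replace=False)
    for i, node_idx in enumerate(school_nodes):
        level = ("primary", "secondary")[i % 2]  # guarantees both levels
        points.append(
            {
                "kind": "school",
                "point_id": f"SCH{i + 1:02d}",
                "company_id": "",
                "level": level,
                "node_id": node_ids[node_idx],
                "x": xs[node_idx],
                "y": ys[node_idx],
            }
        )
    return nodes, edges_df, pd.DataFrame(points)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    config: StudyConfig
    companies: list[LatentCompany]
    products: pd.DataFrame
    commitments: pd.DataFrame
    flyers: pd.DataFrame
    geo_nodes: pd.DataFrame
    geo_edges: pd.DataFrame
    geo_points: pd.DataFrame
    truth: pd.DataFrame

    FILES = (
        "products.csv",
        "commitments.csv",
        "flyers.csv",
        "geo_nodes.csv",
        "geo_edges.csv",
        "geo_points.csv",
        "truth.csv",
    )

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = (
            self.products,
            self.commitments,
            self.flyers,
            self.geo_nodes,
            self.geo_edges,
            self.geo_points,
            self.truth,
        )
        written = []
        for name, frame in zip(self.FILES, frames):
            path = outdir / name
            frame.to_csv(path, index=False, lineterminator="\n")
            written.append(path)
        return written


def generate_study(
    config: StudyConfig, who_rules: Optional[WHORuleTable] = None
) -> StudyBundle:
    """Generate the full bundle; validates category references and
    post-conditions (non-negative nutrients, complete sheets, weekly
    flyer coverage)."""
    who_rules = who_rules or WHORuleTable.default()
    for name in config.category_mix:
        cat = DEFAULT_CATEGORIES[name].who_category
        if cat not in who_rules.categories:
            raise ValueError(
                f"category_mix: category '{name}' (WHO '{cat}') absent from the WHO rule table"
            )
    companies = generate_companies(config)
    products = generate_portfolios(config, companies)
    commitments = generate_commitments(config, companies)
    flyers = generate_flyers(config, companies)
    geo_nodes, geo_edges, geo_points = generate_geo(config, companies)

    nutrient_cols = [
        "energy_kj", "sugars_g", "saturated_fat_g", "total_fat_g",
        "fibre_g", "protein_g", "sodium_mg", "added_sugars_g",
    ]
    assert (products[nutrient_cols].to_numpy(float) >= 0).all(), "negative nutrient generated"
    assert products["fruit_veg_pct"].between(0, 100).all()
    sheet_domains = commitments.groupby("company_id")["domain"].nunique()
    assert (sheet_domains == len(DOMAINS)).all(), "incomplete commitment sheet"
    if config.n_companies["supermarket"] > 0:
        weeks = flyers.groupby("supermarket_id")["week"].nunique()
        assert (weeks == config.n_flyer_weeks).all(), "flyer weeks without promotions"

    return StudyBundle(
        config=config,
        companies=companies,
        products=products,
        commitments=commitments,
        flyers=flyers,
        geo_nodes=geo_nodes,
        geo_edges=geo_edges,
        geo_points=geo_points,
        truth=truth_frame(config, companies),
    )
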