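"""Per-product nutrient profiling under three classification systems.

All classifiers operate on composition declared per 100 g (foods) or
100 ml (beverages):

* :func:`nutriscore` -- the 2017 Nutri-Score points algorithm (classes
  A-E), including the beverage, water, cheese and added-fat branches.
* :func:`who_permitted` -- category-specific nutrient thresholds deciding
  whether a product may be marketed to children.  Categories may instead
  be prohibited outright.  Threshold semantics are inclusive: a value
  exactly at the limit passes.
* :func:`nova_group` -- NOVA processing groups 1-4 from ingredient
  markers and category defaults, with a per-product curated override.

The vectorised ``*_table`` functions operating on a products dataframe
are the single source of truth; the scalar entry points delegate to them
on a one-row frame.  :func:`profile_products` combines all three into a
``profile_results`` frame, the input of every downstream indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Product",
    "NutriScoreResult",
    "WHODecision",
    "WHOThresholds",
    "WHORuleTable",
    "NOVARules",
    "ProfilingError",
    "MissingNutrientError",
    "UnknownCategoryError",
    "nutriscore",
    "nutriscore_table",
    "who_permitted",
    "who_table",
    "nova_group",
    "nova_table",
    "profile_products",
    "products_to_frame",
    "validate_products_frame",
    "CLASSES",
]

#: grams of salt per mg of sodium (salt = sodium * 2.5 when both in grams)
SALT_G_PER_SODIUM_MG = 2.5 / 1000.0

CLASSES = ("A", "B", "C", "D", "E")


class ProfilingError(ValueError):
    """Base error for invalid profiling inputs."""


class MissingNutrientError(ProfilingError):
    """A nutrient required by an active rule is absent."""


class UnknownCategoryError(ProfilingError):
    """A product references a category absent from the rule table."""


# ---------------------------------------------------------------------------
# Product
# ---------------------------------------------------------------------------


class Product(BaseModel):
    """One branded food or beverage with per-100 g/ml composition.

    ``salt_g`` may be omitted; it is then derived from ``sodium_mg``
    (x 2.5 / 1000).  ``fruit_veg_pct`` defaults to 0, the conservative
    (least healthy) imputation.  ``ingredient_markers`` holds tokens such
    as ``flavouring`` or ``maltodextrin`` consumed by the NOVA rules.
    """

    model_config = ConfigDict(frozen=True)

    product_id: str
    company_id: str = ""
    name: str = ""
    is_beverage: bool = False
    is_cheese: bool = False
    is_added_fat: bool = False
    is_water: bool = False
    energy_kj: float = Field(ge=0)
    sugars_g: float = Field(ge=0)
    saturated_fat_g: float = Field(ge=0)
    total_fat_g: Optional[float] = Field(default=None, ge=0)
    fibre_g: float = Field(ge=0)
    protein_g: float = Field(ge=0)
    sodium_mg: float = Field(ge=0)
    salt_g: Optional[float] = Field(default=None, ge=0)
    added_sugars_g: Optional[float] = Field(default=None, ge=0)
    fruit_veg_pct: float = Field(default=0.0, ge=0, le=100)
    who_category: str = ""
    ingredient_markers: frozenset[str] = frozenset()
    nova_group_override: Optional[int] = Field(default=None, ge=1, le=4)
    displays_nutriscore: bool = False

    @model_validator(mode="after")
    def _check_flags(self) -> "Product":
        special = [f for f in ("is_cheese", "is_added_fat", "is_water") if getattr(self, f)]
        if len(special) > 1:
            raise ValueError(f"flags {special} are mutually exclusive")
        if self.is_water and not self.is_beverage:
            raise ValueError("is_water requires is_beverage")
        if (self.is_cheese or self.is_added_fat) and self.is_beverage:
            raise ValueError(f"{special[0]} is incompatible with is_beverage")
        if self.is_added_fat and self.total_fat_g is None:
            raise ValueError("total_fat_g is required for added fats")
        return self

    @property
    def salt_or_derived(self) -> float:
        """Salt in g/100 g, derived from sodium when not declared."""
        if self.salt_g is not None:
            return self.salt_g
        return self.sodium_mg * SALT_G_PER_SODIUM_MG


_BOOL_COLUMNS = (
    "is_beverage",
    "is_cheese",
    "is_added_fat",
    "is_water",
    "displays_nutriscore",
)
_REQUIRED_NUTRIENTS = (
    "energy_kj",
    "sugars_g",
    "saturated_fat_g",
    "fibre_g",
    "protein_g",
    "sodium_mg",
)
_OPTIONAL_NUMERIC = ("total_fat_g", "salt_g", "added_sugars_g", "fruit_veg_pct")


def _markers_to_set(value) -> frozenset[str]:
    if isinstance(value, (set, frozenset)):
        return frozenset(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(t.strip() for t in text.split("|") if t.strip())


def products_to_frame(products: Iterable[Product]) -> pd.DataFrame:
    """Serialise products into the flat ``products.csv`` schema."""
    rows = []
    for p in products:
        d = p.model_dump()
        d["ingredient_markers"] = "|".join(sorted(p.ingredient_markers))
        rows.append(d)
    return pd.DataFrame(rows)


def validate_products_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and values; return a normalised copy.

    Raises :class:`MissingNutrientError` naming the product and field for
    any missing required nutrient, and :class:`ProfilingError` for
    negative values or inconsistent flags.  Missing ``fruit_veg_pct`` is
    imputed as 0 (worst case).
    """
    df = df.copy()
    for col in ("product_id", "who_category"):
        if col not in df.columns:
            raise ProfilingError(f"products frame: missing column '{col}'")
    for col in _BOOL_COLUMNS:
        if col not in df.columns:
            df[col] = False
        df[col] = df[col].astype(bool)
    ids = df["product_id"].astype(str)
    for col in _REQUIRED_NUTRIENTS:
        if col not in df.columns:
            raise MissingNutrientError(f"products frame: missing column '{col}'")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = ids[vals.isna()].iloc[0]
            raise MissingNutrientError(f"product '{bad}': missing required nutrient '{col}'")
        if (vals < 0).any():
            bad = ids[vals < 0].iloc[0]
            raise ProfilingError(f"product '{bad}': negative value for '{col}'")
        df[col] = vals.astype(float)
    for col in _OPTIONAL_NUMERIC:
        if col not in df.columns:
            df[col] = np.nan
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            bad = ids[vals < 0].iloc[0]
            raise ProfilingError(f"product '{bad}': negative value for '{col}'")
        df[col] = vals.astype(float)
    df["fruit_veg_pct"] = df["fruit_veg_pct"].fillna(0.0)
    if (df["fruit_veg_pct"] > 100).any():
        bad = ids[df["fruit_veg_pct"] > 100].iloc[0]
        raise ProfilingError(f"product '{bad}': fruit_veg_pct above 100")
    multi = df[["is_cheese", "is_added_fat", "is_water"]].sum(axis=1) > 1
    if multi.any():
        raise ProfilingError(
            f"product '{ids[multi].iloc[0]}': cheese/added-fat/water flags are mutually exclusive"
        )
    if (df["is_water"] & ~df["is_beverage"]).any():
        bad = ids[df["is_water"] & ~df["is_beverage"]].iloc[0]
        raise ProfilingError(f"product '{bad}': is_water requires is_beverage")
    if ((df["is_cheese"] | df["is_added_fat"]) & df["is_beverage"]).any():
        bad = ids[(df["is_cheese"] | df["is_added_fat"]) & df["is_beverage"]].iloc[0]
        raise ProfilingError(f"product '{bad}': cheese/added-fat flags incompatible with is_beverage")
    fat_missing = df["is_added_fat"] & df["total_fat_g"].isna()
    if fat_missing.any():
        raise MissingNutrientError(
            f"product '{ids[fat_missing].iloc[0]}': total_fat_g required for added fats"
        )
    if "ingredient_markers" not in df.columns:
        df["ingredient_markers"] = ""
    if "nova_group_override" not in df.columns:
        df["nova_group_override"] = np.nan
    return df


def _salt_column(df: pd.DataFrame) -> pd.Series:
    salt = df["salt_g"].copy()
    derived = df["sodium_mg"] * SALT_G_PER_SODIUM_MG
    return salt.fillna(derived)


# ---------------------------------------------------------------------------
# Nutri-Score (2017 points algorithm)
# ---------------------------------------------------------------------------

# Negative-point thresholds: one point per threshold strictly exceeded.
_FOOD_ENERGY = np.array([335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350], float)
_FOOD_SUGARS = np.array([4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45], float)
_SATFAT = np.arange(1.0, 11.0)
_SODIUM = np.arange(90.0, 901.0, 90.0)
_BEV_ENERGY = np.arange(0.0, 271.0, 30.0)
_BEV_SUGARS = np.arange(0.0, 13.6, 1.5)
# Added fats score saturated fat as the sat-fat / total-fat ratio (in %);
# one point per threshold reached (>=), per the official fats table.
_FAT_RATIO = np.arange(10.0, 65.0, 6.0)
# Positive-point thresholds, strictly exceeded.
_FIBRE = np.array([0.9, 1.9, 2.8, 3.7, 4.7])
_PROTEIN = np.array([1.6, 3.2, 4.8, 6.4, 8.0])


def _pts_gt(values, thresholds) -> np.ndarray:
    """Points = number of thresholds strictly below the value."""
    return np.searchsorted(thresholds, np.asarray(values, float), side="left").astype(int)


def _pts_ge(values, thresholds) -> np.ndarray:
    """Points = number of thresholds at or below the value."""
    return np.searchsorted(thresholds, np.asarray(values, float), side="right").astype(int)


@dataclass(frozen=True)
class NutriScoreResult:
    """Points breakdown and final class for one product."""

    energy_pts: int
    sugars_pts: int
    saturated_fat_pts: int
    sodium_pts: int
    negative_points: int
    fruit_veg_pts: int
    fibre_pts: int
    protein_pts: int
    protein_counted: bool
    final_score: int
    klass: str

    @property
    def positive_points(self) -> int:
        counted = self.protein_pts if self.protein_counted else 0
        return self.fruit_veg_pts + self.fibre_pts + counted


def nutriscore_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised Nutri-Score over a validated products frame."""
    bev = df["is_beverage"].to_numpy()
    water = df["is_water"].to_numpy()
    cheese = df["is_cheese"].to_numpy()
    added_fat = df["is_added_fat"].to_numpy()

    energy = df["energy_kj"].to_numpy(float)
    sugars = df["sugars_g"].to_numpy(float)
    satfat = df["saturated_fat_g"].to_numpy(float)
    sodium = df["sodium_mg"].to_numpy(float)
    fibre = df["fibre_g"].to_numpy(float)
    protein = df["protein_g"].to_numpy(float)
    fv = df["fruit_veg_pct"].to_numpy(float)

    energy_pts = np.where(bev, _pts_gt(energy, _BEV_ENERGY), _pts_gt(energy, _FOOD_ENERGY))
    sugars_pts = np.where(bev, _pts_gt(sugars, _BEV_SUGARS), _pts_gt(sugars, _FOOD_SUGARS))
    total_fat = df["total_fat_g"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total_fat > 0, 100.0 * satfat / total_fat, 0.0)
    satfat_pts = np.where(added_fat, _pts_ge(ratio, _FAT_RATIO), _pts_gt(satfat, _SATFAT))
    sodium_pts = _pts_gt(sodium, _SODIUM)
    negative = energy_pts + sugars_pts + satfat_pts + sodium_pts

    fv_pts = np.where(
        bev,
        np.select([fv > 80, fv > 60, fv > 40], [10, 4, 2], 0),
        np.select([fv > 80, fv > 60, fv > 40], [5, 2, 1], 0),
    )
    fibre_pts = _pts_gt(fibre, _FIBRE)
    protein_pts = _pts_gt(protein, _PROTEIN)

    protein_counted = ~((negative >= 11) & (fv_pts < 5) & ~cheese)
    positive = fv_pts + fibre_pts + np.where(protein_counted, protein_pts, 0)
    score = negative - positive

    food_class = np.select(
        [score <= -1, score <= 2, score <= 10, score <= 18],
        ["A", "B", "C", "D"],
        "E",
    )
    bev_class = np.select([score <= 1, score <= 5, score <= 9], ["B", "C", "D"], "E")
    klass = np.where(water, "A", np.where(bev, bev_class, food_class))

    return pd.DataFrame(
        {
            "energy_pts": energy_pts,
            "sugars_pts": sugars_pts,
            "saturated_fat_pts": satfat_pts,
            "sodium_pts": sodium_pts,
            "negative_points": negative,
            "fruit_veg_pts": fv_pts,
            "fibre_pts": fibre_pts,
            "protein_pts": protein_pts,
            "protein_counted": protein_counted,
            "final_score": score,
            "nutri_class": klass,
        },
        index=df.index,
    )


def nutriscore(product: Product) -> NutriScoreResult:
    """Score a single product; see :func:`nutriscore_table`."""
    df = validate_products_frame(products_to_frame([product]))
    row = nutriscore_table(df).iloc[0]
    return NutriScoreResult(
        energy_pts=int(row["energy_pts"]),
        sugars_pts=int(row["sugars_pts"]),
        saturated_fat_pts=int(row["saturated_fat_pts"]),
        sodium_pts=int(row["sodium_pts"]),
        negative_points=int(row["negative_points"]),
        fruit_veg_pts=int(row["fruit_veg_pts"]),
        fibre_pts=int(row["fibre_pts"]),
        protein_pts=int(row["protein_pts"]),
        protein_counted=bool(row["protein_counted"]),
        final_score=int(row["final_score"]),
        klass=str(row["nutri_class"]),
    )


# ---------------------------------------------------------------------------
# WHO-Europe marketing model
# ---------------------------------------------------------------------------


class WHOThresholds(BaseModel):
    """Per-category rule: prohibited outright, or nutrient limits.

    Limits are maxima per 100 g/ml; a value exactly at the limit passes.
    """

    always_prohibited: bool = False
    max_total_fat_g: Optional[float] = Field(default=None, ge=0)
    max_saturated_fat_g: Optional[float] = Field(default=None, ge=0)
    max_total_sugars_g: Optional[float] = Field(default=None, ge=0)
    max_added_sugars_g: Optional[float] = Field(default=None, ge=0)
    max_salt_g: Optional[float] = Field(default=None, ge=0)
    max_energy_kj: Optional[float] = Field(default=None, ge=0)
    prohibit_non_sugar_sweeteners: bool = False

    @model_validator(mode="after")
    def _at_least_one_rule(self) -> "WHOThresholds":
        if not self.always_prohibited and not self.active_thresholds() and not (
            self.prohibit_non_sugar_sweeteners
        ):
            raise ValueError("category must be always_prohibited or carry at least one threshold")
        return self

    def active_thresholds(self) -> dict[str, float]:
        out = {}
        for name in (
            "max_total_fat_g",
            "max_saturated_fat_g",
            "max_total_sugars_g",
            "max_added_sugars_g",
            "max_salt_g",
            "max_energy_kj",
        ):
            limit = getattr(self, name)
            if limit is not None:
                out[name] = float(limit)
        return out


#: maps threshold name -> column of the products frame it constrains
_WHO_COLUMNS = {
    "max_total_fat_g": "total_fat_g",
    "max_saturated_fat_g": "saturated_fat_g",
    "max_total_sugars_g": "sugars_g",
    "max_added_sugars_g": "added_sugars_g",
    "max_salt_g": "salt_g",
    "max_energy_kj": "energy_kj",
}


class WHORuleTable(BaseModel):
    """Category rule table for the marketing-to-children decision."""

    version: str = "unversioned"
    nss_markers: frozenset[str] = frozenset({"sweetener"})
    categories: dict[str, WHOThresholds]

    @field_validator("categories")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("rule table has no categories")
        return v

    @classmethod
    def from_dict(cls, data: dict) -> "WHORuleTable":
        return cls.model_validate(data)

    @classmethod
    def from_yaml(cls, path) -> "WHORuleTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "WHORuleTable":
        text = resources.files("foodbench").joinpath("data/who_rules.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class WHODecision:
    """Marketing decision plus the complete list of violated rules."""

    permitted: bool
    violations: tuple[str, ...] = ()


def who_table(df: pd.DataFrame, rules: WHORuleTable) -> pd.DataFrame:
    """Vectorised WHO decision over a validated products frame.

    Every active threshold is evaluated (no short-circuiting); the
    ``who_violations`` column joins violated rules with ``;``.
    """
    cats = df["who_category"].astype(str)
    unknown = sorted(set(cats) - set(rules.categories))
    if unknown:
        raise UnknownCategoryError(f"unknown WHO category: {unknown[0]!r}")

    salt = _salt_column(df)
    permitted = np.ones(len(df), dtype=bool)
    violations = [[] for _ in range(len(df))]
    positions = {label: i for i, label in enumerate(df.index)}

    for cat, sub in df.groupby(cats, sort=False):
        rule = rules.categories[str(cat)]
        idx = [positions[label] for label in sub.index]
        if rule.always_prohibited:
            for i in idx:
                permitted[i] = False
                violations[i].append("category")
            continue
        for name, limit in rule.active_thresholds().items():
            col = _WHO_COLUMNS[name]
            values = salt.loc[sub.index] if col == "salt_g" else sub[col]
            missing = values.isna()
            if missing.any():
                pid = sub.loc[missing.index[missing], "product_id"].iloc[0]
                raise MissingNutrientError(
                    f"product '{pid}': nutrient '{col}' required by WHO threshold '{name}' is missing"
                )
            vals = values.to_numpy(float)
            over = vals > limit
            for j, i in enumerate(idx):
                if over[j]:
                    permitted[i] = False
                    violations[i].append(f"{name}:{vals[j]:g}>{limit:g}")
        if rule.prohibit_non_sugar_sweeteners:
            for j, i in enumerate(idx):
                markers = _markers_to_set(sub["ingredient_markers"].iloc[j])
                if markers & rules.nss_markers:
                    permitted[i] = False
                    violations[i].append("non_sugar_sweetener")

    return pd.DataFrame(
        {
            "permitted": permitted,
            "who_violations": [";".join(v) for v in violations],
        },
        index=df.index,
    )


def who_permitted(product: Product, rules: WHORuleTable) -> WHODecision:
    """Decide one product; see :func:`who_table`."""
    df = validate_products_frame(products_to_frame([product]))
    row = who_table(df, rules).iloc[0]
    viol = tuple(v for v in row["who_violations"].split(";") if v)
    return WHODecision(permitted=bool(row["permitted"]), violations=viol)


# ---------------------------------------------------------------------------
# NOVA
# ---------------------------------------------------------------------------


class NOVARules(BaseModel):
    """Marker-token and category-default rules mapping products to NOVA groups."""

    version: str = "unversioned"
    group4_markers: frozenset[str] = frozenset()
    category_groups: dict[str, int] = {}
    default_group: int = Field(default=3, ge=1, le=4)

    @field_validator("category_groups")
    @classmethod
    def _groups_in_range(cls, v):
        for cat, g in v.items():
            if not 1 <= int(g) <= 4:
                raise ValueError(f"NOVA group for category '{cat}' outside 1-4")
        return {k: int(g) for k, g in v.items()}

    @classmethod
    def from_yaml(cls, path) -> "NOVARules":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "NOVARules":
        text = resources.files("foodbench").joinpath("data/nova_rules.yaml").read_text()
        return cls.model_validate(yaml.safe_load(text))


def nova_table(df: pd.DataFrame, rules: NOVARules) -> pd.Series:
    """Vectorised NOVA group; override > group-4 markers > category default."""
    overrides = pd.to_numeric(df["nova_group_override"], errors="coerce")
    bad = overrides.dropna()[(overrides.dropna() < 1) | (overrides.dropna() > 4)]
    if len(bad):
        pid = df.loc[bad.index[0], "product_id"]
        raise ProfilingError(f"product '{pid}': nova_group_override outside 1-4")
    groups = df["who_category"].map(rules.category_groups).fillna(rules.default_group)
    has_marker = df["ingredient_markers"].map(lambda m: bool(_markers_to_set(m) & rules.group4_markers))
    groups = groups.where(~has_marker, 4)
    groups = groups.where(overrides.isna(), overrides)
    return groups.astype(int).rename("nova_group")


def nova_group(product: Product, rules: NOVARules) -> int:
    df = validate_products_frame(products_to_frame([product]))
    return int(nova_table(df, rules).iloc[0])


# ---------------------------------------------------------------------------
# Combined profiling
# ---------------------------------------------------------------------------


def profile_products(
    df: pd.DataFrame,
    who_rules: WHORuleTable | None = None,
    nova_rules: NOVARules | None = None,
) -> pd.DataFrame:
    """Classify every product under all three systems.

    Returns one row per product: identifiers, the Nutri-Score points
    breakdown and class, the WHO decision with violations, and the NOVA
    group.  ``displays_nutriscore`` is carried through for the labelling
    indicator.
    """
    who_rules = who_rules or WHORuleTable.default()
    nova_rules = nova_rules or NOVARules.default()
    df = validate_products_frame(df)
    keep = ["product_id", "company_id", "who_category", "is_beverage", "displays_nutriscore"]
    keep = [c for c in keep if c in df.columns]
    out = pd.concat(
        [
            df[keep].reset_index(drop=True),
            nutriscore_table(df).reset_index(drop=True),
            who_table(df, who_rules).reset_index(drop=True),
        ],
        axis=1,
    )
    out["nova_group"] = nova_table(df, nova_rules).reset_index(drop=True)
    return out
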