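"""Gelatin-Intralipid phantom recipes and recipe-defined water fractions.

A phantom batch is specified by component masses (grams): added distilled
water, gelatin powder, and Intralipid-20% stock.  The stock is itself mostly
water (80% by mass, configurable), so the recipe-defined *true* water
fraction exceeds the *added-water* fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from typing import IO

import pandas as pd

from .errors import DomainError, ParseError

_MASS_TOL_G = 1e-6


@dataclass(frozen=True)
class PhantomRecipe:
    label: str
    m_water: float
    m_gelatin: float
    m_il: float
    il_water_mass_fraction: float = 0.8
    il_stock_pct: float | None = None  # stock loading, % of batch mass (metadata)

    def __post_init__(self):
        if min(self.m_water, self.m_gelatin, self.m_il) < 0:
            raise DomainError(f"{self.label}: component masses must be >= 0")
        if not 0.0 <= self.il_water_mass_fraction <= 1.0:
            raise DomainError(f"{self.label}: il_water_mass_fraction must lie in [0, 1]")

    @property
    def m_total(self) -> float:
        return self.m_water + self.m_gelatin + self.m_il

    def validate_total(self, expected_total: float) -> None:
        if abs(self.m_total - expected_total) > _MASS_TOL_G:
            raise DomainError(
                f"{self.label}: masses sum to {self.m_total} g, expected {expected_total} g"
            )


def true_water_fraction(recipe: PhantomRecipe) -> float:
    """Recipe-defined water fraction: (m_water + c*m_IL)/m_total with c the
    assumed water mass fraction of the Intralipid stock (default 0.8)."""
    if recipe.m_total <= 0:
        raise DomainError(f"{recipe.label}: total mass must be positive")
    fw = (recipe.m_water + recipe.il_water_mass_fraction * recipe.m_il) / recipe.m_total
    return fw


def added_water_fraction(recipe: PhantomRecipe) -> float:
    """Added distilled water divided by total batch mass."""
    if recipe.m_total <= 0:
        raise DomainError(f"{recipe.label}: total mass must be positive")
    return recipe.m_water / recipe.m_total


def load_recipe_table(path_or_buf: str | PathLike | IO) -> list[PhantomRecipe]:
    """Parse a recipe CSV with columns label, m_water_g, m_gelatin_g, m_il_g
    (optional il_water_mass_fraction, il_stock_pct).  Rejects malformed rows."""
    try:
        df = pd.read_csv(path_or_buf, comment="#")
    except pd.errors.EmptyDataError:
        return []
    required = {"label", "m_water_g", "m_gelatin_g", "m_il_g"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"recipe table missing columns: {sorted(missing)}")
    recipes: list[PhantomRecipe] = []
    for i, row in df.iterrows():
        kwargs = {}
        if "il_water_mass_fraction" in df.columns and pd.notna(row["il_water_mass_fraction"]):
            kwargs["il_water_mass_fraction"] = float(row["il_water_mass_fraction"])
        if "il_stock_pct" in df.columns and pd.notna(row["il_stock_pct"]):
            kwargs["il_stock_pct"] = float(row["il_stock_pct"])
        try:
            recipes.append(
                PhantomRecipe(
                    label=str(row["label"]),
                    m_water=float(row["m_water_g"]),
                    m_gelatin=float(row["m_gelatin_g"]),
                    m_il=float(row["m_il_g"]),
                    **kwargs,
                )
            )
        except (DomainError, ValueError, TypeError) as exc:
            raise ParseError(f"recipe table row {i} ({row.get('label')!r}): {exc}") from exc
    return recipes


def packaged_recipes() -> list[PhantomRecipe]:
    """The eight packaged 15.0 g phantom recipes (two Intralipid loadings)."""
    with resources.files("swirsr.data").joinpath("phantom_recipes.csv").open() as fh:
        recipes = load_recipe_table(fh)
    for r in recipes:
        r.validate_total(15.0)
    return recipes


def packaged_recipe_frame() -> pd.DataFrame:
    """Packaged recipe table as a DataFrame, including the printed nominal
    true-water-content column used in round-trip tests."""
    with resources.files("swirsr.data").joinpath("phantom_recipes.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
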