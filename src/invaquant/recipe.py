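"""Matrix-gel dilution arithmetic for the embedding step.

Spheroids are embedded in one of three gels — collagen I, growth-factor-
reduced Matrigel, or agar — by mixing a concentrated stock with medium,
buffer and the spheroid suspension. The only computation is conservation
of mass: C_final = C_stock · V_stock / V_total. Displayed values are
rounded to two significant figures; full precision is kept in JSON.
"""

from __future__ import annotations

from typing import Iterable

from .core import GelRecipe, round_sig

__all__ = [
    "final_concentration",
    "collagen_recipe",
    "matrigel_recipe",
    "agar_recipe",
    "STANDARD_RECIPES",
]


def final_concentration(
    stock_conc: float,
    stock_vol: float,
    other_vols: Iterable[float],
) -> float:
    """Dilute ``stock_conc`` (mg/ml or % w/v) of ``stock_vol`` μl into the mix.

    ``other_vols`` are the remaining component volumes in μl. Returns the
    final concentration in the stock's units, unrounded.
    """
    other = list(other_vols)
    if stock_vol <= 0:
        raise ValueError(f"stock volume must be > 0 μl, got {stock_vol!r}")
    if any(v < 0 for v in other):
        raise ValueError("component volumes must be >= 0 μl")
    total = stock_vol + sum(other)
    if total <= 0:
        raise ValueError("total volume must be > 0 μl")
    return stock_conc * stock_vol / total


def collagen_recipe(scale: float = 1.0) -> GelRecipe:
    """Standard collagen-I embedding mix: 3 mg/ml stock diluted to 1.6 mg/ml."""
    return GelRecipe(
        name="collagen",
        stock_concentration=3.0,  # mg/ml
        stock_volume=533.0 * scale,  # μl
        other_volumes=(
            ("DMEM", 340.0 * scale),
            ("NaHCO3 7.5%", 27.0 * scale),
            ("spheroid suspension", 100.0 * scale),
        ),
    )


def matrigel_recipe(scale: float = 1.0) -> GelRecipe:
    """Standard Matrigel GFR embedding mix: 10.9 mg/ml stock diluted to 5 mg/ml."""
    return GelRecipe(
        name="matrigel",
        stock_concentration=10.9,  # mg/ml
        stock_volume=460.0 * scale,
        other_volumes=(
            ("DMEM", 440.0 * scale),
            ("spheroid suspension", 100.0 * scale),
        ),
    )


def agar_recipe(scale: float = 1.0) -> GelRecipe:
    """Standard agar embedding mix: 0.6% (w/v) stock diluted to 0.3%."""
    return GelRecipe(
        name="agar",
        stock_concentration=0.6,  # % w/v
        stock_volume=500.0 * scale,
        other_volumes=(
            ("DMEM", 375.0 * scale),
            ("NaHCO3 7.5%", 25.0 * scale),
            ("spheroid suspension", 100.0 * scale),
        ),
    )


STANDARD_RECIPES = {
    "collagen": collagen_recipe,
    "matrigel": matrigel_recipe,
    "agar": agar_recipe,
}
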