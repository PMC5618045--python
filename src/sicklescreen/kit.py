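"""Kit bill of materials, buffer recipes, cost arithmetic, and configuration.

The distributable test kit consists of off-the-shelf disposable components
and food-grade reagents.  The hemoglobin solubility buffer combines a
concentrated potassium phosphate buffer (1.24 M monobasic + 1.25 M dibasic
= 2.49 M total phosphate), saponin (4 g/L) to lyse red cells, and a reducing
agent — sodium hydrosulfite (HS, 3% w/v) or sodium metabisulfite
(MS, 10/15/20% w/v) — to deoxygenate the released hemoglobin.

Costs are carried as exact decimals so cent-level sums have no float drift.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Any, Iterable, Mapping

import yaml

from .errors import ConfigurationError, ValidationError

# ---------------------------------------------------------------------------
# Cost ledger
# ---------------------------------------------------------------------------

#: Per-test component costs (USD) of the distributable kit.
DEFAULT_KIT_COMPONENTS: tuple[tuple[str, str], ...] = (
    ("foil pouch", "0.02"),
    ("reagent dropper", "0.05"),
    ("blood dropper", "0.08"),
    ("chromatography paper", "0.01"),
    ("reagent tube", "0.03"),
    ("food grade reagents", "0.02"),
)


@dataclass(frozen=True)
class CostLedger:
    """Named per-test component costs in USD."""

    components: tuple[tuple[str, Decimal], ...]

    def __post_init__(self) -> None:
        for name, cost in self.components:
            if cost < 0:
                raise ValidationError(f"negative cost for {name!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Any]]) -> "CostLedger":
        return cls(tuple((str(n), Decimal(str(c))) for n, c in pairs))


DEFAULT_COST_LEDGER = CostLedger.from_pairs(DEFAULT_KIT_COMPONENTS)


def total_cost(ledger: CostLedger) -> Decimal:
    """Exact decimal sum of all component costs (USD per test)."""
    if not ledger.components:
        raise ValidationError("cost ledger is empty")
    return sum((cost for _, cost in ledger.components), Decimal("0"))


# ---------------------------------------------------------------------------
# Buffer recipes
# ---------------------------------------------------------------------------

_MS_ALLOWED_PERCENT = (10.0, 15.0, 20.0)
_HS_PERCENT = 3.0


@dataclass(frozen=True)
class BufferRecipe:
    """Hemoglobin solubility buffer composition."""

    monobasic_molarity: float = 1.24
    dibasic_molarity: float = 1.25
    saponin_g_per_l: float = 4.0
    reducing_agent: str = "MS"
    reducing_agent_percent_wv: float = 15.0

    def __post_init__(self) -> None:
        for name in ("monobasic_molarity", "dibasic_molarity", "saponin_g_per_l",
                     "reducing_agent_percent_wv"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        agent = self.reducing_agent.upper()
        if agent == "MS":
            if self.reducing_agent_percent_wv not in _MS_ALLOWED_PERCENT:
                raise ValidationError(
                    f"MS concentration must be one of {_MS_ALLOWED_PERCENT} % w/v"
                )
        elif agent == "HS":
            if self.reducing_agent_percent_wv != _HS_PERCENT:
                raise ValidationError(f"HS concentration must be {_HS_PERCENT} % w/v")
        else:
            raise ValidationError(f"unknown reducing agent {self.reducing_agent!r}")


def buffer_molarity(recipe: BufferRecipe) -> float:
    """Total phosphate molarity: monobasic + dibasic (mol/L)."""
    return recipe.monobasic_molarity + recipe.dibasic_molarity


# ---------------------------------------------------------------------------
# Configuration layer
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "alpha": 0.05,
    "class_scheme": "three_class",
    "buffer": {
        "monobasic_molarity": 1.24,
        "dibasic_molarity": 1.25,
        "saponin_g_per_l": 4.0,
        "reducing_agent": "MS",
        "reducing_agent_percent_wv": 15.0,
    },
    "cost_ledger": [list(item) for item in DEFAULT_KIT_COMPONENTS],
    "generator": {
        "n_per_class": 20,
        "hbs_levels": [0.0, 10.0, 20.0, 40.0, 80.0],
        "formulation": "MS",
        "storage": "dry",
        "reagent_age_days": 0.0,
        "noise_sd": 2.0,
        "shape_jitter": 0.0,
        "n_observers": 3,
        "replicates": 1,
        "observer_slope": 40.0,
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | pathlib.Path | None = None) -> dict[str, Any]:
    """Load a YAML config file merged over the documented defaults."""
    if path is None:
        return _deep_merge(DEFAULT_CONFIG, {})
    path = pathlib.Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    try:
        loaded = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(loaded, Mapping):
        raise ConfigurationError("config root must be a mapping")
    return _deep_merge(DEFAULT_CONFIG, loaded)


def ledger_from_config(config: Mapping[str, Any]) -> CostLedger:
    return CostLedger.from_pairs(tuple((n, c) for n, c in config["cost_ledger"]))


def recipe_from_config(config: Mapping[str, Any]) -> BufferRecipe:
    return BufferRecipe(**config["buffer"])
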