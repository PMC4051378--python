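"""Packaged fixtures: the 15-run uniform-design dataset, factor ranges,
the two published regression models and the verification-table constants."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .design import FactorSpec
from .regress import PolyModel

__all__ = [
    "load_table1",
    "load_factors",
    "published_model",
    "load_verification_constants",
]


def _data(name: str):
    return resources.files("fermsurro.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The 15-run U_15(15^5) experiment: factors X1..X5 in physical units,
    Y1 (algicidal ratio, %) and Y2 (dry mycelial weight, g/100 mL)."""
    with _data("table1.csv").open() as f:
        return pd.read_csv(f, index_col="run")


def load_factors() -> list[FactorSpec]:
    """The five factor specifications spanning the design box."""
    with _data("factors.json").open() as f:
        raw = json.load(f)
    return [
        FactorSpec(
            name=d["name"],
            minimum=d["minimum"],
            maximum=d["maximum"],
            n_levels=d["n_levels"],
            units=d["units"],
            label=d.get("label", ""),
        )
        for d in raw
    ]


def published_model(response: str) -> PolyModel:
    """The published quadratic model for ``"Y1"`` (fraction scale) or ``"Y2"``."""
    response = response.upper()
    if response not in ("Y1", "Y2"):
        raise ValueError("response must be 'Y1' or 'Y2'")
    with _data(f"model_{response.lower()}.json").open() as f:
        return PolyModel.from_dict(json.load(f))


def load_verification_constants() -> dict:
    """Verification-experiment constants (means, sds, predictions)."""
    with _data("table3.json").open() as f:
        return json.load(f)
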