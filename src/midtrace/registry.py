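"""Metabolite registry: parent formulas, derivatization, tracer carbons.

The registry tells the correction stage which elemental composition each
measured ion has.  For TBDMS-derivatized metabolites the monitored ion is
the M-57 fragment of the fully derivatized molecule; underivatized species
(e.g. acylcarnitines measured by LC-MS) use the parent formula directly.
Fragment compositions can also be overridden explicitly when a metabolite
is monitored on a non-default fragment.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .chem import (
    DEFAULT_ISOTOPES,
    ElementalFormula,
    FormulaError,
    IsotopeTable,
    parse_formula,
    tbdms_m57_fragment,
)

__all__ = ["MetaboliteEntry", "Registry", "load_registry", "default_registry"]

_REGISTRY_COLUMNS = [
    "name",
    "parent_formula",
    "derivatization",
    "fragment_override_formula",
    "n_tracer_carbons",
]


@dataclass(frozen=True)
class MetaboliteEntry:
    name: str
    parent_formula: str
    derivatization: str  # "tbdms:<n_sites>" or "none"
    fragment_override_formula: str | None
    n_tracer_carbons: int

    def fragment(self, isotopes: IsotopeTable = DEFAULT_ISOTOPES) -> ElementalFormula:
        """Elemental composition of the monitored ion."""
        if self.fragment_override_formula:
            return parse_formula(self.fragment_override_formula, isotopes)
        parent = parse_formula(self.parent_formula, isotopes)
        if self.derivatization == "none":
            return parent
        if self.derivatization.startswith("tbdms:"):
            n_sites = int(self.derivatization.split(":", 1)[1])
            return tbdms_m57_fragment(parent, n_sites)
        raise FormulaError(
            f"{self.name}: unknown derivatization {self.derivatization!r} "
            "(expected 'tbdms:<n>' or 'none')"
        )

    def __post_init__(self) -> None:
        if self.n_tracer_carbons < 1:
            raise ValueError(f"{self.name}: n_tracer_carbons must be >= 1")
        frag = self.fragment()
        if frag["C"] < self.n_tracer_carbons:
            raise ValueError(
                f"{self.name}: fragment {frag} has {frag['C']} carbons but "
                f"{self.n_tracer_carbons} tracer carbons declared"
            )


class Registry(dict):
    """Mapping metabolite name -> :class:`MetaboliteEntry`."""

    def __missing__(self, key: str) -> MetaboliteEntry:
        raise KeyError(
            f"metabolite {key!r} not in registry (known: {sorted(self)[:10]}...)"
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Registry":
        missing = set(_REGISTRY_COLUMNS[:3]) - set(df.columns)
        if missing:
            raise ValueError(f"registry missing columns: {sorted(missing)}")
        reg = cls()
        for row in df.itertuples(index=False):
            override = getattr(row, "fragment_override_formula", None)
            if pd.isna(override) or override == "":
                override = None
            entry = MetaboliteEntry(
                name=str(row.name),
                parent_formula=str(row.parent_formula),
                derivatization=str(row.derivatization),
                fragment_override_formula=override,
                n_tracer_carbons=int(row.n_tracer_carbons),
            )
            reg[entry.name] = entry
        return reg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "parent_formula": e.parent_formula,
                    "derivatization": e.derivatization,
                    "fragment_override_formula": e.fragment_override_formula or "",
                    "n_tracer_carbons": e.n_tracer_carbons,
                }
                for e in self.values()
            ],
            columns=_REGISTRY_COLUMNS,
        )


def load_registry(path: str | Path) -> Registry:
    """Load a registry from CSV or YAML (list of entry mappings)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            records = yaml.safe_load(fh)
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    return Registry.from_frame(df)


def default_registry() -> Registry:
    """Curated registry for the metabolites covered by the tracing scenarios.

    TBDMS site counts follow the usual GC-MS derivatization chemistry (one
    site per carboxyl/hydroxyl/amine proton that is silylated in practice);
    acylcarnitines are listed underivatized as measured by LC-MS.
    """
    ref = importlib.resources.files("midtrace.data") / "default_registry.csv"
    with importlib.resources.as_file(ref) as path:
        return load_registry(path)
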