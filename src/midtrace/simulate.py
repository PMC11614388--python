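"""Synthetic-data generator for every input the pipeline consumes.

Generates (a) isotopologue peak-area tables from declared labeling
scenarios — the forward model of the correction stage: raw areas are the
true pool times the natural-abundance-convolved pattern of the true MID,
under multiplicative lognormal noise with an additive baseline — and (b)
two-group abundance tables with declared fold-change effects, emulating the
study designs of the tracing experiments (n=3/group), conditioned-media
tables (n=6/group), and CSF tables (n=10/group).  Ground truth is always
emitted alongside the data so recovery tests never reach into the
generator's internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import DEFAULT_ISOTOPES, IsotopeTable
from .correction import build_correction_matrix
from .datasets import load_csf_reference, load_media_reference
from .io import channel_name
from .registry import Registry, default_registry

__all__ = [
    "ScenarioEntry",
    "LabelingScenario",
    "NoiseModel",
    "StudyDesign",
    "simulate_isotopologue_areas",
    "simulate_two_group_table",
    "tracing_scenarios",
    "bundled_fixture",
    "FIXTURES",
]

#: default cell count per well and internal-standard spike (area units)
DEFAULT_CELLS = 2e6
DEFAULT_IS_AREA = 750.0


@dataclass(frozen=True)
class ScenarioEntry:
    """Declared truth for one metabolite: per-group true MID and pool."""

    metabolite: str
    mids: Mapping[str, np.ndarray]  # group -> MID over m+0..m+n_tracer
    pools: Mapping[str, float]  # group -> total pool, raw-area units

    def __post_init__(self) -> None:
        for group, mid in self.mids.items():
            mid = np.asarray(mid, dtype=float)
            if np.any(mid < 0) or abs(mid.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.metabolite}/{group}: true MID must be non-negative and sum to 1"
                )
        if any(p < 0 for p in self.pools.values()):
            raise ValueError(f"{self.metabolite}: pools must be >= 0")


@dataclass(frozen=True)
class LabelingScenario:
    """A set of declared per-metabolite truths plus the registry resolving them."""

    entries: tuple[ScenarioEntry, ...]
    registry: Registry
    compartment: str = "cell"

    def __post_init__(self) -> None:
        for e in self.entries:
            self.registry[e.metabolite]  # raises for unresolvable entries


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal channel noise + additive baseline + IS noise.

    ``cv`` is the coefficient of variation of the mean-one lognormal
    multiplier applied independently per channel; peak areas are positive
    and right-skewed, which the lognormal reproduces.  ``cv=0`` gives the
    exact noise-free forward model.
    """

    cv: float = 0.15
    baseline: float = 0.0
    is_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.cv < 0 or self.is_cv < 0 or self.baseline < 0:
            raise ValueError("noise parameters must be >= 0")

    def multiplier(self, rng: np.random.Generator, size, cv: float | None = None) -> np.ndarray:
        cv = self.cv if cv is None else cv
        if cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


@dataclass(frozen=True)
class StudyDesign:
    """Group sizes and per-sample constants of a simulated experiment."""

    groups: Mapping[str, int]
    cells: float = DEFAULT_CELLS
    is_area: float = DEFAULT_IS_AREA
    effects: Mapping[str, float] = field(default_factory=dict)  # metabolite -> FC

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs size >= 2")
        if any(fc <= 0 for fc in self.effects.values()):
            raise ValueError("effect fold changes must be > 0")


def _sample_ids(design: StudyDesign, compartment: str) -> list[tuple[str, str]]:
    return [
        (f"{group}_{compartment}_{k + 1}", group)
        for group in design.groups
        for k in range(design.groups[group])
    ]


def simulate_isotopologue_areas(
    scenario: LabelingScenario,
    noise: NoiseModel,
    design: StudyDesign,
    seed: int,
    isotopes: IsotopeTable = DEFAULT_ISOTOPES,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a raw isotopologue area table under the forward model.

    Returns ``(areas, design_sheet, truth)``: per sample and metabolite the
    raw areas are ``pool * (A @ true_mid)`` times lognormal channel noise
    plus the additive baseline, with an internal-standard area per sample.
    The truth dict records every generator input for recovery tests.
    """
    rng = np.random.default_rng(seed)
    ids = _sample_ids(design, scenario.compartment)
    areas: dict[str, np.ndarray] = {}
    for entry in scenario.entries:
        reg = scenario.registry[entry.metabolite]
        A = build_correction_matrix(
            reg.fragment(isotopes), reg.n_tracer_carbons, purity=1.0, isotopes=isotopes
        )
        K = A.K
        cols = np.zeros((len(ids), K + 1))
        for i, (_, group) in enumerate(ids):
            mid = np.asarray(entry.mids[group], dtype=float)
            if mid.size != reg.n_tracer_carbons + 1:
                raise ValueError(
                    f"{entry.metabolite}/{group}: MID length {mid.size} != "
                    f"n_tracer+1 = {reg.n_tracer_carbons + 1}"
                )
            expected = entry.pools[group] * (A.matrix @ mid)
            cols[i] = expected * noise.multiplier(rng, K + 1) + noise.baseline
        for j in range(K + 1):
            areas[channel_name(entry.metabolite, j)] = cols[:, j]

    is_areas = design.is_area * noise.multiplier(rng, len(ids), cv=noise.is_cv)
    areas_df = pd.DataFrame(areas, index=pd.Index([s for s, _ in ids], name="sample"))
    design_df = pd.DataFrame(
        {
            "sample": [s for s, _ in ids],
            "group": [g for _, g in ids],
            "compartment": scenario.compartment,
            "cells": design.cells,
            "is_area": is_areas,
        }
    ).set_index("sample")
    truth = {
        "compartment": scenario.compartment,
        "seed": seed,
        "noise": {"cv": noise.cv, "baseline": noise.baseline, "is_cv": noise.is_cv},
        "metabolites": {
            e.metabolite: {
                "mids": {g: list(map(float, np.asarray(m))) for g, m in e.mids.items()},
                "pools": {g: float(p) for g, p in e.pools.items()},
            }
            for e in scenario.entries
        },
    }
    return areas_df, design_df, truth


def simulate_two_group_table(
    design: StudyDesign,
    noise: NoiseModel,
    baselines: Mapping[str, float],
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a metabolite x sample two-group abundance table.

    ``design.groups`` must name exactly two groups; the first is the
    control.  Each abundance is lognormal around ``baseline`` (control) or
    ``baseline * FC`` (treated, FC from ``design.effects``, default 1).
    """
    if len(design.groups) != 2:
        raise ValueError("two-group simulation needs exactly two groups")
    if not baselines:
        raise ValueError("baselines must be non-empty")
    control, treated = list(design.groups)
    rng = np.random.default_rng(seed)
    ids = [(f"{g}_{k + 1}", g) for g in design.groups for k in range(design.groups[g])]
    rows = {}
    for met in baselines:
        fc = design.effects.get(met, 1.0)
        means = np.array(
            [baselines[met] * (fc if g == treated else 1.0) for _, g in ids]
        )
        rows[met] = means * noise.multiplier(rng, len(ids))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[s for s, _ in ids])
    table.index.name = "metabolite"
    truth = {
        "seed": seed,
        "control": control,
        "treated": treated,
        "noise_cv": noise.cv,
        "baselines": {m: float(v) for m, v in baselines.items()},
        "effects": {m: float(design.effects.get(m, 1.0)) for m in baselines},
    }
    return table, truth


# ---------------------------------------------------------------------------
# bundled fixtures


def _mid(n: int, **mass: float) -> np.ndarray:
    """MID over m+0..m+n with the named shifts set and the rest on m+0."""
    v = np.zeros(n + 1)
    for key, frac in mass.items():
        v[int(key.lstrip("m_"))] = frac
    v[0] = 1.0 - v[1:].sum()
    if v[0] < -1e-12:
        raise ValueError("labeled fractions exceed 1")
    return v


def tracing_scenarios(name: str, registry: Registry) -> dict[str, LabelingScenario]:
    """Per-compartment scenarios of the two tracing fixtures.

    Labeled fractions encode the qualitative study effects: palmitate
    pretreatment raises beta-oxidation products and the glutamate/itaconate/
    succinate shunt, and raises glycolytic labeling in the glucose tracing.
    """
    if name == "palmitate_4h":
        cell = [
            ("palmitoylcarnitine", 23, {"m_16": (0.40, 0.60)}, (2.0, 3.0)),
            ("acetylcarnitine", 9, {"m_2": (0.25, 0.45)}, (40.0, 50.0)),
            ("acetylserine", 5, {"m_2": (0.10, 0.20)}, (8.0, 8.0)),
            ("glutamate", 5, {"m_2": (0.15, 0.30)}, (400.0, 420.0)),
            ("alpha_ketoglutarate", 5, {"m_2": (0.15, 0.28)}, (60.0, 60.0)),
            ("succinate", 4, {"m_2": (0.10, 0.15)}, (90.0, 110.0)),
            ("fumarate", 4, {"m_2": (0.08, 0.08)}, (30.0, 30.0)),
            ("malate", 4, {"m_2": (0.08, 0.08)}, (120.0, 120.0)),
            ("itaconate", 5, {"m_1": (0.05, 0.15)}, (5.0, 12.0)),
        ]
        media = [
            ("glutamate", 5, {"m_2": (0.10, 0.25)}, (50.0, 120.0)),
            ("itaconate", 5, {"m_1": (0.04, 0.12)}, (2.0, 8.0)),
            ("succinate", 4, {"m_2": (0.06, 0.12)}, (20.0, 45.0)),
        ]
        compartments = {"cell": cell, "media": media}
    elif name == "glucose_6h":
        cell = [
            ("glucose", 6, {"m_6": (0.50, 0.70)}, (900.0, 1100.0)),
            ("lactate", 3, {"m_3": (0.30, 0.45)}, (600.0, 800.0)),
            ("pyruvate", 3, {"m_3": (0.28, 0.40)}, (80.0, 95.0)),
            ("citrate", 6, {"m_2": (0.12, 0.20)}, (150.0, 150.0)),
            ("alpha_ketoglutarate", 5, {"m_2": (0.10, 0.18)}, (60.0, 60.0)),
            ("malate", 4, {"m_2": (0.10, 0.15)}, (120.0, 120.0)),
            ("glutamate", 5, {"m_2": (0.12, 0.22)}, (400.0, 430.0)),
        ]
        media = [
            ("lactate", 3, {"m_3": (0.25, 0.40)}, (300.0, 500.0)),
            ("glutamate", 5, {"m_2": (0.08, 0.18)}, (40.0, 90.0)),
            ("itaconate", 5, {"m_1": (0.03, 0.10)}, (2.0, 6.0)),
            ("succinate", 4, {"m_2": (0.05, 0.10)}, (15.0, 35.0)),
            ("citrate", 6, {"m_2": (0.06, 0.12)}, (25.0, 40.0)),
        ]
        # recipient neurons take up a fixed fraction of what the media holds
        alpha = 0.3
        recipient = [
            (met, n, {k: v for k, v in mids.items()}, tuple(alpha * p for p in pools))
            for met, n, mids, pools in media
        ]
        compartments = {"cell": cell, "media": media, "recipient-cell": recipient}
    else:
        raise KeyError(name)

    scenarios = {}
    for compartment, spec_rows in compartments.items():
        entries = []
        for met, n, shifts, pools in spec_rows:
            mids = {
                "BSA": _mid(n, **{k: v[0] for k, v in shifts.items()}),
                "PA": _mid(n, **{k: v[1] for k, v in shifts.items()}),
            }
            entries.append(
                ScenarioEntry(
                    metabolite=met,
                    mids=mids,
                    pools={"BSA": pools[0], "PA": pools[1]},
                )
            )
        scenarios[compartment] = LabelingScenario(
            entries=tuple(entries), registry=registry, compartment=compartment
        )
    return scenarios


#: fixture name -> short description
FIXTURES = {
    "palmitate_4h": "U-13C-palmitate tracing, BSA vs PA pretreatment, n=3/group, cell+media",
    "glucose_6h": "U-13C-glucose tracing, BSA vs PA, n=3/group, cell+media+recipient neurons",
    "csf_3dHFD": "CSF-style two-group abundance table, control vs 3-day HFD, n=10/group",
    "media_24h": "conditioned-media two-group abundance table, BSA vs PA, n=6/group",
}

#: per-fixture noise CVs (cell compartments are tighter than media)
_FIXTURE_CV = {"palmitate_4h": 0.15, "glucose_6h": 0.10, "csf_3dHFD": 0.20, "media_24h": 0.25}


def bundled_fixture(
    name: str,
    seed: int,
    out_dir: str | Path,
    registry: Registry | None = None,
) -> dict[str, Path]:
    """Write a self-contained input set for one of the named fixtures.

    Tracing fixtures (``palmitate_4h``, ``glucose_6h``) emit
    ``areas.csv`` + ``design.csv`` + ``registry.csv``; table fixtures
    (``csf_3dHFD``, ``media_24h``) emit ``abundance.csv`` + ``groups.csv``.
    All emit ``truth.json``.  Identical seeds give byte-identical files.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; options: {sorted(FIXTURES)}")
    registry = registry if registry is not None else default_registry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cv = _FIXTURE_CV[name]

    if name in {"palmitate_4h", "glucose_6h"}:
        noise = NoiseModel(cv=cv, baseline=0.0, is_cv=0.05)
        design = StudyDesign(groups={"BSA": 3, "PA": 3})
        scenarios = tracing_scenarios(name, registry)
        area_frames, design_frames, truth_parts = [], [], {}
        for i, (compartment, scenario) in enumerate(scenarios.items()):
            a, d, t = simulate_isotopologue_areas(scenario, noise, design, seed=seed + i)
            area_frames.append(a)
            design_frames.append(d)
            truth_parts[compartment] = t
        areas = pd.concat(area_frames).fillna(0.0)
        designs = pd.concat(design_frames)
        paths["areas"] = out_dir / "areas.csv"
        areas.to_csv(paths["areas"])
        paths["design"] = out_dir / "design.csv"
        designs.to_csv(paths["design"])
        paths["registry"] = out_dir / "registry.csv"
        registry.to_frame().to_csv(paths["registry"], index=False)
        truth: dict = {"fixture": name, "seed": seed, "compartments": truth_parts}
    else:
        if name == "csf_3dHFD":
            ref = load_csf_reference()
            groups = {"CT": 10, "HFD 3d": 10}
            effects = {met: float(ref.loc[met, "FC"]) for met in ref.index}
            baselines = {met: 1000.0 * (i + 1) for i, met in enumerate(ref.index)}
        else:  # media_24h
            ref = load_media_reference()
            groups = {"BSA": 6, "PA": 6}
            effects, baselines = {}, {}
            for met in ref.index:
                bsa, pa = float(ref.loc[met, "bsa_mean"]), float(ref.loc[met, "pa_mean"])
                if bsa <= 0 or pa <= 0:
                    continue  # zero-mean rows cannot seed a lognormal
                baselines[met] = bsa
                effects[met] = pa / bsa
        design = StudyDesign(groups=groups, effects=effects)
        table, truth = simulate_two_group_table(
            design, NoiseModel(cv=cv), baselines, seed=seed
        )
        truth = {"fixture": name, **truth}
        paths["abundance"] = out_dir / "abundance.csv"
        table.to_csv(paths["abundance"])
        groups_df = pd.DataFrame(
            {"sample": list(table.columns), "group": [s.rsplit("_", 1)[0] for s in table.columns]}
        )
        paths["groups"] = out_dir / "groups.csv"
        groups_df.to_csv(paths["groups"], index=False)

    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
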