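"""Whole-table correction: raw areas + design + registry -> tidy MID table."""

from __future__ import annotations

import logging

import pandas as pd

from .chem import DEFAULT_ISOTOPES, IsotopeTable
from .correction import (
    DEFAULT_RESIDUAL_THRESHOLD,
    build_correction_matrix,
    correct_mid,
    fractional_enrichment,
    normalize_abundance,
)
from .io import area_matrix, parse_channel
from .registry import Registry

__all__ = ["correct_area_table"]

logger = logging.getLogger(__name__)


def correct_area_table(
    areas: pd.DataFrame,
    design: pd.DataFrame,
    registry: Registry,
    purity: float = 1.0,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    isotopes: IsotopeTable = DEFAULT_ISOTOPES,
) -> pd.DataFrame:
    """Correct every metabolite of every sample and return a tidy frame.

    One output row per (sample, metabolite, isotopologue) with columns:
    ``mid`` (corrected fraction), ``norm_abundance`` (corrected pool x
    fraction, relative to internal standard, per 10^6 cells), ``pool``,
    ``enrichment``, ``residual``, ``flagged``, plus the design columns
    ``group`` and ``compartment``.  Samples present in the area table but
    absent from the design (or vice versa) are an error.
    """
    missing = set(areas.index) - set(design.index)
    if missing:
        raise ValueError(f"samples missing from design sheet: {sorted(missing)}")
    design = design.loc[areas.index]

    metabolites = sorted({parse_channel(c)[0] for c in areas.columns})
    rows: list[dict] = []
    for met in metabolites:
        entry = registry[met]
        A = build_correction_matrix(
            entry.fragment(isotopes), entry.n_tracer_carbons, purity=purity, isotopes=isotopes
        )
        mat, sample_ids = area_matrix(areas, met)
        for i, sample in enumerate(sample_ids):
            if mat[i].sum() == 0:
                # metabolite not measured in this sample (e.g. other compartment)
                logger.debug("skipping %s in %s: all-zero areas", met, sample)
                continue
            mid = correct_mid(
                mat[i], A, residual_threshold=residual_threshold, label=f"{sample}:{met}"
            )
            enrich = fractional_enrichment(mid, entry.n_tracer_carbons)
            is_area = float(design.loc[sample, "is_area"])
            cells = float(design.loc[sample, "cells"])
            for j, frac in enumerate(mid.fractions):
                rows.append(
                    {
                        "sample": sample,
                        "metabolite": met,
                        "isotopologue": j,
                        "mid": float(frac),
                        "norm_abundance": normalize_abundance(
                            mid.pool * float(frac), is_area, cells
                        ),
                        "pool": mid.pool,
                        "enrichment": enrich,
                        "residual": mid.residual,
                        "flagged": mid.flagged,
                        "group": design.loc[sample, "group"],
                        "compartment": design.loc[sample, "compartment"],
                    }
                )
    tidy = pd.DataFrame(rows)
    # per-sample MIDs must be invariant to sample order; sort for stable output
    return tidy.sort_values(["metabolite", "sample", "isotopologue"]).reset_index(drop=True)
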