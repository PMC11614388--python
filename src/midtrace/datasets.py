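"""Bundled reference summary tables.

Two small CSVs ship with the package and serve as worked-example inputs
and as ground truth for the synthetic fixtures:

* ``csf_reference`` — per-metabolite differential summary of a CSF
  targeted-metabolomics comparison (control vs 3-day high-fat diet,
  n=10/group): fold change, log2FC, p, -log10 p, and enrichment call.
* ``media_reference`` — per-metabolite group summaries (mean, SD) of
  metabolites released into conditioned media by BSA- vs palmitate-treated
  cells (n=6/group), with rank-sum p and FDR q as printed (p/q are kept as
  strings because censored values such as ">0.9" appear).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_csf_reference", "load_media_reference"]


def _load(name: str, **kwargs) -> pd.DataFrame:
    ref = importlib.resources.files("midtrace.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, **kwargs)


def load_csf_reference() -> pd.DataFrame:
    """CSF differential summary table, indexed by metabolite."""
    return _load("csf_reference.csv").set_index("metabolite")


def load_media_reference() -> pd.DataFrame:
    """Conditioned-media group-summary table, indexed by metabolite."""
    return _load("media_reference.csv", dtype={"p_value": str, "q_value": str}).set_index(
        "metabolite"
    )
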