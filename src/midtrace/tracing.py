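"""Experiment-level tracing readouts: labeling summaries, group contrasts,
and conditioned-media transfer tables.

A tracing experiment compares two pretreatment groups (e.g. BSA-control vs
palmitate) across compartments: intracellular metabolites, metabolites
released into the media, and — in media-transfer experiments — metabolites
taken up by recipient cells incubated with the conditioned media.  Figure
readouts are per-group mean +/- SEM of either a MID fraction or a
normalized labeled abundance, compared by a two-tailed Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabelReadout",
    "summarize_labeling",
    "compare_conditions",
    "media_transfer_table",
]

_MODES = {"fraction": "mid", "relative_abundance": "norm_abundance"}


@dataclass(frozen=True)
class LabelReadout:
    """Per-group values of one (metabolite, isotopologue) labeling quantity."""

    metabolite: str
    isotopologue: int
    mode: str
    values: Mapping[str, np.ndarray]  # group -> per-sample values

    def means(self) -> dict[str, float]:
        return {g: float(np.mean(v)) for g, v in self.values.items()}

    def sems(self) -> dict[str, float]:
        # SEM = SD/sqrt(n) with ddof=1, the figure-legend convention
        return {
            g: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
            for g, v in self.values.items()
        }

    def sizes(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.values.items()}

    def to_frame(self) -> pd.DataFrame:
        means, sems, sizes = self.means(), self.sems(), self.sizes()
        return pd.DataFrame(
            {
                "metabolite": self.metabolite,
                "isotopologue": self.isotopologue,
                "mode": self.mode,
                "group": list(means),
                "mean": [means[g] for g in means],
                "sem": [sems[g] for g in means],
                "n": [sizes[g] for g in means],
            }
        )


def summarize_labeling(
    tidy: pd.DataFrame,
    metabolite: str,
    isotopologue: int,
    mode: str = "fraction",
    compartment: str | None = None,
) -> LabelReadout:
    """Per-group summary of one isotopologue readout from a corrected table.

    ``tidy`` is the output of :func:`midtrace.pipeline.correct_area_table`.
    ``mode`` selects MID fractions (figure "fractional labeling" panels) or
    normalized labeled abundance (media-release panels, "relative
    abundance").  Raises if the metabolite/isotopologue is absent from any
    sample of the selected compartment.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    sel = tidy[(tidy["metabolite"] == metabolite) & (tidy["isotopologue"] == isotopologue)]
    if compartment is not None:
        sel = sel[sel["compartment"] == compartment]
    if sel.empty:
        raise KeyError(
            f"no rows for {metabolite!r} m+{isotopologue}"
            + (f" in compartment {compartment!r}" if compartment else "")
        )
    expected = tidy["sample"].unique() if compartment is None else tidy.loc[
        tidy["compartment"] == compartment, "sample"
    ].unique()
    absent = set(expected) - set(sel["sample"])
    if absent:
        raise KeyError(f"{metabolite!r} m+{isotopologue} missing in samples {sorted(absent)}")
    col = _MODES[mode]
    values = {
        str(g): grp[col].to_numpy(dtype=float) for g, grp in sel.groupby("group", sort=True)
    }
    return LabelReadout(metabolite=metabolite, isotopologue=isotopologue, mode=mode, values=values)


def compare_conditions(
    readout: LabelReadout,
    groups: tuple[str, str] | None = None,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-tailed two-sample t-test between the readout's two groups.

    Pooled-variance Student's t with df = n1+n2-2 by default; Welch's
    unequal-variance form behind ``welch=True``.  Degenerate zero-variance
    inputs: equal means give (0, 1); unequal means give (+/-inf, 0).
    """
    if groups is None:
        names = sorted(readout.values)
        if len(names) != 2:
            raise ValueError(f"readout has groups {names}; pass `groups` explicitly")
        groups = (names[0], names[1])
    a = np.asarray(readout.values[groups[0]], dtype=float)
    b = np.asarray(readout.values[groups[1]], dtype=float)
    return _two_sample_t(a, b, welch=welch)


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def media_transfer_table(
    donor_media: list[LabelReadout],
    recipient_cells: list[LabelReadout],
) -> pd.DataFrame:
    """Join donor-media release against recipient-cell uptake readouts.

    One row per shared (metabolite, isotopologue, group) with donor and
    recipient means/SEMs side by side.  Recipient-only or donor-only keys
    are excluded (the donor media defines what could have transferred).
    """
    donors = {(r.metabolite, r.isotopologue): r for r in donor_media}
    recipients = {(r.metabolite, r.isotopologue): r for r in recipient_cells}
    shared = sorted(donors.keys() & recipients.keys())
    if not shared:
        raise ValueError("donor and recipient readouts share no (metabolite, isotopologue) keys")
    rows = []
    for key in shared:
        d, r = donors[key], recipients[key]
        d_means, d_sems = d.means(), d.sems()
        r_means, r_sems = r.means(), r.sems()
        for group in sorted(set(d_means) & set(r_means)):
            rows.append(
                {
                    "metabolite": key[0],
                    "isotopologue": key[1],
                    "group": group,
                    "donor_mean": d_means[group],
                    "donor_sem": d_sems[group],
                    "recipient_mean": r_means[group],
                    "recipient_sem": r_sems[group],
                }
            )
    return pd.DataFrame(rows)
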