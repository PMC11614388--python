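"""Two-group differential metabolomics statistics.

Implements the table-style comparisons used for CSF metabolomics (fold
change, log2FC, unpaired two-tailed Student's t, -log10 p, and an
enrichment call at |log2FC| > 1 and p < 0.05) and for conditioned-media
metabolomics (exact Wilcoxon rank-sum with Benjamini-Hochberg FDR and
pooled overall mean/SD summaries).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tracing import _two_sample_t

__all__ = [
    "fold_change",
    "log2fc",
    "student_t_two_tailed",
    "classify_enrichment",
    "wilcoxon_rank_sum",
    "wilcoxon_rank_sum_enumerated",
    "bh_fdr",
    "pooled_summary",
    "differential_table",
]

NOT_SIG = "Not Sig"

#: largest group sizes for which `auto` mode uses the exact null distribution
_EXACT_LIMIT = 25


def fold_change(mean_treated: float, mean_control: float, pseudo: float | None = None) -> float:
    """Ratio of group means, treated over control.

    A zero mean is replaced by ``pseudo`` (typically half the smallest
    nonzero abundance in the table) when provided; with both means zero and
    no pseudo-abundance the fold change is undefined (NaN).
    """
    if mean_treated < 0 or mean_control < 0:
        raise ValueError("group means must be non-negative")
    if pseudo is not None:
        mean_treated = mean_treated or pseudo
        mean_control = mean_control or pseudo
    if mean_control == 0:
        return math.nan if mean_treated == 0 else math.inf
    return mean_treated / mean_control


def log2fc(fc: float) -> float:
    """Base-2 log fold change; requires fc > 0."""
    if not fc > 0:
        raise ValueError(f"fold change must be > 0, got {fc}")
    return math.log2(fc)


def student_t_two_tailed(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed t-test (pooled variance, df = n1+n2-2)."""
    return _two_sample_t(
        np.asarray(group_a, dtype=float), np.asarray(group_b, dtype=float), welch=welch
    )


def classify_enrichment(
    lfc: float,
    p: float,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    treated_label: str = "treated",
    control_label: str = "control",
) -> str:
    """Volcano-style call: enriched in one group iff |log2FC| and p clear both cuts."""
    if math.isnan(lfc) or math.isnan(p):
        return NOT_SIG
    if p < alpha and lfc > lfc_threshold:
        return treated_label
    if p < alpha and lfc < -lfc_threshold:
        return control_label
    return NOT_SIG


def wilcoxon_rank_sum(group_a, group_b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``exact`` uses the exact permutation null of the rank-sum statistic
    (valid only without ties); ``normal-approx`` uses the normal
    approximation with tie and continuity corrections; ``auto`` picks exact
    whenever there are no ties and both groups are small.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact":
        if has_ties:
            raise ValueError("ties present: exact rank-sum undefined, use mode='auto'")
        method = "exact"
    elif mode == "normal-approx":
        method = "asymptotic"
    elif mode == "auto":
        method = (
            "exact" if not has_ties and max(a.size, b.size) <= _EXACT_LIMIT else "asymptotic"
        )
    else:
        raise ValueError(f"mode must be exact|normal-approx|auto, got {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def wilcoxon_rank_sum_enumerated(group_a, group_b) -> float:
    """Exact two-sided rank-sum p by full enumeration of C(n1+n2, n1) labelings.

    Brute-force reference implementation (no ties allowed): enumerates every
    assignment of pooled ranks to group A and counts assignments whose
    rank-sum deviates from its mean by at least as much as observed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size < pooled.size:
        raise ValueError("ties present: enumeration oracle requires distinct values")
    ranks = stats.rankdata(pooled)
    n1 = a.size
    observed = ranks[:n1].sum()
    mean_w = n1 * (pooled.size + 1) / 2.0
    dev = abs(observed - mean_w)
    count = 0
    total = 0
    for combo in combinations(range(pooled.size), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= dev - 1e-9:
            count += 1
        total += 1
    return count / total


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pooled_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Overall mean and SD of two groups from their summary statistics.

    Exact pooling: the overall variance combines within-group variances and
    the between-group spread of the means, so the result equals the mean/SD
    of the concatenated raw samples.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("pooled_summary needs n >= 2 per group")
    n = n_a + n_b
    mean = (n_a * mean_a + n_b * mean_b) / n
    var = (
        (n_a - 1) * sd_a**2
        + (n_b - 1) * sd_b**2
        + n_a * (mean_a - mean) ** 2
        + n_b * (mean_b - mean) ** 2
    ) / (n - 1)
    return mean, math.sqrt(var)


def differential_table(
    table: pd.DataFrame,
    groups: pd.Series | dict,
    control: str,
    treated: str,
    test: str = "student_t",
    with_fdr: bool = False,
    sort: str = "log2fc",
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite differential statistics between two sample groups.

    Parameters
    ----------
    table:
        Metabolite x sample abundance matrix (index = metabolite).
    groups:
        Sample -> group label mapping covering every column of ``table``.
    test:
        ``student_t`` (CSF-style tables) or ``wilcoxon`` (media-style).
    sort:
        ``log2fc`` (descending |log2FC|) or ``p`` (ascending p).

    Zero group means use a pseudo-abundance of half the smallest nonzero
    value in the table.  Per-metabolite failures (e.g. all-zero rows) are
    flagged, never raised.
    """
    groups = pd.Series(groups)
    unlabeled = set(table.columns) - set(groups.index)
    if unlabeled:
        raise ValueError(f"samples without group label: {sorted(unlabeled)}")
    cols_c = [s for s in table.columns if groups[s] == control]
    cols_t = [s for s in table.columns if groups[s] == treated]
    if len(cols_c) < 2 or len(cols_t) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(cols_c)} {control!r} / {len(cols_t)} {treated!r}"
        )
    if test not in {"student_t", "wilcoxon"}:
        raise ValueError(f"test must be student_t|wilcoxon, got {test!r}")

    nonzero = table.values[table.values > 0]
    pseudo = float(nonzero.min()) / 2.0 if nonzero.size else math.nan

    rows = []
    for met, row in table.iterrows():
        a = row[cols_t].to_numpy(dtype=float)  # treated
        b = row[cols_c].to_numpy(dtype=float)  # control
        flag = ""
        if a.sum() == 0 and b.sum() == 0:
            rows.append(
                {
                    "metabolite": met,
                    "FC": math.nan,
                    "log2FC": math.nan,
                    "p": math.nan,
                    "minus_log10_p": math.nan,
                    "enrichment": NOT_SIG,
                    "flag": "all-zero",
                }
            )
            continue
        fc = fold_change(float(a.mean()), float(b.mean()), pseudo=pseudo)
        lfc = log2fc(fc)
        try:
            if test == "student_t":
                _, p = student_t_two_tailed(a, b)
            else:
                p = wilcoxon_rank_sum(a, b, mode="auto")
        except ValueError as exc:
            p = math.nan
            flag = str(exc)
        label = classify_enrichment(
            lfc, p, lfc_threshold=lfc_threshold, alpha=alpha,
            treated_label=treated, control_label=control,
        )
        rows.append(
            {
                "metabolite": met,
                "FC": fc,
                "log2FC": lfc,
                "p": p,
                "minus_log10_p": -math.log10(p) if p and not math.isnan(p) else math.inf,
                "enrichment": label,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    if with_fdr:
        valid = out["p"].notna()
        q = np.full(len(out), math.nan)
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
        out["q"] = q
    if sort == "log2fc":
        out = out.reindex(out["log2FC"].abs().sort_values(ascending=False).index)
    elif sort == "p":
        out = out.sort_values("p")
    else:
        raise ValueError(f"sort must be log2fc|p, got {sort!r}")
    return out.reset_index(drop=True)
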