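"""Natural-abundance correction of isotopologue areas to MIDs.

The raw isotopologue pattern of a fragment mixes tracer incorporation with
naturally occurring heavy isotopes of every atom in the (derivatized)
fragment.  For each metabolite a correction matrix A is built whose column
j is the theoretical observed pattern when exactly j tracer carbons carry
label; the measured areas are then deconvolved by non-negative least
squares, A x ~= raw with x >= 0, and x renormalized to the mass isotopomer
distribution (MID).  The pre-normalization sum of x is the corrected total
pool and feeds abundance normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .chem import DEFAULT_ISOTOPES, ElementalFormula, IsotopeTable, convolve, natural_pattern

__all__ = [
    "MIDError",
    "CorrectionMatrix",
    "MID",
    "build_correction_matrix",
    "correct_mid",
    "fractional_enrichment",
    "normalize_abundance",
]

logger = logging.getLogger(__name__)

#: Extra mass shifts beyond the tracer carbons kept by default, capturing the
#: heavy-isotope tails of Si/S/O in TBDMS fragments.
DEFAULT_EXTRA_SHIFTS = 4

#: Relative residual (2-norm) above which a corrected MID is flagged.
DEFAULT_RESIDUAL_THRESHOLD = 0.05


class MIDError(ValueError):
    """Raised when a raw vector cannot be corrected to a valid MID."""


@dataclass(frozen=True)
class CorrectionMatrix:
    """Maps a true tracer MID to the observed natural-abundance pattern.

    ``matrix`` has shape (K+1, n_tracer+1); column j is the theoretical
    pattern of the fragment with exactly j labeled tracer carbons.  With
    tracer purity 1 the matrix is lower-triangular with positive diagonal.
    """

    matrix: np.ndarray
    fragment: ElementalFormula
    n_tracer: int
    purity: float

    @property
    def K(self) -> int:
        return self.matrix.shape[0] - 1


@dataclass(frozen=True)
class MID:
    """Corrected mass isotopomer distribution plus diagnostics.

    ``fractions`` sum to 1 over m+0..m+n_tracer; ``pool`` is the corrected
    total (sum of the NNLS solution before normalization), in raw-area
    units; ``residual`` is the relative 2-norm misfit of the forward model.
    """

    fractions: np.ndarray
    pool: float
    residual: float
    flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if np.any(frac < -1e-12):
            raise MIDError("MID fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise MIDError(f"MID fractions sum to {frac.sum()!r}, not 1")


def build_correction_matrix(
    fragment: ElementalFormula,
    n_tracer: int,
    purity: float = 1.0,
    K: int | None = None,
    isotopes: IsotopeTable = DEFAULT_ISOTOPES,
) -> CorrectionMatrix:
    """Build the per-fragment natural-abundance correction matrix.

    Column j removes j carbons from the fragment (the labeled positions),
    takes the natural pattern of the remainder — which still contains the
    n_tracer−j unlabeled tracer carbons at natural abundance — and convolves
    it with the tracer-purity pattern of j labeled positions (binomial in
    the tracer enrichment; a delta at shift j when purity is 1).

    Parameters
    ----------
    fragment:
        Elemental composition of the monitored ion (derivatized fragment).
    n_tracer:
        Number of tracer-eligible carbons (of the parent metabolite).
    purity:
        Isotopic enrichment of the supplied tracer, in (0, 1].
    K:
        Highest mass shift retained; defaults to ``n_tracer + 4``.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if fragment["C"] < n_tracer:
        raise ValueError(
            f"fragment {fragment} has {fragment['C']} carbons, fewer than "
            f"{n_tracer} tracer carbons"
        )
    if K is None:
        K = n_tracer + DEFAULT_EXTRA_SHIFTS
    if K < n_tracer:
        raise ValueError(f"K={K} cannot resolve {n_tracer} tracer carbons")

    columns = np.zeros((K + 1, n_tracer + 1))
    for j in range(n_tracer + 1):
        remainder = fragment - ElementalFormula({"C": j})
        base = natural_pattern(remainder, isotopes, K)
        if purity == 1.0:
            tracer = np.zeros(j + 1)
            tracer[j] = 1.0
        else:
            # each labeled position is 13C with probability `purity`
            tracer = stats.binom.pmf(np.arange(j + 1), j, purity)
        columns[:, j] = convolve(base, tracer, K)
    return CorrectionMatrix(matrix=columns, fragment=fragment, n_tracer=n_tracer, purity=purity)


def correct_mid(
    raw: np.ndarray,
    A: CorrectionMatrix,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    label: str = "",
) -> MID:
    """Correct raw isotopologue areas to a MID by non-negative least squares.

    Raw vectors shorter than the matrix row count are zero-padded; longer
    vectors are truncated (with a logged warning).  The all-zero vector has
    no defined MID and raises :class:`MIDError`.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise MIDError("raw isotopologue vector must be 1-D")
    if np.any(raw < 0):
        raise MIDError("raw areas must be non-negative")
    rows = A.matrix.shape[0]
    if raw.size < rows:
        raw = np.pad(raw, (0, rows - raw.size))
    elif raw.size > rows:
        logger.warning(
            "%s: raw vector length %d exceeds matrix rows %d; truncating",
            label or "correct_mid", raw.size, rows,
        )
        raw = raw[:rows]
    total_raw = raw.sum()
    if total_raw == 0:
        raise MIDError(f"{label or 'sample'}: all-zero raw vector has no MID")

    x, _ = optimize.nnls(A.matrix, raw)
    pool = float(x.sum())
    if pool == 0:
        raise MIDError(f"{label or 'sample'}: NNLS solution vanished")
    residual = float(np.linalg.norm(A.matrix @ x - raw) / np.linalg.norm(raw))
    flagged = residual > residual_threshold
    if flagged:
        logger.warning(
            "%s: relative residual %.3g exceeds threshold %.3g",
            label or "correct_mid", residual, residual_threshold,
        )
    return MID(fractions=x / pool, pool=pool, residual=residual, flagged=flagged)


def fractional_enrichment(mid: MID | np.ndarray, n_tracer: int | None = None) -> float:
    """Mean labeled-carbon fraction, sum(j * MID_j) / n_tracer, in [0, 1]."""
    frac = mid.fractions if isinstance(mid, MID) else np.asarray(mid, dtype=float)
    if n_tracer is None:
        n_tracer = frac.size - 1
    if n_tracer < 1:
        raise ValueError("n_tracer must be >= 1")
    return float(np.arange(frac.size) @ frac / n_tracer)


def normalize_abundance(area: float, internal_standard_area: float, cell_count: float) -> float:
    """Peak area relative to the internal standard, per 10^6 cells.

    The internal standard (spiked D-myristic acid) removes run-to-run
    instrument variation; division by cell count puts cell and media
    compartments on a per-cell basis.
    """
    if internal_standard_area <= 0:
        raise ValueError("internal standard area must be > 0")
    if cell_count <= 0:
        raise ValueError("cell count must be > 0")
    if area < 0:
        raise ValueError("area must be >= 0")
    return area / internal_standard_area / cell_count * 1e6
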